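"""Compact convolutional feature extractor, trained from scratch per split.

Three 3x3 conv blocks (8, 16, 16 channels) with ReLU and 2x2 max pooling,
global average pooling, and a 32-unit embedding layer feeding a linear
classifier. Patches are resized to 32x32 before entering the network. The
implementation is pure numpy with explicit gradients and Adam, so feature
extraction is deterministic given a seed and needs no pretrained weights.
The penultimate 32-d activation is the convolutional feature vector used by
downstream heads and by the spectral (+) convolutional fusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .errors import SingleClassError

EMBED_DIM = 32
_INPUT_SIZE = 32
_CHANNELS = (3, 8, 16, 16)


def _conv_forward(X, Wf, b):
    n, c, H, W = X.shape
    Xp = np.pad(X, ((0, 0), (0, 0), (1, 1), (1, 1)))
    out = np.zeros((n, Wf.shape[0], H, W))
    for dy in range(3):
        for dx in range(3):
            out += np.einsum(
                "nchw,oc->nohw", Xp[:, :, dy : dy + H, dx : dx + W], Wf[:, :, dy, dx]
            )
    return out + b[None, :, None, None]


def _conv_backward(dOut, X, Wf):
    n, c, H, W = X.shape
    Xp = np.pad(X, ((0, 0), (0, 0), (1, 1), (1, 1)))
    dWf = np.zeros_like(Wf)
    dXp = np.zeros_like(Xp)
    for dy in range(3):
        for dx in range(3):
            patch = Xp[:, :, dy : dy + H, dx : dx + W]
            dWf[:, :, dy, dx] = np.einsum("nohw,nchw->oc", dOut, patch)
            dXp[:, :, dy : dy + H, dx : dx + W] += np.einsum(
                "nohw,oc->nchw", dOut, Wf[:, :, dy, dx]
            )
    return dWf, dOut.sum(axis=(0, 2, 3)), dXp[:, :, 1:-1, 1:-1]


def _maxpool(X):
    n, c, H, W = X.shape
    Xr = X.reshape(n, c, H // 2, 2, W // 2, 2)
    out = Xr.max(axis=(3, 5))
    mask = Xr == out[:, :, :, None, :, None]
    mask = mask / mask.sum(axis=(3, 5), keepdims=True)
    return out, mask


def _maxpool_backward(dOut, mask):
    n, c, h, _, w, _ = mask.shape
    d = dOut[:, :, :, None, :, None] * mask
    return d.reshape(n, c, h * 2, w * 2)


@dataclass
class CNNFeatureExtractor:
    """Trainable extractor; ``fit`` on a training split, ``transform`` anywhere."""

    seed: int = 0
    epochs: int = 30
    batch_size: int = 32
    lr: float = 1e-3

    def _init(self, n_cls: int) -> None:
        rng = np.random.default_rng(self.seed)

        def u(shape, fan_in):
            b = 1.0 / np.sqrt(fan_in)
            return rng.uniform(-b, b, size=shape)

        self.params_ = {}
        for i in range(3):
            cin, cout = _CHANNELS[i], _CHANNELS[i + 1]
            self.params_[f"W{i}"] = u((cout, cin, 3, 3), cin * 9)
            self.params_[f"b{i}"] = np.zeros(cout)
        self.params_["We"] = u((EMBED_DIM, _CHANNELS[-1]), _CHANNELS[-1])
        self.params_["be"] = np.zeros(EMBED_DIM)
        self.params_["Wo"] = u((n_cls, EMBED_DIM), EMBED_DIM)
        self.params_["bo"] = np.zeros(n_cls)
        self._rng = rng

    @staticmethod
    def preprocess(patches) -> np.ndarray:
        """Resize to 32x32, scale to [0,1], channel-first float tensor."""
        out = np.stack(
            [
                resize(np.asarray(p, dtype=np.float64) / 255.0, (_INPUT_SIZE, _INPUT_SIZE, 3),
                       anti_aliasing=True)
                for p in patches
            ]
        )
        return out.transpose(0, 3, 1, 2)

    def _forward(self, X, cache=None):
        h = X
        for i in range(3):
            conv = _conv_forward(h, self.params_[f"W{i}"], self.params_[f"b{i}"])
            act = np.maximum(conv, 0.0)
            if i < 2:
                pooled, mask = _maxpool(act)
            else:
                pooled, mask = act.mean(axis=(2, 3)), None  # global average pool
            if cache is not None:
                cache[i] = (h, conv, act, mask)
            h = pooled
        gap = h
        e_pre = gap @ self.params_["We"].T + self.params_["be"]
        emb = np.maximum(e_pre, 0.0)
        logits = emb @ self.params_["Wo"].T + self.params_["bo"]
        if cache is not None:
            cache["head"] = (gap, e_pre, emb)
        return logits, emb

    def _step(self, X, y, state, step):
        cache: dict = {}
        logits, _ = self._forward(X, cache)
        n = X.shape[0]
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        probs = e / e.sum(axis=1, keepdims=True)
        loss = float(-np.log(probs[np.arange(n), y] + 1e-300).mean())

        g = {}
        dlog = probs.copy()
        dlog[np.arange(n), y] -= 1.0
        dlog /= n
        gap, e_pre, emb = cache["head"]
        g["Wo"], g["bo"] = dlog.T @ emb, dlog.sum(axis=0)
        demb = (dlog @ self.params_["Wo"]) * (e_pre > 0)
        g["We"], g["be"] = demb.T @ gap, demb.sum(axis=0)
        dgap = demb @ self.params_["We"]

        _, _, act2, _ = cache[2]
        dh = np.broadcast_to(
            dgap[:, :, None, None] / (act2.shape[2] * act2.shape[3]), act2.shape
        )
        for i in (2, 1, 0):
            hin, conv, act, mask = cache[i]
            if mask is not None:
                dh = _maxpool_backward(dh, mask)
            dconv = dh * (conv > 0)
            g[f"W{i}"], g[f"b{i}"], dh = _conv_backward(dconv, hin, self.params_[f"W{i}"])

        m, v = state
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k in self.params_:
            m[k] = b1 * m[k] + (1 - b1) * g[k]
            v[k] = b2 * v[k] + (1 - b2) * g[k] ** 2
            self.params_[k] -= self.lr * (m[k] / (1 - b1**step)) / (
                np.sqrt(v[k] / (1 - b2**step)) + eps
            )
        return loss

    def fit(self, patches, labels) -> "CNNFeatureExtractor":
        y = np.asarray(labels, dtype=np.int64)
        classes = np.unique(y)
        if classes.size < 2:
            raise SingleClassError("CNN training requires >= 2 classes")
        self.classes_ = classes
        y_idx = np.searchsorted(classes, y)
        X = self.preprocess(patches)
        self.mean_ = X.mean(axis=(0, 2, 3), keepdims=True)
        self.std_ = X.std(axis=(0, 2, 3), keepdims=True) + 1e-8
        X = (X - self.mean_) / self.std_
        self._init(classes.size)
        m = {k: np.zeros_like(p) for k, p in self.params_.items()}
        v = {k: np.zeros_like(p) for k, p in self.params_.items()}
        self.loss_trace_ = []
        step = 0
        n = X.shape[0]
        for _ in range(self.epochs):
            order = self._rng.permutation(n)
            for lo in range(0, n, self.batch_size):
                idx = order[lo : lo + self.batch_size]
                step += 1
                self.loss_trace_.append(self._step(X[idx], y_idx[idx], (m, v), step))
        return self

    def transform(self, patches) -> np.ndarray:
        """32-d embedding rows, deterministic after ``fit``."""
        X = (self.preprocess(patches) - self.mean_) / self.std_
        _, emb = self._forward(X)
        return emb

    def predict_proba(self, patches) -> np.ndarray:
        X = (self.preprocess(patches) - self.mean_) / self.std_
        logits, _ = self._forward(X)
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)


def extract_cnn_features(patches, extractor=None, seed: int = 0) -> np.ndarray:
    """Embed patches with a fitted extractor or a user-supplied callable."""
    if callable(extractor):
        return np.asarray([extractor(p) for p in patches], dtype=np.float64)
    if extractor is None or not hasattr(extractor, "transform"):
        raise ValueError("extractor must be a fitted CNNFeatureExtractor or a callable")
    return extractor.transform(patches)
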