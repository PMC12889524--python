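"""Spectral Neural Operator classification head.

Operates on (batch, channel, spectral-bin) tensors of spectral coefficients.
Two SpectralMix layers

    U -> softplus(B [U A] + beta),   A = A_L A_R^T of rank <= r (K x K),
                                     B in R^{C x C}, beta per channel

each followed by dropout (p = 0.10), then a mean over the spectral axis
producing the pooled embedding z in R^C (the auxiliary output used for
fusion), and an MLP head z -> Linear(C, H) -> softplus -> dropout ->
Linear(H, n_cls) -> logits.

Implemented in numpy with explicit reverse-mode gradients and Adam, so the
model is trainable and exactly reproducible from a seed on any CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SingleClassError


@dataclass(frozen=True)
class SNOConfig:
    C: int = 8
    K: int = 25
    r: int = 8
    H: int = 32
    n_cls: int = 2
    dropout: float = 0.10
    lr: float = 1e-3
    epochs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r > self.K:
            raise ValueError("low-rank dimension r must be <= K")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")


PARAM_NAMES = ("A1L", "A1R", "B1", "beta1", "A2L", "A2R", "B2", "beta2", "W1", "b1", "W2", "b2")


@dataclass
class SNOParams:
    """All trainable tensors; A_l = A_lL @ A_lR.T keeps rank(A_l) <= r."""

    tensors: dict[str, np.ndarray]

    def __getitem__(self, key: str) -> np.ndarray:
        return self.tensors[key]

    def copy(self) -> "SNOParams":
        return SNOParams({k: v.copy() for k, v in self.tensors.items()})


def init_params(config: SNOConfig, rng: np.random.Generator | None = None) -> SNOParams:
    """Uniform fan-in initialization, identical for a given seed."""
    rng = rng or np.random.default_rng(config.seed)
    C, K, r, H, n_cls = config.C, config.K, config.r, config.H, config.n_cls

    def u(shape, fan_in):
        bound = 1.0 / np.sqrt(fan_in)
        return rng.uniform(-bound, bound, size=shape)

    t = {}
    for layer in (1, 2):
        t[f"A{layer}L"] = u((K, r), K)
        t[f"A{layer}R"] = u((K, r), r)
        t[f"B{layer}"] = u((C, C), C)
        t[f"beta{layer}"] = np.zeros(C)
    t["W1"] = u((H, C), C)
    t["b1"] = np.zeros(H)
    t["W2"] = u((n_cls, H), H)
    t["b2"] = np.zeros(n_cls)
    return SNOParams(t)


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _dropout_mask(shape, p, training, rng):
    if not training or p == 0.0:
        return None
    if rng is None:
        raise ValueError("training-mode dropout requires a random generator")
    return (rng.random(shape) >= p) / (1.0 - p)


def spectral_mix_forward(
    x: np.ndarray,
    params: SNOParams,
    layer: int,
    training: bool = False,
    rng: np.random.Generator | None = None,
    dropout: float = 0.10,
    cache: dict | None = None,
) -> np.ndarray:
    """One SpectralMix layer on a (Bt, C, K) tensor; dropout when training."""
    A = params[f"A{layer}L"] @ params[f"A{layer}R"].T
    Y = x @ A  # mixes the spectral axis
    Z = np.einsum("cd,bdk->bck", params[f"B{layer}"], Y) + params[f"beta{layer}"][None, :, None]
    S = _softplus(Z)
    mask = _dropout_mask(S.shape, dropout, training, rng)
    out = S if mask is None else S * mask
    if cache is not None:
        cache.update({f"x{layer}": x, f"A{layer}": A, f"Y{layer}": Y, f"Z{layer}": Z, f"mask{layer}": mask})
    return out


def sno_forward(
    x: np.ndarray,
    params: SNOParams,
    config: SNOConfig,
    training: bool = False,
    rng: np.random.Generator | None = None,
    cache: dict | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Full forward pass: returns (logits (Bt, n_cls), embedding z (Bt, C))."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 3 or x.shape[1] != config.C or x.shape[2] != config.K:
        raise ValueError(f"expected (Bt, {config.C}, {config.K}) input, got {x.shape}")
    h1 = spectral_mix_forward(x, params, 1, training, rng, config.dropout, cache)
    h2 = spectral_mix_forward(h1, params, 2, training, rng, config.dropout, cache)
    z = h2.mean(axis=2)
    a1 = z @ params["W1"].T + params["b1"]
    g1 = _softplus(a1)
    mask_h = _dropout_mask(g1.shape, config.dropout, training, rng)
    g1d = g1 if mask_h is None else g1 * mask_h
    logits = g1d @ params["W2"].T + params["b2"]
    if cache is not None:
        cache.update({"h2": h2, "z": z, "a1": a1, "g1": g1, "mask_h": mask_h, "g1d": g1d})
    return logits, z


def _softmax(logits: np.ndarray) -> np.ndarray:
    e = np.exp(logits - logits.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def loss_and_grads(
    params: SNOParams,
    x: np.ndarray,
    y: np.ndarray,
    config: SNOConfig,
    training: bool = True,
    rng: np.random.Generator | None = None,
) -> tuple[float, dict[str, np.ndarray]]:
    """Mean cross-entropy and gradients for every tensor in ``params``."""
    cache: dict = {}
    logits, _ = sno_forward(x, params, config, training, rng, cache)
    n = x.shape[0]
    probs = _softmax(logits)
    loss = float(-np.log(probs[np.arange(n), y] + 1e-300).mean())

    g: dict[str, np.ndarray] = {}
    dlogits = probs.copy()
    dlogits[np.arange(n), y] -= 1.0
    dlogits /= n

    g["W2"] = dlogits.T @ cache["g1d"]
    g["b2"] = dlogits.sum(axis=0)
    dg1d = dlogits @ params["W2"]
    dg1 = dg1d if cache["mask_h"] is None else dg1d * cache["mask_h"]
    da1 = dg1 * _sigmoid(cache["a1"])
    g["W1"] = da1.T @ cache["z"]
    g["b1"] = da1.sum(axis=0)
    dz = da1 @ params["W1"]
    dh = np.repeat(dz[:, :, None], config.K, axis=2) / config.K

    for layer in (2, 1):
        mask = cache[f"mask{layer}"]
        dS = dh if mask is None else dh * mask
        dZ = dS * _sigmoid(cache[f"Z{layer}"])
        Y, A, xin = cache[f"Y{layer}"], cache[f"A{layer}"], cache[f"x{layer}"]
        g[f"B{layer}"] = np.einsum("bck,bdk->cd", dZ, Y)
        g[f"beta{layer}"] = dZ.sum(axis=(0, 2))
        dY = np.einsum("cd,bck->bdk", params[f"B{layer}"], dZ)
        dA = np.einsum("bck,bcm->km", xin, dY)
        g[f"A{layer}L"] = dA @ params[f"A{layer}R"]
        g[f"A{layer}R"] = dA.T @ params[f"A{layer}L"]
        dh = dY @ A.T
    return loss, g


def train_sno(
    features: np.ndarray,
    labels: np.ndarray,
    config: SNOConfig,
) -> tuple[SNOParams, list[float]]:
    """Full-batch Adam training; returns trained parameters and a loss trace."""
    x = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels, dtype=np.int64)
    if np.unique(y).size < 2:
        raise SingleClassError("training set contains a single class")
    rng = np.random.default_rng(config.seed)
    params = init_params(config, rng)

    m = {k: np.zeros_like(v) for k, v in params.tensors.items()}
    v = {k: np.zeros_like(t) for k, t in params.tensors.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8
    trace: list[float] = []
    for step in range(1, config.epochs + 1):
        loss, grads = loss_and_grads(params, x, y, config, training=True, rng=rng)
        trace.append(loss)
        for k in params.tensors:
            m[k] = b1 * m[k] + (1 - b1) * grads[k]
            v[k] = b2 * v[k] + (1 - b2) * grads[k] ** 2
            mhat = m[k] / (1 - b1**step)
            vhat = v[k] / (1 - b2**step)
            params.tensors[k] -= config.lr * mhat / (np.sqrt(vhat) + eps)
    return params, trace


def predict_proba(params: SNOParams, config: SNOConfig, x: np.ndarray) -> np.ndarray:
    logits, _ = sno_forward(x, params, config, training=False)
    return _softmax(logits)


def embed(params: SNOParams, config: SNOConfig, x: np.ndarray) -> np.ndarray:
    """Pooled embedding z (the auxiliary fusion output), eval mode."""
    _, z = sno_forward(x, params, config, training=False)
    return z


def descriptor_to_spectral_tensor(
    rows: np.ndarray, C: int, K: int, pad: bool = False
) -> np.ndarray:
    """Adapt flat feature rows (n, p) to SNO input (n, C, K).

    Native mode (p == C*K) reshapes losslessly, matching a stacked (C, K)
    coefficient matrix. With ``pad=True`` rows are zero-padded or truncated
    to C*K first.
    """
    rows = np.atleast_2d(np.asarray(rows, dtype=np.float64))
    n, p = rows.shape
    if p != C * K:
        if not pad:
            raise ValueError(f"row length {p} incompatible with C*K={C * K} (enable pad)")
        out = np.zeros((n, C * K))
        out[:, : min(p, C * K)] = rows[:, : C * K]
        rows = out
    return rows.reshape(n, C, K)


def save_params(path, params: SNOParams, config: SNOConfig) -> None:
    """Portable JSON-of-arrays serialization with the config embedded."""
    import json

    payload = {
        "config": {k: getattr(config, k) for k in
                   ("C", "K", "r", "H", "n_cls", "dropout", "lr", "epochs", "seed")},
        "tensors": {k: v.tolist() for k, v in params.tensors.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_params(path) -> tuple[SNOParams, SNOConfig]:
    import json

    with open(path) as fh:
        payload = json.load(fh)
    config = SNOConfig(**payload["config"])
    params = SNOParams({k: np.asarray(v, dtype=np.float64) for k, v in payload["tensors"].items()})
    return params, config
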