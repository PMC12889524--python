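"""Classifier heads and spectral (+) convolutional feature fusion.

Fusion reduces each modality to the same PCA dimensionality d, forms the
flattened outer product z (x) f (d^2 entries, bilinear in the two inputs),
and optionally PCA-reduces the result. Heads (gradient-boosted trees via
LightGBM, L2 logistic regression) share one contract: fit on a feature
table, emit class probabilities summing to 1 per row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.linear_model import LogisticRegression

from .descriptors import PCAModel, apply_pca, fit_pca
from .errors import SingleClassError

RESERVED_COLUMNS = ("label", "group", "magnification")


@dataclass
class FeatureTable:
    """Sample-by-feature table with label and slide-group metadata."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if "label" not in self.frame or "group" not in self.frame:
            raise ValueError("feature table needs 'label' and 'group' columns")
        feats = self.frame[self.feature_columns]
        if feats.isna().any().any():
            raise ValueError("feature table contains missing values")

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c not in RESERVED_COLUMNS]

    @property
    def X(self) -> np.ndarray:
        return self.frame[self.feature_columns].to_numpy(dtype=np.float64)

    @property
    def y(self) -> np.ndarray:
        return self.frame["label"].to_numpy()

    @property
    def groups(self) -> np.ndarray:
        return self.frame["group"].to_numpy()

    @classmethod
    def from_arrays(cls, X, y, groups, feature_names=None, magnification=None) -> "FeatureTable":
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        names = list(feature_names) if feature_names else [f"f{i}" for i in range(X.shape[1])]
        frame = pd.DataFrame(X, columns=names)
        frame["label"] = np.asarray(y)
        frame["group"] = np.asarray(groups)
        if magnification is not None:
            frame["magnification"] = magnification
        return cls(frame)


@dataclass(frozen=True)
class FusionConfig:
    modality_dim: int = 8  # equal per-modality PCA dimension
    use_outer_product: bool = True
    final_dim: int | None = 25

    def __post_init__(self) -> None:
        if self.modality_dim < 1:
            raise ValueError("modality_dim must be >= 1")
        if (
            self.use_outer_product
            and self.final_dim is not None
            and self.final_dim > self.modality_dim**2
        ):
            raise ValueError("final_dim cannot exceed modality_dim^2")


def outer_fuse(z_rows: np.ndarray, f_rows: np.ndarray) -> np.ndarray:
    """Flattened outer product per aligned row pair; bilinear by construction."""
    z = np.atleast_2d(np.asarray(z_rows, dtype=np.float64))
    f = np.atleast_2d(np.asarray(f_rows, dtype=np.float64))
    if z.shape[0] != f.shape[0]:
        raise ValueError("misaligned modalities: row counts differ")
    return np.einsum("ni,nj->nij", z, f).reshape(z.shape[0], -1)


@dataclass
class FusionModel:
    """Per-modality PCA + outer-product fusion, fitted on training rows."""

    config: FusionConfig
    pca_spectral: PCAModel | None = None
    pca_cnn: PCAModel | None = None
    pca_final: PCAModel | None = None

    def fit(self, spectral_rows: np.ndarray, cnn_rows: np.ndarray) -> "FusionModel":
        d = self.config.modality_dim
        self.pca_spectral = fit_pca(spectral_rows, d)
        self.pca_cnn = fit_pca(cnn_rows, d)
        if self.config.use_outer_product and self.config.final_dim is not None:
            fused = self.transform(spectral_rows, cnn_rows, before_final_pca=True)
            self.pca_final = fit_pca(fused, self.config.final_dim)
        return self

    def transform(
        self, spectral_rows: np.ndarray, cnn_rows: np.ndarray, before_final_pca: bool = False
    ) -> np.ndarray:
        z = apply_pca(self.pca_spectral, spectral_rows)
        f = apply_pca(self.pca_cnn, cnn_rows)
        if not self.config.use_outer_product:
            return np.hstack([z, f])
        fused = outer_fuse(z, f)
        if before_final_pca or self.pca_final is None:
            return fused
        return apply_pca(self.pca_final, fused)


def fuse(
    spectral_rows: np.ndarray, cnn_rows: np.ndarray, config: FusionConfig = FusionConfig()
) -> np.ndarray:
    """Fit-and-transform convenience over :class:`FusionModel`."""
    return FusionModel(config).fit(spectral_rows, cnn_rows).transform(spectral_rows, cnn_rows)


# hyperparameters fixed and recorded here; min_child_samples lowered so the
# trees can split on the small fixture datasets
BOOSTED_PARAMS = dict(
    n_estimators=200,
    max_depth=6,
    learning_rate=0.05,
    min_child_samples=2,
    min_split_gain=0.0,
    n_jobs=1,
    verbose=-1,
)


def _check_classes(y) -> None:
    if np.unique(np.asarray(y)).size < 2:
        raise SingleClassError("head training requires >= 2 classes")


def train_boosted_head(table: FeatureTable, params: dict | None = None, seed: int = 0):
    """Gradient-boosted tree head (LightGBM), deterministic given the seed."""
    _check_classes(table.y)
    kwargs = dict(BOOSTED_PARAMS)
    if params:
        kwargs.update(params)
    model = LGBMClassifier(random_state=seed, deterministic=True, **kwargs)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", UserWarning)
        model.fit(table.X, table.y)
    return model


def train_logistic_head(table: FeatureTable, l2: float = 1.0, seed: int = 0):
    """L2-regularized multinomial logistic head."""
    _check_classes(table.y)
    model = LogisticRegression(C=1.0 / l2, max_iter=5000, random_state=seed)
    model.fit(table.X, table.y)
    return model


def predict_proba(model, rows: np.ndarray) -> np.ndarray:
    """Shared probability contract: rows sum to 1, columns follow model.classes_."""
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", UserWarning)
        p = model.predict_proba(np.atleast_2d(np.asarray(rows, dtype=np.float64)))
    return p / p.sum(axis=1, keepdims=True)
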