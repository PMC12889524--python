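"""End-to-end task orchestration.

``run_classification_pipeline`` mirrors the four-model comparison layout:
a purely spectral neural-operator classifier (SNO), LightGBM heads over the
SNO embedding and over the convolutional embedding, the outer-product fusion
of the two modalities, plus a LightGBM head over the raw spectral descriptor
(the "SPECTRAL->LGBM" row). Models are compared under grouped k-fold or
leave-one-slide-out cross-validation, and the spectral-vs-CNN AUC gap is
submitted to a TOST equivalence test (margin 0.03, alpha 0.05).

``run_denoise_pipeline`` runs the spot-scarcity experiment for the SSR
smoother against kNN and RBF baselines.
"""

from __future__ import annotations

import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cnn import CNNFeatureExtractor
from .descriptors import (
    DescriptorConfig,
    apply_pca,
    compute_blocks,
    assemble_descriptor,
    fit_pca,
)
from .errors import DegenerateSampleError, EmptyGraphError, StageError
from .evaluation import (
    SplitPlan,
    aggregate_cv,
    fold_classification_report,
    loso_splits,
    make_group_kfold,
    tost,
)
from .fusion import FeatureTable, FusionConfig, FusionModel, predict_proba, train_boosted_head
from .patch_graph import GridSpec, build_grid_graph
from .sno import SNOConfig, SNOParams, embed, predict_proba as sno_proba, train_sno
from .spectral import eigendecompose, spectral_coefficients
from .st_denoise import SpotTable, scarcity_experiment

MODEL_ROWS = ("SNO", "SNO->LGBM", "CNN->LGBM", "FUSED", "SPECTRAL->LGBM")


@dataclass
class RunConfig:
    """Single-file run description; round-trips losslessly through a dict."""

    task: str = "classify"
    grid_size: int = 32
    k_folds: int = 5
    loso: bool = False
    seed: int = 0
    n_eigenpairs: int = 128
    sno_spectral_bins: int = 25
    models: tuple[str, ...] = MODEL_ROWS
    scarcity_fraction: float = 0.25
    n_shuffles: int = 10
    out_dir: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        payload = dict(payload)
        if "models" in payload:
            payload["models"] = tuple(payload["models"])
        return cls(**payload)


def extract_spectral_features(
    patches,
    grid_spec: GridSpec,
    desc_config: DescriptorConfig = DescriptorConfig(),
    sno_bins: int = 25,
):
    """Descriptor rows plus native (C, K) coefficient tensors per patch.

    Returns (descriptor matrix, tensors (n, 8, sno_bins), kept indices,
    descriptor names, exclusion events). Patches whose grid holds no tissue
    are excluded and logged rather than aborting the run.
    """
    desc_rows, tensors, kept, exclusions = [], [], [], []
    names = None
    for i, patch in enumerate(patches):
        try:
            graph = build_grid_graph(patch, grid_spec)
        except EmptyGraphError:
            exclusions.append({"index": i, "reason": "empty graph"})
            continue
        K = min(desc_config.n_eigenpairs, graph.n_nodes)
        eig = eigendecompose(graph.laplacian, K)
        blocks, block_names = compute_blocks(graph, desc_config, eig=eig)
        vec = assemble_descriptor(blocks, desc_config, block_names)
        X = graph.features
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        coeffs = spectral_coefficients(eig.vectors, (X - mu) / sd)
        T = np.zeros((coeffs.shape[0], sno_bins))
        kk = min(sno_bins, coeffs.shape[1])
        T[:, :kk] = coeffs[:, :kk]
        desc_rows.append(vec.values)
        tensors.append(T)
        kept.append(i)
        names = vec.names
    if not desc_rows:
        raise StageError("extract", EmptyGraphError("no patch produced a graph"))
    return np.vstack(desc_rows), np.stack(tensors), np.array(kept), names, exclusions


def _fold_models(
    models, patches, desc, tensors, y, classes, seed, fold_idx, pca_dim
):
    """Train each requested model on one fold; return per-model test probas."""

    def run(train, test):
        out = {}
        cache: dict = {}
        y_enc = np.searchsorted(classes, y)
        if "SPECTRAL->LGBM" in models:
            # trees consume the full descriptor; PCA is reserved for the SNO
            # input and the fusion step
            table = FeatureTable.from_arrays(desc[train], y[train], train)
            head = train_boosted_head(table, seed=seed)
            out["SPECTRAL->LGBM"] = predict_proba(head, desc[test])
        needs_sno = {"SNO", "SNO->LGBM"} & set(models)
        if needs_sno:
            cfg = SNOConfig(
                C=tensors.shape[1], K=tensors.shape[2], n_cls=classes.size,
                seed=seed + 17 * fold_idx,
            )
            params, _ = train_sno(tensors[train], y_enc[train], cfg)
            cache["sno"] = (params, cfg)
        if "SNO" in models:
            params, cfg = cache["sno"]
            out["SNO"] = sno_proba(params, cfg, tensors[test])
        if "SNO->LGBM" in models:
            params, cfg = cache["sno"]
            z_tr, z_te = embed(params, cfg, tensors[train]), embed(params, cfg, tensors[test])
            head = train_boosted_head(FeatureTable.from_arrays(z_tr, y[train], train), seed=seed)
            out["SNO->LGBM"] = predict_proba(head, z_te)
        needs_cnn = {"CNN->LGBM", "FUSED"} & set(models)
        if needs_cnn:
            ext = CNNFeatureExtractor(seed=seed + 31 * fold_idx)
            ext.fit([patches[i] for i in train], y[train])
            cache["cnn"] = (ext, ext.transform([patches[i] for i in train]),
                            ext.transform([patches[i] for i in test]))
        if "CNN->LGBM" in models:
            _, f_tr, f_te = cache["cnn"]
            head = train_boosted_head(FeatureTable.from_arrays(f_tr, y[train], train), seed=seed)
            out["CNN->LGBM"] = predict_proba(head, f_te)
        if "FUSED" in models:
            _, f_tr, f_te = cache["cnn"]
            d = min(8, len(train) - 1, desc.shape[1], f_tr.shape[1])
            final = min(25, d * d, len(train) - 1)
            fm = FusionModel(FusionConfig(modality_dim=d, final_dim=final))
            fm.fit(desc[train], f_tr)
            head = train_boosted_head(
                FeatureTable.from_arrays(fm.transform(desc[train], f_tr), y[train], train),
                seed=seed,
            )
            out["FUSED"] = predict_proba(head, fm.transform(desc[test], f_te))
        return out

    return run


def run_classification_pipeline(
    patches,
    manifest: pd.DataFrame,
    config: RunConfig = RunConfig(),
    grid_spec: GridSpec | None = None,
    desc_config: DescriptorConfig | None = None,
) -> dict:
    """Extract -> models -> grouped CV -> metrics -> TOST; returns the report."""
    t0 = time.time()
    grid_spec = grid_spec or GridSpec(grid_size=config.grid_size)
    desc_config = desc_config or DescriptorConfig(n_eigenpairs=config.n_eigenpairs)

    try:
        desc, tensors, kept, names, exclusions = extract_spectral_features(
            patches, grid_spec, desc_config, config.sno_spectral_bins
        )
    except StageError:
        raise
    except Exception as exc:  # pragma: no cover - defensive stage context
        raise StageError("extract", exc) from exc

    manifest = manifest.iloc[kept].reset_index(drop=True)
    patches = [patches[i] for i in kept]
    y = manifest["label"].to_numpy()
    groups = manifest["group"].to_numpy()
    classes = np.unique(y)

    try:
        plan = loso_splits(groups) if config.loso else make_group_kfold(
            y, groups, k=config.k_folds, seed=config.seed
        )
    except Exception as exc:
        raise StageError("split", exc) from exc

    per_model_folds: dict[str, list[dict]] = {m: [] for m in config.models}
    deltas = []
    for fold_idx, (train, test) in enumerate(plan.folds):
        runner = _fold_models(
            config.models, patches, desc, tensors, y, classes, config.seed,
            fold_idx, desc_config.pca_dim,
        )
        try:
            probas = runner(train, test)
        except Exception as exc:
            raise StageError(f"fold{fold_idx}", exc) from exc
        fold_auc = {}
        for model, proba in probas.items():
            report = fold_classification_report(y[test], proba, classes)
            per_model_folds[model].append(report)
            fold_auc[model] = report["auc"]
        if fold_auc.get("SNO") is not None and fold_auc.get("CNN->LGBM") is not None:
            deltas.append(fold_auc["SNO"] - fold_auc["CNN->LGBM"])

    report = {
        "config": config.to_dict(),
        "n_samples": int(len(patches)),
        "classes": classes.tolist(),
        "exclusions": exclusions,
        "models": {
            m: {"folds": folds, "summary": aggregate_cv(folds)}
            for m, folds in per_model_folds.items()
        },
        "runtime_s": time.time() - t0,
    }
    if len(deltas) >= 2:
        try:
            t = tost(np.asarray(deltas))
            report["tost"] = {
                "deltas": deltas, "mean": t.mean, "sd": t.sd, "n": t.n,
                "ci90": list(t.ci90), "p_left": t.p_left, "p_right": t.p_right,
                "margin": t.margin, "alpha": t.alpha, "equivalent": t.equivalent,
            }
        except DegenerateSampleError:
            report["tost"] = None
    if config.out_dir:
        from .io import write_json

        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_json(out / "classification_report.json", report)
    return report


def run_denoise_pipeline(spots: SpotTable, config: RunConfig = RunConfig(task="denoise")) -> pd.DataFrame:
    """Scarcity experiment for SSR vs kNN vs RBF; optionally writes the table."""
    if not 0 < config.scarcity_fraction < 1:
        raise ValueError("scarcity fraction must lie strictly in (0, 1)")
    table = scarcity_experiment(
        spots,
        fraction=config.scarcity_fraction,
        n_shuffles=config.n_shuffles,
        seed=config.seed,
    )
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "scarcity_metrics.csv")
        from .io import write_json

        write_json(out / "denoise_config.json", config.to_dict())
    return table
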