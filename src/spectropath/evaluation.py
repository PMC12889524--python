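"""Grouped cross-validation, metrics, and TOST equivalence testing.

Splits never separate patches from the same slide (group) across train and
test, preventing within-slide leakage; leave-one-slide-out (LOSO) is the
k = #groups special case. Model comparison uses the two one-sided tests
(TOST) procedure on per-fold AUC differences: equivalence at margin
Delta0 is declared when both one-sided t tests reject at level alpha,
equivalently when the 90% confidence interval lies inside (-Delta0, +Delta0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import balanced_accuracy_score, roc_auc_score

from .errors import DegenerateSampleError, SingleClassError, TooFewGroupsError


@dataclass
class SplitPlan:
    """Per-fold train/test indices keyed by the grouping column."""

    folds: list[tuple[np.ndarray, np.ndarray]]
    group_key: str = "group"

    @property
    def k(self) -> int:
        return len(self.folds)


def make_group_kfold(
    labels: np.ndarray, groups: np.ndarray, k: int = 5, seed: int = 0
) -> SplitPlan:
    """Assign whole groups to k folds, greedily balancing class counts.

    Groups are processed largest-first (ties shuffled by seed); each goes to
    the fold whose running (size, class-imbalance) cost is lowest.
    """
    labels = np.asarray(labels)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if uniq.size < k:
        raise TooFewGroupsError(f"{uniq.size} groups cannot fill {k} folds")
    classes = np.unique(labels)
    rng = np.random.default_rng(seed)

    order = rng.permutation(uniq.size)
    sizes = np.array([(groups == uniq[g]).sum() for g in order])
    order = order[np.argsort(-sizes, kind="stable")]

    fold_counts = np.zeros((k, classes.size))
    assignment: dict = {}
    for gi in order:
        gname = uniq[gi]
        members = groups == gname
        gcounts = np.array([(labels[members] == c).sum() for c in classes])
        cost = fold_counts.sum(axis=1) + np.abs(fold_counts + gcounts - fold_counts.mean(axis=0)).sum(axis=1)
        f = int(np.argmin(cost))
        assignment[gname] = f
        fold_counts[f] += gcounts

    idx = np.arange(labels.size)
    folds = []
    for f in range(k):
        test_groups = {g for g, ff in assignment.items() if ff == f}
        test_mask = np.isin(groups, list(test_groups))
        folds.append((idx[~test_mask], idx[test_mask]))
    return SplitPlan(folds=folds)


def loso_splits(groups: np.ndarray) -> SplitPlan:
    """Leave-one-slide-out: one fold per group, test = that group."""
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if uniq.size < 2:
        raise TooFewGroupsError("LOSO needs at least two groups")
    idx = np.arange(groups.size)
    folds = [(idx[groups != g], idx[groups == g]) for g in uniq]
    return SplitPlan(folds=folds)


def balanced_accuracy(y_true, y_pred) -> float:
    """Unweighted mean of per-class recalls."""
    y_true = np.asarray(y_true)
    if y_true.size == 0:
        raise ValueError("empty input")
    return float(balanced_accuracy_score(y_true, y_pred))


def auc_binary(y_true, scores) -> float:
    """Rank-based (Mann-Whitney) AUC with ties counted half."""
    y_true = np.asarray(y_true)
    if np.unique(y_true).size < 2:
        raise SingleClassError("AUC undefined with a single class present")
    return float(roc_auc_score(y_true, np.asarray(scores, dtype=np.float64)))


def mauc(y_true, score_matrix, classes=None) -> float:
    """Macro one-vs-rest mean AUC; classes absent from y_true are skipped."""
    y_true = np.asarray(y_true)
    S = np.atleast_2d(np.asarray(score_matrix, dtype=np.float64))
    if classes is None:
        classes = np.unique(y_true)
    vals = []
    for ci, c in enumerate(classes):
        mask = y_true == c
        if mask.all() or not mask.any():
            continue
        vals.append(auc_binary(mask.astype(int), S[:, ci]))
    if not vals:
        raise SingleClassError("no one-vs-rest problem had both classes")
    return float(np.mean(vals))


def regression_metrics(y_true, y_pred) -> dict:
    """PCC, MAE, RMSE, R2 and MSE under their standard definitions.

    PCC is reported as None when either side has zero variance.
    """
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y_true.size < 2:
        raise ValueError("need at least two samples")
    err = y_pred - y_true
    mse = float((err**2).mean())
    mae = float(np.abs(err).mean())
    ss_tot = float(((y_true - y_true.mean()) ** 2).sum())
    r2 = 1.0 - float((err**2).sum()) / ss_tot if ss_tot > 0 else 0.0
    if y_true.std() == 0 or y_pred.std() == 0:
        pcc = None
    else:
        pcc = float(np.corrcoef(y_true, y_pred)[0, 1])
    return {"pcc": pcc, "mae": mae, "mse": mse, "rmse": float(np.sqrt(mse)), "r2": r2}


@dataclass
class TOSTResult:
    mean: float
    sd: float
    n: int
    ci90: tuple[float, float]
    p_left: float
    p_right: float
    margin: float
    alpha: float
    equivalent: bool


def tost(deltas, margin: float = 0.03, alpha: float = 0.05) -> TOSTResult:
    """Two one-sided t tests for equivalence of paired per-fold differences.

    p_left tests H0: mu <= -margin, p_right tests H0: mu >= +margin;
    equivalence requires both below alpha, which coincides with the
    (1 - 2 alpha) = 90% CI lying inside (-margin, +margin).
    """
    d = np.asarray(deltas, dtype=np.float64)
    n = d.size
    if n < 2:
        raise DegenerateSampleError("TOST needs n >= 2 differences")
    sd = float(d.std(ddof=1))
    if sd == 0 or np.ptp(d) == 0:
        raise DegenerateSampleError("TOST undefined for zero-spread differences")
    mean = float(d.mean())
    se = sd / np.sqrt(n)
    df = n - 1
    p_left = float(stats.t.sf((mean + margin) / se, df))
    p_right = float(stats.t.cdf((mean - margin) / se, df))
    tcrit = float(stats.t.ppf(1.0 - alpha, df))
    ci90 = (mean - tcrit * se, mean + tcrit * se)
    return TOSTResult(
        mean=mean,
        sd=sd,
        n=n,
        ci90=ci90,
        p_left=p_left,
        p_right=p_right,
        margin=margin,
        alpha=alpha,
        equivalent=(p_left < alpha) and (p_right < alpha),
    )


def aggregate_cv(reports: list[dict]) -> dict:
    """Per-metric mean and sample sd over folds; missing entries excluded.

    Returns {metric: {"mean", "sd", "n", "n_missing", "display"}} where
    display is the conventional "mean +/- sd" string.
    """
    keys = sorted({k for r in reports for k in r})
    out = {}
    for key in keys:
        vals = np.array([r[key] for r in reports if r.get(key) is not None], dtype=np.float64)
        n_missing = len(reports) - vals.size
        if vals.size == 0:
            out[key] = {"mean": None, "sd": None, "n": 0, "n_missing": n_missing, "display": "-"}
            continue
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        out[key] = {
            "mean": mean,
            "sd": sd,
            "n": int(vals.size),
            "n_missing": n_missing,
            "display": f"{mean:.3f} ± {sd:.3f}",
        }
    return out


def fold_classification_report(y_true, proba, classes) -> dict:
    """Accuracy, balanced accuracy and (m)AUC for one test fold.

    Single-class folds get AUC = None with a warning, mirroring fold
    exclusion for class-imbalanced test slides.
    """
    y_true = np.asarray(y_true)
    proba = np.atleast_2d(proba)
    pred = np.asarray(classes)[proba.argmax(axis=1)]
    report = {
        "accuracy": float((pred == y_true).mean()),
        "balanced_accuracy": balanced_accuracy(y_true, pred),
    }
    try:
        if len(classes) == 2:
            report["auc"] = auc_binary((y_true == classes[1]).astype(int), proba[:, 1])
        else:
            report["auc"] = mauc(y_true, proba, classes)
    except SingleClassError:
        warnings.warn("single-class test fold: AUC dropped for this fold", stacklevel=2)
        report["auc"] = None
    return report
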