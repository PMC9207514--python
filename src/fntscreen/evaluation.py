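"""Classification metrics, stratified cross-validation, method ranking.

Metric conventions for the screening task (positive = disease-related):

* TPR (recall)   = tp / (tp + fn)
* FPR            = fp / (fp + tn)
* Precision      = tp / (tp + fp)
* Specificity    = tn / (tn + fp) = 1 - FPR
* F1             = 2 * precision * TPR / (precision + TPR)
* AUC            = Mann-Whitney rank statistic (ties contribute 1/2)

Hard labels come from the strict rule ``score > threshold``. Metrics with a
zero denominator are reported as 0 and flagged rather than NaN so reports
stay machine-readable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from . import hybrid_trainer
from .decoy_selection import FingerprintSet, select_negatives
from .errors import InputError, MetricError, SelectionError

__all__ = [
    "MetricsReport",
    "CVResult",
    "compute_metrics",
    "auc",
    "cross_validate",
    "rank_methods",
    "ratio_experiment",
]

METRIC_NAMES = ("tpr", "fpr", "precision", "specificity", "f1", "auc")


@dataclass
class MetricsReport:
    tp: int
    fp: int
    tn: int
    fn: int
    tpr: float
    fpr: float
    precision: float
    specificity: float
    f1: float
    auc: float
    undefined: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "tpr": self.tpr, "fpr": self.fpr, "precision": self.precision,
            "specificity": self.specificity, "f1": self.f1, "auc": self.auc,
        }


def _safe_ratio(num: float, den: float, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC; tied scores contribute 1/2 each."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, float)
    n_pos = int(np.sum(y_true == 1))
    n_neg = int(np.sum(y_true == 0))
    if n_pos == 0 or n_neg == 0:
        raise MetricError("AUC requires both classes present")
    ranks = rankdata(scores)  # average ranks handle ties
    pos_rank_sum = float(ranks[y_true == 1].sum())
    return (pos_rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def compute_metrics(
    y_true: np.ndarray, scores: np.ndarray, threshold: float = 0.5
) -> MetricsReport:
    """Confusion-matrix metrics from the strict score > threshold rule."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, float)
    if y_true.size == 0:
        raise InputError("cannot compute metrics on empty input")
    if y_true.shape != scores.shape:
        raise InputError("y_true and scores must have equal length")
    pred = scores > threshold
    pos = y_true == 1
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & ~pos))
    fn = int(np.sum(~pred & pos))
    tn = int(np.sum(~pred & ~pos))

    flags: list[str] = []
    tpr = _safe_ratio(tp, tp + fn, "tpr", flags)
    fpr = _safe_ratio(fp, fp + tn, "fpr", flags)
    precision = _safe_ratio(tp, tp + fp, "precision", flags)
    specificity = _safe_ratio(tn, tn + fp, "specificity", flags)
    f1 = _safe_ratio(2 * precision * tpr, precision + tpr, "f1", flags)
    try:
        auc_value = auc(y_true, scores)
    except MetricError:
        flags.append("auc")
        auc_value = 0.0
    return MetricsReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        tpr=tpr, fpr=fpr, precision=precision,
        specificity=specificity, f1=f1, auc=auc_value,
        undefined=flags,
    )


@dataclass
class CVResult:
    fold_reports: list[MetricsReport]
    mean: dict[str, float]
    sd: dict[str, float]
    fold_assignment: np.ndarray  # fold index per sample
    seed: int

    def as_frame(self) -> pd.DataFrame:
        rows = [r.as_dict() for r in self.fold_reports]
        df = pd.DataFrame(rows)
        df.insert(0, "fold", range(len(rows)))
        return df


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    cfg: hybrid_trainer.TrainConfig | None = None,
    k: int = 10,
) -> CVResult:
    """Stratified k-fold CV of the hybrid trainer; deterministic per seed."""
    cfg = cfg or hybrid_trainer.TrainConfig()
    X = np.asarray(X, float)
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise InputError(
            f"smallest class has {counts.min()} samples < k={k}; use a smaller k"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=cfg.seed)
    assignment = np.full(len(y), -1, dtype=int)
    reports: list[MetricsReport] = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(X, y)):
        assignment[test_idx] = fold
        tm = hybrid_trainer.train(X[train_idx], y[train_idx], cfg)
        scores, _ = hybrid_trainer.predict(tm, X[test_idx])
        reports.append(compute_metrics(y[test_idx], scores, cfg.threshold))
    mean = {m: float(np.mean([getattr(r, m) for r in reports])) for m in METRIC_NAMES}
    sd = {m: float(np.std([getattr(r, m) for r in reports], ddof=1))
          for m in METRIC_NAMES}
    return CVResult(reports, mean, sd, assignment, cfg.seed)


def rank_methods(
    metric_table: pd.DataFrame, higher_is_better: bool = True
) -> pd.Series:
    """Average rank of each method (row) across datasets (columns).

    Rank 1 = best within each column; ties get the mean of the tied ranks.
    """
    if metric_table.isna().any().any():
        raise InputError("metric table contains missing entries")
    ranks = metric_table.rank(axis=0, ascending=not higher_is_better, method="average")
    return ranks.mean(axis=1)


def ratio_experiment(
    positives: FingerprintSet,
    decoy_pool: FingerprintSet,
    ratios: list[int],
    cfg: hybrid_trainer.TrainConfig | None = None,
    k: int = 10,
) -> tuple[pd.DataFrame, dict[int, str]]:
    """Class-imbalance sweep: CV AUC at several positive:negative ratios.

    For each ratio r the r*m least-similar pool decoys become the negative
    class (fingerprint bits as features) and the classifier is
    cross-validated. Ratios the pool cannot satisfy are reported in the
    error map; the remaining ratios still run.
    """
    cfg = cfg or hybrid_trainer.TrainConfig()
    pos_X = positives.to_dense()
    rows = []
    errors: dict[int, str] = {}
    for r in ratios:
        try:
            sel = select_negatives(positives, decoy_pool, ratio=r)
        except SelectionError as exc:
            errors[r] = str(exc)
            continue
        neg_X = decoy_pool.to_dense()[sel.indices]
        X = np.vstack([pos_X, neg_X])
        y = np.concatenate([np.ones(len(pos_X)), np.zeros(len(neg_X))])
        cv = cross_validate(X, y, cfg, k=k)
        rows.append({
            "ratio": r,
            "n_pos": len(pos_X),
            "n_neg": len(neg_X),
            "mean_auc": cv.mean["auc"],
            "sd_auc": cv.sd["auc"],
        })
    return pd.DataFrame(rows), errors
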