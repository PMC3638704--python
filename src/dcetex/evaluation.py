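"""Voxelwise TPF/FPF evaluation and reader-comparison statistics.

Predicted malignancy masks are scored voxelwise against the primary
ground-truth segmentation: true/false positives and negatives are
counted over an evaluation universe (by default body tissue within the
texture validity region) minus an exclusion mask (the voxels that were
sampled for training/verification, to avoid bias).  TPF = TP/(TP+FN)
and FPF = FP/(FP+TN).  Classifier and second-reader performance are
compared with a paired one-sample t-test on the per-subject difference
vector (classifier minus reader) against mean zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ConfusionCounts",
    "EvaluationResult",
    "TTestResult",
    "confusion_counts",
    "tpf_fpf",
    "evaluate_thresholds",
    "scatter_table",
    "paired_difference_ttest",
    "plot_scatter",
]


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def universe_size(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class EvaluationResult:
    """Per-subject and pooled (TPF, FPF) per threshold."""

    per_subject: dict  # subject -> {threshold: (TPF, FPF)}
    pooled: dict       # threshold -> (TPF, FPF)
    excluded_voxel_count: int = 0


@dataclass
class TTestResult:
    difference_vector: np.ndarray
    mean_diff: float
    t_statistic: float
    df: int
    p_value: float
    alpha: float = 0.05
    reject: bool = False
    degenerate_variance: bool = False


def confusion_counts(
    pred_mask: np.ndarray,
    truth_mask: np.ndarray,
    exclusion_mask: np.ndarray | None = None,
    universe_mask: np.ndarray | None = None,
) -> ConfusionCounts:
    """Voxelwise confusion counts over universe minus exclusions."""
    pred = np.asarray(pred_mask, bool)
    truth = np.asarray(truth_mask, bool)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth masks must share one shape")
    universe = (
        np.ones(pred.shape, bool) if universe_mask is None else np.asarray(universe_mask, bool)
    )
    if exclusion_mask is not None:
        excl = np.asarray(exclusion_mask, bool)
        if excl.shape != pred.shape:
            raise ValueError("exclusion mask shape mismatch")
        universe = universe & ~excl
    if universe.shape != pred.shape:
        raise ValueError("universe mask shape mismatch")
    p, t = pred[universe], truth[universe]
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return ConfusionCounts(tp, fp, tn, fn)


def tpf_fpf(c: ConfusionCounts) -> tuple[float | None, float | None]:
    """(TPF, FPF); a fraction with an empty denominator is None, not 0."""
    tpf = c.TP / (c.TP + c.FN) if (c.TP + c.FN) > 0 else None
    fpf = c.FP / (c.FP + c.TN) if (c.FP + c.TN) > 0 else None
    return tpf, fpf


def evaluate_thresholds(
    scores: np.ndarray,
    truth_mask: np.ndarray,
    thresholds,
    exclusion_mask: np.ndarray | None = None,
    universe_mask: np.ndarray | None = None,
) -> dict[float, ConfusionCounts]:
    """Confusion counts of ``scores >= t`` for each threshold t."""
    out = {}
    for t in thresholds:
        pred = np.asarray(scores) >= t
        out[float(t)] = confusion_counts(pred, truth_mask, exclusion_mask, universe_mask)
    return out


def scatter_table(results: EvaluationResult, reader2: dict) -> pd.DataFrame:
    """Long-format table of classifier and second-reader operating points.

    One row per (subject, threshold) for the classifier plus one row per
    subject for the reader; deterministic (subject, threshold) order.
    Suitable for the TPF-vs-FPF scatter plot.
    """
    missing = set(results.per_subject) - set(reader2)
    if missing:
        raise ValueError(f"missing reader results for subjects: {sorted(missing)}")
    rows = []
    for subject in sorted(results.per_subject):
        for thr in sorted(results.per_subject[subject]):
            tpf, fpf = results.per_subject[subject][thr]
            rows.append((subject, "classifier", thr, tpf, fpf))
        tpf, fpf = reader2[subject]
        rows.append((subject, "reader2", np.nan, tpf, fpf))
    return pd.DataFrame(rows, columns=["subject", "source", "threshold", "TPF", "FPF"])


def paired_difference_ttest(
    vec_classifier,
    vec_reader2,
    alpha: float = 0.05,
) -> TTestResult:
    """One-sample two-sided t-test of classifier-minus-reader differences.

    t = d_bar / (s_d / sqrt(n)) with df = n - 1; p from the Student t
    distribution.  A zero-variance difference vector is flagged: a
    non-zero mean rejects with p ~ 0, a zero mean fails to reject.
    """
    a = np.asarray(vec_classifier, float)
    b = np.asarray(vec_reader2, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("difference inputs must be equal-length vectors")
    n = a.size
    if n < 2:
        raise ValueError("need at least two paired observations")
    d = a - b
    mean = float(d.mean())
    s = float(d.std(ddof=1))
    df = n - 1
    if np.all(d == d[0]):  # identical differences: zero variance up to roundoff
        if mean == 0.0:
            return TTestResult(d, mean, 0.0, df, 1.0, alpha, False, True)
        t = np.inf if mean > 0 else -np.inf
        return TTestResult(d, mean, t, df, 0.0, alpha, True, True)
    t = mean / (s / np.sqrt(n))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return TTestResult(d, mean, float(t), df, p, alpha, p < alpha, False)


def plot_scatter(table: pd.DataFrame, path) -> None:
    """TPF-vs-FPF scatter of classifier operating points and reader marks."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    cls = table[table.source == "classifier"]
    rdr = table[table.source == "reader2"]
    ax.scatter(cls.FPF, cls.TPF, c=cls.threshold, cmap="viridis", label="classifier")
    ax.scatter(rdr.FPF, rdr.TPF, marker="x", color="red", label="second reader")
    ax.set_xlabel("FPF")
    ax.set_ylabel("TPF")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
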