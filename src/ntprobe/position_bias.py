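"""Positional-bias quantification, normalization and classification scoring.

Raw channel probabilities at the first, middle and last within-window
positions sit on visibly different scales, so no single raw threshold works
across positions.  Two simple normalizations restore a common decision
boundary: a Z-score (threshold 0) and channel subtraction (exon minus
intron probability, threshold 0).  Classification is scored against a
binary exon truth track; AUC is computed as the rank statistic (probability
that a random positive outscores a random negative, ties counted half),
which equals the trapezoidal area under the full-threshold-sweep ROC curve.
"""
from __future__ import annotations

import sys
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve

__all__ = [
    "P_FLOOR",
    "P_FLOOR_DISPLAY",
    "PositionalSample",
    "ComparisonResult",
    "ClassificationReport",
    "format_p",
    "summarize",
    "compare_positions",
    "zscore_normalize",
    "subtract_channels",
    "classify",
    "roc_auc",
    "evaluate",
]

# Smallest positive normal double: p-values reported by Python underflow to
# 0.0 below this, so smaller p-values are displayed as a bounded string.
P_FLOOR = sys.float_info.min  # 2.2250738585072014e-308
P_FLOOR_DISPLAY = "< 2.23e-308"

STRATA = ("exonic", "intronic", "all")


def format_p(p: float) -> tuple[str, bool]:
    """Human-readable p-value with the underflow floor rule applied.

    Returns ``(display, floored)``; the raw float should be kept alongside
    whenever it is representable.
    """
    if p == 0.0 or p < P_FLOOR:
        return P_FLOOR_DISPLAY, True
    return f"{p:.6g}", False


@dataclass
class PositionalSample:
    """Scores for every focal nucleotide at one position class and channel."""

    values: np.ndarray
    truth: np.ndarray
    position_class: str
    channel: str
    normalization: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.truth = np.asarray(self.truth, dtype=np.uint8)
        if self.values.shape != self.truth.shape:
            raise ValueError("values and truth must be aligned")
        if self.normalization == "raw" and (
            (self.values < 0).any() or (self.values > 1).any()
        ):
            raise ValueError("raw probabilities must lie in [0, 1]")

    def stratum_mask(self, stratum: str) -> np.ndarray:
        if stratum == "exonic":
            return self.truth == 1
        if stratum == "intronic":
            return self.truth == 0
        if stratum == "all":
            return np.ones_like(self.truth, dtype=bool)
        raise ValueError(f"unknown stratum {stratum!r}; expected one of {STRATA}")


@dataclass
class ComparisonResult:
    """Two-sample location test between position classes."""

    statistic: float
    p_value: float
    p_display: str
    floored: bool
    median_a: float
    median_b: float
    iqr_a: float
    iqr_b: float


@dataclass
class ClassificationReport:
    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    sensitivity: float
    specificity: float
    threshold: float
    normalization: str
    auc: float | None = None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _iqr(x: np.ndarray) -> float:
    q1, q3 = np.percentile(x, [25, 75])  # linear-interpolation quantiles
    return float(q3 - q1)


def summarize(sample: PositionalSample, stratum: str = "all") -> tuple[float, float]:
    """(median, IQR) of the sample restricted to a truth stratum."""
    x = sample.values[sample.stratum_mask(stratum)]
    if x.size == 0:
        raise ValueError(f"stratum {stratum!r} is empty")
    return float(np.median(x)), _iqr(x)


def compare_positions(
    sample_a: PositionalSample,
    sample_b: PositionalSample,
    stratum: str = "all",
    equal_var: bool = False,
) -> ComparisonResult:
    """Two-sample t-test between position classes within one stratum.

    Welch (unequal variance) by default; set ``equal_var=True`` for the
    pooled-variance variant.  P-values that underflow the double floor are
    displayed as a bounded string while the raw float is retained.
    """
    a = sample_a.values[sample_a.stratum_mask(stratum)]
    b = sample_b.values[sample_b.stratum_mask(stratum)]
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group for a t-test")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    display, floored = format_p(float(p))
    return ComparisonResult(
        statistic=float(t),
        p_value=float(p),
        p_display=display,
        floored=floored,
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        iqr_a=_iqr(a),
        iqr_b=_iqr(b),
    )


def zscore_normalize(sample: PositionalSample, ddof: int = 0) -> PositionalSample:
    """Z-score a sample against its own mean and sd over all L values.

    Population (n) denominator by default; the normalized sample has mean 0
    and sd 1 and shares the raw sample's ranking, so AUC is unchanged.
    """
    sd = float(sample.values.std(ddof=ddof))
    if sd == 0.0:
        raise ValueError("zero variance; cannot Z-score")
    z = (sample.values - sample.values.mean()) / sd
    return PositionalSample(
        values=z,
        truth=sample.truth,
        position_class=sample.position_class,
        channel=sample.channel,
        normalization="zscore",
    )


def subtract_channels(
    exon_sample: PositionalSample, intron_sample: PositionalSample
) -> PositionalSample:
    """Exon-minus-intron score in [-1, 1]; decision boundary 0."""
    if exon_sample.values.shape != intron_sample.values.shape:
        raise ValueError("misaligned channel samples")
    if exon_sample.position_class != intron_sample.position_class:
        raise ValueError("channel samples come from different position classes")
    return PositionalSample(
        values=exon_sample.values - intron_sample.values,
        truth=exon_sample.truth,
        position_class=exon_sample.position_class,
        channel="exon-intron",
        normalization="subtraction",
    )


def classify(
    scores: np.ndarray,
    truth: np.ndarray,
    threshold: float,
    direction: str = "greater",
    normalization: str = "raw",
) -> ClassificationReport:
    """Confusion counts and rates at a fixed threshold.

    ``direction='greater'`` calls score >= threshold positive (ties are
    positive); ``'less'`` flips the inequality.  With single-class truth the
    undefined rate is reported as NaN with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must be aligned")
    if direction == "greater":
        pos = scores >= threshold
    elif direction == "less":
        pos = scores <= threshold
    else:
        raise ValueError(f"unknown direction {direction!r}")
    t = truth == 1
    tp = int(np.sum(pos & t))
    fp = int(np.sum(pos & ~t))
    fn = int(np.sum(~pos & t))
    tn = int(np.sum(~pos & ~t))
    L = scores.size
    accuracy = (tp + tn) / L if L else float("nan")
    if tp + fn == 0:
        warnings.warn("truth has no positives; sensitivity undefined")
        sensitivity = float("nan")
    else:
        sensitivity = tp / (tp + fn)
    if tn + fp == 0:
        warnings.warn("truth has no negatives; specificity undefined")
        specificity = float("nan")
    else:
        specificity = tn / (tn + fp)
    return ClassificationReport(
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        threshold=threshold,
        normalization=normalization,
    )


def roc_auc(scores: np.ndarray, truth: np.ndarray) -> tuple[float, np.ndarray]:
    """AUC as the Mann-Whitney rank statistic plus ROC curve points.

    ``auc = P(score_pos > score_neg) + 0.5 * P(score_pos == score_neg)``,
    computed from midranks; curve points are (fpr, tpr) pairs over the full
    threshold sweep.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must be aligned")
    pos = truth == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC undefined: truth contains a single class")
    ranks = stats.rankdata(scores)  # midranks handle ties at weight 1/2
    auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    fpr, tpr, _ = roc_curve(truth, scores)
    return float(auc), np.column_stack([fpr, tpr])


def evaluate(
    scores: np.ndarray,
    truth: np.ndarray,
    threshold: float,
    direction: str = "greater",
    normalization: str = "raw",
) -> ClassificationReport:
    """Classification report with AUC filled in when both classes are present."""
    report = classify(scores, truth, threshold, direction, normalization)
    t = np.asarray(truth)
    if (t == 1).any() and (t == 0).any():
        report.auc = roc_auc(scores, truth)[0]
    return report
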