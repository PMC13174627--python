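"""Oscillation detection, phase-group testing, and stabilization distances
for probe traces.

A probe trace holds one nucleotide's probability at every within-window
offset.  Periodicity is quantified with an explained-variance (EV)
estimator: for a candidate period m, the trace is grouped into residue
classes modulo m and EV(m) = 1 - SS_within / SS_total measures how much of
the variance the phase means capture.  EV is nondecreasing along divisor
chains (EV(km) >= EV(m)), so the reported period is the *smallest* m whose
EV reaches a fraction tau of the best candidate — immune to the
multiple-of-the-true-period ambiguity.  Tails are trimmed before analysis
because offsets near the window edge are attenuated and noisy; the trace is
detrended (centered moving mean removed) before period estimation but
amplitudes and phase ANOVA use raw trimmed probabilities.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .position_bias import format_p

__all__ = [
    "TRIM_FRACTION",
    "PeriodEstimate",
    "PhaseDecomposition",
    "AmplitudeReport",
    "PhaseAnovaReport",
    "StabilizationEntry",
    "StabilizationReport",
    "default_trim",
    "trim_tails",
    "detrend",
    "explained_variance",
    "estimate_period",
    "decimate_phases",
    "interleave_phases",
    "estimate_amplitude",
    "phase_anova",
    "rolling_average",
    "stabilization_distances",
]

# Per-side trim fraction: reproduces a 4,800-context trim at W = 24,576.
TRIM_FRACTION = 0.1953


@dataclass
class PeriodEstimate:
    period: int
    explained_variance: dict[int, float]
    oscillating: bool
    tau: float
    trim: int | None = None
    detrend_window: int | None = None


@dataclass
class PhaseDecomposition:
    """Residue-class subseries: subseries[r][j] = trace[r + j*m]."""

    modulus: int
    subseries: list[np.ndarray]


@dataclass
class AmplitudeReport:
    period: int
    phase_means: np.ndarray
    minimum: float
    maximum: float
    amp_range: float
    n: int


@dataclass
class PhaseAnovaReport:
    f_stat: float
    p_value: float
    p_display: str
    floored: bool
    n_groups: int
    alpha: float
    table: pd.DataFrame  # columns: group_i, group_j, diff, p_adj, reject
    degenerate: bool = False


@dataclass
class StabilizationEntry:
    threshold: float
    distance_from_start: int | None
    distance_from_end: int | None
    reached_start: bool
    reached_end: bool


@dataclass
class StabilizationReport:
    window: int
    entries: list[StabilizationEntry]


# ---------------------------------------------------------------------------
# trace preparation


def default_trim(n: int) -> int:
    """Default per-side trim: round(TRIM_FRACTION * n)."""
    return int(round(TRIM_FRACTION * n))


def trim_tails(trace: np.ndarray, trim: int | None = None) -> np.ndarray:
    """Drop ``trim`` values from each end (default ~19.53% per side)."""
    x = np.asarray(trace, dtype=float)
    t = default_trim(x.size) if trim is None else int(trim)
    if t < 0:
        raise ValueError("trim must be non-negative")
    if 2 * t >= x.size:
        raise ValueError(f"trim {t} per side leaves nothing of a length-{x.size} trace")
    return x[t : x.size - t].copy() if t else x.copy()


def detrend(trace: np.ndarray, window: int = 101) -> np.ndarray:
    """Subtract a centered moving mean (edges use truncated windows)."""
    x = np.asarray(trace, dtype=float)
    if window < 3 or window % 2 == 0:
        raise ValueError("detrend window must be odd and >= 3")
    if window >= x.size:
        raise ValueError("detrend window must be shorter than the trace")
    trend = (
        pd.Series(x).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )
    return x - trend


# ---------------------------------------------------------------------------
# period estimation


def explained_variance(trace: np.ndarray, m: int) -> float:
    """EV(m): variance fraction captured by residue-class means modulo m."""
    x = np.asarray(trace, dtype=float)
    ss_total = float(((x - x.mean()) ** 2).sum())
    if ss_total == 0.0:
        return 0.0
    idx = np.arange(x.size) % m
    cnt = np.bincount(idx, minlength=m)
    means = np.bincount(idx, weights=x, minlength=m) / cnt
    ss_within = float(((x - means[idx]) ** 2).sum())
    return 1.0 - ss_within / ss_total


def estimate_period(
    trace: np.ndarray,
    m_max: int = 48,
    tau: float = 0.99,
    min_ev: float = 0.2,
    trim: int | None = None,
    detrend_window: int | None = None,
) -> PeriodEstimate:
    """Smallest candidate period whose EV reaches ``tau`` of the EV maximum.

    The input should already be trimmed and detrended; ``trim`` and
    ``detrend_window`` are recorded as metadata only.  Traces with no
    periodic structure (flat, low EV profile below ``min_ev``, or zero
    variance) are flagged non-oscillating with period 1.
    """
    x = np.asarray(trace, dtype=float)
    if x.size < 4 * m_max:
        raise ValueError(f"trace length {x.size} < 4 * m_max = {4 * m_max}")
    ss_total = float(((x - x.mean()) ** 2).sum())
    ev = {m: 0.0 for m in range(1, m_max + 1)}
    if ss_total > 0.0:
        idx_all = np.arange(x.size)
        for m in range(1, m_max + 1):
            idx = idx_all % m
            means = np.bincount(idx, weights=x, minlength=m) / np.bincount(
                idx, minlength=m
            )
            ev[m] = 1.0 - float(((x - means[idx]) ** 2).sum()) / ss_total
    ev_max = max(ev.values())
    if ss_total == 0.0 or ev_max < min_ev:
        return PeriodEstimate(
            period=1,
            explained_variance=ev,
            oscillating=False,
            tau=tau,
            trim=trim,
            detrend_window=detrend_window,
        )
    period = min(m for m, v in ev.items() if v >= tau * ev_max)
    return PeriodEstimate(
        period=period,
        explained_variance=ev,
        oscillating=period > 1,
        tau=tau,
        trim=trim,
        detrend_window=detrend_window,
    )


def decimate_phases(trace: np.ndarray, m: int) -> PhaseDecomposition:
    """Split a trace into m residue-class subseries ("every m-th value")."""
    if m < 1:
        raise ValueError("modulus must be >= 1")
    x = np.asarray(trace, dtype=float)
    return PhaseDecomposition(modulus=m, subseries=[x[r::m].copy() for r in range(m)])


def interleave_phases(decomp: PhaseDecomposition) -> np.ndarray:
    """Inverse of :func:`decimate_phases`."""
    n = sum(len(s) for s in decomp.subseries)
    out = np.empty(n)
    for r, s in enumerate(decomp.subseries):
        out[r :: decomp.modulus] = s
    return out


def estimate_amplitude(
    trace: np.ndarray, period: int, phase_origin: int = 0
) -> AmplitudeReport:
    """Per-phase means plus min/max/range of a (raw, trimmed) trace.

    ``phase_origin`` aligns residue classes with within-window offsets when
    the trace has been trimmed by an amount not divisible by the period.
    """
    x = np.asarray(trace, dtype=float)
    if period < 1 or period >= x.size:
        raise ValueError("period must satisfy 1 <= period < trace length")
    idx = (np.arange(x.size) + phase_origin) % period
    means = np.bincount(idx, weights=x, minlength=period) / np.bincount(
        idx, minlength=period
    )
    return AmplitudeReport(
        period=period,
        phase_means=means,
        minimum=float(x.min()),
        maximum=float(x.max()),
        amp_range=float(x.max() - x.min()),
        n=x.size,
    )


def phase_anova(trace: np.ndarray, period: int = 24, alpha: float = 0.05) -> PhaseAnovaReport:
    """One-way ANOVA across residue-class groups plus Tukey HSD on all pairs.

    ``period`` groups give period*(period-1)/2 pairwise contrasts at
    family-wise level ``alpha``.  A constant trace is degenerate: F is
    reported as 0 with p = 1 and no rejections.
    """
    x = np.asarray(trace, dtype=float)
    idx = np.arange(x.size) % period
    counts = np.bincount(idx, minlength=period)
    if counts.min() < 2:
        raise ValueError("need at least 2 observations per phase group")
    pairs = list(itertools.combinations(range(period), 2))
    if float(x.var()) == 0.0:
        table = pd.DataFrame(
            {
                "group_i": [i for i, _ in pairs],
                "group_j": [j for _, j in pairs],
                "diff": 0.0,
                "p_adj": 1.0,
                "reject": False,
            }
        )
        return PhaseAnovaReport(
            f_stat=0.0,
            p_value=1.0,
            p_display="1",
            floored=False,
            n_groups=period,
            alpha=alpha,
            table=table,
            degenerate=True,
        )
    groups = [x[idx == r] for r in range(period)]
    f_stat, p = stats.f_oneway(*groups)
    display, floored = format_p(float(p))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tukey = pairwise_tukeyhsd(endog=x, groups=idx, alpha=alpha)
    # statsmodels orders results as itertools.combinations over sorted groups
    table = pd.DataFrame(
        {
            "group_i": [i for i, _ in pairs],
            "group_j": [j for _, j in pairs],
            "diff": np.asarray(tukey.meandiffs, dtype=float),
            "p_adj": np.asarray(tukey.pvalues, dtype=float),
            "reject": np.asarray(tukey.reject, dtype=bool),
        }
    )
    return PhaseAnovaReport(
        f_stat=float(f_stat),
        p_value=float(p),
        p_display=display,
        floored=floored,
        n_groups=period,
        alpha=alpha,
        table=table,
    )


# ---------------------------------------------------------------------------
# stabilization


def rolling_average(trace: np.ndarray, window: int = 6) -> np.ndarray:
    """Trailing mean of the last ``window`` values; NaN before index window-1."""
    x = np.asarray(trace, dtype=float)
    if window < 1 or window > x.size:
        raise ValueError("window must satisfy 1 <= window <= trace length")
    return pd.Series(x).rolling(window).mean().to_numpy()


def _first_crossing(values: np.ndarray, threshold: float) -> tuple[int | None, bool]:
    hits = np.nonzero(values >= threshold)[0]  # NaN compares False
    if hits.size == 0:
        return None, False
    return int(hits[0]) + 1, True  # 1-based position


def stabilization_distances(
    trace: np.ndarray,
    thresholds: tuple[float, ...] = (0.90, 0.95),
    window: int = 6,
) -> StabilizationReport:
    """Positions from each trace end until the trailing rolling mean first
    reaches each threshold.

    Distances are 1-based; the from-end distance uses the mirror-image scan
    of the reversed trace so both ends are treated symmetrically.  A trace
    that never crosses a threshold is flagged rather than erroring.
    """
    x = np.asarray(trace, dtype=float)
    sm_fwd = rolling_average(x, window)
    sm_rev = rolling_average(x[::-1], window)
    entries = []
    for theta in thresholds:
        d_start, ok_start = _first_crossing(sm_fwd, theta)
        d_end, ok_end = _first_crossing(sm_rev, theta)
        entries.append(
            StabilizationEntry(
                threshold=float(theta),
                distance_from_start=d_start,
                distance_from_end=d_end,
                reached_start=ok_start,
                reached_end=ok_end,
            )
        )
    return StabilizationReport(window=window, entries=entries)
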