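"""Performance as a function of input window length, and plateau location.

Longer inputs sharpen per-nucleotide predictions with diminishing returns;
the sweep evaluates each design length at one position class (middle by
default) and the plateau finder reports the smallest length whose metric is
within epsilon of the sweep maximum.  Both an AUC-based and a raw
median-probability criterion are supported, since the two can plateau at
different lengths; reports carry both side by side.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from . import position_bias, probing
from .genome_io import PaddedRegion, TruthTrack
from .probing import WindowDesign
from .synthetic import Predictor

__all__ = ["sweep", "find_plateau"]

SWEEP_COLUMNS = [
    "W",
    "tokens",
    "median_exonic",
    "median_intronic",
    "mean_exonic",
    "sd_exonic",
    "auc",
]


def sweep(
    predictor: Predictor,
    padded: PaddedRegion,
    truth: TruthTrack,
    design: WindowDesign,
    position_class: str = "middle",
    channel: str = "exon",
) -> pd.DataFrame:
    """Per-window-length medians (by truth stratum), mean +/- sd, and AUC.

    One row per design entry.  Deterministic given the predictor's seed:
    the noise stream is keyed by window start, not call order.
    """
    if padded.flank < design.max_length - 1:
        raise ValueError(
            f"insufficient flank {padded.flank} for largest window {design.max_length}"
        )
    if len(truth.labels) != padded.focal.length:
        raise ValueError("truth track does not match the focal region")
    t = truth.labels == 1
    both_classes = bool(t.any() and (~t).any())
    rows = []
    for entry in design.entries:
        vals = probing.extract_position_values(
            predictor, padded, entry.length, position_class
        )[channel]
        if both_classes:
            auc = position_bias.roc_auc(vals, truth.labels)[0]
            med_in = float(np.median(vals[~t]))
        else:
            auc, med_in = float("nan"), float("nan")
        rows.append(
            {
                "W": entry.length,
                "tokens": entry.tokens,
                "median_exonic": float(np.median(vals[t])) if t.any() else float("nan"),
                "median_intronic": med_in,
                "mean_exonic": float(vals[t].mean()) if t.any() else float("nan"),
                "sd_exonic": float(vals[t].std(ddof=1)) if t.sum() > 1 else float("nan"),
                "auc": auc,
            }
        )
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


def find_plateau(
    table: pd.DataFrame, epsilon_auc: float = 0.005, metric: str = "auc"
) -> int:
    """Smallest window length whose metric reaches (max - epsilon).

    ``metric`` may be any sweep column ("auc" default; "median_exonic" or
    "mean_exonic" give the raw-probability criterion).
    """
    if len(table) == 0:
        raise ValueError("empty sweep table")
    if metric not in table.columns:
        raise KeyError(f"metric {metric!r} not in sweep table")
    order = table.sort_values("W")
    vals = order[metric].to_numpy(dtype=float)
    target = np.nanmax(vals) - epsilon_auc
    hits = np.nonzero(vals >= target)[0]
    return int(order["W"].to_numpy()[hits[0]])
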