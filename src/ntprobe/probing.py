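"""Window designs, stride-1 sliding-window prediction, and position-sorted
organization of the outputs.

A region of length L probed with windows of length W requires L + W - 1
stride-1 windows: the union of placements puts every focal nucleotide at
every within-window offset 0..W-1 exactly once.  The resulting grid
(position x offset x channel) is the position-sorted store; one row of it,
a single nucleotide's probability at every offset, is a probe trace.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_io import GenomicRegion, PaddedRegion
from .synthetic import Predictor, WindowInput

__all__ = [
    "WindowEntry",
    "WindowDesign",
    "PositionSortedStore",
    "ProbeTrace",
    "make_window_design",
    "count_windows",
    "class_offset",
    "run_sliding_probe",
    "extract_position_class",
    "extract_position_values",
    "probe_traces",
    "extract_probe_trace",
    "save_store",
    "load_store",
]

logger = logging.getLogger(__name__)

POSITION_CLASSES = ("first", "middle", "last")


@dataclass(frozen=True)
class WindowEntry:
    n: int
    tokens: int
    length: int


@dataclass(frozen=True)
class WindowDesign:
    """Strictly increasing window lengths, each a whole number of tokens."""

    entries: tuple[WindowEntry, ...]

    def __post_init__(self) -> None:
        lengths = [e.length for e in self.entries]
        if any(b <= a for a, b in zip(lengths, lengths[1:])):
            raise ValueError("window lengths must be strictly increasing")

    @property
    def lengths(self) -> tuple[int, ...]:
        return tuple(e.length for e in self.entries)

    @property
    def max_length(self) -> int:
        return self.entries[-1].length


def make_window_design(n_min: int = 2, n_max: int = 12, token_size: int = 6) -> WindowDesign:
    """Token counts 2**n for n_min <= n <= n_max; length = token_size * 2**n."""
    if n_min > n_max:
        raise ValueError("n_min must be <= n_max")
    if n_min < 0 or token_size < 1:
        raise ValueError("need n_min >= 0 and token_size >= 1")
    return WindowDesign(
        tuple(WindowEntry(n, 2**n, token_size * 2**n) for n in range(n_min, n_max + 1))
    )


def count_windows(L: int, W: int) -> int:
    """Number of stride-1 windows covering at least one focal base: L + W - 1."""
    if L < 1 or W < 1:
        raise ValueError("L and W must be >= 1")
    return L + W - 1


def class_offset(W: int, position_class: str, middle_offset: int | None = None) -> int:
    """Within-window offset of a named position class (0-based).

    ``middle`` defaults to W // 2; pass ``middle_offset`` to override the
    convention for even window lengths.
    """
    if position_class == "first":
        return 0
    if position_class == "last":
        return W - 1
    if position_class == "middle":
        k = W // 2 if middle_offset is None else middle_offset
        if not (0 <= k < W):
            raise ValueError(f"middle offset {k} outside window of length {W}")
        return k
    raise ValueError(f"unknown position class {position_class!r}; expected one of {POSITION_CLASSES}")


@dataclass
class PositionSortedStore:
    """Probing output indexed as [focal position, window offset] per channel."""

    region: GenomicRegion
    W: int
    channels: dict[str, np.ndarray]
    mask: np.ndarray

    def __post_init__(self) -> None:
        L = self.region.length
        for name, grid in self.channels.items():
            if grid.shape != (L, self.W):
                raise ValueError(f"channel {name!r} grid shape {grid.shape} != ({L}, {self.W})")
        if self.mask.shape != (L, self.W):
            raise ValueError("mask shape mismatch")

    @property
    def complete(self) -> bool:
        return bool(self.mask.all())


@dataclass
class ProbeTrace:
    """One nucleotide's channel probability at every within-window offset."""

    nucleotide: int
    channel: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def _window_input(padded: PaddedRegion, start: int, W: int) -> WindowInput:
    ls = start - padded.origin
    if ls < 0 or ls + W > len(padded.sequence):
        raise ValueError(f"window [{start}, {start + W}) escapes the padded span")
    return WindowInput(
        sequence=padded.sequence[ls : ls + W],
        labels=None if padded.labels is None else padded.labels[ls : ls + W],
        window_start=start,
    )


def run_sliding_probe(
    predictor: Predictor,
    padded: PaddedRegion,
    W: int,
    store_dir: str | Path | None = None,
    resume: bool = False,
    log_every: int = 0,
) -> PositionSortedStore:
    """Execute all L + W - 1 stride-1 windows and populate the store.

    Predictions over padding nucleotides are computed but only focal-region
    cells are kept.  With ``store_dir`` the store is persisted as sharded
    TSV; ``resume=True`` reloads an existing complete store instead of
    recomputing.
    """
    focal = padded.focal
    L = focal.length
    if padded.flank < W - 1:
        raise ValueError(f"insufficient flank {padded.flank}; need >= W - 1 = {W - 1}")
    if resume and store_dir is not None and (Path(store_dir) / "manifest.json").exists():
        logger.info("resuming store from %s", store_dir)
        return load_store(store_dir)

    names = tuple(predictor.channels)
    grids = {c: np.full((L, W), np.nan) for c in names}
    mask = np.zeros((L, W), dtype=bool)
    first_start = focal.start - (W - 1)
    n_win = count_windows(L, W)
    for i in range(n_win):
        s = first_start + i
        pred = predictor.predict(_window_input(padded, s, W))
        if pred.window_length != W:
            raise ValueError(
                f"predictor returned length {pred.window_length}, expected {W}"
            )
        g0, g1 = max(s, focal.start), min(s + W, focal.end)
        if g0 >= g1:
            continue
        rows = np.arange(g0 - focal.start, g1 - focal.start)
        ks = np.arange(g0 - s, g1 - s)
        for c in names:
            grids[c][rows, ks] = pred.channels[c][ks[0] : ks[-1] + 1]
        mask[rows, ks] = True
        if log_every and (i + 1) % log_every == 0:
            logger.info("probe %s W=%d: %d/%d windows", focal, W, i + 1, n_win)

    store = PositionSortedStore(region=focal, W=W, channels=grids, mask=mask)
    if store_dir is not None:
        save_store(store, store_dir)
    return store


def extract_position_class(
    store: PositionSortedStore,
    position_class: str,
    channel: str,
    middle_offset: int | None = None,
) -> np.ndarray:
    """Column of the store at the offset of a position class (first/middle/last)."""
    k = class_offset(store.W, position_class, middle_offset)
    if not store.mask[:, k].all():
        raise ValueError(f"store incomplete at offset {k} ({position_class})")
    return store.channels[channel][:, k].copy()


def extract_position_values(
    predictor: Predictor,
    padded: PaddedRegion,
    W: int,
    position_class: str = "middle",
    middle_offset: int | None = None,
) -> dict[str, np.ndarray]:
    """Per-channel values of every focal base at one position class.

    Runs only the L windows that place a focal base at the requested offset
    (instead of materializing the full L x W store), with the same
    window-start-keyed noise as :func:`run_sliding_probe`, so results are
    placement-wise identical to the corresponding store column.
    """
    focal = padded.focal
    k = class_offset(W, position_class, middle_offset)
    if padded.flank < W - 1:
        raise ValueError(f"insufficient flank {padded.flank}; need >= W - 1 = {W - 1}")
    out = {c: np.empty(focal.length) for c in predictor.channels}
    for j, g in enumerate(range(focal.start, focal.end)):
        pred = predictor.predict(_window_input(padded, g - k, W))
        for c in predictor.channels:
            out[c][j] = pred.channels[c][k]
    return out


def probe_traces(
    predictor: Predictor, padded: PaddedRegion, nucleotide: int, W: int
) -> dict[str, ProbeTrace]:
    """All-channel probe traces for one nucleotide: W windows, one per offset.

    ``values[k]`` is the prediction from the window whose start places the
    nucleotide at within-window offset k.  Does not materialize a store.
    """
    focal = padded.focal
    if not focal.contains(nucleotide):
        raise ValueError(f"nucleotide {nucleotide} outside focal region {focal}")
    if padded.flank < W - 1:
        raise ValueError(f"insufficient flank {padded.flank}; need >= W - 1 = {W - 1}")
    vals = {c: np.empty(W) for c in predictor.channels}
    for k in range(W):
        pred = predictor.predict(_window_input(padded, nucleotide - k, W))
        for c in predictor.channels:
            vals[c][k] = pred.channels[c][k]
    return {
        c: ProbeTrace(nucleotide=nucleotide, channel=c, values=vals[c])
        for c in predictor.channels
    }


def extract_probe_trace(
    predictor: Predictor,
    padded: PaddedRegion,
    nucleotide: int,
    W: int,
    channel: str = "exon",
) -> ProbeTrace:
    return probe_traces(predictor, padded, nucleotide, W)[channel]


# ---------------------------------------------------------------------------
# sharded persistence

_SHARD_COLUMNS = ["chrom", "pos_0based", "window_offset", "channel", "probability"]


def save_store(
    store: PositionSortedStore,
    outdir: str | Path,
    block_size: int = 512,
    extra: dict | None = None,
) -> Path:
    """Persist a store as TSV shards (one per window-offset block) + manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    shards = []
    for b0 in range(0, store.W, block_size):
        b1 = min(store.W, b0 + block_size)
        frames = []
        for c, grid in store.channels.items():
            rows, ks = np.nonzero(store.mask[:, b0:b1])
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": store.region.chrom,
                        "pos_0based": rows + store.region.start,
                        "window_offset": ks + b0,
                        "channel": c,
                        "probability": grid[:, b0:b1][rows, ks],
                    }
                )
            )
        name = f"shard_{b0:06d}.tsv"
        pd.concat(frames).to_csv(out / name, sep="\t", index=False)
        shards.append(name)
    manifest = {
        "region": {
            "chrom": store.region.chrom,
            "start": store.region.start,
            "end": store.region.end,
            "strand": store.region.strand,
        },
        "W": store.W,
        "channels": sorted(store.channels),
        "block_size": block_size,
        "shards": shards,
    }
    if extra:
        manifest.update(extra)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def load_store(indir: str | Path) -> PositionSortedStore:
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    reg = manifest["region"]
    region = GenomicRegion(reg["chrom"], reg["start"], reg["end"], reg.get("strand", "."))
    W = manifest["W"]
    L = region.length
    grids = {c: np.full((L, W), np.nan) for c in manifest["channels"]}
    mask = np.zeros((L, W), dtype=bool)
    for name in manifest["shards"]:
        df = pd.read_csv(indir / name, sep="\t")
        for c, sub in df.groupby("channel"):
            r = sub["pos_0based"].to_numpy() - region.start
            k = sub["window_offset"].to_numpy()
            grids[c][r, k] = sub["probability"].to_numpy()
            mask[r, k] = True
    return PositionSortedStore(region=region, W=W, channels=grids, mask=mask)
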