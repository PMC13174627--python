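"""Synthetic genomes and a label-driven emulator of a two-channel
nucleotide-resolution predictor.

The emulator reproduces, with independently tunable magnitudes, three
context effects documented for segmentation-style genomic language models:

* **edge attenuation** — predictions shrink toward a neutral probability
  near the window boundaries, where the model lacks flanking context;
* **phase-locked oscillation** — a periodic modulation (default period
  24 nt, echoing 6-mer tokenization with a four-token cycle) tied to the
  nucleotide's offset within the window;
* **length-dependent sharpening** — separation between the matching and
  non-matching state grows with window length and saturates at ``w_sat``.

For the exon channel at within-window offset ``k`` with per-base label
``l`` (1 = exonic), the generative model is::

    b       = logit(p_high) if l == 1 else logit(p_low)
    s_k     = (1 - exp(-(k+1)/lambda_start)) * (1 - exp(-(W-k)/lambda_end))
    g       = min(W, w_sat) / w_sat
    logit_k = logit(mu0) + s_k * g * (b - logit(mu0))
              + phase_offsets[(k + k_phase_origin) mod P] + eps_k
    prob_k  = expit(logit_k),   eps_k ~ Normal(0, noise_sd)

The intron channel uses its own parameters with label ``1 - l`` as the
matching state, and independent noise.  Channels are not constrained to
sum to one.  Noise lives on the logit scale so probabilities stay in
(0, 1) without clipping.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping, Protocol, runtime_checkable

import numpy as np
from scipy.special import expit, logit

from .genome_io import GeneModel, GenomicRegion

__all__ = [
    "ChannelParams",
    "EmulatorParams",
    "PredictionWindow",
    "WindowInput",
    "SyntheticGenomeSpec",
    "EmulatorPredictor",
    "SegmentNTAdapter",
    "ModelNotInstalledError",
    "default_params",
    "apoe850_mimic",
    "phase_shape",
    "emulate_window",
    "generate_synthetic_genome",
    "simulate_central_trace",
    "fit_edge_decay",
    "params_to_dict",
    "params_from_dict",
]

CHANNELS = ("exon", "intron")


@dataclass(frozen=True)
class ChannelParams:
    """Plateau and oscillation parameters of one output channel.

    ``p_high``/``p_low`` are the saturated probabilities for the matching /
    non-matching label; ``mu0`` is the neutral probability edge positions
    shrink toward; ``phase_offsets`` holds one additive logit offset per
    window-offset residue class.
    """

    p_high: float
    p_low: float
    mu0: float
    phase_offsets: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (0.0 < self.p_low < self.mu0 < self.p_high < 1.0):
            raise ValueError(
                f"need 0 < p_low ({self.p_low}) < mu0 ({self.mu0}) "
                f"< p_high ({self.p_high}) < 1"
            )
        object.__setattr__(self, "phase_offsets", tuple(float(x) for x in self.phase_offsets))


@dataclass(frozen=True)
class EmulatorParams:
    """Full generative parameter set of the synthetic predictor."""

    exon: ChannelParams
    intron: ChannelParams
    lambda_start: float = 400.0
    lambda_end: float = 150.0
    period: int = 24
    noise_sd: float = 0.05
    w_sat: int = 3_072
    token_size: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.period < 1:
            raise ValueError("period must be >= 1")
        if self.lambda_start <= 0 or self.lambda_end <= 0:
            raise ValueError("decay lengths must be positive")
        if self.w_sat <= 0:
            raise ValueError("w_sat must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        for name in ("exon", "intron"):
            cp = getattr(self, name)
            if len(cp.phase_offsets) != self.period:
                raise ValueError(
                    f"{name} phase_offsets length {len(cp.phase_offsets)} != period {self.period}"
                )

    def channel(self, name: str) -> ChannelParams:
        if name not in CHANNELS:
            raise KeyError(f"unknown channel {name!r}")
        return getattr(self, name)


@dataclass
class PredictionWindow:
    """Per-nucleotide channel probabilities for one input window."""

    window_length: int
    channels: dict[str, np.ndarray]
    window_start: int

    def __post_init__(self) -> None:
        for name, vals in self.channels.items():
            vals = np.asarray(vals, dtype=float)
            if vals.shape != (self.window_length,):
                raise ValueError(f"channel {name!r} length != window length")
            if (vals < 0).any() or (vals > 1).any():
                raise ValueError(f"channel {name!r} has probabilities outside [0, 1]")
            self.channels[name] = vals


@dataclass
class WindowInput:
    """One predictor call: a sequence and/or label window plus its genome offset."""

    sequence: str | None = None
    labels: np.ndarray | None = None
    window_start: int = 0


@runtime_checkable
class Predictor(Protocol):
    """Pluggable per-nucleotide predictor backend."""

    channels: tuple[str, ...]

    def predict(self, window: WindowInput) -> PredictionWindow: ...


# ---------------------------------------------------------------------------
# parameter presets


def phase_shape(period: int = 24) -> np.ndarray:
    """Canonical zero-mean oscillation shape for one period.

    A 6-nt primary cycle modulated by a full-period component, so phase
    decimation by 6 leaves a residual four-token cycle when ``period=24``.
    The shape peaks at residue 0 (offsets divisible by 6).
    """
    r = np.arange(period)
    if period % 6 == 0 and period > 6:
        return np.cos(2 * np.pi * r / 6) + 0.5 * np.cos(2 * np.pi * r / period)
    return np.cos(2 * np.pi * r / period)


def default_params(
    period: int = 24,
    noise_sd: float = 0.05,
    seed: int = 0,
    exon_amplitude: float = 0.3,
    intron_amplitude: float = 0.5,
    **overrides,
) -> EmulatorParams:
    """Default oscillation preset.

    Plateaus are chosen so first/last distributions are visibly distinct
    from the middle; the exon channel peaks (and the intron channel dips)
    at window offsets divisible by 6.
    """
    shape = phase_shape(period)
    exon = ChannelParams(
        p_high=0.97, p_low=0.02, mu0=0.30, phase_offsets=tuple(exon_amplitude * shape)
    )
    intron = ChannelParams(
        p_high=0.97, p_low=0.03, mu0=0.50, phase_offsets=tuple(-intron_amplitude * shape)
    )
    return EmulatorParams(
        exon=exon, intron=intron, period=period, noise_sd=noise_sd, seed=seed, **overrides
    )


def apoe850_mimic(noise_sd: float = 0.0, seed: int = 0, **overrides) -> EmulatorParams:
    """Preset calibrated to the oscillation amplitudes reported for an
    exonic probe nucleotide of a real segmentation model.

    With ``noise_sd=0`` the central (fully-contexted) trace of an exonic
    nucleotide oscillates between exactly 0.938 and 0.978 on the exon
    channel and between 0.079 and 0.310 on the intron channel.
    """
    shape = phase_shape(24)
    u = (shape - shape.min()) / np.ptp(shape)  # in [0, 1], max at residue 0

    lo_e, hi_e = logit(0.938), logit(0.978)
    mid_e = 0.5 * (lo_e + hi_e)
    off_e = lo_e + u * (hi_e - lo_e) - mid_e  # exon peaks at residue 0

    lo_i, hi_i = logit(0.079), logit(0.310)
    mid_i = 0.5 * (lo_i + hi_i)
    off_i = hi_i - u * (hi_i - lo_i) - mid_i  # intron dips at residue 0

    exon = ChannelParams(
        p_high=float(expit(mid_e)), p_low=0.02, mu0=0.30, phase_offsets=tuple(off_e)
    )
    intron = ChannelParams(
        p_high=0.97, p_low=float(expit(mid_i)), mu0=0.50, phase_offsets=tuple(off_i)
    )
    return EmulatorParams(
        exon=exon, intron=intron, period=24, noise_sd=noise_sd, seed=seed, **overrides
    )


def params_to_dict(params: EmulatorParams) -> dict:
    """JSON-serializable form of an :class:`EmulatorParams`."""
    d = {
        "lambda_start": params.lambda_start,
        "lambda_end": params.lambda_end,
        "period": params.period,
        "noise_sd": params.noise_sd,
        "w_sat": params.w_sat,
        "token_size": params.token_size,
        "seed": params.seed,
    }
    for name in CHANNELS:
        cp = params.channel(name)
        d[name] = {
            "p_high": cp.p_high,
            "p_low": cp.p_low,
            "mu0": cp.mu0,
            "phase_offsets": list(cp.phase_offsets),
        }
    return d


def params_from_dict(d: Mapping) -> EmulatorParams:
    chans = {
        name: ChannelParams(
            p_high=d[name]["p_high"],
            p_low=d[name]["p_low"],
            mu0=d[name]["mu0"],
            phase_offsets=tuple(d[name]["phase_offsets"]),
        )
        for name in CHANNELS
    }
    scalar = {k: d[k] for k in (
        "lambda_start", "lambda_end", "period", "noise_sd", "w_sat", "token_size", "seed"
    ) if k in d}
    return EmulatorParams(exon=chans["exon"], intron=chans["intron"], **scalar)


# ---------------------------------------------------------------------------
# the generative model


@lru_cache(maxsize=64)
def _edge_factor(W: int, lambda_start: float, lambda_end: float) -> np.ndarray:
    k = np.arange(W)
    s = (1.0 - np.exp(-(k + 1) / lambda_start)) * (1.0 - np.exp(-(W - k) / lambda_end))
    s.setflags(write=False)
    return s


def emulate_window(
    labels: np.ndarray,
    k_phase_origin: int,
    params: EmulatorParams,
    rng: np.random.Generator | None = None,
    window_start: int = 0,
) -> PredictionWindow:
    """Generate both channel probability vectors for one label window.

    ``k_phase_origin`` shifts which residue class each within-window offset
    falls in; probing keeps it constant across a sweep so the oscillation is
    locked to the within-window offset.
    """
    labels = np.asarray(labels)
    W = labels.size
    if W == 0 or W % params.token_size != 0:
        raise ValueError(f"window length {W} is not a positive multiple of {params.token_size}")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary")

    s = _edge_factor(W, params.lambda_start, params.lambda_end)
    g = min(W, params.w_sat) / params.w_sat
    phase = (np.arange(W) + k_phase_origin) % params.period
    if params.noise_sd > 0 and rng is None:
        rng = np.random.default_rng(params.seed)

    channels: dict[str, np.ndarray] = {}
    for name in CHANNELS:
        cp = params.channel(name)
        match = labels if name == "exon" else 1 - labels
        b = np.where(match == 1, logit(cp.p_high), logit(cp.p_low))
        m0 = logit(cp.mu0)
        lg = m0 + s * g * (b - m0) + np.asarray(cp.phase_offsets)[phase]
        if params.noise_sd > 0:
            lg = lg + rng.normal(0.0, params.noise_sd, W)
        channels[name] = expit(lg)
    return PredictionWindow(window_length=W, channels=channels, window_start=window_start)


class EmulatorPredictor:
    """Label-driven predictor backend wrapping :func:`emulate_window`.

    Stateless across calls: the noise stream is keyed by ``window_start``
    (and the params seed), so re-predicting the same window reproduces the
    same probabilities bitwise.
    """

    channels = CHANNELS

    def __init__(
        self,
        params: EmulatorParams,
        design_lengths: tuple[int, ...] | None = None,
        k_phase_origin: int = 0,
    ) -> None:
        self.params = params
        self.design_lengths = tuple(design_lengths) if design_lengths else None
        self.k_phase_origin = k_phase_origin

    def fingerprint(self) -> dict:
        return {
            "backend": "emulator",
            "k_phase_origin": self.k_phase_origin,
            "params": params_to_dict(self.params),
        }

    def _rng(self, window_start: int) -> np.random.Generator:
        if window_start < 0:
            raise ValueError("window_start must be non-negative for keyed noise streams")
        return np.random.default_rng(
            np.random.SeedSequence([int(self.params.seed), int(window_start)])
        )

    def predict(self, window: WindowInput) -> PredictionWindow:
        if window.labels is None:
            raise ValueError("EmulatorPredictor requires a label window")
        W = len(window.labels)
        if self.design_lengths is not None and W not in self.design_lengths:
            raise ValueError(f"unsupported window length {W}; design allows {self.design_lengths}")
        rng = self._rng(window.window_start) if self.params.noise_sd > 0 else None
        return emulate_window(
            window.labels,
            self.k_phase_origin,
            self.params,
            rng=rng,
            window_start=window.window_start,
        )


class ModelNotInstalledError(RuntimeError):
    pass


class SegmentNTAdapter:
    """Adapter stub for a real sequence-based segmentation model.

    Satisfies the predictor contract so pipelines type-check end to end,
    but raises until actual model weights and runtime are wired in.
    """

    channels = CHANNELS

    def __init__(self, model_path: str | None = None) -> None:
        self.model_path = model_path

    def fingerprint(self) -> dict:
        return {"backend": "segmentnt-adapter", "model_path": self.model_path}

    def predict(self, window: WindowInput) -> PredictionWindow:
        raise ModelNotInstalledError(
            "model not installed: the segmentation-model runtime is not available; "
            "use EmulatorPredictor or wire this adapter to installed weights"
        )


# ---------------------------------------------------------------------------
# synthetic genome


@dataclass
class SyntheticGenomeSpec:
    """Layout of a synthetic chromosome: alternating intergenic gaps and
    genes with internal exon/intron structure.

    Defaults: gene sizes span the 3-10 kb band used for desk-scale audits,
    and intergenic gaps are wide enough (>= 30 kb) that a full 24,575-nt
    flank fits around any gene.
    """

    n_genes: int = 5
    gene_length_range: tuple[int, int] = (3_000, 10_000)
    exon_count_range: tuple[int, int] = (3, 8)
    exon_length_range: tuple[int, int] = (100, 400)
    intergenic_length_range: tuple[int, int] = (30_000, 50_000)
    gc_content: float = 0.41
    seed: int = 0
    chrom_name: str = "chrS"

    def __post_init__(self) -> None:
        for name in (
            "gene_length_range",
            "exon_count_range",
            "exon_length_range",
            "intergenic_length_range",
        ):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name}={lo, hi} must be positive and ordered")
        if not (0.0 < self.gc_content < 1.0):
            raise ValueError("gc_content must be in (0, 1)")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")


def _random_sequence(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    idx = rng.choice(4, size=n, p=p)
    return np.frombuffer(b"ACGT", dtype="S1")[idx].tobytes().decode("ascii")


def generate_synthetic_genome(
    spec: SyntheticGenomeSpec,
) -> tuple[dict[str, str], list[GeneModel]]:
    """Generate a single-contig genome and its gene models, deterministically.

    Genes never overlap; the first exon starts at the gene start and the
    last exon ends at the gene end, with at least 1 nt of intron between
    consecutive exons.
    """
    rng = np.random.default_rng(spec.seed)
    chrom = spec.chrom_name

    def gap() -> int:
        lo, hi = spec.intergenic_length_range
        return int(rng.integers(lo, hi + 1))

    genes: list[GeneModel] = []
    cursor = gap()
    for gi in range(spec.n_genes):
        n_ex = int(rng.integers(spec.exon_count_range[0], spec.exon_count_range[1] + 1))
        ex_lens = rng.integers(
            spec.exon_length_range[0], spec.exon_length_range[1] + 1, size=n_ex
        )
        strand = "+" if rng.integers(2) == 0 else "-"
        symbol = f"SYNG{gi + 1:04d}"
        lo_g, hi_g = spec.gene_length_range

        if n_ex == 1:
            glen = int(rng.integers(lo_g, hi_g + 1))
            starts = np.array([0])
            ex_lens = np.array([glen])
        else:
            min_len = int(ex_lens.sum()) + (n_ex - 1)
            if min_len > hi_g:
                raise ValueError(
                    f"exon draw needs {min_len} nt but gene_length_range caps at {hi_g}"
                )
            glen = int(rng.integers(max(lo_g, min_len), hi_g + 1))
            intron_budget = glen - int(ex_lens.sum())
            extra = rng.multinomial(
                intron_budget - (n_ex - 1), np.full(n_ex - 1, 1.0 / (n_ex - 1))
            )
            intron_lens = extra + 1
            starts = np.concatenate([[0], np.cumsum(ex_lens[:-1] + intron_lens)])

        region = GenomicRegion(chrom, cursor, cursor + glen, strand)
        exons = [
            GenomicRegion(chrom, cursor + int(s), cursor + int(s) + int(l), strand)
            for s, l in zip(starts, ex_lens)
        ]
        genes.append(GeneModel(symbol, region, exons, source="synthetic"))
        cursor += glen + gap()

    genome = {chrom: _random_sequence(rng, cursor, spec.gc_content)}
    return genome, genes


# ---------------------------------------------------------------------------
# calibration helpers


def simulate_central_trace(
    params: EmulatorParams,
    channel: str = "exon",
    label: int = 1,
    n: int = 14_976,
    seed: int = 0,
    phase_origin: int = 0,
) -> np.ndarray:
    """Closed-form central-plateau probe trace, bypassing window enumeration.

    Assumes full context on both sides (edge factor 1) and a saturated
    window (g = 1), i.e. the regime left after tail trimming at large W.
    Useful for calibration experiments and estimator stress tests where the
    O(W^2) window sweep is unnecessary.
    """
    cp = params.channel(channel)
    match = label if channel == "exon" else 1 - label
    b = logit(cp.p_high) if match == 1 else logit(cp.p_low)
    j = np.arange(n)
    lg = b + np.asarray(cp.phase_offsets)[(j + phase_origin) % params.period]
    if params.noise_sd > 0:
        lg = lg + np.random.default_rng(seed).normal(0.0, params.noise_sd, n)
    return expit(lg)


def fit_edge_decay(
    trace_values: np.ndarray,
    params: EmulatorParams,
    channel: str = "exon",
    label: int = 1,
    g: float = 1.0,
    phase_origin: int = 0,
    n_fit: int = 1_500,
    grid: np.ndarray | None = None,
) -> float:
    """Recover ``lambda_start`` from the leading edge of a noise-free trace.

    Inverts the generative model at known channel parameters: the scaled
    residual ``(logit(v_k) - logit(mu0) - phase_k) / (g * (b - logit(mu0)))``
    approaches ``1 - exp(-(k+1)/lambda_start)`` for offsets far from the
    trailing end.  A coarse geometric grid search returns the best-fitting
    decay length.
    """
    cp = params.channel(channel)
    match = label if channel == "exon" else 1 - label
    b = logit(cp.p_high) if match == 1 else logit(cp.p_low)
    m0 = logit(cp.mu0)
    n = min(n_fit, len(trace_values))
    k = np.arange(n)
    off = np.asarray(cp.phase_offsets)[(k + phase_origin) % params.period]
    y = (logit(np.asarray(trace_values[:n], dtype=float)) - m0 - off) / (g * (b - m0))
    lam_grid = np.geomspace(10.0, 5_000.0, 400) if grid is None else np.asarray(grid)
    sse = [float(((y - (1.0 - np.exp(-(k + 1) / lam))) ** 2).sum()) for lam in lam_grid]
    return float(lam_grid[int(np.argmin(sse))])
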