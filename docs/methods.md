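# Methods

## The audit

`ntprobe` treats a per-nucleotide predictor as a black box
`f(window) -> (p_exon[0..W-1], p_intron[0..W-1])` and asks how its output
for a fixed genomic base changes with (a) the base's offset inside the
window, and (b) the window length.  Three analyses share one probing
primitive: sliding a length-`W` window one base at a time across a region
of length `L` produces `L + W − 1` windows whose placements put every focal
base at every offset `0..W−1` exactly once.  Organized by offset this is
the *position-sorted store*; a single row (one base at all `W` offsets) is
a *probe trace*.

Truth for classification is the union of a gene's annotated exons across
transcripts (optionally restricted to one transcript).  Strand is recorded
but ignored for labelling: predictions and truth both live on reference
coordinates.  Internal coordinates are 0-based half-open; GFF3 is converted
at the boundary.

## The emulator

Real segmentation models at audit scale need GPUs; the package instead
emulates one, injecting the documented context effects with independently
tunable magnitudes.  For the exon channel at offset `k` with base label
`ℓ ∈ {0,1}`:

```
b       = logit(p_high)  if ℓ = 1 else logit(p_low)
s_k     = (1 − e^{−(k+1)/λ_start}) · (1 − e^{−(W−k)/λ_end})    (edge factor)
g       = min(W, w_sat) / w_sat                                 (length factor)
logit_k = logit(μ0) + s_k · g · (b − logit(μ0)) + φ[(k + k0) mod P] + ε_k
p_k     = expit(logit_k),   ε_k ~ N(0, σ²) on the logit scale
```

The intron channel is generated identically with its own parameters and
label `1 − ℓ` as the matching state; channels carry independent noise and
are not constrained to sum to one.  The form is deliberately the simplest
one producing all three effects: logit-additive, so noise never needs
clipping; multiplicative shrinkage toward a neutral probability `μ0`, so
edge positions lose confidence symmetrically in logit space; a saturating
linear length gain; and a phase-offset table `φ` indexed by within-window
offset (plus a constant origin `k0`), because the observed oscillation
tracks the offset of the base inside the window, not its genome coordinate.
The emulator is label-driven — sequence content does not influence it — so
tests know the exact data-generating process.

Noise streams are keyed by `(seed, window_start)`: re-predicting any window
reproduces it bitwise, probe traces equal the corresponding store rows even
under noise, and sweeps are order-independent.

### Parameters and defaults

| parameter | default | meaning |
| --- | --- | --- |
| `p_high`, `p_low` (exon) | 0.97 / 0.02 | saturated probability for matching / non-matching label |
| `μ0` (exon) | 0.30 | neutral value edge positions shrink toward |
| `p_high`, `p_low`, `μ0` (intron) | 0.97 / 0.03 / 0.50 | intron-channel counterparts |
| `λ_start`, `λ_end` | 400 / 150 nt | edge-attenuation decay lengths (asymmetric on purpose: the two window ends stabilize at different rates) |
| `P` | 24 nt | oscillation period |
| `φ` | `a·[cos(2πr/6) + ½·cos(2πr/P)]` | 6-nt primary cycle modulated over the full period, peaking (exon) / dipping (intron) at offsets divisible by 6; amplitudes a = 0.3 (exon), −0.5 (intron) |
| `σ` (`noise_sd`) | 0.05 | logit-scale context noise |
| `w_sat` | 3,072 nt | length at which sharpening saturates |
| token size | 6 nt | window lengths must be multiples of this |

These plateau/decay defaults are package choices, selected once so that
first/last distributions are visibly distinct from the middle while all
three positions keep predictive signal; they are config-overridable and not
claims about any real model.

The `apoe850_mimic` preset instead *calibrates* the phase table and
plateaus so that the noise-free central trace of an exonic base oscillates
between exactly 0.938–0.978 (exon channel) and 0.079–0.310 (intron
channel), the amplitudes reported for a real model's exonic probe
nucleotide.  The table is the canonical shape affinely mapped so its logit
extrema hit `logit` of those four values, with the channel plateau set to
the midpoint.

### Synthetic genomes

The generator lays out alternating intergenic gaps and genes on one contig:
gene lengths 3,000–10,000 nt (the size band used for desk-scale candidate
genes), 3–8 exons of 100–400 nt with ≥1 nt introns, first/last exon flush
with the gene bounds, intergenic gaps 30,000–50,000 nt so that a full
24,575-nt flank fits around any gene, GC 0.41 (human-like), five genes by
default.  Base composition is i.i.d.; the emulator never reads sequence, so
no repeat structure, isoform complexity, or composition bias is modeled.
Consequently, passing tests demonstrate that the *audit machinery*
(probing, normalization, estimators, reports) is correct and calibrated
against a known generative process — they say nothing about how any real
predictor behaves on real genomes, where truth annotations are imperfect
and predictions are sequence-dependent.

## Estimators and conventions

**Position classes.**  first = offset 0, last = `W−1`, middle = `W//2`
(0-based; configurable — the choice between the two central offsets of an
even window is arbitrary).

**Normalizations.**  Z-score uses the sample's own mean and population-`n`
standard deviation over all `L` values of one position class and channel;
subtraction is `p_exon − p_intron` per base.  Both leave rankings (hence
AUC) unchanged or re-centered; their value is a common threshold (0)
across position classes where raw probabilities need three different ones.

**Classification.**  Score ≥ threshold is a positive call (ties positive).
Raw threshold 0.50; normalized threshold 0.  Single-class truth yields NaN
for the undefined rate, with a warning, rather than an error.  AUC is the
midrank Mann–Whitney statistic; the emitted ROC curve's trapezoidal area
equals it exactly.

**Welch t.**  Position contrasts use the unequal-variance t-test (a pooled
option exists).  P-values that underflow the smallest positive normal
double (2.2250738585072014e-308) are displayed as the string
`"< 2.23e-308"`; the raw float is kept alongside.

**Tail trim.**  Default per-side trim is `round(0.1953·W)`, i.e. 4,800
contexts at `W = 24,576` — the attenuated, high-variance window tails are
excluded before oscillation analysis.

**Detrending.**  A centered moving mean (window 101, odd, edges truncated)
is removed before period estimation only; amplitudes and the phase ANOVA
use raw trimmed probabilities.  A width-101 boxcar leaks ≈4.6% of a
period-24 component into the trend, which is negligible for the EV
estimator (EV(24) > 0.9999 on noise-free traces).

**Period estimation.**  `EV(m) = 1 − SS_within/SS_total` over residue
classes modulo `m`, for `m = 1..48`.  EV is nondecreasing under group
refinement, so every multiple of the true period scores as high as the
period itself; the estimator returns the *smallest* `m` with
`EV(m) ≥ τ·max EV` (τ = 0.99).  A flat-low profile (max EV < 0.2) or a
constant trace is flagged non-oscillating with period 1 — without that
floor, pure noise would report `m_max`, since EV of noise grows linearly in
the number of groups.

**Phase ANOVA.**  One-way ANOVA across the 24 residue-class groups of the
trimmed raw trace, then Tukey HSD on all 276 pairs at family-wise α = 0.05
(studentized-range adjusted p-values via statsmodels).

**Stabilization.**  Trailing rolling mean of window 6, defined from index 5
onward; the from-start distance is the first 1-based position where the
smoothed trace reaches the threshold, and the from-end distance applies the
identical scan to the reversed trace, so both ends are treated
symmetrically.  Thresholds never reached are flagged, not imputed.  These
index conventions are package choices; distances are comparable within runs
of this package, not across tools with different rolling conventions.

**Plateau.**  The sweep scores the middle position class per design length;
`find_plateau` returns the smallest `W` within ε (default 0.005) of the
maximum for a chosen metric.  AUC and raw-median criteria are reported side
by side because they genuinely disagree: ranking can saturate (AUC
plateau) while medians keep rising toward `w_sat`.  On noise-free emulator
data the AUC criterion is degenerate — any positive separation gives
AUC = 1 at every length — so exact saturation-length recovery is a property
of the median criterion.

## Problem sizes

Desk-scale defaults keep everything on one CPU: full-scale probe traces at
`W = 24,576` (one trace ≈ `W` windows, about a minute), position-class and
sweep analyses on ~2 kb regions with windows up to 768 nt, period-recovery
experiments on 14,976-point central traces (the trimmed length at full
scale), and 100-replicate recovery grids / 500-replicate ANOVA calibration
runs.  The sliding-store path materializes `L × W` grids and is meant for
regions × windows that fit memory; sweeps and traces use the
`L`-window/`W`-window shortcuts instead of full stores.  Stores persist as
sharded TSV for resumable large runs.

## Known limitations

- The emulator is label-driven and cannot reproduce sequence-dependent
  artifacts (repeat confusion, strand effects, isoform signals).
- One oscillation phase table per channel; real models may mix periods or
  drift in phase across the window.
- Edge attenuation is separable and exponential; real context decay need
  not be either.
- The period estimator assumes an integer period ≤ `m_max` in window-offset
  units.
- `SegmentNTAdapter` is a stub: wiring a real model in requires its runtime
  and weights, and real-model audits inherit GPU/storage costs the package
  does not manage.
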