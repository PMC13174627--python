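# ntprobe

**Contextual-bias audit for nucleotide-resolution genomic predictors.**

Genomic language models such as SegmentNT emit per-nucleotide probabilities
(e.g. "is this base exonic? intronic?") for a fixed-length input window.
Those probabilities are not a property of the nucleotide alone: they depend
on *where* the nucleotide sits inside the window and on *how long* the
window is.  `ntprobe` is a probing harness for quantifying three such
context effects against a gene-annotation truth set:

1. **Positional bias.**  Slide a window one base at a time across a region
   so every nucleotide occupies every within-window offset, then compare the
   probability distributions when a base is the *first*, *middle* (offset
   `W//2`) or *last* position.  Raw distributions differ strongly across
   positions; Z-score and exon-minus-intron subtraction normalizations
   restore a single decision threshold.  Performance is scored against the
   exon-union truth track as accuracy / sensitivity / specificity and the
   rank AUC

   `AUC = P(s⁺ > s⁻) + ½·P(s⁺ = s⁻)`,

   the probability that a random exonic base outscores a random non-exonic
   one.

2. **Input-length bias.**  Sweep window lengths `W = 6·2ⁿ` nt (4 to 4,096
   six-nucleotide tokens, i.e. 24 to 24,576 nt), score each, and locate the
   diminishing-returns plateau: the smallest `W` whose metric is within ε of
   the sweep maximum.

3. **Periodic oscillation and stabilization.**  A *probe trace* collects one
   nucleotide's probability at all `W` window offsets.  After trimming the
   attenuated tails (~19.5% per side) and removing the slow trend, the
   period is estimated by explained variance over residue classes:
   `EV(m) = 1 − SS_within/SS_total` for phase groups modulo `m`, reporting
   the smallest `m` reaching `τ·max EV` (immune to period-multiple
   ambiguity).  Phase groups are compared by one-way ANOVA with Tukey HSD;
   stabilization distances measure how many positions from each window end a
   trailing rolling average (window 6) needs to reach 0.90 / 0.95.

Because running the real model at audit scale needs GPUs and a reference
genome, the package ships a **label-driven emulator** that injects all three
effects with known, tunable magnitudes (logit-additive edge attenuation,
phase-locked periodic offsets, saturating length gain) plus a synthetic
genome/annotation generator, so every stage of the audit is testable and
exactly checkable on a desktop.  A real sequence-based model can be plugged
in through the same predictor interface (`SegmentNTAdapter` is the stub).

Intended users: people evaluating or post-processing nucleotide-resolution
foundation-model outputs, and developers of such models who want a
regression harness for context artifacts.

## Worked example

Run a small end-to-end audit on a synthetic gene (one ~2 kb gene, windows
24–768 nt):

```bash
cat > config.json <<'EOF'
{"seed": 11, "outdir": "demo_out",
 "genome": {"n_genes": 1, "gene_length_range": [2000, 2000],
            "intergenic_length_range": [800, 1000]},
 "n_min": 2, "n_max": 7}
EOF
ntprobe --config config.json audit
python - <<'EOF'
import json
import pandas as pd

pr = pd.read_csv("demo_out/positions_report.tsv", sep="\t")
for pc in ("first", "middle", "last"):
    row = pr[(pr.position_class == pc) & (pr.normalization == "zscore")
             & (pr.stratum == "all")].iloc[0]
    print(f"{pc:6s} zscore: accuracy {row.accuracy:.3f}  AUC {row.auc:.4f}")
print("plateau:", json.load(open("demo_out/plateau.json")))
osc = json.load(open("demo_out/oscillation.json"))["exon"]
print(f"exon-channel period: {osc['period']} nt "
      f"(trace oscillates {osc['min']:.3f}-{osc['max']:.3f}, "
      f"{osc['tukey_rejections']}/{osc['tukey_pairs']} Tukey pairs differ)")
e = json.load(open("demo_out/stabilization.json"))["exon"]["thresholds"][0]
print("stabilization @0.90: reached from start:", e["reached_start"],
      "| from end:", e["reached_end"])
EOF
```

which prints:

```
first  zscore: accuracy 0.523  AUC 0.5187
middle zscore: accuracy 1.000  AUC 1.0000
last   zscore: accuracy 0.538  AUC 0.5601
plateau: {'epsilon': 0.005, 'by_auc': 384, 'by_median_exonic': 768}
exon-channel period: 24 nt (trace oscillates 0.289-0.571, 222/276 Tukey pairs differ)
stabilization @0.90: reached from start: False | from end: False
```

Reading the output: the middle position classifies the synthetic gene's
exons perfectly while the first and last positions are near chance — the
emulator's edge attenuation at work.  The AUC-based plateau lands at 384 nt
and the raw-median plateau at the largest window, because medians keep
growing toward saturation after ranking has stopped improving.  The
oscillation detector recovers the injected 24-nt cycle from the probe
trace, with most of the 276 phase pairs significantly different under Tukey
HSD.  At this small 768-nt trace the rolling average never reaches 0.90
(windows this short sit far below the emulator's 3,072-nt saturation
length, so probabilities stay shrunk toward neutral) and the report flags
"never reached" rather than inventing a distance.  `demo_out/` also
contains per-stratum medians and IQRs, confusion counts, ROC curves,
`sweep.tsv`, Tukey tables, and a `manifest.json` whose config hash makes
the bundle reproducible bitwise.

## Layout

| module | role |
| --- | --- |
| `ntprobe.genome_io` | FASTA/GFF3/BED/TSV I/O, truth tracks, candidate-gene filtering, control-region sampling, repeat-profile matching |
| `ntprobe.synthetic` | synthetic genome generator, bias-injecting emulator, predictor interface + adapter stub |
| `ntprobe.probing` | window designs, sliding probe, position-sorted store, probe traces |
| `ntprobe.position_bias` | summaries, Welch t contrasts, normalizations, classification, rank AUC |
| `ntprobe.length_sweep` | window-length sweep and plateau detection |
| `ntprobe.periodicity` | trimming, detrending, EV period estimator, phase ANOVA/Tukey, stabilization |
| `ntprobe.pipeline` / `ntprobe.cli` / `ntprobe.reports` | audit stages, `ntprobe` CLI, config + manifest schema |

See `docs/methods.md` for the underlying models, conventions and
limitations.
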