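"""End-to-end audit pipeline: synthetic inputs -> positional bias ->
normalization/classification -> length sweep -> probe trace -> periodicity
-> stabilization, with TSV/JSON reports and a manifest.

Each stage is an ordinary function over library objects so the CLI stays a
thin shell; `run_audit` strings them together with per-stage timing and a
degraded mode when truth is unavailable (classification stages are skipped
with a warning, trace-based stages still run).
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, length_sweep, periodicity, position_bias, probing
from .genome_io import (
    GeneModel,
    GenomicRegion,
    PaddedRegion,
    TruthTrack,
    attach_truth_labels,
    build_truth_track,
    extract_padded_region,
    write_fasta,
    write_gff3,
)
from .probing import WindowDesign, make_window_design
from .reports import (
    AuditManifest,
    RunConfig,
    StageRecord,
    config_hash,
    describe_design,
)
from .synthetic import (
    EmulatorParams,
    EmulatorPredictor,
    SyntheticGenomeSpec,
    apoe850_mimic,
    default_params,
    generate_synthetic_genome,
    params_to_dict,
)

__all__ = [
    "AuditContext",
    "build_spec",
    "emulator_params_from_config",
    "build_context",
    "run_audit",
    "design_summary",
]

logger = logging.getLogger(__name__)


@dataclass
class AuditContext:
    """Resolved inputs shared by all stages."""

    cfg: RunConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    gene: GeneModel | None
    focal: GenomicRegion
    padded: PaddedRegion
    truth: TruthTrack | None
    predictor: EmulatorPredictor
    design: WindowDesign
    trace_window: int
    probe_nucleotide: int


def build_spec(cfg: RunConfig) -> SyntheticGenomeSpec:
    g = cfg.genome
    return SyntheticGenomeSpec(
        n_genes=g.n_genes,
        gene_length_range=g.gene_length_range,
        exon_count_range=g.exon_count_range,
        exon_length_range=g.exon_length_range,
        intergenic_length_range=g.intergenic_length_range,
        gc_content=g.gc_content,
        seed=cfg.seed,
        chrom_name=g.chrom_name,
    )


def emulator_params_from_config(cfg: RunConfig) -> EmulatorParams:
    e = cfg.emulator
    kwargs = {}
    for name in ("w_sat", "lambda_start", "lambda_end"):
        if getattr(e, name) is not None:
            kwargs[name] = getattr(e, name)
    if e.preset == "apoe850_mimic":
        if e.period is not None and e.period != 24:
            raise ValueError("apoe850_mimic preset is defined for period 24")
        return apoe850_mimic(
            noise_sd=0.0 if e.noise_sd is None else e.noise_sd,
            seed=cfg.seed,
            **kwargs,
        )
    if e.period is not None:
        kwargs["period"] = e.period
    return default_params(
        noise_sd=0.05 if e.noise_sd is None else e.noise_sd, seed=cfg.seed, **kwargs
    )


def build_context(cfg: RunConfig) -> AuditContext:
    genome, genes = generate_synthetic_genome(build_spec(cfg))
    design = make_window_design(cfg.n_min, cfg.n_max, cfg.token_size)
    trace_window = cfg.trace_window or design.max_length
    flank = max(design.max_length, trace_window) - 1

    gene: GeneModel | None = None
    if genes:
        if cfg.gene is not None:
            matches = [g for g in genes if g.symbol == cfg.gene]
            if not matches:
                raise KeyError(f"gene {cfg.gene!r} not among generated genes")
            gene = matches[0]
        else:
            gene = genes[0]
        focal = gene.region
    else:
        chrom = cfg.genome.chrom_name
        n = len(genome[chrom])
        L = min(cfg.control_region_length, max(1, n - 2 * flank))
        start = (n - L) // 2
        focal = GenomicRegion(chrom, start, start + L)

    padded = extract_padded_region(genome, focal, flank=flank)
    if gene is not None:
        padded = attach_truth_labels(padded, gene)
        truth: TruthTrack | None = build_truth_track(gene, focal)
    else:
        padded = dataclasses.replace(
            padded, labels=np.zeros(len(padded.sequence), dtype=np.uint8)
        )
        truth = None

    predictor = EmulatorPredictor(emulator_params_from_config(cfg))

    if cfg.probe_offset is not None:
        probe = focal.start + cfg.probe_offset
        if not focal.contains(probe):
            raise ValueError(f"probe offset {cfg.probe_offset} outside focal region")
    elif gene is not None and gene.exons:
        ex = gene.exons[0]
        probe = (ex.start + ex.end) // 2  # mid-exon, mirroring an exonic probe variant
    else:
        probe = (focal.start + focal.end) // 2
    return AuditContext(
        cfg=cfg,
        genome=genome,
        genes=genes,
        gene=gene,
        focal=focal,
        padded=padded,
        truth=truth,
        predictor=predictor,
        design=design,
        trace_window=trace_window,
        probe_nucleotide=probe,
    )


# ---------------------------------------------------------------------------
# stages (each returns the list of files it wrote)


def stage_simulate(ctx: AuditContext, outdir: Path) -> list[str]:
    fa = outdir / "genome.fa"
    gff = outdir / "genes.gff3"
    write_fasta(ctx.genome, fa)
    write_gff3(ctx.genes, gff)
    if not ctx.genes:
        warnings.warn("synthetic genome has no gene features")
    return [fa.name, gff.name]


def _position_samples(
    ctx: AuditContext, W: int, position_class: str
) -> dict[str, position_bias.PositionalSample]:
    vals = probing.extract_position_values(ctx.predictor, ctx.padded, W, position_class)
    assert ctx.truth is not None
    return {
        ch: position_bias.PositionalSample(
            values=vals[ch],
            truth=ctx.truth.labels,
            position_class=position_class,
            channel=ch,
        )
        for ch in ctx.predictor.channels
    }


def stage_positions(ctx: AuditContext, outdir: Path) -> list[str]:
    """First/middle/last extraction, normalization, classification and ROC."""
    cfg = ctx.cfg
    if ctx.truth is None or len(set(ctx.truth.labels.tolist())) < 2:
        warnings.warn("truth unavailable or single-class; classification skipped")
        return []
    W = ctx.design.max_length
    rows = []
    roc_files = []
    exonic_by_class: dict[str, position_bias.PositionalSample] = {}
    for pclass in cfg.position_classes:
        samples = _position_samples(ctx, W, pclass)
        exon = samples["exon"]
        exonic_by_class[pclass] = exon
        scored = {
            "raw": (exon, cfg.raw_threshold),
            "zscore": (position_bias.zscore_normalize(exon), cfg.normalized_threshold),
            "subtraction": (
                position_bias.subtract_channels(exon, samples["intron"]),
                cfg.normalized_threshold,
            ),
        }
        for norm, (sample, threshold) in scored.items():
            report = position_bias.evaluate(
                sample.values, sample.truth, threshold, normalization=norm
            )
            for stratum in ("exonic", "intronic", "all"):
                med, iqr = position_bias.summarize(sample, stratum)
                rows.append(
                    {
                        "position_class": pclass,
                        "normalization": norm,
                        "stratum": stratum,
                        "median": med,
                        "iqr": iqr,
                        "threshold": threshold,
                        "tp": report.tp,
                        "fp": report.fp,
                        "fn": report.fn,
                        "tn": report.tn,
                        "accuracy": report.accuracy,
                        "sensitivity": report.sensitivity,
                        "specificity": report.specificity,
                        "auc": report.auc,
                    }
                )
            _, curve = position_bias.roc_auc(sample.values, sample.truth)
            roc_name = f"roc_{pclass}_{norm}.tsv"
            pd.DataFrame(curve, columns=["fpr", "tpr"]).to_csv(
                outdir / roc_name, sep="\t", index=False
            )
            roc_files.append(roc_name)
    pd.DataFrame(rows).to_csv(outdir / "positions_report.tsv", sep="\t", index=False)

    comparisons = {}
    if "middle" in exonic_by_class:
        for other in cfg.position_classes:
            if other == "middle" or other not in exonic_by_class:
                continue
            for stratum in ("exonic", "intronic"):
                res = position_bias.compare_positions(
                    exonic_by_class["middle"], exonic_by_class[other], stratum
                )
                comparisons[f"middle_vs_{other}_{stratum}"] = {
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "p_display": res.p_display,
                    "floored": res.floored,
                    "median_middle": res.median_a,
                    f"median_{other}": res.median_b,
                    "iqr_middle": res.iqr_a,
                    f"iqr_{other}": res.iqr_b,
                }
    (outdir / "comparisons.json").write_text(json.dumps(comparisons, indent=1))
    return ["positions_report.tsv", "comparisons.json"] + roc_files


def stage_sweep(ctx: AuditContext, outdir: Path) -> list[str]:
    if ctx.truth is None or len(set(ctx.truth.labels.tolist())) < 2:
        warnings.warn("truth unavailable or single-class; sweep skipped")
        return []
    table = length_sweep.sweep(ctx.predictor, ctx.padded, ctx.truth, ctx.design)
    table.to_csv(outdir / "sweep.tsv", sep="\t", index=False)
    plateau = {
        "epsilon": ctx.cfg.epsilon_auc,
        "by_auc": length_sweep.find_plateau(table, ctx.cfg.epsilon_auc, "auc"),
        "by_median_exonic": length_sweep.find_plateau(
            table, ctx.cfg.epsilon_auc, "median_exonic"
        ),
    }
    (outdir / "plateau.json").write_text(json.dumps(plateau, indent=1))
    return ["sweep.tsv", "plateau.json"]


def stage_trace(ctx: AuditContext, outdir: Path) -> list[str]:
    traces = probing.probe_traces(
        ctx.predictor, ctx.padded, ctx.probe_nucleotide, ctx.trace_window
    )
    files = []
    for ch, trace in traces.items():
        name = f"trace_{ch}.tsv"
        pd.DataFrame(
            {"window_offset": np.arange(trace.values.size), "probability": trace.values}
        ).to_csv(outdir / name, sep="\t", index=False)
        files.append(name)
    return files


def stage_oscillation(ctx: AuditContext, outdir: Path) -> list[str]:
    cfg = ctx.cfg
    files = []
    summary = {}
    for ch in ctx.predictor.channels:
        trace = pd.read_csv(outdir / f"trace_{ch}.tsv", sep="\t")["probability"].to_numpy()
        t = cfg.trim if cfg.trim is not None else periodicity.default_trim(trace.size)
        central = periodicity.trim_tails(trace, t)
        residual = periodicity.detrend(central, cfg.detrend_window)
        est = periodicity.estimate_period(
            residual, cfg.m_max, cfg.tau, trim=t, detrend_window=cfg.detrend_window
        )
        amp = periodicity.estimate_amplitude(
            central, max(est.period, 1) if est.oscillating else cfg.anova_period,
            phase_origin=t,
        )
        anova = periodicity.phase_anova(central, cfg.anova_period)
        tukey_name = f"tukey_{ch}.tsv"
        anova.table.to_csv(outdir / tukey_name, sep="\t", index=False)
        files.append(tukey_name)
        summary[ch] = {
            "trim_per_side": t,
            "central_length": int(central.size),
            "period": est.period,
            "oscillating": est.oscillating,
            "explained_variance_at_period": est.explained_variance.get(est.period),
            "phase_means": amp.phase_means.tolist(),
            "min": amp.minimum,
            "max": amp.maximum,
            "range": amp.amp_range,
            "anova_F": anova.f_stat,
            "anova_p": anova.p_display,
            "tukey_rejections": int(anova.table["reject"].sum()),
            "tukey_pairs": int(len(anova.table)),
        }
    (outdir / "oscillation.json").write_text(json.dumps(summary, indent=1))
    return ["oscillation.json"] + files


def stage_stabilize(ctx: AuditContext, outdir: Path) -> list[str]:
    cfg = ctx.cfg
    out = {}
    for ch in ctx.predictor.channels:
        trace = pd.read_csv(outdir / f"trace_{ch}.tsv", sep="\t")["probability"].to_numpy()
        rep = periodicity.stabilization_distances(
            trace, tuple(cfg.stabilization_thresholds), cfg.rolling_window
        )
        out[ch] = {
            "rolling_window": rep.window,
            "thresholds": [dataclasses.asdict(e) for e in rep.entries],
        }
    (outdir / "stabilization.json").write_text(json.dumps(out, indent=1))
    return ["stabilization.json"]


def design_summary(ctx: AuditContext) -> dict:
    regions = [
        {
            "name": g.symbol,
            "length": g.region.length,
            "role": "validation" if g.symbol in ctx.cfg.validation_genes else "primary",
        }
        for g in ctx.genes
    ]
    if not regions:
        regions = [
            {"name": str(ctx.focal), "length": ctx.focal.length, "role": "primary"}
        ]
    return describe_design(regions, ctx.design)


_STAGES = [
    ("simulate", stage_simulate),
    ("positions", stage_positions),
    ("sweep", stage_sweep),
    ("trace", stage_trace),
    ("oscillation", stage_oscillation),
    ("stabilize", stage_stabilize),
]


def run_audit(cfg: RunConfig, resume: bool = False) -> Path:
    """Run all stages, write the report bundle, return the manifest path.

    With ``resume=True`` a stage whose outputs already exist is skipped.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ctx = build_context(cfg)
    records = []
    for name, fn in _STAGES:
        t0 = time.perf_counter()
        try:
            if resume:
                marker = outdir / f".stage_{name}.json"
                if marker.exists():
                    prior = json.loads(marker.read_text())
                    if all((outdir / f).exists() for f in prior["outputs"]):
                        records.append(StageRecord(**prior))
                        logger.info("stage %s: resumed", name)
                        continue
            outputs = fn(ctx, outdir)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed on {ctx.focal}: {exc}") from exc
        dt = time.perf_counter() - t0
        skipped = not outputs
        rec = StageRecord(
            name=name,
            seconds=round(dt, 4),
            outputs=outputs,
            skipped=skipped,
            note="truth unavailable" if skipped and name in ("positions", "sweep") else "",
        )
        records.append(rec)
        (outdir / f".stage_{name}.json").write_text(rec.model_dump_json())
        logger.info("stage %s: %.2fs, %d file(s)", name, dt, len(outputs))

    manifest = AuditManifest(
        config=cfg,
        config_hash=config_hash(cfg),
        package_version=__version__,
        stages=records,
    )
    path = outdir / "manifest.json"
    path.write_text(manifest.model_dump_json(indent=1))
    (outdir / "design.json").write_text(json.dumps(design_summary(ctx), indent=1))
    (outdir / "emulator_params.json").write_text(
        json.dumps(params_to_dict(ctx.predictor.params), indent=1)
    )
    return path
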