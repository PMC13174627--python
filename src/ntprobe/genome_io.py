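"""Genomes, annotations, truth tracks and control-region sampling.

Internal coordinates are 0-based half-open throughout; GFF3 (1-based,
inclusive) is converted at the read/write boundary.  Classification truth
is the union of a gene's annotated exons across transcripts unless a
single transcript is requested.  Strand is recorded but ignored for truth
labelling: predictions and truth both live on reference coordinates.
"""
from __future__ import annotations

import gzip
import json
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from intervaltree import IntervalTree

__all__ = [
    "GenomicRegion",
    "GeneModel",
    "PaddedRegion",
    "TruthTrack",
    "RepeatProfile",
    "GeneFilter",
    "read_genome",
    "read_gene_model",
    "read_bed",
    "read_repeat_profiles",
    "extract_padded_region",
    "attach_truth_labels",
    "build_truth_track",
    "filter_candidate_genes",
    "sample_control_regions",
    "match_repeat_profile",
    "write_fasta",
    "write_gff3",
]


@dataclass(frozen=True, order=True)
class GenomicRegion:
    """Half-open genomic interval; ``start`` inclusive, ``end`` exclusive."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid region {self.chrom}:{self.start}-{self.end}: need 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicRegion") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class GeneModel:
    """A gene with its (possibly overlapping) exon set, interpreted as a union."""

    symbol: str
    region: GenomicRegion
    exons: list[GenomicRegion]
    source: str = ""

    def __post_init__(self) -> None:
        for ex in self.exons:
            if ex.chrom != self.region.chrom or not (
                self.region.start <= ex.start and ex.end <= self.region.end
            ):
                raise ValueError(
                    f"exon {ex} outside gene bounds {self.region} for {self.symbol!r}"
                )

    @property
    def exonic_bases(self) -> int:
        """Size of the exon union in nucleotides."""
        track = build_truth_track(self, self.region)
        return int(track.labels.sum())


@dataclass
class PaddedRegion:
    """A focal region plus symmetric flanking context.

    ``sequence`` covers ``[origin, origin + focal.length + 2*flank)`` and
    ``labels`` (optional) is a per-base exon/non-exon vector aligned with it.
    The flank must be at least ``W - 1`` for a window length ``W`` so every
    focal base can occupy every within-window offset.
    """

    focal: GenomicRegion
    flank: int
    sequence: str
    origin: int
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        expect = self.focal.length + 2 * self.flank
        if len(self.sequence) != expect:
            raise ValueError(
                f"sequence length {len(self.sequence)} != focal.length + 2*flank = {expect}"
            )
        if self.labels is not None and len(self.labels) != expect:
            raise ValueError("labels length must match sequence length")


@dataclass
class TruthTrack:
    """Per-nucleotide binary exon labels over a region (1 = exonic)."""

    region: GenomicRegion
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if len(self.labels) != self.region.length:
            raise ValueError("labels length must equal region length")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")


@dataclass
class RepeatProfile:
    """Repeat content summary of a region (computed externally)."""

    region: GenomicRegion
    pct_sine: float
    pct_line: float
    pct_ltr: float

    def __post_init__(self) -> None:
        for name in ("pct_sine", "pct_line", "pct_ltr"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{name}={v} outside [0, 100]")


# ---------------------------------------------------------------------------
# readers


def read_genome(path: str | Path) -> dict[str, str]:
    """Read a (possibly gzipped) FASTA into a contig -> upper-case sequence map."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    opener = gzip.open if path.suffix == ".gz" else open
    genome: dict[str, str] = {}
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in genome:
                raise ValueError(f"duplicate contig name {rec.id!r} in {path}")
            seq = str(rec.seq).upper()
            if not seq:
                raise ValueError(f"empty FASTA record {rec.id!r} in {path}")
            genome[rec.id] = seq
    if not genome:
        raise ValueError(f"no FASTA records in {path}")
    return genome


def _open_gff(path: str | Path) -> gffutils.FeatureDB:
    return gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )


def _symbol_of(feat) -> str | None:
    for key in ("gene", "Name", "gene_name", "gene_id"):
        if key in feat.attributes:
            return feat.attributes[key][0]
    return None


def _to_region(feat) -> GenomicRegion:
    strand = feat.strand if feat.strand in ("+", "-") else "."
    return GenomicRegion(feat.seqid, feat.start - 1, feat.end, strand)


_GENE_FEATURE_TYPES = ("gene", "lncRNA", "ncRNA_gene", "pseudogene")


def read_gene_model(
    path: str | Path, symbol: str, transcript: str | None = None
) -> GeneModel:
    """Extract one gene and its exon union from a GFF3 file.

    ``transcript`` restricts the exon set to children of a single transcript
    (matched against exon ``Parent``/``transcript_id`` attributes), for use
    when only a canonical transcript should define truth.
    """
    db = _open_gff(path)
    gene_feat = None
    for ftype in _GENE_FEATURE_TYPES:
        for feat in db.features_of_type(ftype):
            if _symbol_of(feat) == symbol:
                gene_feat = feat
                break
        if gene_feat is not None:
            break
    if gene_feat is None:
        raise KeyError(f"gene symbol {symbol!r} not found in {path}")

    exons: list[GenomicRegion] = []
    seen: set[tuple[int, int]] = set()
    for feat in db.features_of_type("exon"):
        if _symbol_of(feat) != symbol:
            continue
        if transcript is not None:
            parents = list(feat.attributes.get("Parent", [])) + list(
                feat.attributes.get("transcript_id", [])
            )
            if transcript not in parents:
                continue
        reg = _to_region(feat)
        key = (reg.start, reg.end)
        if key in seen:  # identical exon shared across transcripts
            continue
        seen.add(key)
        exons.append(reg)
    if not exons:
        warnings.warn(f"gene {symbol!r} has no exon records in {path}")
    exons.sort(key=lambda r: (r.start, r.end))
    return GeneModel(symbol, _to_region(gene_feat), exons, source=str(path))


def read_bed(path: str | Path) -> list[GenomicRegion]:
    """Read BED intervals (0-based half-open; first three columns used)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
    )
    return [
        GenomicRegion(str(r.chrom), int(r.start), int(r.end)) for r in df.itertuples()
    ]


def read_repeat_profiles(path: str | Path) -> list[RepeatProfile]:
    """Read a repeat-content table (TSV: chrom, start, end, pct_sine, pct_line, pct_ltr)."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "pct_sine", "pct_line", "pct_ltr"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"repeat table missing columns: {sorted(missing)}")
    return [
        RepeatProfile(
            GenomicRegion(str(r.chrom), int(r.start), int(r.end)),
            float(r.pct_sine),
            float(r.pct_line),
            float(r.pct_ltr),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# region/truth construction


def extract_padded_region(
    genome: Mapping[str, str],
    region: GenomicRegion,
    flank: int = 50_000,
    n_fill: bool = False,
) -> PaddedRegion:
    """Slice a region plus ``flank`` nt of context per side out of a genome.

    Out-of-bounds flanks raise by default; with ``n_fill=True`` the missing
    context is padded with ``N``.
    """
    if region.chrom not in genome:
        raise KeyError(f"contig {region.chrom!r} not in genome")
    seq = genome[region.chrom]
    lo, hi = region.start - flank, region.end + flank
    if lo < 0 or hi > len(seq):
        if not n_fill:
            raise ValueError(
                f"flank {flank} around {region} exceeds contig bounds (0, {len(seq)})"
            )
        core = seq[max(0, lo) : min(len(seq), hi)]
        out = "N" * max(0, -lo) + core + "N" * max(0, hi - len(seq))
    else:
        out = seq[lo:hi]
    return PaddedRegion(focal=region, flank=flank, sequence=out, origin=lo)


def attach_truth_labels(padded: PaddedRegion, model: GeneModel) -> PaddedRegion:
    """Return a copy of ``padded`` carrying per-base exon labels over the full span."""
    n = len(padded.sequence)
    labels = np.zeros(n, dtype=np.uint8)
    lo0, hi0 = padded.origin, padded.origin + n
    for ex in model.exons:
        if ex.chrom != padded.focal.chrom:
            continue
        lo, hi = max(ex.start, lo0), min(ex.end, hi0)
        if lo < hi:
            labels[lo - lo0 : hi - lo0] = 1
    return replace(padded, labels=labels)


def build_truth_track(model: GeneModel, region: GenomicRegion) -> TruthTrack:
    """Per-base exon-union labels of ``model`` restricted to ``region``."""
    labels = np.zeros(region.length, dtype=np.uint8)
    hit = False
    for ex in model.exons:
        if ex.chrom != region.chrom:
            continue
        lo, hi = max(ex.start, region.start), min(ex.end, region.end)
        if lo < hi:
            labels[lo - region.start : hi - region.start] = 1
            hit = True
    if model.exons and not hit:
        warnings.warn(
            f"region {region} does not overlap exons of {model.symbol}; truth is all-zero"
        )
    return TruthTrack(region=region, labels=labels)


# ---------------------------------------------------------------------------
# candidate filtering and control sampling


@dataclass
class GeneFilter:
    """Candidate-gene criteria: primary contig, allowed feature type,
    length in [min_length, max_length), no pseudogenes, no placeholder
    symbols, and not on an excluded chromosome."""

    min_length: int = 3_000
    max_length: int = 10_000  # exclusive
    feature_types: tuple[str, ...] = ("gene", "lncRNA")
    excluded_prefixes: tuple[str, ...] = ("LOC",)
    excluded_chroms: frozenset[str] = field(default_factory=frozenset)
    primary_chrom_pattern: str = r"^(chr)?([0-9]+|X|Y)$"


def filter_candidate_genes(
    path: str | Path, criteria: GeneFilter | None = None
) -> list[GeneModel]:
    """Return genes passing all filter criteria, ordered by (chrom, start)."""
    crit = criteria or GeneFilter()
    db = _open_gff(path)
    pat = re.compile(crit.primary_chrom_pattern)

    exons_by_symbol: dict[str, list[GenomicRegion]] = {}
    for feat in db.features_of_type("exon"):
        sym = _symbol_of(feat)
        if sym is not None:
            exons_by_symbol.setdefault(sym, []).append(_to_region(feat))

    out: list[GeneModel] = []
    for ftype in crit.feature_types:
        for feat in db.features_of_type(ftype):
            sym = _symbol_of(feat)
            if sym is None:
                continue
            if not pat.match(feat.seqid):
                continue
            if feat.seqid in crit.excluded_chroms:
                continue
            region = _to_region(feat)
            if not (crit.min_length <= region.length < crit.max_length):
                continue
            if any(sym.startswith(p) for p in crit.excluded_prefixes):
                continue
            biotype = (
                feat.attributes.get("gene_biotype")
                or feat.attributes.get("biotype")
                or [""]
            )[0]
            if "pseudogene" in biotype:
                continue
            uniq = {
                (e.start, e.end): e
                for e in exons_by_symbol.get(sym, [])
                if e.chrom == region.chrom
                and region.start <= e.start
                and e.end <= region.end
            }
            exons = sorted(uniq.values(), key=lambda r: (r.start, r.end))
            out.append(GeneModel(sym, region, exons, source=str(path)))
    out.sort(key=lambda g: (g.region.chrom, g.region.start))
    return out


def sample_control_regions(
    genome: Mapping[str, str],
    exclusions: Sequence[GenomicRegion],
    size: int,
    count: int = 20,
    seed: int = 0,
    max_attempts: int | None = None,
) -> list[GenomicRegion]:
    """Rejection-sample ``count`` regions of ``size`` nt avoiding all exclusions.

    A chromosome is drawn uniformly among contigs long enough to host the
    region, then a uniform start; candidates touching any exclusion interval
    are rejected.  Deterministic given ``seed``.
    """
    if size <= 0:
        raise ValueError("size must be positive")
    trees: dict[str, IntervalTree] = {}
    for reg in exclusions:
        trees.setdefault(reg.chrom, IntervalTree()).addi(reg.start, reg.end)
    chroms = [c for c, s in genome.items() if len(s) >= size]
    if not chroms:
        raise ValueError(f"no contig can host a region of {size} nt")
    rng = np.random.default_rng(seed)
    cap = max_attempts if max_attempts is not None else 1000 * count
    picked: list[GenomicRegion] = []
    attempts = 0
    while len(picked) < count:
        if attempts >= cap:
            raise RuntimeError(
                f"could not place {count} regions of {size} nt within {cap} attempts"
            )
        attempts += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, len(genome[chrom]) - size + 1))
        if chrom in trees and trees[chrom].overlap(start, start + size):
            continue
        picked.append(GenomicRegion(chrom, start, start + size))
    return picked


def match_repeat_profile(
    candidates: Sequence[RepeatProfile], target: RepeatProfile
) -> GenomicRegion:
    """Candidate region closest to ``target`` in (SINE, LINE, LTR) space.

    Euclidean distance over the three percentages; ties broken by candidate
    order (``argmin`` keeps the first minimum).
    """
    if not candidates:
        raise ValueError("empty candidate list")

    def vec(p: RepeatProfile) -> np.ndarray:
        return np.array([p.pct_sine, p.pct_line, p.pct_ltr], dtype=float)

    dists = np.array([np.linalg.norm(vec(c) - vec(target)) for c in candidates])
    return candidates[int(np.argmin(dists))].region


# ---------------------------------------------------------------------------
# writers


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(
    genes: Sequence[GeneModel], path: str | Path, source: str = "ntprobe"
) -> None:
    """Serialize gene models as GFF3 (gene + exon features, 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in genes:
            r = gene.region
            attrs = (
                f"ID=gene-{gene.symbol};Name={gene.symbol};gene={gene.symbol};"
                "gene_biotype=protein_coding"
            )
            fh.write(
                "\t".join(
                    [r.chrom, source, "gene", str(r.start + 1), str(r.end), ".", r.strand, ".", attrs]
                )
                + "\n"
            )
            for i, ex in enumerate(gene.exons, 1):
                attrs = (
                    f"ID=exon-{gene.symbol}-{i};Parent=gene-{gene.symbol};gene={gene.symbol}"
                )
                fh.write(
                    "\t".join(
                        [ex.chrom, source, "exon", str(ex.start + 1), str(ex.end), ".", r.strand, ".", attrs]
                    )
                    + "\n"
                )
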