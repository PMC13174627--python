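"""Run configuration, report manifests and design accounting.

Every report bundle embeds a hash of the configuration that produced it so
emitted numbers are traceable to a config + seed; for deterministic
backends a re-run reproduces the bundle bitwise.
"""
from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Literal, Sequence

from pydantic import BaseModel, Field

from .probing import WindowDesign, count_windows

__all__ = [
    "GenomeSpecConfig",
    "EmulatorConfig",
    "RunConfig",
    "StageRecord",
    "AuditManifest",
    "config_hash",
    "load_config",
    "validate_manifest",
    "manifest_schema",
    "describe_design",
]


class GenomeSpecConfig(BaseModel):
    n_genes: int = 2
    gene_length_range: tuple[int, int] = (3_000, 6_000)
    exon_count_range: tuple[int, int] = (3, 6)
    exon_length_range: tuple[int, int] = (100, 400)
    intergenic_length_range: tuple[int, int] = (4_000, 8_000)
    gc_content: float = 0.41
    chrom_name: str = "chrS"


class EmulatorConfig(BaseModel):
    preset: Literal["default", "apoe850_mimic"] = "default"
    noise_sd: float | None = None
    period: int | None = None
    w_sat: int | None = None
    lambda_start: float | None = None
    lambda_end: float | None = None


class RunConfig(BaseModel):
    """Everything a run needs; fully JSON-serializable."""

    seed: int = 0
    outdir: str = "ntprobe_out"
    genome: GenomeSpecConfig = GenomeSpecConfig()
    emulator: EmulatorConfig = EmulatorConfig()
    # window design
    n_min: int = 2
    n_max: int = 7
    token_size: int = 6
    # region / probe selection
    gene: str | None = None  # audited gene symbol; default: first generated gene
    validation_genes: list[str] = Field(default_factory=list)
    control_region_length: int = 2_000
    probe_offset: int | None = None  # offset within the focal region
    trace_window: int | None = None  # default: largest design window
    # classification
    position_classes: list[str] = Field(
        default_factory=lambda: ["first", "middle", "last"]
    )
    raw_threshold: float = 0.5
    normalized_threshold: float = 0.0
    # sweep
    epsilon_auc: float = 0.005
    # periodicity / stabilization
    trim: int | None = None
    detrend_window: int = 101
    m_max: int = 48
    tau: float = 0.99
    anova_period: int = 24
    rolling_window: int = 6
    stabilization_thresholds: list[float] = Field(default_factory=lambda: [0.90, 0.95])


class StageRecord(BaseModel):
    name: str
    seconds: float
    outputs: list[str]
    skipped: bool = False
    note: str = ""


class AuditManifest(BaseModel):
    config: RunConfig
    config_hash: str
    package_version: str
    stages: list[StageRecord]


def config_hash(cfg: RunConfig) -> str:
    payload = cfg.model_dump_json(exclude={"outdir"})
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path | None, **overrides) -> RunConfig:
    """Load a JSON config file (or defaults) and apply keyword overrides."""
    data = json.loads(Path(path).read_text()) if path else {}
    cfg = RunConfig.model_validate(data)
    clean = {k: v for k, v in overrides.items() if v is not None}
    if clean:
        cfg = cfg.model_copy(update=clean)
    return cfg


def validate_manifest(obj: dict) -> AuditManifest:
    """Validate a manifest dict against the published schema's model."""
    return AuditManifest.model_validate(obj)


def manifest_schema() -> dict:
    """The JSON schema the repository publishes for audit manifests."""
    with resources.files("ntprobe.schemas").joinpath(
        "audit_manifest.schema.json"
    ).open() as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# design accounting


def describe_design(
    regions: Sequence[dict],
    design: WindowDesign,
    probes_per_primary: int = 1,
    probes_per_validation: int = 5,
) -> dict:
    """Window and probe bookkeeping for a set of regions.

    ``regions`` holds dicts with keys ``name``, ``length`` and ``role``
    ("primary" or "validation").  Per region and window length the number of
    stride-1 input windows is L + W - 1; probe counts default to 1 per
    primary region and 5 per validation region.
    """
    per_region = []
    total_windows = 0
    total_bases = 0
    total_probes = 0
    for reg in regions:
        name, L, role = reg["name"], int(reg["length"]), reg.get("role", "primary")
        windows = {e.length: count_windows(L, e.length) for e in design.entries}
        probes = probes_per_primary if role == "primary" else probes_per_validation
        n_win = sum(windows.values())
        n_bases = sum(e.length * windows[e.length] for e in design.entries)
        per_region.append(
            {
                "name": name,
                "role": role,
                "length": L,
                "windows": windows,
                "total_windows": n_win,
                "total_bases": n_bases,
                "probes": probes,
            }
        )
        total_windows += n_win
        total_bases += n_bases
        total_probes += probes
    return {
        "design": [
            {"n": e.n, "tokens": e.tokens, "length": e.length} for e in design.entries
        ],
        "regions": per_region,
        "total_windows": total_windows,
        "total_bases": total_bases,
        "total_probes": total_probes,
    }
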