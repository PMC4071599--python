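"""Schema-checked CSV I/O and YAML configuration.

All tables are UTF-8 CSV with '.' decimal separators. Writers prepend a
comment line recording the package version and, when available, a hash of
the active configuration, so any output file can be traced to the exact
parameter set that produced it. Readers skip comment lines.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Dict, Iterable, Optional

import pandas as pd
import yaml

from . import __version__
from .constants import (
    DEFAULT_A260_FACTOR,
    DEFAULT_CARBOHYDRATE_RESIDUE_MW,
    DEFAULT_CHAINS_PER_LIPID,
    DEFAULT_GLYCEROL_RESIDUE_MW,
    DEFAULT_GLYCEROLIPID_SHARE,
    DEFAULT_INTENSITY_CUTOFF,
    DEFAULT_PHOSPHO_BACKBONE_MW,
    DEFAULT_PHOSPHOLIPID_SHARE,
    DEFAULT_PRESENCE_THRESHOLD,
    DEFAULT_SALT_COEFFICIENT,
    GENOME_GC,
    SEAWATER_SPECIFIC_GRAVITY,
    TRANSCRIPTOME_GC,
)

__all__ = ["PipelineConfig", "read_table", "write_table", "load_config", "config_hash"]


@dataclass
class PipelineConfig:
    """Everything the pipeline needs: input paths and open parameters."""

    inputs: Dict[str, str] = field(default_factory=dict)
    outdir: str = "outputs"
    salt_coefficient: float = DEFAULT_SALT_COEFFICIENT
    seawater_specific_gravity: float = SEAWATER_SPECIFIC_GRAVITY
    a260_factor: float = DEFAULT_A260_FACTOR
    fame_mw_basis: str = "fatty_acid"          # or 'methyl_ester'
    fame_rel_cutoff: float = DEFAULT_INTENSITY_CUTOFF
    fame_presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD
    fame_istd_compound: str = "nondecanoic_acid"
    glycerolipid_share: float = DEFAULT_GLYCEROLIPID_SHARE
    phospholipid_share: float = DEFAULT_PHOSPHOLIPID_SHARE
    glycerol_residue_mw: float = DEFAULT_GLYCEROL_RESIDUE_MW
    phospho_backbone_mw: float = DEFAULT_PHOSPHO_BACKBONE_MW
    chains_per_lipid: int = DEFAULT_CHAINS_PER_LIPID
    genome_gc: float = GENOME_GC
    transcriptome_gc: float = TRANSCRIPTOME_GC
    rna_mw_basis: str = "default"              # or 'standard'
    carbohydrate_residue_mw: float = DEFAULT_CARBOHYDRATE_RESIDUE_MW
    pool_amino_acids: bool = False
    seed: int = 0

    INPUT_TABLES = (
        "biopsies", "displacement", "standards", "assay_readings",
        "gravimetric", "fame_peaks", "fame_lipid_masses",
        "aa_total", "aa_skeleton",
    )

    def __post_init__(self) -> None:
        unknown = set(self.inputs) - set(self.INPUT_TABLES)
        if unknown:
            raise ValueError(f"unknown input table names: {sorted(unknown)}")
        if self.fame_mw_basis not in ("fatty_acid", "methyl_ester"):
            raise ValueError("fame_mw_basis must be 'fatty_acid' or 'methyl_ester'")
        if self.rna_mw_basis not in ("default", "standard"):
            raise ValueError("rna_mw_basis must be 'default' or 'standard'")


def config_hash(config: PipelineConfig) -> str:
    """Short stable hash of the analysis parameters.

    File locations (inputs, outdir) are excluded: the hash identifies the
    parameter set that produced a table, not where it was read or written.
    """
    payload = asdict(config)
    payload.pop("inputs", None)
    payload.pop("outdir", None)
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def load_config(path) -> PipelineConfig:
    """Load a YAML pipeline configuration, rejecting unknown keys."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config YAML must be a mapping")
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def write_table(
    df: pd.DataFrame, path, config: Optional[PipelineConfig] = None
) -> None:
    """Write a CSV with a provenance comment header (byte-deterministic)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = f"# spongebiomass v{__version__}"
    if config is not None:
        header += f" config={config_hash(config)}"
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, index=False)


def read_table(path, required: Optional[Iterable[str]] = None) -> pd.DataFrame:
    """Read a CSV written by write_table (or any plain CSV), checking columns."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise ValueError(f"no records in {path}") from None
    if df.empty:
        raise ValueError(f"no records in {path}")
    if required is not None:
        missing = set(required) - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    return df
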