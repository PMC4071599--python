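"""Hydrolysate amino-acid profiles.

Acid hydrolysis converts asparagine to aspartate and glutamine to glutamate,
so the measured ASX/GLX pools are split 50:50 between amide and acid forms.
Methionine and cysteine are destroyed/not derivatized and are absent by
design; tryptophan survives only partially and is carried as a lower bound.
The cellular profile is obtained by subtracting the skeleton (spongin)
profile from the whole-biomass profile; because the two are averages over
different sample sets, small negative differences can occur and are flagged
rather than silently clamped.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Tuple

import numpy as np
import pandas as pd

from .constants import AMINO_ACIDS

__all__ = [
    "split_amide_pairs",
    "mole_fractions",
    "cellular_profile",
    "normalize_percent",
    "average_samples",
    "profile_from_frame",
]


def _as_profile(profile: pd.Series) -> pd.Series:
    s = pd.Series(profile, dtype=float)
    unknown = set(s.index) - set(AMINO_ACIDS)
    if unknown:
        raise ValueError(f"unknown amino acids: {sorted(unknown)}")
    return s.reindex(AMINO_ACIDS).fillna(0.0)


def split_amide_pairs(
    asx_total: float, glx_total: float
) -> Tuple[float, float, float, float]:
    """Resolve hydrolysate ASX/GLX pools into (ASP, ASN, GLN, GLU), 50:50 each."""
    if asx_total < 0 or glx_total < 0:
        raise ValueError("ASX/GLX totals must be non-negative")
    return asx_total / 2, asx_total / 2, glx_total / 2, glx_total / 2


def mole_fractions(profile: pd.Series) -> pd.Series:
    """Per-amino-acid mole fractions (mol/mol) of a mmol/gDW profile."""
    s = _as_profile(profile)
    total = s.sum()
    if total <= 0:
        raise ValueError("all-zero amino-acid profile")
    return s / total


def cellular_profile(
    total: pd.Series, skeleton: pd.Series
) -> Tuple[pd.Series, pd.Series]:
    """Cellular fraction = whole biomass minus skeleton, species-wise.

    Returns (difference, negative_flag). Negative differences are reported
    as-is with their flag set.
    """
    t = _as_profile(total)
    k = _as_profile(skeleton)
    diff = t - k
    negative = diff < 0
    if negative.any():
        warnings.warn(
            f"negative cellular abundances for {list(diff.index[negative])} "
            "(skeleton mean exceeds whole-biomass mean)",
            stacklevel=2,
        )
    return diff, negative


def normalize_percent(profile: pd.Series) -> pd.Series:
    """Percentage composition; negative entries are excluded from the
    denominator and rendered as 0% (with a warning)."""
    s = _as_profile(profile)
    negative = s < 0
    if negative.any():
        warnings.warn(
            f"excluding negative abundances from percentages: {list(s.index[negative])}",
            stacklevel=2,
        )
    positive = s.clip(lower=0.0)
    total = positive.sum()
    if total <= 0:
        raise ValueError("no positive abundances to normalize")
    return 100.0 * positive / total


def average_samples(samples: pd.DataFrame) -> pd.DataFrame:
    """Average per-sample measurements into a mean/SD profile.

    Expects tidy columns sample_id, amino_acid, mmol_per_gDW. ASX and GLX
    rows are split 50:50 into ASP/ASN and GLN/GLU per sample before
    averaging. Returns a frame indexed in the canonical species order with
    columns mmol_per_gDW (mean) and sd.
    """
    required = {"sample_id", "amino_acid", "mmol_per_gDW"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"amino-acid table missing columns: {sorted(missing)}")
    expanded = []
    for rec in samples.itertuples(index=False):
        aa = rec.amino_acid
        if aa == "ASX":
            asp, asn, _, _ = split_amide_pairs(rec.mmol_per_gDW, 0.0)
            expanded += [
                (rec.sample_id, "ASP", asp),
                (rec.sample_id, "ASN", asn),
            ]
        elif aa == "GLX":
            _, _, gln, glu = split_amide_pairs(0.0, rec.mmol_per_gDW)
            expanded += [
                (rec.sample_id, "GLN", gln),
                (rec.sample_id, "GLU", glu),
            ]
        elif aa in AMINO_ACIDS:
            expanded.append((rec.sample_id, aa, rec.mmol_per_gDW))
        else:
            raise ValueError(f"unknown amino acid code {aa!r}")
    tidy = pd.DataFrame(expanded, columns=["sample_id", "amino_acid", "mmol_per_gDW"])
    grouped = tidy.groupby("amino_acid")["mmol_per_gDW"]
    out = pd.DataFrame(
        {"mmol_per_gDW": grouped.mean(), "sd": grouped.std(ddof=1).fillna(0.0)}
    )
    return out.reindex(AMINO_ACIDS).fillna(0.0)


def profile_from_frame(frame: pd.DataFrame, column: str = "mmol_per_gDW") -> pd.Series:
    """Extract a canonical-order abundance Series from a profile frame."""
    return _as_profile(frame[column] if column in frame else frame.squeeze())
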