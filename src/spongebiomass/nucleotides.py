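"""Nucleotide composition of DNA and RNA from GC content.

Double-stranded DNA forces fraction(G) = fraction(C) and fraction(A) =
fraction(T); the same even-ratio assumption is applied to the transcriptome
(A = U, G = C). Given the total nucleic-acid mass per gram dry weight, the
mean residue MW converts mass to moles of average nucleotide, distributed
over the four residues by their mole fractions.
"""

from __future__ import annotations

from typing import Dict, Mapping

import pandas as pd

from .constants import DNA_RESIDUE_MW, RNA_RESIDUE_MW_DEFAULT

__all__ = [
    "base_fractions",
    "mean_residue_mw",
    "residue_abundances",
    "composition_table",
]

DNA_RESIDUES = ["dAMP", "dCMP", "dGMP", "dTMP"]
RNA_RESIDUES = ["AMP", "CMP", "GMP", "UMP"]


def base_fractions(gc_fraction: float, molecule: str = "DNA") -> pd.Series:
    """Mole fractions of the four residues given a GC fraction in (0, 1)."""
    if not 0 < gc_fraction < 1:
        raise ValueError("gc_fraction must lie strictly between 0 and 1")
    gc_half = gc_fraction / 2
    at_half = (1.0 - gc_fraction) / 2
    if molecule == "DNA":
        return pd.Series(
            {"dAMP": at_half, "dCMP": gc_half, "dGMP": gc_half, "dTMP": at_half}
        )
    if molecule == "RNA":
        return pd.Series(
            {"AMP": at_half, "CMP": gc_half, "GMP": gc_half, "UMP": at_half}
        )
    raise ValueError("molecule must be 'DNA' or 'RNA'")


def mean_residue_mw(fractions: pd.Series, mw_table: Mapping[str, float]) -> float:
    """Abundance-weighted mean nucleotide MW (g/mol)."""
    fr = pd.Series(fractions, dtype=float)
    if abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    mws = pd.Series(mw_table, dtype=float).reindex(fr.index)
    if mws.isna().any() or (mws <= 0).any():
        raise ValueError("MW table must cover all residues with positive values")
    return float((fr * mws).sum())


def residue_abundances(
    total_mass_g_per_gdw: float,
    fractions: pd.Series,
    mw_table: Mapping[str, float],
) -> pd.Series:
    """Per-residue abundances in umol/gDW given the total polymer mass."""
    if total_mass_g_per_gdw < 0:
        raise ValueError("total mass must be non-negative")
    avg_mw = mean_residue_mw(fractions, mw_table)
    total_umol = total_mass_g_per_gdw / avg_mw * 1e6
    return pd.Series(fractions, dtype=float) * total_umol


def composition_table(
    molecule: str,
    gc_fraction: float,
    total_mass_g_per_gdw: float,
    mw_table: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Full composition table: residue, MW, mole fraction, umol/gDW."""
    if mw_table is None:
        mw_table = DNA_RESIDUE_MW if molecule == "DNA" else RNA_RESIDUE_MW_DEFAULT
    fractions = base_fractions(gc_fraction, molecule)
    abundances = residue_abundances(total_mass_g_per_gdw, fractions, mw_table)
    return pd.DataFrame(
        {
            "residue": fractions.index,
            "mw_g_per_mol": [mw_table[r] for r in fractions.index],
            "mole_fraction": fractions.to_numpy(),
            "umol_per_gDW": abundances.to_numpy(),
        }
    )
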