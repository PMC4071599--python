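"""Assembly of the biomass equation.

The biomass equation is the drain reaction of a genome-scale metabolic
model: the moles of each building block (amino acids, nucleotides, fatty
acids, sterols, sugar monomers) consumed to form one gram of dry biomass.
Cellular and skeleton (spongin) amino acids are kept as separate classes;
carbohydrate enters as anhydroglucose monomer equivalents; the inorganic
skeleton remainder is carried on a mass basis because no molecular species
can be assigned to it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional

import numpy as np
import pandas as pd

from .constants import AMINO_ACID_MW, DEFAULT_CARBOHYDRATE_RESIDUE_MW

__all__ = [
    "BiomassCoefficient",
    "BiomassEquation",
    "assemble",
    "mass_closure",
    "write_equation",
    "read_equation",
    "reaction_string",
]

MACRO_CLASSES = [
    "protein_aa",
    "skeleton_aa",
    "dna_nt",
    "rna_nt",
    "fatty_acid",
    "sterol",
    "carbohydrate",
    "skeleton_inorganic",
]


@dataclass(frozen=True)
class BiomassCoefficient:
    species: str
    macro_class: str
    coefficient: float  # mmol/gDW for molar entries, g/gDW for mass entries
    basis: str          # 'molar' or 'mass'
    mw: Optional[float] = None
    unresolved: bool = False


@dataclass
class BiomassEquation:
    coefficients: List[BiomassCoefficient] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {
                "species": c.species,
                "macro_class": c.macro_class,
                "coefficient": c.coefficient,
                "basis": c.basis,
                "mw_g_per_mol": c.mw if c.mw is not None else np.nan,
                "unresolved": c.unresolved,
            }
            for c in self.coefficients
        ]
        df = pd.DataFrame(
            rows,
            columns=[
                "species", "macro_class", "coefficient", "basis",
                "mw_g_per_mol", "unresolved",
            ],
        )
        order = {c: i for i, c in enumerate(MACRO_CLASSES)}
        return df.sort_values(
            ["macro_class", "species"],
            key=lambda col: col.map(order) if col.name == "macro_class" else col,
        ).reset_index(drop=True)


def _aa_coefficients(
    profile: pd.Series,
    macro_class: str,
    flags: Optional[pd.Series] = None,
    suffix: str = "",
) -> List[BiomassCoefficient]:
    coeffs = []
    for aa, mmol in profile.items():
        if flags is not None and bool(flags.get(aa, False)):
            warnings.warn(
                f"{aa} in {macro_class} is negative; carried as 0 in the equation",
                stacklevel=3,
            )
            mmol = 0.0
        coeffs.append(
            BiomassCoefficient(
                aa + suffix, macro_class, float(mmol), "molar", AMINO_ACID_MW[aa]
            )
        )
    return coeffs


def assemble(
    aa_cellular: pd.Series,
    aa_skeleton: pd.Series,
    dna_table: pd.DataFrame,
    rna_table: pd.DataFrame,
    lipid_summary: Optional[pd.DataFrame],
    carbohydrate_g_per_gdw: float,
    skeleton_inorganic_g_per_gdw: float = 0.0,
    carbohydrate_monomer_mw: float = DEFAULT_CARBOHYDRATE_RESIDUE_MW,
    aa_cellular_negative: Optional[pd.Series] = None,
    pool_amino_acids: bool = False,
) -> BiomassEquation:
    """Assemble building-block coefficients into one biomass equation.

    Amino-acid profiles are mmol/gDW; nucleotide tables come from the
    nucleotide-composition module (umol/gDW, converted here to mmol); the
    lipid summary from the FAME module (umol/gDW). Carbohydrate is converted
    to glucose-equivalent monomers; any inorganic skeleton remainder stays
    on a mass basis.
    """
    eq = BiomassEquation()
    if pool_amino_acids:
        pooled = aa_cellular.clip(lower=0.0) + aa_skeleton
        eq.coefficients += _aa_coefficients(pooled, "protein_aa")
    else:
        eq.coefficients += _aa_coefficients(
            aa_cellular, "protein_aa", aa_cellular_negative
        )
        # same metabolites, distinct sink (spongin); suffixed so species
        # labels stay unique across classes
        eq.coefficients += _aa_coefficients(aa_skeleton, "skeleton_aa", suffix="_skel")

    for table, macro_class in ((dna_table, "dna_nt"), (rna_table, "rna_nt")):
        for rec in table.itertuples(index=False):
            eq.coefficients.append(
                BiomassCoefficient(
                    rec.residue, macro_class, rec.umol_per_gDW / 1e3, "molar",
                    rec.mw_g_per_mol,
                )
            )

    if lipid_summary is None or lipid_summary.empty:
        warnings.warn("empty lipid profile; equation has a zero lipid class", stacklevel=2)
    else:
        for rec in lipid_summary.itertuples(index=False):
            cls = "sterol" if "sterol" in rec.compound_class else "fatty_acid"
            eq.coefficients.append(
                BiomassCoefficient(
                    rec.compound_id, cls, rec.mean_umol_per_gDW / 1e3, "molar",
                    rec.mw_used, unresolved=bool(rec.mw_imputed),
                )
            )

    if carbohydrate_g_per_gdw < 0:
        raise ValueError("carbohydrate mass must be non-negative")
    eq.coefficients.append(
        BiomassCoefficient(
            "glucose_equivalent", "carbohydrate",
            carbohydrate_g_per_gdw / carbohydrate_monomer_mw * 1e3, "molar",
            carbohydrate_monomer_mw,
        )
    )
    if skeleton_inorganic_g_per_gdw > 0:
        eq.coefficients.append(
            BiomassCoefficient(
                "skeleton_inorganic", "skeleton_inorganic",
                skeleton_inorganic_g_per_gdw, "mass",
            )
        )

    seen: Dict[str, str] = {}
    for c in eq.coefficients:
        if c.species in seen and seen[c.species] != c.macro_class:
            raise ValueError(
                f"species {c.species!r} appears in classes "
                f"{seen[c.species]!r} and {c.macro_class!r}"
            )
        seen.setdefault(c.species, c.macro_class)
    return eq


def mass_closure(equation: BiomassEquation) -> float:
    """Total g/gDW accounted for by the equation.

    Molar coefficients are re-multiplied by their species MW; mass-basis
    entries are added directly. Comparing the result with the summed
    measured macro-component means checks the accounting end to end.
    """
    total = 0.0
    for c in equation.coefficients:
        if c.basis == "mass":
            total += c.coefficient
        else:
            if c.mw is None:
                raise ValueError(f"molar species {c.species!r} lacks a MW")
            total += c.coefficient * 1e-3 * c.mw
    return total


def reaction_string(equation: BiomassEquation) -> str:
    """Deterministic 'a ALA + b GLY + ... -> 1 g_biomass' rendering.

    Coefficients are printed at fixed 6-decimal precision (half-even
    rounding), species sorted by class then label; zero-coefficient species
    are kept so the equation structure is explicit.
    """
    df = equation.as_frame()
    terms = [
        f"{round(rec.coefficient, 6):.6f} {rec.species}"
        for rec in df.itertuples(index=False)
    ]
    return " + ".join(terms) + " -> 1 g_biomass"


def write_equation(equation: BiomassEquation, path, fmt: str = "csv") -> None:
    """Write the equation as CSV or as a reaction string (byte-deterministic)."""
    df = equation.as_frame()
    if fmt == "csv":
        out = df.copy()
        out["coefficient"] = [f"{round(v, 6):.6f}" for v in out["coefficient"]]
        out.to_csv(path, index=False)
    elif fmt == "reaction_string":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(reaction_string(equation) + "\n")
    else:
        raise ValueError("fmt must be 'csv' or 'reaction_string'")


def read_equation(path) -> BiomassEquation:
    """Read back a CSV-format equation written by write_equation."""
    df = pd.read_csv(path)
    eq = BiomassEquation()
    for rec in df.itertuples(index=False):
        mw = None if pd.isna(rec.mw_g_per_mol) else float(rec.mw_g_per_mol)
        eq.coefficients.append(
            BiomassCoefficient(
                rec.species, rec.macro_class, float(rec.coefficient),
                rec.basis, mw, bool(rec.unresolved),
            )
        )
    return eq
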