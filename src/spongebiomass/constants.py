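"""Physical constants, molecular-weight tables and study defaults.

All masses are grams, volumes millilitres, molecular weights g/mol.
Composition values are normalized to grams of dry weight (gDW).
"""

from __future__ import annotations

WATER_MW = 18.015
METHYL_GROUP_MW = 14.027  # CH2 added on methyl esterification of a fatty acid

# Salt correction: mass of dissolved salt per gram of seawater-derived water.
# The alternative reading (specific gravity of seawater minus 1) is exposed via
# config; see docs/methods.md.
DEFAULT_SALT_COEFFICIENT = 0.035
SEAWATER_SPECIFIC_GRAVITY = 1.025

# UV absorbance at 260 nm: micrograms RNA per mL per absorbance unit.
DEFAULT_A260_FACTOR = 40.0

# GC content of the A. queenslandica genome and adult transcriptome (fractions).
GENOME_GC = 0.3114
TRANSCRIPTOME_GC = 0.3976

# Free fatty-acid molecular weights, keyed by compound label.
FATTY_ACID_MW = {
    "myristic_acid": 228.37,        # C14:0
    "pentadecanoic_acid": 242.40,   # C15:0
    "palmitic_acid": 256.42,        # C16:0
    "heptadecanoic_acid": 270.45,   # C17:0
    "octadecanoic_acid": 284.48,    # C18:0
    "nondecanoic_acid": 298.50,     # C19:0, internal standard
    "eicosenoic_acid": 310.51,      # C20:1
    "11-eicosenoic_acid": 310.51,   # C20:1w9
    "docosanoic_acid": 340.58,      # C22:0
    "erucic_acid": 338.57,          # C22:1w9
    "tricosanoic_acid": 354.61,     # C23:0
    "tetracosanoic_acid": 368.63,   # C24:0
    "nervonic_acid": 366.62,        # C24:1w9
}

STEROL_MW = {
    "cholesterol": 386.65,
    "brassicasterol": 398.66,
}


def methyl_ester_mw(fatty_acid_mw: float) -> float:
    """MW of the FAME derivative of a free fatty acid."""
    return fatty_acid_mw + METHYL_GROUP_MW


# Nucleotide residue MWs as used for the reference composition of this species
# (DNA-like values carried over to AMP/CMP/GMP; UMP differs). A standard
# polymerized-ribonucleotide table is available as an alternative basis.
DNA_RESIDUE_MW = {"dAMP": 313.0, "dCMP": 289.0, "dGMP": 329.0, "dTMP": 304.0}
RNA_RESIDUE_MW_DEFAULT = {"AMP": 313.0, "CMP": 289.0, "GMP": 329.0, "UMP": 308.0}
RNA_RESIDUE_MW_STANDARD = {"AMP": 329.21, "CMP": 305.18, "GMP": 345.21, "UMP": 306.17}

# The 18 amino acids quantifiable after acid hydrolysis (MET and CYS are
# destroyed/underivatized and are absent by design, not zero; TRP is a lower
# bound). Three-letter codes, free amino-acid MWs.
AMINO_ACIDS = [
    "ALA", "ARG", "ASP", "ASN", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]
AMINO_ACID_MW = {
    "ALA": 89.09, "ARG": 174.20, "ASP": 133.10, "ASN": 132.12,
    "GLN": 146.15, "GLU": 147.13, "GLY": 75.07, "HIS": 155.15,
    "ILE": 131.17, "LEU": 131.17, "LYS": 146.19, "PHE": 165.19,
    "PRO": 115.13, "SER": 105.09, "THR": 119.12, "TRP": 204.23,
    "TYR": 181.19, "VAL": 117.15,
}

# Glycerolipid/phospholipid backbone accounting (see docs/methods.md):
# glycerol esterified at two positions, and glycerol + phosphate for
# phospholipids (three condensations).
GLYCEROL_MW = 92.09
PHOSPHORIC_ACID_MW = 98.00
DEFAULT_GLYCEROL_RESIDUE_MW = GLYCEROL_MW - 2 * WATER_MW            # 56.06
DEFAULT_PHOSPHO_BACKBONE_MW = GLYCEROL_MW + PHOSPHORIC_ACID_MW - 3 * WATER_MW  # 136.05
DEFAULT_GLYCEROLIPID_SHARE = 0.20
DEFAULT_PHOSPHOLIPID_SHARE = 0.80
DEFAULT_CHAINS_PER_LIPID = 2

# Anhydroglucose residue for carbohydrate expressed as glucose-equivalents.
DEFAULT_CARBOHYDRATE_RESIDUE_MW = 162.0

# FAME peak-table filters.
DEFAULT_INTENSITY_CUTOFF = 5e-4     # fraction of the largest peak
DEFAULT_PRESENCE_THRESHOLD = 0.75   # unknowns must appear in > this share of samples

MACRO_COMPONENTS = ["skeleton", "lipid", "protein", "carbohydrate", "RNA", "DNA"]
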