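"""Synthetic input generator.

No raw per-biopsy data are deposited for this system, so every pipeline
stage is exercised against synthetic inputs generated with the statistical
structure the analysis assumes: a hierarchy of individuals x biopsies with
Gaussian individual effects and residuals whose total SD and
between-individual share default to the reference population values for
adult A. queenslandica; triplicate assay noise at a fixed CV; FAME peak
tables drawn lognormally around the reference compound catalogue with
arbitrary per-sample gains, sub-cutoff junk peaks and inconsistently
detected unknowns; and per-sample amino-acid tables with combined ASX/GLX
pools so the amide splitter is exercised.

Truncation at zero uses resampling, not clipping, to avoid biasing the mean
of small-mean components (DNA, RNA). All randomness flows from one
integer-seeded numpy Generator, so identical seeds give identical bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .constants import (
    DEFAULT_INTENSITY_CUTOFF,
    DEFAULT_SALT_COEFFICIENT,
    FATTY_ACID_MW,
    STEROL_MW,
)
from .lipid_fame import IDENTIFIED_CLASSES, average_identified_mw, backbone_fraction

__all__ = [
    "SimulationConfig",
    "MACRO_REFERENCE",
    "FAME_CATALOGUE",
    "AA_TOTAL_REFERENCE",
    "AA_SKELETON_REFERENCE",
    "simulate_biopsy_dataset",
    "simulate_displacement_pairs",
    "simulate_assay_readings",
    "simulate_fame_tables",
    "simulate_aa_tables",
    "simulate_bundle",
]

# Reference macro-composition of the study population:
# component -> (mean g/gDW, total SD, between-individual share %).
MACRO_REFERENCE: Dict[str, Tuple[float, float, float]] = {
    "skeleton": (0.6343, 0.0647, 58.0),
    "lipid": (0.1252, 0.0251, 54.0),
    "protein": (0.0881, 0.0082, 24.0),
    "carbohydrate": (0.0197, 0.0055, 15.0),
    "RNA": (0.0021, 0.0005, 1.0),
    "DNA": (0.0003, 0.0001, 32.0),
}

# Reference FAME compound catalogue: compound -> (class, mean umol/gDW, SD).
FAME_CATALOGUE: Dict[str, Tuple[str, float, float]] = {
    "docosanoic_acid": ("known_fa", 9.769, 4.299),
    "eicosenoic_acid": ("known_fa", 1.947, 0.579),
    "erucic_acid": ("known_fa", 1.721, 0.668),
    "heptadecanoic_acid": ("known_fa", 0.922, 0.234),
    "myristic_acid": ("known_fa", 3.957, 1.455),
    "nervonic_acid": ("known_fa", 10.090, 3.451),
    "octadecanoic_acid": ("known_fa", 62.210, 19.095),
    "palmitic_acid": ("known_fa", 98.140, 22.426),
    "pentadecanoic_acid": ("known_fa", 7.065, 2.468),
    "tetracosanoic_acid": ("known_fa", 6.769, 3.546),
    "tricosanoic_acid": ("known_fa", 1.147, 0.323),
    "11-eicosenoic_acid": ("database_fa", 5.342, 1.737),
    "U6-FA": ("unknown_fa", 1.005, 0.580),
    "U7-FA": ("unknown_fa", 5.973, 3.845),
    "U8-FA": ("unknown_fa", 2.279, 0.722),
    "U10-FA": ("unknown_fa", 3.288, 3.014),
    "UU2-FA": ("unknown_fa", 7.732, 2.805),
    "UU3-FA": ("unknown_fa", 5.669, 1.897),
    "UU4-FA": ("unknown_fa", 71.749, 17.820),
    "UU7-FA": ("unknown_fa", 0.690, 0.604),
    "UU8-FA": ("unknown_fa", 4.215, 2.155),
    "UU9-FA": ("unknown_fa", 29.843, 10.551),
    "UU11-FA": ("unknown_fa", 4.460, 1.846),
    "UU1": ("other", 1.728, 1.766),
    "UU6": ("other", 9.617, 4.268),
    "cholesterol": ("sterol", 4.706, 2.477),
    "brassicasterol": ("sterol", 7.581, 4.806),
    "UU13-sterol": ("unknown_sterol", 6.264, 3.375),
}

# Reference amino-acid profiles, mmol/gDW: whole biomass and skeleton,
# species -> (mean, SD). ASP/ASN and GLN/GLU are the already-split halves.
AA_TOTAL_REFERENCE: Dict[str, Tuple[float, float]] = {
    "ALA": (1.538, 0.565), "ARG": (0.694, 0.258), "ASP": (0.841, 0.312),
    "ASN": (0.841, 0.312), "GLN": (0.767, 0.287), "GLU": (0.767, 0.287),
    "GLY": (4.582, 1.702), "HIS": (0.110, 0.042), "ILE": (0.402, 0.149),
    "LEU": (0.597, 0.222), "LYS": (0.688, 0.268), "PHE": (0.369, 0.137),
    "PRO": (1.050, 0.387), "SER": (0.806, 0.318), "THR": (0.826, 0.304),
    "TRP": (0.089, 0.053), "TYR": (0.157, 0.060), "VAL": (0.753, 0.281),
}
AA_SKELETON_REFERENCE: Dict[str, Tuple[float, float]] = {
    "ALA": (1.257, 0.537), "ARG": (0.545, 0.226), "ASP": (0.594, 0.250),
    "ASN": (0.594, 0.250), "GLN": (0.573, 0.243), "GLU": (0.573, 0.243),
    "GLY": (4.248, 1.807), "HIS": (0.034, 0.016), "ILE": (0.176, 0.080),
    "LEU": (0.290, 0.121), "LYS": (0.442, 0.173), "PHE": (0.239, 0.102),
    "PRO": (0.916, 0.351), "SER": (0.534, 0.211), "THR": (0.559, 0.226),
    "TRP": (0.100, 0.041), "TYR": (0.066, 0.028), "VAL": (0.440, 0.177),
}

# True assay curves used when emitting raw readings (signal = slope*conc+b,
# concentrations ug/mL): component -> (slope, intercept, max standard conc,
# dilution factor, extract volume mL).
ASSAY_SETUP: Dict[str, Tuple[float, float, float, float, float]] = {
    "protein": (0.0015, 0.05, 1500.0, 10.0, 3.0),
    "carbohydrate": (0.010, 0.02, 100.0, 50.0, 6.0),
    "DNA": (10.0, 5.0, 60.0, 1.0, 3.0),
}
RNA_SETUP = {"dilution": 2.0, "volume_ml": 4.0, "a260_factor": 40.0}

ISTD_COMPOUND = "nondecanoic_acid"
ISTD_MASS_UG = 5.1


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic bundle."""

    n_individuals: int = 4
    n_biopsies: int = 5
    macro_reference: Dict[str, Tuple[float, float, float]] = field(
        default_factory=lambda: dict(MACRO_REFERENCE)
    )
    assay_cv: float = 0.03                # triplicate relative noise
    standards_cv: float = 0.01
    n_fame_samples: int = 23
    fame_catalogue: Dict[str, Tuple[str, float, float]] = field(
        default_factory=lambda: dict(FAME_CATALOGUE)
    )
    fame_gain_cv: float = 0.2             # per-sample arbitrary detector gain
    n_inconsistent_unknowns: int = 3      # unknowns present in < 75% of samples
    inconsistent_presence: float = 0.6
    n_junk_peaks: int = 3                 # sub-cutoff noise peaks per sample
    extra_signal_fraction: float = 0.175  # non-retained share of total signal
    aa_total_reference: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(AA_TOTAL_REFERENCE)
    )
    aa_skeleton_reference: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(AA_SKELETON_REFERENCE)
    )
    aa_noise_scale: float = 1.0           # multiplier on reference AA SDs
    n_aa_samples: int = 20
    n_displacement_pairs: int = 97
    displacement_ratio: float = 0.091     # gDW per mL
    displacement_ratio_sd: float = 0.012
    salt_coefficient: float = DEFAULT_SALT_COEFFICIENT
    seed: int = 0


def _truncated_normal(
    rng: np.random.Generator, mean, sd, size=None, floor: float = 0.0
) -> np.ndarray:
    """Normal draws resampled (not clipped) until strictly above `floor`."""
    out = rng.normal(mean, sd, size)
    out = np.atleast_1d(np.asarray(out, dtype=float))
    for _ in range(1000):
        bad = out <= floor
        if not bad.any():
            break
        out[bad] = rng.normal(
            np.broadcast_to(mean, out.shape)[bad],
            np.broadcast_to(sd, out.shape)[bad],
        )
    else:
        raise RuntimeError("truncated-normal resampling failed to converge")
    return out if size is not None else out


def _lognormal_from_moments(
    rng: np.random.Generator, mean: float, sd: float, size=None
) -> np.ndarray:
    if mean <= 0:
        raise ValueError("lognormal mean must be positive")
    s2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - s2 / 2
    return rng.lognormal(mu, np.sqrt(s2), size)


def simulate_biopsy_dataset(
    config: SimulationConfig, rng: np.random.Generator
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Biopsy mass records plus true per-biopsy component values.

    For each component, individual effects a_i ~ N(0, sigma2_b) and residuals
    e_ij ~ N(0, sigma2_w) are drawn with sigma2_b + sigma2_w equal to the
    configured total variance and sigma2_b its configured share; values are
    mean + a_i + e_ij, resampled while non-positive.
    """
    sponges = [f"S{i+1}" for i in range(config.n_individuals)]
    biopsies = [f"B{j+1}" for j in range(config.n_biopsies)]

    records = []
    for s in sponges:
        for b in biopsies:
            wet = _truncated_normal(rng, 2.0, 0.3)[0]
            water_frac = float(np.clip(rng.normal(0.85, 0.02), 0.7, 0.95))
            lyo = wet * (1.0 - water_frac)
            water_loss = wet - lyo
            corrected = lyo - config.salt_coefficient * water_loss
            ratio = _truncated_normal(
                rng, config.displacement_ratio, config.displacement_ratio_sd
            )[0]
            records.append(
                {
                    "sponge_id": s,
                    "biopsy_id": b,
                    "wet_mass_g": wet,
                    "lyophilized_mass_g": lyo,
                    "displacement_mL": corrected / ratio,
                }
            )
    biopsy_df = pd.DataFrame(records)

    rows = []
    for component, (mean, total_sd, share_pct) in config.macro_reference.items():
        sigma_b = total_sd * np.sqrt(share_pct / 100.0)
        sigma_w = total_sd * np.sqrt(1.0 - share_pct / 100.0)
        a = rng.normal(0.0, sigma_b, config.n_individuals) if sigma_b > 0 else np.zeros(
            config.n_individuals
        )
        for i, s in enumerate(sponges):
            vals = _truncated_normal(
                rng, mean + a[i], max(sigma_w, 1e-12), config.n_biopsies
            )
            for j, b in enumerate(biopsies):
                rows.append(
                    {
                        "component": component,
                        "sponge_id": s,
                        "biopsy_id": b,
                        "g_per_gDW": float(vals[j]),
                    }
                )
    return biopsy_df, pd.DataFrame(rows)


def simulate_displacement_pairs(
    config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """(displacement volume, corrected dry mass) pairs for the conversion factor."""
    volumes = rng.uniform(5.0, 30.0, config.n_displacement_pairs)
    ratios = _truncated_normal(
        rng, config.displacement_ratio, config.displacement_ratio_sd,
        config.n_displacement_pairs,
    )
    return pd.DataFrame(
        {"displacement_mL": volumes, "corrected_dry_mass_g": volumes * ratios}
    )


def simulate_assay_readings(
    measurements: pd.DataFrame,
    biopsy_df: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Invert the assay arithmetic: true values -> standards + raw readings.

    Returns (standards, readings). Protein/carbohydrate/DNA go through their
    configured true curves; RNA is emitted as A260 triplicates. Skeleton and
    lipid are gravimetric and are not assayed here.
    """
    dry_mass = {
        (r.sponge_id, r.biopsy_id): r.lyophilized_mass_g
        - config.salt_coefficient * (r.wet_mass_g - r.lyophilized_mass_g)
        for r in biopsy_df.itertuples(index=False)
    }

    std_rows = []
    for component, (slope, intercept, cmax, _, _) in ASSAY_SETUP.items():
        for conc in np.linspace(0.0, cmax, 6):
            signal = (slope * conc + intercept) * (
                1.0 + rng.normal(0.0, config.standards_cv)
            )
            std_rows.append(
                {"component": component, "concentration": conc, "signal": signal}
            )
    standards = pd.DataFrame(std_rows)

    read_rows = []
    for rec in measurements.itertuples(index=False):
        key = (rec.sponge_id, rec.biopsy_id)
        dm = dry_mass[key]
        if rec.component in ASSAY_SETUP:
            slope, intercept, _, dilution, volume = ASSAY_SETUP[rec.component]
            conc_extract = rec.g_per_gDW * 1e6 * dm / volume / dilution
            true_signal = slope * conc_extract + intercept
        elif rec.component == "RNA":
            dilution = RNA_SETUP["dilution"]
            volume = RNA_SETUP["volume_ml"]
            true_signal = (
                rec.g_per_gDW * 1e6 * dm
                / (volume * RNA_SETUP["a260_factor"] * dilution)
            )
        else:
            continue  # gravimetric components
        s1, s2, s3 = true_signal * (1.0 + rng.normal(0.0, config.assay_cv, 3))
        read_rows.append(
            {
                "component": rec.component,
                "sponge_id": rec.sponge_id,
                "biopsy_id": rec.biopsy_id,
                "s1": s1, "s2": s2, "s3": s3,
                "dilution": dilution,
                "volume_mL": volume,
                "dry_mass_g": dm,
            }
        )
    return standards, pd.DataFrame(read_rows)


def simulate_gravimetric(
    measurements: pd.DataFrame,
    biopsy_df: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Gravimetric records (skeleton residue and lipid extract masses)."""
    dry_mass = {
        (r.sponge_id, r.biopsy_id): r.lyophilized_mass_g
        - config.salt_coefficient * (r.wet_mass_g - r.lyophilized_mass_g)
        for r in biopsy_df.itertuples(index=False)
    }
    rows = []
    for rec in measurements.itertuples(index=False):
        if rec.component not in ("skeleton", "lipid"):
            continue
        dm = dry_mass[(rec.sponge_id, rec.biopsy_id)]
        rows.append(
            {
                "component": rec.component,
                "sponge_id": rec.sponge_id,
                "biopsy_id": rec.biopsy_id,
                "component_mass_g": rec.g_per_gDW * dm,
                "dry_mass_g": dm,
            }
        )
    return pd.DataFrame(rows)


def _catalogue_mw_map(config: SimulationConfig) -> Dict[str, float]:
    mw_map: Dict[str, float] = {}
    for cid, (cls, _, _) in config.fame_catalogue.items():
        if cls in IDENTIFIED_CLASSES:
            mw = FATTY_ACID_MW.get(cid) or STEROL_MW.get(cid)
            if mw is None:
                raise ValueError(f"no MW on record for identified compound {cid!r}")
            mw_map[cid] = mw
    return mw_map


def simulate_fame_tables(
    config: SimulationConfig, rng: np.random.Generator
) -> Tuple[pd.DataFrame, pd.DataFrame, Dict[str, float]]:
    """FAME peak tables plus matching per-sample lipid masses.

    Per-compound true abundances are lognormal around the catalogue moments;
    areas are mass-proportional (abundance x MW, unknowns at the mean
    identified MW) times an arbitrary per-sample gain. The per-sample lipid
    mass is set so that the backbone-corrected chain mass equals the summed
    catalogue compound mass, making the quantification exactly invertible.
    Inconsistent unknowns (below the presence rule) and sub-cutoff junk
    peaks are added to exercise the filters.

    Returns (peaks, lipid_masses, true_f_b_info).
    """
    mw_map = _catalogue_mw_map(config)
    avg_mw = average_identified_mw(mw_map)
    fa_mws = [FATTY_ACID_MW[c] for c in mw_map if c in FATTY_ACID_MW]
    mean_fa_mw = float(np.mean(fa_mws))
    f_b = backbone_fraction(mean_fa_mw=mean_fa_mw)

    peak_rows = []
    lipid_rows = []
    extra_ids = [f"X{k+1}-FA" for k in range(config.n_inconsistent_unknowns)]
    for s in range(config.n_fame_samples):
        sample_id = f"F{s+1}"
        gain = _lognormal_from_moments(rng, 1.0, config.fame_gain_cv)
        masses = {}
        for cid, (cls, mean, sd) in config.fame_catalogue.items():
            mol = _lognormal_from_moments(rng, mean, sd)
            mw = mw_map.get(cid, avg_mw)
            masses[cid] = float(mol * mw)  # ug/gDW
        retained_mass = sum(masses.values())
        lipid_rows.append(
            {
                "sample_id": sample_id,
                "lipid_g_per_gDW": retained_mass * 1e-6 / (1.0 - f_b),
            }
        )
        for cid, (cls, _, _) in config.fame_catalogue.items():
            peak_rows.append(
                {
                    "sample_id": sample_id,
                    "compound_id": cid,
                    "compound_class": cls,
                    "area": gain * masses[cid],
                    "mw": mw_map.get(cid, np.nan),
                }
            )
        # internal standard
        peak_rows.append(
            {
                "sample_id": sample_id,
                "compound_id": ISTD_COMPOUND,
                "compound_class": "known_fa",
                "area": gain * ISTD_MASS_UG * 20.0,
                "mw": FATTY_ACID_MW[ISTD_COMPOUND],
            }
        )
        # inconsistently detected unknowns carrying the non-retained signal
        if config.n_inconsistent_unknowns and config.extra_signal_fraction > 0:
            extra_total = retained_mass * config.extra_signal_fraction / (
                1.0 - config.extra_signal_fraction
            )
            per_extra = extra_total / (
                config.n_inconsistent_unknowns * config.inconsistent_presence
            )
            for xid in extra_ids:
                if rng.random() < config.inconsistent_presence:
                    peak_rows.append(
                        {
                            "sample_id": sample_id,
                            "compound_id": xid,
                            "compound_class": "unknown_fa",
                            "area": gain * per_extra * rng.uniform(0.7, 1.3),
                            "mw": np.nan,
                        }
                    )
        # sub-cutoff junk
        max_area = gain * max(masses.values())
        for k in range(config.n_junk_peaks):
            peak_rows.append(
                {
                    "sample_id": sample_id,
                    "compound_id": f"junk{k+1}-{sample_id}",
                    "compound_class": "unknown_fa",
                    "area": rng.uniform(0.05, 0.9)
                    * DEFAULT_INTENSITY_CUTOFF * max_area,
                    "mw": np.nan,
                }
            )
    info = {"f_b": f_b, "mean_fa_mw": mean_fa_mw, "avg_identified_mw": avg_mw}
    return pd.DataFrame(peak_rows), pd.DataFrame(lipid_rows), info


def simulate_aa_tables(
    config: SimulationConfig, rng: np.random.Generator
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample amino-acid tables (whole biomass, skeleton), mmol/gDW.

    ASX/GLX are emitted combined (the sum of the reference amide/acid
    halves, which covary perfectly because the split is deterministic) so
    downstream code must run the amide splitter.
    """

    def one_table(reference: Dict[str, Tuple[float, float]], prefix: str) -> pd.DataFrame:
        rows = []
        for i in range(config.n_aa_samples):
            sample_id = f"{prefix}{i+1}"
            for aa, (mean, sd) in reference.items():
                if aa in ("ASN", "GLU"):
                    continue  # emitted via the combined pools below
                if aa == "ASP":
                    label, m, s = "ASX", 2 * mean, 2 * sd
                elif aa == "GLN":
                    label, m, s = "GLX", 2 * mean, 2 * sd
                else:
                    label, m, s = aa, mean, sd
                s_eff = s * config.aa_noise_scale
                value = (
                    float(_truncated_normal(rng, m, s_eff)[0]) if s_eff > 0 else m
                )
                rows.append(
                    {"sample_id": sample_id, "amino_acid": label, "mmol_per_gDW": value}
                )
        return pd.DataFrame(rows)

    total = one_table(config.aa_total_reference, "T")
    skeleton = one_table(config.aa_skeleton_reference, "K")
    return total, skeleton


def simulate_bundle(config: SimulationConfig, outdir) -> Dict[str, Path]:
    """Write the full synthetic input bundle plus a ground-truth YAML.

    Returns a name -> path map of everything written. Identical config and
    seed give byte-identical files.
    """
    from .io import write_table  # local import to avoid a cycle

    rng = np.random.default_rng(config.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    biopsy_df, measurements = simulate_biopsy_dataset(config, rng)
    displacement = simulate_displacement_pairs(config, rng)
    standards, readings = simulate_assay_readings(measurements, biopsy_df, config, rng)
    gravimetric = simulate_gravimetric(measurements, biopsy_df, config, rng)
    fame_peaks, fame_lipids, fame_info = simulate_fame_tables(config, rng)
    aa_total, aa_skeleton = simulate_aa_tables(config, rng)

    paths: Dict[str, Path] = {}
    tables = {
        "biopsies": biopsy_df,
        "true_measurements": measurements,
        "displacement": displacement,
        "standards": standards,
        "assay_readings": readings,
        "gravimetric": gravimetric,
        "fame_peaks": fame_peaks,
        "fame_lipid_masses": fame_lipids,
        "aa_total": aa_total,
        "aa_skeleton": aa_skeleton,
    }
    for name, df in tables.items():
        path = outdir / f"{name}.csv"
        write_table(df, path)
        paths[name] = path

    truth = {
        "seed": config.seed,
        "n_individuals": config.n_individuals,
        "n_biopsies": config.n_biopsies,
        "macro_reference": {
            k: {"mean": v[0], "sd": v[1], "between_share_pct": v[2]}
            for k, v in config.macro_reference.items()
        },
        "displacement_ratio": config.displacement_ratio,
        "displacement_ratio_sd": config.displacement_ratio_sd,
        "fame": {
            "f_b": float(fame_info["f_b"]),
            "mean_fa_mw": float(fame_info["mean_fa_mw"]),
            "catalogue_mean_umol_per_gDW": {
                k: v[1] for k, v in config.fame_catalogue.items()
            },
        },
    }
    truth_path = outdir / "ground_truth.yaml"
    with open(truth_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(truth, fh, sort_keys=True)
    paths["ground_truth"] = truth_path
    return paths
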