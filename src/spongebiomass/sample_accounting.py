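"""Dry-weight bookkeeping for sponge biopsies.

Biopsies are weighed wet, lyophilized and reweighed. Because sponge tissue is
saturated with seawater, the lyophilized mass still contains the salt that was
dissolved in the evaporated water; the salt mass is estimated from the water
loss and subtracted. A displacement-volume to dry-weight conversion factor
relates live sponge volume to dry biomass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

import numpy as np
import pandas as pd

from .constants import DEFAULT_SALT_COEFFICIENT

__all__ = [
    "ConversionFactor",
    "correct_for_salt",
    "displacement_conversion",
    "mass_to_volume",
    "skeleton_fraction",
    "process_biopsy_table",
]


@dataclass(frozen=True)
class ConversionFactor:
    """Grams of dry sponge per mL of displacement volume."""

    mean_gdw_per_ml: float
    sd: float
    n: int


def correct_for_salt(
    lyophilized_mass: float,
    water_loss: float,
    salt_coefficient: float = DEFAULT_SALT_COEFFICIENT,
) -> float:
    """Subtract the residual sea-salt mass from a lyophilized dry mass.

    Parameters
    ----------
    lyophilized_mass : grams after freeze-drying.
    water_loss : grams of water evaporated (wet mass minus lyophilized mass).
    salt_coefficient : grams of salt carried per gram of seawater-derived
        water, default 0.035. The alternative reading (seawater specific
        gravity minus one, ~0.025) can be passed instead.

    Returns
    -------
    Salt-corrected dry mass in grams.

    Raises
    ------
    ValueError if the implied salt mass meets or exceeds the lyophilized mass
    (an implausible record).
    """
    if lyophilized_mass <= 0:
        raise ValueError("lyophilized_mass must be positive")
    if water_loss < 0:
        raise ValueError("water_loss must be non-negative")
    if not 0 <= salt_coefficient < 1:
        raise ValueError("salt_coefficient must lie in [0, 1)")
    corrected = lyophilized_mass - water_loss * salt_coefficient
    if corrected <= 0:
        raise ValueError(
            f"salt mass {water_loss * salt_coefficient:.4g} g >= lyophilized mass "
            f"{lyophilized_mass:.4g} g; implausible record"
        )
    return corrected


def displacement_conversion(
    records: Iterable[Tuple[float, float]],
) -> ConversionFactor:
    """Estimate gDW per mL of displacement from (volume, dry mass) pairs.

    The estimator is the mean of per-sample mass/volume ratios with the
    sample SD of those ratios (n-1 denominator) — not a regression through
    the origin — so the spread of the factor itself is reported.
    """
    pairs = list(records)
    if len(pairs) < 2:
        raise ValueError("need at least 2 (volume, mass) records")
    volumes = np.asarray([p[0] for p in pairs], dtype=float)
    masses = np.asarray([p[1] for p in pairs], dtype=float)
    if np.any(volumes <= 0) or np.any(masses <= 0):
        raise ValueError("volumes and masses must all be positive")
    ratios = masses / volumes
    return ConversionFactor(
        mean_gdw_per_ml=float(np.mean(ratios)),
        sd=float(np.std(ratios, ddof=1)),
        n=len(pairs),
    )


def mass_to_volume(mass: float, specific_gravity: float) -> float:
    """Convert a weighed reagent mass (g) to a volume (mL) via its specific gravity."""
    if mass < 0:
        raise ValueError("mass must be non-negative")
    if specific_gravity <= 0:
        raise ValueError("specific_gravity must be positive")
    return mass / specific_gravity


def skeleton_fraction(skeleton_dry_mass: float, total_dry_mass: float) -> float:
    """Fraction of total dry mass that is SDS-resistant skeleton (spicules + spongin)."""
    if skeleton_dry_mass <= 0:
        raise ValueError("skeleton_dry_mass must be positive")
    if skeleton_dry_mass > total_dry_mass:
        raise ValueError("skeleton dry mass exceeds total dry mass")
    return skeleton_dry_mass / total_dry_mass


def process_biopsy_table(
    biopsies: pd.DataFrame,
    salt_coefficient: float = DEFAULT_SALT_COEFFICIENT,
) -> pd.DataFrame:
    """Augment a biopsy mass table with water loss and salt-corrected dry mass.

    Expects columns sponge_id, biopsy_id, wet_mass_g, lyophilized_mass_g and
    optionally displacement_mL; returns a copy with water_loss_g and
    corrected_dry_mass_g appended.
    """
    required = {"sponge_id", "biopsy_id", "wet_mass_g", "lyophilized_mass_g"}
    missing = required - set(biopsies.columns)
    if missing:
        raise ValueError(f"biopsy table missing columns: {sorted(missing)}")
    out = biopsies.copy()
    out["water_loss_g"] = out["wet_mass_g"] - out["lyophilized_mass_g"]
    if (out["water_loss_g"] < 0).any():
        bad = out.loc[out["water_loss_g"] < 0, ["sponge_id", "biopsy_id"]]
        raise ValueError(f"wet mass below lyophilized mass for records:\n{bad}")
    out["corrected_dry_mass_g"] = [
        correct_for_salt(m, w, salt_coefficient)
        for m, w in zip(out["lyophilized_mass_g"], out["water_loss_g"])
    ]
    return out
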