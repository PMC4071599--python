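"""Colorimetric / UV assay quantification.

Standard curves (Bradford protein against BSA, Hoechst DNA against calf
thymus DNA, phenol-sulfuric carbohydrate against glucose) are fit by ordinary
least squares; triplicate readings are averaged, back-calculated through the
curve, scaled by dilution and reaction volume, and normalized to the biopsy's
salt-corrected dry mass. RNA is quantified directly from A260. Outputs are
g/gDW; curve concentrations are ug/mL throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .constants import DEFAULT_A260_FACTOR

__all__ = [
    "StandardCurve",
    "ComponentSummary",
    "fit_standard_curve",
    "quantify_component",
    "rna_from_a260",
    "summarize_component",
    "quantify_reading_table",
    "summary_table",
]

UG_PER_G = 1e6


@dataclass(frozen=True)
class StandardCurve:
    """OLS line signal = slope * concentration + intercept."""

    slope: float
    intercept: float
    r_squared: float
    signal_min: float
    signal_max: float

    def concentration(self, signal: float) -> float:
        return (signal - self.intercept) / self.slope


@dataclass(frozen=True)
class ComponentSummary:
    component: str
    mean: float
    sd: float
    se: float
    cv_percent: float
    n: int
    cv_undefined: bool = False


def fit_standard_curve(points: Iterable[Tuple[float, float]]) -> StandardCurve:
    """Fit an OLS standard curve to (concentration ug/mL, signal) points."""
    pts = list(points)
    if len(pts) < 3:
        raise ValueError("need at least 3 standard points")
    conc = np.asarray([p[0] for p in pts], dtype=float)
    sig = np.asarray([p[1] for p in pts], dtype=float)
    if np.unique(conc).size < 2:
        raise ValueError("standard concentrations are all identical; cannot fit")
    res = stats.linregress(conc, sig)
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        signal_min=float(sig.min()),
        signal_max=float(sig.max()),
    )


def quantify_component(
    signals: Sequence[float],
    curve: StandardCurve,
    dilution_factor: float,
    extract_volume_ml: float,
    dry_mass_g: float,
) -> Tuple[float, bool]:
    """Back-calculate one biopsy's component content in g/gDW.

    Triplicate signals are averaged before back-calculation. A negative
    back-calculated concentration (signal below the curve intercept) is
    clamped to zero and flagged so population summaries stay computable.

    Returns (value in g/gDW, clamped flag).
    """
    if len(signals) != 3:
        raise ValueError("exactly 3 triplicate signals required")
    if dilution_factor < 1:
        raise ValueError("dilution_factor must be >= 1")
    if extract_volume_ml <= 0 or dry_mass_g <= 0:
        raise ValueError("extract volume and dry mass must be positive")
    mean_signal = float(np.mean(signals))
    if not (curve.signal_min <= mean_signal <= curve.signal_max):
        warnings.warn(
            f"mean signal {mean_signal:.4g} outside standard-curve range "
            f"[{curve.signal_min:.4g}, {curve.signal_max:.4g}]",
            stacklevel=2,
        )
    conc = curve.concentration(mean_signal) * dilution_factor  # ug/mL in extract
    clamped = False
    if conc < 0:
        warnings.warn("negative back-calculated concentration clamped to 0", stacklevel=2)
        conc = 0.0
        clamped = True
    ug_per_g = conc * extract_volume_ml / dry_mass_g
    return ug_per_g / UG_PER_G, clamped


def rna_from_a260(
    a260: float,
    conversion: float = DEFAULT_A260_FACTOR,
    dilution_factor: float = 1.0,
    extract_volume_ml: float = 1.0,
    dry_mass_g: float = 1.0,
) -> float:
    """RNA in g/gDW from a 260 nm absorbance reading.

    conversion is ug RNA per mL per absorbance unit (default 40).
    """
    if a260 < 0:
        raise ValueError("a260 must be non-negative")
    ug_per_g = a260 * conversion * dilution_factor * extract_volume_ml / dry_mass_g
    return ug_per_g / UG_PER_G


def summarize_component(values: Sequence[float], component: str = "") -> ComponentSummary:
    """Sample mean, SD (n-1), SE and CV% of per-biopsy composition values."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 1:
        raise ValueError("need at least one value")
    if np.any(vals < 0):
        raise ValueError("composition values must be non-negative")
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    se = sd / np.sqrt(vals.size)
    cv_undefined = mean == 0 and sd > 0
    if cv_undefined:
        warnings.warn(f"CV undefined for {component!r}: zero mean, nonzero SD", stacklevel=2)
        cv = float("nan")
    else:
        cv = 100.0 * sd / mean if mean > 0 else 0.0
    return ComponentSummary(component, mean, sd, float(se), cv, int(vals.size), cv_undefined)


def quantify_reading_table(
    readings: pd.DataFrame,
    curves: Dict[str, StandardCurve],
    a260_factor: float = DEFAULT_A260_FACTOR,
) -> pd.DataFrame:
    """Quantify a tidy assay-reading table into per-biopsy g/gDW values.

    Expected columns: component, sponge_id, biopsy_id, s1, s2, s3, dilution,
    volume_mL, dry_mass_g. Components named 'RNA' are treated as A260
    readings (the mean of the triplicate absorbances); all others go through
    their fitted standard curve in `curves`.
    """
    required = {
        "component", "sponge_id", "biopsy_id", "s1", "s2", "s3",
        "dilution", "volume_mL", "dry_mass_g",
    }
    missing = required - set(readings.columns)
    if missing:
        raise ValueError(f"reading table missing columns: {sorted(missing)}")
    rows = []
    for rec in readings.itertuples(index=False):
        signals = [rec.s1, rec.s2, rec.s3]
        if rec.component == "RNA":
            value = rna_from_a260(
                float(np.mean(signals)), a260_factor, rec.dilution,
                rec.volume_mL, rec.dry_mass_g,
            )
            clamped = False
        else:
            if rec.component not in curves:
                raise ValueError(f"no standard curve for component {rec.component!r}")
            value, clamped = quantify_component(
                signals, curves[rec.component], rec.dilution,
                rec.volume_mL, rec.dry_mass_g,
            )
        rows.append(
            {
                "component": rec.component,
                "sponge_id": rec.sponge_id,
                "biopsy_id": rec.biopsy_id,
                "g_per_gDW": value,
                "clamped": clamped,
            }
        )
    return pd.DataFrame(rows)


def summary_table(measurements: pd.DataFrame) -> pd.DataFrame:
    """Population summary per macro-component (mean, SD, SE, CV%, n)."""
    rows = []
    for component, grp in measurements.groupby("component", sort=False):
        s = summarize_component(grp["g_per_gDW"].to_numpy(), component)
        rows.append(
            {
                "component": s.component,
                "mean_g_per_gDW": s.mean,
                "sd": s.sd,
                "se": s.se,
                "cv_percent": s.cv_percent,
                "n": s.n,
            }
        )
    return pd.DataFrame(rows)
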