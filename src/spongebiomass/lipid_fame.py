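"""FAME peak-table processing: from GC-MS peak areas to fatty-acid and sterol
abundances in umol/gDW.

The procedure mirrors standard practice for whole-lipid FAME profiling of an
uncharacterized lipidome:

1. drop peaks below a relative intensity cut-off (default 0.05% of the
   largest peak in the sample);
2. keep compounds identified against standards or a spectral database
   unconditionally; keep unknowns only if present in more than 75% of
   samples (cross-sample consistency);
3. subtract the glycerol/phosphate backbone mass fraction from the
   gravimetric lipid mass (glycerolipid:phospholipid assumed 20:80),
   since FAME signal reflects acyl chains and sterols, not backbones;
4. normalize peak areas to the total retained signal per sample (areas are
   treated as mass-proportional) and convert to moles with the compound MW,
   imputing the mean identified MW for unknowns.

Peak tables arrive pre-annotated (compound_id, compound_class, area, mw);
spectral deconvolution and identification are upstream of this module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Set

import numpy as np
import pandas as pd

from .constants import (
    DEFAULT_CHAINS_PER_LIPID,
    DEFAULT_GLYCEROL_RESIDUE_MW,
    DEFAULT_GLYCEROLIPID_SHARE,
    DEFAULT_INTENSITY_CUTOFF,
    DEFAULT_PHOSPHO_BACKBONE_MW,
    DEFAULT_PHOSPHOLIPID_SHARE,
    DEFAULT_PRESENCE_THRESHOLD,
)

__all__ = [
    "LipidProfile",
    "IDENTIFIED_CLASSES",
    "UNKNOWN_CLASSES",
    "apply_intensity_cutoff",
    "consistency_filter",
    "average_identified_mw",
    "backbone_fraction",
    "quantify_lipids",
    "coverage",
]

# Compounds confirmed with standards or matched in a spectral database carry a
# molecular weight; unknowns (classified from fragmentation patterns) do not.
IDENTIFIED_CLASSES = {"known_fa", "database_fa", "sterol"}
UNKNOWN_CLASSES = {"unknown_fa", "unknown_sterol", "other"}

PEAK_COLUMNS = {"sample_id", "compound_id", "compound_class", "area"}


@dataclass
class LipidProfile:
    """Aggregated lipid composition across samples."""

    summary: pd.DataFrame       # compound_id, compound_class, mean/sd umol/gDW, mw_used
    per_sample: pd.DataFrame    # sample_id, compound_id, umol_per_gDW
    coverage_fraction: float    # retained share of total pre-filter signal


def _check_peaks(peaks: pd.DataFrame) -> None:
    missing = PEAK_COLUMNS - set(peaks.columns)
    if missing:
        raise ValueError(f"peak table missing columns: {sorted(missing)}")
    if (peaks["area"] < 0).any():
        raise ValueError("peak areas must be non-negative")


def apply_intensity_cutoff(
    peaks: pd.DataFrame,
    rel_cutoff: float = DEFAULT_INTENSITY_CUTOFF,
    istd_compound: Optional[str] = None,
) -> pd.DataFrame:
    """Drop, per sample, peaks below rel_cutoff x the largest non-ISTD peak.

    The internal standard is never the reference maximum and is always
    retained (it is needed for QC, not composition). Idempotent.
    """
    _check_peaks(peaks)
    if not 0 < rel_cutoff < 1:
        raise ValueError("rel_cutoff must lie in (0, 1)")
    if peaks.empty:
        raise ValueError("empty peak table")

    kept = []
    for sample_id, grp in peaks.groupby("sample_id", sort=False):
        is_istd = (
            grp["compound_id"] == istd_compound
            if istd_compound is not None
            else pd.Series(False, index=grp.index)
        )
        composition = grp.loc[~is_istd]
        if composition.empty:
            kept.append(grp)
            continue
        threshold = rel_cutoff * composition["area"].max()
        kept.append(grp.loc[is_istd | (grp["area"] >= threshold)])
    return pd.concat(kept, ignore_index=True)


def consistency_filter(
    peaks: pd.DataFrame,
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
    istd_compound: Optional[str] = None,
) -> Set[str]:
    """Retained compound ids after the cross-sample presence rule.

    Identified compounds (standard or database match) pass unconditionally;
    unknowns must be present — post-cutoff — in strictly more than
    `presence_threshold` of the samples. Expects the post-cutoff tidy table
    covering all samples.
    """
    _check_peaks(peaks)
    n_samples = peaks["sample_id"].nunique()
    if n_samples < 2:
        raise ValueError("consistency filter needs at least 2 samples")
    retained: Set[str] = set()
    for compound_id, grp in peaks.groupby("compound_id", sort=False):
        if compound_id == istd_compound:
            continue
        cls = grp["compound_class"].iloc[0]
        if cls in IDENTIFIED_CLASSES:
            retained.add(compound_id)
        elif cls in UNKNOWN_CLASSES:
            if grp["sample_id"].nunique() / n_samples > presence_threshold:
                retained.add(compound_id)
        else:
            raise ValueError(f"unrecognized compound_class {cls!r} for {compound_id!r}")
    return retained


def average_identified_mw(mw_map: Mapping[str, float]) -> float:
    """Mean MW of all identified FAs and sterols; imputed for unknowns."""
    mws = [v for v in mw_map.values() if v and np.isfinite(v)]
    if not mws:
        raise ValueError("no identified molecular weights to average")
    return float(np.mean(mws))


def backbone_fraction(
    glycerolipid_share: float = DEFAULT_GLYCEROLIPID_SHARE,
    phospholipid_share: float = DEFAULT_PHOSPHOLIPID_SHARE,
    mean_fa_mw: float = 270.0,
    chains_per_lipid: int = DEFAULT_CHAINS_PER_LIPID,
    glycerol_residue_mw: float = DEFAULT_GLYCEROL_RESIDUE_MW,
    phospho_backbone_mw: float = DEFAULT_PHOSPHO_BACKBONE_MW,
) -> float:
    """Mass fraction of the lipid extract attributed to glycerol/phosphate backbones.

    Lipid classes are weighted by mole share; each average molecule carries
    `chains_per_lipid` acyl chains of `mean_fa_mw` plus its class backbone
    residue, so

        f_b = sum(share_c * B_c) / sum(share_c * (B_c + k * M_fa)).

    With the default 20:80 glycerolipid:phospholipid split this lands near
    0.18 for typical acyl-chain MWs.
    """
    if not np.isclose(glycerolipid_share + phospholipid_share, 1.0):
        raise ValueError("class shares must sum to 1")
    if mean_fa_mw <= 0:
        raise ValueError("mean_fa_mw must be positive")
    shares = np.array([glycerolipid_share, phospholipid_share])
    backbones = np.array([glycerol_residue_mw, phospho_backbone_mw])
    chain_mass = chains_per_lipid * mean_fa_mw
    numerator = float(np.dot(shares, backbones))
    denominator = float(np.dot(shares, backbones + chain_mass))
    return numerator / denominator


def quantify_lipids(
    peaks: pd.DataFrame,
    lipid_g_per_gdw: Mapping[str, float],
    f_b: float,
    mw_map: Mapping[str, float],
    retained: Set[str],
    istd_compound: Optional[str] = None,
) -> LipidProfile:
    """Convert retained peak areas into umol/gDW per compound.

    Per sample: abundance_i = (area_i / sum_j area_j) * lipid * (1 - f_b) / MW_i
    with the sums over retained compounds only (post-filter renormalization,
    so retained abundances close exactly on the backbone-corrected lipid
    mass). Unknown-MW compounds get the mean identified MW.
    """
    _check_peaks(peaks)
    if not retained:
        raise ValueError("empty retained compound set")
    avg_mw = average_identified_mw(mw_map)

    def compound_mw(cid: str) -> float:
        mw = mw_map.get(cid)
        return float(mw) if mw and np.isfinite(mw) else avg_mw

    rows = []
    for sample_id, grp in peaks.groupby("sample_id", sort=False):
        if sample_id not in lipid_g_per_gdw:
            warnings.warn(f"no lipid mass for sample {sample_id!r}; skipped", stacklevel=2)
            continue
        sel = grp[grp["compound_id"].isin(retained) & (grp["compound_id"] != istd_compound)]
        total_area = sel["area"].sum()
        if total_area <= 0:
            warnings.warn(f"no retained signal in sample {sample_id!r}; skipped", stacklevel=2)
            continue
        chain_mass_g = lipid_g_per_gdw[sample_id] * (1.0 - f_b)
        for rec in sel.itertuples(index=False):
            mw = compound_mw(rec.compound_id)
            umol = (rec.area / total_area) * chain_mass_g / mw * 1e6
            rows.append(
                {
                    "sample_id": sample_id,
                    "compound_id": rec.compound_id,
                    "compound_class": rec.compound_class,
                    "umol_per_gDW": umol,
                    "mw_used": mw,
                }
            )
    per_sample = pd.DataFrame(rows)
    if per_sample.empty:
        raise ValueError("no samples could be quantified")

    # Absent-in-sample retained compounds count as 0 for the cross-sample stats.
    n_samples = per_sample["sample_id"].nunique()
    summary_rows = []
    for cid, grp in per_sample.groupby("compound_id", sort=False):
        values = np.zeros(n_samples)
        values[: len(grp)] = grp["umol_per_gDW"].to_numpy()
        summary_rows.append(
            {
                "compound_id": cid,
                "compound_class": grp["compound_class"].iloc[0],
                "mean_umol_per_gDW": float(values.mean()),
                "sd_umol_per_gDW": float(values.std(ddof=1)) if n_samples > 1 else 0.0,
                "n_samples_detected": len(grp),
                "mw_used": grp["mw_used"].iloc[0],
                "mw_imputed": cid not in mw_map
                or not (mw_map.get(cid) and np.isfinite(mw_map[cid])),
            }
        )
    summary = pd.DataFrame(summary_rows)
    cov = coverage(retained, peaks, istd_compound)
    return LipidProfile(summary=summary, per_sample=per_sample, coverage_fraction=cov)


def coverage(
    retained: Set[str],
    all_peaks: pd.DataFrame,
    istd_compound: Optional[str] = None,
) -> float:
    """Share of total pre-filter signal captured by the retained compounds.

    Computed per sample as retained area over total area (internal standard
    excluded from both) and averaged across samples.
    """
    _check_peaks(all_peaks)
    fractions = []
    for _, grp in all_peaks.groupby("sample_id", sort=False):
        sel = grp[grp["compound_id"] != istd_compound]
        total = sel["area"].sum()
        if total <= 0:
            continue
        kept = sel.loc[sel["compound_id"].isin(retained), "area"].sum()
        fractions.append(kept / total)
    if not fractions:
        raise ValueError("no samples with positive signal")
    return float(np.mean(fractions))
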