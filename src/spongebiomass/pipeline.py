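"""End-to-end pipeline: accounting -> assays -> building blocks -> equation.

Each stage is a plain function taking/returning DataFrames so it can be used
from Python; `run_pipeline` wires them together from a PipelineConfig,
writes every table output with a provenance header, and logs each
decision-relevant parameter at INFO. Missing optional inputs (e.g. no FAME
table) skip their stage with a warning so partial bundles still run.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from . import amino_acids, assay_quant, lipid_fame, nucleotides, variance_partition
from .biomass_equation import assemble, mass_closure, write_equation
from .constants import AMINO_ACID_MW, METHYL_GROUP_MW, WATER_MW, RNA_RESIDUE_MW_STANDARD
from .io import PipelineConfig, read_table, write_table
from .sample_accounting import displacement_conversion, process_biopsy_table

logger = logging.getLogger("spongebiomass")

__all__ = ["run_pipeline"]


def _fame_mw_map(peaks: pd.DataFrame, config: PipelineConfig) -> Dict[str, float]:
    """Compound -> MW for identified compounds, on the configured basis.

    The input mw column carries free-compound MWs; on the methyl-ester basis
    FA MWs gain one CH2 (sterols are not methylated).
    """
    mw_map: Dict[str, float] = {}
    for rec in peaks.drop_duplicates("compound_id").itertuples(index=False):
        if rec.compound_class in lipid_fame.IDENTIFIED_CLASSES and np.isfinite(rec.mw):
            mw = float(rec.mw)
            if (
                config.fame_mw_basis == "methyl_ester"
                and rec.compound_class in ("known_fa", "database_fa")
            ):
                mw += METHYL_GROUP_MW
            mw_map[rec.compound_id] = mw
    return mw_map


def _stage_fame(
    config: PipelineConfig, lipid_means: pd.Series, outdir: Path
) -> Optional[lipid_fame.LipidProfile]:
    if "fame_peaks" not in config.inputs:
        warnings.warn("no FAME peak table configured; lipid stage skipped")
        return None
    peaks = read_table(
        config.inputs["fame_peaks"],
        required=["sample_id", "compound_id", "compound_class", "area"],
    )
    if "fame_lipid_masses" in config.inputs:
        lm = read_table(
            config.inputs["fame_lipid_masses"],
            required=["sample_id", "lipid_g_per_gDW"],
        )
        lipid_mass = dict(zip(lm["sample_id"], lm["lipid_g_per_gDW"]))
    else:
        # fall back to the population mean lipid content for every sample
        lipid_mass = {s: float(lipid_means) for s in peaks["sample_id"].unique()}

    istd = config.fame_istd_compound
    cut = lipid_fame.apply_intensity_cutoff(peaks, config.fame_rel_cutoff, istd)
    retained = lipid_fame.consistency_filter(cut, config.fame_presence_threshold, istd)
    mw_map = _fame_mw_map(peaks, config)
    fa_mws = [
        mw
        for cid, mw in mw_map.items()
        if cid != istd
        and peaks.loc[peaks["compound_id"] == cid, "compound_class"].iloc[0]
        in ("known_fa", "database_fa")
    ]
    mean_fa_mw = float(np.mean(fa_mws)) if fa_mws else 270.0
    f_b = lipid_fame.backbone_fraction(
        config.glycerolipid_share,
        config.phospholipid_share,
        mean_fa_mw,
        config.chains_per_lipid,
        config.glycerol_residue_mw,
        config.phospho_backbone_mw,
    )
    logger.info(
        "FAME: cutoff=%.2g presence>%.2f mw_basis=%s f_b=%.4f mean_fa_mw=%.2f",
        config.fame_rel_cutoff, config.fame_presence_threshold,
        config.fame_mw_basis, f_b, mean_fa_mw,
    )
    mw_quant = {k: v for k, v in mw_map.items() if k != istd}
    profile = lipid_fame.quantify_lipids(cut, lipid_mass, f_b, mw_quant, retained, istd)
    profile.coverage_fraction = lipid_fame.coverage(retained, peaks, istd)
    write_table(profile.summary, outdir / "fame_profile.csv", config)
    return profile


def run_pipeline(config: PipelineConfig) -> Dict[str, object]:
    """Run every configured stage and write the output bundle.

    Returns a dict of the in-memory results (tables, profiles, equation,
    summary scalars). Raises on malformed mandatory inputs; optional stages
    (FAME, amino acids, displacement) are skipped with a warning when their
    inputs are absent.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: Dict[str, object] = {}
    summary: Dict[str, object] = {}

    logger.info(
        "parameters: salt_coefficient=%.4g a260_factor=%.3g rna_mw_basis=%s "
        "carbohydrate_residue_mw=%.4g pool_amino_acids=%s seed=%d",
        config.salt_coefficient, config.a260_factor, config.rna_mw_basis,
        config.carbohydrate_residue_mw, config.pool_amino_acids, config.seed,
    )

    # --- sample accounting -------------------------------------------------
    if "biopsies" in config.inputs:
        biopsies = read_table(
            config.inputs["biopsies"],
            required=["sponge_id", "biopsy_id", "wet_mass_g", "lyophilized_mass_g"],
        )
        corrected = process_biopsy_table(biopsies, config.salt_coefficient)
        write_table(corrected, outdir / "biopsies_corrected.csv", config)
        results["biopsies"] = corrected

    if "displacement" in config.inputs:
        disp = read_table(
            config.inputs["displacement"],
            required=["displacement_mL", "corrected_dry_mass_g"],
        )
        factor = displacement_conversion(
            zip(disp["displacement_mL"], disp["corrected_dry_mass_g"])
        )
        write_table(
            pd.DataFrame(
                [{"mean_gDW_per_mL": factor.mean_gdw_per_ml, "sd": factor.sd, "n": factor.n}]
            ),
            outdir / "conversion_factor.csv",
            config,
        )
        results["conversion_factor"] = factor
        summary["conversion_factor_gDW_per_mL"] = factor.mean_gdw_per_ml

    # --- assays and gravimetric components --------------------------------
    measurement_frames = []
    if "standards" in config.inputs and "assay_readings" in config.inputs:
        standards = read_table(
            config.inputs["standards"], required=["component", "concentration", "signal"]
        )
        curves = {
            comp: assay_quant.fit_standard_curve(
                list(zip(grp["concentration"], grp["signal"]))
            )
            for comp, grp in standards.groupby("component")
        }
        for comp, curve in curves.items():
            logger.info(
                "standard curve %s: slope=%.4g intercept=%.4g r2=%.5f",
                comp, curve.slope, curve.intercept, curve.r_squared,
            )
        readings = read_table(config.inputs["assay_readings"])
        measurement_frames.append(
            assay_quant.quantify_reading_table(readings, curves, config.a260_factor)
        )
    if "gravimetric" in config.inputs:
        grav = read_table(
            config.inputs["gravimetric"],
            required=["component", "sponge_id", "biopsy_id", "component_mass_g", "dry_mass_g"],
        )
        grav_vals = grav.assign(
            g_per_gDW=grav["component_mass_g"] / grav["dry_mass_g"], clamped=False
        )[["component", "sponge_id", "biopsy_id", "g_per_gDW", "clamped"]]
        measurement_frames.append(grav_vals)

    if not measurement_frames:
        raise ValueError("no assay or gravimetric inputs configured; nothing to quantify")
    measurements = pd.concat(measurement_frames, ignore_index=True)
    order = ["skeleton", "lipid", "protein", "carbohydrate", "RNA", "DNA"]
    measurements["component"] = pd.Categorical(
        measurements["component"], categories=order, ordered=True
    )
    measurements = measurements.sort_values(
        ["component", "sponge_id", "biopsy_id"]
    ).reset_index(drop=True)
    measurements["component"] = measurements["component"].astype(str)
    write_table(measurements, outdir / "composition_measurements.csv", config)
    results["measurements"] = measurements

    comp_summary = assay_quant.summary_table(measurements)
    write_table(comp_summary, outdir / "composition_summary.csv", config)
    results["composition_summary"] = comp_summary
    means = comp_summary.set_index("component")["mean_g_per_gDW"]

    # --- variance partition -------------------------------------------------
    varcomp = variance_partition.partition_table(measurements)
    write_table(varcomp, outdir / "variance_partition.csv", config)
    results["variance_partition"] = varcomp

    # --- lipid building blocks ----------------------------------------------
    profile = _stage_fame(config, means.get("lipid", np.nan), outdir)
    results["lipid_profile"] = profile
    if profile is not None:
        summary["fame_coverage_fraction"] = profile.coverage_fraction

    # --- amino acids --------------------------------------------------------
    aa_cellular = aa_skeleton_profile = None
    aa_negative = None
    if "aa_total" in config.inputs and "aa_skeleton" in config.inputs:
        aa_total_samples = read_table(config.inputs["aa_total"])
        aa_skel_samples = read_table(config.inputs["aa_skeleton"])
        total_prof = amino_acids.average_samples(aa_total_samples)
        skel_prof = amino_acids.average_samples(aa_skel_samples)
        total_prof["mole_fraction"] = amino_acids.mole_fractions(
            total_prof["mmol_per_gDW"]
        )
        skel_prof["mole_fraction"] = amino_acids.mole_fractions(skel_prof["mmol_per_gDW"])
        write_table(
            total_prof.reset_index(names="amino_acid"),
            outdir / "aa_total_profile.csv", config,
        )
        write_table(
            skel_prof.reset_index(names="amino_acid"),
            outdir / "aa_skeleton_profile.csv", config,
        )
        cellular, negative = amino_acids.cellular_profile(
            total_prof["mmol_per_gDW"], skel_prof["mmol_per_gDW"]
        )
        comparison = pd.DataFrame(
            {
                "amino_acid": cellular.index,
                "cellular_pct": amino_acids.normalize_percent(cellular).to_numpy(),
                "skeleton_pct": amino_acids.normalize_percent(
                    skel_prof["mmol_per_gDW"]
                ).to_numpy(),
                "cellular_negative_flag": negative.to_numpy(),
            }
        )
        write_table(comparison, outdir / "aa_comparison_pct.csv", config)
        results["aa_total"] = total_prof
        results["aa_skeleton"] = skel_prof
        results["aa_comparison"] = comparison
        aa_cellular = cellular.clip(lower=0.0)
        aa_negative = negative
        aa_skeleton_profile = skel_prof["mmol_per_gDW"]
    else:
        warnings.warn("amino-acid inputs missing; stage skipped")

    # --- nucleotides --------------------------------------------------------
    rna_mw = RNA_RESIDUE_MW_STANDARD if config.rna_mw_basis == "standard" else None
    dna_table = nucleotides.composition_table(
        "DNA", config.genome_gc, float(means.get("DNA", 0.0))
    )
    rna_table = nucleotides.composition_table(
        "RNA", config.transcriptome_gc, float(means.get("RNA", 0.0)), rna_mw
    )
    write_table(dna_table, outdir / "dna_composition.csv", config)
    write_table(rna_table, outdir / "rna_composition.csv", config)
    results["dna_composition"] = dna_table
    results["rna_composition"] = rna_table

    # --- biomass equation ---------------------------------------------------
    if aa_cellular is not None:
        skeleton_mean = float(means.get("skeleton", 0.0))
        # polymerized (residue) mass of the spongin amino acids
        residue_mw = pd.Series(AMINO_ACID_MW) - WATER_MW
        aa_mass = float((aa_skeleton_profile / 1e3 * residue_mw).sum())
        inorganic = skeleton_mean - aa_mass
        if inorganic < 0:
            warnings.warn(
                "skeleton amino-acid mass exceeds measured skeleton mass; "
                "inorganic remainder clamped to 0"
            )
            inorganic = 0.0
        equation = assemble(
            aa_cellular=aa_cellular,
            aa_skeleton=aa_skeleton_profile,
            dna_table=dna_table,
            rna_table=rna_table,
            lipid_summary=profile.summary if profile is not None else None,
            carbohydrate_g_per_gdw=float(means.get("carbohydrate", 0.0)),
            skeleton_inorganic_g_per_gdw=inorganic,
            carbohydrate_monomer_mw=config.carbohydrate_residue_mw,
            aa_cellular_negative=aa_negative,
            pool_amino_acids=config.pool_amino_acids,
        )
        write_equation(equation, outdir / "biomass_equation.csv", "csv")
        write_equation(equation, outdir / "biomass_reaction.txt", "reaction_string")
        results["equation"] = equation
        summary["mass_closure_g_per_gDW"] = mass_closure(equation)
        summary["measured_total_g_per_gDW"] = float(means.sum())

    with open(outdir / "pipeline_summary.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(summary, fh, sort_keys=True)
    results["summary"] = summary
    logger.info("pipeline complete: %s", ", ".join(sorted(summary)))
    return results
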