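import filecmp
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from spongebiomass.amino_acids import mole_fractions, average_samples
from spongebiomass.assay_quant import fit_standard_curve, quantify_reading_table
from spongebiomass.lipid_fame import apply_intensity_cutoff, consistency_filter
from spongebiomass.synthetic_data import (
    AA_TOTAL_REFERENCE,
    ISTD_COMPOUND,
    SimulationConfig,
    simulate_aa_tables,
    simulate_assay_readings,
    simulate_biopsy_dataset,
    simulate_bundle,
    simulate_fame_tables,
)


class TestDeterminism:
    def test_same_seed_gives_byte_identical_bundle(self, tmp_path):
        a = simulate_bundle(SimulationConfig(seed=123), tmp_path / "a")
        b = simulate_bundle(SimulationConfig(seed=123), tmp_path / "b")
        for name, path_a in a.items():
            assert filecmp.cmp(path_a, b[name], shallow=False), name

    def test_different_seed_differs(self, tmp_path):
        a = simulate_bundle(SimulationConfig(seed=1), tmp_path / "a")
        b = simulate_bundle(SimulationConfig(seed=2), tmp_path / "b")
        assert not filecmp.cmp(a["biopsies"], b["biopsies"], shallow=False)


class TestBiopsyDataset:
    def test_hierarchical_moments(self):
        # pool many replicate datasets: per-component grand mean and total SD
        # must match the configured reference
        cfg = SimulationConfig(seed=5)
        rng = np.random.default_rng(cfg.seed)
        values = []
        for _ in range(200):
            _, m = simulate_biopsy_dataset(cfg, rng)
            values.append(m[m["component"] == "lipid"]["g_per_gDW"].to_numpy())
        pooled = np.concatenate(values)
        mean, sd, _ = cfg.macro_reference["lipid"]
        assert pooled.mean() == pytest.approx(mean, abs=3 * sd / np.sqrt(pooled.size))
        assert pooled.std() == pytest.approx(sd, rel=0.1)

    def test_values_positive_and_design_shape(self):
        cfg = SimulationConfig(seed=9)
        biopsies, m = simulate_biopsy_dataset(cfg, np.random.default_rng(9))
        assert len(biopsies) == cfg.n_individuals * cfg.n_biopsies
        assert (m["g_per_gDW"] > 0).all()
        counts = m.groupby("component").size()
        assert (counts == cfg.n_individuals * cfg.n_biopsies).all()

    def test_biopsy_masses_consistent(self):
        cfg = SimulationConfig(seed=9)
        biopsies, _ = simulate_biopsy_dataset(cfg, np.random.default_rng(9))
        assert (biopsies["wet_mass_g"] > biopsies["lyophilized_mass_g"]).all()
        assert (biopsies["displacement_mL"] > 0).all()


class TestAssayRoundTrip:
    def test_zero_noise_is_exact(self):
        cfg = SimulationConfig(seed=4, assay_cv=0.0, standards_cv=0.0)
        rng = np.random.default_rng(cfg.seed)
        biopsies, measurements = simulate_biopsy_dataset(cfg, rng)
        standards, readings = simulate_assay_readings(measurements, biopsies, cfg, rng)
        curves = {
            comp: fit_standard_curve(list(zip(g["concentration"], g["signal"])))
            for comp, g in standards.groupby("component")
        }
        recovered = quantify_reading_table(readings, curves)
        merged = recovered.merge(
            measurements, on=["component", "sponge_id", "biopsy_id"], suffixes=("_rec", "")
        )
        assert np.allclose(merged["g_per_gDW_rec"], merged["g_per_gDW"], rtol=1e-10)

    def test_noisy_recovery_unbiased(self):
        cfg = SimulationConfig(seed=21)
        rng = np.random.default_rng(cfg.seed)
        errors = []
        for _ in range(30):
            biopsies, measurements = simulate_biopsy_dataset(cfg, rng)
            standards, readings = simulate_assay_readings(measurements, biopsies, cfg, rng)
            curves = {
                comp: fit_standard_curve(list(zip(g["concentration"], g["signal"])))
                for comp, g in standards.groupby("component")
            }
            recovered = quantify_reading_table(readings, curves)
            merged = recovered.merge(
                measurements, on=["component", "sponge_id", "biopsy_id"],
                suffixes=("_rec", ""),
            )
            sel = merged[merged["component"] == "protein"]
            errors.append(
                float((sel["g_per_gDW_rec"] / sel["g_per_gDW"]).mean()) - 1.0
            )
        # relative recovery error across replicates centred on zero
        assert abs(np.mean(errors)) < 3 * np.std(errors) / np.sqrt(len(errors)) + 1e-3

    def test_zero_value_reading_round_trips_to_zero(self):
        cfg = SimulationConfig(seed=4, assay_cv=0.0, standards_cv=0.0)
        rng = np.random.default_rng(0)
        biopsies, measurements = simulate_biopsy_dataset(cfg, rng)
        measurements = measurements.copy()
        idx = measurements[measurements["component"] == "DNA"].index[0]
        measurements.loc[idx, "g_per_gDW"] = 0.0
        standards, readings = simulate_assay_readings(measurements, biopsies, cfg, rng)
        curves = {
            comp: fit_standard_curve(list(zip(g["concentration"], g["signal"])))
            for comp, g in standards.groupby("component")
        }
        recovered = quantify_reading_table(readings, curves)
        row = recovered[
            (recovered["component"] == "DNA")
            & (recovered["sponge_id"] == measurements.loc[idx, "sponge_id"])
            & (recovered["biopsy_id"] == measurements.loc[idx, "biopsy_id"])
        ]
        assert row["g_per_gDW"].iloc[0] == pytest.approx(0.0, abs=1e-12)


class TestFameTables:
    def test_cutoff_recovers_catalogue_and_drops_junk(self):
        cfg = SimulationConfig(seed=6, n_inconsistent_unknowns=0)
        peaks, lipids, info = simulate_fame_tables(cfg, np.random.default_rng(6))
        cut = apply_intensity_cutoff(peaks, istd_compound=ISTD_COMPOUND)
        kept = set(cut["compound_id"]) - {ISTD_COMPOUND}
        assert kept == set(cfg.fame_catalogue)

    def test_inconsistent_unknowns_excluded_end_to_end(self):
        cfg = SimulationConfig(seed=6, inconsistent_presence=0.5)
        peaks, _, _ = simulate_fame_tables(cfg, np.random.default_rng(6))
        cut = apply_intensity_cutoff(peaks, istd_compound=ISTD_COMPOUND)
        retained = consistency_filter(cut, istd_compound=ISTD_COMPOUND)
        assert retained == set(cfg.fame_catalogue)

    def test_sample_count_and_positive_lipid_mass(self):
        cfg = SimulationConfig(seed=6)
        peaks, lipids, _ = simulate_fame_tables(cfg, np.random.default_rng(6))
        assert peaks["sample_id"].nunique() == cfg.n_fame_samples
        assert (lipids["lipid_g_per_gDW"] > 0).all()


class TestAaTables:
    def test_zero_noise_reproduces_reference_fractions(self):
        cfg = SimulationConfig(seed=2, aa_noise_scale=0.0, n_aa_samples=3)
        total, skeleton = simulate_aa_tables(cfg, np.random.default_rng(2))
        prof = average_samples(total)
        frac = mole_fractions(prof["mmol_per_gDW"])
        assert frac["GLY"] == pytest.approx(0.289, abs=5e-4)
        assert prof.loc["ASP", "mmol_per_gDW"] == pytest.approx(
            AA_TOTAL_REFERENCE["ASP"][0]
        )

    def test_amide_pools_emitted_combined(self):
        cfg = SimulationConfig(seed=2, n_aa_samples=2)
        total, _ = simulate_aa_tables(cfg, np.random.default_rng(2))
        codes = set(total["amino_acid"])
        assert {"ASX", "GLX"} <= codes
        assert not {"ASP", "ASN", "GLN", "GLU"} & codes
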