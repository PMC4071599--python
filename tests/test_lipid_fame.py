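import numpy as np
import pandas as pd
import pytest

from spongebiomass.lipid_fame import (
    apply_intensity_cutoff,
    average_identified_mw,
    backbone_fraction,
    consistency_filter,
    coverage,
    quantify_lipids,
)


def peaks_frame(rows):
    return pd.DataFrame(rows, columns=["sample_id", "compound_id", "compound_class", "area"])


class TestIntensityCutoff:
    def test_hand_threshold(self):
        df = peaks_frame(
            [
                ("s1", "a", "known_fa", 10000.0),
                ("s1", "b", "known_fa", 6.0),
                ("s1", "c", "known_fa", 4.0),
            ]
        )
        out = apply_intensity_cutoff(df, 5e-4)
        assert sorted(out["compound_id"]) == ["a", "b"]

    def test_single_peak_and_all_equal_kept(self):
        assert len(apply_intensity_cutoff(peaks_frame([("s1", "a", "known_fa", 100.0)]))) == 1
        df = peaks_frame([("s1", c, "known_fa", 7.0) for c in "abc"])
        assert len(apply_intensity_cutoff(df)) == 3

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        df = peaks_frame(
            [("s1", f"c{i}", "known_fa", float(a)) for i, a in enumerate(rng.lognormal(3, 2, 30))]
        )
        once = apply_intensity_cutoff(df)
        twice = apply_intensity_cutoff(once)
        pd.testing.assert_frame_equal(once.reset_index(drop=True), twice.reset_index(drop=True))

    def test_istd_never_sets_threshold_and_is_kept(self):
        df = peaks_frame(
            [
                ("s1", "istd", "known_fa", 1e6),
                ("s1", "a", "known_fa", 100.0),
                ("s1", "b", "known_fa", 0.06),
            ]
        )
        out = apply_intensity_cutoff(df, 5e-4, istd_compound="istd")
        # threshold comes from peak a (0.05), not from the istd (500), so b
        # survives; the istd itself is always retained
        assert sorted(out["compound_id"]) == ["a", "b", "istd"]


class TestConsistencyFilter:
    def build(self, n_present, n_total=23):
        rows = []
        for s in range(n_total):
            rows.append((f"s{s}", "palmitic", "known_fa", 100.0))
            if s < n_present:
                rows.append((f"s{s}", "UU-x", "unknown_fa", 10.0))
        return peaks_frame(rows)

    def test_majority_rule(self):
        assert "UU-x" in consistency_filter(self.build(18))      # 78.3% > 75%
        assert "UU-x" not in consistency_filter(self.build(17))  # 73.9%
        assert "UU-x" in consistency_filter(self.build(23))

    def test_known_compounds_pass_unconditionally(self):
        df = peaks_frame(
            [("s1", "rare-known", "known_fa", 1.0), ("s2", "other", "sterol", 1.0)]
        )
        assert "rare-known" in consistency_filter(df)


class TestBackboneFraction:
    def test_single_class_hand_case(self):
        f = backbone_fraction(1.0, 0.0, mean_fa_mw=256.0, chains_per_lipid=2,
                              glycerol_residue_mw=38.0, phospho_backbone_mw=0.0)
        assert f == pytest.approx(38.0 / 550.0, abs=1e-6)

    def test_zero_backbones(self):
        assert backbone_fraction(0.2, 0.8, 270.0, 2, 0.0, 0.0) == 0.0

    def test_shares_must_sum_to_one(self):
        with pytest.raises(ValueError):
            backbone_fraction(0.5, 0.2, 270.0)

    def test_default_value_frozen(self):
        # regression value computed once from the configured residue masses
        assert backbone_fraction(mean_fa_mw=270.0) == pytest.approx(0.18187, abs=1e-4)


class TestQuantify:
    def test_single_compound_closure(self):
        df = peaks_frame([("s1", "a", "known_fa", 500.0)])
        prof = quantify_lipids(df, {"s1": 0.1}, 0.0, {"a": 250.0}, {"a"})
        assert prof.summary["mean_umol_per_gDW"].iloc[0] == pytest.approx(400.0)

    def test_two_compound_hand_case(self):
        df = peaks_frame([("s1", "a", "known_fa", 300.0), ("s1", "b", "known_fa", 100.0)])
        prof = quantify_lipids(df, {"s1": 0.1}, 0.0, {"a": 250.0, "b": 500.0}, {"a", "b"})
        vals = prof.summary.set_index("compound_id")["mean_umol_per_gDW"]
        assert vals["a"] == pytest.approx(300.0)
        assert vals["b"] == pytest.approx(50.0)

    def test_mass_conservation_per_sample(self):
        rng = np.random.default_rng(8)
        rows, mw_map = [], {}
        for s in range(4):
            for i in range(6):
                rows.append((f"s{s}", f"c{i}", "known_fa", float(rng.lognormal(2, 1))))
        for i in range(6):
            mw_map[f"c{i}"] = float(rng.uniform(200, 400))
        df = peaks_frame(rows)
        lipid = {f"s{s}": float(rng.uniform(0.05, 0.2)) for s in range(4)}
        f_b = 0.18
        prof = quantify_lipids(df, lipid, f_b, mw_map, set(mw_map))
        for s, grp in prof.per_sample.groupby("sample_id"):
            total = (grp["umol_per_gDW"] * grp["mw_used"]).sum() * 1e-6
            assert total == pytest.approx(lipid[s] * (1 - f_b), rel=1e-12)

    def test_invariant_to_uniform_area_rescaling(self):
        df = peaks_frame([("s1", "a", "known_fa", 3.0), ("s1", "b", "known_fa", 1.0)])
        df2 = df.assign(area=df["area"] * 1e4)
        p1 = quantify_lipids(df, {"s1": 0.1}, 0.1, {"a": 250.0, "b": 300.0}, {"a", "b"})
        p2 = quantify_lipids(df2, {"s1": 0.1}, 0.1, {"a": 250.0, "b": 300.0}, {"a", "b"})
        pd.testing.assert_frame_equal(p1.summary, p2.summary)

    def test_equal_mws_give_area_share_proportionality(self):
        df = peaks_frame(
            [("s1", "a", "unknown_fa", 60.0), ("s1", "b", "unknown_fa", 40.0)]
        )
        prof = quantify_lipids(df, {"s1": 0.1}, 0.0, {"x": 300.0}, {"a", "b"})
        vals = prof.summary.set_index("compound_id")["mean_umol_per_gDW"]
        assert vals["a"] / vals["b"] == pytest.approx(60.0 / 40.0)

    def test_empty_retained_set_errors(self):
        df = peaks_frame([("s1", "a", "known_fa", 1.0)])
        with pytest.raises(ValueError):
            quantify_lipids(df, {"s1": 0.1}, 0.0, {"a": 250.0}, set())

    def test_missing_lipid_mass_skips_sample_with_warning(self):
        df = peaks_frame([("s1", "a", "known_fa", 1.0), ("s2", "a", "known_fa", 1.0)])
        with pytest.warns(UserWarning, match="skipped"):
            prof = quantify_lipids(df, {"s1": 0.1}, 0.0, {"a": 250.0}, {"a"})
        assert prof.per_sample["sample_id"].nunique() == 1


class TestCoverage:
    def test_everything_retained(self):
        df = peaks_frame([("s1", "a", "known_fa", 5.0), ("s1", "b", "known_fa", 5.0)])
        assert coverage({"a", "b"}, df) == pytest.approx(1.0)

    def test_hand_ratio(self):
        df = peaks_frame([("s1", "a", "known_fa", 825.0), ("s1", "junk", "unknown_fa", 175.0)])
        assert coverage({"a"}, df) == pytest.approx(0.825)

    def test_istd_excluded_from_both_sums(self):
        df = peaks_frame(
            [
                ("s1", "a", "known_fa", 80.0),
                ("s1", "junk", "unknown_fa", 20.0),
                ("s1", "istd", "known_fa", 1000.0),
            ]
        )
        assert coverage({"a"}, df, istd_compound="istd") == pytest.approx(0.8)


def test_average_identified_mw_ignores_missing():
    assert average_identified_mw({"a": 200.0, "b": 300.0, "c": None}) == pytest.approx(250.0)
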