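import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from spongebiomass.variance_partition import (
    VarCompResult,
    fit_random_intercept,
    lrt_random_effect,
    partition_table,
    pct_between,
)


def simulate(share, rng, mean=10.0, sd=2.0, n_groups=4, n_per=5):
    sb = sd * np.sqrt(share)
    sw = sd * np.sqrt(1 - share)
    a = rng.normal(0, sb, n_groups) if sb > 0 else np.zeros(n_groups)
    y = np.concatenate([rng.normal(mean + a[i], sw, n_per) for i in range(n_groups)])
    return y, np.repeat(np.arange(n_groups), n_per)


def mvn_loglik(y, groups, mu, sigma2_b, sigma2_w):
    """Direct Gaussian log-likelihood with explicit covariance (oracle path)."""
    z = (groups[:, None] == groups[None, :]).astype(float)
    cov = sigma2_w * np.eye(y.size) + sigma2_b * z
    return stats.multivariate_normal(mean=np.full(y.size, mu), cov=cov).logpdf(y)


def oracle_ml_fit(y, groups, lam_step=1e-4):
    """Brute-force grid over the variance ratio; inner Nelder-Mead over
    (mu, log sigma2_w) against the direct multivariate-normal likelihood."""

    def best_at(lam):
        def nll(params):
            mu, log_s2w = params
            s2w = np.exp(log_s2w)
            return -mvn_loglik(y, groups, mu, lam * s2w, s2w)

        res = optimize.minimize(
            nll, [y.mean(), np.log(y.var())], method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12},
        )
        return -res.fun, res.x

    coarse = np.arange(0.0, 10.0, 0.05)
    lls = [best_at(l)[0] for l in coarse]
    lam0 = coarse[int(np.argmax(lls))]
    fine = np.arange(max(0.0, lam0 - 0.06), lam0 + 0.06, lam_step)
    lls = [best_at(l)[0] for l in fine]
    k = int(np.argmax(lls))
    lam = fine[k]
    ll, (mu, log_s2w) = best_at(lam)
    s2w = float(np.exp(log_s2w))
    return lam * s2w, s2w, ll


class TestFit:
    def test_perfect_separation(self):
        with pytest.warns(UserWarning, match="floored"):
            res = fit_random_intercept([0, 0, 1, 1], ["a", "a", "b", "b"], "ml")
        assert res.pct_between > 99.9

    def test_all_equal_values(self):
        res = fit_random_intercept([2.0] * 6, ["a", "a", "b", "b", "c", "c"], "ml")
        assert res.sigma2_between == pytest.approx(0.0, abs=1e-15)
        assert res.pct_between == 0.0

    def test_fewer_than_two_groups_errors(self):
        with pytest.raises(ValueError):
            fit_random_intercept([1, 2, 3], ["a", "a", "a"])

    def test_matches_brute_force_likelihood_oracle(self):
        rng = np.random.default_rng(42)
        y, g = simulate(0.5, rng)
        mine = fit_random_intercept(y, g, "ml")
        s2b, s2w, ll = oracle_ml_fit(y, g)
        assert mine.sigma2_between == pytest.approx(s2b, abs=2e-4)
        assert mine.sigma2_within == pytest.approx(s2w, abs=2e-4)
        assert mine.loglik >= ll - 1e-6  # optimizer at least as good as the grid

    def test_matches_statsmodels_mixedlm(self):
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(3)
        y, g = simulate(0.4, rng)
        df = pd.DataFrame({"y": y, "g": g})
        for reml in (True, False):
            sm_fit = smf.mixedlm("y ~ 1", df, groups=df["g"]).fit(reml=reml)
            mine = fit_random_intercept(y, g, "reml" if reml else "ml")
            assert mine.sigma2_within == pytest.approx(float(sm_fit.scale), rel=1e-4)
            assert mine.sigma2_between == pytest.approx(
                float(sm_fit.cov_re.iloc[0, 0]), rel=1e-3, abs=1e-5
            )
            assert mine.loglik == pytest.approx(float(sm_fit.llf), abs=1e-5)

    def test_reml_at_least_ml_between_variance(self):
        for seed in (1, 2, 3, 4):
            y, g = simulate(0.5, np.random.default_rng(seed))
            reml = fit_random_intercept(y, g, "reml")
            ml = fit_random_intercept(y, g, "ml")
            assert reml.sigma2_between >= ml.sigma2_between - 1e-10

    def test_location_scale_equivariance(self):
        rng = np.random.default_rng(17)
        y, g = simulate(0.5, rng)
        base = fit_random_intercept(y, g, "reml")
        shifted = fit_random_intercept(y + 100.0, g, "reml")
        scaled = fit_random_intercept(3.0 * y, g, "reml")
        assert shifted.sigma2_between == pytest.approx(base.sigma2_between, rel=1e-6)
        assert shifted.sigma2_within == pytest.approx(base.sigma2_within, rel=1e-6)
        assert scaled.sigma2_between == pytest.approx(9 * base.sigma2_between, rel=1e-6)
        assert scaled.sigma2_within == pytest.approx(9 * base.sigma2_within, rel=1e-6)

    def test_unbalanced_design_supported(self):
        rng = np.random.default_rng(5)
        y, g = simulate(0.5, rng)
        y, g = y[:-2], g[:-2]  # 4 groups of 5,5,5,3
        res = fit_random_intercept(y, g, "reml")
        assert 0 <= res.pct_between <= 100


class TestPctBetween:
    def test_equal_components(self):
        r = VarCompResult(2.0, 2.0, 0.0, 0.0, "reml")
        assert pct_between(r) == pytest.approx(50.0)

    def test_zero_between(self):
        r = VarCompResult(0.0, 2.0, 0.0, 0.0, "reml")
        assert pct_between(r) == 0.0


class TestLrt:
    def test_no_group_structure(self):
        rng = np.random.default_rng(10)
        y, g = simulate(0.0, rng)
        chi2, p, p_mix = lrt_random_effect(y, g)
        assert chi2 < 1.0
        assert p > 0.3

    def test_strong_separation_significant(self):
        y = np.concatenate([np.random.default_rng(1).normal(m, 0.1, 5) for m in (0, 5, 10, 15)])
        g = np.repeat(np.arange(4), 5)
        chi2, p, p_mix = lrt_random_effect(y, g)
        assert chi2 > 3.84
        assert p < 0.05
        assert p_mix == pytest.approx(p / 2)

    def test_boundary_fit_gives_p_of_one(self):
        y = np.array([1.0, 2.0, 1.0, 2.0, 1.0, 2.0])
        g = np.array(["a", "a", "b", "b", "c", "c"])
        chi2, p, p_mix = lrt_random_effect(y, g)
        assert chi2 == pytest.approx(0.0, abs=1e-8)
        assert p == pytest.approx(1.0, abs=1e-6)
        assert p_mix == pytest.approx(1.0)


def test_partition_table_shape():
    rng = np.random.default_rng(2)
    frames = []
    for comp, share in (("lipid", 0.54), ("DNA", 0.0)):
        y, g = simulate(share, rng)
        frames.append(
            pd.DataFrame({"component": comp, "sponge_id": g, "g_per_gDW": y})
        )
    out = partition_table(pd.concat(frames, ignore_index=True))
    assert list(out["component"]) == ["lipid", "DNA"]
    assert ((out["pct_between"] >= 0) & (out["pct_between"] <= 100)).all()
    assert (out["chi2"] >= 0).all()
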