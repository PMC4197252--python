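"""Multilevel discrete-time logistic survival model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.special import expit

import geosurv as gs
from geosurv.multilevel import Z_075
from tests.conftest import small_cohort


def make_pp(rows):
    """rows: list of (e, interval, area, grp)."""
    df = pd.DataFrame(rows, columns=["e", "interval", "area_id", "grp"])
    df["patient_id"] = range(len(df))
    for t in range(1, 6):
        df[f"D{t}"] = (df["interval"] == t).astype(int)
    return df


class TestLoglik:
    def test_single_row_even_odds(self):
        pp = make_pp([(1, 1, 0, "a")])
        m = gs.DiscreteTimeMultilevel(pp, [], n_areas=1)
        assert m.loglik(np.zeros(5), np.zeros(1)) == pytest.approx(np.log(0.5))

    def test_matches_brute_force_row_sum(self):
        """Hand-summed Bernoulli log-pmfs over a 3-row toy file."""
        pp = make_pp([(0, 1, 0, "a"), (1, 2, 1, "b"), (0, 3, 0, "b")])
        m = gs.DiscreteTimeMultilevel(pp, ["grp"], n_areas=2)
        # params: intercept, year[2..5], grp[b]
        beta = np.array([-1.2, 0.3, -0.4, 0.1, 0.0, 0.7])
        u = np.array([0.25, -0.5])
        # independent re-implementation, row by row
        expected = 0.0
        for e, t, j, g in [(0, 1, 0, "a"), (1, 2, 1, "b"), (0, 3, 0, "b")]:
            eta = beta[0] + (beta[t - 1] if t >= 2 else 0.0) + (beta[5] if g == "b" else 0.0) + u[j]
            p = expit(eta)
            expected += np.log(p if e else 1 - p)
        assert m.loglik(beta, u) == pytest.approx(expected, abs=1e-12)

    def test_intercept_shift_absorbed_by_area_effects(self):
        pp = make_pp([(0, 1, 0, "a"), (1, 2, 1, "b"), (0, 3, 0, "b")])
        m = gs.DiscreteTimeMultilevel(pp, ["grp"], n_areas=2)
        beta = np.array([-1.0, 0.2, 0.0, 0.0, 0.0, 0.5])
        u = np.array([0.1, -0.3])
        c = 0.77
        shifted = beta.copy()
        shifted[0] += c
        assert m.loglik(shifted, u - c) == pytest.approx(m.loglik(beta, u), abs=1e-12)

    def test_dimension_mismatch(self):
        pp = make_pp([(1, 1, 0, "a")])
        m = gs.DiscreteTimeMultilevel(pp, [], n_areas=1)
        with pytest.raises(ValueError, match="expected"):
            m.loglik(np.zeros(3), np.zeros(1))

    def test_log_posterior_matches_grid_oracle(self):
        """On a 6-row, 2-area toy file the unnormalised log-posterior equals
        an independent brute-force evaluation over a parameter grid."""
        rows = [(0, 1, 0, "a"), (1, 2, 0, "b"), (0, 1, 1, "b"),
                (0, 2, 1, "a"), (1, 3, 1, "a"), (0, 1, 0, "b")]
        pp = make_pp(rows)
        m = gs.DiscreteTimeMultilevel(pp, ["grp"], n_areas=2)
        rng = np.random.default_rng(11)
        for _ in range(20):
            beta = rng.normal(size=6)
            u = rng.normal(size=2)
            s2 = float(rng.uniform(0.01, 1.0))
            # brute force: likelihood row by row + prior terms
            ll = 0.0
            for e, t, j, g in rows:
                eta = beta[0] + (beta[t - 1] if t >= 2 else 0) + (beta[5] if g == "b" else 0) + u[j]
                ll += np.log(expit(eta) if e else 1 - expit(eta))
            ll += stats.norm.logpdf(u, scale=np.sqrt(s2)).sum()
            ll += stats.gamma.logpdf(1 / s2, 0.1, scale=1000.0)
            assert m.log_posterior(beta, u, s2) == pytest.approx(ll, abs=1e-10)

    def test_map_matches_plain_logistic_regression(self):
        """With u = 0 the posterior mode is ordinary logistic regression on
        the expanded file (independent oracle: statsmodels GLM)."""
        import statsmodels.api as sm

        cohort, _ = small_cohort(seed=8, n=2000, J=100)
        pp = gs.expand_person_period(cohort)
        m = gs.DiscreteTimeMultilevel(pp, ["g"], n_areas=100)
        beta_hat, _ = m.map_fit()
        x = np.column_stack(
            [np.ones(len(pp))]
            + [(pp["interval"] == t).astype(float) for t in range(2, 6)]
            + [(pp["g"] == "b").astype(float)]
        )
        glm = sm.GLM(pp["e"].to_numpy(), x, family=sm.families.Binomial()).fit()
        assert beta_hat == pytest.approx(glm.params, abs=1e-6)


class TestMOR:
    @pytest.mark.parametrize("s2,expected", [(0.025, 1.16), (0.0, 1.00)])
    def test_point_values(self, s2, expected):
        mor, _ = gs.median_odds_ratio(np.array([s2]))
        assert round(mor, 2) == expected

    def test_formula_constant(self):
        assert Z_075 == pytest.approx(0.674490, abs=1e-6)

    def test_cri_from_variance_posterior(self):
        rng = np.random.default_rng(0)
        s2 = rng.gamma(5, 0.005, 4000)
        mor, (lo, hi) = gs.median_odds_ratio(s2)
        per_draw = np.exp(np.sqrt(2 * s2) * Z_075)
        assert lo == pytest.approx(np.percentile(per_draw, 2.5))
        assert hi == pytest.approx(np.percentile(per_draw, 97.5))
        assert lo <= mor <= hi

    @settings(deadline=None, max_examples=50)
    @given(st.floats(0, 5), st.floats(0, 5))
    def test_mor_at_least_one_and_monotone(self, a, b):
        ma, _ = gs.median_odds_ratio(np.array([a]))
        mb, _ = gs.median_odds_ratio(np.array([b]))
        assert ma >= 1.0 and mb >= 1.0
        if a < b:
            assert ma < mb

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            gs.median_odds_ratio(np.array([-0.1]))


class TestWald:
    def test_large_statistic_limit(self):
        rng = np.random.default_rng(1)
        s2 = rng.normal(1.0, 0.01, 1000).clip(min=0)
        _, p = gs.area_effect_test(s2)
        assert p < 0.001

    def test_mean_equals_sd(self):
        """chi2(1) upper tail at 1: p = 0.3173."""
        samples = np.array([1 - 2 ** -0.5, 1 + 2 ** -0.5])  # mean 1, sd 1
        stat, p = gs.area_effect_test(samples)
        assert stat == pytest.approx(1.0)
        assert p == pytest.approx(stats.chi2.sf(1, 1), abs=1e-12)

    def test_zero_mean(self):
        _, p = gs.area_effect_test(np.zeros(10))
        assert p == 1.0


class TestFit:
    def test_requires_events(self):
        pp = make_pp([(0, 1, 0, "a")])
        with pytest.raises(ValueError, match="events"):
            gs.DiscreteTimeMultilevel(pp, [], n_areas=1)

    def test_determinism_same_seed(self):
        cohort, _ = small_cohort(seed=6, n=1500)
        pp = gs.expand_person_period(cohort)
        m = gs.DiscreteTimeMultilevel(pp, ["g"], n_areas=100)
        a = m.fit(n_iter=200, burn_in=100, seed=3).posterior.draws
        b = m.fit(n_iter=200, burn_in=100, seed=3).posterior.draws
        pd.testing.assert_frame_equal(a, b)
        c = m.fit(n_iter=200, burn_in=100, seed=4).posterior.draws
        assert not a.equals(c)

    def test_null_cohort_small_variance(self):
        """Zero-heterogeneity cohort: posterior median area variance falls
        below the prior-sensitivity floor."""
        cohort, _ = small_cohort(seed=15, sigma2_u=0.0, sigma2_v=0.0)
        pp = gs.expand_person_period(cohort)
        m = gs.DiscreteTimeMultilevel(pp, ["g"], n_areas=100)
        res = m.fit(n_iter=2000, burn_in=1000, seed=2)
        assert np.median(res.sigma2_u) < 0.01

    def test_geweke_passes_on_long_chain(self):
        cohort, _ = small_cohort(seed=16, n=4000)
        pp = gs.expand_person_period(cohort)
        m = gs.DiscreteTimeMultilevel(pp, ["g"], n_areas=100)
        res = m.fit(n_iter=3000, burn_in=1500, seed=5)
        table = res.geweke_table(["intercept", "g[b]", "sigma2_u"])
        assert table["converged"].all()

    def test_acceptance_rates_in_contract_band(self):
        cohort, _ = small_cohort(seed=17, n=2000)
        pp = gs.expand_person_period(cohort)
        res = gs.DiscreteTimeMultilevel(pp, ["g"], n_areas=100).fit(
            n_iter=1000, burn_in=1000, seed=1
        )
        assert 0.2 <= res.posterior.meta["accept_beta"] <= 0.5
        assert 0.2 <= res.posterior.meta["accept_u_mean"] <= 0.5

    def test_summary_renders(self):
        cohort, _ = small_cohort(seed=18, n=1000)
        pp = gs.expand_person_period(cohort)
        res = gs.DiscreteTimeMultilevel(pp, ["g"], n_areas=100).fit(
            n_iter=300, burn_in=300, seed=1
        )
        text = res.summary()
        assert "MOR" in text and "DIC" in text
        assert len(res.baseline_hazards()) == 5
        assert set(res.odds_ratios().index) == {"g[b]"}
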