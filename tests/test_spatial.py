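"""Bayesian spatial piecewise-exponential Poisson survival model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import geosurv as gs
from geosurv.adjacency import AdjacencyStructure
from tests.conftest import small_cohort


def make_strata(rows):
    """rows: (d, y, interval, area, grp)."""
    return pd.DataFrame(rows, columns=["d", "y", "interval", "area_id", "grp"])


@pytest.fixture(scope="module")
def path3():
    return AdjacencyStructure(3, np.array([[0, 1], [1, 2]]))


class TestLoglik:
    def test_zero_deaths_is_minus_mu(self, path3):
        strata = make_strata([(1, 2.0, 1, 0, "a"), (0, 3.0, 2, 1, "a")])
        m = gs.SpatialPoissonModel(strata, path3, [])
        alpha = np.array([-1.0, -0.5, 0.0, 0.0, 0.0])
        ll = m.loglik(alpha, np.empty(0), np.zeros(3), np.zeros(3))
        # second stratum contributes exactly -mu; check via difference
        mu1 = 2.0 * np.exp(-1.0)
        mu2 = 3.0 * np.exp(-0.5)
        expected = (1 * np.log(mu1) - mu1 - np.log(1)) + (-mu2)
        assert ll == pytest.approx(expected, abs=1e-12)

    def test_matches_scipy_poisson_oracle(self, path3):
        strata = make_strata([(2, 1.5, 1, 0, "a"), (0, 2.0, 2, 1, "b"), (3, 0.7, 5, 2, "b")])
        m = gs.SpatialPoissonModel(strata, path3, ["grp"])
        alpha = np.array([-1.0, -0.8, -0.6, -0.4, -0.2])
        beta = np.array([0.3])
        u = np.array([0.1, -0.05, 0.2])
        v = np.array([-0.1, 0.0, 0.05])
        expected = 0.0
        for d, y, t, j, g in [(2, 1.5, 1, 0, "a"), (0, 2.0, 2, 1, "b"), (3, 0.7, 5, 2, "b")]:
            mu = y * np.exp(alpha[t - 1] + (0.3 if g == "b" else 0) + u[j] + v[j])
            expected += stats.poisson.logpmf(d, mu)
        assert m.loglik(alpha, beta, u, v) == pytest.approx(expected, abs=1e-12)

    def test_offset_identity(self, path3):
        """Doubling person-time while lowering the intercepts by log 2
        leaves the likelihood unchanged."""
        rows = [(2, 1.5, 1, 0, "a"), (1, 2.0, 2, 1, "a")]
        strata = make_strata(rows)
        doubled = strata.assign(y=strata["y"] * 2)
        m1 = gs.SpatialPoissonModel(strata, path3, [])
        m2 = gs.SpatialPoissonModel(doubled, path3, [])
        alpha = np.array([-1.0, -0.5, 0.0, 0.0, 0.0])
        z = np.zeros(3)
        assert m2.loglik(alpha - np.log(2), np.empty(0), z, z) == pytest.approx(
            m1.loglik(alpha, np.empty(0), z, z), abs=1e-12
        )

    def test_saturated_strata_equal_individual_likelihood(self, path3):
        """Aggregating with one patient per stratum reproduces the
        individual-level piecewise-exponential likelihood exactly."""
        frame = pd.DataFrame(
            {
                "patient_id": ["p0", "p1", "p2", "p3"],
                "area_id": [0, 1, 2, 1],
                "pid": ["p0", "p1", "p2", "p3"],
                "time_years": [1.5, 2.0, 4.2, 0.3],
                "event": [1, 0, 1, 1],
            }
        )
        cohort = gs.Cohort(frame, covariates=["pid"])
        strata = gs.aggregate_strata(cohort, ["pid"])
        m = gs.SpatialPoissonModel(strata, path3, ["pid"])
        alpha = np.linspace(-1.5, -0.5, 5)
        beta = np.array([0.4, -0.3, 0.2])  # p1..p3 dummies (p0 reference)
        u = np.array([0.1, 0.0, -0.1])
        v = np.array([0.0, 0.05, 0.0])
        # independent oracle straight from the individual records
        pid_beta = {"p0": 0.0, "p1": 0.4, "p2": -0.3, "p3": 0.2}
        expected = 0.0
        for _, r in frame.iterrows():
            rr = min(r.time_years, 5.0)
            k = int(np.ceil(r.time_years))
            for t in range(1, min(k, 5) + 1):
                y = max(min(rr, t) - (t - 1), 0)
                if y <= 0:
                    continue
                d = int(r.event == 1 and t == k)
                mu = y * np.exp(alpha[t - 1] + pid_beta[r.pid] + u[r.area_id] + v[r.area_id])
                expected += stats.poisson.logpmf(d, mu)
        assert m.loglik(alpha, beta, u, v) == pytest.approx(expected, abs=1e-10)

    def test_validation_errors(self, path3):
        with pytest.raises(ValueError, match="outside"):
            gs.SpatialPoissonModel(make_strata([(1, 1.0, 1, 7, "a")]), path3, [])
        with pytest.raises(ValueError, match="deaths"):
            gs.SpatialPoissonModel(make_strata([(0, 1.0, 1, 0, "a")]), path3, [])
        with pytest.raises(ValueError, match="person-time"):
            gs.SpatialPoissonModel(make_strata([(1, 0.0, 1, 0, "a")]), path3, [])
        with pytest.raises(ValueError, match="include_u"):
            gs.SpatialPoissonModel(
                make_strata([(1, 1.0, 1, 0, "a")]), path3, [], include_u=False, include_v=False
            )


class TestIcarDensity:
    def test_constant_field_is_zero(self, path3):
        assert gs.icar_logdensity(np.full(3, 2.7), path3, 1.3) == 0.0

    def test_path_graph_hand_value(self, path3):
        assert gs.icar_logdensity(np.array([0.0, 1.0, 3.0]), path3, 1.0) == pytest.approx(-2.5)

    def test_shift_invariance_within_component(self, path3):
        u = np.array([0.3, -0.2, 0.6])
        a = gs.icar_logdensity(u, path3, 0.7)
        b = gs.icar_logdensity(u + 5.0, path3, 0.7)
        assert a == pytest.approx(b, abs=1e-12)


class TestSpatialFraction:
    def test_printed_components_give_55_percent(self):
        psi = gs.spatial_fraction_from_components(0.006, 0.005)
        assert round(psi, 2) == 0.55

    def test_degenerate_cases(self):
        assert gs.spatial_fraction_from_components(0.01, 0.0) == 1.0
        assert gs.spatial_fraction_from_components(0.0, 0.01) == 0.0
        with pytest.raises(ValueError):
            gs.spatial_fraction_from_components(0.0, 0.0)

    def test_zero_total_draws_dropped_with_warning(self):
        draws = pd.DataFrame(
            {"sigma2_u_marginal": [0.006, 0.0], "sigma2_v": [0.005, 0.0]}
        )
        with pytest.warns(UserWarning, match="zero total"):
            psi, _ = gs.spatial_fraction(gs.PosteriorSamples(draws))
        assert psi == pytest.approx(0.006 / 0.011)


class TestSmoothedRR:
    def test_null_effects_give_unit_rr(self):
        draws = pd.DataFrame(
            np.zeros((10, 4)), columns=["u[0]", "u[1]", "v[0]", "v[1]"]
        )
        rr = gs.smoothed_rr(gs.PosteriorSamples(draws))
        assert (rr["rr"] == 1.0).all()
        assert (rr["cri_2.5"] <= 1.0).all() and (rr["cri_97.5"] >= 1.0).all()

    def test_centered_effects_median_near_one(self):
        rng = np.random.default_rng(3)
        u = rng.normal(0, 0.1, (500, 20))
        u -= u.mean(axis=1, keepdims=True)
        draws = pd.DataFrame(u, columns=[f"u[{j}]" for j in range(20)])
        rr = gs.smoothed_rr(gs.PosteriorSamples(draws))
        assert np.median(rr["rr"]) == pytest.approx(1.0, abs=0.05)


class TestFit:
    def test_recovery_and_invariants(self, bym_fit, lattice100):
        """Dominantly-spatial truth: beta recovered within 2 posterior SD,
        spatial fraction concentrates above one half, sum-to-zero holds at
        every retained draw, psi in [0,1] and total variance additivity."""
        cohort, truth, res = bym_fit
        post = res.posterior
        # fixed effect (log-rate scale ~ logit scale at these hazards)
        b = post["g[b]"]
        assert abs(b.mean() - np.log(1.5)) < 2 * b.std(ddof=1)
        # spatial fraction dominated by u
        psi, _ = res.spatial_fraction()
        assert psi > 0.5
        # sum-to-zero at every draw
        u = post.vector("u")
        assert np.abs(u.sum(axis=1)).max() < 1e-8
        # per-draw psi in [0, 1]
        su, sv = post["sigma2_u_marginal"], post["sigma2_v"]
        frac = su / (su + sv)
        assert ((frac >= 0) & (frac <= 1)).all()
        # conditional sigma2_u covers the generating value
        s2u = post["sigma2_u"]
        lo, hi = np.percentile(s2u, [2.5, 97.5])
        assert lo <= truth.sigma2_u_true <= hi

    def test_null_data_rr_intervals_cover_one(self, lattice100):
        """On a no-heterogeneity cohort at least 90% of area RR CrIs
        overlap 1."""
        cohort, _ = small_cohort(seed=31, sigma2_u=0.0, sigma2_v=0.0)
        strata = gs.aggregate_strata(cohort, ["g"])
        res = gs.SpatialPoissonModel(strata, lattice100, ["g"]).fit(
            n_iter=1500, burn_in=1500, seed=9
        )
        rr = res.smoothed_rr()
        covers = (rr["cri_2.5"] <= 1.0) & (rr["cri_97.5"] >= 1.0)
        assert covers.mean() >= 0.9

    def test_no_spatial_variant_matches_glm_oracle(self, lattice100):
        """include_u=False reduces to an exchangeable Poisson random-effects
        model; on null data its fixed effects match an independent Poisson
        GLM fit."""
        import statsmodels.api as sm

        cohort, _ = small_cohort(seed=33, sigma2_u=0.0, sigma2_v=0.0, n=10_000)
        strata = gs.aggregate_strata(cohort, ["g"])
        res = gs.SpatialPoissonModel(strata, lattice100, ["g"], include_u=False).fit(
            n_iter=1500, burn_in=1500, seed=4
        )
        z = np.column_stack(
            [(strata["interval"] == t).astype(float) for t in range(1, 6)]
            + [(strata["g"] == "b").astype(float)]
        )
        glm = sm.GLM(
            strata["d"], z, family=sm.families.Poisson(), offset=np.log(strata["y"])
        ).fit()
        b = res.posterior["g[b]"]
        assert abs(b.mean() - glm.params.iloc[5]) < 2 * b.std(ddof=1)
        assert (res.posterior["sigma2_u"] == 0).all()

    def test_determinism(self, path3):
        strata = make_strata(
            [(2, 5.0, 1, 0, "a"), (1, 4.0, 2, 1, "b"), (3, 6.0, 1, 2, "a"), (1, 3.0, 3, 1, "a")]
        )
        m = gs.SpatialPoissonModel(strata, path3, ["grp"])
        a = m.fit(n_iter=200, burn_in=200, seed=5).posterior.draws
        b = m.fit(n_iter=200, burn_in=200, seed=5).posterior.draws
        pd.testing.assert_frame_equal(a, b)

    def test_uniform_sd_hyperprior_runs(self, path3):
        strata = make_strata([(2, 5.0, 1, 0, "a"), (1, 4.0, 2, 1, "a"), (3, 6.0, 1, 2, "a")])
        hp = gs.HYPERPRIOR_GRID["unif-sd(0,10)"]
        res = gs.SpatialPoissonModel(strata, path3, [], hyperprior=hp).fit(
            n_iter=300, burn_in=300, seed=2
        )
        sd_u = np.sqrt(res.posterior["sigma2_u"])
        assert (sd_u < 10).all() and (sd_u > 0).all()

    def test_summary_renders(self, bym_fit):
        _, _, res = bym_fit
        text = res.summary()
        assert "Spatial fraction" in text and "DIC" in text
        vc = res.variance_components()
        assert {"sigma2_u_conditional", "sigma2_u_marginal", "sigma2_v", "total"} <= set(vc.index)
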