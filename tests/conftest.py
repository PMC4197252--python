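import numpy as np
import pandas as pd
import pytest

import geosurv as gs


@pytest.fixture(scope="session")
def lattice100():
    return gs.lattice_adjacency(10, 10)


@pytest.fixture(scope="session")
def toy_cohort():
    """Six hand-written patients in two areas; times chosen to exercise the
    truncation, censoring and within-interval exposure rules."""
    frame = pd.DataFrame(
        {
            "patient_id": ["p1", "p2", "p3", "p4", "p5", "p6"],
            "area_id": [0, 0, 1, 1, 0, 1],
            "grp": ["a", "b", "a", "b", "a", "b"],
            "time_years": [2.4, 3.0, 6.2, 0.5, 5.0, 1.0],
            "event": [1, 0, 1, 1, 1, 0],
        }
    )
    return gs.Cohort(frame, covariates=["grp"])


def small_cohort(
    seed,
    n=20_000,
    J=100,
    sigma2_u=0.0,
    sigma2_v=0.025,
    effect=np.log(1.5),
    target=0.581,
    adj=None,
):
    """One-binary-covariate synthetic cohort on a 10x10 lattice."""
    cfg = gs.SyntheticCohortConfig(
        n_areas=J,
        lattice_dims=(10, 10),
        n_patients=n,
        covariate_levels={"g": ["a", "b"]},
        covariate_freqs={"g": [0.5, 0.5]},
        covariate_effects={"g": [0.0, effect]},
        sigma2_u=sigma2_u,
        sigma2_v=sigma2_v,
        target_5yr_survival=target,
        seed=seed,
    )
    return gs.generate_cohort(cfg, adj)


@pytest.fixture(scope="session")
def bym_fit(lattice100):
    """A spatial fit on data with dominant spatial heterogeneity, shared by
    the recovery, diagnostics and smoothed-RR tests."""
    mf = gs.icar_marginal_factor(lattice100)
    cohort, truth = small_cohort(
        seed=21, sigma2_u=0.018 / mf, sigma2_v=0.006, adj=lattice100
    )
    strata = gs.aggregate_strata(cohort, ["g"])
    model = gs.SpatialPoissonModel(strata, lattice100, ["g"])
    res = model.fit(n_iter=3000, burn_in=2000, seed=7)
    return cohort, truth, res
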