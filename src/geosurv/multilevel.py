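"""Multilevel discrete-time logistic survival model with area random
intercepts.

The model treats each survived year of each patient as a Bernoulli trial:
the discrete hazard ``h_tij`` — the probability that patient i in area j
dies during year t given survival to t-1 — follows

    logit(h_tij) = f_t + x_ij' beta + u_j,      u_j ~ N(0, sigma2_u)

with a separate baseline logit hazard ``f_t`` per follow-up year (coded as
an intercept plus year dummies, reference year 1) and independent normal
area effects.  Estimation is Metropolis-within-Gibbs: a joint random-walk
update for the fixed effects with a proposal covariance from the
logistic-regression mode, simultaneous per-area random-walk updates for the
``u_j`` (independent given the fixed effects), and a conjugate Gibbs draw of
the precision ``tau_u = 1/sigma2_u`` from its Gamma full conditional.
Priors follow common multilevel-software defaults: improper flat priors on
fixed effects and Gamma(shape 0.1, scale 1000) on the precision.

Between-area heterogeneity is summarised by the median odds ratio
``MOR = exp(sqrt(2 sigma2_u) * z_0.75)`` — the median of the odds ratio
between the higher- and lower-risk area of two randomly drawn areas, for
identical individuals — which is >= 1 by construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from . import diagnostics
from .design import categorical_design
from .samples import PosteriorSamples

__all__ = [
    "DiscreteTimeMultilevel",
    "MultilevelResults",
    "median_odds_ratio",
    "area_effect_test",
    "fit_multilevel",
    "loglik_discrete",
    "Z_075",
]

#: 75th percentile of the standard normal, the constant in the MOR formula
Z_075 = float(stats.norm.ppf(0.75))

#: precision hyperprior (shape, scale): Gamma(0.1, 1000), mean 100
TAU_PRIOR_SHAPE = 0.1
TAU_PRIOR_SCALE = 1000.0


def _bernoulli_loglik(eta: np.ndarray, d: np.ndarray, n: np.ndarray) -> float:
    """Sum of Bernoulli log-pmfs over aggregated rows: d successes out of n
    trials at linear predictor eta (no binomial coefficient — the data are a
    product of Bernoullis, merely grouped)."""
    return float(d @ eta - n @ np.logaddexp(0.0, eta))


class DiscreteTimeMultilevel:
    """Discrete-time multilevel logistic survival model.

    Parameters
    ----------
    person_period : DataFrame
        Expanded person-period file from
        :func:`geosurv.data.expand_person_period` (columns ``e``,
        ``interval``, ``area_id`` and the covariates).
    covariates : list of str
        Categorical covariates to adjust for (may be empty: null model).
    n_areas : int
        Total number of areas J (areas without patients keep a random effect
        drawn from its prior).
    references : dict, optional
        Reference level per covariate; defaults to each covariate's first
        category.
    """

    def __init__(
        self,
        person_period: pd.DataFrame,
        covariates: list[str],
        n_areas: int | None = None,
        references: dict[str, str] | None = None,
        max_years: int = 5,
    ) -> None:
        if len(person_period) == 0:
            raise ValueError("empty person-period table")
        if person_period["e"].sum() == 0:
            raise ValueError("no events in the person-period table")
        self.covariates = list(covariates)
        self.max_years = max_years
        xcov, cov_names = categorical_design(person_period, self.covariates, references)
        interval = person_period["interval"].to_numpy()
        year_dummies = np.column_stack(
            [(interval == t).astype(float) for t in range(2, max_years + 1)]
        )
        x = np.column_stack([np.ones(len(person_period)), year_dummies, xcov])
        self.param_names = (
            ["intercept"] + [f"year[{t}]" for t in range(2, max_years + 1)] + cov_names
        )
        area = person_period["area_id"].to_numpy(dtype=np.int64)
        self.n_areas = int(n_areas) if n_areas is not None else int(area.max()) + 1

        # aggregate identical (design row, area) combinations into binomial
        # counts: the Bernoulli likelihood only depends on these totals
        key = pd.DataFrame(x, columns=self.param_names)
        key["__area"] = area
        key["__e"] = person_period["e"].to_numpy()
        grouped = key.groupby(self.param_names + ["__area"], sort=False, observed=True)
        agg = grouped["__e"].agg(["sum", "size"]).reset_index()
        self._x = agg[self.param_names].to_numpy()
        self._area = agg["__area"].to_numpy(dtype=np.int64)
        self._d = agg["sum"].to_numpy(dtype=float)
        self._n = agg["size"].to_numpy(dtype=float)
        self.n_params = self._x.shape[1]

    # -- likelihood ---------------------------------------------------------

    def loglik(self, beta: np.ndarray, u: np.ndarray) -> float:
        """Log-likelihood at fixed effects ``beta`` (intercept, year dummies,
        covariate dummies) and area effects ``u``."""
        beta = np.asarray(beta, dtype=float)
        u = np.asarray(u, dtype=float)
        if beta.shape != (self.n_params,) or u.shape != (self.n_areas,):
            raise ValueError(
                f"expected beta of length {self.n_params} and u of length "
                f"{self.n_areas}, got {beta.shape} and {u.shape}"
            )
        eta = self._x @ beta + u[self._area]
        return _bernoulli_loglik(eta, self._d, self._n)

    def log_posterior(self, beta: np.ndarray, u: np.ndarray, sigma2_u: float) -> float:
        """Unnormalised log-posterior: likelihood, N(0, sigma2_u) prior on
        each u_j, Gamma(0.1, scale 1000) prior on the precision (flat priors
        on beta contribute nothing)."""
        if sigma2_u <= 0:
            raise ValueError("sigma2_u must be positive")
        u = np.asarray(u, dtype=float)
        tau = 1.0 / sigma2_u
        lp = self.loglik(beta, u)
        lp += float(stats.norm.logpdf(u, scale=np.sqrt(sigma2_u)).sum())
        lp += float(stats.gamma.logpdf(tau, TAU_PRIOR_SHAPE, scale=TAU_PRIOR_SCALE))
        return lp

    def map_fit(self, max_iter: int = 100, tol: float = 1e-10):
        """Posterior mode of beta with u fixed at 0 (flat priors: the plain
        logistic-regression MLE on the expanded file).  Newton-Raphson with
        step halving; returns (beta_hat, covariance)."""
        x, d, n = self._x, self._d, self._n
        beta = np.zeros(self.n_params)
        ll = _bernoulli_loglik(x @ beta, d, n)
        for _ in range(max_iter):
            eta = x @ beta
            p = expit(eta)
            grad = x.T @ (d - n * p)
            w = n * p * (1.0 - p)
            hess = x.T @ (x * w[:, None])
            step = np.linalg.solve(hess, grad)
            scale = 1.0
            for _ in range(30):
                cand = beta + scale * step
                ll_new = _bernoulli_loglik(x @ cand, d, n)
                if ll_new >= ll:
                    break
                scale *= 0.5
            if abs(ll_new - ll) < tol:
                beta, ll = cand, ll_new
                break
            beta, ll = cand, ll_new
        eta = x @ beta
        p = expit(eta)
        w = n * p * (1.0 - p)
        cov = np.linalg.inv(x.T @ (x * w[:, None]))
        return beta, cov

    # -- sampler -------------------------------------------------------------

    def fit(
        self,
        n_iter: int = 10_000,
        burn_in: int = 5_000,
        seed: int = 0,
        n_chains: int = 1,
        thin: int = 1,
    ) -> "MultilevelResults":
        """Run the Metropolis-within-Gibbs sampler.

        ``n_iter`` draws are retained after ``burn_in`` adaptation
        iterations (proposal scales adapt towards 20-50% acceptance during
        burn-in only).  Deterministic given ``seed``; chains beyond the first
        get independent sub-streams and are concatenated.
        """
        seeds = [seed] if n_chains == 1 else list(
            np.random.SeedSequence(seed).generate_state(n_chains) % (2**31)
        )
        chains = [self._run_chain(n_iter, burn_in, int(s), thin) for s in seeds]
        draws = pd.concat([c.draws for c in chains], ignore_index=True)
        dev = np.concatenate([c.deviance for c in chains])
        meta = dict(chains[0].meta, n_chains=n_chains, seed=seed)
        return MultilevelResults(self, PosteriorSamples(draws, deviance=dev, meta=meta))

    def _run_chain(self, n_iter: int, burn_in: int, seed: int, thin: int) -> PosteriorSamples:
        rng = np.random.default_rng(seed)
        J = self.n_areas
        x, d, n, area = self._x, self._d, self._n, self._area

        beta, map_cov = self.map_fit()
        chol = np.linalg.cholesky(map_cov + 1e-12 * np.eye(self.n_params))
        u = np.zeros(J)
        sigma2 = 0.01
        # counts of data rows per area; areas with no rows are prior-only
        rows_per_area = np.bincount(area, minlength=J)

        eta = x @ beta + u[area]
        row_ll = d * eta - n * np.logaddexp(0.0, eta)
        ll = float(row_ll.sum())

        log_scale_beta = np.log(2.38 / np.sqrt(self.n_params))
        log_scale_u = np.full(J, np.log(0.5))
        acc_beta = 0
        acc_u = np.zeros(J)

        total = burn_in + n_iter * thin
        kept = np.empty((n_iter, self.n_params + J + 1))
        dev = np.empty(n_iter)
        k = 0
        for it in range(total):
            adapt = it < burn_in
            gamma = min(0.1, 10.0 / (it + 1)) if adapt else 0.0

            # --- joint fixed-effect update
            prop = beta + np.exp(log_scale_beta) * (chol @ rng.standard_normal(self.n_params))
            eta_prop = x @ prop + u[area]
            ll_prop = _bernoulli_loglik(eta_prop, d, n)
            accept = np.log(rng.random()) < ll_prop - ll
            if accept:
                beta, eta, ll = prop, eta_prop, ll_prop
                row_ll = d * eta - n * np.logaddexp(0.0, eta)
                acc_beta += 0 if adapt else 1
            if adapt:
                log_scale_beta += gamma * ((1.0 if accept else 0.0) - 0.3)

            # --- simultaneous per-area random-effect updates (iid prior:
            # areas are conditionally independent given beta and sigma2)
            step = np.exp(log_scale_u) * rng.standard_normal(J)
            u_prop = u + step
            eta_new = eta + step[area]
            row_ll_new = d * eta_new - n * np.logaddexp(0.0, eta_new)
            dll = np.bincount(area, weights=row_ll_new - row_ll, minlength=J)
            dprior = (u**2 - u_prop**2) / (2.0 * sigma2)
            acc = np.log(rng.random(J)) < dll + dprior
            u = np.where(acc, u_prop, u)
            moved = acc[area]
            eta = np.where(moved, eta_new, eta)
            row_ll = np.where(moved, row_ll_new, row_ll)
            ll = float(row_ll.sum())
            if adapt:
                log_scale_u += gamma * (acc.astype(float) - 0.35)
            elif it >= burn_in:
                acc_u += acc

            # --- conjugate Gibbs draw for the precision
            shape = TAU_PRIOR_SHAPE + 0.5 * J
            rate = 1.0 / TAU_PRIOR_SCALE + 0.5 * float(u @ u)
            tau = rng.gamma(shape, 1.0 / rate)
            sigma2 = 1.0 / tau

            if it >= burn_in and (it - burn_in) % thin == 0:
                kept[k, : self.n_params] = beta
                kept[k, self.n_params : -1] = u
                kept[k, -1] = sigma2
                dev[k] = -2.0 * ll
                k += 1

        names = self.param_names + [f"u[{j}]" for j in range(J)] + ["sigma2_u"]
        meta = {
            "burn_in": burn_in,
            "n_iter": n_iter,
            "thin": thin,
            "seed": seed,
            "accept_beta": acc_beta / max(n_iter * thin, 1),
            "accept_u_mean": float(np.mean(acc_u) / max(n_iter * thin, 1)),
            "n_prior_only_areas": int((rows_per_area == 0).sum()),
        }
        return PosteriorSamples(pd.DataFrame(kept[:k], columns=names), deviance=dev[:k], meta=meta)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def median_odds_ratio(sigma2_samples: np.ndarray) -> tuple[float, tuple[float, float]]:
    """MOR point estimate and 95% CrI from posterior draws of the area-level
    variance.

    The point estimate applies ``exp(sqrt(2 sigma2) * z_0.75)`` to the
    posterior median variance; the interval takes the 2.5/97.5 percentiles of
    the per-draw MOR.  A single value may be passed for plain arithmetic.
    """
    s = np.atleast_1d(np.asarray(sigma2_samples, dtype=float))
    if s.size == 0:
        raise ValueError("need at least one variance draw")
    if (s < 0).any():
        raise ValueError("negative variance draw")
    per_draw = np.exp(np.sqrt(2.0 * s) * Z_075)
    point = float(np.exp(np.sqrt(2.0 * np.median(s)) * Z_075))
    lo, hi = np.percentile(per_draw, [2.5, 97.5])
    return point, (float(lo), float(hi))


def area_effect_test(sigma2_samples: np.ndarray) -> tuple[float, float]:
    """Approximate Wald chi-square test of sigma2_u = 0 (1 df) from the
    posterior mean and SD; returns (statistic, p)."""
    s = np.asarray(sigma2_samples, dtype=float)
    sd = s.std(ddof=1)
    if sd == 0:
        return (np.inf, 0.0) if s.mean() > 0 else (0.0, 1.0)
    w = (s.mean() / sd) ** 2
    return float(w), float(stats.chi2.sf(w, df=1))


class MultilevelResults:
    """Posterior summaries for a fitted discrete-time multilevel model."""

    def __init__(self, model: DiscreteTimeMultilevel, posterior: PosteriorSamples) -> None:
        self.model = model
        self.posterior = posterior

    @property
    def sigma2_u(self) -> np.ndarray:
        return self.posterior["sigma2_u"]

    def mor(self) -> tuple[float, tuple[float, float]]:
        return median_odds_ratio(self.sigma2_u)

    def wald_area_test(self) -> tuple[float, float]:
        return area_effect_test(self.sigma2_u)

    def odds_ratios(self) -> pd.DataFrame:
        """Posterior median OR with 95% CrI per covariate dummy."""
        names = [n for n in self.model.param_names if "[" in n and not n.startswith("year")]
        rows = {}
        for nm in names:
            draw = np.exp(self.posterior[nm])
            rows[nm] = {
                "or": float(np.median(draw)),
                "cri_2.5": float(np.percentile(draw, 2.5)),
                "cri_97.5": float(np.percentile(draw, 97.5)),
            }
        return pd.DataFrame(rows).T

    def baseline_hazards(self) -> np.ndarray:
        """Posterior median baseline logit hazards f_1..f_T (intercept +
        year-dummy parameterisation mapped back)."""
        inter = self.posterior["intercept"]
        f = [np.median(inter)]
        for t in range(2, self.model.max_years + 1):
            f.append(np.median(inter + self.posterior[f"year[{t}]"]))
        return np.array(f)

    def dic(self) -> tuple[float, float]:
        beta_bar = np.array([self.posterior[p].mean() for p in self.model.param_names])
        u_bar = self.posterior.vector("u").mean(axis=0)
        return diagnostics.dic(self.posterior.deviance, self.model.loglik(beta_bar, u_bar))

    def geweke_table(self, names: list[str] | None = None) -> pd.DataFrame:
        monitored = names or (self.model.param_names + ["sigma2_u"])
        return diagnostics.geweke_table(self.posterior, monitored)

    def summary(self) -> str:
        fixed = self.posterior.summary(self.model.param_names + ["sigma2_u"])
        mor_pt, (mor_lo, mor_hi) = self.mor()
        wald, p = self.wald_area_test()
        dic_val, pd_val = self.dic()
        lines = [
            "Multilevel discrete-time survival model",
            f"  areas: {self.model.n_areas}   draws: {self.posterior.n_draws}",
            "",
            fixed.round(4).to_string(),
            "",
            f"MOR: {mor_pt:.2f} (95% CrI {mor_lo:.2f}, {mor_hi:.2f})",
            f"Wald test of area variance: chi2 = {wald:.2f}, p = {p:.3g}",
            f"DIC: {dic_val:.1f} (pD = {pd_val:.1f})",
        ]
        return "\n".join(lines)

    def plot_trace(self, names: list[str], ax=None):
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(len(names), 1, squeeze=False, figsize=(7, 2 * len(names)))
        for a, nm in zip(axes[:, 0], names):
            a.plot(self.posterior[nm], lw=0.5)
            a.set_ylabel(nm)
        axes[-1, 0].set_xlabel("draw")
        return fig


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------

def loglik_discrete(
    beta: np.ndarray,
    u: np.ndarray,
    person_period: pd.DataFrame,
    covariates: list[str],
    n_areas: int | None = None,
    **kwargs,
) -> float:
    """Discrete-time log-likelihood on a person-period table (convenience
    wrapper constructing the model object)."""
    m = DiscreteTimeMultilevel(person_period, covariates, n_areas=n_areas, **kwargs)
    return m.loglik(beta, u)


def fit_multilevel(
    person_period: pd.DataFrame,
    covariates: list[str],
    n_areas: int | None = None,
    mcmc: dict | None = None,
    **kwargs,
) -> MultilevelResults:
    """Build and fit the multilevel model in one call; ``mcmc`` may contain
    ``n_iter``, ``burn_in``, ``seed``, ``n_chains``, ``thin``."""
    m = DiscreteTimeMultilevel(person_period, covariates, n_areas=n_areas, **kwargs)
    return m.fit(**(mcmc or {}))
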