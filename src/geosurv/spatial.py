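"""Bayesian spatial piecewise-exponential Poisson survival model.

Deaths aggregated by covariate stratum m, annual interval t and area j are
modelled as

    d_mtj ~ Poisson(mu_mtj),   mu_mtj = y_mtj * exp(alpha_t + x_m' beta + u_j + v_j)

with person-time ``y_mtj`` as offset, a time-varying intercept ``alpha_t``
(constant hazard within each year: the piecewise-exponential construction,
a close approximation to the Cox model), and the classic convolution
decomposition of the area effect: ``u_j`` spatially structured under an
intrinsic CAR prior over the adjacency graph and ``v_j`` exchangeable
N(0, sigma2_v).  Exponentiated area effects are the smoothed relative risks
(RR) of death; the *spatial fraction* Psi — the marginal variance of the
realised ``u`` field over the total area-level variance — measures how much
of the residual heterogeneity is spatially structured.

Sampling is Metropolis-within-Gibbs: a joint random-walk for
(alpha, beta) with a mode-based proposal covariance, blocked per-area
random-walk updates of ``u`` over a graph colouring (areas of one colour
are conditionally independent under the ICAR prior), simultaneous updates
of ``v``, and conjugate Gamma draws for both precisions (random-walk on
log sigma under Uniform-on-SD hyperpriors).  ``u`` is recentred to
sum-to-zero within each connected component after every sweep; islands are
pinned at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from . import diagnostics
from .adjacency import AdjacencyStructure
from .design import categorical_design
from .samples import PosteriorSamples

__all__ = [
    "HyperPrior",
    "HYPERPRIOR_GRID",
    "DEFAULT_HYPERPRIOR",
    "SpatialPoissonModel",
    "SpatialResults",
    "icar_logdensity",
    "spatial_fraction",
    "spatial_fraction_from_components",
    "smoothed_rr",
    "fit_spatial",
    "loglik_poisson",
]


@dataclass(frozen=True)
class HyperPrior:
    """Variance-hyperprior setting for the two area-effect precisions.

    ``kind`` is ``"gamma"`` (Gamma on the precisions, shape-scale
    parameterisation: Gamma(0.1, 100) has mean 10 and variance 1000) or
    ``"uniform_sd"`` (Uniform on the standard deviations).
    """

    kind: str
    u_params: tuple[float, float]
    v_params: tuple[float, float]

    def __post_init__(self) -> None:
        if self.kind not in ("gamma", "uniform_sd"):
            raise ValueError(f"unknown hyperprior kind {self.kind!r}")


#: default setting: Gamma(shape 0.1, scale 100) on both precisions
DEFAULT_HYPERPRIOR = HyperPrior("gamma", (0.1, 100.0), (0.1, 100.0))

#: the five standard sensitivity-analysis settings: three Gamma-on-precision
#: choices and two Uniform-on-SD choices
HYPERPRIOR_GRID: dict[str, HyperPrior] = {
    "gamma(0.1,100)": DEFAULT_HYPERPRIOR,
    "gamma(0.5,1000)": HyperPrior("gamma", (0.5, 1000.0), (0.5, 1000.0)),
    "gamma(0.1,10)/(0.001,1000)": HyperPrior("gamma", (0.1, 10.0), (0.001, 1000.0)),
    "unif-sd(0,10)": HyperPrior("uniform_sd", (0.0, 10.0), (0.0, 10.0)),
    "unif-sd(0,1000)": HyperPrior("uniform_sd", (0.0, 1000.0), (0.0, 1000.0)),
}


def icar_logdensity(u: np.ndarray, adj: AdjacencyStructure, sigma2_u: float) -> float:
    """Unnormalised intrinsic-CAR log-density
    ``-(1/(2 sigma2_u)) * sum_{j<k} w_jk (u_j - u_k)^2`` (islands contribute
    nothing: they have no edges)."""
    u = np.asarray(u, dtype=float)
    if u.shape != (adj.n_areas,):
        raise ValueError(f"u must have length {adj.n_areas}")
    if sigma2_u <= 0:
        raise ValueError("sigma2_u must be positive")
    diff = u[adj.edges[:, 0]] - u[adj.edges[:, 1]]
    return float(-(diff @ diff) / (2.0 * sigma2_u))


class SpatialPoissonModel:
    """Piecewise-exponential Poisson survival model with BYM area effects.

    Parameters
    ----------
    strata : DataFrame
        Aggregated table from :func:`geosurv.data.aggregate_strata` with
        columns ``d`` (deaths), ``y`` (person-time > 0), ``interval`` and
        ``area_id`` plus the covariates.
    adj : AdjacencyStructure
        Area adjacency graph for the ICAR prior.
    covariates : list of str
        Categorical covariates (may be empty: null model).
    include_u, include_v : bool
        Drop the spatial or the unstructured effect to fit the reduced
        variants; at least one must be kept.
    """

    def __init__(
        self,
        strata: pd.DataFrame,
        adj: AdjacencyStructure,
        covariates: list[str],
        include_u: bool = True,
        include_v: bool = True,
        hyperprior: HyperPrior = DEFAULT_HYPERPRIOR,
        references: dict[str, str] | None = None,
        max_years: int = 5,
        fixed_effect_prior_sd: float = 1000.0,
    ) -> None:
        if not include_u and not include_v:
            raise ValueError("at least one of include_u / include_v must be True")
        if len(strata) == 0:
            raise ValueError("empty stratum table")
        if (strata["y"] <= 0).any():
            raise ValueError("strata with non-positive person-time must be dropped")
        if strata["d"].sum() == 0:
            raise ValueError("no deaths in the stratum table")
        area = strata["area_id"].to_numpy(dtype=np.int64)
        if area.min() < 0 or area.max() >= adj.n_areas:
            raise ValueError("strata reference areas outside the adjacency structure")
        self.adj = adj
        self.covariates = list(covariates)
        self.include_u = include_u
        self.include_v = include_v
        self.hyperprior = hyperprior
        self.max_years = max_years
        self.prior_sd = fixed_effect_prior_sd

        self._d = strata["d"].to_numpy(dtype=float)
        self._y = strata["y"].to_numpy(dtype=float)
        self._area = area
        interval = strata["interval"].to_numpy(dtype=np.int64)
        if interval.min() < 1 or interval.max() > max_years:
            raise ValueError("interval outside 1..max_years")
        self._t = interval - 1
        self._xcov, cov_names = categorical_design(strata, self.covariates, references)
        self.alpha_names = [f"alpha[{t}]" for t in range(1, max_years + 1)]
        self.beta_names = cov_names
        self._log_y = np.log(self._y)
        self._logfact = gammaln(self._d + 1.0)
        self.n_areas = adj.n_areas
        # areas in components of size >= 2 carry the ICAR constraint
        self._non_island = adj.neighbor_counts > 0
        comp = adj.component_labels
        self._icar_components = [
            np.flatnonzero((comp == c) & self._non_island)
            for c in range(adj.n_components)
            if ((comp == c) & self._non_island).sum() >= 2
        ]
        self._icar_rank = int(self._non_island.sum() - len(self._icar_components))

    # -- likelihood ---------------------------------------------------------

    def _eta(self, alpha, beta, u, v):
        eta = alpha[self._t] + u[self._area] + v[self._area]
        if self._xcov.shape[1]:
            eta = eta + self._xcov @ beta
        return eta

    def loglik(self, alpha: np.ndarray, beta: np.ndarray, u: np.ndarray, v: np.ndarray) -> float:
        """Poisson log-likelihood (log-factorial terms included) at
        time intercepts ``alpha`` (length T), covariate effects ``beta``,
        and area effects ``u``, ``v``."""
        alpha = np.asarray(alpha, dtype=float)
        beta = np.asarray(beta, dtype=float)
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        if alpha.shape != (self.max_years,) or beta.shape != (self._xcov.shape[1],):
            raise ValueError("alpha/beta dimension mismatch")
        if u.shape != (self.n_areas,) or v.shape != (self.n_areas,):
            raise ValueError("u/v dimension mismatch")
        eta = self._eta(alpha, beta, u, v)
        log_mu = self._log_y + eta
        return float(self._d @ log_mu - np.exp(log_mu).sum() - self._logfact.sum())

    def map_fit(self, max_iter: int = 100, tol: float = 1e-10):
        """Mode of (alpha, beta) with u = v = 0 by Newton-Raphson on the
        Poisson log-likelihood; returns (theta_hat, covariance)."""
        z = np.column_stack(
            [(self._t == t).astype(float) for t in range(self.max_years)] + [self._xcov]
        ) if self._xcov.shape[1] else np.column_stack(
            [(self._t == t).astype(float) for t in range(self.max_years)]
        )
        p = z.shape[1]
        theta = np.zeros(p)
        # start alpha at the crude log rate
        theta[: self.max_years] = np.log(max(self._d.sum(), 0.5) / self._y.sum())
        for _ in range(max_iter):
            mu = self._y * np.exp(z @ theta)
            grad = z.T @ (self._d - mu) - theta / self.prior_sd**2
            hess = z.T @ (z * mu[:, None]) + np.eye(p) / self.prior_sd**2
            step = np.linalg.solve(hess, grad)
            theta = theta + step
            if np.abs(step).max() < tol:
                break
        mu = self._y * np.exp(z @ theta)
        cov = np.linalg.inv(z.T @ (z * mu[:, None]) + np.eye(p) / self.prior_sd**2)
        return theta, cov

    # -- sampler -------------------------------------------------------------

    def fit(
        self,
        n_iter: int = 20_000,
        burn_in: int = 10_000,
        seed: int = 0,
        n_chains: int = 1,
        thin: int = 1,
    ) -> "SpatialResults":
        """Run the sampler; ``n_iter`` retained draws after ``burn_in``
        adaptation iterations, deterministic given ``seed``."""
        seeds = [seed] if n_chains == 1 else list(
            np.random.SeedSequence(seed).generate_state(n_chains) % (2**31)
        )
        chains = [self._run_chain(n_iter, burn_in, int(s), thin) for s in seeds]
        draws = pd.concat([c.draws for c in chains], ignore_index=True)
        dev = np.concatenate([c.deviance for c in chains])
        meta = dict(chains[0].meta, n_chains=n_chains, seed=seed)
        return SpatialResults(self, PosteriorSamples(draws, deviance=dev, meta=meta))

    def _gibbs_tau(self, rng, params, quad, k):
        """Conjugate Gamma draw of a precision given its quadratic form
        ``quad`` and degrees of freedom ``k``; returns the variance."""
        shape0, scale0 = params
        tau = rng.gamma(shape0 + 0.5 * k, 1.0 / (1.0 / scale0 + 0.5 * quad))
        return 1.0 / tau

    def _mh_sigma_uniform(self, rng, sigma, bounds, quad, k, log_step):
        """Random-walk on log sigma under a Uniform(lo, hi) prior on sigma;
        target density sigma^-k * exp(-quad / (2 sigma^2))."""
        lo, hi = bounds
        prop = sigma * np.exp(np.exp(log_step) * rng.standard_normal())
        if not lo < prop < hi:
            return sigma, False
        logr = (
            -k * np.log(prop) - quad / (2.0 * prop**2) + np.log(prop)
            - (-k * np.log(sigma) - quad / (2.0 * sigma**2) + np.log(sigma))
        )
        if np.log(rng.random()) < logr:
            return prop, True
        return sigma, False

    def _run_chain(self, n_iter, burn_in, seed, thin) -> PosteriorSamples:
        rng = np.random.default_rng(seed)
        J = self.n_areas
        d, y, a, t = self._d, self._y, self._area, self._t
        edges = self.adj.edges
        ncount = self.adj.neighbor_counts.astype(float)
        colors = self.adj.coloring() if self.include_u else []
        p_beta = self._xcov.shape[1]
        p_theta = self.max_years + p_beta

        theta, map_cov = self.map_fit()
        chol = np.linalg.cholesky(map_cov + 1e-12 * np.eye(p_theta))
        # start the area effects at shrunken crude log-SMR residuals rather
        # than zero: the random-walk amplitude of the u field grows slowly,
        # so a cold start biases short chains towards too-small variances
        mu0 = self._y * np.exp(self._eta(theta[: self.max_years], theta[self.max_years :],
                                         np.zeros(J), np.zeros(J)))
        d_area = np.bincount(a, weights=d, minlength=J)
        mu_area = np.bincount(a, weights=mu0, minlength=J)
        resid = np.log((d_area + 0.5) / (mu_area + 0.5))
        resid[mu_area == 0] = 0.0
        if self.include_u:
            u = np.where(self._non_island, resid, 0.0)
            for comp in self._icar_components:
                u[comp] -= u[comp].mean()
            u *= 0.5
        else:
            u = np.zeros(J)
        v = np.zeros(J)
        sigma2_u = max(float(u[self._non_island].var()) , 1e-3) if self.include_u else 0.01
        sigma2_v = 0.01

        def row_loglik(eta):
            log_mu = self._log_y + eta
            return d * log_mu - np.exp(log_mu)

        def neighbor_sums(u):
            s = np.zeros(J)
            np.add.at(s, edges[:, 0], u[edges[:, 1]])
            np.add.at(s, edges[:, 1], u[edges[:, 0]])
            return s

        alpha = theta[: self.max_years]
        beta = theta[self.max_years :]
        eta = self._eta(alpha, beta, u, v)
        rll = row_loglik(eta)
        ll = float(rll.sum())

        log_scale_theta = np.log(2.38 / np.sqrt(p_theta))
        log_scale_u = np.full(J, np.log(0.5))
        log_scale_v = np.full(J, np.log(0.5))
        log_scale_su = log_scale_sv = np.log(0.5)
        acc_theta = 0

        total = burn_in + n_iter * thin
        ncols = p_theta + 2 * J + 4
        kept = np.empty((n_iter, ncols))
        dev = np.empty(n_iter)
        k = 0
        for it in range(total):
            adapt = it < burn_in
            gamma = min(0.1, 10.0 / (it + 1)) if adapt else 0.0

            # --- joint (alpha, beta) update
            prop = theta + np.exp(log_scale_theta) * (chol @ rng.standard_normal(p_theta))
            eta_prop = self._eta(prop[: self.max_years], prop[self.max_years :], u, v)
            rll_prop = row_loglik(eta_prop)
            ll_prop = float(rll_prop.sum())
            dprior = float((theta @ theta - prop @ prop) / (2.0 * self.prior_sd**2))
            accept = np.log(rng.random()) < ll_prop - ll + dprior
            if accept:
                theta, eta, rll, ll = prop, eta_prop, rll_prop, ll_prop
                alpha = theta[: self.max_years]
                beta = theta[self.max_years :]
                if not adapt:
                    acc_theta += 1
            if adapt:
                log_scale_theta += gamma * ((1.0 if accept else 0.0) - 0.3)

            # --- spatial effects, one colour class at a time
            if self.include_u:
                tau_u = 1.0 / sigma2_u
                for cls in colors:
                    cls = cls[self._non_island[cls]]
                    if cls.size == 0:
                        continue
                    step = np.zeros(J)
                    step[cls] = np.exp(log_scale_u[cls]) * rng.standard_normal(cls.size)
                    u_prop = u + step
                    eta_new = eta + step[a]
                    rll_new = row_loglik(eta_new)
                    dll = np.bincount(a, weights=rll_new - rll, minlength=J)
                    s = neighbor_sums(u)  # within-class neighbours absent by colouring
                    dpri = -0.5 * tau_u * (
                        ncount * u_prop**2 - 2.0 * u_prop * s - (ncount * u**2 - 2.0 * u * s)
                    )
                    acc = np.zeros(J, dtype=bool)
                    acc[cls] = np.log(rng.random(cls.size)) < (dll + dpri)[cls]
                    u = np.where(acc, u_prop, u)
                    moved = acc[a]
                    eta = np.where(moved, eta_new, eta)
                    rll = np.where(moved, rll_new, rll)
                    if adapt:
                        log_scale_u[cls] += gamma * (acc[cls].astype(float) - 0.35)
                # recentre per connected component (sum-to-zero constraint)
                for comp in self._icar_components:
                    u[comp] -= u[comp].mean()
                eta = self._eta(alpha, beta, u, v)
                rll = row_loglik(eta)
                ll = float(rll.sum())
                diff = u[edges[:, 0]] - u[edges[:, 1]]
                quad_u = float(diff @ diff)
                if self.hyperprior.kind == "gamma":
                    sigma2_u = self._gibbs_tau(rng, self.hyperprior.u_params, quad_u, self._icar_rank)
                else:
                    s_u, _ = self._mh_sigma_uniform(
                        rng, np.sqrt(sigma2_u), self.hyperprior.u_params, quad_u,
                        self._icar_rank, log_scale_su,
                    )
                    sigma2_u = s_u**2

            # --- unstructured effects, all areas at once (iid prior)
            if self.include_v:
                step = np.exp(log_scale_v) * rng.standard_normal(J)
                v_prop = v + step
                eta_new = eta + step[a]
                rll_new = row_loglik(eta_new)
                dll = np.bincount(a, weights=rll_new - rll, minlength=J)
                dpri = (v**2 - v_prop**2) / (2.0 * sigma2_v)
                acc = np.log(rng.random(J)) < dll + dpri
                v = np.where(acc, v_prop, v)
                moved = acc[a]
                eta = np.where(moved, eta_new, eta)
                rll = np.where(moved, rll_new, rll)
                ll = float(rll.sum())
                if adapt:
                    log_scale_v += gamma * (acc.astype(float) - 0.35)
                quad_v = float(v @ v)
                if self.hyperprior.kind == "gamma":
                    sigma2_v = self._gibbs_tau(rng, self.hyperprior.v_params, quad_v, J)
                else:
                    s_v, _ = self._mh_sigma_uniform(
                        rng, np.sqrt(sigma2_v), self.hyperprior.v_params, quad_v, J, log_scale_sv,
                    )
                    sigma2_v = s_v**2

            if it >= burn_in and (it - burn_in) % thin == 0:
                kept[k, :p_theta] = theta
                kept[k, p_theta : p_theta + J] = u
                kept[k, p_theta + J : p_theta + 2 * J] = v
                non_island_u = u[self._non_island]
                kept[k, -4] = sigma2_u if self.include_u else 0.0
                kept[k, -3] = float(non_island_u.var(ddof=1)) if self.include_u else 0.0
                kept[k, -2] = sigma2_v if self.include_v else 0.0
                dev[k] = -2.0 * (ll - float(self._logfact.sum()))
                kept[k, -1] = dev[k]
                k += 1

        names = (
            self.alpha_names
            + self.beta_names
            + [f"u[{j}]" for j in range(J)]
            + [f"v[{j}]" for j in range(J)]
            + ["sigma2_u", "sigma2_u_marginal", "sigma2_v", "_dev"]
        )
        frame = pd.DataFrame(kept[:k], columns=names).drop(columns="_dev")
        meta = {
            "burn_in": burn_in,
            "n_iter": n_iter,
            "thin": thin,
            "seed": seed,
            "hyperprior": f"{self.hyperprior.kind} u={self.hyperprior.u_params} v={self.hyperprior.v_params}",
            "accept_theta": acc_theta / max(n_iter * thin, 1),
        }
        return PosteriorSamples(frame, deviance=dev[:k], meta=meta)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def spatial_fraction_from_components(sigma2_u_marginal: float, sigma2_v: float) -> float:
    """Spatial fraction Psi = s_u / (s_u + s_v) from the marginal spatial and
    unstructured variance components."""
    if sigma2_u_marginal < 0 or sigma2_v < 0:
        raise ValueError("variance components must be non-negative")
    total = sigma2_u_marginal + sigma2_v
    if total == 0:
        raise ValueError("both variance components are zero: Psi undefined")
    return sigma2_u_marginal / total


def spatial_fraction(samples: PosteriorSamples) -> tuple[float, tuple[float, float]]:
    """Posterior median and 95% CrI of the per-draw spatial fraction
    ``Psi = sigma2_u_marginal / (sigma2_u_marginal + sigma2_v)``.  Draws with
    both components zero are dropped with a warning."""
    su = samples["sigma2_u_marginal"]
    sv = samples["sigma2_v"]
    total = su + sv
    ok = total > 0
    if not ok.all():
        warnings.warn(f"dropping {int((~ok).sum())} draw(s) with zero total variance", stacklevel=2)
    if not ok.any():
        raise ValueError("spatial fraction undefined: all draws have zero total variance")
    psi = su[ok] / total[ok]
    lo, hi = np.percentile(psi, [2.5, 97.5])
    return float(np.median(psi)), (float(lo), float(hi))


def smoothed_rr(samples: PosteriorSamples, n_areas: int | None = None) -> pd.DataFrame:
    """Per-area posterior median smoothed relative risk exp(u_j + v_j) with
    95% CrIs, sorted by median (caterpillar-plot order).  Models without one
    of the effects use the remaining one."""
    parts = []
    for prefix in ("u", "v"):
        try:
            parts.append(samples.vector(prefix))
        except KeyError:
            pass
    if not parts:
        raise ValueError("samples contain neither u nor v effects")
    effect = sum(parts)
    rr = np.exp(effect)
    med = np.median(rr, axis=0)
    lo, hi = np.percentile(rr, [2.5, 97.5], axis=0)
    out = pd.DataFrame({"area_id": np.arange(effect.shape[1]), "rr": med, "cri_2.5": lo, "cri_97.5": hi})
    return out.sort_values("rr").reset_index(drop=True)


class SpatialResults:
    """Posterior summaries for a fitted spatial survival model."""

    def __init__(self, model: SpatialPoissonModel, posterior: PosteriorSamples) -> None:
        self.model = model
        self.posterior = posterior

    def spatial_fraction(self) -> tuple[float, tuple[float, float]]:
        if not (self.model.include_u and self.model.include_v):
            raise ValueError("spatial fraction needs both u and v in the model")
        return spatial_fraction(self.posterior)

    def smoothed_rr(self) -> pd.DataFrame:
        keep = []
        if self.model.include_u:
            keep.append(self.posterior.vector("u"))
        if self.model.include_v:
            keep.append(self.posterior.vector("v"))
        rr = np.exp(sum(keep))
        med = np.median(rr, axis=0)
        lo, hi = np.percentile(rr, [2.5, 97.5], axis=0)
        out = pd.DataFrame(
            {"area_id": np.arange(self.model.n_areas), "rr": med, "cri_2.5": lo, "cri_97.5": hi}
        )
        return out.sort_values("rr").reset_index(drop=True)

    def variance_components(self) -> pd.DataFrame:
        """Median and 95% CrI of the conditional spatial, marginal spatial,
        unstructured and total (marginal + unstructured) variances."""
        su_c = self.posterior["sigma2_u"]
        su_m = self.posterior["sigma2_u_marginal"]
        sv = self.posterior["sigma2_v"]
        rows = {
            "sigma2_u_conditional": su_c,
            "sigma2_u_marginal": su_m,
            "sigma2_v": sv,
            "total": su_m + sv,
        }
        return pd.DataFrame(
            {
                name: {
                    "median": float(np.median(x)),
                    "cri_2.5": float(np.percentile(x, 2.5)),
                    "cri_97.5": float(np.percentile(x, 97.5)),
                }
                for name, x in rows.items()
            }
        ).T

    def relative_risks(self) -> pd.DataFrame:
        """Posterior median RR with 95% CrI per covariate dummy."""
        rows = {}
        for nm in self.model.beta_names:
            draw = np.exp(self.posterior[nm])
            rows[nm] = {
                "rr": float(np.median(draw)),
                "cri_2.5": float(np.percentile(draw, 2.5)),
                "cri_97.5": float(np.percentile(draw, 97.5)),
            }
        return pd.DataFrame(rows).T if rows else pd.DataFrame(columns=["rr", "cri_2.5", "cri_97.5"])

    def dic(self) -> tuple[float, float]:
        post = self.posterior
        alpha_bar = np.array([post[nm].mean() for nm in self.model.alpha_names])
        beta_bar = np.array([post[nm].mean() for nm in self.model.beta_names])
        u_bar = post.vector("u").mean(axis=0)
        v_bar = post.vector("v").mean(axis=0)
        return diagnostics.dic(post.deviance, self.model.loglik(alpha_bar, beta_bar, u_bar, v_bar))

    def geweke_table(self, names: list[str] | None = None) -> pd.DataFrame:
        monitored = names or (
            self.model.alpha_names + self.model.beta_names + ["sigma2_u", "sigma2_v"]
        )
        return diagnostics.geweke_table(self.posterior, monitored)

    def summary(self) -> str:
        fixed = self.posterior.summary(self.model.alpha_names + self.model.beta_names)
        vc = self.variance_components()
        dic_val, p_d = self.dic()
        lines = [
            "Bayesian spatial piecewise-exponential survival model",
            f"  areas: {self.model.n_areas}   draws: {self.posterior.n_draws}",
            f"  hyperprior: {self.posterior.meta.get('hyperprior', '?')}",
            "",
            fixed.round(4).to_string(),
            "",
            "Variance components:",
            vc.round(4).to_string(),
        ]
        if self.model.include_u and self.model.include_v:
            psi, (lo, hi) = self.spatial_fraction()
            lines.append(f"Spatial fraction Psi: {psi:.2f} (95% CrI {lo:.2f}, {hi:.2f})")
        lines.append(f"DIC: {dic_val:.1f} (pD = {p_d:.1f})")
        return "\n".join(lines)

    def plot_caterpillar(self, ax=None):
        import matplotlib.pyplot as plt

        rr = self.smoothed_rr()
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        xs = np.arange(len(rr))
        ax.plot(xs, rr["rr"], "k-", lw=1)
        ax.fill_between(xs, rr["cri_2.5"], rr["cri_97.5"], color="grey", alpha=0.4)
        ax.axhline(1.0, color="red", lw=0.8)
        ax.set_xlabel("area (sorted by smoothed RR)")
        ax.set_ylabel("smoothed RR")
        return ax


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------

def loglik_poisson(
    alpha, beta, u, v, strata: pd.DataFrame, adj: AdjacencyStructure, covariates: list[str], **kwargs
) -> float:
    """Poisson log-likelihood on a stratum table (convenience wrapper)."""
    m = SpatialPoissonModel(strata, adj, covariates, **kwargs)
    return m.loglik(alpha, beta, u, v)


def fit_spatial(
    strata: pd.DataFrame,
    adj: AdjacencyStructure,
    covariates: list[str],
    mcmc: dict | None = None,
    **kwargs,
) -> SpatialResults:
    """Build and fit the spatial model in one call."""
    m = SpatialPoissonModel(strata, adj, covariates, **kwargs)
    return m.fit(**(mcmc or {}))
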