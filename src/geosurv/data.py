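"""Cohort data model and the two survival-data transformations.

The package's models consume the same individual-level cohort in two
different shapes:

* a *person-period file* — one row per patient per survived year with a
  binary death response, the input of the multilevel discrete-time logistic
  model;
* a *stratum table* — deaths and person-time aggregated over covariate
  pattern x year x area, the input of the piecewise-exponential Poisson
  model.

Both transformations truncate follow-up at ``max_years`` (5 by default, so
a death after year 5 counts as censored at 5).  Kaplan-Meier descriptives
and the log-rank test (via lifelines) are provided for cohort description.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

__all__ = [
    "Cohort",
    "expand_person_period",
    "aggregate_strata",
    "km_estimate",
    "log_rank",
]

#: reserved column names in a cohort file; everything else is a covariate
CORE_COLUMNS = ("patient_id", "area_id", "time_years", "event")


@dataclass
class Cohort:
    """Individual-level survival records: one row per patient.

    ``frame`` must contain ``patient_id``, ``area_id`` (integer area index
    into the adjacency structure), ``time_years`` (death or censoring time
    r > 0) and ``event`` (1 = died, 0 = censored); every remaining listed
    column is a categorical covariate.
    """

    frame: pd.DataFrame
    covariates: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in CORE_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"cohort frame missing columns {missing}")
        if not self.covariates:
            self.covariates = [c for c in self.frame.columns if c not in CORE_COLUMNS]
        t = self.frame["time_years"].to_numpy()
        if (t <= 0).any():
            bad = self.frame.loc[t <= 0, "patient_id"].iloc[0]
            raise ValueError(
                f"non-positive survival time for patient {bad!r}; "
                "patients must survive at least one day"
            )
        ev = self.frame["event"].to_numpy()
        if not np.isin(ev, (0, 1)).all():
            raise ValueError("event indicator must be 0 or 1")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n_events(self) -> int:
        return int(self.frame["event"].sum())

    def to_csv(self, path: str) -> None:
        cols = list(CORE_COLUMNS) + self.covariates
        self.frame[cols].to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str, covariates: list[str] | None = None) -> "Cohort":
        return cls(pd.read_csv(path), covariates or [])


def _truncate(time: np.ndarray, event: np.ndarray, max_years: float):
    """Administrative truncation: deaths after max_years become censorings."""
    t = np.minimum(time, max_years)
    e = np.where(time <= max_years, event, 0)
    return t, e


def expand_person_period(cohort: Cohort, max_years: int = 5) -> pd.DataFrame:
    """Expand a cohort into the annual person-period file.

    A patient contributes one row per year survived, up to
    ``k = min(ceil(r), max_years)``; the binary response ``e`` is 1 only in
    the final row and only for a death within follow-up — a death during
    year 3 has responses (0, 0, 1), a censoring in year 3 has (0, 0, 0).
    Year-dummy columns ``D1..D{max_years}`` encode the interval for the
    piecewise baseline hazard.
    """
    df = cohort.frame
    r = df["time_years"].to_numpy(dtype=float)
    t5, e5 = _truncate(r, df["event"].to_numpy(), max_years)
    k = np.minimum(np.ceil(r).astype(int), max_years)

    idx = np.repeat(np.arange(len(df)), k)
    interval = np.concatenate([np.arange(1, ki + 1) for ki in k]) if len(df) else np.array([], int)
    out = pd.DataFrame(
        {
            "patient_id": df["patient_id"].to_numpy()[idx],
            "area_id": df["area_id"].to_numpy()[idx],
            "interval": interval,
        }
    )
    out["e"] = ((interval == k[idx]) & (e5[idx] == 1)).astype(int)
    for c in cohort.covariates:
        out[c] = df[c].to_numpy()[idx]
    for t in range(1, max_years + 1):
        out[f"D{t}"] = (interval == t).astype(int)
    return out


def aggregate_strata(
    cohort: Cohort, covariate_list: list[str], max_years: int = 5
) -> pd.DataFrame:
    """Aggregate the cohort into deaths ``d`` and person-time ``y`` by
    covariate stratum x annual interval x area.

    Each patient contributes their exact within-interval time at risk
    ``min(r, t) - (t - 1)`` to ``y`` and, if they died within follow-up, a
    single death to ``d`` in the interval containing r.  Rows with zero
    person-time are dropped (the Poisson offset is undefined there).
    """
    unknown = [c for c in covariate_list if c not in cohort.frame.columns]
    if unknown:
        raise ValueError(f"unknown covariate(s) {unknown}")
    if not covariate_list:
        raise ValueError("covariate_list must be non-empty (use a constant column for a null model)")
    df = cohort.frame
    r = np.minimum(df["time_years"].to_numpy(dtype=float), float(max_years))
    _, e5 = _truncate(df["time_years"].to_numpy(dtype=float), df["event"].to_numpy(), max_years)
    k = np.minimum(np.ceil(df["time_years"].to_numpy(dtype=float)).astype(int), max_years)

    idx = np.repeat(np.arange(len(df)), k)
    interval = np.concatenate([np.arange(1, ki + 1) for ki in k]) if len(df) else np.array([], int)
    y = np.minimum(r[idx], interval) - (interval - 1)
    y = np.maximum(y, 0.0)
    d = ((interval == k[idx]) & (e5[idx] == 1)).astype(int)

    long = pd.DataFrame({"area_id": df["area_id"].to_numpy()[idx], "interval": interval, "d": d, "y": y})
    for c in covariate_list:
        long[c] = df[c].to_numpy()[idx]
    grouped = (
        long.groupby(covariate_list + ["interval", "area_id"], observed=True, sort=True)[["d", "y"]]
        .sum()
        .reset_index()
    )
    grouped = grouped[grouped["y"] > 0].reset_index(drop=True)
    return grouped


def km_estimate(
    cohort: Cohort, group_by: str | None = None, max_years: float = 5.0
) -> pd.DataFrame:
    """Kaplan-Meier survival curve(s) with Greenwood 95% CIs, follow-up
    restricted to ``max_years``.  Returns a long table with columns
    ``group`` (or 'all'), ``time``, ``survival``, ``lower``, ``upper``."""
    df = cohort.frame
    groups = [("all", df)] if group_by is None else list(df.groupby(group_by, observed=True))
    frames = []
    for name, sub in groups:
        if len(sub) == 0:
            raise ValueError(f"empty group {name!r}")
        t, e = _truncate(sub["time_years"].to_numpy(dtype=float), sub["event"].to_numpy(), max_years)
        kmf = KaplanMeierFitter()
        kmf.fit(t, e)
        ci = kmf.confidence_interval_survival_function_
        out = pd.DataFrame(
            {
                "group": name,
                "time": kmf.survival_function_.index.to_numpy(),
                "survival": kmf.survival_function_["KM_estimate"].to_numpy(),
                "lower": ci.iloc[:, 0].to_numpy(),
                "upper": ci.iloc[:, 1].to_numpy(),
            }
        )
        frames.append(out)
    return pd.concat(frames, ignore_index=True)


def log_rank(cohort: Cohort, group: str, max_years: float = 5.0) -> tuple[float, float]:
    """Log-rank test for equality of survivor functions across the levels of
    ``group``; returns (chi-square statistic, p-value)."""
    df = cohort.frame
    if cohort.n_events == 0:
        raise ValueError("log-rank test requires at least one event")
    t, e = _truncate(df["time_years"].to_numpy(dtype=float), df["event"].to_numpy(), max_years)
    res = multivariate_logrank_test(t, df[group].to_numpy(), e)
    stat = float(res.test_statistic)
    if math.isnan(stat):  # identical outcomes in all groups degenerate to 0
        return 0.0, 1.0
    return stat, float(res.p_value)
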