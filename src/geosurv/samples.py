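"""Container for MCMC posterior draws shared by both model backends."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PosteriorSamples"]


@dataclass
class PosteriorSamples:
    """Matrix of posterior draws with a parameter-name registry.

    ``draws`` is a DataFrame (one column per monitored parameter, one row per
    retained draw); ``deviance`` holds -2 x log-likelihood per draw;
    ``meta`` records burn-in, thinning, seed and acceptance rates.
    """

    draws: pd.DataFrame
    deviance: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.draws) == 0:
            raise ValueError("posterior must contain at least one draw")
        if self.draws.columns.duplicated().any():
            raise ValueError("parameter names must be unique")
        if not np.isfinite(self.draws.to_numpy()).all():
            raise ValueError("non-finite posterior draws")

    # -- access -------------------------------------------------------------

    @property
    def n_draws(self) -> int:
        return len(self.draws)

    @property
    def names(self) -> list[str]:
        return list(self.draws.columns)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.draws[name].to_numpy()

    def vector(self, prefix: str) -> np.ndarray:
        """Stack parameters named ``{prefix}[i]`` into a (draws, len) matrix."""
        cols = [c for c in self.draws.columns if c.startswith(prefix + "[")]
        cols.sort(key=lambda c: int(c[len(prefix) + 1 : -1]))
        if not cols:
            raise KeyError(f"no parameters with prefix {prefix!r}")
        return self.draws[cols].to_numpy()

    def posterior_mean(self) -> pd.Series:
        return self.draws.mean()

    def summary(self, names: list[str] | None = None) -> pd.DataFrame:
        """Median / mean / SD / 95% CrI per parameter."""
        sub = self.draws if names is None else self.draws[names]
        q = sub.quantile([0.5, 0.025, 0.975])
        return pd.DataFrame(
            {
                "median": q.loc[0.5],
                "mean": sub.mean(),
                "sd": sub.std(ddof=1),
                "cri_2.5": q.loc[0.025],
                "cri_97.5": q.loc[0.975],
            }
        )

    # -- I/O ------------------------------------------------------------------

    def save(self, path_base: str) -> None:
        """Write draws to ``{path_base}.csv`` and metadata to
        ``{path_base}.json``; the deviance travels as column ``_deviance``."""
        out = self.draws.copy()
        if self.deviance is not None:
            out["_deviance"] = self.deviance
        out.to_csv(path_base + ".csv", index=False)
        with open(path_base + ".json", "w") as fh:
            json.dump(self.meta, fh, indent=1, default=float)

    @classmethod
    def load(cls, path_base: str) -> "PosteriorSamples":
        df = pd.read_csv(path_base + ".csv")
        dev = None
        if "_deviance" in df.columns:
            dev = df.pop("_deviance").to_numpy()
        try:
            with open(path_base + ".json") as fh:
                meta = json.load(fh)
        except FileNotFoundError:
            meta = {}
        return cls(df, deviance=dev, meta=meta)
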