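"""Design-matrix construction for categorical covariates.

Both backends code categorical covariates as treatment (reference-level)
dummies; the reference level defaults to the first category of a pandas
Categorical column, or the first level in sorted order otherwise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["categorical_design"]


def categorical_design(
    df: pd.DataFrame,
    covariates: list[str],
    references: dict[str, str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Dummy-code ``covariates`` (no intercept column).

    Returns the (n, p) design matrix and the column names
    ``"{covariate}[{level}]"`` for every non-reference level, in covariate
    order.  Raises if the resulting matrix is rank-deficient.
    """
    references = references or {}
    cols: list[np.ndarray] = []
    names: list[str] = []
    for name in covariates:
        s = df[name]
        if isinstance(s.dtype, pd.CategoricalDtype):
            levels = list(s.cat.categories)
        else:
            levels = sorted(pd.unique(s))
        ref = references.get(name, levels[0])
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} not found in covariate {name!r}")
        vals = s.to_numpy()
        for lev in levels:
            if lev == ref:
                continue
            cols.append((vals == lev).astype(float))
            names.append(f"{name}[{lev}]")
    x = np.column_stack(cols) if cols else np.empty((len(df), 0))
    if x.shape[1] and np.linalg.matrix_rank(x - x.mean(axis=0)) < x.shape[1]:
        raise ValueError("design matrix is rank deficient (aliased covariate levels)")
    return x, names
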