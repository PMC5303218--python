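"""Variable normalization and latent-confounder covariates.

Two readings of "quantile normalization" are provided: the default
rank-based inverse-normal transform applied per variable (the usual choice
for forcing approximate normality of a single quantitative trait before a
Gaussian mixed model), and array-style cross-sample quantile normalization
that maps every column onto the average empirical distribution. Unknown
sources of biological/technical covariation can be absorbed by including
the leading principal components of the response matrix as fixed-effect
covariates.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .phenotype import PhenotypeTable

__all__ = [
    "quantile_normalize",
    "quantile_normalize_array",
    "normalize_table",
    "confounder_pcs",
]


def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform of one variable.

    A non-missing value with (average, for ties) rank r among n maps to
    ``Phi^{-1}((r - 0.5) / n)``; missing values stay missing. The output
    depends on the input only through ranks, so any monotone transform of
    the input yields the identical result.
    """
    values = np.asarray(values, dtype=float)
    out = np.full(values.shape, np.nan)
    obs = ~np.isnan(values)
    n = int(obs.sum())
    if n < 3:
        raise ValueError(f"inverse-normal transform needs >=3 non-missing values, have {n}")
    ranks = rankdata(values[obs], method="average")
    out[obs] = norm.ppf((ranks - 0.5) / n)
    return out


def quantile_normalize_array(df: pd.DataFrame) -> pd.DataFrame:
    """Cross-sample quantile normalization against the mean distribution.

    Each column is mapped onto the across-column average of the sorted
    values (the expression-array method). Columns with missing entries are
    mapped through interpolated quantiles of the reference distribution.
    """
    ref_quantiles = np.linspace(0, 1, df.shape[0])
    sorted_cols = []
    for c in df.columns:
        col = df[c].dropna().to_numpy()
        if col.size < 3:
            raise ValueError(f"column {c!r} has fewer than 3 non-missing values")
        sorted_cols.append(
            np.interp(ref_quantiles, np.linspace(0, 1, col.size), np.sort(col))
        )
    reference = np.mean(sorted_cols, axis=0)
    out = df.copy()
    for c in df.columns:
        col = df[c].to_numpy(dtype=float)
        obs = ~np.isnan(col)
        n = int(obs.sum())
        ranks = rankdata(col[obs], method="average")
        q = (ranks - 0.5) / n
        col = col.copy()
        col[obs] = np.interp(q, ref_quantiles, reference)
        out[c] = col
    return out


def normalize_table(table: PhenotypeTable, method: str = "inverse_normal") -> PhenotypeTable:
    """Normalize every variable of a table; ``method`` is ``inverse_normal``,
    ``quantile_array`` or ``none``."""
    if method == "none":
        return table
    if method == "inverse_normal":
        data = table.data.apply(
            lambda col: pd.Series(quantile_normalize(col.to_numpy()), index=col.index)
        )
    elif method == "quantile_array":
        data = quantile_normalize_array(table.data)
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return PhenotypeTable(data, positions=table.positions)


def confounder_pcs(
    matrix: pd.DataFrame,
    pct_variance: float,
    scale: bool = False,
) -> pd.DataFrame:
    """Principal-component covariates explaining ``pct_variance`` percent.

    PCA of the column-centered (optionally unit-variance-scaled) matrix on
    complete cases; returns the smallest leading set of component score
    columns whose cumulative explained-variance fraction reaches
    ``pct_variance / 100``, indexed like the input (incomplete individuals
    get missing scores).
    """
    if not (0 < pct_variance <= 100):
        raise ValueError("pct_variance must be in (0, 100]")
    if matrix.shape[1] < 2:
        raise ValueError("confounder PCA needs at least 2 variables")
    complete = matrix.dropna(axis=0)
    Z = complete.to_numpy(dtype=float)
    Z = Z - Z.mean(axis=0)
    if scale:
        sd = Z.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Z = Z / sd
    _u, s, vt = np.linalg.svd(Z, full_matrices=False)
    var = s**2
    total = var.sum()
    if total == 0:
        raise ValueError("matrix has zero variance")
    frac = np.cumsum(var) / total
    k = int(np.searchsorted(frac, pct_variance / 100 - 1e-12) + 1)
    k = min(k, int(np.sum(var > total * 1e-12)))
    scores = Z @ vt[:k].T
    cols = [f"PC{i + 1}" for i in range(k)]
    return pd.DataFrame(scores, index=complete.index, columns=cols).reindex(
        matrix.index
    )
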