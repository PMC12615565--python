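"""Cohort-level behavioural statistics.

Pairwise Pearson correlation matrix with two-tailed p-values (t-transform,
n-2 df), Benjamini-Hochberg FDR adjustment over the unique off-diagonal
pairs, and the recruitment power computation for a fixed-effect regression
(noncentral-F with lambda = f^2 * n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationMatrix",
    "PowerSpec",
    "pearson_matrix",
    "fdr_adjust",
    "regression_power",
    "minimal_n",
]

#: variables reported on an inverse scale (higher value = lower sensitivity);
#: correlations with them flip sign in interpretation
INVERSE_MEASURES = frozenset({"is_filters"})


@dataclass
class CorrelationMatrix:
    variables: list[str]
    R: pd.DataFrame
    p_raw: pd.DataFrame
    p_fdr: pd.DataFrame
    n_used: pd.DataFrame
    significant: pd.DataFrame  # at the uncorrected alpha
    alpha: float
    inverse_annotated: list[tuple[str, str]]


@dataclass(frozen=True)
class PowerSpec:
    f_squared: float = 0.15
    alpha: float = 0.05
    target_power: float = 0.80
    n_predictors: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.f_squared <= 0:
            raise ValueError("f_squared must be positive")
        if self.n_predictors < 1:
            raise ValueError("n_predictors must be >= 1")
        if not 0 < self.target_power < 1:
            raise ValueError("target_power must be in (0, 1)")


def pearson_matrix(
    table: pd.DataFrame, variables: list[str] | None = None, alpha: float = 0.05
) -> CorrelationMatrix:
    """All-pairs Pearson correlations with raw and FDR-adjusted p-values.

    Pairs are evaluated on complete observations.  A constant column yields an
    explicit missing value (NaN), never a silent zero.  Pairs involving an
    inverse-scaled measure (interoceptive sensitivity counts filters, so high
    values mean low sensitivity) are listed in ``inverse_annotated``.
    """
    if variables is None:
        variables = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    k = len(variables)
    R = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n_used = np.zeros((k, k), dtype=int)
    np.fill_diagonal(R, 1.0)
    np.fill_diagonal(p, 0.0)
    pairs: list[tuple[int, int]] = []
    for i in range(k):
        n_used[i, i] = table[variables[i]].notna().sum()
        for j in range(i + 1, k):
            sub = table[[variables[i], variables[j]]].dropna()
            n = len(sub)
            n_used[i, j] = n_used[j, i] = n
            if n < 3:
                raise ValueError(
                    f"fewer than 3 complete observations for pair "
                    f"({variables[i]}, {variables[j]})"
                )
            x, y = sub.iloc[:, 0].to_numpy(float), sub.iloc[:, 1].to_numpy(float)
            if np.std(x) == 0 or np.std(y) == 0:
                pairs.append((i, j))
                continue  # undefined correlation stays NaN
            r, pv = stats.pearsonr(x, y)
            R[i, j] = R[j, i] = r
            p[i, j] = p[j, i] = pv
            pairs.append((i, j))
    # BH family: all unique off-diagonal pairs with a defined p-value
    flat_idx = [(i, j) for i, j in pairs if np.isfinite(p[i, j])]
    p_fdr = np.full_like(p, np.nan)
    np.fill_diagonal(p_fdr, 0.0)
    if flat_idx:
        adj = fdr_adjust(np.array([p[i, j] for i, j in flat_idx]))
        for (i, j), a in zip(flat_idx, adj):
            p_fdr[i, j] = p_fdr[j, i] = a
    as_df = lambda a: pd.DataFrame(a, index=variables, columns=variables)
    sig = (p < alpha) & ~np.eye(k, dtype=bool)
    inverse = [
        (variables[i], variables[j])
        for i, j in pairs
        if (variables[i] in INVERSE_MEASURES) != (variables[j] in INVERSE_MEASURES)
    ]
    return CorrelationMatrix(
        variables=list(variables),
        R=as_df(R),
        p_raw=as_df(p),
        p_fdr=as_df(p_fdr),
        n_used=as_df(n_used),
        significant=as_df(sig),
        alpha=alpha,
        inverse_annotated=inverse,
    )


def fdr_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p.ravel(), method="fdr_bh")[1].reshape(p.shape)


def regression_power(spec: PowerSpec, n: int) -> float:
    """Power of the F-test for the full regression effect at sample size n.

    Noncentral-F with numerator df = number of predictors, denominator
    df = n - predictors - 1 and noncentrality lambda = f^2 * n.
    """
    df1 = spec.n_predictors
    df2 = n - spec.n_predictors - 1
    if df2 < 1:
        raise ValueError(f"n={n} too small for {spec.n_predictors} predictors")
    f_crit = stats.f.ppf(1.0 - spec.alpha, df1, df2)
    return float(stats.ncf.sf(f_crit, df1, df2, spec.f_squared * n))


def minimal_n(spec: PowerSpec, n_max: int = 10_000) -> int:
    """Smallest n achieving the target power, by integer search."""
    for n in range(spec.n_predictors + 2, n_max + 1):
        if regression_power(spec, n) >= spec.target_power:
            return n
    raise ValueError(f"target power not reached by n={n_max}")
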