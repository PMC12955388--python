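"""Distance-based multivariate ANOVA by permutation (PERMANOVA).

Single-factor tests permute raw sample labels.  Marginal (by-margin)
tests assess each factor with all other model terms retained, using
permutation of residuals under the reduced model (Freedman-Lane), which
is what "controlling for all other variables" requires.

Categorical factors are expanded to treatment-coded indicator columns;
aliased columns are dropped in input order.  Age-like continuous factors
enter as a single column.  Negative eigenvalue contributions of
non-Euclidean matrices are retained in the sum-of-squares accounting.
"""

from __future__ import annotations

import math
from itertools import permutations as _iterperms

import numpy as np
import pandas as pd

from .cohort import AssociationResult, DistanceMatrix

__all__ = [
    "gower_center",
    "design_columns",
    "permanova_single",
    "permanova_marginal",
]

_RANK_TOL = 1e-8


def gower_center(dist: DistanceMatrix | np.ndarray) -> np.ndarray:
    """Gower-centered inner-product matrix G = -1/2 J A J, A = d^2.

    G is symmetric with zero row sums; trace(G) is the total sum of
    squares (1/n) sum_{i<j} d_ij^2.
    """
    d = dist.values if isinstance(dist, DistanceMatrix) else np.asarray(dist, float)
    n = d.shape[0]
    a = -0.5 * d ** 2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def design_columns(values, name: str = "factor") -> np.ndarray:
    """Centered design-matrix block for one factor.

    Numeric input gives one centered column; anything else is treated as
    categorical and expanded to treatment coding (first sorted level
    dropped).
    """
    s = pd.Series(values)
    if s.isna().any():
        raise ValueError(f"factor {name!r} has missing values")
    if pd.api.types.is_numeric_dtype(s) and not isinstance(s.dtype, pd.CategoricalDtype):
        x = s.to_numpy(dtype=float)[:, None]
    else:
        levels = sorted(s.astype(str).unique())
        if len(levels) < 2:
            raise ValueError(f"factor {name!r} has one level")
        x = np.column_stack(
            [(s.astype(str) == lev).to_numpy(dtype=float) for lev in levels[1:]]
        )
    return x - x.mean(axis=0)


def _hat(x: np.ndarray) -> tuple[np.ndarray, int]:
    """Projection matrix onto the column space of x, and its rank."""
    n = x.shape[0]
    if x.size == 0:
        return np.zeros((n, n)), 0
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    keep = s > _RANK_TOL * max(s[0], 1.0)
    u = u[:, keep]
    return u @ u.T, int(keep.sum())


def _check_factor_levels(values, name: str) -> None:
    s = pd.Series(values)
    if s.astype(str).nunique() < 2:
        raise ValueError(f"factor {name!r} has one level")


def permanova_single(
    dist: DistanceMatrix,
    factor,
    n_perm: int = 999,
    seed: int | None = None,
    exact: bool = False,
    name: str = "factor",
) -> AssociationResult:
    """One-factor PERMANOVA with whole-sample label permutation.

    With ``exact=True`` all n! permutations are enumerated (n <= 9) and
    the p-value is the exact fraction with F at least as large as
    observed (identity included).
    """
    n = len(dist)
    _check_factor_levels(factor, name)
    if len(pd.Series(factor)) != n:
        raise ValueError("factor length does not match distance matrix")
    g = gower_center(dist)
    x = design_columns(factor, name)
    h, rank = _hat(x)
    ss_total = float(np.trace(g))
    ss_model = float(np.sum(h * g))
    ss_resid = ss_total - ss_model
    df_model = rank
    df_resid = n - rank - 1
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    eps = 1e-12 * max(abs(ss_total), 1.0)

    def f_stat(ssm: float, ssr: float) -> float:
        if ssr <= eps:  # model absorbs everything
            return float("inf")
        return (ssm / df_model) / (ssr / df_resid)

    f_obs = f_stat(ss_model, ss_resid)
    r2 = ss_model / ss_total if ss_total > 0 else 0.0

    def f_of_perm(perm: np.ndarray) -> float:
        gp = g[np.ix_(perm, perm)]
        ssm = float(np.sum(h * gp))
        return f_stat(ssm, ss_total - ssm)

    if exact:
        if n > 9:
            raise ValueError("exact enumeration limited to n <= 9")
        total = math.factorial(n)
        count = sum(
            1
            for perm in _iterperms(range(n))
            if f_of_perm(np.asarray(perm)) >= f_obs - 1e-12
        )
        p = count / total
        n_permutations = total - 1
    else:
        if n_perm < 99:
            raise ValueError("n_perm must be >= 99")
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            if f_of_perm(rng.permutation(n)) >= f_obs - 1e-12:
                count += 1
        p = (1 + count) / (1 + n_perm)
        n_permutations = n_perm
    return AssociationResult(
        factor=name,
        r_squared=max(0.0, min(1.0, r2)),
        p_value=p,
        n_permutations=n_permutations,
        f_statistic=f_obs,
    )


def permanova_marginal(
    dist: DistanceMatrix,
    factors: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = None,
) -> list[AssociationResult]:
    """Marginal-effects PERMANOVA: each factor controlling for the rest.

    ``factors`` is a sample-aligned frame (rows in distance-matrix label
    order).  For each factor, SS_margin = SS(full) - SS(without factor);
    significance comes from Freedman-Lane permutation of residuals under
    the reduced model.  A factor adding no rank beyond the others is
    flagged aliased with R^2 = 0.
    """
    n = len(dist)
    if factors.shape[0] != n:
        raise ValueError("factor frame does not align with distance matrix")
    if factors.shape[1] < 1:
        raise ValueError("need at least one factor")
    g = gower_center(dist)
    ss_total = float(np.trace(g))
    blocks = {
        name: design_columns(factors[name], str(name)) for name in factors.columns
    }
    x_full = np.hstack([blocks[name] for name in factors.columns])
    h_full, rank_full = _hat(x_full)
    ss_full = float(np.sum(h_full * g))
    df_resid = n - rank_full - 1
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom in the full model")
    ss_resid = ss_total - ss_full

    rng = np.random.default_rng(seed)
    eye = np.eye(n)
    results: list[AssociationResult] = []
    for name in factors.columns:
        others = [blocks[o] for o in factors.columns if o != name]
        x_red = np.hstack(others) if others else np.zeros((n, 0))
        h_red, rank_red = _hat(x_red)
        df_f = rank_full - rank_red
        if df_f == 0:
            results.append(
                AssociationResult(
                    factor=str(name), r_squared=0.0, p_value=float("nan"),
                    n_permutations=n_perm, f_statistic=float("nan"),
                    aliased=True,
                )
            )
            continue
        eps = 1e-12 * max(abs(ss_total), 1.0)
        ss_margin = max(0.0, ss_full - float(np.sum(h_red * g)))
        f_obs = (
            float("inf") if ss_resid <= eps
            else (ss_margin / df_f) / (ss_resid / df_resid)
        )
        h_margin = h_full - h_red
        resid_proj = eye - h_red
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            t = h_red + resid_proj[perm]  # fitted + permuted residual operator
            g_star = t @ g @ t.T
            ssm = float(np.sum(h_margin * g_star))
            ssr = float(np.sum((eye - h_full) * g_star))
            if ssr <= eps:
                f_star = float("inf")
            else:
                f_star = (ssm / df_f) / (ssr / df_resid)
            if f_star >= f_obs - 1e-12:
                count += 1
        p = (1 + count) / (1 + n_perm)
        results.append(
            AssociationResult(
                factor=str(name),
                r_squared=max(0.0, min(1.0, ss_margin / ss_total)) if ss_total > 0 else 0.0,
                p_value=p,
                n_permutations=n_perm,
                f_statistic=f_obs,
            )
        )
    return results
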