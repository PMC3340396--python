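"""Variation partitioning and lmg hierarchical relative importance.

Two complementary decompositions of a response's explained variance:

* :func:`partition` splits R² between a spatial predictor table (AEM
  eigenfunctions) and an environmental table into pure-spatial, pure-
  environmental, shared, and residual fractions (the two-circle Venn
  diagram of two-table ecological partitioning).  Adjusted R² (Ezekiel) is
  the default for the Venn fractions; small negative adjusted fractions are
  reported as-is, never clipped.

* :func:`lmg_importance` decomposes a single model's R² over predictors by
  the lmg rule: each predictor's share is its sequential R² contribution
  averaged over all p! orderings of entry, computed exactly through the
  equivalent subset reformulation (2^p subset R² values).

:func:`despatialized_importance` chains the two: response and environmental
predictors are first residualized on the spatial basis (true partial
regression), then lmg is applied to the residualized system — the relative
importance of local conditions once upstream connectivity is removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd

__all__ = [
    "PartitionResult",
    "ImportanceResult",
    "partition",
    "lmg_importance",
    "despatialized_importance",
]


@dataclass
class PartitionResult:
    """Venn fractions of a two-table variation partitioning."""

    pure_spatial: float
    pure_environmental: float
    shared: float
    residual: float
    r2_spatial: float       # R² of the spatial-only model (adjusted if flagged)
    r2_environmental: float
    r2_full: float
    adjusted: bool

    def as_dict(self) -> dict[str, float]:
        return {
            "pure_spatial": self.pure_spatial,
            "pure_environmental": self.pure_environmental,
            "shared": self.shared,
            "residual": self.residual,
            "r2_spatial": self.r2_spatial,
            "r2_environmental": self.r2_environmental,
            "r2_full": self.r2_full,
        }


@dataclass
class ImportanceResult:
    """lmg relative-importance decomposition of one model's R²."""

    predictors: list[str]
    shares: np.ndarray              # fractions of total variance; sum = R²
    r2: float
    percentages: np.ndarray = field(init=False)  # normalised to sum 100

    def __post_init__(self) -> None:
        total = self.shares.sum()
        self.percentages = (
            100.0 * self.shares / total if total > 0 else np.zeros_like(self.shares)
        )

    def to_series(self) -> pd.Series:
        return pd.Series(self.shares, index=self.predictors)


@dataclass
class DespatializedImportance:
    """lmg importance after removing the spatial signal from both sides."""

    predictors: list[str]
    shares_residual: np.ndarray     # fractions of residualized variance
    shares_total: np.ndarray        # rescaled to fractions of total variance
    r2_residual: float
    residual_variance_fraction: float  # var(y residual) / var(y)
    degenerate: bool = False

    @property
    def pct_of_environmental(self) -> np.ndarray:
        total = self.shares_residual.sum()
        return (
            100.0 * self.shares_residual / total
            if total > 0
            else np.zeros_like(self.shares_residual)
        )


def _r2(X: np.ndarray, y: np.ndarray) -> float:
    n = y.size
    Xd = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    resid = y - Xd @ beta
    tss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - float(resid @ resid) / tss if tss > 0 else 0.0


def _adjust(r2: float, n: int, p: int) -> float:
    """Ezekiel adjustment; can legitimately be negative."""
    if n - p - 1 <= 0:
        raise ValueError(f"cannot adjust R² with n={n}, p={p}")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def partition(
    y,
    X_spatial,
    X_env,
    adjusted: bool = True,
) -> PartitionResult:
    """Two-table variation partitioning of y between spatial and environmental sets.

    Fits the three OLS models (spatial, environmental, union) and returns
    pure_spatial = R²(union) − R²(env), pure_environmental = R²(union) −
    R²(spatial), shared = R²(spatial) + R²(env) − R²(union), residual = 1 −
    R²(union).  With ``adjusted`` (default) each R² is Ezekiel-adjusted
    before differencing, which debiases the fractions for unequal numbers of
    predictors; negative adjusted fractions are possible and reported as-is.
    """
    y = np.asarray(y, dtype=float)
    Xs = np.atleast_2d(np.asarray(X_spatial, dtype=float))
    Xe = np.atleast_2d(np.asarray(X_env, dtype=float))
    if Xs.shape[0] != y.size:
        Xs = Xs.T
    if Xe.shape[0] != y.size:
        Xe = Xe.T
    n = y.size
    p_s, p_e = Xs.shape[1], Xe.shape[1]
    if n <= p_s + p_e + 1:
        raise ValueError(f"n={n} too small for {p_s + p_e} combined predictors")
    r2_s = _r2(Xs, y)
    r2_e = _r2(Xe, y)
    r2_u = _r2(np.column_stack([Xs, Xe]), y)
    if adjusted:
        r2_s = _adjust(r2_s, n, p_s)
        r2_e = _adjust(r2_e, n, p_e)
        r2_u = _adjust(r2_u, n, p_s + p_e)
    return PartitionResult(
        pure_spatial=r2_u - r2_e,
        pure_environmental=r2_u - r2_s,
        shared=r2_s + r2_e - r2_u,
        residual=1.0 - r2_u,
        r2_spatial=r2_s,
        r2_environmental=r2_e,
        r2_full=r2_u,
        adjusted=adjusted,
    )


def lmg_importance(
    y, X: pd.DataFrame, max_exact_p: int = 10
) -> ImportanceResult:
    """Exact lmg shares: average sequential R² contribution over all orderings.

    Computed through the subset reformulation: share_j = Σ over subsets S of
    the other predictors of w(|S|) · [R²(S ∪ {j}) − R²(S)], with weights
    w(k) = k!(p−1−k)!/p! — identical to enumerating all p! orderings but
    needing only the 2^p subset R² values.  Shares are fractions of total
    variance and sum exactly to the full model's R².
    """
    y = np.asarray(y, dtype=float)
    names = list(X.columns)
    p = len(names)
    if p > max_exact_p:
        raise ValueError(
            f"exact lmg enumeration limited to p <= {max_exact_p}; "
            "reduce the predictor set or average over sampled orderings"
        )
    Xa = X.to_numpy(dtype=float)
    # R² of every subset, keyed by frozenset of column indices
    r2_cache: dict[frozenset, float] = {frozenset(): 0.0}
    for k in range(1, p + 1):
        for combo in combinations(range(p), k):
            r2_cache[frozenset(combo)] = _r2(Xa[:, list(combo)], y)
    shares = np.zeros(p)
    fact = [factorial(i) for i in range(p + 1)]
    for j in range(p):
        others = [i for i in range(p) if i != j]
        total = 0.0
        for k in range(0, p):
            w = fact[k] * fact[p - 1 - k] / fact[p]
            for s in combinations(others, k):
                fs = frozenset(s)
                total += w * (r2_cache[fs | {j}] - r2_cache[fs])
        shares[j] = total
    return ImportanceResult(
        predictors=names, shares=shares, r2=r2_cache[frozenset(range(p))]
    )


def _residualize(M: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Residuals of each column of M after OLS on basis (with intercept)."""
    n = M.shape[0]
    B = np.column_stack([np.ones(n), basis]) if basis.size else np.ones((n, 1))
    beta, *_ = np.linalg.lstsq(B, M, rcond=None)
    return M - B @ beta


def despatialized_importance(
    y,
    X_spatial,
    X_env: pd.DataFrame,
    max_exact_p: int = 10,
) -> DespatializedImportance:
    """lmg importance of environmental predictors with spatial signal removed.

    The response and every environmental column are residualized on the
    spatial basis (partial regression), then exact lmg is applied to the
    residualized system.  Shares come back on two scales: fractions of the
    residualized variance (``shares_residual``, summing to the residualized
    model's R²) and rescaled to fractions of the original total variance
    (``shares_total``).  An empty spatial basis reduces exactly to
    :func:`lmg_importance`.  If the spatial basis spans y (residual variance
    numerically zero) the result is flagged degenerate.
    """
    y = np.asarray(y, dtype=float)
    Xs = np.asarray(X_spatial, dtype=float)
    if Xs.ndim == 1:
        Xs = Xs[:, None]
    if Xs.size and Xs.shape[0] != y.size:
        raise ValueError("spatial basis row count must match response length")
    y_res = _residualize(y[:, None], Xs)[:, 0]
    Xe_res = _residualize(X_env.to_numpy(dtype=float), Xs)
    var_y = float(np.var(y - y.mean()))
    var_res = float(np.var(y_res - y_res.mean()))
    if var_y == 0 or var_res / var_y < 1e-12:
        return DespatializedImportance(
            predictors=list(X_env.columns),
            shares_residual=np.zeros(X_env.shape[1]),
            shares_total=np.zeros(X_env.shape[1]),
            r2_residual=0.0,
            residual_variance_fraction=0.0,
            degenerate=True,
        )
    imp = lmg_importance(
        y_res, pd.DataFrame(Xe_res, columns=X_env.columns), max_exact_p=max_exact_p
    )
    frac = var_res / var_y
    return DespatializedImportance(
        predictors=imp.predictors,
        shares_residual=imp.shares,
        shares_total=imp.shares * frac,
        r2_residual=imp.r2,
        residual_variance_fraction=frac,
    )
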