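"""Preprocessing and exhaustive best-subsets regression with AIC ranking.

Covers the regression machinery used to rank predictor sets for underwater
color ratios and the cyano/euk community ratio: Box-Cox normalisation,
variance-inflation-factor (VIF) collinearity screening, an exhaustive
search for the best predictor subset of each size (minimum residual sum of
squares), and AIC ranking across sizes with Akaike differences Δi.

The subset search returns the best model of each size without any size
penalty; the AIC then arbitrates across sizes, so the two concerns stay
separable as they are in the standard best-subsets workflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ModelFit",
    "VIFReport",
    "box_cox",
    "vif_screen",
    "best_subsets",
    "aic_rank",
    "delta_aic",
]


@dataclass
class ModelFit:
    """One fitted OLS model in a comparison set."""

    predictors: tuple[str, ...]
    coef: np.ndarray            # intercept first
    rss: float
    n: int
    p: int                      # parameters including intercept
    r2: float
    aic: float
    delta_i: float | None = None


@dataclass
class VIFReport:
    """Outcome of iterative VIF screening."""

    retained: list[str]
    dropped: list[str]
    rounds: list[pd.Series]     # VIFs at each round, before that round's drop


def box_cox(
    x: Sequence[float],
    lam: float | None = None,
    grid: tuple[float, float, float] = (-3.0, 3.0, 0.01),
) -> tuple[np.ndarray, float]:
    """Box-Cox power transform with profile-likelihood λ on a fixed grid.

    y = (x^λ − 1)/λ for λ ≠ 0, ln x at λ = 0.  When ``lam`` is None, λ is
    the grid point in [grid lo, grid hi] (step ``grid[2]``) maximising the
    profile log-likelihood.  Returns (transformed, λ).
    """
    x = np.asarray(x, dtype=float)
    bad = np.flatnonzero(x <= 0)
    if bad.size:
        raise ValueError(f"box_cox requires positive values; offending rows: {bad.tolist()}")
    if lam is None:
        lo, hi, step = grid
        lams = np.arange(lo, hi + step / 2, step)
        llf = np.array([stats.boxcox_llf(l, x) for l in lams])
        lam = float(lams[np.argmax(llf)])
    lam = float(lam)
    if lam == 0.0:
        return np.log(x), lam
    return (x**lam - 1.0) / lam, lam


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, float]:
    """OLS with intercept: (coef, RSS, R²)."""
    n = y.size
    Xd = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    resid = y - Xd @ beta
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return beta, rss, r2


def vif_screen(X: pd.DataFrame, threshold: float = 5.0) -> VIFReport:
    """Iteratively drop the largest-VIF predictor while any VIF > threshold.

    VIF_j = 1 / (1 − R²_j), R²_j from regressing predictor j on the others
    (with intercept).  Perfect collinearity gives an infinite VIF and an
    immediate drop.  Every round's VIF table is kept in the report.
    """
    if X.shape[1] < 2:
        raise ValueError("VIF screening needs at least 2 predictors")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need n > p for VIF screening")
    cols = list(X.columns)
    dropped: list[str] = []
    rounds: list[pd.Series] = []
    while True:
        vifs = {}
        for j, c in enumerate(cols):
            others = [k for k in cols if k != c]
            _, _, r2 = _ols(X[others].to_numpy(), X[c].to_numpy())
            vifs[c] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        series = pd.Series(vifs)
        rounds.append(series)
        worst = series.idxmax()
        if series[worst] <= threshold or len(cols) == 1:
            break
        cols.remove(worst)
        dropped.append(worst)
        if len(cols) < 2:
            break
    return VIFReport(retained=cols, dropped=dropped, rounds=rounds)


def _gaussian_aic(rss: float, n: int, p: int) -> float:
    """Profile-Gaussian AIC: n ln(RSS/n) + 2(p + 1); p counts the intercept,
    +1 counts the estimated error variance.  Additive constants cancel in Δi."""
    if rss <= 0:
        return -np.inf
    return n * np.log(rss / n) + 2 * (p + 1)


def best_subsets(
    X: pd.DataFrame, y: Sequence[float], max_size: int | None = None
) -> dict[int, ModelFit]:
    """Best predictor subset of each size by exhaustive RSS minimisation.

    For every size k ≤ max_size, returns the subset of the columns of X with
    minimum residual sum of squares over all C(p, k) candidates; ties break
    lexicographically by predictor name.  Sizes with n ≤ k + 1 are skipped
    with a warning.  Feasible for p ≤ 20.
    """
    y = np.asarray(y, dtype=float)
    names = list(X.columns)
    p_total = len(names)
    if p_total > 20:
        raise ValueError("exhaustive search limited to p <= 20 predictors")
    if max_size is None:
        max_size = p_total
    n = y.size
    Xa = X.to_numpy(dtype=float)
    out: dict[int, ModelFit] = {}
    for k in range(1, min(max_size, p_total) + 1):
        if n <= k + 1:
            warnings.warn(f"size {k} skipped: n={n} too small")
            continue
        best: ModelFit | None = None
        for combo in combinations(sorted(range(p_total), key=lambda i: names[i]), k):
            cols = list(combo)
            coef, rss, r2 = _ols(Xa[:, cols], y)
            if best is None or rss < best.rss - 1e-15 * max(1.0, best.rss):
                best = ModelFit(
                    predictors=tuple(names[i] for i in cols),
                    coef=coef,
                    rss=rss,
                    n=n,
                    p=k + 1,
                    r2=r2,
                    aic=_gaussian_aic(rss, n, k + 1),
                )
        assert best is not None
        out[k] = best
    return out


def delta_aic(aics: Sequence[float]) -> np.ndarray:
    """Akaike differences Δi = AIC_i − min AIC, in the input order."""
    a = np.asarray(aics, dtype=float)
    if a.size == 0:
        return a
    return a - a.min()


def aic_rank(models: Sequence[ModelFit]) -> list[ModelFit]:
    """Rank models by AIC ascending and attach Δi = AIC − min AIC.

    All models must be fits to the same response (equal n); mixing sample
    sizes makes AICs incomparable and raises.
    """
    models = list(models)
    if not models:
        return []
    ns = {m.n for m in models}
    if len(ns) > 1:
        raise ValueError(f"models fitted on different n: {sorted(ns)}")
    best = min(m.aic for m in models)
    for m in models:
        m.delta_i = m.aic - best
    return sorted(models, key=lambda m: m.aic)
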