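"""Multiple imputation by chained equations and Rubin's-rules pooling.

Covariates with missing cells are imputed by fully conditional
specification: per sweep, each incomplete column is modelled on all other
variables using the cases where it is observed, and its missing cells are
drawn from the fitted predictive distribution — a Bayesian-flavoured
linear draw (parameter draw plus residual draw) for continuous columns,
and a multinomial-logistic category draw (fit on a bootstrap resample to
propagate parameter uncertainty) for categorical ones. Predictive-mean
matching is deliberately not used. The imputation model is congenial: the
exposure score, mediators and outcomes all serve as predictors.

Downstream estimates computed per completed dataset are combined with
Rubin's rules: the pooled point is the mean of per-imputation points, the
total variance W + (1 + 1/m) B, and intervals use a t reference with
Barnard-Rubin adjusted degrees of freedom.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ImputationSet", "PooledEstimate", "impute_chained", "pool_rubin"]


@dataclass
class ImputationSet:
    """m completed copies of a dyad table, identical on observed cells."""

    tables: list
    m: int
    iterations: int
    seed: int


@dataclass
class PooledEstimate:
    """Rubin combination of m (point, SE) pairs."""

    point: float
    W: float  # within-imputation variance
    B: float  # between-imputation variance
    T: float  # total variance = W + (1 + 1/m) B
    df: float
    ci_low: float
    ci_high: float
    p: float


def _design(frame: pd.DataFrame, exclude: str) -> np.ndarray:
    """Numeric design from all columns but ``exclude``: dummies for categoricals."""
    parts = [np.ones((len(frame), 1))]
    for col in frame.columns:
        if col in (exclude, "id"):
            continue
        s = frame[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            d = pd.get_dummies(s, drop_first=True, dtype=float)
            if d.shape[1]:
                parts.append(d.to_numpy())
        else:
            parts.append(s.to_numpy(dtype=float)[:, None])
    X = np.hstack(parts)
    # guard against numerically collinear columns downstream via lstsq
    return X


def _draw_continuous(X: np.ndarray, y: np.ndarray, obs: np.ndarray, mis: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    """Bayesian linear-regression draw for the missing entries of y."""
    Xo, yo = X[obs], y[obs]
    beta, _, rank, _ = np.linalg.lstsq(Xo, yo, rcond=None)
    resid = yo - Xo @ beta
    nu = max(len(yo) - rank, 1)
    sigma2 = resid @ resid / rng.chisquare(nu)
    XtX = Xo.T @ Xo + 1e-8 * np.eye(Xo.shape[1])
    cov = sigma2 * np.linalg.pinv(XtX)
    beta_star = rng.multivariate_normal(beta, cov, method="svd")
    return X[mis] @ beta_star + rng.normal(0.0, math.sqrt(sigma2), mis.sum())


def _draw_categorical(X: np.ndarray, y: pd.Series, obs: np.ndarray, mis: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Multinomial-logistic category draw; frequency fallback if the fit fails."""
    from sklearn.linear_model import LogisticRegression

    levels = np.array(sorted(y[obs].unique()))
    if len(levels) == 1:
        return np.full(mis.sum(), levels[0], dtype=object)
    # z-scale (keep the intercept column) so lbfgs converges on raw-unit columns
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    X = (X - X.mean(axis=0)) / scale
    X[:, 0] = 1.0
    idx_obs = np.flatnonzero(obs)
    boot = rng.choice(idx_obs, size=len(idx_obs), replace=True)
    try:
        if len(pd.unique(y.iloc[boot])) < 2:
            raise ValueError("bootstrap sample lost a category")
        clf = LogisticRegression(max_iter=500)
        clf.fit(X[boot], y.iloc[boot])
        proba = clf.predict_proba(X[mis])
        classes = clf.classes_
    except Exception as err:  # non-convergence: fall back to observed frequencies
        warnings.warn(f"categorical imputation model failed ({err}); frequency draw", stacklevel=2)
        classes, counts = np.unique(y[obs], return_counts=True)
        proba = np.tile(counts / counts.sum(), (mis.sum(), 1))
    cum = np.cumsum(proba, axis=1)
    u = rng.random(len(cum))[:, None]
    pick = (u > cum).sum(axis=1)
    return classes[np.minimum(pick, len(classes) - 1)]


def impute_chained(table: pd.DataFrame, m: int = 10, iterations: int = 50,
                   seed: int = 0, columns: Sequence[str] | None = None) -> ImputationSet:
    """Chained-equation multiple imputation of a dyad table.

    Returns m completed tables from independent chains (each a fixed number
    of full sweeps over the incomplete columns). Observed cells are never
    altered. A column with no observed values raises.
    """
    targets = list(columns) if columns is not None else [
        c for c in table.columns if table[c].isna().any()]
    for c in targets:
        if table[c].notna().sum() == 0:
            raise ValueError(f"column {c!r} has no observed values to model from")
    if not targets:
        return ImputationSet(tables=[table.copy() for _ in range(m)], m=m,
                             iterations=iterations, seed=seed)

    masks = {c: table[c].isna().to_numpy() for c in targets}
    completed = []
    for chain in range(m):
        rng = np.random.default_rng(np.random.SeedSequence([seed, chain]))
        frame = table.copy()
        for c in targets:  # initial fill: random draws from the observed margin
            obs_vals = table[c].dropna().to_numpy()
            frame.loc[masks[c], c] = rng.choice(obs_vals, size=masks[c].sum())
        for _ in range(iterations):
            for c in targets:
                obs, mis = ~masks[c], masks[c]
                X = _design(frame, exclude=c)
                if table[c].dtype == object or isinstance(table[c].dtype, pd.CategoricalDtype):
                    drawn = _draw_categorical(X, frame[c], obs, mis, rng)
                else:
                    drawn = _draw_continuous(X, frame[c].to_numpy(dtype=float), obs, mis, rng)
                frame.loc[mis, c] = drawn
        completed.append(frame)
    return ImputationSet(tables=completed, m=m, iterations=iterations, seed=seed)


def pool_rubin(estimates: Sequence[tuple[float, float]], conf: float = 0.95,
               df_com: float | None = None) -> PooledEstimate:
    """Rubin's rules for m >= 2 per-imputation (point, SE) pairs.

    Degrees of freedom follow Barnard-Rubin when a complete-data df is
    supplied, otherwise the classical large-sample formula; with zero
    between-imputation variance the reference collapses to the normal.
    """
    est = [(float(p), float(s)) for p, s in estimates]
    m = len(est)
    if m < 2:
        raise ValueError("pooling requires m >= 2 estimates")
    points = np.array([p for p, _ in est])
    ses = np.array([s for _, s in est])
    if not np.all(np.isfinite(points)) or not np.all(np.isfinite(ses)):
        raise ValueError("non-finite estimate or SE")
    qbar = points.mean()
    W = float((ses ** 2).mean())
    B = float(points.var(ddof=1))
    if B < 1e-14 * max(1.0, qbar * qbar):  # identical estimates up to rounding
        B = 0.0
    T = W + (1.0 + 1.0 / m) * B

    if B == 0 or T == 0:
        # all per-imputation estimates identical: the evidence is that of a
        # single complete dataset, so fall back to its df when known
        df = df_com if df_com is not None else math.inf
    else:
        lam = (1.0 + 1.0 / m) * B / T
        df = (m - 1) / lam ** 2
        if df_com is not None:
            nu_obs = (df_com + 1.0) / (df_com + 3.0) * df_com * (1.0 - lam)
            df = 1.0 / (1.0 / df + 1.0 / nu_obs)
    half = 0.5 + conf / 2
    tcrit = stats.norm.ppf(half) if math.isinf(df) else stats.t.ppf(half, df)
    se = math.sqrt(T)
    if se == 0:
        p = 0.0 if qbar != 0 else 1.0
    elif math.isinf(df):
        p = float(2 * stats.norm.sf(abs(qbar / se)))
    else:
        p = float(2 * stats.t.sf(abs(qbar / se), df))
    return PooledEstimate(point=float(qbar), W=W, B=B, T=float(T), df=float(df),
                          ci_low=float(qbar - tcrit * se), ci_high=float(qbar + tcrit * se), p=p)
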