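"""Covariate-adjusted linear models and Benjamini-Hochberg FDR control.

Model 1 (main analysis) regresses each child outcome on the maternal diet
score adjusted for child sex and age at assessment, household income,
maternal age, education, national origin, smoking, psychopathology (GSI)
and energy intake; model 2 additionally adjusts for the child's own diet
score at age 8. Volume outcomes at ages 10 and 14 form one 8-test family,
IQ plus the four subtests a 5-test family; raw p-values are converted to
Benjamini-Hochberg q-values within family at FDR 0.05.

When handed an :class:`~dietbrain.impute.ImputationSet` the family runner
fits every completed dataset and pools estimates with Rubin's rules before
the FDR step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import scoring
from .impute import ImputationSet, pool_rubin

__all__ = [
    "ModelSpec",
    "FitResult",
    "MODEL1_COVARIATES",
    "VOLUME_FAMILY",
    "IQ_FAMILY",
    "fit_linear",
    "bh_adjust",
    "run_family",
    "run_component_exclusion",
    "run_stratified",
]

CATEGORICAL_REFERENCES = {
    "sex": "boy",
    "income": "gt2200",
    "education": "high",
    "national_origin": "dutch",
    "smoking": "never",
    "breastfeeding": "lt2mo",
    "folic_acid": "none",
}

MODEL1_COVARIATES = [
    "sex", "age_at_assessment", "income", "maternal_age", "education",
    "national_origin", "smoking", "gsi", "energy_kcal",
]

VOLUME_FAMILY = ["tbv_10", "white_10", "gray_10", "subcortical_10",
                 "tbv_14", "white_14", "gray_14", "subcortical_14"]
IQ_FAMILY = ["iq_14", "t_vocabulary", "t_matrix_reasoning", "t_digit_span", "t_coding"]


@dataclass(frozen=True)
class ModelSpec:
    """One exposure-outcome regression: outcome, covariate set, extras, stratum."""

    outcome: str
    model: int = 1  # 1 or 2 (adds child diet score)
    exposure: str = "diet_score"
    extras: tuple = ()
    stratum: tuple | None = None  # (column, value)
    covariates: tuple | None = None  # override: None -> the model-1/2 set

    def __post_init__(self):
        if self.model not in (1, 2):
            raise ValueError("model must be 1 or 2")
        if self.exposure in (MODEL1_COVARIATES if self.covariates is None else self.covariates):
            raise ValueError("exposure cannot appear among covariates")


@dataclass
class FitResult:
    """Exposure coefficient with inference for one outcome and model."""

    outcome: str
    model: int
    exposure: str
    B: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    df_resid: float
    q: float | None = None
    significant: bool | None = None
    stratum: tuple | None = None

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome, "model": self.model, "stratum": self.stratum,
            "B": self.B, "SE": self.se, "CI_low": self.ci_low, "CI_high": self.ci_high,
            "p": self.p, "q": self.q, "significant": self.significant, "n": self.n,
        }


def age_column(outcome: str) -> str:
    """Child age covariate matching the outcome's assessment wave."""
    if outcome.endswith("_10"):
        return "age_10"
    return "age_14"


def _dummies(series: pd.Series, name: str) -> pd.DataFrame:
    """Indicator contrasts with the documented reference level dropped."""
    ref = CATEGORICAL_REFERENCES.get(name)
    levels = [l for l in pd.unique(series.dropna()) if l != ref]
    return pd.DataFrame(
        {f"{name}[{l}]": (series == l).astype(float) for l in sorted(map(str, levels))},
        index=series.index,
    )


def design_matrix(table: pd.DataFrame, spec: ModelSpec) -> tuple[pd.Series, pd.DataFrame]:
    """Response vector and design matrix (const, exposure, covariates, extras)."""
    cols: list[pd.DataFrame | pd.Series] = []
    covariates = list(MODEL1_COVARIATES if spec.covariates is None else spec.covariates)
    if spec.stratum is not None:
        strat_col, strat_val = spec.stratum
        table = table[table[strat_col] == strat_val]
        if len(table) == 0:
            raise ValueError(f"empty stratum {strat_col}={strat_val!r}")
        covariates = [c for c in covariates if c != strat_col]
    if spec.model == 2:
        covariates = covariates + ["child_diet_score"]

    y = table[spec.outcome].astype(float)
    X = pd.DataFrame({"const": np.ones(len(table))}, index=table.index)
    X[spec.exposure] = table[spec.exposure].astype(float)
    for cov in covariates:
        col = "age_10" if cov == "age_at_assessment" and spec.outcome.endswith("_10") else (
            "age_14" if cov == "age_at_assessment" else cov)
        series = table[col]
        if series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype):
            cols.append(_dummies(series, col))
        else:
            cols.append(series.astype(float).rename(col))
    for extra in spec.extras:
        col = {"intracranial_volume": "icv_10" if spec.outcome.endswith("_10") else "icv_14"}.get(extra, extra)
        series = table[col]
        if series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype):
            frame = _dummies(series, col)
            frame = frame.loc[:, frame.std(axis=0) > 0]
            cols.append(frame)
        else:
            series = series.astype(float)
            if series.std() == 0:  # constant extra carries no information
                continue
            cols.append(series.rename(col))
    for c in cols:
        if isinstance(c, pd.Series):
            X[c.name] = c
        else:
            for name in c.columns:
                X[name] = c[name]
    # structurally empty categories contribute all-zero columns; drop them
    zero = [c for c in X.columns if c != "const" and X[c].std() == 0]
    X = X.drop(columns=zero)
    return y, X


def fit_linear(spec: ModelSpec, table: pd.DataFrame, conf: float = 0.95) -> FitResult:
    """Ordinary least squares for one ModelSpec; t-based inference.

    Requires a complete (or imputed) table: missing cells in any used
    column raise rather than being silently listwise-dropped.
    """
    y, X = design_matrix(table, spec)
    if y.isna().any() or X.isna().any().any():
        bad = [c for c in X.columns if X[c].isna().any()]
        if y.isna().any():
            bad = [spec.outcome] + bad
        raise ValueError(f"missing cells in {bad}; impute or pass a complete table")
    n, p = X.shape
    if n <= p:
        raise ValueError(f"n={n} must exceed number of parameters p={p}")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < p:
        # identify columns whose removal restores full rank
        culprits = []
        for c in X.columns:
            if np.linalg.matrix_rank(X.drop(columns=[c]).to_numpy()) == rank:
                culprits.append(c)
        raise ValueError(f"rank-deficient design; collinear columns: {culprits}")
    res = sm.OLS(y.to_numpy(), X.to_numpy()).fit()
    i = list(X.columns).index(spec.exposure)
    B, se = float(res.params[i]), float(res.bse[i])
    dfr = float(res.df_resid)
    tcrit = stats.t.ppf(0.5 + conf / 2, dfr)
    if se == 0:
        pval = 0.0 if B != 0 else 1.0
    else:
        pval = float(2 * stats.t.sf(abs(B / se), dfr))
    return FitResult(
        outcome=spec.outcome, model=spec.model, exposure=spec.exposure,
        B=B, se=se, ci_low=B - tcrit * se, ci_high=B + tcrit * se,
        p=pval, n=n, df_resid=dfr, stratum=spec.stratum,
    )


def bh_adjust(p_values: Sequence[float], fdr: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up q-values and significance flags.

    q_(i) = min_{j >= i} m * p_(j) / j, capped at 1 and mapped back to the
    input order; a test is flagged when q <= fdr.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, q <= fdr


def _pooled_result(spec: ModelSpec, fits: list[FitResult], conf: float = 0.95) -> FitResult:
    pooled = pool_rubin([(f.B, f.se) for f in fits], conf=conf, df_com=fits[0].df_resid)
    return FitResult(
        outcome=spec.outcome, model=spec.model, exposure=spec.exposure,
        B=pooled.point, se=math.sqrt(pooled.T), ci_low=pooled.ci_low,
        ci_high=pooled.ci_high, p=pooled.p, n=fits[0].n,
        df_resid=pooled.df, stratum=spec.stratum,
    )


def run_family(data, family: str = "volumes", model: int = 1, fdr: float = 0.05,
               extras: tuple = (), exposure: str = "diet_score") -> list[FitResult]:
    """Fit every outcome in a test family and apply within-family BH.

    ``data`` is either a complete dyad table or an ImputationSet, in which
    case each outcome is fitted per completed dataset and pooled with
    Rubin's rules before adjustment.
    """
    outcomes = {"volumes": VOLUME_FAMILY, "iq": IQ_FAMILY}.get(family)
    if outcomes is None:
        raise ValueError("family must be 'volumes' or 'iq'")
    results = []
    for outcome in outcomes:
        spec = ModelSpec(outcome=outcome, model=model, extras=extras, exposure=exposure)
        if isinstance(data, ImputationSet):
            fits = [fit_linear(spec, t) for t in data.tables]
            results.append(_pooled_result(spec, fits))
        else:
            results.append(fit_linear(spec, data))
    q, flags = bh_adjust([r.p for r in results], fdr)
    for r, qi, fi in zip(results, q, flags):
        r.q, r.significant = float(qi), bool(fi)
    return results


def run_component_exclusion(table: pd.DataFrame, outcome: str, model: int = 1,
                            registry=None) -> dict[str, FitResult]:
    """Leave-one-food-component-out sensitivity analysis.

    For each of the 15 components the exposure becomes the remaining
    14-component score and the excluded component's own intake enters as an
    additional covariate (indicator contrasts for the categorical ones).
    """
    registry = list(registry) if registry is not None else scoring.default_registry()
    out = {}
    for comp in registry:
        reduced = scoring.score_table_excluding(table[[c.name for c in registry]], comp.name, registry)
        aug = table.copy()
        aug["diet_score_14"] = reduced["diet_score_14"]
        if comp.name == "alcohol_any":
            aug[comp.name] = aug[comp.name].astype(float)
        spec = ModelSpec(outcome=outcome, model=model, exposure="diet_score_14",
                         extras=(comp.name,))
        out[comp.name] = fit_linear(spec, aug)
    return out


def run_stratified(table: pd.DataFrame, outcome: str, stratifier: str = "national_origin",
                   model: int = 1) -> dict[str, FitResult]:
    """Per-stratum model fits with the stratifier dropped from the covariates."""
    levels = list(pd.unique(table[stratifier].dropna()))
    if len(levels) < 2:
        raise ValueError(f"stratifier {stratifier!r} has fewer than two strata")
    out = {}
    for level in levels:
        spec = ModelSpec(outcome=outcome, model=model, stratum=(stratifier, level))
        out[level] = fit_linear(spec, table)
    return out
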