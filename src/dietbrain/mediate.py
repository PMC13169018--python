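"""Quasi-Bayesian causal mediation through a brain-volume mediator.

For a linear mediator model M ~ X + C and outcome model Y ~ X + M + C
(no exposure-mediator interaction), the average causal mediation effect is
ACME = a*b, the average direct effect ADE = c', and the total effect their
sum. Uncertainty is propagated by drawing model parameters from the
normal approximation to their sampling distribution — n_sims independent
draws per model, the two models drawn independently — computing the
effects per draw, and summarising with percentile intervals. Effects are
summarised by the mean of draws by default; the proportion mediated
ACME/total is summarised by the median, which is robust when a total-
effect draw crosses zero.

Across multiply-imputed datasets, draws are concatenated (a mixture over
imputations) before summarising.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .associate import ModelSpec, design_matrix
from .impute import ImputationSet

__all__ = ["MediationSpec", "MediationResult", "Estimate",
           "mediate_quasi_bayes", "mediate_pooled", "proportion_mediated"]

_MEDIATORS = {"tbv_10", "white_10", "gray_10", "subcortical_10"}


@dataclass(frozen=True)
class MediationSpec:
    """Exposure -> (age-10 volume mediator) -> age-14 outcome, model-1 covariates."""

    mediator: str = "tbv_10"
    outcome: str = "iq_14"
    exposure: str = "diet_score"
    n_sims: int = 1000
    seed: int = 0
    point_estimator: str = "mean"        # for ACME / ADE / total
    proportion_estimator: str = "median"
    covariates: tuple | None = None      # None -> the model-1 set

    def __post_init__(self):
        if self.n_sims < 100:
            raise ValueError("n_sims must be >= 100")
        # temporal ordering enforced through column naming: mediator measured
        # at the earlier wave than the outcome
        if not self.mediator.endswith("_10"):
            raise ValueError("mediator must be an age-10 measure (suffix _10)")
        if not (self.outcome.endswith("_14") or self.outcome.startswith("t_")):
            raise ValueError("outcome must be an age-14 measure")
        if self.point_estimator not in ("mean", "median"):
            raise ValueError("point_estimator must be 'mean' or 'median'")
        if self.proportion_estimator not in ("mean", "median"):
            raise ValueError("proportion_estimator must be 'mean' or 'median'")


@dataclass(frozen=True)
class Estimate:
    point: float
    ci_low: float
    ci_high: float


@dataclass
class MediationResult:
    """ACME, ADE, total effect and proportion mediated with simulation CIs."""

    mediator: str
    outcome: str
    acme: Estimate
    ade: Estimate
    total: Estimate
    proportion: Estimate
    n_sims: int
    seed: int
    n: int
    unstable_denominator: bool = False
    draws: dict = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        return {
            "mediator": self.mediator,
            "outcome": self.outcome,
            "ACME": vars(self.acme),
            "ADE": vars(self.ade),
            "total": vars(self.total),
            "proportion_mediated": vars(self.proportion),
            "n_sims": self.n_sims,
            "seed": self.seed,
            "n": self.n,
            "unstable_denominator": self.unstable_denominator,
        }


def _ols(y: pd.Series, X: pd.DataFrame):
    if y.isna().any() or X.isna().any().any():
        raise ValueError("mediation requires a complete table; impute first")
    n, p = X.shape
    if np.linalg.matrix_rank(X.to_numpy()) < p:
        raise ValueError("rank-deficient mediator/outcome design")
    return sm.OLS(y.to_numpy(), X.to_numpy()).fit()


def _draws_one_table(spec: MediationSpec, table: pd.DataFrame,
                     rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Parameter draws (a; c', b) and derived effect draws for one table."""
    med_spec = ModelSpec(outcome=spec.mediator, model=1, exposure=spec.exposure,
                         covariates=spec.covariates)
    y_m, X_m = design_matrix(table, med_spec)
    fit_m = _ols(y_m, X_m)
    ia = list(X_m.columns).index(spec.exposure)
    a_hat = fit_m.params[ia]
    a_se = np.sqrt(fit_m.cov_params()[ia, ia])

    out_spec = ModelSpec(outcome=spec.outcome, model=1, exposure=spec.exposure,
                         extras=(spec.mediator,), covariates=spec.covariates)
    y_o, X_o = design_matrix(table, out_spec)
    fit_o = _ols(y_o, X_o)
    cols = list(X_o.columns)
    ic, ib = cols.index(spec.exposure), cols.index(spec.mediator)
    mean = fit_o.params[[ic, ib]]
    cov = fit_o.cov_params()[np.ix_([ic, ib], [ic, ib])]

    a = rng.normal(a_hat, a_se, spec.n_sims)
    cb = rng.multivariate_normal(mean, cov, size=spec.n_sims, method="svd")
    acme = a * cb[:, 1]
    ade = cb[:, 0]
    return {"a": a, "b": cb[:, 1], "c_prime": ade, "acme": acme,
            "ade": ade, "total": acme + ade,
            "a_hat": np.array([a_hat]), "b_hat": np.array([mean[1]]),
            "c_hat": np.array([mean[0]])}


def _summarise(spec: MediationSpec, draws: dict, n: int) -> MediationResult:
    def est(x: np.ndarray, how: str) -> Estimate:
        point = float(np.mean(x)) if how == "mean" else float(np.median(x))
        lo, hi = np.percentile(x, [2.5, 97.5])
        return Estimate(point, float(lo), float(hi))

    with np.errstate(divide="ignore", invalid="ignore"):
        prop_draws = draws["acme"] / draws["total"]
    prop_draws = prop_draws[np.isfinite(prop_draws)]
    total = est(draws["total"], spec.point_estimator)
    unstable = total.ci_low <= 0 <= total.ci_high
    if unstable:
        warnings.warn("total effect CI crosses zero: proportion mediated has an "
                      "unstable denominator", stacklevel=3)
    return MediationResult(
        mediator=spec.mediator, outcome=spec.outcome,
        acme=est(draws["acme"], spec.point_estimator),
        ade=est(draws["ade"], spec.point_estimator),
        total=total,
        proportion=est(prop_draws, spec.proportion_estimator),
        n_sims=spec.n_sims, seed=spec.seed, n=n,
        unstable_denominator=unstable, draws=draws,
    )


def mediate_quasi_bayes(spec: MediationSpec, table: pd.DataFrame) -> MediationResult:
    """Quasi-Bayesian Monte Carlo mediation analysis on one complete table.

    ACME + ADE = total holds exactly for every draw (linear models, no
    interaction), so the identity carries to any summary of the draws.
    """
    rng = np.random.default_rng(spec.seed)
    draws = _draws_one_table(spec, table, rng)
    return _summarise(spec, draws, n=len(table))


def mediate_pooled(spec: MediationSpec, imputations: ImputationSet) -> MediationResult:
    """Mediation across an ImputationSet: concatenate the m x n_sims draws."""
    rng = np.random.default_rng(spec.seed)
    all_draws: dict[str, list[np.ndarray]] = {}
    for t in imputations.tables:
        d = _draws_one_table(spec, t, rng)
        for k, v in d.items():
            all_draws.setdefault(k, []).append(v)
    merged = {k: np.concatenate(v) for k, v in all_draws.items()}
    return _summarise(spec, merged, n=len(imputations.tables[0]))


def proportion_mediated(result: MediationResult) -> Estimate:
    """ACME/total summarised over the simulation draws (see module docstring)."""
    if result.unstable_denominator:
        warnings.warn("proportion mediated has an unstable denominator", stacklevel=2)
    return result.proportion
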