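"""Synthetic mother-child dyad generator.

Emulates the statistical structure of a pregnancy-nutrition neuroimaging
cohort so that every downstream stage (scoring, imputation, regression,
mediation) can be exercised and validated without access to real data.

Structural model, per dyad:

1. A latent socioeconomic factor ``U ~ N(0,1)`` loads (with
   ``confounding_strength``) on a healthy-diet factor ``F`` and on the
   observed covariates (income, education, national origin, smoking,
   maternal age, psychopathology GSI) via thresholded continuous scores.
   Outcome-side confounding enters as a standardized linear index of those
   observed covariates — socioeconomic position affects brain and IQ
   through its measurable expressions — so the model-1 covariate set
   removes it exactly while any crude regression remains confounded.
2. Food-component intakes follow per-component log-normal distributions
   sharing the factor ``F``; :func:`calibrate_intakes` tunes a global
   healthy-shift and the factor loading so the scored 0-15 total matches
   the target mean/SD (defaults 7.8 / 1.6).
3. The child's own diet score at age 8 correlates with the maternal total
   (default r = 0.29) and carries a direct effect into volumes and IQ
   sized so that adjusted (model-2) coefficients equal their configured
   targets — which is what makes model-2 attenuation real rather than
   cosmetic.
4. Brain volumes at age 10 are generated as cerebral white + gray +
   subcortical + a remainder compartment (brainstem/cerebellum etc.), so
   the total-brain coefficient equals the sum of its parts; age-14 volumes
   add a growth increment with its own noise; intracranial volume is the
   total plus a strictly positive margin.
5. IQ at 14 depends structurally on total brain volume at 10 (the single
   generative mediator), with the mediator slope solved from the
   configured total diet->IQ effect and proportion mediated.

All draws are taken from one seeded generator in a fixed order, so a
configuration plus seed fully determines the table.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import asdict, dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from . import scoring

__all__ = [
    "GeneratorConfig",
    "IntakeModel",
    "CalibrationError",
    "calibrate_intakes",
    "sample_intakes",
    "generate_cohort",
    "ground_truth",
    "inject_missingness",
    "write_cohort",
    "INTAKE_COLUMNS",
    "VOLUME_COLUMNS",
    "OUTCOME_COLUMNS",
]

# ---------------------------------------------------------------------------
# configuration

_DEF_VOL_M1 = {"total_brain": 4.54, "cerebral_white": 1.83, "cerebral_gray": 1.99, "subcortical": 0.16}
_DEF_VOL_M2 = {"total_brain": 4.16, "cerebral_white": 1.71, "cerebral_gray": 1.75, "subcortical": 0.15}
_DEF_VOL14_M1 = {"total_brain": 4.01, "cerebral_white": 1.69, "cerebral_gray": 1.93, "subcortical": 0.15}
_DEF_VOL14_M2 = {"total_brain": 3.47, "cerebral_white": 1.51, "cerebral_gray": 1.65, "subcortical": 0.11}

# volume noise SDs (cm^3) and SES loadings per compartment; intercepts are the
# at-mean compartment volumes of a 10-year-old (free defaults: the method's
# coefficient recovery does not depend on them)
_PART_INTERCEPT = {"cerebral_white": 440.0, "cerebral_gray": 600.0, "subcortical": 61.0, "remainder": 130.0}
_PART_NOISE = {"cerebral_white": 45.0, "cerebral_gray": 55.0, "subcortical": 8.0, "remainder": 20.0}
_PART_SES_SCALE = {"cerebral_white": 10.7, "cerebral_gray": 12.0, "subcortical": 1.0, "remainder": 3.0}
_GROWTH_MEAN = {"cerebral_white": 35.0, "cerebral_gray": -15.0, "subcortical": 3.0, "remainder": 7.0}
_GROWTH_NOISE = {"cerebral_white": 12.0, "cerebral_gray": 15.0, "subcortical": 3.0, "remainder": 6.0}

_SUBTESTS = ("vocabulary", "matrix_reasoning", "digit_span", "coding")
_DEF_SUBTEST_M1 = {"vocabulary": 0.14, "matrix_reasoning": 0.16, "digit_span": 0.0, "coding": 0.0}
_DEF_SUBTEST_M2 = {"vocabulary": 0.12, "matrix_reasoning": 0.15, "digit_span": 0.0, "coding": 0.0}
_SUBTEST_MEAN = {"vocabulary": 10.0, "matrix_reasoning": 9.5, "digit_span": 9.8, "coding": 13.0}
_SUBTEST_NOISE = {"vocabulary": 2.8, "matrix_reasoning": 2.6, "digit_span": 2.7, "coding": 3.2}

CHILD_DIET_MEAN = 4.5   # child diet-quality score at 8 y (0-10 scale)
CHILD_DIET_SD = 1.2
IQ_MEAN = 103.7
SES_IQ_SCALE = 5.0       # gamma_iq = confounding_strength * SES_IQ_SCALE
SES_SUBTEST_SCALE = 1.5

_DEF_MISSING = {"gsi": 0.10, "smoking": 0.07, "breastfeeding": 0.15, "folate_conc": 0.20, "maternal_age": 0.03}
_MISSABLE = {"maternal_age", "gsi", "smoking", "breastfeeding", "folate_conc", "child_diet_score", "energy_kcal"}

INTAKE_COLUMNS = [c.name for c in scoring.default_registry()]
VOLUME_COLUMNS = [
    "tbv_10", "white_10", "gray_10", "subcortical_10", "icv_10",
    "tbv_14", "white_14", "gray_14", "subcortical_14", "icv_14",
]
OUTCOME_COLUMNS = ["iq_14", "t_vocabulary", "t_matrix_reasoning", "t_digit_span", "t_coding"]


@dataclass
class GeneratorConfig:
    """Targets and structural knobs of the synthetic cohort.

    Effect targets are stated on the scale the analysis reports them:
    ``effect_volume`` / ``effect_iq_total`` are the covariate-adjusted
    (model-1) slopes per 1-unit diet score the generator is built to make
    recoverable; the ``*_adjusted`` dictionaries are the corresponding
    model-2 targets, and their gap determines the child-diet direct path.
    """

    n_dyads: int = 2223
    seed: int = 0
    score_mean: float = 7.8
    score_sd: float = 1.6
    maternal_child_diet_corr: float = 0.29
    effect_volume: dict = field(default_factory=lambda: dict(_DEF_VOL_M1))
    effect_volume_adjusted: dict = field(default_factory=lambda: dict(_DEF_VOL_M2))
    effect_volume_14: dict = field(default_factory=lambda: dict(_DEF_VOL14_M1))
    effect_volume_14_adjusted: dict = field(default_factory=lambda: dict(_DEF_VOL14_M2))
    effect_iq_total: float = 0.65
    effect_iq_adjusted: float = 0.58
    effect_subtests: dict = field(default_factory=lambda: dict(_DEF_SUBTEST_M1))
    effect_subtests_adjusted: dict = field(default_factory=lambda: dict(_DEF_SUBTEST_M2))
    proportion_mediated_total_brain: float = 0.077
    confounding_strength: float = 0.3
    missingness_rates: dict = field(default_factory=lambda: dict(_DEF_MISSING))
    noise_sd: dict = field(default_factory=lambda: {**_PART_NOISE, "iq": 11.5, **{f"t_{s}": _SUBTEST_NOISE[s] for s in _SUBTESTS}})

    def validate(self) -> None:
        if self.n_dyads < 1:
            raise ValueError("n_dyads must be >= 1")
        if not 0 <= self.proportion_mediated_total_brain <= 1:
            raise ValueError("proportion_mediated_total_brain must lie in [0, 1]")
        if not -1 < self.maternal_child_diet_corr < 1:
            raise ValueError("maternal_child_diet_corr must lie in (-1, 1)")
        if not 0 <= self.confounding_strength <= 0.99:
            raise ValueError("confounding_strength must lie in [0, 0.99]")
        if self.score_sd < 0 or not 0 <= self.score_mean <= 15:
            raise ValueError("score targets must satisfy 0 <= mean <= 15, sd >= 0")
        for name, sd in self.noise_sd.items():
            if sd <= 0:
                raise ValueError(f"noise SD for {name!r} must be > 0")
        for name, rate in self.missingness_rates.items():
            if not 0 <= rate < 1:
                raise ValueError(f"missingness rate for {name!r} must lie in [0, 1)")
            if name not in _MISSABLE:
                raise ValueError(f"missingness is restricted to covariates; {name!r} not allowed")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# intake calibration

class CalibrationError(RuntimeError):
    pass


# log median of intake/cutoff at zero healthy-shift, and log-scale spreads:
# rough Dutch pregnancy-cohort intake levels (dairy above, legumes/nuts well
# below recommendation, salt slightly above its maximum)
_BASE_LOG_MEDIAN = {
    "vegetables": math.log(0.65), "fruit": math.log(0.65), "whole_grains": math.log(0.90),
    "legumes": math.log(0.25), "nuts": math.log(0.50), "dairy": math.log(1.20),
    "fish": math.log(0.50), "tea": math.log(0.55),
    "grain_quality_ratio": math.log(0.55), "soft_fat_ratio": math.log(0.75),
    "red_meat": math.log(0.75), "sugary_beverages": math.log(0.90), "salt": math.log(1.05),
}
_BASE_LOG_SD = {
    "vegetables": 0.6, "fruit": 0.6, "whole_grains": 0.6, "legumes": 0.9, "nuts": 0.9,
    "dairy": 0.6, "fish": 0.8, "tea": 0.8,
    "grain_quality_ratio": 0.4, "soft_fat_ratio": 0.35,
    "red_meat": 0.5, "sugary_beverages": 0.7, "salt": 0.35,
}
_MODERATION = {"red_meat", "sugary_beverages", "salt"}
_RATIOS = {"grain_quality_ratio", "soft_fat_ratio"}
_CONTINUOUS = list(_BASE_LOG_MEDIAN)

P_NO_ALCOHOL = 0.50
FOLIC_PROBS = (0.45, 0.30, 0.25)  # periconceptional, first_10_weeks, none


@dataclass(frozen=True)
class IntakeModel:
    """Calibrated per-component log-normal parameters plus the factor loading."""

    mu: dict
    sigma: dict
    tau: float
    p_no_alcohol: float
    folic_probs: tuple
    achieved_mean: float
    achieved_sd: float
    degenerate: str | None = None  # "max" | "min" | None


_CUTOFF = {c.name: c.cutoff for c in scoring.default_registry() if c.cutoff}
_CALIBRATION_CACHE: dict = {}


def _component_scores(mu: np.ndarray, sigma: np.ndarray, tau: float,
                      F: np.ndarray, E: np.ndarray, x_alc: np.ndarray, x_fol: np.ndarray,
                      p_no_alcohol: float, folic_probs: tuple) -> np.ndarray:
    """Total diet score for simulated latents (n,) given calibration params."""
    root = math.sqrt(1.0 - tau * tau)
    x = tau * F[:, None] + root * E  # (n, 13)
    total = np.zeros(len(F))
    for j, name in enumerate(_CONTINUOUS):
        if name in _MODERATION:
            ratio = np.exp(mu[j] - sigma[j] * x[:, j])
            total += np.clip(2.0 - ratio, 0.0, 1.0)
        else:
            total += np.minimum(np.exp(mu[j] + sigma[j] * x[:, j]), 1.0)
    z_alc = norm.ppf(1.0 - p_no_alcohol)
    xa = tau * F + root * x_alc
    total += (xa > z_alc).astype(float)
    p_peri, p_first, _ = folic_probs
    xf = tau * F + root * x_fol
    t_peri = norm.ppf(1.0 - p_peri)
    t_first = norm.ppf(1.0 - p_peri - p_first)
    total += np.where(xf > t_peri, 1.0, np.where(xf > t_first, 0.5, 0.0))
    return total


def calibrate_intakes(score_mean: float = 7.8, score_sd: float = 1.6, *,
                      seed: int = 20060101, n_sim: int = 60000,
                      tol_mean: float = 0.01, tol_sd: float = 0.02,
                      max_iter: int = 8) -> IntakeModel:
    """Find intake-distribution parameters inducing the target score moments.

    Two free scalars are searched: a global healthy shift ``delta`` added to
    every continuous component's log-median (subtracted for moderation
    components, so a healthier population eats less red meat), and the
    common-factor loading ``tau`` that sets between-component correlation
    and hence the spread of the total. Each is solved by root finding on
    seeded Monte Carlo moments (common random numbers keep the objective
    smooth); the two one-dimensional solves are alternated to convergence.

    The alcohol and folic-acid marginals are fixed population frequencies,
    so achievable means span roughly [1.2, 14.1]; the exact boundary
    targets (15, 0) and (0, 0) return degenerate configurations.
    """
    key = (round(score_mean, 6), round(score_sd, 6), seed, n_sim)
    if key in _CALIBRATION_CACHE:
        return _CALIBRATION_CACHE[key]

    if score_sd == 0 and score_mean in (0.0, 15.0):
        kind = "max" if score_mean == 15.0 else "min"
        model = IntakeModel(mu={}, sigma={}, tau=0.0, p_no_alcohol=1.0 if kind == "max" else 0.0,
                            folic_probs=(1.0, 0.0, 0.0) if kind == "max" else (0.0, 0.0, 1.0),
                            achieved_mean=score_mean, achieved_sd=0.0, degenerate=kind)
        _CALIBRATION_CACHE[key] = model
        return model

    rng = np.random.default_rng(seed)
    F = rng.standard_normal(n_sim)
    E = rng.standard_normal((n_sim, len(_CONTINUOUS)))
    x_alc = rng.standard_normal(n_sim)
    x_fol = rng.standard_normal(n_sim)
    base_mu = np.array([_BASE_LOG_MEDIAN[c] for c in _CONTINUOUS])
    sign = np.array([-1.0 if c in _MODERATION else 1.0 for c in _CONTINUOUS])
    sigma = np.array([_BASE_LOG_SD[c] for c in _CONTINUOUS])

    def moments(delta: float, tau: float) -> tuple[float, float]:
        total = _component_scores(base_mu + sign * delta, sigma, tau,
                                  F, E, x_alc, x_fol, P_NO_ALCOHOL, FOLIC_PROBS)
        return float(total.mean()), float(total.std())

    delta, tau = 0.0, 0.35
    for _ in range(max_iter):
        f_mean = lambda d: moments(d, tau)[0] - score_mean
        lo, hi = -4.0, 4.0
        if f_mean(lo) > 0 or f_mean(hi) < 0:
            raise CalibrationError(
                f"target mean {score_mean} outside achievable range "
                f"[{moments(lo, tau)[0]:.2f}, {moments(hi, tau)[0]:.2f}] at tau={tau:.2f}")
        delta = brentq(f_mean, lo, hi, xtol=1e-4)

        f_sd = lambda t: moments(delta, t)[1] - score_sd
        if f_sd(0.0) > 0:
            raise CalibrationError(
                f"target SD {score_sd} below independent-component floor {moments(delta, 0.0)[1]:.2f}")
        if f_sd(0.97) < 0:
            raise CalibrationError(
                f"target SD {score_sd} above achievable maximum {moments(delta, 0.97)[1]:.2f}")
        tau = brentq(f_sd, 0.0, 0.97, xtol=1e-4)

        mean, sd = moments(delta, tau)
        if abs(mean - score_mean) <= tol_mean and abs(sd - score_sd) <= tol_sd:
            break
    else:
        mean, sd = moments(delta, tau)
        if abs(mean - score_mean) > 0.05 or abs(sd - score_sd) > 0.1:
            raise CalibrationError(
                f"calibration did not converge: achieved ({mean:.3f}, {sd:.3f}) "
                f"for targets ({score_mean}, {score_sd})")

    mu = {c: float(base_mu[j] + sign[j] * delta) for j, c in enumerate(_CONTINUOUS)}
    model = IntakeModel(mu=mu, sigma={c: float(s) for c, s in zip(_CONTINUOUS, sigma)},
                        tau=float(tau), p_no_alcohol=P_NO_ALCOHOL, folic_probs=FOLIC_PROBS,
                        achieved_mean=mean, achieved_sd=sd)
    _CALIBRATION_CACHE[key] = model
    return model


def sample_intakes(model: IntakeModel, n: int, rng: np.random.Generator,
                   F: np.ndarray | None = None) -> pd.DataFrame:
    """Draw component intakes for n mothers, optionally tied to a factor F."""
    if model.degenerate == "max":
        data = {c: np.full(n, _CUTOFF[c]) for c in _CONTINUOUS if c not in _RATIOS and c not in _MODERATION}
        data.update({c: np.ones(n) for c in _RATIOS})
        data.update({c: np.zeros(n) for c in _MODERATION})
        data["alcohol_any"] = np.zeros(n, dtype=int)
        data["folic_acid"] = np.full(n, "periconceptional", dtype=object)
        return pd.DataFrame(data)[INTAKE_COLUMNS]
    if model.degenerate == "min":
        data = {c: np.zeros(n) for c in _CONTINUOUS if c not in _MODERATION}
        data.update({c: np.full(n, 2.0 * _CUTOFF[c]) for c in _MODERATION})
        data["alcohol_any"] = np.ones(n, dtype=int)
        data["folic_acid"] = np.full(n, "none", dtype=object)
        return pd.DataFrame(data)[INTAKE_COLUMNS]

    if F is None:
        F = rng.standard_normal(n)
    tau = model.tau
    root = math.sqrt(1.0 - tau * tau)
    data = {}
    for c in _CONTINUOUS:
        x = tau * F + root * rng.standard_normal(n)
        if c in _MODERATION:
            val = np.exp(model.mu[c] - model.sigma[c] * x)
            data[c] = _CUTOFF[c] * val
        elif c in _RATIOS:
            data[c] = np.minimum(np.exp(model.mu[c] + model.sigma[c] * x), 1.0)
        else:
            data[c] = _CUTOFF[c] * np.exp(model.mu[c] + model.sigma[c] * x)
    xa = tau * F + root * rng.standard_normal(n)
    data["alcohol_any"] = (xa <= norm.ppf(1.0 - model.p_no_alcohol)).astype(int)
    p_peri, p_first, _ = model.folic_probs
    xf = tau * F + root * rng.standard_normal(n)
    folic = np.full(n, "none", dtype=object)
    folic[xf > norm.ppf(1.0 - p_peri - p_first)] = "first_10_weeks"
    folic[xf > norm.ppf(1.0 - p_peri)] = "periconceptional"
    data["folic_acid"] = folic
    return pd.DataFrame(data)[INTAKE_COLUMNS]


# ---------------------------------------------------------------------------
# structural ground truth

def _parts(config: GeneratorConfig, m1: Mapping, m2: Mapping) -> dict:
    """Per-compartment structural (direct, child-diet) slopes from model-1/2 targets."""
    k = config.maternal_child_diet_corr / config.score_sd if config.score_sd > 0 else 0.0
    parts = {}
    names = ["cerebral_white", "cerebral_gray", "subcortical"]
    rem_m1 = m1["total_brain"] - sum(m1[p] for p in names)
    rem_m2 = m2["total_brain"] - sum(m2[p] for p in names)
    for p in names + ["remainder"]:
        b1 = m1[p] if p != "remainder" else rem_m1
        b2 = m2[p] if p != "remainder" else rem_m2
        child = (b1 - b2) / k if k != 0 else 0.0
        parts[p] = {"direct": b2 if k != 0 else b1, "child": child}
    return parts


def ground_truth(config: GeneratorConfig) -> dict:
    """Structural coefficients implied by a configuration.

    ``direct`` slopes are per diet-score unit holding child diet fixed;
    ``child`` slopes are per SD of the child diet score. The mediator slope
    ``b`` (IQ points per cm^3) is solved from the configured total effect
    and proportion mediated: ACME = effect_volume[total_brain] * b.
    """
    config.validate()
    c = config.confounding_strength
    k = config.maternal_child_diet_corr / config.score_sd if config.score_sd > 0 else 0.0
    a = config.effect_volume["total_brain"]
    total_iq = config.effect_iq_total
    acme = config.proportion_mediated_total_brain * total_iq
    b = acme / a if a != 0 else 0.0
    d_iq = (total_iq - config.effect_iq_adjusted) / k if k != 0 else 0.0
    c_prime = total_iq - b * a - d_iq * k

    parts10 = _parts(config, config.effect_volume, config.effect_volume_adjusted)
    parts14 = _parts(config, config.effect_volume_14, config.effect_volume_14_adjusted)
    subtests = {}
    for s in _SUBTESTS:
        b1 = config.effect_subtests[s]
        b2 = config.effect_subtests_adjusted[s]
        subtests[s] = {"direct": b2 if k != 0 else b1, "child": (b1 - b2) / k if k != 0 else 0.0}

    return {
        "k": k,
        "acme": a * b,
        "b": b,
        "c_prime": c_prime,
        "d_iq": d_iq,
        "total_effect_iq": total_iq,
        "proportion_mediated": config.proportion_mediated_total_brain if a != 0 else 0.0,
        "gamma_iq": c * SES_IQ_SCALE,
        "gamma_volume": {p: c * _PART_SES_SCALE[p] for p in _PART_SES_SCALE},
        "parts10": parts10,
        "parts14": parts14,
        "subtests": subtests,
        "tbv_intercept": sum(_PART_INTERCEPT.values()),
    }


# ---------------------------------------------------------------------------
# cohort generation

def _threshold(latent: np.ndarray, cum_probs: list[float], labels: list[str]) -> np.ndarray:
    """Map a standard-normal latent to ordered categories with given frequencies."""
    cuts = [norm.ppf(q) for q in cum_probs]
    out = np.full(len(latent), labels[-1], dtype=object)
    prev = -np.inf
    for cut, lab in zip(cuts, labels[:-1]):
        out[(latent > prev) & (latent <= cut)] = lab
        prev = cut
    return out


def generate_cohort(config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Generate a complete dyad table (no missing cells) for a configuration."""
    config = config or GeneratorConfig()
    config.validate()
    truth = ground_truth(config)
    n = config.n_dyads
    rng = np.random.default_rng(config.seed)
    lam = config.confounding_strength

    U = rng.standard_normal(n)
    F = lam * U + math.sqrt(1.0 - lam * lam) * rng.standard_normal(n)

    model = calibrate_intakes(config.score_mean, config.score_sd)
    intakes = sample_intakes(model, n, rng, F)
    scores = scoring.score_table(intakes)
    S = scores["diet_score"].to_numpy()
    Sc = S - config.score_mean
    S_std = Sc / config.score_sd if config.score_sd > 0 else np.zeros(n)

    r = config.maternal_child_diet_corr
    child_z = r * S_std + math.sqrt(1.0 - r * r) * rng.standard_normal(n)
    child_diet = np.clip(CHILD_DIET_MEAN + CHILD_DIET_SD * child_z, 0.0, 10.0)

    def loaded(w: float) -> np.ndarray:
        return w * U + math.sqrt(1.0 - w * w) * rng.standard_normal(n)

    maternal_age = 31.2 + 4.6 * loaded(0.35)
    gsi = 0.30 - 0.15 * U + 0.20 * rng.standard_normal(n)
    income = _threshold(loaded(0.75), [0.12, 0.34], ["lt1200", "1200_2200", "gt2200"])
    education = np.where(loaded(0.65) > norm.ppf(0.344), "high", "low")
    origin = np.where(loaded(0.45) > norm.ppf(0.361), "dutch", "non_dutch")
    smoking = _threshold(-loaded(0.40), [0.123, 0.215], ["continued", "until_known", "never"])
    breastfeeding = _threshold(loaded(0.40), [0.35, 0.75], ["lt2mo", "2to6mo", "ge6mo"])
    energy = (1700.0
              + 0.30 * (intakes["vegetables"] + intakes["fruit"] + intakes["whole_grains"]
                        + intakes["dairy"] + intakes["nuts"])
              + (intakes["legumes"] + intakes["fish"] + intakes["red_meat"]) / 7.0
              + 200.0 * rng.standard_normal(n)).to_numpy()
    folic_score = scores["folic_acid"].to_numpy()
    folate_conc = 8.5 + 6.0 * folic_score + 3.0 * rng.standard_normal(n)

    # observed-covariate SES index: the channel through which socioeconomic
    # position reaches the outcomes (so model-1 adjustment removes it exactly)
    W_raw = (0.9 * (income == "gt2200") + 0.45 * (income == "1200_2200")
             + 0.7 * (education == "high") + 0.45 * (origin == "dutch")
             - 0.5 * (smoking == "continued") - 0.2 * (smoking == "until_known")
             - 0.8 * gsi + 0.03 * (maternal_age - 31.2))
    sd_W = W_raw.std()
    W = (W_raw - W_raw.mean()) / sd_W if sd_W > 0 else np.zeros(n)

    sex = np.where(rng.random(n) < 0.505, "girl", "boy")
    age_10 = 9.6 + rng.gamma(2.0, 0.17, n)
    age_14 = age_10 + 3.95 + 0.15 * rng.standard_normal(n)

    parts10, parts14 = truth["parts10"], truth["parts14"]
    gamma_v = truth["gamma_volume"]
    vols10, vols14 = {}, {}
    for p in _PART_INTERCEPT:
        eff = parts10[p]
        vols10[p] = (_PART_INTERCEPT[p] + eff["direct"] * Sc + eff["child"] * child_z
                     + gamma_v[p] * W + config.noise_sd[p] * rng.standard_normal(n))
        inc = parts14[p]
        vols14[p] = (vols10[p] + _GROWTH_MEAN[p]
                     + (inc["direct"] - eff["direct"]) * Sc
                     + (inc["child"] - eff["child"]) * child_z
                     + _GROWTH_NOISE[p] * rng.standard_normal(n))
    for vols in (vols10, vols14):
        vols["remainder"] = np.maximum(vols["remainder"], 0.0)
        for p in ("cerebral_white", "cerebral_gray", "subcortical"):
            vols[p] = np.maximum(vols[p], 1.0)
    tbv_10 = sum(vols10.values())
    tbv_14 = sum(vols14.values())
    icv_10 = tbv_10 + 200.0 * np.exp(0.18 * rng.standard_normal(n))
    icv_14 = tbv_14 + 230.0 * np.exp(0.18 * rng.standard_normal(n))

    iq = (IQ_MEAN + truth["c_prime"] * Sc + truth["b"] * (tbv_10 - truth["tbv_intercept"])
          + truth["d_iq"] * child_z + truth["gamma_iq"] * W
          + config.noise_sd["iq"] * rng.standard_normal(n))
    tscores = {}
    for s in _SUBTESTS:
        eff = truth["subtests"][s]
        tscores[s] = np.clip(
            _SUBTEST_MEAN[s] + eff["direct"] * Sc + eff["child"] * child_z
            + config.confounding_strength * SES_SUBTEST_SCALE * W
            + config.noise_sd[f"t_{s}"] * rng.standard_normal(n),
            1.0, 19.0)

    fiber = (2.0 + 0.02 * intakes["vegetables"] + 0.015 * intakes["fruit"]
             + 0.06 * intakes["whole_grains"] + 0.03 * intakes["legumes"] / 7.0
             + 0.10 * intakes["nuts"] + 1.5 * rng.standard_normal(n)).to_numpy()
    satfat = (10.0 + 0.05 * intakes["red_meat"] / 7.0 + 10.0 * (1.0 - intakes["soft_fat_ratio"])
              + 0.01 * intakes["sugary_beverages"] + 2.0 * rng.standard_normal(n)).to_numpy()

    table = pd.DataFrame({
        "id": np.arange(1, n + 1),
        "maternal_age": maternal_age,
        "education": education,
        "national_origin": origin,
        "income": income,
        "smoking": smoking,
        "gsi": gsi,
        "energy_kcal": energy,
        "folate_conc": folate_conc,
        "breastfeeding": breastfeeding,
        **{c: intakes[c].to_numpy() for c in INTAKE_COLUMNS},
        "diet_score": S,
        "sex": sex,
        "age_10": age_10,
        "age_14": age_14,
        "child_diet_score": child_diet,
        "white_10": vols10["cerebral_white"],
        "gray_10": vols10["cerebral_gray"],
        "subcortical_10": vols10["subcortical"],
        "tbv_10": tbv_10,
        "icv_10": icv_10,
        "white_14": vols14["cerebral_white"],
        "gray_14": vols14["cerebral_gray"],
        "subcortical_14": vols14["subcortical"],
        "tbv_14": tbv_14,
        "icv_14": icv_14,
        "iq_14": iq,
        **{f"t_{s}": tscores[s] for s in _SUBTESTS},
        "fiber_proxy": fiber,
        "satfat_proxy": satfat,
    })
    return table


# ---------------------------------------------------------------------------
# missingness injection

def inject_missingness(table: pd.DataFrame, rates: Mapping[str, float] | None = None,
                       seed: int = 0) -> pd.DataFrame:
    """Blank covariate cells under a missing-at-random mechanism.

    Each listed covariate cell goes missing with a probability that scales
    a logistic-style weight in the (always-observed) income and education
    indicators, normalised so the marginal rate matches the configured one.
    Exposure intakes, mediators and outcomes are never blanked, mirroring
    the analysis's imputation scope.
    """
    rates = dict(_DEF_MISSING) if rates is None else dict(rates)
    for name, rate in rates.items():
        if name not in _MISSABLE:
            raise ValueError(f"missingness is restricted to covariates; {name!r} not allowed")
        if not 0 <= rate < 1:
            raise ValueError(f"rate for {name!r} must lie in [0, 1)")
    out = table.copy()
    rng = np.random.default_rng(seed)
    w = np.exp(0.8 * (table["income"] == "lt1200").to_numpy()
               + 0.4 * (table["income"] == "1200_2200").to_numpy()
               + 0.5 * (table["education"] == "low").to_numpy())
    w = w / w.mean()
    for name, rate in rates.items():
        if rate == 0 or name not in out.columns:
            continue
        p = np.clip(rate * w, 0.0, 0.95)
        mask = rng.random(len(out)) < p
        col = out[name]
        if col.dtype == object:
            out[name] = col.where(~mask, other=None)
        else:
            out[name] = col.mask(mask)
    return out


def write_cohort(table: pd.DataFrame, path, config: GeneratorConfig) -> None:
    """Write the dyad table as CSV with a JSON sidecar of generative truth."""
    import pathlib

    path = pathlib.Path(path)
    table.to_csv(path, index=False)
    sidecar = {
        "config": asdict(config),
        "config_hash": config.hash(),
        "seed": config.seed,
        "ground_truth": ground_truth(config),
    }
    path.with_suffix(".truth.json").write_text(json.dumps(sidecar, indent=2, default=float))
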