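"""Pregnancy diet-quality score.

A predefined index of adherence to Dutch dietary guidelines for pregnant
individuals. Fifteen food components each contribute a score in [0, 1]:

* adequacy components (vegetables, fruit, whole grains, legumes, nuts,
  dairy, fish, tea): intake / recommended intake, truncated at 1;
* ratio components (whole grains of total grains; soft fats and oils of
  total fat): the fraction itself;
* moderation components (red meat, sugar-containing beverages, salt):
  reverse-coded — full credit at or below the recommended maximum,
  linearly decreasing to zero at twice the maximum;
* alcohol: 1 for no intake, 0 for any intake;
* folic-acid supplementation: 1 if periconceptional, 0.5 if started in
  the first 10 weeks of gestation, 0 otherwise.

The total score is the sum over components, ranging 0-15, higher = a
healthier diet. Weekly-unit components (legumes, fish, red meat) are
scored in g/week without conversion.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ComponentDefinition",
    "DietQualityScore",
    "FOLIC_ACID_LEVELS",
    "default_registry",
    "score_adequacy_component",
    "score_moderation_component",
    "score_ratio_component",
    "score_alcohol",
    "score_folic_acid",
    "score_pregnancy_diet",
    "score_excluding_component",
    "score_table",
    "score_table_excluding",
]

FOLIC_ACID_LEVELS = ("periconceptional", "first_10_weeks", "none")
_FOLIC_SCORES = {"periconceptional": 1.0, "first_10_weeks": 0.5, "none": 0.0}


@dataclass(frozen=True)
class ComponentDefinition:
    """One scored food component: its kind, cut-off and unit."""

    name: str
    kind: str  # adequacy | moderation | ratio | binary | categorical
    cutoff: float | None
    unit: str
    direction: str

    def __post_init__(self) -> None:
        if self.kind not in {"adequacy", "moderation", "ratio", "binary", "categorical"}:
            raise ValueError(f"unknown component kind {self.kind!r}")
        if self.kind in {"adequacy", "moderation"} and not (self.cutoff and self.cutoff > 0):
            raise ValueError(f"component {self.name!r}: cutoff must be > 0")
        if self.kind == "ratio" and self.cutoff != 1.0:
            raise ValueError(f"ratio component {self.name!r} must have cutoff 1")


@dataclass(frozen=True)
class DietQualityScore:
    """Per-component scores in [0,1] and their sum in [0,15]."""

    subject_id: object
    component_scores: dict
    total: float


def default_registry() -> list[ComponentDefinition]:
    """The 15-component registry shipped with the package (registry.json)."""
    raw = json.loads(resources.files("dietbrain").joinpath("registry.json").read_text())
    comps = [ComponentDefinition(**c) for c in raw["components"]]
    names = [c.name for c in comps]
    if len(set(names)) != len(names):
        raise ValueError("duplicate component names in registry")
    if len(comps) != 15:
        raise ValueError(f"default registry must have 15 components, got {len(comps)}")
    return comps


def _validate_nonneg(intake, what: str):
    arr = np.asarray(intake, dtype=float)
    if np.any(np.isnan(arr)):
        raise ValueError(f"{what}: missing (NaN) intake")
    if np.any(arr < 0):
        raise ValueError(f"{what}: intake must be non-negative")
    return arr


def score_adequacy_component(intake, cutoff: float):
    """min(intake / cutoff, 1): proportional credit up to the recommendation.

    E.g. a fruit intake of 120 g/d against the recommended 200 g/d scores
    120/200 = 0.6; intakes at or above the recommendation score 1.
    """
    if not cutoff or cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    arr = _validate_nonneg(intake, "adequacy component")
    out = np.minimum(arr / cutoff, 1.0)
    return float(out) if np.isscalar(intake) else out


def score_moderation_component(intake, cutoff: float):
    """clamp(2 - intake/cutoff, 0, 1): reverse-coded moderation credit.

    Full score at or below the recommended maximum, declining linearly to
    zero at twice the maximum.
    """
    if not cutoff or cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    arr = _validate_nonneg(intake, "moderation component")
    out = np.clip(2.0 - arr / cutoff, 0.0, 1.0)
    return float(out) if np.isscalar(intake) else out


def score_ratio_component(ratio):
    """Identity on a fraction in [0, 1] (e.g. whole grains / total grains).

    An undefined ratio (zero denominator upstream, encoded as NaN) scores 0
    with a warning: quality that was not observed earns no credit.
    """
    arr = np.asarray(ratio, dtype=float)
    undefined = np.isnan(arr)
    if np.any(undefined):
        warnings.warn("undefined ratio component (zero denominator); scored 0", stacklevel=2)
        arr = np.where(undefined, 0.0, arr)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("ratio must lie in [0, 1]")
    return float(arr) if np.isscalar(ratio) else arr


def score_alcohol(alcohol_any):
    """1 for no alcohol intake during pregnancy, 0 for any intake."""
    arr = np.asarray(alcohol_any)
    out = np.where(arr.astype(bool), 0.0, 1.0)
    return float(out) if np.isscalar(alcohol_any) or isinstance(alcohol_any, (bool, np.bool_)) else out


def score_folic_acid(category):
    """periconceptional -> 1, first_10_weeks -> 0.5, none -> 0."""
    if isinstance(category, str):
        if category not in _FOLIC_SCORES:
            raise ValueError(f"unknown folic-acid category {category!r}; expected one of {FOLIC_ACID_LEVELS}")
        return _FOLIC_SCORES[category]
    cats = pd.Series(category, dtype=object)
    bad = set(cats.unique()) - set(_FOLIC_SCORES)
    if bad:
        raise ValueError(f"unknown folic-acid categories {sorted(map(str, bad))!r}")
    return cats.map(_FOLIC_SCORES).to_numpy(dtype=float)


def _score_component(comp: ComponentDefinition, value):
    if comp.kind == "adequacy":
        return score_adequacy_component(value, comp.cutoff)
    if comp.kind == "moderation":
        return score_moderation_component(value, comp.cutoff)
    if comp.kind == "ratio":
        return score_ratio_component(value)
    if comp.kind == "binary":
        return score_alcohol(value)
    return score_folic_acid(value)


def score_pregnancy_diet(
    record: Mapping, registry: Iterable[ComponentDefinition] | None = None, subject_id=None
) -> DietQualityScore:
    """Score a single mother's intake record against the registry.

    ``record`` maps component names to values (amounts in the component's
    unit, fractions for ratio kinds, a boolean for alcohol, a category
    string for folic acid). A missing component raises, naming it — there
    is no silent zero-fill.
    """
    registry = list(registry) if registry is not None else default_registry()
    scores: dict = {}
    for comp in registry:
        if comp.name not in record:
            raise ValueError(f"record is missing component {comp.name!r}")
        scores[comp.name] = float(np.asarray(_score_component(comp, record[comp.name])))
    return DietQualityScore(
        subject_id=subject_id if subject_id is not None else record.get("subject_id"),
        component_scores=scores,
        total=float(sum(scores.values())),
    )


def score_excluding_component(
    record: Mapping,
    registry: Iterable[ComponentDefinition] | None = None,
    excluded: str = "",
    subject_id=None,
):
    """Leave-one-component-out score (0-14) plus the excluded raw intake.

    Used by the sensitivity analysis that drops each food component in turn
    and adjusts for the excluded component's intake instead.
    """
    registry = list(registry) if registry is not None else default_registry()
    names = {c.name for c in registry}
    if excluded not in names:
        raise ValueError(f"unknown component {excluded!r}")
    reduced = [c for c in registry if c.name != excluded]
    score = score_pregnancy_diet(record, reduced, subject_id=subject_id)
    return score, record[excluded]


def score_table(table: pd.DataFrame, registry: Iterable[ComponentDefinition] | None = None) -> pd.DataFrame:
    """Vectorised scoring of an intake table (one row per mother).

    Returns a frame with one column per component score plus ``diet_score``
    (the 0-15 total), indexed like the input.
    """
    registry = list(registry) if registry is not None else default_registry()
    out = {}
    for comp in registry:
        if comp.name not in table.columns:
            raise ValueError(f"intake table is missing component column {comp.name!r}")
        out[comp.name] = np.asarray(_score_component(comp, table[comp.name].to_numpy()), dtype=float)
    scores = pd.DataFrame(out, index=table.index)
    scores["diet_score"] = scores.sum(axis=1)
    return scores


def score_table_excluding(
    table: pd.DataFrame, excluded: str, registry: Iterable[ComponentDefinition] | None = None
) -> pd.DataFrame:
    """Leave-one-out variant of :func:`score_table`; total column ``diet_score_14``."""
    registry = list(registry) if registry is not None else default_registry()
    if excluded not in {c.name for c in registry}:
        raise ValueError(f"unknown component {excluded!r}")
    reduced = [c for c in registry if c.name != excluded]
    scores = score_table(table, reduced)
    return scores.rename(columns={"diet_score": "diet_score_14"})
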