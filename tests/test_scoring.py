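"""Diet-quality score: worked examples, bounds, monotonicity, additivity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dietbrain import scoring

# intake record with every continuous component at half its cut-off except
# fruit (120 g/d), moderation components exactly at their maxima
HALF_RECORD = {
    "vegetables": 100.0, "fruit": 120.0, "whole_grains": 45.0, "legumes": 67.5,
    "nuts": 7.5, "dairy": 150.0, "fish": 50.0, "tea": 225.0,
    "grain_quality_ratio": 0.5, "soft_fat_ratio": 0.5,
    "red_meat": 375.0, "sugary_beverages": 150.0, "salt": 6.0,
    "alcohol_any": False, "folic_acid": "first_10_weeks",
}
# component-by-component hand oracle for HALF_RECORD
HALF_EXPECTED = {
    "vegetables": 0.5, "fruit": 0.6, "whole_grains": 0.5, "legumes": 0.5,
    "nuts": 0.5, "dairy": 0.5, "fish": 0.5, "tea": 0.5,
    "grain_quality_ratio": 0.5, "soft_fat_ratio": 0.5,
    "red_meat": 1.0, "sugary_beverages": 1.0, "salt": 1.0,
    "alcohol_any": 1.0, "folic_acid": 0.5,
}

MAX_RECORD = {
    "vegetables": 250.0, "fruit": 200.0, "whole_grains": 95.0, "legumes": 140.0,
    "nuts": 20.0, "dairy": 400.0, "fish": 100.0, "tea": 500.0,
    "grain_quality_ratio": 1.0, "soft_fat_ratio": 1.0,
    "red_meat": 100.0, "sugary_beverages": 0.0, "salt": 3.0,
    "alcohol_any": False, "folic_acid": "periconceptional",
}

MIN_RECORD = {
    **{k: 0.0 for k in ("vegetables", "fruit", "whole_grains", "legumes", "nuts",
                        "dairy", "fish", "tea", "grain_quality_ratio", "soft_fat_ratio")},
    "red_meat": 750.0, "sugary_beverages": 300.0, "salt": 12.0,
    "alcohol_any": True, "folic_acid": "none",
}


@pytest.mark.parametrize(
    "intake,cutoff,expected",
    [(120.0, 200.0, 0.6), (0.0, 200.0, 0.0), (450.0, 200.0, 1.0), (200.0, 200.0, 1.0)],
)
def test_adequacy_ratio_truncated(intake, cutoff, expected):
    assert scoring.score_adequacy_component(intake, cutoff) == pytest.approx(expected)


@pytest.mark.parametrize(
    "intake,cutoff,expected",
    [(375.0, 375.0, 1.0), (750.0, 375.0, 0.0), (0.0, 150.0, 1.0), (562.5, 375.0, 0.5)],
)
def test_moderation_reverse_coded(intake, cutoff, expected):
    assert scoring.score_moderation_component(intake, cutoff) == pytest.approx(expected)


def test_ratio_is_identity_and_undefined_scores_zero():
    assert scoring.score_ratio_component(0.5) == 0.5
    assert scoring.score_ratio_component(1.0) == 1.0
    assert scoring.score_ratio_component(0.0) == 0.0
    with pytest.warns(UserWarning, match="undefined ratio"):
        assert scoring.score_ratio_component(float("nan")) == 0.0
    with pytest.raises(ValueError):
        scoring.score_ratio_component(1.5)


def test_alcohol_and_folic_acid_scores():
    assert scoring.score_alcohol(False) == 1.0
    assert scoring.score_alcohol(True) == 0.0
    assert scoring.score_folic_acid("periconceptional") == 1.0
    assert scoring.score_folic_acid("first_10_weeks") == 0.5
    assert scoring.score_folic_acid("none") == 0.0
    with pytest.raises(ValueError, match="folic-acid"):
        scoring.score_folic_acid("sometimes")


def test_invalid_inputs_raise():
    with pytest.raises(ValueError):
        scoring.score_adequacy_component(-1.0, 200.0)
    with pytest.raises(ValueError):
        scoring.score_adequacy_component(10.0, 0.0)
    with pytest.raises(ValueError):
        scoring.score_moderation_component(10.0, -5.0)


def test_total_score_worked_example():
    score = scoring.score_pregnancy_diet(HALF_RECORD)
    for name, expected in HALF_EXPECTED.items():
        assert score.component_scores[name] == pytest.approx(expected), name
    assert score.total == pytest.approx(sum(HALF_EXPECTED.values()))
    assert score.total == pytest.approx(9.6)


def test_total_score_extremes():
    assert scoring.score_pregnancy_diet(MAX_RECORD).total == pytest.approx(15.0)
    assert scoring.score_pregnancy_diet(MIN_RECORD).total == pytest.approx(0.0)


def test_missing_component_raises_by_name():
    record = dict(HALF_RECORD)
    del record["nuts"]
    with pytest.raises(ValueError, match="nuts"):
        scoring.score_pregnancy_diet(record)


def test_leave_one_out_totals():
    reduced, raw = scoring.score_excluding_component(MAX_RECORD, excluded="fruit")
    assert reduced.total == pytest.approx(14.0)
    assert raw == MAX_RECORD["fruit"]
    reduced, _ = scoring.score_excluding_component(HALF_RECORD, excluded="folic_acid")
    assert reduced.total == pytest.approx(9.1)
    with pytest.raises(ValueError, match="unknown component"):
        scoring.score_excluding_component(HALF_RECORD, excluded="coffee")


amount = st.floats(min_value=0, max_value=5000, allow_nan=False)
fraction = st.floats(min_value=0, max_value=1, allow_nan=False)
random_record = st.fixed_dictionaries({
    **{k: amount for k in ("vegetables", "fruit", "whole_grains", "legumes", "nuts",
                           "dairy", "fish", "tea", "red_meat", "sugary_beverages", "salt")},
    "grain_quality_ratio": fraction,
    "soft_fat_ratio": fraction,
    "alcohol_any": st.booleans(),
    "folic_acid": st.sampled_from(scoring.FOLIC_ACID_LEVELS),
})


@settings(deadline=None, max_examples=150, derandomize=True)
@given(record=random_record)
def test_bounds_and_additivity_hold_for_arbitrary_records(record):
    score = scoring.score_pregnancy_diet(record)
    assert all(0.0 <= v <= 1.0 for v in score.component_scores.values())
    assert 0.0 <= score.total <= 15.0
    assert score.total == pytest.approx(sum(score.component_scores.values()), abs=1e-9)
    for name in ("fruit", "red_meat", "folic_acid"):
        reduced, _ = scoring.score_excluding_component(record, excluded=name)
        assert reduced.total + score.component_scores[name] == pytest.approx(score.total, abs=1e-9)


def test_monotonicity_in_intake():
    grid = np.linspace(0, 900, 200)
    adequacy = scoring.score_adequacy_component(grid, 200.0)
    moderation = scoring.score_moderation_component(grid, 375.0)
    assert np.all(np.diff(adequacy) >= 0)
    assert np.all(np.diff(moderation) <= 0)


def test_score_table_matches_per_record_scoring():
    table = pd.DataFrame([HALF_RECORD, MAX_RECORD, MIN_RECORD])
    scores = scoring.score_table(table)
    assert list(scores["diet_score"]) == pytest.approx([9.6, 15.0, 0.0])
    excl = scoring.score_table_excluding(table, "folic_acid")
    assert excl["diet_score_14"].iloc[0] == pytest.approx(9.1)
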