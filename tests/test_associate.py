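"""Association models: OLS oracle equivalence, BH-FDR, families, sensitivity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from dietbrain import GeneratorConfig, generate_cohort
from dietbrain.associate import (
    IQ_FAMILY,
    VOLUME_FAMILY,
    ModelSpec,
    bh_adjust,
    fit_linear,
    run_component_exclusion,
    run_family,
    run_stratified,
)
from dietbrain.impute import ImputationSet
from dietbrain.scoring import score_table


def test_noiseless_line_recovered_exactly():
    x = np.arange(10, dtype=float)
    table = pd.DataFrame({"x": x, "y": 2.0 * x + 1.0})
    res = fit_linear(ModelSpec(outcome="y", exposure="x", covariates=()), table)
    assert res.B == pytest.approx(2.0, abs=1e-10)
    assert res.se == pytest.approx(0.0, abs=1e-8)
    assert res.ci_low == pytest.approx(res.ci_high, abs=1e-7)


def test_three_point_slope_matches_hand_normal_equations():
    table = pd.DataFrame({"x": [0.0, 1.0, 2.0], "y": [0.0, 1.0, 3.0]})
    res = fit_linear(ModelSpec(outcome="y", exposure="x", covariates=()), table)
    assert res.B == pytest.approx(1.5)
    # intercept = ybar - B xbar = 4/3 - 1.5 = -1/6
    assert (table["y"].mean() - res.B * table["x"].mean()) == pytest.approx(-1 / 6)


def _normal_equations(X, y):
    return np.linalg.solve(X.T @ X, X.T @ y)


@pytest.mark.parametrize("seed", range(10))
def test_ols_equals_normal_equations_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(10, 50))
    p = int(rng.integers(1, 5))
    cols = {f"c{j}": rng.normal(size=n) for j in range(p)}
    table = pd.DataFrame({"x": rng.normal(size=n), **cols})
    table["y"] = rng.normal(size=n)
    res = fit_linear(ModelSpec(outcome="y", exposure="x", covariates=tuple(cols)), table)
    X = np.column_stack([np.ones(n), table["x"], *[table[c] for c in cols]])
    beta = _normal_equations(X, table["y"].to_numpy())
    assert res.B == pytest.approx(beta[1], rel=1e-9, abs=1e-12)


def test_rank_deficient_design_names_collinear_columns(default_cohort):
    t = default_cohort.head(100).copy()
    t["dup"] = t["diet_score"]
    with pytest.raises(ValueError, match="collinear"):
        fit_linear(ModelSpec(outcome="iq_14", extras=("dup",)), t)


def test_missing_cells_are_rejected(default_cohort):
    t = default_cohort.head(50).copy()
    t.loc[t.index[0], "gsi"] = np.nan
    with pytest.raises(ValueError, match="missing cells"):
        fit_linear(ModelSpec(outcome="iq_14"), t)


def test_bh_hand_example_and_edges():
    q, flags = bh_adjust([0.005, 0.04, 0.03])
    assert q == pytest.approx([0.015, 0.04, 0.04])
    assert list(flags) == [True, True, True]
    q, _ = bh_adjust([0.0, 0.0])
    assert q == pytest.approx([0.0, 0.0])
    q, _ = bh_adjust([0.123])
    assert q == pytest.approx([0.123])
    empty_q, empty_flags = bh_adjust([])
    assert len(empty_q) == 0 and len(empty_flags) == 0
    with pytest.raises(ValueError):
        bh_adjust([1.2])


def _brute_force_bh_rejections(p, alpha):
    """Largest k with p_(k) <= k*alpha/m, reject the k smallest."""
    p = np.asarray(p)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k = 0
    for i, idx in enumerate(order, start=1):
        if p[idx] <= i * alpha / m:
            k = i
    rejected = np.zeros(m, dtype=bool)
    rejected[order[:k]] = True
    return rejected


@settings(deadline=None, max_examples=200, derandomize=True)
@given(p=st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=12),
       alpha=st.sampled_from([0.01, 0.05, 0.1, 0.25]))
def test_bh_matches_brute_force_stepup_oracle(p, alpha):
    q, flags = bh_adjust(p, fdr=alpha)
    assert np.array_equal(flags, _brute_force_bh_rejections(p, alpha))
    _, _, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    q_sm = multipletests(p, alpha=alpha, method="fdr_bh")[1]
    assert q == pytest.approx(q_sm)


def test_families_have_expected_cardinalities(default_cohort):
    vol = run_family(default_cohort, family="volumes", model=1)
    iq = run_family(default_cohort, family="iq", model=1)
    assert [r.outcome for r in vol] == VOLUME_FAMILY and len(vol) == 8
    assert [r.outcome for r in iq] == IQ_FAMILY and len(iq) == 5
    for r in vol + iq:
        assert 0 <= r.p <= 1 and r.q >= r.p and 0 <= r.q <= 1
        assert r.ci_low <= r.B <= r.ci_high
        assert r.significant == (r.q <= 0.05)


def test_model2_attenuates_on_replicate_average():
    diffs = []
    for seed in range(10):
        t = generate_cohort(GeneratorConfig(n_dyads=2000, seed=200 + seed))
        b1 = fit_linear(ModelSpec(outcome="tbv_10", model=1), t).B
        b2 = fit_linear(ModelSpec(outcome="tbv_10", model=2), t).B
        diffs.append(abs(b1) - abs(b2))
    assert np.mean(diffs) > 0


def test_pooled_family_on_complete_copies_equals_single_fit(default_cohort):
    t = default_cohort.head(600)
    imps = ImputationSet(tables=[t.copy(), t.copy(), t.copy()], m=3, iterations=0, seed=0)
    pooled = run_family(imps, family="iq", model=1)
    single = run_family(t, family="iq", model=1)
    for rp, rs in zip(pooled, single):
        assert rp.B == pytest.approx(rs.B)
        assert rp.se == pytest.approx(rs.se)
        assert rp.p == pytest.approx(rs.p)
        assert rp.q == pytest.approx(rs.q)


def test_stratified_fits(default_cohort):
    res = run_stratified(default_cohort, outcome="tbv_10")
    assert set(res) == {"dutch", "non_dutch"}
    assert sum(r.n for r in res.values()) == len(default_cohort)
    # homogeneous-effect generator: stratum estimates agree within sampling error
    b_d, b_nd = res["dutch"], res["non_dutch"]
    assert abs(b_d.B - b_nd.B) < 4 * (b_d.se + b_nd.se)
    with pytest.raises(ValueError, match="strata"):
        run_stratified(default_cohort.assign(national_origin="dutch"), outcome="tbv_10")


def test_component_exclusion_returns_all_15(default_cohort):
    t = default_cohort.head(800)
    res = run_component_exclusion(t, outcome="tbv_10")
    assert len(res) == 15
    for r in res.values():
        assert r.exposure == "diet_score_14"
        assert np.isfinite(r.B)


def test_excluding_constant_component_leaves_slope_unchanged(default_cohort):
    from dietbrain.cohort import INTAKE_COLUMNS

    t = default_cohort.head(800).copy()
    t["nuts"] = 10.0  # zero population variance
    t["diet_score"] = score_table(t[INTAKE_COLUMNS])["diet_score"]
    full = fit_linear(ModelSpec(outcome="tbv_10", model=1), t)
    excl = run_component_exclusion(t, outcome="tbv_10")["nuts"]
    assert excl.B == pytest.approx(full.B, rel=1e-9)
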