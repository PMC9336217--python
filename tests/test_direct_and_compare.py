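"""Design-based direct estimator, percentile operator and comparison harness."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from saeintervals.compare import compare_methods, coverage_experiment, run_all_methods
from saeintervals.direct import direct_estimate
from saeintervals.drawset import STATE_ID, DrawSet, percentile_interval
from saeintervals.synthetic import GeneratorConfig, generate_world


# ---------------------------------------------------------------- percentile
def test_order_statistic_convention_at_b_1000():
    lo, hi = percentile_interval(np.arange(1, 1001, dtype=float))
    assert (lo, hi) == (25.0, 975.0)


def test_constant_vector_gives_degenerate_interval():
    lo, hi = percentile_interval(np.full(50, 0.3))
    assert lo == hi == 0.3


def test_normal_draw_endpoints_near_plus_minus_1_96():
    z = np.random.default_rng(1).standard_normal(10_000)
    lo, hi = percentile_interval(z)
    assert lo == pytest.approx(-1.96, abs=0.08)
    assert hi == pytest.approx(1.96, abs=0.08)


def test_too_few_values_refused():
    with pytest.raises(ValueError, match="at least 40"):
        percentile_interval(np.arange(39, dtype=float))


@given(st.floats(1.0, 10.0))
def test_percentile_upper_end_is_monotone_in_added_values(extra):
    base = np.linspace(0.0, 1.0, 80)
    lo0, hi0 = percentile_interval(base)
    lo1, hi1 = percentile_interval(np.append(base, extra))
    assert hi1 >= hi0
    assert lo1 >= lo0 - 1e-12  # adding a high value cannot lower the interval


# ------------------------------------------------------------------- direct
def test_equal_weights_reduce_to_sample_proportion(small_world):
    s = small_world.survey.copy()
    s["design_weight"] = 2.5
    est = direct_estimate(s)
    state = est[est.area_id == STATE_ID].iloc[0]
    assert state["mean"] == pytest.approx(s["outcome"].mean(), abs=1e-12)
    for cid, sub in s.groupby("county_id"):
        row = est[est.area_id == str(cid)].iloc[0]
        assert row["mean"] == pytest.approx(sub["outcome"].mean(), abs=1e-12)


def test_certain_outcome_truncates_interval(small_world):
    s = small_world.survey.copy()
    s["outcome"] = 1
    est = direct_estimate(s)
    np.testing.assert_allclose(est["mean"], 1.0, atol=1e-12)
    assert (est["hi95"] <= 1.0).all()  # truncated at the boundary
    np.testing.assert_allclose(est["hi95"], 1.0, atol=1e-12)


def test_direct_state_estimate_near_truth():
    w = generate_world(GeneratorConfig(n_counties=15, n_per_county=400, seed=33))
    est = direct_estimate(w.survey)
    state = est[est.area_id == STATE_ID].iloc[0]
    se = (state["hi95"] - state["lo95"]) / 3.92
    assert abs(state["mean"] - w.truth.state_prevalence) < 4 * se


def test_direct_width_shrinks_with_sample_size():
    widths = []
    for n in (100, 500, 2000):
        w = generate_world(GeneratorConfig(n_counties=5, n_per_county=n, seed=44,
                                           prevalence_preset="binge"))
        est = direct_estimate(w.survey)
        state = est[est.area_id == STATE_ID].iloc[0]
        widths.append(state["hi95"] - state["lo95"])
    assert widths[0] > widths[1] > widths[2]


def test_zero_weight_area_is_an_error(small_world):
    s = small_world.survey.copy()
    s.loc[0, "design_weight"] = -1.0
    with pytest.raises(ValueError, match="positive"):
        direct_estimate(s)


# ------------------------------------------------------------------ compare
def _fake_estimates(method, areas, mean, width):
    return pd.DataFrame({
        "area_id": areas, "method": method,
        "mean": mean, "lo95": np.asarray(mean) - width / 2,
        "hi95": np.asarray(mean) + width / 2, "n_draws": 100,
    })


def test_self_comparison_gives_unit_ratios_and_equal_ranks():
    areas = ["1", "2", "3", STATE_ID]
    means = [0.1, 0.2, 0.15, 0.14]
    a = _fake_estimates("a", areas, means, 0.04)
    b = _fake_estimates("b", areas, means, 0.04)
    rep = compare_methods([a, b])
    assert rep.median_width_ratio("a", "b") == pytest.approx(1.0)
    ra = rep.ranking_data("a")["area_id"].tolist()
    rb = rep.ranking_data("b")["area_id"].tolist()
    assert ra == rb == ["1", "3", "2"]


def test_mismatched_area_sets_raise_with_difference():
    a = _fake_estimates("a", ["1", "2", STATE_ID], [0.1, 0.2, 0.15], 0.05)
    b = _fake_estimates("b", ["1", "3", STATE_ID], [0.1, 0.2, 0.15], 0.05)
    with pytest.raises(ValueError, match="'2', '3'"):
        compare_methods([a, b])


def test_coverage_column_against_known_truth(small_world):
    truth = small_world.truth
    areas = [str(c) for c in truth.county_ids] + [STATE_ID]
    means = list(truth.county_prevalence) + [truth.state_prevalence]
    wide = _fake_estimates("wide", areas, means, 0.2)  # always covers
    offset = _fake_estimates("off", areas, np.asarray(means) + 0.5, 0.01)  # never
    rep = compare_methods([wide, offset], truth=truth)
    assert rep.method_summary.loc["wide", "county_coverage"] == 1.0
    assert rep.method_summary.loc["off", "county_coverage"] == 0.0


def test_unknown_method_name_is_rejected(small_world):
    with pytest.raises(ValueError, match="valid"):
        run_all_methods(small_world, methods=("nonsense",))


def test_coverage_experiment_is_deterministic():
    cfg = GeneratorConfig(n_counties=5, n_per_county=80)
    kw = dict(methods=("mc", "direct"), n_worlds=2,
              budgets={"mc": {"R": 50}}, seed=77)
    t1 = coverage_experiment(cfg, **kw)
    t2 = coverage_experiment(cfg, **kw)
    pd.testing.assert_frame_equal(t1, t2)
    assert (t1["n_intervals"] == 10).all()


def test_drawset_rejects_out_of_range_values():
    with pytest.raises(ValueError, match="inside"):
        DrawSet(method="x", values=np.array([[0.5, 1.0]]), area_ids=["1", STATE_ID])
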