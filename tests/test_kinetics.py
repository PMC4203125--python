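"""Physiological kinetics: colour index, curve fitting and inversion,
reference stages, lag and rate tables, and the Tukey rate comparison."""

import numpy as np
import pandas as pd
import pytest

import ripesync as rs
from ripesync import kinetics as kin


# ---------------------------------------------------------------------------
# colour index
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "L,h,C,expected",
    [(50.0, 0.0, 10.0, 0.0), (40.0, 1.0, 5.0, 4.0), (45.0, 2.0, 45.0, 4.0)],
)
def test_colour_index_ratio_formula(L, h, C, expected):
    assert kin.colour_index(L, h, C) == pytest.approx(expected)


def test_colour_index_literal_interpretation():
    assert kin.colour_index(40.0, 1.0, 5.0, formula="literal") == pytest.approx(
        180.0 / 40.0 + 5.0
    )


def test_colour_index_rejects_degenerate_denominator():
    with pytest.raises(ValueError):
        kin.colour_index(0.0, 1.0, 0.0)


# ---------------------------------------------------------------------------
# curve fitting
# ---------------------------------------------------------------------------

def _table_from_curve(days, values, cls="RS"):
    return pd.DataFrame(
        {
            "class": cls,
            "day": np.repeat(days, 1),
            "brix": values,
        }
    )


def test_linear_fit_recovers_generating_slope_exactly():
    days = np.array([0.0, 7.0, 14.0, 21.0])
    tab = _table_from_curve(days, 10.0 + 0.5 * days)
    fit = kin.fit_ripening_curve(tab, "RS", "brix", window=(0, 21), degree=1)
    assert fit.coefficients[0] == pytest.approx(0.5, abs=1e-9)
    assert fit.coefficients[1] == pytest.approx(10.0, abs=1e-9)
    assert fit.r_squared == pytest.approx(1.0)


def test_quadratic_fit_recovers_coefficients_exactly():
    days = np.array([0.0, 7.0, 14.0, 21.0, 28.0])
    y = 11.0 + 0.4 * days + 0.004 * days**2
    fit = kin.fit_ripening_curve(
        _table_from_curve(days, y), "RS", "brix", window=(0, 28), degree=2
    )
    np.testing.assert_allclose(fit.coefficients, [0.004, 0.4, 11.0], atol=1e-9)


def test_noisy_fit_matches_normal_equations_oracle():
    rng = np.random.default_rng(5)
    days = np.array([0.0, 7.0, 14.0, 21.0])
    y = 10.0 + 0.3 * days + rng.normal(0, 0.2, days.size)
    fit = kin.fit_ripening_curve(
        _table_from_curve(days, y), "RS", "brix", window=(0, 21), degree=1
    )
    X = np.column_stack([days, np.ones_like(days)])
    beta = np.linalg.solve(X.T @ X, X.T @ y)  # brute-force normal equations
    np.testing.assert_allclose(fit.coefficients, beta, atol=1e-9)


def test_non_monotone_fit_rejected():
    days = np.array([0.0, 7.0, 14.0, 21.0])
    y = np.array([15.0, 10.0, 10.0, 15.0])
    with pytest.raises(ValueError, match="non-monotone"):
        kin.fit_ripening_curve(
            _table_from_curve(days, y), "RS", "brix", window=(0, 21), degree=2
        )


def test_insufficient_days_rejected():
    days = np.array([0.0, 7.0, 14.0])
    with pytest.raises(ValueError, match="distinct days"):
        kin.fit_ripening_curve(
            _table_from_curve(days, 10 + days), "RS", "brix", window=(0, 14),
            degree=2,
        )


# ---------------------------------------------------------------------------
# inversion
# ---------------------------------------------------------------------------

def _linear_fit(intercept, slope):
    return kin.KineticsFit(
        cls="PS", response="brix", coefficients=(slope, intercept),
        window=(0.0, 21.0), r_squared=1.0, n_points=4,
    )


def test_days_to_reference_closed_form_linear():
    fit = _linear_fit(10.0, 0.5)
    assert kin.days_to_reference(fit, 12.6) == pytest.approx(5.2, abs=1e-6)


def test_days_to_reference_matches_grid_search_quadratic():
    fit = kin.KineticsFit(
        cls="GS", response="brix", coefficients=(0.005, 0.2, 11.0),
        window=(0.0, 21.0), r_squared=1.0, n_points=5,
    )
    ref = 14.2
    t = kin.days_to_reference(fit, ref)
    grid = np.arange(-5.0, 28.0, 1e-4)
    idx = np.argmax(np.polyval(fit.coefficients, grid) >= ref)
    assert t == pytest.approx(grid[idx], abs=2e-4)


def test_days_to_reference_identity_with_fitted_curve():
    fit = kin.KineticsFit(
        cls="GH", response="brix", coefficients=(0.003, 0.25, 10.5),
        window=(0.0, 21.0), r_squared=1.0, n_points=5,
    )
    for ref in (11.0, 12.5, 14.0, 16.0):
        t = kin.days_to_reference(fit, ref)
        assert fit.predict(t) == pytest.approx(ref, abs=1e-5)


def test_unreachable_reference_raises():
    with pytest.raises(ValueError, match="not .*reachable|reachable"):
        kin.days_to_reference(_linear_fit(10.0, 0.1), 50.0, margin=2.0)


# ---------------------------------------------------------------------------
# reference stages
# ---------------------------------------------------------------------------

def test_reference_stages_are_rs_class_means(phys_kinetics):
    table, stages = phys_kinetics
    assert list(stages["stage"]) == ["R1", "R2", "R3", "R4"]
    rs_means = (
        table[table["class"] == "RS"].groupby("day")["brix"].mean()
    )
    np.testing.assert_allclose(
        stages["brix_ref"], rs_means.loc[[0.0, 7.0, 14.0, 21.0]], atol=1e-12
    )
    # generator truth: references equal the configured curve at 0/7/14/21
    cfg = rs.SimConfig()
    true_vals = cfg.brix_curve.value(np.array([0.0, 7.0, 14.0, 21.0]))
    se = cfg.phys_noise_sd / np.sqrt(cfg.berries_per_class_per_week)
    assert np.all(np.abs(stages["brix_ref"] - true_vals) < 4 * se)


def test_constant_rs_trajectory_rejected():
    table = pd.DataFrame(
        {
            "class": "RS",
            "day": np.repeat([0.0, 7.0, 14.0, 21.0], 2),
            "brix": 12.0,
            "L": 32.0,
            "h": 1.0,
            "C": 8.0,
        }
    )
    with pytest.raises(ValueError, match="strictly increasing"):
        kin.define_reference_stages(table)


def test_missing_rs_timepoint_rejected(default_phys):
    table = default_phys[default_phys["day"] != 7.0]
    with pytest.raises(ValueError, match="day 7"):
        kin.define_reference_stages(rs.add_colour_index(table))


# ---------------------------------------------------------------------------
# lag and rate tables
# ---------------------------------------------------------------------------

TABLE1_BRIX_DAYS = {
    "RS": {"R1": 0.0, "R2": 7.0, "R3": 14.0},
    "PS": {"R1": 6.5, "R2": 10.8, "R3": 15.4},
    "GS": {"R1": 9.9, "R2": 13.2, "R3": 17.0},
    "GH": {"R1": 13.0, "R2": 16.1, "R3": 19.1},
}


def test_lag_table_reproduces_published_rounded_lags():
    lags = kin.lag_table(TABLE1_BRIX_DAYS)
    piv = lags.pivot(index="class", columns="stage", values="rounded_lag")
    assert piv.loc["PS", "R1"] == 7
    assert piv.loc["GS", "R1"] == 10
    assert piv.loc["GH", "R1"] == 13
    assert piv.loc["PS", "R3"] == 1
    assert piv.loc["GS", "R3"] == 3
    assert piv.loc["GH", "R3"] == 5


def test_lag_table_identical_days_gives_zero_lags():
    days = {c: {"R1": 3.0} for c in ("RS", "PS", "GS")}
    lags = kin.lag_table(days, rs_days={"R1": 3.0})
    assert (lags["lag_vs_rs"] == 0).all()
    assert (lags["rounded_lag"] == 0).all()


def test_lag_rounding_is_half_up():
    lags = kin.lag_table({"PS": {"R1": 6.5}}, rs_days={"R1": 0.0})
    assert lags.loc[0, "rounded_lag"] == 7


def test_accumulation_rate_from_published_reference_values():
    stages = pd.DataFrame(
        {
            "stage": ["R1", "R2", "R3"],
            "rs_day": [0.0, 7.0, 14.0],
            "brix_ref": [12.6, 13.9, 15.3],
            "ci_ref": [3.4, 4.4, 5.1],
        }
    )
    days = pd.DataFrame(
        {"class": "RS", "stage": ["R1", "R2", "R3"], "response": "brix",
         "day": [0.0, 7.0, 14.0]}
    )
    rates = kin.accumulation_rates(stages, days)
    # (13.9 - 12.6) / 7 for R1->R2
    assert rates.loc[rates["interval"] == "R1-R2", "rate"].iloc[0] == pytest.approx(
        1.3 / 7.0
    )
    assert rates.loc[rates["interval"] == "R2-R3", "rate"].iloc[0] == pytest.approx(
        1.4 / 7.0
    )


def test_linear_trajectory_gives_constant_rate_and_shift_invariance():
    stages = pd.DataFrame(
        {"stage": ["R1", "R2", "R3"], "rs_day": [0.0, 7.0, 14.0],
         "brix_ref": [12.0, 13.4, 14.8], "ci_ref": [3.0, 4.0, 5.0]}
    )
    days = pd.DataFrame(
        {"class": "GS", "stage": ["R1", "R2", "R3"], "response": "brix",
         "day": [5.0, 12.0, 19.0]}
    )
    rates = kin.accumulation_rates(stages, days)
    assert np.allclose(rates["rate"], 0.2)
    shifted = days.assign(day=days["day"] + 11.0)  # re-label the day axis
    pd.testing.assert_frame_equal(
        kin.accumulation_rates(stages, shifted)[["rate"]], rates[["rate"]]
    )


def test_smaller_day_span_gives_strictly_larger_rate():
    stages = pd.DataFrame(
        {"stage": ["R1", "R2"], "rs_day": [0.0, 7.0],
         "brix_ref": [12.0, 14.0], "ci_ref": [3.0, 4.0]}
    )
    slow = kin.accumulation_rates(
        stages, pd.DataFrame({"class": "GH", "stage": ["R1", "R2"],
                              "response": "brix", "day": [0.0, 10.0]})
    )
    fast = kin.accumulation_rates(
        stages, pd.DataFrame({"class": "PS", "stage": ["R1", "R2"],
                              "response": "brix", "day": [0.0, 5.0]})
    )
    assert fast["rate"].iloc[0] > slow["rate"].iloc[0]


def test_non_increasing_days_rejected():
    stages = pd.DataFrame(
        {"stage": ["R1", "R2"], "rs_day": [0.0, 7.0],
         "brix_ref": [12.0, 14.0], "ci_ref": [3.0, 4.0]}
    )
    days = pd.DataFrame({"class": "GH", "stage": ["R1", "R2"],
                         "response": "brix", "day": [5.0, 5.0]})
    with pytest.raises(ValueError, match="not increasing"):
        kin.accumulation_rates(stages, days)


# ---------------------------------------------------------------------------
# generator-truth lag recovery
# ---------------------------------------------------------------------------

TRUE_LAGS = {"GH": 13.0, "GS": 10.0, "PS": 7.0, "RS": 0.0}


def test_noise_free_lag_recovery_is_tight():
    cfg = rs.SimConfig(seed=0, phys_noise_sd=0.0, berries_per_class_per_week=2)
    table = rs.add_colour_index(rs.simulate_physiology(cfg))
    stages = kin.define_reference_stages(table)
    days = kin.ripening_day_table(table, stages, response="brix",
                                  stage_ids=("R1",))
    lags = kin.lag_table(days).set_index("class")["lag_vs_rs"]
    for cls, true in TRUE_LAGS.items():
        # residual error is pure polynomial-approximation bias
        assert lags[cls] == pytest.approx(true, abs=0.15)


def test_noisy_lag_recovery_within_half_day(phys_kinetics):
    table, stages = phys_kinetics
    days = kin.ripening_day_table(table, stages, response="brix",
                                  stage_ids=("R1",))
    lags = kin.lag_table(days).set_index("class")["lag_vs_rs"]
    for cls, true in TRUE_LAGS.items():
        assert abs(lags[cls] - true) < 0.5


def test_between_class_spread_shrinks_towards_maturity(default_phys):
    spread_v = kin.between_class_spread(default_phys, 0.0, "brix")
    spread_late = kin.between_class_spread(default_phys, 35.0, "brix")
    assert spread_late < spread_v
    mids = [kin.between_class_spread(default_phys, d, "brix")
            for d in (0.0, 7.0, 14.0, 21.0, 35.0)]
    assert all(a >= b for a, b in zip(mids[:-1], mids[1:]))


def test_between_class_spread_simple_values():
    tab = pd.DataFrame(
        {"class": ["A", "A", "B", "C"], "day": 0.0,
         "brix": [10.0, 10.0, 12.0, 15.0]}
    )
    assert kin.between_class_spread(tab, 0.0, "brix") == pytest.approx(5.0)
    with pytest.raises(ValueError, match="no samples"):
        kin.between_class_spread(tab, 3.0, "brix")


# ---------------------------------------------------------------------------
# equivalent-stage ratios
# ---------------------------------------------------------------------------

def test_equivalent_stage_ratio_basics():
    assert kin.equivalent_stage_ratio([2.0, 3.0], [2.0, 3.0]).tolist() == [1.0, 1.0]
    rs_levels = np.array([10.0, 8.0, 5.0])
    ratio = kin.equivalent_stage_ratio(0.7 * rs_levels, rs_levels)
    np.testing.assert_allclose(ratio, 0.70)  # e.g. hormone 30% lower in GS
    fwd = kin.equivalent_stage_ratio([1.0, 4.0], [2.0, 5.0])
    rev = kin.equivalent_stage_ratio([2.0, 5.0], [1.0, 4.0])
    np.testing.assert_allclose(fwd * rev, 1.0)
    with pytest.raises(ValueError, match="positive"):
        kin.equivalent_stage_ratio([1.0], [0.0])


# ---------------------------------------------------------------------------
# rate comparison
# ---------------------------------------------------------------------------

def test_identical_groups_share_a_letter():
    df = pd.DataFrame({"class": ["A"] * 4 + ["B"] * 4,
                       "rate": [0.2, 0.21, 0.19, 0.2] * 2})
    res = kin.compare_rates(df)
    assert res["letters"]["A"] == res["letters"]["B"]
    assert not res["degenerate"]


def test_widely_separated_groups_get_distinct_letters():
    rng = np.random.default_rng(0)
    df = pd.DataFrame(
        {"class": ["A"] * 6 + ["B"] * 6,
         "rate": np.r_[rng.normal(0.2, 0.01, 6), rng.normal(0.4, 0.01, 6)]}
    )
    res = kin.compare_rates(df)
    assert set(res["letters"]["A"]) & set(res["letters"]["B"]) == set()
    assert res["p_anova"] < 0.001


def test_degenerate_zero_variance_flagged():
    df = pd.DataFrame({"class": ["A"] * 3 + ["B"] * 3,
                       "rate": [0.2] * 3 + [0.4] * 3})
    res = kin.compare_rates(df)
    assert res["degenerate"]
    assert res["letters"]["A"] != res["letters"]["B"]


def test_time_shifted_classes_share_equivalent_stage_rates(phys_kinetics):
    """Under the generator's pure time-shift model every class traverses
    the same curve segment between equivalent stages, so the R1->R2 and
    R2->R3 accumulation rates must agree across classes (up to fit noise).
    """
    table, stages = phys_kinetics
    days = kin.ripening_day_table(table, stages, response="brix")
    rates = kin.accumulation_rates(stages, days, response="brix")
    for _, grp in rates.groupby("interval"):
        r = grp["rate"].to_numpy()
        assert np.ptp(r) / np.mean(r) < 0.10
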