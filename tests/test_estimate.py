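"""Odds ratios, risk differences, difference-in-differences, adjusted fits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tripletrial import (Comparison, TrialConfig, adjusted_comparison,
                         apply_effects, difference_in_differences,
                         fit_logistic, odds_ratio_2x2, randomize_trial,
                         ratio_of_odds_ratios, risk_difference,
                         simulate_trial)
from tripletrial.estimate import (regression_odds_ratio, round_half_up,
                                  two_by_two_from_records)
from tripletrial.fixtures import week6_two_by_two
from tripletrial.records import TwoByTwo

# Published unadjusted week-6 odds-ratio grid (rounded to 2 dp).
PRINTED_OR = {
    ("fear", "control", "all"): 1.03,
    ("social", "control", "all"): 1.58,
    ("social", "fear", "all"): 1.54,
    ("fear", "control", "consistent"): 0.70,
    ("social", "control", "consistent"): 1.61,
    ("social", "fear", "consistent"): 2.30,
    ("fear", "control", "inconsistent"): 1.66,
    ("social", "control", "inconsistent"): 1.84,
    ("social", "fear", "inconsistent"): 1.11,
}


@pytest.mark.parametrize("exposed, reference, subgroup", PRINTED_OR)
def test_week6_cross_product_ors_match_published_grid(exposed, reference,
                                                      subgroup):
    t = week6_two_by_two(exposed, reference, subgroup)
    est = odds_ratio_2x2(t)
    assert round_half_up(est.odds_ratio, 2) == \
        PRINTED_OR[(exposed, reference, subgroup)]


def test_symmetric_table_gives_unit_odds_ratio():
    est = odds_ratio_2x2(TwoByTwo(10, 10, 10, 10))
    assert est.odds_ratio == 1.0 and est.log_or == 0.0


def test_zero_cells_flag_without_raising():
    assert odds_ratio_2x2(TwoByTwo(5, 0, 3, 7)).odds_ratio == math.inf
    assert odds_ratio_2x2(TwoByTwo(0, 5, 3, 7)).odds_ratio == 0.0
    assert math.isnan(odds_ratio_2x2(TwoByTwo(0, 5, 0, 7)).odds_ratio)


@given(a=st.integers(1, 60), b=st.integers(1, 60),
       c=st.integers(1, 60), d=st.integers(1, 60))
@settings(deadline=None, derandomize=True, max_examples=60)
def test_swapping_exposed_and_reference_inverts_the_or(a, b, c, d):
    forward = odds_ratio_2x2(TwoByTwo(a, b, c, d)).odds_ratio
    backward = odds_ratio_2x2(TwoByTwo(c, d, a, b)).odds_ratio
    assert forward * backward == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize("exposed, reference, subgroup", PRINTED_OR)
def test_regression_path_equals_cross_product(paper_roster, exposed,
                                              reference, subgroup):
    """With a single arm indicator, exp(beta) is the 2x2 OR (>=6 dp)."""
    records, _ = paper_roster
    sg = {"all": "all", "consistent": "baseline_consistent",
          "inconsistent": "baseline_inconsistent"}[subgroup]
    sided = "two" if "control" not in (exposed, reference) else "one"
    c = Comparison(exposed, reference, subgroup=sg, sided=sided)
    reg = regression_odds_ratio(records, c)
    cross = odds_ratio_2x2(two_by_two_from_records(records, c))
    assert reg.odds_ratio == pytest.approx(cross.odds_ratio, abs=5e-7)


def test_logistic_matches_grid_search_oracle():
    from test_randomize import grid_search_logistic

    rng = np.random.default_rng(21)
    X = np.column_stack([np.ones(40), rng.normal(size=(40, 3))])
    beta_true = np.array([0.2, 0.8, -0.5, 0.3])
    y = (rng.random(40) < 1 / (1 + np.exp(-X @ beta_true))).astype(float)
    fit = fit_logistic(y, X, ["intercept", "x1", "x2", "x3"])
    oracle = grid_search_logistic(y, X)
    got = np.array(list(fit["coefficients"].values()))
    assert np.max(np.abs(got - oracle)) < 1e-4


def test_constant_outcome_gives_flat_flag_and_zero_slope():
    X = np.column_stack([np.ones(12), np.repeat([0, 1], 6)])
    fit = fit_logistic(np.ones(12), X, ["intercept", "arm"])
    assert fit["flag"] == "degenerate"
    assert fit["coefficients"]["arm"] == 0.0


def test_collinear_columns_raise_naming_them():
    rng = np.random.default_rng(2)
    x = rng.normal(size=20)
    X = np.column_stack([np.ones(20), x, 2 * x])
    y = (rng.random(20) < 0.5).astype(float)
    with pytest.raises(ValueError, match="x_twice"):
        fit_logistic(y, X, ["intercept", "x_once", "x_twice"])


# --- covariate-adjusted comparisons -----------------------------------------

def _assigned_trial(seed, effects_config):
    rng = np.random.default_rng(seed)
    records = simulate_trial(effects_config, rng=rng)
    assigned, _, _ = randomize_trial(records, seed=seed + 1, covariates=())
    return apply_effects(assigned, effects_config, rng)


def test_constant_controls_reduce_to_unadjusted_exactly():
    config = TrialConfig(n_participants=150, covariate_missingness=0.0)
    records = _assigned_trial(5, config)
    records = [r.__class__(**{**r.__dict__, "married": 1,
                              "driving_setting": "urban",
                              "night_freq": "never",
                              "weekend_freq": "always"}) for r in records]
    c = Comparison("social", "control", adjusted=True)
    adj = adjusted_comparison(records, c)
    unadj = regression_odds_ratio(
        records, Comparison("social", "control"))
    assert adj.odds_ratio == pytest.approx(unadj.odds_ratio, rel=1e-9)


def test_adjusted_tracks_unadjusted_when_covariates_carry_no_effect():
    """Covariates are independent of outcome in the generator, so the
    adjusted log-OR differs from the unadjusted one only by estimation
    noise; over replicates the mean difference is ~0."""
    diffs = []
    config = TrialConfig(covariate_missingness=0.0)
    for rep in range(40):
        records = _assigned_trial(100 + rep, config)
        c_adj = Comparison("social", "control", adjusted=True)
        adj = adjusted_comparison(records, c_adj)
        unadj = regression_odds_ratio(records,
                                      Comparison("social", "control"))
        diffs.append(adj.log_or - unadj.log_or)
    se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
    assert abs(np.mean(diffs)) < max(3 * se, 0.02)


def test_adjusted_subgroup_too_small_reports_rank_deficiency():
    """More non-constant dummy columns than rows cannot be fit."""
    from tripletrial.records import ParticipantRecord

    settings_cycle = ["urban", "suburban", "both"]
    freq_cycle = ["never", "sometimes", "usually", "always"]
    tiny = [ParticipantRecord(
        id=f"s{i}", baseline_consistent=1,
        arm="social" if i % 2 else "control", outcome_wk6=i % 2,
        married=i % 2, driving_setting=settings_cycle[i % 3],
        night_freq=freq_cycle[i % 4], weekend_freq=freq_cycle[(i + 1) % 4])
        for i in range(6)]
    c = Comparison("social", "control", adjusted=True,
                   subgroup="baseline_consistent")
    with pytest.raises(ValueError, match="rank|collinear"):
        adjusted_comparison(tiny, c)


# --- differences ------------------------------------------------------------

@pytest.mark.parametrize("args, expected", [
    ((74, 116, 58, 110), 11.1),   # week-6 social vs control
    ((28, 58, 18, 50), 12.3),     # inconsistent stratum, fear vs control
    ((29, 57, 18, 50), 14.9),     # inconsistent stratum, social vs control
    ((50, 100, 25, 50), 0.0),
])
def test_risk_difference_reproduces_published_values(args, expected):
    assert round_half_up(risk_difference(*args), 1) == expected


def test_difference_in_differences_from_unrounded_proportions():
    fear_wk6 = risk_difference(63, 118, 58, 110)
    fear_base = risk_difference(69, 131, 69, 130)
    assert round_half_up(
        difference_in_differences(fear_wk6, fear_base), 1) == 1.1
    social_wk6 = risk_difference(74, 116, 58, 110)
    social_base = risk_difference(69, 130, 69, 130)
    assert round_half_up(
        difference_in_differences(social_wk6, social_base), 1) == 11.1
    assert difference_in_differences(2.5, 2.5) == 0.0


# --- ratio of odds ratios ----------------------------------------------------

@pytest.mark.parametrize("pair, expected", [
    (("fear", "control"), 0.42),
    (("social", "control"), 0.87),
    (("social", "fear"), 2.07),
])
def test_ratio_of_odds_ratios_matches_published_row(pair, expected):
    exposed, reference = pair
    num = odds_ratio_2x2(
        week6_two_by_two(exposed, reference, "consistent")).odds_ratio
    den = odds_ratio_2x2(
        week6_two_by_two(exposed, reference, "inconsistent")).odds_ratio
    assert round_half_up(ratio_of_odds_ratios(num, den), 2) == expected


def test_ratio_of_equal_ors_is_one_and_infinite_inputs_pass_through():
    assert ratio_of_odds_ratios(1.58, 1.58) == 1.0
    assert ratio_of_odds_ratios(math.inf, 2.0) == math.inf
    assert ratio_of_odds_ratios(0.0, 2.0) == 0.0
    assert math.isnan(ratio_of_odds_ratios(0.0, 0.0))


def test_rounding_is_half_up_as_in_the_tables():
    assert round_half_up(0.875, 2) == 0.88  # exact binary tie, away from 0
    assert round_half_up(-0.875, 2) == -0.88
    assert round_half_up(1.0677, 1) == 1.1  # fear difference-in-differences
    assert round_half_up(1.5796, 2) == 1.58
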