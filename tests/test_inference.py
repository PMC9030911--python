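"""Permutation engine, enumeration oracle, Holm-Bonferroni."""

import collections
import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from tripletrial import (Comparison, PermutationPlan, TrialConfig,
                         apply_effects, effect_modification_test,
                         exact_pvalue, holm_bonferroni, permutation_pvalue,
                         randomize_trial, rerandomize, simulate_trial)
from tripletrial.randomize import TripletAssignment
from tripletrial.records import ParticipantRecord

from conftest import make_triplet_records


# --- rerandomization mechanism ----------------------------------------------

def test_single_triplet_relabeling_is_one_of_six_arrangements():
    _, triplets = make_triplet_records([(1, 0, 1)])
    seen = set()
    rng = np.random.default_rng(0)
    for _ in range(200):
        labels = rerandomize(triplets, rng)
        seen.add(tuple(labels[m] for m in triplets[0].member_ids))
    valid = set(itertools.permutations(("control", "fear", "social")))
    assert seen == valid


def test_zero_triplets_is_identity():
    assert rerandomize([], np.random.default_rng(0)) == {}


def test_joint_arrangements_uniform_over_216():
    _, triplets = make_triplet_records([(1, 0, 1), (0, 0, 1), (1, 1, 0)])
    rng = np.random.default_rng(42)
    counts = collections.Counter()
    n_draws = 21_600
    for _ in range(n_draws):
        labels = rerandomize(triplets, rng)
        key = tuple(labels[m] for t in triplets for m in t.member_ids)
        counts[key] += 1
    assert len(counts) == 216
    observed = np.array([counts[k] for k in counts])
    expected = n_draws / 216
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    from scipy.stats import chi2 as chi2_dist
    assert chi2 < chi2_dist.ppf(0.99, 215)


# --- permutation p-values ----------------------------------------------------

def test_constant_outcome_gives_p_one():
    records, triplets = make_triplet_records([(1, 1, 1), (1, 1, 1)])
    plan = PermutationPlan(triplets, B=200, seed=3)
    res = permutation_pvalue(records, plan,
                             Comparison("social", "control", sided="one"))
    assert res.p_value == 1.0


def test_observed_statistic_beyond_every_draw_gives_p_zero():
    # social wins every pair; with 2 triplets a random draw reproduces
    # the extreme only with probability (2/6)^2 per draw
    records, triplets = make_triplet_records([(0, 0, 1), (0, 0, 1)],
                                             stratum="inconsistent")
    plan = PermutationPlan(triplets, B=12, seed=11)
    res = permutation_pvalue(records, plan,
                             Comparison("social", "control", sided="one"))
    if res.p_value == 0.0:
        assert res.exceedance_count == 0
    else:  # seed happened to reproduce a tie; plain fraction still small
        assert res.p_value <= 0.5


def test_engine_matches_exhaustive_enumeration_on_five_triplets():
    rng = np.random.default_rng(17)
    outcomes = [tuple(int(rng.random() < p) for p in (0.4, 0.5, 0.7))
                for _ in range(5)]
    records, triplets = make_triplet_records(outcomes)
    comparison = Comparison("social", "control", sided="one")
    exact = exact_pvalue(records, triplets, comparison)
    assert exact.B == 6 ** 5
    plan = PermutationPlan(triplets, B=20_000, seed=5)
    approx = permutation_pvalue(records, plan, comparison)
    p = exact.p_value
    assert abs(approx.p_value - p) <= 3 * math.sqrt(p * (1 - p) / 20_000)


def test_two_sided_p_at_least_one_sided_on_same_draws():
    rng = np.random.default_rng(23)
    outcomes = [tuple(int(rng.random() < p) for p in (0.3, 0.5, 0.8))
                for _ in range(12)]
    records, triplets = make_triplet_records(outcomes)
    p1 = permutation_pvalue(records, PermutationPlan(triplets, B=4000, seed=9),
                            Comparison("social", "control", sided="one"))
    p2 = permutation_pvalue(records, PermutationPlan(triplets, B=4000, seed=9),
                            Comparison("social", "control", sided="two"))
    assert p2.p_value >= p1.p_value


def test_seed_reproducibility_is_bit_identical():
    records, triplets = make_triplet_records(
        [(1, 0, 1), (0, 1, 1), (1, 1, 0), (0, 0, 1)])
    plan = PermutationPlan(triplets, B=1000, seed=99)
    c = Comparison("social", "control", sided="one")
    r1 = permutation_pvalue(records, plan, c)
    r2 = permutation_pvalue(records, plan, c)
    assert r1 == r2


def test_plus_one_variant_shifts_the_plain_fraction():
    records, triplets = make_triplet_records(
        [(1, 0, 1), (0, 1, 1), (1, 1, 0)])
    plan = PermutationPlan(triplets, B=500, seed=4)
    c = Comparison("social", "control", sided="one")
    plain = permutation_pvalue(records, plan, c)
    shifted = permutation_pvalue(records, plan, c, plus_one=True)
    assert shifted.p_value == pytest.approx(
        (plain.exceedance_count + 1) / 501)


def test_missing_outcomes_travel_with_the_individual():
    records, triplets = make_triplet_records(
        [(1, None, 1), (0, 1, None), (1, 1, 0), (0, 0, 1)])
    plan = PermutationPlan(triplets, B=2000, seed=6)
    res = permutation_pvalue(records, plan,
                             Comparison("social", "control", sided="one"))
    assert 0.0 <= res.p_value <= 1.0 and res.n_undefined <= 200


def test_attrition_subset_recomputed_per_permutation():
    """The permuted denominator varies with which arms the attrited
    individuals land in, so null draws must differ from a fixed-subset
    relabeling; verified via the exact enumeration with missingness."""
    records, triplets = make_triplet_records(
        [(1, None, 1), (0, 1, 0), (1, 0, 1)])
    comparison = Comparison("social", "control", sided="one")
    exact = exact_pvalue(records, triplets, comparison)
    plan = PermutationPlan(triplets, B=20_000, seed=13)
    approx = permutation_pvalue(records, plan, comparison)
    p = exact.p_value
    assert abs(approx.p_value - p) <= 3 * math.sqrt(p * (1 - p) / 20_000) + 1e-9


def test_undefined_statistic_on_most_draws_aborts():
    # a lone triplet with a single success: permuted 2x2s are degenerate
    records, triplets = make_triplet_records([(0, 0, 0)])
    plan = PermutationPlan(triplets, B=100, seed=2)
    records[2] = ParticipantRecord(id=records[2].id, baseline_consistent=1,
                                   arm="social", outcome_wk6=1)
    with pytest.raises(ValueError, match="undefined"):
        permutation_pvalue(records, plan,
                           Comparison("social", "control", sided="one"))


# --- Holm-Bonferroni ---------------------------------------------------------

def test_published_pvalues_survive_holm():
    """The trial's primary family {.47, .04, .12} rejects nothing at
    alpha=.05: the smallest p (.04) exceeds .05/3 = .0167."""
    res = holm_bonferroni([0.47, 0.04, 0.12], alpha=0.05)
    assert res.reject == [False, False, False]
    assert res.alpha / 3 == pytest.approx(0.0167, abs=5e-4)


def test_step_down_thresholds_reject_all_when_each_step_passes():
    res = holm_bonferroni([0.001, 0.02, 0.04], alpha=0.05)
    assert res.reject == [True, True, True]


def test_stopping_at_first_failure_blocks_later_hypotheses():
    # second-ranked p fails its threshold .025, so .03 < .05 is not tested
    res = holm_bonferroni([0.001, 0.04, 0.03], alpha=0.05)
    assert res.reject == [True, False, False]


def test_empty_family_is_empty():
    res = holm_bonferroni([])
    assert res.reject == [] and res.adjusted_p == []


@given(st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
                min_size=1, max_size=8))
@settings(deadline=None, derandomize=True, max_examples=100)
def test_holm_agrees_with_statsmodels(pvals):
    ours = holm_bonferroni(pvals, alpha=0.05)
    ref_reject, ref_adj, _, _ = multipletests(pvals, alpha=0.05,
                                              method="holm")
    assert ours.reject == list(ref_reject)
    assert np.allclose(ours.adjusted_p, ref_adj, atol=1e-12)


# --- effect modification ----------------------------------------------------

def test_identical_stratum_tables_give_zero_statistic():
    cons_records, cons_triplets = make_triplet_records(
        [(1, 0, 1), (0, 1, 1), (1, 1, 0), (0, 0, 1)], stratum="consistent",
        prefix="C")
    inc_records, inc_triplets = make_triplet_records(
        [(1, 0, 1), (0, 1, 1), (1, 1, 0), (0, 0, 1)], stratum="inconsistent",
        prefix="I")
    records = cons_records + inc_records
    plan = PermutationPlan(cons_triplets + inc_triplets, B=100, seed=1)
    res = effect_modification_test(records, ("social", "control"), plan)
    assert res.observed_statistic == 0.0
    assert res.sided == "two"


def test_effect_modification_p_matches_enumeration_oracle():
    rng = np.random.default_rng(31)
    cons = [tuple(int(rng.random() < p) for p in (0.5, 0.5, 0.8))
            for _ in range(4)]
    inc = [tuple(int(rng.random() < p) for p in (0.4, 0.4, 0.4))
           for _ in range(4)]
    cons_records, cons_triplets = make_triplet_records(
        cons, stratum="consistent", prefix="C")
    inc_records, inc_triplets = make_triplet_records(
        inc, stratum="inconsistent", prefix="I")
    records = cons_records + inc_records
    triplets = cons_triplets + inc_triplets
    comparison = Comparison("social", "control", sided="two")
    exact = exact_pvalue(records, triplets, comparison, statistic="log_ror")
    plan = PermutationPlan(triplets, B=20_000, seed=8)
    approx = effect_modification_test(records, ("social", "control"), plan)
    p = exact.p_value
    assert abs(approx.p_value - p) <= 3 * math.sqrt(p * (1 - p) / 20_000)


def test_effect_modification_type_one_error_is_nominal():
    """With identical arm effects in both strata the ratio-of-odds-ratios
    null holds; rejection at alpha=.05 stays within 3 binomial SE of 5%
    over 400 simulated trials."""
    config = TrialConfig(covariate_missingness=0.0,
                         effects={
                             "control": {"consistent": 0, "inconsistent": 0},
                             "fear": {"consistent": 0.3, "inconsistent": 0.3},
                             "social": {"consistent": 0.5,
                                        "inconsistent": 0.5}})
    n_trials, rejections = 400, 0
    for i in range(n_trials):
        rng = np.random.default_rng(5_000 + i)
        records = simulate_trial(config, rng=rng)
        assigned, triplets, _ = randomize_trial(records, seed=9_000 + i,
                                                covariates=())
        assigned = apply_effects(assigned, config, rng)
        plan = PermutationPlan(triplets, B=400, seed=13_000 + i)
        res = effect_modification_test(assigned, ("social", "control"), plan)
        rejections += res.p_value <= 0.05
    rate = rejections / n_trials
    se = math.sqrt(0.05 * 0.95 / n_trials)
    assert abs(rate - 0.05) <= 3 * se


def test_empty_stratum_in_an_arm_is_an_error():
    records, triplets = make_triplet_records([(1, 0, 1)],
                                             stratum="consistent")
    plan = PermutationPlan(triplets, B=10, seed=0)
    with pytest.raises(ValueError, match="stratum"):
        effect_modification_test(records, ("social", "control"), plan)
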