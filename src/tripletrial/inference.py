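"""Randomization (permutation) inference over the matched-triplet design.

P-values are obtained by re-drawing treatment assignments under the
actual assignment mechanism: each matched triplet (and the short
leftover unit) is independently re-assigned one of the six arm
permutations, uniformly with replacement, and the test statistic is
recomputed on every rerandomized dataset. The fraction of null draws at
least as extreme as the observed statistic is the p-value.

Conventions:

* one-sided p = #(permuted statistic >= observed)/B, with the statistic
  signed toward the hypothesized benefit of the exposed arm;
* two-sided p = #(|permuted| >= |observed|)/B;
* plain-fraction p by default (ties count as exceedance); the
  finite-sample-valid (+1)/(B+1) variant is available via
  ``plus_one=True``.

Assignments are permuted over the full roster; each permuted statistic
is computed on the observed-outcome subset, so wave-wise attrition
travels with the individual and the permuted assignment distribution is
identical to the original randomization distribution.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .estimate import (Comparison, adjusted_comparison, odds_ratio_2x2,
                       ratio_of_odds_ratios, two_by_two_from_records)
from .randomize import DEFAULT_ARM_ORDER, PERM_CODES, TripletAssignment, _as_rng
from .records import ParticipantRecord, subgroup_mask, to_frame

_ARM_INDEX = {arm: i for i, arm in enumerate(DEFAULT_ARM_ORDER)}


@dataclass
class PermutationPlan:
    """How to rerandomize: the matched units, draw count, seed, statistic.

    ``statistic`` is a named plug-in: ``log_or`` (unadjusted log odds
    ratio, the default), ``log_or_adjusted`` (covariate-adjusted), or
    ``log_ror`` (log ratio-of-odds-ratios between baseline strata), or
    any callable ``f(frame_with_arm_column) -> float``.
    """

    triplets: Sequence[TripletAssignment]
    B: int = 10_000
    seed: Optional[int] = None
    statistic: Union[str, Callable] = "log_or"

    def __post_init__(self):
        if self.B < 1:
            raise ValueError("B must be >= 1")


@dataclass
class InferenceResult:
    """A permutation test's outcome, fully seed-reproducible."""

    observed_statistic: float
    p_value: float
    sided: str
    B: int
    seed: Optional[int]
    null_mean: float
    null_sd: float
    exceedance_count: int
    n_undefined: int = 0

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "observed_statistic", "p_value", "sided", "B", "seed",
            "null_mean", "null_sd", "exceedance_count", "n_undefined")}


def _layout(records: Sequence[ParticipantRecord],
            triplets: Sequence[TripletAssignment]):
    """Per-record (unit index, within-unit position); errors on orphans."""
    where = {}
    for u, t in enumerate(triplets):
        for pos, mid in enumerate(t.member_ids):
            if mid in where:
                raise ValueError(f"participant {mid!r} in two units")
            where[mid] = (u, pos)
    unit = np.empty(len(records), dtype=np.int64)
    pos = np.empty(len(records), dtype=np.int64)
    for i, r in enumerate(records):
        if r.id not in where:
            raise ValueError(
                f"participant {r.id!r} belongs to no triplet or leftover "
                "unit; inference requires the realized assignment units")
        unit[i], pos[i] = where[r.id]
    return unit, pos


def rerandomize(triplets: Sequence[TripletAssignment], rng,
                arm_order=DEFAULT_ARM_ORDER) -> dict:
    """One fresh uniform draw of arms per unit: ``{participant_id: arm}``."""
    rng = _as_rng(rng)
    draws = rng.integers(0, 6, size=len(triplets))
    labels = {}
    for t, k in zip(triplets, draws):
        for p, mid in enumerate(t.member_ids):
            labels[mid] = arm_order[PERM_CODES[k, p]]
    return labels


def _outcome_vector(records, outcome_field) -> np.ndarray:
    y = np.full(len(records), np.nan)
    for i, r in enumerate(records):
        v = getattr(r, outcome_field)
        if v is not None:
            y[i] = float(v)
    return y


def _logor_from_counts(a, b, c, d):
    with np.errstate(all="ignore"):
        return np.log((a * d) / (b * c))


def _stats_logor(M, unit, pos, y, keep, e_code, r_code):
    """Vectorized log-OR for draw matrix M (n_draws x n_units)."""
    idx = np.flatnonzero(keep & ~np.isnan(y))
    yy = y[idx]
    arms = PERM_CODES[M[:, unit[idx]], pos[idx]]  # (n_draws, m)
    is_e = arms == e_code
    is_r = arms == r_code
    a = is_e @ yy
    ne = is_e.sum(axis=1)
    c = is_r @ yy
    nr = is_r.sum(axis=1)
    return _logor_from_counts(a, ne - a, c, nr - c)


def _observed_codes(records) -> np.ndarray:
    codes = np.empty(len(records), dtype=np.int64)
    for i, r in enumerate(records):
        if r.arm is None:
            raise ValueError(f"participant {r.id!r} has no assigned arm")
        codes[i] = _ARM_INDEX[r.arm]
    return codes


def _stats_logor_codes(arm_codes, y, keep, e_code, r_code) -> float:
    idx = np.flatnonzero(keep & ~np.isnan(y))
    yy = y[idx]
    arms = arm_codes[idx]
    a = yy[arms == e_code].sum()
    ne = (arms == e_code).sum()
    c = yy[arms == r_code].sum()
    nr = (arms == r_code).sum()
    return float(_logor_from_counts(a, ne - a, c, nr - c))


def permutation_pvalue(records: Sequence[ParticipantRecord],
                       plan: PermutationPlan,
                       comparison: Comparison,
                       plus_one: bool = False) -> InferenceResult:
    """Permutation p-value for a pairwise arm contrast.

    Fast, fully vectorized for the count-based statistics (``log_or``,
    ``log_ror``); the adjusted statistic refits a logistic model per
    draw. Aborts if the statistic is undefined (empty cells on both
    diagonals) on more than 10% of draws.
    """
    rng = np.random.default_rng(plan.seed)
    unit, pos = _layout(records, plan.triplets)
    y = _outcome_vector(records, comparison.outcome_field)
    keep = subgroup_mask(records, comparison.subgroup)
    e_code = _ARM_INDEX[comparison.exposed_arm]
    r_code = _ARM_INDEX[comparison.reference_arm]

    stat_name = plan.statistic
    if stat_name == "log_or":
        obs = _stats_logor_codes(_observed_codes(records), y, keep,
                                 e_code, r_code)
        M = rng.integers(0, 6, size=(plan.B, len(plan.triplets)))
        null = _stats_logor(M, unit, pos, y, keep, e_code, r_code)
    elif stat_name == "log_ror":
        obs, null = _ror_statistics(records, plan, comparison, rng,
                                    unit, pos, y)
    else:
        obs, null = _loop_statistics(records, plan, comparison, rng)

    return _summarize(obs, null, comparison.sided, plan, plus_one)


def _ror_statistics(records, plan, comparison, rng, unit, pos, y):
    cons = subgroup_mask(records, "consistent")
    inc = subgroup_mask(records, "inconsistent")
    e_code = _ARM_INDEX[comparison.exposed_arm]
    r_code = _ARM_INDEX[comparison.reference_arm]
    codes = _observed_codes(records)
    with np.errstate(all="ignore"):
        obs = (_stats_logor_codes(codes, y, cons, e_code, r_code)
               - _stats_logor_codes(codes, y, inc, e_code, r_code))
        M = rng.integers(0, 6, size=(plan.B, len(plan.triplets)))
        null = (_stats_logor(M, unit, pos, y, cons, e_code, r_code)
                - _stats_logor(M, unit, pos, y, inc, e_code, r_code))
    return obs, null


def _loop_statistics(records, plan, comparison, rng):
    """Generic slow path: recompute an arbitrary statistic per draw."""
    if plan.statistic == "log_or_adjusted":
        adj = Comparison(comparison.exposed_arm, comparison.reference_arm,
                         wave=comparison.wave, subgroup=comparison.subgroup,
                         adjusted=True, sided=comparison.sided)

        def stat_fn(recs):
            return adjusted_comparison(recs, adj).log_or
    elif callable(plan.statistic):
        fn = plan.statistic

        def stat_fn(recs):
            return fn(to_frame(recs))
    else:
        raise ValueError(f"unknown statistic {plan.statistic!r}")

    obs = stat_fn(records)
    null = np.empty(plan.B)
    for b in range(plan.B):
        labels = rerandomize(plan.triplets, rng)
        relabeled = [r.__class__(**{**r.__dict__, "arm": labels[r.id]})
                     for r in records]
        try:
            null[b] = stat_fn(relabeled)
        except ValueError:
            null[b] = np.nan
    return obs, null


def _summarize(obs, null, sided, plan, plus_one) -> InferenceResult:
    null = np.asarray(null, dtype=float)
    n_undef = int(np.isnan(null).sum())
    if math.isnan(obs):
        if n_undef == null.size:
            # statistic constant/undefined under every relabeling (e.g. a
            # constant outcome): no assignment is more extreme, p = 1
            return InferenceResult(
                observed_statistic=float(obs), p_value=1.0, sided=sided,
                B=plan.B, seed=plan.seed, null_mean=math.nan,
                null_sd=math.nan, exceedance_count=plan.B,
                n_undefined=n_undef)
        raise ValueError("statistic undefined on the observed assignment")
    if n_undef > 0.1 * plan.B:
        raise ValueError(
            f"statistic undefined on {n_undef}/{plan.B} permuted datasets; "
            "the design cells are too sparse for this contrast")
    with np.errstate(invalid="ignore"):
        if sided == "one":
            exceed = int(np.nansum(null >= obs))
        else:
            exceed = int(np.nansum(np.abs(null) >= abs(obs)))
    if plus_one:
        p = (exceed + 1) / (plan.B + 1)
    else:
        p = exceed / plan.B
    finite = null[np.isfinite(null)]
    return InferenceResult(
        observed_statistic=float(obs), p_value=float(p), sided=sided,
        B=plan.B, seed=plan.seed,
        null_mean=float(finite.mean()) if finite.size else math.nan,
        null_sd=float(finite.std(ddof=1)) if finite.size > 1 else math.nan,
        exceedance_count=exceed, n_undefined=n_undef)


def exact_pvalue(records: Sequence[ParticipantRecord],
                 triplets: Sequence[TripletAssignment],
                 comparison: Comparison,
                 statistic: str = "log_or") -> InferenceResult:
    """Exhaustive-enumeration p over all 6^U equally likely assignments.

    Tractable for small unit counts (the oracle for engine validation).
    """
    U = len(triplets)
    if U > 8:
        raise ValueError("exhaustive enumeration is limited to <=8 units")
    M = np.array(list(itertools.product(range(6), repeat=U)), dtype=np.int64)
    unit, pos = _layout(records, triplets)
    y = _outcome_vector(records, comparison.outcome_field)
    keep = subgroup_mask(records, comparison.subgroup)
    e_code = _ARM_INDEX[comparison.exposed_arm]
    r_code = _ARM_INDEX[comparison.reference_arm]
    codes = _observed_codes(records)
    if statistic == "log_or":
        obs = _stats_logor_codes(codes, y, keep, e_code, r_code)
        null = _stats_logor(M, unit, pos, y, keep, e_code, r_code)
    elif statistic == "log_ror":
        cons = subgroup_mask(records, "consistent")
        inc = subgroup_mask(records, "inconsistent")
        obs = (_stats_logor_codes(codes, y, cons, e_code, r_code)
               - _stats_logor_codes(codes, y, inc, e_code, r_code))
        null = (_stats_logor(M, unit, pos, y, cons, e_code, r_code)
                - _stats_logor(M, unit, pos, y, inc, e_code, r_code))
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    plan = PermutationPlan(triplets, B=M.shape[0], seed=None,
                           statistic=statistic)
    return _summarize(obs, null, comparison.sided, plan, plus_one=False)


@dataclass
class HolmResult:
    """Step-down Holm-Bonferroni decisions and adjusted p-values."""

    reject: list
    adjusted_p: list
    alpha: float


def holm_bonferroni(p_values: Sequence[float],
                    alpha: float = 0.05) -> HolmResult:
    """Holm's step-down procedure controlling the family-wise error rate.

    Sorted ascending, p(i) is compared with alpha/(m-i+1); testing stops
    at the first failure. Adjusted p-values are the running maximum of
    (m-i+1)*p(i), capped at 1.
    """
    p = list(p_values)
    if any(not (0 <= x <= 1) for x in p):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return HolmResult([], [], alpha)
    order = sorted(range(m), key=lambda i: p[i])
    reject = [False] * m
    adjusted = [0.0] * m
    running = 0.0
    still_rejecting = True
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adjusted[i] = min(1.0, running)
        if still_rejecting and p[i] <= alpha / (m - rank):
            reject[i] = True
        else:
            still_rejecting = False
    return HolmResult(reject, adjusted, alpha)


def effect_modification_test(records: Sequence[ParticipantRecord],
                             contrast: tuple,
                             plan: PermutationPlan) -> InferenceResult:
    """Two-sided permutation test of the ratio of odds ratios.

    Observed statistic: log of (OR in the baseline-consistent stratum /
    OR in the baseline-inconsistent stratum) for the given
    (exposed, reference) arm pair. Separation in a permuted stratum
    yields a sign-preserving infinite magnitude, counted by the
    exceedance rule.
    """
    exposed, reference = contrast
    for stratum in ("baseline_consistent", "baseline_inconsistent"):
        c = Comparison(exposed, reference, subgroup=stratum, sided="two")
        t = two_by_two_from_records(records, c)
        if t.n_exposed == 0 or t.n_reference == 0:
            raise ValueError(f"stratum {stratum!r} empty in one arm")
    comparison = Comparison(exposed, reference, sided="two")
    plan = PermutationPlan(plan.triplets, B=plan.B, seed=plan.seed,
                           statistic="log_ror")
    return permutation_pvalue(records, plan, comparison)


def observed_ror(records: Sequence[ParticipantRecord],
                 exposed: str, reference: str, wave: str = "wk6") -> float:
    """Point estimate of the ratio of odds ratios between strata."""
    ors = []
    for sg in ("baseline_consistent", "baseline_inconsistent"):
        c = Comparison(exposed, reference, wave=wave, subgroup=sg,
                       sided="two")
        ors.append(odds_ratio_2x2(two_by_two_from_records(records, c))
                   .odds_ratio)
    return ratio_of_odds_ratios(ors[0], ors[1])
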