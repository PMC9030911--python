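"""Matched-triplet propensity randomization for a three-arm trial.

The assignment mechanism has four steps:

1. fit a logistic propensity model for baseline consistent helmet use on
   baseline covariates and score every driver;
2. stratify drivers by baseline consistency (consistent / inconsistent);
3. within each stratum, sort by propensity score (ties broken by stable
   input order) and group consecutive runs of three into matched
   triplets, starting from the lowest scores — any 1-2 highest-score
   drivers left over form their own short unit;
4. per triplet, draw one of the 6 arm permutations (ABC, ACB, BAC, BCA,
   CAB, CBA) uniformly with replacement and assign the score-ordered
   members accordingly; a short unit draws a permutation and takes its
   first position(s).

Each complete triplet therefore contributes exactly one member to each
arm, and each stratum contributes equal per-arm counts up to the
leftover unit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._design import DesignBuilder
from .records import ARMS, ParticipantRecord, to_frame

logger = logging.getLogger(__name__)

#: The six ways three ordered members can be assigned to arms A, B, C.
PERMUTATIONS = ("ABC", "ACB", "BAC", "BCA", "CAB", "CBA")

#: Arm permutations as position -> arm-code (0=A, 1=B, 2=C) rows.
PERM_CODES = np.array([[{"A": 0, "B": 1, "C": 2}[ch] for ch in p]
                       for p in PERMUTATIONS])

#: Default letter -> arm mapping (configurable via ``arm_order``).
DEFAULT_ARM_ORDER = ARMS  # A=control, B=fear, C=social

DEFAULT_PROPENSITY_COVARIATES = (
    "district", "age", "education", "married", "has_children",
    "household_size", "driving_setting", "night_freq", "speeding_freq",
    "weekend_freq",
)

_SEPARATION_COEF = 15.0  # |log-odds| beyond this flags quasi-separation


@dataclass
class PropensityModel:
    """Fitted logistic model of baseline consistency on covariates."""

    covariate_names: tuple
    coefficients: np.ndarray  # aligned with column_names, log-odds scale
    column_names: tuple
    converged: bool
    separation: bool
    builder: DesignBuilder

    def score_frame(self, frame: pd.DataFrame) -> np.ndarray:
        """Propensity scores in (0,1); missing covariates are imputed."""
        X = self.builder.transform(frame, impute=True)
        eta = X @ self.coefficients
        return 1.0 / (1.0 + np.exp(-eta))

    def score(self, record: ParticipantRecord) -> float:
        return float(self.score_frame(to_frame([record]))[0])


@dataclass
class TripletAssignment:
    """A matched unit: up to three drivers adjacent in propensity order."""

    stratum: str
    member_ids: tuple  # ascending propensity score
    permutation_index: Optional[int] = None  # 1..6 once drawn
    leftover: bool = False

    def __post_init__(self):
        if self.leftover and len(self.member_ids) >= 3:
            raise ValueError("leftover unit must have fewer than 3 members")
        if not self.leftover and len(self.member_ids) != 3:
            raise ValueError("complete triplet needs exactly 3 members")


def fit_propensity(records: Sequence[ParticipantRecord],
                   covariates=DEFAULT_PROPENSITY_COVARIATES,
                   ) -> PropensityModel:
    """Maximum-likelihood logistic fit (IRLS) of baseline consistency.

    With an empty covariate list the model is intercept-only and every
    score equals the sample rate. Complete separation (including an
    all-one or all-zero outcome) is flagged rather than raised; scores
    are then pinned toward 0/1.
    """
    frame = to_frame(records)
    y = frame["baseline_consistent"].to_numpy(dtype=float)
    builder = DesignBuilder(covariates=tuple(covariates)).fit(frame)
    X = builder.transform(frame, impute=True)

    if y.min() == y.max():
        # Degenerate outcome: intercept pinned, slopes zero.
        coefs = np.zeros(X.shape[1])
        coefs[0] = _SEPARATION_COEF if y[0] == 1 else -_SEPARATION_COEF
        logger.warning("all baseline outcomes equal; propensity degenerate")
        return PropensityModel(tuple(covariates), coefs,
                               builder.column_names, converged=True,
                               separation=True, builder=builder)

    model = sm.GLM(y, X, family=sm.families.Binomial())
    with np.errstate(all="ignore"):
        try:
            res = model.fit(maxiter=50, tol=1e-8)
            coefs = np.asarray(res.params)
            converged = bool(getattr(res, "converged", True))
        except Exception:  # pragma: no cover - perfect-separation paths
            res = model.fit_regularized(alpha=1e-8, maxiter=200)
            coefs = np.asarray(res.params)
            converged = False
    separation = bool(np.max(np.abs(coefs)) > _SEPARATION_COEF)
    if not converged:
        logger.warning("propensity IRLS did not converge in 50 iterations")
    if separation:
        logger.warning("propensity fit shows (quasi-)separation")
    return PropensityModel(tuple(covariates), coefs, builder.column_names,
                           converged=converged, separation=separation,
                           builder=builder)


def stratify(records: Sequence[ParticipantRecord]
             ) -> tuple[list[ParticipantRecord], list[ParticipantRecord]]:
    """Partition by baseline consistency: (consistent, inconsistent)."""
    consistent = [r for r in records if r.baseline_consistent == 1]
    inconsistent = [r for r in records if r.baseline_consistent == 0]
    return consistent, inconsistent


def make_triplets(records: Sequence[ParticipantRecord],
                  scores: Sequence[float],
                  stratum: Optional[str] = None) -> list[TripletAssignment]:
    """Group a scored stratum into matched triplets, lowest scores first.

    Sorting is ascending by score with ties broken by stable input
    order; consecutive runs of three form complete triplets and the 1-2
    highest-score drivers left at the end form a leftover unit.
    """
    if len(records) != len(scores):
        raise ValueError("records and scores differ in length")
    if not records:
        return []
    if stratum is None:
        strata = {r.stratum for r in records}
        if len(strata) > 1:
            raise ValueError("records span multiple strata; stratify first")
        stratum = strata.pop()
    order = sorted(range(len(records)), key=lambda i: (scores[i], i))
    triplets = []
    for start in range(0, len(order) - len(order) % 3, 3):
        ids = tuple(records[i].id for i in order[start:start + 3])
        triplets.append(TripletAssignment(stratum=stratum, member_ids=ids))
    rem = len(order) % 3
    if rem:
        ids = tuple(records[i].id for i in order[-rem:])
        triplets.append(TripletAssignment(stratum=stratum, member_ids=ids,
                                          leftover=True))
    return triplets


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    if isinstance(rng, (int, np.integer)):
        return np.random.default_rng(int(rng))
    raise ValueError(
        "assignment requires an explicit seed or numpy Generator; "
        "implicit global randomness would not be reproducible")


def assign_arms(records: Sequence[ParticipantRecord],
                triplets: Sequence[TripletAssignment],
                rng,
                arm_order=DEFAULT_ARM_ORDER) -> list[ParticipantRecord]:
    """Draw a permutation per unit and assign members to arms.

    ``arm_order`` maps the permutation letters (A, B, C) to arm names.
    Permutation indices (1-6) are recorded on the triplet objects.
    Returns new record objects in the original roster order.
    """
    rng = _as_rng(rng)
    if tuple(sorted(arm_order)) != tuple(sorted(ARMS)):
        raise ValueError(f"arm_order must be a permutation of {ARMS}")
    arm_of = {}
    draws = rng.integers(0, 6, size=len(triplets))
    for unit, k in zip(triplets, draws):
        unit.permutation_index = int(k) + 1
        for pos, member in enumerate(unit.member_ids):
            arm_of[member] = arm_order[PERM_CODES[k, pos]]
    assigned = []
    for r in records:
        if r.id in arm_of:
            assigned.append(r.with_arm(arm_of[r.id]))
        else:
            assigned.append(r)
    return assigned


def randomize_trial(records: Sequence[ParticipantRecord],
                    seed,
                    covariates=DEFAULT_PROPENSITY_COVARIATES,
                    arm_order=DEFAULT_ARM_ORDER):
    """Run the full 4-step randomization.

    Returns ``(assigned_records, triplets, propensity_model)`` with
    records in roster order and triplets listed consistent-stratum
    first, ascending score.
    """
    rng = _as_rng(seed)
    model = fit_propensity(records, covariates=covariates)
    scores = model.score_frame(to_frame(records))
    consistent, inconsistent = stratify(records)
    idx = {r.id: i for i, r in enumerate(records)}
    triplets = (
        make_triplets(consistent, [scores[idx[r.id]] for r in consistent],
                      stratum="consistent")
        + make_triplets(inconsistent,
                        [scores[idx[r.id]] for r in inconsistent],
                        stratum="inconsistent"))
    assigned = assign_arms(records, triplets, rng, arm_order=arm_order)
    return assigned, triplets, model


def triplet_table(triplets: Sequence[TripletAssignment]) -> pd.DataFrame:
    """Assignment log: one row per unit (stratum, members, drawn index)."""
    rows = []
    for t in triplets:
        rows.append({
            "stratum": t.stratum,
            "members": "|".join(t.member_ids),
            "size": len(t.member_ids),
            "leftover": t.leftover,
            "permutation_index": t.permutation_index,
            "permutation": (PERMUTATIONS[t.permutation_index - 1]
                            if t.permutation_index else None),
        })
    return pd.DataFrame(rows)
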