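"""Point estimation: proportions, risk differences, odds ratios.

Everything the trial's result tables print is derivable from these
operations: arm-wise proportions of consistent helmet use per wave,
percentage-point differences from control, difference-in-differences
against baseline, 2x2 cross-product odds ratios, regression-based odds
ratios (unadjusted and covariate-adjusted), and ratios of odds ratios
between baseline strata (effect modification).

With a single arm-indicator regressor the logistic-regression odds
ratio equals the 2x2 cross-product ratio; both paths are exposed and
tested against each other.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._design import dummy_columns
from .records import ParticipantRecord, TwoByTwo, subgroup_mask, to_frame

logger = logging.getLogger(__name__)

#: Adjustment set used by the covariate-adjusted specifications.
DEFAULT_ADJUSTMENT = ("married", "driving_setting", "night_freq",
                      "weekend_freq")

_SEPARATION_COEF = 15.0


@dataclass(frozen=True)
class Comparison:
    """A named pairwise arm contrast.

    ``sided`` records the test convention: one-sided for
    intervention-vs-control contrasts (interventions were expected only
    to help), two-sided when the two message arms are compared with each
    other.
    """

    exposed_arm: str
    reference_arm: str
    wave: str = "wk6"
    subgroup: str = "all"
    adjusted: bool = False
    sided: str = "one"

    def __post_init__(self):
        if self.exposed_arm == self.reference_arm:
            raise ValueError("exposed and reference arm must differ")
        if self.sided not in ("one", "two"):
            raise ValueError("sided must be 'one' or 'two'")
        if self.sided == "one" and "control" not in (self.exposed_arm,
                                                     self.reference_arm):
            raise ValueError(
                "one-sided tests are reserved for intervention-vs-control "
                "contrasts")

    @property
    def outcome_field(self) -> str:
        return {"wk3": "outcome_wk3", "wk6": "outcome_wk6",
                "baseline": "baseline_consistent"}[self.wave]


@dataclass
class EffectEstimate:
    """An odds-ratio (and optionally risk-difference) estimate."""

    odds_ratio: float
    log_or: float
    n_exposed: int
    n_reference: int
    risk_difference: Optional[float] = None  # percentage points
    flag: Optional[str] = None  # 'separation', 'degenerate', ...

    def __post_init__(self):
        if math.isfinite(self.odds_ratio) and self.odds_ratio > 0:
            assert abs(self.odds_ratio - math.exp(self.log_or)) <= \
                1e-9 * max(1.0, self.odds_ratio)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal rounding with ties away from zero, as in the report tables."""
    if not math.isfinite(x):
        return x
    q = 10 ** ndigits
    return math.copysign(math.floor(abs(x) * q + 0.5) / q, x)


def odds_ratio_2x2(t: TwoByTwo) -> EffectEstimate:
    """Cross-product odds ratio (a*d)/(b*c) with zero-cell flagging."""
    num, den = t.a * t.d, t.b * t.c
    if den == 0 and num == 0:
        return EffectEstimate(math.nan, math.nan, t.n_exposed,
                              t.n_reference, flag="degenerate")
    if den == 0:
        return EffectEstimate(math.inf, math.inf, t.n_exposed,
                              t.n_reference, flag="separation")
    if num == 0:
        return EffectEstimate(0.0, -math.inf, t.n_exposed, t.n_reference,
                              flag="separation")
    orr = num / den
    rd = None
    if t.n_exposed and t.n_reference:
        rd = 100.0 * (t.a / t.n_exposed - t.c / t.n_reference)
    return EffectEstimate(orr, math.log(orr), t.n_exposed, t.n_reference,
                          risk_difference=rd)


def two_by_two_from_records(records: Sequence[ParticipantRecord],
                            c: Comparison) -> TwoByTwo:
    """Tabulate the comparison's 2x2 from records with observed outcomes."""
    field = c.outcome_field
    mask = subgroup_mask(records, c.subgroup)
    cells = {"a": 0, "b": 0, "c": 0, "d": 0}
    for r, keep in zip(records, mask):
        if not keep:
            continue
        y = getattr(r, field)
        if y is None or r.arm is None:
            continue
        if r.arm == c.exposed_arm:
            cells["a" if y else "b"] += 1
        elif r.arm == c.reference_arm:
            cells["c" if y else "d"] += 1
    return TwoByTwo(**cells)


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Columns linearly dependent on their predecessors (QR residual test)."""
    bad = []
    for j in range(1, X.shape[1]):
        prev = X[:, :j]
        resid = X[:, j] - prev @ np.linalg.lstsq(prev, X[:, j], rcond=None)[0]
        if np.linalg.norm(resid) < 1e-8 * max(1.0, np.linalg.norm(X[:, j])):
            bad.append(names[j])
    return bad


def fit_logistic(y: np.ndarray, X: np.ndarray,
                 names: Sequence[str]) -> dict:
    """IRLS maximum-likelihood logistic regression.

    Returns ``{'coefficients': {name: value}, 'converged', 'flag'}``.
    A constant outcome yields a zero slope vector with a ``degenerate``
    flag (flat likelihood in the slopes); collinear columns raise,
    naming the offending columns.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("design and outcome lengths differ")
    if not np.allclose(X[:, 0], 1.0):
        raise ValueError("design must include an intercept as first column")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = _collinear_columns(X, names)
        raise ValueError(f"collinear design columns: {bad}")
    if y.min() == y.max():
        coefs = np.zeros(X.shape[1])
        coefs[0] = _SEPARATION_COEF if y[0] == 1 else -_SEPARATION_COEF
        return {"coefficients": dict(zip(names, coefs)),
                "converged": True, "flag": "degenerate"}
    model = sm.GLM(y, X, family=sm.families.Binomial())
    with np.errstate(all="ignore"):
        res = model.fit(maxiter=100, tol=1e-10)
    coefs = np.asarray(res.params)
    flag = None
    if np.max(np.abs(coefs)) > _SEPARATION_COEF:
        flag = "separation"
    return {"coefficients": dict(zip(names, coefs)),
            "converged": bool(getattr(res, "converged", True)),
            "flag": flag}


def regression_odds_ratio(records: Sequence[ParticipantRecord],
                          c: Comparison) -> EffectEstimate:
    """Unadjusted odds ratio via a one-regressor logistic fit."""
    frame, y, exposed = _comparison_frame(records, c)
    X = np.column_stack([np.ones(len(y)), exposed])
    fit = fit_logistic(y, X, ["intercept", "exposed"])
    beta = fit["coefficients"]["exposed"]
    return EffectEstimate(math.exp(beta), beta,
                          int(exposed.sum()), int((1 - exposed).sum()),
                          flag=fit["flag"])


def _comparison_frame(records, c: Comparison):
    frame = to_frame(records)
    mask = subgroup_mask(records, c.subgroup)
    frame = frame[mask & frame["arm"].isin([c.exposed_arm, c.reference_arm])
                  & frame[c.outcome_field].notna()]
    y = frame[c.outcome_field].to_numpy(dtype=float)
    exposed = (frame["arm"] == c.exposed_arm).to_numpy(dtype=float)
    return frame, y, exposed


def adjusted_comparison(records: Sequence[ParticipantRecord],
                        c: Comparison,
                        controls=DEFAULT_ADJUSTMENT) -> EffectEstimate:
    """Covariate-adjusted odds ratio for an arm contrast.

    Controls are dummy-coded; rows with any missing control are dropped
    (complete-case) with the dropped count logged. Returns exp of the
    arm coefficient.
    """
    if not c.adjusted:
        raise ValueError("comparison is not marked adjusted")
    frame, y, exposed = _comparison_frame(records, c)
    complete = frame[list(controls)].notna().all(axis=1).to_numpy()
    dropped = int((~complete).sum())
    if dropped:
        logger.info("adjusted comparison: dropped %d rows with missing "
                    "controls", dropped)
    frame, y, exposed = frame[complete], y[complete], exposed[complete]
    Z, znames = dummy_columns(frame, controls)
    # constant dummy columns carry no information; drop them rather than fail
    keep = [j for j in range(Z.shape[1]) if np.ptp(Z[:, j]) > 0]
    Z, znames = Z[:, keep], [znames[j] for j in keep]
    X = np.column_stack([np.ones(len(y)), exposed, Z])
    names = ["intercept", "exposed", *znames]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"rank-deficient adjusted design for subgroup {c.subgroup!r}: "
            f"{_collinear_columns(X, names)}")
    fit = fit_logistic(y, X, names)
    beta = fit["coefficients"]["exposed"]
    return EffectEstimate(math.exp(beta), beta, int(exposed.sum()),
                          int((1 - exposed).sum()), flag=fit["flag"])


def risk_difference(k_exposed: int, n_exposed: int,
                    k_reference: int, n_reference: int) -> float:
    """Difference in percentage points: 100*(k1/n1 - k0/n0)."""
    if n_exposed <= 0 or n_reference <= 0:
        raise ValueError("denominators must be positive")
    return 100.0 * (k_exposed / n_exposed - k_reference / n_reference)


def difference_in_differences(week6_diff: float,
                              baseline_diff: float) -> float:
    """Week-6 difference from control net of the baseline difference (pp)."""
    return week6_diff - baseline_diff


def ratio_of_odds_ratios(or_consistent: float,
                         or_inconsistent: float) -> float:
    """Effect-modification ratio: baseline-consistent OR over inconsistent.

    Zero or infinite inputs pass through (the ratio is then 0, inf or
    nan) rather than raising, so permutation draws with separation keep
    a sign-preserving magnitude.
    """
    if or_inconsistent == 0 and or_consistent == 0:
        return math.nan
    with np.errstate(all="ignore"):
        return float(np.divide(or_consistent, or_inconsistent))
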