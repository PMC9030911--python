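"""End-to-end analysis runs and the published table set.

:func:`run_full_analysis` renders, from any assigned roster: the
baseline balance table, arm-wise proportions of consistent helmet use
per wave with differences from control and week-6
difference-in-differences, the unadjusted (and optionally
covariate-adjusted) odds-ratio grid over the three pairwise contrasts
and three subgroups, the effect-modification (ratio of odds ratios)
row, permutation p-values for every cell, and the Holm-Bonferroni
decision for the primary family — the three all-observations
comparisons, which is the trial-registered primary outcome.

:func:`fixture_roster` expands the packaged aggregate count tables into
a minimal participant-level roster (arm, baseline stratum, outcomes
only), sufficient to regenerate every unadjusted estimate the published
tables print. Because the realized triplet composition is not public,
its triplets are reconstructed (one member per arm within stratum) and
permutation p-values computed on it are labelled approximate.
"""

from __future__ import annotations

import json
import math
from typing import Optional, Sequence

import numpy as np

from . import __version__
from .balance import balance_table
from .estimate import (Comparison, adjusted_comparison, odds_ratio_2x2,
                       ratio_of_odds_ratios, risk_difference, round_half_up,
                       two_by_two_from_records, difference_in_differences)
from .fixtures import fixtures_table
from .inference import (InferenceResult, PermutationPlan, holm_bonferroni,
                        permutation_pvalue)
from .randomize import TripletAssignment
from .records import ARMS, ParticipantRecord

#: The pairwise contrasts in published order, with their sidedness.
CONTRASTS = (
    ("fear", "control", "one"),
    ("social", "control", "one"),
    ("social", "fear", "two"),
)
SUBGROUPS = ("all", "baseline_consistent", "baseline_inconsistent")
WAVES = ("baseline", "wk3", "wk6")


def fixture_roster(pairing_seed: int = 20140501
                   ) -> tuple[list[ParticipantRecord],
                              list[TripletAssignment]]:
    """Participant-level reconstruction of the published count tables.

    Week-6 outcomes honor the stratum-level counts exactly; week-3
    outcomes honor the arm-level counts (their stratum split was not
    published). Covariates are absent.

    Triplets are synthetic: one member per arm within stratum, paired
    after a deterministic shuffle of each arm-stratum pool
    (``pairing_seed``) so the reconstruction carries no artificial
    within-triplet outcome correlation. The true triplet composition
    was never published, so permutation p-values computed on this
    roster are approximate; point estimates are exact.
    """
    t2, t3 = fixtures_table("table2"), fixtures_table("table3")
    arm_sizes = {a: t2.cell("baseline_consistent", a)
                 + t2.cell("baseline_inconsistent", a) for a in ARMS}
    records: list[ParticipantRecord] = []
    by_arm_stratum: dict[tuple, list[str]] = {}
    for arm in ARMS:
        rows = []
        for stratum, flag in (("consistent", 1), ("inconsistent", 0)):
            size = t2.cell(f"baseline_{stratum}", arm)
            k6 = t3.cell(f"{stratum}_week6_consistent", arm)
            n6 = k6 + t3.cell(f"{stratum}_week6_inconsistent", arm)
            outcomes6 = [1] * k6 + [0] * (n6 - k6) + [None] * (size - n6)
            rows.extend((flag, y6) for y6 in outcomes6)
        # week-3 outcomes: arm-level counts distributed in roster order
        k3 = t2.cell("week3_consistent", arm)
        n3 = k3 + t2.cell("week3_inconsistent", arm)
        outcomes3 = [1] * k3 + [0] * (n3 - k3) + \
            [None] * (arm_sizes[arm] - n3)
        for j, ((flag, y6), y3) in enumerate(zip(rows, outcomes3)):
            rid = f"{arm[0].upper()}{j + 1:03d}"
            records.append(ParticipantRecord(
                id=rid, baseline_consistent=flag, arm=arm,
                outcome_wk3=y3, outcome_wk6=y6))
            by_arm_stratum.setdefault(
                (arm, "consistent" if flag else "inconsistent"),
                []).append(rid)

    rng = np.random.default_rng(pairing_seed)
    triplets = []
    for stratum in ("consistent", "inconsistent"):
        pools = {a: list(by_arm_stratum[(a, stratum)]) for a in ARMS}
        for pool in pools.values():
            rng.shuffle(pool)
        depth = min(len(p) for p in pools.values())
        for j in range(depth):
            triplets.append(TripletAssignment(
                stratum=stratum,
                member_ids=tuple(pools[a][j] for a in ARMS)))
        leftover = [p[j] for p in pools.values() for j in
                    range(depth, len(p))]
        for mid in leftover:
            triplets.append(TripletAssignment(
                stratum=stratum, member_ids=(mid,), leftover=True))
    return records, triplets


def _wave_counts(records, wave, arm):
    field = {"baseline": "baseline_consistent", "wk3": "outcome_wk3",
             "wk6": "outcome_wk6"}[wave]
    obs = [getattr(r, field) for r in records
           if r.arm == arm and getattr(r, field) is not None]
    return sum(obs), len(obs)


def run_full_analysis(records: Sequence[ParticipantRecord],
                      triplets: Optional[Sequence[TripletAssignment]] = None,
                      B: int = 10_000,
                      seed: Optional[int] = None,
                      adjusted: bool = False,
                      B_adjusted: int = 5_000,
                      alpha: float = 0.05,
                      approximate_triplets: bool = False) -> dict:
    """Full deterministic analysis report as a JSON-serializable dict.

    Permutation p-values require ``triplets`` (the realized assignment
    units); without them the report carries point estimates only.
    Per-test seeds are spawned deterministically from ``seed``.
    """
    if not any(r.arm for r in records):
        raise ValueError("roster has no assigned arms; run randomization "
                         "(`tripletrial randomize`) first")
    report: dict = {"metadata": {
        "package_version": __version__, "seed": seed, "B": B,
        "n_records": len(records),
        "triplet_inference": triplets is not None,
        "approximate_triplets": bool(approximate_triplets),
    }}

    # --- proportions, differences, difference-in-differences ------------
    proportions: dict = {}
    for wave in WAVES:
        proportions[wave] = {}
        for arm in ARMS:
            k, n = _wave_counts(records, wave, arm)
            proportions[wave][arm] = {
                "k": k, "n": n,
                "percent": round_half_up(100 * k / n, 1) if n else None}
    diffs = {wave: {} for wave in WAVES}
    for wave in WAVES:
        kc, nc = _wave_counts(records, wave, "control")
        for arm in ("fear", "social"):
            k, n = _wave_counts(records, wave, arm)
            diffs[wave][arm] = (risk_difference(k, n, kc, nc)
                                if n and nc else None)
    did = {}
    for arm in ("fear", "social"):
        if diffs["wk6"][arm] is not None and diffs["baseline"][arm] is not None:
            did[arm] = difference_in_differences(diffs["wk6"][arm],
                                                 diffs["baseline"][arm])
    report["proportions"] = proportions
    report["differences_pp"] = {
        w: {a: (round_half_up(v, 1) if v is not None else None)
            for a, v in d.items()} for w, d in diffs.items()}
    report["week6_difference_in_differences_pp"] = {
        a: round_half_up(v, 1) for a, v in did.items()}

    # --- balance ---------------------------------------------------------
    try:
        report["balance"] = [
            {"variable": row.variable, "test": row.test,
             "statistic": (round_half_up(row.statistic, 2)
                           if math.isfinite(row.statistic) else None),
             "df": row.df,
             "p_value": (round_half_up(row.p_value, 2)
                         if math.isfinite(row.p_value) else None),
             "n": row.n, "flag": row.flag}
            for row in balance_table(records)]
    except ValueError as exc:
        report["balance"] = {"error": str(exc)}

    # --- odds-ratio grids with permutation p-values ----------------------
    seed_seq = np.random.SeedSequence(seed if seed is not None else 0)
    child_seeds = iter(s.generate_state(1)[0] % (2**31)
                       for s in seed_seq.spawn(64))

    def infer(comparison: Comparison, statistic: str,
              n_draws: int) -> Optional[dict]:
        if triplets is None:
            return None
        plan = PermutationPlan(triplets, B=n_draws,
                               seed=int(next(child_seeds)),
                               statistic=statistic)
        res = permutation_pvalue(records, plan, comparison)
        out = res.as_dict()
        out["approximate"] = bool(approximate_triplets)
        return out

    grid: dict = {}
    primary_ps: list = []
    for exposed, reference, sided in CONTRASTS:
        key = f"{exposed}_vs_{reference}"
        grid[key] = {}
        for subgroup in SUBGROUPS:
            comparison = Comparison(exposed, reference, wave="wk6",
                                    subgroup=subgroup, sided=sided)
            est = odds_ratio_2x2(two_by_two_from_records(records, comparison))
            cell = {"odds_ratio": round_half_up(est.odds_ratio, 2),
                    "odds_ratio_full": est.odds_ratio,
                    "sided": sided, "flag": est.flag,
                    "inference": infer(comparison, "log_or", B)}
            grid[key][subgroup] = cell
            if subgroup == "all" and cell["inference"] is not None:
                primary_ps.append(cell["inference"]["p_value"])
        cons = grid[key]["baseline_consistent"]["odds_ratio_full"]
        inc = grid[key]["baseline_inconsistent"]["odds_ratio_full"]
        ror = ratio_of_odds_ratios(cons, inc)
        em_comparison = Comparison(exposed, reference, wave="wk6",
                                   subgroup="all", sided="two")
        grid[key]["effect_modification"] = {
            "ratio_of_odds_ratios": round_half_up(ror, 2),
            "ratio_of_odds_ratios_full": ror,
            "sided": "two",
            "inference": infer(em_comparison, "log_ror", B)}
    report["unadjusted"] = grid

    if adjusted:
        adj_grid: dict = {}
        for exposed, reference, sided in CONTRASTS:
            key = f"{exposed}_vs_{reference}"
            adj_grid[key] = {}
            for subgroup in SUBGROUPS:
                comparison = Comparison(exposed, reference, wave="wk6",
                                        subgroup=subgroup, adjusted=True,
                                        sided=sided)
                try:
                    est = adjusted_comparison(records, comparison)
                except ValueError as exc:
                    adj_grid[key][subgroup] = {"error": str(exc)}
                    continue
                adj_grid[key][subgroup] = {
                    "odds_ratio": round_half_up(est.odds_ratio, 2),
                    "odds_ratio_full": est.odds_ratio,
                    "sided": sided, "flag": est.flag,
                    "inference": infer(comparison, "log_or_adjusted",
                                       B_adjusted)}
        report["adjusted"] = adj_grid

    # --- Holm-Bonferroni over the primary (all-observations) family ------
    if len(primary_ps) == len(CONTRASTS):
        holm = holm_bonferroni(primary_ps, alpha=alpha)
        report["holm_primary_family"] = {
            "comparisons": [f"{e}_vs_{r}" for e, r, _ in CONTRASTS],
            "p_values": primary_ps,
            "reject": holm.reject,
            "adjusted_p": holm.adjusted_p,
            "alpha": alpha,
            "threshold_smallest": alpha / len(primary_ps),
        }
    return report


def render_tables(report: dict) -> str:
    """Human-readable rendering of the report's main tables."""
    lines = []
    lines.append("Consistent helmet use by wave (k/n, %):")
    for wave in WAVES:
        cells = []
        for arm in ARMS:
            c = report["proportions"][wave][arm]
            cells.append(f"{arm} {c['k']}/{c['n']} ({c['percent']}%)"
                         if c["n"] else f"{arm} —")
        lines.append(f"  {wave:9s} " + "  ".join(cells))
    lines.append("Week-6 difference from control (pp): "
                 + ", ".join(f"{a}: {v}" for a, v in
                             report["differences_pp"]["wk6"].items()))
    lines.append("Week-6 difference in differences (pp): "
                 + ", ".join(f"{a}: {v}" for a, v in
                             report["week6_difference_in_differences_pp"]
                             .items()))
    lines.append("Unadjusted odds ratios (permutation p):")
    for key, row in report["unadjusted"].items():
        parts = []
        for sg in SUBGROUPS:
            cell = row[sg]
            p = (f", p={cell['inference']['p_value']:.3g}"
                 if cell["inference"] else "")
            parts.append(f"{sg}: {cell['odds_ratio']}{p}")
        em = row["effect_modification"]
        p = (f", p={em['inference']['p_value']:.3g}"
             if em["inference"] else "")
        parts.append(f"ROR: {em['ratio_of_odds_ratios']}{p}")
        lines.append(f"  {key:18s} " + " | ".join(parts))
    if "holm_primary_family" in report:
        h = report["holm_primary_family"]
        lines.append(
            f"Holm-Bonferroni (primary family, alpha={h['alpha']}): "
            f"rejected {sum(h['reject'])} of {len(h['reject'])} "
            f"(smallest-p threshold {h['threshold_smallest']:.4f})")
    return "\n".join(lines)


def report_to_json(report: dict, path) -> None:
    """Serialize a report deterministically (sorted keys, no NaN)."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=default,
                  allow_nan=True)
        fh.write("\n")
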