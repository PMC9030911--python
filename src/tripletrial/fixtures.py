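"""Packaged aggregate count tables from the published trial report.

The participant-level data of the study were never deposited; what the
report prints are arm-wise count tables — the baseline balance table
(one sub-table per covariate), helmet-use counts by wave, and week-6
counts split by baseline-adherence stratum. These are shipped as CSVs
and exposed as :class:`~tripletrial.records.CountTable` objects so every
derivable statistic (proportions, differences, odds ratios, chi-squares)
can be regenerated from them.

Balance sub-table columns follow the printed arm order
(social, fear, control); the wave tables follow (control, fear, social).
For binary covariates the complement ("no") row is reconstructed from the
printed n (%) values; the reconstruction is exact for every variable.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .records import CountTable, TwoByTwo

FIXTURE_KEYS = (
    "table1_district", "table1_education", "table1_married",
    "table1_children", "table1_phone", "table1_setting", "table1_night",
    "table1_consistent", "table1_speeding", "table1_weekend",
    "table2", "table3",
)

#: Printed test statistics for the categorical balance sub-tables
#: (chi-square value, degrees of freedom), used by regeneration tests.
PRINTED_CHISQ = {
    "table1_district": (1.71, 4),
    "table1_education": (0.57, 2),
    "table1_married": (0.15, 2),
    "table1_children": (0.37, 2),
    "table1_phone": (4.05, 2),
    "table1_setting": (2.81, 4),
    "table1_night": (3.00, 6),
    "table1_consistent": (0.01, 2),
    "table1_speeding": (3.55, 6),
    "table1_weekend": (8.71, 6),
}


def fixtures_table(name: str) -> CountTable:
    """Return a packaged count table by key.

    Keys are ``table1_<covariate>`` for the balance sub-tables, ``table2``
    for helmet-use counts by wave, and ``table3`` for week-6 counts by
    baseline stratum.
    """
    if name not in FIXTURE_KEYS:
        raise KeyError(
            f"unknown fixture {name!r}; valid keys: {', '.join(FIXTURE_KEYS)}")
    path = resources.files("tripletrial.data").joinpath(f"{name}.csv")
    with resources.as_file(path) as p:
        frame = pd.read_csv(p, index_col=0)
    return CountTable(
        row_labels=tuple(frame.index),
        col_labels=tuple(frame.columns),
        counts=frame.to_numpy(dtype=int),
    )


def wave_counts(wave: str, arm: str) -> tuple[int, int]:
    """(k, n) consistent wearers at a wave for an arm, from the wave table.

    ``wave`` in {baseline, week3, week6}; e.g. week-6 social is (74, 116).
    """
    t = fixtures_table("table2")
    k = t.cell(f"{wave}_consistent", arm)
    n = k + t.cell(f"{wave}_inconsistent", arm)
    return k, n


def subgroup_week6_counts(stratum: str, arm: str) -> tuple[int, int]:
    """(k, n) week-6 consistent wearers within a baseline stratum."""
    t = fixtures_table("table3")
    k = t.cell(f"{stratum}_week6_consistent", arm)
    n = k + t.cell(f"{stratum}_week6_inconsistent", arm)
    return k, n


def week6_two_by_two(exposed_arm: str, reference_arm: str,
                     subgroup: str = "all") -> TwoByTwo:
    """Week-6 exposure-by-outcome 2x2 for a pairwise arm contrast.

    ``subgroup`` is ``all`` (wave table) or a baseline stratum
    (``consistent`` / ``inconsistent``, stratum table).
    """
    if subgroup == "all":
        k1, n1 = wave_counts("week6", exposed_arm)
        k0, n0 = wave_counts("week6", reference_arm)
    else:
        k1, n1 = subgroup_week6_counts(subgroup, exposed_arm)
        k0, n0 = subgroup_week6_counts(subgroup, reference_arm)
    return TwoByTwo(a=k1, b=n1 - k1, c=k0, d=n0 - k0)


def arm_rosters() -> dict[str, int]:
    """Arm sizes at baseline from the wave table (130/131/130)."""
    t = fixtures_table("table2")
    return {arm: t.cell("baseline_consistent", arm)
            + t.cell("baseline_inconsistent", arm)
            for arm in t.col_labels}
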