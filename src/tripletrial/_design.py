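"""Shared design-matrix construction for the logistic fits.

Categorical covariates are dummy-coded against their first level; ordered
frequency scales are dummy-coded too (no integer scoring is imposed).
Numeric covariates enter linearly. Imputation (mode for categorical,
median for numeric) is fitted on one sample and can then be applied to
score further records, which is how the propensity model scores drivers
with item missingness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import (DISTRICTS, DRIVING_SETTINGS, EDUCATION_LEVELS,
                      FREQ_LEVELS)

_NUMERIC = ("age", "household_size")
_LEVELS = {
    "district": DISTRICTS,
    "education": EDUCATION_LEVELS,
    "driving_setting": DRIVING_SETTINGS,
    "night_freq": FREQ_LEVELS,
    "speeding_freq": FREQ_LEVELS,
    "weekend_freq": FREQ_LEVELS,
}
_BINARY = ("married", "has_children", "phone_self_owned",
           "baseline_consistent")


@dataclass
class DesignBuilder:
    """Maps roster frames to a fixed-column numeric design matrix."""

    covariates: tuple
    impute_values: dict = field(default_factory=dict)
    column_names: tuple = ()

    def fit(self, frame: pd.DataFrame) -> "DesignBuilder":
        """Learn imputation values (mode/median) from ``frame``."""
        for cov in self.covariates:
            col = frame[cov]
            if cov in _NUMERIC:
                med = col.dropna().median()
                self.impute_values[cov] = float(med) if not np.isnan(med) else 0.0
            elif cov in _BINARY:
                nonmiss = col.dropna()
                self.impute_values[cov] = (
                    int(nonmiss.mode().iloc[0]) if len(nonmiss) else 0)
            else:
                nonmiss = col.dropna()
                self.impute_values[cov] = (
                    nonmiss.mode().iloc[0] if len(nonmiss)
                    else _LEVELS[cov][0])
        names = ["intercept"]
        for cov in self.covariates:
            if cov in _NUMERIC or cov in _BINARY:
                names.append(cov)
            else:
                names.extend(f"{cov}[{lv}]" for lv in _LEVELS[cov][1:])
        self.column_names = tuple(names)
        return self

    def transform(self, frame: pd.DataFrame, impute: bool = True) -> np.ndarray:
        """Build the design matrix; imputes missing cells when ``impute``."""
        n = len(frame)
        cols = [np.ones(n)]
        for cov in self.covariates:
            col = frame[cov]
            if impute:
                col = col.fillna(self.impute_values[cov])
            if cov in _NUMERIC:
                cols.append(col.to_numpy(dtype=float))
            elif cov in _BINARY:
                cols.append(col.to_numpy(dtype=float))
            else:
                for lv in _LEVELS[cov][1:]:
                    cols.append((col == lv).to_numpy(dtype=float))
        return np.column_stack(cols)


def dummy_columns(frame: pd.DataFrame, covariates) -> tuple[np.ndarray, list]:
    """Dummy-code ``covariates`` (no intercept, no imputation).

    Rows with missing values are the caller's concern; used by the
    covariate-adjusted fits, which are complete-case.
    """
    n = len(frame)
    cols, names = [], []
    for cov in covariates:
        col = frame[cov]
        if cov in _NUMERIC:
            cols.append(col.to_numpy(dtype=float))
            names.append(cov)
        elif cov in _BINARY:
            cols.append(col.to_numpy(dtype=float))
            names.append(cov)
        else:
            for lv in _LEVELS[cov][1:]:
                cols.append((col == lv).to_numpy(dtype=float))
                names.append(f"{cov}[{lv}]")
    if not cols:
        return np.empty((n, 0)), names
    return np.column_stack(cols), names
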