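"""Group-comparison statistics for cohort description.

Categorical variables are compared between the with/without-SB groups with
Pearson's chi-squared test (Yates continuity correction on 2x2 tables, the
convention that reproduces the instrument validation sample's published
statistics from its integer counts); summary-level means are compared with a
two-sample t-test (pooled or Welch).

The validation sample's contingency tables (n=650, groups 326/324) ship as
:data:`REFERENCE_TABLES` so the statistical routines have an exact regression
surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import questionnaire_io as qio
from .questionnaire_io import derive_sb_group


@dataclass
class ContingencyTable:
    counts: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...] = ("without_sb", "with_sb")

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        r, c = self.counts.shape
        if r < 2 or c < 2:
            raise ValueError("contingency table needs at least 2 rows and 2 columns")
        if (self.counts < 0).any():
            raise ValueError("negative count")


@dataclass
class TestResult:
    statistic: float
    df: float
    p_value: float
    method: str


#: Validation-sample counts, rows ordered as published.  Columns are
#: (group without SB, group with SB).
REFERENCE_TABLES: dict[str, ContingencyTable] = {
    "gender": ContingencyTable(
        [[257, 260], [67, 66]], ("woman", "man")),
    "education": ContingencyTable(
        [[178, 158], [146, 168]], ("without_higher", "with_higher")),
    "living_with": ContingencyTable(
        [[31, 36], [49, 35], [244, 255]], ("alone", "couple", "family")),
    "marital_status": ContingencyTable(
        [[115, 156], [135, 103], [18, 13], [56, 54]],
        ("single", "married", "free_union", "separated_or_widowed")),
    "occupation": ContingencyTable(
        [[187, 142], [52, 90], [18, 21], [60, 67], [7, 6]],
        ("employed", "student", "unemployed", "housewife", "not_working")),
    "age_band": ContingencyTable(
        [[24, 52], [54, 65], [57, 66], [72, 53], [75, 71], [42, 19]],
        qio.AGE_BANDS_STUDY),
    "diagnosis": ContingencyTable(
        [[91, 191], [59, 46], [32, 22], [11, 1], [45, 25], [53, 22],
         [13, 2], [16, 14], [4, 3]],
        ("major_depressive", "bipolar", "moderate_depressive", "mild_depressive",
         "adjustment", "anxiety", "mixed_episode", "other", "dysthymia")),
}

#: Validation-sample age summaries: (mean, sd, n) without SB vs with SB.
REFERENCE_AGE_SUMMARY = ((42.13, 14.8, 324), (37.42, 14.91, 326))


def chi_squared_test(table: ContingencyTable | np.ndarray, yates: str = "auto") -> TestResult:
    """Pearson chi-squared test of independence.

    ``yates='auto'`` applies the continuity correction exactly on 2x2 tables
    (df=1); ``'never'`` disables it.  Expected counts below 5 trigger a
    warning, not an error.
    """
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    if counts.sum() == 0:
        raise ValueError("empty contingency table")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("contingency table has an all-zero row or column")
    if yates not in ("auto", "never"):
        raise ValueError("yates must be 'auto' or 'never'")
    correction = yates == "auto"
    res = stats.chi2_contingency(counts, correction=correction)
    if (res.expected_freq < 5).any():
        warnings.warn("some expected counts are below 5; the chi-squared "
                      "approximation may be poor", stacklevel=2)
    method = "chi_squared"
    if correction and counts.shape == (2, 2):
        method += "_yates"
    return TestResult(float(res.statistic), float(res.dof), float(res.pvalue), method)


def t_test_from_summary(mean1: float, sd1: float, n1: int,
                        mean2: float, sd2: float, n2: int,
                        variant: str = "pooled") -> TestResult:
    """Two-sided two-sample t-test from summary statistics."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    if variant == "pooled":
        sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
        t = (mean1 - mean2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = float(n1 + n2 - 2)
    else:
        t = (mean1 - mean2) / np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return TestResult(float(t), float(df), float(p), f"t_{variant}")


def group_comparison_report(records: Sequence[qio.PatientRecord]) -> dict[str, dict]:
    """Counts, within-group percentages and tests for each demographic field.

    All fields in a record are categorical, so every comparison uses the
    chi-squared test (rows with zero total count are dropped from the test).
    """
    groups = [derive_sb_group(r) for r in records]
    if len(set(groups)) < 2:
        raise ValueError("both SB groups must be present")
    frame = pd.DataFrame({f: [getattr(r, f) for r in records] for f in qio.DEMOGRAPHIC_FIELDS})
    frame["sb_group"] = groups
    report: dict[str, dict] = {}
    for fld in qio.DEMOGRAPHIC_FIELDS:
        tab = pd.crosstab(frame[fld], frame["sb_group"])
        for col in (qio.WITHOUT_SB, qio.WITH_SB):
            if col not in tab.columns:
                tab[col] = 0
        tab = tab[[qio.WITHOUT_SB, qio.WITH_SB]]
        counts = tab.to_numpy()
        keep = counts.sum(axis=1) > 0
        counts = counts[keep]
        pct = 100 * counts / counts.sum(axis=0, keepdims=True)
        test = None
        if counts.shape[0] >= 2:
            ct = ContingencyTable(counts, tuple(np.asarray(tab.index)[keep]),
                                  (qio.WITHOUT_SB, qio.WITH_SB))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                test = chi_squared_test(ct)
        report[fld] = {
            "levels": tuple(np.asarray(tab.index)[keep]),
            "counts": counts,
            "percent": pct,
            "test": test,
        }
    return report
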