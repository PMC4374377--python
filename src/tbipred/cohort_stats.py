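"""Univariable case-control comparisons: contingency-table tests and
summary t-tests, with a configurable test-selection rule.

The study compared cases and controls variable by variable: Student
t-tests for continuous measures, and chi-square or Fisher's exact test
for categorical ones. All p-values are two-sided; no multiplicity
correction is applied, mirroring the original analysis.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import (
    CASE,
    CONTROL,
    Cohort,
)

__all__ = [
    "ContingencyTable",
    "TestResult",
    "pearson_chi2",
    "fisher_exact_2sided",
    "chi2_rxc",
    "t_test_from_summary",
    "expected_counts",
    "select_test",
    "univariable_report",
    "report_to_csv",
    "report_to_json",
]


@dataclass(frozen=True)
class ContingencyTable:
    """An r x c table of non-negative integer counts with axis labels."""

    counts: np.ndarray
    row_labels: list[str]
    col_labels: list[str]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be 2-dimensional")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class TestResult:
    """Outcome of a univariable test.

    ``statistic`` and ``df`` are absent (None) for exact tests; ``method``
    names the procedure actually applied.
    """

    p: float
    method: Literal["pearson", "fisher", "chi2_rxc", "t_summary", "not_evaluable"]
    statistic: float | None = None
    df: int | None = None

    def __post_init__(self) -> None:
        if not (math.isnan(self.p) or 0.0 <= self.p <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def expected_counts(table: ContingencyTable) -> np.ndarray:
    """Expected cell counts under row/column independence."""
    c = table.counts.astype(float)
    return np.outer(c.sum(axis=1), c.sum(axis=0)) / c.sum()


def pearson_chi2(table: ContingencyTable) -> TestResult:
    """Pearson chi-square on a 2x2 table, without continuity correction.

    Undefined (raises) when any margin is zero.
    """
    if table.shape != (2, 2):
        raise ValueError("pearson_chi2 requires a 2x2 table")
    c = table.counts
    if (c.sum(axis=0) == 0).any() or (c.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: zero margin")
    stat, p, df, _ = stats.chi2_contingency(c, correction=False)
    return TestResult(p=float(p), method="pearson", statistic=float(stat), df=int(df))


def fisher_exact_2sided(table: ContingencyTable) -> TestResult:
    """Fisher's exact test, two-sided by the probability-mass convention:
    the p-value sums hypergeometric probabilities of all tables with the
    observed margins whose probability does not exceed the observed one
    (with a 1+1e-7 relative guard on the comparison, the standard
    floating-point safeguard). Degenerate tables (a zero margin) carry no
    evidence and return p = 1.
    """
    if table.shape != (2, 2):
        raise ValueError("fisher_exact_2sided requires a 2x2 table")
    c = table.counts
    if (c.sum(axis=0) == 0).any() or (c.sum(axis=1) == 0).any():
        return TestResult(p=1.0, method="fisher")
    _, p = stats.fisher_exact(c, alternative="two-sided")
    return TestResult(p=float(min(p, 1.0)), method="fisher")


def chi2_rxc(table: ContingencyTable, drop_empty_rows: bool = True) -> TestResult:
    """Pearson chi-square on an r x c table; df = (r-1)(c-1).

    Rows with zero counts in every column may be dropped first (the
    published mechanism-of-injury subgroup table retains only categories
    that occur). Fails if fewer than two non-empty rows remain.
    """
    c = table.counts
    if drop_empty_rows:
        c = c[c.sum(axis=1) > 0]
    if c.shape[0] < 2:
        raise ValueError("chi2_rxc needs at least two non-empty rows")
    if (c.sum(axis=0) == 0).any():
        raise ValueError("chi-square undefined: zero column margin")
    stat, p, df, _ = stats.chi2_contingency(c, correction=False)
    return TestResult(p=float(p), method="chi2_rxc", statistic=float(stat), df=int(df))


def t_test_from_summary(n1: int, mean1: float, sd1: float,
                        n2: int, mean2: float, sd2: float,
                        pooled: bool = True) -> TestResult:
    """Two-sample t-test from summary statistics.

    Pooled-variance (classical Student) by default, matching the published
    age comparison; ``pooled=False`` gives the Welch variant.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                     equal_var=pooled)
    df = n1 + n2 - 2 if pooled else None
    return TestResult(p=float(res.pvalue), method="t_summary",
                      statistic=float(res.statistic), df=df)


def select_test(table: ContingencyTable,
                rule: Literal["fisher", "cochran"] = "fisher") -> TestResult:
    """Apply the chosen 2x2 test-selection rule.

    ``"fisher"`` (default) always uses Fisher's exact test — the only rule
    consistent with every verifiable published history/examination
    p-value. ``"cochran"`` applies the textbook small-expected-count rule:
    Fisher when any expected cell is below 5, Pearson otherwise.
    """
    if table.shape != (2, 2):
        return chi2_rxc(table)
    c = table.counts
    degenerate = (c.sum(axis=0) == 0).any() or (c.sum(axis=1) == 0).any()
    if rule == "fisher" or degenerate:
        return fisher_exact_2sided(table)
    if rule == "cochran":
        if expected_counts(table).min() < 5:
            return fisher_exact_2sided(table)
        return pearson_chi2(table)
    raise ValueError(f"unknown selection rule {rule!r}")


# ---------------------------------------------------------------------------
# Cohort-level report
# ---------------------------------------------------------------------------

def _table_from_cohort(cohort: Cohort, var: str) -> ContingencyTable | None:
    """Build the case/control 2x2 for one binary variable, restricted to
    subjects for whom the item applies (non-missing)."""
    sub = cohort.data[["group", var]].dropna(subset=[var])
    if sub.empty:
        return None
    a = int(((sub["group"] == CASE) & (sub[var] == 1)).sum())
    b = int(((sub["group"] == CASE) & (sub[var] == 0)).sum())
    c = int(((sub["group"] == CONTROL) & (sub[var] == 1)).sum())
    d = int(((sub["group"] == CONTROL) & (sub[var] == 0)).sum())
    return ContingencyTable(np.array([[a, b], [c, d]]),
                            ["case", "control"], ["yes", "no"])


def univariable_report(cohort: Cohort,
                       variables: list[str] | None = None,
                       rule: Literal["fisher", "cochran"] = "fisher") -> pd.DataFrame:
    """Case-control comparison of every binary variable in the cohort.

    Returns one row per variable: counts and integer-rounded percentages
    per class (as printed in the source tables), the applicable Ns, the
    two-sided p-value and the method used. Variables with no applicable
    subjects in one class are marked not-evaluable rather than raising.
    """
    if not (cohort.data["group"] == CASE).any() or not (cohort.data["group"] == CONTROL).any():
        raise ValueError("cohort must contain both cases and controls")
    variables = variables if variables is not None else cohort.predictors
    rows = []
    for var in variables:
        tab = _table_from_cohort(cohort, var)
        if tab is None or tab.counts[0].sum() == 0 or tab.counts[1].sum() == 0:
            rows.append({"variable": var, "n_case": 0, "n_control": 0,
                         "case_yes": 0, "control_yes": 0,
                         "case_pct": np.nan, "control_pct": np.nan,
                         "p": np.nan, "method": "not_evaluable"})
            continue
        (a, b), (c, d) = tab.counts
        res = select_test(tab, rule=rule)
        rows.append({
            "variable": var,
            "n_case": int(a + b), "n_control": int(c + d),
            "case_yes": int(a), "control_yes": int(c),
            "case_pct": int(round(100 * a / (a + b))),
            "control_pct": int(round(100 * c / (c + d))),
            "p": res.p, "method": res.method,
        })
    return pd.DataFrame(rows).set_index("variable")


def report_to_csv(report: pd.DataFrame, path) -> None:
    report.to_csv(path)


def report_to_json(report: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        json.dump(json.loads(report.reset_index().to_json(orient="records")),
                  fh, indent=2)
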