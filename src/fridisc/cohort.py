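"""Cohort-description inferential statistics.

Two-sided Fisher exact tests on 2x2 categorical tables and two-sided
matched (paired) t-tests on continuous variables, as used to compare the
FRI and control arms of a matched case-control cohort.  The published
cohort's categorical counts ship as a packaged fixture
(``_data/table2_counts.csv``) so the printed p-values can be recomputed
from the counts alone; the continuous rows of that table cannot be
re-tested from summary statistics (pair-level data unpublished) and are
reported as such.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable2x2",
    "TestResult",
    "fisher_exact_2x2",
    "matched_ttest",
    "cohort_report",
    "load_cohort_counts",
]

_TIE_SLACK = 1e-7  # relative slack when comparing hypergeometric point masses


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows = category level, columns = FRI/control."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if int(v) != v or v < 0:
                raise ValueError("counts must be non-negative integers")
        if self.a + self.b + self.c + self.d < 1:
            raise ValueError("table must contain at least one observation")

    @property
    def counts(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


@dataclass
class TestResult:
    statistic: float
    p: float
    method: str
    detail: dict | None = None


def fisher_exact_2x2(table: ContingencyTable2x2) -> TestResult:
    """Two-sided Fisher exact test by hypergeometric enumeration.

    The two-sided p-value sums the probabilities of every table with the
    observed margins whose point probability does not exceed the
    observed one (with a small relative slack absorbing floating-point
    ties) — the convention of R's ``fisher.test``.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    if row1 == 0 or row1 == n or col1 == 0 or col1 == n:
        raise ValueError("both margins must be positive for a 2x2 Fisher test")
    kmin = max(0, row1 + col1 - n)
    kmax = min(row1, col1)
    support = np.arange(kmin, kmax + 1)
    pmf = stats.hypergeom.pmf(support, n, row1, col1)
    p_obs = pmf[support == a][0]
    p = float(np.sum(pmf[pmf <= p_obs * (1.0 + _TIE_SLACK)]))
    odds = (a * d) / (b * c) if b * c > 0 else np.inf
    return TestResult(float(odds), min(p, 1.0), "fisher_exact", {"table": table.counts.tolist()})


def matched_ttest(case_values: np.ndarray, control_values: np.ndarray) -> TestResult:
    """Two-sided paired t-test: one-sample t on differences, df = n - 1."""
    x = np.asarray(case_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired samples must be equal-length vectors")
    if len(x) < 2:
        raise ValueError("need at least 2 pairs")
    diffs = x - y
    if np.var(diffs, ddof=1) == 0:
        raise ValueError("zero-variance differences: paired t-test undefined")
    t, p = stats.ttest_1samp(diffs, 0.0)
    return TestResult(float(t), float(p), "matched_ttest", {"n_pairs": len(x)})


def load_cohort_counts() -> pd.DataFrame:
    """Packaged per-level FRI/control counts of the published cohort table."""
    with resources.files("fridisc._data").joinpath("table2_counts.csv").open() as fh:
        return pd.read_csv(fh)


def cohort_report(
    counts: pd.DataFrame | None = None,
    continuous: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
) -> pd.DataFrame:
    """One test per variable: Fisher on 2x2 counts, paired t on continuous.

    ``counts`` needs columns variable/level/fri/control (two levels per
    variable); defaults to the packaged cohort counts.  ``continuous``
    maps variable name to (case values, control values) paired by pair
    id; variables for which only summary statistics exist (no pair-level
    data) cannot be re-tested and should simply be absent.
    """
    counts = load_cohort_counts() if counts is None else counts
    rows = []
    for var, grp in counts.groupby("variable", sort=False):
        if len(grp) != 2:
            rows.append({"variable": var, "method": "fisher_exact", "p": np.nan,
                         "note": f"{len(grp)} levels: not a 2x2 table"})
            continue
        (a, b), (c, d) = grp[["fri", "control"]].to_numpy(dtype=int)
        res = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
        rows.append({"variable": var, "method": res.method, "p": res.p, "note": ""})
    for var, (case, control) in (continuous or {}).items():
        res = matched_ttest(case, control)
        rows.append({"variable": var, "method": res.method, "p": res.p, "note": ""})
    return pd.DataFrame(rows)
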