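"""Diagnostic-validation statistics.

Positive predictive value and sensitivity as exact binomial proportions with
Clopper–Pearson 95% intervals, the histopathology-vs-chart-review 2x2
contingency table, Pearson chi-square, an exact Fisher test for small r x c
tables by full enumeration of margin-preserving tables (with a seeded
Monte-Carlo fallback for larger ones), and Welch's t from summary
statistics.

Specificity and likelihood ratios are deliberately not estimable from a
case-validation design that reviews no code-negative patients; the
corresponding functions raise :class:`NotEstimableError`.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator
from scipy import stats as sps

from .phenotyping import CaseClassification, CaseGroup, Suspicion

__all__ = [
    "ProportionEstimate",
    "ContingencyTable",
    "NotEstimableError",
    "clopper_pearson",
    "ppv",
    "sensitivity",
    "specificity",
    "positive_likelihood_ratio",
    "build_validation_table",
    "chi_square_test",
    "fisher_exact",
    "welch_t_from_summary",
    "validation_report",
]


class NotEstimableError(ValueError):
    """The quantity is not estimable under the declared study design."""


class ProportionEstimate(BaseModel):
    """A binomial proportion with its exact (Clopper–Pearson) interval."""

    model_config = ConfigDict(frozen=True)

    numerator: int
    denominator: int
    estimate: float
    ci_low: float
    ci_high: float
    level: float = 0.95

    @model_validator(mode="after")
    def _invariants(self) -> "ProportionEstimate":
        if not 0 <= self.numerator <= self.denominator:
            raise ValueError("need 0 <= numerator <= denominator")
        if not (0.0 <= self.ci_low <= self.estimate <= self.ci_high <= 1.0):
            raise ValueError("need 0 <= ci_low <= estimate <= ci_high <= 1")
        return self


class ContingencyTable(BaseModel):
    """An r x c table of nonnegative integer counts with labeled margins."""

    model_config = ConfigDict(frozen=True)

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: tuple[tuple[int, ...], ...]

    @model_validator(mode="after")
    def _invariants(self) -> "ContingencyTable":
        r, c = len(self.row_labels), len(self.col_labels)
        if r < 2 or c < 2:
            raise ValueError("table needs at least 2 rows and 2 columns")
        if len(self.counts) != r or any(len(row) != c for row in self.counts):
            raise ValueError("counts shape must match labels")
        if any(x < 0 for row in self.counts for x in row):
            raise ValueError("counts must be nonnegative")
        return self

    @classmethod
    def from_counts(
        cls,
        counts: Sequence[Sequence[int]],
        row_labels: Optional[Sequence[str]] = None,
        col_labels: Optional[Sequence[str]] = None,
    ) -> "ContingencyTable":
        r, c = len(counts), len(counts[0])
        return cls(
            row_labels=tuple(row_labels) if row_labels else tuple(f"row{i}" for i in range(r)),
            col_labels=tuple(col_labels) if col_labels else tuple(f"col{j}" for j in range(c)),
            counts=tuple(tuple(int(x) for x in row) for row in counts),
        )

    def to_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)

    @property
    def total(self) -> int:
        return int(self.to_array().sum())


# ---------------------------------------------------------------------------
# exact binomial proportions
# ---------------------------------------------------------------------------

def clopper_pearson(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial interval via the beta-quantile formulation.

    low = Beta(alpha/2; x, n-x+1), high = Beta(1-alpha/2; x+1, n-x), with
    low = 0 at x = 0 and high = 1 at x = n (where low = (alpha/2)^(1/n)).
    """
    if not 0 <= x <= n or n <= 0:
        raise ValueError("need 0 <= x <= n with n > 0")
    if not 0 < level < 1:
        raise ValueError("confidence level must lie in (0, 1)")
    alpha = 1.0 - level
    low = 0.0 if x == 0 else float(sps.beta.ppf(alpha / 2, x, n - x + 1))
    high = 1.0 if x == n else float(sps.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return low, high


def _proportion(numerator: int, denominator: int, level: float) -> ProportionEstimate:
    if denominator <= 0:
        raise NotEstimableError("denominator is zero: proportion not estimable")
    low, high = clopper_pearson(numerator, denominator, level)
    return ProportionEstimate(
        numerator=numerator,
        denominator=denominator,
        estimate=numerator / denominator,
        ci_low=low,
        ci_high=high,
        level=level,
    )


def ppv(n_true: int, n_flagged: int, level: float = 0.95) -> ProportionEstimate:
    """Positive predictive value: gold-standard positives among flagged."""
    return _proportion(n_true, n_flagged, level)


def sensitivity(n_detected: int, n_condition: int, level: float = 0.95) -> ProportionEstimate:
    """Sensitivity: detected among gold-standard positives."""
    return _proportion(n_detected, n_condition, level)


def specificity(*_args, **_kwargs) -> ProportionEstimate:
    """Not estimable here: a code-based case-validation design reviews no
    code-negative patients, so true negatives are unobserved."""
    raise NotEstimableError(
        "specificity is not estimable from this design: no code-negative "
        "patients were reviewed"
    )


def positive_likelihood_ratio(*_args, **_kwargs) -> float:
    """Not estimable: requires specificity (see :func:`specificity`)."""
    raise NotEstimableError(
        "positive likelihood ratio is not estimable: specificity is not "
        "estimable from this design"
    )


# ---------------------------------------------------------------------------
# validation table
# ---------------------------------------------------------------------------

def build_validation_table(classifications: list[CaseClassification]) -> ContingencyTable:
    """2x2 table of histopathology documentation (granuloma-confirmed vs not
    available) against the chart-review index of suspicion (high vs low)."""
    if not classifications:
        raise ValueError("cannot build a validation table from an empty cohort")
    counts = [[0, 0], [0, 0]]
    for cl in classifications:
        i = 0 if cl.granuloma_documented else 1
        j = 0 if cl.index_of_suspicion == Suspicion.high else 1
        counts[i][j] += 1
    return ContingencyTable.from_counts(
        counts,
        row_labels=("granuloma_confirmed", "not_available"),
        col_labels=("high_index", "low_index"),
    )


# ---------------------------------------------------------------------------
# contingency-table tests
# ---------------------------------------------------------------------------

def chi_square_test(table: ContingencyTable, yates: bool = False) -> tuple[float, int, float]:
    """Pearson chi-square: (statistic, df, upper-tail p).  No continuity
    correction by default."""
    arr = table.to_array()
    res = sps.chi2_contingency(arr, correction=yates)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def _log_table_prob(arr: np.ndarray, lg_const: float) -> float:
    # multivariate hypergeometric point probability, log scale
    return lg_const - sum(math.lgamma(x + 1) for x in arr.flat)


def _enumerate_tables(row_sums: list[int], col_rem: list[int], row: int, prefix: list[list[int]]):
    """Yield all nonnegative integer tables with the given margins."""
    r = len(row_sums)
    c = len(col_rem)
    if row == r - 1:
        if all(x >= 0 for x in col_rem) and sum(col_rem) == row_sums[-1]:
            yield prefix + [list(col_rem)]
        return

    def fill(j: int, remaining: int, current: list[int]):
        if j == c - 1:
            if 0 <= remaining <= col_rem[j]:
                yield current + [remaining]
            return
        for v in range(min(remaining, col_rem[j]) + 1):
            yield from fill(j + 1, remaining - v, current + [v])

    for rowvals in fill(0, row_sums[row], []):
        new_rem = [col_rem[j] - rowvals[j] for j in range(c)]
        yield from _enumerate_tables(row_sums, new_rem, row + 1, prefix + [rowvals])


def fisher_exact(
    table: ContingencyTable,
    method: str = "exact",
    n_resamples: int = 100_000,
    seed: Optional[int] = None,
    max_total: int = 500,
    max_dim: int = 6,
) -> float:
    """Two-sided Fisher exact test for an r x c table.

    The two-sided p is the sum of probabilities of all margin-preserving
    tables whose multivariate-hypergeometric point probability does not
    exceed the observed one (the "no more probable" rule).  ``method="exact"``
    enumerates all such tables and is limited to small tables
    (total <= ``max_total``, dimensions <= ``max_dim``);
    ``method="monte-carlo"`` samples margin-preserving tables with a fixed
    seed instead.
    """
    arr = table.to_array()
    n = int(arr.sum())
    if n == 0:
        raise ValueError("Fisher test undefined for an all-zero table")
    row_sums = arr.sum(axis=1).tolist()
    col_sums = arr.sum(axis=0).tolist()
    lg_const = (
        sum(math.lgamma(s + 1) for s in row_sums)
        + sum(math.lgamma(s + 1) for s in col_sums)
        - math.lgamma(n + 1)
    )
    lp_obs = _log_table_prob(arr, lg_const)

    if method == "exact":
        if n > max_total or arr.shape[0] > max_dim or arr.shape[1] > max_dim:
            raise ValueError(
                f"table too large for exact enumeration (total {n}, shape "
                f"{arr.shape}); use method='monte-carlo' with a fixed seed"
            )
        total_p = 0.0
        for cand in _enumerate_tables(row_sums, list(col_sums), 0, []):
            lp = _log_table_prob(np.asarray(cand), lg_const)
            if lp <= lp_obs + 1e-7:
                total_p += math.exp(lp)
        return min(total_p, 1.0)

    if method == "monte-carlo":
        rng = np.random.default_rng(seed)
        # sample margin-preserving tables by permuting column labels of the
        # expanded observation vector
        rows = np.repeat(np.arange(arr.shape[0]), row_sums)
        cols = np.repeat(np.arange(arr.shape[1]), col_sums)
        hits = 0
        for _ in range(n_resamples):
            perm = rng.permutation(cols)
            cand = np.zeros_like(arr)
            np.add.at(cand, (rows, perm), 1)
            if _log_table_prob(cand, lg_const) <= lp_obs + 1e-7:
                hits += 1
        # add-one correction keeps the p-value strictly positive
        return (hits + 1) / (n_resamples + 1)

    raise ValueError(f"unknown method {method!r}")


def welch_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float, float]:
    """Welch's unequal-variance t test from summary statistics:
    (t, Satterthwaite df, two-sided p)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 in each group")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    t = (mean1 - mean2) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2 * float(sps.t.sf(abs(t), df))
    return t, df, p


# ---------------------------------------------------------------------------
# cohort-level validation report
# ---------------------------------------------------------------------------

def validation_report(classifications: list[CaseClassification], level: float = 0.95) -> dict:
    """Full diagnostic-accuracy report for a classified, code-captured cohort.

    Returns the histopathology-vs-index 2x2 table and, where estimable:
    PPV of the diagnostic codes alone (sarcoidosis = high index), PPV of the
    codes for histopathologically confirmed disease, PPV of codes combined
    with the high index of suspicion, and the sensitivity of histopathology
    documentation alone relative to the chart-review index.
    """
    if not classifications:
        raise ValueError("empty cohort")
    n = len(classifications)
    n_high = sum(1 for c in classifications if c.index_of_suspicion == Suspicion.high)
    n_confirmed = sum(1 for c in classifications if c.case_group == CaseGroup.confirmed_biopsy)
    n_sarcoid_among_high = sum(
        1
        for c in classifications
        if c.index_of_suspicion == Suspicion.high and c.case_group != CaseGroup.unlikely
    )
    table = build_validation_table(classifications)

    def est(x: int, d: int) -> Optional[dict]:
        if d == 0:
            return None
        e = _proportion(x, d, level)
        return e.model_dump()

    report = {
        "n": n,
        "table": {
            "row_labels": list(table.row_labels),
            "col_labels": list(table.col_labels),
            "counts": [list(r) for r in table.counts],
        },
        "ppv_icd_alone": est(n_high, n),
        "ppv_icd_confirmed": est(n_confirmed, n),
        "ppv_icd_plus_index": est(n_sarcoid_among_high, n_high),
        "sensitivity_histopathology": est(n_confirmed, n_high) if n_high else None,
        "specificity": "not estimable from this design (no code-negative patients reviewed)",
        "ci_method": "clopper_pearson_exact",
        "level": level,
    }
    return report
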