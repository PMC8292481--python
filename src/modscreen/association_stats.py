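"""Contingency-table association statistics for biallelic variants.

Implements the estimator family used for validation-phase count tables:
sample odds ratios with Woolf (log-normal) confidence intervals and an
uncorrected Pearson chi-square test for the allelic comparisons, plus the
exact machinery (Fisher two-sided test, conditional-MLE odds ratio with an
exact interval) appropriate for sparse person-level tables.

Table orientation: rows are the two groups (exposed first), columns the
allele-or-carriage categories with the alternate/carrier column first, so
``a``/``b`` are the exposed group's alt/ref tallies and ``c``/``d`` the
reference group's.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats
from scipy.stats.contingency import odds_ratio as _scipy_odds_ratio

from .cohort_io import GenotypeCounts
from .errors import DegenerateTableError

Coding = Literal["allelic", "dominant", "recessive"]


@dataclass(frozen=True)
class TwoByTwo:
    """A 2x2 table of non-negative integer cells.

    ``a, b`` = exposed row (alt-category count, ref-category count);
    ``c, d`` = reference row.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    def margins(self) -> tuple[int, int, int, int]:
        """(row1, row2, col1, col2) totals."""
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)

    def swap_rows(self) -> "TwoByTwo":
        return TwoByTwo(self.c, self.d, self.a, self.b)

    def transpose(self) -> "TwoByTwo":
        return TwoByTwo(self.a, self.c, self.b, self.d)

    def has_zero_cell(self) -> bool:
        return 0 in self.cells()


@dataclass(frozen=True)
class AssociationResult:
    """An odds-ratio estimate with CI, p-value and method tags."""

    or_estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    coding: Coding
    estimator: Literal["sample", "conditional_mle"]
    ci_method: Literal["woolf", "exact"]
    test: Literal["pearson_chi2", "fisher_exact"]
    correction_applied: bool = False


# ---------------------------------------------------------------------------
# Table construction
# ---------------------------------------------------------------------------


def _require_nonempty(g1: GenotypeCounts, g2: GenotypeCounts) -> None:
    if g1.total() == 0 or g2.total() == 0:
        raise DegenerateTableError("both groups must be non-empty")


def allelic_table(g1: GenotypeCounts, g2: GenotypeCounts) -> TwoByTwo:
    """Alt vs ref allele counts, treating the two alleles of one person
    as independent observations."""
    _require_nonempty(g1, g2)
    return TwoByTwo(g1.alt_alleles(), g1.ref_alleles(), g2.alt_alleles(), g2.ref_alleles())


def dominant_table(g1: GenotypeCounts, g2: GenotypeCounts) -> TwoByTwo:
    """Carriers (>=1 alt allele) vs non-carriers, per person."""
    _require_nonempty(g1, g2)
    return TwoByTwo(g1.carriers(), g1.hom_ref, g2.carriers(), g2.hom_ref)


def recessive_table(g1: GenotypeCounts, g2: GenotypeCounts) -> TwoByTwo:
    """Alternate homozygotes vs everyone else, per person."""
    _require_nonempty(g1, g2)
    return TwoByTwo(
        g1.hom_alt, g1.hom_ref + g1.het, g2.hom_alt, g2.hom_ref + g2.het
    )


_TABLE_BUILDERS = {
    "allelic": allelic_table,
    "dominant": dominant_table,
    "recessive": recessive_table,
}


def build_table(g1: GenotypeCounts, g2: GenotypeCounts, coding: Coding) -> TwoByTwo:
    try:
        return _TABLE_BUILDERS[coding](g1, g2)
    except KeyError:
        raise ValueError(f"unknown coding: {coding!r}") from None


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------


def _check_estimable(t: TwoByTwo) -> None:
    # Two zero cells in one row or column (a zero margin) leave the OR
    # undefined even after correction.
    if 0 in t.margins():
        raise DegenerateTableError(f"zero margin in table {t.cells()}; OR undefined")


def corrected_cells(t: TwoByTwo) -> tuple[tuple[float, float, float, float], bool]:
    """Haldane–Anscombe: add 0.5 to every cell if any cell is zero."""
    if t.has_zero_cell():
        return tuple(x + 0.5 for x in t.cells()), True  # type: ignore[return-value]
    return tuple(float(x) for x in t.cells()), False  # type: ignore[return-value]


def sample_or(t: TwoByTwo) -> float:
    """Cross-product odds ratio (a*d)/(b*c), Haldane–Anscombe corrected
    when a zero cell is present."""
    _check_estimable(t)
    (a, b, c, d), _ = corrected_cells(t)
    return (a * d) / (b * c)


def woolf_ci(t: TwoByTwo, level: float = 0.95) -> tuple[float, float]:
    """Woolf confidence interval exp(ln OR +- z*sqrt(1/a+1/b+1/c+1/d))."""
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    _check_estimable(t)
    (a, b, c, d), _ = corrected_cells(t)
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf((1 + level) / 2)
    return math.exp(log_or - z * se), math.exp(log_or + z * se)


def pearson_chi2_p(t: TwoByTwo) -> float:
    """Uncorrected Pearson chi-square p (1 df): n(ad-bc)^2 / product of margins."""
    r1, r2, c1, c2 = t.margins()
    if 0 in (r1, r2, c1, c2):
        raise DegenerateTableError(f"zero margin in table {t.cells()}; test undefined")
    a, b, c, d = t.cells()
    n = t.total()
    chi2 = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return float(stats.chi2.sf(chi2, df=1))


def fisher_exact_p(t: TwoByTwo) -> float:
    """Two-sided Fisher exact p by the probability-mass rule (sum of all
    tables with the observed margins whose probability does not exceed the
    observed table's)."""
    table = np.array([[t.a, t.b], [t.c, t.d]])
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def conditional_mle_or(
    t: TwoByTwo, level: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Conditional maximum-likelihood odds ratio with an exact CI.

    The estimate maximizes the noncentral hypergeometric likelihood of
    ``a`` given the table margins; the interval inverts the conditional
    tail probabilities at (1-level)/2 per side.  When ``a`` sits on the
    boundary of its support the estimate is 0 or inf and the interval is
    one-sided.
    """
    if 0 in t.margins():
        raise DegenerateTableError(f"zero margin in table {t.cells()}; OR undefined")
    res = _scipy_odds_ratio([[t.a, t.b], [t.c, t.d]], kind="conditional")
    ci = res.confidence_interval(confidence_level=level)
    return float(res.statistic), (float(ci.low), float(ci.high))


def associate(
    g1: GenotypeCounts,
    g2: GenotypeCounts,
    coding: Coding = "allelic",
    estimator: Literal["sample", "conditional_mle"] = "sample",
    test: Literal["pearson_chi2", "fisher_exact"] = "pearson_chi2",
    level: float = 0.95,
) -> AssociationResult:
    """One-call association analysis between two genotype-count groups."""
    t = build_table(g1, g2, coding)
    if estimator == "sample":
        est = sample_or(t)
        lo, hi = woolf_ci(t, level)
        ci_method: Literal["woolf", "exact"] = "woolf"
        corrected = t.has_zero_cell()
    elif estimator == "conditional_mle":
        est, (lo, hi) = conditional_mle_or(t, level)
        ci_method = "exact"
        corrected = False
    else:
        raise ValueError(f"unknown estimator: {estimator!r}")
    if test == "pearson_chi2":
        p = pearson_chi2_p(t)
    elif test == "fisher_exact":
        p = fisher_exact_p(t)
    else:
        raise ValueError(f"unknown test: {test!r}")
    return AssociationResult(
        or_estimate=est,
        ci_low=lo,
        ci_high=hi,
        p_value=p,
        coding=coding,
        estimator=estimator,
        ci_method=ci_method,
        test=test,
        correction_applied=corrected,
    )
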