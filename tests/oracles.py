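"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: exact integer/Fraction
arithmetic and direct enumeration only.
"""

from __future__ import annotations

import math
from fractions import Fraction


def fisher_enum_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive enumeration with exact integers.

    All tables with the observed margins are weighted by
    C(r1, k) * C(r2, c1 - k); the p-value is the exact fraction of weight
    on tables no more probable than the observed one.
    """
    r1, r2, c1 = a + b, c + d, a + c
    w_obs = math.comb(r1, a) * math.comb(r2, c1 - a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    num = sum(
        w
        for k in range(lo, hi + 1)
        if (w := math.comb(r1, k) * math.comb(r2, c1 - k)) <= w_obs
    )
    return float(Fraction(num, math.comb(r1 + r2, c1)))


def conditional_mean(a_support: range, weights: list[int], log_psi: float) -> float:
    """Mean of the noncentral hypergeometric distribution at odds ratio
    exp(log_psi), computed stably from exact integer weights."""
    ks = list(a_support)
    log_terms = [math.log(w) + k * log_psi for k, w in zip(ks, weights)]
    m = max(log_terms)
    probs = [math.exp(t - m) for t in log_terms]
    z = sum(probs)
    return sum(k * p for k, p in zip(ks, probs)) / z


def cmle_or_bisect(a: int, b: int, c: int, d: int) -> float:
    """Conditional-MLE odds ratio by bisection on the conditional mean.

    The conditional MLE solves E_psi[A] = a; the mean is strictly
    increasing in psi.  Returns 0/inf when ``a`` sits on its support
    boundary.
    """
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    if a == lo:
        return 0.0
    if a == hi:
        return math.inf
    support = range(lo, hi + 1)
    weights = [math.comb(r1, k) * math.comb(r2, c1 - k) for k in support]
    left, right = -40.0, 40.0
    for _ in range(200):
        mid = (left + right) / 2
        if conditional_mean(support, weights, mid) < a:
            left = mid
        else:
            right = mid
    return math.exp((left + right) / 2)


def mh_pooled_or_fraction(tables: list[tuple[int, int, int, int]]) -> Fraction:
    """Mantel–Haenszel pooled OR as an exact fraction."""
    R = sum((Fraction(a * d, a + b + c + d) for a, b, c, d in tables), Fraction(0))
    S = sum((Fraction(b * c, a + b + c + d) for a, b, c, d in tables), Fraction(0))
    return R / S


def saturated_logit_coefficients(cell_counts: dict[tuple[int, int], tuple[int, int]]):
    """Closed-form coefficients of the saturated 2x2 (carrier x binary
    dosage) logistic model from per-cell (cases, controls) counts.

    Returns (intercept, carrier, dosage, interaction) log-odds contrasts.
    """

    def lo(cell):
        cases, controls = cell_counts[cell]
        return math.log(cases / controls)

    b0 = lo((0, 0))
    b1 = lo((1, 0)) - b0
    b2 = lo((0, 1)) - b0
    b3 = lo((1, 1)) - b0 - b1 - b2
    return b0, b1, b2, b3
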