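"""Gene–gene interaction machinery.

Three routes to an interaction estimate are provided:

* per-stratum **case-only** 2x2 tables (risk-allele carriage vs modifier
  carriage among affected individuals only), valid as an interaction OR
  when the loci are independent in the source population and the disease
  is rare;
* fixed-effect **Mantel–Haenszel pooling** across study strata, with the
  Robins–Breslow–Greenland variance for the CI and the Mantel–Haenszel
  chi-square (no continuity correction) for the p-value;
* a case-control **logistic model** with a carrier x modifier-dosage
  interaction term, tested against the no-interaction model by a 1-df
  likelihood-ratio test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .association_stats import TwoByTwo, allelic_table, dominant_table
from .cohort_io import StratumPair
from .errors import ConvergenceError, DegenerateTableError, SeparationError


def case_only_table(
    s: StratumPair, coding: Literal["dominant", "allelic"] = "dominant"
) -> TwoByTwo:
    """Cross-tabulate modifier carriage (or alleles) against risk-allele
    carrier status within a single all-case stratum.

    Rows: carriers then non-carriers; columns: modifier-positive first.
    """
    if s.exposed.total() == 0:
        raise DegenerateTableError(f"empty carrier group in stratum {s.stratum_label!r}")
    if coding == "dominant":
        return dominant_table(s.exposed, s.unexposed)
    if coding == "allelic":
        return allelic_table(s.exposed, s.unexposed)
    raise ValueError(f"unknown coding: {coding!r}")


@dataclass(frozen=True)
class MHResult:
    pooled_or: float
    ci_low: float
    ci_high: float
    p_value: float
    n_strata: int
    #: Mantel–Haenszel weight b_i*c_i/n_i per retained stratum.
    weights: tuple[float, ...] = field(default=())


def mantel_haenszel(strata: Sequence[TwoByTwo], level: float = 0.95) -> MHResult:
    """Mantel–Haenszel pooled odds ratio over 2x2 strata.

    Pooled OR = sum(a_i*d_i/n_i) / sum(b_i*c_i/n_i).  The confidence
    interval uses the Robins–Breslow–Greenland variance of the pooled
    log-OR; the p-value is the uncorrected Mantel–Haenszel chi-square.
    Strata contributing zero to both sums are dropped with a warning.
    """
    if not strata:
        raise ValueError("at least one stratum required")
    kept: list[TwoByTwo] = []
    for t in strata:
        if t.total() == 0:
            raise DegenerateTableError("stratum with zero total")
        n = t.total()
        if t.a * t.d / n == 0 and t.b * t.c / n == 0:
            warnings.warn(
                f"dropping stratum {t.cells()}: no information for the pooled OR",
                stacklevel=2,
            )
            continue
        kept.append(t)
    if not kept:
        raise DegenerateTableError("all strata degenerate; pooled OR undefined")

    R = S = 0.0
    # RBG variance accumulators.
    sum_PR = sum_PSQR = sum_QS = 0.0
    # MH chi-square accumulators.
    sum_a = sum_E = sum_V = 0.0
    weights = []
    for t in kept:
        a, b, c, d = (float(x) for x in t.cells())
        n = a + b + c + d
        Ri, Si = a * d / n, b * c / n
        Pi, Qi = (a + d) / n, (b + c) / n
        R += Ri
        S += Si
        weights.append(Si)
        sum_PR += Pi * Ri
        sum_PSQR += Pi * Si + Qi * Ri
        sum_QS += Qi * Si
        sum_a += a
        sum_E += (a + b) * (a + c) / n
        if n > 1:
            sum_V += (a + b) * (c + d) * (a + c) * (b + d) / (n * n * (n - 1))

    pooled = R / S if S > 0 else math.inf
    if R > 0 and S > 0:
        var = sum_PR / (2 * R * R) + sum_PSQR / (2 * R * S) + sum_QS / (2 * S * S)
        z = stats.norm.ppf((1 + level) / 2)
        half = z * math.sqrt(var)
        ci_low, ci_high = math.exp(math.log(pooled) - half), math.exp(math.log(pooled) + half)
    else:
        ci_low, ci_high = (0.0, math.inf)
    if sum_V > 0:
        chi2 = (sum_a - sum_E) ** 2 / sum_V
        p = float(stats.chi2.sf(chi2, df=1))
    else:
        p = float("nan")
    return MHResult(
        pooled_or=pooled,
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=p,
        n_strata=len(kept),
        weights=tuple(weights),
    )


# ---------------------------------------------------------------------------
# Logistic interaction model
# ---------------------------------------------------------------------------

_CORE_TERMS = ("intercept", "carrier", "dosage")
_INTERACTION_TERM = "carrier:dosage"


@dataclass(frozen=True)
class FittedLogit:
    """Coefficients, standard errors and log-likelihood of one logit fit."""

    params: dict[str, float]
    bse: dict[str, float]
    log_likelihood: float
    n_obs: int
    n_iterations: int

    def odds_ratios(self) -> dict[str, float]:
        return {k: math.exp(v) for k, v in self.params.items()}


@dataclass(frozen=True)
class InteractionModelResult:
    plain: FittedLogit
    interaction: FittedLogit
    lrt_statistic: float
    lrt_p: float

    @property
    def interaction_or(self) -> float:
        return math.exp(self.interaction.params[_INTERACTION_TERM])


def _fit_logit(y: np.ndarray, X: pd.DataFrame, maxiter: int = 100, tol: float = 1e-8) -> FittedLogit:
    model = sm.Logit(y, X)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
            res = model.fit(method="newton", maxiter=maxiter, tol=tol, disp=0, warn_convergence=False)
    except (
        sm.tools.sm_exceptions.PerfectSeparationError,
        sm.tools.sm_exceptions.PerfectSeparationWarning,
    ) as exc:
        raise SeparationError(f"perfect separation while fitting {list(X.columns)}: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise ConvergenceError(
            f"logit fit did not converge in {maxiter} iterations "
            f"(retvals: {res.mle_retvals})"
        )
    # Huge coefficients that "converged" still indicate separation.
    if np.any(np.abs(res.params.values) > 30):
        bad = [c for c, v in res.params.items() if abs(v) > 30]
        raise SeparationError(f"separation suspected for term(s) {bad}")
    return FittedLogit(
        params=dict(res.params),
        bse=dict(res.bse),
        log_likelihood=float(res.llf),
        n_obs=int(res.nobs),
        n_iterations=int(res.mle_retvals.get("iterations", -1)),
    )


def fit_interaction_model(
    data: pd.DataFrame,
    outcome: str = "case",
    carrier: str = "carrier",
    dosage: str = "dosage",
    covariates: Sequence[str] = (),
    maxiter: int = 100,
    tol: float = 1e-8,
) -> InteractionModelResult:
    """Fit the plain and interaction logistic models and their 1-df LRT.

    Plain model:       logit P(case) = b0 + b1*carrier + b2*dosage + covariates
    Interaction model: ... + b3*carrier*dosage

    ``carrier`` is a 0/1 indicator; ``dosage`` the 0/1/2 modifier allele
    count entering additively.
    """
    y = np.asarray(data[outcome], dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    X = pd.DataFrame(
        {
            "intercept": np.ones(len(data)),
            "carrier": np.asarray(data[carrier], dtype=float),
            "dosage": np.asarray(data[dosage], dtype=float),
        }
    )
    for cov in covariates:
        if np.ptp(np.asarray(data[cov], dtype=float)) == 0:
            raise ValueError(f"covariate {cov!r} is constant (collinear with intercept)")
        X[cov] = np.asarray(data[cov], dtype=float)
    plain = _fit_logit(y, X, maxiter=maxiter, tol=tol)
    Xi = X.copy()
    Xi.insert(3, _INTERACTION_TERM, X["carrier"] * X["dosage"])
    inter = _fit_logit(y, Xi, maxiter=maxiter, tol=tol)
    stat, p = likelihood_ratio_test(plain, inter)
    return InteractionModelResult(plain=plain, interaction=inter, lrt_statistic=stat, lrt_p=p)


def likelihood_ratio_test(plain: FittedLogit, interaction: FittedLogit) -> tuple[float, float]:
    """1-df likelihood-ratio test of the interaction term.

    statistic = 2*(ll_interaction - ll_plain); tiny negative values from
    round-off are clamped to zero.
    """
    if plain.n_obs != interaction.n_obs:
        raise ValueError(
            f"models fitted on different record counts: {plain.n_obs} vs {interaction.n_obs}"
        )
    stat = 2.0 * (interaction.log_likelihood - plain.log_likelihood)
    if stat < 0:
        if stat < -1e-6:
            raise ValueError(
                f"interaction model log-likelihood below plain model ({stat=}); models not nested?"
            )
        stat = 0.0
    return stat, float(stats.chi2.sf(stat, df=1))
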