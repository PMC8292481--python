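"""Synthetic cohorts for exercising every pipeline stage without data.

The population model: a rare risk locus carried as a dominant 0/1
indicator, a biallelic modifier in Hardy–Weinberg equilibrium entering as
an additive 0/1/2 dosage, and a logistic disease model

    logit P(case) = beta0 + beta_carrier*carrier + beta_modifier*dosage
                    + beta_interaction*carrier*dosage.

The two loci are simulated independently, so under a rare disease the
case-only odds ratio targets exp(beta_interaction).

All randomness flows from one root seed through spawned child streams, so
identical configs give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit
from statsmodels.stats.proportion import proportion_confint

from .association_stats import pearson_chi2_p
from .candidate_selection import (
    SelectionCriteria,
    frequency_records_from_matrix,
    recessive_screen,
    select_candidates,
)
from .cohort_io import GenotypeCounts, GenotypeMatrix, write_genotype_tsv
from .errors import InsufficientSamplesError
from .interaction_analysis import case_only_table, fit_interaction_model

_LINEAR_CLIP = 500.0  # expit argument bound; well inside float64 range


@dataclass(frozen=True)
class SimulationConfig:
    n_individuals: int = 10_000
    carrier_freq: float = 0.02
    modifier_maf: float = 0.15
    beta0: float = -2.0
    beta_carrier: float = math.log(2.0)
    beta_modifier: float = 0.0
    beta_interaction: float = 0.0
    n_strata: int = 1
    stratum_multipliers: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        for name in ("carrier_freq", "modifier_maf"):
            x = getattr(self, name)
            if not 0.0 <= x <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_strata < 1:
            raise ValueError("n_strata must be >= 1")
        if self.stratum_multipliers is not None and len(self.stratum_multipliers) != self.n_strata:
            raise ValueError("stratum_multipliers length must equal n_strata")


@dataclass
class SimulatedCohort:
    carrier: np.ndarray  # 0/1
    dosage: np.ndarray  # 0/1/2
    disease: np.ndarray  # 0/1
    stratum: np.ndarray  # small ints
    config: SimulationConfig

    def __len__(self) -> int:
        return self.carrier.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "case": self.disease,
                "carrier": self.carrier,
                "dosage": self.dosage,
                "stratum": self.stratum,
            }
        )

    def subset(self, idx: np.ndarray) -> "SimulatedCohort":
        return SimulatedCohort(
            carrier=self.carrier[idx],
            dosage=self.dosage[idx],
            disease=self.disease[idx],
            stratum=self.stratum[idx],
            config=self.config,
        )


def _stratum_sizes(cfg: SimulationConfig) -> list[int]:
    mult = cfg.stratum_multipliers or tuple([1.0] * cfg.n_strata)
    total = sum(mult)
    sizes = [int(round(cfg.n_individuals * m / total)) for m in mult]
    sizes[-1] += cfg.n_individuals - sum(sizes)
    return sizes


def simulate_population(cfg: SimulationConfig) -> SimulatedCohort:
    """Draw a population under the logistic two-locus model (seeded)."""
    return _simulate_with_seedseq(cfg, np.random.SeedSequence(cfg.seed))


def sample_case_series(
    cohort: SimulatedCohort, n_cases: int | None = None, seed: int | None = None
) -> SimulatedCohort:
    """All cases, or a seeded without-replacement subsample of them."""
    case_idx = np.flatnonzero(cohort.disease == 1)
    if n_cases is None:
        return cohort.subset(case_idx)
    if n_cases > case_idx.size:
        raise InsufficientSamplesError(
            f"requested {n_cases} cases but only {case_idx.size} available "
            f"(short by {n_cases - case_idx.size})"
        )
    rng = np.random.default_rng(seed)
    return cohort.subset(np.sort(rng.choice(case_idx, size=n_cases, replace=False)))


def sample_case_control(
    cohort: SimulatedCohort, n_cases: int, n_controls: int, seed: int | None = None
) -> SimulatedCohort:
    """Seeded without-replacement case-control sample."""
    rng = np.random.default_rng(seed)
    case_idx = np.flatnonzero(cohort.disease == 1)
    control_idx = np.flatnonzero(cohort.disease == 0)
    for label, idx, want in (("cases", case_idx, n_cases), ("controls", control_idx, n_controls)):
        if want > idx.size:
            raise InsufficientSamplesError(
                f"requested {want} {label} but only {idx.size} available "
                f"(short by {want - idx.size})"
            )
    chosen = np.concatenate(
        [
            rng.choice(case_idx, size=n_cases, replace=False),
            rng.choice(control_idx, size=n_controls, replace=False),
        ]
    )
    return cohort.subset(np.sort(chosen))


# ---------------------------------------------------------------------------
# Calibration harness
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ErrorRateResult:
    rejection_rate: float
    wilson_low: float
    wilson_high: float
    n_replicates: int
    n_rejected: int


def _case_only_p(cohort: SimulatedCohort) -> float:
    cases = sample_case_series(cohort)
    exposed = GenotypeCounts(
        hom_ref=int(np.sum((cases.carrier == 1) & (cases.dosage == 0))),
        het=int(np.sum((cases.carrier == 1) & (cases.dosage == 1))),
        hom_alt=int(np.sum((cases.carrier == 1) & (cases.dosage == 2))),
    )
    unexposed = GenotypeCounts(
        hom_ref=int(np.sum((cases.carrier == 0) & (cases.dosage == 0))),
        het=int(np.sum((cases.carrier == 0) & (cases.dosage == 1))),
        hom_alt=int(np.sum((cases.carrier == 0) & (cases.dosage == 2))),
    )
    from .cohort_io import StratumPair

    try:
        t = case_only_table(StratumPair("sim", exposed, unexposed), coding="dominant")
        return pearson_chi2_p(t)
    except Exception:
        return 1.0  # degenerate replicate: never a rejection


def _lrt_p(cohort: SimulatedCohort) -> float:
    try:
        res = fit_interaction_model(cohort.to_frame())
        return res.lrt_p
    except Exception:
        return 1.0


def estimate_error_rates(
    cfg: SimulationConfig,
    n_replicates: int,
    alpha: float = 0.05,
    test: Literal["case_only", "lrt"] = "case_only",
) -> ErrorRateResult:
    """Rejection rate of the chosen interaction test over seeded replicates.

    Under ``beta_interaction = 0`` this estimates the type-I error rate,
    otherwise power.  The Wilson score interval quantifies the Monte Carlo
    uncertainty.
    """
    if n_replicates < 100:
        raise ValueError("n_replicates must be >= 100")
    p_fn = {"case_only": _case_only_p, "lrt": _lrt_p}[test]
    seeds = np.random.SeedSequence(cfg.seed).spawn(n_replicates)
    n_rej = 0
    for s in seeds:
        cohort = _simulate_with_seedseq(cfg, s)
        # alpha >= 1 rejects unconditionally (p-values can equal 1 exactly).
        if p_fn(cohort) < alpha or alpha >= 1.0:
            n_rej += 1
    rate = n_rej / n_replicates
    lo, hi = proportion_confint(n_rej, n_replicates, alpha=0.05, method="wilson")
    return ErrorRateResult(rate, float(lo), float(hi), n_replicates, n_rej)


def _simulate_with_seedseq(cfg: SimulationConfig, seq: np.random.SeedSequence) -> SimulatedCohort:
    geno_rng, disease_rng = (np.random.default_rng(s) for s in seq.spawn(2))
    n = cfg.n_individuals
    carrier = (geno_rng.random(n) < cfg.carrier_freq).astype(np.int8)
    q = cfg.modifier_maf
    dosage = geno_rng.choice(3, size=n, p=[(1 - q) ** 2, 2 * q * (1 - q), q * q]).astype(np.int8)
    eta = (
        cfg.beta0
        + cfg.beta_carrier * carrier
        + cfg.beta_modifier * dosage
        + cfg.beta_interaction * carrier * dosage
    )
    prob = expit(np.clip(eta, -_LINEAR_CLIP, _LINEAR_CLIP))
    disease = (disease_rng.random(n) < prob).astype(np.int8)
    sizes = _stratum_sizes(cfg)
    stratum = np.repeat(np.arange(cfg.n_strata), sizes).astype(np.int16)
    return SimulatedCohort(carrier, dosage, disease, stratum, cfg)


# ---------------------------------------------------------------------------
# Discovery-shaped planted fixture
# ---------------------------------------------------------------------------


@dataclass
class DiscoveryFixture:
    """A discovery-layout genotype matrix with known planted truth."""

    matrix: GenotypeMatrix
    records: list  # VariantFrequencyRecord per variant, with pseudo references
    planted_enriched: list[str]
    planted_recessive: str
    criteria: SelectionCriteria = field(default_factory=SelectionCriteria)

    def run_selection(self):
        return select_candidates(self.records, self.criteria)

    def run_screen(self, min_hom_carriers: int = 2) -> list[str]:
        return recessive_screen(self.matrix, "carrier", ["fbc", "crc"], min_hom_carriers)


_GROUP_SIZES = {"carrier": 28, "fbc": 28, "crc": 70}


def _hwe_draw(rng: np.random.Generator, n: int, q: float, allow_hom: bool = True) -> np.ndarray:
    p = np.array([(1 - q) ** 2, 2 * q * (1 - q), q * q])
    if not allow_hom:
        p[2] = 0.0
        p = p / p.sum()
    return rng.choice(3, size=n, p=p).astype(np.int8)


def _emp_maf(calls: np.ndarray) -> float:
    return float(np.sum(calls)) / (2 * calls.size)


def make_discovery_fixture(
    seed: int,
    out_dir: str | Path | None = None,
    n_enriched: int = 14,
    n_background: int = 10,
    max_tries: int = 500,
) -> DiscoveryFixture:
    """Build a 28/28/70 discovery-shaped genotype matrix with planted truth.

    Plants ``n_enriched`` frequency-enriched variants (high carrier MAF,
    low elsewhere), one recessive modifier (three alternate homozygotes in
    the carrier group, none elsewhere) and ``n_background`` null variants.

    At these group sizes empirical frequencies are noisy, so each
    variant's genotypes are redrawn until the realized frequencies honour
    the planted classification under the default selection criteria; the
    fixture's contract is exact planted-truth recovery, not unconditional
    sampling.
    """
    root = np.random.SeedSequence([seed, 0xD15C])
    rng = np.random.default_rng(root)
    criteria = SelectionCriteria()
    groups = list(_GROUP_SIZES)
    sizes = [_GROUP_SIZES[g] for g in groups]

    variant_ids: list[str] = []
    columns: list[np.ndarray] = []
    references: dict[str, dict[str, float]] = {}

    def realized(calls_by_group: dict[str, np.ndarray]) -> tuple[float, float, float]:
        return (
            _emp_maf(calls_by_group["carrier"]),
            _emp_maf(calls_by_group["fbc"]),
            _emp_maf(calls_by_group["crc"]),
        )

    def passes_freq(carrier: float, fbc: float, crc: float) -> bool:
        r_crc = carrier / crc if crc > 0 else math.inf if carrier > 0 else math.nan
        r_fbc = carrier / fbc if fbc > 0 else math.inf if carrier > 0 else math.nan
        return (r_crc >= criteria.ratio_vs_controls) or (r_fbc >= criteria.ratio_vs_familial)

    def draw_variant(vid: str, target: dict[str, float], want_selected: bool, refs_q: float):
        for _ in range(max_tries):
            calls = {g: _hwe_draw(rng, _GROUP_SIZES[g], target[g]) for g in groups}
            ref_a = rng.binomial(2000, refs_q) / 2000
            ref_b = rng.binomial(2000, refs_q) / 2000
            carrier, fbc, crc = realized(calls)
            freq_ok = passes_freq(carrier, fbc, crc)
            enrich_ok = (carrier > criteria.reference_enrichment * ref_a) and (
                carrier > criteria.reference_enrichment * ref_b
            )
            # Must not trip the recessive screen (that is the planted
            # recessive variant's exclusive signature).
            carrier_hom = int(np.sum(calls["carrier"] == 2))
            comp_hom = int(np.sum(calls["fbc"] == 2) + np.sum(calls["crc"] == 2))
            screen_safe = not (carrier_hom >= 2 and comp_hom == 0)
            ok = screen_safe and ((freq_ok and enrich_ok) if want_selected else not freq_ok)
            if ok:
                variant_ids.append(vid)
                columns.append(np.concatenate([calls[g] for g in groups]))
                references[vid] = {"panel_a": ref_a, "panel_b": ref_b}
                return
        raise RuntimeError(f"could not realize planted classification for {vid}")

    planted_enriched = []
    for i in range(n_enriched):
        vid = f"enriched_{i + 1:02d}"
        draw_variant(
            vid,
            {"carrier": 0.35, "fbc": 0.08, "crc": 0.08},
            want_selected=True,
            refs_q=0.08,
        )
        planted_enriched.append(vid)

    for i in range(n_background):
        q = float(rng.uniform(0.10, 0.30))
        draw_variant(
            f"background_{i + 1:02d}",
            {"carrier": q, "fbc": q, "crc": q},
            want_selected=False,
            refs_q=q,
        )

    # Recessive modifier: exactly three carrier-group homozygotes, none in
    # the comparison groups; must also stay below the frequency thresholds.
    rec_id = "recessive_mod"
    for _ in range(max_tries):
        carrier_calls = _hwe_draw(rng, _GROUP_SIZES["carrier"], 0.15, allow_hom=False)
        hom_pos = rng.choice(_GROUP_SIZES["carrier"], size=3, replace=False)
        carrier_calls[hom_pos] = 2
        other = {
            g: _hwe_draw(rng, _GROUP_SIZES[g], 0.18, allow_hom=False) for g in ("fbc", "crc")
        }
        carrier, fbc, crc = (
            _emp_maf(carrier_calls),
            _emp_maf(other["fbc"]),
            _emp_maf(other["crc"]),
        )
        if not passes_freq(carrier, fbc, crc):
            variant_ids.append(rec_id)
            columns.append(np.concatenate([carrier_calls, other["fbc"], other["crc"]]))
            references[rec_id] = {"panel_a": 0.18, "panel_b": 0.18}
            break
    else:
        raise RuntimeError("could not realize the planted recessive variant")

    sample_ids = [f"{g}_{i + 1:03d}" for g, size in zip(groups, sizes) for i in range(size)]
    group_of = {s: s.rsplit("_", 1)[0] for s in sample_ids}
    matrix = GenotypeMatrix(sample_ids, variant_ids, np.column_stack(columns), group_of)
    records = frequency_records_from_matrix(
        matrix,
        "carrier",
        "fbc",
        "crc",
        reference_mafs=references,
        driver_flags={v: True for v in planted_enriched},
    )
    fixture = DiscoveryFixture(
        matrix=matrix,
        records=records,
        planted_enriched=planted_enriched,
        planted_recessive=rec_id,
        criteria=criteria,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_genotype_tsv(matrix, out / "discovery_genotypes.tsv")
        _write_validation_counts(rng, planted_enriched, out / "validation_counts.tsv")
    return fixture


def _write_validation_counts(
    rng: np.random.Generator, variants: Sequence[str], path: Path
) -> None:
    """Validation-shaped genotype count tables for the planted candidates."""
    cohorts = {"CHEK2": 72, "Familial": 408, "Sporadic": 328, "Controls": 284}
    rows = []
    for vid in variants:
        q0 = float(rng.uniform(0.03, 0.15))
        for cohort, n in cohorts.items():
            q = min(0.5, q0 * (1.6 if cohort == "CHEK2" else 1.0))
            counts = rng.multinomial(n, [(1 - q) ** 2, 2 * q * (1 - q), q * q])
            rows.append(
                {
                    "gene": vid,
                    "rsid": vid,
                    "cohort": cohort,
                    "het": int(counts[1]),
                    "hom_alt": int(counts[2]),
                    "hom_ref": int(counts[0]),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def hwe_gof_p(dosage: np.ndarray) -> float:
    """Chi-square goodness-of-fit p of 0/1/2 genotype counts against HWE
    at the empirical allele frequency (1 df)."""
    n = dosage.size
    counts = np.array([np.sum(dosage == k) for k in (0, 1, 2)], dtype=float)
    q = (counts[1] + 2 * counts[2]) / (2 * n)
    expected = n * np.array([(1 - q) ** 2, 2 * q * (1 - q), q * q])
    mask = expected > 0
    chi2 = float(np.sum((counts[mask] - expected[mask]) ** 2 / expected[mask]))
    return float(stats.chi2.sf(chi2, df=1))
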