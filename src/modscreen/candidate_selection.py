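"""Discovery-phase candidate filters and the recessive homozygote screen.

Four per-variant criteria are implemented:

* **frequency ratios** — carrier-cohort MAF at least ``ratio_vs_controls``
  times the healthy-control MAF, and/or at least ``ratio_vs_familial``
  times the familial-case MAF (OR of the two branches);
* **reference enrichment** — carrier MAF strictly greater than
  ``reference_enrichment`` times *every* available reference-panel MAF;
* **call rate** — genotyping call rate of at least ``min_call_rate`` in
  every study group;
* **driver flag** — a pass-through boolean for manual gene-function
  curation, disabled by default.

The overall verdict is the conjunction of the criteria enabled in the
:class:`SelectionCriteria`.  Criteria that cannot be evaluated (missing
inputs) fail by default, with the reason recorded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort_io import GenotypeMatrix, VariantFrequencyRecord, counts_from_matrix, allele_frequency


@dataclass(frozen=True)
class SelectionCriteria:
    """Thresholds and switches for candidate-variant selection."""

    ratio_vs_controls: float = 2.0
    ratio_vs_familial: float = 1.5
    reference_enrichment: float = 1.3
    min_call_rate: float = 0.65
    require_driver_flag: bool = False
    apply_frequency: bool = True
    apply_reference_enrichment: bool = True
    apply_call_rate: bool = True
    #: Verdict assigned when a criterion's inputs are entirely absent.
    not_evaluable_passes: bool = False

    def __post_init__(self) -> None:
        for name in ("ratio_vs_controls", "ratio_vs_familial", "reference_enrichment"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.min_call_rate <= 1.0:
            raise ValueError("min_call_rate must be in [0, 1]")


@dataclass(frozen=True)
class CriterionVerdict:
    passed: bool
    evaluable: bool = True
    reason: str = ""


@dataclass(frozen=True)
class VariantVerdict:
    """Per-variant selection outcome with the computed ratios."""

    rsid: str
    gene: str
    ratio_vs_controls: float
    ratio_vs_familial: float
    frequency: CriterionVerdict
    reference_enrichment: CriterionVerdict
    call_rate: CriterionVerdict
    driver: CriterionVerdict
    overall: bool


@dataclass
class SelectionReport:
    verdicts: list[VariantVerdict] = field(default_factory=list)

    @property
    def n_selected(self) -> int:
        return sum(v.overall for v in self.verdicts)

    def selected(self) -> list[str]:
        return [v.rsid for v in self.verdicts if v.overall]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v in self.verdicts:
            rows.append(
                {
                    "rsid": v.rsid,
                    "gene": v.gene,
                    "ratio_vs_controls": v.ratio_vs_controls,
                    "ratio_vs_familial": v.ratio_vs_familial,
                    "pass_frequency": v.frequency.passed,
                    "pass_reference_enrichment": v.reference_enrichment.passed,
                    "pass_call_rate": v.call_rate.passed,
                    "pass_driver": v.driver.passed,
                    "selected": v.overall,
                }
            )
        return pd.DataFrame(rows)


def maf_ratio(num: float, den: float) -> float:
    """num/den with the degenerate cases encoded in the return value:
    x/0 -> inf for x > 0 (passes any threshold), 0/0 -> nan (fails all)."""
    if num < 0 or den < 0:
        raise ValueError("frequencies must be non-negative")
    if den == 0:
        return math.inf if num > 0 else math.nan
    return num / den


def passes_frequency_criteria(
    v: VariantFrequencyRecord, c: SelectionCriteria
) -> tuple[CriterionVerdict, float, float]:
    """Frequency-ratio filter; returns the verdict plus both ratios.

    Comparison is on unrounded ratios with >= (nan never passes).
    """
    if v.carrier_maf is None or v.fbc_maf is None or v.crc_maf is None:
        missing = [
            name
            for name, x in (
                ("carrier_maf", v.carrier_maf),
                ("fbc_maf", v.fbc_maf),
                ("crc_maf", v.crc_maf),
            )
            if x is None
        ]
        return (
            CriterionVerdict(False, evaluable=False, reason=f"missing {', '.join(missing)}"),
            math.nan,
            math.nan,
        )
    r_crc = maf_ratio(v.carrier_maf, v.crc_maf)
    r_fbc = maf_ratio(v.carrier_maf, v.fbc_maf)
    passed = (r_crc >= c.ratio_vs_controls) or (r_fbc >= c.ratio_vs_familial)
    return CriterionVerdict(passed), r_crc, r_fbc


def passes_reference_enrichment(
    v: VariantFrequencyRecord, c: SelectionCriteria
) -> CriterionVerdict:
    """Strictly more than ``reference_enrichment`` times every available
    reference MAF; absent references are skipped, none at all is
    not-evaluable."""
    if not v.reference_mafs:
        return CriterionVerdict(
            c.not_evaluable_passes, evaluable=False, reason="no reference frequencies"
        )
    if v.carrier_maf is None:
        return CriterionVerdict(False, evaluable=False, reason="missing carrier_maf")
    passed = all(v.carrier_maf > c.reference_enrichment * r for r in v.reference_mafs.values())
    return CriterionVerdict(passed)


def passes_call_rate(v: VariantFrequencyRecord, c: SelectionCriteria) -> CriterionVerdict:
    """Call rate >= ``min_call_rate`` (inclusive) in every group."""
    if not v.call_rates:
        return CriterionVerdict(
            c.not_evaluable_passes, evaluable=False, reason="no call rates"
        )
    return CriterionVerdict(all(r >= c.min_call_rate for r in v.call_rates.values()))


def select_candidates(
    records: Iterable[VariantFrequencyRecord],
    criteria: SelectionCriteria | None = None,
) -> SelectionReport:
    """Apply the enabled criteria to every record, preserving order."""
    c = criteria or SelectionCriteria()
    report = SelectionReport()
    for v in records:
        freq, r_crc, r_fbc = passes_frequency_criteria(v, c)
        enrich = passes_reference_enrichment(v, c)
        rate = passes_call_rate(v, c)
        driver = CriterionVerdict(bool(v.driver_flag))
        checks: list[bool] = []
        if c.apply_frequency:
            checks.append(freq.passed)
        if c.apply_reference_enrichment:
            checks.append(enrich.passed)
        if c.apply_call_rate:
            checks.append(rate.passed)
        if c.require_driver_flag:
            checks.append(driver.passed)
        report.verdicts.append(
            VariantVerdict(
                rsid=v.rsid,
                gene=v.gene,
                ratio_vs_controls=r_crc,
                ratio_vs_familial=r_fbc,
                frequency=freq,
                reference_enrichment=enrich,
                call_rate=rate,
                driver=driver,
                overall=all(checks),
            )
        )
    return report


def recessive_screen(
    m: GenotypeMatrix,
    carrier_group: str,
    comparison_groups: Sequence[str],
    min_hom_carriers: int = 2,
) -> list[str]:
    """Flag variants with at least ``min_hom_carriers`` alternate
    homozygotes in the carrier group and none in any comparison group.

    Missing calls are ignored.
    """
    if min_hom_carriers < 1:
        raise ValueError("min_hom_carriers must be >= 1")
    carrier_rows = m.group_rows(carrier_group)
    comparison_rows = [m.group_rows(g) for g in comparison_groups]
    flagged = []
    carrier_hom = np.sum(m.calls[carrier_rows, :] == 2, axis=0)
    comp_hom = np.zeros(len(m.variant_ids), dtype=int)
    for rows in comparison_rows:
        comp_hom += np.sum(m.calls[rows, :] == 2, axis=0)
    for j, vid in enumerate(m.variant_ids):
        if carrier_hom[j] >= min_hom_carriers and comp_hom[j] == 0:
            flagged.append(vid)
    return flagged


def frequency_records_from_matrix(
    m: GenotypeMatrix,
    carrier_group: str,
    fbc_group: str,
    crc_group: str,
    reference_mafs: dict[str, dict[str, float]] | None = None,
    driver_flags: dict[str, bool] | None = None,
) -> list[VariantFrequencyRecord]:
    """Build selection inputs from a genotype matrix: per-group empirical
    MAFs and call rates, plus optional per-variant reference MAFs."""
    reference_mafs = reference_mafs or {}
    driver_flags = driver_flags or {}
    records = []
    for vid in m.variant_ids:
        mafs = {}
        rates = {}
        for label, group in (
            ("carrier", carrier_group),
            ("fbc", fbc_group),
            ("crc", crc_group),
        ):
            counts, rate = counts_from_matrix(m, vid, group)
            mafs[label] = allele_frequency(counts) if counts.total() else None
            rates[label] = rate
        records.append(
            VariantFrequencyRecord(
                rsid=vid,
                gene=vid,
                chrom="NA",
                carrier_maf=mafs["carrier"],
                fbc_maf=mafs["fbc"],
                crc_maf=mafs["crc"],
                reference_mafs=dict(reference_mafs.get(vid, {})),
                driver_flag=driver_flags.get(vid, False),
                call_rates=rates,
            )
        )
    return records
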