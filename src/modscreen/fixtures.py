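"""Packaged fixtures transcribed from the published study tables.

Three TSVs ship with the package:

* ``case_only_strata.tsv`` — per-stratum genotype triplets for the modifier
  variant among risk-allele carriers vs non-carriers (all breast-cancer
  cases), with the published per-stratum OR/CI/P columns.
* ``candidate_variants.tsv`` — the 14 discovery-phase candidate variants
  with per-cohort and per-reference MAF columns and the published
  frequency-ratio columns.
* ``validation_counts.tsv`` — genotype counts for the 11 validated
  candidates in four cohorts, with the published allelic OR/CI/P columns.

Published-value columns are kept as *strings* so their printed precision
survives; ``discrepancy`` lists cells whose printed value is known not to
be reproducible from the printed counts (transcription defects in the
source, documented per row in ``note``).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .cohort_io import GenotypeCounts, StratumPair, VariantFrequencyRecord, read_variant_table

#: Published pooled (study-stratified) case-only result for the modifier.
PUBLISHED_COMBINED = {"or": "0.69", "ci_low": "0.46", "ci_high": "1.03", "p": "0.073"}

#: Columns holding published values in fixture files (kept as text).
_PUB_COLUMNS = ("pub_or", "pub_ci_low", "pub_ci_high", "pub_p", "pub_af", "pub_ratio_crc", "pub_ratio_fbc")


def _data_path(name: str) -> Path:
    return Path(resources.files("modscreen").joinpath("data", name))  # type: ignore[arg-type]


def _read_fixture(name: str) -> pd.DataFrame:
    df = pd.read_csv(
        _data_path(name),
        sep="\t",
        dtype={c: str for c in _PUB_COLUMNS + ("discrepancy", "note", "chrom")},
        keep_default_na=False,
        na_values=[],
    )
    for col in ("discrepancy", "note"):
        if col not in df.columns:
            df[col] = ""
    return df


def load_case_only_strata() -> pd.DataFrame:
    """Raw per-stratum fixture table (counts + published columns)."""
    return _read_fixture("case_only_strata.tsv")


def case_only_strata() -> list[StratumPair]:
    """The per-stratum fixture as :class:`StratumPair` objects."""
    df = load_case_only_strata()
    return [
        StratumPair(
            stratum_label=row.stratum,
            exposed=GenotypeCounts(
                int(row.exposed_hom_ref), int(row.exposed_het), int(row.exposed_hom_alt)
            ),
            unexposed=GenotypeCounts(
                int(row.unexposed_hom_ref), int(row.unexposed_het), int(row.unexposed_hom_alt)
            ),
        )
        for row in df.itertuples(index=False)
    ]


def load_candidate_variants() -> pd.DataFrame:
    """Raw candidate-variant fixture table (MAFs + published ratio columns)."""
    return _read_fixture("candidate_variants.tsv")


def candidate_variant_records() -> list[VariantFrequencyRecord]:
    """The candidate fixture as :class:`VariantFrequencyRecord` objects."""
    return read_variant_table(_data_path("candidate_variants.tsv"))


def load_validation_counts() -> pd.DataFrame:
    """Raw validation-cohort genotype-count fixture table."""
    return _read_fixture("validation_counts.tsv")


def validation_counts() -> dict[tuple[str, str], GenotypeCounts]:
    """Validation genotype counts keyed by (rsid, cohort)."""
    df = load_validation_counts()
    return {
        (row.rsid, row.cohort): GenotypeCounts(
            int(row.hom_ref), int(row.het), int(row.hom_alt)
        )
        for row in df.itertuples(index=False)
    }
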