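"""Domain types and I/O for genotype-count and individual-level cohort data.

The central currency of the package is the genotype-count triple
(hom-ref, het, hom-alt) for one biallelic variant in one group of
individuals.  Published tables print these triples in a dash-separated
notation (``"549–138–16"``); per-individual data arrive as VCF or as a
simple wide TSV genotype matrix with a group label per sample.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    FormatError,
    LookupError_,
    TripletParseError,
    UndefinedFrequencyError,
)

#: Sentinel genotype code for a missing call (codes are 0/1/2 otherwise).
MISSING: int = -1

# Dash characters accepted between triplet fields: hyphen-minus, en-dash,
# minus sign, figure dash.  En-dash is what the published tables print.
_DASHES = "–−‒-"
_TRIPLET_SEP = re.compile(f"[{_DASHES}]")

EN_DASH = "–"


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts (hom_ref, het, hom_alt) for one biallelic variant."""

    hom_ref: int
    het: int
    hom_alt: int

    def __post_init__(self) -> None:
        for name in ("hom_ref", "het", "hom_alt"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                raise TypeError(f"{name} must be an integer, got {v!r}")
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")

    def total(self) -> int:
        return self.hom_ref + self.het + self.hom_alt

    def alt_alleles(self) -> int:
        return self.het + 2 * self.hom_alt

    def ref_alleles(self) -> int:
        return 2 * self.hom_ref + self.het

    def carriers(self) -> int:
        """Individuals carrying at least one alternate allele."""
        return self.het + self.hom_alt


@dataclass(frozen=True)
class StratumPair:
    """One cohort stratum: genotype counts for exposed vs unexposed groups.

    "Exposed" means carriers of the primary risk allele; "unexposed" the
    non-carriers of the same cohort.
    """

    stratum_label: str
    exposed: GenotypeCounts
    unexposed: GenotypeCounts


@dataclass
class VariantFrequencyRecord:
    """One candidate-variant row: identifiers plus per-cohort and
    per-reference minor-allele frequencies.

    Absent frequencies are ``None``; ``reference_mafs`` maps a reference
    panel name to its MAF and may be empty.
    """

    rsid: str
    gene: str
    chrom: str
    carrier_maf: float | None
    fbc_maf: float | None
    crc_maf: float | None
    reference_mafs: dict[str, float] = field(default_factory=dict)
    driver_flag: bool = False
    call_rates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, x in self._named_frequencies():
            if x is not None and not (0.0 <= x <= 1.0):
                raise ValueError(f"{label} out of [0, 1]: {x}")
        for grp, r in self.call_rates.items():
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"call rate for {grp!r} out of [0, 1]: {r}")

    def _named_frequencies(self):
        yield "carrier_maf", self.carrier_maf
        yield "fbc_maf", self.fbc_maf
        yield "crc_maf", self.crc_maf
        for name, x in self.reference_mafs.items():
            yield f"ref {name}", x


class GenotypeMatrix:
    """Per-sample, per-variant genotype codes with group labels.

    Codes are 0 (hom ref), 1 (het), 2 (hom alt), ``MISSING`` (-1).  The
    calls array has shape (n_samples, n_variants).
    """

    def __init__(
        self,
        sample_ids: Sequence[str],
        variant_ids: Sequence[str],
        calls: np.ndarray,
        group_of: Mapping[str, str],
    ) -> None:
        self.sample_ids = list(sample_ids)
        self.variant_ids = list(variant_ids)
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(self.sample_ids), len(self.variant_ids)):
            raise ValueError(
                f"calls shape {calls.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.variant_ids)} variants"
            )
        bad = ~np.isin(calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(
                f"genotype codes restricted to 0/1/2/{MISSING}; "
                f"found {sorted(np.unique(calls[bad]).tolist())}"
            )
        self.calls = calls
        self.group_of = dict(group_of)
        missing_groups = set(self.sample_ids) - set(self.group_of)
        if missing_groups:
            raise ValueError(f"samples without a group label: {sorted(missing_groups)[:5]}")
        self._variant_index = {v: i for i, v in enumerate(self.variant_ids)}
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.group_of[s], None)
        return list(seen)

    def group_rows(self, group: str) -> np.ndarray:
        rows = np.array(
            [i for i, s in enumerate(self.sample_ids) if self.group_of[s] == group],
            dtype=int,
        )
        if rows.size == 0:
            raise LookupError_(f"unknown group: {group!r}")
        return rows

    def variant_column(self, variant: str) -> int:
        try:
            return self._variant_index[variant]
        except KeyError:
            raise LookupError_(f"unknown variant: {variant!r}") from None


def parse_genotype_triplet(text: str) -> GenotypeCounts:
    """Parse ``"549–138–16"`` (hom ref – het – hom alt) into counts.

    Accepts en-dash as printed as well as plain hyphen-minus.
    """
    fields = [f.strip() for f in _TRIPLET_SEP.split(text.strip())]
    if len(fields) != 3:
        raise TripletParseError(
            f"expected three dash-separated fields, got {len(fields)} in {text!r}"
        )
    values = []
    for tok in fields:
        if not tok.isdigit():
            raise TripletParseError(f"non-integer token {tok!r} in {text!r}")
        values.append(int(tok))
    return GenotypeCounts(hom_ref=values[0], het=values[1], hom_alt=values[2])


def format_genotype_triplet(g: GenotypeCounts) -> str:
    """Serialize counts back to the printed en-dash notation."""
    return EN_DASH.join(str(x) for x in (g.hom_ref, g.het, g.hom_alt))


def allele_frequency(g: GenotypeCounts) -> float:
    """Alternate-allele frequency (het + 2*hom_alt) / (2*total)."""
    n = g.total()
    if n == 0:
        raise UndefinedFrequencyError("allele frequency undefined for an empty group")
    return g.alt_alleles() / (2 * n)


def counts_from_matrix(
    m: GenotypeMatrix, variant: str, group: str
) -> tuple[GenotypeCounts, float]:
    """Tally genotype counts for one variant within one group.

    Returns the counts over non-missing calls and the call rate
    (non-missing / group size).
    """
    col = m.variant_column(variant)
    rows = m.group_rows(group)
    calls = m.calls[rows, col]
    observed = calls[calls != MISSING]
    counts = GenotypeCounts(
        hom_ref=int(np.sum(observed == 0)),
        het=int(np.sum(observed == 1)),
        hom_alt=int(np.sum(observed == 2)),
    )
    call_rate = observed.size / rows.size
    return counts, call_rate


# ---------------------------------------------------------------------------
# Variant frequency tables (TSV)
# ---------------------------------------------------------------------------

_REQUIRED_VARIANT_COLUMNS = ("rsid", "gene", "chrom", "carrier_maf", "fbc_maf", "crc_maf")
_REF_PREFIX = "ref_"
_CALL_RATE_PREFIX = "call_rate_"


def _optional_float(value) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, str) and value.strip() in ("", "NA", "nan", "."):
        return None
    return float(value)


def read_variant_table(path: str | Path) -> list[VariantFrequencyRecord]:
    """Read a TSV of candidate-variant frequency records.

    Required columns: rsid, gene, chrom, carrier_maf, fbc_maf, crc_maf.
    Optional: ``ref_<name>`` reference MAFs, ``call_rate_<group>`` columns,
    and a boolean ``driver_flag``.  Empty/NA cells become absent values.
    """
    df = pd.read_csv(path, sep="\t", dtype={"rsid": str, "gene": str, "chrom": str})
    missing = [c for c in _REQUIRED_VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"variant table {path} missing columns: {missing}")
    ref_cols = [c for c in df.columns if c.startswith(_REF_PREFIX)]
    cr_cols = [c for c in df.columns if c.startswith(_CALL_RATE_PREFIX)]
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        refs = {
            c[len(_REF_PREFIX):]: v
            for c in ref_cols
            if (v := _optional_float(d[c])) is not None
        }
        rates = {
            c[len(_CALL_RATE_PREFIX):]: v
            for c in cr_cols
            if (v := _optional_float(d[c])) is not None
        }
        records.append(
            VariantFrequencyRecord(
                rsid=str(d["rsid"]),
                gene=str(d["gene"]),
                chrom=str(d["chrom"]),
                carrier_maf=_optional_float(d["carrier_maf"]),
                fbc_maf=_optional_float(d["fbc_maf"]),
                crc_maf=_optional_float(d["crc_maf"]),
                reference_mafs=refs,
                driver_flag=bool(d.get("driver_flag", False)),
                call_rates=rates,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Genotype matrices (TSV and VCF)
# ---------------------------------------------------------------------------


def read_genotypes(
    path: str | Path,
    format: str = "tsv",
    groups: Mapping[str, str] | None = None,
) -> GenotypeMatrix:
    """Read a per-individual genotype matrix.

    ``format="tsv"``: wide table with columns ``sample_id``, ``group``,
    then one column per variant holding 0/1/2 or NA.

    ``format="vcf"``: standard VCF; only biallelic SNV records are kept,
    others are skipped with a warning reporting the skipped count.  VCF
    carries no group labels, so ``groups`` maps sample -> group (samples
    absent from the mapping fall into group ``"all"``).
    """
    if format == "tsv":
        return _read_genotype_tsv(path)
    if format == "vcf":
        return _read_genotype_vcf(path, groups)
    raise ValueError(f"unknown genotype format: {format!r}")


def _read_genotype_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise FormatError(f"genotype TSV {path} missing column {col!r}")
    variant_ids = [c for c in df.columns if c not in ("sample_id", "group")]
    calls = np.full((len(df), len(variant_ids)), MISSING, dtype=np.int8)
    for j, v in enumerate(variant_ids):
        col = df[v]
        for i, raw in enumerate(col):
            if raw is None or (isinstance(raw, float) and np.isnan(raw)):
                continue
            if isinstance(raw, str):
                if raw.strip() in ("", "NA", "."):
                    continue
                raw = float(raw)
            code = int(raw)
            if code != raw or code not in (0, 1, 2):
                raise FormatError(
                    f"non-biallelic genotype code {raw!r} for variant {v!r} "
                    f"(row {i}) in {path}"
                )
            calls[i, j] = code
    return GenotypeMatrix(
        sample_ids=df["sample_id"].tolist(),
        variant_ids=variant_ids,
        calls=calls,
        group_of=dict(zip(df["sample_id"], df["group"])),
    )


def _read_genotype_vcf(
    path: str | Path, groups: Mapping[str, str] | None
) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    variant_ids: list[str] = []
    columns: list[np.ndarray] = []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_skipped += 1
            continue
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}:{rec.REF}>{rec.ALT[0]}"
        # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
        gt = np.asarray(rec.gt_types)
        codes = np.full(gt.shape, MISSING, dtype=np.int8)
        codes[gt == 0] = 0
        codes[gt == 1] = 1
        codes[gt == 3] = 2
        variant_ids.append(vid)
        columns.append(codes)
    vcf.close()
    if n_skipped:
        warnings.warn(
            f"skipped {n_skipped} non-biallelic/non-SNV record(s) in {path}",
            stacklevel=2,
        )
    calls = (
        np.column_stack(columns)
        if columns
        else np.empty((len(sample_ids), 0), dtype=np.int8)
    )
    groups = dict(groups or {})
    group_of = {s: groups.get(s, "all") for s in sample_ids}
    return GenotypeMatrix(sample_ids, variant_ids, calls, group_of)


def write_genotype_tsv(m: GenotypeMatrix, path: str | Path) -> None:
    """Write a matrix in the wide TSV dialect read by :func:`read_genotypes`."""
    df = pd.DataFrame(m.calls, columns=m.variant_ids)
    df = df.astype(object).mask(df.values == MISSING, "NA")
    df.insert(0, "group", [m.group_of[s] for s in m.sample_ids])
    df.insert(0, "sample_id", m.sample_ids)
    df.to_csv(path, sep="\t", index=False)
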