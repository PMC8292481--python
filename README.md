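# modscreen

A toolkit for searching for **genetic modifiers of a rare risk allele** in
case/control cohort data. It implements the two phases of such a study as a
tested, reusable pipeline:

1. **Discovery** — candidate-variant selection from small exome-style cohorts
   (a carrier case series plus familial-case and healthy-control comparison
   groups) using explicit allele-frequency-ratio, reference-database
   enrichment and call-rate filters, together with a recessive homozygote
   screen.
2. **Validation** — contingency-table association statistics (allelic and
   dominant 2×2 tables, sample and conditional-MLE odds ratios, Woolf and
   exact confidence intervals, Pearson chi-square and Fisher exact tests),
   per-stratum case-only interaction analysis, study-stratified
   Mantel–Haenszel pooling, and a case-control logistic interaction model
   tested by a 1-df likelihood ratio.

A seeded synthetic-cohort simulator (Hardy–Weinberg modifier genotypes, a
dominant rare-carrier indicator, and a logistic disease model with an
optional multiplicative interaction term) makes every stage testable without
any external download, and a set of packaged fixtures transcribed from
published study tables allows cell-by-cell reproduction of the original
numbers.

## Layout

| Module | Role |
| --- | --- |
| `modscreen.cohort_io` | genotype-count types, triplet notation ("549–138–16") parsing, VCF/TSV genotype matrices, variant-frequency tables |
| `modscreen.fixtures` | packaged published-table fixtures (counts + printed statistics) |
| `modscreen.candidate_selection` | frequency/enrichment/call-rate filters, recessive screen |
| `modscreen.association_stats` | 2×2 ORs, Woolf/exact CIs, chi-square/Fisher p, conditional MLE |
| `modscreen.interaction_analysis` | case-only tables, Mantel–Haenszel pooling, logistic interaction model + LRT |
| `modscreen.synthetic_cohorts` | seeded simulation, error-rate calibration, planted discovery fixtures |
| `modscreen.cli` / `modscreen.reproduce` | command line and published-table diffing |

## Command line

```sh
modscreen select --variants variants.tsv --frequency-only      # candidate filters
modscreen select --matrix discovery_genotypes.tsv --screen     # + recessive screen
modscreen assoc --counts validation_counts.tsv                 # OR/CI/p per cohort row
modscreen caseonly --strata strata.tsv                         # per-stratum case-only ORs
modscreen mh --strata strata.tsv                               # pooled Mantel–Haenszel OR
modscreen interact --data individuals.tsv                      # logistic interaction + LRT
modscreen simulate --kind discovery --seed 1 --out sim/        # planted synthetic data
modscreen reproduce --out report/                              # diff vs published tables
```

Every output embeds the tool version, a configuration hash and the seed.
Exit codes: 0 success, 1 runtime error, 2 usage error.

`modscreen reproduce` recomputes all packaged fixture tables and reports a
per-cell `match` / `known_discrepancy` / `mismatch` status at the printed
precision; the handful of documented source typos (duplicated cells,
inconsistent digit runs) are flagged in the fixtures themselves and
reported as known discrepancies, never silently passed.

## Notes

- Genotype codes are 0 / 1 / 2 with an explicit missing sentinel; dosage
  coding is always derived, never stored.
- Zero cells in a 2×2 table get the Haldane–Anscombe +0.5 correction before
  sample-OR/Woolf computations (flagged via `correction_applied`); exact
  methods are never corrected.
- The Fisher two-sided p uses the probability-mass rule; it is verified in
  the test suite against an exact integer-enumeration oracle on **all**
  135,750 tables with total ≤ 40.
- The Mantel–Haenszel CI uses the Robins–Breslow–Greenland variance and the
  p-value the uncorrected Mantel–Haenszel chi-square.
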