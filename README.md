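# umprofiler

A toolkit for targeted-amplicon molecular profiling of uveal melanoma
cohorts. It implements the analytical stages downstream of primary variant
calling:

- **Panel model** — 15 genes in four categories (initiating, prognostic,
  emergent, control), full-CDS or hotspot target regions, and 55 SNP loci
  on both arms of chromosomes 1, 3 and 8 (`umprofiler.panel_model`, with a
  bundled reference panel file).
- **Variant filtering** — VAF computation and a filter chain
  (VAF ≥ 10%, depth > 100, Phred quality > 40, caller p < 0.01, synonymous
  and benign/common-SNP exclusion) with auditable first-failure reason
  codes, plus offline ClinVar-style clinical classification
  (`umprofiler.variant_filtering`).
- **Imbalance calling** — zygosity banding of SNP VAFs (homozygous 0–5% /
  95–100%, heterozygous 45–55%, deviant otherwise) and per-chromosome
  balanced / imbalanced / non-informative calls with arm-level sub-calls
  (`umprofiler.imbalance`).
- **Prognostic classification** — per-patient profiles, cohort mutation
  and imbalance rates, GNAQ/GNA11 mutual-exclusivity flags, and risk
  stratification by BAP1 status or chromosome 1/3/8 imbalance against a
  disomy-3 baseline (`umprofiler.profiles`).
- **Concordance & QC** — coverage summaries with a 0.2×-mean uniformity
  rule, FDR-controlled robust (ROUT-style) outlier detection, OLS
  regression, Bland–Altman limits of agreement, Cohen's κ with
  sensitivity/specificity in both reference directions, and percent
  concordance accounting with a documented truncation convention
  (`umprofiler.concordance`).
- **Survival** — Kaplan–Meier product-limit estimation and two-group
  log-rank comparison for each stratification scheme
  (`umprofiler.survival`).
- **Synthetic cohorts** — a simulator producing variant/SNP/clinical/
  survival tables with known ground truth under a purity-aware allele
  dosage model (disomy, monosomy, single-copy gain) so the full pipeline
  is testable offline (`umprofiler.simulate`).

## CLI

```sh
# simulate a 44-patient cohort with ground truth
umprofiler simulate --n 44 --seed 7 --out cohort/

# run every stage; writes a sha256 manifest for reproducibility
umprofiler run-all --variants cohort/variants.tsv --snps cohort/snps.tsv \
    --clinical cohort/clinical.csv --survival cohort/survival.csv --out out/

# individual stages
umprofiler filter --variants cohort/variants.tsv --out out/
umprofiler imbalance --snps cohort/snps.tsv --out out/imbalance.tsv
umprofiler profile --variants out/filtered_variants.tsv \
    --imbalance out/imbalance.tsv --out out/
umprofiler survive --variants out/filtered_variants.tsv \
    --imbalance out/imbalance.tsv --survival cohort/survival.csv --scheme chr3
umprofiler concordance --pos-pos 8 --pos-neg 0 --neg-pos 0 --neg-neg 1
```

Variant input may be a TSV (columns `patient_id, gene, chrom, pos, ref,
alt, total_depth, alt_depth, qual, pvalue, consequence[, clin_class,
hgvs_p]`) or an uncompressed VCF 4.2 (depth from `FORMAT/DP` or `INFO/DP`,
alt depth from `FORMAT/AD`, `FORMAT/AO` or `INFO/AO`; optional `GENE`,
`CSQ`, `CLIN`, `HGVSP`, `PVAL` INFO keys). SNP tables are TSV with
`patient_id, rsid, chrom, arm, pos, total_depth, alt_depth`. Chromosome
names are accepted with or without a `chr` prefix; coordinates are
1-based inclusive (BED input is converted on ingestion).

## Conventions worth knowing

- The 10% VAF cut-off is inclusive; depth, quality and p-value cut-offs
  are strict, mirroring their `>` / `<` phrasing.
- Band boundaries are inclusive on both ends; a chromosome call requires
  at least 2 informative (het or deviant) loci, and imbalance requires at
  least 2 deviant loci making up ≥ half the informative ones. Both knobs
  are configurable.
- Cohort percentages use half-up rounding to one decimal. Concordance
  percentages are reported at the printed precision of the source being
  matched; the 103/104 figure uses truncation (99.03, not 99.04), flagged
  at the call site.
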