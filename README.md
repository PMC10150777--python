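# lfsmo — germline multi-omic modifiers in Li-Fraumeni syndrome

Li-Fraumeni syndrome (LFS) is a highly penetrant hereditary cancer
syndrome classically caused by germline pathogenic *TP53* variants, yet
penetrance is incomplete and a substantial minority of clinically
defined LFS families carry wildtype *TP53*. `lfsmo` implements, as a
tested and reusable pipeline, the germline analyses needed to look
*beyond TP53* for modifiers of cancer risk:

* **Small-variant prioritization** — short-read artifact QC filters,
  population allele-frequency filtering, the null-variant
  loss-of-function upgrade, family co-segregation coding (ACMG PP1/BS4),
  and a five-class schema combining pathogenicity (P/LP/VUS/LB/B) with a
  four-tier cancer-gene prioritization (tier 1 = autosomal dominant
  cancer predisposition genes, 2 = autosomal recessive CPGs,
  3 = somatically mutated cancer genes, 4 = all other genes):
  class *k* ∈ {1..4} is a P/LP variant in a tier-*k* gene (class 4
  requiring literature support), class 5 a cancer-segregating VUS in a
  tier 1–3 gene. Per-patient burdens, Fisher/Wilcoxon cohort
  comparisons, hallmark-style pathway enrichment and class-based
  survival grouping (Kaplan–Meier, log-rank) sit on top.
* **Structural and copy-number variants** — dual-caller SV consensus
  with a size-tiered breakpoint tolerance (100 bp ≤ 10 kb, 1 kb ≤ 50 kb,
  10 kb beyond), panel-of-normals recurrence filtering (≥ 3 controls),
  annotation-score and population-database filters; CNV caller
  intersection minus repetitive/low-complexity exclusion regions.
* **cis-CSCE discovery** — a *cancer-associated secondary constitutional
  epimutation* is a CpG whose methylation (i) associates with cancer
  status in a discovery cohort and replicates in two validation cohorts
  (per-cohort Benjamini–Hochberg FDR < 0.1), and (ii) correlates, by
  Spearman ρ, with a SNP within ±10 kb (genotypes coded additively
  1/3/4; the strongest cis-SNP represents each probe; BH FDR < 0.05
  over retained pairs). Preprocessing (PCA ±3 SD outlier trimming, a
  covariate + latent-factor residualization contract), cancer-type
  ANOVA, genomic-feature enrichment against a 100,000-probe resampled
  baseline (paired Wilcoxon, Cohen's d_z) and single-locus group tests
  are included.
* **Risk stratification** — UMAP/PCA embedding with k-means (k = 3)
  tested against cancer status (χ²) and survival (log-rank), and a
  random-forest cancer risk score trained with repeated stratified
  5-fold cross-validation over an mtry grid, with AUROC/AUPRC bootstrap
  CIs and a Youden-index operating threshold.

Because the original patient-level data are access-controlled, the
package ships a first-class synthetic cohort generator
(`lfsmo.simulate`) that reproduces the *statistical structure* the
analysis assumes — family segregation, planted class 1–5 variants,
jittered dual-caller SV callsets, three methylation cohorts with planted
cis-meQTLs and cis-CSCE, right-censored survival — together with a truth
ledger, so every stage is testable end to end.

## Worked example

```python
from lfsmo import SimConfig, simulate_cohort, EpimutationAnalysis
from lfsmo.variants import (apply_qc_filters, apply_population_filter,
                            classify_variants, per_patient_burden, survival_groups)

cohort = simulate_cohort(SimConfig(seed=7, n_probes=800))
passed, failed = apply_qc_filters(cohort.variants)
rare, common = apply_population_filter(passed)
classified = classify_variants(rare, cohort.families, cohort.gene_tiers,
                               cohort.lof_mechanism_genes, cohort.class4_support)
burden = per_patient_burden(classified, cohort.wgs_samples)
print(f"{len(cohort.variants)} records -> {len(passed)} QC-pass -> {len(rare)} rare")
print(f"samples with a class 1-3 variant: {(burden['class1_3'] >= 1).sum()}")
sg = survival_groups(cohort.samples[cohort.samples.has_wgs], classified,
                     set(cohort.gene_sets['WNT_SIGNALING']))
print(sg.summary())
res = EpimutationAnalysis(cohort.methylation, cohort.genotypes).fit()
print(res.summary())
```

prints

```
2096 records -> 1788 QC-pass -> 1077 rare
samples with a class 1-3 variant: 11
survival groups:
  class1_3: 11
  wnt_modifier: 1
  neither: 71
  dual membership: S0021
  log-rank p = 0.39
EWAS of 'cancer_status' (BH FDR < 0.1)
  discovery: 27 significant probes
  internal: 30 significant probes
  external: 28 significant probes
  validated in all cohorts: 25
cis-CSCE discovery (window +/-10000 bp, BH FDR < 0.05)
  probes tested: 25 (no cis-SNP: 0)
  significant cis-CSCE: 25
  alt allele increases methylation: 16
  hypomethylation-risk: 19
```

The QC and population filters drop artifact-like and common background
variants; 11 genomes carry a pathogenic/likely-pathogenic variant in a
known cancer gene (the planted modifiers plus protective WNT-pathway
hits, one genome holding both); and all 25 planted cis-CSCE probes
survive the triple-cohort EWAS gate and the cis-Spearman scan at the
47-sample WGS–methylation overlap.

The same stages run from the shell on files:

```bash
lfsmo simulate --out cohort/ --seed 7
lfsmo run-all --vcf cohort/variants.vcf --annot cohort/variants_annot.tsv \
    --ped cohort/samples.ped.tsv --tiers cohort/gene_tiers.tsv \
    --gmt cohort/gene_sets.gmt --caller-a cohort/sv_caller_a.tsv \
    --caller-b cohort/sv_caller_b.tsv --pon-dir cohort/pon \
    --cnv-a cohort/cnv_caller_a.tsv --cnv-b cohort/cnv_caller_b.tsv \
    --exclusion-bed cohort/exclusion.bed --beta cohort/beta.tsv \
    --probe-annot cohort/probe_annot.tsv \
    --sample-covariates cohort/sample_covariates.tsv \
    --geno cohort/genotypes.tsv --seed 7 --out results/
```

Every run writes a provenance manifest (seed, thresholds, input
checksums, per-stage record counts).

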