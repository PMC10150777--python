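# Methods

This note documents the models and procedures `lfsmo` implements, the
parameters that matter, what the synthetic cohort generator does and
does not emulate, and the numerical choices made where the design was
genuinely open.

## Small-variant prioritization

Records enter as one row per (variant, sample) with QC metrics,
population allele frequencies, a consequence term, and an upstream
ACMG-style pathogenicity call. The pipeline deliberately does **not**
re-derive the ACMG evidence combination — that belongs to the upstream
annotation engine — and applies only the overrides that the analysis
itself defines:

* **Artifact filters.** A record passes iff read position percentile ∈
  [10, 90], strandedness ∈ [1, 99]%, distance to the 3′ end > 20 bp,
  homopolymer length < 5, mapping-quality difference < 30, read-length
  difference < 25, mismatch-quality-sum difference < 100, and ≥ 5
  alternate reads. All eight bounds are applied exactly as printed
  inequalities; a missing metric fails conservatively with the label
  `missing_metric` (an explicit design choice — silent passes on absent
  evidence are worse than false rejections in a germline context).
* **Population filter.** Common iff *any* of gnomAD/ExAC/1kGP AF is
  strictly > 0.01; a variant at exactly 0.01 is retained and absence
  from a database counts as frequency 0.
* **Null-variant upgrade.** Nonsense, frameshift, canonical ±2 splice,
  initiation-codon and exon-deletion variants in genes with an
  established loss-of-function disease mechanism are upgraded to LP;
  calls are never downgraded.
* **Segregation coding.** Within each sequenced family: carried by all
  affected members → PP1 = 1 (cancer-segregating); by no affected
  member → BS4 = 1 (unaffected-segregating if an unaffected member
  carries it, otherwise unknown); by some but not all affected →
  "shared", contributing neither code; singletons and families with no
  sequenced affected member code (0, 0). The "shared" and
  no-affected-member conventions are this package's choices where the
  published coding is silent.
* **Class assignment** is a pure function of (final pathogenicity, gene
  tier, segregation label, class-4 allow-list) and therefore
  idempotent. Class 4's "sufficient literature evidence" has no
  operational definition, so it is modeled as an explicit gene
  allow-list input. Genes absent from tiers 1–3 default to tier 4.

Cohort comparisons use a two-sided Fisher exact test on
carrier/non-carrier prevalence or a two-sided Wilcoxon rank-sum test on
per-sample counts; pathway enrichment is a per-set Fisher test over
P/LP-mutated genes with Benjamini–Hochberg (BH) correction. BH is used
everywhere an FDR is required. Survival grouping assigns `class1_3`
(≥ 1 class 1–3 variant), `wnt_modifier` (P/LP variant in a
WNT-signaling gene) or `neither`; a sample qualifying for both defaults
to the risk-dominant `class1_3` with a flag, and a configuration switch
flips the convention since the published resolution of the one dual
case is not stated. Kaplan–Meier curves and the log-rank test come from
`lifelines`.

## SV consensus and CNV intersection

Two callers' single-sample callsets are matched per (chromosome, SV
type) under a size-tiered breakpoint tolerance: 100 bp for events
≤ 10 kb, 1 kb for (10 kb, 50 kb], 10 kb above — evaluated at the mean of
the two call lengths, with the stricter tier winning at the 10 kb
boundary. Each call joins at most one consensus event. The pairing is
solved as an **assignment problem** (maximum number of matches, then
minimum total breakpoint delta, via `linear_sum_assignment` with
infeasible pairs at prohibitive cost): a greedy smallest-delta sweep
was considered but is not guaranteed to reach the optimum in chained
configurations, whereas the assignment solution provably equals the
exhaustive enumeration oracle the tests check against. The merged
interval takes breakpoint midpoints (rounded down) since neither
caller's coordinates are privileged.

Panel-of-normals filtering flags a consensus event found (under the
same tolerance rule, another unstated detail resolved here) in ≥ 3
control genomes; annotation filtering flags events with annotation
score < 3 (missing scores fail by default, logged) or a population-SV
database hit. Filters only flag — `filter_status` keeps provenance and
events are never deleted, so counts are auditable. PoN and annotation
filters are record-wise, so their order does not change the outcome.

CNV consensus is the interval intersection of two callers' calls with
matching copy state, minus normalized exclusion regions
(repetitive/low-complexity), dropping residual fragments < 1 kb
(configurable). The operation is commutative and idempotent.

## Methylation preprocessing and the EWAS

Beta values (methylation fractions ∈ [0, 1]) arrive as probes ×
samples, with probe coordinates and per-sample covariates. Sample QC
removes, per cohort independently, samples beyond mean ± 3 SD on PC1 or
PC2 of the beta matrix. `residualize()` is an explicit stand-in for a
full factor-analysis correction: per-probe linear regression on the
named covariates followed by removal of the top *n* singular-vector
components of the residual matrix, re-centered to the original probe
means. It defaults to 10 latent factors at desk scale (a production
array analysis would use many more); the interface is pluggable so a
heavier factor model can be substituted. Residualized values may leave
[0, 1] slightly and are flagged as such.

The EWAS tests each probe against a binary outcome separately per
cohort, with BH per cohort; a probe is **validated** when q < 0.1 in
discovery *and* both validation cohorts. The per-probe association
test is a plug-in; the default is a vectorized two-sided Wilcoxon
rank-sum test, chosen because it is distribution-free and matches the
package's other group tests. The original analysis used a specific
variance-component association test whose exact formulation is not
reproducible from public sources; the plug-in seam is the honest
representation of that uncertainty.

## cis-CSCE discovery

For each validated probe, every SNP within ±10 kb (inclusive — window
inclusivity is this package's choice) is tested by Spearman correlation
between beta values and additive genotype codes over the samples with
both data types (pairwise-complete on missing genotypes; pairs with
< 10 complete observations are skipped). Genotypes are coded 1
(hom-ref) / 3 (het) / 4 (hom-alt): the spacing is irrelevant for a rank
correlation — the tests assert bitwise equality with 0/1/2 coding — and
is kept purely for fidelity. The strongest SNP per probe (max |ρ|,
ties → smaller p, smaller |distance|, lexicographic SNP ID) represents
it; BH runs over the retained per-probe p-values with a 0.05 cutoff.
Direction annotations: `allele_direction` from sign(ρ);
`risk_direction` from the sign of the discovery-cohort mean beta
difference (cancer − cancer-free), so probes where lower methylation
accompanies cancer are `hypomethylation_risk`.

Cancer-type association is a per-probe one-way ANOVA (singleton levels
dropped with a warning). Feature enrichment compares per-sample mean
signal over the cis-CSCE probes with means over 100,000 probes sampled
with replacement from the universe, using a paired Wilcoxon signed-rank
test per feature and Cohen's d_z = mean(diff)/SD(diff); it requires ≥ 5
paired samples for the test to be meaningful.

## Risk stratification

The unsupervised view embeds samples (UMAP with n_neighbors = 15,
n_components = 2, euclidean metric; or a deterministic full-SVD PCA,
the default, so results never depend on UMAP's seeding behaviour) and
clusters with k-means (k = 3, n_init = 10, fixed seed), testing cluster
× cancer status by χ² and survival differences by log-rank.

The supervised view trains a random forest on the external validation
cohort, tunes `max_features` (mtry) by grid search —
{⌊√p/2⌋, ⌊√p⌋, ⌊2√p⌋} clipped to [1, p] by default; the published grid
is unstated — under repeated stratified 5-fold cross-validation
(5 repeats by default; the published repeat count is unstated), then
scores the internal validation cohort and the discovery cohort (test
set). Prediction probabilities are the risk scores. AUROC and AUPRC
carry stratified-bootstrap percentile CIs (2,000 resamples by default).
The operating threshold maximizes the Youden index J = sensitivity +
specificity − 1 over observed score cutpoints; the comparison uses the
integer quantity tp·n₋ − fp·n₊ so exact ties resolve deterministically
to the smaller threshold; a reference-specificity mode reports the
smallest threshold achieving a target specificity instead, since a
published "optimal specificity threshold" can be read either way.

## The synthetic cohort generator

Defaults encode the study conditions: 47 families (~84 genomes, family
sizes geometrically weighted toward singletons), ~74% of families
segregating a deleterious TP53 allele, cancer probability 0.79 given a
variant allele; methylation cohorts of 88/122/142 samples (discovery /
internal / external) with a 47-sample WGS overlap; planted per-allele
meQTL shifts of 0.1 beta units and cancer-associated shifts of 0.15;
beta noise ≈ 0.05 on the beta scale. The default probe count is 2,000
(the package's chosen desk scale; tests that need 10,000 null probes
pass it explicitly). Betas are built on the logit scale from a bimodal
baseline, with genotype and cancer effects added on the beta scale
before the logit transform and a batch shift on 20% of probes; cis-SNPs
(3 per probe, MAF ~ U(0.1, 0.4), binomial genotypes) sit within ±10 kb
of probes spaced so windows never overlap. SV callsets carry each true
event under both caller labels with N(0, 30 bp) breakpoint jitter,
caller-private false positives on disjoint contigs, and recurrent
artifacts shared with ≥ 3 panel-of-normals controls. Survival times are
exponential with hazard multipliers 2 (class 1–3 carrier), 0.5
(WNT-pathway carrier) and 1 otherwise, censored uniformly at the
configured rate. A truth ledger records every planted feature.

What the generator does **not** emulate — and therefore what passing
tests cannot show about real data: linkage disequilibrium among
cis-SNPs (one causal SNP per planted probe, independent neighbours),
cell-type composition and age-related methylation drift, probe
cross-reactivity and array chemistry, sequencing-depth-dependent QC
metric correlations, and realistic gene/variant length distributions.
Recovery rates on synthetic cohorts are best-case power statements
under the planted effect sizes, not estimates of performance on
patient data.

## Numerical choices and degenerate inputs

Determinism: every stochastic component takes a seed; the pipeline
manifest records it, and re-runs produce byte-identical artifacts. PCA
uses full SVD (deterministic up to sign, which a symmetric ±k·SD window
ignores). Spearman correlations returning NaN (constant input) are
skipped; probes with no cis-SNP are excluded and counted. All-tied
group tests return p = 1 with a warning. Collinear residualization
covariates fall back to the pseudoinverse with a warning. Coordinates
are 1-based inclusive in memory (VCF convention) and 0-based half-open
in BED interchange, converted only at I/O boundaries; annotations
assume a single fixed genome build throughout with no liftover.

## Known limitations

The EWAS default test is a rank-sum stand-in behind a plug-in seam, not
the original association statistic. The class-4 allow-list and the
LoF-mechanism gene set are inputs, not derivations. Trans-effects
(beyond the cis window) are out of scope, as are read-level evidence
for SVs, translocations, calibration of the risk score, and
competing-risks survival modeling.
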