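# Methods

`repairimmune` re-implements, as a tested and reusable pipeline, an
immunogenomic analysis that links deleterious variants in DNA-repair
genes to tumor mutation burden (TMB), predicted neoantigen burden,
immune-cell infiltration calls from bulk expression, a 2×2
immunophenotype classification, and a combined DNA-repair/TGFB1/WNT2
score that predicts activated T-cell infiltration in lung squamous cell
carcinoma cohorts.  This note describes the models and procedures, the
parameters that matter, what the synthetic cohorts do and do not
emulate, and the numerical choices made where the design was open.

## Deleterious-variant filter and repair-pathway status

Samples are screened for somatic variants in three DNA-repair gene
lists: 15 homologous-recombination (HR) genes (ATR, ATM, CHEK1, CHEK2,
BRCA1, BRCA2, BAP1, BARD1, FANCD2, FANCE, FANCC, FANCA, RAD50, RAD51,
PALB2), 18 mismatch-repair (MMR) genes (MLH1, MLH3, MSH2, MSH3, MSH4,
MSH5, MSH6, PMS1, PMS2, PMS2L3, PCNA, EXO1, POLD1, RFC1, RFC2, RFC3,
RFC4, RFC5) and POLE.  A variant is *deleterious* when it is

* a nonsense, frameshift-indel or in-frame-indel change (no score
  needed; "indel" is treated as unqualified, so both indel classes
  count),
* a splice change — when a signed intron offset is available it must
  lie on the intronic side within 2 bp of the junction
  (offset ∈ {−1, −2}); without an offset the MAF splice classification
  is trusted, or
* a missense change with SIFT < 0.05 **or** CADD > 20 (strict
  inequalities; a missense with neither score available is treated as
  benign rather than imputed — a conservative choice that only matters
  for incompletely annotated inputs).

A pathway flag (HR/MMR/POLE) is set by ≥ 1 deleterious variant in a
listed gene; `affected_gene_count` counts *distinct* affected genes
(multiple hits in one gene count once), bounded by 34.  TMB defaults to
counting every MAF row ("all"); a "nonsynonymous" mode excluding silent
and unclassified rows is exposed because the neoantigen stage operates
on the non-synonymous subset.  The cohort is split at the median TMB;
values exactly at the median go to "low" (configurable tie rule — the
convention keeps `high` strictly above the median).

## Neoantigen calling

Only missense variants yield peptides (frameshift neo-ORFs are a
documented limitation).  For a variant at protein residue `pos`, all
9-mer windows covering the residue are enumerated — starts
`max(1, pos−8) … min(pos, L−8)` — as mutant/wild-type pairs differing
at exactly one position.  A (peptide, allele) call passes when

    mutant IC50 < 500 nM  ∧  wild-type IC50 > 500 nM  ∧  expression > 0

with mutant and wild-type compared **on the same allele** and an IC50 of
exactly 500 nM failing both strict tests.  Binding affinities and HLA
types are inputs (an affinity TSV or any callable); HLA typing and MHC
affinity prediction are out of scope.  `ToyPredictor` is a deterministic
position-weight stand-in: each allele gets a fixed 9×20 residue weight
matrix (seeded from a constant and a CRC of the allele name) and IC50 =
500·exp(0.8·score), log-centred at the 500 nM threshold so random
peptide sets span both sides of it.  Per-sample burden defaults to the
number of distinct passing mutant peptides ("peptide"); counting
passing (peptide, allele) pairs is exposed as "peptide_allele".  Both
units are monotone in the allele list.

## Infiltration calling

Per sample, genes are ranked by their cohort z-score (per-gene
standardization across samples, sample SD with n−1; zero-variance genes
get z = 0 and are flagged).  For each cell-type metagene set the
enrichment score (ES) is the signed maximum deviation of a weighted
Kolmogorov–Smirnov running sum — hits add |z|^α (α = 1 by default,
α = 0 gives a rank-only statistic) normalized by the total hit weight,
misses subtract 1/(N − N_hits).  Because the statistic is single-sample,
sample-label permutation is impossible; the null is B random gene sets
of equal size (B = 1000 by default, shared across sets of equal size
within a sample), and p = (1 + #{null ES ≥ observed}) / (B + 1), a
one-sided test matching the directional "positively infiltrating" call.
p-values are converted to Storey q-values per sample across cell types
(a global batching mode is available), and a cell type is called
infiltrating at q ≤ 0.10.

## Immunophenotype groups and the combined score

Crossing repair-variant status with activated-T-cell infiltration
(activated CD4 **or** activated CD8 by default; "both"/"cd4"/"cd8"
conventions available) partitions the cohort into groups I–IV
(I: no variant/not infiltrated, II: variant/not infiltrated,
III: no variant/infiltrated, IV: variant/infiltrated).  The combined
score awards one point each for a TGFB1 z-score strictly above the
cohort median, a WNT2 z-score strictly above the median, and the
absence of any repair-gene variant; medians are taken over all cohort
samples, an exactly-median z contributes nothing, and scores ≤ 1 are
"low" — the stratum predicted to be T-cell infiltrated.

Panel analyses delegate to the statistics layer: per-gene one-way ANOVA
with Tukey-adjusted pairwise comparisons across groups (the
immunosuppressive TGF-β/Wnt panel: APC, CTNNB1, WNT1, WNT2, WNT3A,
WNT5A, WNT7A, TGFB1, TGFB2, TGFB3, VEGFA), two-group t-test volcano
tables with Storey q over a gene panel, and per-level pooled
two-proportion z-tests of a binary flag against a categorical subtype
label with Storey adjustment across levels.

## Statistical primitives

* **Two-proportion z**: pooled variance, no continuity correction;
  undefined (reported missing) when the pooled proportion is 0 or 1.
* **t-test / ANOVA / Tukey / Pearson**: scipy implementations
  (`ttest_ind`, `f_oneway`, `tukey_hsd`, `pearsonr`); with two groups
  the Tukey pairwise p equals the ANOVA p.
* **Storey q**: single-λ estimator at λ = 0.5,
  π̂0 = min(1, #{p > λ}/((1−λ)m)), with the step-up running minimum;
  when π̂0 = 1 the result is exactly Benjamini–Hochberg.  The single-λ
  estimator is unstable for small batches — with a handful of p-values,
  π̂0 collapses to zero whenever all p ≤ λ, declaring everything
  significant — so for m < 20 the implementation falls back to π̂0 = 1
  (plain BH).  Both λ and the fallback size are configurable.
* **Multinomial logistic regression**: statsmodels maximum likelihood
  with Wald standard errors and p-values, outcome levels against a
  caller-chosen baseline; rank-deficient designs are rejected and
  non-convergence is flagged, never silent.
* **Survival**: Kaplan–Meier curves and the log-rank test via
  lifelines; the univariate hazard ratio comes from an in-package
  Newton–Raphson fit of the Cox partial likelihood with **Breslow** tie
  handling (CI = exp(β̂ ± 1.96·SE) from the inverse observed
  information).  lifelines' Efron-ties fit serves as an independent
  cross-check in the tests (the two coincide on untied data).  Monotone
  partial likelihoods (separation) and arms without events report a
  missing HR while the log-rank test is still computed.

## Synthetic cohorts

The generator emulates the statistical structure of the analyzed study
so every stage can be exercised and scored without external data.
Defaults (fixed once, as the study conditions):

| parameter | default | meaning |
|---|---|---|
| `n_samples` | 178 | cohort size |
| `tmb_baseline_mean` | 232 | mean mutation count, non-carriers |
| `tmb_dispersion` | 2 | negative-binomial shape k (var = m + m²/k) |
| `p_repair_carrier` | 0.3 | fraction with a planted deleterious repair-gene variant |
| `tmb_fold_change` | 2.5 | burden multiplier for carriers |
| `n_cell_types` / `metagene_set_size` | 24 / 10 | immune metagene sets |
| `infiltration_prevalence` | 0.3 | per cell type |
| `metagene_shift` | 2.0 | log-scale SD units added to a cell type's metagenes in its infiltrated samples |
| `tgfb1_wnt2_shift` | 1.5 | SD added to TGFB1/WNT2 in samples **without** activated-T infiltration |
| `neoantigen_rate` | 0.15 | fraction of eligible missense variants given a planted strong binder |
| `dfs_hr_high_neoantigen` | 0.64 | disease-free-survival hazard ratio, high vs low planted neoantigens |
| `censoring_rate` | 0.3 | exponential censoring fraction |

Mutation counts are negative-binomial (overdispersed, as empirical
tumor burdens are; Poisson is the k → ∞ limit).  Background mutations
draw from a gene pool that *excludes* the 34 repair genes, so planted
carrier flags are exactly recoverable by the deterministic filter —
carrier recovery is a correctness check, not a statistical one.
Carriers receive 1–3 planted deleterious variants (nonsense, or
missense with SIFT/CADD beyond the cutoffs) in random repair genes.
Expression is log-normal (σ_log = 0.5) with shifts applied on the log
scale; a subset of mutation genes carries simulated protein sequences,
and planted strong binders override the toy predictor's affinities for
a chosen window/allele.  Survival is exponential with exponential
censoring calibrated to the requested censoring fraction; MMR carriers
have 3-fold odds of a "secretory" subtype label.  By default carrier
and infiltration flags are sampled independently; setting
`score_infiltration_or` instead assigns activated-CD4/CD8 flags from a
two-point logistic model on the planted combined score, planting a
chosen odds ratio between score ≤ 1 and infiltration (in that mode the
TGFB1/WNT2 shift is not additionally applied, since the association is
already planted through the flags).

What the generator does **not** emulate: real mutational signatures,
gene–gene expression covariance beyond the planted shifts, fractional
immune deconvolution, batch effects, or the 812-metagene compendium
(metagene sets are synthetic labels).  Passing recovery tests therefore
demonstrates correctness and calibration of the pipeline's statistics
under its stated generative model, not fidelity to any real cohort.

## Problem sizes and numerical choices

The test suite validates each stage against independent oracles:
brute-force re-scans of the variant and neoantigen filters on ~1,000
records, the closed-form window count min(pos, L−8) − max(1, pos−8) + 1,
a hand-computed running-sum example (ES = 0.8), ANOVA versus a 5,000-rep
label-permutation reference, the Cox β̂ versus grid maximization of the
Breslow partial likelihood (1e−4), and Monte-Carlo calibration: type-I
error of the two-proportion z, t, ANOVA and log-rank tests in
[0.03, 0.07] at α = 0.05 over 1,000 null replicates each; planted TMB
fold-change 2.5 detected at p < 0.01 in ≥ 95/100 cohorts of n = 200;
a planted odds ratio of 5 between low combined score and infiltration
detected at q < 0.05 in ≥ 90/100 cohorts; hazard ratio 0.6 recovered
within [0.45, 0.80] in ≥ 90/100 simulations at 500 per arm with ~30%
censoring; and a no-signal infiltration rate ≤ 0.12 at q ≤ 0.10
averaged over 200 replicates (300 genes × 10 sets, B = 200).  Smaller
gene/sample counts than the defaults are used inside simulation loops
to keep the suite fast; single-run checks use the default conditions.

Other numerical conventions: permutation p-values use the +1/(B+1)
convention so p > 0 always; q-values are monotone in p by construction;
ES ties resolve to the first maximal deviation in ranking order
(stable mergesort ranking makes this deterministic); all randomness
flows through `numpy.random.default_rng` seeds, and identical
parameters reproduce byte-identical synthetic bundles and pipeline
outputs.

## Known limitations

* Frameshift/indel-derived neo-ORFs produce no peptides.
* The enrichment statistic and random-gene-set null are explicit
  substitutes for an unspecified GSEA configuration; they are validated
  by parameter recovery, not by matching any published call set.
* The hazard-ratio model is univariate; no multivariable adjustment.
* No germline/somatic distinction beyond the MAF, no copy-number or
  epigenetic silencing of repair genes, and no HGNC symbol aliasing.
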