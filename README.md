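# repairimmune

Deficient DNA repair — mismatch repair (MMR), homologous recombination
(HR) or polymerase epsilon (POLE) — raises a tumor's mutation burden
and, with it, the supply of mutant peptides (neoantigens) the immune
system can recognize.  Whether that translates into actual T-cell
infiltration depends on the tumor microenvironment: TGF-β and Wnt
signaling can exclude T cells from otherwise antigenic tumors.
`repairimmune` is a Python toolkit for analyzing this interplay in
tumor cohorts (bulk expression + somatic variants + clinical data),
built for lung squamous cell carcinoma-style analyses but generic over
inputs.

It provides, as a library and a CLI:

* **Repair status** — deleterious-variant filtering (nonsense, splice
  ≤ 2 bp intronic, indels, or missense with SIFT < 0.05 / CADD > 20)
  over curated HR/MMR/POLE gene lists; per-sample pathway flags,
  affected-gene counts, tumor mutation burden (TMB) and the median
  split.
* **Neoantigens** — mutant/wild-type 9-mer windows around missense
  sites, called against ≤ 6 HLA alleles with the filter
  `mut IC50 < 500 nM ∧ wt IC50 > 500 nM ∧ expression > 0`; per-sample
  burden.  Affinities are inputs (a deterministic toy predictor is
  included for tests and simulations).
* **Infiltration** — per-sample, per-cell-type enrichment of immune
  metagene sets via a weighted KS running-sum score on the cohort
  z-score ranking, a random-gene-set permutation null, and Storey
  q ≤ 0.10 calls; co-infiltration (phi) correlations.
* **Immunophenotype** — the 2×2 groups I–IV (repair variant ×
  activated-T infiltration) and the combined score
  `[z_TGFB1 > median] + [z_WNT2 > median] + [no repair variant]`,
  where score ≤ 1 predicts infiltration.
* **Statistics** — pooled two-proportion z, Student/Welch t, ANOVA +
  Tukey, Pearson, Storey q-values, multinomial logistic regression
  (Wald output), Kaplan–Meier / log-rank / univariate Cox (Breslow
  ties) hazard ratios.
* **Synthetic cohorts** — a generator that emits a complete plain-text
  bundle (MAF, expression TSV, GMT, affinity TSV, protein FASTA,
  clinical TSV) with planted, recoverable effects, plus a scorecard
  for parameter-recovery testing.

See `docs/methods.md` for the models, defaults and limitations.

## Worked example

Simulate a small cohort and run every stage:

```bash
repairimmune simulate --out bundle/ --seed 7
repairimmune run-all --out results/ --seed 7
```

or in Python:

```python
from repairimmune.pipeline import RunConfig, run_all

config = RunConfig(simulate=True, seed=3, permutation_B=200,
                   sim_params=dict(n_samples=30, tmb_baseline_mean=20,
                                   n_genes=400, n_cell_types=6,
                                   n_mutation_genes=60, n_protein_genes=8))
outputs = run_all(config)
print(outputs["summary"]["group_sizes"])
print(outputs["summary"]["tmb_carrier_t"])
```

which prints

```
{'III': 13, 'II': 8, 'I': 7, 'IV': 2}
{'t': 5.037320272556324, 'p': 2.504303396143105e-05}
```

— the cohort partitioned into the four immunophenotype groups (here 10
of 30 samples carry a deleterious repair-gene variant, groups II + IV),
and the carrier-vs-noncarrier TMB contrast (t = 5.04, p ≈ 2.5e-5: the
planted 2.5-fold burden elevation in carriers is recovered).  The full
output bundle additionally holds per-sample repair status, neoantigen
burden, infiltration calls (sample × cell type with ES/p/q), phenotype
groups with combined scores, panel ANOVA tables, a differential
expression table, survival contrasts and a manifest stamped with the
configuration hash and seed.

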