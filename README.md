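# epipair

Two-stage pairwise SNP–SNP epistasis analysis for case-control GWAS,
restricted to a candidate panel of cancer-related genes.

Large genome-wide interaction scans face a brutal multiple-testing burden:
among ~35,000 SNPs inside ~2,000 oncogenesis-related genes there are hundreds
of millions of pairwise tests. `epipair` implements the standard two-stage
answer as a tested, reusable pipeline:

1. **Fast allelic screen.** For each SNP pair, the 2×2 allele-pairing table
   (double heterozygotes split evenly across their two possible phases) gives
   an allelic odds ratio within cases and within controls; the contrast

   *Z = (ln OR₁ − ln OR₀) / √(SE₁² + SE₀²)*

   is an imprecise-but-fast screen run exhaustively over all cross-gene pairs
   via matrix products.
2. **Logistic interaction model.** Screen survivors get the regression

   logit P(D=1) = β₀ + β₁·snp₁ + β₂·snp₂ + β₃·snp₁·snp₂ + Σᵢ βᵢ·covᵢ

   on additive dosages (0–2), fitted by an internal IRLS with separation
   detection; exp(β₃) is the interaction odds ratio, tested with Wald z.
3. **Replication + meta-analysis.** Survivors are refitted in independent
   replication cohorts; inverse-variance fixed-effect pooling with Cochran's
   Q decides replication (meta p < 0.05 and direction-consistent ORs), and a
   joint meta over all cohorts gives the final estimate. Standard errors can
   also be recovered from published (OR, p) cells: se = |ln OR| / Φ⁻¹(1−p/2).
4. **Multiplicity.** The effective number of independent SNPs (Meff) comes
   from per-block LD eigen-spectra (each eigenvalue contributes
   𝟙(λ≥1) + frac(λ)); the family-wise threshold is α / [Meff·(Meff−1)/2].
5. **Characterization.** Significant pairs get stratified single-SNP
   association by partner carrier status, joint-genotype odds ratios versus
   the 0/0 reference, and a dominant-coded linear interaction model on
   expression traits (eQTL view).

A synthetic-cohort generator (LD blocks, exact Hardy–Weinberg, logistic
disease risk with planted interactions, covariates, expression traits) makes
the whole design testable without any controlled-access genotype data.

## Worked example

```sh
epipair simulate --seed 7 --cases 4000 --out fixtures/
```

writes three cohorts (`discovery`, `replication1`, `replication2`) with one
planted protective interaction (OR 0.4 between `snp0010` and `snp0310`, MAFs
0.05/0.20). A YAML config pointing at those tables then drives the whole
scan:

```sh
epipair run --config run.yaml
```

```
pipeline done: {'snps_retained': 500, 'pairs_eligible': 122500,
 'pairs_screened': 675, 'pairs_stage2': 670, 'pairs_replicated': 9,
 'pairs_significant': 1} (m_eff=440, threshold=5.18e-07); results in out/
```

Reading the funnel: of 122,500 eligible cross-gene pairs, 675 pass the
allelic screen, 670 pass the discovery regression, 9 replicate with
consistent direction, and exactly one — the planted pair — clears the
Bonferroni bound implied by the 440 effective independent SNPs. `joint.tsv`
holds per-cohort and pooled ORs/p-values per pair; `report.json` holds the
stage counts, Meff, threshold and config hash. (The desk-scale thresholds
`p_screen: 0.05`, `p_regress: 0.01` in the YAML are deliberate — see
`docs/methods.md` on scaling the funnel to cohort size.)

The same stages are importable directly: `epipair.screen_pairs`,
`epipair.interaction_test`, `epipair.fixed_effect_meta`,
`epipair.effective_snp_count`, `epipair.run_pipeline`, …

## Layout

```
src/epipair/
  core_io.py              VCF/TSV/BED readers, results tables, data model
  snp_filtering.py        gene-interval mapping + MAF filter
  fast_epistasis.py       stage-1 allelic Z screen (vectorized)
  logistic_interaction.py stage-2 IRLS logistic interaction fit, genotype PCs
  meta_analysis.py        fixed-effect pooling, Q/I², replication rules
  multiplicity.py         Meff from LD eigenvalues, Bonferroni arithmetic
  downstream.py           stratified / joint-genotype / expression views
  synthetic_data.py       multi-cohort simulator with planted interactions
  pipeline.py, cli.py     end-to-end orchestration + `epipair` CLI
```
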