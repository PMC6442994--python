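# Methods

## The statistical design

`epipair` implements a two-stage gene–gene (epistasis) interaction scan for
case-control genetic data restricted to a candidate gene panel. The unit of
analysis is a cohort (`GenotypeStudy`): a samples × variants matrix of
minor-allele dosages in [0, 2] (hard calls or imputed dosages, NaN for
missing), case/control status, and an optional covariate table. The first
cohort is the discovery set; any further cohorts are replication sets.

### Panel filtering

SNPs are kept when (a) their position falls inside a retained gene's
transcript interval (1-based inclusive internally; BED inputs are 0-based
half-open and converted on read) and (b) their minor allele frequency is at
least `maf_min` (default 0.005; rarer variants carry almost no information
for a product-term test). MAF is computed from the cohort's own samples,
cases and controls pooled, which makes orientation deterministic; a tie at
exactly 0.5 is broken toward the later-sorting allele string. A SNP inside
overlapping genes belongs to all of them; a pair is eligible for the scan
only when the two SNPs' gene assignments differ (within-gene pairs are
confounded by LD and excluded by default; `within_gene=True` lifts this).

### Stage 1 — allelic Z screen

For SNPs with hard calls a, b ∈ {0,1,2}, each individual contributes
a·b, a·(2−b), (2−a)·b, (2−a)·(2−b) to the four cells of an allele-pairing
table, scaled by ½ so each individual carries weight 2. This is the standard
approximation for unphased data: a non-double-heterozygote's two allele
pairings are determined; a double heterozygote is split evenly over its two
possible phases (the test suite checks this against a direct phase-enumeration
oracle over every genotype configuration). The allelic log odds ratio and its
Woolf standard error (Haldane–Anscombe +0.5 on every cell when any cell is
zero) are computed within cases and within controls, and

    z = (lnOR_case − lnOR_control) / sqrt(se_case² + se_control²)

is referred to the standard normal. Dosages are rounded to hard calls at this
stage only. All pairs are evaluated at once through three matrix
cross-products (including pairwise complete-case handling of missing calls),
so a 500-SNP panel screens in well under a second and results are independent
of sample and execution order.

The screen's null is *not* exactly nominal: measured once by Monte Carlo
(2,000 independent null pairs, n = 1,000), the rejection rate at α = 0.05 is
0.006 — the even phase split under-disperses the statistic, making the screen
conservative. That empirical rate is frozen as the reference value in the
calibration test (exact-binomial 99% band); inference never rests on the
screen, which exists to cut the pair count before the regression stage.

### Stage 2 — logistic interaction model

Screen survivors are fitted with
logit P(D=1) = β₀ + β₁g₁ + β₂g₂ + β₃g₁g₂ + Σᵢβᵢcovᵢ on additive dosages
(imputed dosages are used as-is here). The null β₃ = 0 is tested with a Wald
z statistic; exp(β₃) is the per-cohort interaction odds ratio. Covariates are
entirely caller-specified (genotype principal components from
`compute_pcs`, age/sex/smoking, …) — nothing is hard-coded.

The fitter is an internal IRLS with step halving: convergence when
max |score| < 1e-8 or the relative log-likelihood change is below 1e-10,
at most 50 iterations; the covariance is the inverse observed information at
the optimum. Rank-deficient designs raise an error naming the collinear
columns (a constant partner SNP is the canonical case: its interaction column
is proportional to the other SNP). Quasi-complete separation is flagged when
any genetic coefficient exceeds 30 in absolute value; such fits are reported
as non-converged with p = NaN rather than silently dropped or penalized —
the MAF filter exists precisely to make these rare. The tolerances and the
|β| > 30 heuristic are fixed constants of the implementation. The suite
verifies the MLE against a BFGS maximization of the exact likelihood and
against statsmodels `Logit`, which is never used in the pipeline itself.

### Replication and meta-analysis

Per-cohort estimates are pooled on the log-OR scale with inverse-variance
weights wᵢ = 1/seᵢ²; Cochran's Q (df = k−1) and I² = max(0, (Q−df)/Q)
quantify heterogeneity. Fixed-effect pooling (not random-effects) matches the
design's single-joint-OR reporting. A pair *replicates* when the
replication-cohorts meta p is below 0.05 **and** the OR direction agrees
across discovery and every replication cohort. The joint meta then includes
the discovery cohort, which knowingly carries winner's-curse bias — the
run report states this. Pairs that survive discovery but fail replication are
kept in an appendix table.

When only a published (OR, p) cell is available for a cohort, the SE is
recovered as |ln OR| / Φ⁻¹(1 − p/2), exact for a Wald summary; when a p-value
underflows printed precision the SE must come from the fit instead.

### Multiplicity

The effective number of independent SNPs uses the eigen-spectrum of the
inter-SNP Pearson correlation matrix in consecutive non-overlapping blocks
(default 200 SNPs, never spanning chromosomes): each eigenvalue λ contributes
𝟙(λ ≥ 1) + (λ − ⌊λ⌋), a Li–Ji-style rule under which an uncorrelated block
contributes its size and a perfectly correlated block contributes 1.
Eigenvalues within 1e-8 of an integer are snapped before flooring (the rule
is discontinuous at integers and a block of duplicated SNPs would otherwise
count ~2). Meff is rounded half-up to an integer, the pairwise test count is
Meff·(Meff−1)/2, and the per-test threshold is α divided by that count.
Residual inter-block LD slightly inflates Meff, i.e. the threshold errs
conservative. Constant SNP columns are treated as independent with a warning.

### Downstream characterization

*Stratified association*: samples are split by dominant-coded genotype
(carrier = dosage ≥ 0.5) at the conditioning SNP; within each stratum a
logistic model of status on the tested SNP's additive dosage (+ covariates)
gives the stratum OR and Wald p. Strata with fewer than 10 cases or 10
controls are reported as not estimable.
*Joint-genotype ORs*: one logistic model with indicators for carrier patterns
1/0, 0/1, 1/1 against the 0/0 reference (OR ≡ 1); empty groups are reported
as not estimable rather than fitted.
*Expression interaction*: OLS of an expression trait on d₁ + d₂ + d₁·d₂
(+ covariates) with dominant coding, p from the product term's t statistic;
group means are reported for the four joint-carrier groups and the result is
flagged fragile when any group has fewer than 5 samples. Pre-adjusting
expression for covariates by residualization is equivalent to supplying them
to the model and is left to the caller.

## The synthetic generator

`synthetic_data` emulates what the analysis assumes about real cohorts:

* **Genotypes.** Two independent haplotypes per individual per LD block; a
  haplotype is drawn by thresholding a correlated standard normal vector at
  Φ⁻¹(maf) per SNP. This guarantees exact Hardy–Weinberg equilibrium per SNP
  (the allelic screen's null depends on it) and exact marginal MAFs, with
  block correlation models independent, AR(ρ) and equicorrelated(ρ).
* **Disease.** A source population receives logistic risk with main effects,
  planted interactions (additive×additive or dominant×dominant coding) and
  covariate effects; cases and controls are then drawn without replacement to
  the exact requested counts (retrospective design). The source population
  grows in batches until both arms are covered, since planted effects shift
  realized prevalence away from the intercept-implied value.
* **Expression.** trait = baseline + effects on dominant-coded genotypes +
  δ·d₁·d₂ + covariate effects + N(0, σ²) noise.
* **Determinism.** One integer seed drives everything through numpy
  seed-sequence spawning; identical configs give bit-identical cohorts.

What it does **not** emulate: coalescent-realistic haplotype structure,
imputation error, genotyping batch effects, admixture beyond simple block
divergence, or case-control ascertainment artifacts. Passing tests therefore
demonstrate the statistical machinery is correct under the stated model, not
that any particular real-data finding is right.

### Desk-scale demonstration conditions

`demo_config` is the standing test bed: 500 SNPs in 50 genes (ten 50-SNP
blocks cycling independent / AR(0.8) / equicorrelated(0.3) over two
chromosomes), MAFs uniform on (0.01, 0.5), one planted additive×additive
interaction at OR 0.4 between SNPs at MAF 0.05 and 0.20 in two uncorrelated
blocks, two standard-normal covariates (one with a real effect), baseline
prevalence 0.15. Discovery is 4,000 cases / 3,000 controls; replication
cohorts are 2,400/2,600 and 800/880. The replication cohorts are scaled
*less* aggressively than discovery on purpose: a full-size design can afford
proportionally smaller replication sets because its discovery arm is ~5×
larger, while at desk scale the replication meta-analysis needs these sizes
to retain power for an OR-0.4 interaction.

For the same reason the demonstration thresholds are scaled: the production
defaults (`p_screen` 1e-6, `p_regress` 1e-5) are calibrated for tens of
thousands of samples, where the planted effect yields discovery Z ≈ 8–10; at
4k/3k it yields screen Z ≈ 3.8, so the demo runs use `p_screen` 0.05 and
`p_regress` 0.01. The replication rule (meta p < 0.05, direction-consistent)
and the Bonferroni significance bound are *not* relaxed. Under these
conditions the end-to-end suite requires the planted pair to pass replication
— and no unplanted pair to reach the Bonferroni threshold — in ≥95% of 20
seeded runs.

## Numerical and design notes

* Missing genotypes use complete-case handling per SNP pair (screen:
  pairwise over the cross-product matrices; regression: listwise over the
  pair plus covariates). PCs and LD correlations mean-impute missing calls.
* p-values are floored at the smallest positive double so downstream log
  transforms never see zero.
* Screen output ordering is fully deterministic: ascending p, ties broken by
  (snp1, snp2) ids.
* PCs come from the SVD of the column-standardized dosage matrix
  (zero-variance SNPs dropped); the sign convention makes each component's
  largest-magnitude loading positive.
* Multi-allelic VCF records are skipped, not decomposed (array-genotyped
  panels are biallelic); the DS FORMAT field, when present, takes precedence
  over GT.
* The module-level example of type-I behaviour at α = 1e-5 over 10⁶ pooled
  null fits is beyond desk scale; calibration is instead checked at
  α = 0.05/0.01 over 2,000 replicates in the module tests and at α = 0.05
  over 10⁴ replicates at n = 2,000 in the acceptance suite.

## Known limitations

* The allelic screen's conservativeness means marginally sub-threshold true
  interactions can be lost at stage 1; the regression stage is authoritative,
  and the screen threshold should be chosen with cohort size in mind.
* Fixed-effect pooling assumes one common effect; strong heterogeneity shows
  up in Q/I² but does not switch the model.
* Separated pairs are flagged, not rescued (no Firth penalization).
* `stratify_by_subtype` retains all controls in every stratum, so subtype
  analyses share controls and are not independent across strata.
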