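# Methods

## The generative model and what it emulates

The synthetic-data module (`twindmr.simulate`) generates a desk-scale
analogue of a monozygotic-twin methylation study.  Per bin *b* and sample
*j* in family *i*:

    y_bij = μ_b + β_b·case_j + Σ_c γ_c·cov_cj + u_bi + e_bij

* `μ_b ~ N(0, 1)` is a bin baseline (removed by normalization).
* `β_b` equals `dmr_effect` (default **0.8** normalized units) at the
  `n_planted_dmrs` planted bins and 0 elsewhere.
* `u_bi ~ N(0, sigma_family_sq)` is a **bin-specific** family intercept
  shared by co-twins (bins are therefore independent given the design —
  deliberately so, to make genome-wide calibration measurable).
* `e_bij ~ N(0, sigma_resid_sq)` is residual noise.  Defaults
  `sigma_family_sq = sigma_resid_sq = 1` give a within-pair intraclass
  correlation (ICC) of 0.5 at null bins.

The default design mirrors an adult twin cohort: 17 disease-discordant,
3 concordant-case and 7 concordant-control MZ pairs (54 discovery
samples), plus 42 unrelated cases and 221 matched controls as a
replication cohort.  Covariates: age ~ U(40, 80) and sex ~ Bernoulli(0.5)
shared within pair; BMI ~ N(27, 4²) with correlation 0.5 between co-twins.
Covariate effects default to small per-unit coefficients (age 0.005/yr,
sex 0.05, BMI 0.01) so that adjustment matters without dominating.
Discordance is assigned, not emergent: the design conditions on it.

Genotypes are binomial(2, MAF) dosages drawn once per family — MZ co-twins
are genetically identical by construction.  Up to half of the SNPs are
each assigned a planted DMR bin, placed within its cis window, and add
`cis_effect` per alternate allele to that bin.  Metabolites (default 503,
the panel size of the emulated study) are baseline + noise, except a small
coupled set tied to the top planted DMR; round-robin run-day labels and a
multiplicative per-day scale give the run-day normalization real work.

One root seed spawns a named child stream per component (methylome,
genotypes, annotations, fragments, metabolites, mediation), so any stage
can be regenerated alone and identical (seed, config) pairs are
byte-reproducible, including written files.

**What the generator does not emulate** — and hence what passing tests do
not establish about real MeDIP-seq data: CpG-density-dependent capture
efficiency, count overdispersion and GC bias, spatial autocorrelation of
methylation along the genome, correlated bins, cell-composition mixtures,
population structure and linkage disequilibrium, and non-Gaussian
metabolite distributions.  Tests on this generator validate the
statistical machinery, not robustness to those artefacts.

## Mixed-model fitting and inference

Families have size ≤ 2, so the per-bin covariance is block diagonal and an
orthonormal pair sum/difference transform whitens every block up to scalar
weights (1+ρ for pair sums, 1−ρ for pair differences, 1 for singletons),
where ρ = σ²_f/(σ²_f+σ²_e).  The restricted likelihood is profiled over ρ
and minimized by a coarse grid (65 points for the vectorized scan, 513 for
single fits) followed by 45 golden-section iterations, bracketing the
optimum to ~1e-11 in ρ; total variance is profiled out in closed form.
The scan path evaluates the objective for all bins simultaneously (batched
2×2-block algebra), which is why a 4,000-bin scan takes well under a
second.

Inference on the disease coefficient uses a Wald statistic with two
small-sample corrections, both standard in the mixed-model literature:

* **Satterthwaite degrees of freedom**, from the delta-method variance of
  the contrast-variance estimate under the inverse REML information of
  (σ², ρ) (central finite differences in ρ; stencils shifted inward at the
  ρ ∈ {0, 1} boundary; degenerate information falls back to residual df).
* **Kackar–Harville standard-error correction** for plug-in GLS:
  Var_adj(β̂) = Var_GLS + (∂β̂/∂ρ)²·Var(ρ̂).

Without these, the 54-sample twin design shows null tail ratios of
~1.25–1.3 at p ≈ 0.005–0.02 and the realized false-discovery proportion at
the q ≤ 0.25 tier exceeds its nominal level; with them, tails are within
Monte-Carlo error of nominal and BH control holds.  Plain `residual`
(t with n−p df) and `normal` references remain available via `df_method`.
A *known limitation*: with the 27-pair discovery set alone, residual
miscalibration leaves the mean FDP at the suggestive tier near 0.28; the
documented FDR-control property is therefore stated for the full default
cohort (317 samples), where it holds.

REML rather than ML is used for the variance components (small-sample
standard); the Wald test rather than a likelihood-ratio test keeps the
scan a single optimization per bin.

## Design-contrast property

A pair-shared exposure is cancelled exactly by within-pair differencing —
the defining property of the giDMR construction.  The generator's
`shared_env_effect` plants such an exposure at the planted bins in every
case-containing *family* (both co-twins of discordant and concordant-case
pairs, and unrelated cases, for whom the family is the individual).  The
cohort-level mixed-model scan detects it (power ≈ 0.9 at shift 0.8) while
the within-pair scan stays at its type-I rate.  Restricted to twin pairs
only, the per-bin REML legitimately absorbs a pair-level shift into the
family variance component, capping cohort-scan power near 0.35 at this
design size — a real feature of the design, documented rather than hidden:
pair-level environmental effects are close to unidentifiable from 27 pairs.

## Quantification conventions

Coordinates are 0-based half-open everywhere; BED I/O is native.  Bins are
500 bp sliding every 250 bp; trailing windows shorter than the step are
dropped.  A fragment counts in every bin it overlaps by ≥ 1 bp.  RPM is
count / (total mapped fragments / 10⁶).  Normalization to N(0,1) is a
per-bin z-score by default (the literal reading of the convention), with a
rank-based inverse-normal transform (Blom offset) as an option for
heavy-tailed signal; zero-variance bins are excluded and counted, never
silently dropped.  AMS (CpG-density-adjusted signal) is accepted as an
externally supplied matrix; its computation is out of scope.

## Enrichment constructions

Fisher tests are one-sided toward enrichment via the hypergeometric upper
tail (two-sided available by flag); the unit for the region test is the
bin, and a bin is "in a window" on ≥ 1 bp overlap.  The per-gene summary
p-value for rank resampling is the minimum across assigned DMRs (a
mean-rank variant is available).  All permutation and resampling p-values
carry the add-one correction, so the minimum attainable p is 1/(n+1) — 20
TSS permutations, the historical default, can therefore never report
p < 1/21, and a warning is attached below 999.  The TSS permutation
preserves per-chromosome TSS counts and relocates uniformly.  The "x% more
than expected by chance" reading is exposed as `(fold − 1)·100`.

## Causal inference test

Components: p1 (T ~ L), p2 (M ~ L | T), p3 (T ~ M | L), p4 (equivalence:
L ⊥ T | M), omnibus = max.  Binary traits are modelled by linear
probability regressions throughout so every component reduces to a
partial-correlation F statistic (a logistic option exists for the three
parametric components).  The equivalence component permutes **the mediator
within genotype strata** (dosage classes, or deciles for fractional
dosage): this preserves the joint (L, M) distribution while severing any
M–T link, so the permuted F statistics for L in T ~ M* + L represent
"no-mediation" data in which L keeps its full marginal effect.  Under a
causal chain the observed F collapses once the real mediator is adjusted
for, giving p4 = (1 + #{F* ≤ F_obs})/(B+1) near its minimum; under
independent pleiotropy conditioning on M changes little and the observed
and permuted statistics are exchangeable, leaving p4 uniform.  Scenario
simulations (liability-threshold binary trait, 50% prevalence, n = 200,
B = 1000) separate the architectures cleanly: causal chains are called at
~98%, pleiotropic and reactive wirings at ≤ 5%.  The permuting-the-locus
alternative was evaluated and rejected: it makes both observed and
permuted statistics central under the chain, leaving the equivalence
component powerless.

Mediation architectures are generated by a dedicated triple simulator
rather than by rewiring the cohort's disease labels, which are fixed by
the assigned-discordance design.

## Metabolite stage

Values are divided by their per-(metabolite, run-day) median and then
standardized per metabolite; the normalization is scale-invariant to
per-day multiplicative drift by construction and idempotent up to the
final standardization.  Discovery uses the exact Wilcoxon signed-rank null
for ≤ 25 usable pairs (zero differences dropped by the standard
convention, counts logged) and the continuity-corrected normal
approximation above; the reported statistic is W⁺, the positive-difference
rank sum.  Metabolites with discovery p < 0.05 are carried to an OLS
replication on methylation with age/sex/BMI adjustment.  The two stages
combine by direction-signed Stouffer with √n weights (the natural choice
when only p, direction and sample size are retained per stage; Fisher's
combination ignores direction), Bonferroni-corrected over the
meta-analysed metabolites.  A documented variant correlates within-pair
metabolite differences with within-pair methylation differences
(Spearman), for the reading of the discovery stage that conditions on the
chosen DMR.

## Numerical and degenerate-input choices

* ρ is searched in [0, 0.9999]; boundary solutions snap to exactly 0.
* BH q-values: step-up `min_{j≥i} p_(j)·m/j`, capped at 1; p-values are
  clipped away from 0 at the float minimum before adjustment.
* Zero-variance bins, SNPs, covariates and metabolite groups are flagged
  untestable or skipped with logged counts, never assigned p = 0.
* Collinear designs raise a model error naming the cause (e.g., a
  confounder identical to disease status).
* Ties in rank statistics use average ranks.
* Replication records missing from the replication matrix are flagged and
  excluded from summary denominators; a discovery effect of exactly 0
  makes direction agreement undefined and is flagged ambiguous.

## Problem sizes used in the packaged checks

The test suite and `scripts/acceptance.py` run at desk scale, chosen so
each property is measured with meaningful Monte-Carlo precision: 2,000
bins for type-I calibration; 200 (tests) / 100 (script) replicates of 600
bins with 5% planted effects for FDR control; 50 six-pair instances for
the optimizer-vs-grid oracle; 500 bins for effect recovery and 600 for ICC
recovery; 1,000 random tables for the Fisher oracle; 200 replicates of 199
permutations for permutation-test calibration; 200 × 3 scenario replicates
at B = 1,000 for the causal inference test.  The full simulated pipeline
(2,000 bins, 317 samples, all stages) completes in a few seconds on one
CPU.
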