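# Methods

## Data model

Methylation is quantified as log-scale normalized coverage (logRPKM) over
non-overlapping 150-bp bins. `log_rpkm` uses base 10 with a pseudocount
offset of 1 on the RPKM scale (`log10(RPKM + 1)`, so zero coverage maps to
0). Neither the base nor the offset is canonical for this assay class; both
are configuration, and every downstream inference is affine-invariant per
region, so the choice only sets the absolute scale of coefficients.
Matrices must be complete — missing values are rejected at load time rather
than imputed, since a retained-bin matrix is by construction restricted to
bins with sufficient coverage in all samples.

Coordinates are 0-based half-open (BED convention). A bin is *genic* when
it carries at least one of {promoter, exon, intron, UTR}; *intergenic* is
the complement. `cpg_island` and repeat labels (rRNA, LTR) are orthogonal
to that split, so a bin may be, e.g., both exon and CpG island.

## Per-region mixed model

Each bin is fitted independently with

    logRPKM ~ age + BW0 + medianLifeSpan + (1 | StrainDiet)

— fixed effects for age at collection (days, untransformed), baseline body
weight (grams) and the strain-by-diet group's median life span (days, from
the parallel longevity cohort), plus a random intercept per strain-by-diet
group, estimated by REML. Assumptions: Gaussian residuals on the log scale,
a common residual variance within a bin, and exchangeable group intercepts.
medianLifeSpan is constant within a group and therefore partially
confounded with the random intercept; the model is fitted as written and
the confounding is logged when the group count is small relative to the
fixed-effect rank.

### Numerics

The fixed-effect design is identical at every bin; only the response
changes. For a single random intercept the marginal covariance
V = σ²(I + λZZᵀ) with λ = τ²/σ² admits a closed-form whitening: subtracting
c_g = 1 − 1/√(1 + λ n_g) times the group mean from each observation reduces
GLS at fixed λ to OLS on transformed data. The scan therefore:

1. evaluates the profiled −2·REML criterion, (n−p)·log RSS(λ) + log|V| +
   log|X̃ᵀX̃|, for **all** bins simultaneously at each point of a shared
   grid (λ = 0 plus log₁₀λ from −5 to 5 in steps of 0.05);
2. refines each bin's grid minimum by one parabolic interpolation in
   log₁₀λ (interior minima only; boundary λ = 0 is kept exactly);
3. refits each bin at its λ̂ for coefficients, with standard errors from
   sqrt(diag((XᵀV̂⁻¹X)⁻¹)) — the GLS/lme4 convention, cross-checked in the
   tests against a dense-matrix recomputation and against statsmodels
   MixedLM coefficients and variance components.

This makes a 10,000-bin scan a few seconds on one CPU. A bin with a
constant response is flagged `degenerate` (all coefficients 0, p = 1); a
bin whose solve fails numerically falls back to OLS with `converged =
False`, so the output always has one row per input bin.

### P-values and thresholds

Default p-values are Wald z (normal approximation) on the fixed effects —
the mixed-model fitter this pipeline mirrors provides none natively, so
this is an explicit implementation choice. A Satterthwaite-style t
approximation (`df_method="satterthwaite"`), with denominator df from the
REML expected information, is available and is never smaller than the
normal approximation; it is the choice for small cohorts where the z
approximation is mildly anticonservative (at n = 69 the inflation at
p = 1e-4 is roughly two- to four-fold on the false-positive *count*, i.e.
a few bins in 10,000 — visible in the acceptance run's null FPR of ~4e-4).

Two DMR thresholds are used: Bonferroni at family-wise α = 0.10
(0.10 / n_bins) and a fixed suggestive threshold of p ≤ 1e-4. DMR sets are
ordered by p then region id, and direction is the sign of the coefficient.

## DMR characterization

Tallies count DMRs by direction × genic/intergenic × variant overlap, with
percentages 100·count/total (an empty set reports zeros plus a flag).
Enrichment per feature class and for variant-containing bins is the
one-sided hypergeometric tail — upper for enrichment, lower for depletion —
against the retained RegionSet as background (not the whole genome). A bin
with several labels contributes to each label's contingency independently;
this convention is explicit and tested, not a claim about any particular
published table. Coefficient profiles report Pearson r between the DMR
coefficients and (a) bin CpG count, (b) mean methylation, overall and per
direction; undefined correlations (constant covariate, < 3 DMRs) are
flagged rather than NaN-propagated silently.

## The DMRmAge clock

The clock is deliberately not a penalized-regression age predictor: it
summarizes the age-DMRs by the weighted sum S_i = Σ_j β_age,j · m_ij and
rescales affinely to the training cohort's age range,

    DMRmAge_i = (S_i − min S) · age.range / range(S) + min.age,

with min S, range(S), min.age and age.range taken from training samples
only. "Weighted average" is implemented as this unnormalized weighted sum:
with mixed-sign weights a conventional normalized average is ill-defined,
and the min/range scaling makes any positive-affine variant produce
identical DMRmAge — an equivalence asserted numerically in the tests
(weight rescaling and constant shifts of the sums are absorbed to 1e-6).
On the training samples the predictions span exactly [min.age, min.age +
age.range]; new samples may fall outside.

Age acceleration is the residual from the OLS regression of DMRmAge on
chronological age, fitted over a reference subset — the full cohort when no
split is active, the training split during validation — and applied to all
samples, so held-out samples are scored against the reference trend.
Association analyses relate acceleration to strain maximum life span, BW0
and final weight (Pearson, overall and CD-only), to diet within strains
carrying both diets (Welch's t by default; a strain-paired t is available
since the compared groups are strain-matched and no convention is claimed
to be canonical), and to all three jointly via partial (Type-II-style)
F-tests.

`split_validate` redraws the whole pipeline: a random training subset
(default 55 samples from the sex-filtered pool, females by default, leaving
14 held out), EWAS and age-DMR calling on the training split only, clock
scaling and residual line from the training split, evaluation on both
splits. Everything is deterministic given the supplied generator.

## PCA and outlier screening

PCA treats samples as observations with region-centred, unscaled values, so
variance fractions are interpretable shares of methylome variance; scores
are reproducible up to per-component sign and are checked against a direct
SVD. The trait screen correlates each top PC with age, weights and the
strain-level life-span statistics, and compares diets by Welch's t. Visual
outlier exclusion is formalized as a deterministic rule: a sample is
flagged when its (PC1, PC2) distance to its strain's component-wise median
centroid exceeds k·(cohort median within-strain distance), default k = 6.
The median centroid resists the very outlier being hunted; flagging is
advisory — exclusion is a user decision.

## Synthetic cohort generator

The generator's defaults emulate the study conditions the pipeline is built
for: 69 samples in 17 strain-by-diet groups (12 strains on control chow,
5 of them also on high-fat diet, per-group sizes matching the study's
biospecimen table), all female by default with males opt-in, collection
ages uniform on 181–759 days, strain mean life spans ~ Normal(700, 150²)
days truncated at 200 with an 85-day HFD penalty (≈ −12%), per-animal
life spans Normal(group mean, 130²) with 13 animals per longevity group.
BW0 is a strain effect (SD 2.5 g) negatively coupled to strain life span
(−0.012 g/day, giving r ≈ −0.3 at the strain level) plus 0.03 g/day times
the age at weighing (Normal(134, 81²) days, truncated below the collection
age) plus noise; final weight adds 6 g on CD or 15 g on HFD (reproducing
the ~41 vs ~26 g contrast) plus noise.

The methylome is y_ij = μ_j + β_age,j·(bioage_i − mean) + β_bw,j·(BW0_i −
mean) + β_ls,j·(medLS_g − mean) + u_gj + ε_ij with τ = 0.10 (group
intercept SD), σ = 0.15 (residual SD) — values chosen for testability, not
fidelity; no per-region variance components are published for this assay.
Covariates enter centred so μ_j is each region's expected mean methylation
(a pure intercept reparametrization). Baseline μ_j falls with CpG density
(CpG-dense bins are lowly methylated). Planted effects occupy disjoint
region sets: 1% age-DMRs with |β_age| ~ U(0.0010, 0.0020) per day and
P(positive) = logistic(1.5·z(cpg) − 1.5·z(μ)) — hypermethylation
concentrated in CpG-dense, low-baseline bins; 1% BW0-DMRs, negative with
probability 0.75, |β_bw| ~ U(0.015, 0.030) per gram; 0.6% LS-DMRs, positive
with probability 0.59, |β_ls| ~ U(0.0008, 0.0016) per day. The age-effect
magnitudes give analytic per-region power near 1 at p ≤ 1e-4 for n = 69
(signal-to-SE ratio ≥ 9), which is what makes recovery testable.

Group-level differential aging is planted through a biological-age offset
bioage_i = age_i + accel_g, with accel_g = −30·z(group median life span) +
40·1[HFD] days: short-lived groups and HFD groups age epigenetically
faster, at magnitudes comparable to the study's reported acceleration
contrasts (tens of days). Setting both couplings to 0 yields a null cohort
for calibration tests.

Matched expression covers a random 52-sample subset: each DMR's cognate
transcript is cis_strength·z(methylation) + √(1−cis_strength²)·noise
(default 0.8), with the sign matching the trait coefficient for age- and
BW0-DMRs and fixed negative for LS-DMRs, so hypermethylated age-DMRs
correlate positively with their transcript and BW0-hypomethylated DMRs
fall in the negative-r / positive mRNA–BW0 quadrant; 200 additional null
transcripts are pure noise.

What the generator does **not** emulate: read-level sampling noise and
coverage-dependent variance, linkage between neighbouring bins (planted
DMRs are independent bins, so no regional autocorrelation), genotype-driven
alignment artefacts in variant-containing bins, sex differences, and any
nonlinearity of methylation in age. Passing tests therefore demonstrate
correctness of the estimators under the stated generative model, not
robustness to those real-data features.

## Problem sizes

The default cohort is 10,000 regions × 69 samples — large enough that
genome-wide thresholds and false-positive rates are meaningful, and a full
pipeline run (simulate, scan, clock, split validation) takes seconds. The
multi-seed stability experiments (20 seeds for the acceleration–life-span
sign) run at 1,200 regions per seed, which preserves ~12 planted age-DMRs
per replicate — plenty for a clock — while keeping the whole acceptance
run under a minute. Unit tests use 150–8,000 regions depending on what the
assertion needs.

## Known limitations

- Wald z p-values are mildly anticonservative at n ≈ 69; the Satterthwaite
  option trades ~30× runtime for calibration. Neither implements the exact
  small-sample distribution of the REML fixed effects.
- The λ grid spans 10⁻⁵–10⁵; variance ratios outside that range clamp to
  the nearest grid point (in practice only λ→0 matters, and 0 is on the
  grid exactly).
- Enrichment treats multi-label bins independently per label, so label
  contingencies are not mutually exclusive.
- The clock's affine scaling extrapolates linearly outside the training
  weighted-sum range; no shrinkage is applied for new cohorts.
- `pair_dmrs_to_transcripts` pairs by gene id and resolves multi-transcript
  genes by maximum variance; with one transcript per gene (the generator's
  convention) this is exact, with real annotation it is a heuristic.
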