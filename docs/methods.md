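# Methods

## Scope and data model

`tmtqc` operates on wide protein-group abundance tables (proteins in rows,
samples in columns, missing entries allowed) plus per-sample metadata. A
matrix carries a processing-stage tag (`raw` → `ratio` → `log2` →
`batch_corrected`) and each stage asserts its input scale, so stages cannot
be silently composed out of order. Every QC operation appends an auditable
step record (parameters, protein/sample counts before and after, per-round
removal lists) to a versioned JSON report.

## QC pipeline

**Missingness filter.** A protein is removed only when its missing fraction
is *strictly greater* than `max_missing_frac` (default 0.5): a protein
missing in exactly half the samples is retained. The boundary is exposed as
a parameter because reasonable pipelines differ on it.

**Loading normalization.** Each observed value is divided by its sample's
total observed abundance, correcting unequal protein input per TMT channel.
Observed column sums become exactly 1. A consequence worth knowing: any
perturbation that multiplies a whole sample by a constant (a uniform log2
shift) is removed *exactly* by this step. The synthetic generator's outlier
mechanism is exactly such a shift, so planted outliers are visible on the
generated (pre-normalization) scale and tests of the outlier rule operate
there; real outlier samples typically also distort relative profiles and
survive normalization.

**log2 transform.** Applied to ratios; zeros are treated as missing at read
time (configurable), so all observed values are strictly positive.

**Iterative PCA outlier removal.** Each round: per-protein mean-center,
mean-impute missing entries (imputation is used *only* inside PCA/MDS — no
other stage ever fills values), take sample scores on the leading
`outlier_pcs` components (default 2) via SVD, and flag samples whose score
is more than `outlier_sd_threshold` (default 4) population SDs (n
denominator) from the component mean. All flagged samples are removed
together, then PCA is recomputed; the loop ends when a round flags nothing
or `max_outlier_rounds` (30) is reached (recorded as a warning). Component
signs are fixed by making each component's largest-magnitude loading
positive, so results do not depend on the linear-algebra backend. Proteins
are centered but not variance-scaled: log2 ratios share a scale, and
scaling would up-weight noise-only proteins.

**Batch regression.** Per protein, an OLS fit of log2 abundance on batch as
a categorical factor over observed entries; for a single factor this equals
subtracting per-batch means and restoring the protein's grand mean, which
keeps the matrix on the log2-ratio scale and equalizes per-batch means
(machine precision for complete proteins). Proteins observed in only one
batch are passed through and flagged; batches with fewer than two samples
trigger a warning. A covariate-protected variant is deliberately not the
default: the pipeline regresses batch only.

## Diagnostics

**Classical MDS.** Torgerson double-centering of squared Euclidean sample
distances (same imputation as PCA), eigendecomposition, coordinates scaled
by root eigenvalues. On complete data this coincides with PCA sample scores
up to sign; tests verify both that duality and agreement with an external
principal-coordinates implementation.

**Variance partitioning.** Per protein, categorical factors (sex, race,
diagnosis, batch) enter as crossed random intercepts and age as a fixed
effect. Continuous fixed effects are residualized first by OLS and their
share is the variance of the fitted linear term; the remaining variance
components are estimated by REML (statsmodels MixedLM, Powell optimization
— it handles boundary/zero components far more reliably than gradient
methods here). Non-convergent fits fall back to a method-of-moments
estimator and are flagged: exact one-way ANOVA (Henderson) components for a
single factor, and for several crossed factors a Haseman–Elston-style
regression of off-diagonal cross-products on same-level indicators (with an
intercept absorbing the O(1/n) centering bias). Reported fractions are each
component over the total, so rows sum to 1 on every code path. Samples
missing any modeled factor are dropped per protein (never imputed);
proteins with fewer than 10 complete samples are skipped with a warning;
single-level factors are excluded; one-to-one aliased factor pairs (e.g. a
batch layout that determines site and vice versa) produce a warning because
their split is arbitrary.

## Validation analyses

**Differential abundance.** Per-protein one-way ANOVA across group levels
on observed values, Benjamini–Hochberg adjustment across the tested set
(proteome-wide, not per-figure), and the two-group mean difference as the
direction. Calibration is tested on null simulations.

**Ordinal trend.** Jonckheere–Terpstra statistic: the sum over ordered
stage pairs of Mann–Whitney counts (ties counted ½). Being rank-based it is
invariant to strictly monotone transforms of abundance. The p-value is a
one-sided (increasing) permutation p with `(1 + #{T* ≥ T}) / (n_perm + 1)`;
the standardized `z` uses the permutation null's mean and SD. Replicate
tissues are reduced to the first sample per individual (documented,
order-based selector) before testing, matching per-individual reporting;
the same de-duplication applies to proteotype concordance.

**APOE proteotype.** The ε4-specific peptide row's log2 abundances (missing
values floored at the row's minimum observed value — absence of an
allele-specific signal is informative) are fit with a two-component
equal-variance Gaussian mixture by EM with deterministic quantile
initialization (component means start at the 10th/90th percentiles). The
carrier threshold is the midpoint of the component means; a separation
below 1 log2 unit marks the result uncallable instead of thresholding
noise. Concordance, false-positive/negative counts, and the linear-scale
fold change between called groups are reported. Because the threshold moves
with the mixture, concordance is invariant to adding a constant to all
abundances. CERAD codings of 0–3 or 1–4 are both accepted; analyses use the
observed ordered levels.

## Synthetic cohort generator

Per protein `p` and sample `j`:

    log2 a_pj = μ_p + b_{batch(j),p} + site term + Σ_f β_{p,f} x_{j,f}
                + γ_p (age_j − 75) + ε_pj,   ε ~ N(0, noise_sd²)

with μ_p ~ N(20, 1.5²) (log2 reporter-intensity scale), per-protein×batch
offsets b ~ N(0, batch_sd²) (batch effects are protein-specific, which is
what makes per-protein regression non-trivial), batches nested within
sites, and site offsets defaulting to 0 (site structure beyond batch
nesting is not separately modeled). Marker proteins carry signed sex-,
race- (African-American indicator), and diagnosis-linked effects. A latent
pathology axis (mean 0 in controls, 1 in AD) is thresholded into CERAD
(0–3) and Braak (0–6) and also scales the AD-marker effects, so ordinal
trends have true signal and the AD-vs-control mean gap equals
`effect_size_ad`. The reserved row `APOE4|LGADMEDVR` is multimodal:
non-carriers at a low background mode (residual chemical noise is always
measured, so this row is exempt from MNAR dropout), ε4 heterozygotes
`apoe4_log2_separation` (default 3, i.e. 8×) above it, and ε4/ε4
homozygotes one further log2 unit up (allele dose) — which is why the
called-group fold change sits at ~9× rather than exactly 8×. Recorded
genotypes flip carrier status at `genotype_error_rate` (default 2%),
reproducing proteotype/genotype discordance. Outlier samples receive a
uniform `outlier_shift` on every protein. A `replicate_frac` (default 5%)
of samples are donor replicates sharing all traits.

Missingness is applied afterwards: entry-wise Bernoulli with probability
logistic in the negative standardized log2 intensity,
`p = expit(a − s·z)`, `s = mnar_steepness`; the intercept `a` is solved by
root finding so the expected missing fraction equals
`missing_rate_target`. `s = 0` reduces to missing-completely-at-random.

Defaults are a desk-scale cohort keeping the multi-center study shape
(400 proteins, 240 samples, 16 batches across 4 sites ≈ 15 samples per
batch); `dlpfc_like()` / `stg_like()` presets carry the full cohort
dimensions (1105 samples/72 batches/4 sites and 280/19/2). Effect sizes
(sex 1.0, AD 0.5, race 0.5 log2), batch_sd = noise_sd = 0.3, 15% missing,
2 outliers at +3 log2, carrier frequency 0.35 and age slope SD 0.01
log2/year were chosen once as realistic magnitudes for brain TMT data.

**What the generator does not emulate** — and therefore what passing tests
do not show about real data: reporter-ion co-isolation interference,
peptide-to-protein roll-up, non-additive or intensity-dependent batch
effects, site-specific preprocessing differences, correlated protein
modules, and outliers that distort relative profiles rather than overall
level.

## Numerical choices and problem sizes

Ratio-stage column sums are enforced to 1 within 1e-9; batch-mean
equalization to 1e-8 on complete proteins; variance fractions sum to 1
within 1e-6. Ties in factor ranking break lexicographically by protein id.
All randomness flows through explicit seeds (`numpy.random.default_rng`);
`scripts/acceptance.py` derives independent sub-seeds from `--seed` via
`SeedSequence`. The acceptance script uses a 400×240 pipeline cohort, a
150-protein variance-partition subset, a 1000-sample APOE cohort, and a
1000-protein null for ANOVA calibration — sizes chosen so the whole run
completes in well under a minute while keeping Monte-Carlo noise small
relative to the reported quantities.

## Known limitations

- REML on many crossed variance components can be slow per protein; the
  `method="mom"` path is the fast, closed-form alternative and the
  automatic fallback.
- Mean imputation inside PCA biases scores toward zero for high-missingness
  samples; it is used only for outlier screening and visualization.
- The batch regression assumes additive protein-specific batch offsets; it
  does not protect biological covariates and will absorb any biology
  perfectly confounded with batch.
- Proteotype calling assumes a two-mode abundance structure; cohorts with
  very low or very high ε4 frequency can be flagged uncallable even when
  individual calls would be correct.
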