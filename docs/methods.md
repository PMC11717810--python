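# Methods

## Model and assumptions

All phenotypes are analysed at the single-plot level with univariate
linear mixed models.  The random structure is a sum of kernel terms: each
term binds an observation-to-entity incidence (line, line-by-environment
pair, plot, malting batch) to a positive semi-definite similarity kernel.
The additive genomic kernel is VanRaden's G = QQ′/(2Σpᵢ(1−pᵢ)) with Q the
dosage matrix centred by twice the observed post-QC allele frequencies
(an external frequency vector can be supplied for prediction sets).
Genotype-by-environment effects use independent copies of G per
year-location environment, i.e. a block-diagonal kernel over (environment,
line) pairs; the environment count follows from the data, not a constant.
Spatial effects use S = WW′/(tr(WW′)/n) where W marks the at most eight
row/column-adjacent plots (Chebyshev distance 1) inside the same trial;
the plot itself is excluded (diagonal of W zero), so S encodes pure
neighbour similarity, and the trace normalisation still gives d(S) = 1
exactly.  Omics kernels treat features as independent with equal
contributions: Q_MI = M M′/q over centred/scaled metabolomic intensities
and Q_NIR = M M′/t over the leading principal-component scores of the
preprocessed NIR spectra.  No per-feature weighting is applied; a feature
subset (e.g. only features whose heritability passes the significance
threshold) can be selected before kernel construction.

The two-step omics-augmented fit adds a plot-level effect
u ~ N(0, Q σ²_u) in step 1 and refits the identical structure (minus the
omics term) to the predicted û in step 2; combined breeding values are
ĝ₁ + ĝ₂.  Step 2's response is the plot-level û (one value per
observation); aggregation to line means first is available via
`step2_level="line"`.  For protein content the NIR variant is refused by
default, since protein is itself calibrated from NIR spectra — predicting
it from its own predictor would be circular; `force=True` overrides.

## Preprocessing

SNP QC removes markers with minor allele frequency below 0.05 (computed on
observed calls) or call rate below 0.90, then imputes missing dosages with
the SNP's mean dosage 2p̂.  Spectra are normalised feature-wise to mean 0
and sample variance 1 (zero-variance features dropped and counted).  NIR
spectra additionally receive a Savitzky-Golay first derivative
(window 11, polynomial order 2 by default — common NIR practice; both
exposed in the config) with respect to the sample index; on the uniform
5 nm grid this differs from d/dnm only by a constant absorbed by the
subsequent re-normalisation.  The default order is normalise → derivative
→ normalise → PCA; a config switch (`nir_derivative_first`) runs the
derivative before the first normalisation instead.  PCA keeps the
smallest component count reaching the explained-variance target (0.99).

## AI-REML

Variance components are estimated on the variance scale directly.  Each
iteration computes the restricted log-likelihood, scores and the
average-information matrix from dense V = Σ σ²ᵢ ZᵢKᵢZᵢ′ + σ²ₑI (Cholesky
factorisation; the problem sizes this package targets, ≲ 2,500
observations, are comfortably dense).  An AI step is accepted only if it
stays feasible and does not decrease the restricted likelihood; otherwise
it is halved up to 12 times, then a classical EM-REML update is
substituted.  Components at the boundary (pinned to 1e-6 × var(y)) whose
gradient points outward are frozen out of the AI system (an active-set
strategy), which keeps quadratic convergence for the interior components
— without it, a collapsing component makes the iteration crawl.
Convergence: relative parameter change < 1e-8 or restricted
log-likelihood change < 1e-6; maximum 200 iterations; non-convergence is
always reported explicitly.  Standard errors come from the inverse AI
matrix at the optimum.  A fit whose omics variance ends on the boundary is
reported as failed for that trait rather than silently degenerate.

BLUPs are computed from the GLS identities (b̂ = (X′V⁻¹X)⁻¹X′V⁻¹y,
âᵢ = σ²ᵢKᵢZᵢ′Py), which solve Henderson's equations without inverting
possibly singular kernels and give predictions for kernel entities with no
observations — this is how masked lines are predicted in
cross-validation.  The fixed factor is the year-location-trial
combination, reference-level parameterised; collinear columns that appear
after cross-validation subsetting are dropped.

## Heritability

Plot-level narrow-sense heritability is h² = d(G)σ̂²_g/σ̂²_P with σ̂²_P the
weighted component sum (weights: d(G) for the additive and, by default,
the G×E term; d(S) − mean(S) for the spatial term; d(Q) for the omics
term; 1 otherwise).  The G×E weight is switchable to 1
(`gxe_diag_weight`), reproducing a published convention in which the G×E
variance enters unweighted.  Presentation rounding is half-away-from-zero
to 2 decimals and happens only in report tables.

The significance test for feature heritabilities is simulation-based:
phenotypes are simulated from the fitted null model (additive variance
forced to zero, every other component at its estimated value on the real
design), the model is refitted to each replicate, and the empirical
(1−α) quantile of the null ĥ² distribution is the threshold (default
n_sim = 1,000; α = 0.01).  Refit failures are counted and the threshold is
flagged unreliable above 10% failures.  The resulting threshold is
design-specific by construction.

## Cross-validation and accuracy

Fivefold CV masks all replicates of 20% of candidate lines per fold;
folds are stratified by breeding cycle (so a random fold cannot
accidentally become a leave-cycle-out run; plain random assignment
remains available by omitting the cycle map).  Leave-one-breeding-cycle-
out masks a whole crossing year; lines observed in several cycles are
masked with their first cycle.  Control lines are never validated.  For
omics-augmented models the training omics kernel is restricted to
training plots, and a per-fold audit verifies that no masked line
contributes a phenotype or omics row to any training design.

Predictive ability pairs line-level GEBVs with line-mean fixed-effect-
corrected phenotypes y_c (GEBVs are per line, so line level is the natural
pairing); the headline value is the pooled correlation over all masked
candidate lines, with per-fold values retained for the paired t-tests.
Fixed effects for y_c come from the whole-data fit of the same model
family.  The dispersion slope b_wp regresses whole-information on
partial-information GEBVs.  LR-method ratios correlate GEBVs across
nested validation-set information states: genomic only; plus omics (the
full-plot kernel lets step 1 predict û for validation plots, and step 2
then sees those predictions); plus phenotypes (the whole-data fit).
Bootstrap standard errors resample validation lines (the exchangeable
unit) with replacement, 10,000 replicates by default.  Model comparison
uses two-tailed paired t-tests on per-fold predictive ability at α = 0.01
with a compact letter display; with fewer than two paired units (e.g.
two-cycle leave-cycle-out) the test is reported not applicable and all
models share a letter, with bootstrap SEs carrying the uncertainty.

## Synthetic data

The generator runs the analysis model forward.  Defaults emulate a
two-cycle commercial programme: 600 candidate lines plus 2 control lines
replicated 3 times per trial, 2 years × 2 locations × 3 trials on
10 × 12 plot grids, 8,000 SNPs with MAF ~ U(0.05, 0.5) and 0.3% missing
calls, inbreeding 0.85 (F6-like panel; mean G diagonal ≈ 1.85), 30,000
metabolomic features and 141 NIR wavelengths (950–1650 nm, 5 nm step).
Each candidate line is tested once per environment of its own crossing
year; micro-malting batches group 24 consecutive plots.  Per-trait
variance components default to magnitudes consistent with the trait
scales (yield in kg/plot, β-glucan in mg/L, ...); filtering speed and
wort colour carry no omics-mediated variance, which is what makes the
NIR-augmented model collapse for them — a deliberate degeneracy the test
suite exercises.

SNP effects are i.i.d. Gaussian (matching the GBLUP prior; no
linkage-disequilibrium map or pedigree structure is simulated), and every
effect vector is rescaled so its realized variance equals the configured
value exactly for kernel-drawn effects (additive, G×E, spatial, mediated)
and in expectation for i.i.d. effects.  Feature heritabilities follow a
three-class mixture (default 40% zero — empty spectral regions, 50%
moderate in (0.01, 0.2), 10% high in (0.2, 0.9)); each feature's genomic
part is its own Qα_f draw, with the non-genetic remainder split 30/70
between an environment-common component and plot noise.  NIR spectra are
built from 8 latent basis curves (Legendre polynomials plus Gaussian
bumps) whose coefficients carry genetic and environmental parts, plus
small white noise.  The omics-mediated trait contribution is Mβ over the
heritable features, rescaled to the configured variance; the truth record
stores the direct additive value, the line-level genetic component of the
mediated path, and their sum (the total additive merit the combined GEBV
targets), alongside realized variance components and feature
heritabilities.

What the generator does not emulate — linkage disequilibrium, multi-year
pedigree accumulation, NMR peak chemistry, instrument drift, non-additive
feature-trait maps — bounds what passing tests show: they validate the
estimation and validation machinery under the model's own assumptions,
not robustness to their violation on real data.

## Problem sizes and numerical choices

The test suite and the acceptance script run deliberately scaled-down
problems chosen as the smallest sizes at which the statistical behaviour
of interest is visible: 120–150 lines / 300–350 plots for end-to-end
model and CV checks, 300 lines × 2 plots × 20 seeds for REML parameter
recovery, 40 lines × 3 replicates with 500 null simulations plus 300
fresh null fits for the threshold calibration.  Kernel symmetry is
enforced to 1e-10, PSD to a relative 1e-8; ties in fold assignment and
level ordering are broken by sorted label order so all results are
reproducible from the seeds alone.  Degenerate inputs (empty SNP panels
after QC, all-isolated layouts, zero-variance spectra, monomorphic
panels, zero phenotypic variance) raise typed errors rather than
propagating NaNs.

## Known limitations

Single-trait REML only; no Bayesian samplers; no single-step joint
omics-genomic likelihood (only the two-step procedure); dense algebra
limits practical size to a few thousand observations; no VCF input, LD
pruning or pedigree relationships; no NIR scatter correction (SNV/MSC)
variants; the compact letter display uses a greedy insertion and is not
guaranteed minimal in pathological non-transitive cases.
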