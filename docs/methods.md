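# Methods

This note documents the models, numerical choices, and the limits of what the
synthetic data can show. Everything quantitative stated here is computed by
the test suite or by `scripts/acceptance.py`.

## DWI signal model and tensor fit

The signal follows the single-tensor model `S(g, b) = S0 exp(-b gᵀDg)` with
`D` a symmetric positive-semi-definite 3×3 tensor in the scanner frame
(x = right–left, y = anterior–posterior, z = superior–inferior). Fitting is
plain ordinary least squares on `ln S` with design rows
`(1, -b gx², -b gy², -b gz², -2b gx gy, -2b gx gz, -2b gy gz)`, solved once
per volume via a pseudoinverse and applied to all voxels. No weighted or
robust variant is used: OLS on the log signal is exact to machine precision
on noiseless data for any PSD generating tensor, which is what the phantom
oracles rely on, and it mirrors the default behavior of the standard
tensor-fitting tools.

Numerical choices:

- signals ≤ 0 are clipped to `1e-8 · S0` (per-voxel mean b0) before the log,
  so deep diffusion attenuation under noise cannot produce `-inf`;
- negative eigenvalues of the fitted tensor are clamped to zero and the voxel
  flagged in a `clamped` mask; `fit_ok` is reserved for voxels with no usable
  b0 signal (those yield zero tensors and are excluded from ROI means);
- a fit requires ≥ 6 diffusion-weighted directions plus ≥ 1 b0 volume.

The ALPS index uses the *diagonal elements* `Dxx, Dyy, Dzz` of the fitted
tensor in the scanner frame, not eigenvalues. The two coincide only for
axis-aligned tensors; a dedicated test pins this semantic down by rotating a
prolate tensor off-axis. FA is the usual normalized eigenvalue dispersion
and is rotation-invariant; the axis diffusivities are not.

## Gradient scheme

Clinical acquisitions rarely publish their direction tables, so the package
uses a deterministic 32-point spherical-Fibonacci scheme at b = 1000 s/mm²
plus one b0 volume: reproducible, near-uniform angular coverage, written and
read in the FSL single-row `bval` / three-row `bvec` dialect.

## ROI placement

ROIs are spheres of 5 mm diameter holding 12 voxels on the 2.5 mm grid. The
manual, SOP-guided placement of a human rater is determinized as: the
`target_voxel_count` voxels nearest the ROI center in Euclidean millimeters,
ties broken by lexicographic voxel index; an ROI whose sphere would cross
the grid boundary is an error. ROIs sit in the left hemisphere by
convention and no left/right averaging is performed. The subcortical ROI is
carried for completeness but does not enter the index, which uses only the
projection and association terms.

## Phantom construction

Phantoms are block phantoms on a 16×16×12 grid of 2.5 mm voxels: three 5³
fiber regions (projection with dominant `Dzz = 1.4e-3 mm²/s`, association
with dominant `Dyy`, subcortical with dominant `Dxx`) in isotropic
background (`0.8e-3`). The perpendicular diffusivities default to
`Dy_proj = 0.8e-3` and `Dz_assoc = 0.7e-3`. Given a target index `A`, the
two x-axis diffusivities are solved with an equal split,
`Dx_proj = Dx_assoc = A · (Dy_proj + Dz_assoc)/2`, so the noiseless
pipeline returns `A` exactly (verified to 1e-6 across targets 1.0–2.5).

Noise is Rician: the magnitude of the complex signal after adding two
independent Gaussian channels with SD `S0 / snr_b0`. The default
`snr_b0 = 30` is a typical b0 SNR for a 3T single-shot EPI diffusion scan.
At that SNR the DWI signal itself sits near SNR 10 (attenuation ≈ e⁻¹), so
the Rician floor biases individual estimates slightly; a 20-phantom group
mean still recovers the target within ±0.05 (tested). Phantoms are
artifact-free by design — no eddy currents, motion, or susceptibility — so
preprocessing is intentionally out of scope.

## Cohort generative model

The cohort generator draws, per subject: age from a normal (38.47 ± 8.63 y)
truncated to [25, 65]; sex (male fraction 19/60); ePVS presence as a
Bernoulli with prevalence 0.433; group-dependent binary risk factors
(family history 46.2% vs 8.8%, hypertension 30.7% vs 2.9%); group-dependent
normals for SBP and BMI; and group-dependent *gamma* variables for QRISK3
matched to the printed group mean/SD (4.5 ± 5.9 vs 1.3 ± 1.7). A gamma is
used because risk scores are positive and right-skewed, and a truncated
normal with those parameters would shift the group mean by >20% of itself.
Because QRISK3 is group-dependent it is genuinely correlated with the
exposure, which exercises the covariate adjustment in the mediation fits.

The mediator and outcome follow a linear structural model on standardized
scales, with standardized covariates `C = (age_z, sex_z, qrisk_z)`:

```
M* = a·X + γ'C + ε_m,   ε_m ~ N(0, 0.966²)
Y* = b·M* + c'·X + δ'C + ε_y,   ε_y ~ N(0, 0.418²)
```

with defaults `a = -0.2813`, `b = +0.8861`, `c' = 0.0412`,
`γ = (-0.20, 0, -0.05)`, `δ = (-0.10, 0, 0)`. The residual SDs are chosen
analytically so that `M*` and `Y*` have marginal variance ≈ 1 under these
defaults (the realized SDs are 0.996 and 0.991; the shortfall comes from the
truncation of age). The negative age effect reproduces the negative
age–ALPS correlation seen in this population.

**Two scales, one dataset.** The published group means of ALPS
(1.80 ± 0.15 without ePVS vs 1.55 ± 0.30 with) imply a standardized group
difference near −1, which is mutually inconsistent with the published
standardized path a = −0.2813. No single column can reproduce both. The
table therefore carries the structural variables `alps_std` / `psi_std`
(the scale on which the path coefficients live and on which recovery is
tested) alongside raw `alps` / `psi` obtained by a per-group affine map of
the structural variables onto the printed group means and SDs, using the
analytic conditional moments of the structural model. The raw columns feed
the phantom ground truth and the demographic-table statistics; the
standardized columns feed the mediation replication. The map is monotone
within group, so the two views are rank-consistent within each group.

ePVS counts for positive subjects are `1 + NegativeBinomial` with means 6
(basal ganglia) and 9 (centrum semiovale) and dispersion 3 — free choices,
since only the grade scale is published — and grades derive from counts
through the 0 / 1–10 / 11–20 / 21–40 / ≥41 scale. Subjects without ePVS
have zero counts. ALPS is floored at 0.01 to keep the positivity invariant
(the flooring probability under the defaults is ~1e-7 per subject).

## Statistics battery

Group comparisons use the pooled-variance t test by default (a config flag
switches to Mann–Whitney; the publication did not state its normality
gating), two-sided throughout. Chi-square (optional Yates correction) and
Fisher's exact test cover 2×2 tables; Fisher's two-sided p sums
hypergeometric probabilities no larger than the observed table's, and is
verified against an independent full-enumeration oracle exhaustively for
all tables with n ≤ 20 plus seeded random tables up to n = 60. Cohen's d
uses the pooled SD; on the published processing-speed summaries this gives
−0.465, not the printed −0.41, which is not reproducible from the published
summary statistics by any standard pooled/control-SD formula — the package
does not force agreement. Logistic fits are Newton maximum likelihood with
Wald intervals (the convention of the clinical software the field uses);
separation is flagged as non-convergence rather than silently reported.
"OR per 1 SD" refits with z-scored continuous predictors. VIF is
`1/(1 - R²)` from auxiliary regressions with intercept.

## Mediation

Bias-corrected (BC, no acceleration) percentile bootstrap with case
resampling of whole rows, 10,000 resamples by default, seed-deterministic.
The mediator and outcome are z-scored on the analysis sample; the binary
exposure stays 0/1, so `a` is in mediator-SD units per exposure switch —
the convention most consistent with the published coefficient magnitudes
for a binary exposure. The bias constant is
`z0 = Φ⁻¹(#{ab_boot < ab_hat}/B)`, clipped one resample away from 0/1 so it
stays finite; bounds are type-7 empirical quantiles at
`Φ(2z0 ∓ z_{1-α/2})`. Replicates whose resampled exposure is single-level
are redrawn (up to 10 rounds) and then dropped; a resample that makes a 0/1
covariate constant is handled by minimum-norm OLS, which leaves the
identified path coefficients unchanged. The bootstrap is vectorized over
replicates via batched normal equations, which is what makes the
500-cohort coverage test affordable.

Measured properties (computed in the test suite): at n = 60 with the
default generating paths, the 95% BC interval covers the true indirect
effect in ~94% of 500 simulated cohorts (2,000 resamples per cohort — a
test problem size; the default stays 10,000); with a pure-noise mediator
the interval excludes zero in well under 7% of runs; at n = 5,000 the
refitted paths recover the generating a and b within ±0.03 (averaged over
five cohorts, since a single n = 5,000 cohort has Monte-Carlo SE ≈ 0.028 on
path a). The published indirect effect (−0.235) differs from the published
a×b (−0.249); recovery therefore anchors on the paths individually. The
"t statistic" for the indirect effect is exposed as `indirect / boot_sd`
but has no published definition and is not validated.

## Pipeline

`run(config)` executes cohort → imaging → ePVS grading → statistics →
mediation, failing fast with stage-labelled errors. One global seed fans
out to per-stage child seeds through `SeedSequence` in a fixed order, so
reruns are bit-identical and stages are individually reproducible. In
replication mode each subject gets a phantom whose ground-truth ALPS is the
subject's raw `alps` value, degraded at SNR 30 and re-measured through the
full pipeline; the second ePVS rater is simulated by flipping a grade ±1
with probability 0.06, giving kappa values in the high-0.8s on average
(cosmetic for the report; not asserted). The rounded summary mirrors
clinical reporting (2 decimals for indices and p values, 1 for
percentages); `report.json` keeps full precision.

## What the synthetic data cannot show

The phantoms contain axis-aligned single-fiber blocks, not anatomy: no
crossing fibers, partial-volume mixing, CSF contamination, or motion, so
passing tests demonstrate correctness of the estimation chain, not
robustness to real-world acquisition artifacts. The cohort model is linear
with Gaussian residuals; real ALPS–cognition relationships need not be
linear, and the generator reproduces published *summary* structure, not
subject-level data (which were never deposited). Grade agreement between
simulated raters is a toy disagreement model. QRISK3 is consumed as a
score; the scoring algorithm itself is external and out of scope.
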