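# Methods

## Problem

Intravoxel incoherent motion (IVIM) imaging separates tissue water
diffusion from perfusion-driven pseudo-diffusion in the diffusion-weighted
MRI signal. In breast imaging the three IVIM coefficients — tissue
diffusivity D_t, pseudo-diffusion D_p, and perfusion fraction f_p — carry
diagnostic information (malignant lesions tend to lower D_t, and their
perfusion signature differs from benign lesions), but every vendor and
research package estimates them with a different algorithm. This package
asks the multi-software robustness question quantitatively: *which
first-order radiomic features of the IVIM maps survive a change of fitting
algorithm, and which of the robust ones remain diagnostic?*

The signal model is the biexponential decay

    S(b) / S0 = f_p · exp(−b · D_p) + (1 − f_p) · exp(−b · D_t)

with b the diffusion weighting in s/mm², D_p ≥ D_t ≥ 0 and f_p ∈ [0, 1].

## Synthetic cohort

Real multi-site patient data of this kind are not shareable, so the
analysis runs on a seeded synthetic cohort that reproduces the published
study conditions and provides ground truth:

- **Composition.** 58 / 89 / 155 patients at sites A / B / C with
  12+46 / 70+19 / 38+117 benign+malignant lesions (302 patients, one
  lesion each; malignant prevalence 79.3%, 21.3%, 75.5%).
- **Acquisition.** Each site's printed b-value scheme; Site A's five
  sub-schemes are assigned deterministically in proportion to their
  published usage counts (9/24/10/14/1) by a largest-remainder round-robin,
  since the publication does not say which patients received which scheme.
- **Parameter distributions.** Patient-level centers are drawn from the
  published per-(site, class) mean ± SD of ROI means (reference-software
  column), truncated to f_p ∈ [0,1], D_p ∈ [0, 0.1], D_t ∈ [0, 0.003]
  mm²/s, with D_p ≥ D_t enforced by resampling. Voxel values perturb the
  center multiplicatively by independent Gaussian factors with SD fraction
  0.10 per parameter — the within-lesion dispersion is not published, so
  this is a free parameter chosen to make the variance/skew/kurtosis
  features non-degenerate at realistic ROI sizes.
- **ROI size.** Voxel counts are lognormal, moment-matched to the
  published mean ± SD per (site, class) (counts are positive and strongly
  right-skewed, e.g. 1363 ± 1644 for Site A malignant), floored at the
  3-voxel minimum ROI rule.
- **Noise.** Magnitude (Rician) noise: |S + n₁ + i·n₂| with n₁, n₂
  Gaussian of SD S0/SNR. Default SNR at b=0 is 40 — typical for clinical
  breast DWI; the publication does not state one. The fitters assume
  Gaussian residuals, mirroring the studied software, so the Rician floor
  is a deliberate, realistic model mismatch.
- **Geometry.** Lesions are bags of voxels. Every downstream statistic
  (histograms, correlations, AUCs) is geometry-free, so no spatial layout
  is simulated; a toy 3-D layout exists only for NIfTI round-trips.
- **Reproducibility.** One master seed; per-lesion streams are split by
  counter (`SeedSequence(seed, spawn_key=(site, lesion))`), so one
  lesion's draw never depends on another's.

What passing tests on this cohort do *not* show about real data: there are
no scanner/protocol differences beyond the b-scheme, no partial-volume or
fat-suppression artifacts, no spatial correlation inside lesions, and the
class distributions are exactly the published Gaussians. Study-level
results are therefore qualitative reproductions (orderings, agreement
structure), not reproductions of the published patient-data correlation
or AUC values.

## Fitters

Three production estimators emulate the studied algorithm families; their
internals are proprietary, so these are documented emulations, not clones.

**Segmented least squares (`seg_a`, `seg_b`).** Step 1 fits ln S against b
by OLS over the diffusion-only regime b ≥ 200 s/mm² (the pseudodiffusion
regime is b < 200; threshold configurable), giving D_t and the
back-extrapolated tissue intercept; Step 2 sets f_p = 1 − intercept
fraction; Step 3 fits D_p by bounded 1-D least squares with the rest
frozen. These steps are then *iterated*: the estimated perfusion component
is subtracted and the log-linear stage refit (up to 50 passes, per-voxel
stop at 10⁻⁴ relative change). The refinement matters: with the printed
b-schemes the perfusion signal has not fully decayed at 200 s/mm²
whenever D_p is small, and the plain one-pass segmented fit overestimates
D_t by well over 10% on noiseless data at weak compartment separation
(e.g. D_p = 0.005, f_p = 0.2; the tests demonstrate this); the
subtraction iteration is a contraction whose fixed point is the
generating parameter set, bringing the noiseless D_t bias under 1% at
that corner and within the asserted 3% (D_t) / 10% (f_p) bounds across
the whole tested grid. The variants share Steps 1–2 (identical D_t) and differ in the final
step: `seg_a` keeps the 1-D D_p fit and additionally rejects voxels whose
D_p lands on the fit bound (0.3 mm²/s) — emulating the aggressive outlier
rejection of that software family — while `seg_b` jointly refines
(f_p, D_p) by bounded nonlinear least squares with D_t frozen. Fit bounds
(D_p ≤ 0.3, D_t ≤ 0.01 mm²/s) are deliberately wider than the histogram
ranges so out-of-range voxels can occur. All fitting operates on
S / S(b=0) ratios; signals are clipped at 10⁻⁶·S0 before the log.

**Bayesian grid fit (`bayes`).** Uniform priors f_p ∈ [0,1], D_p ∈ [0,
0.1], D_t ∈ [0, 0.003] mm²/s with the constraint D_p ≥ D_t; flat prior on
the amplitude and Jeffreys prior on the Gaussian noise scale, both
marginalized analytically, leaving a 3-D marginal likelihood ∝
|m|⁻¹·(SSR⊥)^−(N−1)/2. The estimate is the marginal posterior mean,
computed on deterministic grids in two stages: a global cell-weighted grid
(f_p linear; D_p, D_t log-spaced, 48 nodes per axis in the study
configuration, 64 for single-voxel calls) and a linear zoom grid spanning
the posterior mass (mean ± 6 posterior SDs, at least 1.5 coarse cells).
A single global grid cannot be simultaneously wide enough for the prior
and fine enough for a posterior that collapses inside one cell (noiseless
or high-SNR voxels), which is why the zoom stage exists; a convergence
test doubles both grids and checks the means move by well under the error
budget. Both stages exploit the separability of the model in f_p × D_p ×
D_t, so the full 3-D likelihood costs O(grid) elementwise work per voxel.
Because the prior support equals the histogram ranges, Bayesian estimates
are always "in range" (100% utilization), as observed for the Bayesian
package in the study. Zero-decay voxels return the prior mean, flagged
non-converged.

**Oracle (`oracle`, tests only).** Multi-start bounded nonlinear least
squares over all four parameters (8 deterministic coarse-grid starts);
winner = lowest residual, ties broken by lowest D_p. Solutions are
canonicalized to the D_p ≥ D_t labelling first, because the biexponential
is exactly symmetric under (f_p, D_p) ↔ (1−f_p, D_t). On noiseless data
the oracle recovers the generating parameters to < 0.5%.

Numerical notes: the 1-D D_p fit uses a shared coarse log-grid bracket
plus vectorized golden-section refinement (unimodal in practice); all
per-voxel reductions are implemented so that a voxel's estimate is
bit-identical whether fitted alone or in a batch; f_p = 0 voxels have
unidentifiable D_p and report the initialization value (0.01 mm²/s),
converged but excluded from nothing — the histogram range decides usage.

## Histogram radiomics

Each parameter map is binned into 100 equal-width bins over fixed ranges
(f_p: 0–1; D_p: 0–0.1; D_t: 0–0.003 mm²/s); bins are half-open with the
last bin closed. Features (minimum, maximum, mean, variance, skewness,
kurtosis) are computed from the binned representation — centers weighted
by counts — because the emulated workflow extracted features from a fixed
histogram module; tests bound the quantization error (≤ half a bin width
on location features). Moments are population moments; kurtosis is
non-excess m₄/m₂² by default (a config switch gives excess). Out-of-range
or fitter-flagged voxels are excluded *per parameter*, and the utilized
fraction is tracked. Minimum is computed for all parameters but headlined
only for D_t; the f_p and D_p minima of a 100+-voxel lesion sit in the
lowest occupied bin near zero almost surely, which makes them degenerate
as features. The 16 reported metrics are 6 for D_t and 5 each for f_p and
D_p.

## Agreement statistics

Per metric: Pearson r for each software pair within each site (patients
are never pooled across sites), the mean and CV% (sample SD / mean) of the
9 pair × site correlations, Bland-Altman summaries per pair and site, and
the three-rater ICC per site. The ICC form is ICC(2,1) — two-way
random-effects, absolute agreement, single measurement — because the
question is agreement of software treated as random raters, and absolute
agreement (unlike consistency) penalizes calibration offsets between
packages. The Bland-Altman "CV%" is the within-subject CV, 100·(SD of
signed differences/√2)/grand mean, with the absolute-difference variant
reported alongside since the convention is ambiguous. Undefined cells
(zero variance, non-positive grand mean) are flagged NaN and excluded
from averages, never imputed.

## Diagnostics

Each metric is z-scored over the pooled sample and entered into a logistic
regression of malignancy with site-specific intercept *and* slope (the
full site interaction; "adjusted by site (coefficient and intercept)" is
read as both, with a shared-slope switch available). The fit is
Newton/IRLS, max 100 iterations, 10⁻⁸ log-likelihood tolerance; complete
separation (|slope| of a z-scored metric > 10, or non-convergence) is
flagged and refit with a weak ridge (10⁻⁴), to which AUC is
rank-invariant. Apparent AUC is computed on the pooled predicted
probabilities (the site terms make probabilities comparable across sites);
the leave-one-patient-out (LOU) AUC refits the model n times, predicting
each held-out patient, reusing the full-sample z-scoring constants (these
use no label information). Folds that lose a class predict the training
prevalence and are flagged. AUC is the Mann-Whitney statistic with ties
at ½; standard errors and the paired two-sided test between methods use
DeLong's structural components. Per metric the three methods' AUCs are
averaged and their CV% reported, for apparent and LOU separately.

A calibration caveat established while testing: under a permutation null
with fixed class totals, LOU-CV AUC is systematically *pessimistic*
(mean ≈ 0.44 at n = 300 for this model), because removing a positive
lowers the training prevalence and anti-correlates predictions with the
held-out labels. Chance-level checks therefore average over permutation
replicates rather than judging a single draw.

## Problem sizes and determinism

The default study is 302 patients (~75k lesion voxels) × 3 fitters,
chosen to match the published cohort; it runs in a few minutes on one
core. Estimator benchmarks use a 27-point truth grid × 3 schemes
(noiseless) and 500-voxel Monte-Carlo panels at SNR 40. The entire study
is a pure function of (config, seed): per-lesion counter-split streams,
deterministic grids and start points, and fixed-format CSV output make
repeated runs byte-identical.

## Known limitations

- The two segmented variants share their high-b stage, so their D_t maps
  are identical and D_t pair correlations between them are exactly 1 —
  slightly stronger than the near-unity agreement seen between real
  segmented packages.
- The Bayesian fitter's log-grid floors (10⁻⁴ for D_p, 10⁻⁵ for D_t)
  place no mass at exactly zero; irrelevant for decaying signals.
- No noise-floor correction in any fitter (as in the studied software);
  at SNR 40 this inflates f_p slightly, a known effect of magnitude noise.
- Bland-Altman CVs for skewness metrics are frequently undefined (signed
  features, near-zero grand means) and are reported as NaN.
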