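# Methods

## The fibrosis-index dose-response model

The package models late radiation-induced lung fibrosis as a
*deterministic* severity response: the fibrosis index FI is a
continuous CT-derived score, not an event indicator, so the sigmoid

FI(D) = (A/2) {1 − erf(√π γ (1 − D/ED50))}

describes the population-mean severity at total dose D. A is the
saturation FI (default 7.20, the experimentally measured maximum that
normalises all FI values; by default it is held fixed during fitting
and fitting it is available behind a flag), ED50 the dose of
half-maximal fibrosis, and γ the maximum normalised dose-response
gradient. ED50 here means "the average animal reaches FI = A/2", not
"half the animals respond". The closed-form inverse

D(FI) = ED50 [1 − erfinv(1 − 2FI/A)/(√π γ)]

is exact on 0 < FI < A; in double precision the forward model
saturates to A beyond roughly 3×ED50, which bounds the range over
which inversion identities can be verified (the suite uses
FI ∈ [0.05, 7.15]).

Fitting is unweighted nonlinear least squares over (ED50, γ) on
per-animal rows (group-mean fitting is an option; which of the two the
original analysis used is not documented, so both are provided).
Initialisation: ED50₀ from linear interpolation of the dose where
group-mean FI crosses A/2 (median dose as fallback), γ₀ = 1, bounds
ED50 ∈ (0, 10·max dose], γ ∈ (0, 20]. Standard errors come from the
fit covariance; goodness of fit is the residual-vs-total adjusted R²
(stated explicitly because no single convention exists for nonlinear
fits).

## Alpha/beta estimation

Three routes, all rooted in the biologically-effective-dose identity
D₁(1 + d₁/(α/β)) = D₂(1 + d₂/(α/β)):

1. **Isoeffect pairing.** For any FI level, the two arm sigmoids are
   inverted to isoeffective totals (D₁, D₂) and
   α/β = (D₂d₂ − D₁d₁)/(D₁ − D₂). The effective FI range for the
   profile is not enumerable from the source analysis, so the default
   grid is FI = 0.05 to 7.15 in steps of 0.05 with per-level values
   reported alongside the mean ± SD, letting any sub-range be
   recomputed. With d₁ = d₂ the identity collapses to −d; the value is
   returned unmodified (it is algebraically exact) and is outside the
   model's assumptions.
2. **Fe plot.** OLS of reciprocal total isoeffect dose on dose per
   fraction; α/β = intercept/slope. Under the LQ model 1/D is exactly
   linear in d, so on schedules constructed isoeffective at a known
   α/β both routes recover it to numerical precision — this algebraic
   identity is used as the oracle in the test-suite.
3. **LQ regression.** The response y = −log10(FI) is regressed as
   y = c − (αD + βdD) with a free intercept. The linkage between the
   log-transformed FI and the LQ effect scale is deliberately exposed
   as a pluggable transform: the ratio α/β is invariant to the log
   base (α, β, c all rescale by the same constant) and is the
   contract-level output, while the individual α and β depend on the
   normalisation. FI values below 0.05 are floored to 0.05 before the
   log (the lower end of the effective FI range) to keep zero-dose
   controls finite.

Isoeffect curves solve the BED identity for the positive quadratic
root of d at each fraction number; negative/complex roots raise a
domain error rather than being clipped.

## BED modelling and landmarks

BED = D(1 + d/(α/β)) maps both arms to a common scale, where FI
follows the four-parameter log-logistic
FI(BED) = A2 + (A1 − A2)/(1 + (BED/k)^p). Landmarks:

* **cut-off** (maximum slope): numeric argmax of f′ on a 4096-point
  grid over [0, 1.5·max BED] with golden-section refinement to 1e-6
  Gy; for p > 1 the closed form k((p−1)/(p+1))^(1/p) exists and is
  used as an independent oracle, not as the implementation.
* **threshold** (maximum curvature): argmax of the arc-length
  curvature κ = f″/(1 + f′²)^(3/2) on the rising toe below the
  cut-off. Curvature landmarks depend on axis scaling; the default is
  the raw (Gy, FI) coordinates, with an explicit option to normalise
  both axes first. The choice is surfaced in the fit object because
  the two conventions give different thresholds and the original
  convention is not recoverable.
* **BED_ED50**: solved from the model at FI = A2/2 (equal to k when
  A1 = 0).

For p ≤ 1 the slope has no interior maximum and landmarks are
reported as NaN rather than extrapolated.

## Synthetic data

The generator emulates the study design the analysis assumes: two
fractionation arms (single fractions of 0, 10.5, 12.5, 14.5, 17.5,
20 Gy; five daily fractions of 0, 2, 4, 6, 7, 8.5 Gy each), 12 animals
per dose group, endpoint at week 24. Per-animal FI is the sigmoid mean
plus additive Gaussian noise truncated at zero; the default
fi_sd = 0.2 FI units is a synthetic convention (the source data report
only group means), chosen so that group-mean scatter is comparable to
the published fit quality (adjusted R² ≈ 0.97). Reference-cohort
defaults (−550 HU, 400 mm³, SD 5% of mean) are likewise synthetic
conventions of plausible murine magnitude.

Volume and mean-HU columns are back-filled from the noisy FI by
splitting it symmetrically (dHU = dV = FI) and inverting the relative
FI convention with a back-fill scale constant (default 10), so the
imaging-free FI computation reproduces the stored FI exactly. The
scale exists because a relative convention with scale 1 cannot reach
FI = 7.2 with a positive lung volume; it is a bookkeeping convention,
consistent with the fact that the normalisation giving the measured
saturation A = 7.20 is defined outside the analysis reproduced here
and is therefore exposed as a parameter, never guessed. All
dose-response mathematics operate on FI values and are independent of
the convention.

Phantoms are axis-aligned HU arrays with one 6-connected lung region
grown by seeded random breadth-first walk, exact voxel-count/volume/
mean-HU ground truth, and an optional fibrotic voxel subset. They test
the imaging chain's exactness, not anatomical realism: no airways,
lobes, breathing motion, beam physics or scanner noise — so passing
the imaging tests demonstrates correctness of segmentation and
metrics, not robustness to real CT artefacts.

## Imaging conventions

Segmentation is 6-connectivity region growing (conservative standard;
26 available) inside the HU window, with an optional exclusion mask as
the reproducible replacement for manual trachea/bronchi resection.
Coordinates are 0-based array indices; no affine resampling. PPSH uses
10 HU bins with a 50 HU centred moving average (rounded to an odd
number of bins) and breaks peak ties towards lower HU; the histogram
parameters are conventions, configurable, since none are prescribed.
FI clamps to 0 when either delta is non-positive and flags negative
deltas as a non-fibrotic pattern (emphysema/effusion-like).

## Meta-pooling

Fixed-effect inverse-variance pooling (wᵢ = 1/SEᵢ²) with the
unweighted mean ± SD always co-reported, because published pooled
figures do not always state their weighting. Forest rows carry
±1.96·SE intervals and normalised percentage weights. Random-effects
heterogeneity modelling is out of scope.

## Problem sizes and determinism

Parameter-recovery experiments run 200 replicates of the full two-arm
design (144 animals each), seeds spawned from a single integer via
`numpy.random.SeedSequence`; the whole suite and the acceptance script
each run in well under a minute on one CPU. All generators take
explicit seeds; there is no hidden global random state, and identical
configurations reproduce outputs bit-identically.

## Known limitations

* Endpoint-only simulation; no longitudinal 4-weekly trajectories.
* No incidence-probability (quantal) dose-response fitting — the
  severity model is deliberately deterministic.
* No repopulation/incomplete-repair corrections to BED (fractions are
  once daily).
* The FI delta normalisation and the curvature axis convention are
  exposed parameters, not recovered constants; threshold/cut-off BED
  values therefore depend on stated conventions.
* Lethality endpoints, histology, dosimetry and particle-beam RBE are
  outside the package's scope.
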