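# Methods

## Pipeline model and assumptions

The package classifies subjects, not slices: each subject is a stack of
2-D grayscale slices sharing one label (+1 patient, −1 control), and the
feature vector concatenates per-slice wavelet features. The underlying
assumption is that the discriminating signal is a *structural* difference
(shape/size of anatomical regions, texture of boundaries) visible at an
intermediate spatial scale, and that slice-to-slice correspondence across
subjects is approximate at best — which is why near-shift-invariant
magnitude features are used rather than raw coefficients.

## Dual-tree complex wavelet transform

Two real wavelet trees run over rows and columns in all four combinations;
per detail orientation (LH, HL, HH) the four real subbands combine
unitarily into two complex subbands, six per level. Because the
combination is unitary and each tree is a perfect-reconstruction filter
bank, inversion is exact (≈1e-15 max abs error in the tests) for *any*
plugged-in filter set; shift invariance, not reconstruction, is what the
specific filters buy.

Filter choices (the `FilterBankSet` is pluggable; all transform tests are
property-based, so any analytic pair passes):

* **Level 1** — LeGall/CDF 5/3 biorthogonal pair. Its taps are dyadic
  rationals, so per-tree perfect reconstruction is exact in floating
  point. Tree *b* uses the same filters delayed by one input sample,
  giving the half-sample inter-tree offset after decimation.
* **Levels ≥ 2** — Kingsbury's 10-tap Q-shift orthonormal lowpass for
  tree *a*, its time reverse for tree *b* (group delays ¼ vs ¾ sample).
  The published taps carry 8 decimals (orthonormality residual ≈ 4e-9);
  at import they are Gauss–Newton-projected onto the paraunitary manifold
  with an added zero-at-Nyquist constraint, so reconstruction is exact to
  ≈1e-12 and the derived highpass annihilates constants exactly.
* **Boundary handling** — periodic (circular convolution). Symmetric
  extension does not give exact reconstruction for even-length orthonormal
  filters; the slices this pipeline sees have near-constant borders (brain
  phantoms and skull-stripped MRI alike), so wrap-around leakage is
  negligible. Images whose sides are not divisible by 2^levels are
  rejected with an error naming the required padding, never padded
  silently.

The six orientations are labelled with the standard ±15°, ±45°, ±75° set.
The shift-invariance diagnostic `shift_invariance_score` measures the
relative change of per-subband energy under a 1-pixel circular shift; on a
diagonal step edge at level 3 it is ≈0.03 for the DTCWT vs ≈0.24 for the
critically sampled single-tree DWT.

## Features

Default scale is defined *operationally* as the level whose directional
subbands are 16×16 (level 4 at 256×256, level 3 at 128×128), reproducing
1536 features per slice and 49,152 for a 32-slice subject. Complex
magnitudes are used — the shift-invariant quantity — ordered slice-major,
then orientation, then row-major pixels. The DWT baseline
(`extract_dwt_features`, PyWavelets `bior2.2`, periodization mode) takes
the approximation plus three detail subbands at the same scale:
4·(N/2^s)² per slice. No per-feature standardization is applied beyond
mean-centering inside PCA.

## PCA and Fisher LDA

PCA is computed by thin SVD of the centered matrix; with n subjects and
p ≫ n features at most n−1 components carry variance, and requesting more
raises an error naming the bound. Default retained components: **20**
(configurable), the value at which this pipeline family is typically
operated. Component signs are fixed by making each component's
largest-magnitude entry positive.

LDA uses between-class scatter averaged over the c classes and
unnormalized within-class scatter; any consistent rescaling changes only
the eigenvalues, not the axes. `S_w` gets a ridge `ε = 1e-6·tr(S_w)/p`
before the symmetric-definite generalized eigensolve — PCA-then-LDA
ordering plus this ridge keeps the problem well posed in the small-sample
regime (a literal inverse of a singular `S_w` is not meaningful). For two
classes exactly one axis is retained; its sign follows the same
largest-entry convention.

## Twin SVM

Both primal QPs keep the minus sign in their constraints (plane 2 is
plane 1 with the class roles swapped), so swapping the input classes
exchanges the fitted planes exactly; only |w·x + b| enters prediction, so
plane orientation is immaterial. Each dual is a box-constrained QP
`max e'α − ½ α'G(H'H + εI)⁻¹G'α, 0 ≤ α ≤ C`, solved by projected Newton
iterations with active-set identification; the contract is the KKT
residual (projected-gradient ∞-norm) ≤ 1e-6 — `tsvm_fit` raises if the
solver cannot meet it. On every small instance tested, the dual solution
matches an independent generic-QP solve of the primal to ≲1e-8 relative.

Defaults: `C1 = C2 = 1` with an optional grid search (`tsvm_grid_search`,
inner 3-fold stratified CV, ties toward smaller penalties — the grid is
scanned in ascending order keeping strict improvements only). The ridge
`ε` is relative to `tr(H'H)/dim` and is required because `H'H` is rank
deficient whenever features ≥ samples. Note the relative ridge penalizes
the bias, so plane *distances* are scale-equivariant only up to ~1e-2 at
extreme input scalings; *predictions* are scale-invariant. Exact distance
ties go to class 1 (patients). Only the linear kernel is provided.

## Cross-validation and statistics

`make_cv_plan` builds per-run stratified partitions (per-fold class counts
within one of proportionality) from seeds derived from one master seed;
runs default to 10. Within each fold the entire chain — PCA, optional LDA,
TSVM — is refit on training folds only (leak-free; this may make
accuracies conservative relative to protocols that fit the projections
once on all data). Per-run statistics pool confusion counts over folds
(ratios of totals, not means of ratios); the summary is mean ± sd *across
runs*, and the per-fold accuracy table is kept run-wise and fold-wise.
Undefined ratios (a fold missing one class) are NaN, excluded from means,
and logged. `recall ≡ sensitivity` exactly;
`g-mean = √(sensitivity·specificity)`.

## Synthetic phantoms

`PhantomSpec` defaults: 256×256 images, 32 slices/subject, effect size 1,
noise sd 0.05, texture scale 8. Each subject is an elliptical brain with a
textured cortical band (smoothed-noise texture, shared across the
subject's slices) and two dark ventricles; per-subject jitter (~3–10%) of
all geometric parameters models anatomical variability, a through-plane
profile scales structures across slices, and i.i.d. Gaussian noise is
added per pixel. The patient class enlarges ventricle axes by 45% and
thins the cortical band by 25% per unit effect size — label-independent
randomness, so `effect_size=0` is an exact null. What the phantoms do
*not* emulate: MRI physics (bias fields, partial-volume effects, Rician
noise), 3-D anatomy, registration error, and scanner/site heterogeneity —
passing tests demonstrate the pipeline's mechanics and its sensitivity to
controlled structural effects, not clinical performance.

## Problem sizes used in tests and the acceptance script

Statistical end-to-end checks run on reduced stacks (128×128, 8 slices —
the level-3 subbands are again 16×16, so per-slice feature counts match
the full-resolution layout): null calibration on 40 subjects, the
effect-size sweep (0, 0.5, 1.5) on 30. The strongly separated cohort
(effect 1.0, noise 0.02) uses 60 subjects at full 256×256 × 32 slices.
PCA component-bound checks use 172- and 95-subject cohorts with 4 slices
per subject, since the bound is governed by the subject count. These sizes
are the package's own choices for routine verification; larger cohorts
only tighten the sampling intervals.

## Known limitations

* Linear TSVM only; no kernelized variant.
* The CLI drives two-class problems; the LDA code supports c ≥ 2 classes
  but the pipeline assumes binary labels.
* Periodic boundary handling assumes near-constant image borders.
* Cross-validated accuracy under the null on small cohorts has binomial
  sampling spread of several percent; single-cohort values near the edge
  of the interval are expected occasionally.
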