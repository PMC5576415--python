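# adwave

Two-class classification of 2-D brain image slices (e.g. dementia patients
vs. healthy controls on axial MRI) from dual-tree complex wavelet features,
with PCA + Fisher LDA projection, a from-scratch linear Twin SVM, and a
repeated stratified cross-validation harness. A synthetic brain-phantom
generator makes the whole pipeline runnable and testable without any
clinical data.

## Method

Each subject contributes a stack of grayscale slices (PNG), min–max
normalized and bilinearly resized to 256×256. The **dual-tree complex
wavelet transform (DTCWT)** runs two real wavelet trees whose outputs form
the real and imaginary parts `T_h + j T_g` of approximately analytic
coefficients, giving six directional subbands (±15°, ±45°, ±75°) per scale
whose *magnitudes* are nearly shift invariant — unlike a critically sampled
DWT. Per slice, the magnitudes of the six subbands at the 16×16-subband
scale give 6·16·16 = 1536 features; a 32-slice stack gives 49,152 per
subject.

Features are reduced by **PCA** (SVD of the centered data; at most
n−1 components, default 20) and projected onto the **Fisher discriminant**
axis maximizing `J(w) = (w'S_B w)/(w'S_w w)` via the generalized
eigenproblem `S_B W = λ S_w W` (ridge-regularized `S_w`; one axis for two
classes). The **Twin SVM** then fits two nonparallel hyperplanes
`(w1, b1), (w2, b2)`, each proximal to one class and pushed unit distance
from the other, by solving the two box-constrained dual QPs of the primal

    min 1/2 ||X1 w1 + e b1||^2 + C1 e'ξ   s.t.  −(X2 w1 + e b1) + ξ ≥ e, ξ ≥ 0

(and symmetrically for the other plane); a sample takes the class of the
nearer plane. Evaluation is repeated stratified k-fold cross-validation
with per-fold refitting of the whole chain, reporting accuracy,
sensitivity, specificity, precision, recall, F-measure and
g-mean = √(sensitivity·specificity) as mean ± sd over runs.

See `docs/methods.md` for assumptions, parameter defaults, and numerical
choices.

## Worked example

```python
from adwave import (PhantomSpec, generate_cohort, build_feature_matrix,
                    PipelineConfig, run_pipeline_cv)

spec = PhantomSpec(image_size=128, n_slices=8, effect_size=1.0,
                   noise_sd=0.05, seed=42)
stacks, labels = generate_cohort(spec, n_patients=15, n_controls=15)
fm = build_feature_matrix(stacks, transform="dtcwt", scale=3)
report = run_pipeline_cv(fm, PipelineConfig(scale=3, n_components=20,
                                            k=5, runs=10, seed=0))
for name, (m, s) in report.summary.items():
    print(f"{name:12s} {100*m:6.2f} +- {100*s:.2f} %")
```

prints

```
accuracy      99.67 +- 1.05 %
sensitivity   99.33 +- 2.11 %
specificity  100.00 +- 0.00 %
precision    100.00 +- 0.00 %
recall        99.33 +- 2.11 %
f_measure     99.66 +- 1.09 %
gmean         99.66 +- 1.07 %
```

i.e. on a 30-subject phantom cohort whose patient class has enlarged
ventricles and a thinned cortical band (effect size 1.0, noise sd 0.05),
the DTCWT + PCA + LDA + TSVM chain separates the classes almost perfectly;
the per-run per-fold accuracy table is in `report.fold_accuracy`. Setting
`effect_size=0` drops accuracy to chance, and `use_lda=False` /
`transform="dwt"` in `PipelineConfig` select the ablation variants.

The same pipeline runs from the shell:

```sh
adwave synth --out cohort/ --n-patients 15 --n-controls 15 \
             --image-size 128 --n-slices 8 --seed 42
adwave evaluate --manifest cohort/manifest.tsv --scale 3 \
                --out-prefix results/run --k 5 --runs 10 --seed 0
```

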