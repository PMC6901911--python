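# dilradiomics

Discriminating the dominant intra-prostatic lesion (DIL) from contralateral
normal prostatic tissue (NT) on paired T2-weighted and ADC MR volumes, using
radiomics, partial least squares correlation (PLSC) and a small neural
classifier — exercised end to end on synthetic cohorts.

## Who this is for

Researchers in quantitative prostate MRI who want a fully inspectable,
deterministic implementation of the classic radiomics → latent-variable →
classifier cascade: 168 texture/intensity features per region per modality,
two-block PLSC with non-parametric inference, an 8:5:1 multilayer
perceptron with two validation strategies, sliding-window lesion
probability mapping, and a contour-robustness test. Because no patient
data ships with the package, a first-class synthetic-cohort module
generates paired-modality phantoms with controllable lesion effect size
(including a null setting) so every stage is testable offline.

## The method

For each subject, the DIL and a mirrored contralateral NT region are
contoured on co-registered T2W and ADC volumes (the ADC map comes from a
per-voxel log-linear fit of mono-exponential DWI decay,
S(b) = S0·e^(−b·ADC)). After harmonization (division by the subject's
NT-mean intensity, cancelling scanner gain), 168 radiomics features are
extracted per ROI per modality in eight categories: intensity histogram
(9), gray-level run length (7), Laws kernels (18), discrete orthonormal
Stockwell transform (18), local binary patterns (6), 2-D wavelets (48),
Gabor filters (40) and gray-level co-occurrence (22).

Two observation blocks X (T2W) and Y (ADC), rows = ROIs, columns = 168
z-scored features, are related by the SVD of their cross-covariance

    R = XᵀY/(n−1) = U · diag(δ) · Vᵀ,

whose singular-vector pairs (saliences) define latent variables
Lx = XU, Ly = YV with maximal covariance; the inertia Σδ² is the total
common variance. Inference is non-parametric: a row-permutation test on
the inertia, and bootstrap ratios (mean/std of a salience over resamples,
|ratio| > 2 ≈ significant) to rank the original features. Latent
variables that pass Holm-corrected one-way ANOVA (DIL vs NT, α = 0.05)
and a mean-silhouette filter (≥ 0.5) form the discriminant set fed to a
feed-forward 8:5:1 perceptron with bipolar sigmoid activations, trained
by full-batch back-propagation (MSE loss, learning rate 0.01, momentum
0.01). Validation uses subject-level leave-one-out cross-validation and
100 stratified 67/33 splits, with ROC analytics (trapezoidal AUROC,
optimal cut-point closest to the (0,1) corner, PPV/NPV). A trained model
applied to every 25×25 window of a slice yields a lesion probability
map; robustness to contouring is probed by re-running the analysis with
contours scaled 1.2× and shifted one voxel per axis, comparing latent
scores by ANOVA against Fc = F₀.₉₅(1, 2n−2).

## Worked example

```python
from dilradiomics import synthcohort, plsc, ann
from dilradiomics.pipeline import extract_features, latent_dataset

cohort = synthcohort.generate_cohort(synthcohort.CohortConfig(seed=42))
table = extract_features(cohort)                  # 468 rows x 168 features
bx, by = plsc.build_blocks(table)
model = plsc.fit_plsc(bx, by)
perm = plsc.permutation_test_inertia(bx, by, n_permutations=10_000, seed=1)
sel = plsc.select_discriminant(model)
X, y, subjects, _ = latent_dataset(sel)
cv = ann.loocv(X, y, subjects, n_hidden=5, init_seed=42)
print(f"permutation p = {perm.p_value:.6f}")
print(f"selected latents per modality: {len(sel.selected_x)}, {len(sel.selected_y)}")
print(f"LOOCV AUROC = {cv.roc.auroc:.3f}")
```

prints

```
permutation p = 0.000100
selected latents per modality: 1, 1
LOOCV AUROC = 1.000
```

The permutation p of 1/10001 means the observed cross-modality inertia
was never reached in 10,000 row permutations — the two modalities share
significant common variance. On this strongly separated synthetic cohort
a single latent variable per modality passes the ANOVA + silhouette
filter and carries essentially all of the class contrast, so the
classifier separates DIL from NT rows perfectly under leave-one-out.

The same computation is available stage-by-stage from the shell:

```bash
dilradiomics all --workdir results/pipeline --seed 42
```

or through the numbered drivers under `analysis/`
(`01_simulate_cohort.py` … `06_contour_robustness.py`), each of which
writes its tables under `results/pipeline/`.

## Layout

- `src/dilradiomics/synthcohort.py` — synthetic paired-modality cohorts,
  DWI simulation, fixture images
- `src/dilradiomics/radfeat/` — ADC fitting, harmonization, the
  168-feature extractor
- `src/dilradiomics/plsc.py` — two-block PLSC, permutation/bootstrap
  inference, latent selection
- `src/dilradiomics/ann.py` — the MLP, training, LOOCV/split validation,
  ROC analytics
- `src/dilradiomics/lesionmap.py` — probability mapping, Dice, contour
  perturbation and robustness ANOVA
- `src/dilradiomics/pipeline.py`, `cli.py` — stage orchestration and the
  `dilradiomics` command
- `docs/methods.md` — modelling assumptions, parameter choices and known
  limitations
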