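# Methods

This note documents the models, conventions and design choices behind
`dilradiomics`, in the order the pipeline runs them.

## Synthetic cohorts

No patient imaging ships with the package; the generator produces the
cohorts every statistical claim is tested on, so its design *is* the
study design.

**Tissue model.** Each modality volume is a Gaussian random field: white
noise smoothed with an anisotropic Gaussian kernel (in-plane correlation
length `corr_length` voxels, half that along z), renormalized to unit
marginal variance via the kernel's L2 norm, then scaled and shifted to
the tissue's marginal std and mean. Defaults: T2W normal tissue mean 2.0,
std 0.25 (arbitrary units); ADC normal tissue mean 1.4×10⁻³, std
1.5×10⁻⁴ mm²/s; correlation length 1.5 voxels. A latent field shared
between the modalities with weight `cross_modality_coupling` (default
0.5) provides the common variance the PLSC is meant to find.

**Lesion model.** The contoured DIL is an ellipsoid (default in-plane
radius 8 voxels = 8 mm diameter at 0.5 mm spacing, z semi-axis r/3
slices ≈ 15 mm at 3 mm slices) placed off-midline; the NT reference is
its mirror across the mid-sagittal plane. The lesion *signal* is a
second random field with lower mean (deficit `mean_contrast` = 1 NT-std
per unit effect size) and longer correlation length (+35 % per unit
effect), blended into the background by a smooth weight that extends
~50 % beyond the contoured core with a blurred margin. The rim encodes
two facts about real lesions that a hard-edged phantom gets wrong: the
visible abnormality exceeds a conservative contour (point-spread and
partial-volume blur, peritumoral signal change), and consequently
moderate contour perturbations re-sample lesion-like tissue. Without it,
the 1.2× scaling of the contour test samples pure normal tissue — a
regime no real contour experiment is in. Per-subject lesion severity is
drawn from U(0.6, 1.4)× the cohort effect size, emulating the spread of
tumor grades in a real cohort; between-subject variance of latent scores
is dominated by this heterogeneity, as it is in patient data. With
`effect_size = 0` no lesion modification is applied at all: DIL and NT
regions are samples of the identical process (verified bit-exactly and
by calibrated two-sample tests).

**DWI.** Optional DWI stacks follow S(b) = S0·e^(−b·ADC) at b = 50, 400,
800 s/mm², with optional Gaussian or Rician noise. Noiseless simulation
followed by the log-linear fit returns the input ADC to machine
precision (round-trip test).

**What the generator does not emulate.** Prostate anatomy and zonal
structure, coil/bias fields, Rician noise floors in the weighted images,
registration error between modalities (volumes are generated
co-registered, which replaces the affine co-registration a real pipeline
would need), slice-profile effects, and lesion-shape variability (the
mask geometry is identical across subjects; only texture and severity
vary). Passing tests therefore demonstrate correctness and calibration
of the *analysis*, not expected performance on patient data.

## Feature extraction

All texture categories run per axial slice on the ROI bounding box, with
out-of-mask voxels replaced by the slice's in-mask mean (avoids
mask-edge gradients dominating filter responses), and per-slice features
averaged over slices with ≥ 16 in-mask pixels. Intensity histogram
features pool the full 3-D masked voxel set. Two uniform conventions
apply everywhere: **energy** of a map is its mean squared value;
**entropy** is the Shannon entropy (bits) of a 256-bin min–max histogram
of the map. Skewness/kurtosis of zero-variance data are 0.

Category specifics:

- **IBHF (9)** — mean, std, skewness, kurtosis, histogram entropy,
  central moments 3–6.
- **GLRL (7)** — Galloway SRE/LRE/GLN/RP/RLN/LGRE/HGRE on a 16-level
  quantization, runs enumerated inside maximal in-mask line segments
  (run counts conserve the in-mask pixel count per direction), averaged
  over the four in-plane directions.
- **LAWS (18)** — 2-D outer products of L5/E5/S5/R5; the nine map groups
  with asymmetric pairs averaged *before* the energy/entropy operators
  (configurable).
- **DOST (18)** — an FFT-based orthonormal dyadic band partition: the
  unitary DFT spectrum is split into octave bands and each band is
  inverse-transformed by a unitary DFT of its own length, applied
  separably to the edge-padded power-of-two square. Parseval holds
  exactly. The |coefficient| matrix is split 3×3; block energies and
  entropies are the features.
- **LBP (6)** — square eight-neighborhood codes (threshold neighbor ≥
  center, no sub-pixel interpolation); energy, entropy, mean, std,
  skewness, kurtosis of the code map. The published feature list for
  this category repeats "entropy" twice, which we read as a typo for
  energy + entropy.
- **2DWT (48)** — six iterated `dwt2` levels (Daubechies-4,
  periodization mode, so the transform is orthonormal), keeping the
  approximation and the three detail maps at every level (24 maps).
  Slices are symmetrically padded to at least 16×16 and even dimensions.
- **2DGF (40)** — 5 wavelengths {2,4,8,16,32} voxels × 4 orientations
  {0°,45°,90°,135°}, bandwidth 1; kernels are DC-subtracted and applied
  with edge-replicated padding so constant inputs give exactly zero
  response.
- **GLCM (22)** — `skimage` co-occurrence matrices (8-bit quantization,
  symmetric, normalized, averaged over the four unit offsets), with the
  22 Haralick/Soh/Clausi statistics computed vectorized; sum variance is
  defined about the sum average; correlation-type statistics of a
  degenerate matrix are 0.

Harmonization divides the whole volume by the NT-mask mean and is
applied to both modalities by default (`harmonize_adc` flag exempts the
ADC map); any global gain then cancels exactly, which is asserted as a
pipeline invariance. ADC fitting flags voxels with non-positive signal
and sets them to 0 rather than taking an invalid logarithm.

## PLSC and inference

The cross-product uses the covariance scaling 1/(n−1); any positive
scale leaves saliences, score geometry and p-values unchanged. SVD signs
are fixed deterministically (largest-|loading| element of each left
salience made positive, right salience flipped along with it).

- **Permutation test** — whole rows of the second block are permuted
  (preserving within-block feature correlation), the inertia ‖XᵀY‖²_F
  recomputed, p = (#{null ≥ observed}+1)/(B+1). Type-I error is
  calibrated ≈ 5 % and null p-values are uniform (checked over 200
  replicate random blocks at B = 200).
- **Bootstrap ratios** — rows resampled with replacement, PLSC refitted,
  each resampled salience column sign-aligned to the original (full
  Procrustes alignment is deliberately not applied; per-column sign
  alignment suffices at these separations). The ratio mean/std is taken
  per original feature for a chosen latent dimension (default: the
  first), matching the convention of ranking original features rather
  than latent variables; |ratio| > 2 flags significance. A salience
  reproduced identically in every resample (std ≤ 1e-9·|mean|) gets an
  infinite-ratio sentinel and ranks first. Under pure noise the flag
  rate is ≈ 5 %.
- **Selection** — per block, the leading latents are tested by one-way
  ANOVA with Holm step-down across the tested family (per modality) at
  α = 0.05, plus a mean-silhouette filter at 0.5; the first
  `k_per_modality` (default 4) passing both are retained. On the default
  synthetic cohort the class contrast concentrates in the first latent
  of each modality, so the selected set has 2 variables rather than the
  full 8; the classifier interface is dimension-agnostic.
- **Projection** — new raw rows are standardized with the stored
  training column means/scales and multiplied by the saliences. The
  leave-one-out pipeline variant that refits PLSC, selection and scaling
  inside every fold (no leakage) is `pipeline.loocv_with_plsc_refit`;
  the plain `ann.loocv` operates on a fixed latent dataset (fit-once
  protocol). Both are exposed because the refit protocol is the
  conservative default for real studies while the fit-once protocol is
  cheaper and matches the fixed-latent validation design.

## Classifier

The bipolar sigmoid is f(x) = 2/(1+e^(−x)) − 1 = tanh(x/2); hidden and
output layers use it. Weights initialize uniformly on [−0.5, 0.5] from a
stored seed; training is full-batch gradient descent on MSE with
momentum (defaults 0.01/0.01, targets DIL = +1, NT = −1), gradients
verified against central finite differences to 1e−6 relative. The eight
(or fewer) latent inputs are z-scored with training-set statistics
before training — raw PLSC scores have arbitrary scale, and a fixed
learning rate of 0.01 presumes O(1) inputs; the scaler is stored with
the model and applied to every projected row at inference.

Validation: (1) subject-level LOOCV — a subject's DIL and NT rows leave
together, the same initial weights are reused per fold, held-out
predictions are pooled into one ROC and a CCF-vs-epoch curve whose
stopping epoch is the first within 10 % of the plateau (plateau = mean
of the final 10 % of epochs; the alternative "10 % of total rise"
reading is selectable); (2) 100 stratified 67/33 subject-level splits
with percentile (2.5/97.5) confidence intervals for AUROC/PPV/NPV. CCF
during training uses the sign rule (score ≥ 0); reported operating
points use the ROC cut-point closest to (0,1). Cross-cohort evaluation
trains on group A and applies the frozen model to the disjoint group B.

## Probability mapping and contour robustness

Each 25×25 in-plane window (default stride 1; the pipeline stage uses
stride 4 and analysis-sized strides for tractability) is treated as a
full-square ROI of a volume harmonized by the subject's NT mean,
featurized in both modalities, projected onto the selected latents,
z-scored with the training scaler and scored by the network;
p = (score+1)/2. Thresholding at `p_thr` assigns each window probability
to the stride-block of voxels nearest its center. The printed threshold
0.001 is extremely permissive — on synthetic subjects it selects nearly
the whole mapped area, so the Dice against the true lesion is low
(~0.18) even though in-lesion probabilities clearly exceed out-of-lesion
ones; the threshold is kept as printed and exposed as a parameter.

The contour test perturbs the DIL mask (nearest-neighbor isotropic
scaling 1.2× about the centroid, then a +1 voxel shift per axis — read
as a single translation, not a union over directions), re-extracts,
re-projects, and compares original vs perturbed DIL-row scores per
latent variable by one-way ANOVA: two groups of n subjects, df (1,
2n−2), pass iff F < F₀.₉₅. For n = 19 the critical value is 4.11. Using
DIL rows gives one score per subject per latent, consistent with that
degrees-of-freedom accounting.

## Numerical choices and problem sizes

- Salience orthonormality is asserted to 1e−8; SVD ties are broken by
  the deterministic sign convention.
- Degenerate inputs: constant ROIs quantize to all zeros; zero-variance
  feature columns standardize to zero with unit stored scale; silhouette
  of a constant score column is 0; ANOVA of identical groups returns
  F = 0, p = 1.
- The test suite runs its statistical calibrations at stated reduced
  sizes chosen for a single-CPU run: 200 replicate cohorts for the
  null-rejection rate, 200×B=200 for permutation calibration, n_boot =
  500 for the bootstrap false-positive rate, 20 generator seeds for the
  finiteness fuzz; the study-scale fixture (117 subjects, 468 ROI
  extractions, B = 10,000) is built once per session.
- Master seeds: every stage derives its RNG seed from the pipeline seed
  by hashing the stage name, so stages are independently reproducible.

## Known limitations

- All transform-based features are 2-D per slice; no 3-D texture or
  morphological/shape features (the latter deliberately excluded from
  the descriptor).
- The synthetic lesion geometry is fixed across subjects; Dice values on
  phantoms are therefore not comparable to patient results, and
  identical masks can yield identical Dice across subjects when the
  permissive threshold saturates the patch.
- Silhouette and ANOVA assume two labeled clusters; multi-lesion or
  multi-class extensions are out of scope.
- The MLP is intentionally minimal (no regularization, no early
  stopping beyond the CCF analysis); it is the analysis object, not a
  production classifier.
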