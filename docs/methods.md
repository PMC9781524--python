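# Methods

This note documents the models, conventions and design choices behind
`oxyradiomics`: what each stage computes, which parameters matter, what the
synthetic cohort does and does not emulate, and the numerical edge-case
rules. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. qBOLD biomarker model

The pipeline derives four voxelwise oxygen-metabolism biomarkers from
transverse relaxation rates R2* and R2 (1/s), cerebral blood volume CBV
(fraction) and cerebral blood flow CBF (mL/100 g/min), all co-registered on
one grid:

| quantity | formula | units |
|---|---|---|
| OEF | (R2* − R2) / ((4/3)·π·γ·Δχ·Hct·B0 · CBV) | fraction (percent for feature extraction) |
| CMRO2 | Ca · CBF · OEF | µmol/100 g/min |
| capiPO2 | P50 · (2/OEF − 1)^(1/h) | mmHg |
| mitoPO2 | capiPO2 − CMRO2 / L | mmHg |

Default constants: γ = 2.67502×10⁸ rad/s/T, Δχ = 0.264×10⁻⁶,
Hct = 0.42·0.85 (microvascular correction), B0 = 3 T, Ca = 8.68 µmol O2/mL
blood, P50 = 27 mmHg, h = 2.7, L = 4.4 µmol/100 g/min/mmHg. All are
overridable through `QBOLDConstants`.

**Unit conventions.** Ca is carried in µmol/mL so the Fick product
Ca·CBF·OEF lands directly in µmol/100 g/min when CBF is in mL/100 g/min.
The conductivity L is carried per 100 g so CMRO2/L is a tension in mmHg.
These bookkeeping choices are stated here because the biomarker literature
is inconsistent about them; changing either rescales CMRO2 or mitoPO2 by a
constant factor.

The capillary model gives capiPO2 → P50 as OEF → 1 and diverges as
OEF → 0; voxels with OEF ≤ 0, CBV ≤ 0 or R2* < R2 have no physical solution
and are marked invalid rather than clamped. mitoPO2 may be negative before
range masking (it proxies hypoxia; strongly negative values are artefacts
and are removed by the range threshold).

**Physiological ranges.** Values outside the closed interval per quantity
are *removed* (invalidated), never clipped: OEF 0–100 % (bin width 1.5),
CMRO2 0–1000 µmol/100 g/min (width 15), capiPO2 and mitoPO2 0–200 mmHg
(width 3). Each range/width pair yields ceil(range/width) = 67 bins.
Boundary values are retained (closed interval); the interval convention is
ours — the source protocol does not state one.

## 2. Relaxometry

Rate maps are fitted voxelwise by unweighted least squares on
log-magnitude vs. echo time (slope negated). The choice of a log-linear
fit over a nonlinear one is a documented convention: it is deterministic,
exact on noiseless mono-exponential data, invariant to global magnitude
scaling, and has a closed-form standard error used in the tests. Voxels
with any non-positive magnitude are invalid; fitted rates are clamped at
zero. Background-field and stimulated-echo corrections are **not**
implemented — inputs are assumed corrected upstream.

## 3. Radiomic features

107 features per map VOI: 14 shape, 18 first-order, and 75 texture
features over five matrix families (24 GLCM, 14 GLDM, 16 GLRLM, 16 GLSZM,
5 NGTDM), following the IBSI-aligned naming and definitions of the
mainstream radiomics literature.

**Discretization** is fixed-bin-width on the fixed physiological range
(lower bound anchored at the stated range minimum, not at the VOI minimum):
label = floor((v − lower)/width) + 1, with the upper bound assigned the
last bin. Gray levels *are* the bin numbers 1..67; empty bins keep their
index. Where a formula needs the number of gray levels (GLCM Idmn/Idn),
the fixed bin count is used. Note that the printed range/width pairs give
66.67 bins exactly; we use fixed widths with a ceiling (67 bins), one of
the two readings consistent with the stated bin number, and document it
here because the alternative (exact 67 equal bins) changes widths by 0.5 %.

**Texture conventions.**
- GLCM and GLRLM: distance 1, the 13 unique 3D directions, symmetric
  co-occurrence matrices, features computed per direction then averaged;
  directions without voxel pairs are skipped.
- GLSZM: zones are 26-connected components of equal level (direction-free).
- GLDM: a 26-neighbor is dependent if |Δlevel| ≤ α (default 0); the
  recorded dependence size is the dependent-neighbor count + 1, so sizes
  start at 1 and small/large-dependence emphases are well defined.
- NGTDM: per-voxel comparison with the mean level of its valid
  26-neighbors; voxels without valid neighbors are excluded from Nvp.

**Degenerate rules** (all unit-tested): GLCM Correlation of a
zero-variance VOI is 1; MCC of a single-level matrix is 1; a single-voxel
VOI synthesizes the certain co-occurrence of its lone level with itself;
NGTDM Coarseness is capped at 10⁶ when its denominator vanishes, and
Busyness/Complexity/Strength/Contrast fall back to 0 with one gray level.
First-order: entropy/uniformity on the discretized histogram; kurtosis is
non-excess (Gaussian = 3); a constant VOI has variance 0, entropy 0,
uniformity 1, skewness 0, kurtosis 3. Energy carries no intensity shift;
Total Energy = voxel volume × Energy.

**Shape.** Surface quantities come from marching cubes on the zero-padded
mask with light Gaussian anti-aliasing (σ = 0.8 voxels) — this removes most
of the staircase surface-area bias (≈9 % for a voxelized sphere) while
changing the enclosed volume by < 1.5 %; tiny masks fall back to the raw
binary iso-surface. Axis lengths are 4·√eigenvalue of the sample
covariance of physical voxel centers. Maximum diameters use surface-voxel
centers: 3D over all pairs, 2D within each plane of fixed slice/row/column
index. Single-voxel masks return documented fallbacks (axis lengths 0,
elongation/flatness 1, diameters 0) instead of failing.

Every texture feature is verified on small volumes against brute-force
oracles that enumerate voxel pairs, runs, zones, dependences and
neighborhoods with explicit loops (1e-9 relative tolerance).

## 4. Feature stability

ICC(2,1) — two-way random effects, absolute agreement, single measurement —
from the ANOVA mean-squares decomposition; configurable to ICC(3,1). The
form is our choice of the radiomics-stability literature's standard; a
table with zero total variance returns 1.0 (perfect agreement). The
implementation is cross-checked against `pingouin`'s ICC(A,1) in the tests.
Features with ICC ≥ 0.8 are retained. A curated 74-feature list (3 shape /
18 first-order / 19 GLCM / 9 GLDM / 10 GLRLM / 11 GLSZM / 4 NGTDM) is
bundled as package data so the stability-filtered pipeline runs without a
second-segmentation experiment.

## 5. Balancing, partitioning, normalization

SMOTE: each synthetic minority vector is x + u·(x_nn − x) with
u ~ U(0,1) and x_nn one of the k = 5 nearest minority neighbors (k is the
original SMOTE default; the source protocol states none). Parent ids are
recorded per synthetic row, making colinearity and the convex-hull
property verifiable. Balancing 96 vs 37 yields 59 synthetic rows, 192
total.

Two modes:

- **train-only (default)**: split first, oversample the training partition
  only. Validation/test stay purely real.
- **paper-faithful**: balance the full cohort, then split — reproducing the
  192-case bookkeeping of the study design.

*Measured caveat*: under a null configuration (classes identical), the
paper-faithful mode still produces held-out AUROC far above 0.5, because
synthetic rows carry the minority label and are detectably interpolated —
oversampling-before-splitting leaks label information into the test set.
This is why train-only is the default and why the null-control check runs
in train-only mode.

Partitioning is stratified 70/15/15 with *global* largest-remainder sizes
(192 → 134/29/29) and controlled per-class rounding that preserves class
proportions within ±1 case; train receives ties. Z-scoring uses
training-partition statistics (sample SD) for all partitions; zero-variance
columns are dropped with a warning.

## 6. 1D-CNN

Architecture (input length 74 for one map, 296 for all four):
conv(8 filters, kernel 2, stride 1, same) + ReLU → maxpool(2, stride 1,
same) → conv(8, 3, 1, same) + ReLU → dropout 0.2 → maxpool(2, 1, same) →
conv(8, 3, 1, same) + ReLU → dropout 0.2 → maxpool(2, stride 2, same) →
flatten → dense(flatten size) + ReLU → dropout 0.2 → dense(1, sigmoid).
Stride-1 same-padded layers preserve length, so 74 → 37×8 = 296 flatten
units and 296 → 148×8 = 1184. "Same" padding for the even kernel 2 pads on
the right. The first dense width equals the flatten size, as implied by
the layer-size table of the source architecture (it states no width
explicitly).

Training: binary cross-entropy, Adam (lr 10⁻³, β₁ 0.9, β₂ 0.999), up to
300 epochs of 5 batches each (batch size = ceil(n_train/5)), shuffling
every epoch. The output layer is initialized near zero so training starts
at p ≈ 0.5 (first-batch BCE ≈ ln 2). Model selection keeps the
best-validation-accuracy checkpoint (earliest on ties) — a documented
choice, since the source states no selection rule. The network is
implemented in NumPy (explicit forward/backward passes); all randomness —
initialization, shuffling, dropout — flows from one seeded generator, so
training is bit-reproducible on a fixed platform, and dropout is disabled
at inference, so prediction is deterministic.

## 7. Evaluation

Accuracy, sensitivity, specificity, precision, F-score at threshold 0.5 on
the sigmoid output, and AUROC from the full ranking via the Mann–Whitney
pair statistic with half-weight ties (equal to trapezoidal ROC
integration, asserted in tests). The positive class defaults to GB;
undefined ratios are NaN with a warning, never silently 0. Metrics are
binary-task only.

## 8. Synthetic cohort: what it emulates, and what it does not

The generator stands in for an unavailable clinical cohort of 96
glioblastoma and 37 brain-metastasis cases. Its central design constraint
mirrors the study's key observation: *per-case mean/median biomarker values
carry no class signal, while intratumoral spatial texture does.*

- **Masks**: randomly rotated perturbed ellipsoids (semi-axes 8–14 mm on a
  48³ grid at 1 mm isotropic), single 26-connected component, ≥ 200 voxels.
  A collapsed radius range degenerates to an exact sphere (deterministic
  voxel count).
- **Fields**: Gaussian random fields (white noise smoothed with a Gaussian
  kernel), standardized over the mask and rescaled to a per-case target
  mean and SD, plus white measurement noise.
- **Class structure**: the per-case target means of all quantities are
  drawn from the *same* distributions for both classes (R2 12±1 s⁻¹,
  R2*−R2 4.5±0.7 s⁻¹, CBV 0.04±0.004, CBF 40±5 mL/100 g/min — chosen once
  to land OEF near 0.35 and CMRO2 near 120 µmol/100 g/min, mid-physiological
  for contrast-enhancing tumors). Classes differ **only** in the spatial
  correlation length of the CMRO2-driving fields (R2*−R2 and CBF): 1.5 mm
  for GB-like vs 3.5 mm for BM-like, at equal texture contrast (relative SD
  0.35). CBV and the R2 baseline share one texture (2.5 mm, contrast 0.15)
  across classes.

Equal contrast with differing correlation length means the *marginal*
voxel-value distribution is class-identical by construction, so the
per-case mean of any (even nonlinear) derived map is class-matched in
distribution, while second-order texture statistics separate the classes.
The correlation-length gap is a calibration choice, not a clinical fact:
the source reports no quantitative texture difference between the tumor
types. Passing end-to-end checks therefore demonstrates that the
*pipeline* can recover texture-coded class structure that mean values miss
— not that real GB/BM differ by this mechanism or this effect size. The
generator also makes no attempt at MR physics beyond mono-exponential echo
decay: no k-space sampling, no perfusion bolus dynamics, no
contrast-enhancement morphology, no spatially varying noise.

## 9. Problem sizes and determinism

Default end-to-end runs use the 96/37 cohort on a 48³ grid; one full
pipeline (generation, mapping, extraction of 107 features per case,
training 300 epochs, evaluation) takes about a minute on one CPU core.
The replicate-based checks use 5 pipeline replicates and 20
mean-comparison cohorts of 50 cases per class — sizes chosen to keep the
whole suite at desk scale while leaving the statistical assertions
well-powered. All stages are seeded through `numpy.random.SeedSequence`
spawning; identical configuration and seed reproduce cohorts, feature
tables and trained weights bit-identically.

## 10. Known limitations

- CBV/CBF arrive precomputed (or synthetic); no DSC deconvolution or AIF
  detection.
- The relaxometry inputs are assumed corrected for background fields and
  stimulated echoes.
- Shape mesh quantities are exact only up to the iso-surface triangulation
  (axis permutations change Mesh Volume/Surface Area at the 10⁻³ relative
  level).
- The stability module quantifies two-segmentation ICC only; no
  erosion/dilation robustness analysis.
- Binary task only; no multi-class averaging, no AUROC comparison tests
  (DeLong), no calibration analysis.
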