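# Methods

## Phantom and acquisition model

Each synthetic patient is a scene of axis-aligned ellipsoidal organs and
spherical lesions rasterized on a (slice, row, col) grid with voxel centers
at `index × spacing` (defaults 3.27 mm slices, 2.73 mm pixels; clinical-geometry
frames are 256 × 256, the desk-scale test grids are 64 × 64 × 40). Later
scene entries overwrite earlier ones, so lesions are painted over organs.
Every shape is given a *target SUV*; the stored concentration is
`SUV × decayed_dose / weight` (kBq/ml), which makes SUV conversion an exact
round trip — ROI statistics on the noiseless truth recover the scene
definition to machine precision, giving every downstream test a sharp
oracle.

Patients are sampled as: weight ~ Normal(79, 18) kg clipped to [34, 150]
(the cohort statistics of the study protocol this emulates), dose
7 MBq/kg, ¹⁸F half-life 6586.2 s, injection-to-scan delay 3600 s; 20% of
patients carry no lesions, the rest 1–5 spherical lesions with diameters
6–30 mm and SUV 2–15, deliberately straddling the 7 mm / SUV 0.5 analysis
filters so both filter branches occur in realistic datasets.

Acquisition at `t` seconds per bed draws
`counts ~ Poisson(blur(C) × 1000 × V_vox × t × η)` and returns
`counts / (1000 × V_vox × t × η)`, with `blur` an isotropic Gaussian PSF
(FWHM 5 mm default) and detector sensitivity η = 0.01 — both order-of-
magnitude clinical values, both configurable. The estimator is unbiased
for the blurred truth and its variance scales as 1/t, which is the
statistical content of a short-time-frame protocol: the 30 s/90 s error-SD
ratio is √3. All three bed times are simulated from one shared truth per
session, so volumes are intrinsically co-registered.

**What the phantom does not emulate.** Iterative-reconstruction noise
texture (the Poisson surrogate is a declared modeling choice, not inferred
from scanner data), attenuation/scatter/randoms, anatomical texture,
motion, and inter-scan misregistration. Consequently, passing tests show
that the *measurement chain* (metrics, filters, agreement statistics,
training loop) behaves correctly and that denoisers exploit genuine
counting-noise structure; they do not certify performance on clinical
reconstructions.

## SUV quantitation

Body-weight SUV with tissue density 1 g/ml; no lean-body-mass variant.
SUVpeak follows the common 1.0 cm³-sphere definition: candidate centers are
restricted to lesion voxels, sphere membership is voxel-center-in-sphere
under the anisotropic spacing (radius 6.204 mm; 39 voxels ≈ 0.95 cm³ at
default spacing), and sphere voxels may extend beyond the mask. Sphere
voxels beyond the *grid* are excluded from the mean, so the fast
convolution path and a brute-force clipped-sphere scan agree exactly (this
equivalence is asserted in tests). Because the sphere can reach outside the
mask, a hotter neighboring structure can make SUVpeak exceed the in-mask
SUVmax for faint lesions; the dominance `SUVmax ≥ SUVpeak` is therefore a
property of isolated lesions, not a constructor invariant.

`max_length` defaults to the largest axis-aligned bounding-box extent
(counting each voxel at full spacing) — cheap and monotone in lesion size;
an `exact` flag switches to the maximum pairwise voxel-center distance for
small lesions where the box overestimates oblique extents.

## Similarity metrics and agreement

RMSE and ISSIM = 1 − SSIM per axial slice; SSIM uses the 7 × 7 uniform
window with K1 = 0.01, K2 = 0.03 (the scikit-image defaults), with
`data_range` set to the study's FT-volume maximum (configurable — the
choice matters because PET slices have no fixed dynamic range). Relative
metrics are computed from slice-averaged absolutes pooled over the test
set; per-slice-relative-then-average is available behind a flag but is not
the default aggregation. Bland–Altman differences are absolute SUV
differences (denoised − FT); quartiles use linear interpolation (frozen in
tests). R² is the squared Pearson correlation — a coefficient of
determination about the identity line would double-count the bias that the
median-bias column already reports, so the correlation form was chosen and
is documented here.

## Lesion pipeline

Masks come from a pluggable provider: phantom ground truth, an SUV
threshold on the FT volume (default 2.5, giving a fully automatic
download-free mode), or an external label file from any outside segmenter.
Components use 26-connectivity (6 available), labeled deterministically in
first-voxel raster order. Exclusion is strict: a lesion is dropped iff
`max_length < 7 mm` **or** `mean SUV < 0.5`; borderline equality retains.
The ROI is segmented once on FT and the identical voxel set is reused on
the denoised volume.

## Model zoo and losses

Full-scale architectures are *layer specifications* with analytic
parameter accounting (U-Net generator 54,407,809 parameters at 1-in/1-out;
3-layer PatchGAN on paired input 2,764,609; ResNet generator ≈ 11.4 M).
"Base width 64" is the interpretation adopted for the generators'
channel progression, since a literal 64-channel innermost layer is
inconsistent with those counts. Norm-followed convolutions carry no bias.

Runtime-trainable models are a **tiny tier**: stride-1 residual CNNs
(width 8, depth 2 by default; 2.5D variants take 2k+1 slice channels and
predict the central-slice residual; a 3D variant runs on 32-slice chunks
with tail-aligned overlap-averaged reassembly). They run on a small
hand-written reverse-mode autograd over numpy whose N-d convolution is
gradient-checked against finite differences in the test suite. The choice
keeps the whole pipeline dependency-light and CPU-reproducible; externally
trained networks can be plugged in through the same volume-wise denoiser
interface.

Losses: L1 everywhere by default; Charbonnier (ε = 1e−3, sum convention)
as the SwinIR-style alternative; least-squares adversarial objective for
both pix2pix and CycleGAN;
identity, image-prior, cycle and supervised reconstruction terms with
default weights 2.2, 9.2, 10.0 and 9.2 respectively, the pix2pix distance
weight 10.0. The pix2pix discriminator consumes the image difference. The
CycleGAN loop trains two residual generators and two patch discriminators;
LT/FT pairing is ignored except in supervised mode.

Training: Adam, optional decoupled weight decay, in-plane flip
augmentation applied identically to input and target, intensities
normalized by a fixed scale (99.9th percentile of FT training values,
inverted before any metric is computed), best checkpoint selected by
validation SSIM. Schedules: constant, cosine, constant-then-linear-to-zero
(2/3 hold), and reduce-on-plateau (factor 0.5, patience 5 — declared
defaults, as the plateau hyperparameters were an open choice).

## Problem sizes and numerical choices

The default benchmark runs 6/2/2 patients on 40 × 64 × 64 grids, tiny-tier
width-8/depth-2 models trained 5 epochs × 40 steps at batch 8 and learning
rate 2e−3 — sizes chosen so the full suite and benchmark are comfortable
on a single CPU while leaving clear daylight between the identity, tuned
Gaussian and learned rows. Full-tier training configurations (batch 32/16, per-model maximum
learning rates) are expressible in `TrainConfig` but are GPU-scale and not
exercised by the test suite.

Other fixed choices: Gaussian-baseline grid search over
σ ∈ {0, 0.5, …, 6} mm minimizing mean ISSIM with ties broken toward the
smaller σ; Poisson rates above 1e12 rejected with guidance to lower η;
replicate padding for 2.5D boundary slices; empty masks, empty lesion
tables and constant series raise informative errors rather than returning
NaN; degenerate perfectly-collinear agreement pairs (e.g. FT vs. itself)
report 1 − R² = 0.

## Known limitations

Lesions are homogeneous spheres, so phantom SUVpeak/SUVmax relationships
are smoother than in heterogeneous tumors; the SUV-threshold mask provider
is a stand-in for a trained segmenter and under-segments faint lesions by
construction; the tiny tier's capacity is far below the full-scale
architectures, so its *absolute* relative-metric values are not comparable
with published full-scale results — only orderings and signs are
meaningful at desk scale; CycleGAN training at tiny scale demonstrates the
objective wiring and reproducibility, not GAN image quality.
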