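# Methods

This note documents the models, the numerical choices, and what the
synthetic phantom does and does not emulate.  It is the package's own
account of its science; every empirical statement here is computed by the
test suite or by `scripts/acceptance.py`.

## The problem

The locus coeruleus (LC) is a thin noradrenergic nucleus in the rostral
pons, roughly 14.5 mm long and 2–2.5 mm wide, with a per-side volume in
the 7–17 mm³ range depending on the delineation protocol.  On standard
T1-weighted MRI the LC produces no usable contrast, so its position can
only be estimated *geometrically*, relative to neighbouring structures:
about 3 mm lateral of the midline, about 1 mm rostral (anterior) of the
fourth-ventricle floor, and 16–20 mm above the pontomedullary junction
(PMJ).  A mask drawn this way is deliberately inflated — it prioritizes
sensitivity over specificity — and the package treats that inflated
*presumptive region*, not the anatomical LC, as the prediction target.

### The Dice cap

If a region of volume `α·|L|` fully contains a label `L`, the Dice
coefficient between them is exactly `2/(1+α)`.  An inflated region with
`α = 2.7` can therefore never exceed Dice 0.54 against the contained
label, no matter how well it is placed.  `geometry.dice_cap` implements
this bound and the acceptance script verifies it both by the formula and
structurally on constructed nested masks.

## Modules

### Landmark geometry (`geometry`)

`geometric_lc_mask` codifies the manual protocol as an analytic
construction in world space: an axis-aligned tapered cylinder (radius
profile `r0·(1−u²)^t`, default taper `t = 0.25`) centred 3 mm lateral of
the midline, offset 1 mm along the anterior normal from the ventricle
reference, spanning the 16–20 mm PMJ band.  Open choices, and how they
were fixed:

* the "1 mm rostral to the fourth ventricle" direction is not defined
  precisely by anatomical protocols; it is implemented as the anterior
  normal of the ventricle floor and exposed as `rostral_sign` so users
  can flip it;
* the 16–20 mm band is read as the rostro-caudal span of the mask
  (length 4 mm by default), with the radius solved from the target
  volume (19.7 mm³ — the mean of the manually drawn regions) and then
  refined against the discrete voxel count (two deterministic
  fixed-point passes), because the printed mask volume and the LC length
  are not jointly consistent with any single obvious shape;
* a voxel belongs to the mask iff its center is inside the analytic
  surface, making the construction exactly equivariant under rigid
  transforms applied jointly to landmarks and grid.

### Phase image (`phase`)

The "phase image" is spectral whitening: `Re(IDFT(F/(|F| + ε‖F‖)))` with
`F = DFT(image)` and `ε = 0.001`.  `‖F‖` is the L2 norm over all DFT
coefficients (the Parseval-consistent reading of "the norm of the Fourier
transform"; an L∞ option is exposed).  The transform discards the Fourier
magnitude — which carries most scanner- and sequence-dependent intensity
variation — while preserving spatial structure as enhanced edges, and is
exactly invariant to global intensity rescaling.  It is applied to the
whole 3D volume, not per slice.  The DFT convention (unnormalized
forward, 1/N inverse) is immaterial because the ratio is scale-consistent.

### Expected label value (`elv`)

The ELV localizer fuses atlas labels over a family of candidate
atlas-to-image transformations without deformable registration:

    w_a(T) ∝ exp(sim(T(image_a), test)/κ),   Σ_T w_a(T) = 1
    ELV(x) = (1/|A|) Σ_a Σ_T w_a(T)·[T(label_a)](x)

Choices made here (the original formulation leaves them open, and they are
all exposed in the estimator's parameters): the transform family is a grid
of integer 3D translations (default radius 5 voxels; `None` selects the
full circular family, for which the map is exactly translation-
equivariant); the validity measure is a softmax (temperature `κ = 0.01`)
of normalized cross-correlation between the globally-normalized test
image and the atlas image restricted to a window around the atlas masks
(bounding box + 8 mm).  Windowing the atlas side rather than the test
side is what makes the equivariance exact.  All translations are scored
at once by FFT circular cross-correlation, which the tests verify against
direct sliding-window dot products.  Inputs are whitened with the phase
transform by default; an optional Gaussian intensity prior (pooled
in-mask mean/std, rescaled to peak 1) multiplies the map for the
"phase + image" variant.

### Patch-based 3D U-Net (`unet`)

A two-stage contracting/expanding network with skip connections, 16
initial filters by default, zero-padded "same" convolutions (so stride-10
overlap averaging needs no margin bookkeeping), trained with Adam for 20
epochs with learning rate 0.002 dropped by 95% every 5 epochs, and
sliding-window inference that averages the scores of overlapping patches.
The implementation is pure NumPy: im2col + BLAS matmul convolutions with
exact analytic gradients (verified against finite differences), seeded
initialization and patch sampling, hence bit-reproducible training on a
single thread.

Several design choices matter and are the package's own:

* **Objective.** The default training objective is the *batch* Dice: one
  two-class generalized Dice (classes weighted by inverse squared
  volume) computed over the whole mini-batch, with each batch containing
  at least one target-intersecting patch.  Plain per-patch soft Dice is
  provably unstable for a ~50-voxel target inside a 24³ patch — the
  aggregate gradient from background voxels exceeds the foreground pull,
  the network drifts to the empty prediction and the sigmoid saturates —
  and per-patch class weighting swings the gradient scale wildly between
  patch types.  Computing one class-weighted Dice per batch gives a
  single coherent gradient scale (and is what strong 3D segmentation
  baselines do).  Per-patch `loss='generalized'` and `loss='plain'`
  remain available, and for an empty-target input the generalized form
  falls back to the plain soft Dice so false positives stay penalized.
* **Normalization.** Each convolution is followed by instance
  normalization (per-sample, per-channel spatial standardization with
  learned scale and shift).  Without any normalization layer the network
  was not trainable at any learning rate tried — activations drift into
  sigmoid saturation — which matches standard practice in 3D medical
  segmentation, where instance norm is the default.
* **Stability details.** The segmentation head's bias starts at −2
  (a "mostly background" prior that avoids early saturation), and Adam
  clips the global gradient norm at 1.

Training patches: a `fg_fraction` share of draws (plus the first patch
of every batch) is centred on a randomly chosen target voxel with ±patch/4
jitter — so most forced draws contain the whole tiny target rather than
cutting it — and the rest are uniform random origins.  An optional
left-right mirror augmentation (`augment_mirror`) treats the
contralateral side as a reflected training example; it is off by default
(on the phantom cohorts it increased overconfidence on training
subjects).  The five input variants mirror the domain-shift experiment:
raw image, `nmz` (volume divided by its foreground standard deviation,
plus patch-wise zero-mean/unit-std at the input layer), `phase`, and the
two-channel `image+phase` and `nmz+phase` stacks.  Patch-wise input
normalization applies to all channels of the `nmz` variants.

### Fuzzy atlas and demons registration (`atlas`)

The comparison baseline: average intensity-normalized images and binary
masks (optionally through supplied case-to-template deformations;
identity for the pre-aligned phantoms, whose template space is simply the
common phantom grid) into a template with fuzzy labels, then register the
template to each test image with an asymmetric intensity-driven demons
scheme and propagate the labels.  The demons update is the classic
intensity-difference force, Gaussian-smoothed (σ_update = 1 voxel), with
optional scaling-and-squaring exponentiation of each update
(diffeomorphic mode, default on), field smoothing σ_field = 1.5 voxels,
3 resolution levels × 30 iterations, step 1.0.  These values are
hand-tuned defaults and all exposed.  A level that fails to reduce the
mean squared intensity difference flags the result as non-converged —
registration failure is an expected outcome on some subjects and is
carried into evaluation as a failure flag (scored Dice 0), never raised
as an exception.

### Evaluation (`evaluation`)

Dice, sensitivity (`|pred∩truth|/|truth|`), binarization at 0.5 followed
by largest 26-connected component, soft-mask combination by voxelwise
product, LOOCV and summary statistics (median, mean, SEM), paired t-tests
on left/right volumes and Pearson correlation between left and right Dice
scores.  Conventions fixed here: Dice of two empty masks is 1 (with a
warning); empty prediction against nonempty truth is 0; component-size
ties break toward the smallest flat voxel index (determinism).

### Regional statistics (`stats`)

Regional means are taken after propagating the soft mask to each map's
grid (linear resampling, binarize at 0.5) — e.g. anatomical (0.7 mm)³ to
diffusion (1.25 mm)³.  The correlation scan multiplies each Pearson
p-value by the number of imaging and non-imaging variables
(`p_B = p·N_i·N_e`, capped at 1; significance at `p_B < 0.05`).  ICV
adjustment is a partial correlation: both variables are residualized on
intracranial volume and the t-test degrees of freedom reduced by one.
In place of a manual visual inspection for outlier-driven hits, every
pair carries a leverage diagnostic — the largest leave-one-out change in
`r`, flagged above 0.2 — and flagged pairs are never auto-excluded.

## The phantom (`phantom`)

The generator produces, at (0.7 mm)³ on a 64×64×96 grid, the minimal
anatomy the landmark protocol needs: a brainstem column that narrows
below the PMJ plane, a fourth-ventricle CSF wedge dorsal to the pons
(tissue means 100 and 30, arbitrary units, zero background as in
brain-extracted data), a smooth multiplicative bias field (±10%) and
Gaussian noise (σ = 5).  The LC truth is a thin filament with a fusiform
mid bulge (base radius 0.26 mm, peak radius 0.95 mm, length 14.5 mm),
rasterized by supersampled coverage fraction; the constants were
calibrated once so the discrete per-side volume lands near the external
label scale (~7 mm³; the literature's printed length, width, and volume
are not jointly attainable, and the volume is what the evaluation
arithmetic depends on).  The enlarged presumptive mask is the same
spindle dilated by 0.22 mm and lengthened by 2 mm, landing near 19.7 mm³
per side, giving a cohort mean enlarged-to-truth volume ratio α ≈ 2.8.
Crucially the LC is painted with pons intensity — localizers can only use
the surrounding geometry, as on real T1-weighted data.

Per-case variability: bounded uniform landmark jitter (±1 mm for the
ventricle and PMJ references, ±0.25 mm midline shift, ±0.4 mm per-side
placement jitter — bounds chosen so left/right mirror symmetry holds
within 2× the jitter by construction) and ±10% shape scale jitter.  Site
B applies a monotone gamma remap (`I → I^0.8` on the peak-normalized
scale) and 1.5× noise, emulating a 3T-vs-7T contrast change while the
truth geometry for a given seed is bit-identical across sites.

What the phantom does **not** emulate: whole-head anatomy, MR physics
(partial volume beyond linear resampling, coil profiles, distortions),
realistic inter-subject deformation (jitter is rigid and small), or
inter-rater labelling variability.  Passing tests on phantoms therefore
demonstrate the *machinery* — geometry, fusion, training, registration,
statistics — under controlled conditions, not clinical segmentation
accuracy on real cohorts.

## Desk-scale problem sizes

The reference training recipe (patch 132³, stride 10, batch 8, 20
epochs, 16 filters, lr 0.002) targets full-resolution human data and
remains the estimator's default.  The test suite's phantom experiments
use scaled-down conditions chosen once as the package's own desk-scale
recipe: patch 24 (stride 16), 6 base filters, 7 epochs × 40 steps,
batch 2, lr 0.004 dropped 95% after 6 epochs, 6-case LOOCV cohorts, and
a 4-case site-B cohort for the cross-site comparison.  The demons checks
use 2-level/10-iteration runs except where full defaults are exercised.

## Known limitations

* The ELV instantiation is faithful to the published one-sentence
  description, not to any specific released implementation; its internal
  validity measure and transform prior are this package's choices.
* The NumPy U-Net is single-threaded CPU code; it is meant for
  reproducibility and desk-scale experiments, not GPU-scale training.
* Binary masks are resampled by linear interpolation + 0.5 threshold; no
  partial-volume model.
* The correlation scan's leverage flag is a screening diagnostic, not a
  formal outlier test.
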