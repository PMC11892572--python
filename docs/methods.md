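# Methods

## Problem and data model

Optical coherence tomography (OCT) of thick skin (finger pads, palms) resolves
five structural regions along every A-scan, in fixed depth order: the space
between probe and skin (class 1), a thin bright upper stratum corneum of
disordered scales (2), a thick dimmer ordered stratum corneum (3), the
brighter cellular epidermis (4) and the dimmer dermis (5), whose lower border
lies beyond the probing depth.  Volumes are voxel grids indexed `(z, y, x)` —
depth, fast lateral, slow lateral — with the acquisition geometry
256×512×512 voxels over 1.2×3.0×3.0 mm.  Depth is optical path length: the
optical voxel depth is Δz_opt = extent_z / n_z (4.6875 µm at acquisition
scale), and geometric lengths are optical lengths divided by the tissue
refractive index n = 1.4.  Because probe optics distort B-scan borders, the
slow axis is centre-cropped from 512 to 256 voxels before analysis; for odd
remainders the extra voxel is trimmed from the high-index side.

No clinical volumes are distributed with the package, so every quantitative
claim is validated on the synthetic phantom described next.

## Speckle phantom

The generator plants four boundary surfaces z₂ ≤ z₃ ≤ z₄ ≤ z₅.  Surfaces 2
and 3 are smooth (a random plane tilt, default amplitude 2 voxels); surfaces
4 and 5 additionally carry a papillary relief modelled as a product of
sinusoids in y and x with random phases (amplitude 3 voxels, period 40
voxels — the minimal model of dermo-epidermal undulation).  Consecutive
surfaces are separated by the layer's geometric thickness converted to
optical voxels, t·n/Δz_opt; ordering is enforced by clamping.  Defaults: probe
gap 15 voxels; thicknesses 20 µm (upper SC; comparable to the 15 µm axial
resolution), 153 µm (ordered SC) and 137 µm (epidermis) — the latter two being
the cohort means the thickness estimator is expected to recover; the dermis
fills the remaining depth.

The noise-free image assigns each class a mean intensity in relative units —
(5, 100, 40, 70, 30) for classes 1..5, reproducing the observed contrast
ordering I₂ > I₄ > I₃ > I₅ > I₁ — attenuated by exp(−µ·d) with µ = 1 mm⁻¹ and
d the optical depth below the tissue surface (the probe gap is not
attenuated).  Speckle is modelled as i.i.d. multiplicative unit-mean gamma
noise with shape k (default 4), giving intensity contrast 1/√k; this is the
standard surrogate for fully developed intensity speckle.  Per-volume
thickness jitter (relative SD, default 0 in the API, 0.05 in cohort
examples) emulates between-subject variation.  All randomness flows from a
single seed through `numpy.random.SeedSequence` spawning, so datasets are
bit-reproducible.

What the phantom does **not** model: coherent PSF convolution and laterally
correlated speckle, hair follicles and air lacunae, curved or tilted probe
contact, refraction at layer boundaries, and detector noise floors.  Passing
phantom tests therefore demonstrates correctness of the algorithms under the
stated intensity model, not clinical-grade performance.

## Semi-automatic labeler

For each layer i = 2..5 an operator-style cuboid ROI M_i guaranteed to lie
inside the layer supplies statistics for the threshold

    I_t(i) = mean(M_i) − α_i · std(M_i)    (population SD).

Each lateral column is scanned downward, starting strictly below the previous
layer's smoothed boundary, for the first voxel crossing I_t(i) — upward
(rising) for the bright layers 2 and 4, downward (falling) for the dark
layers 3 and 5.  Columns without a crossing are flagged and assigned the
deepest scanned index.  The boundary z-map is median filtered with a w_i×w_i
lateral window (default 11; a 2D window was chosen over per-B-scan 1D
filtering for lateral isotropy), and after the first boundary is found the
image below it is median filtered in 3D (3×3×3) to suppress speckle before
deeper layers are processed.  Surfaces are clamped to be depth-ordered, and
labels are assigned per column with half-up rounding of boundary depths.

The original expert-driven procedure relies on re-selecting α_i and w_i until
the boundary looks right.  The package replaces that loop with explicit
presets plus automated checks against phantom truth:

* default preset (speckled data): α = (2, −2, 0.7, −2) for layers 2..5,
  w = 11, despeckle 3.  Negative α raises the threshold above the ROI mean,
  which falling crossings into dark layers need: the first dark voxel sits
  above the deeper ROI's mean because attenuation keeps shallower voxels
  brighter.
* noise-free preset: α = (2, −30, 0.5, −4), w = 1, despeckle 1.  With no
  speckle the ROI SD collapses to the tiny attenuation-induced spread, so a
  falling threshold needs a large |α| to clear the attenuation gap between
  the ROI depth and the boundary; the wide margin to the bright layer above
  (factor ≈ 2.5 in intensity) makes the exact value uncritical.

With these presets the labeler reproduces noise-free phantom truth exactly,
and at speckle shape 8 reaches DSC ≥ 0.9 (classes 3–5) with median boundary
error ≤ 2 voxels.

## U-Nets and block inference

Both networks are symmetric encoder–decoders with five stages at full size:
each stage is conv3 → batch norm → ReLU → conv3 → ReLU, stages are linked by
2× max-pooling, and the encoder widths are 32, 64, 128, 256, 512 (halved
stages available through a width multiplier, floor 1, for desk-scale runs).
The decoder mirrors the encoder widths, upsamples with stride-2 transposed
convolutions and concatenates the matching encoder stage's features; a final
1×1 convolution emits five raw per-class confidence channels.  No softmax is
applied inside the network.  The 3D variant replaces every operation with its
3D analogue and pools all three axes (depth 256 and lateral 64 are both
divisible by 2⁴).

The networks, their gradients and the Adam optimizer are implemented directly
on NumPy: convolutions run as im2col matrix products, the data gradient of a
stride-1 padded convolution is computed as a convolution with the flipped,
transposed kernel, and every layer's analytic gradient is verified against
central differences in the test suite.  This keeps the package dependency-free
beyond the scientific Python stack and fully deterministic on CPU.

Training blocks: one B-scan per slow-axis index (256 per cropped volume) for
the 2D model; disjoint full-depth 256×64×64 tiles (32 per volume) for the 3D
model.  Inference: the 2D model segments slice-wise and the slices are
reassembled; the 3D model scores overlapping full-depth blocks on a lateral
stride lattice (default stride 32, i.e. 50 % overlap; the last row/column is
clamped inward so coverage is complete).  Per-voxel class confidence is the
Gaussian-weighted average over covering blocks, w = exp(−d²/2σ²) with σ = 16
voxels and d the lateral distance to the block centre ("radius 16" is read as
the Gaussian σ; blocks span the full depth, so overlap exists only
laterally).  Block scores are softmax-normalized before weighting so they are
comparable across blocks; raw-score blending is available behind a flag.
Blended confidences are a convex combination of block scores, so agreeing
blocks cannot produce seams; classification is argmax with ties broken toward
the lowest class index.

## Training protocol

Per-voxel softmax cross-entropy over all five classes (no class weighting) is
minimized with Adam at learning rate 0.001 and betas (0.9, 0.98).  Of the
available volumes a seeded subset (2 of 7 in the reference protocol) is held
out entirely; the remaining volumes form leave-one-out folds — each volume
validates exactly one fold — and the fold with the best validation score is
selected.  The selection metric is the mean DSC over the four tissue classes;
background is excluded because it is large, trivially segmented and would
mask tissue differences.  Inputs are normalized per volume by the 99th
intensity percentile (robust to speckle tails).  Epoch count and batch size
are free parameters (defaults 40 and 8/2 for 2D/3D); an optional elastic
B-scan augmentation is off by default.  Test volumes never contribute blocks
to any gradient step, which the fold bookkeeping enforces by construction.

## Evaluation

Per-class Dice: DSC_i = 2·n(true = pred = i) / (n(true = i) + n(pred = i)),
with the both-empty convention DSC = 1.  The typeset source formula contains
an "=" where the denominator's "+" belongs; the implementation follows the
prose definition.  Layer thickness is estimated per lateral column as voxel
count × Δz_opt / n with n = 1.4, excluding columns without the layer; cohort
statistics are mean ± sample SD over per-volume means.  The dermis is
excluded from thickness estimation since its lower border is not imaged.
Column counting (rather than surface-to-surface distance) matches the
label-volume output of the segmentation models.

## Desk-scale problem sizes

CPU-only runs use reduced grids that keep the acquisition's lateral pitch
(5.86 µm/voxel, applied isotropically): 128×256×128 for labeler and training
demonstrations, 112×128×64 for the quickest training checks (depths chosen
divisible by 2⁴ with room for the default layer stack).  The scaled-down
2D U-Net (width multiplier 0.25, a few hundred Adam steps over subsampled
B-scans) reaches held-out mean tissue DSC well above the 0.87 floor on these
phantoms — the phantom task is easier than clinical data, so this validates
the training/inference machinery rather than clinical accuracy.  Acceptance
numbers are recomputed from scratch by `scripts/acceptance.py`.

## Numerical choices and edge cases

* Boundary depths are real-valued during estimation and rounded half-up at
  label assignment.
* Median filters use edge-including reflection at borders.
* Degenerate detection thresholds never fail: a threshold below the scan
  range returns the scan start, one above it returns the deepest scanned
  index with the column flagged.
* Checkpoints embed the full network configuration, so a weights file is
  self-describing.
* All stochastic components (phantoms, cross-validation splits, weight
  initialization, batch shuffling) are seeded; two runs with equal seeds are
  bit-identical on the same platform.

## Known limitations

* The phantom's simplifications (above) mean reported DSC values do not
  transfer to clinical volumes.
* The NumPy networks are CPU-bound; full-width training at acquisition scale
  is out of reach (minutes per optimizer step) and the package makes no GPU
  claims.
* The labeler's ROI helper assumes phantom-like layer positions; on real
  data ROIs must be supplied by the operator, as in the original workflow.
* Thickness by voxel counting is unbiased only when a layer appears once per
  column, which the depth-monotone label model guarantees.
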