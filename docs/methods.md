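# Methods

`plaqseg3d` re-implements, at desk scale, a weakly supervised pipeline for
segmenting and quantifying bright blob-like objects (amyloid plaques in
immunostained light-sheet volumes are the motivating case) in 3D fluorescence
microscopy.  Only object-level bounding boxes are needed as training labels;
voxel-level masks are produced by post-processing network outputs.

## Pipeline

1. **Preprocessing.** Per-slice brightness calibration divides slice `z` by
   `I_mean(z) / I_mean(z_mid)`, where `I_mean` is the mean over tissue voxels
   only and `z_mid` the middle slice of the section; this removes the
   multiplicative depth profile caused by antibody penetration and light
   absorption.  A 3D Gaussian blur (`sigma = 2` voxels, reflect boundaries)
   then raises SNR.  Large stacks are partitioned into non-overlapping blocks
   (256 × 256 × 75 in y, x, z by default; edge blocks zero-padded) and blocks
   with under 1% tissue voxels are dropped.
2. **Detection.** A 3D HRNet backbone (parallel multi-resolution streams,
   branch `r` at `1/2^(r-1)` resolution with `base_channels * 2^(r-1)`
   channels, repeated all-pairs fusion) feeds a Faster-RCNN-style head:
   a region-proposal network scoring cubic anchors (edges {6, 10, 14, 20,
   28} voxels on a stride-4 lattice) plus an RoI head (3D RoI-Align 4³,
   two-layer MLP) that refines proposal geometry.  Training uses SGD
   (lr 0.01, momentum 0.9, weight decay 1e-4) on bounding boxes only.
   The objectness logit is the sum of two paths plus one shared per-anchor
   bias: a free-sign conv over the learned features and a non-negative 1×1
   conv over a fixed intensity-evidence pyramid (stride-4 mean pooling
   followed by repeated 3³ lattice means; each anchor channel reads the
   level closest to its own box size).  See "Walkable peaks" below for why
   the second path exists.
3. **Peak response mapping (PRM).** At test time, strict local maxima of the
   RPN objectness map are back-propagated to input resolution as a random
   walk: the transition probability from an output location to an input
   location of a conv layer is proportional to
   `activation x ReLU(weight)`, normalised per output location.  The result
   is a per-peak visiting-probability field over input voxels.
4. **2D-Otsu segmentation.** Each block is thresholded on the joint
   (intensity, PRM) histogram (64 × 64 bins on [0, 1]²): the threshold pair
   maximises the between-class scatter of the low/low (background) versus
   high/high (foreground) quadrants; the mixed quadrants are treated as
   noise.  The histogram is restricted to tissue within detection boxes
   dilated by 4 voxels so background cannot dominate.  Per-block masks are
   montaged back into the whole volume.
5. **Evaluation and quantification.** Dice (`2TP/(2TP+FP+FN)`), sensitivity
   (`TP/(TP+FN)`) and HD95 (95th percentile, linear interpolation, of the
   pooled directed nearest-neighbour distances between foreground voxel
   sets, spacing-scaled).  Masks are resampled to a 4 µm isotropic analysis
   grid; 26-connected components are classified small (< 300 voxels),
   medium (300–1500) or big (> 1500) and assigned to the atlas region
   holding the majority of their voxels (ties to the smaller label), giving
   per-region total volume, count, volume ratio, count density (per mm³)
   and mean volume.

## Numerical core

No GPU framework is used: the conv nets run on a small tape-based autodiff
core (`plaqseg3d.nn`) built on numpy/BLAS.  3D convolutions use a tap-slab
im2col (`(C·k³, N)` column matrices built from one strided slab copy per
kernel tap) with a tap-loop fallback when the column matrix would exceed
512 MiB, and a direct tensordot path for transposed convolutions whose
stride equals their kernel (the RPN's stride-4 reduction).  The same
recorded graph serves gradient back-propagation and the PRM walk; PRM
transitions are computed in float64 on the cached float32 activations, so
walker mass is conserved to machine precision and the walk can be checked
against an explicit transition-matrix oracle at 1e-9.

Design choices in the walk, where the formulas are silent:

* **Absorption.** An output location whose admissible inputs all have zero
  `activation x ReLU(weight)` has an undefined normaliser; its walker mass
  is dropped and the dropped total reported per peak, so
  `mass + absorbed = 1` is always checkable.  Redistributing the mass would
  invent dynamics the model does not define.
* **Normalisation layers.** Evaluation-mode channel scalings are folded into
  the adjacent convolution's weights before the ReLU-of-weights step.
* **Sums** (skip connections, fusion, the HR-fuse output) split mass across
  branches proportionally to each branch's non-negative contribution at that
  location; all-non-positive locations absorb.
* **Nearest-neighbour upsampling** routes mass to its unique source voxel
  (absorbing where the source activation is non-positive).
* **Peaks** are found per anchor channel with a 3³ strict-maximum window at
  the detection score threshold; peaks sharing a spatial location across
  anchor channels describe the same object and are walked once (best
  channel).  The aggregate map is the per-voxel maximum over peaks rescaled
  to [0, 1].

## Walkable peaks

The back-propagation formulas admit only positive-weight transitions, so a
peak is traceable to the input exactly when positive evidence for it exists
at every layer.  Empirically, a free-sign objectness conv trained for a few
hundred iterations settles on the opposite solution: background-activated
features with negative weights ("anti-evidence"), which ranks objects
correctly but leaves the walk without a single admissible transition at the
first layer — every walk absorbs immediately.  Constraining the objectness
weights non-negative (projected SGD) deadlocks instead: early features
respond more to background than to objects, so the projected weights are
driven against the constraint and the head dies at zero.  The resolution is
architectural: a second, fixed evidence path — per-anchor-size mean
intensity, scored by a projected non-negative 1×1 conv — guarantees every
peak a positive-evidence route from the start, and its walk mass lands on
the bright voxels responsible for the detection, which is precisely the
"most informative region" the segmentation stage needs.  Biases live in a
separate graph node outside both paths: the transition formulas ignore
biases, and a bias folded into either branch would turn the branch
contribution negative wherever logits are negative and absorb the walker at
the final sum.

## Training scheme

Single-volume batches make classic batch-norm statistics unreliable: running
averages collected from small biased training crops transfer poorly to full
test blocks.  Normalisation layers therefore always use the current input's
per-channel spatial statistics (instance-style), identically in training and
evaluation, which keeps inference deterministic and PRM folding exact.

Each SGD iteration samples one training block and cuts a random
lattice-aligned 32³ crop biased to contain at least one object.  The RPN
objectness loss (binary cross-entropy) uses every positive anchor plus a
negative batch mixing the hardest (highest-scoring) negatives with random
ones — without hard-negative mining the background score tail is never
corrected and spurious peaks survive.  Box regression uses smooth-L1 on
positive anchors.  The RoI head trains on decoded top-scoring RPN proposals
(so its test-time input distribution is represented) plus jittered
ground-truth boxes and random negatives.  Gradients are clipped to a global
L2 norm of 5 before each step; at this depth and learning rate the
occasional large normalisation-layer gradient otherwise diverges.  A
detection's final score is its RPN sigmoid; the RoI head refines box
geometry but does not gate scores (at short training budgets its classifier
is too uncalibrated, and multiplying it in suppresses real detections).
Proposals are drawn with per-anchor-channel quotas (512/5 each) so one
bright object cannot crowd dimmer ones out of the candidate set, then
deduplicated by 3D NMS at IoU 0.3 (128 kept per block).

Anchor assignment: positive at IoU ≥ 0.5 with any ground truth or as the
argmax-IoU anchor of a ground truth; negative below IoU 0.2.  These are
looser than the 0.7/0.3 2D conventions because IoU concentrates lower in
three dimensions.

## Synthetic data

The generator (`plaqseg3d.synthgen`) emulates the features this pipeline
actually relies on: bright anisotropic Gaussian blobs whose half-max
ellipsoid is the ground-truth mask (semi-axes = the declared radii, so a
radius-4 sphere covers exactly the 257 lattice points within distance 4);
per-axis radii sampled per size class and re-rendered until the exact voxel
count falls in the declared class; rejection-sampled non-overlapping
placement inside an ellipsoidal "brain" of moderate background intensity;
a positive multiplicative depth profile `b(z)`; additive Gaussian sensor
noise, clipped to [0, 1].  The toy atlas is a nearest-seed (Voronoi)
partition of the brain ellipsoid — convex cells intersected with a convex
ellipsoid, hence connected regions by construction.

It deliberately does **not** model light-sheet PSF anisotropy, stripe
artefacts, vascular amyloid morphology, autofluorescence texture, or
registration error, so green tests here show the pipeline's machinery is
correct and recoverable under its own assumptions, not that it reaches any
particular accuracy on real rat-brain data.  Blob peak amplitudes
(0.55–0.95 of full scale) are a modelling choice, not calibrated to
measured plaque intensity distributions.

## Scaled-down study conditions

The end-to-end checks train on 8 blocks of 64³ voxels with ~15 plaques each
(size mix 0.4/0.4/0.2 small/medium/big), a 3-branch × 8-channel backbone
with 2 fusion stages, and 300 SGD iterations at lr 0.01 / weight decay
1e-4, then evaluate detection recall (IoU 0.3, medium/big objects) and
whole-scene Dice on a held-out 64 × 64 × 128 scene (two blocks, 20 plaques)
with a depth-decay profile.  The fixture's detection operating threshold is
0.2: at 300 iterations the sigmoid scores are compressed toward the anchor
batch prior (positives ≈ 0.25–0.38, negatives ≈ 0.1), so the conventional
0.5 sits above every score; the threshold is an operating point on a
well-separated score distribution, not a learned quantity.  PRM walks the
top 24 deduplicated peaks per block.  These sizes keep a full run in
CPU-minutes; the library accepts arbitrarily larger blocks, thresholds and
iteration counts (default 3000) without code changes.

## Degenerate inputs and tie-breaks

* 2D-Otsu: pairs leaving either diagonal quadrant empty are invalid; exact
  ties resolve to the smallest intensity threshold, then smallest PRM
  threshold.  A histogram whose PRM (or intensity) marginal occupies a
  single bin carries no 2D information and reduces to classic 1D Otsu on
  the informative marginal, with the degenerate-axis threshold set just
  below its occupied bin.  Blocks with an all-zero PRM map yield an empty
  mask with a warning.
* Metrics: Dice of two empty masks is 1 by convention (warning); sensitivity
  of an empty ground truth and HD95 of any empty mask are errors.
* Calibration: slices without tissue keep gain 1 (warning); calibration is
  idempotent and commutes with positive global rescaling.
* NMS ties break by score, then lexicographic box coordinates, making the
  kept set independent of input order.
* Component labelling orders ids by each component's first voxel in
  lexicographic order, a pure function of the mask.

## Known limitations

* Kernels are cubic (k³); the backbone treats z isotropically, appropriate
  for the near-isotropic 4 µm analysis grid but not for raw 1 × 1 × 3.5 µm
  stacks (resample first).
* The RoI head is deliberately small (4³ pooling, 64 hidden units); at desk
  scale it refines boxes but contributes little classification signal.
* Atlas registration is out of scope: quantification consumes a pre-aligned
  integer label volume.
* Terabyte-scale streaming is out of scope; block processing is in-memory.
* Training runs single-threaded deterministic; identical seeds give
  identical checkpoints, at the cost of wall time.
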