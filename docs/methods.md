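# Methods

`pulmocad` implements a classical pulmonary-nodule CAD pipeline as a
testable toolkit: lung parenchyma segmentation, a multiscale dense/dilated
U-Net detector with a transfer-learning fine-tuning harness, and FROC-based
evaluation.  Synthetic thorax phantoms with exact ground truth make every
stage verifiable on a laptop, with no external CT data.

## Lung parenchyma segmentation

The pipeline composes four steps, each exposed as its own operation with
its intermediate mask retained in the result:

1. **Rough thoracic segmentation.**  A global Otsu threshold over a
   256-bin intensity histogram separates the dark class (air + lung,
   roughly below −400 HU in a thorax) from soft tissue and bone; the
   foreground is the dark class.  Dark components touching the lateral
   (x/y) image border — the ambient air and scanner tray — are removed by
   maximum-connectivity labeling.  Axial scans crop anatomy in z, and the
   trachea legitimately reaches the top slice, so z-face contact does not
   disqualify a component.  Per-slice hole filling then absorbs vessels
   and nodules (bright structures inside the lung) into the rough mask.
2. **Airway removal.**  The main trachea is grown from a seed in the top
   axial slices (the most circular dark region, circularity
   4πA/P² ≥ 0.5).  The intensity threshold rises in steps of 20 HU; at
   each level the 26-connected component containing the seed is the grown
   region, and growth stops at the largest threshold for which the volume
   does not jump by more than a factor 1.5 between steps — the classic
   leak-explosion test that keeps the growth out of the parenchyma.  The
   stated increment and explosion factor are this package's defaults (both
   in `SegmentationConfig`); the stopping principle, not the constants, is
   the method.  Finer bronchi are recovered by grayscale
   closing-by-reconstruction: the marker is a grayscale closing with a
   3 mm ball, reconstruction by erosion under the original image shrinks
   it back except inside dark tubes too thin for the ball, and the
   positive difference above 100 HU is the bronchi mask.  The
   reconstruction obeys original ≤ reconstruction ≤ marker voxelwise,
   which the tests assert.
3. **Left/right separation.**  Fusion is detected from the two largest
   component volumes A1 ≥ A2 via the ratio rule A1/max(A2, 1) > T with
   T = 4 (a single component therefore reads as fused; an
   absolute-difference variant sits behind `fusion_mode`).  When fused,
   the per-slice vertical integral projection (column-wise foreground
   count, restricted to the central third of the x-range) attains its
   minimum at the adhesion; the minimizing column per slice is the
   dividing line, linearly interpolated across slices where undefined.
   Each slice clears the column span covering its neighbours' line
   columns as well — a single-column cut at per-slice varying positions
   would leave the halves 26-connected through z.
4. **Boundary repair.**  The rolling-ball method is realized as
   per-component, per-slice binary closing with a disc of radius
   12.5 mm / in-plane spacing (rounded half-up; a 3D ball sits behind
   `rolling_ball_3d`).  Closing is extensive, so repair only adds voxels,
   and components are closed separately so the ball cannot bridge the two
   lungs across the mediastinum.  A rolling ball fills a boundary pocket
   only up to the envelope of ball positions: a shallow dimple of depth
   ≈ r − √(r² − w²/4) survives at a mouth of width w, so pockets with
   mouths comparable to the ball radius are only partially restored —
   this is the method's true geometry, not an implementation limit.

## Synthetic thorax phantoms

A phantom is a 150 × 120 × 60 mm volume at 1 mm isotropic spacing (so
radii in mm equal voxels): air background (−1000), an elliptical body
(+40) with a bone ring (+700), two lung ellipsoids (−800) with semi-axes
(24, 30, 24) mm, and a 3 mm-radius trachea descending from the top slice
to a carina, branching into two 2 mm bronchi that enter the lungs.  A
2 mm soft-tissue wall surrounds the airway lumen, as in real anatomy, so
the airway is a dark structure distinct from the parenchyma.  Nodules are
spheres of 3–30 mm at lung + contrast (default +700, i.e. −100 HU —
a solid nodule against aerated lung).

Two optional pathologies exercise steps 3 and 4: `fused` inserts a
lung-density bridge joining the two lungs (one dark component, the fusion
test fires), and `pleural_notch` carves the pocket of a mostly-embedded
juxtapleural mass — a 5 mm sphere sunk 0.85 radii into the lateral lung
wall, leaving a ~6 mm mouth, well under the 25 mm ball diameter.  An
earlier half-ball design was discarded: its mouth is twice its depth and
the ball envelope geometrically cannot restore 90% of it.

Gaussian noise of configurable sigma is added last; the default is 0 so
default phantoms are bit-deterministic given the seed.  Per-item streams
in `generate_dataset` are spawned from the master seed with
`SeedSequence`, so datasets are reproducible and order-independent.

What the phantoms do **not** emulate: lung texture, vessels, realistic
airway trees, partial-volume effects, and ground-glass (non-solid)
nodules.  Passing tests therefore demonstrate the correctness of the
algorithms' mechanisms, not clinical performance on real CT.

## The multiscale dense/dilated U-Net

The architecture is declared as an ordered layer table (`ArchTable`) and
built from it; a symbolic shape trace reports (spatial, channels) at every
named layer.  The normative default table has three encoder levels, each
with two branches: a dense branch (max-pool → dense block of growth rate
3 → 1×1 transition + pool → 3×3 conv) and a dilated branch (two pools →
3×3 convolution with dilation 2), concatenated per level.  Channel counts
follow the design's nominal anchors: Conv1 32; D1/T1 128; dilated branch
96; combined Conv2/Conv3 224; Conv4 480 at the 8×8 bottleneck (on a
512×512 input); decoder Up6 = 512 + 480 = 992 after the skip
concatenation, Up8 = 1600, Up12 = 256; the output head is two 1×1
convolutions ending in a sigmoid and returns the input's channel count.
Spatial scales follow successive halving 512 → … → 8, two halvings per
encoder level.  Where the design leaves a quantity open, the table makes
the choice explicit: Conv5 carries 512 channels (matching the Up6
up-convolution width), and Up8's 1600 decomposes as up-conv 1376 + skip
224.  Dense blocks end in a channel-setting 1×1 projection, since growth
rate 3 alone cannot reach the nominal widths in a plausible layer count.

Up-convolutions are resize convolutions — a convolution at the incoming
scale followed by nearest-neighbour 2× upsampling — chosen for CPU cost
and checkerboard-free output.  Activations are ReLU throughout, pooling is
max, and dropout (rate set at training time) applies after the two deepest
encoder concatenations.  The network builds rank-agnostically: `2d` mode
keeps kernels and pools out of the z axis (the 512×512 single-slice trace
is validated there), `3d` mode extends them isotropically.

A desk-scale variant (`reduced_multiscale_table`) divides all channel
anchors by 8 and keeps one encoder level with in-plane pooling only, so
40×40×26 patches (whose z extent, 26 = 2·13, admits no repeated halving)
pass through unchanged in z.  All block types — dense block of growth 3,
dilated branch, skip concatenations, up-conv decoder with a dense block,
two-convolution sigmoid head — are retained.

### Numpy autodiff

Training runs on a compact reverse-mode autodiff written for this package
(`pulmocad._autograd`): float32 tensors, topological backward pass, and
exactly the primitives the U-Net family needs.  Convolutions are stride-1
same-padded and evaluated channels-last as a shift-and-matmul sum over
kernel offsets (one BLAS GEMM per offset); the input gradient of such a
convolution is itself a same-padded convolution with the spatially flipped,
channel-transposed kernel, so backward reuses the forward path.
Correctness is pinned by central-difference gradient checks in the tests.

## Training

The Adam update follows the bias-corrected form with defaults μ = 0.9,
υ = 0.9999, η = 0.01 and denominator offset ε = 1e−8 (ε is not weight
decay).  At step 1 the corrections give m̂ = g and n̂ = g², so the first
step is −η·sign(g) up to ε.  Training-time learning rates default to
0.001, the middle of the {0.00075, 0.001, 0.005} grid.  The loss is mean
binary cross-entropy with an optional ignore mask excluding voxels from
the mean.  Augmentation emits exactly six views per sample — original,
horizontal and vertical flips, 90/180/270° in-plane rotations — with
labels transformed identically; all six preserve foreground volume.

Transfer-learning freeze schedules resolve a named group (conv1–Up12,
conv2–Up10, conv3–Up8, conv4–Up6, conv5, Up6–Up8, Up9–Up11, Up12) to a
contiguous span of architecture blocks left trainable; all other layers
are frozen by exclusion from the optimizer update, so their parameters
remain bit-identical.  A span ending at Up12 includes the output head —
otherwise the full span would not mean "every layer trainable".

`fit` runs seeded mini-batch training with Adam or plain SGD, records the
loss history, snapshots checkpoints every `checkpoint_every` steps, and
evaluates TrainAcc/ValAcc every `eval_every` steps.  At desk scale an
image counts as correctly detected when the Dice of its thresholded
prediction against the truth is ≥ 0.5; the overfitting ratio is
OverRatio = TrainAcc/ValAcc, and training stops early after 3 consecutive
evaluations with OverRatio > 1.15 (both bounds configurable — the source
design states the principle, not the constants).

The desk-scale learnability configuration trains the 1/8-width network in
3d mode on 100 standardized 40×40×26 phantom patches (80% nodule-centred
with ±6-voxel jitter, 20% background lung; diameters uniform on 6–20 mm;
no noise) with Adam at lr 0.001, batch 1, dropout 0, stopping once the
training-subsample mean Dice reaches 0.85.  On one CPU this reaches a
full-training-set mean Dice above 0.8 in a few hundred steps (~5 min).

## Evaluation

Candidates are supra-threshold connected components of a probability map,
one candidate per component at its score-weighted centroid with the
component maximum as score.  A candidate hits a ground-truth nodule when
its distance to the centre is at most d/2 (the public-challenge
convention); each nodule counts as detected at most once, extra candidates
inside an already-hit nodule are neither TP nor FP, and all remaining
candidates are false positives of their scan.  The FROC sweep enumerates
all distinct candidate scores; sensitivity at each of the seven operating
points {0.125, 0.25, 0.5, 1, 2, 4, 8} FP/scan is the best sensitivity
achievable at or below that FP rate (a step function, last value carried
forward; 0 before the first step).  The scalar summary is the arithmetic
mean of the seven sensitivities — a bounded [0, 1] score — with a
trapezoid over log₂ FP/scan behind a flag.  Size classes are small
(d < 5 mm), middle (5 ≤ d ≤ 15 mm, boundaries inclusive) and large
(d > 15 mm).  `kfold_split` provides the seeded five-fold partition.

## Numerical and degenerate-input choices

* Index order is (z, y, x) internally; annotation CSVs are world-mm
  (x, y, z) in the public dialect; patch shapes are stated (x, y, z).
* Resampling is trilinear for intensities, nearest-neighbour for masks,
  via an edge-clamped zoom, so constants are preserved exactly and
  resampling at the current spacing is the identity.
* Patch padding defaults to −1000 (air), keeping padded context
  physically plausible; the centre voxel lands at floor(shape/2).
* Component connectivity is 26 in 3D, 8 in 2D; speck removal deletes
  components under 64 voxels but never the two principal ones.
* Constant volumes raise a degenerate-input error at thresholding; a
  missing trachea seed is a signal, not an error — the pipeline continues
  without airway removal.
* Projection-minimum ties take the middle minimizer; k-fold uses a seeded
  permutation with near-equal `array_split` folds.

## Known limitations

* The phantom's geometric simplicity means segmentation scores here are
  upper bounds; real CT adds texture, vessels and pathology the pipeline
  is not tested against.
* The autodiff is single-threaded CPU numpy; full-width 3D training is
  out of reach by design, and only the reduced table is intended for
  training.
* Non-solid (ground-glass) nodules are not simulated and the default
  contrast assumes solid lesions.
* DICOM ingestion and compressed `.zraw` volumes are unsupported
  (MetaImage `.mhd`/`.raw` only).
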