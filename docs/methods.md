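# Methods

## Problem and pipeline

The mandibular canal is a bilateral radiolucent corridor in the lower jaw
that carries the inferior alveolar nerve. Locating it precisely in cone-beam
CT (CBCT) is a prerequisite for implant planning. `canalseg` implements a
complete segmentation pipeline for this task: grey-value standardisation,
coarse tube annotations as training labels, a 3D fully convolutional network
trained with a soft-Dice loss on canal-containing patches, tiled whole-volume
inference with connected-component post-processing, and an evaluation suite
of voxel-overlap and surface/curve distance measures.

Clinical CBCT with voxel-level canal annotations is not freely available, so
the package ships a phantom generator that reproduces the *structure* of the
problem — a dark tube of known geometry inside bright bone, annotated only
coarsely — and the whole pipeline is exercised and validated on these
phantoms.

## Grey-value standardisation

Three fixed steps: (1) isotropic resampling to a common spacing (default
0.4 mm) with trilinear interpolation, output shape per axis
`round(shape * spacing / target)` with ties away from zero, voxel-centre
convention, so physical extent is preserved to within one voxel; (2) clipping
to the valid Hounsfield range [−1000, 3095]; (3) the fixed affine map
`v ↦ (v + 1000) / 4095` onto [0, 1]. The normalisation is deliberately *not*
per-volume min–max: a fixed map is device-independent and keeps the three
steps order-safe. Label volumes are resampled with nearest-neighbour
interpolation so they stay strictly binary.

## Coarse annotations (training labels)

The clinical annotation procedure places roughly 10 control points along the
canal; software interpolates a pathway, expands it to a 3.0 mm diameter tube
and discretises it. We model the interpolant as a natural cubic spline
through the control points (chord-length parametrised; C² between knots —
the clinical software's interpolant is unspecified, this is the standard
choice), densely resampled at `spacing / 4` so the rasterisation error stays
well below half a voxel. The tube is the set of voxel centres within
`diameter / 2` of the resampled polyline, i.e. capped with half-balls at the
endpoints. For phantoms, `perturb_annotation` synthesises a reader by
sampling n points at uniform arc length from the exact centerline and adding
isotropic Gaussian jitter (default 10 points, SD 0.5 mm); the resulting
3.0 mm tube around a 3.0 mm canal reproduces the systematic label noise of
the clinical labels (sparsity, fixed diameter, discretisation).

## Phantoms

Each phantom is an isotropic volume (default 96³ voxels at 0.4 mm) with one
or two canals. A canal centerline is a natural cubic spline through 4–8
knots running along the first axis, with transverse wander bounded by
`curve_amplitude` (default 2.5 mm); two canals occupy separate lanes along
the left–right axis and are rejected and resampled until their minimum
separation is at least two canal diameters. Intensities (HU): tissue 0,
bone 1500 in a slab around the canals plus a 2 mm collar around each canal,
canal interior 200, additive Gaussian noise with SD 100, then the HU clip.
Optional bright streak planes imitate metal artifacts qualitatively. These
values are plausible CBCT-scale choices giving a clearly learnable but
non-trivial contrast; they are not fitted to any dataset.

What the phantoms do *not* model: mandible anatomy, CBCT physics (beam
hardening, scatter, partial volume), device-dependent HU calibration, and
anatomical variation between patients. Results on phantoms therefore
validate the pipeline's mechanics (geometry, training dynamics, metrics) —
they do not predict clinical accuracy.

Every sample draws its randomness from a stream derived from
`(master seed, sample index)`, so a dataset is reproducible independent of
generation order. Train/validation/test splits are disjoint by sample.

## Network

A U-net-style 3D fully convolutional network. Contracting pathway:
per level, a residual block (two 3×3×3 conv + batch-norm + ReLU stages with
an additive shortcut; a 1×1×1 projection where channel counts differ)
followed by a stride-2 3×3×3 convolution. The expanding pathway mirrors it
with stride-2 3×3×3 transpose convolutions; after each up-sampling the
same-resolution encoder feature map is concatenated along channels and
consumed by a decoder residual block. The head is a 1×1×1 convolution with
a logistic sigmoid producing a per-voxel canal probability. Weights use
He fan-in initialisation; the head bias starts at −2 so an untrained network
predicts a low probability everywhere, reflecting the extreme class
imbalance. Channel plan: `base_channels` at full resolution, doubled per
level — 32 × 3 levels at full scale, 8 × 2 levels in the desk-scale
configuration used for all phantom experiments.

The layers are implemented in NumPy (channels-last float32) with explicit
backprop; convolutions are phrased as an im2col gather (a tight loop
compiled with numba) followed by one large BLAS matrix product, the input
gradient as a stride-1 convolution of the zero-stuffed upstream gradient
with the flipped kernel. A module-level `mallopt` call keeps the large
activation buffers on the heap between steps; without it every layer call
page-faults its buffers back in. Gradients are verified against numerical
differentiation and the forward pass against `scipy.ndimage.correlate` in
the test suite.

## Training

Patches of 32³ voxels are taken on a stride-22 grid; per axis a final
position snapped to `shape − 32` is added so no canal voxel is unsampleable
(stride 22 < 32 then guarantees full coverage). Patches without a single
canal voxel are discarded to curb class imbalance. Each epoch shuffles the
retained set and draws mini-batches without replacement; each patch is
augmented by independent random flips of the three axes (p = 0.5 each).

Loss: soft Dice, `DL = −2 Σ tₙ pₙ / (Σ (tₙ + pₙ) + ε)` with ε = 1e−6
defining the all-empty case, pooled over all voxels of a mini-batch (the
sum over n runs over voxels; batch-level pooling is the stabler reading).
With ε = 0 and binary predictions, DL equals minus the Dice similarity
coefficient — the bridge between the training loss and the evaluation
metric, asserted in the tests. Optimiser: Adam, β₁ = 0.9, β₂ = 0.999.
Full-scale schedule: 400 epochs, batch 24, learning rate 1e−4. No learning
rate schedule, weight decay or early stopping; the final-epoch weights are
returned and validation history is informational only.

Desk-scale schedule (the `scaled_down` flag; used by the bundled phantom
experiment): 20 epochs, batch 8, at most 48 training patches, learning rate
1e−3. The patch cap and learning rate are the package's choices for a
single-CPU problem size: with ~120 optimisation steps, the larger step size
is needed for convergence, and 48 patches (from 20 phantoms, two canals
each) already cover the phantom variability. On this configuration the
training loss falls from ≈ −0.1 to ≈ −0.75 and held-out phantoms are
recovered with median DSC ≈ 0.97 and median MCD ≈ 0.23 mm.

## Inference and post-processing

Whole volumes are predicted in 32³ tiles on the training stride grid with
boundary snap; each voxel's probability is the mean over covering tiles.
Binarisation at 0.5 (strict inequality, configurable). The binary map is
filtered with 26-connectivity connected components and the n largest
components are kept, n being the known number of canals; size ties break
towards the component containing the lowest linear voxel index. An empty
prediction raises a warning flag and is reported as a failure, never
silently dropped. For evaluation the filtered mask is split per canal and
paired with ground truth by component centroid along the left–right axis
(declared in the dataset manifest; axis 0 by default for external data).

## Performance measures

From exact confusion counts: DSC = 2TP/(2TP+FP+FN), precision, recall;
0/0 cases return NaN (undefined), not 0. Distance measures, all in mm:

* **ASSD** — mean nearest-neighbour distance between the two surface voxel
  sets, symmetrised. Surfaces are mask voxels with an outside 6-face
  neighbour (the volume border counts as outside).
* **MCD** — mean distance from ground-truth centerline points to the
  predicted centerline; intentionally asymmetric (truth → prediction). The
  predicted centerline is the longest geodesic path through the 26-connected
  graph of the thinned (skeletonised) mask, found with a double Dijkstra
  sweep; side branches are discarded. Ground-truth centerlines for phantoms
  come from the generator and are exact.
* **RHD** — max of the two directed 95th-percentile surface distances;
  percentiles interpolate linearly between order statistics (convention
  choice).

The positional profile evaluates the curve distance at 100 uniformly spaced
arc-length positions along the truth centerline, oriented from the proximal
(mandibular-foramen) end to the distal (mental-foramen) end — phantom
manifests declare the orientation; for external data without metadata the
endpoint with greater z is taken as proximal and flagged. Aggregation
reports per-position mean, median and population SD (a fixed case set, not
a sample estimate) over non-failed cases, with failures counted.

## Numerical and degenerate-case choices

* Resampling targets below 0.05 mm are rejected (runaway memory guard).
* `d(a, B) = min_{b∈B} ‖a − b‖₂` throughout, via k-d trees; brute-force
  all-pairs oracles in the tests pin these to 1e−9 mm.
* Component-size ties and curve orientation are resolved deterministically;
  two identically seeded runs produce byte-identical reports.
* Skeletons of blobs that thin to fewer than 2 voxels fall back to the
  principal-axis diameter of the mask.
* Empty masks: surfaces and skeletons are errors; distance metrics return a
  NaN failure marker that summaries count rather than average away.

## Problem sizes used by the bundled experiment

The standard run (also what `scripts/acceptance.py` executes) generates 20
training and 4 test phantoms of 96³ voxels at 0.4 mm with two canals each,
trains the 2-level/8-channel network on coarse labels under the desk-scale
schedule, and evaluates all four distance/overlap measures plus the
positional profile on the held-out phantoms. One run takes roughly 8
minutes on a single CPU.

## Known limitations

* The phantom's contrast task is easier than clinical CBCT; phantom scores
  (DSC ≈ 0.97) are far above the clinically reported range and should not be
  read as clinical performance.
* MCD compares point sets, not continuous curves; its value contains a
  sampling term of order half the skeleton voxel spacing.
* Thinning-based centerlines shorten near the tube ends (endpoint erosion),
  which inflates the profile near the foramina — consistent with the
  qualitative end-effect expected there, but not a calibrated model of it.
* The NumPy/numba training stack is single-threaded and desk-scale; the
  full-scale 400-epoch regime is out of its intended range.
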