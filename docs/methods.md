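# Methods

This note documents the models and procedures implemented in `cender`, the
parameter choices that matter, what the synthetic benchmark does and does not
demonstrate, and the numerical conventions.

## Coordinate and box conventions

Pixels are 0-based with (x, y) = (column, row); boxes are half-open,
covering [x, x+w) × [y, y+h), so box IoU equals pixel-set counting for
integer boxes. Stacks are (Z, H, W). The worm frame maps pixel points to
(x', y', z') with x' along the anterior–posterior axis (anterior positive),
y' along the ventral–dorsal axis (ventral positive), z' in frame units
scaled by `z_scale` (default 1 frame; the physical ratio for a 1.5 µm z-step
at 0.30 µm/px lateral would be 5). Cylindrical coordinates use
φ = atan2(y', x'), so φ ∈ [−π/2, π/2] is the territory containing the
anterior axis, labeled the ventral ("V") territory in the density feature.

## Head segmentation and worm frame

Median blur 5 × 5; greyscale closing with a disk-5 dilation and disk-4
erosion (the larger dilation connects nuclei without fusing head and body at
synthetic scales); global Otsu threshold (an adaptive-mean variant is
config-exposed); largest connected component = head, other components =
body. The longest chord through the center of mass is searched over
directions at 1° resolution with 0.5 px ray marching inside the mask, ties
broken toward the smaller angle index. Orientation (anterior, ventral) is
the side of each axis holding more points of interest; an exact tie falls
back to the side of the contour point farthest from the center and logs a
warning. Degenerate inputs (constant image, empty mask, failed chord) raise
rather than guess; strongly self-occluding postures are expected to surface
this way rather than be recovered.

The recovered axes carry noise: on the easy synthetic regime the
anterior–posterior axis deviates from the generative pose by ~3–13° (median
per animal), dominated by head bending, which genuinely rotates the longest
chord. Features inherit this as a per-volume rotation; see *Recognition*.

## Detection

Local maxima: 3 × 3 neighborhood, intensity floor = head mean + 0.5 σ. The
small neighborhood matters: dim span-edge nuclei sitting next to bright
neighbors lose their local maximum in wider windows. One anchor size (9 × 9,
the typical nucleus footprint) by default; {7, 11} behind a config flag.

The network is deliberately small, sized for single-CPU numpy training: a
stride-3 5 × 5 conv stem (5→12 channels), a residual block, a stride-2 conv
(12→24), a second residual block, global average pooling, and two heads — a
sigmoid score and a linear 4-vector whose scale components pass through exp
so ω̂, η̂ > 0. Training: binary cross-entropy on the score (positive anchors
weighted 2.5×, which buys recall from a precision-saturated operating point)
plus L2 on the corrections of positive anchors; SGD with momentum 0.9 and
cosine-annealed warm restarts (period 4 epochs, 10 epochs total, peak lr
0.02); anchors with best ground-truth IoU ≥ 0.3 are positives, < 0.1
negatives (subsampled to 2 per positive), between ignored; anchors
re-centered on each annotated box are added as guaranteed positives. All
randomness flows from one seed; inference is deterministic.

Score floor 0.4, NMS overlap 0.20 and the evaluation IoU 0.3 are fixed
operating points of the method. Note a structural consequence: ground-truth
regions of distinct stacked nuclei can themselves overlap by more than 0.20
in a frame, so NMS bounds attainable region recall (≈ 0.86 on the easy
regime even for a perfect scorer); nearly every *neuron* still retains at
least one detectable region.

Detection metrics use optimal (Hungarian) one-to-one matching of predictions
to ground truth per frame — greedy descending-IoU matching is only maximal
and can undercount true positives.

## Merging

Adjacent-frame matching maximizes total IoU (costs = −IoU, weights < τ =
0.05 zeroed, zero-weight assignments discarded); the chain objective
separates over adjacent pairs, so per-pair Hungarian solutions attain the
global chain optimum. Splitting scans the raw member-intensity profile for
strict interior local minima and assigns the minimum frame to the *later*
fragment (keeps both parts non-empty when the minimum is at index 1); an
optional 3-point-mean smoothing is off by default. The optional longitudinal
bound re-splits objects longer than the maximum annotated span (4 frames on
the easy regime) at their weakest internal IoU link; the end-to-end pipeline
enables it because nucleus X-Y and Z sizes are strongly correlated, making
the bound readable from annotations.

The 3D evaluation criterion (no canonical definition exists) counts a
predicted object as a true positive when matched one-to-one to a ground
truth object with mean member-region IoU ≥ 0.3 over shared frames and shared
frames covering ≥ half the span union; both constants are config-exposed.

## Features

Density: nested cylinders C_t = {ρ ≤ t·Δl, |z| ≤ t·Δz/2}, t = 1..q; shell t
is C_t \ C_{t−1}, split into 4 territories (V/D × z±), giving q × 4
non-negative counts whose sum equals the population of C_q. Defaults q = 8,
Δl = head radius / q, Δz = stack depth / q (full depth covered at t = q).
The nested set-difference form (rather than a product of radial and axial
bands) is what makes the shells a partition of the outer cylinder.

KNN: the K = 25 nearest neuron-object centroids by Euclidean worm-frame
distance, ascending, ties broken by context index, each contributing
(ρ, φ, z); deficits are zero-padded and the pad count recorded. The
concatenated vector has length 4q + 3K = 107.

Density context uses member-region centers of all other objects
(`source_mode="regions"`); a centroid-only mode exists for data without
region information.

## Recognition

Embedding MLP: 512 → 256 hidden units with batch normalization and ReLU,
linear output of dimension d = 64; class-weight matrix W with N columns
(tracked IDs + 1 extra class for annotated-but-untracked neurons; the extra
class is excluded from matching and its assignments reported unassigned).
Loss: the combined-margin form above; θ is computed by clipped arccos and
the target-logit gradient uses s·m₁·sin(m₁θ + m₂)/sin θ with sin θ floored,
which is the smooth composite away from the arccos endpoints. With
(m₁, m₂, m₃) = (1, 0, 0) the loss equals the normalized s-scaled softmax
cross-entropy (a tested identity). Optimizer: Adam (lr 2 × 10⁻³, cosine
decay, 160 epochs, batch 256), deterministic per seed. Features are
standardized with training-set statistics stored in the model.

Two measures against feature noise, both first-class options:

- *Rotation augmentation*: training features are recomputed under worm-frame
  rotations of {0, ±6, ±12}°, matching the observed axis-recovery noise.
- *Seed ensemble*: two models trained from different seeds; their cosine
  distance matrices are averaged before the Hungarian assignment.

Rectangular assignment problems are padded at cost 2.0 (the cosine-distance
maximum); ties break toward lower column index.

For end-to-end training labels, detected objects are matched one-to-one to
annotated objects by centroid distance (Hungarian, gated at 6 px); unmatched
detections are dropped from training. Tracking top-1 is reported over
neurons whose assigned and ground-truth ids are comparable (the matched
objects), keeping detection and recognition errors in separate metrics as
is standard; the stricter composite over *all* annotated neurons — where a
neuron lost in detection counts as a tracking failure — is additionally
computed by the acceptance script (`tracking_top1_all_neurons_pct`). On the
easy regime the two differ by roughly the object-level detection recall
(~0.87), which is structurally bounded by the fixed NMS threshold in
crowded frames.

## Activity extraction

F_RFP is the mean red intensity over a neuron's member-region pixels; the
green channel is sampled at affine-mapped coordinates (nearest pixel;
identity map by default, least-squares calibration from ≥ 3 landmark pairs
provided). A per-frame median background is subtracted from each channel
before the ratio (disableable); without it the diffuse background biases the
box-mean ratio toward 1. Neurons whose mapped region leaves the green frame
are flagged `missing` with R = NaN, never zero. Box-mean is used rather than
a segmented-mask mean (the boxes are tight).

## The synthetic generator

The generator defines the study conditions. The easy regime: 256 × 256 × 12
volumes, 60 nuclei of radius 2.2–3.6 px (axial span 1–4 consecutive frames
proportional to radius), intensities 130–250 with 12 % per-volume lognormal
jitter, background level 12 with σ = 5 Gaussian noise, a dim body-shaped
smear outside the head, per-step in-plane drift ≤ 2 px accumulated across
the Z-scan, and per-volume rigid rotation ≤ 20°, translation ≤ 8 px and
bending ≤ 25° (anterior and posterior halves counter-rotated with a linear
ramp). A `hard` preset (150 neurons, 512 × 512 × 18, stronger motion) is
provided but not part of the default benchmark.

Blob placement is skewed: 72 % of nuclei fall on the anterior (resp.
ventral) side with their spread compressed to 0.60 (resp. 0.65) of the
posterior (dorsal) extent, and brightness rises by 25 % (18 %) toward the
anterior (ventral) pole. This emulates the compact bright nerve-ring/amphid
cluster and ventral cord, and it is load-bearing: orientation by
point-of-interest count dominance is only well-posed when the distribution
is skewed about its own intensity-weighted centroid — with symmetric spread
the counts on either side of the centroid balance by construction and the
anterior/ventral calls degrade to coin flips under bending.

What the generator does **not** emulate: optics (PSF, spectral
bleed-through), nucleus shape variation (blobs are isotropic Gaussians),
occlusion and self-touching postures, z-dependent aberrations, and
worm-to-worm systematic anatomy beyond a re-seeded layout. Passing the
synthetic benchmark therefore demonstrates the internal consistency and
trainability of the pipeline under known geometry and noise — not
performance on real recordings, which hinges on annotation quality and
optical effects absent here.

## Problem sizes and determinism

The default benchmark trains the detector on 30 volumes (~21 000 multi-field
patches, 10 epochs) and evaluates on 10 held-out volumes; the recognizer
trains on ~1 500 labeled neurons (× 5 rotation augmentations, × 2 ensemble
seeds). These sizes keep a full from-scratch run in the tens of minutes on a
single CPU with the numpy networks. Every stochastic step (layout, poses,
rendering noise, batch order, initialization, negative subsampling) derives
from explicit integer seeds; identical seeds give bit-identical datasets and
training trajectories.

## Known limitations

- Orientation relies on anatomical asymmetry; near-symmetric heads (or
  extreme bends) can flip an axis for a volume, which silently mirrors that
  volume's features (~1 in 40 volumes on the easy regime).
- NMS at fixed 0.20 bounds region recall in crowded frames (see Detection);
  recovering such regions would need instance segmentation, which is out of
  scope.
- The accidental-fusion split uses only the axial intensity profile;
  same-brightness nuclei stacked with smooth profiles are not split unless
  the longitudinal bound catches them.
- Cross-animal (template-mode) accuracy is intrinsically limited by
  layout differences between animals; the pipeline reports it but makes no
  attempt at cell-type identification.
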