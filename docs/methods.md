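# Methods

`acnsim` simulates *augmented capillary network* (ACN) image data: volumetric
OCT-like images of skin capillaries, paired voxel-for-voxel with binary
ground truth, for training and evaluating capillary-segmentation models.
This note records the models implemented, the parameters that matter, the
numerical choices made where the construction was genuinely open, and the
limitations of the synthetic data.

## Capillary pathway model

Pathways are grown on a 2D en-face working domain of `Lx x Ly` pixels
(default 128 x 128) by analogy with a river basin: one **root point**
sampled on the boundary is the sink, and each capillary grows from an
interior **end point** toward it along the steepest descent of a scalar
potential.  The root contributes

    U_root(x, y) = alpha * [(x - x0)^2 + (y - y0)^2]^(1/4),

i.e. `alpha * sqrt(r)` — zero at the root and monotonically increasing with
distance.  Every previously grown pathway `i` adds a shallow valley

    U_i(x, y) = beta * sum_j [(x - x_ij)^2 + (y - y_ij)^2]^(gamma / 2),

with `beta < 0` (valley depth) and `gamma < 0` (valley range).  Defaults
`alpha = 100`, `beta = -20`, `gamma = -1`.  Because later pathways descend
the *total* potential, one growing near an earlier pathway can be captured
by its valley and attach to it as a branch rather than reaching the root —
this is what produces branched networks.  Capillary branches keep a single
width throughout; there is deliberately no arterial-style tapering.

Numerical choices (the growth rule is stated in continuous terms and had to
be discretised):

- **Neighborhood**: 8-connected steepest descent; ties broken by the fixed
  neighbor order E, NE, N, NW, W, SW, S, SE, making growth deterministic.
- **Singularity**: with `gamma < 0` the pathway potential diverges on the
  pathway; squared distances below 1 px² get +0.5 px² added inside the
  bracket, so fields are finite everywhere on the grid.
- **Attachment**: a pathway attaches when its next point coincides with or
  is 8-adjacent to a point of an earlier pathway.
- **Budgets**: a pathway may take at most `4 * (Lx + Ly)` steps; a trapped
  or over-budget walk discards the end point and resamples it, up to 10
  times, after which network construction fails loudly.
- **Sampling**: the root is uniform over the four edges; end points are
  uniform over the interior excluding a 10-px margin (clamped for small
  domains), keeping curves inside the frame.  Networks carry 3–6 end
  points by default.

### Smoothing

Steepest descent yields straight, sharply-folded polylines.  Each pathway
is replaced by a third-order polynomial — `x = a3 y^3 + a2 y^2 + a1 y + a0`
or `y = b3 x^3 + ... + b0` — through four control points: the first point,
the points at the one-third and two-thirds positions, and the last point.
The independent coordinate must change monotonically along the branch; when
both coordinates qualify the one with the larger span is used (better
conditioning), and when neither does the branch is split in half and each
half smoothed recursively.  Near-straight branches (maximum perpendicular
deviation from the chord < 1.5 px) get their two middle control points
shifted laterally — by 6 % of the chord length with a random sign — before
fitting, bending dead-straight runs into gentle curves.  End points of each
branch are preserved exactly.  The 1.5-px straightness tolerance and 6 %
shift are this package's quantification of an unquantified "slight shift";
both are configurable.

## Frame synthesis

A smoothed network is rendered by pasting a 2D Gaussian spot

    f(x, y) = Ic * exp(-[(x - x0)^2 + (y - y0)^2] / (2 sigma_c^2))

at every curve point.  `Ic` (default range 0.05–0.08 in normalised units)
sets capillary brightness and `sigma_c` (5–8 px) the lumen diameter.
Overlapping identical spots combine by pixelwise **maximum** (additive
combination would double intensities wherever the curve is densely
sampled); for identical spots this maximum equals the spot profile
evaluated at the distance to the nearest curve point, which is how the
render is computed, exactly and at subpixel precision.

**Ground truth** is geometric: pixels within `1 * sigma_c` of the curve.
It depends only on the curve geometry and `sigma_c` — never on intensity or
noise — so re-rendering with different noise seeds can never change a mask.
(A fixed intensity threshold on the noiseless render would give the same
family of discs, offset by a constant radius factor; the radius rule makes
the equivalence explicit and configurable via `gt_radius_mult`.)

**Fragmentation.** Capillaries are visible only while red blood cells pass,
so each frame shows a different subset of the network.  Along each curve's
arclength, kept segments and gaps alternate with exponential lengths (means
20 px and 12 px); `keep_fraction` (0.6) is the approximate expected visible
fraction and decides the initial state.  Fragmented point sets are strict
subsets of the curve, and unions over many frames converge to the full
network mask.

**Speckle.** Granular speckle (melanin granules, multiply backscattered
signal) is modelled as bright Gaussian patches with width
`sigma_speckle = k * sigma_c`, `k = 8` (the model requires `k > 4`), peak
`I_speckle ~= Ic`, and a Poisson(3) patch count per frame.  Patches are
max-combined with the noiseless capillary render *before* noise is added:
patches are scene structure riding on the background level, and
max-combining them with an already-noisy image would either vanish below
the background mean or clip the noise distribution.

**Background noise.** White Gaussian noise is added on top of a constant
background level (default 0.25) and the result clipped to [0, 1].  The
noise standard deviation realises a requested SNR,

    SNR = 10 * log10(Ic^2 / sigma_noise^2)   [dB],

sampled in [1, 10] dB per frame.  The background level keeps clipping
statistically negligible (>= 3.5 sigma away at the noisiest setting), so
the measured SNR of generated backgrounds matches the request to within
0.1 dB over 1e5 pixels.  An explicit `noise_std` override bypasses the SNR
formula when a direct noise amplitude is wanted.

## Volume assembly

About 20 independently fragmented frames of one network form a
**sub-volume**; 1–3 of its layers are replaced by pure-background frames
(no flow at that instant), whose ground truth is empty.  One or two
sub-volumes of *different* networks are embedded into a 128 x 128 x 64
target volume at random z-positions with at least 1 background slice at
the top and bottom and at least 2 between sub-volumes ("well separated",
quantified here); remaining slices are background-only frames.  Volumes
are stored as 8-bit unsigned integers — `round(v * 255)`, invertible to
within 1/510 — as two multi-page TIFF stacks (input, GT) plus a JSON
sidecar with placements and the generation seed.

Dataset generation derives per-volume seeds from the master seed via
`SeedSequence([master, index])`, so any volume can be regenerated in
isolation and the whole dataset is bit-reproducible.  The full study scale
(10,400 smooth-background volumes split 7000/3000/400 and 7,000 speckled
split 5200/1400/400) is a configuration choice; the defaults generate
desk-scale datasets with the same structure.

## Segmentation model

The segmentation network is a 3D U-Net: four contracting blocks (two
3x3x3 convolutions, ReLU, each followed by batch normalization, then 2x2x2
max pooling), a bottleneck, four expanding blocks (2x up-sampling, skip
concatenation with the matching contracting block, two conv+BN pairs), and
a 1x1x1 sigmoid head.  All convolutions pad to preserve spatial size, so
the output volume matches the input shape with per-voxel scores in [0, 1].
Up-sampling defaults to nearest-neighbor resize followed by a 2x2x2
convolution, with a learned transposed convolution as an option.  Filter
counts double per level from `base_filters` (default 16); dropout (default
0.1) follows each block's convolutions.  The loss is binary cross-entropy
on the sigmoid output — the natural choice for this head; it is exposed in
the training configuration rather than hard-wired as a claim.

The implementation is pure numpy with explicit backward passes (im2col
convolutions, batch-norm backprop, max-pool argmax routing) and Adam.
Every gradient is regression-tested against finite differences, and the
per-block shape trace and a closed-form parameter count are asserted in
the suite.  Training is reproducible to identical loss curves for fixed
seeds.  Per-epoch subset sampling (uniform, without replacement, fresh
each epoch) mirrors the pool-sampling protocol used at full scale.

**Desk scale.**  The package's own experiments run a reduced model —
32 x 32 x 8 volumes, depth 2, 8 base filters, batch 2, learning rate 3e-3,
300 epochs — chosen so a single CPU drives the model to overfit two
generated volumes (training F1 > 0.8 under per-frame mode+2·std
binarization) in about two minutes.  Desk-scale volumes use `sigma_c =
2.5` so the capillary area stays a minor fraction of the 32 x 32 frame;
the mode-plus-deviations threshold *assumes* the background is the modal
pixel value, and a full-width capillary on a small frame would break that
assumption (this is a property of the threshold, not of the model).  The
full-scale recipe (128 x 128 x 64, base 16, depth 4, 1500 epochs, batch 4,
lr 1e-4) is configuration, not test.

## Binarization and evaluation

The threshold `p_thresd = p_mode + c * p_std` (default `c = 2`) is computed
on the 8-bit scale: `p_mode` is the most frequent pixel value (ties break
toward the lowest — the background is dark), `p_std` the population
standard deviation of all pixels, and foreground is *strictly* above the
threshold.  Floating images in [0, 1] are quantized to the 8-bit scale
first; 8-bit-scale floats (frame averages) are rounded.

Scheme 1 averages predicted frames and thresholds the mean image.
Scheme 2 thresholds each frame, counts per-pixel foreground appearances,
keeps pixels appearing in >= N frames (read as "at least N", matching the
reported N = 1, 2, 3 series), and assigns them their maximum intensity
across frames, so the merged image binarizes as "value > 0".  Masks are
monotone non-increasing in N by construction.

Confusion counts compare full frames pixel by pixel (no border exclusion).
Rates are normalised within the GT-positive class (TP, FN over TP + FN)
and GT-negative class (TN, FP over TN + FP); accuracy, precision, recall
and F1 use the standard definitions with 0/0 -> 0 conventions.  The
bundled reference score rows are used as worked examples of two exact
identities — F1 is the harmonic mean of the printed precision/recall, and
recall equals the printed TP rate — for the single-volume rows; rows that
average scores over 400 test volumes do not satisfy mean-of-ratio
identities exactly and are checked only where rounding happens to preserve
them.

## What the synthetic data does and does not show

The generator reproduces the *statistical appearance* of en-face OCT
capillary data: branched single-width networks, Gaussian-profile bright
segments, frame-to-frame fragmentation, interlaced empty frames, low SNR
backgrounds and coarse bright speckle.  It does not model coherent
(interference) speckle, motion artifacts, shadowing, depth-dependent
signal decay, or z-varying vessel geometry (networks are en-face 2D,
replicated across a sub-volume's layers).  Passing tests therefore
demonstrate the internal consistency of the simulator and the correctness
of the evaluation pipeline on data of this kind — not segmentation
performance on real FF-OCT volumes, which additionally depends on
full-scale training and real annotated data.
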