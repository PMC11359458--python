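# Methods

This note records the models, conventions and design choices behind
`colloidspot`, in the order data flows through the package.

## Conventions

Coordinates are `(row, col)`, 0-based, pixel centres at integers; the
image-processing `(x, y)` maps to `(col, row)`. Intensities are 8-bit
`[0, 255]` (deeper inputs are max-normalized and rounded; multi-channel
inputs are collapsed by luminance averaging). Binary masks use `{0, 255}`
so every detector output is itself a displayable image. Detections and
ground truth travel as plain CSV (`frame, method, row, col, area` and
`frame, particle_id, row, col, attached`).

## Detectors

**k-means (k = 3).** One-dimensional Lloyd iterations on pixel
intensities: initial centres are k distinct intensity values sampled
uniformly without replacement, assignment is nearest-centre (ties to the
lowest cluster index), and iteration stops when the largest centre shift
drops below ε = 10⁻⁴ (cap 300 iterations). An emptied cluster is
re-seeded at the sample farthest from its centre. Because k-means is
sensitive to initialization, 10 restarts are run and the lowest-SSE model
kept; a fixed seed makes the fit bit-reproducible. Fitting operates on
the 256-bin histogram with counts as weights, which is algebraically
identical to clustering the raw pixel list. The cluster with the highest
centre is declared the colloid cluster ("white dots" are the brightest
region of a micromodel frame).

**Otsu.** The between-class variance
`Var(T) = P₀(T)·P₁(T)·(m₀(T) − m₁(T))²` is evaluated for every
`T ∈ 0…255` with classes background = `{i < T}` and foreground =
`{i ≥ T}` (this partition keeps the class-mean sums and the detector's
`≥ T` foreground rule mutually consistent); `Var` is defined as 0 when a
class is empty, and argmax ties resolve to the smallest `T`. The result
object carries the full variance curve, histogram, CDF and global mean
for inspection, and the implementation is tested pixel-for-pixel against
an exhaustive two-loop scan.

**Frame differencing.** All differences are absolute values computed in a
signed dtype (unsigned wraparound would corrupt them), and the motion
threshold `T` is strict. The default `T = 25` is a conventional value for
8-bit imagery with a ~100-intensity colloid/pore contrast; it is a config
knob (`bg.threshold`). The background model is the per-pixel temporal
median over all frames, rounded — no alignment is performed because the
camera is fixed. FDBS takes the previous frame as its reference frame B
(t−1, not a fixed anchor frame). Detectors needing both temporal
neighbours yield no output on the first/last frame rather than inventing
padding. A colloid stationary across frames is invisible to this whole
family; the test suite asserts that blindness rather than hiding it.

**Laplacian.** The negated 4-neighbour stencil (centre +4, edge
neighbours −1, corners 0), so a bright spot yields a positive central
response with four negative side lobes; the 4-neighbour form matches the
"one white dot, four dark dots" signature used to identify a colloid.
Default response threshold 40 on 0–255 inputs (about a third of the
colloid/pore contrast); configurable.

**DoG.** Each truncated Gaussian `exp(−r²/2σ²)` is normalized to sum 1
over the size×size support *before* subtraction, which guarantees an
exactly zero-sum band-pass kernel even at the aggressive default
truncation (3×3 with σ₂ = 2). The detection rule is a conjunction:
response above threshold (default 10) AND at least one 8-neighbour of
opposite sign — the zero-crossing that marks a spot edge. Convolution is
discrete correlation with replicate-edge padding.

**Morphology.** Binary erosion/dilation follow the set definitions
(footprint fits / reflected footprint hits), with out-of-bounds treated
as background; grayscale forms are local min/max with identity-element
padding (255 for erosion, 0 for dilation). The disk footprint is
inclusive: offsets with `dr² + dc² ≤ r²`. The detectors run grayscale
morphology directly on the raw frame — dilation with disk(4) to enlarge
1-px colloids, white top-hat with disk(2) to keep only features smaller
than the disk — and binarize the result with Otsu by default
(parameter-free; a fixed threshold can be configured instead).

## Object extraction and the ensemble

Connected components (8-connectivity by default, since 1–2 px spots may
touch diagonally) become detections with unweighted-mean centroids.
The benchmark pipeline filters areas to `[1, 200]` px: thresholded
whole-pore-space blobs and long boundary chains are rejected as
detections while genuine spots (≤ ~80 px even after dilation) pass.
Exactly co-centred concentric components — possible for ring-shaped
filter responses — are merged into one detection, as they describe one
object.

The majority vote is object-level: the unclustered cross-method pair with
the smallest centroid distance ≤ vote radius (default 5 px ≈ 2× the
colloid image radius) seeds a cluster, which then absorbs the nearest
third-method detection within the radius of the cluster centroid and of
each member. Clusters supported by ≥ 2 of the 3 methods are emitted with
the mean centroid and summed area; singletons are dropped (two methods
voted "not a colloid"). Ties break on distance, then method name, making
the vote invariant to the order of the input sets. A pixel-level mode
(foreground where ≥ 2 of 3 masks agree) is provided for comparison but
the object-level vote is the default, as voting is about *colloids*, not
pixels. The fixed constituent trio is top-hat, DoG, k-means — the three
best single methods — but any three can be configured.

## Evaluation

Matching is greedy one-to-one by ascending detection↔target distance with
tolerance 3 px (≈ 2× the colloid image radius; generous enough for the
≤ 0.7 px rounding offset of a stamped centre, strict enough that distinct
colloids — kept ≥ 10 px apart by the generator — can never swap).
Duplicate detections of an already-matched target count as false alarms;
one merged detection spanning two targets scores one TP and leaves the
rest as misses. The 0/0 convention for P, R and F is 0; TCR with an
all-zero denominator raises instead, since such a frame carries no
information. Metrics are computed per frame first and then averaged
(mean ± population std), so the reported mean F need not equal the F of
the mean P and R.

The Friedman test ranks methods within each frame (rank 1 = highest
F-measure; ties get average ranks) and uses the tie-corrected chi-square
statistic with k−1 degrees of freedom, verified against an independent
reference implementation to 10⁻⁹. Post-hoc pairwise comparisons use the
rank-difference z-test `z = (R̄ᵢ − R̄ⱼ)/√(k(k+1)/6n)` with two-sided
normal p-values and Holm's step-down adjustment (the choice of pairwise
statistic is a documented interpretation; the Holm step is exact). The
benchmark ranks the eight single methods only — the ensemble is scored
but not ranked, since it is built from three of the contestants.

## Synthetic scenes

The generator emulates the *structure* of micromodel imagery, not its
optics: three intensity levels (grain 10, pore 150, colloid 250), real
porosity (0.42 ± 0.02, tuned by bisection), point-like colloids, a mobile/
attached mix, inlet/outlet exchange, and optional additive Gaussian
noise (default off). Grain geometry is thresholded smoothed Gaussian
noise (smoothing length 12 px), regularized by a disk(2) closing+opening:
a soft-lithography micromodel has no features below the fabrication
scale, and the regularization gives the pore network the same property.
Colloid centres are placed in pore space with ≥ 3 px clearance from grain
walls (a 4.3 µm sphere cannot centre itself on a wall) and ≥ 10 px
pairwise separation (2× the vote radius), maintained during motion as an
excluded-volume constraint. Mobile colloids advance each frame by
|N(1.9, 0.48)| px along a direction drawn about the flow axis
(σ = 0.6 rad), re-sampled on grain collision; 1.9 px/frame corresponds to
the 4.8 m/day pore velocity of the emulated experiment at 10 frames/s and
2.9 µm/px. Colloids crossing the domain edge are removed and replacements
enter at the inlet strip. The attached fraction defaults to 0.5 (the
emulated experiment contains both populations; no fraction is reported).
Everything is deterministic under the seed, and frame 0 is independent of
the total frame count.

What the generator does **not** model: the point-spread function and
photobleaching, intensity variation between colloids, sub-pixel rendering
(centres are stamped at the nearest pixel), grain-wall optical artifacts,
and realistic sensor noise spectra. Perfect scores on this benchmark
therefore show that the pipeline is correct under the three-level model
— they do not promise perfect scores on real microscopy, where thresholds
and the noise floor matter.

Default sizes: tests use 256×256 scenes with 20 colloids and 25 evaluated
frames; `scripts/acceptance.py` uses the full 1684×1688 geometry with 81
colloids, the scale of the emulated dataset.

## Known limitations and failure modes

* On a trimodal frame whose grain and pore populations are both large, a
  single Otsu threshold necessarily splits grain|pore, not pore|colloid —
  the between-class variance of the grain split is two orders of
  magnitude larger. Plain Otsu and dilation+Otsu therefore mark the whole
  pore network as foreground on such scenes; the area filter then rejects
  it wholesale, and both methods score near zero on the synthetic
  benchmark even though they perform respectably on imagery whose
  histogram is dominated by pore space. The dilation detector's
  disk-growing behaviour is asserted on pore-dominated frames.
* DoG and Laplacian respond along grain/pore boundaries. Long boundary
  chains exceed the 200-px area cap and are dropped, but fragments around
  small grains survive as false positives; the ensemble removes them
  because no second method confirms them.
* The greedy matcher and the greedy vote are not globally optimal for
  pathologically dense constellations; both are verified against
  exhaustive enumeration on separated constellations, and the generator's
  10-px separation keeps benchmark scenes in that regime.
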