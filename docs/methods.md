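# Methods

This note documents the models, estimators and numerical choices behind each
stage of the pipeline, what the synthetic generators do and do not emulate,
and the known limitations.

## Coordinate and unit conventions

Volumes are arrays ordered `(channel, z, y, x)`. All physical quantities are
nanometres; positions are `(z, y, x)` nm with the centre of voxel `(k, i, j)`
at `((k + 0.5)·p_z, (i + 0.5)·p_xy, (j + 0.5)·p_xy)`. Defaults follow the
SIM acquisition geometry this pipeline was built around: 32.1 nm XY pixels
and 200 nm z-steps. Localization tables are planar `(x, y)` nm. Times are
seconds in traces; kinetic parameters (τ, rates) are reported in minutes, the
natural scale of Aβo binding.

## 3D puncta segmentation

Punctate objects are enhanced with an anisotropic Laplacian-of-Gaussian
filter (σ_xy = 2 px, σ_z = 1 px by default), negated and clipped at zero so
blobs become positive peaks. "Kernel size" is parameterized as the Gaussian σ
in pixels. A plain-Gaussian smoothing mode is retained behind a flag, but a
blob detector is the default because the purpose of the step is to suppress
extended structures (dendritic shafts) while keeping compact puncta; a flat
plateau has zero Laplacian response regardless of its brightness.

The mask threshold is the higher of the two cut points of a three-class
(two-level) Otsu decomposition of the enhanced-intensity histogram; the lower
cut absorbs background/shaft levels. Densely packed channels additionally get
a per-z-slice watershed pass: watershed lines of the Gaussian-smoothed
(σ_xy = 1 px) inverted intensity, computed slice-by-slice with 1-connectivity,
are subtracted from the mask, so the operation can only remove voxels
(conservation is a tested invariant).

Labeling uses 26-connectivity in 3D by default: puncta are compact, and the
coarse z-sampling (200 nm steps vs 32 nm pixels) under-connects genuinely
single objects at 6-connectivity. Centres of mass are intensity-weighted on
the original (not enhanced) intensities; an unweighted option exists. Because
Otsu cuts scale with the data, the whole chain is invariant to multiplying
the image by any positive constant.

## Distance-shell enrichment with a randomization null

The reference channel's label map defines an exact anisotropic Euclidean
distance transform (scipy EDT with `sampling=(p_z, p_xy, p_xy)`), so every
voxel holds the nm distance to the nearest reference voxel. Each amyloid
punctum is assigned the distance of its containing voxel and binned into
half-open shells `[i·w, (i+1)·w)`; the default shell width is 64.2 nm (two XY
pixels) out to 642 nm.

The null model redistributes the same puncta uniformly over the voxels whose
distance is at most the placement radius (642 nm = 20 XY pixels by default),
sampling without replacement at voxel resolution, and preserving the number
of puncta in each z-plane. The per-plane constraint prevents the z-anisotropy
from biasing shells: planes far from any reference object contain only
far-shell candidates, and their puncta must stay there. The expected shell
counts are averaged over `n_simulations` randomizations — 7 by default, the
replicate count used when this statistic is presented as an averaged null
curve; a single simulation is supported as the minimal variant. Shells with
zero expected count are reported as undefined (NaN), never divided.

The per-plane counts handed to the null include only the puncta found within
the placement radius. This is a normalization requirement, not a
convenience: redistributing puncta that lie beyond the radius into the
≤ 642 nm region would inflate every shell's expectation by the out-of-radius
fraction and push the normalized density below 1 even for perfectly uniform
data. A consequence worth noting is that the statistic measures the *shape*
of the puncta distribution inside the probed perisynaptic volume;
concentration tighter than the placement radius (e.g. within 100–300 nm of
the reference) registers as near-shell enrichment, while a change in the
overall fraction of puncta near synapses does not by itself move the ratio.

Two properties pin the implementation down and are enforced in tests:
shell counts on small scenes equal an all-pairs brute-force computation
exactly, and data generated by the null's own sampler produce normalized
densities statistically indistinguishable from 1 in every shell.

## SMLM preprocessing

The pipeline ingests localization tables (frame, x, y, σ, uncertainty,
photons, channel); raw-frame PSF fitting and temporal-median background
subtraction are upstream concerns. Filtering keeps localizations with
uncertainty < 20 nm and σ inside a closed per-fluorophore window (100–200 nm
CF568, 90–190 nm AF647); it is idempotent and order-preserving.

Channel registration fits the displacement between two channels from matched
bead positions, either as a degree-2 bivariate polynomial per axis
(least squares on centred, scaled coordinates) or as a Gaussian-kernel
locally weighted mean displacement. Degree 2 is the default: a smooth
full-field distortion bounded by 100 nm is captured at low order, and higher
degrees only amplify edge extrapolation. The fit stores its control-point
RMS; the acceptance check evaluates held-out beads, where the residual floor
is set by the quadrature sum of the two channels' localization noise
(≈ 10 nm for 5 nm per channel per axis), comfortably below the 15 nm
acceptance bound.

Drift correction follows the redundant cross-correlation scheme: frames are
grouped into 500-frame segments, each segment is rendered as a 10 nm 2D
histogram, every segment pair's offset is estimated from the FFT
cross-correlation peak refined by the centroid of its 3×3 neighbourhood, and
per-segment drifts are the least-squares solution of the redundant pairwise
system (first segment pinned at zero). Pairs whose residual exceeds
5 camera pixels (5 × 100 nm; the error threshold is stated in camera pixels,
not correlation bins) are discarded once and the system re-solved. Per-frame
drift is linearly interpolated between segment centres and subtracted.

## Nanocluster analysis

Local density at a coordinate is the number of coordinates within a fixed
radius (self-inclusive) divided by πR². The radius is not dictated by the
upstream workflow; the default of 30 nm is commensurate with the nanocluster
scale (α = 11 nm boundaries, mean cluster areas of a few thousand nm²) and
with the < 20 nm filtered localization precision. A k-nearest-neighbour
variant is deliberately out of scope.

Synaptic-region segmentation thresholds at the lower 10% of the density
*range* (`d_min + 0.1·(d_max − d_min)`); a percentile variant is available
behind a flag since "lower 10%" is ambiguous between the two readings. In the
degenerate zero-range case (all densities equal) every coordinate is
retained. Supra-threshold coordinates are grouped by the connected components
of the alpha complex at α = 100 nm, and components with boundary area below
1.5×10³ nm² are discarded.

Alpha shapes use the alpha-radius convention: the union of Delaunay triangles
with circumradius ≤ α, with the boundary as the union's outer edges. For α
larger than the point-set diameter this reduces to the convex hull (a tested
limit). Areas and overlaps are exact polygon arithmetic (shapely); a 2 nm
rasterization serves as an independent oracle in tests only.

Nanocluster detection randomizes the region's own localizations uniformly
over its polygon (seeded rejection sampling from the bounding box), pools the
randomized local densities over 20 randomizations (1 reproduces the minimal
variant; 20 stabilizes the mean + 2 SD cutoff), and groups experimental
coordinates above the cutoff by the α = 11 nm alpha complex. Components need
at least 3 members — the minimum that forms a triangle, hence a boundary with
area. A cluster is PSD-overlapping when area(cluster ∩ PSD)/area(cluster) ≥
0.23 (the threshold is treated as a fixed constant, and the boundary case is
inclusive); overlapping clusters get centre-to-edge distance 0, others the
distance from their weighted centre (mean of member coordinates) to the
nearest PSD boundary point. All of these statistics are rigid-motion
invariant by construction and by test.

## Trans-synaptic axis mapping

Pre/post objects are paired when mutually nearest; a pair is kept when at
least one amyloid punctum lies within per-axis Chebyshev windows of the pair
midpoint (20 px in X and Y, 3 px in Z, converted to nm via the voxel sizes —
a physical-units override exists because the effective pixel size of expanded
samples varies with the expansion factor). The manual "well-separated
pre/post" curation step is replaced by an automatic criterion — centre
separation at least twice the markers' mean equivalent-sphere radius —
because a reproducible pipeline cannot contain a human step. Distances are
reported in post-expansion nm; dividing by the expansion factor (typically
~4) is left to the caller.

Each punctum maps to cylindrical coordinates: z is the signed projection of
(p − origin) on the post→pre unit vector (positive = presynaptic), r the
perpendicular distance. Axial histograms use half-open bins centred on zero
and include only puncta with r ≤ r_max; bin width and r_max are required
parameters with no silent default.

## Kinetics

Compartment traces integrate (pixel − mean background) per frame over the
PSD mask (synaptic) and cell-fill-minus-PSD mask (extrasynaptic); the two
compartments are disjoint by construction. Background is the per-frame mean
over a user ROI — the simplest estimator consistent with
background-subtracted integrated density.

Association fits F(t) = 1 + (plateau − 1)(1 − e^(−t/τ)) with the baseline
fixed at the pre-addition normalization F/F₀ = 1; a free offset is not
identifiable from typical 10-minute binding windows and is not part of the
single-exponential model. A trace whose fitted amplitude is within twice the
residual noise is reported `converged=False` (τ unidentifiable) rather than
returning an arbitrary number. Washout loss is
100·(1 − F(t_w + h)/F(t_w)), linearly interpolating between samples, minus an
optional photobleaching-control loss; it is invariant to rescaling the trace.

FRAP normalizes to the pre-bleach mean and fits
F(t) = F_b + (F_∞ − F_b)(1 − e^(−kt)) over the post-bleach points with the
bleach depth F_b as a fitted parameter (initialized at the first post-bleach
sample; fitting it rather than pinning it to one noisy sample markedly
reduces estimator variance). The mobile fraction (F_∞ − F_b)/(1 − F_b) is
clipped to [0, 1] with a warning. The reported recovery rate is the rate
constant k in min⁻¹; because "rate" in this context is sometimes quoted in
minutes, the reciprocal time constant 1/k is exposed alongside it.

## Synthetic scenes: what they emulate, and what they do not

Generators derive all randomness from one seed per call (bit-identical
reruns) and return truth objects verifiable by independent brute-force
checks. Puncta are isotropic-in-nm 3D Gaussians truncated at 3σ; intensity
noise is additive Gaussian; localization noise is Gaussian jitter — matching
the precision-filtered regime the analyses assume.

Default parameter regimes mirror the experimental conditions the pipeline
targets: SIM geometry of 256×256×8 voxels at 32.1/200 nm with ~20 reference
objects and ~200 amyloid puncta; a 642 nm placement radius; bead fields of
200 beads over 25×25 µm with ≤ 100 nm smooth distortion and 5 nm noise;
2000-frame streams with ~100 nm drift and 10 nm precision; binding traces
with τ ≈ 3.6 min and plateaus around 3; washout stabilizing near 87% of the
pre-wash signal over 15 min; FRAP with mobile fractions 0.06–0.25, recovery
rate 0.15 min⁻¹ and a bleach depth of 0.3.

The enriched placement of `gen_sim_scene` deliberately reuses the enrichment
null's candidate-voxel sampler, with the marker footprint obtained by running
the same enhancement/threshold chain the analysis uses on the rendered
marker channel. This makes the null-self-consistency test exact by
construction: any residual deviation isolates detection error (merging,
centre shifts), not sampler mismatch.

Not emulated: optical reconstruction artifacts, dipole emission, camera
EM-gain statistics, fluorophore blinking kinetics, sample-drift correlations
with intensity, gel distortion in expansion microscopy, or spatially
structured background. Passing tests therefore demonstrate correctness of
the statistics under their stated noise models, not robustness to every
instrument pathology.

## Problem sizes

The test suite and the acceptance script run full pipelines at the scene
sizes above (20 replicate scenes for the null-consistency check, 20 seeds
for each parameter-recovery sweep, 100 traces for τ recovery); smaller
32×32×4 scenes are used where a brute-force oracle must enumerate all pairs.

## Known limitations

* The watershed split is per-slice (frame-to-frame), so objects touching
  only along z are not separated; this mirrors the intended behaviour.
* The null is defined on the voxel grid; continuous point-process nulls
  (Ripley's K, pair correlation) are explicit non-goals.
* Drift correction assumes enough emitters per 500-frame segment to form a
  correlatable histogram; sparse streams need longer segments.
* FRAP fitting is single-exponential pure-exchange; diffusion-shaped
  recoveries will bias k.
* Alpha-shape areas of very sparse regions (≪ 3 points per α²) are unstable;
  the 1.5×10³ nm² area filter removes most such cases.
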