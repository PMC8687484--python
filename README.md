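# perisynmap

Quantitative-imaging pipeline for mapping where amyloid-β oligomers (Aβo) bind
around excitatory synapses. Soluble Aβo binds neuronal surfaces within minutes
and accumulates at or immediately adjacent to the postsynaptic density (PSD) —
*perisynaptically* — rather than inside the synaptic cleft. Resolving that
distinction requires nanoscale statistics over several imaging modalities, and
this package implements them as a tested, reusable library for microscopists
and analysts working with:

* 3D multichannel fluorescence volumes (SIM / expansion microscopy),
* single-molecule localization tables (dSTORM, ThunderSTORM-style CSV),
* fluorescence time series (binding, washout, FRAP).

Because such analyses are usually locked inside bespoke scripts, every stage
here ships with a synthetic-scene generator carrying exact ground truth, so
each statistic can be validated end-to-end without microscope data.

## What it computes

**Distance-shell enrichment** (`sim_enrichment`). Puncta are segmented in 3D
(Laplacian-of-Gaussian enhancement, two-level Otsu threshold, per-slice
watershed splitting), an anisotropic Euclidean distance transform is taken
from the reference (e.g. PSD95) mask, and Aβ puncta centres are counted in
distance shells. Counts are normalized by the expectation under a constrained
uniform null: the same number of puncta redistributed uniformly over voxels
within 642 nm of the reference, preserving the number of puncta per z-plane.
For shell *s*,

```
density(s) = N_observed(s) / E_null[N(s)]
```

so 1 means no spatial relationship and >1 means enrichment above uniform.

**SMLM preprocessing** (`smlm_preprocess`). Quality filtering (uncertainty
< 20 nm; σ in 100–200 nm for CF568, 90–190 nm for AF647), bead-based
two-channel registration (degree-2 bivariate polynomial or locally weighted
displacement field; raw distortions up to 100 nm are reduced to < 15 nm RMS),
and redundant cross-correlation drift correction (500-frame segments, 10 nm
histogram bins, least-squares solution of all pairwise offsets with one
outlier-rejection pass at 5 camera pixels).

**Nanocluster geometry** (`nanocluster_analysis`). Coordinate-by-coordinate
local density, PSD segmentation by a density threshold at the lower 10% of
the density range with an α = 100 nm alpha-shape boundary (regions ≥ 1.5×10³
nm²), in-PSD localization fractions, nanocluster detection against a
mean + 2 SD uniform-randomization cutoff with α = 11 nm boundaries, and
PSD-overlap classification at the 0.23 area-fraction threshold
(centre-to-PSD-edge distance is 0 for overlapping clusters).

**Trans-synaptic axis mapping** (`exm_axis`). Pre/post marker objects are
paired into synapses; Aβ puncta are projected into cylindrical coordinates on
the post→pre axis (origin at the midpoint; positive z = presynaptic) and
histogrammed along the axis.

**Kinetics** (`kinetics`). Synaptic vs extrasynaptic integrated-density
traces from PSD and cell-fill masks, single-exponential association fits
F(t) = 1 + (plateau − 1)(1 − e^(−t/τ)), washout percent loss with a
photobleaching control, FRAP mobile fraction and recovery rate, and
windowed F/F₀ means.

## Worked example

```python
from perisynmap.synthetic_scenes import gen_sim_scene, gen_traces, TraceTruth
from perisynmap.volumetric_segmentation import segment_puncta
from perisynmap.sim_enrichment import enrichment_profile
from perisynmap.kinetics import fit_association

img, truth = gen_sim_scene(shape=(8, 256, 256), n_markers=20, n_ab=120,
                           enriched_fraction=0.8, enrichment_radius=321.0, seed=1)
psd = segment_puncta(img, "marker")
ab = segment_puncta(img, "ab", use_watershed=True)
print(f"segmented {psd.n_objects} PSD objects and {ab.n_objects} amyloid puncta")
prof = enrichment_profile(psd, ab.centers_nm(), shell_width=64.2,
                          n_simulations=7, seed=2)
for lo, hi, r in zip(prof.shell_edges[:-1], prof.shell_edges[1:],
                     prof.normalized_density):
    print(f"  {lo:5.1f}-{hi:5.1f} nm  normalized density {r:.2f}")

trace = gen_traces("association", TraceTruth(tau=3.6, plateau=3.0, noise_sd=0.2),
                   n_points=60, dt=10, seed=3)
fit = fit_association(trace)
print(f"association fit: tau = {fit.tau:.2f} min, plateau = {fit.plateau:.2f}")
```

prints

```
segmented 20 PSD objects and 89 amyloid puncta
    0.0- 64.2 nm  normalized density 2.00
   64.2-128.4 nm  normalized density 4.20
  128.4-192.6 nm  normalized density 5.25
  192.6-256.8 nm  normalized density 5.03
  256.8-321.0 nm  normalized density 8.96
  321.0-385.2 nm  normalized density 0.00
  385.2-449.4 nm  normalized density 0.00
  449.4-513.6 nm  normalized density 0.19
  513.6-577.8 nm  normalized density 0.00
  577.8-642.0 nm  normalized density 0.00
association fit: tau = 3.50 min, plateau = 2.98
```

80% of the planted amyloid puncta were placed within 321 nm of a marker, and
the profile shows exactly that: densities well above 1 out to 321 nm and
essentially 0 beyond (detection merges some of the 120 planted puncta into
89 segmented objects). The noisy binding trace generated with τ = 3.6 min is
recovered at 3.50 min.

A thin CLI wraps the same functions, e.g.
`perisynmap simulate sim --seed 1 --out scene/` and
`perisynmap enrich --image scene/scene.tif --out profile.csv`.

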