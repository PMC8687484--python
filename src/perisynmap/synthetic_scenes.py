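"""Synthetic scenes with known ground truth for every pipeline stage.

Each generator emulates the statistical structure of one experimental data
type — volumetric two-channel puncta scenes with tunable perisynaptic
enrichment, 2D localization scenes with a dense PSD and planted nanoclusters,
two-channel bead fields under smooth distortion, drifting localization
streams, three-channel expansion-microscopy synapses, and exponential
binding/washout/FRAP traces — and returns both the data and a truth object
that an independent brute-force check can verify.

All randomness derives from a single user-supplied seed per call; the same
seed gives bit-identical output.  Puncta are rendered as isotropic-in-nm 3D
Gaussians truncated at 3 sigma; intensity noise is additive Gaussian and
localization noise is Gaussian jitter.

The enriched placement of ``gen_sim_scene`` uses the *same* candidate-voxel
sampler as the enrichment analysis' randomization null (uniform over voxels
within the enrichment radius of the marker footprint), which is what makes
the null-self-consistency property of the enrichment statistic exact by
construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .kinetics import IntensityTrace
from .sim_enrichment import DistanceField
from .volumetric_segmentation import VolumetricImage

__all__ = [
    "SceneTruth",
    "SmlmTruth",
    "TraceTruth",
    "gen_sim_scene",
    "gen_smlm_scene",
    "gen_bead_field",
    "gen_drift_series",
    "gen_exm_scene",
    "gen_traces",
    "write_scene",
]


@dataclass
class SceneTruth:
    """Ground truth for a volumetric puncta scene; positions are (z,y,x) nm."""

    marker_centers: np.ndarray
    ab_centers: np.ndarray
    enrichment_radius: float
    enriched_fraction: float
    seed: int
    n_enriched: int = 0
    marker_footprint_radius: float = 0.0
    # ExM extras
    pre_center: np.ndarray | None = None
    post_center: np.ndarray | None = None
    axial_offsets: np.ndarray | None = None
    radial_offsets: np.ndarray | None = None


@dataclass
class SmlmTruth:
    """Ground truth for 2D localization scenes."""

    psd_polygon: np.ndarray | None = None  # (V, 2) nm vertices
    cluster_memberships: np.ndarray | None = None  # per-loc id, -1 = background
    in_psd_fraction: float | None = None
    drift_trace: np.ndarray | None = None  # (n_frames, 2) nm
    distortion_field: dict | None = None
    true_positions: np.ndarray | None = None
    displacements: np.ndarray | None = None  # per-bead true channel shift


@dataclass
class TraceTruth:
    """Ground-truth kinetic parameters for generated intensity traces."""

    tau: float = 3.6  # minutes
    plateau: float = 3.0  # asymptotic F/F0 (association) or stable fraction (washout)
    mobile_fraction: float = 0.25
    rate: float = 0.15  # per minute (FRAP recovery)
    noise_sd: float = 0.0
    bleach_depth: float = 0.3  # post-bleach F/F0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not 0 <= self.mobile_fraction <= 1:
            raise ValueError("mobile_fraction must lie in [0, 1]")


def _render_blobs(
    shape: tuple[int, int, int],
    centers_nm: np.ndarray,
    sigma_nm: float,
    voxel_size_xy: float,
    voxel_size_z: float,
    amplitude: float,
) -> np.ndarray:
    """Sum of 3 sigma-truncated isotropic-in-nm Gaussians on a voxel grid."""
    out = np.zeros(shape, dtype=float)
    sizes = np.array([voxel_size_z, voxel_size_xy, voxel_size_xy])
    half = np.ceil(3 * sigma_nm / sizes).astype(int)
    for c in np.atleast_2d(centers_nm):
        idx = np.floor(c / sizes).astype(int)
        lo = np.maximum(idx - half, 0)
        hi = np.minimum(idx + half + 1, shape)
        if np.any(lo >= hi):
            continue
        zz, yy, xx = np.meshgrid(
            (np.arange(lo[0], hi[0]) + 0.5) * sizes[0] - c[0],
            (np.arange(lo[1], hi[1]) + 0.5) * sizes[1] - c[1],
            (np.arange(lo[2], hi[2]) + 0.5) * sizes[2] - c[2],
            indexing="ij",
        )
        d2 = zz**2 + yy**2 + xx**2
        blob = amplitude * np.exp(-0.5 * d2 / sigma_nm**2)
        blob[d2 > (3 * sigma_nm) ** 2] = 0.0
        out[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += blob
    return out


def _marker_distance_field(
    shape: tuple[int, int, int],
    marker_centers: np.ndarray,
    footprint_radius: float,
    voxel_size_xy: float,
    voxel_size_z: float,
) -> DistanceField:
    """Distance field (nm) from the marker footprint mask.

    The footprint is the set of voxels whose centres lie within
    ``footprint_radius`` nm of any marker centre — the rendered-blob core the
    segmentation stage recovers.
    """
    sizes = (voxel_size_z, voxel_size_xy, voxel_size_xy)
    seed_mask = np.zeros(shape, dtype=bool)
    idx = np.floor(np.atleast_2d(marker_centers) / np.array(sizes)).astype(int)
    idx = np.clip(idx, 0, np.array(shape) - 1)
    seed_mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    d_centers = ndimage.distance_transform_edt(~seed_mask, sampling=sizes)
    footprint = d_centers <= footprint_radius
    dist = ndimage.distance_transform_edt(~footprint, sampling=sizes)
    return DistanceField(dist, voxel_size_xy, voxel_size_z)


def _sample_candidate_voxels_global(
    fld: DistanceField, n: int, radius: float, rng: np.random.Generator
) -> np.ndarray:
    """Uniform without-replacement draw over all voxels with distance <= radius.

    Global analogue of the per-plane sampler used by the randomization null:
    conditioning this draw on its realized per-plane counts reproduces the
    null's per-plane uniform draw exactly.
    """
    flat = np.flatnonzero(fld.distances.ravel() <= radius)
    if flat.size < n:
        raise ValueError(
            f"only {flat.size} candidate voxels within {radius} nm for {n} puncta"
        )
    chosen = rng.choice(flat, size=n, replace=False)
    idx = np.column_stack(np.unravel_index(chosen, fld.shape)).astype(float)
    sizes = np.array([fld.voxel_size_z, fld.voxel_size_xy, fld.voxel_size_xy])
    return (idx + 0.5) * sizes


def gen_sim_scene(
    shape: tuple[int, int, int] = (8, 256, 256),
    voxel_size_xy: float = 32.1,
    voxel_size_z: float = 200.0,
    n_markers: int = 20,
    n_ab: int = 200,
    enriched_fraction: float = 0.0,
    enrichment_radius: float = 642.0,
    psf_sigma: float = 64.2,
    noise_sd: float = 1.0,
    amplitude: float = 10.0,
    seed: int = 0,
    marker_mask_mode: str = "segmented",
) -> tuple[VolumetricImage, SceneTruth]:
    """Two-channel 3D scene of marker and amyloid puncta.

    A fraction ``enriched_fraction`` of the ``n_ab`` amyloid puncta is placed
    uniformly at random over the voxels within ``enrichment_radius`` nm of
    the marker footprint (the enrichment analysis' null sampler); the rest is
    uniform over the whole volume.  Defaults match the SIM acquisition
    geometry: 32.1 nm XY pixels, 200 nm z-steps, 642 nm placement radius.
    """
    shape = tuple(int(s) for s in shape)
    if n_markers <= 0 or n_ab <= 0:
        raise ValueError("puncta counts must be positive")
    if voxel_size_xy <= 0 or voxel_size_z <= 0:
        raise ValueError("voxel sizes must be positive")
    if not 0 <= enriched_fraction <= 1:
        raise ValueError("enriched_fraction must lie in [0, 1]")
    extent = np.array(
        [shape[0] * voxel_size_z, shape[1] * voxel_size_xy, shape[2] * voxel_size_xy]
    )
    volume_nm3 = float(np.prod(extent))
    blob_vol = 4.0 / 3.0 * np.pi * (2 * psf_sigma) ** 3
    if (n_markers + n_ab) * blob_vol > 0.5 * volume_nm3:
        raise ValueError(
            "scene too small to hold the requested puncta without exceeding the "
            "packing limit (blob volume x count > half the scene volume)"
        )
    rng = np.random.default_rng(seed)
    margin = np.minimum(2 * psf_sigma, 0.25 * extent)
    marker_centers = rng.uniform(margin, extent - margin, size=(n_markers, 3))

    marker_ch = _render_blobs(
        shape, marker_centers, psf_sigma, voxel_size_xy, voxel_size_z, amplitude
    )
    if noise_sd > 0:
        marker_ch += rng.normal(0, noise_sd, shape)

    # Enriched placement uses the footprint the analysis itself recovers:
    # the marker channel is segmented with the same LoG + two-level-Otsu
    # chain, and candidates are voxels within the radius of that mask — the
    # identical distance field the randomization null will later use.
    footprint = 2 * psf_sigma
    if marker_mask_mode == "segmented":
        from .volumetric_segmentation import enhance_puncta, two_level_threshold

        tmp = VolumetricImage(
            marker_ch[None], voxel_size_xy, voxel_size_z, ["marker"]
        )
        enhanced = enhance_puncta(tmp, "marker")
        _, high = two_level_threshold(enhanced, "marker")
        footprint_mask = enhanced.channel("marker") >= high
        dist = ndimage.distance_transform_edt(
            ~footprint_mask,
            sampling=(voxel_size_z, voxel_size_xy, voxel_size_xy),
        )
        fld = DistanceField(dist, voxel_size_xy, voxel_size_z)
    elif marker_mask_mode == "sphere":
        fld = _marker_distance_field(
            shape, marker_centers, footprint, voxel_size_xy, voxel_size_z
        )
    else:
        raise ValueError("marker_mask_mode must be 'segmented' or 'sphere'")
    n_enriched = int(round(enriched_fraction * n_ab))
    parts = []
    if n_enriched:
        parts.append(
            _sample_candidate_voxels_global(fld, n_enriched, enrichment_radius, rng)
        )
    if n_ab - n_enriched:
        parts.append(
            _sample_candidate_voxels_global(fld, n_ab - n_enriched, np.inf, rng)
        )
    ab_centers = np.concatenate(parts, axis=0)

    ab_ch = _render_blobs(
        shape, ab_centers, psf_sigma, voxel_size_xy, voxel_size_z, amplitude
    )
    if noise_sd > 0:
        ab_ch += rng.normal(0, noise_sd, shape)
    image = VolumetricImage(
        np.stack([marker_ch, ab_ch]), voxel_size_xy, voxel_size_z, ["marker", "ab"]
    )
    truth = SceneTruth(
        marker_centers=marker_centers,
        ab_centers=ab_centers,
        enrichment_radius=enrichment_radius,
        enriched_fraction=enriched_fraction,
        seed=seed,
        n_enriched=n_enriched,
        marker_footprint_radius=footprint,
    )
    return image, truth


def _disk_polygon(center: np.ndarray, radius: float, n_vertices: int = 64) -> np.ndarray:
    ang = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    return center + radius * np.column_stack([np.cos(ang), np.sin(ang)])


def _loc_table(
    xy: np.ndarray, rng: np.random.Generator, loc_precision: float, channel: str
) -> pd.DataFrame:
    n = len(xy)
    return pd.DataFrame(
        {
            "frame": rng.integers(0, 20000, n),
            "x_nm": xy[:, 0],
            "y_nm": xy[:, 1],
            "sigma_nm": rng.uniform(120, 180, n),
            "uncertainty_nm": np.full(n, float(loc_precision)),
            "photons": rng.integers(500, 5000, n).astype(float),
            "channel": channel,
        }
    )


def gen_smlm_scene(
    field_nm: float = 2000.0,
    psd_radius: float = 150.0,
    n_background: int = 200,
    clusters: list[tuple[tuple[float, float], float, int]] = (),
    in_psd_target: float = 0.4,
    n_psd: int | None = None,
    loc_precision: float = 10.0,
    seed: int = 0,
    channel: str = "AF647",
) -> tuple[pd.DataFrame, SmlmTruth]:
    """2D localization scene: dense PSD disk + planted clusters + background.

    ``clusters`` is a list of ``((x, y), radius_nm, n)`` planted nanoclusters
    (points uniform in the disc).  The number of PSD-fill points is chosen so
    the realized in-PSD fraction approximates ``in_psd_target`` (or set
    ``n_psd`` explicitly).  All points receive Gaussian jitter of
    ``loc_precision``.  The truth records per-localization cluster
    memberships (-1 = background/PSD fill) and the realized in-PSD fraction.
    """
    from shapely.geometry import Point, Polygon

    if loc_precision <= 0:
        raise ValueError("loc_precision must be positive")
    rng = np.random.default_rng(seed)
    center = np.array([field_nm / 2, field_nm / 2])
    psd_vertices = _disk_polygon(center, psd_radius)
    psd_poly = Polygon(psd_vertices)

    cluster_pts = []
    cluster_ids = []
    n_cluster_in_psd = 0
    for cid, (c, radius, n) in enumerate(clusters):
        c = np.asarray(c, dtype=float)
        if radius <= 0:
            raise ValueError("cluster radii must be positive")
        if np.any(c < 0) or np.any(c > field_nm):
            raise ValueError(f"cluster {cid} centred outside the field")
        r = radius * np.sqrt(rng.uniform(0, 1, n))
        th = rng.uniform(0, 2 * np.pi, n)
        pts = c + np.column_stack([r * np.cos(th), r * np.sin(th)])
        cluster_pts.append(pts)
        cluster_ids.append(np.full(n, cid))
        if psd_poly.covers(Point(c)):
            n_cluster_in_psd += n
    n_cl = sum(len(p) for p in cluster_pts)

    if n_psd is None:
        # size the PSD fill so the expected realized fraction hits the target
        area_ratio = psd_poly.area / field_nm**2
        bg_in = n_background * area_ratio
        if in_psd_target >= 1.0:
            if n_background or n_cl - n_cluster_in_psd:
                raise ValueError("in_psd_target=1 requires no out-of-PSD points")
            n_psd = 500
        else:
            num = in_psd_target * (n_background + n_cl) - bg_in - n_cluster_in_psd
            n_psd = max(int(round(num / (1.0 - in_psd_target))), 0)

    r = psd_radius * np.sqrt(rng.uniform(0, 1, n_psd))
    th = rng.uniform(0, 2 * np.pi, n_psd)
    psd_pts = center + np.column_stack([r * np.cos(th), r * np.sin(th)])
    bg_pts = rng.uniform(0, field_nm, size=(n_background, 2))

    parts = [psd_pts, bg_pts] + cluster_pts
    ids = [np.full(n_psd, -1), np.full(n_background, -1)] + cluster_ids
    xy = np.concatenate(parts, axis=0)
    memberships = np.concatenate(ids).astype(int)
    xy = xy + rng.normal(0, loc_precision, xy.shape)

    inside = np.array([psd_poly.covers(Point(p)) for p in xy])
    realized = float(inside.mean()) if len(xy) else float("nan")
    table = _loc_table(xy, rng, loc_precision, channel)
    truth = SmlmTruth(
        psd_polygon=psd_vertices,
        cluster_memberships=memberships,
        in_psd_fraction=realized,
        true_positions=np.concatenate(parts, axis=0),
    )
    return table, truth


def _random_poly_displacement(
    degree: int, field_nm: float, amplitude: float, rng: np.random.Generator
):
    """Random smooth polynomial displacement with max magnitude == amplitude."""
    n_terms = (degree + 1) * (degree + 2) // 2
    coeffs = rng.normal(0, 1, size=(n_terms, 2))

    def raw(xy: np.ndarray) -> np.ndarray:
        u = (xy[:, 0] - field_nm / 2) / (field_nm / 2)
        v = (xy[:, 1] - field_nm / 2) / (field_nm / 2)
        cols = [u**i * v**j for i in range(degree + 1) for j in range(degree + 1 - i)]
        return np.column_stack(cols) @ coeffs

    g = np.linspace(0, field_nm, 41)
    gx, gy = np.meshgrid(g, g)
    grid = np.column_stack([gx.ravel(), gy.ravel()])
    max_mag = np.linalg.norm(raw(grid), axis=1).max()
    scale = 0.0 if max_mag == 0 else amplitude / max_mag

    def disp(xy: np.ndarray) -> np.ndarray:
        return scale * raw(xy)

    return disp, coeffs * scale


def gen_bead_field(
    n_beads: int = 200,
    field_nm: float = 25000.0,
    distortion_amplitude: float = 100.0,
    polynomial_degree: int = 2,
    noise_sd: float = 5.0,
    seed: int = 0,
    constant_shift: tuple[float, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, SmlmTruth]:
    """Two-channel fiducial bead field under smooth inter-channel distortion.

    Channel-2 bead positions equal channel-1 positions plus a smooth
    polynomial displacement whose maximum magnitude over the field equals
    ``distortion_amplitude`` (default up to 100 nm, the realistic raw
    inter-channel misalignment), plus per-channel Gaussian localization noise.
    ``constant_shift`` overrides the random polynomial with a pure
    translation.  Returns (reference table, moving table, truth).
    """
    if distortion_amplitude < 0:
        raise ValueError("distortion_amplitude must be >= 0")
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0, field_nm, size=(n_beads, 2))
    if constant_shift is not None:
        shift = np.asarray(constant_shift, dtype=float)
        disp = np.broadcast_to(shift, pos.shape).copy()
        coeffs = None
    else:
        disp_fn, coeffs = _random_poly_displacement(
            polynomial_degree, field_nm, distortion_amplitude, rng
        )
        disp = disp_fn(pos)
    ref = pos + (rng.normal(0, noise_sd, pos.shape) if noise_sd > 0 else 0.0)
    mov = pos + disp + (rng.normal(0, noise_sd, pos.shape) if noise_sd > 0 else 0.0)
    t_ref = _loc_table(ref, rng, max(noise_sd, 1e-3), "ref")
    t_mov = _loc_table(mov, rng, max(noise_sd, 1e-3), "moving")
    truth = SmlmTruth(
        true_positions=pos,
        displacements=disp,
        distortion_field={
            "degree": polynomial_degree,
            "amplitude": distortion_amplitude,
            "coeffs": None if coeffs is None else coeffs.tolist(),
        },
    )
    return t_ref, t_mov, truth


def gen_drift_series(
    n_frames: int = 2000,
    emitters: np.ndarray | None = None,
    drift_model: str = "linear",
    magnitude: float = 100.0,
    loc_precision: float = 10.0,
    seed: int = 0,
    field_nm: float = 2000.0,
    n_emitters: int = 40,
    direction: tuple[float, float] | None = None,
) -> tuple[pd.DataFrame, SmlmTruth]:
    """Localization stream of fixed emitters under linear or step drift.

    Every emitter is localized in every frame at its true position plus the
    frame's drift plus Gaussian jitter.  ``magnitude`` is the total drift
    displacement (nm) over the movie; the truth stores the per-frame drift
    trace, with the step model jumping at the midpoint frame.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(seed)
    if emitters is None:
        emitters = rng.uniform(0.2 * field_nm, 0.8 * field_nm, size=(n_emitters, 2))
    emitters = np.atleast_2d(np.asarray(emitters, dtype=float))
    if direction is None:
        th = rng.uniform(0, 2 * np.pi)
        u = np.array([np.cos(th), np.sin(th)])
    else:
        u = np.asarray(direction, dtype=float)
        u = u / np.linalg.norm(u)
    if drift_model == "linear":
        trace = np.outer(np.linspace(0, 1, n_frames), magnitude * u)
    elif drift_model == "step":
        trace = np.zeros((n_frames, 2))
        trace[n_frames // 2 :] = magnitude * u
    else:
        raise ValueError("drift_model must be 'linear' or 'step'")
    frames = np.repeat(np.arange(n_frames), len(emitters))
    base = np.tile(emitters, (n_frames, 1))
    xy = base + trace[frames]
    if loc_precision > 0:
        xy = xy + rng.normal(0, loc_precision, xy.shape)
    table = _loc_table(xy, rng, loc_precision, "AF647")
    table["frame"] = frames
    truth = SmlmTruth(drift_trace=trace, true_positions=emitters)
    return table, truth


def gen_exm_scene(
    pre_center: np.ndarray,
    post_center: np.ndarray,
    axial_offsets: np.ndarray,
    radial_offsets: np.ndarray,
    shape: tuple[int, int, int] = (16, 128, 128),
    voxel_size_xy: float = 65.0,
    voxel_size_z: float = 200.0,
    psf_sigma: float = 130.0,
    noise_sd: float = 0.5,
    amplitude: float = 10.0,
    seed: int = 0,
) -> tuple[VolumetricImage, SceneTruth]:
    """Three-channel ExM synapse with amyloid puncta at given (z, r) offsets.

    Channels are (pre marker, post marker, amyloid).  Each punctum is placed
    at axial offset z (positive toward the presynaptic centre) and radial
    offset r from the post->pre axis, at a seeded random azimuth.
    """
    pre_center = np.asarray(pre_center, dtype=float)
    post_center = np.asarray(post_center, dtype=float)
    axial_offsets = np.asarray(axial_offsets, dtype=float)
    radial_offsets = np.asarray(radial_offsets, dtype=float)
    if axial_offsets.shape != radial_offsets.shape:
        raise ValueError("axial and radial offsets must have the same length")
    axis = pre_center - post_center
    length = np.linalg.norm(axis)
    if length == 0:
        raise ValueError("pre and post centres must differ")
    u = axis / length
    origin = (pre_center + post_center) / 2.0
    # orthonormal basis perpendicular to the axis
    helper = np.array([1.0, 0.0, 0.0])
    if abs(u @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    w1 = np.cross(u, helper)
    w1 /= np.linalg.norm(w1)
    w2 = np.cross(u, w1)
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0, 2 * np.pi, len(axial_offsets))
    ab_centers = (
        origin[None, :]
        + axial_offsets[:, None] * u[None, :]
        + radial_offsets[:, None]
        * (np.cos(theta)[:, None] * w1[None, :] + np.sin(theta)[:, None] * w2[None, :])
    )
    extent = np.array(
        [shape[0] * voxel_size_z, shape[1] * voxel_size_xy, shape[2] * voxel_size_xy]
    )
    all_pts = np.vstack([ab_centers, pre_center[None], post_center[None]])
    if np.any(all_pts < 0) or np.any(all_pts > extent):
        raise ValueError("requested offset falls outside the image bounds")
    chans = [
        _render_blobs(shape, pre_center[None], psf_sigma, voxel_size_xy, voxel_size_z, amplitude),
        _render_blobs(shape, post_center[None], psf_sigma, voxel_size_xy, voxel_size_z, amplitude),
        _render_blobs(shape, ab_centers, psf_sigma, voxel_size_xy, voxel_size_z, amplitude),
    ]
    if noise_sd > 0:
        chans = [c + rng.normal(0, noise_sd, shape) for c in chans]
    image = VolumetricImage(
        np.stack(chans), voxel_size_xy, voxel_size_z, ["pre", "post", "ab"]
    )
    truth = SceneTruth(
        marker_centers=np.vstack([pre_center, post_center]),
        ab_centers=ab_centers,
        enrichment_radius=0.0,
        enriched_fraction=0.0,
        seed=seed,
        pre_center=pre_center,
        post_center=post_center,
        axial_offsets=axial_offsets,
        radial_offsets=radial_offsets,
    )
    return image, truth


def gen_traces(
    kind: str,
    truth: TraceTruth,
    n_points: int = 60,
    dt: float = 10.0,
    seed: int = 0,
    n_prebleach: int = 5,
) -> IntensityTrace:
    """Generate an exponential kinetic trace of the given kind.

    * ``association``: F/F0 = 1 + (plateau - 1)(1 - exp(-t/tau)), tau in
      minutes, starting from the pre-addition baseline of 1.
    * ``washout``: exponential decay from 1 toward the stable fraction
      ``plateau``: F = plateau + (1 - plateau) exp(-t/tau).
    * ``frap``: ``n_prebleach`` baseline points at 1, a bleach dip to
      ``bleach_depth``, then recovery toward
      ``F_b + mobile_fraction (1 - F_b)`` at ``rate`` per minute.

    Gaussian noise of ``truth.noise_sd`` is added throughout.
    """
    if n_points < 5:
        raise ValueError("need at least 5 points")
    rng = np.random.default_rng(seed)
    t = np.arange(n_points) * dt  # seconds
    t_min = t / 60.0
    if kind == "association":
        f = 1.0 + (truth.plateau - 1.0) * (1.0 - np.exp(-t_min / truth.tau))
    elif kind == "washout":
        f = truth.plateau + (1.0 - truth.plateau) * np.exp(-t_min / truth.tau)
    elif kind == "frap":
        f = np.ones(n_points)
        fb = truth.bleach_depth
        f_inf = fb + truth.mobile_fraction * (1.0 - fb)
        post = t_min[n_prebleach:] - t_min[n_prebleach]
        f[n_prebleach:] = fb + (f_inf - fb) * (1.0 - np.exp(-truth.rate * post))
    else:
        raise ValueError("kind must be association, washout or frap")
    if truth.noise_sd > 0:
        f = f + rng.normal(0, truth.noise_sd, n_points)
    return IntensityTrace(t, f, "roi", (0, 1) if kind != "frap" else (0, n_prebleach))


def write_scene(image: VolumetricImage, truth, out_dir: str | Path) -> None:
    """Write a scene as a multichannel TIFF plus a JSON truth sidecar."""
    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out_dir / "scene.tif", image.data.astype(np.float32))
    meta = {
        "voxel_size_xy": image.voxel_size_xy,
        "voxel_size_z": image.voxel_size_z,
        "channel_names": image.channel_names,
    }
    truth_dict = {}
    for k, v in asdict(truth).items():
        truth_dict[k] = v.tolist() if isinstance(v, np.ndarray) else v
    (out_dir / "truth.json").write_text(
        json.dumps({"image": meta, "truth": truth_dict}, indent=1)
    )
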