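"""Trans-synaptic axis mapping for expansion-microscopy volumes.

Pairs presynaptic and postsynaptic marker objects into synapses, maps
amyloid-beta puncta into a cylindrical coordinate frame whose longitudinal
axis runs from the postsynaptic to the presynaptic centre of mass (origin at
the midpoint), and histograms axial positions.  Positive axial coordinates
are presynaptic, negative postsynaptic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volumetric_segmentation import ObjectLabelMap

__all__ = [
    "SynapsePair",
    "AxialPosition",
    "pair_synapses",
    "map_to_axis",
    "axial_histogram",
]


@dataclass
class SynapsePair:
    """A matched pre/post synaptic object pair defining the synaptic axis."""

    pre_center: np.ndarray  # (z, y, x) nm
    post_center: np.ndarray

    def __post_init__(self) -> None:
        self.pre_center = np.asarray(self.pre_center, dtype=float)
        self.post_center = np.asarray(self.post_center, dtype=float)

    @property
    def axis_vector(self) -> np.ndarray:
        """Post -> pre vector (nm)."""
        return self.pre_center - self.post_center

    @property
    def axis_length(self) -> float:
        return float(np.linalg.norm(self.axis_vector))

    @property
    def origin(self) -> np.ndarray:
        return (self.pre_center + self.post_center) / 2.0


@dataclass
class AxialPosition:
    """Cylindrical coordinates of one punctum relative to a synapse pair."""

    z: float  # nm along the axis; positive = presynaptic
    r: float  # nm radial distance from the axis
    punctum_id: int


def _object_radius_nm(labelmap: ObjectLabelMap) -> float:
    """Mean equivalent-sphere radius of the labeled objects (nm)."""
    if labelmap.n_objects == 0:
        return 0.0
    voxel_vol = labelmap.voxel_size_xy**2 * labelmap.voxel_size_z
    vols = labelmap.objects["voxel_count"].to_numpy() * voxel_vol
    return float(np.mean((3 * vols / (4 * np.pi)) ** (1 / 3)))


def pair_synapses(
    pre: ObjectLabelMap,
    post: ObjectLabelMap,
    ab: ObjectLabelMap,
    xy_window: float = 20.0,
    z_window: float = 3.0,
    min_separation_nm: float | None = None,
) -> list[SynapsePair]:
    """Pair pre/post objects into synapses with nearby amyloid puncta.

    Candidate pairs are mutually nearest pre/post objects.  A pair is
    retained only if (1) both objects exist, (2) at least one amyloid punctum
    centre lies within ``xy_window`` pixels in both X and Y and ``z_window``
    pixels in Z (per-axis Chebyshev windows, converted to nm with the image
    voxel sizes) of the pair midpoint, and (3) the centre separation is at
    least ``min_separation_nm``, which defaults to twice the mean
    equivalent-sphere radius of the marker objects — an automatic stand-in
    for manual selection of synapses with well-separated pre/post signal.
    """
    if pre.n_objects == 0 or post.n_objects == 0:
        return []
    pre_centers = pre.centers_nm()
    post_centers = post.centers_nm()
    ab_centers = ab.centers_nm() if ab.n_objects else np.empty((0, 3))
    if min_separation_nm is None:
        min_separation_nm = 2.0 * np.mean(
            [_object_radius_nm(pre), _object_radius_nm(post)]
        )
    win_nm = np.array(
        [
            z_window * pre.voxel_size_z,
            xy_window * pre.voxel_size_xy,
            xy_window * pre.voxel_size_xy,
        ]
    )
    d = np.linalg.norm(pre_centers[:, None, :] - post_centers[None, :, :], axis=2)
    nearest_post = d.argmin(axis=1)
    nearest_pre = d.argmin(axis=0)
    pairs = []
    for i, j in enumerate(nearest_post):
        if nearest_pre[j] != i:
            continue  # not mutual
        pair = SynapsePair(pre_centers[i], post_centers[j])
        if pair.axis_length < min_separation_nm or pair.axis_length == 0:
            continue
        if len(ab_centers) == 0:
            continue
        offsets = np.abs(ab_centers - pair.origin)
        if not np.any(np.all(offsets <= win_nm, axis=1)):
            continue
        pairs.append(pair)
    return pairs


def map_to_axis(pair: SynapsePair, puncta: np.ndarray) -> list[AxialPosition]:
    """Project puncta into the pair's cylindrical frame.

    For punctum p: ``z = (p - origin) . u`` with u the post->pre unit vector
    (positive toward the presynaptic side), and ``r`` the distance from p to
    the axis line.
    """
    if pair.axis_length == 0:
        raise ValueError("degenerate synapse pair: coincident pre/post centres")
    puncta = np.atleast_2d(np.asarray(puncta, dtype=float))
    u = pair.axis_vector / pair.axis_length
    rel = puncta - pair.origin
    z = rel @ u
    r = np.linalg.norm(rel - z[:, None] * u[None, :], axis=1)
    return [AxialPosition(float(zi), float(ri), i) for i, (zi, ri) in enumerate(zip(z, r))]


def axial_histogram(
    positions: list[AxialPosition], bin_width: float, r_max: float
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram axial positions in half-open bins centred on zero.

    Only puncta with ``r <= r_max`` are counted.  Returns ``(counts, edges)``
    where bins are ``[edge_i, edge_{i+1})`` and one bin is centred on z = 0.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    kept = [p.z for p in positions if p.r <= r_max]
    if not kept:
        return np.zeros(1, dtype=int), np.array([-bin_width / 2, bin_width / 2])
    z = np.asarray(kept)
    k_max = int(np.floor((np.abs(z).max() + bin_width / 2) / bin_width)) + 1
    edges = np.arange(-k_max, k_max + 1) * bin_width - bin_width / 2
    idx = np.floor((z + bin_width / 2) / bin_width).astype(int) + k_max
    counts = np.bincount(idx, minlength=2 * k_max)
    return counts, edges
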