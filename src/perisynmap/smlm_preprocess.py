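"""SMLM localization-table preprocessing.

Quality filtering, bead-based two-channel registration and segment-wise
redundant cross-correlation drift correction for single-molecule localization
data.  The pipeline starts at localization tables (raw-frame PSF fitting is
upstream); tables are plain pandas DataFrames with the canonical columns

    frame, x_nm, y_nm, sigma_nm, uncertainty_nm, photons, channel

ThunderSTORM-style headers ("x [nm]", "uncertainty [nm]", "sigma [nm]",
"intensity [photon]") are accepted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_COLUMNS",
    "ChannelCalibration",
    "DriftTrace",
    "read_localizations",
    "write_localizations",
    "filter_localizations",
    "fit_channel_calibration",
    "apply_calibration",
    "drift_correct",
]

CANONICAL_COLUMNS = [
    "frame",
    "x_nm",
    "y_nm",
    "sigma_nm",
    "uncertainty_nm",
    "photons",
    "channel",
]

# ThunderSTORM and other common dialects -> canonical names
_ALIASES = {
    "frame": "frame",
    "x [nm]": "x_nm",
    "y [nm]": "y_nm",
    "x": "x_nm",
    "y": "y_nm",
    "x_nm": "x_nm",
    "y_nm": "y_nm",
    "sigma [nm]": "sigma_nm",
    "sigma": "sigma_nm",
    "sigma_nm": "sigma_nm",
    "uncertainty [nm]": "uncertainty_nm",
    "uncertainty_xy [nm]": "uncertainty_nm",
    "uncertainty": "uncertainty_nm",
    "uncertainty_nm": "uncertainty_nm",
    "intensity [photon]": "photons",
    "photons": "photons",
    "channel": "channel",
    "id": "id",
}

_MANDATORY = ["frame", "x_nm", "y_nm"]


def read_localizations(path: str | Path) -> pd.DataFrame:
    """Read a localization CSV, normalizing header dialects.

    Requires at least frame, x and y columns (in any accepted dialect);
    raises with the found-vs-required header lists otherwise.
    """
    df = pd.read_csv(path)
    rename = {c: _ALIASES[c.strip()] for c in df.columns if c.strip() in _ALIASES}
    df = df.rename(columns=rename)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise ValueError(
            f"missing mandatory columns {missing}; found {list(df.columns)}, "
            f"required at least {_MANDATORY}"
        )
    for c in ("x_nm", "y_nm", "sigma_nm", "uncertainty_nm", "photons"):
        if c in df.columns:
            df[c] = df[c].astype(float)
    return df


def write_localizations(table: pd.DataFrame, path: str | Path) -> None:
    """Write a localization table as CSV with canonical headers.

    Floats are written with full round-trip precision so write -> read is an
    identity on the records.
    """
    cols = [c for c in CANONICAL_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    table[cols].to_csv(path, index=False, float_format="%.17g")


def filter_localizations(
    table: pd.DataFrame,
    uncertainty_max: float = 20.0,
    sigma_range: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Quality-filter localizations, preserving record order.

    Keeps records with ``uncertainty < uncertainty_max`` (default 20 nm) and,
    when ``sigma_range`` is given, with sigma inside the channel's closed
    range — e.g. ``{"CF568": (100, 200), "AF647": (90, 190)}``.  Every channel
    present in the table must appear in the map.
    """
    keep = pd.Series(True, index=table.index)
    if "uncertainty_nm" in table.columns:
        keep &= table["uncertainty_nm"] < uncertainty_max
    if sigma_range is not None:
        for lo, hi in sigma_range.values():
            if not lo < hi:
                raise ValueError("sigma_range bounds must satisfy lo < hi")
        channels = set(table["channel"].unique()) if "channel" in table.columns else set()
        unknown = channels - set(sigma_range)
        if unknown:
            raise ValueError(
                f"channels {sorted(unknown)} present in table but missing from "
                f"sigma_range map {sorted(sigma_range)}"
            )
        for ch, (lo, hi) in sigma_range.items():
            in_ch = table["channel"] == ch
            keep &= ~in_ch | (table["sigma_nm"].between(lo, hi))
    return table[keep].copy()


def _poly_terms(xy: np.ndarray, degree: int, center: np.ndarray, scale: float) -> np.ndarray:
    """Bivariate monomial design matrix on centred/scaled coordinates."""
    u = (xy[:, 0] - center[0]) / scale
    v = (xy[:, 1] - center[1]) / scale
    cols = [u**i * v**j for i in range(degree + 1) for j in range(degree + 1 - i)]
    return np.column_stack(cols)


@dataclass
class ChannelCalibration:
    """Smooth per-axis displacement model between two imaging channels.

    The model maps a moving-channel position (x, y) in nm to the displacement
    (dx, dy) that aligns it with the reference channel.  ``polynomial`` mode
    stores least-squares bivariate polynomial coefficients; the
    ``locally_weighted`` mode stores the control points and averages their
    displacements with a Gaussian kernel.
    """

    model_kind: str
    degree: int | None = None
    bandwidth: float | None = None
    coeffs: np.ndarray | None = None  # (n_terms, 2) for polynomial mode
    center: np.ndarray | None = None
    scale: float = 1.0
    control_points: np.ndarray | None = None
    control_disp: np.ndarray | None = None
    control_rms: float = 0.0

    @property
    def n_control_points(self) -> int:
        return 0 if self.control_points is None else len(self.control_points)

    def predict(self, xy: np.ndarray) -> np.ndarray:
        """Displacement (N, 2) nm at the given moving-channel positions."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        if self.model_kind == "polynomial":
            design = _poly_terms(xy, self.degree, self.center, self.scale)
            return design @ self.coeffs
        # locally weighted Gaussian-kernel mean of control displacements
        d2 = ((xy[:, None, :] - self.control_points[None, :, :]) ** 2).sum(axis=2)
        w = np.exp(-0.5 * d2 / self.bandwidth**2)
        w_sum = w.sum(axis=1, keepdims=True)
        w_sum[w_sum == 0] = 1.0
        return (w @ self.control_disp) / w_sum


def fit_channel_calibration(
    ref_points: np.ndarray,
    moving_points: np.ndarray,
    model_kind: str = "polynomial",
    degree: int = 2,
    bandwidth: float | None = None,
) -> ChannelCalibration:
    """Fit the inter-channel displacement field from matched bead positions.

    ``ref_points`` and ``moving_points`` are matched (N, 2) nm position lists
    from the two channels; the fitted displacement is ``ref - moving`` as a
    function of the moving position.
    """
    ref = np.atleast_2d(np.asarray(ref_points, dtype=float))
    mov = np.atleast_2d(np.asarray(moving_points, dtype=float))
    if ref.shape != mov.shape:
        raise ValueError("matched point lists must have the same shape")
    disp = ref - mov
    if model_kind == "polynomial":
        n_terms = (degree + 1) * (degree + 2) // 2
        if len(mov) < n_terms:
            raise ValueError(
                f"under-determined fit: degree-{degree} polynomial needs at least "
                f"{n_terms} matched pairs, got {len(mov)}"
            )
        center = mov.mean(axis=0)
        scale = max(float(np.abs(mov - center).max()), 1.0)
        design = _poly_terms(mov, degree, center, scale)
        coeffs, *_ = np.linalg.lstsq(design, disp, rcond=None)
        cal = ChannelCalibration(
            model_kind="polynomial",
            degree=degree,
            coeffs=coeffs,
            center=center,
            scale=scale,
            control_points=mov,
            control_disp=disp,
        )
    elif model_kind == "locally_weighted":
        if bandwidth is None or bandwidth <= 0:
            raise ValueError("locally_weighted mode requires a positive bandwidth (nm)")
        cal = ChannelCalibration(
            model_kind="locally_weighted",
            bandwidth=bandwidth,
            control_points=mov,
            control_disp=disp,
        )
    else:
        raise ValueError("model_kind must be 'polynomial' or 'locally_weighted'")
    resid = disp - cal.predict(mov)
    cal.control_rms = float(np.sqrt((resid**2).sum(axis=1).mean()))
    return cal


def apply_calibration(table: pd.DataFrame, calibration: ChannelCalibration) -> pd.DataFrame:
    """Shift moving-channel coordinates by the modeled displacement."""
    out = table.copy()
    xy = out[["x_nm", "y_nm"]].to_numpy(dtype=float)
    disp = calibration.predict(xy)
    out["x_nm"] = xy[:, 0] + disp[:, 0]
    out["y_nm"] = xy[:, 1] + disp[:, 1]
    return out


@dataclass
class DriftTrace:
    """Per-segment and interpolated per-frame drift displacements (nm)."""

    segment_edges: np.ndarray  # frame index starting each segment, + end
    segment_centers: np.ndarray  # representative frame per segment
    segment_displacement: np.ndarray  # (n_segments, 2) dx, dy nm
    frame_displacement: np.ndarray = field(default=None)  # (n_frames, 2)

    def at_frames(self, frames: np.ndarray) -> np.ndarray:
        frames = np.asarray(frames)
        out = np.empty((len(frames), 2))
        for ax in range(2):
            out[:, ax] = np.interp(
                frames, self.segment_centers, self.segment_displacement[:, ax]
            )
        return out


def _histogram_segment(
    xy: np.ndarray, extent: tuple[float, float, float, float], bin_size: float
) -> np.ndarray:
    x0, x1, y0, y1 = extent
    bins_x = np.arange(x0, x1 + bin_size, bin_size)
    bins_y = np.arange(y0, y1 + bin_size, bin_size)
    h, _, _ = np.histogram2d(xy[:, 0], xy[:, 1], bins=(bins_x, bins_y))
    return h


def _xcorr_offset(h1: np.ndarray, h2: np.ndarray, bin_size: float) -> np.ndarray:
    """Offset (dx, dy) nm of h2 relative to h1 by FFT cross-correlation.

    The peak is refined to sub-bin precision with the intensity centroid of
    its 3x3 neighbourhood.
    """
    from scipy.signal import fftconvolve

    corr = fftconvolve(h2, h1[::-1, ::-1], mode="full")
    peak = np.unravel_index(np.argmax(corr), corr.shape)
    # 3x3 centroid around the peak (clipped at edges)
    r0, r1 = max(peak[0] - 1, 0), min(peak[0] + 2, corr.shape[0])
    c0, c1 = max(peak[1] - 1, 0), min(peak[1] + 2, corr.shape[1])
    patch = corr[r0:r1, c0:c1]
    patch = patch - patch.min()
    total = patch.sum()
    if total > 0:
        rr, cc = np.mgrid[r0:r1, c0:c1]
        pr = (patch * rr).sum() / total
        pc = (patch * cc).sum() / total
    else:
        pr, pc = peak
    shift_bins = np.array([pr - (h1.shape[0] - 1), pc - (h1.shape[1] - 1)])
    return shift_bins * bin_size


def drift_correct(
    table: pd.DataFrame,
    segment_len: int = 500,
    bin_size: float = 10.0,
    error_threshold: float = 5.0,
    pixel_size: float = 100.0,
) -> tuple[pd.DataFrame, DriftTrace]:
    """Redundant cross-correlation drift correction.

    Frames are split into segments of ``segment_len`` (default 500); each
    segment is rendered as a 2D histogram at ``bin_size`` nm (default 10);
    every segment pair's relative offset is estimated from the
    cross-correlation peak (sub-bin by 3x3 centroid); the per-segment drift is
    the least-squares solution of the redundant pairwise offsets, with one
    rejection pass discarding pairs whose residual exceeds
    ``error_threshold * pixel_size`` nm (default 5 camera pixels of 100 nm);
    drift is interpolated per frame and subtracted, with the first segment
    defining zero.
    """
    frames = table["frame"].to_numpy()
    f_min, f_max = int(frames.min()), int(frames.max())
    n_frames = f_max - f_min + 1
    n_seg = n_frames // segment_len
    if n_seg < 2:
        raise ValueError(
            f"need at least 2 segments of {segment_len} frames; movie spans "
            f"{n_frames} frames"
        )
    edges = f_min + np.arange(n_seg + 1) * segment_len
    edges[-1] = f_max + 1  # trailing frames join the last segment

    xy = table[["x_nm", "y_nm"]].to_numpy(dtype=float)
    pad = 2 * bin_size
    extent = (
        xy[:, 0].min() - pad,
        xy[:, 0].max() + pad,
        xy[:, 1].min() - pad,
        xy[:, 1].max() + pad,
    )
    hists = []
    for s in range(n_seg):
        sel = (frames >= edges[s]) & (frames < edges[s + 1])
        hists.append(_histogram_segment(xy[sel], extent, bin_size))

    pairs = [(i, j) for i in range(n_seg) for j in range(i + 1, n_seg)]
    measured = np.array([_xcorr_offset(hists[i], hists[j], bin_size) for i, j in pairs])

    def solve(active: np.ndarray) -> np.ndarray:
        # unknowns: drift of segments 1..n-1 (segment 0 fixed at zero)
        a = np.zeros((active.sum(), n_seg - 1))
        for row, (i, j) in enumerate(np.array(pairs)[active]):
            if i > 0:
                a[row, i - 1] = -1.0
            a[row, j - 1] = 1.0
        sol = np.zeros((n_seg, 2))
        for ax in range(2):
            sol[1:, ax], *_ = np.linalg.lstsq(a, measured[active, ax], rcond=None)
        return sol

    active = np.ones(len(pairs), dtype=bool)
    drift = solve(active)
    # single rejection/recalculation pass
    resid = np.array(
        [
            np.hypot(*(drift[j] - drift[i] - measured[k]))
            for k, (i, j) in enumerate(pairs)
        ]
    )
    bad = resid > error_threshold * pixel_size
    if bad.any():
        active &= ~bad
        if not active.any():
            raise ValueError(
                "all pairwise drift measurements rejected; residuals (nm): "
                f"{np.round(resid, 1).tolist()}"
            )
        drift = solve(active)

    centers = (edges[:-1] + edges[1:] - 1) / 2.0
    trace = DriftTrace(
        segment_edges=edges,
        segment_centers=centers,
        segment_displacement=drift,
    )
    frame_axis = np.arange(f_min, f_max + 1)
    trace.frame_displacement = trace.at_frames(frame_axis)
    per_loc = trace.at_frames(frames)
    out = table.copy()
    out["x_nm"] = xy[:, 0] - per_loc[:, 0]
    out["y_nm"] = xy[:, 1] - per_loc[:, 1]
    return out, trace
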