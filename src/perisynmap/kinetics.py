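"""Binding, washout and FRAP kinetics from fluorescence time series.

Compartmental intensity traces (synaptic vs extrasynaptic, split by a PSD
mask inside a cell-fill mask), single-exponential association fits of F/F0
versus time, washout signal-loss quantification with an optional
photobleaching control, FRAP mobile fraction and recovery rate, and
window-averaged F/F0 summaries.

Association model (baseline fixed at the pre-addition normalization
F/F0 = 1):

    F(t) = 1 + (plateau - 1) * (1 - exp(-t / tau)),   tau in minutes.

FRAP model (post-bleach, normalized to the pre-bleach mean, bleach depth
F_b fixed at the first post-bleach value):

    F(t) = F_b + (F_inf - F_b) * (1 - exp(-k * t)),
    mobile_fraction = (F_inf - F_b) / (1 - F_b),   k in 1/min.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "IntensityTrace",
    "ExpFitResult",
    "FrapFitResult",
    "compartment_traces",
    "fit_association",
    "quantify_washout",
    "fit_frap",
    "window_mean",
]


@dataclass
class IntensityTrace:
    """A background-subtracted (or normalized) intensity time course."""

    time: np.ndarray  # seconds, strictly increasing
    value: np.ndarray
    compartment: str = "roi"
    normalization_frame_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.time.shape != self.value.shape:
            raise ValueError("time and value must have the same length")
        if len(self.time) > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")

    def normalized(self, frame_range: tuple[int, int] | None = None) -> "IntensityTrace":
        """Normalize to the mean over ``frame_range`` (default: stored range,
        else the first frame).  Idempotent when re-applied with the same
        range."""
        if frame_range is None:
            frame_range = self.normalization_frame_range or (0, 1)
        lo, hi = frame_range
        baseline = self.value[lo:hi].mean()
        if baseline == 0:
            raise ValueError("zero baseline; cannot normalize")
        return IntensityTrace(
            self.time, self.value / baseline, self.compartment, frame_range
        )


@dataclass
class ExpFitResult:
    """Single-exponential association fit of F/F0 vs time."""

    plateau: float
    tau: float  # minutes
    sse: float
    converged: bool
    message: str = ""


@dataclass
class FrapFitResult:
    """FRAP recovery fit."""

    mobile_fraction: float
    rate: float  # 1/min; recovery time constant is 1/rate
    bleach_depth: float  # post-bleach F/F0
    converged: bool
    message: str = ""

    @property
    def recovery_tau_min(self) -> float:
        return np.inf if self.rate == 0 else 1.0 / self.rate


def compartment_traces(
    movie: np.ndarray,
    psd_mask: np.ndarray,
    cell_mask: np.ndarray,
    background_mask: np.ndarray,
    time: np.ndarray,
) -> tuple[IntensityTrace, IntensityTrace]:
    """Synaptic and extrasynaptic integrated-density traces from a movie.

    ``movie`` has shape (T, ...) with frames matching the mask shapes.  Per
    frame the integrated density of a compartment is the sum of
    (pixel - mean background) over its mask: the synaptic compartment is the
    PSD mask; the extrasynaptic compartment is the cell-fill mask minus the
    PSD mask, so the two are disjoint by construction.
    """
    movie = np.asarray(movie, dtype=float)
    psd = np.asarray(psd_mask, dtype=bool)
    cell = np.asarray(cell_mask, dtype=bool)
    bg = np.asarray(background_mask, dtype=bool)
    for name, m in [("psd_mask", psd), ("cell_mask", cell), ("background_mask", bg)]:
        if not m.any():
            raise ValueError(f"{name} is empty")
    extrasyn = cell & ~psd
    syn_vals = np.empty(len(movie))
    ext_vals = np.empty(len(movie))
    for t, frame in enumerate(movie):
        b = frame[bg].mean()
        syn_vals[t] = (frame[psd] - b).sum()
        ext_vals[t] = (frame[extrasyn] - b).sum()
    return (
        IntensityTrace(time, syn_vals, "synaptic"),
        IntensityTrace(time, ext_vals, "extrasynaptic"),
    )


def _association_model(t_min: np.ndarray, plateau: float, tau: float) -> np.ndarray:
    return 1.0 + (plateau - 1.0) * (1.0 - np.exp(-t_min / tau))


def fit_association(trace: IntensityTrace) -> ExpFitResult:
    """Fit F(t) = 1 + (plateau - 1)(1 - exp(-t/tau)) to a normalized trace.

    Time is converted from seconds to minutes; tau is reported in minutes.
    A flat trace (amplitude indistinguishable from the residual noise) is
    reported as not converged rather than returning an arbitrary tau.
    """
    if len(trace.time) < 5:
        raise ValueError("need at least 5 points for an association fit")
    t_min = trace.time / 60.0
    y = trace.value
    amp0 = y[-1] - 1.0
    tau0 = max(t_min[-1] / 3.0, 1e-3)
    try:
        popt, _ = curve_fit(
            _association_model,
            t_min,
            y,
            p0=[1.0 + amp0, tau0],
            bounds=([-np.inf, 1e-6], [np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        return ExpFitResult(np.nan, np.nan, np.nan, False, str(exc))
    plateau, tau = popt
    resid = y - _association_model(t_min, *popt)
    sse = float((resid**2).sum())
    noise_sd = float(resid.std())
    if abs(plateau - 1.0) <= max(2.0 * noise_sd, 1e-9):
        return ExpFitResult(
            float(plateau), float(tau), sse, False,
            "amplitude indistinguishable from noise; tau unidentifiable",
        )
    return ExpFitResult(float(plateau), float(tau), sse, True)


def quantify_washout(
    trace: IntensityTrace,
    washout_time: float,
    horizon: float,
    photobleach_control: float = 0.0,
) -> float:
    """Percent signal loss over ``horizon`` seconds after ``washout_time``.

    loss = 100 * (1 - F(washout_time + horizon) / F(washout_time)), minus the
    photobleaching control loss (percent) when provided.  Values between
    sample times are linearly interpolated.  Scale-invariant in the raw
    trace.
    """
    t_end = washout_time + horizon
    if t_end > trace.time[-1] or washout_time < trace.time[0]:
        raise ValueError("washout window extends beyond the trace")
    f0 = float(np.interp(washout_time, trace.time, trace.value))
    f1 = float(np.interp(t_end, trace.time, trace.value))
    if f0 <= 0:
        raise ValueError("signal at washout time is non-positive")
    return 100.0 * (1.0 - f1 / f0) - photobleach_control


def fit_frap(trace: IntensityTrace, bleach_frame: int) -> FrapFitResult:
    """Fit post-bleach recovery and report mobile fraction and rate.

    The trace is normalized to the pre-bleach mean;
    F(t) = F_b + (F_inf - F_b)(1 - exp(-k t)) is fitted over the post-bleach
    points with t measured from the bleach, the bleach depth F_b entering as
    a fitted parameter initialized at the first post-bleach sample.
    ``mobile_fraction = (F_inf - F_b) / (1 - F_b)`` is clipped to [0, 1] with
    a warning when the fit falls outside.
    """
    if bleach_frame < 3:
        raise ValueError("need at least 3 pre-bleach points")
    if len(trace.time) - bleach_frame < 5:
        raise ValueError("need at least 5 post-bleach points")
    pre = trace.value[:bleach_frame].mean()
    if pre <= 0:
        raise ValueError("non-positive pre-bleach level")
    y = trace.value / pre
    fb = y[bleach_frame]
    if fb >= 1.0:
        raise ValueError(
            f"no bleach detected: first post-bleach level {fb:.3f} >= pre-bleach 1.0"
        )
    t = (trace.time[bleach_frame:] - trace.time[bleach_frame]) / 60.0  # minutes
    yy = y[bleach_frame:]

    def model(tt, f_b, f_inf, k):
        return f_b + (f_inf - f_b) * (1.0 - np.exp(-k * tt))

    amp0 = yy[-1] - fb
    if abs(amp0) <= 1e-12 and np.allclose(yy, fb):
        return FrapFitResult(0.0, np.nan, float(fb), True, "no recovery")
    try:
        popt, _ = curve_fit(
            model, t, yy, p0=[fb, fb + max(amp0, 1e-3), 0.1],
            bounds=([-np.inf, -np.inf, 1e-8], [1.0, np.inf, np.inf]), maxfev=10000,
        )
    except RuntimeError as exc:
        return FrapFitResult(np.nan, np.nan, float(fb), False, str(exc))
    fb, f_inf, k = popt
    mobile = (f_inf - fb) / (1.0 - fb)
    if mobile < 0 or mobile > 1:
        warnings.warn(f"mobile fraction {mobile:.3f} outside [0, 1]; clipping")
        mobile = float(np.clip(mobile, 0.0, 1.0))
    return FrapFitResult(float(mobile), float(k), float(fb), True)


def window_mean(trace: IntensityTrace, window: tuple[float, float]) -> float:
    """Arithmetic mean of the trace values in a closed time window (s)."""
    lo, hi = window
    if lo > hi:
        raise ValueError("window must satisfy lo <= hi")
    sel = (trace.time >= lo) & (trace.time <= hi)
    if not sel.any():
        raise ValueError("window contains no trace samples")
    return float(trace.value[sel].mean())
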