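"""Signal conditioning for traces and movies.

The conditioning chain mirrors standard practice for bioluminescence
recordings of the segmentation clock: cosmic-ray spike removal (rolling
median/MAD outlier rule), per-pixel temporal background reduction (rolling
low-percentile subtraction), subtractive moving-average detrending, and
Savitzky-Golay smoothing, applied in that order before phase reconstruction.
Defaults: a 36-frame detrending window for whole-well PMT traces, a 30-frame
window for imaging, and a 41-frame Savitzky-Golay window (order 2).

All operations are length- and time-grid-preserving.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .io import MovieStack, TimeSeries

__all__ = [
    "DetrendParams",
    "SGParams",
    "SpikeEvent",
    "spike_filter",
    "temporal_background_reduce",
    "moving_average_detrend",
    "savitzky_golay",
    "preprocess_pmt",
    "preprocess_movie",
]

#: MAD -> Gaussian-sigma consistency factor
_MAD_SCALE = 1.4826


@dataclass
class DetrendParams:
    """Moving-average detrending window. 36 frames for PMT, 30 for imaging."""

    window_frames: int = 36
    mode: str = "pmt"

    def __post_init__(self) -> None:
        if self.window_frames < 3:
            raise ValueError("window_frames must be >= 3")
        if self.mode not in ("pmt", "imaging"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @classmethod
    def pmt(cls) -> "DetrendParams":
        return cls(window_frames=36, mode="pmt")

    @classmethod
    def imaging(cls) -> "DetrendParams":
        return cls(window_frames=30, mode="imaging")


@dataclass
class SGParams:
    """Savitzky-Golay smoothing window (odd) and polynomial order."""

    window_frames: int = 41
    polyorder: int = 2

    def __post_init__(self) -> None:
        if self.window_frames % 2 == 0:
            raise ValueError("window_frames must be odd")
        if self.window_frames < self.polyorder + 2:
            raise ValueError("window_frames must be >= polyorder + 2")


@dataclass
class SpikeEvent:
    """One sample flagged and replaced by the spike filter."""

    index: tuple[int, ...]
    original: float
    replacement: float


def _loo_median(arr: np.ndarray, half_window: int) -> np.ndarray:
    """Leave-one-out rolling median along axis 0 (edges: edge-replicated).

    Excluding the center sample keeps the residual ``x - median`` free of the
    self-selection artifact (a center-inclusive median returns the sample
    itself ~20% of the time, which skews the residual/MAD ratio and floods
    the spike detector with false positives). Edges are reflect-padded for
    the same reason.
    """
    pad = [(half_window, half_window)] + [(0, 0)] * (arr.ndim - 1)
    # reflect (not edge-replicate): the center sample must not leak into its
    # own neighbor median, or edge residuals collapse to ~0 and drag the
    # rolling MAD down with them
    padded = np.pad(arr, pad, mode="reflect")
    n = arr.shape[0]
    offsets = [o for o in range(2 * half_window + 1) if o != half_window]
    stack = np.stack([padded[o:o + n] for o in offsets], axis=0)
    return np.median(stack, axis=0)


def _rolling_median_mad(arr: np.ndarray, half_window: int,
                        mad_half_window: int) -> tuple[np.ndarray, np.ndarray]:
    """Rolling neighbor median and residual MAD along axis 0.

    The median uses the short leave-one-out window; the MAD of the median
    residual uses the longer window — a short-window MAD is too noisy a scale
    estimate for outlier detection.
    """
    med = _loo_median(arr, half_window)
    mad_size = (2 * mad_half_window + 1,) + (1,) * (arr.ndim - 1)
    # reflect, not nearest: replicating one noisy edge residual across half
    # the window deflates the edge MAD and causes edge false positives
    mad = ndimage.median_filter(np.abs(arr - med), size=mad_size, mode="reflect")
    return med, mad


def spike_filter(x: TimeSeries | MovieStack, half_window: int = 2,
                 k: float = 5.0, eps: float = 1e-9,
                 mad_half_window: int | None = None):
    """Remove cosmic-ray spikes by a rolling-median/MAD outlier rule.

    A sample is a spike iff ``|x - rolling_median| > k * (MAD*1.4826 + eps)``,
    where the rolling median spans ``2*half_window + 1`` frames and the MAD of
    the median residual spans ``2*mad_half_window + 1`` frames (default
    ``max(10*half_window, 25)``; the wider scale window keeps the noise
    estimate stable). Spikes are replaced by the rolling median; non-spike
    samples pass through unchanged. A spike of magnitude <= eps inside an
    all-constant window is, by construction, not flagged.

    Returns ``(cleaned, report)`` where ``cleaned`` has the input's type and
    ``report`` is a list of :class:`SpikeEvent` (time-major indices).
    """
    if half_window < 1:
        raise ValueError("half_window must be >= 1")
    if k <= 0:
        raise ValueError("k must be positive")
    if mad_half_window is None:
        mad_half_window = max(10 * half_window, 25)
    arr = x.value[:, None] if isinstance(x, TimeSeries) else x.frames
    med, mad = _rolling_median_mad(arr, half_window, mad_half_window)
    is_spike = np.abs(arr - med) > k * (mad * _MAD_SCALE + eps)
    # the reflected neighbor median is biased at the recording ends (signal
    # curvature enters the residual there); leave edge samples untouched
    is_spike[:half_window] = False
    is_spike[arr.shape[0] - half_window:] = False
    cleaned = np.where(is_spike, med, arr)
    report = []
    for idx in np.argwhere(is_spike):
        key = tuple(int(v) for v in idx)
        if isinstance(x, TimeSeries):
            key = (key[0],)
        report.append(SpikeEvent(index=key,
                                 original=float(arr[tuple(idx)]),
                                 replacement=float(med[tuple(idx)])))
    if isinstance(x, TimeSeries):
        return x.with_values(cleaned[:, 0]), report
    return MovieStack(cleaned, interval_min=x.interval_min, pixel_um=x.pixel_um,
                      t0_min=x.t0_min, signed=x.signed), report


def temporal_background_reduce(movie: MovieStack, window_frames: int = 30,
                               percentile: float = 10.0) -> MovieStack:
    """Subtract each pixel's rolling low-percentile background.

    Per pixel, a rolling ``percentile``-th percentile over a centered
    ``window_frames`` window is subtracted from the pixel's own trace;
    negative results are clipped to zero. A window longer than the recording
    falls back to the whole-trace percentile (with a warning).
    """
    if window_frames < 3:
        raise ValueError("window_frames must be >= 3")
    t = movie.frames.shape[0]
    if window_frames > t:
        warnings.warn(f"background window ({window_frames}) exceeds movie length "
                      f"({t}); using whole-trace percentile", stacklevel=2)
        bg = np.percentile(movie.frames, percentile, axis=0, keepdims=True)
    else:
        bg = ndimage.percentile_filter(movie.frames, percentile,
                                       size=(window_frames, 1, 1), mode="nearest")
    out = np.clip(movie.frames - bg, 0.0, None)
    return MovieStack(out, interval_min=movie.interval_min,
                      pixel_um=movie.pixel_um, t0_min=movie.t0_min)


def _centered_moving_mean(arr: np.ndarray, window: int) -> np.ndarray:
    """Centered moving mean along axis 0 with symmetrically shrinking edges.

    Interior samples use a symmetric window of half-width ``window // 2``
    (an even nominal window is widened to the next odd count). Toward the
    edges the window shrinks symmetrically, never below 3 points (the two
    outermost samples use the 3 nearest points, one-sided).
    """
    n = arr.shape[0]
    half = max(1, window // 2)
    idx = np.arange(n)
    hl = np.minimum(half, np.minimum(idx, n - 1 - idx))
    lo = idx - hl
    hi = idx + hl + 1
    # enforce >= 3 points inside bounds
    short = (hi - lo) < 3
    lo = np.where(short, np.clip(idx - 1, 0, n - 3), lo)
    hi = np.where(short, lo + 3, hi)
    csum = np.concatenate([np.zeros((1,) + arr.shape[1:]),
                           np.cumsum(arr, axis=0)], axis=0)
    counts = (hi - lo).reshape((-1,) + (1,) * (arr.ndim - 1))
    return (csum[hi] - csum[lo]) / counts


def moving_average_detrend(x: TimeSeries | MovieStack,
                           params: DetrendParams | None = None):
    """Subtract a centered moving average (baseline) from each trace/pixel.

    The output is ``input - centered moving mean``; a constant input maps to
    zeros and a linear ramp to zeros wherever the full symmetric window fits.
    """
    if params is None:
        params = DetrendParams.pmt() if isinstance(x, TimeSeries) else DetrendParams.imaging()
    arr = x.value[:, None] if isinstance(x, TimeSeries) else x.frames
    if arr.shape[0] < 3:
        raise ValueError("series shorter than 3 samples cannot be detrended")
    if arr.shape[0] < params.window_frames:
        raise ValueError(f"series length {arr.shape[0]} shorter than detrend "
                         f"window {params.window_frames}")
    out = arr - _centered_moving_mean(arr, params.window_frames)
    if isinstance(x, TimeSeries):
        return x.with_values(out[:, 0])
    return MovieStack(out, interval_min=x.interval_min, pixel_um=x.pixel_um,
                      t0_min=x.t0_min, signed=True)


def savitzky_golay(x: TimeSeries | MovieStack, params: SGParams | None = None):
    """Savitzky-Golay least-squares polynomial smoothing along time.

    Polynomials of degree <= ``polyorder`` pass through unchanged on interior
    points; edges are handled by polynomial fits to the boundary window
    (no reflected data).
    """
    if params is None:
        params = SGParams()
    arr = x.value[:, None] if isinstance(x, TimeSeries) else x.frames
    if arr.shape[0] < params.window_frames:
        raise ValueError(f"series length {arr.shape[0]} shorter than SG window "
                         f"{params.window_frames}")
    out = signal.savgol_filter(arr, params.window_frames, params.polyorder,
                               axis=0, mode="interp")
    if isinstance(x, TimeSeries):
        return x.with_values(out[:, 0])
    return MovieStack(out, interval_min=x.interval_min, pixel_um=x.pixel_um,
                      t0_min=x.t0_min, signed=x.signed or bool(out.min() < 0))


def preprocess_pmt(ts: TimeSeries, detrend: DetrendParams | None = None,
                   sg: SGParams | None = None, spike_k: float = 5.0,
                   spike_half_window: int = 2,
                   apply_sg: bool = False) -> TimeSeries:
    """Whole-well PMT conditioning chain: spike filter -> 36-frame detrend.

    Savitzky-Golay smoothing is optional for PMT traces (off by default);
    imaging uses :func:`preprocess_movie` instead.
    """
    cleaned, _ = spike_filter(ts, half_window=spike_half_window, k=spike_k)
    out = moving_average_detrend(cleaned, detrend or DetrendParams.pmt())
    if apply_sg:
        out = savitzky_golay(out, sg or SGParams())
    return out


def preprocess_movie(movie: MovieStack, detrend: DetrendParams | None = None,
                     sg: SGParams | None = None, spike_k: float = 5.0,
                     spike_half_window: int = 2, bg_window: int = 30,
                     bg_percentile: float = 10.0,
                     background_reduce: bool = True) -> MovieStack:
    """Imaging chain: spike filter -> background reduction -> 30-frame
    detrend -> 41-frame Savitzky-Golay smoothing."""
    cleaned, _ = spike_filter(movie, half_window=spike_half_window, k=spike_k)
    if background_reduce:
        cleaned = temporal_background_reduce(cleaned, window_frames=bg_window,
                                             percentile=bg_percentile)
    out = moving_average_detrend(cleaned, detrend or DetrendParams.imaging())
    return savitzky_golay(out, sg or SGParams())
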