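"""Single-trace oscillation quantification.

Phase is reconstructed from the detrended trace via the discrete analytic
signal (Hilbert transform), with the cosine convention: phase 0 at signal
maxima. Peaks are then the crossings of the unwrapped phase through integer
multiples of 2*pi, refined by linear interpolation, and peak-to-peak
intervals give the period distribution. Pulse amplitude is the mean of the
three highest peaks of the detrended signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .io import TimeSeries
from .synth import wrap_phase

__all__ = [
    "PhaseTrace",
    "PeakList",
    "PeriodHistogram",
    "Amplitude",
    "OscillationCall",
    "hilbert_phase",
    "detect_peaks",
    "period_stats",
    "amplitude_top3",
    "classify_oscillatory",
]


@dataclass
class PhaseTrace:
    """Instantaneous phase of one trace.

    ``phase_wrapped`` lies in (-pi, pi] with 0 at signal maxima;
    ``phase_unwrapped`` is its continuous lift; ``quality`` is the analytic
    signal amplitude (the oscillation envelope), usable as a per-sample
    confidence weight.
    """

    time_min: np.ndarray
    phase_wrapped: np.ndarray
    phase_unwrapped: np.ndarray
    quality: np.ndarray
    label: str = ""

    @property
    def interval_min(self) -> float:
        return float(np.median(np.diff(self.time_min)))


@dataclass
class PeakList:
    """Oscillation pulses of one trace."""

    peak_times_min: np.ndarray
    peak_heights: np.ndarray

    def __post_init__(self) -> None:
        self.peak_times_min = np.asarray(self.peak_times_min, dtype=float)
        self.peak_heights = np.asarray(self.peak_heights, dtype=float)
        if np.any(np.diff(self.peak_times_min) <= 0):
            raise ValueError("peak times must be strictly increasing")

    @property
    def n_pulses(self) -> int:
        return int(self.peak_times_min.size)


@dataclass
class PeriodHistogram:
    """Histogram of peak-to-peak intervals, plus raw-interval statistics."""

    bin_edges_min: np.ndarray
    counts: np.ndarray
    intervals_min: np.ndarray
    mean_period_min: float
    sem_min: float

    def fraction_in(self, lo_min: float, hi_min: float) -> float:
        """Fraction of raw intervals in [lo, hi) minutes."""
        iv = self.intervals_min
        return float(np.mean((iv >= lo_min) & (iv < hi_min)))


@dataclass
class Amplitude:
    """Mean of the three highest pulses; flagged when fewer than 3 exist."""

    value_cps: float
    n_used: int
    low_confidence: bool


@dataclass
class OscillationCall:
    oscillatory: bool
    score: float


def hilbert_phase(x: TimeSeries, zero_mean_check: bool = True,
                  label: str | None = None) -> PhaseTrace:
    """Instantaneous phase via the discrete analytic signal.

    The input must already be detrended (it should oscillate about zero);
    with ``zero_mean_check`` a residual mean above 0.25 standard deviations
    is a hard error. For a cosine-like oscillation the unwrapped phase
    increases at 2*pi/period per minute, with phase 0 at each maximum.
    A constant-zero input yields all-NaN phase with quality 0.
    """
    v = x.value
    if v.size < 8:
        raise ValueError("need at least 8 samples for phase reconstruction")
    sd = float(np.std(v))
    if sd == 0.0:
        nan = np.full(v.size, np.nan)
        return PhaseTrace(x.time_min.copy(), nan, nan.copy(),
                          np.zeros(v.size), label=label or x.label)
    if zero_mean_check and abs(float(np.mean(v))) > 0.25 * sd:
        raise ValueError("input has a large residual mean: detrend first")
    # mirror-extend both ends before the FFT-based transform: the analytic
    # signal of a finite segment is distorted at the boundaries, which shifts
    # phase crossings near the start/end of the recording
    n_pad = min(v.size // 2, 64)
    left = v[n_pad:0:-1]
    right = v[-2:-n_pad - 2:-1]
    analytic = hilbert(np.concatenate([left, v, right]))[n_pad:n_pad + v.size]
    wrapped = np.angle(analytic)
    unwrapped = np.unwrap(wrapped)
    return PhaseTrace(x.time_min.copy(), wrap_phase(wrapped), unwrapped,
                      np.abs(analytic), label=label or x.label)


def detect_peaks(x: TimeSeries, ph: PhaseTrace,
                 min_period_min: float = 60.0,
                 edge_margin_min: float = 45.0,
                 min_quality_frac: float = 0.5) -> PeakList:
    """Phase-referenced peak detection.

    One pulse per upward crossing of the unwrapped phase through 2*pi*k
    (k integer; phase 0 = signal maximum). The crossing time is refined by
    linear interpolation between samples; the pulse height is the detrended
    value at the nearest sample. Crossings closer than ``min_period_min`` to
    the previous accepted pulse are rejected as double counts; crossings
    within ``edge_margin_min`` of either end of the recording are discarded
    (the discrete analytic signal is distorted at the boundaries); and
    crossings where the analytic amplitude falls below ``min_quality_frac``
    of its trace median are discarded — noise-driven phase slips happen
    exactly where the oscillation envelope collapses.
    """
    if x.value.size != ph.phase_unwrapped.size:
        raise ValueError("trace and phase are not on the same grid")
    phi = ph.phase_unwrapped
    if not np.all(np.isfinite(phi)):
        return PeakList(np.empty(0), np.empty(0))
    t = x.time_min
    two_pi = 2 * np.pi
    k_lo = int(np.ceil(phi.min() / two_pi))
    k_hi = int(np.floor(phi.max() / two_pi))
    crossings: list[tuple[float, float]] = []
    for k in range(k_lo, k_hi + 1):
        level = two_pi * k
        below = phi[:-1] < level
        above = phi[1:] >= level
        for i in np.nonzero(below & above)[0]:
            frac = (level - phi[i]) / (phi[i + 1] - phi[i])
            tc = t[i] + frac * (t[i + 1] - t[i])
            nearest = i if frac < 0.5 else i + 1
            crossings.append((float(tc), float(x.value[nearest])))
        # a sample exactly at the level with no prior below-crossing (k_lo edge)
        if k == k_lo and phi[0] == level:
            crossings.append((float(t[0]), float(x.value[0])))
    crossings.sort()
    lo, hi = t[0] + edge_margin_min, t[-1] - edge_margin_min
    q_floor = min_quality_frac * float(np.median(ph.quality))
    times, heights = [], []
    for tc, h in crossings:
        if not (lo <= tc <= hi):
            continue
        if float(np.interp(tc, t, ph.quality)) < q_floor:
            continue
        if times and tc - times[-1] < min_period_min:
            continue
        times.append(tc)
        heights.append(h)
    return PeakList(np.asarray(times), np.asarray(heights))


def period_stats(peaks: PeakList, bin_width_min: float = 10.0,
                 min_edge_min: float = 140.0,
                 max_edge_min: float = 210.0) -> PeriodHistogram:
    """Peak-to-peak interval statistics and histogram.

    Intervals are successive peak-time differences. Bins are
    ``bin_width_min`` wide with edges aligned to multiples of the width and
    spanning at least [min_edge, max_edge] (140-210 min by default, the
    physiological period range of the mouse segmentation clock); the mean and
    its standard error are computed on the raw intervals, not the binned
    counts.
    """
    if peaks.n_pulses < 2:
        raise ValueError("insufficient pulses: need >= 2 peaks for intervals")
    iv = np.diff(peaks.peak_times_min)
    lo = min(min_edge_min, np.floor(iv.min() / bin_width_min) * bin_width_min)
    hi = max(max_edge_min, np.ceil(iv.max() / bin_width_min) * bin_width_min)
    if hi <= iv.max():  # right edge must include the largest interval
        hi += bin_width_min
    edges = np.arange(lo, hi + bin_width_min / 2, bin_width_min)
    counts, _ = np.histogram(iv, bins=edges)
    sem = float(np.std(iv, ddof=1) / np.sqrt(iv.size)) if iv.size > 1 else 0.0
    return PeriodHistogram(bin_edges_min=edges, counts=counts, intervals_min=iv,
                           mean_period_min=float(np.mean(iv)), sem_min=sem)


def amplitude_top3(x: TimeSeries, peaks: PeakList) -> Amplitude:
    """Mean amplitude of the three highest pulses of the detrended trace.

    With fewer than three pulses the mean of what exists is returned with a
    low-confidence flag; with none, amplitude 0 (flagged).
    """
    h = np.sort(peaks.peak_heights)[::-1]
    if h.size == 0:
        return Amplitude(0.0, 0, True)
    top = h[:3]
    return Amplitude(float(np.mean(top)), int(top.size), top.size < 3)


def classify_oscillatory(x: TimeSeries, peaks: PeakList,
                         noise_floor_cps: float) -> OscillationCall:
    """Call a trace oscillatory.

    Rule: at least two pulses and a top-3 pulse amplitude exceeding three
    times the noise floor. The score is amplitude / noise floor.
    """
    if noise_floor_cps <= 0:
        raise ValueError("noise_floor_cps must be positive")
    amp = amplitude_top3(x, peaks)
    score = amp.value_cps / noise_floor_cps
    return OscillationCall(oscillatory=bool(peaks.n_pulses >= 2 and score > 3.0),
                           score=float(score))
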