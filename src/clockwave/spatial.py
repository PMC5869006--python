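"""Movie-level analysis: ROI traces, kymographs, phase maps, wave metrics.

Traveling waves in an oscillation focus appear as tilted crest stripes in a
kymograph sampled along a radial line; their slope is the wave speed. The
per-pixel imaging chain (spike filter -> temporal background reduction ->
30-frame moving-average detrend -> 41-frame Savitzky-Golay -> Hilbert)
produces a phase movie from which the oscillation center (earliest-phase
locus), center-periphery phase lags and the Kuramoto synchronization index
are computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import hilbert

from .io import MovieStack, TimeSeries
from .oscillation import PhaseTrace
from .preprocess import DetrendParams, SGParams, preprocess_movie, _centered_moving_mean
from .synth import wrap_phase

__all__ = [
    "ROI",
    "Kymograph",
    "PhaseMovie",
    "WaveSpeed",
    "roi_trace",
    "compute_kymograph",
    "phase_movie",
    "phase_lag",
    "locate_center",
    "wave_speed",
    "sync_index",
]


@dataclass
class ROI:
    """A rectangular or polyline region of interest (pixel coordinates).

    Rectangles use half-open bounds ``(y0, x0, y1, x1)``; polylines are
    ordered ``(y, x)`` vertices with a perpendicular averaging width.
    """

    kind: str
    rect: tuple[int, int, int, int] | None = None
    polyline: np.ndarray | None = None
    line_width_px: int = 5

    def __post_init__(self) -> None:
        if self.kind == "rect":
            if self.rect is None:
                raise ValueError("rect ROI needs bounds")
            y0, x0, y1, x1 = self.rect
            if y1 <= y0 or x1 <= x0:
                raise ValueError("rect ROI is empty")
        elif self.kind == "polyline":
            self.polyline = np.asarray(self.polyline, dtype=float)
            if self.polyline is None or self.polyline.ndim != 2 or len(self.polyline) < 2:
                raise ValueError("polyline ROI needs >= 2 (y, x) vertices")
            if self.line_width_px < 1:
                raise ValueError("line_width_px must be >= 1")
        else:
            raise ValueError(f"unknown ROI kind {self.kind!r}")

    @classmethod
    def make_rect(cls, y0: int, x0: int, y1: int, x1: int) -> "ROI":
        return cls(kind="rect", rect=(y0, x0, y1, x1))

    @classmethod
    def make_polyline(cls, vertices, line_width_px: int = 5) -> "ROI":
        return cls(kind="polyline", polyline=np.asarray(vertices, float),
                   line_width_px=line_width_px)


@dataclass
class Kymograph:
    """Space x time intensity matrix sampled along a polyline.

    Rows are arc-length samples (``arc_um``), columns are frames in temporal
    order, left to right (``time_min``).
    """

    matrix: np.ndarray
    arc_um: np.ndarray
    time_min: np.ndarray

    def __post_init__(self) -> None:
        if self.matrix.shape != (self.arc_um.size, self.time_min.size):
            raise ValueError("kymograph matrix shape does not match coordinates")
        if np.any(np.diff(self.time_min) <= 0):
            raise ValueError("columns must be in increasing time order")


@dataclass
class PhaseMovie:
    """Per-pixel wrapped phase with an analysis mask.

    ``phase`` is NaN outside ``mask``; ``quality`` is the per-pixel mean
    analytic-signal amplitude (oscillation envelope).
    """

    phase: np.ndarray          # T x H x W, wrapped radians
    mask: np.ndarray           # H x W bool
    quality: np.ndarray        # H x W
    time_min: np.ndarray

    def trace(self, y: int, x: int, label: str = "") -> PhaseTrace:
        """Phase trace of one masked pixel."""
        if not self.mask[y, x]:
            raise ValueError(f"pixel ({y}, {x}) is outside the analysis mask")
        wrapped = self.phase[:, y, x]
        return PhaseTrace(self.time_min.copy(), wrapped, np.unwrap(wrapped),
                          np.full(wrapped.size, self.quality[y, x]),
                          label=label or f"px({y},{x})")


@dataclass
class WaveSpeed:
    """Crest-slope wave-speed estimate from a kymograph."""

    speed_um_per_min: float
    residual_rms_um: float
    n_crests: int
    finite: bool = True


def roi_trace(movie: MovieStack, roi: ROI, label: str | None = None) -> TimeSeries:
    """Mean intensity inside a rectangular ROI, per frame."""
    if roi.kind != "rect":
        raise ValueError("roi_trace needs a rect ROI")
    y0, x0, y1, x1 = roi.rect
    t, h, w = movie.frames.shape
    if y0 < 0 or x0 < 0 or y1 > h or x1 > w:
        raise ValueError(f"rect {roi.rect} outside {h}x{w} frame")
    vals = movie.frames[:, y0:y1, x0:x1].mean(axis=(1, 2))
    return TimeSeries(movie.time_min, vals,
                      label=label or f"rect[{y0}:{y1},{x0}:{x1}]")


def _sample_polyline(vertices: np.ndarray, step_px: float = 1.0
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Equidistant samples along a polyline: positions, tangents, arc (px)."""
    seg = np.diff(vertices, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    total = float(seg_len.sum())
    if total <= 0:
        raise ValueError("degenerate (zero-length) polyline")
    arc = np.arange(0, total + step_px / 2, step_px)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    pos = np.empty((arc.size, 2))
    tan = np.empty((arc.size, 2))
    for i, a in enumerate(arc):
        j = min(int(np.searchsorted(cum, a, side="right")) - 1, len(seg) - 1)
        frac = (a - cum[j]) / seg_len[j] if seg_len[j] > 0 else 0.0
        pos[i] = vertices[j] + frac * seg[j]
        tan[i] = seg[j] / seg_len[j]
    return pos, tan, arc


def compute_kymograph(movie: MovieStack, roi: ROI) -> Kymograph:
    """Sample a movie along a polyline into a space x time matrix.

    The polyline is sampled at one-pixel arc spacing with bilinear
    interpolation, averaging over ``line_width_px`` parallel offsets along
    the local normal; columns are frames left to right in temporal order.
    """
    if roi.kind != "polyline":
        raise ValueError("compute_kymograph needs a polyline ROI")
    pos, tan, arc_px = _sample_polyline(roi.polyline)
    normal = np.stack([-tan[:, 1], tan[:, 0]], axis=1)
    w = roi.line_width_px
    offsets = np.arange(w) - (w - 1) / 2.0
    # coords: (2, S, W)
    coords = pos.T[:, :, None] + normal.T[:, :, None] * offsets[None, None, :]
    t_frames = movie.frames.shape[0]
    mat = np.empty((arc_px.size, t_frames))
    for ti in range(t_frames):
        samp = ndimage.map_coordinates(movie.frames[ti], coords.reshape(2, -1),
                                       order=1, mode="nearest")
        mat[:, ti] = samp.reshape(arc_px.size, w).mean(axis=1)
    return Kymograph(matrix=mat, arc_um=arc_px * movie.pixel_um,
                     time_min=movie.time_min)


def phase_movie(movie: MovieStack, detrend: DetrendParams | None = None,
                sg: SGParams | None = None,
                intensity_threshold: float | None = None,
                **preprocess_kwargs) -> PhaseMovie:
    """Per-pixel phase map through the full imaging chain.

    Pixels whose temporal-mean raw intensity falls below
    ``intensity_threshold`` are masked out; the default threshold sits 5%
    of the dynamic range above the dimmest pixel mean, which separates
    background from colony for typical baseline-dominated movies.
    """
    mean_img = movie.frames.mean(axis=0)
    if intensity_threshold is None:
        lo, hi = float(mean_img.min()), float(mean_img.max())
        intensity_threshold = lo + 0.05 * (hi - lo)
    mask = mean_img >= intensity_threshold
    if not mask.any():
        raise ValueError("no signal above threshold: every pixel masked")
    processed = preprocess_movie(movie, detrend=detrend or DetrendParams.imaging(),
                                 sg=sg or SGParams(), **preprocess_kwargs)
    t = movie.frames.shape[0]
    flat = processed.frames.reshape(t, -1)[:, mask.ravel()]
    analytic = hilbert(flat, axis=0)
    phase = np.full((t,) + mask.shape, np.nan)
    phase.reshape(t, -1)[:, mask.ravel()] = np.angle(analytic)
    quality = np.zeros(mask.shape)
    quality.ravel()[mask.ravel()] = np.abs(analytic).mean(axis=0)
    return PhaseMovie(phase=phase, mask=mask, quality=quality,
                      time_min=movie.time_min)


def _circular_mean(angles: np.ndarray, axis=None) -> np.ndarray:
    return np.angle(np.exp(1j * np.asarray(angles)).mean(axis=axis))


def phase_lag(a: PhaseTrace, b: PhaseTrace,
              window: slice | None = None) -> dict:
    """Circular-mean phase lag of trace ``a`` relative to ``b``.

    Positive lag means ``a`` leads ``b``. The minute conversion uses the mean
    of the two traces' recovered periods (from the unwrapped-phase slope) and
    is therefore estimate-dependent.
    """
    if a.time_min.size != b.time_min.size or not np.allclose(a.time_min, b.time_min):
        raise ValueError("phase traces are not on the same grid")
    sl = window if window is not None else slice(None)
    da = a.phase_wrapped[sl]
    db = b.phase_wrapped[sl]
    good = np.isfinite(da) & np.isfinite(db)
    if not good.any():
        raise ValueError("window contains no valid phase samples")
    lag_rad = float(_circular_mean(wrap_phase(da[good] - db[good])))

    def _period(ph: PhaseTrace) -> float:
        phi = ph.phase_unwrapped[sl]
        t = ph.time_min[sl]
        slope = (phi[-1] - phi[0]) / (t[-1] - t[0])
        return 2 * np.pi / slope if slope > 0 else np.nan

    p_hat = float(np.nanmean([_period(a), _period(b)]))
    return {"radians": lag_rad, "minutes": lag_rad * p_hat / (2 * np.pi),
            "period_estimate_min": p_hat}


def locate_center(pm: PhaseMovie, mask: np.ndarray | None = None
                  ) -> tuple[int, int, float]:
    """Locate the oscillation center as the earliest-phase (max-lead) pixel.

    The time-averaged circular phase offset of every masked pixel relative
    to the brightest (highest-quality) pixel is computed, then spatially
    unwrapped so that center-to-periphery lags larger than pi do not alias;
    the pixel with the maximal lead over the population mean is the wave
    source. Returns ``(y, x, lead_rad)``. With spatially uniform phase the
    lead is ~0 and the location is arbitrary (documented degeneracy). Pass
    ``mask`` to restrict the search, e.g. to one connected component of a
    multi-focus colony.
    """
    from skimage.restoration import unwrap_phase as _unwrap2d

    m = pm.mask if mask is None else (pm.mask & mask)
    if not m.any():
        raise ValueError("empty mask")
    t = pm.phase.shape[0]
    flat = pm.phase.reshape(t, -1)[:, m.ravel()]
    qual = pm.quality.ravel()[m.ravel()]
    ref = flat[:, int(np.argmax(qual))]
    offs = _circular_mean(wrap_phase(flat - ref[:, None]), axis=0)
    field = np.zeros(m.shape)
    field[m] = offs
    lead_field = _unwrap2d(np.ma.array(field, mask=~m))
    lead_field = lead_field - lead_field.mean()
    idx = int(np.ma.argmax(lead_field))
    y, x = np.unravel_index(idx, m.shape)
    return int(y), int(x), float(lead_field[y, x])


def wave_speed(k: Kymograph, period_hint_min: float | None = None,
               detrend_window: int = 36) -> WaveSpeed:
    """Wave speed from crest slopes in a kymograph.

    Each row's time trace is detrended and Hilbert-transformed; rows are
    phase-aligned across space and each crest (an unwrapped-phase level
    2*pi*k) contributes its crossing time per row. Pooled within-crest least
    squares of arc position on crossing time gives the crest slope
    ``d(arc)/dt``, i.e. the outward speed in µm/min, with its residual RMS.
    A standing (spatially uniform) oscillation has no within-crest time
    spread and is reported as non-finite speed.
    """
    arr = k.matrix.T  # time x space
    t = k.time_min
    n_t, n_s = arr.shape
    win = min(detrend_window, max(3, n_t // 2))
    det = arr - _centered_moving_mean(arr, win)
    phi = np.unwrap(np.angle(hilbert(det, axis=0)), axis=0)
    # align arbitrary 2*pi row offsets at the mid frame
    mid = n_t // 2
    ref = np.unwrap(phi[mid])
    phi = phi + 2 * np.pi * np.round((ref - phi[mid]) / (2 * np.pi))

    two_pi = 2 * np.pi
    k_lo = int(np.ceil(phi.min() / two_pi)) + 1
    k_hi = int(np.floor(phi.max() / two_pi)) - 1
    n_crests = 0
    sxy = sxx = 0.0
    groups = []
    for kk in range(k_lo, k_hi + 1):
        level = two_pi * kk
        t_cross, s_pos = [], []
        for s in range(n_s):
            col = phi[:, s]
            idx = np.nonzero((col[:-1] < level) & (col[1:] >= level))[0]
            if idx.size == 0:
                continue
            i = int(idx[0])
            frac = (level - col[i]) / (col[i + 1] - col[i])
            t_cross.append(t[i] + frac * (t[i + 1] - t[i]))
            s_pos.append(k.arc_um[s])
        if len(t_cross) >= 3:
            n_crests += 1
            tc = np.asarray(t_cross) - np.mean(t_cross)
            sc = np.asarray(s_pos) - np.mean(s_pos)
            sxy += float(np.dot(sc, tc))
            sxx += float(np.dot(tc, tc))
            groups.append((tc, sc))
    if n_crests < 2:
        raise ValueError("no crest stripes found in kymograph")
    dt = float(np.median(np.diff(t)))
    n_pts = sum(g[0].size for g in groups)
    # standing oscillation: crossing times barely vary along the line
    if sxx < n_pts * (dt / 2) ** 2:
        return WaveSpeed(np.inf, np.nan, n_crests, finite=False)
    v = sxy / sxx
    resid = np.concatenate([sc - v * tc for tc, sc in groups])
    return WaveSpeed(float(v), float(np.sqrt(np.mean(resid ** 2))),
                     n_crests, finite=True)


def sync_index(phases: list[PhaseTrace], window: slice | None = None
               ) -> tuple[np.ndarray, float]:
    """Kuramoto order parameter across phase traces.

    ``R(t) = |mean_j exp(i*phi_j(t))|`` is 1 for perfect in-phase synchrony
    and ~0 for incoherent phases. Returns the per-frame R over the window
    and its time average. Invariant under a global phase shift.
    """
    if len(phases) < 2:
        raise ValueError("need at least 2 phase traces")
    sl = window if window is not None else slice(None)
    mat = np.stack([p.phase_wrapped[sl] for p in phases])
    r_t = np.abs(np.exp(1j * mat).mean(axis=0))
    return r_t, float(np.mean(r_t))
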