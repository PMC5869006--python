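"""Synthetic iPSM colony generator.

Ground truth for every analysis stage comes from two generative models:

* a kinematic traveling-wave phase field — one oscillation focus whose phase
  at radius ``r`` (µm) and time ``t`` (min) is ``2*pi*t/P - 2*pi*r/(P*v)``,
  so crests sweep outward from the focus center at speed ``v`` with the
  periphery lagging the center by exactly ``2*pi*r/(P*v)`` radians; and
* a delayed-negative-feedback oscillator cell (delayed autorepression of
  transcription with Hill kinetics and linear decay), the canonical model of
  the Hes/Her segmentation-clock mechanism.

The phase field is rendered to a noisy luminescence movie
(baseline + drift + envelope*(1+cos(phase))/2, optional Poisson photon noise,
optional single-pixel cosmic-ray spikes) and integrated to PMT-style
counts-per-second traces, mirroring how reporter colonies are measured.
Defaults reflect the measured biology: a ~167-min period, a ~137-µm-radius
focus, 5-min sampling and a 48-h recording, which yields well over 10 pulses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import MovieStack, TimeSeries

__all__ = [
    "ColonySimConfig",
    "DDEParams",
    "GroundTruth",
    "CellTrack",
    "simulate_phase_field",
    "render_luminescence",
    "integrate_to_pmt",
    "simulate_pmt_trace",
    "simulate_dde_cell",
    "simulate_single_cells",
    "wrap_phase",
]


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap phase to the interval (-pi, pi]."""
    return -np.mod(-np.asarray(phi) + np.pi, 2 * np.pi) + np.pi


@dataclass
class ColonySimConfig:
    """Parameters of the synthetic colony and its measurement.

    Attributes
    ----------
    period_min
        Oscillation period P in minutes.
    wave_speed_um_per_min
        Outward crest speed v in µm/min.
    colony_radius_um
        Radius of the oscillation focus; envelope is zero outside.
    center_xy
        Focus center ``(y, x)`` in pixels; ``None`` = frame center.
    height_px, width_px, pixel_um
        Rendered frame geometry.
    duration_min, interval_min
        Recording length and frame/sample interval in minutes.
    baseline_cps, baseline_drift_per_min
        Additive background level and its linear drift rate.
    amplitude_cps, amplitude_decay_um
        Oscillation amplitude at the center and the radial e-folding
        length of its falloff.
    noise_model
        ``"none"`` or ``"poisson"`` (photon counting noise).
    spike_rate_per_frame, spike_magnitude
        Expected cosmic-ray spikes per frame and their height as a multiple
        of the local expected value.
    seed
        Single integer governing all stochastic draws.
    """

    period_min: float = 167.0
    wave_speed_um_per_min: float = 1.0
    colony_radius_um: float = 137.0
    center_xy: tuple[float, float] | None = None
    height_px: int = 64
    width_px: int = 64
    pixel_um: float = 4.0
    duration_min: float = 2880.0
    interval_min: float = 5.0
    baseline_cps: float = 1000.0
    baseline_drift_per_min: float = -0.1
    amplitude_cps: float = 300.0
    amplitude_decay_um: float = 200.0
    noise_model: str = "poisson"
    spike_rate_per_frame: float = 0.0
    spike_magnitude: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.period_min <= 0 or self.wave_speed_um_per_min <= 0:
            raise ValueError("period and wave speed must be positive")
        if not (0 < self.interval_min <= self.period_min / 4):
            raise ValueError("interval_min must lie in (0, period/4] "
                             "(at least 4 samples per cycle)")
        if self.noise_model not in ("none", "poisson"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        for name in ("colony_radius_um", "pixel_um", "duration_min",
                     "baseline_cps", "amplitude_cps", "amplitude_decay_um",
                     "spike_rate_per_frame", "spike_magnitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_frames(self) -> int:
        return int(np.floor(self.duration_min / self.interval_min)) + 1

    @property
    def center(self) -> tuple[float, float]:
        if self.center_xy is not None:
            return self.center_xy
        return ((self.height_px - 1) / 2.0, (self.width_px - 1) / 2.0)

    @property
    def time_min(self) -> np.ndarray:
        return self.interval_min * np.arange(self.n_frames)


@dataclass
class DDEParams:
    """Delayed-autorepression oscillator parameters.

    The model is the standard two-variable delayed negative feedback loop:

        m'(t) = alpha / (1 + (p(t - tau)/p0)**h) - mu_m * m(t)
        p'(t) = beta * m(t) - mu_p * p(t)

    with mRNA ``m``, protein ``p``, Hill coefficient ``h`` and a lumped
    transcription+translation delay ``tau`` (minutes). In the relaxation
    limit (steep Hill, strong repression) the period approaches
    ``2 * (tau + 1/mu_m + 1/mu_p)``.
    """

    alpha: float = 1.0
    beta: float = 1.0
    mu_m: float = 1.0 / 24.0
    mu_p: float = 1.0 / 24.0
    p0: float = 40.0
    h: float = 20.0
    tau_min: float = 35.0

    def __post_init__(self) -> None:
        if self.alpha < 0:  # alpha = 0 is the no-production degenerate case
            raise ValueError("alpha must be non-negative")
        for name in ("beta", "mu_m", "mu_p", "p0", "tau_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.h < 1:
            raise ValueError("Hill coefficient h must be >= 1")


@dataclass
class CellTrack:
    """One labelled cell: positions, ground-truth phase and intensity."""

    time_min: np.ndarray
    y_px: np.ndarray
    x_px: np.ndarray
    phase: np.ndarray
    intensity: np.ndarray
    complete: bool = True


@dataclass
class GroundTruth:
    """Ground truth backing a rendered movie."""

    phase: np.ndarray                # T x H x W wrapped radians
    envelope: np.ndarray             # T x H x W amplitude factor (cps)
    spike_log: list[tuple[int, int, int, float]] = field(default_factory=list)
    cell_tracks: list[CellTrack] | None = None


def _radius_map(config: ColonySimConfig) -> np.ndarray:
    cy, cx = config.center
    yy, xx = np.mgrid[0:config.height_px, 0:config.width_px]
    return np.hypot(yy - cy, xx - cx) * config.pixel_um


def _phase_at(config: ColonySimConfig, r_um: np.ndarray | float,
              t_min: np.ndarray | float) -> np.ndarray:
    P, v = config.period_min, config.wave_speed_um_per_min
    return wrap_phase(2 * np.pi * np.asarray(t_min) / P
                      - 2 * np.pi * np.asarray(r_um) / (P * v))


def simulate_phase_field(config: ColonySimConfig) -> GroundTruth:
    """Generate the traveling-wave ground truth for one colony.

    Phase at radius r and time t is ``wrap(2*pi*t/P - 2*pi*r/(P*v))`` —
    a full cycle every P minutes at the center, with the periphery lagging
    by ``2*pi*r/(P*v)``. The amplitude envelope is
    ``amplitude_cps * exp(-r/amplitude_decay_um)`` inside ``colony_radius_um``
    and zero outside. Cosmic-ray spike events are drawn here (Poisson count
    per frame, uniform pixel) so the renderer and the spike filter share one
    log.
    """
    r = _radius_map(config)
    t = config.time_min
    phase = _phase_at(config, r[None, :, :], t[:, None, None])
    env2d = np.where(r <= config.colony_radius_um,
                     config.amplitude_cps * np.exp(-r / config.amplitude_decay_um)
                     if config.amplitude_decay_um > 0 else config.amplitude_cps,
                     0.0)
    envelope = np.broadcast_to(env2d, phase.shape).copy()

    spike_log: list[tuple[int, int, int, float]] = []
    if config.spike_rate_per_frame > 0:
        rng = np.random.default_rng([config.seed, 0])
        counts = rng.poisson(config.spike_rate_per_frame, size=config.n_frames)
        for ti, c in enumerate(counts):
            for _ in range(int(c)):
                y = int(rng.integers(0, config.height_px))
                x = int(rng.integers(0, config.width_px))
                spike_log.append((ti, y, x, config.spike_magnitude))
    return GroundTruth(phase=phase, envelope=envelope, spike_log=spike_log)


def expected_movie(truth: GroundTruth, config: ColonySimConfig) -> np.ndarray:
    """Noise- and spike-free expected pixel values (cps)."""
    t = config.time_min
    baseline = config.baseline_cps + config.baseline_drift_per_min * t
    expected = baseline[:, None, None] + truth.envelope * (1 + np.cos(truth.phase)) / 2
    return np.clip(expected, 0.0, None)


def render_luminescence(truth: GroundTruth, config: ColonySimConfig) -> MovieStack:
    """Render ground truth to a luminescence movie.

    Expected pixel value is ``baseline + drift*t + envelope*(1+cos(phase))/2``;
    Poisson sampling replaces each pixel by a draw with that mean when
    configured, and logged cosmic-ray spikes are added last (additive,
    single pixel, single frame, ``magnitude x`` the local expected value).
    """
    expected = expected_movie(truth, config)
    if config.noise_model == "poisson":
        rng = np.random.default_rng([config.seed, 1])
        frames = rng.poisson(expected).astype(float)
    else:
        frames = expected.copy()
    for (ti, y, x, mag) in truth.spike_log:
        frames[ti, y, x] += mag * expected[ti, y, x]
    return MovieStack(frames, interval_min=config.interval_min,
                      pixel_um=config.pixel_um, t0_min=0.0)


def integrate_to_pmt(movie: MovieStack, exposure_s: float = 5.0,
                     count_scale: float = 1.0) -> TimeSeries:
    """Integrate a movie to a PMT-style counts-per-second trace.

    Per frame, all pixel values are summed, treated as photon counts
    collected during ``exposure_s`` (scaled by ``count_scale`` counts per
    intensity unit), and divided by the exposure to give cps.
    """
    if exposure_s <= 0:
        raise ValueError("exposure_s must be positive")
    total = movie.frames.sum(axis=(1, 2)) * count_scale / exposure_s
    return TimeSeries(movie.time_min, total, label="PMT")


def simulate_pmt_trace(config: ColonySimConfig, r_um: float = 0.0,
                       label: str = "PMT") -> TimeSeries:
    """Simulate a single whole-well PMT trace directly from the closed form.

    The trace is the field evaluated at radius ``r_um`` (default: the focus
    center): ``baseline + drift*t + envelope(r)*(1+cos(phase(r,t)))/2`` with
    Poisson noise and cosmic-ray spikes per the config. Equivalent to
    rendering a one-pixel movie; used for well-level simulations where no
    image is needed.
    """
    t = config.time_min
    if config.amplitude_decay_um > 0:
        env = config.amplitude_cps * np.exp(-r_um / config.amplitude_decay_um)
    else:
        env = config.amplitude_cps
    if r_um > config.colony_radius_um:
        env = 0.0
    phase = _phase_at(config, r_um, t)
    expected = np.clip(config.baseline_cps + config.baseline_drift_per_min * t
                       + env * (1 + np.cos(phase)) / 2, 0.0, None)
    rng = np.random.default_rng([config.seed, 3])
    if config.noise_model == "poisson":
        value = rng.poisson(expected).astype(float)
    else:
        value = expected.copy()
    if config.spike_rate_per_frame > 0:
        n_spikes = rng.poisson(config.spike_rate_per_frame, size=t.size)
        value = value + (n_spikes > 0) * config.spike_magnitude * expected
    return TimeSeries(t, value, label=label)


def simulate_dde_cell(params: DDEParams, duration_min: float, dt_min: float,
                      history: tuple[float, float] = (0.0, 0.0)
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integrate the delayed-autorepression oscillator.

    Fixed-step RK4 with a delay buffer; the delayed protein level is linearly
    interpolated from the stored trajectory (constant ``history`` before
    t = 0). Returns ``(time_min, mrna, protein)``.
    """
    if dt_min > params.tau_min / 20:
        raise ValueError("dt_min must be <= tau_min/20 for the delay buffer")
    n = int(np.floor(duration_min / dt_min)) + 1
    t = dt_min * np.arange(n)
    m = np.empty(n)
    p = np.empty(n)
    m[0], p[0] = history

    m0_hist, p0_hist = history
    tau = params.tau_min

    def p_delayed(time: float, i_done: int) -> float:
        """Protein at `time` from the stored grid (linear interp)."""
        if time <= 0:
            return p0_hist
        idx = time / dt_min
        lo = int(np.floor(idx))
        if lo >= i_done:
            return p[i_done]
        frac = idx - lo
        hi = min(lo + 1, i_done)
        return (1 - frac) * p[lo] + frac * p[hi]

    def deriv(ti: float, mi: float, pi: float, i_done: int) -> tuple[float, float]:
        pd = p_delayed(ti - tau, i_done)
        prod = params.alpha / (1.0 + (pd / params.p0) ** params.h)
        return (prod - params.mu_m * mi, params.beta * mi - params.mu_p * pi)

    for i in range(n - 1):
        ti, mi, pi = t[i], m[i], p[i]
        k1 = deriv(ti, mi, pi, i)
        k2 = deriv(ti + dt_min / 2, mi + dt_min / 2 * k1[0], pi + dt_min / 2 * k1[1], i)
        k3 = deriv(ti + dt_min / 2, mi + dt_min / 2 * k2[0], pi + dt_min / 2 * k2[1], i)
        k4 = deriv(ti + dt_min, mi + dt_min * k3[0], pi + dt_min * k3[1], i)
        m[i + 1] = mi + dt_min / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        p[i + 1] = pi + dt_min / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        if not (np.isfinite(m[i + 1]) and np.isfinite(p[i + 1])):
            raise FloatingPointError(f"non-finite state at step {i + 1} (t={t[i + 1]:g} min)")
    return t, m, p


def simulate_single_cells(config: ColonySimConfig, n_labeled: int,
                          motion_step_um: float = 0.0,
                          dropout_prob: float = 0.0) -> GroundTruth:
    """Sparse labelled cells inside the colony, as in mosaic-reporter imaging.

    Each cell starts at a uniform random position inside the focus, carries
    the local field phase, performs an isotropic Gaussian random walk with
    per-frame step ``motion_step_um`` (reflected at the colony edge), and with
    probability ``dropout_prob`` its track is truncated at a uniform random
    time, emulating cells drifting out of focus.
    """
    if n_labeled < 1:
        raise ValueError("n_labeled must be >= 1")
    truth = simulate_phase_field(config)
    rng = np.random.default_rng([config.seed, 2])
    cy, cx = config.center
    t = config.time_min
    n_t = t.size
    tracks: list[CellTrack] = []
    for _ in range(n_labeled):
        # uniform in the disk
        rr = config.colony_radius_um * np.sqrt(rng.uniform())
        th = rng.uniform(0, 2 * np.pi)
        y = cy + rr * np.sin(th) / config.pixel_um
        x = cx + rr * np.cos(th) / config.pixel_um
        ys, xs = np.empty(n_t), np.empty(n_t)
        for i in range(n_t):
            ys[i], xs[i] = y, x
            if motion_step_um > 0:
                y += rng.normal(0, motion_step_um) / config.pixel_um
                x += rng.normal(0, motion_step_um) / config.pixel_um
                r_now = np.hypot((y - cy) * config.pixel_um, (x - cx) * config.pixel_um)
                if r_now > config.colony_radius_um:  # reflect back inside
                    scale = (2 * config.colony_radius_um - r_now) / r_now
                    y = cy + (y - cy) * scale
                    x = cx + (x - cx) * scale
        r_um = np.hypot((ys - cy), (xs - cx)) * config.pixel_um
        phase = _phase_at(config, r_um, t)
        env = np.where(r_um <= config.colony_radius_um,
                       config.amplitude_cps * np.exp(-r_um / config.amplitude_decay_um)
                       if config.amplitude_decay_um > 0 else config.amplitude_cps, 0.0)
        intensity = np.clip(config.baseline_cps + config.baseline_drift_per_min * t
                            + env * (1 + np.cos(phase)) / 2, 0.0, None)
        if config.noise_model == "poisson":
            intensity = rng.poisson(intensity).astype(float)
        complete = True
        if dropout_prob > 0 and rng.uniform() < dropout_prob:
            cut = int(rng.integers(2, n_t))
            ys, xs, phase, intensity = ys[:cut], xs[:cut], phase[:cut], intensity[:cut]
            complete = False
        tracks.append(CellTrack(time_min=t[:len(ys)], y_px=ys, x_px=xs,
                                phase=phase, intensity=intensity, complete=complete))
    truth.cell_tracks = tracks
    return truth
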