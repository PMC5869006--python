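"""Plate-level reporter-screen analysis.

Each well's raw PMT trace is summarized (mean intensity, pulse amplitude,
period, pulse count, oscillatory call), treated wells are compared with
controls by an unpaired two-sided Student's t-test on mean intensity and on
amplitude, and compounds are classified into two phenotype classes:
*promoter repressing* (oscillation amplitude suppressed together with a
large drop in overall reporter expression) versus *oscillation blocking
without repression* (amplitude suppressed while expression is preserved).
No multiple-testing correction is applied by default — per-compound
significance stars mirror small-scale screening practice; a
Benjamini-Hochberg mode is available for library-scale use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import PlateLayout, TimeSeries
from .oscillation import (amplitude_top3, classify_oscillatory, detect_peaks,
                          hilbert_phase, period_stats)
from .preprocess import DetrendParams, preprocess_pmt

__all__ = [
    "WellSummary",
    "CompoundResult",
    "summarize_well",
    "compare_to_control",
    "call_hits",
    "analyze_plate",
    "significance_stars",
]

CLASS_NO_EFFECT = "no_effect"
CLASS_REPRESSING = "promoter_repressing"
CLASS_BLOCKING = "oscillation_blocking_nonrepressing"


@dataclass
class WellSummary:
    """Per-well oscillation summary derived from one raw PMT trace."""

    well_id: str
    compound: str
    concentration_uM: float
    mean_intensity_cps: float
    amplitude_cps: float
    mean_period_min: float
    n_pulses: int
    oscillatory: bool

    def __post_init__(self) -> None:
        if self.mean_intensity_cps < 0 or self.n_pulses < 0:
            raise ValueError("mean intensity and pulse count must be non-negative")


@dataclass
class CompoundResult:
    """Treated-versus-control comparison for one compound."""

    compound: str
    concentration_uM: float
    n_treated: int
    n_control: int
    control_intensity: float
    control_amplitude: float
    delta_intensity: float
    delta_amplitude: float
    p_intensity: float | None
    p_amplitude: float | None
    stars_intensity: str
    stars_amplitude: str
    hit_class: str = CLASS_NO_EFFECT


def significance_stars(p: float | None) -> str:
    """The conventional 0.05 / 0.01 / 0.001 significance ladder."""
    if p is None or np.isnan(p):
        return "ns"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _noise_floor(raw: TimeSeries) -> float:
    """Noise sigma from first differences (robust MAD estimate).

    diff of i.i.d. noise has variance 2*sigma^2, and differencing removes
    the slow oscillation almost entirely at these sampling rates.
    """
    d = np.diff(raw.value)
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2))


def summarize_well(raw: TimeSeries, layout: PlateLayout,
                   detrend: DetrendParams | None = None,
                   min_period_min: float = 60.0) -> WellSummary:
    """Run the PMT conditioning + oscillation chain for one well."""
    row = layout.row(raw.label)
    detrended = preprocess_pmt(raw, detrend=detrend)
    ph = hilbert_phase(detrended)
    peaks = detect_peaks(detrended, ph, min_period_min=min_period_min)
    amp = amplitude_top3(detrended, peaks)
    if peaks.n_pulses >= 2:
        period = period_stats(peaks).mean_period_min
    else:
        period = float("nan")
    floor = max(_noise_floor(raw), 1e-12)
    call = classify_oscillatory(detrended, peaks, noise_floor_cps=floor)
    return WellSummary(
        well_id=raw.label,
        compound=str(row["compound_name"]),
        concentration_uM=float(row["concentration_uM"]),
        mean_intensity_cps=float(np.mean(raw.value)),
        amplitude_cps=amp.value_cps,
        mean_period_min=period,
        n_pulses=peaks.n_pulses,
        oscillatory=call.oscillatory,
    )


def _ttest(a: np.ndarray, b: np.ndarray, welch: bool) -> float | None:
    if a.size < 2 or b.size < 2:
        return None
    return float(stats.ttest_ind(a, b, equal_var=not welch).pvalue)


def compare_to_control(treated: list[WellSummary], control: list[WellSummary],
                       welch: bool = False) -> CompoundResult:
    """Student's t-test comparison of one treated group against controls.

    Two-sample, two-sided, equal-variance by default (``welch=True`` for the
    unequal-variance variant). Deltas are treated-minus-control means. With
    fewer than 2 wells in a group, effect sizes are reported and the p-value
    is left out (small-n warning).
    """
    if not control:
        raise ValueError("empty control group")
    if not treated:
        raise ValueError("empty treated group")
    t_int = np.array([w.mean_intensity_cps for w in treated])
    c_int = np.array([w.mean_intensity_cps for w in control])
    t_amp = np.array([w.amplitude_cps for w in treated])
    c_amp = np.array([w.amplitude_cps for w in control])
    p_int = _ttest(t_int, c_int, welch)
    p_amp = _ttest(t_amp, c_amp, welch)
    if p_int is None:
        warnings.warn(f"{treated[0].compound}: <2 wells per group, p-values "
                      "not computed (effect sizes only)", stacklevel=2)
    return CompoundResult(
        compound=treated[0].compound,
        concentration_uM=treated[0].concentration_uM,
        n_treated=len(treated),
        n_control=len(control),
        control_intensity=float(c_int.mean()),
        control_amplitude=float(c_amp.mean()),
        delta_intensity=float(t_int.mean() - c_int.mean()),
        delta_amplitude=float(t_amp.mean() - c_amp.mean()),
        p_intensity=p_int,
        p_amplitude=p_amp,
        stars_intensity=significance_stars(p_int),
        stars_amplitude=significance_stars(p_amp),
    )


def call_hits(results: list[CompoundResult], alpha: float = 0.05,
              intensity_drop_frac: float = 0.5,
              bh_correct: bool = False) -> list[CompoundResult]:
    """Classify compounds into phenotype classes.

    * ``promoter_repressing`` — amplitude significantly reduced AND mean
      intensity reduced by more than ``intensity_drop_frac`` of the control
      level with p < alpha (expression itself is shut down);
    * ``oscillation_blocking_nonrepressing`` — amplitude significantly
      reduced while intensity is NOT significantly reduced (the clock stops
      but the promoter stays active);
    * ``no_effect`` otherwise.

    ``bh_correct`` applies Benjamini-Hochberg across compounds to the
    amplitude and intensity p-value families before thresholding.
    """
    if not results:
        raise ValueError("no results to classify")

    def _family(ps: list[float | None]) -> list[float | None]:
        if not bh_correct:
            return ps
        idx = [i for i, p in enumerate(ps) if p is not None]
        if not idx:
            return ps
        raw = np.array([ps[i] for i in idx])
        order = np.argsort(raw)
        m = raw.size
        adj = np.empty(m)
        running = 1.0
        for rank_pos in range(m - 1, -1, -1):
            i = order[rank_pos]
            running = min(running, raw[i] * m / (rank_pos + 1))
            adj[i] = running
        out = list(ps)
        for j, i in enumerate(idx):
            out[i] = float(adj[j])
        return out

    p_amp = _family([r.p_amplitude for r in results])
    p_int = _family([r.p_intensity for r in results])
    for r, pa, pi in zip(results, p_amp, p_int):
        amp_down = pa is not None and pa < alpha and r.delta_amplitude < 0
        int_sig_down = pi is not None and pi < alpha and r.delta_intensity < 0
        big_drop = (r.control_intensity > 0 and
                    -r.delta_intensity > intensity_drop_frac * r.control_intensity)
        if amp_down and int_sig_down and big_drop:
            r.hit_class = CLASS_REPRESSING
        elif amp_down and not int_sig_down:
            r.hit_class = CLASS_BLOCKING
        else:
            r.hit_class = CLASS_NO_EFFECT
    return results


def analyze_plate(traces: list[TimeSeries], layout: PlateLayout,
                  alpha: float = 0.05, intensity_drop_frac: float = 0.5,
                  welch: bool = False, bh_correct: bool = False) -> pd.DataFrame:
    """Full plate analysis: summaries, t-tests and hit classes as a table."""
    summaries = {ts.label: summarize_well(ts, layout) for ts in traces}
    control = [summaries[w] for w in layout.control_wells if w in summaries]
    if not control:
        raise ValueError("no control wells among the supplied traces")
    groups: dict[tuple[str, float], list[WellSummary]] = {}
    for _, row in layout.table.iterrows():
        if row["role"] != "treated" or row["well_id"] not in summaries:
            continue
        key = (str(row["compound_name"]), float(row["concentration_uM"]))
        groups.setdefault(key, []).append(summaries[row["well_id"]])
    results = [compare_to_control(wells, control, welch=welch)
               for wells in groups.values()]
    results = call_hits(results, alpha=alpha,
                        intensity_drop_frac=intensity_drop_frac,
                        bh_correct=bh_correct)
    return pd.DataFrame([{
        "compound": r.compound,
        "concentration_uM": r.concentration_uM,
        "n_treated": r.n_treated,
        "delta_intensity": r.delta_intensity,
        "delta_amplitude": r.delta_amplitude,
        "p_intensity": r.p_intensity,
        "p_amplitude": r.p_amplitude,
        "stars": r.stars_amplitude,
        "class": r.hit_class,
    } for r in results])
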