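"""Simulate a whole-well PMT recording and quantify its oscillation.

A synthetic iPSM colony (period 167 min, baseline 1000 cps, amplitude
300 cps, Poisson photon noise) is recorded for 48 h at 5-min sampling, then
pushed through the standard chain: spike filter -> 36-frame moving-average
detrend -> Hilbert phase -> phase-referenced peaks -> period histogram.
"""

import numpy as np

import clockwave as cw

cfg = cw.ColonySimConfig(period_min=167.0, seed=1)
raw = cw.simulate_pmt_trace(cfg)

detrended = cw.preprocess_pmt(raw)
phase = cw.hilbert_phase(detrended)
peaks = cw.detect_peaks(detrended, phase)
hist = cw.period_stats(peaks)
amp = cw.amplitude_top3(detrended, peaks)

print(f"simulated period        : {cfg.period_min:.1f} min")
print(f"pulses detected         : {peaks.n_pulses}")
print(f"recovered mean period   : {hist.mean_period_min:.1f} +- {hist.sem_min:.1f} min (SEM)")
print(f"intervals in 150-180 min: {100 * hist.fraction_in(150, 180):.0f}%")
print(f"amplitude (top-3 pulses): {amp.value_cps:.0f} cps")
# The recovered period should sit within a few minutes of the configured
# 167 min; the amplitude is the mean detrended height of the three largest
# pulses, somewhat below the configured 300 cps center amplitude because the
# 36-frame (180-min) moving-average window attenuates a 167-min oscillation.
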