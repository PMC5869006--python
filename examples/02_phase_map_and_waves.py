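"""Phase maps, oscillation-center location and wave-speed estimation.

A noiseless traveling-wave colony movie (crests sweeping outward at
1 µm/min) is analyzed per pixel with the imaging chain (30-frame detrend,
41-frame Savitzky-Golay, Hilbert), then the wave source is located and the
crest speed measured from a radial kymograph.
"""

import numpy as np

import clockwave as cw

cfg = cw.ColonySimConfig(seed=2, noise_model="none", duration_min=2880.0)
truth = cw.simulate_phase_field(cfg)
movie = cw.render_luminescence(truth, cfg)

pm = cw.phase_movie(movie)
diff = cw.wrap_phase(pm.phase[40:-40][:, pm.mask] - truth.phase[40:-40][:, pm.mask])
rms = np.sqrt(np.mean(diff ** 2))
y, x, lead = cw.locate_center(pm)

cy, cx = cfg.center
kymo = cw.compute_kymograph(movie, cw.ROI.make_polyline([(cy, cx), (cy, 62)]))
speed = cw.wave_speed(kymo)

central = cw.roi_trace(movie, cw.ROI.make_rect(31, 31, 32, 32))
periph = cw.roi_trace(movie, cw.ROI.make_rect(31, 46, 32, 47))
lag = cw.phase_lag(cw.hilbert_phase(cw.preprocess_pmt(central)),
                   cw.hilbert_phase(cw.preprocess_pmt(periph)),
                   window=slice(40, -40))

print(f"phase RMS error vs truth : {rms:.3f} rad ({pm.mask.sum()} px analyzed)")
print(f"oscillation center       : ({y}, {x}), true ({cy:.1f}, {cx:.1f}), lead {lead:.2f} rad")
print(f"wave speed               : {speed.speed_um_per_min:.2f} µm/min "
      f"(true {cfg.wave_speed_um_per_min}, residual {speed.residual_rms_um:.1f} µm)")
print(f"center-periphery lag     : {lag['radians']:.2f} rad = {lag['minutes']:.0f} min")
# Positive lag means the center leads the periphery: waves start at the
# focus center and sweep outward, so peripheral phase is delayed by
# 2*pi*r/(P*v) — here ~2.1 rad over 60 µm.
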