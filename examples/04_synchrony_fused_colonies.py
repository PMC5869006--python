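"""Phase synchrony between oscillation foci of a fused colony.

Two foci sharing one clock (same period, same phase) are rendered into one
movie; the per-focus mean phases are extracted through the imaging chain and
compared with the Kuramoto order parameter R: 1 = perfect in-phase synchrony,
~0 = incoherent.
"""

import numpy as np
from scipy import ndimage

import clockwave as cw

cfg_a = cw.ColonySimConfig(seed=3, noise_model="none", center_xy=(16, 16),
                           colony_radius_um=50.0, duration_min=1500.0)
cfg_b = cw.ColonySimConfig(seed=3, noise_model="none", center_xy=(48, 48),
                           colony_radius_um=50.0, duration_min=1500.0)
ma = cw.render_luminescence(cw.simulate_phase_field(cfg_a), cfg_a)
mb = cw.render_luminescence(cw.simulate_phase_field(cfg_b), cfg_b)
fused = cw.MovieStack(ma.frames + mb.frames - cfg_a.baseline_cps,
                      interval_min=5.0, pixel_um=4.0)

pm = cw.phase_movie(fused)
labels, n_foci = ndimage.label(pm.mask)
t_frames = fused.frames.shape[0]
focus_traces = []
for i in range(1, n_foci + 1):
    flat = pm.phase.reshape(t_frames, -1)[:, (labels == i).ravel()]
    mean_phase = np.angle(np.exp(1j * flat).mean(axis=1))
    focus_traces.append(cw.PhaseTrace(fused.time_min, mean_phase,
                                      np.unwrap(mean_phase),
                                      np.ones(t_frames), f"focus{i}"))
r_t, r_mean = cw.sync_index(focus_traces, window=slice(40, t_frames - 40))

rng = np.random.default_rng(0)
t = fused.time_min
incoherent = []
for i in range(100):
    w = cw.wrap_phase(2 * np.pi * t / 167.0 + rng.uniform(-np.pi, np.pi))
    incoherent.append(cw.PhaseTrace(t, w, np.unwrap(w), np.ones(t.size), str(i)))
_, r_incoherent = cw.sync_index(incoherent)

print(f"foci found               : {n_foci}")
print(f"R, in-phase fused foci   : {r_mean:.3f}  (1 = locked in phase)")
print(f"R, 100 incoherent phases : {r_incoherent:.3f}  (~0 = no synchrony)")
# Fused colonies whose foci share one clock give R near 1; randomly phased
# oscillators give R near 1/sqrt(N).
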