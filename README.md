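# clockwave

Quantification of segmentation-clock reporter oscillations in bioluminescence
recordings, with a synthetic-colony generator that provides exact ground
truth for every analysis stage.

## The problem

Mouse presomitic-mesoderm (PSM) tissue — and PSM-like colonies derived from
ES cells — expresses the transcriptional repressor Hes7 in pulses with a
period of roughly 2–3 hours. With a Hes7 promoter-driven luciferase reporter,
these pulses are recorded either as whole-well photon counts from a
photomultiplier tube (counts per second, sampled every 3 or 5 min) or as
time-lapse CCD image stacks in which expression waves sweep from the center
of an oscillation focus toward its periphery. Extracting biology from these
recordings requires a chain of standard but easy-to-get-wrong steps:
cosmic-ray spike removal, background reduction, detrending, smoothing,
instantaneous-phase reconstruction, peak statistics, kymographs, wave-speed
and synchrony metrics, and treated-versus-control statistics for chemical
screens. `clockwave` implements that chain as a tested library for people
analyzing reporter time series and movies of genetic oscillators.

## The core quantities

For a detrended trace $x(t)$ the analytic signal
$x(t) + i\,\mathcal{H}[x](t)$ gives a wrapped instantaneous phase
$\phi(t) \in (-\pi, \pi]$ with $\phi = 0$ at signal maxima. Pulses are the
upward crossings of the unwrapped phase through $2\pi k$; peak-to-peak
intervals give the period distribution (10-min bins spanning 140–210 min);
pulse amplitude is the mean of the three highest detrended peaks. For
movies the same chain runs per pixel (30-frame moving-average detrend,
41-frame Savitzky–Golay window, Hilbert transform), yielding phase maps from
which the wave source (earliest-phase locus), the crest speed
$v = \mathrm{d}r/\mathrm{d}t$ along a kymograph, center–periphery lags
$\Delta\phi = 2\pi r / (P v)$, and the Kuramoto order parameter
$R(t) = \lvert \langle e^{i\phi_j(t)} \rangle_j \rvert$ are measured.

The synthetic colony is a kinematic traveling-wave field,
$\phi(r, t) = 2\pi t / P - 2\pi r / (P v)$, with an exponentially decaying
amplitude envelope, baseline drift, Poisson photon noise and logged
cosmic-ray spikes; single cells are modeled by the canonical
delayed-autorepression loop
$m'(t) = \alpha / (1 + (p(t-\tau)/p_0)^h) - \mu_m m$,
$p'(t) = \beta m - \mu_p p$, which oscillates with period
$\approx 2(\tau + 1/\mu_m + 1/\mu_p)$ in the relaxation limit.

## Worked example

```python
import clockwave as cw

cfg = cw.ColonySimConfig(period_min=167.0, seed=1)   # 48 h, 5-min sampling
raw = cw.simulate_pmt_trace(cfg)                     # Poisson-noise cps trace

detrended = cw.preprocess_pmt(raw)                   # spike filter + 36-frame detrend
phase = cw.hilbert_phase(detrended)
peaks = cw.detect_peaks(detrended, phase)
hist = cw.period_stats(peaks)
amp = cw.amplitude_top3(detrended, peaks)

print(peaks.n_pulses, hist.mean_period_min, amp.value_cps)
```

Running `python examples/01_simulate_and_quantify_pmt.py` prints:

```
simulated period        : 167.0 min
pulses detected         : 16
recovered mean period   : 166.3 +- 1.9 min (SEM)
intervals in 150-180 min: 93%
amplitude (top-3 pulses): 218 cps
```

16 pulses over two days with a mean interval within a minute of the
configured 167-min period; the amplitude sits below the configured 300 cps
center amplitude because a 180-min moving-average window attenuates a
167-min oscillation (the attenuation is a property of the published window
choice, not a defect).

The other scripts in `examples/` cover phase maps and wave-speed estimation,
the delayed-feedback oscillator, synchrony between fused-colony foci, and a
small inhibitor screen. A thin CLI wraps the same functions
(`clockwave simulate|preprocess|analyze|kymo|phasemap|screen|all`), writing a
manifest (config hash, seed, input checksums) next to every output.

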