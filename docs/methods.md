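# Methods

## Signal model

A reporter recording is modeled as

    x(t) = b(t) + A(r) * (1 + cos phi(r, t)) / 2 + noise + spikes

where `b(t)` is a slowly drifting baseline (cps), `A(r)` an amplitude
envelope, and `phi(r, t) = 2*pi*t/P - 2*pi*r/(P*v)` the phase of an outward
traveling wave of period `P` and crest speed `v` originating at the focus
center. Photon counting makes the noise Poisson with variance equal to the
expected count; cosmic rays add rare single-pixel, single-frame spikes.

## Conditioning chain

The chain is fixed as: spike filter → temporal background reduction (movies
only) → moving-average detrending → Savitzky–Golay smoothing → Hilbert
transform. All stages preserve length and time grid.

**Spike filter.** A sample is a spike iff
`|x − rolling_median| > k·(1.4826·MAD + ε)` with `k = 5`, and is replaced by
the rolling median. Two numerical choices matter and were made after the
naive version produced percent-level false-positive rates on clean Poisson
input:

* the rolling median (half-window 2, i.e. 5 frames) *excludes the center
  sample* (leave-one-out, reflect-padded). A center-inclusive median returns
  the sample itself ~20% of the time, which deflates the residual/MAD ratio
  for typical samples and inflates it for ordinary noise excursions;
* the MAD of the median residual is taken over a much longer window
  (`max(10·half_window, 25)` frames on each side, reflect-padded): a
  5-sample MAD is far too noisy a scale estimate for a 5-sigma rule.

The first and last `half_window` samples are never flagged (the reflected
neighbor median is curvature-biased there). With these choices the filter
recovers ≥95% of injected spikes at <0.1% collateral alterations; a spike of
magnitude ≤ ε inside an all-constant window is by construction not flagged.

**Temporal background reduction.** Per pixel, a rolling low percentile
(default 10th over a 30-frame window) of the pixel's own trace is
subtracted; negatives are clipped to zero. The window is centered rather
than trailing — behaviorally equivalent for oscillation extraction, and a
centered window avoids a systematic half-window lag under baseline drift. A
window longer than the recording falls back to the whole-trace percentile
with a warning.

**Moving-average detrending.** Subtractive (`x − centered moving mean`),
never divisive: detrended reporter traces oscillate about zero with negative
excursions. Window defaults: 36 frames for whole-well PMT traces, 30 frames
for imaging. Edges use symmetrically shrinking windows (minimum 3 points,
one-sided at the outermost samples) rather than reflection padding — no
fabricated data at the boundaries of a two-day recording. An even nominal
window is widened to the next odd count so the filter stays zero-phase.
Note the attenuation this implies: a 36-frame window at 5-min sampling spans
1.08 periods of a 167-min oscillation and passes ~73% of its amplitude;
amplitude statistics inherit that factor by design.

**Savitzky–Golay smoothing.** 41-frame window, polynomial order 2 (the order
is a package choice; order 2 preserves pulse shape at this window length).
Boundary handling is scipy's polynomial-fit mode, again avoiding reflected
data. Applied in the imaging chain; optional (off by default) for PMT
traces, whose whole-well averaging already suppresses pixel noise.

## Phase, peaks, periods, amplitude

Phase is the argument of the discrete analytic signal, cosine convention
(phase 0 at maxima); the per-sample analytic amplitude is kept as a quality
channel. The finite-segment FFT Hilbert transform distorts phase near the
recording boundaries, so the input is mirror-extended by
`min(n/2, 64)` samples on each side before the transform and cropped after.
With `zero_mean_check` on, an input whose mean exceeds 0.25 standard
deviations is rejected ("detrend first"); an all-constant input yields NaN
phase with quality 0.

Peaks are upward crossings of the unwrapped phase through `2*pi*k`, refined
by linear interpolation; the pulse height is the detrended value at the
nearest sample. Three acceptance rules:

* refractory period `min_period_min = 60` (well below the physiological
  140–210 min range) suppresses noise double counts;
* crossings within 45 min of either end of the recording are discarded
  (residual boundary distortion of the analytic signal);
* crossings where the analytic amplitude falls below half its trace median
  are discarded — noise-driven phase slips occur precisely where the
  envelope collapses, and each slip would otherwise insert one spurious
  sub-period interval.

Period statistics are computed on the raw peak-to-peak intervals (mean,
SEM), binned at 10 min with edges aligned to multiples of 10 and always
covering 140–210 min. Both interval-weighted and colony-weighted band
fractions are available; note that a fixed-length recording yields more
intervals from faster colonies, so the two weightings differ. Amplitude is
the mean of the three highest pulse heights, flagged low-confidence below
three pulses. A trace is called oscillatory iff it has ≥2 accepted pulses
and a top-3 amplitude above 3× the noise floor; the rule's threshold is a
package choice, with the score (amplitude/noise floor) always reported.

## Movie analysis

Kymographs sample a polyline at one-pixel arc spacing with bilinear
interpolation, averaging over `line_width_px = 5` perpendicular offsets;
columns are frames in temporal order. Wave speed is estimated from crest
crossings: each row's detrended, Hilbert-transformed trace contributes its
`2*pi*k` crossing time per crest; rows are phase-aligned across space at the
mid frame (2π-offset correction); pooled within-crest least squares of arc
position on crossing time gives `d(arc)/dt` in µm/min with a residual RMS.
When the within-crest spread of crossing times falls below half a frame
interval the oscillation is standing and the speed is reported non-finite.

The oscillation center is the pixel with maximal phase lead: per-pixel
circular mean offsets from the brightest pixel are spatially unwrapped
(2-D masked unwrapping) before taking the arg-max, because center-to-edge
lags beyond π would otherwise alias; with spatially uniform phase the lead
is ~0 and the location is arbitrary (documented degeneracy). Multi-focus
colonies are handled by restricting the mask to one connected component at
a time. Phase lags between regions are circular means of wrapped phase
differences (positive = first trace leads); lags are intrinsically
mod-2π, so regions should be chosen within half a wavelength of each other.
The minute conversion divides by the mean recovered period of the two traces
and is therefore estimate-dependent. Synchrony is the Kuramoto order
parameter over unit phasors, reported per frame and time-averaged.

The phase-movie mask keeps pixels whose temporal-mean intensity exceeds a
threshold; the default threshold sits 5% of the dynamic range above the
dimmest pixel mean, which separates background from colony in
baseline-dominated movies but should be set explicitly for low-contrast
data.

## The delayed-autorepression oscillator

The mechanism — a repressor shutting down its own transcription after a
lumped delay — is implemented as the standard two-variable delay model
(Hill-repressed production, linear decay). Integration is fixed-step RK4
with a linearly interpolated delay buffer and constant pre-history;
`dt ≤ τ/20` is enforced, and halving dt changes the measured period by
<1%. Defaults (τ = 35 min, mRNA and protein half-lives ≈ 17 min, h = 20,
strong repression) put the relaxation-limit period `2(τ + 1/μ_m + 1/μ_p)`
at 166 min, matching the tissue-level period scale; the integrated period
runs ~6% above the asymptotic formula, as expected at finite h. Short
delays with shallow Hill coefficients sit below the Hopf threshold and
decay to the fixed point.

## Synthetic colonies: what they do and do not emulate

The generator reproduces: one oscillation focus per colony (~137 µm radius,
half the measured ~273 µm colony diameter), a ~167-min period, outward
traveling waves with an exact closed-form phase field, >10 pulses over a
48-h recording at 5-min sampling, baseline level ~1000 cps with linear
drift, center amplitude ~300 cps with exponential radial falloff (200-µm
length scale), Poisson photon noise, logged cosmic-ray spikes, sparse
labeled single cells with random-walk motion and focus-loss dropout, and
(by superposition) fused colonies with multiple in-phase foci. A single
integer seed makes every output bit-reproducible.

It deliberately does not emulate: emergent synchronization (the phase field
is kinematic, not a coupled-oscillator simulation — ground truth must be
exact for validation), focus growth/shrinkage, colony motion, cell division,
3-D geometry, or camera artifacts beyond Poisson noise and spikes. Passing
tests therefore demonstrate correct recovery of the stated signal model,
not robustness to tissue deformation or optical aberrations.

## Screening statistics

Per well: the PMT chain, then mean raw intensity, top-3 amplitude, period,
pulse count and the oscillatory call (noise floor from the MAD of first
differences, which cancels the slow oscillation). Group comparison is a
two-sample, two-sided, equal-variance Student's t-test on mean intensity
and on amplitude (Welch behind a flag), with the 0.05/0.01/0.001 star
ladder and treated-minus-control deltas. Classification:
*promoter_repressing* if amplitude is significantly reduced and mean
intensity is significantly reduced by more than `intensity_drop_frac = 0.5`
of the control level; *oscillation_blocking_nonrepressing* if amplitude is
significantly reduced while intensity is not significantly reduced;
otherwise *no_effect*. Both thresholds are explicit package
operationalizations of qualitative phenotype classes and are configurable.
No multiple-testing correction is applied by default (per-compound stars,
matching small-plate practice); Benjamini–Hochberg is available for
library-scale use. With fewer than two wells per group only effect sizes
are reported, with a small-n warning — duplicate-well screens should lean
on effect sizes, not p-values.

Note one consequence of the signal model: blocking an oscillation of
amplitude A removes its mean contribution A/2, so "intensity preserved"
test constructions compensate the baseline accordingly, and plate-level
simulations add ~10% lognormal colony-to-colony brightness variation so
that significance tests see realistic between-well variance.

## Simulation sizes

Test and acceptance runs use: 20 traces for period recovery; one noiseless
64×64×600 movie for phase-map fidelity plus 20 noisy seeds for the
lead-sign check; speeds {0.5, 1, 2} µm/min for wave-speed recovery; 10
spike-removal seeds (~400 spikes each); 100 seeds (tests) / 50 seeds
(acceptance script) for screen power; 3 seeds of an 80-pseudo-compound
null plate (n = 3 wells each, 7 controls); 5 seeds for phenotype
classification. These sizes keep the whole suite in the minutes range while
leaving Monte-Carlo error well inside the asserted margins.

## Known limitations

* Phase-referenced peak detection assumes a dominant oscillation; broadband
  or multi-component signals need spectral methods (wavelet, Lomb–Scargle)
  that are out of scope here.
* The wave-speed estimator assumes a single coherent wave train along the
  sampled line; colliding wave fronts from multiple foci violate it.
* Mean-intensity masking fails for movies without background pixels; pass
  an explicit threshold there.
* The period–minute conversion of phase lags inherits period-estimation
  error; lags are exact only in radians.
* Peak heights at crossings are point estimates at the nearest sample; for
  very noisy traces consider smoothing (SG on) before amplitude statistics.
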