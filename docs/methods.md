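# Methods

## Coordinate and unit conventions

Head-centered axes: +x toward the fly's right, +y up, identical for both
eyes; "retinal shift" means deep-pseudopupil shift in degrees. Image
coordinates inside the tracker are x = column (rightward), y = row
(downward), origin at the top-left pixel center; the y-axis is flipped on
conversion to degrees. Time is in seconds; traces are uniformly sampled
(resampling by linear interpolation is available at ingest).

Pixel-to-degree calibration goes through the inter-photoreceptor spacing
of the dot pattern: one spacing corresponds to one inter-ommatidial angle,
`deg_per_spacing` = Δϕ = 5° by default. The same Δϕ parameterizes the
aliasing model, and it is configurable (e.g. for higher-acuity species
with roughly twice the ommatidial count, which invert at smaller
wavelengths).

## Pseudopupil tracking

A frame is thresholded at `median + k·MAD` (default k = 6), which is
insensitive to overall illumination; for noise-free frames (MAD = 0)
Otsu's threshold is the fallback. Above-threshold pixels are grouped into
connected components, ranked by integrated background-subtracted
intensity, and up to seven are kept. The cluster centroid is the
intensity-weighted center of mass over the retained pixels, giving
sub-pixel precision (measured RMS error ≈ 0.03 px on the synthetic
stacks). Frames with no component above threshold raise `NoPupilFound`;
more than `max_components` (default 40) raises `AmbiguousScene`. Failed
frames are flagged and filled by hold-last (default) or left as gaps, so
the trace always has one sample per frame.

The spacing estimate is the median distance from the central dot (nearest
the cluster centroid) to the others — robust to one or two missing or
merged dots in the hexagon-plus-center pattern.

## Velocity and saccades

Velocities come from a Savitzky–Golay differentiator (window 5 samples,
order 2, mirror-padded). Saccades are detected by threshold crossing on
the 2-D speed of the velocity *residual* after subtracting a rolling-
median baseline velocity (window 0.5 s): the rolling median tracks smooth
optokinetic drift of any gain while passing brief saccadic transients, so
detection neither triggers on fast smooth tracking nor lets event bounds
bleed into it. Onset/offset extend to where the residual speed falls
below `threshold/3`; events closer than 100 ms are merged. Amplitude per
axis is the difference of 50-ms median windows after offset and before
onset; peak velocity is the maximum raw speed inside the event.

The default threshold is 15 °/s. At the default 100 Hz sample rate the
Savitzky–Golay filter attenuates a 30-ms saccade's peak velocity by
roughly half, so analyses of low-noise data that must resolve amplitudes
down to 0.2° should lower the threshold according to the velocity noise
floor; the tests use 8 °/s, ≈12× the velocity noise SD at trace noise
0.02°. With this setting, recall and precision on generated trains exceed
0.99 for amplitudes ≥ 0.2°.

`desaccade` removes each detected step and linearly interpolates the
event interval. The step is re-measured with the local pre-onset slope
(Theil–Sen over 0.3 s) subtracted, so smooth tracking passes through
unbiased; without this correction, each removed step would absorb the
drift accrued across its measurement windows and accumulate a slope bias.

The main-sequence fit is an ordinary least-squares line on
(log |A|, log v_peak); k = exp(intercept), b = slope. Because the
Savitzky–Golay attenuation of a fixed-duration waveform is the same
multiplicative factor at every amplitude, the fitted exponent is
unbiased while the coefficient k is attenuated — exponent comparisons
across conditions are therefore safe at 100 Hz, absolute k values are
not.

Initial optokinetic velocity is the Theil–Sen slope of the desaccaded
position over 0.5 s from stimulus onset (robust to residual undetected
steps); gain is |v|/v_stim with the sign reported separately (tracking
opposes the stimulus). The optomotor index per motion epoch is
`−sign(direction) · net displacement / total |displacement|` of the
desaccaded trace, averaged over epochs and clipped to [−1, 1]; a trace
with zero total displacement returns 0 with a degenerate flag. This
formula is one reasonable operationalization of "response strength in the
expected optokinetic direction" and is config-exposed.

## Binocular analysis

The vergence metric `V(t) = −(x_L − b_L)(x_R − b_R)` is positive when the
eyes move by equal and opposite amounts (convergence) and negative for
conjugate movements. Baselines are the per-eye trace means for continuous
display, or per-event means over [−2.5, −1.5] s before each crossing in
event analyses — the same window the vergence delta uses.

Gap crossings are threshold crossings of the unwrapped wheel angle with a
hysteresis band (default 5 wheel-degrees) and a 10-s minimum inter-event
interval so that ±5 s analysis windows never overlap; the threshold level
is replicated every 180° because the wheel carries two gaps per
revolution. Crossing instants are linearly interpolated between samples.

Event deltas use fixed windows relative to the crossing: position
channels mean[+2, +5] − mean[−5, −2] s; vergence mean[−0.5, +0.5] −
mean[−2.5, −1.5] s. Distributions of per-event (or per-fly) deltas are
tested against zero with two-sided one-sample t-tests at α/m (Bonferroni,
default m = 9). Crossing heights are summarized per fly as the median of
per-cross minimum y and compared between groups with a two-sided Welch
test; crossing rates are forward events per epoch duration, compared
across flies with a paired t-test.

## Receptive-field shift

Flash-grid maps subtract a 100-ms pre-flash baseline from the mean
voltage in a 200-ms response window (windows validated against the flash
boundaries). Widths are full width at half of (peak − minimum) with
linear interpolation.

Bar-sweep tuning curves are voltage time series mapped to screen position
via the bar speed; a fixed response latency therefore displaces the two
sweep directions' curves by equal and opposite offsets ±v_bar·t_lat. The
shift between two curves maximizes the normalized cross-correlation over
a ±20° search range (step = range/400) on the overlapping support, with
parabolic sub-sample refinement around the peak; positive shift means the
second curve sits at more positive screen positions. To estimate a
retinal shift free of latency bias, each direction's activated curve is
compared against the direction-pooled control curve (whose latency
offsets cancel in the pooling); the two per-direction estimates carry
±v_bar·t_lat and their mean is the latency-free shift. Peak normalization
of the curves leaves the estimate unchanged up to noise on the peaks.

## Aliasing model

Receptors at positions i·Δϕ see a drifting sinusoid; each
nearest-neighbour pair feeds an opponent delay-and-multiply correlator
with a first-order low-pass delay filter (τ = 50 ms, exponential
recursion at dt = min(period/200, τ/20)). The time average over whole
periods (after a 5τ transient) equals
`contrast² · ωτ/(1+ω²τ²) · sin(2πΔϕ/λ)`; the reported response divides
out the frequency-dependent gain so the curve is sin(2πΔϕ/λ) up to
simulation error (<2% at contrast ≤ 0.5). τ and optional Gaussian
acceptance-angle blur scale the magnitude but never move the zero
crossings, which is what the inversion-band edges are read from (by
Brent root bracketing of the simulated curve). The stimulus default is
sinusoidal at 4 Hz; a square-wave mode exists for completeness but its
odd harmonics make the closed form above inexact.

A note on the fine-wavelength regime: wavelengths below Δϕ alias again —
λ = 3° with Δϕ = 5° lies in the second inverted lobe (2.5°, 3.33°), so
the sign pattern over {3, 7.5, 20}° is (−, −, +) by the closed form.

## Synthetic data: what it emulates, and what not

The generator's defaults are the study conditions the analyses are tested
under: 100 Hz sampling, additive Gaussian noise of 0.02° on positions and
of 2 intensity units on pixels, seven Gaussian dots (spacing 12 px,
σ = 2 px) on a 128² frame, OKR gain 0.2 against a 15 °/s grating
(initial velocity ≈ 3 °/s), 2° per-eye vergence pulses of 1 s at wheel
crossings, bar sweeps at 21 °/s sampled every 0.21° (10-ms voltage bins),
flash-grid receptive fields with σ = 21.2° (≈50° FWHM), and gap-crossing
minima at −1.0 vs −1.4 mm with 0.3 mm SD over 20 flies × 10 crosses.
Saccades are minimum-jerk steps; with the default 30-ms rise the peak
velocity is 62.5·A °/s (main-sequence exponent 1, near the observed
regime of >140 °/s counter-saccades at a few degrees and ~600 °/s maximal
saccades); other (k, b) are realized by scaling the waveform duration
T = 1.875·A^(1−b)/k. Crossing-time wheel jitter is encoder-scale (0.02°)
so the generated ground-truth times agree with the noisy trace's actual
threshold crossings to within a sample.

Deliberately not emulated: optics of pseudopupil image formation (dots
are ideal Gaussians; real frames have glare, vignetting and occasional
dot merging), trial-to-trial response variability beyond additive white
noise (no drift, bursting or adaptation in voltage records), torsional or
head movements, and any dependence of saccade kinematics on direction or
eye. Passing recovery tests on this generator therefore demonstrates the
correctness and calibration of the analysis chain, not robustness to
every artifact of real recordings; the detection thresholds and fill
policies exist precisely for the conditions the generator does not
produce.

## Numerical choices and degenerate inputs

Thresholding uses medians/MADs throughout for outlier robustness. The
correlation peak refinement clamps the parabolic step to one grid cell.
Flat traces return zero initial velocity rather than a fit error; an
all-equal-amplitude saccade catalog raises a degenerate-input error in
the main-sequence fit (zero log-amplitude variance). Wheel thresholds
outside the trace range return an empty event list. All generators take
a single integer seed and are bit-reproducible; the pipeline report
embeds the resolved config and package version, and its comparable
payload excludes wall-clock metadata.

## Problem sizes used in the test suite

Tracking accuracy runs 600-frame stacks over 10 seeds; the saccade suite
uses eight 60-s trains (≈260 ground-truth events); the Welch power check
runs 100 seeded group pairs; the aliasing comparisons use a 12-receptor
array and ≥5 temporal periods per wavelength. These sizes keep the full
suite under a minute while leaving each statistical check comfortably
powered.
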