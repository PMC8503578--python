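# Methods

`ictalcoh` quantifies how much of a focal seizure's onset activity can be
recovered from scalp EEG, using simultaneous intracerebral (SEEG)
recordings as the within-brain reference. The chain is: synchronise the
two independently clocked amplifiers, cut a 30 s peri-onset epoch,
unmix the scalp channels with extended-infomax ICA, localise each
component with an equivalent current dipole (ECD), measure wavelet
coherence between components and SEEG bipolar channels against a
surrogate-calibrated significance threshold, and relate coherence to
dipole-contact geometry.

## Synthetic sessions

Because every stage must be testable against known ground truth, the
package ships a generator for simultaneous scalp/SEEG sessions.

**Head and forward models.** The head is a single homogeneous conducting
sphere (radius 90 mm, conductivity 0.33 S/m). Scalp potentials of a
current dipole use the closed-form Legendre series for an insulated
sphere — the infinite-medium multipole expansion with each degree-*n*
term amplified by (2n+1)/n; the series is summed to machine precision
(adaptive truncation, eccentricity capped at 0.95 R). Depth-contact
potentials use the infinite-homogeneous-medium dipole potential
V = p·d/(4πσ|d|³), adequate far from the skull. A single sphere rather
than a realistic boundary-element model is a deliberate trade: it is
analytic, exactly invertible in tests, and the qualitative
depth-visibility physics (surface RMS monotone in eccentricity,
extended patches fitting as deeper dipoles) carries over. What does
*not* carry over is the skull's spatial low-pass: point sources close
to the sphere surface produce sharper topographies than any real scalp
map. The generator therefore models the ictal source as an extended
patch (below), which is also the physiologically defensible choice.

**Sensors.** The scalp cap is a reduced 10–20 set (21 labels, template
positions radially projected onto the sphere; electrodes can be dropped
to mimic positions blocked by implantation anchors). SEEG electrodes
are straight shafts with 3.5 mm centre-to-centre contact pitch, up to 18
contacts per shaft. The standard depth scenario places one 16-contact
shaft along the radial line through the source, so contacts straddle
the generator at any depth (the tip shifts by half a pitch when a
contact would otherwise sit on the generator itself), plus two remote
12-contact shafts sampling regions away from the focus — real
implantations carry many electrodes, and the remote pairs anchor the
unremarkable end of the Ns distribution that the outlier rule needs.

**Sources.** The ictal generator is a patch: 13 sub-dipoles on the
source's depth shell (centre plus two rings, total moment preserved,
orientations parallel-transported), default extent 18 mm — roughly the
10 cm² of synchronous cortex regarded as the minimum for
scalp-recordable ictal rhythms. Waveform patterns: `lvfa`
(low-voltage fast activity, narrowband 30–80 Hz with an onset ramp, a
slowly varying envelope and a small phase random walk),
`polyspike_burst` (recurring 3–6-spike bursts at ~20 Hz intra-burst
rate), `repetitive_discharge` (sharp transients at exactly the
characteristic rate, default ~10 Hz), and `preictal_spikes` (sporadic
spikes throughout the record — the one pattern active before onset).
The standard scenario emits LVFA (40 Hz, 75 nA·m) *plus* preictal
spikes (0.8× moment) from the same patch: seizure-onset cortex that
also spikes interictally is the typical clinical picture, and it is why
the analysis epoch keeps 20 s of preictal data.

**Background and noise.** 200 background sources (11 nA·m each, 1/f
amplitude spectra, uniform in the inner 0.85 R) project to both
modalities, giving ~10 µV RMS scalp background in the 5–100 Hz band and
depth-contact background of a few to tens of µV. A *high-rank*
background matters: with few background generators, a scalp component
and a depth pair that both look at the same region share one dominant
source and show broadband coherence far above the chance level, which
real recordings do not. EMG (20–100 Hz band noise, 4 µV RMS) is added
to temporal-row scalp channels only — the depth stream, referenced
intracranially, is EMG-free. Both streams get 2 µV white sensor noise.
With these settings the 40 Hz patch adds ~30% extra variance on the
nearest scalp channels at 0.85 R (visible in a time–frequency display,
not in raw traces) and is buried at 0.45 R, while the SEEG seizure
signature at the SOZ contacts is one order of magnitude above its
background — the regime the method is designed for.

**Dual-clock acquisition.** Both streams carry a trigger channel
(pulses at every `trigger_interval`, first pulse one sample into the
record so its rising edge is recordable) and a 50 Hz reference sine.
The SEEG stream may start `imposed_lag` samples late (fractional
allowed) and runs at fs/(1+drift·1e-6); its neural channels are
cubic-spline resampled from a padded master grid, while triggers and
sine are evaluated analytically at the drifted sample times. Records
span [0, duration] inclusive, so at the default lag 0 both streams
carry floor(duration/interval)+1 pulses; a late-started stream misses
leading pulses, which the alignment tolerates.

## Alignment

Trigger rising edges are matched across streams allowing for missed
leading pulses; among equally consistent pairings the smallest median
offset wins (inter-amplifier lags are far below the trigger interval).
The coarse lag is the median integer offset. Each trigger's lag is then
refined on a 2 s window of the reference sine: cross-correlation
restricted to ± half a sine period around the trigger estimate,
three-point parabolic peak interpolation, then an analytic polish that
fits A·cos(ωs)+B·sin(ωs) through the three points (the correlation of
two windowed sines is locally sinusoidal; the bare parabola is biased
by ~0.1 sample at 10 samples/cycle). Drift is the slope of per-trigger
lag versus time; the reported `fine_lag` is the intercept mapped back
to master-clock samples (×(1+drift)). Merging resamples stream b onto
stream a's clock through the piecewise-linear time map defined by the
aligned trigger pairs, keeping the overlap only. On synthetic sessions
a 1234.25-sample lag with 100 ppm drift is recovered to ~1e-4 samples;
the limiting factor on real data would be sine SNR and trigger jitter,
not the estimator.

## Preprocessing

Band-pass 5–100 Hz by a Hamming windowed-sinc FIR with 2 Hz transition
width; the tap count follows the Hamming design rule (≈3.3/Δf·fs,
odd), −6 dB cutoffs at band edge ∓ half transition, and the symmetric
kernel is applied with centred convolution — exactly zero phase.
SEEG channels get the same band by default (comparability across
modalities; a flag disables it). SEEG is re-referenced to consecutive
same-shaft bipolar pairs ("V01-V02"), never across shafts; each pair's
geometric midpoint is kept for the spatial analysis. The analysis epoch
is 20 s before to 10 s after the seizure-onset marker.

## ICA and screening

Extended-infomax ICA runs on PCA-whitened scalp epochs (dimension
reduced to the numerical rank with a warning if needed); activations
are rescaled to unit variance with the amplitude pushed into the mixing
columns. The stopping tolerance is 1e-7 weight change — the reference
implementation's criterion; iterating to 1e-12 costs an order of
magnitude more time for no measurable change in recovery.

Components with an outlier electrode are discarded: the criterion is a
leave-one-out Z on absolute topography weights, max over electrodes,
threshold 10. Leave-one-out is the only reading under which the
threshold can fire at all — the all-in Z is bounded by (n−1)/√n < 6
for caps of ≤ 37 electrodes. A standard-normal topography over 30
electrodes is flagged with probability well below 1e-3. Note a caveat
of the spherical model: without a skull layer, a genuine but very
superficial point source can produce a single-electrode-dominated map
and trip this screen; the extended-patch source model keeps genuine
maps broad, and the selection API treats the screen as advisory for the
expert-override path (below).

Remaining components are ranked by dipole goodness of fit (GOF)
descending, ties broken by component variance; only GOF > 90% counts as
a candidate brain source. The final choice of "the" ictal component is
an expert step in practice. The pipeline implements three modes:
`auto` (top-ranked candidate), an explicit integer override, and
`max_sna_soz` (used throughout the tests: the component with maximal
SNA against the known SOZ bipolar pair — the ground-truth-informed
stand-in for the expert). In the override modes every component stays
on the table and the selected one is dipole-fitted even if screened,
since screening exists to prune the automatic suggestion list.

## Dipole fitting

A single ECD is fitted to each average-referenced topography in the
sphere: position by bounded nonlinear least squares in spherical
coordinates (eccentricity ≤ 0.95 to avoid the surface singularity),
moment by closed-form linear least squares at each candidate position,
10 uniform-in-sphere restarts by default. GOF = 100·(1 − residual
power / topography power). Noiseless forward topographies at 0.6 R are
recovered to < 0.1 mm with GOF > 99.9%; 5% RMS sensor noise moves the
position by a few mm. With ~20 electrodes the inverse problem is
shallow: near-equivalent minima can differ by tens of mm for extended
or noisy patterns, which is the honest reason localisation error, not
GOF, is the quantity tracked downstream.

## Wavelet coherence and its statistics

The time–frequency transform uses analytic Morlet wavelets with
oscillation parameter ξ = 7 on a log grid of 10 voices per octave from
5 to 100 Hz (44 frequencies); the wavelet width is 2σ = ξ/(πf). Kernels
are normalised so a unit-amplitude sine gives |coefficient| = 1.
A display-only per-frequency Z-score (baseline = lowest-20%-amplitude
points of the row) is provided for visual inspection and never feeds
the statistics.

Coherence is C = |S(XY*)|² / (S|X|²·S|Y|²) with S a rectangular
smoother spanning 20σ(f) in time (per frequency row, truncated and
renormalised at the record edges) and 10 voice rows in frequency
(truncated at the grid boundary). Points whose time window overruns the
record are edge-masked and excluded from all counts; the mask is wider
at lower frequencies. The optimised implementation (FFT convolution +
cumulative-sum smoothing) is held to a naive direct-convolution,
explicit-window oracle to 1e-6 on short inputs.

Significance is empirical: per frequency, the 95% quantile of non-edge
coherence pooled over 200 independent two-channel Gaussian white-noise
realizations of the same length and parameters. Validation on fresh
noise holds the per-frequency false-positive rate at 0.05 ± 0.01 (the
residual wiggle is the Monte-Carlo error of a 200-realization
quantile). Thresholds from 1/f ("pink") surrogates differ by well under
20% relative — the choice of surrogate colour is not critical. For each
(component, SEEG-pair) plane the count of significant non-edge points
is Ns and the significant normalized area SNA = Ns/total. Planes that
stand out are flagged by the robust rule Ns > median + 5·(Q₀.₇₅−Q₀.₂₅)
(linear-interpolation quantiles, strict inequality).

## Spatial statistics

Distances are Euclidean in the common mm frame; distances to a bipolar
pair use the pair midpoint. The SOZ geometric centre is the unweighted
mean of its contact coordinates; d_SOZ is the dipole's distance to it.
Coherence–distance association is reported as Pearson r and Spearman ρ
with two-sided p-values; LOWESS (tricube local linear, span 0.7,
display layer only) smooths the scatter.

## What the synthetic experiments show — and what they do not

On sessions with the generator at eccentricities 0.45–0.85 R (five
seeds each, 256 Hz / 36 s, epoch 30 s), the median SNA between the
selected component and the true SOZ pair rises monotonically with
eccentricity (≈0.14 at 0.45 R to ≈0.25 at 0.85 R, against a chance
floor of ≈0.05), the dipole-to-SOZ error falls from ~30–40 mm to
~10 mm, and max-pair SNA is negatively rank-correlated with the
dipole-to-pair distance (ρ ≈ −0.6) — the depth-visibility effect the
method exists to exploit. These are *qualitative* reproductions: the
sphere has no skull, the background is stationary and Gaussian by
construction, there are no movement or electrode-popping artifacts, no
physiological rhythms (alpha, spindles), and SEEG coverage always
includes a shaft aimed straight at the source. Passing these tests
shows the estimators and
the pipeline logic are correct under known ground truth; it does not
certify clinical performance on real recordings.

## Numerical and scale choices

Desk-scale defaults (256–512 Hz, 30–60 s sessions, triggers every
10 s) keep a full test run in minutes on one CPU; all rates and
durations are configurable, and the statistical procedures
(200-realization calibration, per-frequency quantiles, 30 s epochs)
follow the analysis conventions stated above regardless of scale.
Determinism: every stochastic step takes an explicit seed, and a
pipeline rerun with the same config writes byte-identical tables (the
manifest records the config hash and all seeds). Degenerate inputs are
handled explicitly: zero-variance Z-score baselines are floored with a
warning, α ≥ 1 yields zero thresholds, records too short for the
smoothing window at the lowest frequency are rejected, and an all-zero
topography refuses to fit.
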