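# Methods

This note records the model assumptions, the numerical choices and the
design decisions behind `spikefield`, and what the synthetic experiments do
and do not demonstrate.

## Kernels on multiscale windows

**Windows.** The atomic input is an analysis window pairing every unit's
spike times (support `(0, T_s]`, default `T_s = 9` ms) with every LFP
channel's samples (support `(0, T_x]`, default `T_x = 20` ms).  Windows are
causal and right-aligned: the window "at time t" covers `(t − T, t]`, and
LFP sample `i` represents the interval ending at `(i + 1)·τ`.  The default
window lengths are the timescales at which each modality's autocorrelation
falls into the zero confidence band in the modeled experiment; the
estimator that produces such values is part of the package
(`estimate_window_length`).

**Spike kernel.** A windowed spike train is represented by its intensity
estimate: the event sequence convolved with a rectangular kernel of width
`smoothing_width` (default: the window length, honoring the requirement
that the width far exceed the interspike interval; this makes the estimate
a scaled cumulative spike count).  Two trains are compared with the
Gaussian-type (Schoenberg) kernel on these intensities.  Because the
smoothed intensities are piecewise constant, the squared-difference
integral is a finite sum of rectangle overlaps, evaluated in closed form
over `[0, T_s]` with rectangles truncated at the window edge — no gridding,
no tolerance.  An empty window maps to the zero intensity and is a valid
element.  `σ_s²` carries the units of that integral (1/ms).

**LFP kernel.** Same Gaussian form on sampled waveforms, with the integral
approximated by a left Riemann sum scaled by the sample period, so `σ_x²`
has time-integral units and values are stable under resampling.

**Composition.** Units and channels combine by direct sums, matched by
index.  By default each sum is divided by its channel count so that
self-similarity is exactly 1 and the RKHS distance reduces to
`sqrt(2 − 2κ)`; the unnormalized literal sum is a flag
(`normalize_channels=False`).  Modalities combine by a tensor product
(default) or a direct sum.  Products and sums of positive-definite kernels
are positive definite; the test suite checks Gram matrices of random
windows for eigenvalues above −1e−10 under every rule.

**Kernel sizes.** The data-driven kernel size follows the
average-pairwise-distance rule: `σ²` is the mean over unordered training
pairs (and over units/channels) of the *pre-exponential* squared distance.
Measuring the distances before exponentiation resolves the circularity of
defining a kernel scale through distances in the very RKHS the scale
parameterizes.

**Floating point.** All kernel work is double precision; square-root
arguments are clipped at zero; Gram matrices are symmetrized exactly by
averaging with their transpose.

## Q-KLMS

The learner keeps a shared dictionary of center windows and one coefficient
column per center across all outputs.  Each update computes the prediction
error `e = d − y`, then either adds `η·e` to the nearest center's column
(if the RKHS distance is within the quantization size `ε`) or appends a new
center with column `η·e`.  Defaults: `η = 0.5` (stable below
1/self-similarity = 1 for normalized kernels), `ε = 0` so that only exact
repeats merge — with distinct inputs the algorithm is plain KLMS, which the
suite verifies bit-for-bit against an independent reference.  Nearest-center
search is an exhaustive scan with ties broken toward the lowest index, so
runs replay deterministically.  Training presents samples in data order
(no shuffling) and precomputes the pairwise kernel table once, making each
step a vector operation; repeated epochs re-visit the same samples, so the
dictionary stops growing after the first pass while the coefficients keep
converging.

## Decoding

Targets are read from the stimulus trace at each window's right edge by
nearest-sample lookup (matching the 5 ms stimulus discretization; no
interpolation).  For inverse modeling the target is lagged: the window at
`t` is paired with the stimulation at `t − Δ`, so each window contains the
response the paired stimulus evoked.  Accuracy is the normalized mean
squared error `Σ(y − d)² / Σ(d − d̄)²` (0 = perfect, 1 = predicting the
mean); the normalization is by the target's variance so values are
comparable across channels.  A constant target with zero residual scores 0;
a constant target with nonzero residual is an error.  Spike-response
similarity uses Pearson correlation of 5 ms binned counts, per unit and
averaged over units (degenerate units are skipped).

The window-length criterion implements the cumulative-SE confidence band:
`±2·sqrt((1 + 2Σ_{i<h} ρ̂_i²)/N)`; the estimate is the smallest lag from
which the sample autocorrelation stays inside the band through `max_lag`.
For an AR(1) signal with coefficient 0.9 and N = 10⁴ the band is ≈ ±0.062
and the true crossing sits near lag 26; the estimator's sampling
distribution over seeds spans roughly 23–50 ms.  (The plain `±2/√N` band,
which omits the cumulative term, would put the crossing near lag 37; the
cumulative form is the one the confidence-bound operator implements, and
the two should not be mixed when interpreting the estimates.)

## Adaptive inverse control

The inverse model is a Q-KLMS decoder from neural windows to per-channel
stimulation amplitude, trained on the response to randomly patterned
microstimulation (exponential inter-pulse intervals, mean 100 ms; 8
channels × {10, 20, 30} µA).  The controller starts as a copy; its
dictionary is then frozen and only its coefficients adapt, each update
adding `η_ctrl·ε` (default `η_ctrl = 0.01`) to the column of the center the
delay-aligned target window quantizes onto (nearest center if none is
within ε — synthetic targets do not repeat exactly).

**Delay and emission timing.** The modeling delay defaults to
`Δ = max(T_s, T_x)` so the controller input window fully covers the
response it must anticipate.  Generation is offline (the whole target is
available), so the stimulation for the window ending at `t` is emitted at
`t − Δ` plus one grid step (5 ms): this emission-phase calibration centers
the evoked response on the target's, verified on noise-free renders where
the response cross-correlogram moves exactly one 5 ms bin per 5 ms of
offset.

**Output gain.** Kernel regression attenuates the amplitude scale of its
training targets, so raw controller outputs peak at a few µA; delivered as
is, every pulse would clip to the 8 µA range floor and the response would
lose amplitude modulation.  The controller therefore maps the 95th
percentile of its positive raw output onto the top of the deliverable
range before constraint processing (a stimulator gain calibration,
recomputed each epoch so adaptation cannot push pulses out of range).

**Inverse model during control.** By default the pretrained inverse model
is held fixed while it filters the error, matching offline open-loop
generation; this keeps the filtered-error trajectory a stationary measure
of controller progress.  Online inverse updates
(`update_inverse=True`) are implemented, but at this problem scale they
make the metric non-stationary — the inverse is initially blind to
touch-evoked windows, so the error *grows* as the inverse learns to read
them, and the loop settles into a degenerate quiet solution (suppressing
all stimulation minimizes an error the inverse cannot see).

**Constraints.** Deliverable sequences satisfy: per-channel inter-pulse
interval ≥ 10 ms; at most one channel pulsing at any time point (ties to
the lowest channel index); amplitudes in [8, 30] µA.  Candidate pulses are
strictly positive local maxima of the raw trace, thinned by greedy
non-maximum suppression in descending amplitude order — a deterministic
equivalent of flat-kernel mode seeking on 10 ms neighborhoods.  Surviving
candidates below 8 µA are raised to the floor (the range describes what
the stimulator delivers, not a rejection rule); non-positive candidates
are discarded.  An independent audit function re-checks every emitted
sequence.

## The synthetic plant

The generator emulates the modeled sensory-stimulation experiment at desk
scale: 10 units, 4 LFP channels, 8 stimulation channels, baseline 5
spikes/s.  Touches are non-overlapping 100 ms raised-cosine force pulses at
Poisson times (default 0.5/s, amplitudes jittered ±30%); microstimulation
is exponentially spaced pulses (mean 100 ms) on random channels at
{10, 20, 30} µA.  Each stimulation channel drives a Gaussian neighborhood
of units (peak gain 12 spikes/s per µA); every evoked spiking component —
onset bump (8 ms), pulse response and the touch-sustained term — carries
the same 3 ms conduction latency (plus the bump's 4 ms group delay for the
sustained term), so controlled and natural responses are mutually
time-consistent.  Spikes are drawn by Lewis–Shedler thinning against the
piecewise-linear intensity on a 1 ms grid; LFPs are the stimulus drive
convolved with per-channel damped sinusoids (18–36 Hz, 25 ms decay) plus
white Gaussian noise (sd 8).  All randomness flows from one seed through
named substreams (stimulus / spikes / noise).

The defaults are calibrated so the modalities are complementary the way the
modeled recordings were: the sustained term (scale 1.5 relative to the
onset peak) gives spikes real but sparse stimulus information, and the LFP
noise keeps the LFP decoder robust but imperfect.  With these settings the
20-seed median test NMSEs order as product ≈ 0.5 < LFP ≈ 0.66 < spikes
≈ 0.9.  What passing synthetic experiments shows is that the pipeline
extracts and fuses the information the generator encodes; it does not show
robustness to real-data phenomena the generator omits — electrode drift,
correlated (non-Poisson) spiking, volume-conducted LFP mixing, stimulation
artifacts, or nonlinear stimulation-response saturation (a tanh-saturating
variant exists but is off by default).

## Experiment protocols

`decoder_comparison_trial` simulates one touch session (8 s train / 4 s
test), resolves kernel sizes on the training windows, and trains the three
decoders (product, spike-only, LFP-only) on shared per-modality Gram
blocks so they see numerically identical factor kernels.  Touch arrivals
are Poisson, so the trial deterministically redraws from sub-seeds until
both splits actually contain touches (decoding error is undefined on a
constant target).

`virtual_touch_trial` trains the inverse model on 6 s of random
microstimulation, builds two 4 s touch targets sharing identical touch
times but exciting different sites (different stimulation-channel
receptive fields), controls toward site A for 5 epochs, and scores the
final response by (i) the filtered-error trajectory, (ii) binned
correlation against the matched vs the mismatched target, and (iii) the
cross-correlogram of *event-locked average* responses (pooled-unit PSTH
and channel-averaged LFP, 5 ms bins).  Event-locked averaging is essential
for the timing statistic: whole-recording correlograms of 100 ms responses
have a flat top whose single-bin argmax is noise-determined at any
realistic trial count, while the touch-triggered averages retain the
deterministic alignment at high signal-to-noise.  Even so, the location of
the median correlogram's maximum carries about one bin (5 ms) of sampling
variability across independent 20-trial batches, the residual of a sub-bin
systematic offset interacting with trial noise.  Problem sizes (6 s + 4 s,
20 trials) keep a full experiment battery in minutes on one CPU while
leaving every qualitative effect measurable.

## Known limitations

* The inverse decoding of sparse single-bin stimulation targets is weak in
  absolute terms (NMSE near 1): the kernel regression smears single-bin
  pulses.  The controller compensates through the output-gain calibration
  and the constraint stage's maxima selection, which need only the
  *relative* structure of the raw output.
* Controller adaptation assumes the plant is stationary across epochs;
  plant drift is not modeled.
* Channel attribution within a receptive-field neighborhood is ambiguous
  (adjacent stimulation channels drive nearly collinear responses), so the
  virtual touch may distribute pulses over neighboring channels of the
  correct region.
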