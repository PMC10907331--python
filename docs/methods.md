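# Model and methods

This note documents the modelling choices behind `ecapsim`: what the
simulation assumes, which parameters matter, how the genuinely open
design points were settled, and what the simulated conditions do and do
not say about real eCAP recordings.

## The 2-D cochlea

The cochlear duct is unrolled onto a straight longitudinal axis, base at
0 mm, apex at 33.9 mm (the average human cochlear length; 0–900° in
angular terms). Auditory nerve fibers are modelled as independent,
identical, equidistant point sites on the neural axis at height 0 — each
fiber stands for one site of excitation, not a full multi-compartment
neuron. Neural survival is represented purely by fiber count (500, 1000,
1500, 2000 across the default grid); density is uniform because the
studied effects do not depend on the natural apex-base density gradient.

The 12 electrode contacts are point sources on the lateral wall, 2 mm
apart, contact #1 most apical at 24 mm from the base (so the stimulating
contact #6 sits mid-cochlea at 14 mm). The insertion depth is not pinned
by any published coordinate table, so it is configurable, and per-contact
characteristic frequencies can be supplied instead and are mapped through
the inverse Greenwood function (A = 165.4, a = 2.1, k = 0.88; highest
frequencies at the base).

The electrode-neuron distance is set by two cubic scala-tympani height
profiles standing for the 10 % ("short") and 90 % ("long") quantiles of
anatomical height variation. The published quantile curves are shown only
graphically anywhere, so the package ships its own defaults:

```
short: h(x) = 0.75 − 0.018 x + 3.2e-4 x² − 2.5e-6 x³   (0.41–0.75 mm)
long:  h(x) = 1.33 − 0.020 x + 3.2e-4 x² − 2.5e-6 x³   (0.85–1.33 mm)
```

Both decrease monotonically base → apex within the anatomically plausible
0.4–1.4 mm band, and their difference is nearly constant (~0.55 mm)
across the array, so conclusions that rest on the *difference* between
profiles are insensitive to the exact coefficients. The coefficients used
are recorded in every output's metadata.

Field spread is isotropic 2 dB/mm amplitude attenuation in both
directions (stimulating contact → fiber, fiber → recording contact).
Asymmetric spread, cross-turn paths, electrode orientation/size and
perimodiolar geometries are out of scope.

## Single-fiber model

Each fiber low-pass filters the attenuated stimulus current with a
first-order recursive filter ("leaky integrator"),
`v[n] = a·v[n−1] + b0·I[n] + b1·I[n−1]`, `a = exp(−dt/τ_m)`, with the
published gain coefficients `b0 = b1 = 602.6e-6` (the tripled values;
`FiberParams.original()` restores 200.9e-6) defined at 1 µs sampling and
rescaled with `dt` so behaviour is step-size independent. The membrane
time constant τ_m defaults to 100 µs.

Spiking is stochastic-threshold: per pulse each polarity's threshold is
drawn from a normal law with SD δ = 9.2 µV (the doubled published value)
about its current effective mean, floored at 5 % of the resting mean.
Spike initiation follows a critical-period rule: a threshold crossing
commits to a spike only if the membrane stays above the drawn threshold
for `critical_period` (default 15 µs). This one rule produces the IPG
effect: with a 2.1 µs gap the charge-balancing phase repolarizes the
membrane almost immediately after the leading phase, cancelling
crossings that occur late in the phase, whereas a 30 µs gap gives them
time to complete — equivalent to lowering the commit level by ~0.9 dB of
charge. An alternative considered — cancelling a provisional spike
whenever the membrane falls below threshold before the full observable
latency (hundreds of µs) elapses — would have annulled essentially every
spike, since the integrator decays with τ_m ≪ latency; the critical
period is the physiologically meaningful horizon for abolishing
action-potential initiation.

Two unit bookkeeping constants are not published anywhere: the mean
resting threshold and the unit of the filter's input. They are exposed as
`mean_threshold` (150 µV) and `input_scale` (18.77, filter input units
per µA). The pair was fixed once, as follows: the relative threshold
spread δ/mean = 9.2/150 ≈ 6 % was chosen to match typical relative-spread
values for electrically stimulated auditory nerve fibers, and
`input_scale` was then calibrated by `scripts/calibrate.py` so the full
model's mean fitted eCAP threshold at the contacts adjacent to the
stimulating one lands on the clinically expected 10.01 ± 3.31 nC range —
the same criterion by which the gain/SD modifications of the single-fiber
model are motivated in the first place.

Threshold dynamics (all config-exposed; defaults chosen at cat-fiber
scales): after a spike, both polarities' thresholds rise by a refractory
increment (300 µV, τ = 0.7 ms; an absolute refractory period of 330 µs
blocks spiking outright) and by a slow adaptation increment (0.5 µV,
τ = 50 ms) that accumulates under sustained 80 Hz spiking;
a subthreshold pulse whose peak drive reaches half the threshold lowers
*only the stimulated polarity's* threshold by a facilitation decrement
(1.5 µV, τ = 1.5 ms). At the 12.5 ms pulse spacing of the fine-grain
paradigm, refractoriness and facilitation have essentially decayed
between pulses; adaptation is the one carrier of cross-pulse history.
Anodic and cathodic thresholds are statistically identical — no
polarity-dependent sensitivity or latency differences are introduced.

Observable spike latency is a monotone map of the suprathreshold margin
m = peak-drive/threshold − 1: `lat = 370 + 100·exp(−m/0.5)` µs from the
crossing. The range was chosen so that the compound N1 trough (which
precedes the spike time by 180 µs given the unitary-response timing)
falls inside the standard N1 search window for the whole amplitude
range; the decreasing shape realises the expected latency-vs-amplitude
behaviour and is a model-internal choice — only its monotonicity and
range are meaningful.

## Recording

Each spike contributes the biphasic unitary response
`U(t) = (u_x/∂_x²)(t−t₀)·exp(0.5 − (t−t₀)²/(2∂_x²))` (negative branch
u_N = 12 µV, ∂_N = 0.12 ms for t < t₀; positive branch u_P = 45 µV,
∂_P = 0.15 ms), support −0.6 to 1.1 ms, t₀ = −60 µs. (The source of
these constants prints t₀ in ms; −60 ms is irreconcilable with the
stated support and is read as −60 µs, configurable.) Contributions are
summed per recording contact with 2 dB/mm attenuation; spike times are
binned to the 1 µs sample grid. The recording window is 1.7 ms starting
`d_R = 145 µs + (IPG − 2.1 µs)` after pulse onset; N1 is the minimum in
the first 300 µs of the window, P2 the maximum within 400 µs after N1.
The two traces of a polarity pair are averaged before peak extraction.
Zero-amplitude-template subtraction is omitted on purpose: the model has
no recording-system signature to remove. Optional additive Gaussian
recording noise (off by default) is available to emulate the
measurement-noise floor that makes log-scale AGFs ragged at low
amplitudes.

## Simulated conditions

The default grid crosses fiber count {500, 1000, 1500, 2000} × height
profile {short, long} × IPG {2.1, 30 µs}; contact #6 stimulates and all
11 other contacts record simultaneously. The fine-grain paradigm ramps
charge 0 → 30 nC at 1.5 nC/s and 80 Hz with alternating leading
polarity. The stated ramp and the statement that both polarities are
presented *at each amplitude* cannot both hold exactly; the default
schedule increments charge per polarity *pair* (0.0375 nC/pair), so the
pair shares one charge and its two traces can be averaged; a strict
per-slot mode is also available. For grid-scale runs the default is a
coarse charge grid of 0.25 nC steps (121 levels × 2 polarities per
condition) — the AGF and all fitted summaries are insensitive to grid
density at this scale and the cost drops ~13×; the mode is recorded in
the metadata. One sweep per condition is simulated (the repetition count
is configurable). Matched conditions differing only in IPG or height
profile share their threshold-draw stream (common random numbers), so
paired quantities — IPG effects, threshold ratios between profiles — are
not blurred by between-sweep sampling noise; marginal statistics are
unaffected.

Simulation time step: 1 µs. It resolves the 40 µs phases and the 30 µs
gap exactly; the 2.1 µs gap is realised as 2 µs and the realised value is
logged. A full 16-condition grid takes ~15 s on one CPU.

## Analysis

Sigmoid fits use Levenberg-Marquardt from the initial guess y₀ = min(y),
B = max − min, C = charge at half-maximum, D = 4·(max gradient)/B, z = 1;
if LM fails or leaves the admissible region (B, D, z > 0), a bounded
trust-region fit is tried, and fits at bounds or non-converged are
flagged and excluded from the metrics. Degenerate AGFs (flat, or fewer
than 6 points) are flagged likewise. The closed forms for x₀, θ and
x_THR are mutually consistent with the tangent-baseline geometry (the
tangent through (x₀, y(x₀)) with slope θ meets y = y₀ exactly at x_THR);
the test suite asserts this identity numerically at 1e-6.

The IPG-offset's "applicable eCAP range" is chosen automatically (the
published procedure selected it by hand): both fitted, baseline-corrected
AGFs are expressed in dB (amplitude re 1 µV vs charge re 1 nC), and the
range grows contiguously from the −6 dB (half-maximum) point of each
curve while the local log-log slope stays within 25 % of its value there,
excluding the exponential foot and the saturating top; the ranges of the
two curves are intersected and the offset is the mean horizontal
difference over 50 amplitude levels in that range. A manual range
override reproduces the hand-picked procedure.

The threshold-increase rate between the height profiles is the mean over
recording contacts of 20·log₁₀(x_THR_long / x_THR_short), divided by the
mean electrode-neuron distance difference between the profiles (mean over
the 12 contacts of the contact-to-nearest-fiber distance difference,
0.554 mm for the default profiles).

## What the simulation shows — and what it does not

The model reproduces the qualitative dependence pattern: AGF slopes fall
with fewer fibers and with stimulating-recording distance; thresholds are
insensitive to both but rise with electrode-neuron distance at ~2 dB/mm
and fall when the IPG is prolonged; the absolute IPG effect scales with
fiber count while the relative effect and the IPG offset are flat in all
varied factors. These are statements about this idealised model —
identical healthy fibers, uniform density, isotropic spread, no
measurement noise or artifact — not about any individual patient's
cochlea; dead regions, gradual demyelination, polarity asymmetries and
electrode-array variants are explicitly outside scope.

One quantitative nuance is worth knowing. The pure attenuation mechanism
would put the threshold-increase rate at exactly the configured 2 dB/mm,
and the reported reference value is 2.1 dB/mm; the simulation measures
~1.83 ± 0.05 dB/mm. The shortfall is geometric: a fiber at longitudinal
offset x from the stimulating contact sees a profile distance difference
√(x² + h_long²) − √(x² + h_short²), which is smaller than h_long −
h_short, and the sigmoid-fit threshold integrates over such off-axis
fibers. Sharpening the single-fiber threshold spread moves the rate
toward 2; no parameter was adjusted beyond the calibration described
above.

Other known limitations: the unitary response is identical for all
fibers (no latency- or place-dependent waveform changes); spike times are
binned to the sample grid; the per-fiber threshold streams are drawn
jointly from one per-condition generator rather than per-fiber
generators; and the latency map, critical period, τ_m and the threshold-
dynamics constants are phenomenological placeholders wherever no
published value exists — all are config-exposed rather than asserted.
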