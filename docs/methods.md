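# Methods

This note documents the models implemented in `retinfo`, the assumptions of
the synthetic-data generator, and the numerical choices made where the
underlying procedures leave freedom. Nothing here states a result that the
test suite or `scripts/acceptance.py` does not itself compute.

## The scientific setting

Bipolar cells carry all visual information from photoreceptors into the
inner retina and release glutamate in integer numbers of vesicles
("quanta"), often several at once (multivesicular release, MVR). The
reporter iGluSnFR converts each release event into a fluorescence transient
whose amplitude is an integer multiple of a unitary event. At the
behavioral level, the optomotor response (OMR) of a free-swimming larva is
built from discrete swim bouts; visual drive modulates the *frequency* of
bouts, not the angle turned per bout. The package quantifies both levels
with a common currency — contrast-response functions and Shannon
information — and relates them: across retinal states, the rate at which
synapses transmit information about contrast predicts the contrast gain of
the behavior (a 4-fold change in information rate against a 2.4-fold change
in gain on the default cohort), while the efficiency of transmission in
bits per vesicle falls with release rate as a power law (`E = 0.49·R^−0.74`
in the morning regime, `E = 2.18·R^−1.12` in the afternoon).

## Synthetic-data generator

The generator is first-class, tested code; it defines the study conditions
on which every recovery claim is made.

**Release model.** Spontaneous release is a homogeneous Poisson process of
*events* at rate `spont_rate / m̄` where `m̄` is the mean event size under
the MVR weight vector, so the vesicle rate equals `spont_rate` (3.6 /s in
the morning regime, 0.8 /s in the afternoon). Evoked release is
cycle-locked: per 5 Hz stimulus cycle the number of events is Poisson with
mean `λ(C)/m̄`, where `λ(C) = evoked_max · Hill(C)/Hill(100)` — i.e.
`evoked_max` is the expected vesicles per cycle *at 100% contrast* (2.7
morning, 4.3 afternoon), and the contrast dependence follows the regime's
Hill curve (morning h = 1.6, C₁/₂ = 45%; afternoon h = 1.5, C₁/₂ = 35%).
All evoked events sit at one preferred phase (a quarter cycle), each
jittered by a Gaussian of SD 10 ms; the literature reports phase-locked
release without giving a phase distribution, so a single jittered phase is
the minimal model. Event sizes are drawn i.i.d. from a truncated geometric
distribution over 1–5 quanta (ratio 0.45, mean ≈ 1.72 vesicles/event); the
MVR size law is not published, so this is a configurable stand-in.

**Rendering.** Each event contributes `quanta × quantal_dff` (default
0.4 ΔF/F₀ per vesicle) convolved with the peak-normalised reporter kernel,
placed on a spatial Gaussian (default: one active zone, σ = 1.2 µm, on a
48-pixel, 0.25 µm/pixel line scanned at 1 kHz). The resting brightness
shares the spatial profile; the whole signal bleaches mono-exponentially
(τ = 300 s — the original analyses only state that signals were
bleach-corrected, so a single slow exponential is assumed) and per-pixel
Gaussian noise of SD `noise_sd × F₀` is added. The default
`noise_sd = 0.08` puts the per-pixel quantal signal-to-noise ratio at 5.

**Behavior.** Bouts arrive as a Poisson process with rate
`base + (max − base)·Hill(C)` (shared behavioral Hill shape h = 1.9,
C₁/₂ = 31% for all conditions — the diurnal change is purely
multiplicative). A refractory dead time of one bout duration (200 ms)
prevents overlap; the drawn intensity is compensated by
`λ = r/(1 − r·T_dead)` so the *realized* bout rate equals the configured
one. Each bout is a forward scoot with probability 0.35, otherwise a turn
of magnitude |N(0.5, 0.15)| rad. Stimulus-evoked bouts turn with the drift
with probability `p_correct = 0.85`; spontaneous bouts are unbiased, so at
zero contrast left and right turns are equally probable. Heading integrates
a raised-cosine angular-velocity waveform; position advances at the bout
speed waveform (peak 20 mm/s) along the heading, with 10 µm Gaussian
tracking noise per frame at 150 Hz. Angle parameters are shared across all
six conditions.

**The six-condition cohort.** `configure_cohort()` returns morning and
afternoon controls plus four drug states (NK1R antagonist L733,060 and D1R
agonist ADTN in the morning; substance P and the D1R antagonist SCH23390 in
the afternoon). Behavioral gain multipliers are spaced linearly over
[1.0, 2.4] and the per-condition synaptic information-rate targets linearly
over [0.9, 3.6] bits/s (a 4-fold span; the published figure does not print
axis values, so the scale is a plausible choice and only the spans and the
linearity of the relation matter). Drug conditions also scale the synaptic
`evoked_max` relative to their diurnal control, so the synaptic simulations
differ across all six states.

**What the generator does not emulate:** photon shot noise with its
intensity dependence, scan or motion artefacts, reporter saturation and
dye-specific nonlinearity, eye movements, multi-fish occlusion, or
closed-loop visual feedback (fixed-contrast open-loop trials stand in for
the closed-loop assay). Passing recovery tests therefore demonstrates
correctness of the analysis chain under the stated statistical model, not
robustness to every artefact of real two-photon or tracking data.

## Quantal decomposition

1. **Spatial components.** The time-averaged spatial profile is fitted with
   a sum of Gaussians by nonlinear least squares; k grows while the BIC
   improves, capped at 4. Profiles whose excursion is below 3× the spatial
   noise SD (estimated from second differences) yield no components.
2. **Time series.** With component shapes fixed, the per-line amplitudes
   are one linear least-squares solve for all time points. A Gram-matrix
   condition number above 1e6 flags nearly coincident components, which are
   merged (amplitude-weighted) with a warning.
3. **ΔF/F₀.** An optional mono-exponential is fitted to a running
   20th-percentile baseline and divided out; F₀ is the mode of the
   corrected trace, from a Freedman–Diaconis histogram with parabolic
   refinement of the peak bin. Bleach correction precedes F₀ estimation
   (the original order is unstated; correcting first makes the mode
   well-defined on long recordings).
4. **Wiener deconvolution.** The trace is deconvolved in the frequency
   domain with the peak-normalised kernel, so a kernel-shaped transient of
   peak a returns an impulse of height (and integral) a. By default the
   noise power is the median spectral power above 100 Hz and the signal
   spectrum is the kernel spectrum scaled to the above-noise trace power;
   a scalar `snr_param` override gives the filter
   `H*/(|H|² + 1/snr)` (the plain inverse filter as snr → ∞).
5. **Event detection.** Threshold = baseline + 3.5 robust SDs (median
   absolute deviation of the deconvolved trace, insensitive to the events
   themselves). Supra-threshold runs separated by < 5 ms merge; runs
   containing several peaks (prominence ≥ threshold, spacing ≥ 5 ms) are
   split at the intervening minima. Event amplitude defaults to the summed
   excursion over the run ("area"): the Wiener filter preserves an
   impulse's integral even when regularisation spreads it over a few
   samples, and near-coincident events then sum their quanta correctly.
   A "peak" mode reproduces the exact impulse height in the noise-free
   inverse-filter limit.
6. **Quantal clustering.** Event amplitudes are fitted by EM with a
   Gaussian mixture whose means are k·q for k = 1..5 with shared relative
   width (σ_k = cv·k·q), 10 restarts seeded deterministically. The mixture
   is fitted on amplitudes ≥ 0.3× the median — sub-half-quantum threshold
   crossings otherwise drag q toward a subharmonic — and, after assignment,
   events below q/2 are discarded as noise crossings. With fewer than 20
   events the unitary size cannot be estimated and must be supplied; batch
   analyses therefore pool event amplitudes across synapses of one regime
   to estimate q once (`pipeline._decompose_batch`). An alternative
   constant-width mixture (σ_k = cv·q) is available; the proportional-width
   default recovers q more reliably on rendered data.

**Evoked vesicles per cycle** are counted in a ±35 ms phase window around
the circular-mean event phase, separating stimulus-locked release from
spontaneous events elsewhere in the cycle; the window passes > 99.9% of
evoked events at the default 10 ms jitter while admitting only ~7% of
spontaneous ones.

## Information metrics

Quantal series are binned at 20 ms so that bins almost always hold zero or
one event; should two events share a bin their quanta are summed and a
warning logged. The quanta alphabet is capped at 5 (larger merged events
clipped, logged). p(Q|S) is estimated by counting, the joint follows from
the chain rule with a uniform prior over the stimulus set, and I(S;Q) is
the plug-in estimate — no bias correction by default, matching the original
analyses; a shuffle-subtraction correction is available
(`shuffle_corrected_information`). Information rate is bits/bin ÷ 0.02 s
(bits per second, matching the pairing with vesicles per second in the
efficiency analysis); efficiency is rate ÷ release rate. The Fano factor
uses the sample (n−1) variance of vesicle counts per stimulus cycle.

## Behavior analysis

Speed is |Δposition|/Δt. A Gaussian fitted to the contiguous region around
the mode of the per-trial speed histogram gives the noise parameters; the
bout threshold is μ + 3σ (multiplier configurable; whether the original
used a σ-multiple or a quantile is unstated). Excursions shorter than 40 ms
are discarded; gaps shorter than 100 ms merge only if the intervening
trough stays above μ + σ (a dip back to the noise floor separates two
bouts). Starts and ends are refined from the threshold crossings to the
local speed minima, which places detected starts ~2–4 frames after the
kinematic onset at realistic noise. Bout angle is the unwrapped heading
change over the bout, signed positive toward the grating drift; |angle| <
0.1 rad is a scoot, positive is "correct", negative an "error". The trial
turning speed is the final cumulative (signed) heading change divided by
trial duration, and the mean angle per bout is defined as cumulative angle
÷ bout count, making turning speed = bout frequency × mean angle an exact
identity whenever heading changes only within bouts (true of the
generator). Contrast-response functions average trials within fish, then
report mean ± SEM across fish.

## Response models and cross-level relations

Hill fits use bounded nonlinear least squares (h ∈ (0.1, 10],
C₁/₂ ∈ (1, 200]%), initialised from the half-max crossing, weighted by
1/SEM² when SEMs are available; a fitted C₁/₂ outside the sampled range is
flagged as extrapolation. The MCG is the unweighted OLS slope over exactly
11 evenly spaced contrasts spanning 20% (behavior: 15–35%); for synapses,
`coarse_then_fine` first fits a coarse 0–100% CRF, then measures the fine
window at ±10% around the fitted C₁/₂ (clipped to stay within 0–100%).
Power laws are OLS in log-log coordinates. Pooling sorts synapses by
release rate into consecutive blocks of 4–8 (remainder folded into the last
block). The diurnal efficiency-ratio curve is computed from the two fitted
power functions, not from raw points. Pearson r is computed on values and
Spearman ρ on ranks, with an exact permutation p-value for n ≤ 8 and the
asymptotic approximation otherwise; behavioral MCGs are normalised to the
morning control before correlation.

## Problem sizes and determinism

Default analyses run on one CPU in about a minute: 60-synapse efficiency
cohorts, 30 fish per behavioral group with 200 s of trajectory per contrast
(11 contrasts, matching the total exposure of a 100 × 2 s presentation
protocol), and 12–20 rendered synapses of 100 stimulus cycles for quantal
recovery. Every stochastic routine takes an explicit seed; cohort-level
code expands one global seed into per-stage, per-condition children via
`numpy.random.SeedSequence` spawning, so identical (configuration, seed)
pairs give byte-identical outputs.

## Known limitations

* Coincident evoked events on the same 1 kHz sample are physically
  unresolvable; their merged amplitude is assigned ≤ 5 quanta, which
  slightly undercounts extreme multivesicular bursts (≈ 2–4% of quanta at
  the afternoon evoked rate).
* The plug-in information estimator is biased upward at small bin counts;
  comparisons across conditions use matched sample sizes, and the shuffle
  correction exists for absolute estimates.
* The behavioral MCG fold-change estimator has a sampling SD of roughly
  5–10% at the default cohort size; single-seed values scatter accordingly
  around the configured 2.4.
* Event detection at thresholds near 3.5 SD necessarily admits a small
  false-positive rate on long recordings; sub-half-quantum rejection keeps
  these out of the rate estimates, at the cost of discarding genuine events
  smaller than q/2 (none exist under the generator's integer-quantal
  model).
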