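# retinfo

Tools for quantifying the link between retinal synaptic performance and
visually driven behavior in larval zebrafish.

Retinal bipolar cells are the bottleneck through which all visual
information reaches the inner retina, and they release glutamate in
discrete, countable packets — vesicles — that can be imaged one by one with
the fluorescent reporter iGluSnFR. The optomotor response (OMR), the innate
tendency of a fish to turn with whole-field motion, provides a behavioral
readout of the same contrast signal. `retinfo` implements the full
quantitative chain between the two levels:

* **Quantal decomposition** of linescan recordings across synaptic
  terminals: spatial unmixing into Gaussian point sources (active zones),
  ΔF/F₀ with bleach correction, Wiener deconvolution with the reporter
  kernel `h(t) = A·e^(−t/τf)·(1 − e^(−t/τr))` (τf = 60 ms, τr = 1 ms),
  thresholded event detection, and maximum-likelihood clustering of event
  amplitudes into integer numbers of quanta.
* **Information metrics** of vesicular release: 20 ms binning of the
  quantal series, the joint distribution p(S,Q) over stimulus contrasts and
  quanta per bin, the plug-in mutual information I(S;Q) = H(S) − H(S|Q),
  information rate (bits/s), efficiency (bits per vesicle), and the Fano
  factor of vesicles per stimulus cycle.
* **Swim kinematics**: bout detection from speed traces (Gaussian fit to
  the noise mode, threshold μ+3σ), signed turning angles
  (correct/error/scoot classes), and the factorisation of turning speed
  into bout frequency × mean angle per bout.
* **Response models**: Hill contrast-response functions
  `R = R_max·S^h/(S^h + S_1/2^h)`, maximum contrast gain (MCG — the OLS
  slope over 11 contrasts spanning a 20% window around C₁/₂), efficiency–
  rate power laws `E = a·R^b`, pooled-synapse curves, and the cross-level
  Pearson/Spearman correlation between synaptic information rate and
  behavioral gain.
* **A synthetic cohort generator** that produces ground-truth-labelled
  linescans and trajectories under six configurable "retinal states"
  (morning, afternoon, and four neuromodulator manipulations), used to
  validate every stage end to end.

The package is aimed at people analysing glutamate-reporter imaging or
optomotor tracking data, and at anyone who wants a tested reference
implementation of bits-per-vesicle efficiency analysis.

## Worked example

Simulate an afternoon-regime synapse driven at 5 Hz and 100% contrast for
100 cycles, render it as a 1 kHz linescan with per-pixel noise at one fifth
of the quantal amplitude, then run the decomposition chain:

```python
import numpy as np
from retinfo import quantal, synth
from retinfo.regimes import StimulusProtocol, configure_cohort

cohort = configure_cohort()
pm = cohort["pm"].synapse  # afternoon regime

protocol = StimulusProtocol.constant(100.0, 20.0)
train = synth.simulate_release(pm, protocol, seed=7)
component = quantal.SpatialComponent(center=6.0, width=1.2, amplitude=1.0)
recording = synth.render_linescan(
    train, [component], quantal.DeconvolutionKernel(), pm, seed=8
)

series, diag = quantal.decompose_recording(recording, quantal.DeconvolutionKernel())
counts, per_cycle = quantal.quanta_per_cycle(series, 5.0, recording.duration)
print(f"events detected:        {len(series)} (ground truth {len(train)})")
print(f"unitary amplitude q:    {series.quantal_size:.3f} dF/F (true 0.400)")
print(f"vesicles per cycle:     {per_cycle:.2f} (configured 4.30)")
print(f"release rate:           {quantal.release_rate(series, (0, 20.0)):.1f} vesicles/s")
```

prints

```
events detected:        180 (ground truth 267)
unitary amplitude q:    0.377 dF/F (true 0.400)
vesicles per cycle:     4.16 (configured 4.30)
release rate:           21.4 vesicles/s
```

Fewer events are detected than generated because stimulus-locked events
falling within a few milliseconds of each other fuse into one multivesicular
event; their quanta are still counted correctly, which is why the recovered
vesicles per cycle (stimulus-locked events only, counted in a phase window
around the preferred release phase) lands close to the configured 4.3 while
the raw release rate also includes spontaneous events and the full-cycle
total.

## Command line

```
retinfo simulate --cohort default --out data/ --seed 1   # synthetic cohort
retinfo quantal data/am --ksd 3.5 --out out/             # linescan -> quanta CSV
retinfo info out/ --bin-ms 20 --out metrics.csv          # bits/s, bits/vesicle
retinfo behavior data/am/trajectories.csv --out out/     # bouts + trial summaries
retinfo analyze metrics.csv --out report/                # cross-level correlation
retinfo run --out cohort_run/ --seed 1                   # everything, end to end
```

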