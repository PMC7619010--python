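"""Ground-truth-labelled synthetic recordings.

Two generators emulate the study's raw data:

* ``simulate_release`` + ``render_linescan`` — stimulus-locked multivesicular
  glutamate release at a bipolar-cell synapse imaged as a 1 kHz linescan:
  a homogeneous Poisson spontaneous process superimposed on phase-locked
  evoked events whose expected quanta per 5 Hz cycle follow a Hill function
  of contrast, rendered through the reporter kernel onto a spatial Gaussian
  with shot-like additive noise and mono-exponential bleaching.

* ``simulate_behavior`` — free-swimming optomotor trajectories: bouts arrive
  as a Poisson process whose rate is a Hill function of contrast; each bout
  is a forward scoot or a turn whose sign is biased toward the grating drift,
  and the heading trace integrates a smooth angular-velocity waveform.

Every generator is deterministic given (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .behavior import TrajectoryRecording
from .quantal import DeconvolutionKernel, LinescanRecording, SpatialComponent
from .regimes import BehaviorRegime, StimulusProtocol, SynapseRegime

__all__ = [
    "GroundTruthTrain",
    "simulate_release",
    "render_linescan",
    "simulate_behavior",
    "GroundTruthBout",
    "make_efficiency_cohort",
    "make_crf_cohort",
]


@dataclass
class GroundTruthTrain:
    """The true event train behind a synthetic recording."""

    event_times: np.ndarray      # s, strictly increasing
    event_quanta: np.ndarray     # >= 1
    duration: float              # s
    regime_id: str = ""
    seed: int | None = None

    def __post_init__(self):
        self.event_times = np.asarray(self.event_times, float)
        self.event_quanta = np.asarray(self.event_quanta, int)
        if self.event_times.size:
            if np.any(np.diff(self.event_times) <= 0):
                raise ValueError("event times must be strictly increasing")
            if self.event_quanta.min() < 1:
                raise ValueError("event quanta must be >= 1")

    def __len__(self):
        return self.event_times.size

    @property
    def total_quanta(self) -> int:
        return int(self.event_quanta.sum())


def _draw_sizes(rng, n, weights):
    return rng.choice(np.arange(1, len(weights) + 1), size=n, p=np.asarray(weights, float))


def simulate_release(
    regime: SynapseRegime, protocol: StimulusProtocol, seed: int
) -> GroundTruthTrain:
    """Generate a ground-truth release train for one synapse.

    Spontaneous events form a homogeneous Poisson process whose *vesicle*
    rate is ``regime.spont_rate`` (event rate = spont_rate / mean event
    size).  Per stimulus cycle, evoked events occur at one preferred phase
    (a quarter cycle), each jittered by ``phase_jitter_sd``; the number of
    evoked events per cycle is Poisson with mean chosen so the expected
    quanta per cycle equals ``regime.expected_quanta_per_cycle(contrast)``.
    Event sizes (quanta) are drawn from ``regime.mvr_weights``.
    """
    total = protocol.total_duration
    if total <= 0:
        raise ValueError("protocol has zero duration")
    rng = np.random.default_rng(seed)
    m = regime.mean_event_size
    times = []
    quanta = []

    # spontaneous process over the whole recording
    if regime.spont_rate > 0:
        n_spont = rng.poisson(regime.spont_rate / m * total)
        t_spont = rng.uniform(0, total, n_spont)
        times.append(t_spont)
        quanta.append(_draw_sizes(rng, n_spont, regime.mvr_weights))

    # evoked events, cycle by cycle
    period = 1.0 / protocol.temporal_freq
    preferred = 0.25 * period
    t0 = 0.0
    for contrast, dur in protocol.schedule:
        lam_q = regime.expected_quanta_per_cycle(contrast)
        n_cycles = int(np.floor(dur * protocol.temporal_freq))
        if lam_q > 0 and n_cycles > 0:
            n_ev = rng.poisson(lam_q / m, size=n_cycles)
            tot_ev = int(n_ev.sum())
            if tot_ev:
                cyc = np.repeat(np.arange(n_cycles), n_ev)
                t_ev = (
                    t0
                    + cyc * period
                    + preferred
                    + rng.normal(0, regime.phase_jitter_sd, tot_ev)
                )
                t_ev = np.clip(t_ev, 0, total - 1e-9)
                times.append(t_ev)
                quanta.append(_draw_sizes(rng, tot_ev, regime.mvr_weights))
        t0 += dur

    if times:
        t = np.concatenate(times)
        q = np.concatenate(quanta)
    else:
        t = np.empty(0)
        q = np.empty(0, int)
    order = np.argsort(t, kind="stable")
    t, q = t[order], q[order]
    # enforce strictly increasing times (coincident draws nudged by one ns)
    for i in range(1, t.size):
        if t[i] <= t[i - 1]:
            t[i] = t[i - 1] + 1e-9
    return GroundTruthTrain(t, q, duration=total, regime_id="", seed=seed)


def render_linescan(
    train: GroundTruthTrain | list[GroundTruthTrain],
    components: list[SpatialComponent],
    kernel: DeconvolutionKernel,
    regime: SynapseRegime,
    dt: float = 0.001,
    seed: int = 0,
    n_pixels: int = 48,
    dx: float = 0.25,
    f0: float = 100.0,
    bleach: bool = True,
) -> LinescanRecording:
    """Forward model: render ground-truth trains into a pixels x time linescan.

    Each event contributes ``quanta * quantal_dff`` (peak dF/F0) convolved
    with the peak-normalised reporter kernel, placed on its component's
    spatial Gaussian.  The resting fluorescence ``f0`` shares the spatial
    profile; the whole signal decays mono-exponentially with
    ``regime.bleach_tau`` and per-pixel Gaussian noise of SD
    ``regime.noise_sd * f0`` (i.e. noise_sd in dF/F0 units) is added.
    """
    if dt > 0.002:
        raise ValueError("linescan rendering requires dt <= 2 ms")
    trains = train if isinstance(train, list) else [train]
    if len(trains) != len(components):
        if len(components) == 1 and len(trains) == 1:
            pass
        else:
            raise ValueError("need one train per spatial component")
    line_len = (n_pixels - 1) * dx
    for c in components:
        if not (0 <= c.center <= line_len):
            raise ValueError(f"component centre {c.center} um outside the scan line")

    duration = max(tr.duration for tr in trains)
    n_lines = int(round(duration / dt))
    t = np.arange(n_lines) * dt
    h = kernel.sample(dt, unit_peak=True)
    x = np.arange(n_pixels) * dx

    rng = np.random.default_rng(seed)
    values = np.zeros((n_pixels, n_lines))
    for tr, comp in zip(trains, components):
        dff = np.zeros(n_lines)
        idx = np.minimum((tr.event_times / dt).astype(int), n_lines - 1)
        np.add.at(dff, idx, tr.event_quanta * regime.quantal_dff)
        dff = fftconvolve(dff, h)[:n_lines]
        profile = comp.profile(x, unit_peak=True) * comp.amplitude
        values += profile[:, None] * (f0 * (1.0 + dff))[None, :]
    if bleach:
        values *= np.exp(-t / regime.bleach_tau)[None, :]
    if regime.noise_sd > 0:
        values += rng.normal(0, regime.noise_sd * f0, values.shape)
    rec = LinescanRecording(
        values=values,
        dt=dt,
        dx=dx,
        metadata={"f0": f0, "seed": seed, "n_trains": len(trains)},
        ground_truth=trains[0] if len(trains) == 1 else trains,
    )
    return rec


# ---------------------------------------------------------------------------
# Behavior


@dataclass
class GroundTruthBout:
    """One generated swim bout (for recovery tests)."""

    onset: float        # s
    angle: float        # rad, signed + toward drift
    is_scoot: bool
    evoked: bool


def _bout_waveform(frame_rate: float, bout_duration: float = 0.2):
    """Raised-cosine speed/angular-velocity envelope, unit area."""
    n = max(int(round(bout_duration * frame_rate)), 3)
    w = 0.5 * (1 - np.cos(2 * np.pi * np.arange(n) / n))
    return w / w.sum()


def simulate_behavior(
    regime: BehaviorRegime,
    protocol: StimulusProtocol,
    n_fish: int,
    seed: int,
    bout_peak_speed: float = 20.0,
    tracking_noise_mm: float = 0.01,
) -> list[TrajectoryRecording]:
    """Simulate free-swimming optomotor trajectories.

    Returns one :class:`TrajectoryRecording` per (fish, trial).  Bout onsets
    follow an inhomogeneous Poisson process: unbiased spontaneous bouts at
    ``base_bout_rate`` plus stimulus-evoked bouts at
    ``(max_bout_rate - base_bout_rate) * Hill(contrast)`` that turn toward
    the drift with probability ``p_correct``.  Each bout is a forward scoot
    (no turn) with probability ``scoot_fraction``, otherwise a turn of
    magnitude ~ N(angle_mean, angle_sd).  The heading trace integrates a
    smooth angular-velocity waveform; the position trace advances at the
    bout speed waveform, with Gaussian tracking noise on position.

    Drift direction alternates left/right across trials and is recorded in
    each recording's metadata as ``drift_sign``.
    """
    if n_fish < 1:
        raise ValueError("n_fish must be >= 1")
    root = np.random.default_rng(seed)
    fish_seeds = root.spawn(n_fish)
    frame_rate = regime.frame_rate
    dt = 1.0 / frame_rate
    wave = _bout_waveform(frame_rate)
    nwave = wave.size

    recordings = []
    for fish_id, fish_rng in enumerate(fish_seeds):
        trial_id = 0
        for contrast, dur in protocol.schedule:
            drift_sign = 1.0 if trial_id % 2 == 0 else -1.0
            n_frames = int(round(dur * frame_rate))
            ang_vel = np.zeros(n_frames + nwave)
            speed = np.zeros(n_frames + nwave)
            bouts = []
            evoked_rate = regime.bout_rate(contrast) - regime.base_bout_rate
            total_rate = regime.base_bout_rate + max(evoked_rate, 0.0)
            dead = nwave * dt
            if total_rate <= 0:
                onsets = np.empty(0)
            else:
                # draw at an intensity compensated for the refractory dead
                # time, so the realized bout rate matches the configured one
                lam = total_rate / max(1.0 - total_rate * dead, 0.2)
                n_bouts = fish_rng.poisson(lam * (dur - dead))
                onsets = np.sort(fish_rng.uniform(0, dur - dead, n_bouts))
            p_evoked = max(evoked_rate, 0.0) / total_rate if total_rate > 0 else 0.0
            # refractory spacing so bouts never overlap
            last = -np.inf
            for on in onsets:
                if on - last < dead:
                    continue
                last = on
                evoked = fish_rng.uniform() < p_evoked
                is_scoot = fish_rng.uniform() < regime.scoot_fraction
                if is_scoot:
                    angle = 0.0
                else:
                    mag = abs(fish_rng.normal(regime.angle_mean, regime.angle_sd))
                    if evoked:
                        sign = 1.0 if fish_rng.uniform() < regime.p_correct else -1.0
                    else:
                        sign = 1.0 if fish_rng.uniform() < 0.5 else -1.0
                    angle = sign * mag
                i0 = int(round(on * frame_rate))
                ang_vel[i0 : i0 + nwave] += angle * drift_sign * wave
                speed[i0 : i0 + nwave] += bout_peak_speed * wave / wave.max()
                bouts.append(GroundTruthBout(on, angle, is_scoot, evoked))
            ang_vel = ang_vel[:n_frames]
            speed = speed[:n_frames]
            heading = np.concatenate([[0.0], np.cumsum(ang_vel)])[:n_frames]
            # integrate position along the (noisy) heading
            step = speed * dt
            xpos = np.cumsum(step * np.cos(heading))
            ypos = np.cumsum(step * np.sin(heading))
            xpos += fish_rng.normal(0, tracking_noise_mm, n_frames)
            ypos += fish_rng.normal(0, tracking_noise_mm, n_frames)
            rec = TrajectoryRecording(
                time=np.arange(n_frames) * dt,
                x=xpos,
                y=ypos,
                heading=heading,
                metadata={
                    "fish_id": fish_id,
                    "trial_id": trial_id,
                    "contrast": float(contrast),
                    "drift_sign": drift_sign,
                },
                ground_truth=sorted(bouts, key=lambda b: b.onset),
            )
            recordings.append(rec)
            trial_id += 1
    return recordings


# ---------------------------------------------------------------------------
# Law-based cohort generators (population level)


def make_efficiency_cohort(
    a: float,
    b: float,
    n_synapses: int = 60,
    r_range: tuple = (1.0, 50.0),
    noise_cv: float = 0.10,
    seed: int = 0,
):
    """Synapse population on an efficiency-rate power law E = a * R^b.

    Release rates are log-uniform over ``r_range`` (vesicles/s); each
    efficiency carries multiplicative lognormal scatter of coefficient of
    variation ``noise_cv``.  Returns (release_rates, efficiencies).
    """
    rng = np.random.default_rng(seed)
    lo, hi = r_range
    r = np.exp(rng.uniform(np.log(lo), np.log(hi), n_synapses))
    sigma = np.sqrt(np.log1p(noise_cv**2))
    e = a * r**b * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n_synapses)
    return r, e


def make_crf_cohort(
    r_max: float,
    h: float,
    c_half: float,
    contrasts,
    n_fish: int = 30,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Per-fish contrast-response samples from a Hill curve plus Gaussian
    noise (absolute SD ``noise_sd``).  Returns an (n_fish, n_contrasts)
    array of turning-speed responses."""
    from .regimes import hill

    rng = np.random.default_rng(seed)
    c = np.asarray(contrasts, float)
    mean = r_max * hill(c, c_half, h)
    return mean[None, :] + rng.normal(0, noise_sd, (n_fish, c.size))
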