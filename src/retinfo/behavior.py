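"""Swim-bout extraction and optomotor-response metrics.

The optomotor response (OMR) of a free-swimming larva is quantified from its
tracked trajectory: discrete swim bouts are detected from the speed trace,
each bout's turning angle is read off the heading trace (positive toward the
grating drift), and trial-level metrics factorise the turning speed into
bout frequency x mean angle per bout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "TrajectoryRecording",
    "SwimBout",
    "TrialSummary",
    "detect_bouts",
    "measure_bout_angles",
    "summarize_trial",
    "build_behavior_crf",
    "SCOOT_THRESHOLD",
]

#: |angle| below which a bout is classed as a forward scoot (rad).
SCOOT_THRESHOLD = 0.1


@dataclass
class TrajectoryRecording:
    """Tracked trajectory of one fish on one trial (~150 Hz sampling)."""

    time: np.ndarray      # s, uniform
    x: np.ndarray         # mm
    y: np.ndarray         # mm
    heading: np.ndarray   # rad, unwrapped
    metadata: dict = field(default_factory=dict)
    ground_truth: list | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, float)
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        self.heading = np.asarray(self.heading, float)
        n = self.time.size
        if not (self.x.size == self.y.size == self.heading.size == n):
            raise ValueError("trajectory columns must align")
        if n > 1:
            dts = np.diff(self.time)
            if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
                raise ValueError("sampling must be uniform")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def duration(self) -> float:
        return self.time.size * self.dt

    def speed(self) -> np.ndarray:
        """Swim speed |d(position)|/dt (mm/s), length n-1."""
        return np.hypot(np.diff(self.x), np.diff(self.y)) / self.dt


@dataclass
class SwimBout:
    """One detected locomotor event."""

    start: float          # s
    end: float            # s
    peak_speed: float     # mm/s
    angle: float = np.nan  # rad, signed + toward drift
    cls: str = ""          # "correct" | "error" | "scoot"

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError("bout must have start < end")


@dataclass
class TrialSummary:
    cumulative_angle: float      # rad, + toward drift
    turning_speed: float         # rad/s
    bout_frequency: float        # bouts/s
    mean_angle_per_bout: float   # rad
    n_bouts: int
    contrast: float = np.nan
    fish_id: int = -1


def _gauss(x, a, mu, sigma):
    return a * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def _noise_mode_gaussian(speed: np.ndarray) -> tuple[float, float]:
    """Fit a Gaussian to the noise mode of the speed histogram."""
    counts, edges = np.histogram(speed, bins=100)
    centers = 0.5 * (edges[:-1] + edges[1:])
    i_pk = int(np.argmax(counts))
    # fit only the contiguous region around the mode above 20% of the peak
    lo = i_pk
    while lo > 0 and counts[lo - 1] > 0.2 * counts[i_pk]:
        lo -= 1
    hi = i_pk
    while hi < counts.size - 1 and counts[hi + 1] > 0.2 * counts[i_pk]:
        hi += 1
    sel = slice(lo, hi + 1)
    if hi - lo < 2:
        raise ValueError("no resolvable noise mode in the speed histogram")
    sigma0 = max((edges[hi + 1] - edges[lo]) / 4, 1e-6)
    try:
        popt, _ = optimize.curve_fit(
            _gauss,
            centers[sel],
            counts[sel],
            p0=[counts[i_pk], centers[i_pk], sigma0],
            maxfev=5000,
        )
    except RuntimeError as exc:
        raise ValueError("no resolvable noise mode in the speed histogram") from exc
    return float(popt[1]), float(abs(popt[2]))


def detect_bouts(
    recording: TrajectoryRecording,
    threshold_multiplier: float = 3.0,
    min_interval: float = 0.1,
    min_duration: float = 0.04,
) -> list[SwimBout]:
    """Extract swim bouts from the speed trace by thresholded peak detection.

    A Gaussian is fitted to the noise mode of the per-trial speed histogram;
    the bout threshold is mu + ``threshold_multiplier`` * sigma of that fit.
    Supra-threshold excursions shorter than ``min_duration`` are discarded
    and excursions closer than ``min_interval`` (s) are merged, preventing
    double counting within one bout.
    """
    if recording.duration < 2.0:
        raise ValueError("recording shorter than 2 s")
    speed = recording.speed()
    mu, sigma = _noise_mode_gaussian(speed)
    thr = mu + threshold_multiplier * sigma
    above = speed > thr
    if not above.any():
        return []
    dt = recording.dt
    idx = np.flatnonzero(above)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    gap = max(int(round(min_interval / dt)), 1)
    merged = [[starts[0], ends[0]]]
    for s, e in zip(starts[1:], ends[1:]):
        prev_end = merged[-1][1]
        trough = speed[prev_end : s + 1].min()
        # a short sub-threshold dip that never returns to the noise level is
        # part of the same bout; a return to baseline separates two bouts
        if s - prev_end < gap and trough > mu + sigma:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    min_len = max(int(round(min_duration / dt)), 1)
    bouts = []
    for s, e in merged:
        if e - s + 1 < min_len:
            continue
        peak = float(speed[s : e + 1].max())
        # refine start/end from the threshold crossing back to the local
        # speed minimum, so the bout spans the whole excursion
        while s > 0 and speed[s - 1] < speed[s]:
            s -= 1
        while e < speed.size - 1 and speed[e + 1] < speed[e]:
            e += 1
        if bouts and s * dt <= bouts[-1].end:
            s = int(round(bouts[-1].end / dt)) + 1
            if s > e:
                continue
        bouts.append(SwimBout(start=s * dt, end=(e + 1) * dt, peak_speed=peak))
    return bouts


def measure_bout_angles(
    recording: TrajectoryRecording,
    bouts: list[SwimBout],
    drift_sign: float | None = None,
    scoot_threshold: float = SCOOT_THRESHOLD,
) -> list[SwimBout]:
    """Assign each bout its signed turning angle and class.

    The angle is heading(end) - heading(start) on the unwrapped heading
    trace, signed so that positive means a turn in the direction of the
    grating drift (``drift_sign``, taken from the recording metadata when
    not given).  Bouts with |angle| below ``scoot_threshold`` are scoots;
    otherwise positive angles are "correct" turns and negative are "errors".
    """
    if drift_sign is None:
        drift_sign = float(recording.metadata.get("drift_sign", 1.0))
    heading = np.unwrap(recording.heading)
    dt = recording.dt
    n = heading.size
    out = []
    for b in bouts:
        i0 = min(int(round(b.start / dt)), n - 1)
        i1 = min(int(round(b.end / dt)), n - 1)
        angle = (heading[i1] - heading[i0]) * drift_sign
        if abs(angle) < scoot_threshold:
            cls = "scoot"
        elif angle > 0:
            cls = "correct"
        else:
            cls = "error"
        out.append(
            SwimBout(start=b.start, end=b.end, peak_speed=b.peak_speed,
                     angle=float(angle), cls=cls)
        )
    return out


def summarize_trial(
    recording: TrajectoryRecording,
    bouts: list[SwimBout],
    drift_sign: float | None = None,
) -> TrialSummary:
    """Trial-level OMR metrics.

    The turning speed is the final cumulative angle (heading change over the
    whole trial, positive toward the drift) divided by the trial duration.
    The mean angle per bout is cumulative angle / bout count, so the
    factorisation turning_speed = bout_frequency x mean_angle_per_bout is an
    identity whenever all heading change occurs within bouts.
    """
    if drift_sign is None:
        drift_sign = float(recording.metadata.get("drift_sign", 1.0))
    heading = np.unwrap(recording.heading)
    duration = recording.duration
    cum = float((heading[-1] - heading[0]) * drift_sign)
    n = len(bouts)
    return TrialSummary(
        cumulative_angle=cum,
        turning_speed=cum / duration,
        bout_frequency=n / duration,
        mean_angle_per_bout=cum / n if n else 0.0,
        n_bouts=n,
        contrast=float(recording.metadata.get("contrast", np.nan)),
        fish_id=int(recording.metadata.get("fish_id", -1)),
    )


def build_behavior_crf(summaries: list[TrialSummary]):
    """Mean +/- SEM turning speed per contrast, averaged across fish.

    Trials are first averaged within fish at each contrast; the SEM is then
    taken across fish.  Returns a :class:`retinfo.models.ContrastResponseFunction`.
    """
    from .models import ContrastResponseFunction

    by_contrast: dict[float, dict[int, list[float]]] = {}
    for s in summaries:
        by_contrast.setdefault(s.contrast, {}).setdefault(s.fish_id, []).append(
            s.turning_speed
        )
    contrasts = sorted(by_contrast)
    means, sems, ns = [], [], []
    for c in contrasts:
        fish_means = np.array([np.mean(v) for v in by_contrast[c].values()])
        means.append(fish_means.mean())
        sems.append(
            fish_means.std(ddof=1) / np.sqrt(fish_means.size)
            if fish_means.size > 1
            else 0.0
        )
        ns.append(fish_means.size)
    return ContrastResponseFunction(
        contrasts=np.array(contrasts),
        responses=np.array(means),
        sems=np.array(sems),
        n=np.array(ns),
    )
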