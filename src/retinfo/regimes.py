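"""Condition regimes and stimulus protocols for the synthetic cohort.

A *regime* bundles the parameters that define how a retinal bipolar-cell
synapse (:class:`SynapseRegime`) or a free-swimming larva
(:class:`BehaviorRegime`) behaves under one experimental condition — the
morning (a.m.) and afternoon (p.m.) phases of the diurnal cycle and the four
pharmacological manipulations of dopamine (D1R) and substance P (NK1R)
signalling that push the retina between those two operating points.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SynapseRegime",
    "BehaviorRegime",
    "StimulusProtocol",
    "CohortCondition",
    "configure_cohort",
    "hill",
    "CONDITION_NAMES",
]


def hill(contrast, c50, h):
    """Hill saturation C^h / (C^h + C50^h), defined as 0 at C = 0."""
    c = np.asarray(contrast, dtype=float)
    out = np.zeros_like(c)
    pos = c > 0
    ch = np.power(c[pos], h)
    out[pos] = ch / (ch + c50**h)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class SynapseRegime:
    """Release statistics of one bipolar-cell synapse condition.

    ``evoked_max`` is the expected number of vesicles released per stimulus
    cycle at 100% contrast; at contrast C the expectation follows the Hill
    curve normalised to its 100%-contrast value.  ``mvr_weights[k-1]`` is the
    probability that a single exocytic event comprises k vesicles
    (multivesicular release).
    """

    spont_rate: float = 3.6          # vesicles / s
    evoked_max: float = 2.7          # vesicles / cycle at 100% contrast
    hill_c50: float = 45.0           # % contrast
    hill_h: float = 1.6
    # truncated geometric (ratio 0.45) over 1..5 quanta
    mvr_weights: tuple = (0.560339, 0.252152, 0.113469, 0.051061, 0.022979)
    quantal_dff: float = 0.4         # dF/F0 per vesicle
    noise_sd: float = 0.08           # additive per-pixel noise, dF/F0 units
    bleach_tau: float = 300.0        # s
    phase_jitter_sd: float = 0.010   # s

    def __post_init__(self):
        w = np.asarray(self.mvr_weights, float)
        if w.ndim != 1 or w.size < 1 or np.any(w < 0) or abs(w.sum() - 1) > 1e-6:
            raise ValueError("mvr_weights must be a probability vector over 1..kmax")
        if self.spont_rate < 0 or self.evoked_max < 0 or self.noise_sd < 0:
            raise ValueError("rates and noise_sd must be >= 0")
        if not (0 < self.hill_c50 <= 100):
            raise ValueError("hill_c50 must lie in (0, 100]")
        if self.quantal_dff <= 0:
            raise ValueError("quantal_dff must be > 0")
        if self.bleach_tau <= 0 or self.phase_jitter_sd < 0:
            raise ValueError("bleach_tau must be > 0 and phase_jitter_sd >= 0")

    @property
    def mean_event_size(self) -> float:
        """Expected vesicles per exocytic event under ``mvr_weights``."""
        w = np.asarray(self.mvr_weights, float)
        return float(np.sum(np.arange(1, w.size + 1) * w))

    def expected_quanta_per_cycle(self, contrast: float) -> float:
        """E[vesicles/cycle] at a contrast (%), anchored to evoked_max at 100%."""
        return self.evoked_max * hill(contrast, self.hill_c50, self.hill_h) / hill(
            100.0, self.hill_c50, self.hill_h
        )


@dataclass(frozen=True)
class BehaviorRegime:
    """Swim-bout statistics of one behavioral condition.

    Bouts arrive as a Poisson process with rate
    ``base_bout_rate + (max_bout_rate - base_bout_rate) * Hill(C)``.
    The stimulus-evoked component is directionally biased (probability
    ``p_correct`` of turning with the grating drift); spontaneous bouts at the
    base rate are unbiased, so at zero contrast left and right turns are
    equally probable.
    """

    base_bout_rate: float = 0.5      # bouts / s at zero contrast
    max_bout_rate: float = 1.5       # bouts / s at saturating contrast
    bout_hill_c50: float = 31.0      # %
    bout_hill_h: float = 1.9
    p_correct: float = 0.85
    angle_mean: float = 0.5          # rad per turn
    angle_sd: float = 0.15           # rad
    scoot_fraction: float = 0.35
    frame_rate: float = 150.0        # Hz

    def __post_init__(self):
        if not (0 <= self.p_correct <= 1):
            raise ValueError("p_correct must lie in [0, 1]")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if min(self.base_bout_rate, self.max_bout_rate) < 0:
            raise ValueError("bout rates must be >= 0")
        if not (0 <= self.scoot_fraction <= 1):
            raise ValueError("scoot_fraction must lie in [0, 1]")

    def bout_rate(self, contrast: float) -> float:
        return self.base_bout_rate + (self.max_bout_rate - self.base_bout_rate) * hill(
            contrast, self.bout_hill_c50, self.bout_hill_h
        )


@dataclass(frozen=True)
class StimulusProtocol:
    """An open-loop contrast schedule.

    ``schedule`` is the per-trial sequence of (contrast %, duration s) pairs
    actually presented; ``contrasts`` is the ordered set of distinct levels.
    """

    contrasts: tuple
    schedule: tuple                  # ((contrast, duration), ...)
    temporal_freq: float = 5.0       # Hz
    n_repeats: int = 1

    def __post_init__(self):
        c = np.asarray(self.contrasts, float)
        if np.any(c < 0) or np.any(c > 100):
            raise ValueError("contrasts must lie in [0, 100]")
        if len(self.schedule) == 0 or any(d <= 0 for _, d in self.schedule):
            raise ValueError("schedule durations must be > 0")
        if self.temporal_freq <= 0:
            raise ValueError("temporal_freq must be > 0")

    @property
    def total_duration(self) -> float:
        return float(sum(d for _, d in self.schedule))

    @classmethod
    def constant(cls, contrast: float, duration: float, temporal_freq: float = 5.0):
        """Single fixed-contrast trial (30–60 s free-swimming style)."""
        return cls(
            contrasts=(float(contrast),),
            schedule=((float(contrast), float(duration)),),
            temporal_freq=temporal_freq,
        )

    @classmethod
    def pseudorandom(
        cls,
        contrasts,
        trial_duration: float = 2.0,
        n_repeats: int = 100,
        temporal_freq: float = 5.0,
        seed: int = 0,
    ):
        """Pseudo-random interleaving of contrast levels, each repeated n times."""
        rng = np.random.default_rng(seed)
        levels = np.repeat(np.asarray(contrasts, float), n_repeats)
        rng.shuffle(levels)
        return cls(
            contrasts=tuple(float(c) for c in contrasts),
            schedule=tuple((float(c), float(trial_duration)) for c in levels),
            temporal_freq=temporal_freq,
            n_repeats=n_repeats,
        )

    @classmethod
    def mcg_window(
        cls,
        center: float = 25.0,
        trial_duration: float = 2.0,
        n_repeats: int = 100,
        temporal_freq: float = 5.0,
        seed: int = 0,
    ):
        """Eleven evenly spaced contrasts spanning +/-10% around ``center``."""
        contrasts = np.linspace(center - 10.0, center + 10.0, 11)
        return cls.pseudorandom(contrasts, trial_duration, n_repeats, temporal_freq, seed)


#: Behavioral maximum-contrast-gain multipliers relative to the a.m. control,
#: spanning the 2.4-fold range observed over the six retinal states, and the
#: matching synaptic information-rate targets (bits/s) spanning a 4-fold range.
#: MCG multipliers and information rates lie on a common linear relation.
_GAIN_MULTIPLIERS = {
    "am": 1.00,
    "pm_SP": 1.28,
    "pm_SCH23390": 1.56,
    "am_L733060": 1.84,
    "am_ADTN": 2.12,
    "pm": 2.40,
}
_INFO_RATE_SPAN = (0.9, 3.6)  # bits/s, min (a.m.) to max (p.m.), 4-fold

CONDITION_NAMES = tuple(_GAIN_MULTIPLIERS)

#: Efficiency-vs-release-rate power laws E = a * R^b (bits/vesicle vs
#: vesicles/s) for the pooled morning and afternoon operating regimes.
MORNING_LAW = (0.49, -0.74)
AFTERNOON_LAW = (2.18, -1.12)

_AM_SYNAPSE = SynapseRegime()
_PM_SYNAPSE = SynapseRegime(
    spont_rate=0.8, evoked_max=4.3, hill_c50=35.0, hill_h=1.5
)


@dataclass(frozen=True)
class CohortCondition:
    """One retinal state: its synapse and behavior regimes plus the
    condition-level information-rate target used to place it on the
    information-rate vs behavioral-gain relation."""

    name: str
    synapse: SynapseRegime
    behavior: BehaviorRegime
    info_rate_target: float  # bits/s
    gain_multiplier: float   # behavioral MCG relative to a.m.


def _behavior_for(multiplier: float, base: BehaviorRegime) -> BehaviorRegime:
    evoked = (base.max_bout_rate - base.base_bout_rate) * multiplier
    return replace(base, max_bout_rate=base.base_bout_rate + evoked)


def configure_cohort(condition_table: dict | None = None) -> dict:
    """Build the condition → (SynapseRegime, BehaviorRegime) map.

    The default table encodes six retinal states: morning and afternoon
    controls plus the four intraocular drug manipulations (NK1R antagonist
    L733,060 and D1R agonist ADTN in the morning; substance P and the D1R
    antagonist SCH23390 in the afternoon).  Angle parameters are shared
    across conditions — modulation acts on bout frequency, not bout angle.
    Pass ``condition_table`` (mapping name → dict of field overrides with
    optional "synapse"/"behavior" sub-dicts) to override defaults.

    Raises KeyError for unknown condition names in the override table.
    """
    base_behavior = BehaviorRegime()
    lo, hi = _INFO_RATE_SPAN
    cohort = {}
    for name, mult in _GAIN_MULTIPLIERS.items():
        base_syn = _PM_SYNAPSE if name.startswith("pm") else _AM_SYNAPSE
        # drugs scale the evoked synaptic output relative to the diurnal control
        control_mult = _GAIN_MULTIPLIERS["pm" if name.startswith("pm") else "am"]
        syn = replace(base_syn, evoked_max=base_syn.evoked_max * mult / control_mult)
        info_rate = lo + (hi - lo) * (mult - 1.0) / (max(_GAIN_MULTIPLIERS.values()) - 1.0)
        cohort[name] = CohortCondition(
            name=name,
            synapse=syn,
            behavior=_behavior_for(mult, base_behavior),
            info_rate_target=info_rate,
            gain_multiplier=mult,
        )
    if condition_table:
        for name, overrides in condition_table.items():
            if name not in cohort:
                raise KeyError(f"unknown condition {name!r}")
            cond = cohort[name]
            syn = replace(cond.synapse, **overrides.get("synapse", {}))
            beh = replace(cond.behavior, **overrides.get("behavior", {}))
            scalars = {
                k: v for k, v in overrides.items() if k not in ("synapse", "behavior")
            }
            cohort[name] = replace(cond, synapse=syn, behavior=beh, **scalars)
    return cohort
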