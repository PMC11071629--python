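"""Task geometry/timing, behavioral policies, and neuron response archetypes.

These objects define the study conditions the synthetic generator emulates:

* :class:`TaskConfig` — geometry and timing of the choice and fixation
  tasks (target eccentricity 15 deg at six angles, 400-ms accept hold,
  700-ms fixation hold, 1000-ms free viewing, 1-kHz eye sampling).
* :class:`BehaviorPolicy` — per-(value, scene) reaction-time parameters and
  action probabilities, with defaults derived from the published per-monkey
  behavioral tables in :mod:`seqchoice.reference`.
* :class:`NeuronArchetype` — parametric firing-rate kernels for the three
  response types found in the anterior striatum during this task:
  good-preferring (cluster 1), bad-preferring / rejection-related
  (cluster 2), and value-agnostic visual (cluster 3), all with baseline
  rates below 10 spikes/s (the medium-spiny-neuron inclusion criterion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .reference import ACTION_COUNTS_REFERENCE, ACTIONS, RT_REFERENCE

VALUES = ("good", "bad")
DIRECTIONS = ("contra", "ipsi")
SCENES = (1, 2, 3, 4)


class ConfigurationError(ValueError):
    """Raised when a task/policy/archetype configuration is invalid."""


@dataclass(frozen=True)
class TaskConfig:
    """Geometry and timing of the choice and fixation tasks (times in ms)."""

    n_scenes: int = 4
    target_eccentricity: float = 15.0
    target_angles: tuple[float, ...] = (0.0, 45.0, 135.0, 180.0, 225.0, 315.0)
    target_halfwidth: float = 4.0  # target window is an 8-deg square
    accept_hold: float = 400.0
    fp_hold: float = 700.0
    scene_free_view: float = 1000.0
    prep_interval: tuple[float, float] = (1500.0, 2000.0)
    fixation_task_object_duration: float = 400.0
    fixation_task_isi: float = 400.0
    reward_delay_fixation: float = 300.0
    eye_rate: float = 1000.0  # Hz

    def __post_init__(self) -> None:
        durations = (
            self.accept_hold, self.fp_hold, self.scene_free_view,
            self.fixation_task_object_duration, self.fixation_task_isi,
            self.reward_delay_fixation,
        )
        if any(d <= 0 for d in durations) or self.eye_rate <= 0:
            raise ConfigurationError("all task durations and eye rate must be positive")
        if not (0 < self.prep_interval[0] <= self.prep_interval[1]):
            raise ConfigurationError("prep_interval must be a positive (lo, hi) range")
        for a in self.target_angles:
            if abs(math.cos(math.radians(a))) < 1e-9:
                raise ConfigurationError(
                    f"target angle {a} deg has no horizontal component; "
                    "contra/ipsi would be undefined"
                )
        if self.target_eccentricity <= self.target_halfwidth:
            raise ConfigurationError("eccentricity must exceed target half-width")


# Reaction times are drawn from a truncated normal. Good-object saccades
# must land within the 400-ms detection window; outbound return saccades
# may be slower but are kept physiological.
RT_BOUNDS: dict[str, tuple[float, float]] = {"good": (80.0, 400.0), "bad": (80.0, 600.0)}


@dataclass(frozen=True)
class BehaviorPolicy:
    """Per-(value, scene) RT distribution and action probabilities.

    ``rt_mean``/``rt_sd`` are keyed by ``(value, scene)``; ``action_probs``
    maps ``(value, scene)`` to a probability for each action in
    ``("Accept", "Return", "Stay", "Other", "FixBreak")``.
    """

    rt_mean: dict[tuple[str, int], float]
    rt_sd: dict[tuple[str, int], float]
    action_probs: dict[tuple[str, int], dict[str, float]]
    rt_bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(RT_BOUNDS)
    )

    def __post_init__(self) -> None:
        for key, probs in self.action_probs.items():
            total = sum(probs.get(a, 0.0) for a in ACTIONS)
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"action probabilities for {key} sum to {total!r}, not 1"
                )
            if any(p < 0 for p in probs.values()):
                raise ConfigurationError(f"negative action probability for {key}")
        for key, sd in self.rt_sd.items():
            if sd <= 0:
                raise ConfigurationError(f"rt_sd for {key} must be positive")
        for scene in {s for (_, s) in self.rt_mean}:
            if self.rt_mean[("good", scene)] >= self.rt_mean[("bad", scene)]:
                raise ConfigurationError(
                    f"scene {scene}: good-object RT mean must be below bad-object RT mean"
                )

    @classmethod
    def from_reference(cls, monkey: str = "C") -> "BehaviorPolicy":
        """Policy whose RTs and bad-object action frequencies match the
        published per-monkey behavioral tables. Good objects are accepted
        deterministically (both subjects accepted good objects essentially
        always)."""
        rt_mean, rt_sd, action_probs = {}, {}, {}
        for scene in SCENES:
            for value in VALUES:
                _, mean, sd = RT_REFERENCE[(monkey, scene, value)]
                rt_mean[(value, scene)] = mean
                rt_sd[(value, scene)] = sd
            total, *counts = ACTION_COUNTS_REFERENCE[(monkey, scene)]
            action_probs[("bad", scene)] = {
                a: c / total for a, c in zip(ACTIONS, counts)
            }
            action_probs[("good", scene)] = {a: 0.0 for a in ACTIONS}
            action_probs[("good", scene)]["Accept"] = 1.0
        return cls(rt_mean=rt_mean, rt_sd=rt_sd, action_probs=action_probs)


@dataclass(frozen=True)
class ResponseKernel:
    """Difference-of-exponentials transient: zero before ``latency``, then
    ``amplitude``-scaled ``exp(-t/decay) - exp(-t/rise)`` normalized to peak
    at ``amplitude`` spikes/s."""

    amplitude: float  # spikes/s at peak
    latency: float = 90.0  # ms after event onset
    rise: float = 20.0  # ms
    decay: float = 80.0  # ms

    def __post_init__(self) -> None:
        if self.rise <= 0 or self.decay <= 0 or self.rise >= self.decay:
            raise ConfigurationError("kernel requires 0 < rise < decay")

    def peak_time(self) -> float:
        """Time of peak relative to event onset (ms)."""
        r, d = self.rise, self.decay
        return self.latency + math.log(d / r) / (1.0 / r - 1.0 / d)

    def evaluate(self, t_ms: np.ndarray) -> np.ndarray:
        """Rate contribution (spikes/s) at times ``t_ms`` after event onset."""
        t = np.asarray(t_ms, dtype=float) - self.latency
        out = np.zeros_like(t)
        pos = t > 0
        if np.any(pos):
            tp = t[pos]
            raw = np.exp(-tp / self.decay) - np.exp(-tp / self.rise)
            r, d = self.rise, self.decay
            tpk = math.log(d / r) / (1.0 / r - 1.0 / d)
            peak = math.exp(-tpk / d) - math.exp(-tpk / r)
            out[pos] = self.amplitude * raw / peak
        return out


@dataclass(frozen=True)
class NeuronArchetype:
    """Parametric response profile of one of the three response types.

    ``kernels`` maps ``(value, direction)`` to a tuple of
    :class:`ResponseKernel` applied at target/object onset during the
    choice task. During the fixation task every kernel amplitude is
    multiplied by ``fixation_attenuation``. ``latency_coupling`` scales the
    contra-good response amplitude by ``1 + coupling * zscore(RT)``
    (negative coupling: faster saccades on high-activity trials), and is
    only nonzero by default for the good-preferring archetype.
    """

    label: str  # cluster1_good | cluster2_bad | cluster3_visual
    baseline_rate: float
    kernels: dict[tuple[str, str], tuple[ResponseKernel, ...]]
    fixation_attenuation: float = 0.3
    latency_coupling: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.baseline_rate < 10.0):
            raise ConfigurationError(
                "baseline rate must lie in (0, 10) spikes/s (medium-spiny criterion)"
            )
        if not (0.0 <= self.fixation_attenuation <= 1.0):
            raise ConfigurationError("fixation_attenuation must lie in [0, 1]")
        for key in self.kernels:
            if key[0] not in VALUES or key[1] not in DIRECTIONS:
                raise ConfigurationError(f"unknown kernel condition {key}")

    def max_rate_bound(self) -> float:
        """Upper bound on the instantaneous rate (for Poisson thinning)."""
        per_cond = [
            sum(abs(k.amplitude) for k in ks) for ks in self.kernels.values()
        ] or [0.0]
        # latency coupling can boost the contra-good amplitude; RT z-scores
        # are truncated to +-3 by the generator
        boost = 1.0 + 3.0 * abs(self.latency_coupling)
        return self.baseline_rate + max(per_cond) * boost

    def scaled(self, separation: float) -> "NeuronArchetype":
        """Archetype with all kernel amplitudes scaled by ``separation``."""
        kernels = {
            cond: tuple(replace(k, amplitude=k.amplitude * separation) for k in ks)
            for cond, ks in self.kernels.items()
        }
        return replace(self, kernels=kernels)


def default_archetypes() -> dict[str, NeuronArchetype]:
    """The three response archetypes at their default effect sizes.

    Amplitudes follow the qualitative orderings seen in vivo: the
    good-preferring type responds good > bad and contra > ipsi; the
    bad-preferring (rejection) type responds bad > good with no laterality;
    the visual type gives an early value-agnostic transient plus a
    sustained component for bad objects (whose visual response is not cut
    short by an early accept saccade).
    """
    k = ResponseKernel
    return {
        "cluster1_good": NeuronArchetype(
            label="cluster1_good",
            baseline_rate=5.0,
            kernels={
                ("good", "contra"): (k(amplitude=30.0),),
                ("good", "ipsi"): (k(amplitude=18.0),),
                ("bad", "contra"): (k(amplitude=14.0),),
                ("bad", "ipsi"): (k(amplitude=12.0),),
            },
            fixation_attenuation=0.2,
            latency_coupling=-0.4,
        ),
        "cluster2_bad": NeuronArchetype(
            label="cluster2_bad",
            baseline_rate=4.0,
            kernels={
                ("good", "contra"): (k(amplitude=6.0),),
                ("good", "ipsi"): (k(amplitude=6.0),),
                ("bad", "contra"): (k(amplitude=28.0),),
                ("bad", "ipsi"): (k(amplitude=27.0),),
            },
            fixation_attenuation=0.2,
        ),
        "cluster3_visual": NeuronArchetype(
            label="cluster3_visual",
            baseline_rate=5.0,
            kernels={
                ("good", "contra"): (k(amplitude=32.0, latency=70.0),),
                ("good", "ipsi"): (k(amplitude=30.0, latency=70.0),),
                ("bad", "contra"): (
                    k(amplitude=32.0, latency=70.0),
                    k(amplitude=5.0, latency=120.0, rise=40.0, decay=300.0),
                ),
                ("bad", "ipsi"): (
                    k(amplitude=30.0, latency=70.0),
                    k(amplitude=5.0, latency=120.0, rise=40.0, decay=300.0),
                ),
            },
            fixation_attenuation=0.2,
        ),
    }
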