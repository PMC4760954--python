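"""Core data model for gamble-task electrophysiology sessions.

Conventions used throughout the package:

* all times are milliseconds; event times live on a single session clock,
  spike offsets are relative to an alignment event (negative = before it);
* analysis windows are half-open ``[lo, hi)``;
* saccade target directions are degrees in mathematical convention
  (45 deg = up-right), stored mod 360;
* reward amounts are in reward units (1 unit = 30 ul of water).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: the four target directions used in the task, degrees
TESTED_DIRECTIONS = (45.0, 135.0, 225.0, 315.0)


class ValidationError(ValueError):
    """A record violates a data-model invariant."""


class ParseError(ValueError):
    """A session file field could not be parsed."""


@dataclass(frozen=True)
class GambleOption:
    """A two-outcome lottery.

    ``p_max`` is the probability of the large outcome; with probability
    ``1 - p_max`` the small outcome ``min_reward`` is paid instead.
    """

    id: int
    max_reward: float
    min_reward: float
    p_max: float
    colors: tuple[str, str] = ("cyan", "cyan")

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_max <= 1.0):
            raise ValidationError(f"gamble {self.id}: p_max={self.p_max} not in [0,1]")
        if self.max_reward < self.min_reward:
            raise ValidationError(f"gamble {self.id}: max_reward < min_reward")

    @property
    def expected_value(self) -> float:
        return self.p_max * self.max_reward + (1.0 - self.p_max) * self.min_reward


@dataclass(frozen=True)
class Target:
    """One saccade target: a direction plus the gamble it promises."""

    direction: float  # degrees, mod 360
    gamble_id: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "direction", float(self.direction) % 360.0)


@dataclass
class TrialRecord:
    """One behavioral trial.

    Choice trials carry exactly two targets at distinct directions,
    no-choice trials exactly one.  ``chosen_index`` addresses ``targets``.
    """

    trial_id: int
    block_id: int
    trial_type: str  # "choice" | "no_choice"
    targets: tuple[Target, ...]
    chosen_index: int
    t_fix_on: float
    t_target_on: float
    t_saccade_on: float
    t_outcome: float
    t_reward: float
    reward_delivered: float

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.trial_type not in ("choice", "no_choice"):
            raise ValidationError(
                f"trial {self.trial_id}: unknown trial_type {self.trial_type!r}"
            )
        n_expected = 2 if self.trial_type == "choice" else 1
        if len(self.targets) != n_expected:
            raise ValidationError(
                f"trial {self.trial_id}: {self.trial_type} trial has "
                f"{len(self.targets)} targets, expected {n_expected}"
            )
        if self.trial_type == "choice":
            if self.targets[0].direction == self.targets[1].direction:
                raise ValidationError(
                    f"trial {self.trial_id}: choice targets share a direction"
                )
        if not (0 <= self.chosen_index < len(self.targets)):
            raise ValidationError(
                f"trial {self.trial_id}: chosen_index {self.chosen_index} out of range"
            )
        if self.rt <= 0:
            raise ValidationError(f"trial {self.trial_id}: rt={self.rt} <= 0")

    @property
    def rt(self) -> float:
        """Saccade reaction time, ms."""
        return self.t_saccade_on - self.t_target_on

    @property
    def chosen_target(self) -> Target:
        return self.targets[self.chosen_index]

    @property
    def nonchosen_target(self) -> Target | None:
        if self.trial_type != "choice":
            return None
        return self.targets[1 - self.chosen_index]

    def event_time(self, event: str) -> float:
        try:
            return {
                "fix_on": self.t_fix_on,
                "target_on": self.t_target_on,
                "saccade_on": self.t_saccade_on,
                "outcome": self.t_outcome,
                "reward": self.t_reward,
            }[event]
        except KeyError:
            raise KeyError(f"unknown alignment event {event!r}") from None


@dataclass
class NeuronData:
    """Spike timestamps of one unit, keyed by trial id (session clock, ms)."""

    neuron_id: int
    spike_times: dict[int, np.ndarray]
    metadata: dict = field(default_factory=dict)

    def validate(self) -> None:
        for trial_id, st in self.spike_times.items():
            st = np.asarray(st)
            if st.ndim != 1:
                raise ValidationError(
                    f"neuron {self.neuron_id} trial {trial_id}: spikes not 1-D"
                )
            if st.size > 1 and not np.all(np.diff(st) > 0):
                raise ValidationError(
                    f"neuron {self.neuron_id} trial {trial_id}: "
                    "spike times not strictly increasing"
                )


@dataclass
class RateTensor:
    """Time-resolved firing rates, ``values[unit, trial_or_condition, bin]``.

    ``bin_edges`` are ms relative to ``align_event`` and bound half-open
    bins; ``normalization`` records which scaling has been applied.
    """

    values: np.ndarray
    align_event: str
    bin_edges: np.ndarray
    normalization: str = "raw"
    unit_ids: tuple[int, ...] | None = None
    trial_ids: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        if self.values.ndim != 3:
            raise ValidationError("RateTensor.values must be 3-D (unit, trial, bin)")
        if not np.all(np.diff(self.bin_edges) > 0):
            raise ValidationError("bin edges must be strictly increasing")
        if self.values.shape[2] != self.bin_edges.size - 1:
            raise ValidationError("values/bin_edges shape mismatch")
        if self.normalization not in ("raw", "unit_minmax", "map_baseline", "zscore"):
            raise ValidationError(f"unknown normalization {self.normalization!r}")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def snap_direction(angle_deg: float) -> float:
    """Nearest tested direction to ``angle_deg``; ties go to the smaller angle."""
    angle = float(angle_deg) % 360.0
    dists = [min(abs(angle - d), 360.0 - abs(angle - d)) for d in TESTED_DIRECTIONS]
    best = min(dists)
    # ties resolved toward the smaller tested angle by scan order
    for d, dist in zip(TESTED_DIRECTIONS, dists):
        if dist == best:
            return d
    raise AssertionError("unreachable")


def circular_diff_deg(a: float, b: float) -> float:
    """Signed circular difference a - b in (-180, 180] degrees."""
    d = (float(a) - float(b)) % 360.0
    if d > 180.0:
        d -= 360.0
    return d
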