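"""Interaction mechanisms and trajectory simulation for the ego's two
cultural identification scores.

At every discrete time step the ego interacts with one uniformly drawn alter.
The interaction moves one or both identification scores by a base increment
scaled by the alter's same-culture degree, and each score is clamped into the
scale bounds immediately after the update:

* POSITIVE — identification with the alter's culture rises by
  ``base + degree * base``; the other score is untouched.
* NEGATIVE — identification with the *other* culture falls by the same
  amount; the alter's own culture is untouched.
* MIXED — the rise is weighted by ``alpha`` and the fall by ``1 - alpha``,
  both computed from the pre-update state.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np

from .ego_network import CultureLabel, EgoNetwork, same_culture_degree

__all__ = [
    "MechanismKind",
    "Mechanism",
    "IdentityState",
    "SimulationConfig",
    "Trajectory",
    "apply_interaction",
    "simulate",
    "final_state",
    "write_trajectory_csv",
]


class MechanismKind(Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    MIXED = "mixed"


@dataclass(frozen=True)
class Mechanism:
    """An update rule, plus the mixing weight for the MIXED rule.

    ``alpha`` is meaningful only for MIXED; MIXED with ``alpha=1`` reproduces
    POSITIVE exactly and MIXED with ``alpha=0`` reproduces NEGATIVE exactly
    under identical random draws.
    """

    kind: MechanismKind
    alpha: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind is MechanismKind.MIXED:
            if self.alpha is None:
                raise ValueError("MIXED mechanism requires alpha")
            if not 0.0 <= self.alpha <= 1.0:
                raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        elif self.alpha is not None:
            raise ValueError(f"alpha is only meaningful for MIXED, got kind={self.kind}")

    @property
    def label(self) -> str:
        if self.kind is MechanismKind.MIXED:
            return f"mixed(alpha={self.alpha:g})"
        return self.kind.value


@dataclass(frozen=True)
class IdentityState:
    """Ego's identification with each culture, both bounded on the scale."""

    id_a: float
    id_b: float

    def get(self, culture: CultureLabel) -> float:
        return self.id_a if culture is CultureLabel.CULTURE_A else self.id_b

    def swapped(self) -> "IdentityState":
        return IdentityState(id_a=self.id_b, id_b=self.id_a)


@dataclass(frozen=True)
class SimulationConfig:
    n_steps: int = 50
    initial_identification: float = 3.5
    base_increment: float = 0.1
    lower_bound: float = 1.0
    upper_bound: float = 6.0

    def __post_init__(self) -> None:
        if self.n_steps < 0:
            raise ValueError(f"n_steps must be >= 0, got {self.n_steps}")
        if self.base_increment <= 0:
            raise ValueError(f"base_increment must be > 0, got {self.base_increment}")
        if not self.lower_bound <= self.initial_identification <= self.upper_bound:
            raise ValueError(
                "initial_identification must lie within "
                f"[{self.lower_bound}, {self.upper_bound}], "
                f"got {self.initial_identification}"
            )

    @property
    def initial_state(self) -> IdentityState:
        return IdentityState(
            id_a=self.initial_identification, id_b=self.initial_identification
        )


@dataclass(frozen=True)
class Trajectory:
    """States over time (index 0 = initial) and the alter drawn at each step."""

    states: tuple[IdentityState, ...]
    interactions: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.states) != len(self.interactions) + 1:
            raise ValueError(
                f"expected {len(self.interactions) + 1} states for "
                f"{len(self.interactions)} interactions, got {len(self.states)}"
            )


def _clamp(value: float, lo: float, hi: float) -> float:
    return lo if value < lo else hi if value > hi else value


def apply_interaction(
    state: IdentityState,
    alter_culture: CultureLabel,
    degree: int,
    mechanism: Mechanism,
    config: SimulationConfig = SimulationConfig(),
) -> IdentityState:
    """Apply a single interaction; pure function of the pre-update state."""
    if degree < 0:
        raise ValueError(f"degree must be >= 0, got {degree}")
    delta = config.base_increment + degree * config.base_increment
    lo, hi = config.lower_bound, config.upper_bound

    same = state.get(alter_culture)
    other = state.get(alter_culture.other)

    if mechanism.kind is MechanismKind.POSITIVE:
        same = _clamp(same + delta, lo, hi)
    elif mechanism.kind is MechanismKind.NEGATIVE:
        other = _clamp(other - delta, lo, hi)
    else:  # MIXED: both moves computed from the pre-update state
        alpha = mechanism.alpha
        same, other = (
            _clamp(same + alpha * delta, lo, hi),
            _clamp(other - (1.0 - alpha) * delta, lo, hi),
        )

    if alter_culture is CultureLabel.CULTURE_A:
        return IdentityState(id_a=same, id_b=other)
    return IdentityState(id_a=other, id_b=same)


def simulate(
    network: EgoNetwork,
    mechanism: Mechanism,
    config: SimulationConfig = SimulationConfig(),
    *,
    rng: np.random.Generator,
) -> Trajectory:
    """Simulate the ego's identification trajectory over ``config.n_steps``.

    At each step one alter is drawn uniformly at random, independently and
    with replacement.  Same-culture degrees are computed once up front: the
    network is static throughout.  Deterministic given the state of ``rng``.
    """
    n = network.n_alters
    if n == 0:
        raise ValueError("network must contain at least one alter")

    degrees = [same_culture_degree(network, a.id) for a in network.alters]
    cultures = [a.culture for a in network.alters]

    draws = rng.integers(0, n, size=config.n_steps)
    states = [config.initial_state]
    state = states[0]
    for alter_id in draws:
        state = apply_interaction(
            state, cultures[alter_id], degrees[alter_id], mechanism, config
        )
        states.append(state)
    return Trajectory(states=tuple(states), interactions=tuple(int(i) for i in draws))


def final_state(trajectory: Trajectory) -> IdentityState:
    """The outcome identification pair: the last state of the trajectory."""
    return trajectory.states[-1]


def write_trajectory_csv(
    path, trajectory: Trajectory, network: EgoNetwork, *, decimals: int = 6
) -> None:
    """Tidy per-step CSV; row 0 carries the initial state with empty
    interaction fields."""
    fmt = f"{{:.{decimals}f}}".format
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["step", "interacted_alter_id", "alter_culture", "id_a", "id_b"])
        first = trajectory.states[0]
        writer.writerow([0, "", "", fmt(first.id_a), fmt(first.id_b)])
        for step, (alter_id, state) in enumerate(
            zip(trajectory.interactions, trajectory.states[1:]), start=1
        ):
            writer.writerow(
                [
                    step,
                    alter_id,
                    network.alters[alter_id].culture.value,
                    fmt(state.id_a),
                    fmt(state.id_b),
                ]
            )
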