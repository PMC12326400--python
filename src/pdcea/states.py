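"""Health-state space for advanced Parkinson's disease cohort models.

The state space combines Hoehn & Yahr (H&Y) severity bands with the
proportion of waking time spent in OFF, plus flagged states for surgical
and PEG complications, adverse-event discontinuation, treatment switch,
second-line therapy and death.  The packaged default has twelve states:
three H&Y bands x two OFF strata (six on-treatment states) plus the six
flagged states.  The enumeration is configurable; nothing in the engine
assumes twelve states beyond the default template.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "HealthState",
    "StateSpace",
    "StateSpaceError",
    "build_state_space",
    "default_template",
    "load_template",
]

VALID_FLAGS = frozenset(
    {
        "on_treatment",
        "surgery_complication",
        "peg_complication",
        "ae_discontinued",
        "switched",
        "dead",
    }
)


class StateSpaceError(ValueError):
    """Raised when a state-space template violates a structural invariant."""


@dataclass(frozen=True)
class HealthState:
    """One Markov health state.

    Parameters
    ----------
    id : str
        Short unique label, e.g. ``"hy23_high_off"``.
    flag : str
        One of :data:`VALID_FLAGS`.  Exactly one state in a space carries
        ``"dead"``.
    hy_stage : int or None
        Hoehn & Yahr stage (2-5) for on-treatment states; ``None`` for
        flagged states where staging is not tracked.
    off_stratum : str or None
        ``"low_off"`` (<50% of waking time in OFF) or ``"high_off"``
        (>=50%), or ``None``.
    utility : float
        Health-state utility in [-0.5, 1]; the dead state has 0.
    cost_per_cycle : float
        Per-cycle state cost in EUR (>= 0); 0 for the dead state.
    """

    id: str
    flag: str = "on_treatment"
    hy_stage: int | None = None
    off_stratum: str | None = None
    utility: float = 0.0
    cost_per_cycle: float = 0.0

    def __post_init__(self) -> None:
        if self.flag not in VALID_FLAGS:
            raise StateSpaceError(
                f"state {self.id!r}: unknown flag {self.flag!r}"
            )
        if not -0.5 <= self.utility <= 1.0:
            raise StateSpaceError(
                f"state {self.id!r}: utility {self.utility} outside [-0.5, 1]"
            )
        if self.cost_per_cycle < 0:
            raise StateSpaceError(
                f"state {self.id!r}: negative cost_per_cycle"
            )
        if self.hy_stage is not None and self.hy_stage not in (2, 3, 4, 5):
            raise StateSpaceError(
                f"state {self.id!r}: hy_stage must be in 2..5 or None"
            )
        if self.off_stratum not in (None, "low_off", "high_off"):
            raise StateSpaceError(
                f"state {self.id!r}: off_stratum {self.off_stratum!r} invalid"
            )

    @property
    def is_dead(self) -> bool:
        return self.flag == "dead"

    @property
    def is_alive(self) -> bool:
        return self.flag != "dead"


@dataclass(frozen=True)
class StateSpace:
    """Ordered collection of :class:`HealthState` with a cycle length.

    ``cycle_length`` is in years (default 1); monthly models use 1/12.
    """

    states: tuple[HealthState, ...]
    cycle_length: float = 1.0

    def __post_init__(self) -> None:
        ids = [s.id for s in self.states]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise StateSpaceError(f"duplicate state ids: {sorted(dupes)}")
        dead = [s for s in self.states if s.is_dead]
        if len(dead) != 1:
            raise StateSpaceError(
                f"exactly one dead state required, found {len(dead)}"
            )
        d = dead[0]
        if d.utility != 0.0 or d.cost_per_cycle != 0.0:
            raise StateSpaceError(
                f"dead state {d.id!r} must have utility 0 and cost 0 "
                f"(got utility={d.utility}, cost={d.cost_per_cycle})"
            )
        if not 0 < self.cycle_length <= 1:
            raise StateSpaceError(
                f"cycle_length must be in (0, 1] years, got {self.cycle_length}"
            )

    def __len__(self) -> int:
        return len(self.states)

    def __iter__(self):
        return iter(self.states)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.states]

    @property
    def dead_index(self) -> int:
        return next(i for i, s in enumerate(self.states) if s.is_dead)

    @property
    def alive_mask(self) -> np.ndarray:
        return np.array([s.is_alive for s in self.states])

    @property
    def utilities(self) -> np.ndarray:
        return np.array([s.utility for s in self.states], dtype=float)

    @property
    def costs_per_cycle(self) -> np.ndarray:
        return np.array([s.cost_per_cycle for s in self.states], dtype=float)

    def index(self, state_id: str) -> int:
        try:
            return self.ids.index(state_id)
        except ValueError:
            raise KeyError(f"unknown state id {state_id!r}") from None

    def with_utilities(self, utilities: Mapping[str, float] | np.ndarray) -> "StateSpace":
        """Return a copy with replaced utilities (dead stays at 0)."""
        if isinstance(utilities, Mapping):
            vec = [utilities.get(s.id, s.utility) for s in self.states]
        else:
            vec = list(np.asarray(utilities, dtype=float))
        new = []
        for s, u in zip(self.states, vec):
            if s.is_dead:
                new.append(s)
            else:
                new.append(
                    HealthState(
                        id=s.id,
                        flag=s.flag,
                        hy_stage=s.hy_stage,
                        off_stratum=s.off_stratum,
                        utility=float(u),
                        cost_per_cycle=s.cost_per_cycle,
                    )
                )
        return StateSpace(tuple(new), self.cycle_length)


def build_state_space(
    template: Mapping | Sequence[Mapping],
    cycle_length: float | None = None,
) -> StateSpace:
    """Build a validated :class:`StateSpace` from a config mapping.

    ``template`` is either a mapping with keys ``states`` (list of state
    mappings) and optional ``cycle_length``, or the bare list of state
    mappings.  Each state mapping provides ``id`` plus any of ``flag``,
    ``hy_stage``, ``off_stratum``, ``utility``, ``cost_per_cycle``.
    Validation errors name the offending state.
    """
    if isinstance(template, Mapping):
        entries: Iterable[Mapping] = template["states"]
        if cycle_length is None:
            cycle_length = float(template.get("cycle_length", 1.0))
    else:
        entries = template
        if cycle_length is None:
            cycle_length = 1.0
    states = []
    for entry in entries:
        known = {
            k: entry[k]
            for k in ("id", "flag", "hy_stage", "off_stratum", "utility", "cost_per_cycle")
            if k in entry
        }
        states.append(HealthState(**known))
    return StateSpace(tuple(states), cycle_length)


def load_template(path: str | Path) -> StateSpace:
    """Read a state-space template from a YAML or JSON file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)  # JSON is a YAML subset
    return build_state_space(data)


def default_template() -> StateSpace:
    """The packaged 12-state advanced-PD template.

    Three H&Y bands (2-3, 4, 5) crossed with two OFF strata give six
    on-treatment states; surgical complication, PEG complication,
    adverse-event discontinuation, switch, second-line therapy and death
    complete the twelve.  Utilities are plausible defaults ordered by
    severity; calibration rescales them per therapy.
    """
    with resources.files("pdcea.data").joinpath("states_12.yaml").open() as fh:
        data = yaml.safe_load(fh)
    return build_state_space(data)


def default_initial_distribution(space: StateSpace) -> np.ndarray:
    """Initial cohort distribution: half of the on-treatment mass in the
    high-OFF stratum (treatment starts when patients spend >50% of waking
    time in OFF for half the cohort), split uniformly over H&Y bands."""
    init = np.zeros(len(space))
    low = [i for i, s in enumerate(space) if s.off_stratum == "low_off"]
    high = [i for i, s in enumerate(space) if s.off_stratum == "high_off"]
    if not low or not high:
        raise StateSpaceError(
            "default initial distribution needs low_off and high_off states"
        )
    init[low] = 0.5 / len(low)
    init[high] = 0.5 / len(high)
    return init
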