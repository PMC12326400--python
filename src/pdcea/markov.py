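"""Markov cohort engine: transition validation, cohort propagation,
discounted accumulation of life-years, QALYs and state costs, and an
individual-level microsimulation cross-check.

Conventions
-----------
The cohort trace stores occupancy at cycle boundaries 0..n.  Effects are
accumulated at the *end* of each cycle: cycle t contributes
``(1 + r) ** (-t * cycle_length)`` times ``cycle_length`` times the
occupancy at t, for t = 1..n; the time-zero occupancy is not counted.
An optional half-cycle correction instead credits cycle t with the mean
of the adjacent boundary occupancies, discounted at t - 1/2 cycles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .states import StateSpace

__all__ = [
    "TransitionError",
    "CohortTrace",
    "EffectSummary",
    "MicrosimulationResult",
    "MarkovCohort",
    "validate_transitions",
    "run_cohort",
    "discounted_effects",
    "discounted_state_costs",
    "microsimulate",
    "trace_to_frame",
]

ROW_TOL = 1e-9


class TransitionError(ValueError):
    """Raised for transition matrices that are not valid dead-absorbing
    row-stochastic matrices on the given state space."""


@dataclass(frozen=True)
class EffectSummary:
    """Discounted life-years and QALYs for one therapy scenario."""

    life_years: float
    qalys: float
    therapy_id: str = ""


@dataclass(frozen=True)
class MicrosimulationResult(EffectSummary):
    """Monte-Carlo estimate of the cohort effects with standard errors."""

    se_life_years: float = 0.0
    se_qalys: float = 0.0
    n_individuals: int = 0


@dataclass(frozen=True)
class CohortTrace:
    """Cohort occupancy per (cycle, state).

    ``occupancy`` has shape ``(n_cycles + 1, n_states)``; row 0 is the
    initial distribution.  Every row sums to 1 (mass conservation).
    """

    occupancy: np.ndarray
    initial_distribution: np.ndarray

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1


def validate_transitions(m: np.ndarray, space: StateSpace) -> np.ndarray:
    """Validate a transition matrix against a state space.

    Returns the matrix (as float ndarray) unchanged if it is square with
    one row per state, non-negative, row-stochastic within ``1e-9`` and
    absorbing in the dead state; raises :class:`TransitionError` naming
    the first offending row otherwise.
    """
    m = np.asarray(m, dtype=float)
    n = len(space)
    if m.shape != (n, n):
        raise TransitionError(
            f"matrix shape {m.shape} does not match {n}-state space"
        )
    if (m < 0).any():
        i, j = np.argwhere(m < 0)[0]
        raise TransitionError(
            f"negative probability {m[i, j]:.6g} at "
            f"({space.ids[i]!r} -> {space.ids[j]!r})"
        )
    sums = m.sum(axis=1)
    bad = np.abs(sums - 1.0) > ROW_TOL
    if bad.any():
        i = int(np.argmax(bad))
        raise TransitionError(
            f"row {space.ids[i]!r} sums to {sums[i]:.12g}, expected 1"
        )
    d = space.dead_index
    unit = np.zeros(n)
    unit[d] = 1.0
    if not np.allclose(m[d], unit, atol=ROW_TOL, rtol=0):
        raise TransitionError("dead state row is not absorbing")
    return m


def run_cohort(
    space: StateSpace,
    m: np.ndarray,
    init: np.ndarray,
    n_cycles: int,
) -> CohortTrace:
    """Propagate a cohort through the chain for ``n_cycles`` cycles.

    ``occupancy[t + 1] = occupancy[t] @ m``.  ``init`` must sum to 1.
    """
    m = validate_transitions(m, space)
    init = np.asarray(init, dtype=float)
    if init.shape != (len(space),):
        raise ValueError(
            f"initial distribution has length {init.size}, expected {len(space)}"
        )
    if (init < 0).any() or abs(init.sum() - 1.0) > ROW_TOL:
        raise ValueError(
            f"initial distribution must be non-negative and sum to 1 "
            f"(sum={init.sum():.12g})"
        )
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    occ = np.empty((n_cycles + 1, len(space)))
    occ[0] = init
    for t in range(n_cycles):
        occ[t + 1] = occ[t] @ m
    return CohortTrace(occupancy=occ, initial_distribution=init)


def _discount_weights(
    n_cycles: int, cycle_length: float, rate: float, correction: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cycle discount factors and the occupancy weighting.

    Returns ``(d, w)`` where the credited quantity for cycle t (1..n) is
    ``d[t-1] * cycle_length * (w @ occupancy rows)`` — w selects either
    the end-of-cycle occupancy or the adjacent-cycle mean.
    """
    t = np.arange(1, n_cycles + 1, dtype=float)
    if correction == "none":
        d = (1.0 + rate) ** (-t * cycle_length)
    elif correction == "half_cycle":
        d = (1.0 + rate) ** (-(t - 0.5) * cycle_length)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return d, t


def discounted_effects(
    trace: CohortTrace,
    space: StateSpace,
    rate: float = 0.035,
    correction: str = "none",
    therapy_id: str = "",
) -> EffectSummary:
    """Discounted life-years and QALYs from a cohort trace.

    ``rate`` is the annual discount rate (3.5% default, applied to both
    effects and, elsewhere, costs).  ``correction`` is ``"none"``
    (end-of-cycle counting) or ``"half_cycle"``.
    """
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    occ = trace.occupancy
    n = trace.n_cycles
    dt = space.cycle_length
    d, _ = _discount_weights(n, dt, rate, correction)
    alive = occ @ space.alive_mask.astype(float)
    qual = occ @ space.utilities
    if correction == "half_cycle":
        alive_c = 0.5 * (alive[:-1] + alive[1:])
        qual_c = 0.5 * (qual[:-1] + qual[1:])
    else:
        alive_c = alive[1:]
        qual_c = qual[1:]
    ly = float(np.sum(d * dt * alive_c))
    qaly = float(np.sum(d * dt * qual_c))
    return EffectSummary(life_years=ly, qalys=qaly, therapy_id=therapy_id)


def discounted_state_costs(
    trace: CohortTrace,
    space: StateSpace,
    rate: float = 0.035,
    correction: str = "none",
) -> float:
    """Discounted accumulated per-cycle state costs (EUR)."""
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    d, _ = _discount_weights(trace.n_cycles, space.cycle_length, rate, correction)
    cost = trace.occupancy @ space.costs_per_cycle
    cost_c = 0.5 * (cost[:-1] + cost[1:]) if correction == "half_cycle" else cost[1:]
    return float(np.sum(d * cost_c))


def microsimulate(
    space: StateSpace,
    m: np.ndarray,
    init: np.ndarray,
    n_individuals: int,
    n_cycles: int,
    seed: int,
    rate: float = 0.035,
    therapy_id: str = "",
) -> MicrosimulationResult:
    """Individual-level Monte-Carlo walk through the same chain.

    Serves as a stochastic oracle for :func:`run_cohort`: mean
    life-years/QALYs converge to the cohort values.  ``seed`` is
    mandatory; there is no hidden global random state.
    """
    m = validate_transitions(m, space)
    init = np.asarray(init, dtype=float)
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    rng = np.random.default_rng(seed)
    n_states = len(space)
    cum = np.cumsum(m, axis=1)
    cum[:, -1] = 1.0  # guard against rounding in the last column
    states = rng.choice(n_states, size=n_individuals, p=init / init.sum())
    alive = space.alive_mask.astype(float)
    util = space.utilities
    dt = space.cycle_length
    ly = np.zeros(n_individuals)
    qa = np.zeros(n_individuals)
    for t in range(1, n_cycles + 1):
        u = rng.random(n_individuals)
        states = (cum[states] > u[:, None]).argmax(axis=1)
        d = (1.0 + rate) ** (-t * dt)
        ly += d * dt * alive[states]
        qa += d * dt * util[states]
    return MicrosimulationResult(
        life_years=float(ly.mean()),
        qalys=float(qa.mean()),
        therapy_id=therapy_id,
        se_life_years=float(ly.std(ddof=1) / np.sqrt(n_individuals)),
        se_qalys=float(qa.std(ddof=1) / np.sqrt(n_individuals)),
        n_individuals=n_individuals,
    )


def trace_to_frame(trace: CohortTrace, space: StateSpace):
    """Tidy trace export: DataFrame with columns cycle, state_id, occupancy."""
    import pandas as pd

    n = trace.n_cycles
    return pd.DataFrame(
        {
            "cycle": np.repeat(np.arange(n + 1), len(space)),
            "state_id": np.tile(space.ids, n + 1),
            "occupancy": trace.occupancy.ravel(),
        }
    )


class MarkovCohort:
    """Markov cohort model for one therapy scenario.

    Bundles a state space, transition matrix and initial distribution;
    :meth:`run` propagates the cohort and returns a
    :class:`MarkovCohortResults` carrying the trace and discounted
    effect/cost summaries.

    Examples
    --------
    >>> from pdcea.states import default_template, default_initial_distribution
    >>> space = default_template()
    >>> # model = MarkovCohort(space, matrix, default_initial_distribution(space))
    >>> # res = model.run(n_cycles=20, rate=0.035)
    """

    def __init__(
        self,
        space: StateSpace,
        transition_matrix: np.ndarray,
        initial_distribution: np.ndarray,
        therapy_id: str = "",
    ):
        self.space = space
        self.transition_matrix = validate_transitions(transition_matrix, space)
        self.initial_distribution = np.asarray(initial_distribution, dtype=float)
        self.therapy_id = therapy_id

    def run(
        self,
        n_cycles: int = 20,
        rate: float = 0.035,
        correction: str = "none",
    ) -> "MarkovCohortResults":
        trace = run_cohort(
            self.space, self.transition_matrix, self.initial_distribution, n_cycles
        )
        effects = discounted_effects(
            trace, self.space, rate, correction, therapy_id=self.therapy_id
        )
        state_costs = discounted_state_costs(trace, self.space, rate, correction)
        return MarkovCohortResults(self, trace, effects, state_costs, rate, correction)

    def microsimulate(
        self,
        n_individuals: int,
        n_cycles: int,
        seed: int,
        rate: float = 0.035,
    ) -> MicrosimulationResult:
        return microsimulate(
            self.space,
            self.transition_matrix,
            self.initial_distribution,
            n_individuals,
            n_cycles,
            seed,
            rate,
            therapy_id=self.therapy_id,
        )


@dataclass
class MarkovCohortResults:
    """Results of one cohort run: trace plus discounted summaries."""

    model: MarkovCohort
    trace: CohortTrace
    effects: EffectSummary
    state_costs: float
    rate: float
    correction: str

    def to_frame(self):
        return trace_to_frame(self.trace, self.model.space)

    def summary(self) -> str:
        s = self.model.space
        dead = self.trace.occupancy[-1, s.dead_index]
        lines = [
            "Markov cohort results",
            "---------------------",
            f"therapy:            {self.model.therapy_id or '(unnamed)'}",
            f"states / cycles:    {len(s)} / {self.trace.n_cycles}"
            f" (cycle {s.cycle_length:g} y)",
            f"discount rate:      {self.rate:.3%} ({self.correction})",
            f"life-years (disc.): {self.effects.life_years:.4f}",
            f"QALYs (disc.):      {self.effects.qalys:.4f}",
            f"dead at horizon:    {dead:.4f}",
        ]
        return "\n".join(lines)
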