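"""Synthetic transition matrices, utility maps and calibration.

Per-therapy transition probabilities for the advanced-PD model are not
published; this module constructs structurally plausible matrices over
the default state space and calibrates a low-dimensional
parameterization — a per-cycle mortality hazard multiplier and a
utility scale — so that the discounted life-year and QALY totals of the
cohort run reproduce the per-therapy targets.  Discounted life-years
are strictly decreasing in the mortality multiplier and discounted
QALYs are linear in the utility scale, so a nested one-dimensional
root-finding scheme (Brent's method for mortality, an exact ratio for
the utility scale) is deterministic and derivative-free.

A randomized scenario generator supports property testing of the
engine; everything is reproducible from an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from . import markov
from .states import StateSpace, default_initial_distribution, default_template

__all__ = [
    "CalibrationTarget",
    "ScenarioSpec",
    "Scenario",
    "InfeasibleTargetError",
    "TherapyCalibration",
    "CalibrationResult",
    "calibrate",
    "therapy_transition_matrix",
    "generate_scenario",
]

# per-cycle baseline death probabilities before the hazard multiplier
_BASE_DEATH = {"hy3": 0.025, "hy4": 0.045, "hy5": 0.085, "flagged": 0.050}


class InfeasibleTargetError(ValueError):
    """Raised when no parameter choice can reach the target, naming the
    binding bound."""


@dataclass(frozen=True)
class CalibrationTarget:
    therapy_id: str
    target_life_years: float
    target_qalys: float
    tolerance: float = 0.01  # relative

    def __post_init__(self) -> None:
        if self.target_life_years <= 0 or self.target_qalys <= 0:
            raise ValueError("targets must be > 0")
        if not 0 < self.tolerance <= 0.05:
            raise ValueError("tolerance must be in (0, 0.05]")


@dataclass(frozen=True)
class ScenarioSpec:
    seed: int
    n_states: int = 5
    mortality_scale: float = 1.0
    utility_range: tuple[float, float] = (0.1, 0.9)
    progression_bias: float = 1.0

    def __post_init__(self) -> None:
        if self.n_states < 2:
            raise ValueError("n_states must be >= 2")
        lo, hi = self.utility_range
        if not 0 <= lo <= hi <= 1:
            raise ValueError("utility_range must be within [0, 1]")
        if self.mortality_scale < 0 or self.progression_bias <= 0:
            raise ValueError("mortality_scale >= 0 and progression_bias > 0 required")


@dataclass(frozen=True)
class Scenario:
    """A complete model input: space, matrix, initial distribution."""

    space: StateSpace
    transition_matrix: np.ndarray
    initial_distribution: np.ndarray
    therapy_id: str = ""


def _death_base(space: StateSpace) -> np.ndarray:
    base = np.zeros(len(space))
    for i, s in enumerate(space):
        if s.is_dead:
            continue
        if s.hy_stage is None:
            base[i] = _BASE_DEATH["flagged"]
        else:
            base[i] = _BASE_DEATH.get(f"hy{s.hy_stage}", _BASE_DEATH["flagged"])
    return base


def therapy_transition_matrix(
    space: StateSpace,
    mortality_hazard: float = 1.0,
    progression: float = 0.10,
    off_worsening: float = 0.05,
    off_improvement: float = 0.05,
    ae_discontinuation: float = 0.02,
    switch: float = 0.02,
    complication: float = 0.02,
    complication_target: str = "peg_complication",
) -> np.ndarray:
    """Structured transition matrix over the default-template layout.

    On-treatment states progress along H&Y, drift between OFF strata and
    leak into complication / adverse-event / switch states; flagged
    states persist until death (no re-entry into on-treatment states);
    dead is absorbing.  The per-cycle death probability of each state is
    its severity-graded baseline times ``mortality_hazard`` (clipped to
    keep rows stochastic); surviving mass is shared among the outflow
    destinations and the diagonal.
    """
    if mortality_hazard < 0:
        raise ValueError("mortality_hazard must be >= 0")
    n = len(space)
    ids = space.ids
    idx = {sid: i for i, sid in enumerate(ids)}
    dead = space.dead_index
    death = np.clip(_death_base(space) * mortality_hazard, 0.0, 1.0)
    m = np.zeros((n, n))
    next_hy = {3: 4, 4: 5, 5: None}
    for i, s in enumerate(space):
        if s.is_dead:
            m[i, dead] = 1.0
            continue
        flows: dict[int, float] = {}
        if s.flag == "on_treatment" and s.hy_stage is not None:
            nxt = next_hy.get(s.hy_stage)
            if nxt is not None:
                tgt = f"hy{nxt}_{s.off_stratum}"
                if tgt in idx:
                    flows[idx[tgt]] = progression
            if s.off_stratum == "low_off":
                other = ids[i].replace("low_off", "high_off")
                if other in idx:
                    flows[idx[other]] = flows.get(idx[other], 0) + off_worsening
            elif s.off_stratum == "high_off":
                other = ids[i].replace("high_off", "low_off")
                if other in idx:
                    flows[idx[other]] = flows.get(idx[other], 0) + off_improvement
            if "ae_discontinued" in idx:
                flows[idx["ae_discontinued"]] = ae_discontinuation
            if "switched" in idx:
                flows[idx["switched"]] = switch
            if complication_target in idx:
                flows[idx[complication_target]] = (
                    flows.get(idx[complication_target], 0) + complication
                )
        # flagged states: persist or die (no re-entry)
        m[i, dead] = death[i]
        survive = 1.0 - death[i]
        out = sum(flows.values())
        if out > survive and out > 0:
            scale = survive / out
            flows = {j: p * scale for j, p in flows.items()}
            out = survive
        for j, p in flows.items():
            m[i, j] += p
        m[i, i] += survive - out
    return m


def _space_for_utility_scale(space: StateSpace, scale: float) -> StateSpace:
    return space.with_utilities(space.utilities * scale)


@dataclass
class CalibrationResult:
    """Calibrated scenario parameters and achieved effects."""

    target: CalibrationTarget
    mortality_hazard: float
    utility_scale: float
    space: StateSpace
    transition_matrix: np.ndarray
    initial_distribution: np.ndarray
    achieved: markov.EffectSummary
    rate: float
    n_cycles: int

    @property
    def relative_errors(self) -> tuple[float, float]:
        t = self.target
        return (
            abs(self.achieved.life_years - t.target_life_years) / t.target_life_years,
            abs(self.achieved.qalys - t.target_qalys) / t.target_qalys,
        )

    def scenario(self) -> Scenario:
        return Scenario(
            space=self.space,
            transition_matrix=self.transition_matrix,
            initial_distribution=self.initial_distribution,
            therapy_id=self.target.therapy_id,
        )

    def summary(self) -> str:
        e_ly, e_q = self.relative_errors
        t = self.target
        return "\n".join(
            [
                f"Calibration: {t.therapy_id}",
                "-" * (13 + len(t.therapy_id)),
                f"mortality hazard multiplier: {self.mortality_hazard:.6f}",
                f"utility scale:               {self.utility_scale:.6f}",
                f"life-years: {self.achieved.life_years:.4f}"
                f" (target {t.target_life_years:.4f}, rel err {e_ly:.2%})",
                f"QALYs:      {self.achieved.qalys:.4f}"
                f" (target {t.target_qalys:.4f}, rel err {e_q:.2%})",
                f"discount rate {self.rate:.1%}, horizon {self.n_cycles} cycles",
            ]
        )


class TherapyCalibration:
    """Calibrate mortality hazard and utility scale to effect targets.

    ``fit()`` solves, in order: mortality multiplier m such that the
    discounted life-years of the cohort run equal the target (Brent root
    find — life-years are strictly decreasing in m), then the utility
    scale k = target QALYs / QALYs(m, k=1) (QALYs are linear in k).
    """

    def __init__(
        self,
        target: CalibrationTarget,
        space: StateSpace | None = None,
        rate: float = 0.035,
        n_cycles: int = 20,
        initial_distribution: np.ndarray | None = None,
        correction: str = "none",
        **matrix_kwargs,
    ):
        self.target = target
        self.space = space if space is not None else default_template()
        self.rate = rate
        self.n_cycles = n_cycles
        self.init = (
            initial_distribution
            if initial_distribution is not None
            else default_initial_distribution(self.space)
        )
        self.correction = correction
        self.matrix_kwargs = matrix_kwargs

    def _effects(self, hazard: float, space: StateSpace) -> markov.EffectSummary:
        m = therapy_transition_matrix(self.space, hazard, **self.matrix_kwargs)
        trace = markov.run_cohort(self.space, m, self.init, self.n_cycles)
        return markov.discounted_effects(
            trace, space, self.rate, self.correction, self.target.therapy_id
        )

    def fit(self) -> CalibrationResult:
        t = self.target
        umax = float(self.space.utilities.max())
        if t.target_qalys > t.target_life_years:
            raise InfeasibleTargetError(
                f"{t.therapy_id}: target QALYs ({t.target_qalys}) exceed target "
                f"life-years ({t.target_life_years}) with utilities capped at 1"
            )
        ly_max = self._effects(0.0, self.space).life_years
        if t.target_life_years > ly_max * (1 + t.tolerance):
            raise InfeasibleTargetError(
                f"{t.therapy_id}: target life-years {t.target_life_years} exceed "
                f"the zero-mortality bound {ly_max:.4f} at this horizon/rate"
            )
        hi = 1.0
        f = lambda h: self._effects(h, self.space).life_years - t.target_life_years
        while f(hi) > 0:
            hi *= 2.0
            if hi > 1e6:
                raise InfeasibleTargetError(
                    f"{t.therapy_id}: life-year target {t.target_life_years} "
                    "unreachable even at extreme mortality"
                )
        hazard = (
            0.0
            if f(0.0) <= 0
            else float(brentq(f, 0.0, hi, xtol=1e-12, rtol=1e-12))
        )
        base = self._effects(hazard, self.space)
        if base.qalys <= 0:
            raise InfeasibleTargetError(
                f"{t.therapy_id}: baseline utilities give zero QALYs"
            )
        scale = t.target_qalys / base.qalys
        if scale * umax > 1.0 + 1e-12:
            raise InfeasibleTargetError(
                f"{t.therapy_id}: required utility scale {scale:.4f} pushes the "
                f"maximum state utility {umax} above 1 (binding bound: utility cap)"
            )
        space = _space_for_utility_scale(self.space, scale)
        achieved = self._effects(hazard, space)
        matrix = therapy_transition_matrix(self.space, hazard, **self.matrix_kwargs)
        return CalibrationResult(
            target=t,
            mortality_hazard=hazard,
            utility_scale=scale,
            space=space,
            transition_matrix=matrix,
            initial_distribution=self.init,
            achieved=achieved,
            rate=self.rate,
            n_cycles=self.n_cycles,
        )


def calibrate(
    target: CalibrationTarget,
    space: StateSpace | None = None,
    rate: float = 0.035,
    n_cycles: int = 20,
    **kwargs,
) -> CalibrationResult:
    """Functional wrapper around :class:`TherapyCalibration`."""
    return TherapyCalibration(target, space, rate, n_cycles, **kwargs).fit()


def generate_scenario(spec: ScenarioSpec) -> Scenario:
    """Random dead-absorbing scenario for property testing.

    State 0..n-2 are alive with utilities drawn uniformly from
    ``utility_range``; the last state is dead.  Rows are Dirichlet draws
    over the alive states tilted toward higher-index states by
    ``progression_bias``, with a death probability proportional to
    ``mortality_scale`` (0 means no death mass leaves any alive state).
    Reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_states
    lo, hi = spec.utility_range
    from .states import HealthState

    states = [
        HealthState(
            id=f"s{i}",
            flag="on_treatment",
            utility=float(rng.uniform(lo, hi)),
            cost_per_cycle=float(rng.uniform(0, 5000)),
        )
        for i in range(n - 1)
    ]
    states.append(HealthState(id="dead", flag="dead"))
    space = StateSpace(tuple(states), cycle_length=1.0)
    m = np.zeros((n, n))
    alpha = spec.progression_bias ** np.arange(n - 1)
    for i in range(n - 1):
        death = float(np.clip(spec.mortality_scale * rng.uniform(0.0, 0.3), 0, 1))
        alive_part = rng.dirichlet(alpha) * (1.0 - death)
        m[i, : n - 1] = alive_part
        m[i, -1] = death
    m[-1, -1] = 1.0
    m /= m.sum(axis=1, keepdims=True)  # exact row normalization
    init = np.zeros(n)
    weights = rng.dirichlet(np.ones(n - 1))
    init[: n - 1] = weights
    return Scenario(space=space, transition_matrix=m, initial_distribution=init)
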