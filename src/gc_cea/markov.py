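"""Monthly-cycle cohort Markov models with three health states.

Each long-term model (curative resection, palliative resection, chemotherapy)
has a front state (disease-free / progression-free survival), a progressive
disease (PD) state and absorbing death.  Disease transitions come from
parametric survival curves refit to trial Kaplan-Meier data; background
mortality in the front state comes from an annual life table converted to a
monthly probability.  The PD -> death clock runs on time since PD entry,
tracked exactly (within monthly resolution) by per-entry-cycle sub-cohorts,
floored by background mortality.

Costs and QALYs accrue at cycle start (no half-cycle correction by default;
a flag enables trapezoidal state membership) and are discounted at an annual
rate with continuous-in-cycle compounding, ``(1 + r)^(-cycle/12)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .survival import SurvivalModel, cycle_transition_probs
from .tree import Destination, TerminalNode

logger = logging.getLogger(__name__)

__all__ = [
    "LifeTable",
    "EconSettings",
    "CostBlock",
    "MarkovSpec",
    "CohortTrace",
    "monthly_background_mortality",
    "discount_factor",
    "run_cohort",
    "accrue",
    "run_markov",
    "strategy_outcome",
    "read_life_table_csv",
    "write_life_table_csv",
]


@dataclass(frozen=True)
class LifeTable:
    """Annual death probability qx by integer age."""

    ages: np.ndarray
    qx: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        qx = np.asarray(self.qx, dtype=float)
        if ages.shape != qx.shape or ages.size == 0:
            raise ValueError("ages and qx must be equal-length, non-empty")
        if np.any((qx < 0) | (qx > 1)):
            raise ValueError("qx must lie in [0, 1]")
        if np.any(np.diff(ages) != 1):
            raise ValueError("ages must be consecutive integers")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "qx", qx)

    def annual_qx(self, age: float) -> float:
        """qx at completed age, clamping (with a warning) outside the table."""
        a = int(np.floor(age))
        lo, hi = int(self.ages[0]), int(self.ages[-1])
        if a < lo or a > hi:
            logger.warning("age %s outside life table [%d, %d]; clamping", age, lo, hi)
            a = min(max(a, lo), hi)
        return float(self.qx[a - lo])


def monthly_background_mortality(life_table: LifeTable, age: float) -> float:
    """Monthly death probability ``1 - (1 - qx)^(1/12)`` at the given age."""
    qx = life_table.annual_qx(age)
    return 1.0 - (1.0 - qx) ** (1.0 / 12.0)


@dataclass(frozen=True)
class EconSettings:
    """Cohort, horizon, discounting and decision-threshold settings."""

    annual_discount_rate: float = 0.03
    horizon_years: int = 40
    cycle_months: int = 1
    start_age: float = 56.0
    wtp: float = 29313.0  # 3x 2018 Chinese GDP per capita, US$/QALY
    half_cycle_correction: bool = False

    def __post_init__(self) -> None:
        if self.annual_discount_rate < 0:
            raise ValueError("discount rate must be >= 0")
        if self.horizon_years <= 0:
            raise ValueError("horizon must be positive")
        if self.cycle_months != 1:
            raise ValueError("only monthly cycles are supported")

    @property
    def n_cycles(self) -> int:
        return self.horizon_years * 12


def discount_factor(settings: EconSettings, cycle: int | np.ndarray):
    """Discount factor ``(1 + r)^(-cycle/12)`` at the start of ``cycle``."""
    cycle_arr = np.asarray(cycle, dtype=float)
    if np.any(cycle_arr < 0):
        raise ValueError("cycle must be >= 0")
    df = (1.0 + settings.annual_discount_rate) ** (-cycle_arr / 12.0)
    return df if np.ndim(cycle) else float(df)


@dataclass(frozen=True)
class CostBlock:
    """Annual cost triple (2019 US$/year) of one health state."""

    direct_medical: float = 0.0
    indirect: float = 0.0
    direct_nonmedical: float = 0.0

    def __post_init__(self) -> None:
        for name in ("direct_medical", "indirect", "direct_nonmedical"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total(self) -> float:
        return self.direct_medical + self.indirect + self.direct_nonmedical


@dataclass(frozen=True)
class MarkovSpec:
    """One long-term model: transitions, utilities and cost schedule.

    ``utility_switch_month`` > 0 switches the front-state utility (used by
    the curative model, where the first six months are spent on adjuvant
    chemotherapy at utility 0.68 before the post-gastrectomy utility 0.81).
    ``cost_switch_month`` > 0 switches the front-state cost block the same
    way (surgery-year costs for the first twelve cycles).  Adjuvant
    chemotherapy is charged per cycle for the first ``adjuvant_n_cycles``.
    """

    name: str
    progression_model: SurvivalModel  # front -> PD, clock from model entry
    pd_death_model: SurvivalModel  # PD -> death, clock from PD entry
    utility_front_early: float = 0.0
    utility_front_late: float = 0.0
    utility_switch_month: int = 0
    utility_pd: float = 0.0
    cost_front_early: CostBlock = field(default_factory=CostBlock)
    cost_front_late: CostBlock = field(default_factory=CostBlock)
    cost_switch_month: int = 0
    cost_pd: CostBlock = field(default_factory=CostBlock)
    adjuvant_cost_per_cycle: float = 0.0
    adjuvant_n_cycles: int = 0

    def __post_init__(self) -> None:
        for name in ("utility_front_early", "utility_front_late", "utility_pd"):
            u = getattr(self, name)
            if not 0.0 <= u <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.adjuvant_cost_per_cycle < 0 or self.adjuvant_n_cycles < 0:
            raise ValueError("adjuvant cost/cycles must be >= 0")
        if self.utility_switch_month < 0 or self.cost_switch_month < 0:
            raise ValueError("switch months must be >= 0")


@dataclass
class CohortTrace:
    """Per-cycle state occupancy of one cohort (occupancy sums to 1)."""

    cycles: np.ndarray
    ages: np.ndarray
    front: np.ndarray
    pd: np.ndarray
    dead: np.ndarray
    df: np.ndarray  # discount factors at cycle start
    discounted_cost: np.ndarray | None = None
    discounted_qaly: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        data = {
            "cycle": self.cycles,
            "age": self.ages,
            "front": self.front,
            "pd": self.pd,
            "dead": self.dead,
        }
        if self.discounted_cost is not None:
            data["discounted_cost"] = self.discounted_cost
            data["discounted_qaly"] = self.discounted_qaly
        return pd.DataFrame(data)


def run_cohort(
    progression_model: SurvivalModel,
    pd_death_model: SurvivalModel,
    settings: EconSettings,
    life_table: LifeTable,
) -> CohortTrace:
    """Roll one cohort forward; occupancy only (accrual is separate).

    Competing risks in the front state each cycle: background death first
    (p_bg), then progression among survivors, p_pd = (1 - p_bg) * p_prog.
    PD sub-cohorts are indexed by time since PD entry; each dies with
    ``max(p_pd_death(duration), p_bg(age))``.
    """
    n = settings.n_cycles
    cycles = np.arange(n)
    ages = settings.start_age + cycles / 12.0
    p_prog = cycle_transition_probs(progression_model, n)
    p_pd_death = cycle_transition_probs(pd_death_model, n)
    p_bg = np.array(
        [monthly_background_mortality(life_table, a) for a in ages]
    )

    front = np.empty(n)
    pd_total = np.empty(n)
    dead = np.empty(n)
    f = 1.0
    d = 0.0
    pd_occ = np.zeros(n + 1)  # index = time since PD entry (cycles)
    for t in range(n):
        front[t] = f
        pd_total[t] = pd_occ.sum()
        dead[t] = d
        # transitions applied at the end of cycle t
        die_front = f * p_bg[t]
        to_pd = f * (1.0 - p_bg[t]) * p_prog[t]
        p_die_pd = np.maximum(p_pd_death[: t + 1], p_bg[t])
        pd_deaths = float(pd_occ[: t + 1] @ p_die_pd)
        pd_occ[1 : t + 2] = pd_occ[: t + 1] * (1.0 - p_die_pd)
        pd_occ[0] = to_pd
        f -= die_front + to_pd
        d += die_front + pd_deaths
    return CohortTrace(
        cycles=cycles,
        ages=ages,
        front=front,
        pd=pd_total,
        dead=dead,
        df=discount_factor(settings, cycles),
    )


def _membership(trace: CohortTrace, settings: EconSettings):
    """State membership used for accrual (start-of-cycle, or trapezoidal)."""
    front, pd_occ = trace.front, trace.pd
    if settings.half_cycle_correction:
        front = np.append((front[:-1] + front[1:]) / 2.0, front[-1] / 2.0)
        pd_occ = np.append((pd_occ[:-1] + pd_occ[1:]) / 2.0, pd_occ[-1] / 2.0)
    return front, pd_occ


def accrue(
    trace: CohortTrace,
    spec: MarkovSpec,
    settings: EconSettings,
    discounted: bool = True,
) -> tuple[float, float]:
    """Total (cost, QALY) accrued over the trace under one spec."""
    n = trace.cycles.size
    df = trace.df if discounted else np.ones(n)
    front, pd_occ = _membership(trace, settings)

    su = min(spec.utility_switch_month, n)
    u_front = np.full(n, spec.utility_front_late)
    u_front[:su] = spec.utility_front_early
    qaly = float((front * u_front / 12.0) @ df + spec.utility_pd / 12.0 * (pd_occ @ df))

    sc = min(spec.cost_switch_month, n)
    c_front = np.full(n, spec.cost_front_late.total)
    c_front[:sc] = spec.cost_front_early.total
    cost = float((front * c_front / 12.0) @ df + spec.cost_pd.total / 12.0 * (pd_occ @ df))
    na = min(spec.adjuvant_n_cycles, n)
    if na and spec.adjuvant_cost_per_cycle:
        cost += spec.adjuvant_cost_per_cycle * float(front[:na] @ df[:na])
    return cost, qaly


def run_markov(
    spec: MarkovSpec, settings: EconSettings, life_table: LifeTable
) -> CohortTrace:
    """Roll the cohort and fill per-cycle discounted accrual columns."""
    trace = run_cohort(spec.progression_model, spec.pd_death_model, settings, life_table)
    n = trace.cycles.size
    front, pd_occ = _membership(trace, settings)
    su = min(spec.utility_switch_month, n)
    u_front = np.full(n, spec.utility_front_late)
    u_front[:su] = spec.utility_front_early
    sc = min(spec.cost_switch_month, n)
    c_front = np.full(n, spec.cost_front_late.total)
    c_front[:sc] = spec.cost_front_early.total
    qaly = (front * u_front + pd_occ * spec.utility_pd) / 12.0 * trace.df
    cost = (front * c_front + pd_occ * spec.cost_pd.total) / 12.0 * trace.df
    na = min(spec.adjuvant_n_cycles, n)
    if na and spec.adjuvant_cost_per_cycle:
        cost[:na] += spec.adjuvant_cost_per_cycle * front[:na] * trace.df[:na]
    trace.discounted_cost = cost
    trace.discounted_qaly = qaly
    return trace


def strategy_outcome(
    nodes: list[TerminalNode],
    dest_results: dict[Destination, tuple[float, float]],
) -> tuple[float, float]:
    """Tree-Markov composition: expected (cost, QALY) over terminal nodes.

    ``dest_results`` maps each Markov destination to its (cost, qaly)
    totals; perioperative deaths contribute their upfront cost and 0 QALYs.
    """
    total_cost = 0.0
    total_qaly = 0.0
    for node in nodes:
        dest = node.markov_destination
        if dest is Destination.DEAD_UPFRONT:
            mc, mq = 0.0, 0.0
        else:
            if dest not in dest_results:
                raise KeyError(f"no Markov results for destination {dest.value}")
            mc, mq = dest_results[dest]
        total_cost += node.probability * (node.upfront_cost + mc)
        total_qaly += node.probability * mq
    return total_cost, total_qaly


def read_life_table_csv(path) -> LifeTable:
    df = pd.read_csv(path)
    return LifeTable(ages=df["age"].to_numpy(), qx=df["qx"].to_numpy())


def write_life_table_csv(table: LifeTable, path) -> None:
    pd.DataFrame({"age": table.ages, "qx": table.qx}).to_csv(path, index=False)
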