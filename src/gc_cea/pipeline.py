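"""End-to-end evaluation: parameter values -> per-strategy cost and QALYs.

The three cohort traces (curative, palliative surgery, chemotherapy) depend
only on the refit trial survival curves, the life table and the economic
settings -- none of which are varied in sensitivity analysis -- so they are
computed once and reused across one-way, threshold and probabilistic
re-evaluations, which then reduce to tree arithmetic plus linear accrual.
"""

from __future__ import annotations

from dataclasses import dataclass

from .markov import (
    CohortTrace,
    CostBlock,
    EconSettings,
    LifeTable,
    MarkovSpec,
    accrue,
    run_cohort,
    strategy_outcome,
)
from .parameters import SURVIVAL_MODELS
from .tree import Destination, PathwayParams, ProcedureCosts, Strategy, build_tree

__all__ = ["StrategyOutcome", "build_markov_specs", "compute_traces", "evaluate_strategies"]

#: months on adjuvant chemotherapy in the curative arm (cost & low-utility window)
ADJUVANT_N_CYCLES = 6
#: months over which the surgery-year cost block applies after resection
SURGERY_COST_MONTHS = 12


@dataclass(frozen=True)
class StrategyOutcome:
    """Expected discounted and undiscounted totals of one staging strategy."""

    strategy: Strategy
    cost: float
    qaly: float
    cost_undisc: float
    qaly_undisc: float


def _pathway_params(v: dict[str, float]) -> PathwayParams:
    return PathwayParams(
        p_opm=v["p_opm"],
        p_cy1p0=v["p_cy1p0"],
        sens_ppl=v["sens_ppl"],
        sens_lpl=v["sens_lpl"],
        p_compl_ppl=v["p_compl_ppl"],
        p_compl_lpl=v["p_compl_lpl"],
        p_compl_el=v["p_compl_el"],
        p_compl_gastrectomy=v["p_compl_gastrectomy"],
        mort_lpl=v["mort_lpl"],
        mort_el=v["mort_el"],
        mort_gastrectomy=v["mort_gastrectomy"],
        compl_cost_fold=v["compl_cost_fold"],
    )


def _procedure_costs(v: dict[str, float]) -> ProcedureCosts:
    return ProcedureCosts(
        cost_ppl=v["cost_ppl"],
        cost_lpl=v["cost_lpl"],
        cost_el=v["cost_el"],
        gastrectomy_cycle_cost=v["cost_surgery_dm"] / 12.0,
    )


def build_markov_specs(v: dict[str, float]) -> dict[Destination, MarkovSpec]:
    """Assemble the three long-term models from parameter values.

    Curative: surgery-year cost block plus per-cycle adjuvant chemotherapy
    (months 1-6, utility 0.68, then 0.81); disease-free cycles beyond the
    first year accrue no further cost.  Palliative surgery: surgery-year
    block first, chemotherapy block while progression-free thereafter,
    utility 0.54.  Chemotherapy: chemotherapy block throughout PFS, utility
    0.66.  Progressive disease is common to all three: palliative-therapy
    block at utility 0.40, with survival from treatment start of PD.
    """
    surgery = CostBlock(v["cost_surgery_dm"], v["cost_surgery_indirect"], v["cost_surgery_nonmed"])
    chemo = CostBlock(v["cost_chemo_dm"], v["cost_chemo_indirect"], v["cost_chemo_nonmed"])
    palliative = CostBlock(
        v["cost_palliative_dm"], v["cost_palliative_indirect"], v["cost_palliative_nonmed"]
    )
    pd_death = SURVIVAL_MODELS["pd_death"]
    return {
        Destination.CURATIVE: MarkovSpec(
            name="curative",
            progression_model=SURVIVAL_MODELS["curative_progression"],
            pd_death_model=pd_death,
            utility_front_early=v["u_adjuvant"],
            utility_front_late=v["u_postgastrectomy"],
            utility_switch_month=ADJUVANT_N_CYCLES,
            utility_pd=v["u_progressive"],
            cost_front_early=surgery,
            cost_front_late=CostBlock(),
            cost_switch_month=SURGERY_COST_MONTHS,
            cost_pd=palliative,
            adjuvant_cost_per_cycle=v["cost_adjuvant_cycle"],
            adjuvant_n_cycles=ADJUVANT_N_CYCLES,
        ),
        Destination.PALLIATIVE_SURGERY: MarkovSpec(
            name="palliative_surgery",
            progression_model=SURVIVAL_MODELS["palliative_surgery_progression"],
            pd_death_model=pd_death,
            utility_front_late=v["u_palliative_surgery"],
            utility_pd=v["u_progressive"],
            cost_front_early=surgery,
            cost_front_late=chemo,
            cost_switch_month=SURGERY_COST_MONTHS,
            cost_pd=palliative,
            adjuvant_cost_per_cycle=v["cost_adjuvant_cycle"],
            adjuvant_n_cycles=ADJUVANT_N_CYCLES,
        ),
        Destination.CHEMOTHERAPY: MarkovSpec(
            name="chemotherapy",
            progression_model=SURVIVAL_MODELS["chemotherapy_progression"],
            pd_death_model=pd_death,
            utility_front_late=v["u_chemotherapy"],
            utility_pd=v["u_progressive"],
            cost_front_late=chemo,
            cost_pd=palliative,
        ),
    }


def compute_traces(
    settings: EconSettings, life_table: LifeTable
) -> dict[Destination, CohortTrace]:
    """Roll the three cohorts once (transitions are structural constants)."""
    return {
        Destination.CURATIVE: run_cohort(
            SURVIVAL_MODELS["curative_progression"], SURVIVAL_MODELS["pd_death"],
            settings, life_table,
        ),
        Destination.PALLIATIVE_SURGERY: run_cohort(
            SURVIVAL_MODELS["palliative_surgery_progression"], SURVIVAL_MODELS["pd_death"],
            settings, life_table,
        ),
        Destination.CHEMOTHERAPY: run_cohort(
            SURVIVAL_MODELS["chemotherapy_progression"], SURVIVAL_MODELS["pd_death"],
            settings, life_table,
        ),
    }


def evaluate_strategies(
    values: dict[str, float],
    settings: EconSettings,
    life_table: LifeTable,
    traces: dict[Destination, CohortTrace] | None = None,
) -> dict[Strategy, StrategyOutcome]:
    """Full tree + Markov evaluation at one set of parameter values."""
    if traces is None:
        traces = compute_traces(settings, life_table)
    specs = build_markov_specs(values)
    results_disc: dict[Destination, tuple[float, float]] = {}
    results_undisc: dict[Destination, tuple[float, float]] = {}
    for dest, spec in specs.items():
        results_disc[dest] = accrue(traces[dest], spec, settings, discounted=True)
        results_undisc[dest] = accrue(traces[dest], spec, settings, discounted=False)

    params = _pathway_params(values)
    costs = _procedure_costs(values)
    out: dict[Strategy, StrategyOutcome] = {}
    for strat in Strategy:
        nodes = build_tree(strat, params, costs)
        c, q = strategy_outcome(nodes, results_disc)
        cu, qu = strategy_outcome(nodes, results_undisc)
        out[strat] = StrategyOutcome(strat, cost=c, qaly=q, cost_undisc=cu, qaly_undisc=qu)
    return out
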