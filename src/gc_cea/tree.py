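"""Short-term decision-tree pathways for the three staging strategies.

Every patient enters with radiographically curable gastric cancer but an
unknown peritoneal-cytology status.  The tree resolves, per strategy, the
staging procedure (cost, complication surcharge, perioperative mortality),
the test outcome, and any subsequent operation, and hands survivors to one
of three long-term Markov models:

* ``curative``          - true-negative cytology, curative gastrectomy;
* ``palliative_surgery``- occult metastases missed, non-curative resection;
* ``chemotherapy``      - metastases detected, systemic therapy only
  (surgery is not recommended once cytology is positive);
* ``dead_upfront``      - perioperative death (accrues the procedure costs
  incurred before death and zero QALYs).

Pathway rules
-------------
LPL: all patients undergo laparoscopic lavage (mortality 0.07%).  Detected
occult peritoneal metastases (OPM, sensitivity 84.6%) go to chemotherapy;
missed OPM and OPM-free patients proceed to gastrectomy (mortality 2.7%,
complication 21.6%), reaching palliative_surgery / curative respectively.

PPL: all undergo percutaneous lavage (no fatal complications).  OPM
detected pre-operatively go straight to chemotherapy.  Every PPL-negative
patient undergoes an exploratory laparotomy with intraoperative cytology,
which detects all remaining OPM: those patients end in a nontherapeutic
laparotomy and then chemotherapy, while OPM-free patients continue to
gastrectomy in the same operation.  The laparotomy's perioperative
mortality (1.5%) applies to every patient opened, with gastrectomy
mortality applied sequentially to those resected: an open exploration
carries its operative risk whether or not resection follows, and this
risk on the large OPM-free stratum is what the strategy trades against
LPL's cheaper staging of the same patients.

ELNC: all undergo exploratory laparotomy without cytology.  Visible
implants (prevalence p_opm - p_cy1p0) are always found -> nontherapeutic
laparotomy -> chemotherapy.  Cytology-positive patients without implants
(CY1P0) are necessarily missed -> gastrectomy -> palliative_surgery.
OPM-free patients -> gastrectomy -> curative.  Laparotomy mortality
applies to everyone, gastrectomy mortality sequentially to the resected.

Complications are non-fatal, multiply the index procedure's cost by a
fold factor for the complicated fraction, and carry no utility decrement;
gastrectomy complications surcharge the first-cycle surgery direct-medical
cost the same way.  Test specificity is 1, so false positives do not occur.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
import json

__all__ = [
    "Strategy",
    "Destination",
    "PathwayParams",
    "ProcedureCosts",
    "TerminalNode",
    "expected_procedure_cost",
    "build_tree",
    "upfront_mortality",
    "expected_upfront_cost",
    "tree_to_json",
]


class Strategy(str, Enum):
    LPL = "LPL"
    PPL = "PPL"
    ELNC = "ELNC"


class Destination(str, Enum):
    CURATIVE = "curative"
    PALLIATIVE_SURGERY = "palliative_surgery"
    CHEMOTHERAPY = "chemotherapy"
    DEAD_UPFRONT = "dead_upfront"


def _check_prob(name: str, value: float) -> float:
    value = float(value)
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value}")
    return value


@dataclass(frozen=True)
class PathwayParams:
    """Probabilities governing the short-term pathways (Table-1 rows)."""

    p_opm: float  # pretest probability of occult peritoneal metastases
    p_cy1p0: float  # positive cytology without visible implants (whole cohort)
    sens_ppl: float
    sens_lpl: float
    p_compl_ppl: float
    p_compl_lpl: float
    p_compl_el: float
    p_compl_gastrectomy: float
    mort_lpl: float
    mort_el: float
    mort_gastrectomy: float
    compl_cost_fold: float = 3.0
    specificity: float = 1.0  # false positives are not modelled

    def __post_init__(self) -> None:
        for name in (
            "p_opm", "p_cy1p0", "sens_ppl", "sens_lpl", "p_compl_ppl",
            "p_compl_lpl", "p_compl_el", "p_compl_gastrectomy",
            "mort_lpl", "mort_el", "mort_gastrectomy", "specificity",
        ):
            object.__setattr__(self, name, _check_prob(name, getattr(self, name)))
        if self.p_cy1p0 > self.p_opm:
            raise ValueError("p_cy1p0 cannot exceed p_opm")
        if self.compl_cost_fold < 1.0:
            raise ValueError("compl_cost_fold must be >= 1")
        if self.specificity != 1.0:
            raise ValueError("specificity is fixed at 1 (no false positives)")


@dataclass(frozen=True)
class ProcedureCosts:
    """One-time procedure costs in 2019 US$.

    ``gastrectomy_cycle_cost`` is the first-cycle (monthly) surgery
    direct-medical cost, the base to which the gastrectomy complication
    surcharge applies; the surgery itself is costed inside the Markov
    model's first-year block.
    """

    cost_ppl: float
    cost_lpl: float
    cost_el: float
    gastrectomy_cycle_cost: float = 0.0

    def __post_init__(self) -> None:
        for name in ("cost_ppl", "cost_lpl", "cost_el", "gastrectomy_cycle_cost"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class TerminalNode:
    strategy: Strategy
    markov_destination: Destination
    probability: float
    upfront_cost: float
    label: str


def expected_procedure_cost(base_cost: float, p_compl: float, fold: float) -> float:
    """Expected cost of a procedure whose complicated fraction costs fold x base."""
    if base_cost < 0:
        raise ValueError("base_cost must be >= 0")
    _check_prob("p_compl", p_compl)
    if fold < 1.0:
        raise ValueError("fold must be >= 1")
    return base_cost * (1.0 + (fold - 1.0) * p_compl)


def build_tree(
    strategy: Strategy | str,
    params: PathwayParams,
    costs: ProcedureCosts,
) -> list[TerminalNode]:
    """Terminal nodes (leaves) of one strategy's decision tree.

    Leaf probabilities sum to one; perioperative deaths appear as
    ``dead_upfront`` leaves carrying the costs incurred before death.
    """
    strategy = Strategy(strategy)
    fold = params.compl_cost_fold
    # expected staging-procedure costs including the complication surcharge
    c_ppl = expected_procedure_cost(costs.cost_ppl, params.p_compl_ppl, fold)
    c_lpl = expected_procedure_cost(costs.cost_lpl, params.p_compl_lpl, fold)
    c_el_nontx = expected_procedure_cost(costs.cost_el, params.p_compl_el, fold)
    # gastrectomy complication surcharge on the first-cycle surgery cost
    c_gast = (fold - 1.0) * params.p_compl_gastrectomy * costs.gastrectomy_cycle_cost

    p_opm = params.p_opm
    nodes: list[TerminalNode] = []

    def leaf(dest: Destination, p: float, cost: float, label: str) -> None:
        if p > 0.0:
            nodes.append(TerminalNode(strategy, dest, p, cost, label))

    if strategy is Strategy.LPL:
        m = params.mort_lpl
        leaf(Destination.DEAD_UPFRONT, m, c_lpl, "death at laparoscopic lavage")
        alive = 1.0 - m
        detected = alive * p_opm * params.sens_lpl
        leaf(Destination.CHEMOTHERAPY, detected, c_lpl, "OPM detected by LPL")
        for frac, dest, tag in (
            (alive * p_opm * (1.0 - params.sens_lpl), Destination.PALLIATIVE_SURGERY,
             "OPM missed by LPL"),
            (alive * (1.0 - p_opm), Destination.CURATIVE, "no OPM"),
        ):
            mg = params.mort_gastrectomy
            leaf(Destination.DEAD_UPFRONT, frac * mg, c_lpl + c_gast,
                 f"{tag}, death at gastrectomy")
            leaf(dest, frac * (1.0 - mg), c_lpl + c_gast, f"{tag}, gastrectomy")

    elif strategy is Strategy.PPL:
        detected = p_opm * params.sens_ppl  # fatal PPL complications not observed
        leaf(Destination.CHEMOTHERAPY, detected, c_ppl, "OPM detected by PPL")
        me, mg = params.mort_el, params.mort_gastrectomy
        # PPL-negative with OPM: laparotomy cytology detects all of them
        missed = p_opm * (1.0 - params.sens_ppl)
        leaf(Destination.DEAD_UPFRONT, missed * me, c_ppl + c_el_nontx,
             "OPM found at laparotomy, death at laparotomy")
        leaf(Destination.CHEMOTHERAPY, missed * (1.0 - me), c_ppl + c_el_nontx,
             "OPM found at laparotomy (nontherapeutic)")
        # PPL-negative without OPM: laparotomy then gastrectomy, same operation
        clear = 1.0 - p_opm
        c_open = c_ppl + costs.cost_el
        leaf(Destination.DEAD_UPFRONT, clear * me, c_open,
             "no OPM, death at laparotomy")
        leaf(Destination.DEAD_UPFRONT, clear * (1.0 - me) * mg, c_open + c_gast,
             "no OPM, death at gastrectomy")
        leaf(Destination.CURATIVE, clear * (1.0 - me) * (1.0 - mg), c_open + c_gast,
             "no OPM, curative gastrectomy")

    else:  # ELNC
        me, mg = params.mort_el, params.mort_gastrectomy
        visible = p_opm - params.p_cy1p0
        leaf(Destination.DEAD_UPFRONT, visible * me, c_el_nontx,
             "visible implants, death at laparotomy")
        leaf(Destination.CHEMOTHERAPY, visible * (1.0 - me), c_el_nontx,
             "visible implants found (nontherapeutic)")
        for frac, dest, tag in (
            (params.p_cy1p0, Destination.PALLIATIVE_SURGERY, "CY1P0 missed"),
            (1.0 - p_opm, Destination.CURATIVE, "no OPM"),
        ):
            leaf(Destination.DEAD_UPFRONT, frac * me, costs.cost_el,
                 f"{tag}, death at laparotomy")
            leaf(Destination.DEAD_UPFRONT, frac * (1.0 - me) * mg,
                 costs.cost_el + c_gast, f"{tag}, death at gastrectomy")
            leaf(dest, frac * (1.0 - me) * (1.0 - mg), costs.cost_el + c_gast,
                 f"{tag}, gastrectomy")

    total = sum(n.probability for n in nodes)
    if abs(total - 1.0) > 1e-12:
        raise AssertionError(f"leaf probabilities sum to {total!r}, not 1")
    return nodes


def upfront_mortality(strategy: Strategy | str, params: PathwayParams) -> float:
    """Probability-weighted perioperative death mass of one strategy."""
    costs = ProcedureCosts(0.0, 0.0, 0.0, 0.0)
    return sum(
        n.probability
        for n in build_tree(strategy, params, costs)
        if n.markov_destination is Destination.DEAD_UPFRONT
    )


def expected_upfront_cost(nodes: list[TerminalNode]) -> float:
    return sum(n.probability * n.upfront_cost for n in nodes)


def tree_to_json(trees: dict[str, list[TerminalNode]], path) -> None:
    """Dump strategy -> leaves as JSON for audit / oracle comparison."""
    payload = {
        str(Strategy(k).value): [
            {
                "label": n.label,
                "probability": n.probability,
                "upfront_cost": n.upfront_cost,
                "destination": n.markov_destination.value,
            }
            for n in v
        ]
        for k, v in trees.items()
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
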