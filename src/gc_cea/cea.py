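"""Cost-effectiveness analysis over the tree + Markov pipeline.

Implements the decision layer: incremental cost-effectiveness ratios with
strict- and extended-dominance pruning, net monetary benefit, one-way
sensitivity analysis with tornado ordering, threshold analysis by
bisection, probabilistic sensitivity analysis with method-of-moments
beta/gamma/normal draws, and cost-effectiveness acceptability curves.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markov import CohortTrace, EconSettings, LifeTable
from .parameters import Parameter
from .pipeline import StrategyOutcome, evaluate_strategies
from .tree import Destination, Strategy

logger = logging.getLogger(__name__)

__all__ = [
    "IcerRow",
    "PsaSample",
    "icer_table",
    "nmb",
    "icer",
    "owsa",
    "tornado",
    "threshold_search",
    "draw_parameters",
    "run_psa",
    "ceac",
    "ceac_crossing",
]


# ---------------------------------------------------------------------------
# base-case decision analysis


@dataclass(frozen=True)
class IcerRow:
    """One strategy's place on (or off) the efficiency frontier."""

    strategy: Strategy
    cost: float
    qaly: float
    status: str  # reference | dominated | extended_dominated | icer
    icer_value: float | None = None
    comparator: Strategy | None = None


def nmb(outcome: StrategyOutcome, wtp: float, discounted: bool = True) -> float:
    """Net monetary benefit ``wtp * qaly - cost``."""
    if wtp < 0:
        raise ValueError("wtp must be >= 0")
    if discounted:
        return wtp * outcome.qaly - outcome.cost
    return wtp * outcome.qaly_undisc - outcome.cost_undisc


def icer_table(
    outcomes: list[StrategyOutcome], discounted: bool = True
) -> list[IcerRow]:
    """Efficiency frontier with strict and extended dominance pruning.

    Strategies are sorted by cost; any strategy that is costlier and no
    more effective than another is strictly dominated; frontier members
    whose incremental ICER exceeds the next one's are extended-dominated.
    The cheapest frontier strategy is the reference.
    """
    if len(outcomes) < 2:
        raise ValueError("need at least 2 strategies")
    cq = {
        o.strategy: (o.cost, o.qaly) if discounted else (o.cost_undisc, o.qaly_undisc)
        for o in outcomes
    }
    strategies = list(cq)
    status: dict[Strategy, str] = {}
    for s in strategies:
        c, q = cq[s]
        for other in strategies:
            if other is s:
                continue
            oc, oq = cq[other]
            if (oc, oq) == (c, q):
                logger.warning("strategies %s and %s tie in cost and QALY", s, other)
                continue
            if oc <= c and oq >= q:
                status[s] = "dominated"
                break

    frontier = sorted((s for s in strategies if s not in status), key=lambda s: cq[s][0])
    # extended dominance: remove members with non-increasing incremental ICERs
    changed = True
    while changed and len(frontier) > 2:
        changed = False
        for i in range(1, len(frontier) - 1):
            lo, mid, hi = frontier[i - 1], frontier[i], frontier[i + 1]
            icer_mid = _pair_icer(cq[lo], cq[mid])
            icer_hi = _pair_icer(cq[mid], cq[hi])
            if icer_mid is not None and icer_hi is not None and icer_mid >= icer_hi:
                status[mid] = "extended_dominated"
                frontier.pop(i)
                changed = True
                break

    rows: list[IcerRow] = []
    for s in strategies:
        c, q = cq[s]
        if s in status:
            rows.append(IcerRow(s, c, q, status[s]))
        elif s is frontier[0]:
            rows.append(IcerRow(s, c, q, "reference"))
        else:
            prev = frontier[frontier.index(s) - 1]
            rows.append(IcerRow(s, c, q, "icer", _pair_icer(cq[prev], cq[s]), prev))
    return rows


def _pair_icer(low: tuple[float, float], high: tuple[float, float]) -> float | None:
    dq = high[1] - low[1]
    if dq == 0:
        return None
    return (high[0] - low[0]) / dq


def icer(
    outcomes: dict[Strategy, StrategyOutcome],
    strategy: Strategy = Strategy.LPL,
    comparator: Strategy = Strategy.PPL,
    discounted: bool = True,
) -> float:
    """Pairwise ICER of ``strategy`` versus ``comparator`` (signed)."""
    a, b = outcomes[strategy], outcomes[comparator]
    if discounted:
        dc, dq = a.cost - b.cost, a.qaly - b.qaly
    else:
        dc, dq = a.cost_undisc - b.cost_undisc, a.qaly_undisc - b.qaly_undisc
    if dq == 0:
        raise ZeroDivisionError("QALY difference is zero; ICER undefined")
    return dc / dq


# ---------------------------------------------------------------------------
# one-way sensitivity and threshold analysis


def owsa(
    param: Parameter,
    base: dict[str, float],
    settings: EconSettings,
    life_table: LifeTable,
    traces: dict[Destination, CohortTrace],
) -> dict:
    """ICER(LPL vs PPL) at the low and high end of one parameter's range.

    When the QALY difference changes sign inside the range the ICER is
    undefined as a summary; the NMB difference at the WTP threshold is
    reported instead and the row flagged.
    """
    result: dict = {"id": param.id, "low": param.low, "high": param.high}
    vals = []
    for bound in (param.low, param.high):
        v = dict(base)
        v[param.id] = bound
        outs = evaluate_strategies(v, settings, life_table, traces)
        vals.append(outs)
    dqs = [o[Strategy.LPL].qaly - o[Strategy.PPL].qaly for o in vals]
    if dqs[0] * dqs[1] <= 0:
        result["icer_defined"] = False
        result["nmb_diff_low"], result["nmb_diff_high"] = (
            nmb(o[Strategy.LPL], settings.wtp) - nmb(o[Strategy.PPL], settings.wtp)
            for o in vals
        )
    else:
        result["icer_defined"] = True
        result["icer_low"], result["icer_high"] = (icer(o) for o in vals)
    return result


def tornado(
    params: list[Parameter],
    base: dict[str, float],
    settings: EconSettings,
    life_table: LifeTable,
    traces: dict[Destination, CohortTrace],
) -> pd.DataFrame:
    """One-way results for every non-fixed parameter, widest bar first."""
    rows = [
        owsa(p, base, settings, life_table, traces)
        for p in params
        if p.dist != "fixed" and (p.low, p.high) != (p.base, p.base)
    ]
    df = pd.DataFrame(rows)
    spread = np.where(
        df["icer_defined"],
        (df.get("icer_high", np.nan) - df.get("icer_low", np.nan)).abs(),
        np.inf,  # sign-flipping parameters are maximally influential
    )
    df["spread"] = spread
    return df.sort_values("spread", ascending=False, ignore_index=True)


def threshold_search(
    param_id: str,
    bracket: tuple[float, float],
    base: dict[str, float],
    settings: EconSettings,
    life_table: LifeTable,
    traces: dict[Destination, CohortTrace],
    wtp: float | None = None,
    tol_icer: float = 1.0,
    tol_x: float = 1e-6,
    max_iter: int = 200,
) -> float | None:
    """Parameter value at which ICER(LPL vs PPL) crosses the WTP threshold.

    Bisection on the (continuous) NMB difference at the WTP, whose root is
    exactly the ICER = WTP crossing while remaining well defined where a
    strategy is dominated.  Returns None when the decision does not change
    over the bracket.
    """
    wtp = settings.wtp if wtp is None else wtp

    def nmb_diff(x: float) -> float:
        v = dict(base)
        v[param_id] = x
        outs = evaluate_strategies(v, settings, life_table, traces)
        return nmb(outs[Strategy.LPL], wtp) - nmb(outs[Strategy.PPL], wtp)

    lo, hi = float(bracket[0]), float(bracket[1])
    f_lo, f_hi = nmb_diff(lo), nmb_diff(hi)
    if f_lo == 0.0:
        return lo
    if f_hi == 0.0:
        return hi
    if f_lo * f_hi > 0:
        return None
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = nmb_diff(mid)
        if f_mid == 0.0 or hi - lo <= tol_x:
            return mid
        if f_lo * f_mid < 0:
            hi, f_hi = mid, f_mid
        else:
            lo, f_lo = mid, f_mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis


@dataclass
class PsaSample:
    """One Monte Carlo draw and its per-strategy outcomes."""

    draw_index: int
    values: dict[str, float]
    outcomes: dict[Strategy, StrategyOutcome] = field(repr=False, default_factory=dict)


def _moment_sd(p: Parameter) -> float:
    # the plausible range is read as a 95% central interval
    return (p.high - p.low) / 3.92


def draw_parameters(
    params: list[Parameter], rng: np.random.Generator, n: int = 1
) -> pd.DataFrame:
    """Method-of-moments draws, one column per parameter.

    Beta for probabilities/utilities, gamma for costs, normal for the fold;
    distributions are moment-matched so the mean equals the base value and
    the SD is (high - low)/3.92.  A beta whose variance is infeasible for
    its mean falls back to uniform on [low, high] with a warning.
    """
    cols: dict[str, np.ndarray] = {}
    for p in params:
        sd = _moment_sd(p)
        if p.dist == "fixed" or sd == 0.0:
            cols[p.id] = np.full(n, p.base)
            continue
        var = sd * sd
        mean = p.base
        if p.dist == "beta":
            if var >= mean * (1.0 - mean):
                warnings.warn(
                    f"{p.id}: beta variance infeasible; drawing uniform on range"
                )
                cols[p.id] = rng.uniform(p.low, p.high, size=n)
                continue
            kappa = mean * (1.0 - mean) / var - 1.0
            cols[p.id] = rng.beta(mean * kappa, (1.0 - mean) * kappa, size=n)
        elif p.dist == "gamma":
            cols[p.id] = rng.gamma(shape=mean * mean / var, scale=var / mean, size=n)
        elif p.dist == "normal":
            cols[p.id] = rng.normal(mean, sd, size=n)
        else:  # pragma: no cover
            raise ValueError(p.dist)
    return pd.DataFrame(cols)


def run_psa(
    params: list[Parameter],
    settings: EconSettings,
    life_table: LifeTable,
    traces: dict[Destination, CohortTrace],
    n: int = 1000,
    seed: int = 0,
) -> list[PsaSample]:
    """``n`` full pipeline evaluations under parameter uncertainty.

    Reproducible per seed.  Draws violating structural invariants
    (p_cy1p0 > p_opm, fold < 1) are redrawn column-wise; the count is
    logged.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    draws = draw_parameters(params, rng, n=n)
    n_redrawn = 0
    for _ in range(100):
        bad = np.zeros(n, dtype=bool)
        if {"p_cy1p0", "p_opm"} <= set(draws.columns):
            bad |= draws["p_cy1p0"].to_numpy() > draws["p_opm"].to_numpy()
        if "compl_cost_fold" in draws.columns:
            bad |= draws["compl_cost_fold"].to_numpy() < 1.0
        if not bad.any():
            break
        n_redrawn += int(bad.sum())
        draws.loc[bad, :] = draw_parameters(params, rng, n=int(bad.sum())).to_numpy()
    if n_redrawn:
        logger.info("redrew %d PSA samples violating invariants", n_redrawn)

    samples: list[PsaSample] = []
    for i in range(n):
        values = {k: float(draws.iloc[i][k]) for k in draws.columns}
        outs = evaluate_strategies(values, settings, life_table, traces)
        samples.append(PsaSample(draw_index=i, values=values, outcomes=outs))
    return samples


def ceac(samples: list[PsaSample], wtp_grid: np.ndarray) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves.

    For each WTP, the fraction of draws in which each strategy attains the
    maximal net monetary benefit (ties split equally); rows sum to 1.
    """
    if not samples:
        raise ValueError("no PSA samples")
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    strategies = list(Strategy)
    costs = np.array([[s.outcomes[st].cost for st in strategies] for s in samples])
    qalys = np.array([[s.outcomes[st].qaly for st in strategies] for s in samples])
    probs = np.zeros((wtp_grid.size, len(strategies)))
    for j, w in enumerate(wtp_grid):
        benefit = w * qalys - costs
        best = benefit.max(axis=1, keepdims=True)
        winners = benefit == best
        probs[j] = (winners / winners.sum(axis=1, keepdims=True)).mean(axis=0)
    df = pd.DataFrame(probs, columns=[s.value for s in strategies])
    df.insert(0, "wtp", wtp_grid)
    return df


def ceac_crossing(
    curves: pd.DataFrame, a: Strategy = Strategy.LPL, b: Strategy = Strategy.PPL
) -> float | None:
    """WTP at which two acceptability curves cross (linear interpolation)."""
    diff = curves[a.value].to_numpy() - curves[b.value].to_numpy()
    wtp = curves["wtp"].to_numpy()
    sign = np.sign(diff)
    idx = np.nonzero(np.diff(sign) != 0)[0]
    if idx.size == 0:
        return None
    i = idx[0]
    d0, d1 = diff[i], diff[i + 1]
    if d1 == d0:
        return float(wtp[i])
    return float(wtp[i] - d0 * (wtp[i + 1] - wtp[i]) / (d1 - d0))
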