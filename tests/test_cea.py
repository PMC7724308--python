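"""Decision layer: ICER frontier, NMB, OWSA, thresholds, PSA, CEAC."""

import numpy as np
import pandas as pd
import pytest

import gc_cea as g
from gc_cea.cea import (
    ceac,
    ceac_crossing,
    draw_parameters,
    icer,
    icer_table,
    nmb,
    owsa,
    run_psa,
    threshold_search,
)
from gc_cea.parameters import Parameter
from gc_cea.pipeline import StrategyOutcome
from gc_cea.tree import Strategy


def _outcome(strategy, cost, qaly):
    return StrategyOutcome(strategy, cost=cost, qaly=qaly,
                           cost_undisc=cost, qaly_undisc=qaly)


# rounded published base-case (discounted) values, used as a fixed example
TABLE_OUTCOMES = [
    _outcome(Strategy.ELNC, 23738.0, 5.81),
    _outcome(Strategy.LPL, 23736.0, 5.90),
    _outcome(Strategy.PPL, 22515.0, 5.83),
]


class TestIcerTable:
    def test_published_rounded_example(self):
        rows = {r.strategy: r for r in icer_table(TABLE_OUTCOMES)}
        assert rows[Strategy.ELNC].status == "dominated"
        assert rows[Strategy.PPL].status == "reference"
        assert rows[Strategy.LPL].status == "icer"
        # (23736 - 22515) / (5.90 - 5.83)
        assert rows[Strategy.LPL].icer_value == pytest.approx(17442.857, rel=1e-6)
        assert rows[Strategy.LPL].comparator is Strategy.PPL

    def test_strict_dominance_equal_qalys(self):
        rows = {r.strategy: r for r in icer_table(
            [_outcome(Strategy.LPL, 10.0, 1.0), _outcome(Strategy.PPL, 20.0, 1.0)]
        )}
        assert rows[Strategy.PPL].status == "dominated"
        assert rows[Strategy.LPL].status == "reference"

    def test_extended_dominance(self):
        rows = {r.strategy: r for r in icer_table(
            [
                _outcome(Strategy.PPL, 0.0, 0.0),
                _outcome(Strategy.ELNC, 10.0, 1.0),
                _outcome(Strategy.LPL, 11.0, 3.0),
            ]
        )}
        assert rows[Strategy.ELNC].status == "extended_dominated"
        assert rows[Strategy.LPL].status == "icer"
        # after removal: (11 - 0) / (3 - 0)
        assert rows[Strategy.LPL].icer_value == pytest.approx(11.0 / 3.0)

    def test_frontier_icers_increase(self, base_outcomes):
        rows = [r for r in icer_table(list(base_outcomes.values())) if r.status == "icer"]
        icers = [r.icer_value for r in rows]
        assert icers == sorted(icers)

    def test_needs_two_strategies(self):
        with pytest.raises(ValueError):
            icer_table([TABLE_OUTCOMES[0]])


class TestNmb:
    def test_zero_wtp_is_negative_cost(self):
        assert nmb(_outcome(Strategy.LPL, 23736.0, 5.90), 0.0) == -23736.0

    def test_hand_value(self):
        # 29313 * 5.90 - 23736
        assert nmb(_outcome(Strategy.LPL, 23736.0, 5.90), 29313.0) == pytest.approx(
            149210.7
        )

    def test_equal_outcomes_equal_nmb(self):
        a = _outcome(Strategy.LPL, 100.0, 1.0)
        b = _outcome(Strategy.PPL, 100.0, 1.0)
        for wtp in (0.0, 10000.0, 50000.0):
            assert nmb(a, wtp) == nmb(b, wtp)

    def test_negative_wtp_rejected(self):
        with pytest.raises(ValueError):
            nmb(_outcome(Strategy.LPL, 1.0, 1.0), -1.0)


class TestNmbIcerConsistency:
    def test_decision_agreement_on_random_triples(self):
        """At any WTP the max-NMB strategy equals the frontier strategy
        chosen by the highest-ICER-below-WTP rule."""
        rng = np.random.default_rng(7)
        for _ in range(1000):
            outcomes = [
                _outcome(s, float(rng.uniform(0, 30000)), float(rng.uniform(0, 10)))
                for s in Strategy
            ]
            wtp = float(rng.uniform(0, 60000))
            by_nmb = max(outcomes, key=lambda o: nmb(o, wtp)).strategy
            rows = icer_table(outcomes)
            frontier = [r for r in rows if r.status in ("reference", "icer")]
            frontier.sort(key=lambda r: r.cost)
            choice = frontier[0].strategy
            for r in frontier[1:]:
                if r.icer_value is not None and r.icer_value <= wtp:
                    choice = r.strategy
            assert nmb(next(o for o in outcomes if o.strategy is by_nmb), wtp) == (
                pytest.approx(
                    nmb(next(o for o in outcomes if o.strategy is choice), wtp)
                )
            )


class TestDrawParameters:
    def test_moment_matching_beta(self):
        p = Parameter("p_opm", 0.234, 0.085, 0.596, "beta", "pathway")
        rng = np.random.default_rng(0)
        draws = draw_parameters([p], rng, n=1_000_000)["p_opm"].to_numpy()
        sd = (0.596 - 0.085) / 3.92
        assert draws.mean() == pytest.approx(0.234, abs=0.002)
        assert draws.std() == pytest.approx(sd, abs=0.002)
        assert np.all((draws > 0) & (draws < 1))

    def test_moment_matching_gamma(self):
        p = Parameter("cost_lpl", 2213.0, 1107.5, 3319.5, "gamma", "cost")
        rng = np.random.default_rng(1)
        draws = draw_parameters([p], rng, n=500_000)["cost_lpl"].to_numpy()
        assert draws.mean() == pytest.approx(2213.0, rel=0.005)
        assert draws.std() == pytest.approx((3319.5 - 1107.5) / 3.92, rel=0.01)
        assert np.all(draws > 0)

    def test_fixed_parameter_constant(self):
        p = Parameter("specificity", 1.0, 1.0, 1.0, "fixed", "pathway")
        draws = draw_parameters([p], np.random.default_rng(2), n=100)
        assert (draws["specificity"] == 1.0).all()

    def test_vanishing_range_collapses_to_base(self):
        p = Parameter("x", 0.5, 0.5 - 1e-9, 0.5 + 1e-9, "beta", "utility")
        draws = draw_parameters([p], np.random.default_rng(3), n=1000)["x"]
        assert np.allclose(draws, 0.5, atol=1e-4)

    def test_infeasible_beta_falls_back_to_uniform(self):
        p = Parameter("wide", 0.5, 0.0, 4.0, "beta", "utility")  # sd > feasible
        with pytest.warns(UserWarning):
            draws = draw_parameters([p], np.random.default_rng(4), n=1000)["wide"]
        assert draws.min() >= 0.0 and draws.max() <= 4.0

    def test_seed_determinism(self, param_list):
        d1 = draw_parameters(param_list, np.random.default_rng(42), n=50)
        d2 = draw_parameters(param_list, np.random.default_rng(42), n=50)
        pd.testing.assert_frame_equal(d1, d2)


class TestOwsa:
    def test_degenerate_range_reproduces_base_case(
        self, param_list, base_vals, settings, life_table, traces, base_outcomes
    ):
        base_icer = icer(base_outcomes)
        for p in param_list[:6]:
            frozen = Parameter(p.id, p.base, p.base, p.base, p.dist, p.role)
            res = owsa(frozen, base_vals, settings, life_table, traces)
            assert res["icer_defined"]
            assert res["icer_low"] == pytest.approx(base_icer, rel=1e-12)
            assert res["icer_high"] == pytest.approx(base_icer, rel=1e-12)

    def test_influential_parameters_move_icer(
        self, param_list, base_vals, settings, life_table, traces
    ):
        by_id = {p.id: p for p in param_list}
        res = owsa(by_id["mort_el"], base_vals, settings, life_table, traces)
        assert res["icer_defined"] is False or (
            abs(res["icer_high"] - res["icer_low"]) > 10000
        )


class TestThresholdSearch:
    def test_crossing_satisfies_icer_equals_wtp(
        self, base_vals, settings, life_table, traces
    ):
        x = threshold_search(
            "mort_el", (0.0, 0.03), base_vals, settings, life_table, traces
        )
        assert x is not None
        v = dict(base_vals)
        v["mort_el"] = x
        outs = g.evaluate_strategies(v, settings, life_table, traces)
        assert icer(outs) == pytest.approx(settings.wtp, abs=1.0)

    def test_no_sign_change_returns_none(
        self, base_vals, settings, life_table, traces
    ):
        # over a tiny bracket far from the crossing the decision is constant
        x = threshold_search(
            "mort_el", (0.025, 0.03), base_vals, settings, life_table, traces
        )
        assert x is None


class TestPsa:
    def test_single_draw_all_fixed_equals_base_case(
        self, param_list, base_vals, settings, life_table, traces, base_outcomes
    ):
        fixed = [Parameter(p.id, p.base, p.base, p.base, "fixed", p.role)
                 for p in param_list]
        samples = run_psa(fixed, settings, life_table, traces, n=1, seed=0)
        assert len(samples) == 1
        for s in Strategy:
            assert samples[0].outcomes[s].cost == pytest.approx(base_outcomes[s].cost)
            assert samples[0].outcomes[s].qaly == pytest.approx(base_outcomes[s].qaly)

    def test_seed_determinism(self, param_list, settings, life_table, traces):
        a = run_psa(param_list, settings, life_table, traces, n=20, seed=11)
        b = run_psa(param_list, settings, life_table, traces, n=20, seed=11)
        for sa, sb in zip(a, b):
            assert sa.values == sb.values  # bit-for-bit

    def test_invariants_hold_in_draws(self, param_list, settings, life_table, traces):
        samples = run_psa(param_list, settings, life_table, traces, n=100, seed=5)
        for s in samples:
            assert s.values["p_cy1p0"] <= s.values["p_opm"]
            assert s.values["compl_cost_fold"] >= 1.0
            assert all(
                0.0 <= s.values[k] <= 1.0
                for k in s.values if k.startswith(("p_", "u_", "mort_", "sens_"))
            )


class TestCeac:
    def test_single_draw_gives_indicator_curves(self, param_list, settings,
                                                life_table, traces):
        samples = run_psa(param_list, settings, life_table, traces, n=1, seed=3)
        curves = ceac(samples, np.array([0.0, 29313.0, 60000.0]))
        values = curves[[s.value for s in Strategy]].to_numpy()
        assert set(np.unique(values)) <= {0.0, 1.0}

    def test_curves_partition_unity(self, param_list, settings, life_table, traces):
        samples = run_psa(param_list, settings, life_table, traces, n=50, seed=9)
        curves = ceac(samples, np.arange(0.0, 60001.0, 5000.0))
        sums = curves[[s.value for s in Strategy]].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_crossing_interpolation(self):
        curves = pd.DataFrame(
            {"wtp": [0.0, 10.0, 20.0], "LPL": [0.0, 0.4, 0.8],
             "PPL": [1.0, 0.6, 0.2], "ELNC": [0.0, 0.0, 0.0]}
        )
        # curves cross where 0.4 + 0.04w - (0.6 - 0.04w) = 0 on [10, 20]
        assert ceac_crossing(curves) == pytest.approx(12.5)

    def test_no_crossing_returns_none(self):
        curves = pd.DataFrame(
            {"wtp": [0.0, 10.0], "LPL": [0.8, 0.9], "PPL": [0.2, 0.1],
             "ELNC": [0.0, 0.0]}
        )
        assert ceac_crossing(curves) is None

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            ceac([], np.array([0.0]))
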