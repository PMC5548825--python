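"""Cost/effect accrual, ICERs, net monetary benefit and the frontier."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cllcea import (
    EconResult,
    ParameterError,
    UndefinedICERError,
    build_strategy,
    evaluate,
    evaluate_strategy,
    frontier,
    icer,
    nmb,
)
from cllcea.engine import DEATH_CLL, Transition, build_state_space, run_space
from cllcea.params import Parameter, ParameterSet
from cllcea.reference_results import PRINTED_ICERS, PRINTED_MEANS

from _oracles import hull_oracle
from test_engine import toy_params, toy_space


def results_from_printed(table, analysis):
    return [
        EconResult(strategy=s, mean_cost=c, mean_ly=e, mean_qaly=e)
        for s, (e, c) in PRINTED_MEANS[table][analysis].items()
    ]


class TestEvaluate:
    def test_remission_year_accrues_published_utility(self, base_ps):
        # one undiscounted cycle held in remission: LY = 28/365.25 years,
        # QALY = 0.910 * LY
        ps = toy_params({"p_stay": 0.0})
        space = toy_space(["alive"], [], {"alive": "alive"}, "alive")
        states = list(space.states["all"])
        states[0] = states[0].__class__(
            id="alive", role="remission", treatment="fcr", line="first",
            cost_params=(), utility_param="u__remission",
        )
        space.states["all"] = tuple(states)
        import dataclasses

        params = dict(ps.parameters)
        params["u__remission"] = Parameter("u__remission", "utility", 0.910,
                                           0.0, 1.0, "fixed")
        ps = dataclasses.replace(ps, parameters=params,
                                 discount_rate_annual=0.0)
        trace = run_space(space, ps, n_cycles=1)
        res = evaluate(trace, build_strategy("C"), ps)
        cyl = 28 / 365.25
        assert res.mean_ly == pytest.approx(cyl, rel=1e-12)
        assert res.mean_qaly == pytest.approx(0.910 * cyl, rel=1e-12)
        assert res.mean_cost == 0.0

    def test_single_undiscounted_cycle_in_bsc_costs_1650(self, base_ps):
        ps = toy_params({"p_stay": 0.0})
        space = toy_space(["alive"], [], {"alive": "alive"}, "alive")
        import dataclasses

        states = list(space.states["all"])
        states[0] = dataclasses.replace(states[0], cost_params=("cost__bsc__all",))
        space.states["all"] = tuple(states)
        params = dict(ps.parameters)
        params["cost__bsc__all"] = Parameter("cost__bsc__all", "state-cost",
                                             1650.0, 0.0, 9e9, "fixed")
        ps = dataclasses.replace(ps, parameters=params, discount_rate_annual=0.0)
        trace = run_space(space, ps, n_cycles=1)
        res = evaluate(trace, build_strategy("C"), ps)
        assert res.mean_cost == pytest.approx(1650.0)

    def test_discounted_life_years_never_exceed_undiscounted(self, base_ps):
        strategy = build_strategy("C", base_ps)
        space = build_state_space(strategy, base_ps)
        trace = run_space(space, base_ps)
        disc = evaluate(trace, strategy, base_ps)
        undisc = evaluate(trace, strategy, base_ps, discount_rate=0.0)
        assert disc.mean_ly < undisc.mean_ly
        assert evaluate(trace, strategy, base_ps, discount_rate=0.0).mean_ly \
            == pytest.approx(undisc.mean_ly)

    def test_qaly_bounded_by_life_years(self, base_ps):
        for name in ("A", "Int1"):
            r = evaluate_strategy(name, base_ps)
            assert 0.0 <= r.mean_qaly <= r.mean_ly

    def test_invalid_econresult_rejected(self):
        with pytest.raises(ParameterError):
            EconResult("X", mean_cost=-1.0, mean_ly=1.0, mean_qaly=0.5)
        with pytest.raises(ParameterError):
            EconResult("X", mean_cost=0.0, mean_ly=1.0, mean_qaly=1.5)


class TestIcerAndNmb:
    def test_printed_means_give_published_magnitude(self):
        c = EconResult("C", 69_704.0, 6.37, 6.37)
        a = EconResult("A", 71_576.0, 6.61, 6.61)
        value = icer(a, c, "LY")
        assert value == pytest.approx(1872 / 0.24)  # ~7800 per LY
        # the published figure (7903) was computed from unrounded means
        assert value == pytest.approx(7903, rel=0.03)

    def test_zero_cost_difference_gives_zero_icer(self):
        r1 = EconResult("X", 100.0, 2.0, 2.0)
        r2 = EconResult("Y", 100.0, 1.0, 1.0)
        assert icer(r1, r2, "LY") == 0.0

    def test_zero_effect_difference_is_undefined(self):
        r1 = EconResult("X", 100.0, 1.0, 1.0)
        r2 = EconResult("Y", 50.0, 1.0, 1.0)
        with pytest.raises(UndefinedICERError):
            icer(r1, r2, "LY")

    def test_nmb_arithmetic(self):
        a = EconResult("A", 71_576.0, 6.61, 6.61)
        assert nmb(a, 0.0, "LY") == pytest.approx(-71_576.0)
        assert nmb(a, 30_000.0, "LY") == pytest.approx(126_724.0)

    @given(st.integers(0, 10))
    def test_argmax_nmb_agrees_with_frontier_optimum(self, seed):
        rng = np.random.default_rng(seed)
        results = [
            EconResult(f"S{i}", float(rng.uniform(1e4, 2e5)),
                       *(lambda e: (e, e))(float(rng.uniform(1, 10))))
            for i in range(5)
        ]
        fr = frontier(results, "QALY")
        for lam in np.linspace(0, 120_000, 25):
            best_nmb = max(nmb(r, lam) for r in results)
            winners = {r.strategy for r in results
                       if nmb(r, lam) == pytest.approx(best_nmb, abs=1e-6)}
            assert fr.optimal_at(lam) in winners


class TestFrontierOnPrintedTables:
    def test_base_case_cea_classification(self):
        fr = frontier(results_from_printed("nhs_age65", "CEA"), "LY")
        assert fr.dominated == {"Int1"}
        assert fr.extendedly_dominated == {"Int2"}
        assert fr.frontier == ("C", "A", "B")
        assert fr.optimal_at(30_000) == "A"

    def test_base_case_cua_classification(self):
        fr = frontier(results_from_printed("nhs_age65", "CUA"), "QALY")
        assert fr.dominated == frozenset()
        assert fr.extendedly_dominated == {"Int2", "B"}
        assert fr.frontier == ("C", "A", "Int1")
        assert fr.optimal_at(30_000) == "A"
        assert fr.optimal_at(60_000) == "Int1"

    def test_age25_societal_cua_prefers_intervention_1(self):
        fr = frontier(results_from_printed("societal_age25", "CUA"), "QALY")
        assert fr.optimal_at(30_000) == "Int1"
        assert fr.dominated == {"A", "C"}

    def test_printed_icers_consistent_with_rounding_envelope(self):
        # every published ladder ICER must be attainable from means that
        # round to the printed ones (effects to 2 dp, costs to the pound)
        for table, analyses in PRINTED_MEANS.items():
            for analysis, block in analyses.items():
                scale = "LY" if analysis == "CEA" else "QALY"
                fr = frontier(results_from_printed(table, analysis), scale)
                ranked = [s for s in fr.ordering if s not in fr.dominated]
                for prev, cur in zip(ranked, ranked[1:]):
                    printed = PRINTED_ICERS[table][analysis][cur][0]
                    if not isinstance(printed, float):
                        continue
                    de = block[cur][0] - block[prev][0]
                    dc = block[cur][1] - block[prev][1]
                    lo = (dc - 1.0) / (de + 0.01)
                    hi = (dc + 1.0) / max(de - 0.01, 1e-9)
                    assert lo <= printed <= hi, (table, analysis, cur)


class TestFrontierProperties:
    @given(st.integers(0, 200))
    def test_matches_exhaustive_hull_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 7))
        results = [
            EconResult(f"S{i}", float(rng.uniform(1e4, 2e5)),
                       *(lambda e: (e, e))(float(rng.uniform(1, 10))))
            for i in range(n)
        ]
        fr = frontier(results, "QALY")
        oracle_frontier, oracle_dom, oracle_ext = hull_oracle(
            [(r.strategy, r.mean_cost, r.mean_qaly) for r in results]
        )
        assert set(fr.frontier) == oracle_frontier
        assert set(fr.dominated) == oracle_dom
        assert set(fr.extendedly_dominated) == oracle_ext

    @given(st.integers(0, 60))
    def test_final_frontier_is_a_fixed_point_with_increasing_icers(self, seed):
        rng = np.random.default_rng(seed)
        results = [
            EconResult(f"S{i}", float(rng.uniform(1e4, 2e5)),
                       *(lambda e: (e, e))(float(rng.uniform(1, 10))))
            for i in range(6)
        ]
        fr = frontier(results, "QALY")
        icers = [fr.icer_excl_ext_dominated[s] for s in fr.frontier[1:]]
        assert all(a < b for a, b in zip(icers, icers[1:]))
        again = frontier([fr.results[s] for s in fr.frontier], "QALY")
        assert again.frontier == fr.frontier
        assert again.dominated == frozenset()
        assert again.extendedly_dominated == frozenset()

    @given(st.integers(0, 60))
    def test_optimal_effect_nondecreasing_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        results = [
            EconResult(f"S{i}", float(rng.uniform(1e4, 2e5)),
                       *(lambda e: (e, e))(float(rng.uniform(1, 10))))
            for i in range(6)
        ]
        fr = frontier(results, "QALY")
        effs = [fr.results[fr.optimal_at(lam)].mean_qaly
                for lam in np.linspace(0, 150_000, 40)]
        assert all(a <= b + 1e-12 for a, b in zip(effs, effs[1:]))

    def test_equal_cost_equal_effect_keeps_earlier_listed(self):
        r1 = EconResult("first", 100.0, 2.0, 2.0)
        r2 = EconResult("second", 100.0, 2.0, 2.0)
        fr = frontier([r1, r2], "QALY")
        assert fr.dominated == {"second"}
        assert fr.frontier == ("first",)

    def test_duplicate_names_rejected(self):
        r = EconResult("X", 1.0, 1.0, 1.0)
        with pytest.raises(ParameterError):
            frontier([r, r], "QALY")

    def test_single_strategy_is_always_optimal(self):
        r = EconResult("only", 100.0, 2.0, 2.0)
        fr = frontier([r], "QALY")
        assert fr.frontier == ("only",)
        assert fr.optimal_at(0.0) == "only"
        assert fr.icer_excl_ext_dominated == {}
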