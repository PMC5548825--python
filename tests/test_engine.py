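"""Markov engine: state spaces, rows, propagation, discounting."""

import math

import numpy as np
import pytest

from cllcea import (
    Parameter,
    ParameterError,
    ParameterSet,
    build_strategy,
    discount_factor,
    half_cycle_correct,
    run_cohort,
    transition_row,
)
from cllcea.engine import (
    DEATH_CLL,
    DEATH_OTHER,
    HealthState,
    StateSpace,
    Transition,
    build_state_space,
    run_space,
)

from _oracles import enumerate_paths


def toy_params(probs, gompertz_a=0.0, horizon_years=30.0):
    params = {
        "gompertz_a": Parameter("gompertz_a", "rate", gompertz_a, 0.0,
                                max(gompertz_a, 1.0), "fixed"),
        "gompertz_b": Parameter("gompertz_b", "rate", 0.0, 0.0, 1.0, "fixed"),
    }
    for name, v in probs.items():
        params[name] = Parameter(name, "transition-probability", v, 0.0, 1.0,
                                 "fixed")
    ps = ParameterSet(parameters=params, horizon_years=horizon_years)
    ps.validate(complete=False)
    return ps


def toy_space(alive_states, transitions, residual, entry_state):
    """A single-subcohort space with explicit wiring."""
    states = [
        HealthState(id=s, role="bsc", treatment="none", line="none")
        for s in alive_states
    ]
    states.append(HealthState(id=DEATH_CLL, role="death-cll",
                              treatment="none", line="none"))
    states.append(HealthState(id=DEATH_OTHER, role="death-other",
                              treatment="none", line="none"))
    res = dict(residual)
    res[DEATH_CLL] = DEATH_CLL
    res[DEATH_OTHER] = DEATH_OTHER
    return StateSpace(
        strategy_name="toy",
        subcohorts=("all",),
        states={"all": tuple(states)},
        transitions={"all": tuple(transitions)},
        residual={"all": res},
        entry={"all": entry_state},
        entry_distribution={("all", entry_state): 1.0},
    )


class TestStateSpaceStructure:
    @pytest.mark.parametrize("name", ["A", "B", "C", "Int1", "Int2"])
    def test_chemo_lines_have_exactly_six_tunnel_states(self, name, base_ps):
        space = build_state_space(build_strategy(name, base_ps), base_ps)
        for sub in space.subcohorts:
            lines = {}
            for s in space.states[sub]:
                if s.role == "treatment-tunnel" and s.treatment != "ibrutinib":
                    key = s.id.rsplit("_t", 1)[0]
                    lines.setdefault(key, set()).add(s.tunnel_index)
            for key, idxs in lines.items():
                assert idxs == {1, 2, 3, 4, 5, 6}, key

    def test_ibrutinib_states_have_no_tunnel_bound(self, base_ps):
        space = build_state_space(build_strategy("Int1", base_ps), base_ps)
        ibr = [s for sub in space.subcohorts for s in space.states[sub]
               if s.treatment == "ibrutinib"]
        assert ibr and all(s.tunnel_index is None for s in ibr)

    def test_comparator_c_has_no_first_line_to_refractory_route(self, base_ps):
        space = build_state_space(build_strategy("C", base_ps), base_ps)
        for sub in space.subcohorts:
            first_line = {s.id for s in space.states[sub] if s.line == "first"}
            refract_entry = {
                s.id for s in space.states[sub]
                if s.line == "refractory" and s.tunnel_index == 1
            }
            for t in space.transitions[sub]:
                if t.source in first_line:
                    assert t.target not in refract_entry

    def test_comparator_a_routes_acquired_mutations_to_refractory(self, base_ps):
        space = build_state_space(build_strategy("A", base_ps), base_ps)
        kinds = {t.kind for t in space.transitions["unflagged_tn"]}
        assert "acquired-tp53" in kinds

    def test_intervention_1_nonresponders_get_ibrutinib_then_bsc(self, base_ps):
        space = build_state_space(build_strategy("Int1", base_ps), base_ps)
        ids = [s.id for s in space.states["flagged_tp"]]
        assert "s0_ibr_first" in ids and "bsc" in ids
        # ibrutinib exits only to BSC or death
        targets = {t.target for t in space.transitions["flagged_tp"]
                   if t.source == "s0_ibr_first"}
        assert targets <= {"bsc", DEATH_CLL}

    def test_entry_distribution_sums_to_one(self, base_ps):
        for name in ("A", "C", "Int2"):
            space = build_state_space(build_strategy(name, base_ps), base_ps)
            assert sum(space.entry_distribution.values()) == pytest.approx(1.0)

    def test_audit_listing_mentions_every_state(self, base_ps):
        space = build_state_space(build_strategy("B", base_ps), base_ps)
        listing = space.audit_listing()
        for sub in space.subcohorts:
            for s in space.states[sub]:
                assert s.id in listing


class TestTransitionRow:
    def test_absorbing_state_row_is_identity(self, base_ps):
        space = build_state_space(build_strategy("C", base_ps), base_ps)
        row = transition_row(space, "untested_resp", DEATH_CLL, 0, base_ps)
        assert row == {DEATH_CLL: 1.0}

    def test_final_tunnel_state_successors(self, base_ps):
        space = build_state_space(build_strategy("C", base_ps), base_ps)
        row = transition_row(space, "untested_resp", "s0_fcr_first_t6", 0, base_ps)
        allowed = {"s0_fcr_first_rem", "s1_br_second_t1", DEATH_CLL, DEATH_OTHER}
        assert set(row) <= allowed
        assert "s0_fcr_first_t7" not in row  # no seventh tunnel state exists
        assert sum(row.values()) == pytest.approx(1.0)

    def test_complement_arithmetic(self, base_ps):
        # progression 0.05, CLL death 0.02, other-cause 0.001 -> stay 0.929
        b = base_ps.value("gompertz_b")
        h = -math.log(1 - 0.001) * 365.25 / 28  # annual hazard giving p=0.001
        ps = base_ps.resolve({
            "p_prog_rem_first_wt": 0.05,
            "gompertz_a": h / math.exp(b * 65.0),
        })
        space = build_state_space(build_strategy("C", ps), ps)
        row = transition_row(space, "untested_resp", "s0_fcr_first_rem", 0, ps)
        assert row["s0_fcr_first_rem"] == pytest.approx(0.949, abs=1e-9)
        ps2 = ps.resolve({"p_nonresp_br_wt": 0.05, "p_cll_death_br_wt": 0.02})
        row = transition_row(space, "untested_resp", "s1_br_second_t1", 0, ps2)
        assert row["s1_br_second_t2"] == pytest.approx(0.929, abs=1e-9)

    def test_negative_residual_reported_with_state(self, base_ps):
        ps = base_ps.resolve({
            "p_nonresp_ofa_ref": 0.7,
            "p_cll_death_ofa_ref": 0.4,
        })
        space = build_state_space(build_strategy("C", ps), ps)
        with pytest.raises(ParameterError, match="ofatumumab_refractory"):
            transition_row(space, "untested_resp", "s2_ofatumumab_refractory_t1",
                           0, ps)


class TestPropagation:
    def test_two_state_closed_form(self):
        ps = toy_params({"p_die": 0.1}, horizon_years=2.0)
        space = toy_space(
            ["alive"],
            [Transition("alive", DEATH_CLL, "p_die", "cll-death")],
            {"alive": "alive"},
            "alive",
        )
        trace = run_space(space, ps, n_cycles=20)
        alive_idx = 0
        for c in range(21):
            assert trace.occupancy["all"][c, alive_idx] == pytest.approx(
                0.9 ** c, rel=0, abs=1e-15
            )

    def test_no_death_conserves_alive_mass(self):
        ps = toy_params({"p_move": 0.3})
        space = toy_space(
            ["a", "b"],
            [Transition("a", "b", "p_move", "progression")],
            {"a": "a", "b": "b"},
            "a",
        )
        trace = run_space(space, ps, n_cycles=50)
        assert np.allclose(trace.alive_mass(), 1.0, atol=1e-12)

    def test_base_case_runs_391_cycles(self, base_ps):
        assert base_ps.n_cycles == 391
        trace = run_cohort(build_strategy("C", base_ps), base_ps)
        assert trace.n_cycles == 391

    @pytest.mark.parametrize("name", ["A", "B", "C", "Int1", "Int2"])
    def test_conservation_and_death_monotonicity(self, name, base_ps):
        trace = run_cohort(build_strategy(name, base_ps), base_ps)
        trace.check_conservation(1e-10)
        dead = trace.mass(("death-cll", "death-other"))
        assert (np.diff(dead) >= -1e-12).all()

    def test_matrix_propagation_matches_row_by_row(self, base_ps):
        # the vectorised engine must agree with explicit row propagation
        strategy = build_strategy("A", base_ps)
        space = build_state_space(strategy, base_ps)
        trace = run_space(space, base_ps, n_cycles=5)
        for sub in space.subcohorts:
            index = space.state_index(sub)
            v = np.zeros(len(index))
            for (s, sid), frac in space.entry_distribution.items():
                if s == sub:
                    v[index[sid]] = frac
            for c in range(5):
                nxt = np.zeros_like(v)
                for s in space.states[sub]:
                    if v[index[s.id]] == 0.0:
                        continue
                    row = transition_row(space, sub, s.id, c, base_ps)
                    for target, p in row.items():
                        nxt[index[target]] += v[index[s.id]] * p
                v = nxt
                assert np.allclose(trace.occupancy[sub][c + 1], v, atol=1e-12)

    def test_path_enumeration_oracle_on_small_space(self):
        # <=4 states, 10 cycles: exact path-sum enumeration vs the engine
        ps = toy_params({"p_move": 0.25, "p_die1": 0.05, "p_die2": 0.15},
                        gompertz_a=0.01)
        space = toy_space(
            ["a", "b"],
            [
                Transition("a", "b", "p_move", "progression"),
                Transition("a", DEATH_CLL, "p_die1", "cll-death"),
                Transition("b", DEATH_CLL, "p_die2", "cll-death"),
            ],
            {"a": "a", "b": "b"},
            "a",
        )
        trace = run_space(space, ps, n_cycles=10)
        oracle = enumerate_paths(space, "all", ps, 10)
        assert np.abs(trace.occupancy["all"] - oracle).max() < 1e-8

    def test_trace_export_is_tidy(self, base_ps):
        trace = run_cohort(build_strategy("C", base_ps), base_ps, n_cycles=3)
        df = trace.to_frame()
        assert {"cycle", "subcohort", "state", "occupancy"} <= set(df.columns)
        total = df.groupby("cycle")["occupancy"].sum()
        assert np.allclose(total.values, 1.0)


class TestDiscountingAndHalfCycle:
    def test_factor_is_one_at_cycle_zero_and_rate_zero(self):
        assert discount_factor(0, 0.035) == 1.0
        assert discount_factor(200, 0.0) == 1.0

    def test_factor_at_one_year(self):
        one_year_cycles = 365.25 / 28
        assert discount_factor(one_year_cycles, 0.035) == pytest.approx(
            1 / 1.035, rel=1e-12
        )

    def test_factor_strictly_decreasing_for_positive_rate(self):
        f = discount_factor(np.arange(100), 0.035)
        assert (np.diff(f) < 0).all()

    def test_negative_inputs_rejected(self):
        with pytest.raises(ParameterError):
            discount_factor(-1, 0.035)
        with pytest.raises(ParameterError):
            discount_factor(1, -0.01)

    def test_constant_trace_is_fixed_point(self):
        occ = np.tile([0.6, 0.4], (5, 1))
        assert np.allclose(half_cycle_correct(occ), occ[:-1])

    def test_trapezoid_mean_of_successive_occupancies(self):
        occ = np.array([[1.0], [0.8]])
        assert half_cycle_correct(occ)[0, 0] == pytest.approx(0.9)

    def test_applying_twice_differs_from_once(self):
        occ = np.array([[1.0], [0.8], [0.5]])
        once = half_cycle_correct(occ)
        twice = half_cycle_correct(once)
        assert not np.allclose(once[: len(twice)], twice)
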