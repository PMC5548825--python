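"""Tunnel-expanded Markov state spaces and cohort propagation.

Each strategy subcohort is expanded into its own chain of health states:
six 28-day tunnel states per chemotherapy line (FCR, BR, ofatumumab),
unbounded ibrutinib treatment states, a one-cycle transplant (BMT) tunnel,
remission states, best supportive care, and two absorbing death states
(CLL-related and other-cause).  Transition probabilities are competing
per-cycle event probabilities; the residual mass advances the patient along
the tunnel (or keeps them in place), and other-cause mortality - the only
age-varying quantity - is added to every alive state's row at propagation
time.

Occupancy is propagated as cohort proportions for
``floor(horizon_years * 365.25 / cycle_length_days)`` cycles (391 in the
base case).  Inflows into states carrying one-off costs (line entries for
test charging, the BMT tunnel, death states for societal mortality costs)
are recorded alongside occupancy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .fixtures import cost_parameter_name
from .params import ParameterError, ParameterSet
from .strategies import (
    BscLine,
    ChemoLine,
    IbrutinibLine,
    Strategy,
    SubcohortSpec,
    nonresponder_prevalence,
    stratify_cohort,
)

__all__ = [
    "HealthState",
    "Transition",
    "StateSpace",
    "CohortTrace",
    "NegativeResidualError",
    "build_state_space",
    "transition_row",
    "run_cohort",
    "run_space",
    "discount_factor",
    "half_cycle_correct",
]

TUNNEL_CYCLES = 6  # maximum chemotherapy cycles per line
CONSERVATION_TOL = 1e-10

DEATH_CLL = "death_cll"
DEATH_OTHER = "death_other"


class NegativeResidualError(ParameterError):
    """Competing probabilities in one row sum past 1."""


@dataclass(frozen=True)
class HealthState:
    id: str
    role: str  # treatment-tunnel | remission | bmt-tunnel | bmt-remission |
    #            bsc | death-cll | death-other
    treatment: str  # fcr | br | ofatumumab | ibrutinib | none
    line: str  # first | second | refractory | none
    tunnel_index: int | None = None
    cost_params: tuple[str, ...] = ()
    utility_param: str | None = None
    one_off_params: tuple[str, ...] = ()
    compl_param: str | None = None  # complication rate for utility adjustment

    @property
    def absorbing(self) -> bool:
        return self.role in ("death-cll", "death-other")


@dataclass(frozen=True)
class Transition:
    """One competing event out of a state: probability =
    ``value(param) * scale * (1 - value(delta_param))`` (the last factor is
    the responder-effect multiplier, applied only where ``delta_param`` is
    set)."""

    source: str
    target: str
    param: str
    kind: str  # nonresponse | cll-death | progression | acquired-tp53 | bmt
    scale: float = 1.0
    delta_param: str | None = None

    def probability(self, params: ParameterSet) -> float:
        p = params.value(self.param) * self.scale
        if self.delta_param is not None:
            p *= 1.0 - params.value(self.delta_param)
        return p


@dataclass
class StateSpace:
    strategy_name: str
    subcohorts: tuple[str, ...]
    states: dict[str, tuple[HealthState, ...]]  # per subcohort
    transitions: dict[str, tuple[Transition, ...]]
    residual: dict[str, dict[str, str]]  # per sub: state -> residual target
    entry: dict[str, str]  # per sub: entry state id
    entry_distribution: dict[tuple[str, str], float] | None

    def state_index(self, sub: str) -> dict[str, int]:
        return {s.id: i for i, s in enumerate(self.states[sub])}

    def state(self, sub: str, state_id: str) -> HealthState:
        for s in self.states[sub]:
            if s.id == state_id:
                return s
        raise KeyError(f"unknown state {state_id!r} in subcohort {sub!r}")

    def referenced_parameters(self) -> set[str]:
        names: set[str] = set()
        for sub in self.subcohorts:
            for t in self.transitions[sub]:
                names.add(t.param)
                if t.delta_param:
                    names.add(t.delta_param)
            for s in self.states[sub]:
                names.update(s.cost_params)
                names.update(s.one_off_params)
                if s.utility_param:
                    names.add(s.utility_param)
        return names

    def audit_listing(self) -> str:
        """Human-readable adjacency dump of the wiring."""
        lines = [f"strategy {self.strategy_name}"]
        for sub in self.subcohorts:
            lines.append(f"  subcohort {sub} (entry: {self.entry[sub]})")
            by_src: dict[str, list[str]] = {}
            for t in self.transitions[sub]:
                by_src.setdefault(t.source, []).append(
                    f"{t.target} [{t.kind}: {t.param}"
                    + (f" x(1-{t.delta_param})" if t.delta_param else "")
                    + "]"
                )
            for s in self.states[sub]:
                if s.absorbing:
                    lines.append(f"    {s.id} (absorbing)")
                    continue
                outs = by_src.get(s.id, [])
                outs.append(f"{self.residual[sub][s.id]} [residual]")
                lines.append(f"    {s.id} -> " + "; ".join(outs))
        return "\n".join(lines)


@dataclass
class CohortTrace:
    """Per-cycle, per-subcohort state occupancy (proportions of the cohort)
    plus the per-cycle inflows used for one-off cost accrual
    (``inflow[0]`` is the entry distribution)."""

    strategy_name: str
    subcohorts: tuple[str, ...]
    states: dict[str, tuple[HealthState, ...]]
    occupancy: dict[str, np.ndarray]  # (n_cycles+1, n_states) per subcohort
    inflow: dict[str, np.ndarray]
    cycle_length_days: int
    starting_age_years: float

    @property
    def n_cycles(self) -> int:
        first = next(iter(self.occupancy.values()))
        return first.shape[0] - 1

    def total_per_cycle(self) -> np.ndarray:
        """Total occupancy summed over subcohorts and states, per cycle."""
        return sum(occ.sum(axis=1) for occ in self.occupancy.values())

    def mass(self, roles: Iterable[str]) -> np.ndarray:
        """Occupancy mass in the given roles per cycle, across subcohorts."""
        roles = set(roles)
        total = np.zeros(self.n_cycles + 1)
        for sub in self.subcohorts:
            sel = [i for i, s in enumerate(self.states[sub]) if s.role in roles]
            if sel:
                total += self.occupancy[sub][:, sel].sum(axis=1)
        return total

    def alive_mass(self) -> np.ndarray:
        dead = self.mass(("death-cll", "death-other"))
        return self.total_per_cycle() - dead

    def check_conservation(self, tol: float = CONSERVATION_TOL) -> None:
        total = self.total_per_cycle()
        err = np.abs(total - 1.0).max()
        if err > tol:
            raise ParameterError(
                f"cohort mass not conserved: max deviation {err:.3e}"
            )

    def to_frame(self):
        """Occupancy as a tidy DataFrame (cycle x subcohort x state)."""
        import pandas as pd

        frames = []
        for sub in self.subcohorts:
            df = pd.DataFrame(
                self.occupancy[sub],
                columns=[s.id for s in self.states[sub]],
            )
            df.insert(0, "cycle", np.arange(df.shape[0]))
            df.insert(1, "subcohort", sub)
            frames.append(df.melt(
                id_vars=["cycle", "subcohort"],
                var_name="state", value_name="occupancy",
            ))
        return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# state-space construction
# ---------------------------------------------------------------------------

_CHEMO_PARAMS = {
    ("fcr", "first"): ("p_nonresp_fcr_{risk}", "p_cll_death_fcr_{risk}",
                       "p_prog_rem_first_{risk}"),
    ("br", "second"): ("p_nonresp_br_{risk}", "p_cll_death_br_{risk}",
                       "p_prog_rem_second_{risk}"),
    ("ofatumumab", "first"): ("p_nonresp_ofa_first", "p_cll_death_ofa_first",
                              "p_prog_rem_ofa_first"),
    ("ofatumumab", "refractory"): ("p_nonresp_ofa_ref", "p_cll_death_ofa_ref",
                                   "p_prog_rem_ref"),
}

_CHEMO_COST_LABELS = {
    ("fcr", "first"): ("fcr_l1_c1", None, "fcr_l1_subs", "rem_fcr"),
    ("br", "second"): ("br_l2_c1", None, "br_l2_subs", "rem_br"),
    ("ofatumumab", "first"): ("ofa_l1_c1", "ofa_l1_c2", "ofa_l1_subs", "rem_ofa"),
    ("ofatumumab", "refractory"): ("ofa_ref_c1", "ofa_ref_c2", "ofa_ref_subs",
                                   "rem_ofa"),
}

_LINE_UTILITY = {
    "first": "u__first_line_treatment",
    "second": "u__second_line_treatment",
    "refractory": "u__refractory_treatment",
}

_COMPL_PARAM = {
    "fcr": "compl_rate_fcr",
    "br": "compl_rate_br",
    "ofatumumab": "compl_rate_ofa",
    "ibrutinib": "compl_rate_ibr",
}

SOC_PERCYCLE_TREATMENT = "soc__percycle__treatment"
SOC_PERCYCLE_REMISSION = "soc__percycle__remission"
SOC_PERCYCLE_BSC = "soc__percycle__bsc"
SOC_ONEOFF_LINE_ENTRY = "soc__oneoff__line_entry"


def _chemo_param_names(seg: ChemoLine, risk: str) -> tuple[str, str, str]:
    try:
        tmpl = _CHEMO_PARAMS[(seg.treatment, seg.line)]
    except KeyError:
        raise ParameterError(
            f"no probability bindings for {seg.treatment} {seg.line}"
        ) from None
    return tuple(t.format(risk=risk) for t in tmpl)  # type: ignore[return-value]


def _ibr_admin_param(strategy_name: str) -> str:
    return "cost__ibr_admin__b" if strategy_name == "B" else "cost__ibr_admin__int"


def _build_subcohort(
    strategy: Strategy, sub: SubcohortSpec
) -> tuple[tuple[HealthState, ...], tuple[Transition, ...], dict[str, str], str]:
    """Expand one subcohort's segment sequence into states + transitions."""
    states: list[HealthState] = []
    transitions: list[Transition] = []
    residual: dict[str, str] = {}
    sname = strategy.name
    delta_param = strategy.responder_effect_param

    entry_ids: list[str] = []  # entry state per segment
    for i, seg in enumerate(sub.segments):
        if isinstance(seg, ChemoLine):
            entry_ids.append(f"s{i}_{seg.treatment}_{seg.line}_t1")
        elif isinstance(seg, IbrutinibLine):
            entry_ids.append(f"s{i}_ibr_{seg.line}")
        else:
            entry_ids.append("bsc")

    def refractory_entry_after(i: int) -> str | None:
        for j in range(i + 1, len(sub.segments)):
            seg_j = sub.segments[j]
            if isinstance(seg_j, (ChemoLine, IbrutinibLine)) and seg_j.line == "refractory":
                return entry_ids[j]
        return None

    for i, seg in enumerate(sub.segments):
        next_entry = entry_ids[i + 1] if i + 1 < len(sub.segments) else None
        if isinstance(seg, ChemoLine):
            p_nonresp, p_death, p_prog = _chemo_param_names(seg, sub.risk)
            c1, c2, csubs, crem = _CHEMO_COST_LABELS[(seg.treatment, seg.line)]
            boost = delta_param if seg.boosted else None
            one_off_entry: list[str] = [SOC_ONEOFF_LINE_ENTRY]
            if i == 0 and strategy.test.one_off_cost_key:
                one_off_entry.append(strategy.test.one_off_cost_key)
            if i > 0 and seg.retest and strategy.retest_per_line:
                one_off_entry.append("cost_genomic_test")
            rem_id = f"s{i}_{seg.treatment}_{seg.line}_rem"
            acq_target = (
                refractory_entry_after(i) if seg.acquired_escape else None
            )
            for k in range(1, TUNNEL_CYCLES + 1):
                sid = f"s{i}_{seg.treatment}_{seg.line}_t{k}"
                label = c1 if k == 1 else (c2 if (k == 2 and c2) else csubs)
                states.append(HealthState(
                    id=sid,
                    role="treatment-tunnel",
                    treatment=seg.treatment,
                    line=seg.line,
                    tunnel_index=k,
                    cost_params=(cost_parameter_name(label, sname),
                                 SOC_PERCYCLE_TREATMENT),
                    utility_param=_LINE_UTILITY[seg.line],
                    one_off_params=tuple(one_off_entry) if k == 1 else (),
                    compl_param=_COMPL_PARAM[seg.treatment],
                ))
                if next_entry is not None:
                    transitions.append(Transition(
                        sid, next_entry, p_nonresp, "nonresponse",
                        delta_param=boost,
                    ))
                transitions.append(Transition(
                    sid, DEATH_CLL, p_death, "cll-death", delta_param=boost,
                ))
                if acq_target is not None:
                    transitions.append(Transition(
                        sid, acq_target, "p_acquired_tp53", "acquired-tp53",
                    ))
                if seg.bmt and k == TUNNEL_CYCLES:
                    transitions.append(Transition(
                        sid, f"s{i}_bmt", "p_bmt", "bmt",
                    ))
                residual[sid] = (
                    f"s{i}_{seg.treatment}_{seg.line}_t{k + 1}"
                    if k < TUNNEL_CYCLES else rem_id
                )
            # remission after the line
            states.append(HealthState(
                id=rem_id,
                role="remission",
                treatment=seg.treatment,
                line=seg.line,
                cost_params=(cost_parameter_name(crem, sname),
                             SOC_PERCYCLE_REMISSION),
                utility_param="u__remission",
            ))
            if next_entry is not None:
                transitions.append(Transition(
                    rem_id, next_entry, p_prog, "progression", delta_param=boost,
                ))
            residual[rem_id] = rem_id
            if seg.bmt:
                bmt_id, bmt_rem_id = f"s{i}_bmt", f"s{i}_bmt_rem"
                states.append(HealthState(
                    id=bmt_id,
                    role="bmt-tunnel",
                    treatment="none",
                    line=seg.line,
                    tunnel_index=1,
                    cost_params=(SOC_PERCYCLE_TREATMENT,),
                    utility_param="u__bmt",
                    one_off_params=(cost_parameter_name("bmt", sname),),
                    compl_param="compl_rate_bmt",
                ))
                transitions.append(Transition(
                    bmt_id, DEATH_CLL, "p_cll_death_bmt", "cll-death",
                ))
                residual[bmt_id] = bmt_rem_id
                states.append(HealthState(
                    id=bmt_rem_id,
                    role="bmt-remission",
                    treatment="none",
                    line=seg.line,
                    cost_params=(cost_parameter_name("rem_bmt", sname),
                                 SOC_PERCYCLE_REMISSION),
                    utility_param="u__remission",
                ))
                if next_entry is not None:
                    transitions.append(Transition(
                        bmt_rem_id, next_entry, "p_prog_rem_bmt", "progression",
                    ))
                residual[bmt_rem_id] = bmt_rem_id
        elif isinstance(seg, IbrutinibLine):
            sid = entry_ids[i]
            variant = "first" if seg.line == "first" else "ref"
            one_off_entry = [SOC_ONEOFF_LINE_ENTRY]
            if i == 0 and strategy.test.one_off_cost_key:
                one_off_entry.append(strategy.test.one_off_cost_key)
            if i > 0 and seg.retest and strategy.retest_per_line:
                one_off_entry.append("cost_genomic_test")
            states.append(HealthState(
                id=sid,
                role="treatment-tunnel",
                treatment="ibrutinib",
                line=seg.line,
                tunnel_index=None,  # no six-cycle bound for ibrutinib
                cost_params=("cost_ibr_drug_cycle", _ibr_admin_param(sname),
                             SOC_PERCYCLE_TREATMENT),
                utility_param=_LINE_UTILITY[seg.line],
                one_off_params=tuple(one_off_entry),
                compl_param=_COMPL_PARAM["ibrutinib"],
            ))
            if next_entry is not None:
                transitions.append(Transition(
                    sid, next_entry, f"p_nonresp_ibr_{variant}", "nonresponse",
                ))
            transitions.append(Transition(
                sid, DEATH_CLL, f"p_cll_death_ibr_{variant}", "cll-death",
            ))
            residual[sid] = sid
        else:  # BSC
            states.append(HealthState(
                id="bsc",
                role="bsc",
                treatment="none",
                line="none",
                cost_params=(cost_parameter_name("bsc", sname),
                             SOC_PERCYCLE_BSC),
                utility_param="u__bsc",
            ))
            transitions.append(Transition(
                "bsc", DEATH_CLL, "p_cll_death_bsc", "cll-death",
            ))
            residual["bsc"] = "bsc"

    states.append(HealthState(id=DEATH_CLL, role="death-cll",
                              treatment="none", line="none"))
    states.append(HealthState(id=DEATH_OTHER, role="death-other",
                              treatment="none", line="none"))
    residual[DEATH_CLL] = DEATH_CLL
    residual[DEATH_OTHER] = DEATH_OTHER
    return tuple(states), tuple(transitions), residual, entry_ids[0]


def build_state_space(
    strategy: Strategy, params: ParameterSet | None = None
) -> StateSpace:
    """Expand a strategy into its per-subcohort tunnel state space.

    With ``params`` the entry distribution is resolved from the test's
    stratification (for Comparator C, the untested cohort is split into
    responder/non-responder risk groups at the test-independent prevalence);
    without it the space is structural only (used for audits and config
    completeness checks).
    """
    states = {}
    transitions = {}
    residual = {}
    entry = {}
    for sub in strategy.subcohorts:
        st, tr, res, ent = _build_subcohort(strategy, sub)
        states[sub.name] = st
        transitions[sub.name] = tr
        residual[sub.name] = res
        entry[sub.name] = ent

    entry_distribution = None
    if params is not None:
        fractions = stratify_cohort(strategy.test, params)
        if strategy.test.name == "none":
            pi = nonresponder_prevalence(params)
            fractions = {
                "untested_resp": fractions["untested"] * (1.0 - pi),
                "untested_nonresp": fractions["untested"] * pi,
            }
        entry_distribution = {}
        for sub in strategy.subcohorts:
            if sub.name not in fractions:
                raise ParameterError(
                    f"stratification did not produce subcohort {sub.name!r}"
                )
            entry_distribution[(sub.name, entry[sub.name])] = fractions[sub.name]
        total = sum(entry_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(f"entry distribution sums to {total}, not 1")

    return StateSpace(
        strategy_name=strategy.name,
        subcohorts=tuple(s.name for s in strategy.subcohorts),
        states=states,
        transitions=transitions,
        residual=residual,
        entry=entry,
        entry_distribution=entry_distribution,
    )


# ---------------------------------------------------------------------------
# rows and propagation
# ---------------------------------------------------------------------------

def discount_factor(
    cycle, annual_rate: float, cycle_length_days: int = 28
):
    """Discount factor ``(1 + r)^(-t)`` at ``t = cycle * 28/365.25`` years."""
    if annual_rate < 0:
        raise ParameterError("discount rate must be >= 0")
    cycle = np.asarray(cycle, dtype=float)
    if (cycle < 0).any():
        raise ParameterError("cycle must be >= 0")
    t_years = cycle * (cycle_length_days / 365.25)
    out = (1.0 + annual_rate) ** (-t_years)
    return out if out.ndim else float(out)


def half_cycle_correct(occupancy: np.ndarray) -> np.ndarray:
    """Trapezoid half-cycle correction: effective occupancy over cycle ``c``
    is the mean of the cycle-start occupancies at ``c`` and ``c+1``."""
    occupancy = np.asarray(occupancy, dtype=float)
    return 0.5 * (occupancy[:-1] + occupancy[1:])


def _other_cause_probability(params: ParameterSet, cycle) -> np.ndarray:
    from .synth import background_mortality

    age = params.starting_age_years + np.asarray(cycle, dtype=float) * params.cycle_years
    return background_mortality(age, params)


def transition_row(
    space: StateSpace,
    sub: str,
    state_id: str,
    cycle: int,
    params: ParameterSet,
) -> dict[str, float]:
    """One state's outgoing probability row at a given cycle (dict
    successor -> probability, summing to 1)."""
    state = space.state(sub, state_id)
    if state.absorbing:
        return {state_id: 1.0}
    row: dict[str, float] = {}
    for t in space.transitions[sub]:
        if t.source == state_id:
            row[t.target] = row.get(t.target, 0.0) + t.probability(params)
    p_other = float(_other_cause_probability(params, cycle))
    row[DEATH_OTHER] = row.get(DEATH_OTHER, 0.0) + p_other
    residual_target = space.residual[sub][state_id]
    residual = 1.0 - sum(row.values())
    if residual < -1e-12:
        raise NegativeResidualError(
            f"{space.strategy_name}/{sub}/{state_id} at cycle {cycle}: "
            f"competing probabilities sum to {1.0 - residual:.6f} > 1"
        )
    row[residual_target] = row.get(residual_target, 0.0) + max(residual, 0.0)
    return row


def _compile_subcohort(space: StateSpace, sub: str, params: ParameterSet):
    """Event matrix E (events + residual, other-cause mortality excluded),
    residual-target index per state, and the alive mask."""
    states = space.states[sub]
    index = {s.id: i for i, s in enumerate(states)}
    n = len(states)
    E = np.zeros((n, n))
    for t in space.transitions[sub]:
        E[index[t.source], index[t.target]] += t.probability(params)
    alive = np.array([not s.absorbing for s in states])
    res_tgt = np.zeros(n, dtype=int)
    for s in states:
        i = index[s.id]
        res_tgt[i] = index[space.residual[sub][s.id]]
        if s.absorbing:
            E[i, i] = 1.0
        else:
            residual = 1.0 - E[i].sum()
            if residual < -1e-12:
                raise NegativeResidualError(
                    f"{space.strategy_name}/{sub}/{s.id}: competing "
                    f"probabilities sum to {E[i].sum():.6f} > 1"
                )
            E[i, res_tgt[i]] += max(residual, 0.0)
    return E, res_tgt, alive, index


def run_space(space: StateSpace, params: ParameterSet,
              n_cycles: int | None = None) -> CohortTrace:
    """Propagate the cohort through a built state space."""
    if space.entry_distribution is None:
        raise ParameterError("state space has no entry distribution; build "
                             "it with a parameter set")
    n_cycles = params.n_cycles if n_cycles is None else int(n_cycles)
    p_other = np.asarray(
        _other_cause_probability(params, np.arange(n_cycles)), dtype=float
    )
    occupancy: dict[str, np.ndarray] = {}
    inflow: dict[str, np.ndarray] = {}
    for sub in space.subcohorts:
        E, res_tgt, alive, index = _compile_subcohort(space, sub, params)
        n = E.shape[0]
        other_idx = index[DEATH_OTHER]
        alive_idx = np.where(alive)[0]
        max_event = E[alive_idx].sum(axis=1) - np.take_along_axis(
            E[alive_idx], res_tgt[alive_idx, None], axis=1
        ).ravel()
        if (max_event + p_other.max() > 1.0 + 1e-12).any():
            bad = alive_idx[np.argmax(max_event)]
            raise NegativeResidualError(
                f"{space.strategy_name}/{sub}/{space.states[sub][bad].id}: "
                "event probabilities plus other-cause mortality exceed 1"
            )
        occ = np.zeros((n_cycles + 1, n))
        infl = np.zeros((n_cycles + 1, n))
        v0 = np.zeros(n)
        for (s_name, state_id), frac in space.entry_distribution.items():
            if s_name == sub:
                v0[index[state_id]] = frac
        occ[0] = v0
        infl[0] = v0
        v = v0
        rows = alive_idx
        for c in range(n_cycles):
            M = E.copy()
            poc = p_other[c]
            M[rows, res_tgt[rows]] -= poc
            M[rows, other_idx] += poc
            v_next = v @ M
            infl[c + 1] = v_next - v * M.diagonal()
            occ[c + 1] = v_next
            v = v_next
        occupancy[sub] = occ
        inflow[sub] = infl
    return CohortTrace(
        strategy_name=space.strategy_name,
        subcohorts=space.subcohorts,
        states=space.states,
        occupancy=occupancy,
        inflow=inflow,
        cycle_length_days=params.cycle_length_days,
        starting_age_years=params.starting_age_years,
    )


def run_cohort(strategy: Strategy, params: ParameterSet,
               n_cycles: int | None = None) -> CohortTrace:
    """Build the strategy's state space and propagate the cohort through it."""
    space = build_state_space(strategy, params)
    return run_space(space, params, n_cycles=n_cycles)
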