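"""Discounted cost/effect accrual and incremental analysis.

``evaluate`` turns a cohort trace into per-patient discounted mean costs,
life-years and QALYs: half-cycle-corrected state occupancy accrues per-cycle
state costs and utility-weighted time, while recorded inflows accrue one-off
costs (test charges at line entry, the transplant procedure, societal
premature-mortality losses).

``frontier`` performs the incremental analysis: strategies are ordered by
cost, strictly dominated ones (costlier and no more effective) are excluded,
ICERs are laddered over the survivors, and extended dominance (an ICER
exceeding that of the next more-effective strategy) is removed iteratively
until the frontier's ICERs strictly increase.  The optimal strategy at a
willingness-to-pay threshold is the highest-effect frontier member whose
ICER does not exceed the threshold - equivalently the net-monetary-benefit
maximiser.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .engine import (
    CohortTrace,
    StateSpace,
    build_state_space,
    discount_factor,
    half_cycle_correct,
    run_space,
)
from .params import ParameterError, ParameterSet
from .strategies import STRATEGY_NAMES, Strategy, build_strategy

__all__ = [
    "EconResult",
    "FrontierResult",
    "UndefinedICERError",
    "evaluate",
    "evaluate_strategy",
    "evaluate_strategies",
    "icer",
    "nmb",
    "frontier",
]


class UndefinedICERError(ParameterError):
    """ICER requested for a zero effect difference."""


@dataclass(frozen=True)
class EconResult:
    """Per-patient discounted means for one strategy."""

    strategy: str
    mean_cost: float
    mean_ly: float
    mean_qaly: float

    def __post_init__(self):
        for name in ("mean_cost", "mean_ly", "mean_qaly"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ParameterError(f"{self.strategy}: {name} = {v} is invalid")
        if self.mean_qaly > self.mean_ly + 1e-9:
            raise ParameterError(
                f"{self.strategy}: QALYs ({self.mean_qaly}) exceed "
                f"life-years ({self.mean_ly})"
            )

    def effect(self, effect_scale: str) -> float:
        if effect_scale == "LY":
            return self.mean_ly
        if effect_scale == "QALY":
            return self.mean_qaly
        raise ParameterError(f"unknown effect scale {effect_scale!r}")


def _utility_vector(states, params: ParameterSet) -> np.ndarray:
    """State utilities; in complication-adjusted mode, treatment states
    carry ``u - complication_rate * grade-3/4 disutility``."""
    out = np.zeros(len(states))
    adjust = params.utility_mode == "complication-adjusted"
    for i, s in enumerate(states):
        if s.utility_param is None:
            continue
        u = params.value(s.utility_param)
        if adjust and s.compl_param is not None:
            u = u - params.value(s.compl_param) * params.value("du_grade34_ae")
        out[i] = max(u, 0.0)
    return out


def _societal_death_loss(params: ParameterSet, n_cycles: int) -> np.ndarray | None:
    """Premature-mortality production loss per unit inflow into a death
    state at each cycle (zero without a societal spec)."""
    spec = params.societal
    if spec is None:
        return None
    from .societal import mortality_loss_schedule

    return mortality_loss_schedule(params, spec, n_cycles)


def evaluate(
    trace: CohortTrace,
    strategy: Strategy,
    params: ParameterSet,
    discount_rate: float | None = None,
) -> EconResult:
    """Discounted per-patient mean cost, life-years and QALYs for a trace."""
    space_states = trace.states
    rate = params.discount_rate_annual if discount_rate is None else discount_rate
    n_cycles = trace.n_cycles
    cyl = params.cycle_years
    disc = np.asarray(
        discount_factor(np.arange(n_cycles), rate, params.cycle_length_days)
    )
    hc_costs = params.half_cycle in ("both", "costs")
    hc_outcomes = params.half_cycle in ("both", "outcomes")

    death_loss = _societal_death_loss(params, n_cycles)

    total_cost = 0.0
    total_ly = 0.0
    total_qaly = 0.0
    for sub in trace.subcohorts:
        states = space_states[sub]
        occ = trace.occupancy[sub]
        infl = trace.inflow[sub]
        eff_costs = half_cycle_correct(occ) if hc_costs else occ[:-1]
        eff_out = half_cycle_correct(occ) if hc_outcomes else occ[:-1]

        cost_vec = np.array(
            [sum(params.value(p) for p in s.cost_params) for s in states]
        )
        oneoff_vec = np.array(
            [sum(params.value(p) for p in s.one_off_params) for s in states]
        )
        util_vec = _utility_vector(states, params)
        alive_vec = np.array([0.0 if s.absorbing else 1.0 for s in states])

        total_cost += float(disc @ (eff_costs @ cost_vec))
        total_cost += float(disc @ (infl[:-1] @ oneoff_vec))
        if death_loss is not None:
            death_idx = [i for i, s in enumerate(states) if s.absorbing]
            death_inflow = infl[1:, death_idx].sum(axis=1)  # deaths during cycle c
            total_cost += float(disc @ (death_inflow * death_loss))
        total_ly += float(disc @ (eff_out @ alive_vec)) * cyl
        total_qaly += float(disc @ (eff_out @ util_vec)) * cyl

    return EconResult(
        strategy=strategy.name,
        mean_cost=total_cost,
        mean_ly=total_ly,
        mean_qaly=total_qaly,
    )


def evaluate_strategy(
    name: str, params: ParameterSet, n_cycles: int | None = None
) -> EconResult:
    """Convenience: build, run and evaluate a single strategy."""
    strategy = build_strategy(name, params)
    space = build_state_space(strategy, params)
    trace = run_space(space, params, n_cycles=n_cycles)
    return evaluate(trace, strategy, params)


def evaluate_strategies(
    params: ParameterSet, names: Sequence[str] = STRATEGY_NAMES
) -> dict[str, EconResult]:
    return {name: evaluate_strategy(name, params) for name in names}


# ---------------------------------------------------------------------------
# incremental analysis
# ---------------------------------------------------------------------------

def icer(more_effective: EconResult, less_effective: EconResult,
         effect_scale: str = "QALY") -> float:
    """Incremental cost per unit effect between two strategies."""
    d_e = more_effective.effect(effect_scale) - less_effective.effect(effect_scale)
    d_c = more_effective.mean_cost - less_effective.mean_cost
    if d_e == 0.0:
        raise UndefinedICERError(
            f"ICER undefined: {more_effective.strategy} and "
            f"{less_effective.strategy} have equal effect"
        )
    return d_c / d_e


def nmb(result: EconResult, threshold: float, effect_scale: str = "QALY") -> float:
    """Net monetary benefit ``threshold * effect - cost``."""
    if threshold < 0:
        raise ParameterError("threshold must be >= 0")
    return threshold * result.effect(effect_scale) - result.mean_cost


@dataclass
class FrontierResult:
    """Incremental analysis of a strategy set on one effect scale."""

    effect_scale: str
    ordering: tuple[str, ...]  # all strategies, ascending cost
    dominated: frozenset[str]
    extendedly_dominated: frozenset[str]
    icer_excl_dominated: dict[str, float]  # ladder over non-dominated
    icer_excl_ext_dominated: dict[str, float]  # ladder over final frontier
    frontier: tuple[str, ...]  # final survivors, ascending cost
    results: dict[str, EconResult]

    def optimal_at(self, threshold: float) -> str:
        """Highest-effect frontier strategy whose ICER does not exceed the
        willingness-to-pay threshold (the cheapest strategy if none does)."""
        best = self.frontier[0]
        for name in self.frontier[1:]:
            if self.icer_excl_ext_dominated[name] <= threshold:
                best = name
        return best

    def optimal_map(self, thresholds: Iterable[float]) -> dict[float, str]:
        return {t: self.optimal_at(t) for t in thresholds}

    def to_frame(self):
        """Frontier report mirroring the published table layout."""
        import pandas as pd

        rows = []
        for name in self.ordering:
            r = self.results[name]
            if name in self.dominated:
                i_dom = i_ext = "DOM"
            else:
                i_dom = self.icer_excl_dominated.get(name, "")
                i_ext = (
                    "EXT.DOM" if name in self.extendedly_dominated
                    else self.icer_excl_ext_dominated.get(name, "")
                )
            rows.append({
                "strategy": name,
                f"mean_{self.effect_scale.lower()}": r.effect(self.effect_scale),
                "mean_cost": r.mean_cost,
                "icer_excl_dominated": i_dom,
                "icer_excl_ext_dominated": i_ext,
            })
        return pd.DataFrame(rows)


def _ladder(sequence: Sequence[EconResult], effect_scale: str) -> dict[str, float]:
    return {
        cur.strategy: icer(cur, prev, effect_scale)
        for prev, cur in zip(sequence, sequence[1:])
    }


def frontier(
    results: Iterable[EconResult] | Mapping[str, EconResult],
    effect_scale: str = "QALY",
) -> FrontierResult:
    """Incremental analysis with strict and extended dominance exclusion."""
    if isinstance(results, Mapping):
        results = list(results.values())
    else:
        results = list(results)
    if not results:
        raise ParameterError("frontier requires at least one result")
    names = [r.strategy for r in results]
    if len(set(names)) != len(names):
        raise ParameterError("duplicate strategy names in frontier input")

    # sort ascending by cost, stable in input order (ties keep earlier first)
    order = sorted(range(len(results)), key=lambda i: results[i].mean_cost)
    ranked = [results[i] for i in order]

    def eff(r: EconResult) -> float:
        return r.effect(effect_scale)

    # strict dominance: costlier and no more effective than some alternative;
    # on exact cost/effect ties the earlier-listed strategy is kept
    dominated: set[str] = set()
    for i, r in enumerate(results):
        for j, other in enumerate(results):
            if i == j:
                continue
            if other.mean_cost < r.mean_cost and eff(other) >= eff(r):
                dominated.add(r.strategy)
            elif other.mean_cost == r.mean_cost and eff(other) > eff(r):
                dominated.add(r.strategy)
            elif (other.mean_cost == r.mean_cost and eff(other) == eff(r)
                  and j < i):
                dominated.add(r.strategy)

    survivors = [r for r in ranked if r.strategy not in dominated]
    icer_excl_dom = _ladder(survivors, effect_scale)

    # extended dominance: drop any strategy whose ICER is not below the next
    # more-effective strategy's, recomputing the ladder after each removal
    ext_dominated: set[str] = set()
    frontier_seq = list(survivors)
    while True:
        ladder = _ladder(frontier_seq, effect_scale)
        removed = False
        for k in range(1, len(frontier_seq) - 1):
            s_k = frontier_seq[k].strategy
            s_next = frontier_seq[k + 1].strategy
            if ladder[s_k] >= ladder[s_next]:
                ext_dominated.add(s_k)
                frontier_seq.pop(k)
                removed = True
                break
        if not removed:
            break
    icer_excl_ext = _ladder(frontier_seq, effect_scale)

    return FrontierResult(
        effect_scale=effect_scale,
        ordering=tuple(r.strategy for r in ranked),
        dominated=frozenset(dominated),
        extendedly_dominated=frozenset(ext_dominated),
        icer_excl_dominated=icer_excl_dom,
        icer_excl_ext_dominated=icer_excl_ext,
        frontier=tuple(r.strategy for r in frontier_seq),
        results={r.strategy: r for r in results},
    )
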