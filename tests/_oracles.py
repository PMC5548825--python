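"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: the frontier oracle
enumerates net-monetary-benefit winners over all candidate thresholds, and
the cohort oracle enumerates every individual path through a small state
space cycle by cycle.
"""

from __future__ import annotations

import numpy as np

from cllcea.engine import StateSpace, transition_row


def hull_oracle(points):
    """Classify (name, cost, effect) points by exhaustive NMB enumeration.

    Returns (frontier_names, dominated, extendedly_dominated).  A point is
    strictly dominated if another is cheaper and at least as effective (or
    equal-cost and strictly more effective); it is on the frontier if it
    strictly wins the net monetary benefit at some willingness-to-pay
    ``lambda >= 0``; the remainder are extendedly dominated.
    """
    names = [p[0] for p in points]
    cost = {p[0]: p[1] for p in points}
    eff = {p[0]: p[2] for p in points}

    dominated = set()
    for a in names:
        for b in names:
            if a == b:
                continue
            if cost[b] < cost[a] and eff[b] >= eff[a]:
                dominated.add(a)
            elif cost[b] == cost[a] and eff[b] > eff[a]:
                dominated.add(a)

    # candidate thresholds: 0, every pairwise positive ICER, and a value
    # beyond the largest; probe just off each crossover to find strict winners
    candidates = [0.0]
    for a in names:
        for b in names:
            de = eff[a] - eff[b]
            if de != 0:
                lam = (cost[a] - cost[b]) / de
                if lam > 0:
                    candidates.append(lam)
    top = max(candidates) if candidates else 1.0
    probes = []
    eps = 1e-6 * max(1.0, top)
    for lam in candidates:
        probes.extend([max(lam - eps, 0.0), lam + eps])
    probes.append(top * 2 + 1.0)

    frontier = set()
    for lam in probes:
        nmb = {n: lam * eff[n] - cost[n] for n in names}
        best = max(nmb.values())
        winners = [n for n in names if nmb[n] >= best - abs(best) * 1e-12 - 1e-12]
        if len(winners) == 1:
            frontier.add(winners[0])
    ext_dominated = set(names) - dominated - frontier
    return frontier, dominated, ext_dominated


def enumerate_paths(space: StateSpace, sub: str, params, n_cycles: int):
    """Exact occupancy by summing probability over every individual path."""
    index = space.state_index(sub)
    n = len(space.states[sub])
    occ = np.zeros((n_cycles + 1, n))
    entry = {
        index[sid]: frac
        for (s, sid), frac in space.entry_distribution.items()
        if s == sub
    }

    def recurse(state_idx: int, cycle: int, prob: float):
        occ[cycle, state_idx] += prob
        if cycle == n_cycles or prob == 0.0:
            return
        sid = space.states[sub][state_idx].id
        row = transition_row(space, sub, sid, cycle, params)
        for target, p in row.items():
            if p > 0:
                recurse(index[target], cycle + 1, prob * p)

    for idx, frac in entry.items():
        recurse(idx, 0, frac)
    return occ
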