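"""Published per-state cost and utility fixtures (GBP, 2013 price year).

The 28-day-cycle state costs and the utility weights are the printed inputs
of the UK NHS evaluation this package re-implements.  They are immutable
lookup tables; :mod:`cllcea.synth` embeds them verbatim into every generated
parameter set.

Cost labels use ``l1``/``l2``/``ref`` for first/second/refractory line and
``c1``/``c2``/``subs`` for first/second/subsequent cycle of a treatment
line.  Several rows carry different values per strategy group (A/B vs C vs
the intervention strategies), reflecting differences in test-cost loading
and pathway overheads; the group tag is part of the parameter name.
"""

from __future__ import annotations

from types import MappingProxyType
from typing import Mapping

__all__ = [
    "STRATEGY_NAMES",
    "table2_state_costs",
    "table3_utilities",
    "lookup_state_cost",
    "lookup_utility",
    "cost_parameter_name",
]

STRATEGY_NAMES = ("A", "B", "C", "Int1", "Int2")

# label -> {group_tag: (strategies, cost per 28-day cycle in GBP)}
_TABLE2: dict[str, dict[str, tuple[tuple[str, ...], float]]] = {
    "fcr_l1_c1": {
        "ab": (("A", "B"), 4404.0),
        "c": (("C",), 4123.0),
        "int": (("Int1", "Int2"), 3958.0),
    },
    "fcr_l2_c1": {
        "ab": (("A", "B"), 5373.0),
        "c": (("C",), 5092.0),
    },
    "fcr_l1_subs": {
        "abc": (("A", "B", "C"), 4289.0),
        "int": (("Int1", "Int2"), 3805.0),
    },
    "fcr_l2_subs": {
        "abc": (("A", "B", "C"), 5258.0),
    },
    "br_l1_c1": {
        "ab": (("A", "B"), 4535.0),
        "c": (("C",), 4254.0),
    },
    "br_l2_c1": {
        "ab": (("A", "B"), 5542.0),
        "c": (("C",), 5261.0),
        "int": (("Int1", "Int2"), 4573.0),
    },
    "br_l1_subs": {
        "abc": (("A", "B", "C"), 4427.0),
    },
    "br_l2_subs": {
        "abc": (("A", "B", "C"), 5434.0),
        "int": (("Int1", "Int2"), 4427.0),
    },
    "ofa_l1_c1": {
        "ab": (("A", "B"), 12798.0),
        "int2": (("Int2",), 12836.0),
    },
    "ofa_l1_c2": {
        # the printed table gives the second-cycle loading for A/B only;
        # Int2 reuses it (the first-cycle rows differ by a £38 test-cost
        # amortisation that does not recur)
        "ab": (("A", "B", "Int2"), 15334.0),
    },
    "ofa_l1_subs": {
        "ab": (("A", "B", "Int2"), 4455.0),
    },
    "ofa_ref_c1": {
        "ab": (("A", "B"), 13054.0),
        "c": (("C",), 12773.0),
    },
    "ofa_ref_c2": {
        "abc": (("A", "B", "C"), 15590.0),
    },
    "ofa_ref_subs": {
        "abc": (("A", "B", "C"), 4711.0),
    },
    "ibr_l1": {
        "int": (("Int1",), 2704.0),
    },
    "ibr_ref": {
        "b": (("B",), 2780.0),
        "int": (("Int1", "Int2"), 2704.0),
    },
    "rem_fcr": {"all": (STRATEGY_NAMES, 212.0)},
    "rem_br": {"all": (STRATEGY_NAMES, 130.0)},
    "rem_ofa": {"all": (("A", "B", "C", "Int2"), 49.0)},
    "bmt": {"all": (("A", "B", "C", "Int2"), 43724.0)},  # one-off per procedure
    "rem_bmt": {"all": (("A", "B", "C", "Int2"), 233.0)},
    "bsc": {"all": (STRATEGY_NAMES, 1650.0)},
}

_TABLE3: dict[str, float] = {
    "first_line_treatment": 0.803,
    "second_line_treatment": 0.710,
    "refractory_treatment": 0.650,
    "bmt": 0.650,
    "remission": 0.910,
    "grade_3_4_adverse_event_disutility": -0.133,
    "bsc": 0.680,
}

#: ibrutinib per-cycle cost decomposition: drug component (an assumed
#: £30,000/year over 365.25/28 cycles) + administration/monitoring overhead.
#: The printed 2704/2780 state costs are the sums; scenario and threshold
#: analyses act on the drug component alone.
IBRUTINIB_DRUG_COST_PER_CYCLE = 2300.0
IBRUTINIB_ADMIN_COST = {"int": 404.0, "b": 480.0}


def table2_state_costs() -> Mapping[tuple[str, str], float]:
    """The printed per-cycle state-cost table as ``(label, group) -> GBP``."""
    return MappingProxyType(
        {
            (label, group): cost
            for label, groups in _TABLE2.items()
            for group, (_, cost) in groups.items()
        }
    )


def table3_utilities() -> Mapping[str, float]:
    """The printed utility-weight table, disease state -> weight."""
    return MappingProxyType(dict(_TABLE3))


def lookup_state_cost(label: str, strategy: str) -> float:
    """Printed cost of state ``label`` under ``strategy``.

    Raises ``KeyError`` for a (state, strategy) pair the table does not
    define (e.g. BMT under Intervention 1, which has no transplant pathway).
    """
    if label not in _TABLE2:
        raise KeyError(f"unknown state-cost label {label!r}")
    for _, (strategies, cost) in _TABLE2[label].items():
        if strategy in strategies:
            return cost
    raise KeyError(f"state cost {label!r} is not defined for strategy {strategy!r}")


def lookup_utility(state: str) -> float:
    if state not in _TABLE3:
        raise KeyError(f"unknown utility state {state!r}")
    return _TABLE3[state]


def cost_parameter_name(label: str, strategy: str) -> str:
    """Parameter-set name of the cost entry applying to (label, strategy)."""
    if label not in _TABLE2:
        raise KeyError(f"unknown state-cost label {label!r}")
    for group, (strategies, _) in _TABLE2[label].items():
        if strategy in strategies:
            return f"cost__{label}__{group}"
    raise KeyError(f"state cost {label!r} is not defined for strategy {strategy!r}")


def iter_cost_entries():
    """Yield (param_name, label, group, strategies, value) over the table."""
    for label, groups in _TABLE2.items():
        for group, (strategies, cost) in groups.items():
            yield f"cost__{label}__{group}", label, group, strategies, cost
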