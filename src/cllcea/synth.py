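"""Synthetic parameter-set generation.

The printed inputs of the evaluation (state costs, utility weights, test
accuracy, the 20% responder effect, cycle length, horizon, discounting) are
embedded verbatim.  Everything else the model needs - per-cycle transition
probabilities per treatment and risk group, transplant uptake, background
mortality, test unit costs, societal unit costs - was sourced from
supplementary material not reproduced here, so this module generates
complete, internally consistent values that honour the printed constraints:

* TP53-mutated (FCR non-responder) pathways have strictly higher per-cycle
  progression, non-response and CLL mortality than wild-type pathways;
* ibrutinib states have strictly lower per-cycle non-response and CLL
  mortality than refractory ofatumumab states;
* other-cause mortality follows a Gompertz annual hazard
  ``h(age) = a * exp(b * age)`` (defaults calibrated so remaining life
  expectancy at 65 is roughly 20 years), converted to a 28-day probability
  via ``p = 1 - exp(-h * 28/365.25)``;
* the genomic residual false-negative fraction defaults to the value that
  makes non-responder prevalence test-independent.

``efficacy_ordering_strength`` scales the wt/mut and ofatumumab/ibrutinib
gaps (1 = the documented defaults); ``noise_cv`` adds mean-preserving
lognormal noise to every generated (non-printed) value.  Identical seeds
yield bit-identical parameter sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fixtures import (
    IBRUTINIB_ADMIN_COST,
    IBRUTINIB_DRUG_COST_PER_CYCLE,
    iter_cost_entries,
    table3_utilities,
)
from .params import Parameter, ParameterError, ParameterSet

__all__ = [
    "SynthesisSpec",
    "generate_parameter_set",
    "base_parameter_set",
    "background_mortality",
    "ORDERING_PAIRS",
]


@dataclass(frozen=True)
class SynthesisSpec:
    seed: int = 0
    starting_age_years: float = 65.0
    efficacy_ordering_strength: float = 1.0  # in (0, 1]
    noise_cv: float = 0.10

    def validate(self) -> None:
        if not (0.0 < self.efficacy_ordering_strength <= 1.0):
            raise ParameterError(
                "efficacy_ordering_strength must lie in (0, 1]"
            )
        if self.noise_cv < 0:
            raise ParameterError("noise_cv must be >= 0")
        if self.starting_age_years < 0:
            raise ParameterError("starting_age_years must be >= 0")


# ---------------------------------------------------------------------------
# documented default values (28-day-cycle probabilities unless noted)
# ---------------------------------------------------------------------------

#: independently generated quantities: name -> (role, default, distribution)
_BASE_DEFAULTS = {
    # wild-type (likely FCR responder) chemotherapy pathway
    "p_nonresp_fcr_wt": ("transition-probability", 0.020, "beta"),
    "p_cll_death_fcr_wt": ("transition-probability", 0.002, "beta"),
    "p_prog_rem_first_wt": ("transition-probability", 0.0040, "beta"),
    "p_nonresp_br_wt": ("transition-probability", 0.030, "beta"),
    "p_cll_death_br_wt": ("transition-probability", 0.003, "beta"),
    "p_prog_rem_second_wt": ("transition-probability", 0.018, "beta"),
    # ofatumumab, first-line (TP53+ pathway) and refractory
    "p_nonresp_ofa_first": ("transition-probability", 0.050, "beta"),
    "p_cll_death_ofa_first": ("transition-probability", 0.005, "beta"),
    "p_prog_rem_ofa_first": ("transition-probability", 0.012, "beta"),
    "p_nonresp_ofa_ref": ("transition-probability", 0.100, "beta"),
    "p_cll_death_ofa_ref": ("transition-probability", 0.030, "beta"),
    "p_prog_rem_ref": ("transition-probability", 0.080, "beta"),
    # transplant, supportive care, emergent high-risk disease
    "p_cll_death_bmt": ("transition-probability", 0.080, "beta"),
    "p_prog_rem_bmt": ("transition-probability", 0.004, "beta"),
    "p_cll_death_bsc": ("transition-probability", 0.080, "beta"),
    "p_acquired_tp53": ("transition-probability", 0.001, "beta"),
    "p_bmt": ("proportion", 0.40, "beta"),
    # other-cause mortality (Gompertz annual hazard h = a * exp(b*age))
    "gompertz_a": ("rate", 2.3e-5, "gamma"),
    "gompertz_b": ("rate", 0.095, "gamma"),
    # grade 3/4 complication rates per treatment course (utility adjustment)
    "compl_rate_fcr": ("proportion", 0.45, "beta"),
    "compl_rate_br": ("proportion", 0.35, "beta"),
    "compl_rate_ofa": ("proportion", 0.30, "beta"),
    "compl_rate_ibr": ("proportion", 0.15, "beta"),
    "compl_rate_bmt": ("proportion", 0.60, "beta"),
    # test unit costs (microcosting outputs; GBP 2013)
    "cost_genetic_test": ("one-off-cost", 339.0, "gamma"),
    "cost_genomic_test": ("one-off-cost", 520.0, "gamma"),
    # societal unit costs (GBP 2013)
    "soc__daily_wage": ("societal-cost", 110.0, "gamma"),
    "soc__ic_unit_cost": ("societal-cost", 15.0, "gamma"),
    "soc__ic_hours_treatment": ("rate", 20.0, "gamma"),
    "soc__ic_hours_remission": ("rate", 1.0, "gamma"),
    "soc__ic_hours_bsc": ("rate", 60.0, "gamma"),
    "soc__oop_treatment": ("societal-cost", 40.0, "gamma"),
    "soc__oop_remission": ("societal-cost", 5.0, "gamma"),
    "soc__oop_bsc": ("societal-cost", 30.0, "gamma"),
    "soc__emp_16_54": ("proportion", 0.75, "beta"),
    "soc__emp_55_64": ("proportion", 0.60, "beta"),
    "soc__emp_65p": ("proportion", 0.05, "beta"),
    "soc__friction_days": ("rate", 90.0, "gamma"),
}

#: quantities derived from an anchor so the efficacy ordering holds by
#: construction: name -> (anchor, default ratio vs anchor, direction)
_DERIVED_DEFAULTS = {
    # TP53-mutated pathways do strictly worse on chemotherapy
    "p_nonresp_fcr_mut": ("p_nonresp_fcr_wt", 5.5, "above"),
    "p_cll_death_fcr_mut": ("p_cll_death_fcr_wt", 14.0, "above"),
    "p_prog_rem_first_mut": ("p_prog_rem_first_wt", 12.75, "above"),
    "p_nonresp_br_mut": ("p_nonresp_br_wt", 4.3333333333, "above"),
    "p_cll_death_br_mut": ("p_cll_death_br_wt", 10.6666666667, "above"),
    "p_prog_rem_second_mut": ("p_prog_rem_second_wt", 3.6111111111, "above"),
    # ibrutinib does strictly better than refractory ofatumumab
    "p_nonresp_ibr_first": ("p_nonresp_ofa_ref", 0.06, "below"),
    "p_cll_death_ibr_first": ("p_cll_death_ofa_ref", 0.10, "below"),
    "p_nonresp_ibr_ref": ("p_nonresp_ofa_ref", 0.15, "below"),
    "p_cll_death_ibr_ref": ("p_cll_death_ofa_ref", 0.2666666667, "below"),
}

#: (larger, smaller) pairs every generated set must order strictly
ORDERING_PAIRS = tuple(
    (name, anchor) if direction == "above" else (anchor, name)
    for name, (anchor, _, direction) in _DERIVED_DEFAULTS.items()
)

#: printed inputs embedded verbatim (never noised)
_PRINTED_SCALARS = {
    "responder_effect_delta": ("proportion", 0.20, "beta"),
    "flag_rate_genetic": ("proportion", 0.07, "beta"),
    "ppv_genetic": ("proportion", 0.78, "beta"),
    "pfs36_residual_genetic": ("proportion", 0.69, "beta"),
    "flag_rate_genomic": ("proportion", 0.17, "beta"),
    "ppv_genomic": ("proportion", 0.82, "beta"),
    "cost_ibr_drug_cycle": ("state-cost", IBRUTINIB_DRUG_COST_PER_CYCLE, "gamma"),
    "cost__ibr_admin__int": ("state-cost", IBRUTINIB_ADMIN_COST["int"], "gamma"),
    "cost__ibr_admin__b": ("state-cost", IBRUTINIB_ADMIN_COST["b"], "gamma"),
    "du_grade34_ae": ("utility", 0.133, "beta"),
    # fixed plumbing
    "soc__retirement_age": ("rate", 65.0, "fixed"),
    "soc__workdays_per_year": ("rate", 248.0, "fixed"),
    # societal increments resolved by apply_societal (zero = NHS perspective)
    "soc__percycle__treatment": ("societal-cost", 0.0, "fixed"),
    "soc__percycle__remission": ("societal-cost", 0.0, "fixed"),
    "soc__percycle__bsc": ("societal-cost", 0.0, "fixed"),
    "soc__oneoff__line_entry": ("societal-cost", 0.0, "fixed"),
}

_PROB_CAP = 0.95  # generated per-cycle probabilities never reach 1
_STRICT_MARGIN = 1.0001  # minimal multiplicative gap kept by orderings

_UTILITY_PARAM_KEYS = {
    "u__first_line_treatment": "first_line_treatment",
    "u__second_line_treatment": "second_line_treatment",
    "u__refractory_treatment": "refractory_treatment",
    "u__bmt": "bmt",
    "u__remission": "remission",
    "u__bsc": "bsc",
}


def _make_parameter(name, role, value, dist) -> Parameter:
    cap = 1.0 if role in ("transition-probability", "proportion", "utility") else None
    low = max(0.0, 0.5 * value)
    high = 1.5 * value if value > 0 else 0.0
    if cap is not None:
        high = min(high, cap)
    return Parameter(name=name, role=role, value=value, low=low, high=high,
                     distribution=dist)


def _noise(rng: np.random.Generator, cv: float) -> float:
    """Mean-preserving multiplicative lognormal noise with the given CV."""
    if cv <= 0:
        return 1.0
    sigma = float(np.sqrt(np.log1p(cv * cv)))
    return float(np.exp(rng.normal(0.0, sigma) - 0.5 * sigma * sigma))


def generate_parameter_set(spec: SynthesisSpec) -> ParameterSet:
    """Generate a complete, validated parameter set for all five strategies."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    s = spec.efficacy_ordering_strength
    params: dict[str, Parameter] = {}

    values: dict[str, float] = {}
    for name in sorted(_BASE_DEFAULTS):
        role, default, dist = _BASE_DEFAULTS[name]
        v = default * _noise(rng, spec.noise_cv)
        if role in ("transition-probability", "proportion"):
            v = min(v, _PROB_CAP)
        values[name] = v
        params[name] = _make_parameter(name, role, v, dist)
    for name in sorted(_DERIVED_DEFAULTS):
        anchor, ratio, direction = _DERIVED_DEFAULTS[name]
        anchor_v = values[anchor]
        if direction == "above":
            scaled = 1.0 + s * (ratio - 1.0)
            v = anchor_v * scaled * _noise(rng, spec.noise_cv)
            v = max(v, anchor_v * _STRICT_MARGIN)
            v = min(v, _PROB_CAP)
        else:
            scaled = 1.0 - s * (1.0 - ratio)
            v = anchor_v * scaled * _noise(rng, spec.noise_cv)
            v = min(v, anchor_v / _STRICT_MARGIN)
        values[name] = v
        params[name] = _make_parameter(
            name, "transition-probability", v, "beta"
        )

    for name, (role, value, dist) in _PRINTED_SCALARS.items():
        params[name] = _make_parameter(name, role, value, dist)
    for pname, label, _group, _strategies, cost in iter_cost_entries():
        if label in ("ibr_l1", "ibr_ref"):
            continue  # wired as drug + administration components
        role = "one-off-cost" if label == "bmt" else "state-cost"
        params[pname] = _make_parameter(pname, role, cost, "gamma")
    for pname, key in _UTILITY_PARAM_KEYS.items():
        params[pname] = _make_parameter(
            pname, "utility", table3_utilities()[key], "beta"
        )

    ps = ParameterSet(parameters=params,
                      starting_age_years=spec.starting_age_years)
    # genomic residual false negatives: default keeps the population
    # prevalence of true non-responders identical across tests
    from .strategies import nonresponder_prevalence

    pi = nonresponder_prevalence(ps)
    flag = params["flag_rate_genomic"].value
    ppv = params["ppv_genomic"].value
    fn_frac = (pi - flag * ppv) / (1.0 - flag)
    fn_frac = min(1.0, max(0.0, fn_frac))
    params["fn_frac_genomic"] = _make_parameter(
        "fn_frac_genomic", "proportion", fn_frac, "beta"
    )
    ps = ParameterSet(parameters=params,
                      starting_age_years=spec.starting_age_years)
    ps.validate(complete=True)
    return ps


def base_parameter_set(starting_age_years: float = 65.0) -> ParameterSet:
    """The documented default parameter set (no noise; deterministic)."""
    return generate_parameter_set(
        SynthesisSpec(seed=0, starting_age_years=starting_age_years,
                      efficacy_ordering_strength=1.0, noise_cv=0.0)
    )


def background_mortality(age_years, params: ParameterSet):
    """Per-cycle other-cause death probability at a given age.

    Converts the annual Gompertz hazard ``a * exp(b * age)`` to a
    cycle-length probability via ``p = 1 - exp(-h * cycle_days/365.25)``;
    nondecreasing in age.
    """
    age = np.asarray(age_years, dtype=float)
    if (age < 0).any():
        raise ParameterError("age must be >= 0")
    h = params.value("gompertz_a") * np.exp(params.value("gompertz_b") * age)
    p = -np.expm1(-h * params.cycle_length_days / 365.25)
    return p if p.ndim else float(p)
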