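"""Sensitivity, scenario, threshold and probabilistic analyses.

Univariate analysis re-evaluates the decision at each parameter's low/high
bound (+/-50% of base by default, truncated to the parameter's domain).
Scenario analyses bundle the published variations: ibrutinib price changes,
a doubled responder effect, alternative starting ages and horizons, and
equalising the genomic test with the genetic one.  Threshold search bisects
a single parameter for the value at which a target strategy becomes optimal
at a given willingness-to-pay.

The PSA samples every non-fixed parameter independently - beta for
probabilities, proportions and utilities, gamma for costs and rates, both
parameterised by method of moments with a default coefficient of variation
of 0.10 where no variance is reported - evaluates all strategies per draw,
and summarises decision uncertainty as cost-effectiveness acceptability
curves (the per-threshold probability that each strategy maximises net
monetary benefit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .econ import EconResult, FrontierResult, evaluate_strategies, frontier, nmb
from .engine import NegativeResidualError
from .params import BETA_ROLES, GAMMA_ROLES, Parameter, ParameterError, ParameterSet
from .strategies import STRATEGY_NAMES, unflagged_nonresponder_weight

__all__ = [
    "beta_params",
    "gamma_params",
    "sample_parameter_set",
    "sample_psa",
    "ceac",
    "univariate_sa",
    "threshold_search",
    "ScenarioSpec",
    "builtin_scenario",
    "run_scenario",
    "PsaResult",
    "CeacCurve",
    "DEFAULT_CEAC_THRESHOLDS",
]

#: CEAC threshold grid: GBP 0 to 100,000 in 2,500 steps
DEFAULT_CEAC_THRESHOLDS = tuple(float(t) for t in range(0, 100_001, 2_500))


# ---------------------------------------------------------------------------
# method-of-moments parameterisations
# ---------------------------------------------------------------------------

def beta_params(mean: float, sd: float) -> tuple[float, float]:
    """Beta (alpha, beta) matching a mean and standard deviation."""
    if not (0.0 < mean < 1.0):
        raise ParameterError(f"beta mean must lie in (0, 1), got {mean}")
    if sd <= 0.0:
        raise ParameterError("beta sd must be > 0")
    var = sd * sd
    if var >= mean * (1.0 - mean):
        raise ParameterError(
            f"infeasible beta sd {sd} for mean {mean}: variance must be "
            f"below mean*(1-mean)"
        )
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def gamma_params(mean: float, sd: float) -> tuple[float, float]:
    """Gamma (shape, scale) matching a mean and standard deviation."""
    if mean <= 0.0 or sd <= 0.0:
        raise ParameterError("gamma mean and sd must be > 0")
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return shape, scale


def _sample_value(rng: np.random.Generator, p: Parameter, cv: float) -> float:
    sd = cv * abs(p.value)
    if p.distribution == "fixed" or p.value == 0.0 or sd == 0.0:
        return p.value
    if p.distribution == "beta":
        if p.value >= 1.0:
            return p.value
        a, b = beta_params(p.value, min(sd, 0.99 * math.sqrt(p.value * (1 - p.value))))
        return float(rng.beta(a, b))
    shape, scale = gamma_params(p.value, sd)
    return float(rng.gamma(shape, scale))


def sample_parameter_set(
    base: ParameterSet, rng: np.random.Generator
) -> ParameterSet:
    """One PSA draw: every non-fixed parameter sampled independently from
    its assigned distribution (CV-default variance)."""
    overrides = {
        name: _sample_value(rng, p, base.cv_default)
        for name, p in sorted(base.parameters.items())
        if p.distribution != "fixed"
    }
    return base.resolve(overrides)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class PsaResult:
    draws: list[dict[str, EconResult]]
    seed: int
    n_sims: int
    strategies: tuple[str, ...]
    n_resampled: int = 0

    def effects(self, effect_scale: str) -> np.ndarray:
        return np.array(
            [[d[s].effect(effect_scale) for s in self.strategies]
             for d in self.draws]
        )

    def costs(self) -> np.ndarray:
        return np.array(
            [[d[s].mean_cost for s in self.strategies] for d in self.draws]
        )


def sample_psa(
    base: ParameterSet,
    n_sims: int = 1000,
    seed: int = 0,
    strategies: Sequence[str] = STRATEGY_NAMES,
    max_retries: int = 10,
) -> PsaResult:
    """Seeded PSA: ``n_sims`` draws, each evaluated deterministically.

    A draw whose sampled probabilities produce an invalid transition row
    (competing probabilities past 1) is resampled, up to ``max_retries``
    times, and counted in ``n_resampled``.
    """
    if n_sims < 1:
        raise ParameterError("n_sims must be >= 1")
    rng = np.random.default_rng(seed)
    draws: list[dict[str, EconResult]] = []
    n_resampled = 0
    for _ in range(n_sims):
        for attempt in range(max_retries + 1):
            sampled = sample_parameter_set(base, rng)
            try:
                draws.append(evaluate_strategies(sampled, strategies))
                break
            except NegativeResidualError:
                n_resampled += 1
                if attempt == max_retries:
                    raise
    return PsaResult(
        draws=draws,
        seed=seed,
        n_sims=n_sims,
        strategies=tuple(strategies),
        n_resampled=n_resampled,
    )


@dataclass
class CeacCurve:
    thresholds: tuple[float, ...]
    probability: dict[str, np.ndarray]  # strategy -> per-threshold proportion

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"threshold": self.thresholds})
        for s, p in self.probability.items():
            df[s] = p
        return df


def ceac(
    psa: PsaResult,
    thresholds: Sequence[float] = DEFAULT_CEAC_THRESHOLDS,
    effect_scale: str = "QALY",
) -> CeacCurve:
    """Cost-effectiveness acceptability curves from PSA draws.

    At each threshold, a strategy's probability is the fraction of draws in
    which it maximises net monetary benefit; exact ties split evenly, so the
    columns sum to 1.
    """
    if not psa.draws:
        raise ParameterError("PSA result is empty")
    eff = psa.effects(effect_scale)
    cost = psa.costs()
    n_draws, n_strats = eff.shape
    prob = {s: np.zeros(len(thresholds)) for s in psa.strategies}
    for ti, lam in enumerate(thresholds):
        nmb_matrix = lam * eff - cost
        best = nmb_matrix.max(axis=1, keepdims=True)
        winners = nmb_matrix >= best - 1e-9  # even split on ties
        weights = winners / winners.sum(axis=1, keepdims=True)
        shares = weights.mean(axis=0)
        for si, s in enumerate(psa.strategies):
            prob[s][ti] = shares[si]
    return CeacCurve(thresholds=tuple(thresholds), probability=prob)


# ---------------------------------------------------------------------------
# univariate sensitivity analysis
# ---------------------------------------------------------------------------

def univariate_sa(
    base: ParameterSet,
    strategies: Sequence[str] = STRATEGY_NAMES,
    effect_scale: str = "QALY",
    threshold: float = 30_000.0,
    parameters: Sequence[str] | None = None,
) -> pd.DataFrame:
    """One row per (parameter, bound): the decision at the low and high
    bound of each parameter, all else at base values."""
    base_frontier = frontier(evaluate_strategies(base, strategies), effect_scale)
    base_optimal = base_frontier.optimal_at(threshold)
    names = sorted(parameters if parameters is not None else base.parameters)
    rows = []
    for name in names:
        p = base.parameters[name]
        for bound, value in (("low", p.low), ("high", p.high)):
            if value == p.value:
                optimal = base_optimal
                fr = base_frontier
            else:
                varied = base.resolve({name: value})
                fr = frontier(evaluate_strategies(varied, strategies),
                              effect_scale)
                optimal = fr.optimal_at(threshold)
            rows.append({
                "parameter": name,
                "bound": bound,
                "value": value,
                "optimal_strategy": optimal,
                "decision_changed": optimal != base_optimal,
                "frontier": "->".join(fr.frontier),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# scenario analyses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioSpec:
    """A named variation of the base case.

    ``ibrutinib_cost_multiplier`` scales the ibrutinib drug component;
    ``responder_delta`` replaces the 20% responder effect;
    ``equalise_tests`` gives the genomic test the genetic test's accuracy,
    unflagged split and cost.
    """

    id: str
    description: str = ""
    param_overrides: Mapping[str, float] = field(default_factory=dict)
    ibrutinib_cost_multiplier: float | None = None
    responder_delta: float | None = None
    starting_age_years: float | None = None
    horizon_years: float | None = None
    equalise_tests: bool = False


_BUILTIN_SCENARIOS = {
    1: ScenarioSpec(
        id="S1", description="ibrutinib drug cost reduced by 75% "
        "(2300 -> 575 per cycle)", ibrutinib_cost_multiplier=0.25,
    ),
    2: ScenarioSpec(
        id="S2", description="ibrutinib at its undiscounted list price "
        "(about 56,000/year)", ibrutinib_cost_multiplier=56.0 / 30.0,
    ),
    3: ScenarioSpec(
        id="S3", description="responder effect doubled from 20% to 40%",
        responder_delta=0.40,
    ),
    4: ScenarioSpec(
        id="S4-age25", description="starting age 25 years",
        starting_age_years=25.0,
    ),
    5: ScenarioSpec(
        id="S5", description="10-year time horizon", horizon_years=10.0,
    ),
    6: ScenarioSpec(
        id="S6", description="20-year time horizon", horizon_years=20.0,
    ),
    7: ScenarioSpec(
        id="S7", description="genomic test equalised with genetic test "
        "(cost and performance)", equalise_tests=True,
    ),
}
_BUILTIN_SCENARIOS["4b"] = ScenarioSpec(
    id="S4-age85", description="starting age 85 years",
    starting_age_years=85.0,
)


def builtin_scenario(scenario_id) -> ScenarioSpec:
    try:
        return _BUILTIN_SCENARIOS[scenario_id]
    except KeyError:
        raise ParameterError(f"unknown scenario {scenario_id!r}") from None


def scenario_parameter_set(spec: ScenarioSpec, base: ParameterSet) -> ParameterSet:
    """Apply a scenario's overrides to a base parameter set."""
    overrides = dict(spec.param_overrides)
    if spec.ibrutinib_cost_multiplier is not None:
        overrides["cost_ibr_drug_cycle"] = (
            base.value("cost_ibr_drug_cycle") * spec.ibrutinib_cost_multiplier
        )
    if spec.responder_delta is not None:
        overrides["responder_effect_delta"] = spec.responder_delta
    if spec.equalise_tests:
        overrides["flag_rate_genomic"] = base.value("flag_rate_genetic")
        overrides["ppv_genomic"] = base.value("ppv_genetic")
        overrides["cost_genomic_test"] = base.value("cost_genetic_test")
        overrides["fn_frac_genomic"] = unflagged_nonresponder_weight(base)
    out = base.resolve(overrides)
    settings = {}
    if spec.starting_age_years is not None:
        settings["starting_age_years"] = spec.starting_age_years
    if spec.horizon_years is not None:
        settings["horizon_years"] = spec.horizon_years
    if settings:
        out = out.with_settings(**settings)
    return out


def run_scenario(
    spec: ScenarioSpec,
    base: ParameterSet,
    strategies: Sequence[str] = STRATEGY_NAMES,
    effect_scales: Sequence[str] = ("LY", "QALY"),
) -> dict:
    """Evaluate all strategies under a scenario; frontier per effect scale."""
    ps = scenario_parameter_set(spec, base)
    results = evaluate_strategies(ps, strategies)
    report = {
        "scenario": spec.id,
        "description": spec.description,
        "results": results,
        "frontiers": {
            scale: frontier(results, scale) for scale in effect_scales
        },
        "optimal": {},
    }
    for scale, fr in report["frontiers"].items():
        report["optimal"][scale] = {
            t: fr.optimal_at(t) for t in ps.thresholds_gbp
        }
    return report


# ---------------------------------------------------------------------------
# threshold search
# ---------------------------------------------------------------------------

def threshold_search(
    param_name: str,
    base: ParameterSet,
    target_strategy: str,
    threshold: float = 30_000.0,
    effect_scale: str = "QALY",
    bracket: tuple[float, float] | None = None,
    tol: float = 1.0,
    strategies: Sequence[str] = STRATEGY_NAMES,
) -> dict:
    """Bisect ``param_name`` for the value at which ``target_strategy``
    becomes the optimal strategy at the willingness-to-pay ``threshold``.

    Requires the decision to flip across the bracket (checked empirically at
    the ends); returns the critical value to within ``tol`` plus the bracket
    diagnostics.  If both ends already select (or never select) the target,
    the matching bracket edge is returned with ``status`` set accordingly.
    """
    p = base.parameters.get(param_name)
    if p is None:
        raise ParameterError(f"unknown parameter {param_name!r}")
    lo, hi = bracket if bracket is not None else (p.low, p.high)
    if lo > hi:
        raise ParameterError("bracket must be (low, high)")

    def target_optimal(value: float) -> bool:
        varied = base.resolve({param_name: value})
        fr = frontier(evaluate_strategies(varied, strategies), effect_scale)
        return fr.optimal_at(threshold) == target_strategy

    at_lo = target_optimal(lo)
    at_hi = target_optimal(hi)
    if at_lo == at_hi:
        status = "target-optimal-everywhere" if at_lo else "no-threshold-in-range"
        return {
            "parameter": param_name,
            "critical_value": lo if at_lo else None,
            "status": status,
            "bracket": (lo, hi),
        }
    a, b = lo, hi
    while b - a > tol:
        mid = 0.5 * (a + b)
        if target_optimal(mid) == at_lo:
            a = mid
        else:
            b = mid
    # report the edge of the region where the target is optimal
    critical = 0.5 * (a + b)
    return {
        "parameter": param_name,
        "critical_value": critical,
        "status": "found",
        "bracket": (lo, hi),
        "target_optimal_at_low": at_lo,
    }
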