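"""The five test-treatment strategies and cohort stratification.

Three current-practice comparators and two genomic interventions are wired
as treatment pathways per subcohort:

* **A** - genetic (FISH + Sanger) testing; unflagged patients receive
  FCR then BR chemotherapy with refractory ofatumumab (+/- allogeneic
  transplant); flagged (TP53-mutated) patients receive first-line
  ofatumumab (+/- transplant) then a second ofatumumab course.
* **B** - as A, but refractory treatment for all patients is ibrutinib.
* **C** - no testing; everyone follows A's unflagged pathway, with no
  direct first-line-to-refractory route (emergent high-risk disease
  cannot be identified without testing).
* **Int1** - genomic (targeted NGS) testing; flagged likely FCR
  non-responders receive first-line ibrutinib until non-response, then
  best supportive care; unflagged likely responders receive
  FCR/BR (with the 20% responder-effect improvement when correctly
  identified) and refractory ibrutinib.
* **Int2** - as Int1, but flagged patients receive first-line ofatumumab
  (+/- transplant) and refractory ibrutinib.

Genomic strategies re-test before every new treatment line, so the genomic
test cost recurs at each line entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .params import ParameterError, ParameterSet

__all__ = [
    "STRATEGY_NAMES",
    "TestSpec",
    "Strategy",
    "SubcohortSpec",
    "ChemoLine",
    "IbrutinibLine",
    "BscLine",
    "build_strategy",
    "make_test_spec",
    "stratify_cohort",
    "apply_responder_effect",
    "unflagged_nonresponder_weight",
    "nonresponder_prevalence",
    "referenced_parameters",
    "treatment_lines",
]

STRATEGY_NAMES = ("A", "B", "C", "Int1", "Int2")

#: cycles to 36 months at 28 days/cycle (36 * 365.25/12 / 28, floored), split
#: into the six on-treatment cycles and the remainder spent in remission.
PFS36_CYCLES = 39
PFS36_TREATMENT_CYCLES = 6
PFS36_REMISSION_CYCLES = PFS36_CYCLES - PFS36_TREATMENT_CYCLES


@dataclass(frozen=True)
class TestSpec:
    """Accuracy and cost of a pre-treatment stratification test.

    ``flagged_fraction`` is the proportion of the cohort the test flags as
    likely FCR non-responders; ``positive_predictive_value`` the share of
    flagged patients who truly are.  For the genetic test the unflagged
    split is anchored on the reported 69% progression-free proportion of
    the residual group at 36 months; for the genomic test the residual
    false-negative fraction is a named parameter.
    """

    name: str  # genetic | genomic | none
    flagged_fraction: float = 0.0
    positive_predictive_value: float = 0.0
    residual_progression_free_36m: float | None = None
    residual_fn_fraction: float | None = None
    one_off_cost_key: str | None = None

    def __post_init__(self):
        for v in (self.flagged_fraction, self.positive_predictive_value):
            if not (0.0 <= v <= 1.0):
                raise ParameterError(
                    f"test {self.name!r}: proportions must lie in [0, 1]"
                )


# ---------------------------------------------------------------------------
# pathway segments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChemoLine:
    """A six-cycle chemotherapy tunnel line followed by a remission state."""

    treatment: str  # fcr | br | ofatumumab
    line: str  # first | second | refractory
    boosted: bool = False  # responder-effect multiplier applies
    bmt: bool = False  # transplant consolidation offered on completion
    acquired_escape: bool = False  # emergent-TP53 route to the refractory line
    retest: bool = False  # genomic re-test charged at line entry


@dataclass(frozen=True)
class IbrutinibLine:
    """Continuous ibrutinib, no tunnel bound; held until non-response."""

    line: str  # first | refractory
    retest: bool = False


@dataclass(frozen=True)
class BscLine:
    """Best supportive care, terminal non-curative state."""


LineSpec = ChemoLine | IbrutinibLine | BscLine


@dataclass(frozen=True)
class SubcohortSpec:
    """One stratified subcohort and the treatment sequence it follows."""

    name: str
    risk: str  # wt | mut - selects the FCR/BR probability bindings
    segments: tuple[LineSpec, ...]


@dataclass(frozen=True)
class Strategy:
    name: str
    test: TestSpec
    subcohorts: tuple[SubcohortSpec, ...]
    retest_per_line: bool = False
    responder_effect_param: str = "responder_effect_delta"

    @property
    def uses_ibrutinib(self) -> bool:
        return any(
            isinstance(seg, IbrutinibLine)
            for sub in self.subcohorts
            for seg in sub.segments
        )


# ---------------------------------------------------------------------------
# test specs and stratification
# ---------------------------------------------------------------------------

_PRINTED_TEST_DEFAULTS = {
    "genetic": dict(flagged_fraction=0.07, positive_predictive_value=0.78,
                    residual_progression_free_36m=0.69,
                    one_off_cost_key="cost_genetic_test"),
    "genomic": dict(flagged_fraction=0.17, positive_predictive_value=0.82,
                    one_off_cost_key="cost_genomic_test"),
}


def make_test_spec(kind: str, params: ParameterSet | None = None) -> TestSpec:
    """Build a TestSpec from a parameter set (or the printed defaults)."""
    if kind == "none":
        return TestSpec(name="none")
    if kind not in _PRINTED_TEST_DEFAULTS:
        raise ParameterError(f"unknown test kind {kind!r}")
    if params is None:
        return TestSpec(name=kind, **_PRINTED_TEST_DEFAULTS[kind])
    if kind == "genetic":
        return TestSpec(
            name="genetic",
            flagged_fraction=params.value("flag_rate_genetic"),
            positive_predictive_value=params.value("ppv_genetic"),
            residual_progression_free_36m=params.value("pfs36_residual_genetic"),
            one_off_cost_key="cost_genetic_test",
        )
    return TestSpec(
        name="genomic",
        flagged_fraction=params.value("flag_rate_genomic"),
        positive_predictive_value=params.value("ppv_genomic"),
        residual_fn_fraction=params.value("fn_frac_genomic"),
        one_off_cost_key="cost_genomic_test",
    )


def _pfs36(params: ParameterSet, risk: str) -> float:
    """Model-implied probability of being progression-free 36 months after
    starting first-line FCR, for risk group ``risk`` (wt/mut): six treatment
    cycles without a non-response/CLL-death event, then remission without
    progression."""
    on_treatment = (
        1.0
        - params.value(f"p_nonresp_fcr_{risk}")
        - params.value(f"p_cll_death_fcr_{risk}")
    )
    in_remission = 1.0 - params.value(f"p_prog_rem_first_{risk}")
    if on_treatment <= 0.0:
        return 0.0
    return on_treatment ** PFS36_TREATMENT_CYCLES * in_remission ** PFS36_REMISSION_CYCLES


def unflagged_nonresponder_weight(params: ParameterSet) -> float:
    """Fraction of genetic-test-unflagged patients who are true non-responders.

    Solves the mixing weight ``w`` for which the unflagged group's 36-month
    progression-free proportion equals the reported residual figure (0.69 in
    the base case), given the wt/mut PFS curves implied by the parameter set;
    clipped to [0, 1] when the curves cannot bracket the target.
    """
    target = params.value("pfs36_residual_genetic")
    pfs_wt = _pfs36(params, "wt")
    pfs_mut = _pfs36(params, "mut")
    if pfs_wt <= pfs_mut:
        raise ParameterError(
            "unflagged split is undefined: wt PFS must exceed mut PFS"
        )
    w = (pfs_wt - target) / (pfs_wt - pfs_mut)
    return min(1.0, max(0.0, w))


def nonresponder_prevalence(params: ParameterSet) -> float:
    """Population prevalence of true FCR non-responders, independent of the
    test performed: genetic flagged true positives plus the unflagged
    non-responder mass."""
    flagged = params.value("flag_rate_genetic")
    ppv = params.value("ppv_genetic")
    w = unflagged_nonresponder_weight(params)
    return flagged * ppv + (1.0 - flagged) * w


def stratify_cohort(
    test: TestSpec, params: ParameterSet | None = None
) -> dict[str, float]:
    """Entry proportions per subcohort for a stratification test.

    Four subcohorts for a real test (flagged true/false positives, unflagged
    true/false negatives); a single ``untested`` subcohort when no test is
    performed.  Proportions sum to 1.
    """
    if test.name == "none":
        return {"untested": 1.0}
    flagged = test.flagged_fraction
    ppv = test.positive_predictive_value
    ftp = flagged * ppv
    ffp = flagged * (1.0 - ppv)
    residual = 1.0 - flagged
    if test.residual_fn_fraction is not None:
        fn_frac = test.residual_fn_fraction
    else:
        if params is None:
            raise ParameterError(
                f"test {test.name!r} derives its unflagged split from the "
                "parameter set; pass params"
            )
        fn_frac = unflagged_nonresponder_weight(params)
    ufn = residual * fn_frac
    utn = residual - ufn
    out = {
        "flagged_tp": ftp,
        "flagged_fp": ffp,
        "unflagged_tn": utn,
        "unflagged_fn": ufn,
    }
    for name, v in out.items():
        if not (0.0 <= v <= 1.0):
            raise ParameterError(f"subcohort {name} proportion {v} outside [0, 1]")
    return out


# ---------------------------------------------------------------------------
# responder effect
# ---------------------------------------------------------------------------

def apply_responder_effect(
    row: Mapping[str, float],
    delta: float,
    affected: tuple[str, ...],
    stay_key: str,
) -> dict[str, float]:
    """Scale the adverse transition probabilities of a row by ``1 - delta``.

    ``affected`` names the successors whose probabilities represent
    mortality, non-response or progression; the freed mass is absorbed by
    ``stay_key`` so the row still sums to 1.  Used for patients correctly
    identified as FCR responders (first-line FCR and second-line BR only);
    ibrutinib rows are never adjusted.
    """
    if not (0.0 <= delta < 1.0):
        raise ParameterError(f"responder-effect delta must lie in [0, 1), got {delta}")
    out = dict(row)
    freed = 0.0
    for key in affected:
        if key in out:
            reduced = out[key] * (1.0 - delta)
            freed += out[key] - reduced
            out[key] = reduced
    out[stay_key] = out.get(stay_key, 0.0) + freed
    return out


# ---------------------------------------------------------------------------
# the five wirings
# ---------------------------------------------------------------------------

def _unflagged_pathway(risk: str, *, refractory: str, acquired: bool,
                       boosted: bool = False, retest: bool = False) -> tuple[LineSpec, ...]:
    """FCR first / BR second, then the given refractory treatment, then BSC."""
    ref_seg: LineSpec
    if refractory == "ofatumumab":
        ref_seg = ChemoLine("ofatumumab", "refractory", bmt=True)
    elif refractory == "ibrutinib":
        ref_seg = IbrutinibLine("refractory", retest=retest)
    else:
        raise ParameterError(f"unknown refractory treatment {refractory!r}")
    return (
        ChemoLine("fcr", "first", boosted=boosted, acquired_escape=acquired),
        ChemoLine("br", "second", boosted=boosted, acquired_escape=acquired,
                  retest=retest),
        ref_seg,
        BscLine(),
    )


def build_strategy(name: str, params: ParameterSet | None = None) -> Strategy:
    """Wire one of the five strategies (test spec resolved from ``params``
    when given, else from the printed accuracy figures)."""
    if name == "A":
        test = make_test_spec("genetic", params)
        flagged = (
            ChemoLine("ofatumumab", "first", bmt=True),
            ChemoLine("ofatumumab", "refractory"),
            BscLine(),
        )
        subcohorts = (
            SubcohortSpec("flagged_tp", "mut", flagged),
            SubcohortSpec("flagged_fp", "wt", flagged),
            SubcohortSpec("unflagged_tn", "wt",
                          _unflagged_pathway("wt", refractory="ofatumumab",
                                             acquired=True)),
            SubcohortSpec("unflagged_fn", "mut",
                          _unflagged_pathway("mut", refractory="ofatumumab",
                                             acquired=True)),
        )
        return Strategy(name, test, subcohorts)
    if name == "B":
        test = make_test_spec("genetic", params)
        flagged = (
            ChemoLine("ofatumumab", "first", bmt=True),
            IbrutinibLine("refractory"),
            BscLine(),
        )
        subcohorts = (
            SubcohortSpec("flagged_tp", "mut", flagged),
            SubcohortSpec("flagged_fp", "wt", flagged),
            SubcohortSpec("unflagged_tn", "wt",
                          _unflagged_pathway("wt", refractory="ibrutinib",
                                             acquired=True)),
            SubcohortSpec("unflagged_fn", "mut",
                          _unflagged_pathway("mut", refractory="ibrutinib",
                                             acquired=True)),
        )
        return Strategy(name, test, subcohorts)
    if name == "C":
        test = make_test_spec("none")
        subcohorts = (
            SubcohortSpec("untested_resp", "wt",
                          _unflagged_pathway("wt", refractory="ofatumumab",
                                             acquired=False)),
            SubcohortSpec("untested_nonresp", "mut",
                          _unflagged_pathway("mut", refractory="ofatumumab",
                                             acquired=False)),
        )
        return Strategy(name, test, subcohorts)
    if name == "Int1":
        test = make_test_spec("genomic", params)
        flagged = (IbrutinibLine("first"), BscLine())
        subcohorts = (
            SubcohortSpec("flagged_tp", "mut", flagged),
            SubcohortSpec("flagged_fp", "wt", flagged),
            SubcohortSpec("unflagged_tn", "wt",
                          _unflagged_pathway("wt", refractory="ibrutinib",
                                             acquired=False, boosted=True,
                                             retest=True)),
            SubcohortSpec("unflagged_fn", "mut",
                          _unflagged_pathway("mut", refractory="ibrutinib",
                                             acquired=False, retest=True)),
        )
        return Strategy(name, test, subcohorts, retest_per_line=True)
    if name == "Int2":
        test = make_test_spec("genomic", params)
        flagged = (
            ChemoLine("ofatumumab", "first", bmt=True),
            IbrutinibLine("refractory", retest=True),
            BscLine(),
        )
        subcohorts = (
            SubcohortSpec("flagged_tp", "mut", flagged),
            SubcohortSpec("flagged_fp", "wt", flagged),
            SubcohortSpec("unflagged_tn", "wt",
                          _unflagged_pathway("wt", refractory="ibrutinib",
                                             acquired=False, boosted=True,
                                             retest=True)),
            SubcohortSpec("unflagged_fn", "mut",
                          _unflagged_pathway("mut", refractory="ibrutinib",
                                             acquired=False, retest=True)),
        )
        return Strategy(name, test, subcohorts, retest_per_line=True)
    raise ParameterError(f"unknown strategy {name!r}")


def treatment_lines(strategy: Strategy) -> set[tuple[str, str]]:
    """The (treatment, line) pairs present anywhere in the strategy."""
    out: set[tuple[str, str]] = set()
    for sub in strategy.subcohorts:
        for seg in sub.segments:
            if isinstance(seg, ChemoLine):
                out.add((seg.treatment, seg.line))
            elif isinstance(seg, IbrutinibLine):
                out.add(("ibrutinib", seg.line))
    return out


def referenced_parameters(name: str) -> set[str]:
    """Every parameter name a strategy's state space and stratification
    resolve (used for config completeness validation)."""
    from .engine import build_state_space  # lazy: engine imports this module

    strategy = build_strategy(name)
    space = build_state_space(strategy, params=None)
    needed: set[str] = set(space.referenced_parameters())
    needed |= {"gompertz_a", "gompertz_b"}
    # stratification inputs
    if strategy.test.name == "genetic" or name == "C":
        needed |= {
            "flag_rate_genetic", "ppv_genetic", "pfs36_residual_genetic",
            "p_nonresp_fcr_wt", "p_nonresp_fcr_mut",
            "p_cll_death_fcr_wt", "p_cll_death_fcr_mut",
            "p_prog_rem_first_wt", "p_prog_rem_first_mut",
        }
    if strategy.test.name == "genetic":
        needed.add("cost_genetic_test")
    if strategy.test.name == "genomic":
        needed |= {"flag_rate_genomic", "ppv_genomic", "fn_frac_genomic",
                   "cost_genomic_test"}
    return needed
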