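# Methods

## Model structure and assumptions

The engine is a discrete-time Markov cohort model with a 28-day cycle (the
usual length of one chemotherapy cycle) and a 30-year horizon — effectively
lifetime for the 65-year-old base cohort. The number of propagation steps is
`floor(horizon_years · 365.25 / 28)` = 391; there is no partial final
cycle, and one cycle equals 28/365.25 years everywhere (discounting,
life-year accrual, age advancement).

Each strategy subcohort gets its own chain of states:

* **Chemotherapy tunnels.** FCR, BR and ofatumumab lines are limited to six
  cycles, enforced with six tunnel states. From any tunnel state the
  patient can move to the next line (non-response), to CLL death, or (in
  strategies A and B) to the refractory line via emergent high-risk
  disease; the residual mass advances to the next tunnel state, and the
  sixth tunnel's residual enters remission. First-cycle (and for
  ofatumumab, second-cycle) tunnel states carry distinct drug-cost loadings.
* **Ibrutinib states.** No tunnel bound: treatment continues until
  non-response, so a single state with self-residual suffices.
  Treatment benefit is constant over the model course; a waning-benefit
  variant was considered and rejected as unidentifiable from available
  inputs — the same effect is explorable by raising the ibrutinib
  non-response probability in a scenario.
* **Transplant (BMT).** A competing per-cycle event from the final
  ofatumumab tunnel state routes a proportion of completers through a
  one-cycle BMT tunnel into a durable BMT remission. The £43,724 procedure
  cost is charged as a one-off on inflow into the tunnel.
* **Remission / BSC / death.** Remission states progress to the next line;
  CLL death is possible from all non-remission alive states; other-cause
  death from every alive state. Both death states are absorbing.

Other-cause mortality is the only age-varying input: an annual Gompertz
hazard `h(age) = a·exp(b·age)` with defaults `a = 2.3e-5`, `b = 0.095`
(remaining life expectancy at 65 of roughly 20 years), converted per cycle
as `p = 1 − exp(−h·28/365.25)`. All treatment-efficacy probabilities are
time-homogeneous within a state.

Discounting uses `(1+r)^(−t)` at `r = 3.5%/year`, `t = cycle·28/365.25`.
The half-cycle correction is trapezoid averaging of successive cycle-start
occupancies, applied exactly once, to both costs and outcomes by default
(configurable to either or neither); one-off costs (test charges, BMT,
mortality production losses) are event-based inflow charges and are not
half-cycle corrected.

## Strategies and stratification

Five wired strategies: A (genetic testing; unflagged patients FCR → BR →
refractory ofatumumab ± BMT; flagged patients first-line ofatumumab ± BMT
then a second ofatumumab course), B (A with ibrutinib as all refractory
treatment), C (no testing; A's unflagged pathway with no direct
first-line→refractory route), Int1 (genomic testing; flagged patients
first-line ibrutinib then BSC; unflagged FCR/BR with refractory
ibrutinib), Int2 (as Int1 but flagged patients receive first-line
ofatumumab ± BMT then refractory ibrutinib). Genomic strategies re-test
before each new line, so the genomic test cost recurs at line entries.
First-line chemotherapy is wired as FCR (clinically FCR or BR are
interchangeable here; the BR first-line cost rows are shipped for
completeness but unused by the default pathways).

Stratification splits the cohort into flagged true/false positives and
unflagged true/false negatives. Flagged mass and PPV are the published
test-accuracy figures (7%/78% genetic, 17%/82% genomic). The genetic
unflagged split solves the mixing weight `w` for which the unflagged
group's 36-month progression-free proportion equals the published 69%,
using the model's own curves: PFS36 = (1 − p_nonresp − p_cll_death)^6 ·
(1 − p_prog_remission)^33 per risk group (39 cycles ≈ 36 months, six of
them on treatment). With the default parameters `w = 0.110`. The genomic
residual false-negative fraction is a generated parameter whose default
(0.0216) makes the population prevalence of true non-responders
test-independent (π = 0.0546 + 0.93·w = 0.157). Comparator C performs no
test; its single untested subcohort is nevertheless a biological mixture,
so its entry mass is split into responder/non-responder risk groups at π.

False positives under genetic testing follow the flagged (ofatumumab)
pathway; under genomic testing they receive ibrutinib — in both cases the
pathway their label dictates. Unflagged false negatives are treated as
responders but transition with the TP53-mutated probabilities. The 20%
responder effect multiplies mortality, non-response and remission
progression by 0.8 for correctly identified responders in the genomic
strategies only, during first-line FCR and second-line BR; ibrutinib rows
are never adjusted. Emergent ("acquired") high-risk disease is a named
per-cycle probability from FCR/BR tunnel states to the refractory line in
A and B only: C cannot detect it, and the genomic strategies reach
refractory ibrutinib through ordinary non-response anyway.

## Parameters

Every scalar is a `Parameter` (base value, ±50% range truncated to the
domain, PSA distribution family). Config files are YAML, schema version 1,
validated on load with unknown keys rejected; a full config must resolve
every name referenced by the five strategies. Costs are GBP at 2013
prices; no inflation adjustment is performed.

Key defaults (per 28-day cycle unless stated):

| group | parameter | default | rationale |
|---|---|---|---|
| FCR, wild type | non-response / CLL death / remission progression | 0.020 / 0.002 / 0.0040 | long first remissions; the 69% PFS36 anchor caps progression at ≤0.0046 |
| FCR, TP53-mutated | same | 0.110 / 0.028 / 0.051 | median OS on FCR ≈ 2 years, early failure |
| BR (second line) | wt 0.030 / 0.003 / 0.018; mut 0.130 / 0.032 / 0.065 | slightly worse than first line |
| ofatumumab, first-line (flagged pathway) | 0.050 / 0.005 / 0.012 | targeted therapy effective in TP53-mutated disease |
| ofatumumab, refractory | 0.100 / 0.030 / 0.080 | short-lived salvage responses |
| ibrutinib, first-line | 0.006 / 0.003 | very durable responses (mean ≈ 8.5 years on drug) |
| ibrutinib, refractory | 0.015 / 0.008 | relapsed-setting durability ≈ 3.5 years |
| transplant | uptake 0.40 among completers; tunnel mortality 0.080; post-BMT progression 0.004 | potentially curative consolidation |
| BSC | CLL death 0.080 | terminal care ≈ 1 year |
| tests | genetic £339, genomic £520 (one-off) | microcosting-scale values |
| ibrutinib cost | drug £2,300/cycle (≈£30,000/year) + administration £404 (£480 in strategy B) | printed state costs 2,704/2,780 are the sums; scenarios and the threshold search vary the drug component |

The published per-state cycle costs and utility weights (0.803 first line,
0.710 second, 0.650 refractory and BMT, 0.910 remission, 0.680 BSC, −0.133
grade-3/4 disutility) are embedded verbatim and never noised. Utility
handling has two explicit modes: `adjusted` (default — the shipped weights
are taken as already complication-adjusted) and `complication-adjusted`
(each treatment state's utility becomes `u − complication_rate·0.133`,
with per-treatment complication-rate parameters). The Int2 ofatumumab
first-line second-cycle cost is not in the published table; the A/B value
(£15,334) is reused, since the £38 first-cycle difference reflects a
non-recurring test-cost amortisation.

## Synthetic-data generation

`generate_parameter_set(SynthesisSpec(seed, starting_age_years,
efficacy_ordering_strength, noise_cv))` emulates the supplementary
parameter tables: independent quantities get mean-preserving lognormal
noise (CV 0.10 by default) around the documented defaults; derived
quantities (mutated vs wild-type chemotherapy, ibrutinib vs refractory
ofatumumab) are built from their anchor with a strength-scaled ratio and
clipped so the orderings stay strict under noise. Identical seeds give
bit-identical sets; `noise_cv = 0` reproduces the documented defaults
exactly (this is the shipped `data/base_case.yaml`).

What the generator does **not** emulate: the exact supplementary transition
values or their hazard-combination derivations. Consequently, model
results on generated sets reproduce the decision problem's *structure* and
the qualitative orderings (ibrutinib strategies gain the most life-years;
no-testing C gains the fewest among the chemotherapy strategies; genetic
stratification adds life-years over no testing), but not the published
decision surface. One divergence is worth stating plainly: on the default
synthetic set the genomic strategy Int2 is already cost-effective at
£30,000/QALY at the assumed ibrutinib price, whereas the published base
case found genetic testing (A) optimal. The driver is the 69%-PFS-at-36-
months anchor, which pins wild-type first-remission progression low, so
the 20% responder effect converts cheap remission time into QALYs very
efficiently. Passing tests on synthetic sets therefore demonstrates
engine and algorithm correctness and qualitative behaviour — not that the
synthetic parameters match the unavailable source values. The published
dominance labels and ICER ladders are instead reproduced exactly from the
shipped published per-patient means (`reference_results.py`), which is
the quantitative acceptance surface.

## Uncertainty analyses

* **Univariate.** Every parameter evaluated at its low/high bound
  (±50% truncated to the domain), recording the optimal strategy at
  £30,000 and whether the decision changed.
* **Scenarios.** S1 ibrutinib drug cost ×0.25 (£575/cycle), S2 ×56/30
  (list price), S3 responder effect 0.40, S4 starting ages 25/85 (same
  Gompertz curve), S5/S6 10/20-year horizons, S7 genomic test equalised
  with the genetic test (accuracy, unflagged split and cost), plus custom
  overrides.
* **Threshold search.** Bisection to £1 on a single parameter for the
  value at which a target strategy becomes threshold-optimal; the bracket
  ends are checked first and degenerate brackets are flagged rather than
  searched.
* **PSA.** Each draw samples every non-fixed parameter independently —
  beta for probabilities/proportions/utilities, gamma for costs/rates,
  method-of-moments with sd = CV·mean and default CV 0.10 — then evaluates
  all strategies deterministically. No correlation structure is imposed.
  Draws whose sampled probabilities make a transition row exceed unit mass
  are resampled (bounded retries, counted). CEACs use a £0–£100,000 grid
  in £2,500 steps; ties in the net-monetary-benefit argmax are split
  evenly so the curves sum to one. 1000 draws is the reference PSA size
  (≈80 s single-core); examples use 200.

## Societal perspective

Three nonnegative increments on top of NHS costs, resolved into dedicated
parameters so a zero spec reproduces the NHS perspective bit-for-bit:
informal care (hours/cycle per state class × £15/h), out-of-pocket costs
per cycle, and friction-cost productivity losses — one friction period
(90 days, converted to paid days at 248 workdays/year) per treatment-line
entry at the age-band employment rate (0.75 to 55, 0.60 to 65, 0.05
after). Premature-mortality production losses are charged on death inflow,
age-resolved per cycle, by either the friction method (default at 65,
where they are small) or the human-capital method (lost paid days to
retirement at 65 — the default for the age-25 scenario, where they
dominate total costs). Health outcomes are identical across perspectives.
Nursing-home admission costs are deliberately excluded.

## Numerical choices

* Cohort conservation is enforced at 10⁻¹⁰ across all 391 cycles; death
  occupancy is checked nondecreasing.
* A transition row whose competing probabilities (plus other-cause
  mortality) exceed 1 raises an error naming strategy, subcohort, state
  and cycle.
* Frontier tie-breaks: equal cost and effect keep the earlier-listed
  strategy; extended dominance is removed iteratively (re-laddering after
  each removal) until ICERs strictly increase; `optimal_at(λ)` returns the
  cheapest strategy when no frontier ICER clears λ.
* ICER with zero effect difference is an explicit error surfaced to the
  dominance logic, not a silent infinity.
* The propagation engine is vectorised (one event matrix per subcohort,
  age-varying other-cause mortality applied per cycle); a test verifies it
  against explicit row-by-row propagation, a brute-force path-enumeration
  oracle, and a closed-form two-state model.

## Limitations

* One risk group per subcohort: patients who acquire high-risk disease
  mid-pathway are rerouted to refractory care but keep their original
  transition bindings; the emergence probability default is accordingly
  small (0.001/cycle).
* Cohort proportions only — no patient-level simulation; `cohort_size`
  (10,000) scales displayed totals.
* Exponential within-state waiting times cannot reproduce plateaued
  real-world PFS curves, which is why the 36-month anchor forces long
  wild-type remissions (see the synthetic-data divergence above).
* The societal extension uses band-wise employment rates and a single
  national wage; no discount-rate differential between perspectives.
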