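# cllcea

Markov cohort cost-effectiveness analysis of genetic/genomic test-guided
treatment for chronic lymphocytic leukaemia (CLL).

## The problem

Fit ("go-go") CLL patients are usually offered FCR chemotherapy first-line,
but roughly a quarter carry lesions (notably *TP53* mutations) that predict
non-response. Two stratification technologies compete: conventional genetic
testing (FISH + Sanger sequencing, which flags ~7% of patients with a 78%
positive predictive value) and targeted next-generation sequencing (which
flags ~17% at 82% PPV). Flagging more true non-responders lets clinicians
route them to the BTK inhibitor ibrutinib — clinically effective but, at an
assumed £30,000/year, expensive enough to dominate the economics of testing.

This package implements the full decision-analytic comparison for the UK
NHS setting (GBP, 2013 prices): five test-treatment strategies evaluated on
discounted costs, life-years (LY) and quality-adjusted life-years (QALY),
with incremental analysis, sensitivity/scenario/threshold analyses,
probabilistic sensitivity analysis (PSA) and a societal costing extension.
It is aimed at health economists and methods researchers who want a tested,
scriptable implementation of this model family rather than a spreadsheet.

## The model

* **Markov cohort engine** — 28-day cycles over a 30-year horizon
  (391 cycles); six-cycle tunnel states per chemotherapy line (FCR, BR,
  ofatumumab), unbounded ibrutinib states, a one-cycle bone-marrow
  transplant tunnel, remission and best-supportive-care states, and two
  absorbing death states. Other-cause mortality follows a Gompertz hazard
  and is the only age-varying input. Costs and outcomes are discounted at
  3.5%/year with a trapezoid half-cycle correction.
* **Strategies** — A (genetic testing, chemotherapy pathways),
  B (A with refractory ibrutinib for all), C (no testing), Int1 (genomic
  testing, first-line ibrutinib for likely FCR non-responders), Int2
  (genomic testing, first-line ofatumumab then refractory ibrutinib).
  Correctly identified FCR responders in the genomic strategies receive a
  20% reduction in mortality, non-response and progression probabilities.
* **Incremental analysis** — strategies sorted by cost; strictly dominated
  ones excluded; ICERs `ΔC/ΔE` laddered; extended dominance removed
  iteratively until frontier ICERs strictly increase; the optimum at a
  willingness-to-pay λ maximises net monetary benefit `λ·E − C`.
* **Uncertainty** — univariate ±50% sensitivity analysis, seven built-in
  scenarios, bisection threshold search, and a seeded PSA (beta for
  probabilities/utilities, gamma for costs/rates, method-of-moments with a
  default CV of 0.10) summarised as cost-effectiveness acceptability curves.
* **Synthetic parameters** — the published per-state costs and utility
  weights are embedded verbatim; transition probabilities (which come from
  supplementary sources not reproducible here) are generated under ordering
  constraints (TP53-mutated pathways do worse on chemotherapy, ibrutinib
  outperforms refractory ofatumumab) with seeded, reproducible noise.

## Worked example

Feeding the published base-case per-patient means into the incremental
analysis (`python examples/02_published_tables.py`):

```
== nhs_age65 / CUA ==
strategy  mean_qaly  mean_cost icer_excl_dominated icer_excl_ext_dominated
       C       5.60    69704.0
       A       5.82    71576.0         8509.090909             8509.090909
    Int2       5.93    91790.0       183763.636364                 EXT.DOM
       B       6.44   107703.0        31201.960784                 EXT.DOM
    Int1       6.67   119088.0             49500.0            55896.470588
optimal at £30,000: A
```

Reading: C is the cheapest strategy; A buys 0.22 extra QALYs at
£8,509/QALY; Int2 and B are extendedly dominated (their ICERs exceed that
of the more effective Int1); Int1 tops the frontier at £55,896/QALY — above
the standard £30,000 threshold but close to the £50,000 end-of-life bar, so
genetic testing (A) is the optimal strategy at £30,000/QALY.

Other entry points: `examples/01_base_case.py` (full model on the default
synthetic parameter set), `03_psa_ceac.py`, `04_scenarios_and_thresholds.py`,
`05_societal_perspective.py`, and a thin CLI:

```sh
cllcea simulate-params --seed 1 --out params.yaml
cllcea run --config params.yaml --out-dir out/
cllcea frontier-from-table --table means.csv --effect-scale QALY
```

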