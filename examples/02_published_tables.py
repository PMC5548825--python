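"""Incremental analysis of the published per-patient means.

The shipped reference tables hold the published discounted means per
strategy (NHS perspective at 65, societal at 65, societal at 25).  Running
the frontier operation on them reproduces the published dominance labels
and ICER ladders - the strongest check available without the supplementary
transition data.
"""

from cllcea import EconResult, frontier
from cllcea.reference_results import PRINTED_MEANS

for table in ("nhs_age65", "societal_age25"):
    for analysis in ("CEA", "CUA"):
        scale = "LY" if analysis == "CEA" else "QALY"
        results = [
            EconResult(strategy=s, mean_cost=c, mean_ly=e, mean_qaly=e)
            for s, (e, c) in PRINTED_MEANS[table][analysis].items()
        ]
        fr = frontier(results, scale)
        print(f"\n== {table} / {analysis} ==")
        print(fr.to_frame().to_string(index=False))
        print("optimal at £30,000:", fr.optimal_at(30_000))
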