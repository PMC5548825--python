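"""Reported base-case per-patient means of the published UK evaluation.

These are the printed deterministic results (discounted mean life-years or
QALYs and mean costs per patient) for the five strategies under the NHS
perspective, the societal perspective at age 65, and the societal
perspective at age 25.  They are shipped so the incremental-analysis
machinery can be run directly against the published decision surface
(``cllcea frontier-from-table`` does the same from a user CSV).

``PRINTED_ICERS`` records the published incremental ladders: for each
strategy a pair ``(icer_excluding_dominated, icer_excluding_ext_dominated)``
where an entry is a float, the label ``"DOM"``/``"EXT.DOM"``, or ``None``
for the cheapest (baseline) strategy.
"""

from __future__ import annotations

__all__ = ["PRINTED_MEANS", "PRINTED_ICERS", "printed_means_records"]

# table -> analysis -> strategy -> (effect per patient, cost per patient GBP)
PRINTED_MEANS: dict[str, dict[str, dict[str, tuple[float, float]]]] = {
    "nhs_age65": {
        "CEA": {
            "C": (6.37, 69_704.0),
            "A": (6.61, 71_576.0),
            "Int2": (6.65, 91_790.0),
            "B": (7.63, 107_703.0),
            "Int1": (7.45, 119_088.0),
        },
        "CUA": {
            "C": (5.60, 69_704.0),
            "A": (5.82, 71_576.0),
            "Int2": (5.93, 91_790.0),
            "B": (6.44, 107_703.0),
            "Int1": (6.67, 119_088.0),
        },
    },
    "societal_age65": {
        "CEA": {
            "C": (6.37, 73_832.0),
            "A": (6.61, 76_035.0),
            "Int2": (6.65, 95_031.0),
            "B": (7.63, 110_820.0),
            "Int1": (7.45, 122_116.0),
        },
        "CUA": {
            "C": (5.60, 73_832.0),
            "A": (5.82, 76_035.0),
            "Int2": (5.93, 95_031.0),
            "B": (6.44, 110_820.0),
            "Int1": (6.67, 122_116.0),
        },
    },
    "societal_age25": {
        "CEA": {
            "Int2": (7.73, 687_062.0),
            "B": (8.88, 690_438.0),
            "A": (7.35, 697_523.0),
            "Int1": (8.73, 698_459.0),
            "C": (7.00, 707_752.0),
        },
        "CUA": {
            "Int2": (6.91, 687_062.0),
            "B": (7.42, 690_438.0),
            "A": (6.47, 697_523.0),
            "Int1": (7.82, 698_459.0),
            "C": (6.15, 707_752.0),
        },
    },
}

_Entry = "float | str | None"

# table -> analysis -> strategy -> (ICER excl. DOM, ICER excl. EXT.DOM)
PRINTED_ICERS: dict[str, dict[str, dict[str, tuple]]] = {
    "nhs_age65": {
        "CEA": {
            "C": (None, None),
            "A": (7903.0, 7903.0),
            "Int2": (580_390.0, "EXT.DOM"),
            "B": (16_133.0, 35_376.0),
            "Int1": ("DOM", "DOM"),
        },
        "CUA": {
            "C": (None, None),
            "A": (8565.0, 8565.0),
            "Int2": (177_198.0, "EXT.DOM"),
            "B": (31_153.0, "EXT.DOM"),
            "Int1": (50_559.0, 55_891.0),
        },
    },
    "societal_age65": {
        "CEA": {
            "C": (None, None),
            "A": (9302.0, 9302.0),
            "Int2": (545_428.0, "EXT.DOM"),
            "B": (16_007.0, 34_062.0),
            "Int1": ("DOM", "DOM"),
        },
        "CUA": {
            "C": (None, None),
            "A": (10_081.0, 10_081.0),
            "Int2": (166_523.0, "EXT.DOM"),
            "B": (30_908.0, "EXT.DOM"),
            "Int1": (50_164.0, 54_207.0),
        },
    },
    "societal_age25": {
        "CEA": {
            "Int2": (None, None),
            "B": (2943.0, 2943.0),
            "A": ("DOM", "DOM"),
            "Int1": ("DOM", "DOM"),
            "C": ("DOM", "DOM"),
        },
        "CUA": {
            "Int2": (None, None),
            "B": (6701.0, 6701.0),
            "A": ("DOM", "DOM"),
            "Int1": (19_933.0, 19_933.0),
            "C": ("DOM", "DOM"),
        },
    },
}


def printed_means_records(table: str, analysis: str):
    """The printed means as ``[(strategy, effect, cost), ...]`` rows."""
    block = PRINTED_MEANS[table][analysis]
    return [(s, e, c) for s, (e, c) in block.items()]
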