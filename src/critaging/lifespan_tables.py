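"""Published C. elegans lifespan summaries used for arithmetic self-checks.

Mean (and, for drug assays, maximum) adult lifespans in days post-L4/adult
molt, with the relative extensions as printed in the source tables: mutant
strains and RNAi interventions in a Bristol-N2 DRM background, and
pharmacological interventions at 1 and 10 uM.  Printed percentages follow
two rounding conventions: one decimal below 100%, nearest ten above.

Re-deriving the percentages from the printed lifespans reproduces the
printed values only for some rows; the remainder differ in the last digit
because the original percentages were evidently computed from unrounded
lifespans.  ``run_table_checks`` in :mod:`critaging.pipeline` recomputes and
flags each row.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["LifespanRow", "LIFESPAN_ROWS"]


@dataclass(frozen=True)
class LifespanRow:
    label: str
    control: float          # control mean (or max) lifespan, days
    treated: float          # treated mean (or max) lifespan, days
    printed_pct: float      # extension as printed
    rounding: str           # rounding convention of the printed value
    kind: str = "mean"      # 'mean' or 'max' lifespan


LIFESPAN_ROWS: list[LifespanRow] = [
    # long-lived mutant strains (vs wild-type control of the same series)
    LifespanRow("daf-2(e1370)", 17.0, 39.0, 130.0, "nearest-ten"),
    LifespanRow("age-1(mg44) F2", 17.0, 160.0, 840.0, "nearest-ten"),
    LifespanRow("age-1(mg44) F1", 17.0, 38.0, 120.0, "nearest-ten"),
    LifespanRow("daf-2(e1391);daf-12(m20)", 25.5, 60.5, 140.0, "nearest-ten"),
    # RNAi interventions (vs empty-feeding-vector control, 20.1 d)
    LifespanRow("daf-4 RNAi", 20.1, 23.2, 15.5, "one-decimal"),
    LifespanRow("che-3 RNAi", 20.1, 23.3, 16.2, "one-decimal"),
    LifespanRow("cyc-1 RNAi", 20.1, 22.3, 11.1, "one-decimal"),
    LifespanRow("cco-1 RNAi", 20.1, 21.1, 4.9, "one-decimal"),
    LifespanRow("eat-4 RNAi", 20.1, 22.0, 9.4, "one-decimal"),
    # pharmacological interventions, 1 uM, first assay
    LifespanRow("alsterpaullone 1uM", 23.7, 26.9, 13.5, "one-decimal"),
    LifespanRow("anisomycin 1uM", 23.7, 29.3, 23.7, "one-decimal"),
    LifespanRow("azacytidine 1uM", 23.7, 29.8, 25.8, "one-decimal"),
    LifespanRow("metamizole 1uM", 23.7, 28.1, 18.3, "one-decimal"),
    LifespanRow("alsterpaullone 1uM (max)", 31.0, 37.0, 19.4, "one-decimal", "max"),
    LifespanRow("anisomycin 1uM (max)", 31.0, 37.0, 19.4, "one-decimal", "max"),
    # 1 uM, second assay
    LifespanRow("anisomycin 1uM rep1", 23.3, 28.4, 21.8, "one-decimal"),
    LifespanRow("anisomycin 1uM rep2", 23.3, 28.1, 20.4, "one-decimal"),
    LifespanRow("anisomycin 1uM rep (max)", 28.0, 35.0, 25.0, "one-decimal", "max"),
    # 10 uM, first assay
    LifespanRow("alsterpaullone 10uM", 23.9, 25.3, 6.0, "one-decimal"),
    LifespanRow("anisomycin 10uM", 23.9, 22.4, -6.0, "one-decimal"),
    LifespanRow("azacytidine 10uM", 23.9, 26.5, 11.0, "one-decimal"),
    LifespanRow("metamizole 10uM", 23.9, 25.5, 6.8, "one-decimal"),
    LifespanRow("alsterpaullone 10uM (max)", 32.0, 33.0, 3.1, "one-decimal", "max"),
    LifespanRow("anisomycin 10uM (max)", 32.0, 31.0, -3.1, "one-decimal", "max"),
    # 10 uM, second assay
    LifespanRow("alsterpaullone 10uM rep", 22.9, 27.3, 19.1, "one-decimal"),
    LifespanRow("anisomycin 10uM rep", 22.9, 22.1, -3.4, "one-decimal"),
    LifespanRow("azacytidine 10uM rep", 22.9, 25.2, 9.9, "one-decimal"),
    LifespanRow("metamizole 10uM rep", 22.9, 29.7, 29.8, "one-decimal"),
    LifespanRow("alsterpaullone 10uM rep (max)", 30.0, 36.0, 20.0, "one-decimal", "max"),
    LifespanRow("anisomycin 10uM rep (max)", 30.0, 29.0, -3.3, "one-decimal", "max"),
    LifespanRow("azacytidine 10uM rep (max)", 30.0, 36.0, 20.0, "one-decimal", "max"),
    LifespanRow("metamizole 10uM rep (max)", 30.0, 43.0, 43.3, "one-decimal", "max"),
]
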