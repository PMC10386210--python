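"""Demographic comparisons: event vs non-event cases on sex and the two
age cut points (>=70, >=40), Fisher exact per factor.

The generator injects no demographic effect, so this is a negative
control: any factor crossing alpha = 0.05 does so at the false-positive
rate (with three tests per run, roughly one run in seven shows one).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, TABLE_CSV, ensure_dirs

from srs_signal.demographics import compare_demographics, comparisons_to_frame
from srs_signal.io import AnalysisTable
from srs_signal.terms import default_glaucoma_terms


def main() -> None:
    ensure_dirs()
    table = AnalysisTable.read_csv(TABLE_CSV)
    comparisons = compare_demographics(table, default_glaucoma_terms())
    frame = comparisons_to_frame(comparisons)
    frame.to_csv(RESULTS / "04_demographics.csv", index=False)
    for c in comparisons:
        print(
            f"{c.factor}: p = {c.p_value:.3f} "
            f"(event {c.table.a}/{c.table.a + c.table.b} {c.levels[0]}; "
            f"non-event {c.table.c}/{c.table.c + c.table.d}; excluded {c.n_excluded})"
        )


if __name__ == "__main__":
    main()
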