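"""Disproportionality screen: Haldane ROR + Fisher exact per drug, volcano.

Screens the world's six drugs against the shipped glaucoma term set and
checks the flags against the injected truth: the three strongly-associated
corticosteroids and prednisolone (multiplier 2) should light up; aspirin
and dexamethasone (no association) should not.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, TABLE_CSV, WORLD, ensure_dirs

from srs_signal.dispro import results_to_frame, screen_panel, volcano_data
from srs_signal.io import AnalysisTable, normalize_name
from srs_signal.plots import render_volcano
from srs_signal.terms import DrugPanel, default_glaucoma_terms


def main() -> None:
    ensure_dirs()
    table = AnalysisTable.read_csv(TABLE_CSV)
    panel = DrugPanel(drugs=tuple(normalize_name(d) for d in WORLD.drugs))
    terms = default_glaucoma_terms()
    results = screen_panel(table, panel, terms, alpha=0.05)

    frame = results_to_frame(results)
    frame.to_csv(RESULTS / "03_screen_results.csv", index=False)
    volcano_data(results).to_csv(RESULTS / "03_volcano.csv", index=False)
    render_volcano(results, RESULTS / "03_volcano.png")

    cols = ["drug", "a", "n_reports", "ror", "ci_low", "ci_high", "p_value", "is_signal"]
    print(frame[cols].round(3).to_string(index=False))
    n_sig = int(frame["is_signal"].sum())
    print(f"\n{n_sig}/{len(frame)} drugs flagged as signals (ROR >= 1, p < 0.05)")


if __name__ == "__main__":
    main()
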