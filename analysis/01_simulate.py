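"""Generate the synthetic JADER-dialect database for the analysis series.

Writes DEMO/DRUG/REAC CSVs plus the ground-truth sidecar under scratch/
(they are bulky) and a small truth summary under results/.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import DB_DIR, RESULTS, WORLD, ensure_dirs

from srs_signal.synthetic import generate_database, write_jader_dialect


def main() -> None:
    ensure_dirs()
    demo, drug, reac, truth = generate_database(WORLD)
    paths = write_jader_dialect((demo, drug, reac), DB_DIR, truth)
    print(f"wrote {len(paths)} files under {DB_DIR}")
    print(f"rows: DEMO={len(demo)}, DRUG={len(drug)}, REAC={len(reac)} (mess included)")

    summary = pd.DataFrame(truth.as_dict()["pairs"])
    summary = summary[summary["multiplier"] != 1.0]
    summary.to_csv(RESULTS / "01_truth_summary.csv", index=False)
    print("injected associations (multiplier != 1):")
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
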