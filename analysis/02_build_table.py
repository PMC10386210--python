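"""Run the ETL: read the three raw tables, stack ";"-merged fields, drop
duplicates, join on case id, and write the case-level analysis table.

The record-flow log (how many rows at each construction step) goes to
results/; the analysis table itself is bulky and stays in scratch/.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import DB_DIR, RESULTS, TABLE_CSV, ensure_dirs

from srs_signal.io import build_analysis_table, read_demo, read_drug, read_reac


def main() -> None:
    ensure_dirs()
    table, flow = build_analysis_table(
        read_demo(DB_DIR / "DEMO.csv"),
        read_drug(DB_DIR / "DRUG.csv"),
        read_reac(DB_DIR / "REAC.csv"),
    )
    table.to_csv(TABLE_CSV)
    with open(RESULTS / "02_flow_log.json", "w", encoding="utf-8") as fh:
        json.dump(flow.as_dict(), fh, indent=2)
    for label, count in flow.steps:
        print(f"{label}: {count}")
    print(f"analysis table: {len(table)} unique cases -> {TABLE_CSV}")


if __name__ == "__main__":
    main()
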