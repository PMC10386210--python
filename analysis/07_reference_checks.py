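"""Reference checks against the published JADER corticosteroid-glaucoma
screen: demographic Fisher p-values, the 28-signal criterion count, the
five-PT report filter, and the shipped term-set/panel sizes.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, ensure_dirs

from srs_signal.pipeline import selfcheck


def main() -> int:
    ensure_dirs()
    checks = pd.DataFrame(selfcheck())
    checks.to_csv(RESULTS / "07_reference_checks.csv", index=False)
    print(checks.to_string(index=False))
    n_failed = int((~checks["passed"]).sum())
    print(f"\n{len(checks) - n_failed}/{len(checks)} checks passed")
    return 1 if n_failed else 0


if __name__ == "__main__":
    sys.exit(main())
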