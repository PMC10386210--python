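"""Shipped reference datasets from the published JADER 2004-04..2022-06
corticosteroid-glaucoma screen.

These are printed summary tables (not raw reports — the raw database must
be downloaded from PMDA and is not redistributable here).  They serve as
fixtures for self-checks: the published per-PT report counts, the
published 47-drug screen results, the report counts of the drugs that
entered the clustering stage, and the published demographic 2x2 tables.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from srs_signal.dispro import ContingencyTable

#: published demographic comparisons between glaucoma and non-glaucoma
#: reports: cases cross-classified as [[event & level1, event & level2],
#: [non-event & level1, non-event & level2]], with the published two-sided
#: Fisher exact p-value.
DEMOGRAPHIC_TABLES: dict[str, dict] = {
    "sex": {
        "levels": ("male", "female"),
        "table": ContingencyTable(653, 694, 599030, 609980),
        "published_p": 0.445,
    },
    "age70": {
        "levels": (">=70", "<70"),
        "table": ContingencyTable(436, 709, 468717, 702259),
        "published_p": 0.184,
    },
    "age40": {
        "levels": (">=40", "<40"),
        "table": ContingencyTable(949, 196, 960658, 210318),
        "published_p": 0.488,
    },
}

#: number of drugs the published screen flagged as signals (ROR >= 1, p < 0.05)
PUBLISHED_SIGNAL_COUNT = 28

#: number of PTs passing the >=50-report filter in the published screen
PUBLISHED_FILTERED_PT_COUNT = 5


def _read_data_csv(filename: str) -> pd.DataFrame:
    with resources.as_file(resources.files("srs_signal") / "data" / filename) as p:
        return pd.read_csv(p)


def published_screen() -> pd.DataFrame:
    """The published 47-drug screen: drug, ROR, 95% CI, printed p string."""
    return _read_data_csv("corticosteroid_glaucoma_screen.csv").astype({"p_value": str})


def published_pt_report_counts() -> pd.Series:
    """Published report count per glaucoma preferred term (index: PT name)."""
    frame = _read_data_csv("glaucoma_pt_report_counts.csv")
    return frame.set_index("pt_name")["n_reports"]


def published_clustering_report_counts() -> pd.Series:
    """Report counts of the corticosteroids that entered the clustering stage."""
    frame = _read_data_csv("clustering_report_counts.csv")
    return frame.set_index("drug")["n_reports"]
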