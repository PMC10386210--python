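"""Demographic comparisons between event and non-event reports.

Cases are split by event status (the term set) and compared on three
factors with two-sided Fisher exact tests:

* sex (male vs female; cases with missing sex excluded);
* age >= 70 — decades 70s/80s/90s plus the unspecified "elderly" token
  count as >= 70, decades 0s..60s as < 70;
* age >= 40 — decades 40s..90s plus "elderly" count as >= 40, 0s..30s
  as < 40.

For the age factors, cases whose age token is "adult", "unknown" or
missing carry no decade information and are excluded from that factor
(but only that factor).  The under-10 decade sits below both cut points.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from srs_signal.dispro import ContingencyTable, fisher_exact_two_sided
from srs_signal.io import AnalysisTable, ReportCase
from srs_signal.terms import EventTermSet, case_has_event

AGE_70_PLUS = frozenset({"70s", "80s", "90s", "elderly"})
AGE_40_PLUS = frozenset({"40s", "50s", "60s"}) | AGE_70_PLUS
AGE_INFORMATIVE = frozenset({"0s", "10s", "20s", "30s"}) | AGE_40_PLUS


@dataclass(frozen=True)
class GroupComparison:
    """One factor's 2x2 comparison: counts, Fisher p, and exclusion bookkeeping.

    The table rows are (event, non-event); the columns are the factor's two
    levels, e.g. (male, female) or (>=70, <70).
    """

    factor: str
    levels: tuple[str, str]
    table: ContingencyTable
    p_value: float
    n_used: int
    n_excluded: int


def _level_of(factor: str, case: ReportCase) -> str | None:
    """The case's level for a factor, or None if it must be excluded."""
    if factor == "sex":
        return case.sex if case.sex in ("male", "female") else None
    if case.age_token not in AGE_INFORMATIVE:
        return None
    if factor == "age70":
        return ">=70" if case.age_token in AGE_70_PLUS else "<70"
    if factor == "age40":
        return ">=40" if case.age_token in AGE_40_PLUS else "<40"
    raise ValueError(f"unknown factor {factor!r}")


_FACTOR_LEVELS = {
    "sex": ("male", "female"),
    "age70": (">=70", "<70"),
    "age40": (">=40", "<40"),
}


def compare_demographics(
    cases: Sequence[ReportCase] | AnalysisTable,
    terms: EventTermSet,
    factors: Sequence[str] = ("sex", "age70", "age40"),
) -> list[GroupComparison]:
    """Compare event vs non-event cases on each factor with Fisher exact tests.

    Exclusions are per factor: a case missing its sex still contributes to
    both age factors, and vice versa.  A factor with an empty row or column
    degenerates to p = 1 (the Fisher test on a zero margin).
    """
    if isinstance(cases, AnalysisTable):
        cases = cases.cases
    total = len(cases)
    out = []
    for factor in factors:
        levels = _FACTOR_LEVELS[factor]
        counts = {(ev, lv): 0 for ev in (True, False) for lv in levels}
        used = 0
        for case in cases:
            level = _level_of(factor, case)
            if level is None:
                continue
            used += 1
            counts[(case_has_event(case, terms), level)] += 1
        table = ContingencyTable(
            a=counts[(True, levels[0])],
            b=counts[(True, levels[1])],
            c=counts[(False, levels[0])],
            d=counts[(False, levels[1])],
        )
        out.append(
            GroupComparison(
                factor=factor,
                levels=levels,
                table=table,
                p_value=fisher_exact_two_sided(table),
                n_used=used,
                n_excluded=total - used,
            )
        )
    return out


def comparisons_to_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    """One row per factor: cell counts, denominators, p-value, exclusions."""
    rows = []
    for c in comparisons:
        rows.append(
            {
                "factor": c.factor,
                "level_1": c.levels[0],
                "level_2": c.levels[1],
                "event_level_1": c.table.a,
                "event_level_2": c.table.b,
                "nonevent_level_1": c.table.c,
                "nonevent_level_2": c.table.d,
                "n_event": c.table.a + c.table.b,
                "n_nonevent": c.table.c + c.table.d,
                "p_value": c.p_value,
                "n_used": c.n_used,
                "n_excluded": c.n_excluded,
            }
        )
    return pd.DataFrame(rows)
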