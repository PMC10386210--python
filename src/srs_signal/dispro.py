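"""Reporting odds ratios, Fisher exact tests and volcano coordinates.

For one (drug, event-set) pair the analysis table collapses to a 2x2
contingency table over unique cases::

                      event     no event
    exposed to drug     a          b
    all other reports   c          d

The reporting odds ratio is ROR = (a/b)/(c/d) = ad/bc, a disproportionality
measure over reports (not an incidence ratio).  Zero cells make the ratio
undefined and small cells make it unstable, so 0.5 is added to every cell
(the Haldane correction) before computing the ROR and its log-scale Wald
95% confidence interval.  Significance uses the two-sided Fisher exact test
on the *raw* counts; the correction applies only to the ROR/CI.  A drug is
flagged as a signal when ROR >= 1 and p < alpha (0.05 by default), with no
multiple-testing adjustment by default (a Benjamini-Hochberg option is
available for sensitivity analyses).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from srs_signal.errors import DegenerateInputError
from srs_signal.io import AnalysisTable, ReportCase
from srs_signal.terms import DrugPanel, EventTermSet, case_has_event

#: default significance level for the signal criterion
DEFAULT_ALPHA = 0.05
#: z quantile for the 95% CI (standard normal, two-sided)
Z_95 = 1.959964
#: cap for -log10(p) when p underflows to 0
VOLCANO_Y_CAP = 320.0


@dataclass(frozen=True)
class ContingencyTable:
    """Counts of unique cases for one (drug, event) pair; a+b+c+d = n cases."""

    a: int  # exposed, with event
    b: int  # exposed, without event
    c: int  # not exposed, with event
    d: int  # not exposed, without event

    def __post_init__(self):
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise DegenerateInputError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_exposed(self) -> int:
        return self.a + self.b

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass(frozen=True)
class RorEstimate:
    """Haldane-corrected ROR with its natural log and 95% CI."""

    ror: float
    ln_ror: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class DisproResult:
    """Full screen output for one drug against one event term set."""

    drug: str
    table: ContingencyTable
    ror: float
    ln_ror: float
    ci_low: float
    ci_high: float
    p_value: float
    n_reports: int  # a + b: unique cases exposed to the drug
    is_signal: bool
    volcano_y: float  # -log10 p (capped on underflow)
    color_value: float  # log10 n_reports


def haldane_ror(table: ContingencyTable, z: float = Z_95) -> RorEstimate:
    """Haldane-corrected ROR with a log-scale Wald 95% CI.

    ROR = (a+.5)(d+.5) / ((b+.5)(c+.5));
    CI = exp(ln ROR +/- z * sqrt(sum of 1/(cell+.5))).
    Defined for every table, including all-zero ones (every cell becomes
    0.5, giving ROR = 1).
    """
    a, b, c, d = (table.a + 0.5, table.b + 0.5, table.c + 0.5, table.d + 0.5)
    ln = math.log(a) + math.log(d) - math.log(b) - math.log(c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return RorEstimate(
        ror=math.exp(ln),
        ln_ror=ln,
        ci_low=math.exp(ln - z * se),
        ci_high=math.exp(ln + z * se),
    )


def fisher_exact_two_sided(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p on the raw (uncorrected) counts.

    The two-sided p sums the hypergeometric point probabilities of every
    table with the observed margins whose probability does not exceed the
    observed table's (the minimum-likelihood convention used by most
    statistical software).  A table with a zero margin admits only itself,
    so p = 1.
    """
    p = float(stats.fisher_exact(table.as_array(), alternative="two-sided").pvalue)
    return min(p, 1.0)


def build_contingency(
    cases: Sequence[ReportCase] | AnalysisTable,
    drug: str,
    terms: EventTermSet,
) -> ContingencyTable:
    """Tally unique cases into the 2x2 table for one drug vs an event set.

    Each case contributes to exactly one cell; the cells sum to the number
    of cases.  Cases must already be deduplicated by case_id (the analysis
    table guarantees this).
    """
    if isinstance(cases, AnalysisTable):
        cases = cases.cases
    if len(cases) == 0:
        warnings.warn("empty case list: contingency table of zeros", stacklevel=2)
    a = b = c = d = 0
    for case in cases:
        exposed = drug in case.drugs
        event = case_has_event(case, terms)
        if exposed and event:
            a += 1
        elif exposed:
            b += 1
        elif event:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def _screen_one(drug: str, table: ContingencyTable, alpha: float) -> DisproResult:
    est = haldane_ror(table)
    p = fisher_exact_two_sided(table)
    n_reports = table.n_exposed
    if p > 0.0:
        y = -math.log10(p)
    else:
        warnings.warn(f"{drug}: p-value underflowed to 0; -log10 p capped at {VOLCANO_Y_CAP}", stacklevel=3)
        y = VOLCANO_Y_CAP
    return DisproResult(
        drug=drug,
        table=table,
        ror=est.ror,
        ln_ror=est.ln_ror,
        ci_low=est.ci_low,
        ci_high=est.ci_high,
        p_value=p,
        n_reports=n_reports,
        is_signal=bool(est.ror >= 1.0 and p < alpha),
        volcano_y=min(y, VOLCANO_Y_CAP),
        color_value=math.log10(n_reports) if n_reports > 0 else float("-inf"),
    )


def screen_panel(
    cases: Sequence[ReportCase] | AnalysisTable,
    panel: DrugPanel,
    terms: EventTermSet,
    alpha: float = DEFAULT_ALPHA,
) -> list[DisproResult]:
    """Screen every panel drug against the event set over the same cases.

    One result per drug, sorted by ln ROR descending (ties by drug name).
    A drug absent from every case yields a=b=0 (ROR from Haldane cells),
    not an error.  No multiplicity adjustment is applied: the signal
    criterion is exactly (ROR >= 1 and p < alpha).
    """
    if not 0.0 <= alpha < 1.0:  # alpha = 0 is allowed: a vacuous criterion
        raise DegenerateInputError(f"alpha must be in [0, 1), got {alpha}")
    if isinstance(cases, AnalysisTable):
        cases = cases.cases
    # one pass over the cases: per-drug exposure tallies split by event status
    n_total = len(cases)
    panel_set = set(panel)
    n_event = 0
    exposed_event: dict[str, int] = {d: 0 for d in panel}
    exposed_noevent: dict[str, int] = {d: 0 for d in panel}
    for case in cases:
        event = case_has_event(case, terms)
        if event:
            n_event += 1
        for drug in case.drugs & panel_set:
            if event:
                exposed_event[drug] += 1
            else:
                exposed_noevent[drug] += 1
    results = []
    for drug in panel:
        a = exposed_event[drug]
        b = exposed_noevent[drug]
        table = ContingencyTable(a, b, n_event - a, n_total - n_event - b)
        results.append(_screen_one(drug, table, alpha))
    results.sort(key=lambda r: (-r.ln_ror, r.drug))
    return results


def apply_fdr(results: Iterable[DisproResult], alpha: float = DEFAULT_ALPHA) -> list[DisproResult]:
    """Benjamini-Hochberg variant of the signal flag (off the default path).

    Returns new results whose ``is_signal`` uses BH-adjusted p-values at
    level ``alpha`` (still requiring ROR >= 1).
    """
    results = list(results)
    ps = np.array([r.p_value for r in results])
    m = len(ps)
    order = np.argsort(ps, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running = min(running, ps[idx] * m / rank)
        adj[idx] = running
    out = []
    for r, q in zip(results, adj):
        out.append(
            DisproResult(
                drug=r.drug, table=r.table, ror=r.ror, ln_ror=r.ln_ror,
                ci_low=r.ci_low, ci_high=r.ci_high, p_value=r.p_value,
                n_reports=r.n_reports, is_signal=bool(r.ror >= 1.0 and q < alpha),
                volcano_y=r.volcano_y, color_value=r.color_value,
            )
        )
    return out


def volcano_data(results: Sequence[DisproResult], alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Volcano-plot coordinates: x = lnROR, y = -log10 p, colour = log10 n.

    The reference line at y = -log10(alpha) (~1.3 for alpha = 0.05) is
    attached as ``DataFrame.attrs['reference_y']``; signals are the points
    in the upper-right quadrant relative to (x > 0 boundary at ROR = 1,
    y above the reference line).
    """
    if len(results) == 0:
        raise DegenerateInputError("volcano_data requires at least one result")
    frame = pd.DataFrame(
        {
            "drug": [r.drug for r in results],
            "x": [r.ln_ror for r in results],
            "y": [r.volcano_y for r in results],
            "color": [r.color_value for r in results],
            "n_reports": [r.n_reports for r in results],
            "is_signal": [r.is_signal for r in results],
        }
    )
    frame.attrs["reference_y"] = -math.log10(alpha)
    return frame


def results_to_frame(results: Sequence[DisproResult]) -> pd.DataFrame:
    """Flatten screen results to a DataFrame mirroring the published layout."""
    return pd.DataFrame(
        {
            "drug": [r.drug for r in results],
            "a": [r.table.a for r in results],
            "b": [r.table.b for r in results],
            "c": [r.table.c for r in results],
            "d": [r.table.d for r in results],
            "n_reports": [r.n_reports for r in results],
            "ror": [r.ror for r in results],
            "ln_ror": [r.ln_ror for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "p_value": [r.p_value for r in results],
            "is_signal": [r.is_signal for r in results],
        }
    )


def count_signals(ror: Sequence[float], p_value: Sequence[float], alpha: float = DEFAULT_ALPHA) -> int:
    """Apply the signal criterion (ROR >= 1 and p < alpha) to tabulated values.

    Used to re-screen published result tables where only ROR and p are
    available (p strings like "<0.001" should be parsed with
    :func:`parse_p_string` first).
    """
    ror_arr = np.asarray(ror, dtype=float)
    p_arr = np.asarray(p_value, dtype=float)
    if ror_arr.shape != p_arr.shape:
        raise DegenerateInputError("ror and p_value must have the same length")
    return int(np.sum((ror_arr >= 1.0) & (p_arr < alpha)))


def parse_p_string(value: str | float) -> float:
    """Parse a printed p-value, mapping "<x" to x (an upper bound).

    Printed tables truncate small p-values to e.g. "<0.001"; for threshold
    criteria at conventional alpha levels the bound itself is sufficient.
    """
    if isinstance(value, str) and value.strip().startswith("<"):
        return float(value.strip()[1:])
    return float(value)
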