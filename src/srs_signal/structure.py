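"""Report-count filters, the drugs x PTs lnROR matrix, Ward clustering, PCA.

Looking for structure among the signal drugs needs per-term resolution:
instead of one ROR against the whole event set, each drug gets one
Haldane-corrected lnROR against each individual preferred term (same 2x2
scheme, event = that single PT, all analysis cases as denominator).  Rare
drugs and rare terms produce noise-dominated rows/columns, so report-count
filters are applied first: a drug must have at least ``drug_min_reports``
total reports and ``drug_min_event_reports`` event reports; a PT must
appear in at least ``pt_min_reports`` reports.

The filtered matrix is then clustered (Ward linkage on Euclidean distances
between drug row-vectors) and decomposed by PCA on the column covariance
matrix (columns centred, NOT scaled — the shared lnROR scale is
meaningful), reporting PC1/PC2 scores for drugs, loadings for PTs and
percentage variance contributions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from srs_signal.dispro import ContingencyTable, haldane_ror
from srs_signal.errors import DegenerateInputError
from srs_signal.io import AnalysisTable, ReportCase
from srs_signal.terms import DrugPanel, EventTermSet, case_has_event

DRUG_MIN_REPORTS = 100
DRUG_MIN_EVENT_REPORTS = 10
PT_MIN_REPORTS = 50


@dataclass(frozen=True)
class LnRorMatrix:
    """Filtered drugs x PTs matrix of ln(Haldane ROR) values."""

    values: pd.DataFrame  # index: drug names, columns: PT names
    row_report_counts: pd.Series  # total reports per retained drug
    row_event_report_counts: pd.Series  # event reports per retained drug
    col_report_counts: pd.Series  # reports per retained PT

    def __post_init__(self):
        if not np.isfinite(self.values.to_numpy()).all():
            raise DegenerateInputError("lnROR matrix contains non-finite values")

    @property
    def drugs(self) -> list[str]:
        return list(self.values.index)

    @property
    def pts(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class ClusterResult:
    """Ward merge history plus a flat k-cluster labelling of the drugs."""

    linkage: np.ndarray  # scipy linkage matrix, shape (n_rows - 1, 4)
    labels: pd.Series  # drug -> cluster id in 1..k
    k: int


@dataclass(frozen=True)
class PcaResult:
    """Covariance-matrix PCA: drug scores, PT loadings, % contributions."""

    scores: pd.DataFrame  # drugs x components ("PC1", "PC2", ...)
    loadings: pd.DataFrame  # PTs x components; orthonormal columns
    contributions: pd.Series  # % variance per component, sums to 100
    column_means: pd.Series  # per-PT means removed before projection

    @property
    def pc1_pc2_scores(self) -> pd.DataFrame:
        return self.scores[["PC1", "PC2"]]

    @property
    def pc1_pc2_loadings(self) -> pd.DataFrame:
        return self.loadings[["PC1", "PC2"]]


def filter_pts_by_reports(counts: Mapping[str, int] | pd.Series, min_reports: int = PT_MIN_REPORTS) -> list[str]:
    """PTs with at least ``min_reports`` reports, in descending-count order."""
    series = pd.Series(dict(counts)) if not isinstance(counts, pd.Series) else counts
    passing = series[series >= min_reports]
    return list(passing.sort_values(ascending=False, kind="stable").index)


def filter_and_build_matrix(
    cases: Sequence[ReportCase] | AnalysisTable,
    panel: DrugPanel,
    terms: EventTermSet,
    drug_min_reports: int = DRUG_MIN_REPORTS,
    drug_min_event_reports: int = DRUG_MIN_EVENT_REPORTS,
    pt_min_reports: int = PT_MIN_REPORTS,
) -> LnRorMatrix:
    """Apply the report-count filters and build the lnROR matrix.

    Drug filters count unique cases: total reports = cases exposed to the
    drug; event reports = exposed cases whose events intersect the term
    set.  PT filter counts cases reporting that PT among all analysis
    cases.  Each retained (drug, PT) cell is the ln Haldane ROR of the 2x2
    table with event = that single PT over all cases.  Raises if no drug
    or no PT survives.
    """
    for name, value in (
        ("drug_min_reports", drug_min_reports),
        ("drug_min_event_reports", drug_min_event_reports),
        ("pt_min_reports", pt_min_reports),
    ):
        if int(value) != value or value < 1:
            raise DegenerateInputError(f"{name} must be a positive integer, got {value!r}")
    if isinstance(cases, AnalysisTable):
        cases = cases.cases
    n = len(cases)
    panel_set = set(panel)

    # pass 1: marginal counts for the filters
    drug_total = {d: 0 for d in panel}
    drug_event = {d: 0 for d in panel}
    pt_total: dict[str, int] = {p: 0 for p in terms.pts}
    for case in cases:
        event = case_has_event(case, terms)
        for drug in case.drugs & panel_set:
            drug_total[drug] += 1
            if event:
                drug_event[drug] += 1
        for pt in case.events & terms.pts:
            pt_total[pt] += 1

    kept_drugs = [
        d for d in panel if drug_total[d] >= drug_min_reports and drug_event[d] >= drug_min_event_reports
    ]
    kept_pts = filter_pts_by_reports(pt_total, pt_min_reports)
    if not kept_drugs or not kept_pts:
        raise DegenerateInputError(
            f"filters left an empty matrix ({len(kept_drugs)} drugs, {len(kept_pts)} PTs)"
        )

    # pass 2: joint (drug, PT) counts for the retained sets
    kept_drug_set = set(kept_drugs)
    kept_pt_set = set(kept_pts)
    pair = {(d, p): 0 for d in kept_drugs for p in kept_pts}
    for case in cases:
        ds = case.drugs & kept_drug_set
        if not ds:
            continue
        ps = case.events & kept_pt_set
        if not ps:
            continue
        for d in ds:
            for p in ps:
                pair[(d, p)] += 1

    values = pd.DataFrame(index=pd.Index(kept_drugs, name="drug"), columns=kept_pts, dtype=float)
    for d in kept_drugs:
        for p in kept_pts:
            a = pair[(d, p)]
            b = drug_total[d] - a
            c = pt_total[p] - a
            table = ContingencyTable(a, b, c, n - a - b - c)
            values.loc[d, p] = haldane_ror(table).ln_ror
    return LnRorMatrix(
        values=values,
        row_report_counts=pd.Series({d: drug_total[d] for d in kept_drugs}, name="n_reports"),
        row_event_report_counts=pd.Series({d: drug_event[d] for d in kept_drugs}, name="n_event_reports"),
        col_report_counts=pd.Series({p: pt_total[p] for p in kept_pts}, name="n_reports"),
    )


def ward_cluster(matrix: LnRorMatrix | pd.DataFrame, k: int) -> ClusterResult:
    """Agglomerative Ward clustering on Euclidean distances between drug rows.

    Deterministic given the matrix (distance ties broken by row order, the
    scipy convention).  The k-cluster labelling cuts the tree with
    ``fcluster(..., criterion="maxclust")``.
    """
    frame = matrix.values if isinstance(matrix, LnRorMatrix) else matrix
    n_rows = len(frame)
    if not 1 <= k <= n_rows:
        raise DegenerateInputError(f"k must be in [1, {n_rows}], got {k}")
    linkage = hierarchy.linkage(frame.to_numpy(dtype=float), method="ward", metric="euclidean")
    flat = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    return ClusterResult(linkage=linkage, labels=pd.Series(flat, index=frame.index, name="cluster"), k=k)


def covariance_pca(matrix: LnRorMatrix | pd.DataFrame) -> PcaResult:
    """PCA by eigendecomposition of the column covariance matrix.

    Columns are centred but not scaled to unit variance.  Components are
    ordered by decreasing eigenvalue; each loading vector's sign is fixed
    so that its largest-magnitude entry is positive, making runs
    comparable across platforms.  Contributions are eigenvalue / trace as
    percentages and sum to 100 over all components.
    """
    frame = matrix.values if isinstance(matrix, LnRorMatrix) else matrix
    if frame.shape[0] < 2 or frame.shape[1] < 2:
        raise DegenerateInputError(f"PCA needs at least a 2x2 matrix, got {frame.shape}")
    data = frame.to_numpy(dtype=float)
    means = data.mean(axis=0)
    centered = data - means
    cov = np.cov(centered, rowvar=False, ddof=1)
    trace = float(np.trace(cov))
    if trace <= 0.0:
        raise DegenerateInputError("zero total variance: PCA is degenerate")
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # sign convention: largest-|entry| of each loading vector is positive
    for j in range(eigvecs.shape[1]):
        pivot = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[pivot, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    comp_names = [f"PC{i + 1}" for i in range(eigvecs.shape[1])]
    return PcaResult(
        scores=pd.DataFrame(centered @ eigvecs, index=frame.index, columns=comp_names),
        loadings=pd.DataFrame(eigvecs, index=frame.columns, columns=comp_names),
        contributions=pd.Series(eigvals / trace * 100.0, index=comp_names, name="contribution_pct"),
        column_means=pd.Series(means, index=frame.columns, name="mean"),
    )
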