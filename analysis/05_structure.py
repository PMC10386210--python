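"""Structure among the screened drugs: report-count filters, per-PT lnROR
matrix, Ward/Euclidean clustering, covariance PCA with scores and loadings.

Thresholds are scaled to the 20,000-case world (the conventional 100 /
10 / 50 filters assume a database three orders of magnitude larger).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, TABLE_CSV, WORLD, ensure_dirs

from srs_signal.io import AnalysisTable, normalize_name
from srs_signal.plots import render_biplot, render_dendrogram
from srs_signal.structure import covariance_pca, filter_and_build_matrix, ward_cluster
from srs_signal.terms import DrugPanel, default_glaucoma_terms


def main() -> None:
    ensure_dirs()
    table = AnalysisTable.read_csv(TABLE_CSV)
    panel = DrugPanel(drugs=tuple(normalize_name(d) for d in WORLD.drugs))
    matrix = filter_and_build_matrix(
        table, panel, default_glaucoma_terms(),
        drug_min_reports=100, drug_min_event_reports=10, pt_min_reports=20,
    )
    matrix.values.to_csv(RESULTS / "05_lnror_matrix.csv")
    print(f"filtered matrix: {len(matrix.drugs)} drugs x {len(matrix.pts)} PTs")
    print(matrix.values.round(2).to_string())

    k = min(3, len(matrix.drugs))
    clusters = ward_cluster(matrix, k=k)
    clusters.labels.rename_axis("drug").reset_index().to_csv(RESULTS / "05_cluster_labels.csv", index=False)
    print(f"\nWard clusters (k={k}):")
    for label, members in clusters.labels.groupby(clusters.labels):
        print(f"  cluster {label}: {', '.join(members.index)}")

    pca = covariance_pca(matrix)
    pca.scores.to_csv(RESULTS / "05_pca_scores.csv")
    pca.loadings.to_csv(RESULTS / "05_pca_loadings.csv")
    pca.contributions.rename_axis("component").reset_index().to_csv(
        RESULTS / "05_pca_contributions.csv", index=False
    )
    print(f"\nPC1 contribution {pca.contributions['PC1']:.1f}%, PC2 {pca.contributions['PC2']:.1f}%")
    print("PC1/PC2 loadings:")
    print(pca.pc1_pc2_loadings.round(3).to_string())

    render_dendrogram(matrix, clusters, RESULTS / "05_dendrogram.png")
    render_biplot(pca, clusters, RESULTS / "05_pca_biplot.png")


if __name__ == "__main__":
    main()
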