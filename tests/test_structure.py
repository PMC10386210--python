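"""Report-count filters, lnROR matrix, Ward clustering, covariance PCA."""

import math

import numpy as np
import pandas as pd
import pytest

from srs_signal.datasets import published_pt_report_counts
from srs_signal.dispro import ContingencyTable, haldane_ror
from srs_signal.errors import DegenerateInputError
from srs_signal.io import ReportCase
from srs_signal.structure import (
    covariance_pca,
    filter_and_build_matrix,
    filter_pts_by_reports,
    ward_cluster,
)
from srs_signal.terms import DrugPanel, EventTermSet

rng = np.random.default_rng(20240901)


def make_case(cid, drugs=(), events=()):
    return ReportCase(case_id=cid, sex="male", age_token="40s",
                      drugs=frozenset(drugs), events=frozenset(events))


class TestPtFilter:
    def test_published_counts_pass_exactly_five_terms(self):
        passing = filter_pts_by_reports(published_pt_report_counts(), 50)
        assert passing == [
            "Glaucoma",
            "Intraocular pressure increased",
            "Angle-closure glaucoma",
            "Ocular hypertension",
            "Normal tension glaucoma",
        ]

    def test_raising_threshold_never_adds_terms(self):
        counts = published_pt_report_counts()
        previous = set(filter_pts_by_reports(counts, 1))
        for threshold in (10, 50, 300, 2000):
            current = set(filter_pts_by_reports(counts, threshold))
            assert current <= previous
            previous = current


class TestMatrixConstruction:
    @pytest.fixture
    def small_world(self):
        """3 drugs x 2 PTs with hand-countable margins."""
        terms = EventTermSet(name="t", pts=frozenset({"pt1", "pt2"}))
        panel = DrugPanel(drugs=("d1", "d2", "d3"))
        cases = (
            [make_case(f"A{i}", drugs={"d1"}, events={"pt1"}) for i in range(6)]
            + [make_case(f"B{i}", drugs={"d1"}, events={"none"}) for i in range(4)]
            + [make_case(f"C{i}", drugs={"d2"}, events={"pt2"}) for i in range(3)]
            + [make_case(f"D{i}", drugs={"d2"}, events={"none"}) for i in range(9)]
            + [make_case(f"E{i}", drugs={"d3"}, events={"pt1"}) for i in range(1)]
            + [make_case(f"F{i}", events={"pt1", "pt2"}) for i in range(5)]
            + [make_case(f"G{i}", events={"none"}) for i in range(12)]
        )
        return cases, panel, terms

    def test_vacuous_thresholds_keep_everything(self, small_world):
        cases, panel, terms = small_world
        matrix = filter_and_build_matrix(cases, panel, terms, 1, 1, 1)
        assert set(matrix.drugs) == {"d1", "d2", "d3"}
        assert set(matrix.pts) == {"pt1", "pt2"}

    def test_filters_match_hand_applied_thresholds(self, small_world):
        cases, panel, terms = small_world
        # totals: d1=10, d2=12, d3=1; event reports: d1=6, d2=3, d3=1
        # pt counts: pt1 = 6+1+5 = 12, pt2 = 3+5 = 8
        matrix = filter_and_build_matrix(
            cases, panel, terms, drug_min_reports=10, drug_min_event_reports=4, pt_min_reports=10
        )
        assert matrix.drugs == ["d1"]
        assert matrix.pts == ["pt1"]
        assert matrix.row_report_counts["d1"] == 10
        assert matrix.col_report_counts["pt1"] == 12

    def test_cell_is_single_pt_haldane_lnror(self, small_world):
        cases, panel, terms = small_world
        matrix = filter_and_build_matrix(cases, panel, terms, 1, 1, 1)
        n = len(cases)
        # d1 vs pt1: a = 6 exposed-with-pt1, b = 4, c = 6 others with pt1
        expected = haldane_ror(ContingencyTable(6, 4, 6, n - 16)).ln_ror
        assert matrix.values.loc["d1", "pt1"] == pytest.approx(expected, rel=1e-12)
        # d2 vs pt1: no overlap -> a = 0
        expected = haldane_ror(ContingencyTable(0, 12, 12, n - 24)).ln_ror
        assert matrix.values.loc["d2", "pt1"] == pytest.approx(expected, rel=1e-12)

    def test_empty_matrix_raises(self, small_world):
        cases, panel, terms = small_world
        with pytest.raises(DegenerateInputError, match="empty"):
            filter_and_build_matrix(cases, panel, terms, drug_min_reports=10_000)


class TestWardCluster:
    def test_identical_rows_merge_first_at_height_zero(self):
        frame = pd.DataFrame(
            [[0.0, 0.0], [5.0, 5.0], [0.0, 0.0]], index=["a", "b", "c"], columns=["x", "y"]
        )
        result = ward_cluster(frame, k=2)
        first = result.linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 2}
        assert first[2] == pytest.approx(0.0)
        assert result.labels["a"] == result.labels["c"] != result.labels["b"]

    def test_four_point_toy_matches_hand_computed_ward(self):
        """Ward on (0,0), (0,1), (4,0), (6,0).

        Hand merge sequence via d(A,B) = sqrt(2 |A||B| / (|A|+|B|) *
        ||centroid_A - centroid_B||^2): singletons (0,0)+(0,1) merge at 1,
        (4,0)+(6,0) at 2, and the two pairs (centroids (0, 0.5) and (5, 0),
        squared distance 25.25) at sqrt(2 * 25.25) = sqrt(50.5).
        """
        frame = pd.DataFrame(
            [[0.0, 0.0], [0.0, 1.0], [4.0, 0.0], [6.0, 0.0]],
            index=["p0", "p1", "p2", "p3"], columns=["x", "y"],
        )
        result = ward_cluster(frame, k=2)
        linkage = result.linkage
        assert {int(linkage[0][0]), int(linkage[0][1])} == {0, 1}
        assert linkage[0][2] == pytest.approx(1.0)
        assert {int(linkage[1][0]), int(linkage[1][1])} == {2, 3}
        assert linkage[1][2] == pytest.approx(2.0)
        assert {int(linkage[2][0]), int(linkage[2][1])} == {4, 5}
        assert linkage[2][2] == pytest.approx(math.sqrt(50.5))
        assert list(result.labels) == [1, 1, 2, 2]

    def test_heights_non_decreasing_and_k_limits(self):
        frame = pd.DataFrame(rng.normal(size=(10, 4)), index=[f"r{i}" for i in range(10)])
        result = ward_cluster(frame, k=10)
        heights = result.linkage[:, 2]
        assert (np.diff(heights) >= -1e-12).all()
        assert result.labels.nunique() == 10  # singleton clusters at k = n
        with pytest.raises(DegenerateInputError):
            ward_cluster(frame, k=0)
        with pytest.raises(DegenerateInputError):
            ward_cluster(frame, k=11)

    def test_labels_invariant_to_row_permutation(self):
        frame = pd.DataFrame(rng.normal(size=(12, 5)), index=[f"r{i}" for i in range(12)])
        base = ward_cluster(frame, k=3).labels
        permuted = ward_cluster(frame.sample(frac=1.0, random_state=7), k=3).labels
        # same partition of row names, up to relabelling of cluster ids
        base_parts = {frozenset(base.index[base == c]) for c in base.unique()}
        perm_parts = {frozenset(permuted.index[permuted == c]) for c in permuted.unique()}
        assert base_parts == perm_parts


class TestCovariancePca:
    def test_single_varying_column_gives_pc1_all_variance(self):
        frame = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0], "y": [5.0, 5.0, 5.0, 5.0]})
        pca = covariance_pca(frame)
        assert pca.contributions["PC1"] == pytest.approx(100.0)

    def test_contributions_sum_to_100(self):
        frame = pd.DataFrame(rng.normal(size=(14, 5)))
        pca = covariance_pca(frame)
        assert pca.contributions.sum() == pytest.approx(100.0, abs=1e-9)
        assert pca.contributions["PC1"] >= pca.contributions["PC2"]

    def test_reconstruction_and_orthonormality(self):
        frame = pd.DataFrame(rng.normal(size=(14, 5)))
        pca = covariance_pca(frame)
        load = pca.loadings.to_numpy()
        assert np.allclose(load.T @ load, np.eye(5), atol=1e-9)
        reconstructed = pca.scores.to_numpy() @ load.T + pca.column_means.to_numpy()
        assert np.abs(reconstructed - frame.to_numpy()).max() < 1e-9

    def test_matches_independent_eigensolver(self):
        """Cross-check against sklearn's SVD-based PCA on a 5x3 matrix."""
        from sklearn.decomposition import PCA

        frame = pd.DataFrame(rng.normal(size=(5, 3)))
        ours = covariance_pca(frame)
        ref = PCA(n_components=3).fit(frame.to_numpy())
        assert np.allclose(
            ours.contributions.to_numpy(), ref.explained_variance_ratio_ * 100.0, atol=1e-9
        )
        # components agree up to sign
        for j in range(3):
            ref_vec = ref.components_[j]
            our_vec = ours.loadings.to_numpy()[:, j]
            assert np.allclose(np.abs(ref_vec), np.abs(our_vec), atol=1e-9)

    def test_sign_convention_largest_loading_positive(self):
        frame = pd.DataFrame(rng.normal(size=(8, 4)))
        pca = covariance_pca(frame)
        for col in pca.loadings.columns:
            vec = pca.loadings[col].to_numpy()
            assert vec[np.argmax(np.abs(vec))] > 0

    def test_degenerate_inputs_raise(self):
        constant = pd.DataFrame({"x": [1.0, 1.0, 1.0], "y": [2.0, 2.0, 2.0]})
        with pytest.raises(DegenerateInputError, match="variance"):
            covariance_pca(constant)
        with pytest.raises(DegenerateInputError, match="2x2"):
            covariance_pca(pd.DataFrame({"x": [1.0, 2.0]}))
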