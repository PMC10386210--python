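"""Contingency tables, Haldane ROR/CI, Fisher exact test, panel screen, volcano."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srs_signal.dispro import (
    ContingencyTable,
    apply_fdr,
    build_contingency,
    count_signals,
    fisher_exact_two_sided,
    haldane_ror,
    parse_p_string,
    screen_panel,
    volcano_data,
)
from srs_signal.errors import DegenerateInputError
from srs_signal.io import ReportCase
from srs_signal.terms import DrugPanel, EventTermSet
from tests.oracles import fisher_two_sided_exact

cells = st.integers(min_value=0, max_value=200)


def make_case(cid, drugs=(), events=()):
    return ReportCase(case_id=cid, sex="male", age_token="40s",
                      drugs=frozenset(drugs), events=frozenset(events))


class TestContingency:
    def test_four_archetype_cases_fill_four_cells(self, tiny_terms):
        cases = [
            make_case("C1", drugs={"d"}, events={"glaucoma"}),
            make_case("C2", drugs={"d"}, events={"rash"}),
            make_case("C3", drugs={"x"}, events={"glaucoma"}),
            make_case("C4", drugs={"x"}, events={"rash"}),
        ]
        t = build_contingency(cases, "d", tiny_terms)
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_unexposed_drug_has_empty_first_row(self, tiny_terms):
        cases = [make_case("C1", drugs={"x"}, events={"glaucoma"})]
        t = build_contingency(cases, "never-used", tiny_terms)
        assert (t.a, t.b) == (0, 0)
        assert t.total == 1

    def test_twenty_case_fixture_matches_hand_tally(self, tiny_terms):
        # 6 exposed+event, 4 exposed only, 3 event only, 7 neither
        cases = (
            [make_case(f"A{i}", drugs={"d"}, events={"glaucoma"}) for i in range(6)]
            + [make_case(f"B{i}", drugs={"d"}, events={"rash"}) for i in range(4)]
            + [make_case(f"C{i}", drugs={"x"}, events={"ocular hypertension"}) for i in range(3)]
            + [make_case(f"D{i}", drugs={"x"}, events={"rash"}) for i in range(7)]
        )
        t = build_contingency(cases, "d", tiny_terms)
        assert (t.a, t.b, t.c, t.d) == (6, 4, 3, 7)
        assert t.total == 20

    def test_empty_case_list_warns(self, tiny_terms):
        with pytest.warns(UserWarning, match="empty"):
            t = build_contingency([], "d", tiny_terms)
        assert t.total == 0

    def test_negative_counts_rejected(self):
        with pytest.raises(DegenerateInputError):
            ContingencyTable(-1, 0, 0, 0)


class TestHaldaneRor:
    def test_balanced_table_is_unity_with_symmetric_ci(self):
        est = haldane_ror(ContingencyTable(10, 10, 10, 10))
        assert est.ror == pytest.approx(1.0)
        assert est.ci_low * est.ci_high == pytest.approx(1.0)  # symmetric on log scale

    def test_all_zero_table_is_unity(self):
        est = haldane_ror(ContingencyTable(0, 0, 0, 0))
        assert est.ror == pytest.approx(1.0)

    def test_direct_arithmetic_oracle(self):
        # spreadsheet-style arithmetic on the corrected cells
        est = haldane_ror(ContingencyTable(10, 90, 100, 900))
        expected = (10.5 * 900.5) / (90.5 * 100.5)
        assert est.ror == pytest.approx(expected, rel=1e-12)
        se = math.sqrt(1 / 10.5 + 1 / 90.5 + 1 / 100.5 + 1 / 900.5)
        assert est.ci_low == pytest.approx(expected * math.exp(-1.959964 * se), rel=1e-12)
        assert est.ci_high == pytest.approx(expected * math.exp(1.959964 * se), rel=1e-12)
        assert est.ln_ror == pytest.approx(math.log(expected), rel=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(cells, cells, cells, cells)
    def test_row_swap_inverts_ror(self, a, b, c, d):
        direct = haldane_ror(ContingencyTable(a, b, c, d))
        swapped = haldane_ror(ContingencyTable(c, d, a, b))
        assert direct.ror * swapped.ror == pytest.approx(1.0, rel=1e-12)
        assert direct.ci_low * swapped.ci_high == pytest.approx(1.0, rel=1e-9)

    @settings(derandomize=True, max_examples=100)
    @given(cells, cells, cells, cells)
    def test_increasing_a_never_decreases_ror(self, a, b, c, d):
        lower = haldane_ror(ContingencyTable(a, b, c, d)).ror
        higher = haldane_ror(ContingencyTable(a + 1, b, c, d)).ror
        assert higher >= lower


class TestFisher:
    def test_published_sex_table(self):
        p = fisher_exact_two_sided(ContingencyTable(653, 694, 599030, 609980))
        assert p == pytest.approx(0.445, abs=0.002)

    @pytest.mark.parametrize("table", [(0, 0, 5, 7), (5, 7, 0, 0), (0, 5, 0, 7), (5, 0, 7, 0)])
    def test_zero_margin_gives_p_one(self, table):
        assert fisher_exact_two_sided(ContingencyTable(*table)) == 1.0

    @settings(derandomize=True, max_examples=80)
    @given(st.tuples(*[st.integers(0, 12)] * 4))
    def test_matches_exact_enumeration_oracle(self, cells4):
        a, b, c, d = cells4
        p = fisher_exact_two_sided(ContingencyTable(a, b, c, d))
        assert p == pytest.approx(float(fisher_two_sided_exact(a, b, c, d)), rel=1e-9, abs=1e-12)


class TestScreenPanel:
    @pytest.fixture
    def panel_cases(self):
        return (
            [make_case(f"A{i}", drugs={"strong"}, events={"glaucoma"}) for i in range(30)]
            + [make_case(f"B{i}", drugs={"strong"}, events={"rash"}) for i in range(10)]
            + [make_case(f"C{i}", drugs={"weak"}, events={"glaucoma"}) for i in range(2)]
            + [make_case(f"D{i}", drugs={"weak"}, events={"rash"}) for i in range(20)]
            + [make_case(f"E{i}", drugs=set(), events={"glaucoma"}) for i in range(20)]
            + [make_case(f"F{i}", drugs=set(), events={"rash"}) for i in range(100)]
        )

    def test_one_result_per_drug_sorted_by_ln_ror(self, panel_cases, tiny_terms):
        panel = DrugPanel(drugs=("weak", "strong", "absent"))
        results = screen_panel(panel_cases, panel, tiny_terms)
        assert [r.drug for r in results] == ["strong", "absent", "weak"]
        strong = results[0]
        assert (strong.table.a, strong.table.b) == (30, 10)
        assert strong.is_signal
        assert not results[2].is_signal
        assert results[1].table.n_exposed == 0  # absent drug: a = b = 0, not an error

    def test_alpha_zero_yields_no_signals(self, panel_cases, tiny_terms):
        results = screen_panel(panel_cases, DrugPanel(drugs=("strong",)), tiny_terms, alpha=0.0)
        assert not any(r.is_signal for r in results)

    def test_cells_sum_to_case_count(self, panel_cases, tiny_terms):
        for r in screen_panel(panel_cases, DrugPanel(drugs=("strong", "weak")), tiny_terms):
            assert r.table.total == len(panel_cases)

    def test_fdr_flag_is_no_less_strict(self, panel_cases, tiny_terms):
        raw = screen_panel(panel_cases, DrugPanel(drugs=("strong", "weak", "absent")), tiny_terms)
        adjusted = apply_fdr(raw)
        for r_raw, r_adj in zip(raw, adjusted):
            assert not (r_adj.is_signal and not r_raw.is_signal)


class TestVolcano:
    def test_log_coordinates(self, tiny_terms):
        cases = [
            make_case("C1", drugs={"d"}, events={"glaucoma"}),
            make_case("C2", drugs={"d"}, events={"rash"}),
            make_case("C3", drugs={"x"}, events={"glaucoma"}),
            make_case("C4", drugs={"x"}, events={"rash"}),
        ]
        results = screen_panel(cases, DrugPanel(drugs=("d",)), tiny_terms)
        frame = volcano_data(results)
        assert frame.loc[0, "x"] == pytest.approx(0.0)  # ROR = 1 -> x = 0
        assert frame.loc[0, "y"] == pytest.approx(-math.log10(results[0].p_value))
        assert frame.attrs["reference_y"] == pytest.approx(1.301, abs=0.001)  # p = 0.05

    def test_upper_right_quadrant_matches_signal_flag(self, tiny_terms):
        cases = (
            [make_case(f"A{i}", drugs={"hit"}, events={"glaucoma"}) for i in range(25)]
            + [make_case(f"B{i}", drugs={"null"}, events={"rash"}) for i in range(25)]
            + [make_case(f"C{i}", events={"glaucoma"}) for i in range(25)]
            + [make_case(f"D{i}", events={"rash"}) for i in range(500)]
        )
        results = screen_panel(cases, DrugPanel(drugs=("hit", "null")), tiny_terms)
        frame = volcano_data(results)
        in_quadrant = (frame["x"] > 0) & (frame["y"] > frame.attrs["reference_y"])
        assert list(in_quadrant) == list(frame["is_signal"])


def test_published_screen_signal_criterion():
    """Re-applying (ROR >= 1, p < 0.05) to the published 47-row screen."""
    from srs_signal.datasets import published_screen

    screen = published_screen()
    assert len(screen) == 47
    ps = [parse_p_string(v) for v in screen["p_value"]]
    assert count_signals(screen["ror"], ps) == 28
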