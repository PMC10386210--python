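import pandas as pd
import pytest

from srs_signal.io import RawTable
from srs_signal.synthetic import SyntheticConfig
from srs_signal.terms import EventTermSet


def make_raw(name: str, rows: list[dict], columns: list[str]) -> RawTable:
    frame = pd.DataFrame(rows, columns=columns).fillna("").astype(str)
    return RawTable(name=name, frame=frame)


@pytest.fixture
def tiny_terms() -> EventTermSet:
    return EventTermSet(name="glaucoma-mini", pts=frozenset({"glaucoma", "ocular hypertension"}))


@pytest.fixture
def ten_case_tables() -> tuple[RawTable, RawTable, RawTable]:
    """Hand-built 10-case fixture with merged fields, a duplicate and an
    excludable case; expected outcomes are hand-tallied in the tests."""
    demo_rows = [
        {"case_id": f"C{i:02d}", "sex": s, "age": a, "reporter": r}
        for i, (s, a, r) in enumerate(
            [
                ("male", "40s", "physician"),
                ("female", "70s", "physician;pharmacist"),  # merged reporter
                ("male", "adult", "physician"),
                ("female", "", "pharmacist"),  # missing age
                ("", "60s", "physician"),  # missing sex
                ("male", "80s", "physician"),
                ("female", "20s", "physician"),
                ("male", "elderly", "pharmacist"),
                ("female", "50s", "physician"),
                ("male", "30s", "physician"),
            ],
            start=1,
        )
    ]
    drug_rows = [
        {"case_id": "C01", "drug_name": "DrugA", "route": "oral;topical"},  # merged route
        {"case_id": "C02", "drug_name": "druga;drugb", "route": "oral"},  # merged names
        {"case_id": "C03", "drug_name": "DrugC·DrugD", "route": "oral"},  # combination
        {"case_id": "C04", "drug_name": "timolol", "route": "ophthalmic"},  # exclusion target
        {"case_id": "C05", "drug_name": "DrugA", "route": "oral"},
        {"case_id": "C05", "drug_name": "DrugA", "route": "oral"},  # exact duplicate row
        {"case_id": "C06", "drug_name": "DrugB", "route": "injection"},
        {"case_id": "C07", "drug_name": "DrugA", "route": "oral"},
        {"case_id": "C08", "drug_name": "DrugB", "route": "oral"},
        {"case_id": "C09", "drug_name": "DrugC", "route": "oral"},
        {"case_id": "C10", "drug_name": "DrugA", "route": "oral"},
    ]
    reac_rows = [
        {"case_id": "C01", "pt_name": "Glaucoma", "outcome": "recovered"},
        {"case_id": "C02", "pt_name": "Ocular hypertension", "outcome": "recovering"},
        {"case_id": "C03", "pt_name": "Nausea", "outcome": "recovered"},
        {"case_id": "C04", "pt_name": "Glaucoma", "outcome": "unknown"},
        {"case_id": "C05", "pt_name": "Glaucoma", "outcome": "recovered"},
        {"case_id": "C06", "pt_name": "Nausea", "outcome": "recovered"},
        {"case_id": "C07", "pt_name": "Rash", "outcome": "recovered"},
        {"case_id": "C08", "pt_name": "Glaucoma", "outcome": "recovered"},
        {"case_id": "C09", "pt_name": "Rash", "outcome": "recovered"},
        {"case_id": "C10", "pt_name": "Nausea", "outcome": "recovered"},
    ]
    demo_cols = ["case_id", "sex", "age", "reporter"]
    drug_cols = ["case_id", "drug_name", "route", "date", "dose", "dose_unit", "divided_doses", "role"]
    reac_cols = ["case_id", "pt_name", "outcome"]
    return (
        make_raw("DEMO", demo_rows, demo_cols),
        make_raw("DRUG", drug_rows, drug_cols),
        make_raw("REAC", reac_rows, reac_cols),
    )


@pytest.fixture
def small_synthetic_config() -> SyntheticConfig:
    return SyntheticConfig(
        n_cases=2000,
        drugs={"drugA": 0.15, "drugB": 0.10},
        events={"glaucoma": 0.02, "headache": 0.05},
        associations={("drugA", "glaucoma"): 8.0},
        seed=123,
    )
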