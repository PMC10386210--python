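"""Reading JADER-dialect tables and constructing the case-level analysis table.

JADER distributes linked DEMO (demographics), DRUG (drug records) and REAC
(adverse-event records) tables keyed by a case identification number.
Multi-valued fields arrive ";"-merged; combination-drug names are
"·"-joined.  The construction procedure implemented here is the standard
one: stack merged fields into one value per row, drop exact-duplicate rows
within each table, join the three tables on the case key, and drop every
case exposed to an indicator medication (drugs that mark prevalent disease
rather than cause it).  The result is one record per case carrying its
sex, age token, drug set and event (preferred-term) set.

The canonical dialect for this package is UTF-8 comma-separated CSV with a
header row; real JADER exports are Shift-JIS, so every reader takes an
``encoding`` argument.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from srs_signal.errors import SchemaError

logger = logging.getLogger(__name__)

#: canonical column layouts; the first column of each is the case key
DEMO_COLUMNS = ["case_id", "sex", "age", "reporter"]
DRUG_COLUMNS = ["case_id", "drug_name", "route", "date", "dose", "dose_unit", "divided_doses", "role"]
REAC_COLUMNS = ["case_id", "pt_name", "outcome"]

#: fields stacked per table, with the separators split on.  drug_name splits
#: on ";" (merged multi-drug rows) and on "·" (combination products).
DEFAULT_STACK_FIELDS: Mapping[str, Mapping[str, tuple[str, ...]]] = {
    "DRUG": {
        "drug_name": (";", "·"),
        "route": (";",),
        "date": (";",),
        "dose": (";",),
        "dose_unit": (";",),
        "divided_doses": (";",),
    },
    "DEMO": {"reporter": (";",)},
    "REAC": {},
}

#: decade tokens recognised as-is; everything else maps through AGE_SYNONYMS,
#: then falls back to "unknown" (non-empty) or missing "" (empty)
CANONICAL_AGE_TOKENS = frozenset(
    {"0s", "10s", "20s", "30s", "40s", "50s", "60s", "70s", "80s", "90s", "elderly", "adult", "unknown", ""}
)

AGE_SYNONYMS: Mapping[str, str] = {
    "child": "0s",
    "under 10": "0s",
    "teens": "10s",
    "twenties": "20s",
    "thirties": "30s",
    "forties": "40s",
    "fifties": "50s",
    "sixties": "60s",
    "seventies": "70s",
    "eighties": "80s",
    "nineties": "90s",
    "elderly person": "elderly",
    "aged": "elderly",
}

SEX_SYNONYMS: Mapping[str, str] = {
    "m": "male",
    "male": "male",
    "f": "female",
    "female": "female",
}


@dataclass
class RawTable:
    """One of the three source tables, loaded with all fields as strings.

    Rows are never dropped at read time: malformed rows (e.g. an empty case
    identification number) are retained and flagged so that the flow log can
    account for every record.
    """

    name: str
    frame: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.name not in ("DEMO", "DRUG", "REAC"):
            raise SchemaError(f"unknown table name {self.name!r}; expected DEMO, DRUG or REAC")

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class ReportCase:
    """One report after construction: demographics plus drug and event sets."""

    case_id: str
    sex: str  # "male" | "female" | "" (missing)
    age_token: str  # canonical age token, or "" (missing)
    drugs: frozenset[str]
    events: frozenset[str]


@dataclass
class FlowLog:
    """Ordered (step label, record count) pairs documenting the table flow."""

    steps: list[tuple[str, int]] = field(default_factory=list)

    def record(self, label: str, count: int) -> None:
        if count < 0:
            raise ValueError("record counts are non-negative")
        self.steps.append((label, int(count)))

    def as_dict(self) -> dict[str, int]:
        return dict(self.steps)

    def __repr__(self) -> str:
        inner = ", ".join(f"{label}={n}" for label, n in self.steps)
        return f"FlowLog({inner})"


class AnalysisTable:
    """Case-level analysis table: one row per case_id.

    Wraps a DataFrame with columns ``case_id, sex, age_token, drugs, events``
    where ``drugs``/``events`` hold frozensets.  The counting unit for every
    downstream statistic is the unique case, not the record row.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"case_id", "sex", "age_token", "drugs", "events"}
        missing = required - set(frame.columns)
        if missing:
            raise SchemaError(f"analysis table missing columns: {sorted(missing)}")
        if frame["case_id"].duplicated().any():
            raise SchemaError("analysis table has duplicate case_id values")
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def cases(self) -> list[ReportCase]:
        return [
            ReportCase(case_id=r.case_id, sex=r.sex, age_token=r.age_token, drugs=r.drugs, events=r.events)
            for r in self.frame.itertuples(index=False)
        ]

    @classmethod
    def from_cases(cls, cases: Sequence[ReportCase]) -> "AnalysisTable":
        return cls(
            pd.DataFrame(
                {
                    "case_id": [c.case_id for c in cases],
                    "sex": [c.sex for c in cases],
                    "age_token": [c.age_token for c in cases],
                    "drugs": [frozenset(c.drugs) for c in cases],
                    "events": [frozenset(c.events) for c in cases],
                }
            )
        )

    def to_csv(self, path: str | Path) -> Path:
        """Serialise with drugs/events as ";"-joined sorted lists."""
        out = self.frame.copy()
        out["drugs"] = out["drugs"].map(lambda s: ";".join(sorted(s)))
        out["events"] = out["events"].map(lambda s: ";".join(sorted(s)))
        path = Path(path)
        out.to_csv(path, index=False)
        return path

    @classmethod
    def read_csv(cls, path: str | Path) -> "AnalysisTable":
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        frame["drugs"] = frame["drugs"].map(lambda s: frozenset(v for v in s.split(";") if v))
        frame["events"] = frame["events"].map(lambda s: frozenset(v for v in s.split(";") if v))
        return cls(frame)


def normalize_name(raw: str, synonyms: Mapping[str, str] | None = None) -> str:
    """Normalise a drug or PT name: trim, case-fold, apply a synonym map.

    The synonym map is consulted after trimming/case-folding, with
    case-folded keys.  Controlled-vocabulary matching downstream is exact
    string equality on the normalised form.
    """
    name = " ".join(raw.strip().casefold().split())
    if synonyms:
        folded = {" ".join(k.strip().casefold().split()): v for k, v in synonyms.items()}
        if name in folded:
            name = " ".join(folded[name].strip().casefold().split())
    return name


def normalize_age(raw: str) -> str:
    """Map a raw age string to a canonical decade token.

    Canonical tokens pass through; configured spellings map via
    ``AGE_SYNONYMS``; any other non-empty value becomes ``"unknown"``;
    empty stays empty (missing).
    """
    value = raw.strip().casefold()
    if value in CANONICAL_AGE_TOKENS:
        return value
    return AGE_SYNONYMS.get(value, "unknown")


def normalize_sex(raw: str) -> str:
    value = raw.strip().casefold()
    return SEX_SYNONYMS.get(value, "")


def _read_table(path: str | Path, name: str, columns: Sequence[str], encoding: str) -> RawTable:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{name} file not found: {path}")
    frame = pd.read_csv(path, dtype=str, keep_default_na=False, encoding=encoding)
    if "case_id" not in frame.columns:
        raise SchemaError(f"{name} file {path} has no 'case_id' column")
    table = RawTable(name=name, frame=frame)
    missing_cols = [c for c in columns if c not in frame.columns]
    if missing_cols:
        msg = f"{name}: missing optional columns {missing_cols}; filled with empty strings"
        table.warnings.append(msg)
        warnings.warn(msg, stacklevel=3)
        for c in missing_cols:
            frame[c] = ""
    empty_key = frame["case_id"].str.strip() == ""
    if empty_key.any():
        msg = f"{name}: {int(empty_key.sum())} row(s) with empty case_id retained but flagged"
        table.warnings.append(msg)
        warnings.warn(msg, stacklevel=3)
    return table


def read_demo(path: str | Path, encoding: str = "utf-8") -> RawTable:
    """Read a DEMO table (case_id, sex, age, reporter)."""
    return _read_table(path, "DEMO", DEMO_COLUMNS, encoding)


def read_drug(path: str | Path, encoding: str = "utf-8") -> RawTable:
    """Read a DRUG table (case_id, drug_name, route, ... , role)."""
    return _read_table(path, "DRUG", DRUG_COLUMNS, encoding)


def read_reac(path: str | Path, encoding: str = "utf-8") -> RawTable:
    """Read a REAC table (case_id, pt_name, outcome)."""
    return _read_table(path, "REAC", REAC_COLUMNS, encoding)


def _split_field(frame: pd.DataFrame, fieldname: str, separators: Iterable[str]) -> pd.DataFrame:
    col = frame[fieldname].astype(str)
    for sep in separators:
        col = col.str.replace(sep, "\x00", regex=False)
    parts = col.str.split("\x00")
    out = frame.copy()
    out[fieldname] = parts
    out = out.explode(fieldname, ignore_index=True)
    out[fieldname] = out[fieldname].fillna("")
    return out


def stack_semicolon_fields(
    table: RawTable,
    fields: Mapping[str, tuple[str, ...]] | Sequence[str] | None = None,
) -> RawTable:
    """Stack ";"-merged fields: one row per atomic value.

    A row whose listed field holds k separator-joined values becomes k rows,
    identical except that the field carries one value each; row order is
    preserved.  Fields are stacked sequentially, so two merged fields on one
    row expand to their cartesian product.  ``fields`` may be a list of
    field names (split on ";") or a mapping field -> separators; by default
    the table's entry in ``DEFAULT_STACK_FIELDS`` is used, which also splits
    combination-drug names on the "·" interpunct.
    """
    if fields is None:
        spec: Mapping[str, tuple[str, ...]] = DEFAULT_STACK_FIELDS[table.name]
    elif isinstance(fields, Mapping):
        spec = fields
    else:
        spec = {f: (";",) for f in fields}
    frame = table.frame
    for fieldname, seps in spec.items():
        if fieldname not in frame.columns:
            raise SchemaError(f"{table.name}: cannot stack missing field {fieldname!r}")
        frame = _split_field(frame, fieldname, seps)
    return RawTable(name=table.name, frame=frame, warnings=list(table.warnings))


def build_analysis_table(
    demo: RawTable,
    drug: RawTable,
    reac: RawTable,
    exclusion_drugs: Iterable[str] = (),
    drug_synonyms: Mapping[str, str] | None = None,
    log: FlowLog | None = None,
    stack: bool = True,
) -> tuple[AnalysisTable, FlowLog]:
    """Run the full construction: stack, dedup, join, exclude.

    Steps, each recorded in the flow log:

    1. raw record counts of the three tables;
    2. stacking of ";"-merged fields (skipped when ``stack=False`` for
       pre-stacked input);
    3. removal of exact-duplicate rows within each table;
    4. inner join on ``case_id`` — a case needs a DEMO row, at least one
       DRUG row and at least one REAC row to be analysable;
    5. exclusion of every case whose drug set intersects
       ``exclusion_drugs`` (indicator medications marking prevalent
       disease).

    Drug and PT names are normalised (trim, case-fold, synonym map) before
    set construction, so exclusion matching is on normalised names.
    Returns the case-level table and the populated flow log.
    """
    log = log or FlowLog()
    for t in (drug, reac, demo):
        log.record(f"raw {t.name}", len(t))

    if stack:
        demo = stack_semicolon_fields(demo)
        drug = stack_semicolon_fields(drug)
        reac = stack_semicolon_fields(reac)
    log.record("after stacking", len(demo) + len(drug) + len(reac))

    frames = {}
    for t in (demo, drug, reac):
        deduped = t.frame.drop_duplicates(ignore_index=True)
        frames[t.name] = deduped
    log.record("after dedup", sum(len(f) for f in frames.values()))

    demo_f = frames["DEMO"][frames["DEMO"]["case_id"].str.strip() != ""]
    drug_f = frames["DRUG"][frames["DRUG"]["case_id"].str.strip() != ""]
    reac_f = frames["REAC"][frames["REAC"]["case_id"].str.strip() != ""]

    drug_f = drug_f.assign(drug_name=[normalize_name(v, drug_synonyms) for v in drug_f["drug_name"]])
    reac_f = reac_f.assign(pt_name=[normalize_name(v) for v in reac_f["pt_name"]])

    drug_sets = drug_f[drug_f["drug_name"] != ""].groupby("case_id")["drug_name"].agg(frozenset)
    event_sets = reac_f[reac_f["pt_name"] != ""].groupby("case_id")["pt_name"].agg(frozenset)

    # one DEMO record per case; byte-identical duplicates are already gone,
    # conflicting duplicates keep the first occurrence
    demo_one = demo_f.drop_duplicates(subset="case_id", keep="first").set_index("case_id")

    joined_ids = demo_one.index.intersection(drug_sets.index).intersection(event_sets.index)
    joined = pd.DataFrame(
        {
            "case_id": joined_ids,
            "sex": [normalize_sex(v) for v in demo_one.loc[joined_ids, "sex"]],
            "age_token": [normalize_age(v) for v in demo_one.loc[joined_ids, "age"]],
            "drugs": drug_sets.loc[joined_ids].to_numpy(),
            "events": event_sets.loc[joined_ids].to_numpy(),
        }
    )
    log.record("after join", len(joined))
    if len(joined) == 0:
        warnings.warn("join produced zero cases", stacklevel=2)

    excl = frozenset(normalize_name(d, drug_synonyms) for d in exclusion_drugs)
    if excl:
        keep = joined["drugs"].map(lambda s: not (s & excl))
        joined = joined[keep].reset_index(drop=True)
    log.record("after exclusion", len(joined))

    return AnalysisTable(joined), log
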