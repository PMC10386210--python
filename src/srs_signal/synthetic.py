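"""Synthetic JADER-dialect database with known drug-event association strengths.

The real database is a download-only resource, so every downstream stage is
exercised on a generated stand-in that shares its shape: three case-linked
tables (DEMO/DRUG/REAC), ";"-merged multi-value fields, duplicated rows,
decade-coded age strings with "adult"/"unknown" categories, and missing
sex/age as empty strings.

Association model
-----------------
Exposure of each case to each drug is an independent Bernoulli draw with
the drug's marginal usage probability.  Each PT is then reported with
probability given by the PT's baseline odds multiplied by the product of
the association multipliers of the case's exposed drugs::

    odds(case, pt) = baseline_odds(pt) * prod over exposed drugs of m(drug, pt)
    P(report)      = odds / (1 + odds)

(the logistic of baseline log-odds plus the sum of log multipliers; the
odds form also handles m = 0 exactly).  At low baseline rates the true
reporting odds ratio of a (drug, PT) pair approximately equals its
multiplier, which makes the injected truth directly comparable to the
estimator.

Mess (duplicates and semicolon merges) is injected last, from an RNG stream
independent of the core draws, so the mess-free and messy databases of one
seed describe the same cases — the cleaning stage must recover the same
analysis table from either.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from srs_signal.errors import ConfigError
from srs_signal.io import DEMO_COLUMNS, DRUG_COLUMNS, REAC_COLUMNS, RawTable

#: demographics emulating a spontaneous-reporting population: slight female
#: excess, age mass in the 60s-80s, a few percent of coarse ("adult",
#: "elderly", "unknown") and missing entries
DEFAULT_SEX_DIST: Mapping[str, float] = {"male": 0.46, "female": 0.50, "": 0.04}
DEFAULT_AGE_DIST: Mapping[str, float] = {
    "10s": 0.02, "20s": 0.04, "30s": 0.08, "40s": 0.10, "50s": 0.13,
    "60s": 0.18, "70s": 0.20, "80s": 0.12, "90s": 0.03,
    "elderly": 0.02, "adult": 0.04, "unknown": 0.02, "": 0.02,
}
#: duplicate-row and semicolon-merge rates; real JADER exports carry both
DEFAULT_DUPLICATE_RATE = 0.05
DEFAULT_MERGE_RATE = 0.5

#: every spontaneous report names at least one drug and one reaction, so each
#: case also carries one background medication and one background event drawn
#: from these pools (outside any study drug set / event term set); without
#: them the key join would silently condition on exposure and event status
#: and bias every downstream ROR
DEFAULT_BACKGROUND_DRUGS = ("concomitant medication 1", "concomitant medication 2", "concomitant medication 3")
DEFAULT_BACKGROUND_PTS = ("drug ineffective", "nausea", "rash")

_ROUTES = ("oral", "topical", "injection", "inhalation", "ophthalmic")
_REPORTERS = ("physician", "pharmacist", "manufacturer")
_OUTCOMES = ("recovered", "recovering", "not recovered", "unknown")


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ConfigError(f"{name} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters, including the injected ground truth.

    ``drugs`` maps drug name -> marginal usage probability; ``events`` maps
    PT name -> baseline reporting probability; ``associations`` maps
    (drug, PT) -> odds multiplier (1.0 = no association, 0 = event
    impossible when exposed).
    """

    n_cases: int
    drugs: Mapping[str, float]
    events: Mapping[str, float]
    associations: Mapping[tuple[str, str], float] = field(default_factory=dict)
    sex_dist: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_SEX_DIST))
    age_dist: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_AGE_DIST))
    duplicate_rate: float = DEFAULT_DUPLICATE_RATE
    merge_rate: float = DEFAULT_MERGE_RATE
    background_drugs: tuple[str, ...] = DEFAULT_BACKGROUND_DRUGS
    background_pts: tuple[str, ...] = DEFAULT_BACKGROUND_PTS
    seed: int = 0

    def validate(self) -> None:
        if not isinstance(self.n_cases, (int, np.integer)) or self.n_cases < 1:
            raise ConfigError(f"n_cases must be a positive integer, got {self.n_cases!r}")
        if not self.drugs:
            raise ConfigError("drugs must be non-empty")
        if not self.events:
            raise ConfigError("events must be non-empty")
        for name, p in self.drugs.items():
            _check_prob(f"drugs[{name!r}]", p)
        for name, p in self.events.items():
            _check_prob(f"events[{name!r}]", p)
        for (drug, pt), m in self.associations.items():
            if drug not in self.drugs:
                raise ConfigError(f"associations key ({drug!r}, {pt!r}): undeclared drug")
            if pt not in self.events:
                raise ConfigError(f"associations key ({drug!r}, {pt!r}): undeclared PT")
            if m < 0:
                raise ConfigError(f"associations[({drug!r}, {pt!r})] must be >= 0, got {m}")
        for dist_name, dist in (("sex_dist", self.sex_dist), ("age_dist", self.age_dist)):
            for token, p in dist.items():
                _check_prob(f"{dist_name}[{token!r}]", p)
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ConfigError(f"{dist_name} probabilities must sum to 1")
        _check_prob("duplicate_rate", self.duplicate_rate)
        _check_prob("merge_rate", self.merge_rate)
        if not self.background_drugs or not self.background_pts:
            raise ConfigError("background_drugs and background_pts must be non-empty")
        if set(self.background_drugs) & set(self.drugs):
            raise ConfigError("background_drugs must not collide with declared drugs")
        if set(self.background_pts) & set(self.events):
            raise ConfigError("background_pts must not collide with declared PTs")

    @classmethod
    def from_dict(cls, doc: Mapping) -> "SyntheticConfig":
        assoc = {}
        for entry in doc.get("associations", []):
            assoc[(entry["drug"], entry["pt"])] = float(entry["multiplier"])
        kwargs = dict(
            n_cases=int(doc["n_cases"]),
            drugs={str(k): float(v) for k, v in doc["drugs"].items()},
            events={str(k): float(v) for k, v in doc["events"].items()},
            associations=assoc,
            seed=int(doc.get("seed", 0)),
        )
        if "sex_dist" in doc:
            kwargs["sex_dist"] = {str(k): float(v) for k, v in doc["sex_dist"].items()}
        if "age_dist" in doc:
            kwargs["age_dist"] = {str(k): float(v) for k, v in doc["age_dist"].items()}
        if "duplicate_rate" in doc:
            kwargs["duplicate_rate"] = float(doc["duplicate_rate"])
        if "merge_rate" in doc:
            kwargs["merge_rate"] = float(doc["merge_rate"])
        if "background_drugs" in doc:
            kwargs["background_drugs"] = tuple(str(d) for d in doc["background_drugs"])
        if "background_pts" in doc:
            kwargs["background_pts"] = tuple(str(p) for p in doc["background_pts"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth per (drug, PT): injected multiplier and realized counts."""

    multipliers: Mapping[tuple[str, str], float]
    n_exposed: Mapping[str, int]  # cases exposed to each drug
    n_event: Mapping[str, int]  # cases reporting each PT
    n_exposed_event: Mapping[tuple[str, str], int]  # joint counts
    n_cases: int

    def as_dict(self) -> dict:
        return {
            "n_cases": self.n_cases,
            "n_exposed": dict(self.n_exposed),
            "n_event": dict(self.n_event),
            "pairs": [
                {
                    "drug": d,
                    "pt": p,
                    "multiplier": self.multipliers.get((d, p), 1.0),
                    "n_exposed_event": self.n_exposed_event[(d, p)],
                }
                for (d, p) in sorted(self.n_exposed_event)
            ],
        }


def _sample_tokens(rng: np.random.Generator, dist: Mapping[str, float], n: int) -> np.ndarray:
    tokens = list(dist.keys())
    probs = np.array([dist[t] for t in tokens], dtype=float)
    probs = probs / probs.sum()
    return rng.choice(np.array(tokens, dtype=object), size=n, p=probs)


def generate_database(
    config: SyntheticConfig,
) -> tuple[RawTable, RawTable, RawTable, SyntheticTruth]:
    """Generate (demo, drug, reac) RawTables plus the ground truth.

    Before mess injection each case has exactly one DEMO row, one DRUG row
    per exposed drug and one REAC row per reported PT (cases without any
    exposure or any event get none, mirroring a case absent from those
    tables).  Identical configs (including seed) give identical output.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    core_seq, mess_seq = root.spawn(2)
    rng = np.random.default_rng(core_seq)

    n = config.n_cases
    drug_names = list(config.drugs.keys())
    pt_names = list(config.events.keys())
    case_ids = np.array([f"C{i:08d}" for i in range(1, n + 1)], dtype=object)

    # exposures: n x D independent Bernoulli
    drug_probs = np.array([config.drugs[d] for d in drug_names])
    exposed = rng.random((n, len(drug_names))) < drug_probs[None, :]

    # per-(case, pt) odds: baseline odds times multipliers of exposed drugs
    base = np.array([config.events[p] for p in pt_names])
    with np.errstate(divide="ignore"):
        odds = np.broadcast_to(np.where(base < 1.0, base / (1.0 - base), np.inf), (n, len(pt_names))).copy()
    for (drug, pt), m in config.associations.items():
        j = pt_names.index(pt)
        col = exposed[:, drug_names.index(drug)]
        odds[col, j] *= m
    probs = np.where(np.isinf(odds), 1.0, odds / (1.0 + odds))
    events = rng.random((n, len(pt_names))) < probs

    sex = _sample_tokens(rng, config.sex_dist, n)
    age = _sample_tokens(rng, config.age_dist, n)
    reporter = rng.choice(np.array(_REPORTERS, dtype=object), size=n)

    demo = pd.DataFrame(
        {"case_id": case_ids, "sex": sex, "age": age, "reporter": reporter},
        columns=DEMO_COLUMNS,
    )

    # one background medication and one background event per case keep every
    # case present in all three tables (a report always names a drug and a
    # reaction); they sit outside any study drug panel or event term set
    bg_drug = rng.choice(np.array(config.background_drugs, dtype=object), size=n)
    bg_pt = rng.choice(np.array(config.background_pts, dtype=object), size=n)

    case_idx, drug_idx = np.nonzero(exposed)
    study_drug_rows = pd.DataFrame(
        {
            "case_id": case_ids[case_idx],
            "drug_name": np.array(drug_names, dtype=object)[drug_idx],
            "route": rng.choice(np.array(_ROUTES, dtype=object), size=len(case_idx)),
            "date": "",
            "dose": "",
            "dose_unit": "",
            "divided_doses": "",
            "role": "suspected",
        },
        columns=DRUG_COLUMNS,
    )
    bg_drug_rows = pd.DataFrame(
        {
            "case_id": case_ids,
            "drug_name": bg_drug,
            "route": rng.choice(np.array(_ROUTES, dtype=object), size=n),
            "date": "",
            "dose": "",
            "dose_unit": "",
            "divided_doses": "",
            "role": "concomitant",
        },
        columns=DRUG_COLUMNS,
    )
    drug_frame = (
        pd.concat([study_drug_rows, bg_drug_rows], ignore_index=True)
        .sort_values("case_id", kind="stable")
        .reset_index(drop=True)
    )

    case_idx_e, pt_idx = np.nonzero(events)
    study_reac_rows = pd.DataFrame(
        {
            "case_id": case_ids[case_idx_e],
            "pt_name": np.array(pt_names, dtype=object)[pt_idx],
            "outcome": rng.choice(np.array(_OUTCOMES, dtype=object), size=len(case_idx_e)),
        },
        columns=REAC_COLUMNS,
    )
    bg_reac_rows = pd.DataFrame(
        {
            "case_id": case_ids,
            "pt_name": bg_pt,
            "outcome": rng.choice(np.array(_OUTCOMES, dtype=object), size=n),
        },
        columns=REAC_COLUMNS,
    )
    reac = (
        pd.concat([study_reac_rows, bg_reac_rows], ignore_index=True)
        .sort_values("case_id", kind="stable")
        .reset_index(drop=True)
    )

    truth = SyntheticTruth(
        multipliers=dict(config.associations),
        n_exposed={d: int(exposed[:, i].sum()) for i, d in enumerate(drug_names)},
        n_event={p: int(events[:, j].sum()) for j, p in enumerate(pt_names)},
        n_exposed_event={
            (d, p): int((exposed[:, i] & events[:, j]).sum())
            for i, d in enumerate(drug_names)
            for j, p in enumerate(pt_names)
        },
        n_cases=n,
    )

    mess_rng = np.random.default_rng(mess_seq)
    drug_frame = _merge_case_rows(drug_frame, config.merge_rate, mess_rng, merge_cols=["drug_name", "route"])
    demo = _inject_duplicates(demo, config.duplicate_rate, mess_rng)
    drug_frame = _inject_duplicates(drug_frame, config.duplicate_rate, mess_rng)
    reac = _inject_duplicates(reac, config.duplicate_rate, mess_rng)

    return (
        RawTable("DEMO", demo.reset_index(drop=True)),
        RawTable("DRUG", drug_frame.reset_index(drop=True)),
        RawTable("REAC", reac.reset_index(drop=True)),
        truth,
    )


def _merge_case_rows(
    frame: pd.DataFrame, rate: float, rng: np.random.Generator, merge_cols: Sequence[str]
) -> pd.DataFrame:
    """Collapse a case's multi-row block into one ";"-joined row, per case."""
    if rate <= 0.0 or frame.empty:
        return frame
    counts = frame["case_id"].value_counts()
    multi = np.sort(counts[counts > 1].index.to_numpy())  # sorted: draw order is reproducible
    picked = multi[rng.random(len(multi)) < rate]
    if len(picked) == 0:
        return frame
    mask = frame["case_id"].isin(picked)
    agg = {
        col: (lambda s: ";".join(s.astype(str))) if col in merge_cols else "first"
        for col in frame.columns
        if col != "case_id"
    }
    merged = frame[mask].groupby("case_id", sort=False).agg(agg).reset_index()[list(frame.columns)]
    return pd.concat([frame[~mask], merged], ignore_index=True)


def _inject_duplicates(frame: pd.DataFrame, rate: float, rng: np.random.Generator) -> pd.DataFrame:
    """Append exact copies of randomly chosen rows (expected count = rate * n)."""
    if rate <= 0.0 or frame.empty:
        return frame
    n_dup = rng.binomial(len(frame), rate)
    if n_dup == 0:
        return frame
    picks = rng.integers(0, len(frame), size=n_dup)
    return pd.concat([frame, frame.iloc[picks]], ignore_index=True)


def write_jader_dialect(
    tables: tuple[RawTable, RawTable, RawTable],
    out_dir: str | Path,
    truth: SyntheticTruth | None = None,
) -> dict[str, Path]:
    """Write DEMO.csv / DRUG.csv / REAC.csv (+ truth.json) under ``out_dir``.

    The files round-trip through :func:`srs_signal.io.read_demo` and
    friends.  Returns the written paths keyed by table name.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for table in tables:
        path = out_dir / f"{table.name}.csv"
        table.frame.to_csv(path, index=False)
        paths[table.name] = path
    if truth is not None:
        path = out_dir / "truth.json"
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(truth.as_dict(), fh, indent=2)
        paths["truth"] = path
    return paths
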