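"""Event term sets (MedDRA preferred terms) and drug panels as versioned config.

The event definition for a disproportionality screen is a plain set of
preferred-term (PT) names — typically the narrow scope of a standardized
MedDRA query with irrelevant terms (congenital, traumatic, postoperative,
surgical) removed.  PTs arrive pre-coded; no MedDRA hierarchy traversal
happens here.  Matching is exact string equality after the same
normalisation applied to drug names (trim, case-fold, synonyms), because
PTs are controlled vocabulary.

Shipped defaults (under ``data/``): the 32-PT glaucoma event set and the
47-drug corticosteroid panel used in the published JADER 2004–2022
corticosteroid–glaucoma screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from srs_signal.errors import ValidationError
from srs_signal.io import ReportCase, normalize_name


@dataclass(frozen=True)
class EventTermSet:
    """A named set of preferred terms defining one adverse event of interest."""

    name: str
    pts: frozenset[str]
    provenance: str = ""
    synonyms: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.pts:
            raise ValidationError(f"term set {self.name!r}: empty PT set")

    def normalize(self, pt: str) -> str:
        return normalize_name(pt, self.synonyms)

    def __contains__(self, pt: str) -> bool:
        return self.normalize(pt) in self.pts

    def __len__(self) -> int:
        return len(self.pts)


@dataclass(frozen=True)
class DrugPanel:
    """An ordered panel of normalised drug names to screen."""

    drugs: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.drugs)) != len(self.drugs):
            dupes = sorted({d for d in self.drugs if list(self.drugs).count(d) > 1})
            raise ValidationError(f"drug panel has duplicate entries: {dupes}")
        if any(not d for d in self.drugs):
            raise ValidationError("drug panel has empty entries")

    def __len__(self) -> int:
        return len(self.drugs)

    def __iter__(self):
        return iter(self.drugs)


def _load_yaml(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValidationError(f"{path}: expected a YAML mapping")
    return doc


def load_term_set(path: str | Path) -> EventTermSet:
    """Load an event term set from YAML ({name, provenance, pts, synonyms}).

    PT names and synonym keys/values are normalised on load.  Duplicate or
    empty entries raise :class:`ValidationError`.
    """
    doc = _load_yaml(path)
    raw_pts = doc.get("pts", [])
    if not isinstance(raw_pts, list) or not raw_pts:
        raise ValidationError(f"{path}: 'pts' must be a non-empty list")
    pts = [normalize_name(str(p)) for p in raw_pts]
    if any(not p for p in pts):
        raise ValidationError(f"{path}: empty PT entry")
    if len(set(pts)) != len(pts):
        dupes = sorted({p for p in pts if pts.count(p) > 1})
        raise ValidationError(f"{path}: duplicate PT entries: {dupes}")
    synonyms = {str(k): str(v) for k, v in (doc.get("synonyms") or {}).items()}
    return EventTermSet(
        name=str(doc.get("name", Path(path).stem)),
        pts=frozenset(pts),
        provenance=str(doc.get("provenance", "")),
        synonyms=synonyms,
    )


def load_panel(path: str | Path) -> DrugPanel:
    """Load a drug panel from YAML ({name, drugs: [...]})."""
    doc = _load_yaml(path)
    raw = doc.get("drugs", [])
    if not isinstance(raw, list) or not raw:
        raise ValidationError(f"{path}: 'drugs' must be a non-empty list")
    return DrugPanel(drugs=tuple(normalize_name(str(d)) for d in raw))


def case_has_event(case: ReportCase, terms: EventTermSet) -> bool:
    """True iff the case's event set intersects the term set.

    Case events are assumed already normalised (the analysis-table builder
    normalises PT names); term-set synonyms are additionally applied so a
    raw spelling still matches.
    """
    if case.events & terms.pts:
        return True
    return any(terms.normalize(e) in terms.pts for e in case.events)


def _data_path(filename: str):
    return resources.files("srs_signal") / "data" / filename


def default_glaucoma_terms() -> EventTermSet:
    """The shipped 32-PT glaucoma event set (SMQ narrow scope, filtered)."""
    with resources.as_file(_data_path("glaucoma_terms.yaml")) as p:
        return load_term_set(p)


def default_corticosteroid_panel() -> DrugPanel:
    """The shipped 47-drug corticosteroid panel."""
    with resources.as_file(_data_path("corticosteroid_panel.yaml")) as p:
        return load_panel(p)
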