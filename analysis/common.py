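"""Shared world definition and paths for the numbered analysis scripts.

The study world emulates a corticosteroid-glaucoma screen at desk scale:
20,000 reports, five corticosteroids plus one null comparator, three
glaucoma preferred terms from the shipped event set, with strong injected
associations for the periocular corticosteroids and a weak one for
prednisolone.  Seeded so every script is reproducible.
"""

from pathlib import Path

from srs_signal.synthetic import SyntheticConfig

REPO_ROOT = Path(__file__).resolve().parent.parent
SCRATCH = REPO_ROOT / "scratch" / "analysis"
RESULTS = REPO_ROOT / "results"
DB_DIR = SCRATCH / "db"
TABLE_CSV = SCRATCH / "analysis_table.csv"

SEED = 2024

WORLD = SyntheticConfig(
    n_cases=20_000,
    drugs={
        "Triamcinolone acetonide": 0.02,
        "Betamethasone sodium phosphate": 0.03,
        "Fluorometholone": 0.01,
        "Prednisolone": 0.15,
        "Dexamethasone": 0.08,
        "Aspirin": 0.20,
    },
    events={
        "Glaucoma": 0.004,
        "Intraocular pressure increased": 0.002,
        "Ocular hypertension": 0.001,
    },
    associations={
        ("Triamcinolone acetonide", "Glaucoma"): 20.0,
        ("Triamcinolone acetonide", "Intraocular pressure increased"): 25.0,
        ("Triamcinolone acetonide", "Ocular hypertension"): 15.0,
        ("Betamethasone sodium phosphate", "Glaucoma"): 8.0,
        ("Betamethasone sodium phosphate", "Intraocular pressure increased"): 10.0,
        ("Fluorometholone", "Glaucoma"): 12.0,
        ("Prednisolone", "Glaucoma"): 2.0,
    },
    seed=SEED,
)


def ensure_dirs() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
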