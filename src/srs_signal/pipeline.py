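"""End-to-end orchestration: build -> screen -> demographics -> structure.

One :class:`RunConfig` (YAML-loadable) drives a full reproducible run over
either real JADER-dialect files or a synthetic database generated in-run
from a seed.  Every stage writes its outputs under
``out_dir/{build,screen,demographics,structure}/`` and the run closes with
a ``manifest.json`` echoing the config, the record-flow log and a checksum
for every output file.  Identical config + seed gives identical numeric
outputs.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from srs_signal import demographics as demo_mod
from srs_signal import dispro, structure, synthetic
from srs_signal.datasets import (
    DEMOGRAPHIC_TABLES,
    PUBLISHED_FILTERED_PT_COUNT,
    PUBLISHED_SIGNAL_COUNT,
    published_pt_report_counts,
    published_screen,
)
from srs_signal.errors import ConfigError, StageError
from srs_signal.io import FlowLog, build_analysis_table, read_demo, read_drug, read_reac
from srs_signal.plots import render_biplot, render_dendrogram, render_volcano, save_frame
from srs_signal.terms import (
    default_corticosteroid_panel,
    default_glaucoma_terms,
    load_panel,
    load_term_set,
)

__version__ = "0.1.0"


@dataclass
class RunConfig:
    """Everything one pipeline run needs; loadable from a single YAML file."""

    out_dir: Path
    demo_path: Path | None = None
    drug_path: Path | None = None
    reac_path: Path | None = None
    synthetic: synthetic.SyntheticConfig | None = None
    terms_path: Path | None = None  # None -> shipped glaucoma set
    panel_path: Path | None = None  # None -> shipped corticosteroid panel
    exclusion_path: Path | None = None  # newline-separated drug names
    alpha: float = dispro.DEFAULT_ALPHA
    drug_min_reports: int = structure.DRUG_MIN_REPORTS
    drug_min_event_reports: int = structure.DRUG_MIN_EVENT_REPORTS
    pt_min_reports: int = structure.PT_MIN_REPORTS
    k: int = 3
    seed: int = 0
    encoding: str = "utf-8"
    make_plots: bool = True

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        for name in ("drug_min_reports", "drug_min_event_reports", "pt_min_reports"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        has_files = all(p is not None for p in (self.demo_path, self.drug_path, self.reac_path))
        if not has_files and self.synthetic is None:
            raise ConfigError("either demo/drug/reac paths or a synthetic section is required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, Mapping):
            raise ConfigError(f"{path}: expected a YAML mapping")
        kwargs: dict = {"out_dir": Path(doc["out_dir"])}
        for key in ("demo_path", "drug_path", "reac_path", "terms_path", "panel_path", "exclusion_path"):
            if doc.get(key):
                kwargs[key] = Path(doc[key])
        for key in ("alpha", "drug_min_reports", "drug_min_event_reports", "pt_min_reports",
                    "k", "seed", "encoding", "make_plots"):
            if key in doc:
                kwargs[key] = doc[key]
        if "synthetic" in doc:
            syn = dict(doc["synthetic"])
            syn.setdefault("seed", kwargs.get("seed", 0))
            kwargs["synthetic"] = synthetic.SyntheticConfig.from_dict(syn)
        return cls(**kwargs)

    def echo(self) -> dict:
        doc = dataclasses.asdict(self)
        doc = {k: (str(v) if isinstance(v, Path) else v) for k, v in doc.items()}
        if self.synthetic is not None:
            syn = dataclasses.asdict(self.synthetic)
            syn["associations"] = [
                {"drug": d, "pt": p, "multiplier": m} for (d, p), m in self.synthetic.associations.items()
            ]
            doc["synthetic"] = syn
        return doc


@dataclass
class RunManifest:
    """Run metadata: config echo, version, timestamps, flow log, files, checksums."""

    config: dict
    version: str
    started: str
    finished: str
    flow_log: dict
    outputs: dict[str, str] = field(default_factory=dict)  # relpath -> sha256

    def write(self, path: Path) -> Path:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)
        return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_exclusions(path: Path | None) -> list[str]:
    if path is None:
        return []
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip() and not line.startswith("#")]


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages; on failure raise :class:`StageError` naming the stage.

    Outputs already written before a failure are retained, alongside a
    ``FAILED`` marker file naming the failed stage.
    """
    config.validate()
    started = datetime.datetime.now(datetime.timezone.utc).isoformat()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    def register(path: Path) -> None:
        outputs[str(path.relative_to(out_dir))] = _sha256(path)

    stage = "build"
    try:
        build_dir = out_dir / "build"
        build_dir.mkdir(exist_ok=True)
        if config.synthetic is not None:
            demo_t, drug_t, reac_t, truth = synthetic.generate_database(config.synthetic)
            paths = synthetic.write_jader_dialect((demo_t, drug_t, reac_t), build_dir / "input", truth)
            for p in paths.values():
                register(p)
        else:
            demo_t = read_demo(config.demo_path, encoding=config.encoding)
            drug_t = read_drug(config.drug_path, encoding=config.encoding)
            reac_t = read_reac(config.reac_path, encoding=config.encoding)
        exclusions = _load_exclusions(config.exclusion_path)
        table, flow = build_analysis_table(demo_t, drug_t, reac_t, exclusion_drugs=exclusions)
        register(table.to_csv(build_dir / "analysis_table.csv"))
        with open(build_dir / "flow_log.json", "w", encoding="utf-8") as fh:
            json.dump(flow.as_dict(), fh, indent=2)
        register(build_dir / "flow_log.json")

        stage = "screen"
        screen_dir = out_dir / "screen"
        screen_dir.mkdir(exist_ok=True)
        terms = load_term_set(config.terms_path) if config.terms_path else default_glaucoma_terms()
        if config.panel_path:
            panel = load_panel(config.panel_path)
        elif config.synthetic is not None:
            panel = _panel_from_synthetic(config.synthetic)
        else:
            panel = default_corticosteroid_panel()
        results = dispro.screen_panel(table, panel, terms, alpha=config.alpha)
        register(save_frame(dispro.results_to_frame(results), screen_dir / "screen_results.csv"))
        volcano = dispro.volcano_data(results, alpha=config.alpha)
        register(save_frame(volcano, screen_dir / "volcano.csv"))
        if config.make_plots:
            register(render_volcano(results, screen_dir / "volcano.png", alpha=config.alpha))

        stage = "demographics"
        demo_dir = out_dir / "demographics"
        demo_dir.mkdir(exist_ok=True)
        comparisons = demo_mod.compare_demographics(table, terms)
        register(save_frame(demo_mod.comparisons_to_frame(comparisons), demo_dir / "demographics.csv"))

        stage = "structure"
        struct_dir = out_dir / "structure"
        struct_dir.mkdir(exist_ok=True)
        try:
            matrix = structure.filter_and_build_matrix(
                table, panel, terms,
                drug_min_reports=config.drug_min_reports,
                drug_min_event_reports=config.drug_min_event_reports,
                pt_min_reports=config.pt_min_reports,
            )
        except Exception as exc:  # empty matrix is a data property, not a crash
            with open(struct_dir / "SKIPPED.txt", "w", encoding="utf-8") as fh:
                fh.write(f"structure stage skipped: {exc}\n")
            register(struct_dir / "SKIPPED.txt")
            matrix = None
        if matrix is not None:
            register(save_frame(matrix.values, struct_dir / "lnror_matrix.csv", index=True))
            k = min(config.k, len(matrix.values))
            clusters = structure.ward_cluster(matrix, k=k)
            register(save_frame(clusters.labels.rename_axis("drug").reset_index(), struct_dir / "cluster_labels.csv"))
            register(save_frame(
                pd.DataFrame(clusters.linkage, columns=["child_a", "child_b", "height", "size"]),
                struct_dir / "linkage.csv",
            ))
            pca = structure.covariance_pca(matrix)
            register(save_frame(pca.scores, struct_dir / "pca_scores.csv", index=True))
            register(save_frame(pca.loadings, struct_dir / "pca_loadings.csv", index=True))
            register(save_frame(
                pca.contributions.rename_axis("component").reset_index(), struct_dir / "pca_contributions.csv",
            ))
            if config.make_plots:
                register(render_dendrogram(matrix, clusters, struct_dir / "dendrogram.png"))
                register(render_biplot(pca, clusters, struct_dir / "pca_biplot.png"))
    except Exception as exc:
        marker = out_dir / "FAILED"
        with open(marker, "w", encoding="utf-8") as fh:
            fh.write(f"stage: {stage}\nerror: {exc}\n")
        raise StageError(stage, str(exc)) from exc

    manifest = RunManifest(
        config=config.echo(),
        version=__version__,
        started=started,
        finished=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        flow_log=flow.as_dict(),
        outputs=outputs,
    )
    manifest.write(out_dir / "manifest.json")
    return manifest


def _panel_from_synthetic(cfg: synthetic.SyntheticConfig):
    from srs_signal.io import normalize_name
    from srs_signal.terms import DrugPanel

    return DrugPanel(drugs=tuple(normalize_name(d) for d in cfg.drugs))


def selfcheck(alpha: float = 0.05) -> list[dict]:
    """Run the bundled reference checks; returns one record per check.

    Checks (all against the published screen's printed values):

    1-3. the three demographic Fisher exact p-values (+/- 0.002);
    4.   the signal criterion over the published 47-row screen -> 28;
    5.   the >=50-report PT filter over published counts -> 5 terms;
    6.   shipped glaucoma term set holds 32 PTs;
    7.   shipped corticosteroid panel holds 47 drugs.
    """
    checks: list[dict] = []

    for factor, ref in DEMOGRAPHIC_TABLES.items():
        p = dispro.fisher_exact_two_sided(ref["table"])
        checks.append(
            {
                "check": f"demographics {factor} Fisher p",
                "value": round(p, 3),
                "expected": ref["published_p"],
                "passed": abs(p - ref["published_p"]) <= 0.002,
            }
        )

    screen = published_screen()
    n_signals = dispro.count_signals(
        screen["ror"], [dispro.parse_p_string(v) for v in screen["p_value"]], alpha=alpha,
    )
    checks.append(
        {
            "check": "signal criterion on published screen",
            "value": n_signals,
            "expected": PUBLISHED_SIGNAL_COUNT,
            "passed": n_signals == PUBLISHED_SIGNAL_COUNT,
        }
    )

    passing_pts = structure.filter_pts_by_reports(published_pt_report_counts())
    checks.append(
        {
            "check": ">=50-report PT filter on published counts",
            "value": len(passing_pts),
            "expected": PUBLISHED_FILTERED_PT_COUNT,
            "passed": len(passing_pts) == PUBLISHED_FILTERED_PT_COUNT,
        }
    )

    terms = default_glaucoma_terms()
    checks.append(
        {"check": "shipped glaucoma term set size", "value": len(terms), "expected": 32, "passed": len(terms) == 32}
    )
    panel = default_corticosteroid_panel()
    checks.append(
        {"check": "shipped corticosteroid panel size", "value": len(panel), "expected": 47, "passed": len(panel) == 47}
    )
    return checks
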