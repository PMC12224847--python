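"""End-to-end pipeline: synthesize -> flag -> filter -> features -> grid search
-> community detection -> characterization -> classifier benchmark -> odds models.

Every stage writes its artifacts under the output directory and registers them
(with SHA-256 hashes) in ``manifest.json``.  The manifest carries no
timestamps, so identical configs and seeds produce byte-identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    PatientRecord,
    SynthConfig,
    cohort_to_frame,
    default_config,
    filter_cmm,
    flag_diseases,
    generate_cohort,
    read_cohort,
    write_cohort,
)
from .community import louvain, write_partition
from .epi import characterize
from .features import build_feature_matrix
from .ml import run_benchmark, stratified_split
from .network import grid_search
from .odds import fit_multinomial_or, odds_table

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "records_to_covariates"]

STAGES = (
    "synthesize",
    "flag",
    "filter",
    "features",
    "grid_search",
    "louvain",
    "characterize",
    "benchmark",
    "odds",
)

_DEFAULT_ODDS_PREDICTORS = (
    "vigorous_work",
    "moderate_work",
    "walk_bicycle",
    "vigorous_recreational",
    "moderate_recreational",
    "sedentary",
    "choline",
    "iron",
    "niacin",
    "cholesterol",
    "vitamin_b2",
    "potassium",
    "family_pir",
    "bmi",
    "age",
    "gender",
    "education",
    "marital_status",
    "smoking_100",
)

#: dummy-coding reference levels for categorical odds-model predictors
ODDS_REFERENCE_LEVELS = {
    "gender": "male",
    "education": "college_graduate",
    "marital_status": "living_with_partner",
    "smoking_100": "1",
}


@dataclass
class PipelineConfig:
    """Fully serializable run configuration."""

    input_path: str | None = None          # cohort CSV; mutually exclusive with synth
    synth: SynthConfig | None = None       # generator config (default template if both unset)
    n_patients: int = 300
    seed: int = 0
    feature_spec: list[str] | None = None
    include_diseases_in_graph: bool = True
    thresholds: tuple[float, ...] = (0.3, 0.35, 0.4, 0.45, 0.5, 0.55, 0.6, 0.65, 0.7)
    resolutions: tuple[float, ...] = (0.5, 0.75, 1.0, 1.25, 1.5)
    train_fraction: float = 0.7
    models: tuple[str, ...] = (
        "RandomForest",
        "GradientBoosting",
        "SVM",
        "KNN",
        "LogisticRegression",
        "XGBoost",
    )
    odds_predictors: tuple[str, ...] = _DEFAULT_ODDS_PREDICTORS
    reference_pattern_name: str = "UADCG"
    min_pattern_size: int = 5              # smaller communities skip ML/odds stages

    def validate(self) -> None:
        if self.input_path is not None and self.synth is not None:
            raise ValueError("give either input_path or synth, not both")
        if not self.thresholds or not self.resolutions:
            raise ValueError("grids must be non-empty")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synth"] = self.synth.to_dict() if self.synth is not None else None
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth = raw.pop("synth", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in {f.name for f in dataclasses.fields(cls)}})
        if synth is not None:
            cfg.synth = SynthConfig.from_dict(synth)
        for name in ("thresholds", "resolutions", "models", "odds_predictors"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg


def records_to_covariates(
    records: Sequence[PatientRecord], predictors: Sequence[str]
) -> pd.DataFrame:
    """One column per predictor: numeric on raw scale, categoricals as strings."""
    rows = []
    for r in records:
        row = {}
        for name in predictors:
            if name in ("gender", "marital_status", "education"):
                row[name] = getattr(r, name)
            elif name == "smoking_100":
                row[name] = str(int(r.smoking_100))
            elif name in ("age", "family_pir", "bmi"):
                row[name] = float(getattr(r, name))
            elif name in r.activity_minutes:
                row[name] = r.activity_minutes[name]
            elif name in r.nutrient_intakes:
                row[name] = r.nutrient_intakes[name]
            elif name in r.biomarkers:
                row[name] = r.biomarkers[name]
            else:
                raise KeyError(f"unknown predictor {name!r}")
        rows.append(row)
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Execute all stages; returns the manifest (also written to manifest.json).

    Any stage failure raises :class:`StageError` naming the stage; artifacts
    of completed stages stay on disk.
    """
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": cfg.to_dict(),
        "stages": [],
    }

    def register(stage: str, artifacts: dict[str, Path], **info) -> None:
        manifest["stages"].append(
            {
                "stage": stage,
                "artifacts": {k: {"path": p.name, "sha256": _sha256(p)} for k, p in artifacts.items()},
                **info,
            }
        )

    current = "synthesize"
    try:
        # 1. synthesize / load
        if cfg.input_path is not None:
            records = read_cohort(cfg.input_path)
            cohort_path = outdir / "cohort.csv"
            write_cohort(records, cohort_path)
            register(current, {"cohort": cohort_path}, source=str(cfg.input_path))
        else:
            synth = cfg.synth or default_config(n_patients=cfg.n_patients, seed=cfg.seed)
            records = generate_cohort(synth)
            cohort_path = outdir / "cohort.csv"
            write_cohort(records, cohort_path, config=synth)
            register(
                current,
                {"cohort": cohort_path, "synth_config": Path(str(cohort_path) + ".json")},
                n_patients=len(records),
            )

        # 2. flag: re-derive from raw measurements where available
        current = "flag"
        n_rederived = 0
        for r in records:
            if r.raw is not None:
                r.diseases = flag_diseases(r.raw)
                n_rederived += 1
        flag_path = outdir / "flag_summary.json"
        counts = {
            d: int(sum(r.diseases.get(d, False) for r in records))
            for d in sorted({k for r in records for k in r.diseases})
        }
        flag_path.write_text(json.dumps({"rederived": n_rederived, "counts": counts}, indent=2, sort_keys=True))
        register(current, {"summary": flag_path}, rederived=n_rederived)

        # 3. inclusion filter (>= 2 diseases)
        current = "filter"
        filtered = filter_cmm(records)
        filtered_path = outdir / "cohort_filtered.csv"
        write_cohort(filtered, filtered_path)
        register(current, {"cohort": filtered_path}, n_in=len(records), n_kept=len(filtered))

        # 4. feature matrix for the graph
        current = "features"
        fm = build_feature_matrix(
            filtered, spec=cfg.feature_spec, include_diseases=cfg.include_diseases_in_graph
        )
        fm_path = outdir / "features.tsv"
        fm_params = outdir / "feature_params.json"
        fm.export(fm_path, fm_params)
        register(current, {"matrix": fm_path, "params": fm_params}, shape=list(fm.shape))

        # 5. grid search
        current = "grid_search"
        gs = grid_search(fm, cfg.thresholds, cfg.resolutions, seed=cfg.seed)
        grid_path = outdir / "grid.csv"
        gs.table.to_csv(grid_path, index=False)
        edges_path = outdir / "edges.tsv"
        gs.graph.export_edgelist(edges_path)
        graphml_path = outdir / "graph.graphml"
        gs.graph.export_graphml(graphml_path)
        register(
            current,
            {"grid": grid_path, "edges": edges_path, "graphml": graphml_path},
            threshold=gs.threshold,
            resolution=gs.resolution,
            modularity=gs.modularity,
            modularity_at_gamma=gs.modularity_at_gamma,
            n_retained_nodes=gs.n_retained_nodes,
        )

        # 6. final community detection at the selected operating point
        current = "louvain"
        part = louvain(gs.graph, gamma=gs.resolution, seed=cfg.seed)
        part_tsv = outdir / "partition.tsv"
        part_json = outdir / "partition.json"
        write_partition(part, part_tsv, part_json)
        register(
            current,
            {"partition": part_tsv, "report": part_json},
            n_communities=part.n_communities,
            modularity=part.modularity,
        )
        labels = [part.assignment[r.id] for r in filtered]

        # 7. epidemiological characterization
        current = "characterize"
        profile = characterize(filtered, labels)
        profile_path = outdir / "profile.json"
        profile_md = outdir / "profile.md"
        _write_profile(profile, profile_path, profile_md)
        register(
            current,
            {"profile": profile_path, "tables": profile_md},
            n_patterns=len(profile.prevalence.patterns),
            names={str(k): v for k, v in profile.names.items()},
        )

        # 8. classifier benchmark (diseases excluded from features: label leakage)
        current = "benchmark"
        sizes = pd.Series(labels).value_counts()
        keep_patterns = set(sizes[sizes >= max(cfg.min_pattern_size, 2)].index)
        mask = [lab in keep_patterns for lab in labels]
        ml_records = [r for r, m in zip(filtered, mask) if m]
        ml_labels = np.array([lab for lab, m in zip(labels, mask) if m])
        fm_ml = build_feature_matrix(ml_records, spec=cfg.feature_spec, include_diseases=False)
        train_idx, test_idx = stratified_split(
            fm_ml.values, ml_labels, cfg.train_fraction, seed=cfg.seed
        )
        train_records = [ml_records[i] for i in train_idx]
        fm_train = build_feature_matrix(
            train_records, spec=cfg.feature_spec, include_diseases=False
        )
        X_train = fm_train.values
        X_test = fm_train.transform([ml_records[i] for i in test_idx])
        report = run_benchmark(
            X_train,
            ml_labels[train_idx],
            X_test,
            ml_labels[test_idx],
            feature_names=fm_train.feature_names,
            models=cfg.models,
            seed=cfg.seed,
        )
        bench_path = outdir / "benchmark.json"
        bench_path.write_text(
            json.dumps(
                {
                    "metrics": report.metrics.to_dict(orient="records"),
                    "skipped": report.skipped,
                    "importances": report.importances,
                },
                indent=2,
                sort_keys=True,
            )
        )
        cm_paths = {}
        for name, cm in report.confusion.items():
            p = outdir / f"confusion_{name}.csv"
            pd.DataFrame(cm).to_csv(p, index=False)
            cm_paths[f"confusion_{name}"] = p
        imp_path = outdir / "importance.tsv"
        pd.DataFrame(report.importances, columns=["feature", "importance"]).to_csv(
            imp_path, sep="\t", index=False
        )
        register(
            current,
            {"report": bench_path, "importance": imp_path, **cm_paths},
            skipped=report.skipped,
        )

        # 9. odds models vs the reference pattern
        current = "odds"
        name_of = profile.names
        reference = next(
            (p for p, nm in name_of.items() if nm == cfg.reference_pattern_name),
            None,
        )
        if reference is None or reference not in keep_patterns:
            # fall back to the smallest usable pattern
            reference = sizes[sizes.index.isin(keep_patterns)].idxmin()
        cov = records_to_covariates(ml_records, cfg.odds_predictors)
        entries = fit_multinomial_or(
            cov,
            ml_labels,
            cfg.odds_predictors,
            reference=reference,
            reference_levels=ODDS_REFERENCE_LEVELS,
        )
        odds_path = outdir / "odds.csv"
        odds_table(entries).to_csv(odds_path, index=False)
        register(current, {"odds": odds_path}, reference=str(reference))
    except Exception as exc:  # noqa: BLE001 - re-raise with the stage name
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise StageError(current, exc) from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _write_profile(profile, json_path: Path, md_path: Path) -> None:
    prev = profile.prevalence
    payload = {
        "sizes": {str(k): int(v) for k, v in prev.sizes.items()},
        "shares": {str(k): float(v) for k, v in prev.shares.items()},
        "counts": {d: {str(k): int(v) for k, v in prev.counts.loc[d].items()} for d in prev.counts.index},
        "prevalence": {
            d: {str(k): float(v) for k, v in prev.prevalence.loc[d].items()}
            for d in prev.prevalence.index
        },
        "names": {str(k): v for k, v in profile.names.items()},
        "disease_tests": profile.disease_tests.to_dict(orient="records"),
        "categorical_tests": profile.categorical_tests.to_dict(orient="records"),
        "continuous_tests": profile.continuous_tests.to_dict(orient="records"),
        "posthoc": {
            var: {f"{a}|{b}": float(tbl.loc[a, b]) for a in tbl.index for b in tbl.columns if a != b}
            for var, tbl in profile.posthoc.items()
        },
    }
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True))

    lines = ["# Pattern profile", "", "## Disease counts by pattern", "", "```"]
    lines.append(prev.counts.to_string())
    lines += ["```", "", "## Pattern sizes", "", "```", prev.sizes.to_string(), "```"]
    lines += ["", "## Tests", "", "```", profile.disease_tests.to_string(index=False)]
    lines += ["", profile.categorical_tests.to_string(index=False)]
    lines += ["", profile.continuous_tests.to_string(index=False), "```", ""]
    md_path.write_text("\n".join(lines))
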