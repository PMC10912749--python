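"""End-to-end pipeline: simulate -> extract -> classify -> explain -> ablate.

One root seed determines every downstream RNG stream; re-running an
identical config reproduces identical artifacts.  Each stage is also
callable on externally supplied session files matching the session JSON
schema, so real recordings can replace the simulator without code
changes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import ExperimentConfig, run_experiment
from .datamodel import (
    FeatureTable,
    SubjectRecord,
    build_feature_table,
    read_feature_table,
    read_session_file,
    write_feature_table,
    write_session_file,
)
from .features import ExtractionConfig, extract_all
from .importance import (
    ImportanceConfig,
    ablation_experiment,
    explain_experiment,
)
from .simulate import GeneratorConfig, simulate_cohort

log = logging.getLogger(__name__)

SCHEMES = ("PDHC", "HY", "UPDRS")


@dataclass(frozen=True)
class PipelineConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)
    importance: ImportanceConfig = field(default_factory=ImportanceConfig)
    schemes: tuple[str, ...] = SCHEMES
    ablation_task: int = 2
    explain: bool = True
    ablate: bool = True
    seed: int = 0

    def seeded(self) -> "PipelineConfig":
        """Propagate the root seed into every stage config."""
        ss = np.random.SeedSequence(self.seed).generate_state(3)
        return dataclasses.replace(
            self,
            generator=self.generator.replace(seed=int(ss[0] % 2**31)),
            experiment=self.experiment.replace(seed=int(ss[1] % 2**31)),
            importance=self.importance.replace(seed=int(ss[2] % 2**31)),
        )

    def config_hash(self) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return enc(dataclasses.asdict(obj))
            if isinstance(obj, dict):
                return {str(k): enc(v) for k, v in obj.items()}
            if isinstance(obj, (set, frozenset)):
                return sorted(enc(v) for v in obj)
            if isinstance(obj, (tuple, list)):
                return [enc(v) for v in obj]
            return obj
        blob = json.dumps(enc(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def write_cohort(records: list[SubjectRecord], outdir: str | Path) -> pd.DataFrame:
    """Write one session JSON per subject plus a cohort manifest CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        write_session_file(rec, outdir / f"{rec.subject_id}.json")
        rows.append({"subject_id": rec.subject_id, "group": rec.group,
                     "updrs3_score": rec.updrs3_score, "hy_stage": rec.hy_stage})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "cohort.csv", index=False)
    return manifest


def read_cohort(indir: str | Path) -> list[SubjectRecord]:
    indir = Path(indir)
    paths = sorted(p for p in indir.glob("*.json"))
    if not paths:
        raise FileNotFoundError(f"no session JSON files under {indir}")
    return [read_session_file(p) for p in paths]


def extract_cohort(records: list[SubjectRecord],
                   config: ExtractionConfig | None = None) -> FeatureTable:
    config = config or ExtractionConfig()
    vectors = {rec.subject_id: extract_all(rec, config) for rec in records}
    return build_feature_table(vectors, records)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute all configured stages and return the run manifest."""
    t_start = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config.seeded()
    artifacts: dict[str, str] = {}

    def stage(name, fn):
        log.info("stage %s: start", name)
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    records = stage("simulate", lambda: simulate_cohort(cfg.generator))
    write_cohort(records, outdir / "cohort")
    artifacts["cohort"] = str(outdir / "cohort")
    log.info("simulated %d subjects (%d PD / %d HC)", len(records),
             cfg.generator.n_pd, cfg.generator.n_hc)

    table = stage("extract", lambda: extract_cohort(records, cfg.extraction))
    write_feature_table(table, outdir / "features.csv")
    artifacts["features"] = str(outdir / "features.csv")

    results = {}
    for scheme in cfg.schemes:
        exp = cfg.experiment.replace(scheme=scheme)
        res = stage(f"classify:{scheme}", lambda e=exp: run_experiment(table, e))
        results[scheme] = res
        path = outdir / f"results_{scheme}.csv"
        res.to_results_table().to_csv(path)
        res.summary().to_csv(outdir / f"results_{scheme}_summary.csv")
        artifacts[f"results_{scheme}"] = str(path)
        log.info("scheme %s: best model %s, mean accuracy %.3f", scheme,
                 res.best_model(), res.mean_accuracy(res.best_model()))

    if cfg.explain:
        for scheme in cfg.schemes:
            exp = cfg.experiment.replace(scheme=scheme)
            _, gi, ti, name = stage(
                f"explain:{scheme}",
                lambda e=exp, s=scheme: explain_experiment(
                    table, e, cfg.importance, results[s]),
            )
            fpath = outdir / f"importance_features_{scheme}.csv"
            gi.per_class.assign(total=gi.total).loc[gi.ranking()].to_csv(fpath)
            tpath = outdir / f"importance_tasks_{scheme}.csv"
            ti.per_class.assign(total=ti.total).to_csv(tpath)
            artifacts[f"importance_{scheme}"] = str(fpath)
            log.info("scheme %s explained with %s; top task %d", scheme, name,
                     ti.ranking()[0])

    if cfg.ablate:
        abl = stage("ablate", lambda: ablation_experiment(
            table, cfg.experiment.replace(scheme="PDHC"), cfg.ablation_task))
        path = outdir / "ablation_PDHC.csv"
        abl.accuracy_table().to_csv(path)
        artifacts["ablation"] = str(path)

    manifest = {
        "config_hash": config.config_hash(),
        "version": __version__,
        "seed": config.seed,
        "elapsed_s": round(time.time() - t_start, 2),
        "artifacts": artifacts,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def load_or_extract(session_dir: str | Path | None, features_csv: str | Path | None,
                    extraction: ExtractionConfig | None = None) -> FeatureTable:
    """Feature table from a session directory or a pre-extracted CSV."""
    if features_csv is not None:
        return read_feature_table(features_csv)
    if session_dir is None:
        raise ValueError("need either a session directory or a feature CSV")
    return extract_cohort(read_cohort(session_dir), extraction)
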