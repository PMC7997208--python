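"""End-to-end pipeline: simulate -> encode -> select -> benchmark.

Each stage writes one artifact into the output directory and records its
seed and a hash of the full configuration in ``manifest.json``, so any
artifact can be traced to the exact configuration that produced it and
stages can be re-run individually from prior artifacts.  Re-running with
an identical configuration reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .benchmark import (
    ExperimentConfig,
    MDRBenchmark,
    default_model_specs,
)
from .cohort import (
    CohortConfig,
    ConfigError,
    default_generator_config,
    generate_cohort,
    read_cohort,
    write_cohort,
)
from .encoding import encode_one_hot
from .selection import BootstrapConfig, BootstrapSelector

__all__ = ["PipelineConfig", "StageError", "run_pipeline", "load_config"]

log = logging.getLogger("mdrisk")

STAGES = ("simulate", "encode", "select", "benchmark")


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PipelineConfig:
    """Aggregate configuration for the full pipeline."""

    seed: int = 0
    n_total: int = 3013
    n_mdr: int = 270
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)
    families: tuple[str, ...] = ("LR", "DT", "XGB", "SLP", "MLP")

    def cohort_config(self) -> CohortConfig:
        base = default_generator_config(seed=self.seed)
        return replace(base, n_total=self.n_total, n_mdr=self.n_mdr)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_total": self.n_total,
            "n_mdr": self.n_mdr,
            "bootstrap": dataclasses.asdict(self.bootstrap),
            "experiment": dataclasses.asdict(self.experiment),
            "families": list(self.families),
        }

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode("utf-8")).hexdigest()[:16]


def load_config(path=None, seed: int | None = None) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from YAML, with optional seed override."""
    raw: dict = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
    try:
        boot = BootstrapConfig(**raw.get("bootstrap", {}))
        exp = ExperimentConfig(**{
            k: (tuple(v) if k == "balancing" else v)
            for k, v in raw.get("experiment", {}).items()})
        cfg = PipelineConfig(
            seed=raw.get("seed", 0),
            n_total=raw.get("n_total", 3013),
            n_mdr=raw.get("n_mdr", 270),
            bootstrap=boot, experiment=exp,
            families=tuple(raw.get("families",
                                   ("LR", "DT", "XGB", "SLP", "MLP"))))
        if seed is not None:
            cfg = replace(cfg,
                          seed=seed,
                          bootstrap=replace(boot, seed=seed),
                          experiment=replace(exp, seed=seed))
        boot_final = cfg.bootstrap
        boot_final.validate()
        cfg.experiment.validate()
        cfg.cohort_config().validate()
        return cfg
    except (TypeError, ValueError, ConfigError) as exc:
        raise ConfigError(str(exc)) from exc


def _update_manifest(out: Path, stage: str, cfg: PipelineConfig,
                     artifact: str) -> None:
    path = out / "manifest.json"
    manifest = {}
    if path.exists():
        manifest = json.loads(path.read_text(encoding="utf-8"))
    manifest[stage] = {"config_hash": cfg.hash(), "seed": cfg.seed,
                       "artifact": artifact}
    path.write_text(json.dumps(manifest, indent=2), encoding="utf-8")


def run_pipeline(config: PipelineConfig, out_dir,
                 stages=STAGES) -> dict[str, Path]:
    """Run the requested stages in order, returning artifact paths.

    Later stages re-read the artifacts of earlier ones from ``out_dir``,
    so any suffix of the pipeline can be re-run on prior outputs.  On a
    stage failure a ``FAILED`` marker naming the stage is left next to
    the partial outputs and :class:`StageError` is raised.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    current = None

    def _run(stage: str, fn):
        nonlocal current
        current = stage
        log.info("stage %s: seed=%d config=%s", stage, config.seed,
                 config.hash())
        try:
            fn()
        except Exception as exc:  # marker + propagate with stage context
            (out / "FAILED").write_text(f"{stage}: {exc}\n", encoding="utf-8")
            raise StageError(stage, exc) from exc

    def simulate():
        cohort = generate_cohort(config.cohort_config())
        write_cohort(cohort, out / "cohort.csv")
        artifacts["cohort"] = out / "cohort.csv"
        _update_manifest(out, "simulate", config, "cohort.csv")
        log.info("simulated %d episodes (%d MDR)", cohort.n_total,
                 cohort.n_mdr)

    def encode():
        cohort = read_cohort(out / "cohort.csv")
        ds = encode_one_hot(cohort)
        frame = ds.features.to_frame()
        frame[cohort.schema.label] = ds.y
        frame.to_csv(out / "encoded.csv", index=False)
        artifacts["encoded"] = out / "encoded.csv"
        _update_manifest(out, "encode", config, "encoded.csv")
        log.info("encoded %d x %d design matrix", ds.n, ds.features.d)

    def select():
        cohort = read_cohort(out / "cohort.csv")
        ds = encode_one_hot(cohort)
        res = BootstrapSelector(ds, config.bootstrap).fit()
        payload = res.to_dict()
        payload["config_hash"] = config.hash()
        payload["seed"] = config.seed
        (out / "selection.json").write_text(
            json.dumps(payload, indent=2), encoding="utf-8")
        artifacts["selection"] = out / "selection.json"
        _update_manifest(out, "select", config, "selection.json")
        log.info("selected %d features (union %d)",
                 len(res.final.retained), len(res.final.union))

    def benchmark():
        cohort = read_cohort(out / "cohort.csv")
        ds = encode_one_hot(cohort)
        selection = json.loads(
            (out / "selection.json").read_text(encoding="utf-8"))
        retained = selection["union"]["retained"]
        specs = [s for s in default_model_specs()
                 if s.family in config.families]
        res = MDRBenchmark(ds.subset(retained), specs=specs,
                           config=config.experiment).fit()
        res.table.to_csv(out / "performance.csv")
        res.raw.to_json(out / "performance_raw.json", orient="records",
                        indent=2)
        artifacts["performance"] = out / "performance.csv"
        _update_manifest(out, "benchmark", config, "performance.csv")
        log.info("benchmark complete:\n%s", res.summary())

    fns = {"simulate": simulate, "encode": encode, "select": select,
           "benchmark": benchmark}
    handler = logging.FileHandler(out / "pipeline.log", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        for stage in STAGES:
            if stage in stages:
                _run(stage, fns[stage])
    finally:
        log.removeHandler(handler)
        handler.close()
    return artifacts
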