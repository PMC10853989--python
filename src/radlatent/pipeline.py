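"""End-to-end orchestration: simulate -> preprocess -> latent search ->
train -> evaluate -> report, from a single seeded configuration.

Every output directory carries a provenance sidecar (config hash + master
seed); re-running an identical configuration reproduces all numeric
outputs byte-for-byte.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from ._seeds import derive_seed
from .cohort import CohortSpec, RadiomicCohort, generate_cohort, read_cohort, write_cohort
from .evaluation import PipelineConfig, run_cv_three_class, run_cv_two_stage
from .latent import TrainConfig, manifold_2d, search_latent_size
from .models import STAGE1_PRESET, STAGE2_PRESET, THREE_CLASS_PRESET
from .preprocessing import (ImputationStrategy, apply_standardizer,
                            fit_standardizer, impute, split_matrix_by_mask)

log = logging.getLogger("radlatent")

ARCHITECTURES = ("three_class", "two_stage")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full pipeline run.

    Either ``cohort_spec`` (simulate) or ``cohort_path`` (load a written
    cohort) must be set.  All randomness flows from ``seed``.
    """

    cohort_spec: CohortSpec | None = field(default_factory=CohortSpec)
    cohort_path: str | None = None
    imputation: str = "mean"
    architecture: str = "three_class"
    primary_class: str = "GBM"
    latent_dim: int = 15
    latent_candidates: tuple[int, ...] = ()   # empty -> skip the search
    threshold: float = 0.2
    ae_max_epochs: int = 250
    ae_batch_size: int = 32
    mlp_preset: str = "default"               # per-architecture Table presets
    k: int = 5
    repeats: int = 5
    seed: int = 0
    do_manifolds: bool = False
    out: str = "results/run"

    def validate(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"architecture must be one of {ARCHITECTURES}, "
                             f"got '{self.architecture}'")
        if self.cohort_spec is None and self.cohort_path is None:
            raise ValueError("either cohort_spec or cohort_path is required")
        if self.cohort_path is not None and not Path(self.cohort_path).exists():
            raise ValueError(f"cohort_path does not exist: {self.cohort_path}")
        ImputationStrategy(self.imputation)  # raises on unknown kind

    # ---- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.cohort_spec is not None:
            d["cohort_spec"] = self.cohort_spec.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        spec = d.get("cohort_spec")
        if isinstance(spec, dict):
            mr = spec.get("missing_rates")
            d["cohort_spec"] = CohortSpec(
                class_counts=spec.get("class_counts", dict(
                    CohortSpec().class_counts)),
                masks=tuple(spec.get("masks", CohortSpec().masks)),
                sequences=tuple(spec.get("sequences", CohortSpec().sequences)),
                features_per_combination=spec.get(
                    "features_per_combination", 107),
                intrinsic_rank=spec.get("intrinsic_rank", 15),
                class_effect=spec.get("class_effect",
                                      dict(CohortSpec().class_effect)),
                noise_sd=spec.get("noise_sd", 0.3),
                missing_rates=(None if mr is None else
                               {tuple(k.split("|")): v for k, v in mr.items()}),
                seed=spec.get("seed", 0),
            )
        if "latent_candidates" in d and d["latent_candidates"] is not None:
            d["latent_candidates"] = tuple(d["latent_candidates"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _pipeline_config(cfg: RunConfig, latent_dim: int) -> PipelineConfig:
    return PipelineConfig(
        latent_dim=latent_dim,
        ae=TrainConfig(max_epochs=cfg.ae_max_epochs,
                       batch_size=cfg.ae_batch_size,
                       seed=derive_seed(cfg.seed, "ae")),
        mlp=THREE_CLASS_PRESET,
        stage1_mlp=STAGE1_PRESET,
        stage2_mlp=STAGE2_PRESET,
        imputation=ImputationStrategy(cfg.imputation),
        primary_class=cfg.primary_class,
        k=cfg.k, repeats=cfg.repeats,
        seed=derive_seed(cfg.seed, "evaluate"),
        model_name=("Two-Stage" if cfg.architecture == "two_stage"
                    else "Three-Class MLP"),
    )


def _write_provenance(outdir: Path, cfg: RunConfig, timings: dict) -> None:
    prov = {"config_hash": cfg.config_hash(), "seed": cfg.seed,
            "config": cfg.to_dict(), "stage_seconds": timings}
    (outdir / "provenance.json").write_text(json.dumps(prov, indent=1,
                                                       default=str))


def _load_or_simulate(cfg: RunConfig, outdir: Path) -> RadiomicCohort:
    if cfg.cohort_path is not None:
        return read_cohort(cfg.cohort_path)
    spec = dataclasses.replace(cfg.cohort_spec,
                               seed=derive_seed(cfg.seed, "cohort"))
    cohort = generate_cohort(spec)
    write_cohort(cohort, outdir / "cohort")
    return cohort


def _exploratory_blocks(cohort: RadiomicCohort, strategy: ImputationStrategy):
    """Standardize/impute on the full cohort — exploratory use only
    (manifolds and the latent-size curve), clearly outside CV."""
    params = fit_standardizer(cohort.features)
    X = impute(apply_standardizer(cohort.features, params), strategy)
    return {b.mask: b.values
            for b in split_matrix_by_mask(X, cohort.column_meta, cohort.masks)}


def run(config: RunConfig) -> Path:
    """Execute the staged pipeline; returns the run directory.

    Stages: cohort (simulated or loaded), optional bottleneck-size search
    and 2-D manifolds (exploratory, fit on all data and labeled as such),
    then repeated stratified CV of the configured architecture.  Stage
    failures abort with the stage name attached.
    """
    config.validate()
    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO,
                        format="%(asctime)s %(name)s %(message)s")
    timings: dict[str, float] = {}
    stage = "cohort"
    try:
        t0 = time.perf_counter()
        cohort = _load_or_simulate(config, outdir)
        timings[stage] = time.perf_counter() - t0
        log.info("cohort: %d samples x %d features",
                 cohort.n_samples, cohort.n_features)

        strategy = ImputationStrategy(config.imputation)
        selected = {m: config.latent_dim for m in cohort.masks}
        if config.latent_candidates or config.do_manifolds:
            stage = "exploratory-preprocess"
            t0 = time.perf_counter()
            blocks = _exploratory_blocks(cohort, strategy)
            timings[stage] = time.perf_counter() - t0

        if config.latent_candidates:
            stage = "latent-search"
            t0 = time.perf_counter()
            curves = []
            for mi, mask in enumerate(cohort.masks):
                res = search_latent_size(
                    blocks[mask], config.latent_candidates, config.threshold,
                    TrainConfig(max_epochs=config.ae_max_epochs,
                                batch_size=config.ae_batch_size,
                                seed=derive_seed(config.seed, "search", mi)))
                selected[mask] = res.selected_d
                for d, err in sorted(res.curve.items()):
                    curves.append({"mask": mask, "latent_dim": d,
                                   "reconstruction_error": err,
                                   "selected": d == res.selected_d,
                                   "met_threshold": res.met_threshold})
                log.info("latent search %s: selected d=%d (met=%s)",
                         mask, res.selected_d, res.met_threshold)
            import pandas as pd
            pd.DataFrame(curves).to_csv(outdir / "latent_search.csv",
                                        index=False)
            timings[stage] = time.perf_counter() - t0

        if config.do_manifolds:
            stage = "manifolds"
            t0 = time.perf_counter()
            for mi, mask in enumerate(cohort.masks):
                manifold_2d(
                    blocks[mask],
                    TrainConfig(max_epochs=config.ae_max_epochs,
                                batch_size=config.ae_batch_size,
                                seed=derive_seed(config.seed, "manifold", mi)),
                    labels=cohort.labels,
                    out_png=str(outdir / f"manifold_{mask}.png"),
                    out_csv=str(outdir / f"manifold_{mask}.csv"),
                    title=f"{mask} (exploratory fit on all data)")
            timings[stage] = time.perf_counter() - t0

        stage = "evaluate"
        t0 = time.perf_counter()
        pcfg = _pipeline_config(config, config.latent_dim)
        if config.architecture == "two_stage":
            report = run_cv_two_stage(cohort, pcfg)
        else:
            report = run_cv_three_class(cohort, pcfg)
        report.write(outdir, prefix="report")
        timings[stage] = time.perf_counter() - t0
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    _write_provenance(outdir, config, timings)
    log.info("run complete: %s", outdir)
    return outdir
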