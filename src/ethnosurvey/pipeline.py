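"""Pipeline orchestration: staged analysis runs with a reproducible manifest.

A run either loads a three-file survey or generates a synthetic one, then
executes the analysis stages in dependency order:

    load/validate -> indices -> ordination+envfit -> overlap -> consensus -> trend

Each stage writes delimited-text/JSON outputs into the run directory; the
run manifest records the full configuration, the seed, and a SHA-256 hash
of every output file, so re-running with the same config and seed
reproduces every numeric output bit for bit. A failed stage aborts its
downstream dependents but not independent stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import comparative, indices, ordination, trend
from .model import (
    SurveyDataset,
    build_incidence_matrix,
    load_survey,
    validation_report,
)
from .synthetic import GeneratorConfig, generate_survey, write_fixture

logger = logging.getLogger(__name__)

STAGES = ("validate", "indices", "ordinate", "envfit", "overlap", "consensus", "trend")
_DEPENDS = {"envfit": "ordinate"}


class ConfigError(ValueError):
    """The run configuration is invalid before any stage executes."""


@dataclass
class RunConfig:
    """Fully serialisable configuration of one pipeline run."""

    out_dir: str = "ethnosurvey_run"
    seed: int = 0
    # input: either the three file paths, or synthetic generation
    reports_path: str | None = None
    informants_path: str | None = None
    species_path: str | None = None
    simulate: bool = True
    generator: dict = field(default_factory=dict)
    # analysis settings
    stages: tuple = STAGES
    spaces: tuple = ("plant_space", "use_space")
    binarize: bool = False
    k: int = 2
    n_restarts: int = 20
    max_iter: int = 500
    tol: float = 1e-7
    n_perm: int = 999
    quantile: float = 95.0
    n_bins: int = 10

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        for stage, dep in _DEPENDS.items():
            if stage in self.stages and dep not in self.stages:
                raise ConfigError(f"stage '{stage}' requires stage '{dep}'")
        if not self.simulate and not (
            self.reports_path and self.informants_path and self.species_path
        ):
            raise ConfigError("either simulate=true or all three input paths are required")
        if self.k < 1 or self.n_restarts < 1 or self.n_perm < 1:
            raise ConfigError("k, n_restarts and n_perm must be positive")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    names = ("simulate",) + STAGES
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(names, ss.spawn(len(names)))
    }


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str), encoding="utf-8")


def run_pipeline(config: RunConfig, dataset: SurveyDataset | None = None) -> dict:
    """Execute the configured stages and return the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    outputs: list[Path] = []
    errors: dict[str, str] = {}

    if dataset is None:
        if config.simulate:
            gen = GeneratorConfig(**{"seed": seeds["simulate"], **config.generator})
            dataset, manifest_truth = generate_survey(gen)
            outputs.extend(write_fixture(dataset, manifest_truth, out / "survey").values())
        else:
            dataset = load_survey(
                config.reports_path, config.informants_path, config.species_path
            )

    def stage_enabled(name: str) -> bool:
        if name not in config.stages:
            return False
        dep = _DEPENDS.get(name)
        if dep and dep in errors:
            errors[name] = f"skipped: upstream stage '{dep}' failed"
            return False
        return True

    ords: dict[str, ordination.OrdinationResult] = {}
    ordination_summary: dict[str, dict] = {}
    envfit_summary: dict[str, dict] = {}

    if stage_enabled("validate"):
        path = out / "validation.json"
        _write_json(path, validation_report(dataset))
        outputs.append(path)

    if stage_enabled("indices"):
        try:
            scopes = [None] + dataset.regions_present()
            regional = {}
            for region in scopes:
                table = indices.compute_metrics_table(dataset, region)
                label = region or "all"
                path = out / f"metrics_{label}.csv"
                table.to_csv(path, index=False)
                outputs.append(path)
                if region:
                    regional[region] = table
                else:
                    overall = table
            for metric in ("ci", "ud", "uv"):
                top = indices.top_percentile(
                    overall, metric, config.quantile, regional_tables=regional
                )
                path = out / f"top_{metric}.csv"
                top.to_csv(path, index=False)
                outputs.append(path)
            fic_frames = [indices.category_summary(dataset)] + [
                indices.category_summary(dataset, r) for r in dataset.regions_present()
            ]
            path = out / "fic_by_category.csv"
            import pandas as pd

            pd.concat(fic_frames, ignore_index=True).to_csv(path, index=False)
            outputs.append(path)
        except Exception as exc:  # noqa: BLE001 - stage isolation
            errors["indices"] = str(exc)
            logger.exception("indices stage failed")

    if stage_enabled("ordinate"):
        try:
            for space in config.spaces:
                inc = build_incidence_matrix(dataset, mode=space, binarize=config.binarize)
                inc = inc.drop_zero_rows()
                d = ordination.bray_curtis(inc)
                res = ordination.nmds_embed(
                    d,
                    k=config.k,
                    n_restarts=config.n_restarts,
                    max_iter=config.max_iter,
                    tol=config.tol,
                    seed=seeds["ordinate"],
                )
                ords[space] = res
                ordination_summary[space] = {
                    "metric": d.metric,
                    "binarized": config.binarize,
                    "k": res.k,
                    "n_restarts": res.n_restarts,
                    "stress": res.stress,
                    "converged": res.converged,
                    "n_informants": len(res.ids),
                }
                import pandas as pd

                scores = pd.DataFrame(
                    res.scores,
                    index=pd.Index(res.ids, name="informant_id"),
                    columns=[f"axis{i + 1}" for i in range(res.k)],
                )
                path = out / f"nmds_{space}.csv"
                scores.to_csv(path)
                outputs.append(path)
        except Exception as exc:  # noqa: BLE001
            errors["ordinate"] = str(exc)
            logger.exception("ordination stage failed")

    if stage_enabled("envfit"):
        try:
            for space, res in ords.items():
                fits, failures = ordination.envfit_table(
                    res, dataset.informants, n_perm=config.n_perm, seed=seeds["envfit"]
                )
                frame = ordination.envfit_frame(fits)
                envfit_summary[space] = {
                    f.variable: {"kind": f.kind, "r2": f.r2, "p": f.p} for f in fits
                }
                path = out / f"envfit_{space}.csv"
                frame.to_csv(path, index=False)
                outputs.append(path)
                if failures:
                    _write_json(out / f"envfit_{space}_failures.json", failures)
                    outputs.append(out / f"envfit_{space}_failures.json")
        except Exception as exc:  # noqa: BLE001
            errors["envfit"] = str(exc)
            logger.exception("envfit stage failed")

    if stage_enabled("overlap"):
        try:
            overlap = {}
            for kind in ("species", "use"):
                overlap[kind] = comparative.region_overlap(dataset, kind).partition_counts
                overlap[f"{kind}_garden"] = comparative.region_overlap(
                    dataset, kind, origin_filter="garden"
                ).partition_counts
            path = out / "overlap.json"
            _write_json(path, overlap)
            outputs.append(path)
            path = out / "garden_wild_summary.csv"
            comparative.garden_wild_summary(dataset).to_csv(path, index=False)
            outputs.append(path)
        except Exception as exc:  # noqa: BLE001
            errors["overlap"] = str(exc)
            logger.exception("overlap stage failed")

    if stage_enabled("consensus"):
        try:
            for split, label in ((False, "consensus"), (True, "consensus_by_origin")):
                path = out / f"{label}.csv"
                comparative.consensus_by_category(dataset, split_by_origin=split).to_csv(
                    path, index=False
                )
                outputs.append(path)
        except Exception as exc:  # noqa: BLE001
            errors["consensus"] = str(exc)
            logger.exception("consensus stage failed")

    if stage_enabled("trend"):
        try:
            fits, trend_errors = trend.trend_report(dataset, n_bins=config.n_bins)
            path = out / "trend.json"
            _write_json(
                path,
                {
                    "fits": [f.to_dict() for f in fits],
                    "errors": trend_errors,
                },
            )
            outputs.append(path)
        except Exception as exc:  # noqa: BLE001
            errors["trend"] = str(exc)
            logger.exception("trend stage failed")

    manifest = {
        "config": asdict(config),
        "stage_seeds": seeds,
        "ordination": ordination_summary,
        "envfit": envfit_summary,
        "outputs": {
            str(p.relative_to(out)): _sha256(p) for p in sorted(set(outputs))
        },
        "stage_errors": errors,
        "n_informants": int(len(dataset.informants)),
        "n_species": int(dataset.species["species_id"].nunique()),
        "n_reports": int(dataset.n_reports),
    }
    _write_json(out / "run_manifest.json", manifest)
    if errors:
        raise RuntimeError(f"pipeline finished with stage errors: {errors}")
    return manifest
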