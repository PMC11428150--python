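"""End-to-end pipeline orchestration and run configuration.

``run_pipeline`` executes association -> architecture -> training /
cross-validation -> impact scoring -> combination screening -> holdout
evaluation, writing every artifact plus a JSON run report (seed, config
hash, metrics).  Runs are idempotent under a fixed seed.  Inputs are either
file paths (TSV layer tables) or, when ``synthetic`` is set, generated by
the synthetic-data module.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .archinit import BuildConfig
from .exceptions import SlemError
from .io import read_genotypes, write_genotypes_tsv
from .model import SLEM
from .network import TrainConfig
from .screen import records_to_frame
from .synthdata import (
    EndToEndDataset,
    MultilevelDataset,
    SynthConfig,
    gen_end_to_end,
    gen_multilevel,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "StageFailure"]


class StageFailure(SlemError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    """All thresholds and paths of a full pipeline run."""

    outdir: str = "slem_run"
    seed: int = 0
    # step 1: architecture
    fdr_thresholds: tuple[float, float, float] = (0.1, 0.05, 0.05)
    significance_cutoff: float = 0.05
    keep_fraction: float = 0.35
    # step 2: training
    learning_rate: float = 0.005
    batch_size: int = 250
    epochs: int = 750
    folds: int = 10
    # interpretation
    top_k: int = 5
    precision_threshold: float = 0.6
    p_threshold: float = 0.05
    module_fraction: float = 0.10
    # inputs: file mode
    genotypes_path: str | None = None
    isoforms_path: str | None = None
    markers_path: str | None = None
    phenotypes_path: str | None = None
    covariates_path: str | None = None
    e2e_genotypes_path: str | None = None
    e2e_labels_path: str | None = None
    holdout_genotypes_path: str | None = None
    holdout_labels_path: str | None = None
    # inputs: synthetic mode
    synthetic: dict | None = None

    def __post_init__(self):
        for name in (
            "significance_cutoff",
            "keep_fraction",
            "precision_threshold",
            "p_threshold",
            "module_fraction",
        ):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise SlemError(f"{name} must lie in (0, 1], got {v}")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "fdr_thresholds" in raw:
            raw["fdr_thresholds"] = tuple(raw["fdr_thresholds"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["fdr_thresholds"] = list(d["fdr_thresholds"])
        Path(path).write_text(yaml.safe_dump(d))


def _load_multilevel(cfg: RunConfig) -> MultilevelDataset:
    geno = read_genotypes(cfg.genotypes_path, "tsv")
    read = lambda p: pd.read_csv(p, sep="\t", index_col=0)
    covs = read(cfg.covariates_path)
    return MultilevelDataset(
        genotypes=geno,
        isoforms=read(cfg.isoforms_path),
        markers=read(cfg.markers_path),
        phenotypes=read(cfg.phenotypes_path),
        covariates=covs,
        diagnosis=covs["diagnosis"],
    )


def _load_e2e(geno_path: str, labels_path: str) -> EndToEndDataset:
    geno = read_genotypes(geno_path, "tsv")
    labels = pd.read_csv(labels_path, sep="\t", index_col=0).iloc[:, 0]
    return EndToEndDataset(genotypes=geno, labels=labels.astype(int))


def run_pipeline(config: RunConfig) -> dict:
    """Run the full two-step procedure and return the run report dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": [],
    }

    def stage(name):
        logger.info("stage: %s", name)
        report["stages"].append(name)

    try:
        stage("inputs")
        if config.synthetic is not None:
            syn = SynthConfig(**{**config.synthetic, "seed": config.seed})
            dataset, truth = gen_multilevel(syn)
            e2e = gen_end_to_end(syn, truth, seed_offset=0)
            holdout = gen_end_to_end(syn, truth, seed_offset=1)
            write_genotypes_tsv(dataset.genotypes, outdir / "multilevel_genotypes.tsv")
            truth_dict = {
                "e1_nonzero": [[int(i), int(j)] for i, j in sorted(truth.planted_edges(1))],
                "e2_nonzero": [[int(i), int(j)] for i, j in sorted(truth.planted_edges(2))],
                "e3_nonzero": [[int(i), int(j)] for i, j in sorted(truth.planted_edges(3))],
                "liability_intercept": truth.liability_intercept,
            }
            (outdir / "ground_truth.json").write_text(json.dumps(truth_dict))
        else:
            dataset = _load_multilevel(config)
            e2e = _load_e2e(config.e2e_genotypes_path, config.e2e_labels_path)
            holdout = None
            if config.holdout_genotypes_path:
                holdout = _load_e2e(
                    config.holdout_genotypes_path, config.holdout_labels_path
                )
    except StageFailure:
        raise
    except Exception as exc:
        raise StageFailure("inputs", exc) from exc

    try:
        stage("assoc+init")
        build_cfg = BuildConfig(
            fdr_thresholds=config.fdr_thresholds,
            significance_cutoff=config.significance_cutoff,
            keep_fraction=config.keep_fraction,
            seed=config.seed,
        )
        slem = SLEM.from_multilevel(dataset, build_cfg)
        for pair, table in slem.tables.items():
            table.to_tsv(outdir / f"assoc_{pair.replace('->', '_to_')}.tsv")
        slem.initial_model.to_json(outdir / "model_initial.json")
        report["layer_sizes"] = list(slem.architecture.sizes)
        report["edges_kept"] = slem.initial_model.n_edges()
    except Exception as exc:
        raise StageFailure("assoc+init", exc) from exc

    try:
        stage("train")
        tcfg = TrainConfig(
            learning_rate=config.learning_rate,
            batch_size=config.batch_size,
            epochs=config.epochs,
            folds=config.folds,
            seed=config.seed,
        )
        results = slem.fit(e2e, tcfg, cross_validate=True)
        results.network.to_json(outdir / "model_trained.json")
        pd.DataFrame(
            {"fold": range(1, len(results.cv.per_fold) + 1), "auroc": results.cv.per_fold}
        ).to_csv(outdir / "metrics.tsv", sep="\t", index=False)
        report["cv_auroc_mean"] = results.cv.mean
        report["cv_auroc_sd"] = results.cv.sd
        report["train_auroc"] = results.train_auroc()
    except Exception as exc:
        raise StageFailure("train", exc) from exc

    try:
        stage("interpret")
        impact = results.impact_scores()
        impact.to_tsv(outdir / "impact.tsv")
        top = results.top_snps(min(config.top_k, len(impact.scores)))
        report["top_snps"] = top
        anchors = [results.network.architecture.layer("phenotype")[0]]
        module = results.extract_module(anchors, config.module_fraction)
        (outdir / "module.json").write_text(json.dumps(module.to_dict()))
        module.to_edge_list(outdir / "module_edges.tsv")
    except Exception as exc:
        raise StageFailure("interpret", exc) from exc

    try:
        stage("screen")
        records = results.screen(
            e2e, top, config.precision_threshold, config.p_threshold
        )
        records_to_frame(records).to_csv(outdir / "screen.tsv", sep="\t", index=False)
        report["n_combinations"] = len(records)
        report["n_passed"] = sum(r.passed for r in records)
        if holdout is not None:
            holdout_tbl = results.evaluate_holdout(records, holdout)
            holdout_tbl.to_csv(outdir / "holdout.tsv", sep="\t", index=False)
            report["n_holdout_evaluated"] = len(holdout_tbl)
    except Exception as exc:
        raise StageFailure("screen", exc) from exc

    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    return report
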