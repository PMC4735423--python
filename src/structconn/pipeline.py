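"""End-to-end pipeline: simulate -> build networks -> metrics -> compare
-> classify, with a reproducibility manifest.

The run manifest records the package version, the full configuration, the
seed and a SHA-256 checksum of every file written, so two runs with the
same configuration and seed can be verified identical file-by-file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .classify import SVMConfig, build_feature_vectors, jackknife_group_profiles, train_evaluate
from .compare import compare_subject_profiles
from .io import write_feature_table, write_json, write_matrix, write_profiles
from .metrics import METRIC_NAMES, topology_profile
from .networks import density_grid, normalize_pt, symmetrize
from .simulate import CohortConfig, generate_cohort

log = logging.getLogger("structconn")


@dataclass
class PipelineConfig:
    """Everything one run needs; seed propagates to every stochastic stage."""

    out_dir: str
    cohort: CohortConfig = field(default_factory=CohortConfig)
    densities: np.ndarray = field(default_factory=density_grid)
    modes: tuple = ("tractography", "thickness", "fa")
    metrics: tuple = METRIC_NAMES
    compare_groups: tuple = ("CIS", "RRMS")
    classify_metric: str = "C_mean"
    svm: SVMConfig = field(default_factory=SVMConfig)
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = {
            "out_dir": str(self.out_dir),
            "cohort": self.cohort.truth(),
            "densities": [float(x) for x in self.densities],
            "modes": list(self.modes),
            "metrics": list(self.metrics),
            "compare_groups": list(self.compare_groups),
            "classify_metric": self.classify_metric,
            "svm": {
                "kernel": self.svm.kernel,
                "gamma": self.svm.gamma,
                "C_grid": [float(c) for c in self.svm.C_grid],
                "degree_grid": list(self.svm.degree_grid),
                "train_fraction": self.svm.train_fraction,
                "n_folds": self.svm.n_folds,
            },
            "seed": self.seed,
        }
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return (and write) the run manifest."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    if not out.parent.exists():
        raise FileNotFoundError(f"output parent directory {out.parent} does not exist")
    out.mkdir(parents=True, exist_ok=True)
    written: list = []

    def emit(path: Path) -> None:
        written.append(path)

    # stage 1: simulate
    config.cohort.seed = config.seed
    log.info("simulating cohort (%d subjects)", config.cohort.n_subjects)
    cohort = generate_cohort(config.cohort)
    write_feature_table(cohort.thickness_table, out / "thickness.tsv")
    emit(out / "thickness.tsv")
    write_feature_table(cohort.fa_table, out / "fa.tsv")
    emit(out / "fa.tsv")
    pt_dir = out / "pt"
    pt_dir.mkdir(exist_ok=True)
    for sid, mat in cohort.pt_matrices.items():
        write_matrix(mat, pt_dir / f"{sid}.tsv")
        emit(pt_dir / f"{sid}.tsv")
    write_json(cohort.truth, out / "truth.json")
    emit(out / "truth.json")

    ga, gb = config.compare_groups
    comparisons: dict = {}
    reports: dict = {}

    for mode in config.modes:
        log.info("mode %s: building profiles", mode)
        if mode == "tractography":
            profiles = []
            for sid, mat in cohort.pt_matrices.items():
                w = symmetrize(normalize_pt(mat, config.cohort.streamline_total))
                profiles.append(
                    topology_profile(
                        w.counts,
                        config.densities,
                        entity_id=f"{cohort.labels[sid]}/{sid}",
                        region_names=w.region_names,
                        which=config.metrics,
                    )
                )
        elif mode in ("thickness", "fa"):
            table = cohort.thickness_table if mode == "thickness" else cohort.fa_table
            profiles = []
            for grp in (ga, gb):
                profiles += jackknife_group_profiles(
                    table, grp, config.densities, config.classify_metric
                )
        else:
            raise ValueError(f"unknown mode {mode!r}")
        write_profiles(profiles, out / f"profiles_{mode}.tsv")
        emit(out / f"profiles_{mode}.tsv")

        # stage: compare (subject-level profiles only carry all metrics)
        if mode == "tractography":
            for met in config.metrics:
                pa = [p for p in profiles if p.entity_id.startswith(f"{ga}/")]
                pb = [p for p in profiles if p.entity_id.startswith(f"{gb}/")]
                res = compare_subject_profiles(pa, pb, met)
                comparisons[f"{mode}:{met}"] = {
                    "n_significant_densities": res.n_significant_densities,
                    "mean_t": float(np.mean(res.statistic)),
                }

        # stage: classify
        pa = [p for p in profiles if p.entity_id.startswith(f"{ga}/")]
        pb = [p for p in profiles if p.entity_id.startswith(f"{gb}/")]
        X, y = build_feature_vectors(pa + pb, config.classify_metric)
        svm = SVMConfig(**{**config.svm.__dict__, "seed": config.seed})
        rep = train_evaluate(X, y, svm, metric=config.classify_metric)
        reports[mode] = {
            "training_accuracy": rep.training_accuracy,
            "testing_accuracy": rep.testing_accuracy,
            "cv_accuracy": rep.cv_accuracy,
            "chosen_C": rep.chosen_C,
            "chosen_degree": rep.chosen_degree,
            "auc": rep.auc,
            "auc_ci95": list(rep.auc_ci95),
            "auc_p_value": rep.auc_p_value,
        }
        (out / f"report_{mode}.txt").write_text(rep.summary() + "\n")
        emit(out / f"report_{mode}.txt")

    write_json(comparisons, out / "comparisons.json")
    emit(out / "comparisons.json")
    write_json(reports, out / "reports.json")
    emit(out / "reports.json")

    cfg = config.to_dict()
    hashed = {k: v for k, v in cfg.items() if k != "out_dir"}
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(hashed, sort_keys=True).encode()
        ).hexdigest(),
        "config": cfg,
        "checksums": {str(p.relative_to(out)): _sha256(p) for p in written},
    }
    write_json(manifest, out / "manifest.json")
    return manifest
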