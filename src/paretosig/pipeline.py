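"""End-to-end pipeline: prefilter -> normalize -> DE -> Pareto K -> modules -> signature -> CV.

Every stage writes its table to the output directory and a run manifest
records parameters, seeds, and stage-by-stage gene/sample counts so a run is
re-derivable from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cluster_algorithms import kmeans
from .cluster_number import objective_matrix, pareto_rank
from .data_io import (
    ExpressionMatrix,
    GroupLabels,
    align_samples,
    read_expression,
    read_groups,
)
from .de_test import moderated_test, volcano_filter
from .nsc_validate import evaluate_signature
from .preprocess import log_cpm, prefilter, standardize_genes, voom_weights
from .signature import module_scores_frame, pick_signature, score_modules

logger = logging.getLogger(__name__)

ARTIFACTS = [
    "preprocess_report.json",
    "de_table.tsv",
    "objective_matrix.tsv",
    "pareto.json",
    "clusters.tsv",
    "module_scores.tsv",
    "signature.tsv",
    "cv_report.tsv",
    "cv_report.json",
    "manifest.json",
]


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; serializes losslessly to/from YAML/JSON."""

    expression_path: str = ""
    phenotype_path: str = ""
    output_dir: str = "paretosig_out"
    control_label: str = "control"
    case_label: str = "case"
    value_scale: str = "counts"
    # DE parameters
    alpha: float = 0.05
    fc_hi: float = 2.0
    fc_lo: float = 0.5
    use_voom_weights: bool = False
    drop_na_policy: str = "drop_gene"
    # cluster-number parameters
    k_min: int = 2
    k_max: int | None = None
    bootstrap_r: int = 50
    # CV parameters
    cv_folds: int = 10
    cv_repeats: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_min < 2:
            raise ValueError("k_min must be >= 2")
        for name in ("alpha", "fc_hi", "fc_lo"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)


# per-stage seed offsets: all randomness flows from config.seed
_STAGE_SEED = {"cluster_number": 1, "kmeans_modules": 2, "cv": 3}


def _stage_seed(seed: int, stage: str) -> int:
    return (seed * 7919 + _STAGE_SEED[stage]) % (2**31)


def run_pipeline(
    config: PipelineConfig,
    X: ExpressionMatrix | None = None,
    groups: GroupLabels | None = None,
) -> dict:
    """Execute the full pipeline; returns the manifest dictionary.

    ``X``/``groups`` may be passed in-memory (e.g. straight from the synthetic
    generator); otherwise they are read from the configured paths.
    """
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config": config.to_dict(),
        "stages": {},
    }

    def stage(name):
        logger.info("stage: %s (t=%.1fs)", name, time.time() - t0)
        return manifest["stages"].setdefault(name, {})

    if X is None:
        X = read_expression(config.expression_path, value_scale=config.value_scale)
    if groups is None:
        groups = read_groups(
            config.phenotype_path, config.control_label, config.case_label
        )
    X, groups = align_samples(X, groups)
    stage("input")["n_genes"] = X.n_genes
    stage("input")["n_samples"] = X.n_samples
    stage("input")["n_control"] = len(groups.control_samples)
    stage("input")["n_case"] = len(groups.case_samples)

    # 1. prefilter
    Xf, report = prefilter(X, drop_na_policy=config.drop_na_policy)
    # 2. normalization for DE: log-CPM when counts, as-is otherwise
    if Xf.value_scale == "counts":
        Y = log_cpm(Xf)
    else:
        logger.warning(
            "input value_scale=%r: skipping log-CPM, using values as-is for DE",
            Xf.value_scale,
        )
        Y = Xf
    weights = None
    if config.use_voom_weights and Xf.value_scale == "counts":
        weights = voom_weights(Y, groups)
    # 3. moderated DE test + volcano bi-filter
    de, prior = moderated_test(
        Y, groups, weights=weights, alpha=config.alpha,
        fc_hi=config.fc_hi, fc_lo=config.fc_lo,
    )
    de.to_csv(out / "de_table.tsv", sep="\t", index=False)
    up, down = volcano_filter(de, config.alpha, config.fc_hi, config.fc_lo)
    degs = [g for g in de["gene_id"] if g in set(up) | set(down)]
    s = stage("de")
    s.update(
        n_genes_tested=int(len(de)), n_up=len(up), n_down=len(down),
        n_deg=len(degs), ebayes_d0=float(prior.d0), ebayes_s0_sq=float(prior.s0_sq),
    )
    if len(degs) < 2 * config.k_min:
        raise RuntimeError(
            f"only {len(degs)} differentially expressed genes: too few to cluster"
        )

    # 4. gene-wise standardization of the DEG matrix for clustering
    Z = standardize_genes(Y.subset_genes(degs), report)
    with open(out / "preprocess_report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)

    # 5. Pareto-optimal cluster size
    k_max = config.k_max
    if k_max is not None:
        k_max = min(k_max, Z.n_genes // 2)
    M = objective_matrix(
        Z.values, k_min=config.k_min, k_max=k_max, R=config.bootstrap_r,
        seed=_stage_seed(config.seed, "cluster_number"),
    )
    M.to_csv(out / "objective_matrix.tsv", sep="\t")
    pareto = pareto_rank(M)
    pareto.to_json(out / "pareto.json")
    stage("cluster_number").update(
        k_candidates=[int(k) for k in M.index], selected_k=int(pareto.selected_k),
        pareto_k=[int(k) for k in pareto.pareto_k],
    )

    # 6. module extraction at the selected K
    part = kmeans(
        Z.values, pareto.selected_k,
        seed=_stage_seed(config.seed, "kmeans_modules"), object_ids=Z.gene_ids,
    )
    pd.DataFrame({"gene_id": part.object_ids, "cluster": part.labels}).to_csv(
        out / "clusters.tsv", sep="\t", index=False
    )

    # 7. module scoring and signature selection
    scores = score_modules(Z, part, de)
    module_scores_frame(scores).to_csv(out / "module_scores.tsv", sep="\t", index=False)
    sig = pick_signature(scores, part)
    sig.to_tsv(out / "signature.tsv")
    stage("signature").update(
        n_genes=len(sig.gene_ids), source_cluster=int(sig.source_cluster),
        avg_spearman=float(sig.score),
    )

    # 8. nearest-shrunken-centroid validation
    X_sig = Y.subset_genes(sig.gene_ids)
    cv = evaluate_signature(
        X_sig, groups, repeats=config.cv_repeats, folds=config.cv_folds,
        seed=_stage_seed(config.seed, "cv"),
    )
    cv.to_tsv(out / "cv_report.tsv")
    cv.to_json(out / "cv_report.json")
    stage("cv").update(
        {m: float(cv.summary.loc[m, "mean"]) for m in cv.summary.index}
    )

    manifest["runtime_seconds"] = round(time.time() - t0, 2)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    logger.info("pipeline done in %.1fs -> %s", time.time() - t0, out)
    return manifest
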