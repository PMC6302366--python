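"""Synthetic expression data with planted DE genes and correlated gene modules.

The generator emulates the structure the pipeline assumes: two unbalanced
sample groups, a subset of genes with a planted group effect, and correlated
gene modules of known number and membership. Module correlation uses a single
latent factor per module: a member gene's log2 expression is

    baseline_g + sqrt(rho) * f_m(sample) + sqrt(1 - rho) * noise_sd * eps

so the expected pairwise Pearson correlation within a module is rho (for
noise_sd = 1). Counts, when requested, are Poisson draws around the
exponentiated log2 expression.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .data_io import ExpressionMatrix, GroupLabels


@dataclass
class SyntheticConfig:
    """Parameters of the planted-structure generator.

    ``module_rhos`` / ``module_directions`` optionally override the scalar
    ``within_module_rho`` and the sign of ``log2_effect`` per module
    (direction +1 = up in cases, -1 = down, 0 = no effect).
    """

    n_genes: int = 1000
    n_control: int = 22
    n_case: int = 253
    n_modules: int = 5
    genes_per_module: int = 35
    within_module_rho: float = 0.5
    de_fraction: float = 1.0
    log2_effect: float = 1.5
    noise_sd: float = 1.0
    count_model: Literal["lognormal_counts", "gaussian_log"] = "lognormal_counts"
    seed: int = 0
    baseline_range: tuple[float, float] = (4.0, 9.0)
    module_rhos: Sequence[float] | None = None
    module_directions: Sequence[int] | None = None

    def validate(self) -> None:
        problems = []
        if self.n_modules * self.genes_per_module > self.n_genes:
            problems.append(
                f"n_modules * genes_per_module = "
                f"{self.n_modules * self.genes_per_module} exceeds n_genes={self.n_genes}"
            )
        for name in ("n_genes", "n_control", "n_case", "n_modules", "genes_per_module"):
            if getattr(self, name) < 1:
                problems.append(f"{name} must be >= 1")
        if not 0 <= self.within_module_rho < 1:
            problems.append("within_module_rho must be in [0, 1)")
        if not 0 <= self.de_fraction <= 1:
            problems.append("de_fraction must be in [0, 1]")
        if self.noise_sd <= 0:
            problems.append("noise_sd must be positive")
        if self.module_rhos is not None and len(self.module_rhos) != self.n_modules:
            problems.append("module_rhos must have one entry per module")
        if (
            self.module_directions is not None
            and len(self.module_directions) != self.n_modules
        ):
            problems.append("module_directions must have one entry per module")
        if problems:
            raise ValueError("invalid SyntheticConfig: " + "; ".join(problems))


@dataclass
class GroundTruth:
    """Planted structure: per-gene module membership (0 = background) and DE status."""

    module_assignment: np.ndarray  # int per gene, 0 = background
    de_status: np.ndarray          # 'up' / 'down' / 'ns' per gene
    k_star: int

    def module_genes(self, gene_ids: list[str], m: int) -> list[str]:
        return [g for g, a in zip(gene_ids, self.module_assignment) if a == m]

    def to_json(self, path, gene_ids: list[str]) -> None:
        payload = {
            "k_star": int(self.k_star),
            "module_assignment": {
                g: int(a) for g, a in zip(gene_ids, self.module_assignment)
            },
            "de_status": {g: str(s) for g, s in zip(gene_ids, self.de_status)},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def generate(config: SyntheticConfig) -> tuple[ExpressionMatrix, GroupLabels, GroundTruth]:
    """Draw one dataset from the planted-structure model (deterministic per seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    G, S = config.n_genes, config.n_control + config.n_case
    n_mod = config.n_modules
    gpm = config.genes_per_module

    gene_ids = [f"G{i:05d}" for i in range(G)]
    sample_ids = [f"C{i:03d}" for i in range(config.n_control)] + [
        f"T{i:03d}" for i in range(config.n_case)
    ]
    case_mask = np.zeros(S, dtype=bool)
    case_mask[config.n_control:] = True

    rhos = (
        np.asarray(config.module_rhos, dtype=float)
        if config.module_rhos is not None
        else np.full(n_mod, config.within_module_rho)
    )
    directions = (
        np.asarray(config.module_directions, dtype=int)
        if config.module_directions is not None
        else np.ones(n_mod, dtype=int)
    )

    module = np.zeros(G, dtype=int)
    for m in range(n_mod):
        module[m * gpm:(m + 1) * gpm] = m + 1

    baseline = rng.uniform(*config.baseline_range, size=G)
    factors = rng.standard_normal((n_mod, S))
    eps = rng.standard_normal((G, S)) * config.noise_sd

    log2expr = baseline[:, None] + eps
    for m in range(n_mod):
        rows = module == m + 1
        rho = rhos[m]
        log2expr[rows] = (
            baseline[rows][:, None]
            + np.sqrt(rho) * factors[m][None, :]
            + np.sqrt(1.0 - rho) * eps[rows]
        )

    de_status = np.full(G, "ns", dtype=object)
    for m in range(n_mod):
        if directions[m] == 0 or config.log2_effect == 0:
            continue
        rows = np.where(module == m + 1)[0]
        n_de = int(round(config.de_fraction * rows.size))
        de_rows = rows[:n_de]
        effect = directions[m] * config.log2_effect
        log2expr[np.ix_(de_rows, np.where(case_mask)[0])] += effect
        de_status[de_rows] = "up" if effect > 0 else "down"

    if config.count_model == "lognormal_counts":
        lam = 2.0 ** log2expr
        values = rng.poisson(lam).astype(float)
        scale = "counts"
    elif config.count_model == "gaussian_log":
        values = log2expr
        scale = "other"
    else:
        raise ValueError(f"unknown count_model {config.count_model!r}")

    X = ExpressionMatrix(gene_ids, sample_ids, values, scale)
    groups = GroupLabels(
        {s: ("case" if c else "control") for s, c in zip(sample_ids, case_mask)}
    )
    truth = GroundTruth(module_assignment=module, de_status=de_status, k_star=n_mod)
    return X, groups, truth


def make_paper_shaped(seed: int) -> tuple[ExpressionMatrix, GroupLabels, GroundTruth]:
    """Convenience preset mirroring the shape of the motivating cervical-cancer study.

    2,000 genes, 22 control + 253 case samples, five planted 35-gene modules:
    module 1 is a tight all-up-regulated module (rho = 0.8), modules 2-3 are
    looser up modules and modules 4-5 looser down modules (rho = 0.3).
    """
    config = SyntheticConfig(
        n_genes=2000,
        n_control=22,
        n_case=253,
        n_modules=5,
        genes_per_module=35,
        de_fraction=1.0,
        log2_effect=1.5,
        noise_sd=1.0,
        count_model="lognormal_counts",
        seed=seed,
        module_rhos=(0.8, 0.3, 0.3, 0.3, 0.3),
        module_directions=(1, 1, 1, -1, -1),
    )
    return generate(config)


def make_planted_k(
    k_star: int,
    seed: int,
    genes_per_module: int = 20,
    n_control: int = 20,
    n_case: int = 20,
    rho: float = 0.95,
) -> tuple[ExpressionMatrix, GroupLabels, GroundTruth]:
    """Preset for cluster-number recovery: K* tight modules, no background genes.

    With a latent-factor module model, between-module center separation in
    gene space scales as sqrt(2 rho S) while within-module spread per
    dimension is sqrt(1 - rho); at rho = 0.95 and S = 40 samples the
    separation is ~39x the within-module sd, comfortably above the planted
    separation this preset is meant to provide (>= 8x).
    """
    config = SyntheticConfig(
        n_genes=k_star * genes_per_module,
        n_control=n_control,
        n_case=n_case,
        n_modules=k_star,
        genes_per_module=genes_per_module,
        within_module_rho=rho,
        de_fraction=0.0,
        log2_effect=0.0,
        noise_sd=1.0,
        count_model="gaussian_log",
        seed=seed,
        baseline_range=(0.0, 0.0),
    )
    return generate(config)
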