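"""Module scoring by average pairwise Spearman correlation and signature picking.

After modules are extracted at the selected cluster number, each module is
scored by the mean Spearman correlation over all unordered gene pairs within
it (computed across all samples, both groups pooled); the module with the
highest score becomes the gene signature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cluster_algorithms import Partition
from .data_io import ExpressionMatrix

logger = logging.getLogger(__name__)


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman correlation: Pearson correlation of mid-ranks.

    Ties receive average ranks. Returns NaN (the undefined marker) when
    either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


@dataclass
class ModuleScore:
    """Per-module summary: size, up/down composition, average pairwise Spearman.

    ``avg_spearman`` is NaN for singleton modules (no pairs to correlate);
    such modules can never be selected as the signature.
    """

    cluster_id: int
    n_genes: int
    n_up: int
    n_down: int
    avg_spearman: float
    n_undefined_pairs: int = 0

    @property
    def scorable(self) -> bool:
        return self.n_genes >= 2 and np.isfinite(self.avg_spearman)


@dataclass
class Signature:
    """The selected gene signature: the best-correlated module's gene set."""

    gene_ids: list[str]
    source_cluster: int
    score: float

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError("signature must be non-empty")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("signature gene IDs must be unique")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\n")
            for g in self.gene_ids:
                fh.write(f"{g}\n")


def _pairwise_mean_spearman(rows: np.ndarray) -> tuple[float, int]:
    """Mean Spearman over all row pairs; pairs with a constant row excluded.

    Returns (mean, n_excluded_pairs); mean is NaN when no pair is defined.
    """
    m = rows.shape[0]
    ranks = np.apply_along_axis(stats.rankdata, 1, rows)
    const = np.ptp(rows, axis=1) == 0
    vals = []
    n_undef = 0
    # rank-correlation matrix in one shot; constant rows masked afterwards
    if m >= 2:
        with np.errstate(invalid="ignore", divide="ignore"):
            R = np.corrcoef(ranks)
        for i in range(m):
            for j in range(i + 1, m):
                if const[i] or const[j]:
                    n_undef += 1
                else:
                    vals.append(R[i, j])
    if not vals:
        return float("nan"), n_undef
    return float(np.mean(vals)), n_undef


def score_modules(
    X: ExpressionMatrix,
    P: Partition,
    de: pd.DataFrame | None = None,
) -> list[ModuleScore]:
    """Average pairwise Spearman correlation of every module in a partition.

    Pairs involving a constant gene vector are excluded from the mean and
    counted. When a DE table is given, each module's up/down composition is
    tallied from its ``status`` column.
    """
    pos = {g: i for i, g in enumerate(X.gene_ids)}
    missing = [g for g in P.object_ids if g not in pos]
    if missing:
        raise ValueError(f"partition object {missing[0]!r} not in expression matrix")
    status = {}
    if de is not None:
        status = dict(zip(de["gene_id"], de["status"]))
    scores = []
    for k in range(1, P.K + 1):
        genes = P.members(k)
        n_up = sum(1 for g in genes if status.get(g) == "up")
        n_down = sum(1 for g in genes if status.get(g) == "down")
        if len(genes) < 2:
            avg, n_undef = float("nan"), 0
        else:
            rows = X.values[[pos[g] for g in genes]]
            avg, n_undef = _pairwise_mean_spearman(rows)
        if n_undef:
            logger.info("cluster %d: %d undefined pairs excluded", k, n_undef)
        scores.append(
            ModuleScore(
                cluster_id=k, n_genes=len(genes), n_up=n_up, n_down=n_down,
                avg_spearman=avg, n_undefined_pairs=n_undef,
            )
        )
    return scores


def pick_signature(scores: list[ModuleScore], P: Partition) -> Signature:
    """Select the module with the highest average pairwise Spearman score.

    Ties are broken by larger module size, then smaller cluster id. Raises
    when no module has a defined score (all singletons/degenerate).
    """
    candidates = [s for s in scores if s.scorable]
    if not candidates:
        raise ValueError("no scorable module (all modules are singletons or degenerate)")
    best = max(candidates, key=lambda s: (s.avg_spearman, s.n_genes, -s.cluster_id))
    return Signature(
        gene_ids=P.members(best.cluster_id),
        source_cluster=best.cluster_id,
        score=best.avg_spearman,
    )


def module_scores_frame(scores: list[ModuleScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cluster_id": s.cluster_id,
                "n_genes": s.n_genes,
                "n_up": s.n_up,
                "n_down": s.n_down,
                "avg_spearman": s.avg_spearman,
                "n_undefined_pairs": s.n_undefined_pairs,
            }
            for s in scores
        ]
    )
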