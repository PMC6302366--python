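"""Pareto-optimal cluster-number selection from bootstrap stability objectives.

For every candidate K, each of three clustering backends (k-means, neural gas,
single linkage) is scored under four partition-agreement indices (MCA, Jaccard,
Fowlkes-Mallows, CQS) computed between a full-data reference clustering and
clusterings of bootstrap resamples — twelve objectives in total. Candidates
are then ranked by Pareto dominance over the twelve objectives.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .cluster_algorithms import BACKENDS, Partition

logger = logging.getLogger(__name__)

ALGORITHMS = ("kmeans", "neuralgas", "single")
INDICES = ("MCA", "Jaccard", "FM", "CQS")
OBJECTIVE_NAMES = [f"{a}.{i}" for a in ALGORITHMS for i in INDICES]


def _check_shared_objects(P: Partition, Q: Partition) -> None:
    if P.object_ids != Q.object_ids:
        if sorted(P.object_ids) == sorted(Q.object_ids):
            raise ValueError("partitions share objects but in different order")
        raise ValueError("partitions are over different object sets")


def _contingency(P: Partition, Q: Partition) -> np.ndarray:
    C = np.zeros((P.K, Q.K), dtype=np.int64)
    for a, b in zip(P.labels, Q.labels):
        C[a - 1, b - 1] += 1
    return C


def pair_counts(P: Partition, Q: Partition) -> tuple[int, int, int, int]:
    """Counts of object pairs co-clustered in both / only P / only Q / neither.

    Computed from the contingency table; N11+N10+N01+N00 = n(n-1)/2.
    """
    _check_shared_objects(P, Q)
    C = _contingency(P, Q)
    n = len(P.object_ids)
    total = n * (n - 1) // 2

    def comb2(x):
        return int((x * (x - 1) // 2).sum())

    n11 = comb2(C.ravel())
    n10 = comb2(C.sum(axis=1)) - n11
    n01 = comb2(C.sum(axis=0)) - n11
    n00 = total - n11 - n10 - n01
    return n11, n10, n01, n00


def cqs_default(P: Partition, Q: Partition) -> float:
    """Chance-corrected agreement: the adjusted Rand index mapped into [0, 1].

    ARI is computed from the pair counts,
    2(N11 N00 - N10 N01) / ((N11+N10)(N10+N00) + (N11+N01)(N01+N00));
    a zero denominator means the partitions have identical pair structure
    (ARI = 1).
    """
    n11, n10, n01, n00 = pair_counts(P, Q)
    denom = (n11 + n10) * (n10 + n00) + (n11 + n01) * (n01 + n00)
    ari = 2.0 * (n11 * n00 - n10 * n01) / denom if denom else 1.0
    return float(np.clip((ari + 1.0) / 2.0, 0.0, 1.0))


def agreement_indices(P: Partition, Q: Partition, cqs_fn=cqs_default) -> dict[str, float]:
    """The four partition-agreement indices used as stability objectives.

    jaccard = N11/(N11+N10+N01); fm = N11/sqrt((N11+N10)(N11+N01)); mca is
    the fraction of objects in the best one-to-one matching of clusters
    (maximum-weight assignment on the contingency table); cqs is pluggable,
    defaulting to chance-corrected agreement. All lie in [0, 1]; degenerate
    denominators yield 0 for jaccard/fm.
    """
    n11, n10, n01, _ = pair_counts(P, Q)
    denom_j = n11 + n10 + n01
    jaccard = n11 / denom_j if denom_j else 0.0
    f1, f2 = n11 + n10, n11 + n01
    fm = n11 / np.sqrt(f1 * f2) if f1 and f2 else 0.0
    C = _contingency(P, Q)
    rows, cols = linear_sum_assignment(C, maximize=True)
    mca = C[rows, cols].sum() / len(P.object_ids)
    return {
        "mca": float(mca),
        "jaccard": float(jaccard),
        "fm": float(fm),
        "cqs": float(cqs_fn(P, Q)),
    }


def _bootstrap_agreement(
    X: np.ndarray,
    K: int,
    algo: str,
    R: int,
    seed: int,
    cqs_fn=cqs_default,
) -> dict[str, float]:
    """Mean of each agreement index over R bootstrap replicates.

    The reference partition is the backend run on the full matrix; each
    replicate resamples objects with replacement, clusters the resample, and
    is compared against the reference restricted to the unique objects drawn
    (taking each duplicated object's label from its first occurrence).
    """
    if K < 2:
        raise ValueError("bootstrap stability needs K >= 2")
    if R < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    backend = BACKENDS[algo]
    n = X.shape[0]
    ids = [str(i) for i in range(n)]
    ref = backend(X, K, seed)
    sums = dict.fromkeys(("mca", "jaccard", "fm", "cqs"), 0.0)
    for r in range(R):
        rng = np.random.default_rng(seed + r)
        for attempt in range(10):
            idx = rng.choice(n, size=n, replace=True)
            uniq, first_pos = np.unique(idx, return_index=True)
            if len(uniq) >= K:
                break
        else:
            raise RuntimeError(
                f"could not draw a bootstrap replicate with >= {K} unique objects"
            )
        rep = backend(X[idx], K, seed + r)
        uniq_ids = [ids[u] for u in uniq]
        rep_on_uniq = _restrict(rep, first_pos, uniq_ids)
        ref_on_uniq = _restrict(ref, uniq, uniq_ids)
        scores = agreement_indices(rep_on_uniq, ref_on_uniq, cqs_fn=cqs_fn)
        for k, v in scores.items():
            sums[k] += v
    return {k: v / R for k, v in sums.items()}


def _restrict(P: Partition, positions: np.ndarray, new_ids: list[str]) -> Partition:
    """Partition restricted to ``positions`` with labels renumbered densely."""
    labels = P.labels[positions]
    uniq = {l: i + 1 for i, l in enumerate(dict.fromkeys(labels.tolist()))}
    dense = np.array([uniq[l] for l in labels.tolist()])
    return Partition(new_ids, dense, K=len(uniq))


def bootstrap_objective(
    X: np.ndarray,
    K: int,
    algo: str,
    index: str,
    R: int = 50,
    seed: int = 0,
    cqs_fn=cqs_default,
) -> float:
    """Mean bootstrap stability of one (algorithm, index) pair at cluster size K."""
    index = index.lower()
    if index not in ("mca", "jaccard", "fm", "cqs"):
        raise ValueError(f"unknown index {index!r}")
    return _bootstrap_agreement(X, K, algo, R, seed, cqs_fn=cqs_fn)[index]


def _cell_seed(seed: int, K: int, algo: str) -> int:
    return (seed * 1009 + 101 * K + 17 * ALGORITHMS.index(algo)) % (2**31)


def objective_matrix(
    X: np.ndarray,
    k_min: int = 2,
    k_max: int | None = None,
    R: int = 50,
    seed: int = 0,
    cqs_fn=cqs_default,
) -> pd.DataFrame:
    """Candidate-K x 12 table of bootstrap stability objectives.

    Rows are candidate cluster sizes k_min..k_max, columns the cross product
    of the three backends and four indices, in the fixed order
    kmeans.MCA ... single.CQS. Per-(K, algorithm) seeds are derived
    deterministically from ``seed``, so the matrix is reproducible bit for bit.
    """
    n = X.shape[0]
    if k_max is None:
        k_max = max(k_min, min(15, n // 10))
    if not (2 <= k_min <= k_max):
        raise ValueError("need 2 <= k_min <= k_max")
    if k_max > n // 2:
        raise ValueError(f"k_max={k_max} exceeds n/2 = {n // 2}")
    rows = {}
    for K in range(k_min, k_max + 1):
        row = {}
        for algo in ALGORITHMS:
            scores = _bootstrap_agreement(
                X, K, algo, R, _cell_seed(seed, K, algo), cqs_fn=cqs_fn
            )
            for idx_name in INDICES:
                row[f"{algo}.{idx_name}"] = scores[idx_name.lower()]
        rows[K] = row
        logger.info("objectives for K=%d done", K)
    M = pd.DataFrame.from_dict(rows, orient="index")[OBJECTIVE_NAMES]
    M.index.name = "K"
    if not np.isfinite(M.to_numpy()).all():
        raise RuntimeError("non-finite objective score")
    return M


@dataclass
class ParetoResult:
    """Non-dominated candidate cluster sizes and their dominance ranking."""

    pareto_k: list[int]
    #: rows = Pareto-optimal K, columns = every other candidate K'; entries =
    #: number of objectives on which K strictly beats K'
    dominance_counts: pd.DataFrame
    rank_key: dict[int, int]
    selected_k: int

    def to_dict(self) -> dict:
        return {
            "pareto_k": [int(k) for k in self.pareto_k],
            "dominance_counts": {
                str(k): {str(c): int(v) for c, v in row.items() if np.isfinite(v)}
                for k, row in self.dominance_counts.iterrows()
            },
            "rank_key": {str(k): int(v) for k, v in self.rank_key.items()},
            "selected_k": int(self.selected_k),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def pareto_rank(M: pd.DataFrame, tie_break: str = "smallest_k") -> ParetoResult:
    """Non-dominated set and dominance ranking of candidate cluster sizes.

    K dominates K' when K is >= K' on all objectives and > on at least one.
    Pareto-optimal candidates are ordered by descending total dominance count
    (the sum over other candidates of the number of objectives on which the
    candidate strictly beats them); ties broken by smaller K.
    """
    if tie_break != "smallest_k":
        raise ValueError("only the smallest_k tie-break is implemented")
    S = M.to_numpy(dtype=float)
    if not np.isfinite(S).all():
        raise ValueError("objective matrix must be finite")
    ks = [int(k) for k in M.index]
    m = len(ks)
    dominated = np.zeros(m, dtype=bool)
    for i in range(m):
        for j in range(m):
            if i != j and np.all(S[j] >= S[i]) and np.any(S[j] > S[i]):
                dominated[i] = True
                break
    pareto = [ks[i] for i in range(m) if not dominated[i]]
    counts = {}
    for i in (i for i in range(m) if not dominated[i]):
        counts[ks[i]] = {
            ks[j]: int((S[i] > S[j]).sum()) for j in range(m) if j != i
        }
    dom = pd.DataFrame.from_dict(counts, orient="index")
    dom.index.name = "K"
    rank_key = {k: int(sum(counts[k].values())) for k in pareto}
    ordering = sorted(pareto, key=lambda k: (-rank_key[k], k))
    return ParetoResult(
        pareto_k=ordering,
        dominance_counts=dom.loc[ordering] if not dom.empty else dom,
        rank_key=rank_key,
        selected_k=ordering[0],
    )
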