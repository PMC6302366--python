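import itertools

import numpy as np
import pandas as pd
import pytest

from paretosig.cluster_algorithms import Partition
from paretosig.cluster_number import (
    OBJECTIVE_NAMES,
    agreement_indices,
    bootstrap_objective,
    cqs_default,
    objective_matrix,
    pair_counts,
    pareto_rank,
)


def part(labels, ids=None):
    labels = np.asarray(labels)
    ids = ids or [str(i) for i in range(len(labels))]
    return Partition(list(ids), labels, K=len(np.unique(labels)))


# ---------- brute-force oracles ----------

def brute_pair_counts(p, q):
    """O(n^2) enumeration of object pairs."""
    n = len(p.labels)
    n11 = n10 = n01 = n00 = 0
    for i in range(n):
        for j in range(i + 1, n):
            a = p.labels[i] == p.labels[j]
            b = q.labels[i] == q.labels[j]
            n11 += a and b
            n10 += a and not b
            n01 += b and not a
            n00 += not a and not b
    return n11, n10, n01, n00


def brute_mca(p, q):
    """Exhaustive max over one-to-one cluster matchings."""
    n = len(p.labels)
    if p.K <= q.K:
        a_lab, b_lab, ka, kb = p.labels, q.labels, p.K, q.K
    else:
        a_lab, b_lab, ka, kb = q.labels, p.labels, q.K, p.K
    best = 0
    for perm in itertools.permutations(range(1, kb + 1), ka):
        tot = sum(
            int(np.sum((a_lab == a) & (b_lab == b)))
            for a, b in zip(range(1, ka + 1), perm)
        )
        best = max(best, tot)
    return best / n


def brute_indices(p, q):
    n11, n10, n01, n00 = brute_pair_counts(p, q)
    jac = n11 / (n11 + n10 + n01) if (n11 + n10 + n01) else 0.0
    f1, f2 = n11 + n10, n11 + n01
    fm = n11 / np.sqrt(f1 * f2) if f1 and f2 else 0.0
    return {"mca": brute_mca(p, q), "jaccard": jac, "fm": fm}


# ---------- pair_counts ----------

class TestPairCounts:
    def test_identical_partitions(self):
        p = part([1, 1, 2], ["a", "b", "c"])
        assert pair_counts(p, p) == (1, 0, 0, 2)

    def test_one_cluster_vs_singletons(self):
        p = part([1, 1, 1], ["a", "b", "c"])
        q = part([1, 2, 3], ["a", "b", "c"])
        assert pair_counts(p, q) == (0, 3, 0, 0)

    def test_derived_example(self):
        p = part([1, 1, 2, 2])
        q = part([1, 1, 1, 2])
        assert pair_counts(p, q) == (1, 1, 2, 2)
        assert brute_pair_counts(p, q) == (1, 1, 2, 2)

    def test_mismatched_objects_rejected(self):
        with pytest.raises(ValueError, match="different"):
            pair_counts(part([1, 2], ["a", "b"]), part([1, 2], ["a", "z"]))

    def test_sums_to_total_pairs_random(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(3, 12)
            p = part(canon(rng.integers(0, 3, n)))
            q = part(canon(rng.integers(0, 4, n)))
            counts = pair_counts(p, q)
            assert sum(counts) == n * (n - 1) // 2


def canon(labels):
    _, inv = np.unique(labels, return_inverse=True)
    return inv + 1


# ---------- agreement_indices ----------

class TestAgreementIndices:
    def test_identity_gives_all_ones(self):
        p = part([1, 1, 2, 3, 3])
        out = agreement_indices(p, p)
        assert out == {"mca": 1.0, "jaccard": 1.0, "fm": 1.0, "cqs": 1.0}

    def test_derived_example(self):
        p = part([1, 1, 2, 2])
        q = part([1, 1, 1, 2])
        out = agreement_indices(p, q)
        assert out["jaccard"] == 0.25
        np.testing.assert_allclose(out["fm"], 1 / np.sqrt(6))
        assert out["mca"] == 0.75

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(4, 15))
            p = part(canon(rng.integers(0, 4, n)))
            q = part(canon(rng.integers(0, 4, n)))
            got = agreement_indices(p, q)
            want = brute_indices(p, q)
            for key, val in want.items():
                assert got[key] == pytest.approx(val, abs=0), key

    def test_cqs_matches_sklearn_adjusted_rand(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(4, 20))
            p = part(canon(rng.integers(0, 4, n)))
            q = part(canon(rng.integers(0, 5, n)))
            ari = adjusted_rand_score(p.labels, q.labels)
            np.testing.assert_allclose(cqs_default(p, q), (ari + 1) / 2, atol=1e-12)

    def test_mca_one_iff_identical_up_to_relabeling(self):
        p = part([1, 1, 2, 3])
        q = part([2, 2, 3, 1])   # same partition, relabeled
        r = part([1, 2, 2, 3])   # genuinely different
        assert agreement_indices(p, q)["mca"] == 1.0
        assert agreement_indices(p, r)["mca"] < 1.0


# ---------- bootstrap objectives ----------

class TestBootstrapObjective:
    def test_separated_blobs_are_stable(self, two_blobs):
        X, _ = two_blobs
        for seed in range(5):
            for index in ("mca", "jaccard", "fm"):
                val = bootstrap_objective(X, 2, "kmeans", index, R=20, seed=seed)
                assert val >= 0.95, (seed, index)

    def test_overfit_k_less_stable_than_k2_on_noise(self):
        vals = {2: [], 6: []}
        for seed in range(5):
            X = np.random.default_rng(100 + seed).standard_normal((60, 10))
            for k in (2, 6):
                vals[k].append(
                    bootstrap_objective(X, k, "kmeans", "jaccard", R=20, seed=seed)
                )
        assert np.mean(vals[6]) < np.mean(vals[2])

    def test_duplicate_rows_do_not_crash(self):
        X = np.tile(np.arange(10, dtype=float).reshape(-1, 1), (2, 3))
        val = bootstrap_objective(X, 2, "single", "jaccard", R=2, seed=0)
        assert 0.0 <= val <= 1.0

    def test_invalid_k_and_r(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        with pytest.raises(ValueError):
            bootstrap_objective(X, 1, "kmeans", "jaccard", R=10, seed=0)
        with pytest.raises(ValueError):
            bootstrap_objective(X, 2, "kmeans", "jaccard", R=1, seed=0)


@pytest.fixture(scope="module")
def small_matrix():
    rng = np.random.default_rng(3)
    X = np.vstack([rng.normal(c, 0.3, size=(10, 6)) for c in (-4.0, 0.0, 4.0)])
    return objective_matrix(X, k_min=2, k_max=4, R=10, seed=9)


class TestObjectiveMatrix:

    def test_exactly_twelve_named_columns(self, small_matrix):
        assert list(small_matrix.columns) == OBJECTIVE_NAMES
        assert list(small_matrix.columns) == [
            "kmeans.MCA", "kmeans.Jaccard", "kmeans.FM", "kmeans.CQS",
            "neuralgas.MCA", "neuralgas.Jaccard", "neuralgas.FM", "neuralgas.CQS",
            "single.MCA", "single.Jaccard", "single.FM", "single.CQS",
        ]

    def test_scores_in_unit_interval(self, small_matrix):
        vals = small_matrix.to_numpy()
        assert ((vals >= 0) & (vals <= 1)).all()

    def test_same_seed_bitwise_identical(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(24, 5))
        a = objective_matrix(X, k_min=2, k_max=3, R=5, seed=7)
        b = objective_matrix(X, k_min=2, k_max=3, R=5, seed=7)
        pd.testing.assert_frame_equal(a, b, check_exact=True)

    def test_k_max_bounded_by_half_n(self):
        X = np.random.default_rng(5).normal(size=(10, 3))
        with pytest.raises(ValueError, match="n/2"):
            objective_matrix(X, k_min=2, k_max=8, R=5, seed=0)


# ---------- pareto ranking ----------

def brute_nondominated(S):
    m = S.shape[0]
    out = []
    for i in range(m):
        dominated = False
        for j in range(m):
            if i != j and all(S[j] >= S[i]) and any(S[j] > S[i]):
                dominated = True
        if not dominated:
            out.append(i)
    return out


class TestParetoRank:
    def _frame(self, scores, ks=None):
        scores = np.asarray(scores, dtype=float)
        ks = ks or list(range(2, 2 + scores.shape[0]))
        M = pd.DataFrame(scores, index=ks)
        M.index.name = "K"
        return M

    def test_single_dominant_row(self):
        M = self._frame([[0.9, 0.9], [0.5, 0.5], [0.9, 0.8]])
        res = pareto_rank(M)
        assert res.pareto_k == [2]
        assert res.selected_k == 2

    def test_all_identical_rows_tie_to_smallest_k(self):
        M = self._frame([[0.5, 0.5]] * 4)
        res = pareto_rank(M)
        assert res.pareto_k == [2, 3, 4, 5]
        assert all(v == 0 for v in res.rank_key.values())
        assert res.selected_k == 2

    def test_three_way_tradeoff_all_nondominated(self):
        M = self._frame([[0.9, 0.1], [0.1, 0.9], [0.5, 0.5]])
        res = pareto_rank(M)
        assert sorted(res.pareto_k) == [2, 3, 4]

    def test_matches_exhaustive_dominance_on_random(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            S = rng.random((8, 12))
            M = self._frame(S)
            res = pareto_rank(M)
            want = {int(M.index[i]) for i in brute_nondominated(S)}
            assert set(res.pareto_k) == want

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(7)
        S = rng.random((6, 12))
        M = self._frame(S)
        perm = rng.permutation(6)
        M2 = M.iloc[perm]
        a, b = pareto_rank(M), pareto_rank(M2)
        assert a.pareto_k == b.pareto_k
        assert a.selected_k == b.selected_k
        assert a.rank_key == b.rank_key

    def test_dominance_counts_match_definition(self):
        rng = np.random.default_rng(8)
        S = rng.random((5, 12))
        M = self._frame(S)
        res = pareto_rank(M)
        for k in res.pareto_k:
            i = list(M.index).index(k)
            for k2 in M.index:
                if k2 == k:
                    continue
                j = list(M.index).index(k2)
                assert res.dominance_counts.loc[k, k2] == int((S[i] > S[j]).sum())
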