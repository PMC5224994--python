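"""Tests of the comparator scaling-factor methods.

All factors are on the c = S2/S1 scale of the exact test: on non-DE genes
the depth-normalized count of library 1 is c times that of library 2, so a
pair whose library-2 counts are double its library-1 counts at equal depth
has c = 1/2.
"""

import numpy as np
import pytest

from htnorm.baselines import (bull_factor, imm_factor, library_size_factor,
                              nhks_factor, tmm_factor)
from htnorm.simulate import SimConfig, estimate_factor, simulate_pair
from htnorm.de import pool_replicates
from htnorm.types import CountMatrix, CountPair, HousekeepingSet


def _random_pair(n=200, seed=0, mean1=100, mean2=150, N1=500_000, N2=400_000):
    rng = np.random.default_rng(seed)
    y1 = rng.poisson(mean1, n) + 1
    y2 = rng.poisson(mean2, n) + 1
    return CountPair(tuple(f"g{i}" for i in range(n)), y1, y2, N1, N2)


class TestLibrarySize:
    def test_always_one(self):
        res = library_size_factor()
        assert res.c_hat == 1.0
        assert res.method == "library_size"


class TestTMM:
    def test_identical_libraries(self):
        pair = _random_pair(seed=1, mean2=100, N1=100_000, N2=100_000)
        pair = CountPair(pair.gene_ids, pair.y1, pair.y1, 100_000, 100_000)
        assert tmm_factor(pair).c_hat == pytest.approx(1.0)

    def test_doubled_second_library(self):
        y1 = np.arange(1, 101)
        pair = CountPair(tuple(f"g{i}" for i in range(100)), y1, 2 * y1,
                         10_000, 10_000)
        # library 2 doubled at equal depth: S2/S1 = 1/2
        assert tmm_factor(pair).c_hat == pytest.approx(0.5)

    def test_matches_bruteforce_oracle(self):
        pair = _random_pair(seed=42)
        trim_M, trim_A = 0.30, 0.05
        # straight-line reimplementation of trim-then-weighted-mean
        y1, y2 = pair.y1.astype(float), pair.y2.astype(float)
        N1, N2 = pair.N1, pair.N2
        M = np.log2((y2 / N2) / (y1 / N1))
        A = 0.5 * np.log2((y2 / N2) * (y1 / N1))
        w = 1.0 / ((N1 - y1) / (N1 * y1) + (N2 - y2) / (N2 * y2))
        n = len(M)
        keep = np.ones(n, bool)
        kM = int(np.floor(n * trim_M / 2))
        oM = np.argsort(M, kind="stable")
        keep[oM[:kM]] = False
        keep[oM[n - kM:]] = False
        kA = int(np.floor(n * trim_A / 2))
        oA = np.argsort(A, kind="stable")
        keep[oA[:kA]] = False
        keep[oA[n - kA:]] = False
        expected = 2.0 ** (-np.sum(w[keep] * M[keep]) / np.sum(w[keep]))
        assert tmm_factor(pair).c_hat == pytest.approx(expected, rel=1e-12)

    def test_zero_genes_excluded(self):
        pair = CountPair(("a", "b", "c"), [10, 0, 10], [10, 5, 10], 100, 100)
        assert tmm_factor(pair, trim_M=0.0, trim_A=0.0).c_hat == \
            pytest.approx(1.0)


class TestIMM:
    def test_identical_libraries(self):
        y = np.arange(1, 51)
        pair = CountPair(tuple(f"g{i}" for i in range(50)), y, y, 1000, 1000)
        assert imm_factor(pair).c_hat == pytest.approx(1.0)

    def test_tripled_second_library(self):
        y = np.arange(1, 51)
        pair = CountPair(tuple(f"g{i}" for i in range(50)), y, 3 * y,
                         1000, 1000)
        assert imm_factor(pair).c_hat == pytest.approx(1.0 / 3.0)

    def test_equals_direct_median_of_ratios(self):
        pair = _random_pair(n=101, seed=8)
        ratios = (pair.y1 / pair.N1) / (pair.y2 / pair.N2)
        assert imm_factor(pair).c_hat == pytest.approx(
            float(np.median(ratios)), rel=1e-9)


class TestBull:
    def test_equal_counts_equal_depth(self):
        pair = CountPair(("h", "x"), [10, 99], [10, 1], 1000, 1000)
        assert bull_factor(pair, "h").c_hat == pytest.approx(1.0)

    def test_threefold_anchor(self):
        pair = CountPair(("h",), [10], [30], 1000, 1000)
        # anchor gene 3x higher in library 2 at equal depth: c = 1/3
        assert bull_factor(pair, "h").c_hat == pytest.approx(1.0 / 3.0)

    def test_depth_enters_through_normalization(self):
        pair = CountPair(("h",), [10], [10], 2000, 1000)
        assert bull_factor(pair, "h").c_hat == pytest.approx(0.5)

    def test_zero_count_anchor_rejected(self):
        pair = CountPair(("h",), [0], [10], 1000, 1000)
        with pytest.raises(ValueError):
            bull_factor(pair, "h")
        with pytest.raises(ValueError):
            bull_factor(pair, "absent")


def _toy_matrix(counts, n_reps=2):
    counts = np.asarray(counts)
    n = counts.shape[0]
    return CountMatrix(
        tuple(f"g{i}" for i in range(n)), counts,
        tuple(f"s{j}" for j in range(counts.shape[1])),
        ("c1",) * n_reps + ("c2",) * (counts.shape[1] - n_reps),
    )


class TestNHKS:
    def test_proportional_hk_genes_recover_common_ratio(self):
        rng = np.random.default_rng(0)
        base = rng.integers(50, 500, size=30)
        # second condition's samples carry double the relative signal
        counts = np.column_stack([base, base, 2 * base, 2 * base])
        matrix = _toy_matrix(counts)
        hk = HousekeepingSet([f"g{i}" for i in range(20)])
        res = nhks_factor(matrix, hk, k=15)
        # all samples proportional: normalized ratios are exactly 1
        assert res.c_hat == pytest.approx(1.0)

    def test_cv_ranking_matches_hand_computation(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(10, 1000, size=(20, 4))
        matrix = _toy_matrix(counts)
        hk = HousekeepingSet([f"g{i}" for i in range(20)])
        norm = counts / counts.sum(axis=0, keepdims=True)
        cv = norm.std(axis=1, ddof=1) / norm.mean(axis=1)
        chosen = sorted(range(20), key=lambda i: (cv[i], f"g{i}"))[:3]
        pooled = pool_replicates(matrix)
        y1 = sum(pooled.y1[i] for i in chosen) / pooled.N1
        y2 = sum(pooled.y2[i] for i in chosen) / pooled.N2
        res = nhks_factor(matrix, hk, k=3)
        assert res.c_hat == pytest.approx(y1 / y2, rel=1e-12)

    def test_single_sample_per_condition_rejected(self):
        counts = np.array([[10, 20], [30, 40]])
        matrix = CountMatrix(("g0", "g1"), counts, ("s0", "s1"),
                             ("c1", "c2"))
        with pytest.raises(ValueError, match="single sample"):
            nhks_factor(matrix, HousekeepingSet(["g0"]), k=1)

    def test_k_larger_than_candidates_rejected(self):
        matrix = _toy_matrix(np.full((5, 4), 100))
        with pytest.raises(ValueError):
            nhks_factor(matrix, HousekeepingSet(["g0", "g1"]), k=3)


class TestSharedInvariants:
    @pytest.mark.parametrize("factor", [tmm_factor, imm_factor])
    def test_common_multiple_invariance(self, factor):
        pair = _random_pair(seed=4)
        scaled = CountPair(pair.gene_ids, 3 * pair.y1, 3 * pair.y2,
                           3 * pair.N1, 3 * pair.N2)
        assert factor(scaled).c_hat == pytest.approx(factor(pair).c_hat,
                                                     rel=1e-9)

    def test_swap_antisymmetry(self):
        pair = _random_pair(seed=6)
        assert tmm_factor(pair.swap()).c_hat == pytest.approx(
            1.0 / tmm_factor(pair).c_hat, rel=1e-9)
        # odd gene count: the median is a single ratio, so inversion is exact
        odd = _random_pair(n=201, seed=6)
        assert imm_factor(odd.swap()).c_hat == pytest.approx(
            1.0 / imm_factor(odd).c_hat, rel=1e-9)
        assert bull_factor(pair.swap(), "g0").c_hat == pytest.approx(
            1.0 / bull_factor(pair, "g0").c_hat, rel=1e-9)

    def test_all_methods_near_one_on_symmetric_null(self):
        """No DE, equal depths: every method's factor sits in [0.95, 1.05]."""
        config = SimConfig(n_genes=10_000, de_rate=0.0, unique_rate=0.0,
                           n_reps=2, seed=17)
        matrix, truth = simulate_pair(config)
        pair = pool_replicates(matrix)
        hk = HousekeepingSet(g for g, f in zip(truth.gene_ids,
                                               truth.is_housekeeping) if f)
        for method in ("htn", "library", "tmm", "imm", "bull", "nhks"):
            c = estimate_factor(method, pair, matrix, hk).c_hat
            assert 0.95 <= c <= 1.05, method
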