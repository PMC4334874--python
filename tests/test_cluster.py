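import itertools

import numpy as np
import pytest
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

import gbdtax as gx
from gbdtax.cluster import (
    Partition,
    clustering_consistency,
    default_threshold_grid,
    optimize_against_reference,
    optimize_subspecies_threshold,
)
from gbdtax.distance import DistanceMatrix


def dmatrix(labels, v):
    return DistanceMatrix(tuple(labels), np.asarray(v, dtype=float))


def block_matrix(sizes, within, between, rng=None, jitter=0.0):
    """Planted block-diagonal matrix; returns (matrix, truth partition)."""
    labels = []
    group = []
    for g, s in enumerate(sizes):
        for i in range(s):
            labels.append(f"g{g}s{i}")
            group.append(g)
    n = len(labels)
    v = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        base = within if group[i] == group[j] else between
        if jitter and rng is not None:
            base += rng.uniform(-jitter, jitter)
        v[i, j] = v[j, i] = base
    truth = Partition({l: g for l, g in zip(labels, group)})
    return dmatrix(labels, v), truth


def oracle_agglomerate(matrix, T, F):
    """Naive re-implementation of the merge rule: recompute every candidate
    from the raw pair list at every step."""
    labels = list(matrix.labels)
    idx = {l: i for i, l in enumerate(labels)}
    clusters = [frozenset([l]) for l in sorted(labels)]
    while True:
        candidates = []
        for ca, cb in itertools.combinations(clusters, 2):
            ds = [matrix.values[idx[a], idx[b]] for a in ca for b in cb]
            ok = (
                any(d <= T for d in ds)
                if F == 0
                else sum(d <= T for d in ds) / len(ds) >= F
            )
            if ok:
                candidates.append(
                    ((float(np.mean(ds)), tuple(sorted(ca | cb))), ca, cb)
                )
        if not candidates:
            break
        _, ca, cb = min(candidates, key=lambda c: c[0])
        clusters = [c for c in clusters if c not in (ca, cb)] + [ca | cb]
    return {frozenset(c) for c in clusters}


def oracle_ari(p: Partition, q: Partition) -> float:
    """Adjusted Rand index from explicit pair counting."""
    labels = sorted(p.assignment)
    a = b = both = 0
    n_pairs = 0
    for x, y in itertools.combinations(labels, 2):
        same_p = p.assignment[x] == p.assignment[y]
        same_q = q.assignment[x] == q.assignment[y]
        a += same_p
        b += same_q
        both += same_p and same_q
        n_pairs += 1
    expected = a * b / n_pairs
    max_index = (a + b) / 2
    if max_index == expected:
        return 1.0
    return (both - expected) / (max_index - expected)


class TestThresholdCluster:
    def test_two_blocks_recovered_at_any_linkage(self):
        m, truth = block_matrix([3, 4], within=0.01, between=0.5)
        for F in (0.0, 0.5, 1.0):
            p = gx.threshold_cluster(m, T=0.1, F=F)
            assert gx.partition_agreement(p, truth) == 1.0
            assert p.n_clusters == 2

    def test_all_far_apart_stays_singletons(self):
        m, _ = block_matrix([4], within=0.4, between=0.9)
        p = gx.threshold_cluster(m, T=0.1, F=0.0)
        assert p.n_clusters == 4

    def test_matches_bruteforce_oracle_on_planted_matrix(self):
        rng = np.random.default_rng(0)
        m, _ = block_matrix([4, 4, 4], 0.05, 0.5, rng=rng, jitter=0.04)
        for F in (0.0, 0.5, 1.0):
            for T in (0.02, 0.08, 0.3, 0.6):
                p = gx.threshold_cluster(m, T, F)
                got = {frozenset(c) for c in p.clusters()}
                assert got == oracle_agglomerate(m, T, F), (T, F)

    def test_f0_equals_connected_components(self):
        rng = np.random.default_rng(1)
        for trial in range(100):
            n = 20
            v = np.zeros((n, n))
            iu = np.triu_indices(n, 1)
            v[iu] = rng.uniform(0, 1, len(iu[0]))
            v += v.T
            labels = [f"s{i:02d}" for i in range(n)]
            m = dmatrix(labels, v)
            T = float(rng.uniform(0.05, 0.5))
            p = gx.threshold_cluster(m, T, 0.0)
            adj = csr_matrix((v <= T) & ~np.eye(n, dtype=bool))
            n_cc, cc = connected_components(adj, directed=False)
            truth = Partition({l: int(c) for l, c in zip(labels, cc)})
            assert gx.partition_agreement(p, truth) == 1.0, trial
            assert p.n_clusters == n_cc

    def test_cluster_count_monotone_in_T_and_F(self):
        rng = np.random.default_rng(2)
        m, _ = block_matrix([3, 3, 3], 0.1, 0.6, rng=rng, jitter=0.08)
        counts_T = [
            gx.threshold_cluster(m, T, 0.5).n_clusters
            for T in np.linspace(0.0, 1.0, 9)
        ]
        assert all(a >= b for a, b in zip(counts_T, counts_T[1:]))
        counts_F = [
            gx.threshold_cluster(m, 0.3, F).n_clusters for F in (0.0, 0.5, 1.0)
        ]
        assert all(a <= b for a, b in zip(counts_F, counts_F[1:]))

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError):
            dmatrix(["a", "b"], [[0, 0.2], [0.3, 0]])


class TestClusterStats:
    def test_single_pair_cluster(self):
        m = dmatrix(["a", "b"], [[0, 0.2], [0.2, 0]])
        stats = gx.cluster_stats(m, Partition({"a": 0, "b": 0}))
        assert stats.avg_within == (0.2,)
        assert stats.max_within == (0.2,)

    def test_all_singletons_marked(self):
        m = dmatrix(["a", "b"], [[0, 0.2], [0.2, 0]])
        stats = gx.cluster_stats(m, Partition({"a": 0, "b": 1}))
        assert not stats.has_multi_member_clusters
        assert stats.summary == {}

    def test_matches_pair_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        n = 20
        v = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        v[iu] = rng.uniform(0, 1, len(iu[0]))
        v += v.T
        labels = [f"s{i:02d}" for i in range(n)]
        m = dmatrix(labels, v)
        part = Partition({l: int(rng.integers(0, 5)) for l in labels})
        stats = gx.cluster_stats(m, part)
        # independent recomputation straight from the pair list
        for members, avg, mx in zip(
            [c for c in part.clusters() if len(c) >= 2],
            stats.avg_within,
            stats.max_within,
        ):
            ds = [
                m.get(a, b) for a, b in itertools.combinations(members, 2)
            ]
            assert avg == pytest.approx(np.mean(ds))
            assert mx == pytest.approx(max(ds))
        # lower-median convention
        if len(stats.avg_within) % 2 == 0 and stats.avg_within:
            s = sorted(stats.avg_within)
            assert stats.summary["avg_within"]["median"] == s[len(s) // 2 - 1]

    def test_invariant_under_label_permutation(self):
        rng = np.random.default_rng(4)
        m, truth = block_matrix([3, 4], 0.05, 0.5, rng=rng, jitter=0.02)
        perm = list(m.labels)[::-1]
        stats1 = gx.cluster_stats(m, truth)
        stats2 = gx.cluster_stats(m.submatrix(perm), truth)
        assert sorted(stats1.avg_within) == pytest.approx(sorted(stats2.avg_within))


class TestPartitionAgreement:
    def test_identical_partitions(self):
        p = Partition({"a": 0, "b": 0, "c": 1})
        q = Partition({"a": 5, "b": 5, "c": 2})  # same blocks, other names
        assert gx.partition_agreement(p, q) == 1.0

    def test_singletons_vs_lump_is_chance_level(self):
        p = Partition({l: i for i, l in enumerate("abcd")})
        q = Partition({l: 0 for l in "abcd"})
        assert gx.partition_agreement(p, q) == pytest.approx(0.0)

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(5)
        labels = [f"s{i}" for i in range(12)]
        for _ in range(25):
            p = Partition({l: int(rng.integers(0, 4)) for l in labels})
            q = Partition({l: int(rng.integers(0, 3)) for l in labels})
            assert gx.partition_agreement(p, q) == pytest.approx(oracle_ari(p, q))

    def test_label_mismatch_rejected(self):
        with pytest.raises(ValueError):
            gx.partition_agreement(Partition({"a": 0}), Partition({"b": 0}))

    def test_symmetric(self):
        rng = np.random.default_rng(6)
        labels = [f"s{i}" for i in range(10)]
        p = Partition({l: int(rng.integers(0, 3)) for l in labels})
        q = Partition({l: int(rng.integers(0, 3)) for l in labels})
        assert gx.partition_agreement(p, q) == gx.partition_agreement(q, p)


class TestOptimizeAgainstReference:
    def test_block_reference_perfectly_matched(self):
        m, truth = block_matrix([3, 3], 0.01, 0.5)
        T, F, score, part, n = optimize_against_reference(m, truth)
        assert score == 1.0
        assert n == 2

    def test_singleton_reference_prefers_smallest_T(self):
        rng = np.random.default_rng(7)
        m, _ = block_matrix([2, 2], 0.2, 0.6, rng=rng, jitter=0.05)
        ref = Partition({l: i for i, l in enumerate(m.labels)})
        T, F, score, part, n = optimize_against_reference(m, ref)
        assert n == len(m.labels)
        assert T == min(default_threshold_grid(m))

    def test_recovers_truth_from_noisy_reference(self):
        rng = np.random.default_rng(8)
        m, truth = block_matrix([5, 5, 5, 5], 0.02, 0.5, rng=rng, jitter=0.015)
        noisy = dict(truth.assignment)
        for l in list(noisy)[::10]:  # relabel 10%
            noisy[l] = (noisy[l] + 1) % 4
        ref = Partition(noisy)
        _, _, _, part, _ = optimize_against_reference(m, ref)
        assert gx.partition_agreement(part, truth) >= gx.partition_agreement(
            ref, truth
        )

    def test_tiny_reference_rejected(self):
        m, _ = block_matrix([2, 2], 0.01, 0.5)
        with pytest.raises(ValueError):
            optimize_against_reference(m, Partition({"g0s0": 0}))


class TestClusteringConsistency:
    def test_ultrametric_always_consistent(self):
        m, _ = block_matrix([3, 3], 0.1, 0.5)
        for T in (0.05, 0.1, 0.3, 0.5, 0.8):
            assert clustering_consistency([m], T) == 1.0

    def test_chain_matrix_inconsistent(self):
        m = dmatrix(
            ["a", "b", "c"],
            [[0, 0.1, 0.5], [0.1, 0, 0.1], [0.5, 0.1, 0]],
        )
        assert clustering_consistency([m], 0.2) < 1.0

    def test_consistency_maximal_exactly_in_band_gap(self):
        """Brute-force scan: consistency is 1 exactly between the
        within-band and the between-band, and below the within-band."""
        rng = np.random.default_rng(9)
        mats = [
            block_matrix([4, 4], 0.01, 0.05, rng=rng, jitter=0.004)[0]
            for _ in range(10)
        ]
        within_hi = max(
            m.values[i, j]
            for m in mats
            for i, j in itertools.combinations(range(8), 2)
            if m.values[i, j] < 0.03
        )
        between_lo = min(
            m.values[i, j]
            for m in mats
            for i, j in itertools.combinations(range(8), 2)
            if m.values[i, j] > 0.03
        )
        for T in np.linspace(0.001, 0.09, 45):
            c = clustering_consistency(mats, T)
            if within_hi < T < between_lo or T < 0.005:
                assert c == 1.0, T
        # somewhere inside the between-band consistency must drop
        dips = [
            clustering_consistency(mats, T)
            for T in np.linspace(between_lo + 1e-6, 0.055, 8)
        ]
        assert min(dips) < 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            clustering_consistency([], 0.1)


class TestSubspeciesThreshold:
    def test_plateau_midpoint_between_bands(self, model):
        # jittered between-band: single and complete linkage disagree while
        # T sits inside that band, so the maximal plateau is the band gap
        rng = np.random.default_rng(10)
        m, _ = block_matrix([4, 4], 0.01, 0.055, rng=rng, jitter=0.005)
        off = m.off_diagonal()
        within_hi = off[off < 0.03].max()
        between_lo = off[off > 0.03].min()
        grid = np.linspace(0.0, 0.1, 101)
        profile = optimize_subspecies_threshold([m], model, grid)
        assert not profile.degenerate
        plateau = grid[(grid > within_hi) & (grid < between_lo)]
        assert profile.T_star == pytest.approx(
            (plateau[0] + plateau[-1]) / 2, abs=1e-9
        )
        assert within_hi < profile.T_star < between_lo

    def test_no_substructure_flagged_degenerate(self, model):
        m, _ = block_matrix([6], 0.01, 0.5)  # one band only
        profile = optimize_subspecies_threshold(
            [m], model, np.linspace(0.0, 0.1, 101)
        )
        assert profile.degenerate
        assert profile.T_star is not None

    def test_flat_zero_profile_reports_no_threshold(self, model):
        m = dmatrix(
            ["a", "b", "c"],
            [[0, 0.1, 0.5], [0.1, 0, 0.1], [0.5, 0.1, 0]],
        )
        profile = optimize_subspecies_threshold([m], model, [0.2])
        assert profile.no_consistent_threshold
        assert profile.T_star is None

    def test_planted_cohort_threshold_in_subspecies_band(
        self, default_cohort, model
    ):
        """End to end on simulated genomes: the consistency-optimal
        threshold lands between the within- and between-subspecies bands,
        i.e. in the 78-80% dDDH window."""
        _, truth, matrix, _ = default_cohort
        sp = gx.threshold_cluster(matrix, gx.ddh_to_distance(0.70, model), 0.5)
        within = [matrix.submatrix(c) for c in sp.clusters() if len(c) >= 2]
        profile = optimize_subspecies_threshold(
            within, model, np.linspace(0.0, 0.05, 201)
        )
        assert 0.78 <= profile.ddh_star <= 0.80
        subsp = gx.threshold_cluster(matrix, profile.T_star, 0.5)
        assert gx.partition_agreement(subsp, truth.partition_at(1)) == 1.0
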