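"""Read scoring, flat and tree classification, grouping, evaluation."""

import numpy as np
import pytest

import readscreen as rs
from readscreen.classify import order_agreement

from conftest import random_dna


def mk(gid, hashes):
    return rs.GenomeSketch(gid, 1000, np.array(sorted(hashes), dtype=np.uint64))


def toy_screen(sketches, method="minhash", **kw):
    p = rs.ScreenParams(k=5, read_length=50, error_rate=0.0, target_matches=1, hash_seed=None)
    return rs.Screen(params=p, method=rs.MethodParams(method=method, **kw), sketches=sketches)


def read_from_hashes(hashes, read_id="r"):
    arr = np.array(list(hashes), dtype=np.uint64)
    uh, first = np.unique(arr, return_index=True)
    return rs.ReadKmers(read_id=read_id, hashes=uh, order=uh[np.argsort(first)])


class TestScoreRead:
    def test_disjoint_and_superset(self):
        sk = mk("a", {1, 2, 3})
        assert rs.score_read({7, 8}, sk) == (0, 0)
        assert rs.score_read({1, 2, 3, 4, 5}, sk) == (3, 0)

    def test_weighted_secondary_sums_shared_weights(self):
        sk = mk("a", {1, 2, 3})
        sk.weights = np.array([5, 7, 11], dtype=np.int64)
        primary, secondary = rs.score_read({2, 3, 99}, sk, "weighted_minhash")
        assert (primary, secondary) == (2, 18)

    def test_omh_exact_substring_has_perfect_order(self, rng):
        seq = random_dna(rng, 400)
        p = rs.ScreenParams(k=7, read_length=60, error_rate=0.0, target_matches=1, hash_seed=None)
        sk = rs.build_order_minhash([seq], 40, 4, p, "g")
        read = rs.hash_read(seq[100:260], 7, None, "r")
        primary, secondary = rs.score_read(read, sk, "order_minhash")
        assert primary > 0 and secondary == primary

    def test_omh_block_shuffle_lowers_secondary(self, rng):
        # brute-force toy: genome order 1..6, read visits blocks out of order
        g_order = np.array([10, 20, 30, 40, 50, 60], dtype=np.uint64)
        r_order = np.array([30, 40, 10, 20, 50, 60], dtype=np.uint64)

        def lcs(a, b):
            m, n = len(a), len(b)
            T = [[0] * (n + 1) for _ in range(m + 1)]
            for i in range(m):
                for j in range(n):
                    T[i + 1][j + 1] = (
                        T[i][j] + 1 if a[i] == b[j] else max(T[i][j + 1], T[i + 1][j])
                    )
            return T[m][n]

        expected = max(lcs(list(r_order), list(g_order)), lcs(list(r_order[::-1]), list(g_order)))
        got = order_agreement(r_order, g_order)
        assert got == expected == 4
        assert got < len(r_order)


class TestClassifyFlat:
    def test_no_shared_hashes_is_unclassified(self):
        screen = toy_screen([mk("a", {1, 2}), mk("b", {3, 4})])
        res = rs.classify_flat(read_from_hashes({100, 200}), screen, min_shared=1)
        assert res.predicted == rs.UNCLASSIFIED and res.is_unclassified

    def test_error_free_read_hits_uniform_sample_density(self, rng):
        # identity-hash uniform screen: an error-free read must overlap
        # at least floor(R / (n/s)) - 1 sampled positions of its source
        n, R, s, k = 20_000, 2_000, 100, 11
        genomes = [(f"g{i}", random_dna(rng, n)) for i in range(4)]
        p = rs.ScreenParams(k=k, read_length=R, error_rate=0.0, target_matches=10, hash_seed=None)
        sks = [rs.build_uniform([seq], s, p, gid) for gid, seq in genomes]
        screen = rs.Screen(params=p, method=rs.MethodParams(method="uniform"), sketches=sks)
        start = 5_000
        read = rs.hash_read(genomes[2][1][start : start + R], k, None, "r")
        res = rs.classify_flat(read, screen, min_shared=1, rng=np.random.default_rng(0))
        assert res.predicted == "g2"
        assert res.n_shared >= R // (n // s) - 1

    def test_weighted_tie_resolved_by_unique_hash(self):
        # equal shared counts with a and b; hash 10 is unique to a,
        # hash 3 is shared by b and c so it carries less weight
        sks = [mk("a", {1, 2, 10}), mk("b", {1, 2, 3}), mk("c", {3, 77, 78})]
        rs.annotate_weights(sks, M=1)
        screen = toy_screen(sks, method="weighted_minhash")
        read = read_from_hashes({1, 2, 3, 10})
        res = rs.classify_flat(read, screen, rng=np.random.default_rng(0))
        assert res.predicted == "a"
        assert res.tied_with == []

    def test_threshold_monotonicity(self, small_minhash_screen, small_community):
        """Raising min_shared never reclassifies an unclassified read."""
        _, reads = small_community
        params = small_minhash_screen.params
        for r in reads[:30]:
            read = rs.hash_read(r.sequence, params.k, params.hash_seed, r.read_id)
            was_uncl = False
            for ms in (1, 50, 200, 10_000):
                res = rs.classify_flat(read, small_minhash_screen, min_shared=ms,
                                       rng=np.random.default_rng(1))
                if was_uncl:
                    assert res.is_unclassified
                was_uncl = res.is_unclassified

    def test_seeded_tie_resolution_is_deterministic(self):
        screen = toy_screen([mk("a", {1, 2}), mk("b", {1, 2})])
        read = read_from_hashes({1, 2})
        picks1 = [rs.classify_flat(read, screen, rng=np.random.default_rng(s)).predicted
                  for s in range(20)]
        picks2 = [rs.classify_flat(read, screen, rng=np.random.default_rng(s)).predicted
                  for s in range(20)]
        assert picks1 == picks2
        assert set(picks1) == {"a", "b"}
        res = rs.classify_flat(read, screen, rng=np.random.default_rng(0))
        assert sorted(res.tied_with) == ["a", "b"]


class TestClassifyTree:
    def test_two_leaf_tree_matches_flat(self, rng):
        genomes = [("a", random_dna(rng, 5000)), ("b", random_dna(rng, 5000))]
        p = rs.ScreenParams(k=15, read_length=500, error_rate=0.0, target_matches=5, hash_seed=2)
        screen = rs.build_screen([(g, [s]) for g, s in genomes],
                                 rs.MethodParams(method="minhash"), p)
        st = rs.cluster_screen(screen)
        read = rs.hash_read(genomes[1][1][1000:1500], 15, 2, "r")
        flat = rs.classify_flat(read, screen, rng=np.random.default_rng(0))
        tree = rs.classify_tree(read, st, rng=np.random.default_rng(0))
        assert flat.predicted == tree.predicted == "b"

    def test_zero_shared_unclassified_at_root(self, rng):
        genomes = [("a", random_dna(rng, 3000)), ("b", random_dna(rng, 3000))]
        p = rs.ScreenParams(k=15, read_length=500, error_rate=0.0, target_matches=5, hash_seed=2)
        screen = rs.build_screen([(g, [s]) for g, s in genomes],
                                 rs.MethodParams(method="minhash"), p)
        st = rs.cluster_screen(screen)
        read = rs.hash_read(random_dna(rng, 500), 15, 2, "r")
        res = rs.classify_tree(read, st, min_shared=1)
        assert res.is_unclassified

    def test_tie_stop_reports_subtree_containing_source(self, rng):
        # one nearly identical pair plus two random genomes; a read from a
        # pair member that ties at the pair's parent stops with both siblings
        base = random_dna(rng, 20_000)
        spec = rs.CommunitySpec(n_genomes=4, genome_length=20_000, n_clusters=1,
                                cluster_size=2, within_cluster_divergence=0.0,
                                rng_seed=3)
        genomes, _ = rs.generate_community(spec)
        p = rs.ScreenParams(k=21, read_length=2_000, error_rate=0.0, target_matches=20, hash_seed=4)
        screen = rs.build_screen([(g, [s]) for g, s in genomes],
                                 rs.MethodParams(method="minhash"), p)
        st = rs.cluster_screen(screen)
        src = genomes[0]  # cluster0_g0, identical to cluster0_g1
        read = rs.hash_read(src[1][5_000:7_000], 21, 4, "r")
        res = rs.classify_tree(read, st, tie_mode="stop", rng=np.random.default_rng(0))
        assert res.status == "tie_stopped"
        assert set(res.predicted) == {"cluster0_g0", "cluster0_g1"}

    def test_flat_tree_agreement_on_dissimilar_community(self):
        """Greedy descent without downsampling agrees with flat classification."""
        spec = rs.CommunitySpec(n_genomes=16, genome_length=50_000, rng_seed=21)
        genomes, _ = rs.generate_community(spec)
        reads = rs.simulate_reads(genomes, read_length=5_000, error_rate=0.01,
                                  coverage=0.0, seed=22, reads_per_genome=6)
        p = rs.ScreenParams(k=21, read_length=5_000, error_rate=0.01,
                            target_matches=100, hash_seed=23)
        screen = rs.build_screen([(g, [s]) for g, s in genomes],
                                 rs.MethodParams(method="minhash"), p)
        st = rs.cluster_screen(screen, rs.TreeParams(downsample_mode="none"))
        agree = 0
        for r in reads:
            read = rs.hash_read(r.sequence, 21, 23, r.read_id)
            f = rs.classify_flat(read, screen, rng=np.random.default_rng(1))
            t = rs.classify_tree(read, st, rng=np.random.default_rng(1))
            agree += f.predicted == t.predicted
        assert agree / len(reads) >= 0.95

    def test_tree_comparisons_cheaper_than_flat_on_structured_community(self):
        """Constant-factor downsampling cuts per-read hash comparisons."""
        spec = rs.CommunitySpec(n_genomes=16, genome_length=50_000, n_clusters=4,
                                cluster_size=4, within_cluster_divergence=0.02,
                                rng_seed=31)
        genomes, _ = rs.generate_community(spec)
        reads = rs.simulate_reads(genomes, read_length=5_000, error_rate=0.01,
                                  coverage=0.0, seed=32, reads_per_genome=4)
        p = rs.ScreenParams(k=21, read_length=5_000, error_rate=0.01,
                            target_matches=100, hash_seed=33)
        screen = rs.build_screen([(g, [s]) for g, s in genomes],
                                 rs.MethodParams(method="minhash"), p)
        st = rs.cluster_screen(screen, rs.TreeParams(downsample_mode="constant", f=4.0, rng_seed=34))
        flat_cost = sum(len(sk.hashes) for sk in screen.sketches)
        rng = np.random.default_rng(2)
        costs = []
        for r in reads:
            read = rs.hash_read(r.sequence, 21, 33, r.read_id)
            res = rs.classify_tree(read, st, rng=rng)
            costs.append(res.n_hash_comparisons)
        assert np.mean(costs) <= flat_cost


class TestGroupedAndEvaluate:
    def test_grouped_two_level_calls(self, rng):
        spec = rs.CommunitySpec(n_genomes=3, genome_length=30_000, rng_seed=41)
        genomes, _ = rs.generate_community(spec)
        groups = {"genome0": "host", "genome1": "contaminant", "genome2": "contaminant"}
        p = rs.ScreenParams(k=21, read_length=3_000, error_rate=0.01,
                            target_matches=100, hash_seed=42)
        screen = rs.build_screen([(g, [s]) for g, s in genomes],
                                 rs.MethodParams(method="minhash"), p)
        reads = rs.simulate_reads(genomes, read_length=3_000, error_rate=0.01,
                                  coverage=0.0, seed=43, reads_per_genome=3)
        for r in reads:
            read = rs.hash_read(r.sequence, 21, 42, r.read_id)
            grp, res = rs.classify_grouped(read, screen, groups, rng=np.random.default_rng(0))
            assert grp == groups[r.true_genome]
            assert res.predicted == r.true_genome
        # unclassified read maps to the UNCLASSIFIED group
        junk = rs.hash_read(random_dna(rng, 3000), 21, 42, "junk")
        grp, res = rs.classify_grouped(junk, screen, groups, rng=np.random.default_rng(0))
        assert grp == rs.UNCLASSIFIED

    def test_grouped_rejects_unmapped_genome(self):
        screen = toy_screen([mk("a", {1}), mk("b", {2})])
        with pytest.raises(KeyError):
            rs.classify_grouped(read_from_hashes({1}), screen, {"a": "host"})

    def test_evaluate_arithmetic(self):
        def res(rid, pred, status="classified", tied=()):
            return rs.ClassificationResult(read_id=rid, predicted=pred, status=status,
                                           tied_with=list(tied))

        results = [
            res("r1", "a"), res("r2", "a"), res("r3", "b"),
            res("r4", "a"),  # wrong, truth b
            res("r5", rs.UNCLASSIFIED, status="unclassified"),
        ]
        truth = {"r1": "a", "r2": "a", "r3": "b", "r4": "b", "r5": "a"}
        m = rs.evaluate(results, truth)
        assert m["accuracy"] == 0.6
        assert m["unclassified_fraction"] == 0.2
        assert m["per_genome_accuracy"]["a"] == pytest.approx(2 / 3)
        # per-genome corrects sum to the total correct
        assert sum(c for c, _ in m["per_genome_counts"].values()) == 3

    def test_evaluate_group_level(self):
        results = [
            rs.ClassificationResult(read_id="r1", predicted="a"),
            rs.ClassificationResult(read_id="r2", predicted="b"),
        ]
        truth = {"r1": "a", "r2": "c"}
        groups = {"a": "host", "b": "cont", "c": "cont"}
        m = rs.evaluate(results, truth, groups=groups)
        assert m["accuracy"] == 0.5
        assert m["group_accuracy"] == 1.0  # b and c share a group

    def test_all_correct_is_perfect(self):
        results = [rs.ClassificationResult(read_id=f"r{i}", predicted="a") for i in range(5)]
        m = rs.evaluate(results, {f"r{i}": "a" for i in range(5)})
        assert m["accuracy"] == 1.0 and m["tie_fraction"] == 0.0


class TestWmhDominance:
    def test_unique_hash_always_beats_plain_random_tie(self):
        """A shared screen-unique hash deterministically wins under WMH,
        while plain MinHash resolves the same tie randomly (~50/50)."""
        def sketches():
            return [mk("true", {1, 2, 10}), mk("decoy", {1, 2, 3}), mk("other", {3, 77, 78})]

        read = read_from_hashes({1, 2, 3, 10})
        wmh_wins = mh_true = 0
        wrng = np.random.default_rng(0)
        mrng = np.random.default_rng(0)
        for _ in range(100):
            sks = sketches()
            rs.annotate_weights(sks, M=1)
            wscreen = toy_screen(sks, method="weighted_minhash")
            if rs.classify_flat(read, wscreen, rng=wrng).predicted == "true":
                wmh_wins += 1
            mscreen = toy_screen(sketches(), method="minhash")
            if rs.classify_flat(read, mscreen, rng=mrng).predicted == "true":
                mh_true += 1
        assert wmh_wins == 100
        assert 40 <= mh_true <= 60
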