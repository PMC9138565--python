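import itertools
import math

import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage
from Bio import Phylo
from io import StringIO

from scrsasa.hier_clust import (
    DistanceMatrix,
    LinkageTree,
    cophenetic_heights,
    cut_tree,
    euclidean_distances,
    similarity_percent,
    to_newick,
    ward_linkage,
)


def brute_force_ward(labels, x):
    """Exhaustive Ward reference from raw points.

    Maintains explicit clusters and recomputes every candidate merge
    distance from centroids: d(A,B) = sqrt(2|A||B|/(|A|+|B|)) * |cA - cB|
    (the exact quantity the Lance-Williams recurrence propagates).  Ties
    break on the smallest active-index pair, mirroring the production
    rule.
    """
    clusters = [[i] for i in range(len(labels))]
    nodes = list(range(len(labels)))
    next_node = len(labels)
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            ca = np.mean(x[clusters[a]], axis=0)
            cb = np.mean(x[clusters[b]], axis=0)
            na, nb = len(clusters[a]), len(clusters[b])
            d = math.sqrt(2 * na * nb / (na + nb)) * np.linalg.norm(ca - cb)
            if best is None or d < best[0] - 1e-15:
                best = (d, a, b)
        d, a, b = best
        merges.append((nodes[a], nodes[b], d, len(clusters[a]) + len(clusters[b])))
        clusters[a] = clusters[a] + clusters[b]
        nodes[a] = next_node
        next_node += 1
        del clusters[b], nodes[b]
    return merges


class TestEuclideanDistances:
    def test_identical_vectors_zero(self):
        dm = euclidean_distances([("a", [1.0, 2.0]), ("b", [1.0, 2.0])])
        assert dm.d[0, 1] == 0.0

    def test_three_four_five_triangle(self):
        dm = euclidean_distances([("a", [0.0, 0.0]), ("b", [3.0, 4.0])])
        assert dm.d[0, 1] == pytest.approx(5.0)

    def test_matches_elementwise_loop_oracle(self):
        rng = np.random.default_rng(21)
        vecs = [(f"v{i}", rng.uniform(-5, 5, size=4)) for i in range(5)]
        dm = euclidean_distances(vecs)
        for i in range(5):
            for j in range(5):
                expect = math.sqrt(
                    sum((vecs[i][1][k] - vecs[j][1][k]) ** 2 for k in range(4))
                )
                assert dm.d[i, j] == pytest.approx(expect, abs=1e-12)

    def test_length_mismatch_reports_ids(self):
        with pytest.raises(ValueError, match="a.*b"):
            euclidean_distances([("a", [1.0]), ("b", [1.0, 2.0])])


class TestWardLinkage:
    def test_two_leaves_merge_at_their_distance(self):
        dm = euclidean_distances([("a", [0.0]), ("b", [4.0])])
        tree = ward_linkage(dm)
        assert tree.merges == ((0, 1, pytest.approx(4.0), 2),)

    def test_one_dimensional_hand_computation(self):
        """Points {0, 1, 10}: first merge (0,1) at height 1; the merged
        pair then joins {10} at sqrt((2*100 + 2*81 - 1)/3) = sqrt(361/3)
        by the Lance-Williams update."""
        dm = euclidean_distances([("a", [0.0]), ("b", [1.0]), ("c", [10.0])])
        tree = ward_linkage(dm)
        (l0, r0, h0, s0), (l1, r1, h1, s1) = tree.merges
        assert (l0, r0, s0) == (0, 1, 2)
        assert h0 == pytest.approx(1.0)
        assert (l1, r1, s1) == (3, 2, 3)
        assert h1 == pytest.approx(math.sqrt(361 / 3))

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_exhaustive_reference(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        x = rng.uniform(-10, 10, size=(n, 3))
        labels = tuple(f"v{i}" for i in range(n))
        tree = ward_linkage(euclidean_distances(list(zip(labels, x))))
        expect = brute_force_ward(labels, x)
        assert len(tree.merges) == len(expect)
        for got, want in zip(tree.merges, expect):
            assert got[:2] == want[:2]
            assert got[2] == pytest.approx(want[2], abs=1e-9)
            assert got[3] == want[3]

    @pytest.mark.parametrize("seed", range(10))
    def test_heights_match_scipy_ward(self, seed):
        rng = np.random.default_rng(seed + 1000)
        x = rng.uniform(0, 10, size=(6, 4))
        labels = [(f"v{i}", x[i]) for i in range(6)]
        tree = ward_linkage(euclidean_distances(labels))
        ours = sorted(m[2] for m in tree.merges)
        scipys = sorted(linkage(x, method="ward")[:, 2])
        np.testing.assert_allclose(ours, scipys, rtol=1e-9)

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0, 5, size=(8, 2))
        tree = ward_linkage(
            euclidean_distances([(f"v{i}", x[i]) for i in range(8)])
        )
        heights = [m[2] for m in tree.merges]
        assert heights == sorted(heights)

    def test_input_order_invariance_up_to_tie_break(self):
        rng = np.random.default_rng(13)
        x = rng.uniform(0, 10, size=(5, 3))
        labels = [f"v{i}" for i in range(5)]
        base = ward_linkage(euclidean_distances(list(zip(labels, x))))
        perm = [3, 1, 4, 0, 2]
        permuted = ward_linkage(
            euclidean_distances([(labels[i], x[i]) for i in perm])
        )
        def canonical(tree):
            return {
                tuple(sorted(pair)): h
                for pair, h in cophenetic_heights(tree).items()
            }

        got, want = canonical(permuted), canonical(base)
        assert got.keys() == want.keys()
        for pair in want:
            assert got[pair] == pytest.approx(want[pair], abs=1e-9)

    def test_single_leaf_rejected(self):
        dm = DistanceMatrix(labels=("a",), d=np.zeros((1, 1)))
        with pytest.raises(ValueError):
            ward_linkage(dm)


class TestNewick:
    def test_two_leaf_midpoint_convention(self):
        dm = euclidean_distances([("a", [0.0]), ("b", [4.0])])
        assert to_newick(ward_linkage(dm)) == "(a:2.0,b:2.0);"

    def test_round_trip_recovers_topology(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 10, size=(5, 2))
        tree = ward_linkage(
            euclidean_distances([(f"v{i}", x[i]) for i in range(5)])
        )
        parsed = Phylo.read(StringIO(to_newick(tree)), "newick")
        assert {t.name for t in parsed.get_terminals()} == set(tree.labels)
        # cophenetic structure survives the round trip (ultrametric depths)
        depths = parsed.depths()
        leaf_depth = {t.name: d for t, d in depths.items() if t.name}
        assert len(set(round(v, 6) for v in leaf_depth.values())) == 1

    def test_four_leaf_hand_built_tree(self):
        """Two tight pairs far apart: ((a,b),(c,d)) with known heights."""
        tree = ward_linkage(euclidean_distances([
            ("a", [0.0]), ("b", [1.0]), ("c", [100.0]), ("d", [101.0]),
        ]))
        h_root = tree.merges[-1][2]
        expected = (
            f"((a:0.5,b:0.5):{round(h_root / 2 - 0.5, 6)},"
            f"(c:0.5,d:0.5):{round(h_root / 2 - 0.5, 6)});"
        )
        assert to_newick(tree) == expected


class TestCopheneticAndSimilarity:
    def test_ultrametric_three_point_condition(self):
        rng = np.random.default_rng(31)
        x = rng.uniform(0, 10, size=(6, 3))
        labels = [f"v{i}" for i in range(6)]
        tree = ward_linkage(euclidean_distances(list(zip(labels, x))))
        h = cophenetic_heights(tree)

        def ch(i, j):
            a, b = sorted((labels[i], labels[j]))
            return h[(a, b)]

        for i, j, k in itertools.permutations(range(6), 3):
            assert ch(i, j) <= max(ch(i, k), ch(j, k)) + 1e-12

    def test_root_pair_zero_identical_pair_hundred(self):
        tree = ward_linkage(euclidean_distances([
            ("a", [0.0]), ("b", [0.0]), ("c", [50.0]),
        ]))
        sim = similarity_percent(tree)
        assert sim[("a", "b")] == pytest.approx(100.0)
        assert sim[("a", "c")] == pytest.approx(0.0)

    def test_three_leaf_hand_cophenetic(self):
        """{0,1,10}: (a,b) join at 1, both join c at sqrt(361/3) (root),
        so sim(a,b) = 100*(1 - 1/sqrt(361/3)) = 90.878..., sim(*,c) = 0."""
        tree = ward_linkage(euclidean_distances([
            ("a", [0.0]), ("b", [1.0]), ("c", [10.0]),
        ]))
        sim = similarity_percent(tree)
        root = math.sqrt(361 / 3)
        assert sim[("a", "b")] == pytest.approx(100 * (1 - 1 / root))
        assert sim[("a", "c")] == pytest.approx(0.0)
        assert sim[("b", "c")] == pytest.approx(0.0)


class TestCutTree:
    def test_k_equals_n_and_one(self):
        tree = ward_linkage(euclidean_distances([
            ("a", [0.0]), ("b", [1.0]), ("c", [10.0]),
        ]))
        assert len(set(cut_tree(tree, 3).values())) == 3
        assert len(set(cut_tree(tree, 1).values())) == 1

    def test_planted_three_groups_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(4)
        centers = np.array([[0.0, 0.0], [40.0, 0.0], [0.0, 40.0]])
        labels, vecs, truth = [], [], []
        for g, c in enumerate(centers):
            for m in range(4):
                labels.append(f"g{g}m{m}")
                vecs.append(c + rng.normal(0, 0.5, size=2))
                truth.append(g)
        tree = ward_linkage(euclidean_distances(list(zip(labels, vecs))))
        cut = cut_tree(tree, 3)
        assert adjusted_rand_score(truth, [cut[l] for l in labels]) == 1.0
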