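"""F_ST matrix, neighbour joining, bootstrap supports and the Mantel test."""

import itertools
import math

import numpy as np
import pytest

from poolscan.structure import (DistanceMatrix, bootstrap_support,
                                geographic_distances, mantel_test, nj_tree,
                                pairwise_fst_matrix)
from poolscan.variants import PoolPanel, PoolSample
from poolscan.windows import fst_snp_karlsson

from conftest import make_table


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def random_additive_tree(n_taxa, rng):
    """Random unrooted binary tree; returns (distance matrix, bipartitions)."""
    # start from 3 taxa, attach the rest onto random edges
    nodes = {i: {} for i in range(n_taxa)}  # adjacency: node -> {nbr: length}
    next_id = n_taxa

    def add_edge(u, v, ln):
        nodes.setdefault(u, {})[v] = ln
        nodes.setdefault(v, {})[u] = ln

    def del_edge(u, v):
        del nodes[u][v]
        del nodes[v][u]

    center = next_id
    next_id += 1
    nodes[center] = {}
    for i in range(3):
        add_edge(center, i, float(rng.uniform(0.5, 2.0)))
    for leaf in range(3, n_taxa):
        edges = [(u, v) for u in nodes for v in nodes[u] if u < v]
        u, v = edges[rng.integers(0, len(edges))]
        ln = nodes[u][v]
        mid = next_id
        next_id += 1
        split = float(rng.uniform(0.25, 0.75)) * ln
        del_edge(u, v)
        add_edge(u, mid, split)
        add_edge(mid, v, ln - split)
        add_edge(mid, leaf, float(rng.uniform(0.5, 2.0)))

    # all-pairs path lengths among leaves (BFS per leaf)
    labels = [f"t{i}" for i in range(n_taxa)]
    dm = np.zeros((n_taxa, n_taxa))
    for s in range(n_taxa):
        dist = {s: 0.0}
        stack = [s]
        while stack:
            u = stack.pop()
            for v, ln in nodes[u].items():
                if v not in dist:
                    dist[v] = dist[u] + ln
                    stack.append(v)
        for t in range(n_taxa):
            dm[s, t] = dist[t]

    # true bipartitions: remove each internal edge, collect leaf side
    bips = set()
    all_set = frozenset(labels)
    for u in nodes:
        for v in nodes[u]:
            if u < v and u >= n_taxa and v >= n_taxa:
                # side of u without v
                side = set()
                stack = [u]
                seen = {u, v}
                while stack:
                    w = stack.pop()
                    if w < n_taxa:
                        side.add(labels[w])
                    for x in nodes[w]:
                        if x not in seen:
                            seen.add(x)
                            stack.append(x)
                fs = frozenset(side)
                comp = all_set - fs
                if 1 < len(fs) < n_taxa - 1:
                    bips.add(min(fs, comp, key=lambda s: (len(s),
                                                          tuple(sorted(s)))))
    return DistanceMatrix(labels, dm), bips


def four_point_condition_holds(dm, tol=1e-9):
    """Brute-force additivity check: for every quartet, the two largest of
    the three pairings coincide."""
    v = dm.values
    n = len(dm)
    for i, j, k, l in itertools.combinations(range(n), 4):
        s = sorted([v[i, j] + v[k, l], v[i, k] + v[j, l], v[i, l] + v[j, k]])
        if abs(s[2] - s[1]) > tol:
            return False
    return True


def exact_mantel_p(a, b):
    """Exhaustive-permutation oracle for small matrices."""
    n = a.shape[0]
    iu = np.triu_indices(n, 1)
    x = a[iu]
    r_obs = np.corrcoef(x, b[iu])[0, 1]
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        p = np.array(perm)
        r = np.corrcoef(x, b[np.ix_(p, p)][iu])[0, 1]
        count += r >= r_obs - 1e-12
        total += 1
    return count / total


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

class TestDistanceMatrix:
    def test_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0.0]]))
        with pytest.raises(ValueError, match="diagonal"):
            DistanceMatrix(["a", "b"], np.array([[1.0, 1], [1, 0]]))


class TestPairwiseFstMatrix:
    def test_three_pool_hand_average(self, three_pool_panel):
        recs = [
            ("1", 1, "A", "G", 30, True, set(), [(10, 10), (0, 20), (5, 15)]),
            ("1", 2, "C", "T", 30, True, set(), [(20, 0), (0, 20), (10, 10)]),
        ]
        t = make_table(three_pool_panel, recs)
        dm = pairwise_fst_matrix(t)
        for (i, a1, n1), (j, a2, n2) in [
            ((0, [10, 0], [20, 20]), (1, [20, 20], [20, 20])),
        ]:
            expected = np.mean([
                fst_snp_karlsson(a1[s], n1[s], a2[s], n2[s])[2]
                for s in range(2)
            ])
            assert dm.values[i, j] == pytest.approx(expected)
        assert np.allclose(dm.values, dm.values.T)

    def test_pair_count_for_23_pools(self):
        panel = PoolPanel([PoolSample(f"p{i}", 35) for i in range(23)])
        rng = np.random.default_rng(0)
        recs = []
        for s in range(30):
            counts = [(int(rng.integers(5, 40)), int(rng.integers(5, 40)))
                      for _ in range(23)]
            recs.append(("1", s + 1, "A", "G", 30, True, set(), counts))
        dm = pairwise_fst_matrix(make_table(panel, recs))
        off = dm.values[np.triu_indices(23, 1)]
        assert off.size == 253
        assert np.all(np.isfinite(off))

    def test_identical_pools_near_zero(self, three_pool_panel):
        recs = [("1", i + 1, "A", "G", 30, True, set(), [(15, 25)] * 3)
                for i in range(30)]
        dm = pairwise_fst_matrix(make_table(three_pool_panel, recs))
        # small negative values are expected from the unbiased estimator
        off = dm.values[np.triu_indices(3, 1)]
        assert np.all(off <= 0.0) and np.all(off > -0.05)


class TestNeighbourJoining:
    def test_four_taxon_hand_matrix(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> additive distances
        vals = np.array([
            [0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float)
        dm = DistanceMatrix(list("ABCD"), vals)
        tree = nj_tree(dm)
        assert tree.bipartitions() == {frozenset({"A", "B"})}
        # exact branch-length recovery on an additive matrix
        tdm = tree.tree.tip_tip_distances()
        for i, a in enumerate("ABCD"):
            for j, b in enumerate("ABCD"):
                assert tdm[a, b] == pytest.approx(vals[i, j], abs=1e-9)

    def test_recovers_random_additive_trees(self):
        rng = np.random.default_rng(123)
        for _ in range(30):
            n = int(rng.integers(4, 9))
            dm, true_bips = random_additive_tree(n, rng)
            assert four_point_condition_holds(dm)
            tree = nj_tree(dm)
            assert tree.bipartitions() == true_bips
            tdm = tree.tree.tip_tip_distances()
            for a in dm.labels:
                for b in dm.labels:
                    assert tdm[a, b] == pytest.approx(
                        dm.values[dm.labels.index(a), dm.labels.index(b)],
                        abs=1e-8)

    def test_label_permutation_gives_isomorphic_tree(self):
        rng = np.random.default_rng(7)
        dm, _ = random_additive_tree(6, rng)
        perm = rng.permutation(6)
        dm2 = DistanceMatrix([dm.labels[i] for i in perm],
                             dm.values[np.ix_(perm, perm)])
        assert nj_tree(dm).bipartitions() == nj_tree(dm2).bipartitions()

    def test_negative_lengths_clamped_in_newick_only(self):
        vals = np.array([[0, 1, 1, 10], [1, 0, 1, 10],
                         [1, 1, 0, 10], [10, 10, 10, 0]], float)
        tree = nj_tree(DistanceMatrix(list("ABCD"), vals))
        assert ":-" not in tree.to_newick()


class TestBootstrap:
    @pytest.fixture
    def two_clade_table(self):
        """Pools split into two deeply diverged clades."""
        panel = PoolPanel([PoolSample(n, 35) for n in "abcdef"])
        rng = np.random.default_rng(21)
        recs = []
        for s in range(400):
            p_left = rng.uniform(0.05, 0.3)
            p_right = rng.uniform(0.7, 0.95)
            counts = []
            for i in range(6):
                p = p_left if i < 3 else p_right
                alt = rng.binomial(40, np.clip(p + rng.normal(0, 0.05), 0, 1))
                counts.append((40 - alt, alt))
            recs.append(("1", s + 1, "A", "G", 30, True, set(), counts))
        return make_table(panel, recs)

    def test_strong_split_gets_high_support(self, two_clade_table):
        tree = bootstrap_support(two_clade_table, n_reps=50, seed=0)
        key = frozenset({"a", "b", "c"})
        assert key in tree.supports
        assert tree.supports[key] >= 95.0

    def test_single_replicate_supports_binary(self, two_clade_table):
        tree = bootstrap_support(two_clade_table, n_reps=1, seed=0)
        assert set(tree.supports.values()) <= {0.0, 100.0}

    def test_same_seed_reproducible(self, two_clade_table):
        t1 = bootstrap_support(two_clade_table, n_reps=10, seed=42)
        t2 = bootstrap_support(two_clade_table, n_reps=10, seed=42)
        assert t1.supports == t2.supports


class TestMantel:
    def test_self_comparison(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(1, 5, (5, 5))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        dm = DistanceMatrix(list("abcde"), v)
        res = mantel_test(dm, dm, n_perm=99, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 100)

    def test_exact_enumeration_matches_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            a = rng.uniform(1, 5, (4, 4))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 0)
            b = rng.uniform(1, 5, (4, 4))
            b = (b + b.T) / 2
            np.fill_diagonal(b, 0)
            da = DistanceMatrix(list("wxyz"), a)
            db = DistanceMatrix(list("wxyz"), b)
            res = mantel_test(da, db, exact=True)
            assert res.n_perm == 24
            assert res.p == pytest.approx(exact_mantel_p(a, b), abs=1e-12)

    def test_joint_relabel_invariance(self):
        rng = np.random.default_rng(9)
        a = rng.uniform(1, 5, (6, 6))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        b = rng.uniform(1, 5, (6, 6))
        b = (b + b.T) / 2
        np.fill_diagonal(b, 0)
        labels = list("abcdef")
        da, db = DistanceMatrix(labels, a), DistanceMatrix(labels, b)
        perm = rng.permutation(6)
        labels2 = [labels[i] for i in perm]
        da2 = DistanceMatrix(labels2, a[np.ix_(perm, perm)])
        db2 = DistanceMatrix(labels2, b[np.ix_(perm, perm)])
        r1 = mantel_test(da, db, n_perm=9, seed=0).r
        r2 = mantel_test(da2, db2, n_perm=9, seed=0).r
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_r_matches_skbio_mantel(self):
        """Independent route: the observed correlation agrees with the
        scikit-bio Mantel implementation on random matrices."""
        from skbio.stats.distance import mantel as skbio_mantel
        rng = np.random.default_rng(31)
        for _ in range(5):
            a = rng.uniform(1, 5, (6, 6))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 0)
            b = rng.uniform(1, 5, (6, 6))
            b = (b + b.T) / 2
            np.fill_diagonal(b, 0)
            da = DistanceMatrix(list("abcdef"), a)
            db = DistanceMatrix(list("abcdef"), b)
            ours = mantel_test(da, db, n_perm=9, seed=0).r
            theirs = skbio_mantel(da.to_skbio(), db.to_skbio(),
                                  permutations=0, alternative="greater")[0]
            assert ours == pytest.approx(float(theirs), abs=1e-12)

    def test_p_floor(self):
        # p can never be below 1/(n_perm + 1)
        rng = np.random.default_rng(2)
        a = rng.uniform(1, 5, (5, 5))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        dm = DistanceMatrix(list("abcde"), a)
        res = mantel_test(dm, dm, n_perm=49, seed=3)
        assert res.p >= 1 / 50


class TestGeographicDistances:
    def test_known_distances(self):
        panel = PoolPanel([
            PoolSample("o", 35, longitude=0.0, latitude=0.0),
            PoolSample("same", 35, longitude=0.0, latitude=0.0),
            PoolSample("pole", 35, longitude=0.0, latitude=90.0),
            PoolSample("anti", 35, longitude=180.0, latitude=0.0),
        ])
        dm = geographic_distances(panel)
        assert dm.values[0, 1] == 0.0
        assert dm.values[0, 2] == pytest.approx(math.pi / 2 * 6371.0, rel=1e-6)
        assert dm.values[0, 3] == pytest.approx(math.pi * 6371.0, rel=1e-6)

    def test_missing_coordinates_error(self):
        panel = PoolPanel([PoolSample("a", 35, longitude=1.0, latitude=1.0),
                           PoolSample("b", 35)])
        with pytest.raises(ValueError, match="coordinates"):
            geographic_distances(panel)
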