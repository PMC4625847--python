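"""K2P distances, neighbour joining, bootstrap and split decomposition."""

import math

import numpy as np
import pytest

from mlstpop.phylogeny import (
    DistanceMatrix,
    SaturationError,
    bootstrap_support,
    isolation_index,
    k2p_distance,
    k2p_matrix,
    neighbour_joining,
    split_decomposition,
)
from mlstpop.seqdata_io import MLSTError


def random_additive_tree(rng, n_taxa):
    """Random binary tree -> (DistanceMatrix, canonical nontrivial splits).

    Splits are canonicalized to the side not containing the smallest taxon.
    """
    taxa = [f"t{k:02d}" for k in range(n_taxa)]
    clusters = [({t: 0.0}, frozenset([t])) for t in taxa]
    dist = {}
    clades = []
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        (da, sa), (db, sb) = clusters[i], clusters[j]
        la, lb = rng.uniform(0.1, 1.0), rng.uniform(0.1, 1.0)
        for x, dx in da.items():
            for y, dy in db.items():
                dist[frozenset((x, y))] = dx + la + dy + lb
        merged = {x: d + la for x, d in da.items()}
        merged.update({y: d + lb for y, d in db.items()})
        union = sa | sb
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append((merged, union))
        if len(clusters) > 1:
            clades.append(union)
    full = frozenset(taxa)
    ref = min(taxa)
    splits = set()
    for clade in clades:
        if 2 <= len(clade) <= n_taxa - 2:
            side = clade if ref not in clade else full - clade
            splits.add(frozenset(side))
    d = np.zeros((n_taxa, n_taxa))
    for a in range(n_taxa):
        for b in range(a + 1, n_taxa):
            d[a, b] = d[b, a] = dist[frozenset((taxa[a], taxa[b]))]
    return DistanceMatrix(taxa, d), splits


def leaf_path_distances(tree):
    """Pairwise leaf distances induced by a PhyloTree's branch lengths."""
    dists = {}

    def walk(node):
        if not node.children:
            return {node.label: 0.0}
        below = {}
        child_maps = []
        for c in node.children:
            sub = walk(c)
            sub = {k: v + c.length for k, v in sub.items()}
            child_maps.append(sub)
        for a in range(len(child_maps)):
            for b in range(a + 1, len(child_maps)):
                for x, dx in child_maps[a].items():
                    for y, dy in child_maps[b].items():
                        dists[frozenset((x, y))] = dx + dy
        for sub in child_maps:
            below.update(sub)
        return below

    walk(tree.root)
    return dists


class TestK2P:
    def test_identical_sequences(self):
        assert k2p_distance("ACGT" * 10, "ACGT" * 10) == 0.0

    def test_transitions_only_closed_form(self):
        s1 = "A" * 100
        s2 = "G" * 10 + "A" * 90  # 10 transitions, 0 transversions
        assert k2p_distance(s1, s2) == pytest.approx(-0.5 * math.log(0.8), abs=1e-9)
        assert k2p_distance(s1, s2) == pytest.approx(0.111572, abs=1e-6)

    def test_mixed_changes_match_independent_formula(self):
        s1 = "A" * 100
        s2 = "G" * 5 + "C" * 5 + "A" * 90  # 5 transitions + 5 transversions
        P, Q = 0.05, 0.05
        expected = -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)
        assert k2p_distance(s1, s2) == pytest.approx(expected, abs=1e-12)

    def test_n_sites_excluded_pairwise(self):
        assert k2p_distance("ANAA", "AGAA") == 0.0

    def test_saturation_error(self):
        with pytest.raises(SaturationError):
            k2p_distance("A" * 10, "G" * 10)

    def test_matrix_consistent_with_scalar(self, rng):
        base = "".join(rng.choice(list("ACGT"), 60))
        seqs = []
        for _ in range(5):
            chars = list(base)
            for pos in rng.choice(60, size=5, replace=False):
                chars[pos] = "ACGT"[int(rng.integers(4))]
            seqs.append("".join(chars))
        ids = [f"s{k}" for k in range(5)]
        dm = k2p_matrix((ids, seqs))
        assert np.allclose(dm.d, dm.d.T) and np.all(np.diag(dm.d) == 0)
        for i in range(5):
            for j in range(i + 1, 5):
                assert dm.d[i, j] == pytest.approx(
                    k2p_distance(seqs[i], seqs[j]), abs=1e-12
                )


class TestNeighbourJoining:
    def test_two_taxa_split_branch(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0.0, 0.4], [0.4, 0.0]]))
        tree = neighbour_joining(dm)
        assert sorted(tree.leaves()) == ["a", "b"]
        assert all(c.length == pytest.approx(0.2) for c in tree.root.children)

    def test_four_taxon_additive_recovery(self):
        # tree ((a:1,b:2):1.5,(c:3,d:4))
        taxa = ["a", "b", "c", "d"]
        d = np.array(
            [
                [0.0, 3.0, 5.5, 6.5],
                [3.0, 0.0, 6.5, 7.5],
                [5.5, 6.5, 0.0, 7.0],
                [6.5, 7.5, 7.0, 0.0],
            ]
        )
        tree = neighbour_joining(DistanceMatrix(taxa, d))
        assert tree.bipartitions() == {frozenset({"c", "d"})}
        induced = leaf_path_distances(tree)
        for i in range(4):
            for j in range(i + 1, 4):
                assert induced[frozenset((taxa[i], taxa[j]))] == pytest.approx(
                    d[i, j], abs=1e-9
                )

    def test_topology_recovery_on_random_trees(self, rng):
        recovered = 0
        for _ in range(50):
            n = int(rng.integers(8, 17))
            dm, true_splits = random_additive_tree(rng, n)
            tree = neighbour_joining(dm)
            recovered += tree.bipartitions() == true_splits
        assert recovered == 50

    def test_agrees_with_scikit_bio_on_additive_matrices(self, rng):
        """Independent NJ implementation recovers the same topology."""
        import skbio

        for _ in range(5):
            dm, true_splits = random_additive_tree(rng, 8)
            sk_tree = skbio.tree.nj(skbio.DistanceMatrix(dm.d, ids=dm.taxa))
            full = frozenset(dm.taxa)
            ref = min(dm.taxa)
            sk_splits = set()
            for s in sk_tree.subsets():
                s = frozenset(map(str, s))
                if 2 <= len(s) <= len(full) - 2:
                    sk_splits.add(s if ref not in s else full - s)
            assert neighbour_joining(dm).bipartitions() == sk_splits == true_splits

    def test_single_taxon_error(self):
        with pytest.raises(MLSTError):
            neighbour_joining(DistanceMatrix(["a"], np.zeros((1, 1))))

    def test_branch_lengths_nonnegative(self, rng):
        # random (non-additive) matrices may yield negative NJ estimates
        for _ in range(10):
            n = 6
            pts = rng.uniform(size=(n, 3))
            d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            tree = neighbour_joining(DistanceMatrix([f"t{k}" for k in range(n)], d))

            def check(node):
                assert node.length >= 0
                for c in node.children:
                    check(c)

            for c in tree.root.children:
                check(c)


class TestBootstrap:
    def _signal_alignment(self):
        # 10 informative transition columns all supporting ab|cd; the rest
        # constant apart from one private site each in b and d
        base = "ACGT" * 25
        a = base
        b = base[:95] + "G" + base[96:]          # A -> G private transition
        cd = "G" * 5 + "T" * 5 + base[10:]       # 10 group-diagnostic transitions
        c = cd
        d = cd[:99] + "C" + cd[100:]             # T -> C private transition
        return ["a", "b", "c", "d"], [a, b, c, d]

    def test_uniform_signal_gets_full_support(self):
        ids, seqs = self._signal_alignment()
        tree = bootstrap_support((ids, seqs), n_reps=50, seed=3)
        assert set(tree.support.values()) == {100.0}

    def test_same_seed_identical_supports(self):
        ids, seqs = self._signal_alignment()
        t1 = bootstrap_support((ids, seqs), n_reps=30, seed=9)
        t2 = bootstrap_support((ids, seqs), n_reps=30, seed=9)
        assert t1.support == t2.support

    def test_supports_within_range_and_taxon_order_invariance(self, rng):
        base = "".join(rng.choice(list("ACGT"), 50))
        seqs = []
        for _ in range(6):
            chars = list(base)
            for pos in rng.choice(50, size=4, replace=False):
                chars[pos] = "ACGT"[int(rng.integers(4))]
            seqs.append("".join(chars))
        ids = [f"s{k}" for k in range(6)]
        t1 = bootstrap_support((ids, seqs), n_reps=25, seed=5)
        order = [3, 1, 5, 0, 2, 4]
        t2 = bootstrap_support(
            ([ids[i] for i in order], [seqs[i] for i in order]), n_reps=25, seed=5
        )
        assert all(0 <= v <= 100 for v in t1.support.values())
        assert t1.support == t2.support


class TestIsolationIndex:
    def _additive_dm(self):
        taxa = ["a", "b", "c", "d"]
        d = np.array(
            [
                [0.0, 3.0, 5.5, 6.5],
                [3.0, 0.0, 6.5, 7.5],
                [5.5, 6.5, 0.0, 7.0],
                [6.5, 7.5, 7.0, 0.0],
            ]
        )
        return DistanceMatrix(taxa, d)

    def test_tree_edge_alpha_equals_branch_length(self):
        dm = self._additive_dm()
        assert isolation_index(dm, {"a", "b"}) == pytest.approx(1.5)
        assert isolation_index(dm, {"a"}) == pytest.approx(1.0)

    def test_incompatible_split_nonpositive(self):
        dm = self._additive_dm()
        assert isolation_index(dm, {"a", "c"}) <= 0
        assert isolation_index(dm, {"a", "d"}) <= 0

    def test_improper_bipartition(self):
        dm = self._additive_dm()
        with pytest.raises(MLSTError):
            isolation_index(dm, {"a", "b", "c", "d"})

    def test_two_taxon_singleton_formula(self):
        dm = DistanceMatrix(["x", "y"], np.array([[0.0, 0.6], [0.6, 0.0]]))
        assert isolation_index(dm, {"x"}) == pytest.approx(0.6)


class TestSplitDecomposition:
    def test_recovers_tree_edges_with_full_fit(self, rng):
        dm, true_splits = random_additive_tree(rng, 7)
        system = split_decomposition(dm)
        full = frozenset(dm.taxa)
        ref = min(dm.taxa)
        got = set()
        for side, alpha in system.nontrivial():
            assert alpha > 0
            got.add(side if ref not in side else full - frozenset(side))
        assert got == true_splits
        assert system.fit == pytest.approx(100.0, abs=1e-6)

    def test_box_metric_recovers_both_incompatible_splits(self):
        # sum of two crossing weighted splits: ab|cd (w=1) and ac|bd (w=2)
        taxa = ["a", "b", "c", "d"]
        d = np.array(
            [
                [0.0, 2.0, 1.0, 3.0],
                [2.0, 0.0, 3.0, 1.0],
                [1.0, 3.0, 0.0, 2.0],
                [3.0, 1.0, 2.0, 0.0],
            ]
        )
        system = split_decomposition(DistanceMatrix(taxa, d))
        weights = {
            frozenset(side): alpha for side, alpha in system.nontrivial()
        }
        assert weights[frozenset({"a", "b"})] == pytest.approx(1.0)
        assert weights[frozenset({"a", "c"})] == pytest.approx(2.0)

    def test_incremental_equals_exhaustive(self, rng):
        for _ in range(6):
            n = int(rng.integers(5, 9))
            pts = rng.uniform(size=(n, 3))
            d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            dm = DistanceMatrix([f"t{k}" for k in range(n)], d)
            inc = split_decomposition(dm, "incremental")
            exh = split_decomposition(dm, "exhaustive")
            inc_set = {s: round(a, 9) for s, a in inc.splits}
            exh_set = {s: round(a, 9) for s, a in exh.splits}
            assert inc_set == exh_set

    def test_tree_metric_splits_are_pairwise_compatible(self, rng):
        dm, _ = random_additive_tree(rng, 8)
        system = split_decomposition(dm)
        taxa = set(dm.taxa)
        nt = system.nontrivial()
        for i in range(len(nt)):
            for j in range(i + 1, len(nt)):
                a, b = set(nt[i][0]), set(nt[j][0])
                quadrants = [a & b, a - b, b - a, taxa - a - b]
                assert not all(quadrants)  # at least one quadrant empty

    def test_nexus_output(self, tmp_path, rng):
        dm, _ = random_additive_tree(rng, 5)
        system = split_decomposition(dm)
        out = tmp_path / "splits.nex"
        system.write_nexus(out)
        text = out.read_text()
        assert text.startswith("#NEXUS")
        assert f"NSPLITS={len(system.splits)}" in text
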