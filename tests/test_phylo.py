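import math

import networkx as nx
import numpy as np
import pytest

from gliascan import phylo
from gliascan.phylo import (
    Alignment, DistanceMatrix, bootstrap_support, confirm_assignment,
    neighbor_joining, poisson_distance,
)

# ---------------------------------------------------------------------------
# independent oracle: random unrooted binary trees built on a networkx graph


def random_tree(n_taxa, rng):
    """Random unrooted binary tree with branch lengths in [0.05, 1]."""
    g = nx.Graph()
    g.add_edge("t0", "t1", length=float(rng.uniform(0.05, 1)))
    next_internal = 0
    for i in range(2, n_taxa):
        edges = list(g.edges(data=True))
        u, v, data = edges[rng.integers(len(edges))]
        g.remove_edge(u, v)
        mid = f"i{next_internal}"
        next_internal += 1
        split = float(rng.uniform(0.2, 0.8)) * data["length"]
        g.add_edge(u, mid, length=split)
        g.add_edge(mid, v, length=data["length"] - split)
        g.add_edge(mid, f"t{i}", length=float(rng.uniform(0.05, 1)))
    return g


def tree_distance_matrix(g, taxa):
    dist = dict(nx.all_pairs_dijkstra_path_length(g, weight="length"))
    m = np.zeros((len(taxa), len(taxa)))
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            if i != j:
                m[i, j] = dist[a][b]
    return m


def tree_bipartitions(g, taxa):
    anchor = min(taxa)
    parts = set()
    for u, v in list(g.edges()):
        h = g.copy()
        h.remove_edge(u, v)
        comp = nx.node_connected_component(h, u)
        side = frozenset(t for t in taxa if t in comp)
        if 1 < len(side) < len(taxa) - 1:
            canonical = side if anchor not in side else frozenset(taxa) - side
            parts.add(canonical)
    return parts


# ---------------------------------------------------------------------------


class TestPoissonDistance:
    def test_identical_rows_zero(self):
        aln = Alignment(ids=["a", "b"], rows=["MKTA", "MKTA"])
        assert poisson_distance(aln).matrix[0, 1] == 0.0

    def test_half_different(self):
        aln = Alignment(ids=["a", "b"], rows=["AAAA", "AAGG"])
        assert poisson_distance(aln).matrix[0, 1] == pytest.approx(
            0.693147, abs=1e-6
        )

    def test_pairwise_deletion(self):
        # only 3 comparable columns; they are identical
        aln = Alignment(ids=["a", "b"], rows=["AC-T", "ACGT"])
        assert poisson_distance(aln).matrix[0, 1] == 0.0

    def test_x_skipped(self):
        aln = Alignment(ids=["a", "b"], rows=["AXTT", "AGTT"])
        assert poisson_distance(aln).matrix[0, 1] == 0.0

    def test_saturation_errors(self):
        aln = Alignment(ids=["a", "b"], rows=["AAAA", "GGGG"])
        with pytest.raises(ValueError, match="saturated"):
            poisson_distance(aln)

    def test_no_comparable_sites_errors(self):
        aln = Alignment(ids=["a", "b"], rows=["A--", "-GG"])
        with pytest.raises(ValueError, match="comparable"):
            poisson_distance(aln)

    def test_matches_closed_form_random(self, rng):
        letters = np.array(list("ARNDCQEGH"))
        for _ in range(20):
            a = "".join(rng.choice(letters, size=50))
            b = "".join(rng.choice(letters, size=50))
            p = sum(x != y for x, y in zip(a, b)) / 50
            if p >= 1:
                continue
            aln = Alignment(ids=["a", "b"], rows=[a, b])
            assert poisson_distance(aln).matrix[0, 1] == pytest.approx(
                -math.log(1 - p)
            )


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(
            ids=["t1", "t2", "t3"],
            matrix=np.array([[0, 0.2, 0.4], [0.2, 0, 0.4], [0.4, 0.4, 0]]),
        )
        tree = neighbor_joining(dm)
        paths = tree.path_lengths()
        assert paths[("t1", "t2")] == pytest.approx(0.2, abs=1e-9)
        assert paths[("t1", "t3")] == pytest.approx(0.4, abs=1e-9)
        assert paths[("t2", "t3")] == pytest.approx(0.4, abs=1e-9)

    def test_four_taxon_additive_recovery(self, rng):
        g = random_tree(4, rng)
        taxa = sorted(t for t in g.nodes if t.startswith("t"))
        dm = DistanceMatrix(ids=taxa, matrix=tree_distance_matrix(g, taxa))
        tree = neighbor_joining(dm)
        assert tree.bipartitions() == tree_bipartitions(g, taxa)
        paths = tree.path_lengths()
        for i, a in enumerate(taxa):
            for b in taxa[i + 1 :]:
                assert paths[(a, b)] == pytest.approx(
                    dm.matrix[taxa.index(a), taxa.index(b)], abs=1e-9
                )

    def test_equal_distances_deterministic(self):
        m = np.full((4, 4), 1.0)
        np.fill_diagonal(m, 0.0)
        dm = DistanceMatrix(ids=["a", "b", "c", "d"], matrix=m)
        first = neighbor_joining(dm).to_newick()
        second = neighbor_joining(dm).to_newick()
        assert first == second

    def test_fewer_than_three_errors(self):
        dm = DistanceMatrix(ids=["a", "b"], matrix=np.array([[0, 1.0], [1.0, 0]]))
        with pytest.raises(ValueError, match="at least 3"):
            neighbor_joining(dm)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(ids=["a", "b"], matrix=np.array([[0, 1.0], [2.0, 0]]))

    def test_negative_matrix_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            DistanceMatrix(ids=["a", "b"], matrix=np.array([[0, -1.0], [-1.0, 0]]))

    def test_newick_parses_with_dendropy(self):
        import dendropy

        dm = DistanceMatrix(
            ids=["t1", "t2", "t3", "t4"],
            matrix=np.array(
                [[0, 0.3, 0.5, 0.6], [0.3, 0, 0.6, 0.7],
                 [0.5, 0.6, 0, 0.3], [0.6, 0.7, 0.3, 0]]
            ),
        )
        newick = neighbor_joining(dm).to_newick()
        tree = dendropy.Tree.get(data=newick, schema="newick")
        assert {leaf.taxon.label for leaf in tree.leaf_node_iter()} == {
            "t1", "t2", "t3", "t4"
        }


class TestBootstrap:
    @staticmethod
    def _two_cluster_alignment(rng, n_sites=120):
        letters = np.array(list("ARNDCQEGHK"))
        base = rng.choice(letters, size=n_sites)
        other = base.copy()
        flip = rng.random(n_sites) < 0.5
        for i in np.where(flip)[0]:
            choices = letters[letters != base[i]]
            other[i] = choices[rng.integers(len(choices))]
        ids = [f"a{i}" for i in range(5)] + [f"b{i}" for i in range(5)]
        rows = ["".join(base)] * 5 + ["".join(other)] * 5
        return Alignment(ids=ids, rows=rows)

    def test_clean_clusters_highly_supported(self, rng):
        aln = self._two_cluster_alignment(rng)
        _, supports = bootstrap_support(aln, n_reps=100, seed=5)
        cluster_a = frozenset(f"a{i}" for i in range(5))
        cluster_b = frozenset(f"b{i}" for i in range(5))
        found = {bp: s for bp, s in supports.items() if bp in (cluster_a, cluster_b)}
        assert found, "cluster bipartition missing from full-data tree"
        assert all(s >= 0.95 for s in found.values())

    def test_supports_in_unit_interval(self, rng):
        aln = self._two_cluster_alignment(rng)
        _, supports = bootstrap_support(aln, n_reps=20, seed=1)
        assert all(0.0 <= s <= 1.0 for s in supports.values())

    def test_same_seed_reproducible(self, rng):
        aln = self._two_cluster_alignment(rng)
        _, s1 = bootstrap_support(aln, n_reps=30, seed=9)
        _, s2 = bootstrap_support(aln, n_reps=30, seed=9)
        assert s1 == s2

    def test_zero_reps_errors(self, rng):
        aln = self._two_cluster_alignment(rng)
        with pytest.raises(ValueError, match="n_reps"):
            bootstrap_support(aln, n_reps=0, seed=0)


class TestConfirmAssignment:
    @staticmethod
    def _clustered_tree():
        # 3 genome clusters of 3 refs + 1 query each, tight within, far across
        ids, rows = [], []
        blocks = {"A": "AAAAAAAAAA", "B": "GGGGGGGGGG", "D": "KKKKKKKKKK"}
        shared = "MNDESTVLIWPH" * 5
        for genome, block in blocks.items():
            for i in range(4):
                wobble = "RY"[i % 2] + "RY"[(i // 2) % 2]
                ids.append(f"{genome}{i}")
                rows.append(shared + block * 3 + wobble)
        aln = Alignment(ids=ids, rows=rows)
        return neighbor_joining(poisson_distance(aln))

    def test_leaf_in_pure_clade(self):
        tree = self._clustered_tree()
        refs = {f"{g}{i}": g for g in "ABD" for i in range(3)}
        calls = {f"{g}3": g for g in "ABD"}
        out = confirm_assignment(tree, refs, motif_calls=calls, k=3)
        for genome in "ABD":
            assigned, concordant = out[f"{genome}3"]
            assert assigned == genome
            assert concordant is True

    def test_missing_genome_errors(self):
        tree = self._clustered_tree()
        refs = {f"A{i}": "A" for i in range(3)}
        with pytest.raises(ValueError, match="genome B"):
            confirm_assignment(tree, refs)

    def test_no_references_errors(self):
        tree = self._clustered_tree()
        with pytest.raises(ValueError, match="no labeled references"):
            confirm_assignment(tree, {})

    def test_vote_tie_unassigned(self):
        tree = self._clustered_tree()
        refs = {"A0": "A", "B0": "B", "D0": "D"}
        out = confirm_assignment(tree, refs, k=3)
        # k=3 with one reference per genome always ties 1-1-1
        assert all(genome == "unassigned" for genome, _ in out.values())
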