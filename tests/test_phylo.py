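"""K2P distances, neighbor joining, bootstrap and Newick round trips."""

import math

import dendropy
import numpy as np
import pytest

from beetyping.phylo import (
    DistanceMatrix,
    SaturationError,
    bootstrap_support,
    k2p_distance,
    k2p_matrix,
    mean_group_distance,
    nj_tree,
    nj_tree_from_alignment,
    read_newick,
    tree_bipartitions,
    write_newick,
)
from beetyping.seqcore import DnaRecord


class TestK2P:
    def test_identical_sequences(self):
        r = k2p_distance("ACGTACGT", "ACGTACGT")
        assert r.d == 0 and r.P == 0 and r.Q == 0 and r.n_sites == 8

    def test_single_transition_closed_form(self):
        # 1 transition in 20 sites: P = 0.05, d = -1/2 ln(0.9)
        r = k2p_distance("A" * 19 + "G", "A" * 20)
        assert r.P == pytest.approx(0.05)
        assert r.Q == 0
        assert r.d == pytest.approx(-0.5 * math.log(0.9), abs=1e-10)
        assert r.d == pytest.approx(0.05268, abs=5e-6)

    def test_transition_and_transversion_closed_form(self):
        # 10 sites: 1 transition (A->G), 1 transversion (A->C)
        s1, s2 = "AAAAAAAAAA", "GCAAAAAAAA"
        r = k2p_distance(s1, s2)
        assert (r.P, r.Q) == (0.1, 0.1)
        expected = -0.5 * math.log(1 - 0.2 - 0.1) - 0.25 * math.log(1 - 0.2)
        assert r.d == pytest.approx(expected, abs=1e-12)

    def test_saturation_raises(self):
        s1 = "A" * 10
        s2 = "G" * 5 + "A" * 5  # P = 0.5, Q = 0 -> log(0)
        with pytest.raises(SaturationError):
            k2p_distance(s1, s2)

    def test_pairwise_deletion_skips_gap_and_n_sites(self):
        r = k2p_distance("ACG-NT", "ACGTAT")
        assert r.n_sites == 4 and r.d == 0

    def test_small_p_first_order_limit(self):
        # for Q = 0 and small P, d -> P to first order
        n = 1000
        s1 = "A" * n
        s2 = "G" * 5 + "A" * (n - 5)
        r = k2p_distance(s1, s2)
        assert r.P == 0.005
        assert abs(r.d - r.P) / r.P < 0.01

    def test_matrix_complete_deletion_drops_columns_globally(self):
        recs = [
            DnaRecord("a", "ACGTA"),
            DnaRecord("b", "ACGTG"),
            DnaRecord("c", "ACG-A"),
        ]
        dm = k2p_matrix(recs, deletion="complete")
        # column 4 (gap in c) and column 5 (polymorphic) -> with complete
        # deletion the a-b comparison also loses column 4
        assert dm.value("a", "b") == pytest.approx(
            k2p_distance("ACGA", "ACGG").d
        )


class TestMeanGroupDistance:
    def test_identical_group_is_zero(self):
        recs = [DnaRecord("a", "ACGT" * 5), DnaRecord("b", "ACGT" * 5)]
        rep = mean_group_distance(recs, {"a": "g1", "b": "g1"})
        assert rep.within["g1"] == 0.0 and rep.overall == 0.0

    def test_means_equal_hand_computed_averages(self):
        n = 100
        base = "A" * n
        def seq(k_ts):  # k transitions
            return "G" * k_ts + "A" * (n - k_ts)
        recs = [
            DnaRecord("a1", base), DnaRecord("a2", seq(2)),
            DnaRecord("b1", seq(50 // 5)), DnaRecord("b2", seq(14)),
        ]
        groups = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        rep = mean_group_distance(recs, groups)
        assert rep.within["A"] == pytest.approx(k2p_distance(base, seq(2)).d)
        assert rep.within["B"] == pytest.approx(k2p_distance(seq(10), seq(14)).d)
        d_all = [
            k2p_distance(recs[i].seq, recs[j].seq).d
            for i in range(4) for j in range(i + 1, 4)
        ]
        assert rep.overall == pytest.approx(float(np.mean(d_all)))

    def test_singleton_group_is_nan(self):
        recs = [DnaRecord("a", "ACGT"), DnaRecord("b", "ACGA")]
        rep = mean_group_distance(recs, {"a": "g1", "b": "g2"})
        assert math.isnan(rep.within["g1"])


def _splits(tree):
    return tree_bipartitions(tree)


class TestNeighborJoining:
    def test_three_taxon_branch_lengths(self):
        dm = DistanceMatrix(
            ["a", "b", "c"],
            np.array([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]]),
        )
        tree = nj_tree(dm)
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        assert lengths["a"] == pytest.approx((0.2 + 0.3 - 0.4) / 2)
        assert lengths["b"] == pytest.approx((0.2 + 0.4 - 0.3) / 2)
        assert lengths["c"] == pytest.approx((0.3 + 0.4 - 0.2) / 2)

    def test_four_taxon_additive_matrix_recovered(self):
        # tree ((a:1,b:2):1,(c:3,d:4)) -> additive distances
        d = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        tree = nj_tree(DistanceMatrix(["a", "b", "c", "d"], d))
        assert _splits(tree) == {frozenset({"c", "d"})}
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths == pytest.approx({"a": 1, "b": 2, "c": 3, "d": 4})

    def test_random_additive_trees_recovered_exactly(self):
        rng = np.random.default_rng(77)
        for trial in range(15):
            n = int(rng.integers(5, 9))
            labels = [f"t{i}" for i in range(n)]
            # random unrooted binary tree via sequential leaf attachment
            sim = dendropy.Tree()
            tns = dendropy.TaxonNamespace(labels)
            sim.taxon_namespace = tns
            a = dendropy.Node(taxon=tns.get_taxon(labels[0]))
            b = dendropy.Node(taxon=tns.get_taxon(labels[1]))
            c = dendropy.Node(taxon=tns.get_taxon(labels[2]))
            for nd in (a, b, c):
                sim.seed_node.add_child(nd)
            edges = [a.edge, b.edge, c.edge]
            for lab in labels[3:]:
                edge = edges[int(rng.integers(len(edges)))]
                old_child = edge.head_node
                parent = edge.tail_node
                mid = dendropy.Node()
                parent.remove_child(old_child)
                parent.add_child(mid)
                mid.add_child(old_child)
                leaf = dendropy.Node(taxon=tns.get_taxon(lab))
                mid.add_child(leaf)
                edges.extend([leaf.edge, mid.edge, old_child.edge])
                edges.remove(edge)
            for e in sim.preorder_edge_iter():
                if e.tail_node is not None:
                    e.length = float(rng.uniform(0.1, 1.0))
            pdm = sim.phylogenetic_distance_matrix()
            tx = {t.label: t for t in tns}
            d = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    d[i, j] = d[j, i] = pdm.distance(tx[labels[i]], tx[labels[j]])
            mine = nj_tree(DistanceMatrix(labels, d))
            assert _splits(mine) == _splits(sim), f"trial {trial}"

    def test_matches_independent_nj_implementation(self):
        skbio = pytest.importorskip("skbio")
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(5)
        n = 6
        labels = [f"s{i}" for i in range(n)]
        m = rng.uniform(0.1, 1.0, size=(n, n))
        d = (m + m.T) / 2
        np.fill_diagonal(d, 0)
        mine = nj_tree(DistanceMatrix(labels, d))
        ref = skbio_nj(skbio.DistanceMatrix(d, ids=labels))
        import io

        buf = io.StringIO()
        ref.write(buf)
        ref_tree = dendropy.Tree.get(data=buf.getvalue(), schema="newick")
        assert _splits(mine) == _splits(ref_tree)

    def test_identical_rows_give_zero_length_pair(self):
        d = np.array(
            [[0, 0, 0.5, 0.5], [0, 0, 0.5, 0.5], [0.5, 0.5, 0, 0.2], [0.5, 0.5, 0.2, 0]]
        )
        tree = nj_tree(DistanceMatrix(["a", "b", "c", "d"], d))
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths["a"] == 0 and lengths["b"] == 0

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            nj_tree(DistanceMatrix(["a", "b"], np.array([[0, 1.0], [1.0, 0]])))


def _signal_alignment():
    """Mostly constant alignment whose variable columns support the (a,b) clade."""
    labels = ["a", "b", "c", "d", "e"]
    cols = [("A",) * 5] * 150  # constant background keeps distances small
    cols += [("G", "G", "A", "A", "A")] * 30  # a,b share a derived state
    # minor autapomorphies keep c, d, e distinct
    cols += [
        ("A", "A", "G", "A", "A"),
        ("A", "A", "A", "G", "A"),
        ("A", "A", "A", "A", "G"),
    ]
    seqs = ["".join(col[i] for col in cols) for i in range(5)]
    return [DnaRecord(l, s) for l, s in zip(labels, seqs)]


class TestBootstrap:
    def test_overwhelming_signal_gets_full_support(self):
        recs = _signal_alignment()
        tree = bootstrap_support(recs, n_reps=100, seed=11)
        supports = {
            frozenset(lf.taxon.label for lf in nd.leaf_iter()): nd.label
            for nd in tree.preorder_node_iter()
            if nd is not tree.seed_node and not nd.is_leaf()
        }
        ab = [v for k, v in supports.items() if k == frozenset({"a", "b"})]
        assert ab and int(ab[0]) == 100

    def test_single_replicate_supports_are_0_or_100(self):
        recs = _signal_alignment()
        tree = bootstrap_support(recs, n_reps=1, seed=3)
        for nd in tree.preorder_node_iter():
            if nd is not tree.seed_node and not nd.is_leaf() and nd.label:
                assert int(nd.label) in (0, 100)

    def test_same_seed_reproduces_supports(self):
        recs = _signal_alignment()
        t1 = bootstrap_support(recs, n_reps=30, seed=42)
        t2 = bootstrap_support(recs, n_reps=30, seed=42)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_taxon_order_invariance_given_seed(self):
        recs = _signal_alignment()
        t1 = bootstrap_support(recs, n_reps=25, seed=9)
        t2 = bootstrap_support(list(reversed(recs)), n_reps=25, seed=9)
        def support_map(t):
            out = {}
            for nd in t.preorder_node_iter():
                if nd is not t.seed_node and not nd.is_leaf() and nd.label:
                    out[frozenset(lf.taxon.label for lf in nd.leaf_iter())] = nd.label
            return out
        assert support_map(t1) == support_map(t2)


class TestNewick:
    def test_three_taxon_single_line(self, tmp_path):
        dm = DistanceMatrix(
            ["a", "b", "c"], np.array([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]])
        )
        path = tmp_path / "t.nwk"
        write_newick(nj_tree(dm), path)
        text = path.read_text().strip()
        assert text.endswith(";") and text.count(";") == 1

    def test_round_trip_preserves_topology_lengths_and_supports(self, tmp_path):
        recs = _signal_alignment()
        tree = bootstrap_support(recs, n_reps=20, seed=1)
        path = tmp_path / "boot.nwk"
        write_newick(tree, path)
        back = read_newick(path)
        assert _splits(back) == _splits(tree)
        orig = {
            lf.taxon.label: round(lf.edge.length, 6) for lf in tree.leaf_node_iter()
        }
        rt = {lf.taxon.label: round(lf.edge.length, 6) for lf in back.leaf_node_iter()}
        assert orig == rt
        assert "100" in path.read_text()  # supports serialized as node labels

    def test_malformed_newick_rejected(self, tmp_path):
        p = tmp_path / "bad.nwk"
        p.write_text("((a,b,(c;")
        with pytest.raises(ValueError, match="malformed"):
            read_newick(p)


def test_nj_from_fixture_alignment_separates_divergent_haplotype(fixtures):
    # mellifera_H1 carries ten private substitutions: it must be the longest
    # terminal branch on the NJ tree of the five fixtures
    recs = fixtures.record_list()
    tree = nj_tree_from_alignment(recs)
    lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
    assert max(lengths, key=lengths.get) == "mellifera_H1"
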