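import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wrkyscan import phylogeny as phy
from wrkyscan.seq_io import ProteinRecord

from _oracles import random_additive_tree, topology_by_enumeration


def dom(rid, seq):
    return ProteinRecord(id=rid, sequence=seq)


HEPT = "WRKYGQK"


class TestAlignDomains:
    def test_identical_domains_align_gap_free(self):
        records = [dom("a", HEPT + "ACDE"), dom("b", HEPT + "ACDE")]
        aln = phy.align_domains(records)
        assert aln.rows[0] == aln.rows[1]
        assert phy.p_distance(aln.rows[0], aln.rows[1]) == 0.0

    def test_offset_anchors_left_padded(self):
        records = [dom("a", "AAA" + HEPT + "DD"),
                   dom("b", "AAAAAAAAAA" + HEPT + "DD")]
        aln = phy.align_domains(records)
        assert aln.rows[0].startswith("-" * 7)
        assert aln.anchor_col == 10
        for i in range(2):
            assert aln.ungapped(i) == records[i].sequence

    def test_record_without_anchor_errors(self):
        with pytest.raises(phy.AlignmentError, match="noanchor"):
            phy.align_domains([dom("noanchor", "AAAA")])

    def test_trim_to_common_span(self):
        records = [dom("a", "AAA" + HEPT + "DDDDD"),
                   dom("b", HEPT + "DD")]
        aln = phy.align_domains(records, trim=True)
        assert "-" not in "".join(aln.rows)
        assert aln.n_cols == 9


class TestPDistance:
    def test_three_of_sixty_differ(self):
        a = "A" * 60
        b = "G" * 3 + "A" * 57
        assert phy.p_distance(a, b) == pytest.approx(0.05)

    def test_pairwise_deletion_ignores_gap_columns(self):
        a = "--AAAA"
        b = "GGAAAG"
        # 4 overlapping columns, 1 differs
        assert phy.p_distance(a, b) == pytest.approx(0.25)

    def test_disjoint_gap_patterns_error(self):
        with pytest.raises(phy.DistanceError):
            phy.p_distance("AA--", "--AA")

    def test_symmetry(self, rng):
        letters = np.array(list("ACDEFG-"))
        a = "".join(rng.choice(letters, 30))
        b = "".join(rng.choice(letters, 30))
        try:
            assert phy.p_distance(a, b) == phy.p_distance(b, a)
        except phy.DistanceError:
            pass


class TestPoissonCorrect:
    def test_closed_form_values(self):
        assert phy.poisson_correct(0.0) == 0.0
        assert phy.poisson_correct(0.5) == pytest.approx(np.log(2), abs=1e-12)

    def test_saturation_error(self):
        with pytest.raises(phy.DistanceError):
            phy.poisson_correct(1.0)

    def test_strictly_increasing_and_dominates_p(self):
        grid = np.arange(0.0, 0.99 + 1e-9, 1e-3)
        d = phy.poisson_correct(grid)
        assert np.all(np.diff(d) > 0)
        assert np.all(d >= grid)


class TestNeighborJoining:
    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # tree ((A:1,B:2):1,(C:3,D:4))
        D = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        tree = phy.neighbor_joining(phy.DistanceMatrix(["A", "B", "C", "D"], D))
        assert tree.bipartitions() == {
            frozenset({frozenset({"A", "B"}), frozenset({"C", "D"})})
        }
        lengths = {lf.name: lf.length for lf in tree.root.leaves()}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}

    def test_three_taxon_star_resolved(self):
        D = np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0]], float)
        tree = phy.neighbor_joining(phy.DistanceMatrix(["a", "b", "c"], D))
        assert len(tree.root.children) == 3
        assert all(lf.length == pytest.approx(1.0)
                   for lf in tree.root.leaves())

    def test_identical_rows_give_zero_length_cherry(self):
        D = np.array(
            [[0, 0, 5, 5], [0, 0, 5, 5], [5, 5, 0, 2], [5, 5, 2, 0]], float
        )
        tree = phy.neighbor_joining(phy.DistanceMatrix(list("abcd"), D))
        lengths = {lf.name: lf.length for lf in tree.root.leaves()}
        assert lengths["a"] == 0.0 and lengths["b"] == 0.0

    def test_too_few_taxa_rejected(self):
        with pytest.raises(phy.DistanceError):
            phy.neighbor_joining(
                phy.DistanceMatrix(["a", "b"], np.zeros((2, 2)))
            )

    def test_matches_enumeration_oracle_on_small_matrices(self):
        rng = np.random.default_rng(42)
        for n in (4, 5):
            for _ in range(10):
                labels, D, true_bps = random_additive_tree(n, rng)
                assert topology_by_enumeration(D, labels) == true_bps
                tree = phy.neighbor_joining(phy.DistanceMatrix(labels, D))
                assert tree.bipartitions() == true_bps

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        n=st.integers(min_value=4, max_value=8),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_additive_matrix_topology_recovery_property(self, n, seed):
        rng = np.random.default_rng(seed)
        labels, D, true_bps = random_additive_tree(n, rng)
        tree = phy.neighbor_joining(phy.DistanceMatrix(labels, D))
        assert tree.bipartitions() == true_bps

    def test_agrees_with_dendropy_on_noisy_matrix(self):
        dendropy = pytest.importorskip("dendropy")
        rng = np.random.default_rng(9)
        labels, D, _ = random_additive_tree(7, rng)
        noise = rng.uniform(0, 0.02, size=D.shape)
        D = D + noise + noise.T
        np.fill_diagonal(D, 0.0)
        ours = phy.neighbor_joining(phy.DistanceMatrix(labels, D))
        header = "x," + ",".join(labels)
        lines = [header] + [
            labels[i] + "," + ",".join(f"{v:.10f}" for v in D[i])
            for i in range(len(labels))
        ]
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            io.StringIO("\n".join(lines) + "\n"), delimiter=","
        )
        dtree = pdm.nj_tree()
        dtree.encode_bipartitions()
        all_l = frozenset(labels)
        theirs = set()
        for bp in dtree.bipartition_encoding:
            side = frozenset(
                t.label for t in bp.leafset_taxa(dtree.taxon_namespace)
            )
            if 1 < len(side) < len(all_l) - 1:
                theirs.add(frozenset({side, all_l - side}))
        assert ours.bipartitions() == theirs


class TestBootstrap:
    def _cluster_alignment(self):
        # two well-separated 3-leaf clusters, zero within-cluster divergence
        a = HEPT + "AAAAAAAAAAAAAAAAAAAA"
        b = HEPT + "TTTTTTTTTTTTTTTTTTTT"
        return phy.align_domains(
            [dom(f"a{i}", a) for i in range(3)]
            + [dom(f"b{i}", b) for i in range(3)]
        )

    def test_central_edge_support_100(self):
        tree = phy.bootstrap_support(self._cluster_alignment(),
                                     n_reps=100, seed=1)
        supports = [
            node.support for node in tree.postorder()
            if node.support is not None
        ]
        assert supports  # the a-vs-b split exists
        clades = tree.clade_leafsets()
        for node, side in clades.items():
            if side == frozenset({"a0", "a1", "a2"}) or side == frozenset(
                {"b0", "b1", "b2"}
            ):
                assert node.support == pytest.approx(100.0)

    def test_same_seed_identical_supports(self):
        aln = self._cluster_alignment()
        t1 = phy.bootstrap_support(aln, n_reps=50, seed=7)
        t2 = phy.bootstrap_support(aln, n_reps=50, seed=7)
        assert t1.to_newick() == t2.to_newick()

    def test_supports_within_0_100(self, rng):
        letters = np.array(list("ACDEFGIK"))
        records = [
            dom(f"s{i}", HEPT + "".join(rng.choice(letters, 25)))
            for i in range(6)
        ]
        tree = phy.bootstrap_support(phy.align_domains(records),
                                     n_reps=30, seed=2)
        for node in tree.postorder():
            if node.support is not None:
                assert 0.0 <= node.support <= 100.0

    def test_degenerate_identical_sequences_no_crash(self):
        aln = phy.align_domains([dom(f"x{i}", HEPT + "AAAA")
                                 for i in range(4)])
        tree = phy.bootstrap_support(aln, n_reps=10, seed=3)
        assert sorted(tree.leaf_labels()) == ["x0", "x1", "x2", "x3"]

    def test_bad_parameters(self):
        aln = self._cluster_alignment()
        with pytest.raises(ValueError):
            phy.bootstrap_support(aln, n_reps=0, seed=1)
        with pytest.raises(ValueError):
            phy.bootstrap_support(aln, n_reps=10, seed=None)


class TestNewick:
    def test_simple_round_trip(self):
        nwk = "((A:1,B:2):1,C:3);"
        assert phy.read_newick(nwk).to_newick() == nwk

    def test_supports_round_trip(self):
        nwk = "((A:1,B:2)87:1,C:3,(D:1,E:1)55:2);"
        tree = phy.read_newick(nwk)
        assert tree.to_newick() == nwk
        supports = {n.support for n in tree.postorder() if n.support}
        assert supports == {87.0, 55.0}

    def test_unbalanced_parentheses_error_carries_offset(self):
        with pytest.raises(phy.NewickError, match="offset"):
            phy.read_newick("((A:1,B:2:1,C:3);")

    def test_lengths_preserved_to_tolerance(self):
        nwk = "(A:0.123456789,B:1e-05,C:3.5);"
        tree = phy.read_newick(nwk)
        lengths = {lf.name: lf.length for lf in tree.root.leaves()}
        assert lengths["A"] == pytest.approx(0.123456789, abs=1e-9)
        assert lengths["B"] == pytest.approx(1e-5, abs=1e-9)

    def test_round_trip_via_dendropy(self):
        dendropy = pytest.importorskip("dendropy")
        nwk = "((A:1,B:2)90:1,C:3,D:4);"
        ours = phy.read_newick(nwk).to_newick()
        theirs = dendropy.Tree.get(data=nwk, schema="newick")
        assert sorted(phy.read_newick(ours).leaf_labels()) == sorted(
            t.label for t in theirs.taxon_namespace
        )
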