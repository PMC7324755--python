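"""Progressive alignment, column filtering, distance computation, UPGMA/NJ
tree building, Manhattan pan-genome trees, bootstrap and RF comparison."""

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix, TreeNode

import panveil as pv
from panveil import simulate as sim
from panveil.phylo import MAX_DISTANCE, MultipleAlignment, bipartitions
from panveil.records import strain_of


def _tip_depths(tree):
    return {t.name: tree.distance(t) for t in tree.tips()}


class TestAlignFamily:
    def test_identical_sequences_align_gap_free(self):
        aln = pv.align_family({"a": "MKVLWAAL", "b": "MKVLWAAL", "c": "MKVLWAAL"})
        assert aln.rows == ["MKVLWAAL"] * 3
        assert aln.length == 8

    def test_two_sequences_reduce_to_pairwise(self):
        aln = pv.align_family({"a": "MKVLW", "b": "MKLW"})
        assert len(aln.rows) == 2
        assert aln.length == 5
        assert aln.row("a") == "MKVLW"
        assert aln.row("b").count("-") == 1

    def test_substitution_only_family_keeps_ancestral_length(self):
        cfg = sim.SimulationConfig(n_strains=5, n_core=1, n_accessory=0, n_specific=0,
                                   mean_protein_length=90, divergence=0.1, paralog_rate=0.0, seed=3)
        proteomes, _ = sim.simulate_pangenome(cfg)
        seqs = {p.strain_id: p.proteins[0].sequence for p in proteomes}
        aln = pv.align_family(seqs)
        assert aln.length == len(next(iter(seqs.values())))
        assert all("-" not in row for row in aln.rows)

    def test_requires_two_sequences(self):
        with pytest.raises(ValueError):
            pv.align_family({"a": "MKV"})


class TestFilterColumns:
    def test_conserved_gapless_alignment_untouched(self):
        aln = MultipleAlignment(list("abc"), ["MKV", "MKV", "MKV"])
        out = pv.filter_columns(aln)
        assert out.rows == aln.rows and out.column_mask.all()

    def test_all_gap_column_dropped(self):
        aln = MultipleAlignment(list("ab"), ["M-V", "M-V"])
        out = pv.filter_columns(aln, max_gap_fraction=0.99)
        assert out.rows == ["MV", "MV"]
        assert out.column_mask.tolist() == [True, False, True]

    def test_modal_residue_rule(self):
        aln = MultipleAlignment(list("abcd"), ["A", "A", "A", "T"])
        assert pv.filter_columns(aln, min_identity_fraction=0.5).length == 1
        assert pv.filter_columns(aln, min_identity_fraction=0.8).length == 0

    def test_gap_fraction_threshold(self):
        aln = MultipleAlignment(list("abcd"), ["A", "A", "A", "-"])
        assert pv.filter_columns(aln, max_gap_fraction=0.2).length == 0
        assert pv.filter_columns(aln, max_gap_fraction=0.3).length == 1


class TestConcatenate:
    def test_lengths_add_in_family_order(self):
        a = MultipleAlignment(["x", "y"], ["MKVLWAALLV", "MKVLWAALLV"])
        b = MultipleAlignment(["y", "x"], ["ACDEFGHIKLMNPQRSTVWY", "ACDEFGHIKLMNPQRSTVWY"])
        out = pv.concatenate([a, b], ["x", "y"])
        assert out.length == 30
        assert out.labels == ["x", "y"]

    def test_missing_strain_row_rejected(self):
        a = MultipleAlignment(["x", "y"], ["MK", "MK"])
        with pytest.raises(ValueError):
            pv.concatenate([a], ["x", "z"])


class TestProteinDistance:
    def test_identical_rows_zero(self):
        aln = MultipleAlignment(["a", "b"], ["MKVLW", "MKVLW"])
        assert pv.protein_distance(aln)["a", "b"] == 0.0

    def test_p_distance_definition(self):
        row_a = "A" * 100
        row_b = "C" * 5 + "A" * 95
        aln = MultipleAlignment(["a", "b"], [row_a, row_b])
        assert pv.protein_distance(aln, "p")["a", "b"] == pytest.approx(0.05)
        assert pv.protein_distance(aln, "poisson")["a", "b"] == pytest.approx(-np.log(0.95))

    def test_gapped_columns_excluded(self):
        aln = MultipleAlignment(["a", "b"], ["MK-LW", "MKV-W"])
        # only columns 0,1,4 are mutually ungapped and all match
        assert pv.protein_distance(aln)["a", "b"] == 0.0

    def test_saturated_pair_capped(self):
        aln = MultipleAlignment(["a", "b"], ["AAAA", "CCCC"])
        assert pv.protein_distance(aln, "poisson")["a", "b"] == MAX_DISTANCE


class TestUPGMA:
    def test_hand_agglomeration_on_ultrametric_input(self):
        d = DistanceMatrix([[0, 2, 4], [2, 0, 4], [4, 4, 0]], ids=list("ABC"))
        tree = pv.upgma(d)
        depths = _tip_depths(tree)
        assert depths == pytest.approx({"A": 2.0, "B": 2.0, "C": 2.0})
        ab = tree.lca([n for n in tree.tips() if n.name in "AB"])
        assert tree.distance(ab) == pytest.approx(1.0)

    def test_two_taxa_split_distance(self):
        tree = pv.upgma(DistanceMatrix([[0, 3], [3, 0]], ids=list("AB")))
        assert _tip_depths(tree) == pytest.approx({"A": 1.5, "B": 1.5})

    def test_output_always_ultrametric(self, rng):
        for _ in range(5):
            n = 6
            x = rng.random((n, 4))
            d = np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1))
            tree = pv.upgma(DistanceMatrix(d, ids=[f"t{i}" for i in range(n)]))
            depths = list(_tip_depths(tree).values())
            assert max(depths) - min(depths) < 1e-9

    def test_exact_on_ultrametric_matrices(self):
        source = pv.simulate_strain_tree(6, seed=12)
        tips = list(source.tips())
        ids = [t.name for t in tips]
        d = np.zeros((6, 6))
        for i, a in enumerate(tips):
            for j, b in enumerate(tips):
                if i < j:
                    d[i, j] = d[j, i] = a.distance(b)
        tree = pv.upgma(DistanceMatrix(d, ids=ids))
        rebuilt = {frozenset((x.name, y.name)): x.distance(y)
                   for x in tree.tips() for y in tree.tips() if x.name < y.name}
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                if i < j:
                    assert rebuilt[frozenset((a, b))] == pytest.approx(d[i, j], abs=1e-9)


class TestNeighborJoining:
    def test_additive_four_taxon_reconstruction(self):
        d = DistanceMatrix([[0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]],
                           ids=list("ABCD"))
        tree = pv.neighbor_joining(d)
        assert bipartitions(tree) == {frozenset({"C", "D"})}
        # all pairwise path lengths reproduce the additive input
        for a in tree.tips():
            for b in tree.tips():
                if a.name < b.name:
                    assert a.distance(b) == pytest.approx(d[a.name, b.name], abs=1e-9)

    def test_three_taxa_closed_form(self):
        d = DistanceMatrix([[0, 3, 4], [3, 0, 5], [4, 5, 0]], ids=list("ABC"))
        tree = pv.neighbor_joining(d)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_label_equivariance(self):
        base = np.array([[0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]], dtype=float)
        t1 = pv.neighbor_joining(DistanceMatrix(base, ids=list("ABCD")))
        perm = [2, 3, 0, 1]
        t2 = pv.neighbor_joining(DistanceMatrix(base[np.ix_(perm, perm)], ids=["C", "D", "A", "B"]))
        assert pv.rf_distance(t1, t2) == 0

    def test_negative_branch_clamped_with_warning(self):
        # violates the triangle inequality: closed form gives B a negative branch
        d = DistanceMatrix([[0, 1, 5], [1, 0, 1], [5, 1, 0]], ids=list("ABC"))
        with pytest.warns(UserWarning, match="clamped"):
            tree = pv.neighbor_joining(d)
        for node in tree.traverse(include_self=False):
            assert node.length >= 0

    def test_requires_three_taxa(self):
        with pytest.raises(ValueError):
            pv.neighbor_joining(DistanceMatrix([[0, 1], [1, 0]], ids=list("AB")))


class TestManhattanTree:
    def test_worked_presence_example_merge_heights(self):
        m = pd.DataFrame([[1, 1, 1, 0, 1], [1, 1, 0, 0, 1], [1, 0, 1, 1, 0]],
                         index=["A", "B", "C"])
        tree = pv.manhattan_tree(m)
        depths = _tip_depths(tree)
        assert depths == pytest.approx({"A": 1.75, "B": 1.75, "C": 1.75})
        ab = tree.lca([n for n in tree.tips() if n.name in "AB"])
        assert depths["A"] - ab.distance(next(t for t in ab.tips() if t.name == "A")) == pytest.approx(1.25)
        assert next(t for t in ab.tips() if t.name == "A").length == pytest.approx(0.5)

    def test_duplicated_strain_profile_forms_zero_height_cherry(self):
        m = pd.DataFrame([[1, 0, 1], [1, 0, 1], [0, 1, 1]], index=["A", "A2", "C"])
        tree = pv.manhattan_tree(m)
        a = next(t for t in tree.tips() if t.name == "A")
        a2 = next(t for t in tree.tips() if t.name == "A2")
        assert a.distance(a2) == 0.0

    def test_binary_distance_equals_differing_cluster_count(self):
        m = pd.DataFrame([[1, 5, 0, 2], [1, 0, 0, 1]], index=["A", "B"])
        tree = pv.manhattan_tree(m, binarize=True)
        a, b = tree.tips()
        assert a.distance(b) == 1.0  # only the second cluster differs in presence


class TestBootstrap:
    def test_fully_informative_alignment_gets_full_support(self):
        rows = ["AAAAAAAAAA", "AAAAAAAAAA", "TTTTTTTTTT", "TTTTTTTTTT"]
        aln = MultipleAlignment(list("abcd"), rows)

        def builder(a):
            return pv.upgma(pv.protein_distance(a))

        tree = pv.bootstrap_support(aln, builder, n_replicates=30, seed=1)
        supports = [int(n.name) for n in tree.non_tips(include_self=False) if n.name]
        assert supports and all(s == 100 for s in supports)

    def test_supports_bounded_and_reproducible(self, rng):
        m = pd.DataFrame((rng.random((6, 30)) < 0.5).astype(int),
                         index=[f"S{i}" for i in range(6)])
        m = m.loc[:, m.sum() > 0]
        t1 = pv.bootstrap_support(m, pv.manhattan_tree, n_replicates=20, seed=11)
        t2 = pv.bootstrap_support(m, pv.manhattan_tree, n_replicates=20, seed=11)
        s1 = [int(n.name) for n in t1.non_tips(include_self=False) if n.name]
        s2 = [int(n.name) for n in t2.non_tips(include_self=False) if n.name]
        assert s1 == s2
        assert all(0 <= s <= 100 for s in s1)


class TestRFDistance:
    def test_identical_trees_zero(self):
        t = pv.simulate_strain_tree(6, seed=2)
        assert pv.rf_distance(t, t) == 0

    def test_conflicting_four_taxon_trees(self):
        t1 = TreeNode.read(["((A:1,B:1):1,(C:1,D:1):1);"])
        t2 = TreeNode.read(["((A:1,C:1):1,(B:1,D:1):1);"])
        assert pv.rf_distance(t1, t2) == 2
        assert pv.rf_distance(t2, t1) == 2

    def test_leaf_set_mismatch_rejected(self):
        t1 = TreeNode.read(["((A:1,B:1):1,C:1);"])
        t2 = TreeNode.read(["((A:1,B:1):1,D:1);"])
        with pytest.raises(ValueError):
            pv.rf_distance(t1, t2)


class TestCoreGenomeTree:
    def test_recovers_generating_topology_on_one_panel(self):
        cfg = sim.SimulationConfig(n_strains=6, n_core=15, n_accessory=0, n_specific=0,
                                   mean_protein_length=150, divergence=0.05,
                                   paralog_rate=0.0, seed=4)
        proteomes, truth = sim.simulate_pangenome(cfg)
        seq_of = {r.protein_id: r.sequence for p in proteomes for r in p}
        families = [{strain_of(p): seq_of[p] for p in members}
                    for _, members in sorted(truth.members().items())]
        tree, concat = pv.core_genome_tree(families, [p.strain_id for p in proteomes])
        assert pv.rf_distance(tree, truth.strain_tree) == 0
        assert concat.length > 0
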