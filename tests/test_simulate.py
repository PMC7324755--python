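"""The simulator must produce exactly the structure it promises: known
family membership, partition labels recomputable from presence patterns,
an ultrametric strain tree, and exact planted CRISPR arrays."""

import numpy as np
import pytest

import panveil as pv
from panveil import simulate as sim
from panveil.records import strain_of


class TestStrainTree:
    @pytest.mark.parametrize("n", [2, 4, 9])
    def test_binary_ultrametric_height_one(self, n):
        tree = pv.simulate_strain_tree(n, seed=3)
        tips = list(tree.tips())
        assert len(tips) == n
        assert len(set(t.name for t in tips)) == n
        assert sum(1 for node in tree.non_tips(include_self=True)) == n - 1
        for tip in tips:
            assert tree.distance(tip) == pytest.approx(1.0, abs=1e-12)

    def test_rejects_single_strain(self):
        with pytest.raises(ValueError):
            pv.simulate_strain_tree(1, seed=0)


class TestPangenome:
    def test_zero_divergence_yields_identical_core_proteomes(self):
        cfg = sim.SimulationConfig(n_strains=3, n_core=5, n_accessory=0, n_specific=0,
                                   divergence=0.0, paralog_rate=0.0, seed=1)
        proteomes, truth = sim.simulate_pangenome(cfg)
        assert [len(p) for p in proteomes] == [5, 5, 5]
        seqs = [[r.sequence for r in p] for p in proteomes]
        assert seqs[0] == seqs[1] == seqs[2]
        assert set(truth.partition_label.values()) == {"core"}

    def test_zero_divergence_family_members_identical(self, small_panel):
        cfg = sim.SimulationConfig(n_strains=4, n_core=3, n_accessory=2, n_specific=1,
                                   divergence=0.0, paralog_rate=0.1, seed=9)
        proteomes, truth = sim.simulate_pangenome(cfg)
        seq_of = {r.protein_id: r.sequence for p in proteomes for r in p}
        for members in truth.members().values():
            assert len({seq_of[m] for m in members}) == 1

    def test_single_accessory_family_spans_two_strains(self):
        cfg = sim.SimulationConfig(n_strains=3, n_core=0, n_accessory=1, n_specific=0,
                                   paralog_rate=0.0, seed=2)
        proteomes, truth = sim.simulate_pangenome(cfg)
        assert sum(1 for p in proteomes if len(p) > 0) == 2
        assert list(truth.partition_label.values()) == ["accessory"]

    def test_specific_families_are_multicopy_in_one_strain(self):
        cfg = sim.SimulationConfig(n_strains=4, n_core=0, n_accessory=0, n_specific=3,
                                   paralog_rate=0.0, seed=5)
        proteomes, truth = sim.simulate_pangenome(cfg)
        for members in truth.members().values():
            strains = {strain_of(m) for m in members}
            assert len(strains) == 1
            assert len(members) == 2

    def test_per_strain_counts_follow_presence_arithmetic(self):
        cfg = sim.SimulationConfig(n_strains=9, n_core=150, n_accessory=60, n_specific=5,
                                   divergence=0.05, paralog_rate=0.0, seed=11)
        proteomes, truth = sim.simulate_pangenome(cfg)
        lo = cfg.n_core
        hi = cfg.n_core + cfg.n_accessory + cfg.specific_copies * cfg.n_specific
        for p in proteomes:
            assert lo <= len(p) <= hi
        # each protein in exactly one family; totals conserved
        assert sum(len(p) for p in proteomes) == len(truth.cluster_assignment)

    def test_partition_labels_recomputable_from_presence(self, small_panel):
        _, _, truth = small_panel
        true_clusters = pv.ClusterSet(clusters=truth.members())
        matrix = pv.build_presence_matrix(true_clusters)
        partition = pv.partition_clusters(matrix)
        assert partition.label == truth.partition_label

    def test_fixed_seed_reproducible(self):
        cfg = sim.SimulationConfig(n_strains=3, n_core=4, n_accessory=2, n_specific=1, seed=13)
        a = sim.simulate_pangenome(cfg)
        b = sim.simulate_pangenome(cfg)
        assert [[r.sequence for r in p] for p in a[0]] == [[r.sequence for r in p] for p in b[0]]
        assert a[1].cluster_assignment == b[1].cluster_assignment

    def test_rejects_all_zero_family_counts(self):
        cfg = sim.SimulationConfig(n_strains=3, n_core=0, n_accessory=0, n_specific=0)
        with pytest.raises(ValueError):
            sim.simulate_pangenome(cfg)

    @pytest.mark.parametrize("kwargs", [
        {"n_strains": 1}, {"divergence": 0.6}, {"gc_content": 0.0}, {"specific_copies": 0},
    ])
    def test_config_validation(self, kwargs):
        with pytest.raises(ValueError):
            sim.SimulationConfig(**kwargs)


class TestGenomeArrays:
    def test_planted_array_footprint_arithmetic(self):
        cfg = sim.SimulationConfig(seed=5, genome_length=2000,
                                   array_specs=[sim.ArraySpec(4, 30, 35, False)])
        genome, arrays = sim.simulate_genome_with_arrays(cfg)
        (a,) = arrays
        assert a.end - a.start == 4 * 30 + 3 * 35 == 225
        assert len(genome) == 2000

    def test_no_arrays_requested(self):
        cfg = sim.SimulationConfig(seed=5, genome_length=2000, array_specs=[])
        genome, arrays = sim.simulate_genome_with_arrays(cfg)
        assert arrays == []

    def test_truncated_terminal_repeat_is_half_length(self):
        cfg = sim.SimulationConfig(seed=9, genome_length=3000,
                                   array_specs=[sim.ArraySpec(3, 28, 33, True)])
        _, arrays = sim.simulate_genome_with_arrays(cfg)
        s, e, truncated = arrays[0].repeat_instances[-1]
        assert truncated and e - s == 14

    def test_planted_repeats_exact_and_nonoverlapping(self):
        cfg = sim.SimulationConfig(seed=21, genome_length=20000)
        genome, arrays = sim.simulate_genome_with_arrays(cfg)
        spans = sorted((a.start, a.end) for a in arrays)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2
        for a in arrays:
            a.validate(genome)
            assert a.start >= 100 and a.end <= len(genome) - 100
            for s, e, truncated in a.repeat_instances:
                if truncated:
                    assert genome[s:e] == a.repeat_consensus[: e - s]
                else:
                    assert genome[s:e] == a.repeat_consensus

    def test_too_small_genome_rejected(self):
        # footprint 225 bp + 200 bp margin exceeds a 400 bp genome
        cfg = sim.SimulationConfig(seed=1, genome_length=400,
                                   array_specs=[sim.ArraySpec(4, 30, 35, False)])
        with pytest.raises(ValueError):
            sim.simulate_genome_with_arrays(cfg)


class TestAnnotationLabels:
    def test_rate_one_labels_every_protein(self, small_panel):
        _, proteomes, truth = small_panel
        table = sim.simulate_annotation_labels(truth, label_rate=1.0, seed=1)
        pids = {r.protein_id for p in proteomes for r in p}
        for ns in sim.DEFAULT_NAMESPACES:
            assert set(table[table.namespace == ns].protein_id) == pids

    def test_rate_zero_empty(self, small_panel):
        _, _, truth = small_panel
        assert sim.simulate_annotation_labels(truth, label_rate=0.0, seed=1).empty

    def test_labels_constant_within_cluster(self, small_panel):
        _, _, truth = small_panel
        table = sim.simulate_annotation_labels(truth, label_rate=0.6, seed=4)
        table["cluster"] = table.protein_id.map(truth.cluster_assignment)
        for (_, _), group in table.groupby(["cluster", "namespace"]):
            assert group.label.nunique() == 1

    def test_invalid_rate_rejected(self, small_panel):
        _, _, truth = small_panel
        with pytest.raises(ValueError):
            sim.simulate_annotation_labels(truth, label_rate=1.5)
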