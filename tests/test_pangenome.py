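"""Presence-matrix accounting, partition rules, accumulation curves and the
Heaps-law openness fit."""

import numpy as np
import pandas as pd
import pytest

import panveil as pv
from panveil.pangenome import (
    AccumulationCurve,
    read_presence_matrix,
    write_presence_matrix,
)


@pytest.fixture()
def worked_matrix():
    """3 strains x 4 clusters: one of each partition plus a multi-copy core."""
    return pd.DataFrame(
        {"c1": [1, 1, 1], "c2": [1, 1, 0], "c3": [2, 0, 0], "c4": [1, 2, 1]},
        index=pd.Index(["A", "B", "C"], name="Strain"),
    )


class TestPresenceMatrix:
    def test_counts_conserve_clustered_proteins(self):
        cs = pv.ClusterSet(clusters={"cluster1": ["A|p1", "B|p2"], "cluster2": ["A|p3", "A|p4", "C|p5"]})
        matrix = pv.build_presence_matrix(cs)
        assert matrix.to_numpy().sum() == 5
        assert matrix.loc["A", "cluster2"] == 2
        assert list(matrix.index) == ["A", "B", "C"]

    def test_two_member_cluster_column(self):
        cs = pv.ClusterSet(clusters={"cluster1": ["A|p1", "B|p2"]})
        matrix = pv.build_presence_matrix(cs, strain_list=["A", "B"])
        assert matrix["cluster1"].tolist() == [1, 1]

    def test_unknown_strain_rejected(self):
        cs = pv.ClusterSet(clusters={"cluster1": ["A|p1", "B|p2"]})
        with pytest.raises(ValueError):
            pv.build_presence_matrix(cs, strain_list=["A"])

    def test_tsv_roundtrip(self, worked_matrix, tmp_path):
        path = tmp_path / "matrix.tsv"
        write_presence_matrix(worked_matrix, path)
        back = read_presence_matrix(path)
        assert (back.to_numpy() == worked_matrix.to_numpy()).all()
        assert list(back.columns) == list(worked_matrix.columns)


class TestPartition:
    def test_worked_example_partition(self, worked_matrix):
        part = pv.partition_clusters(worked_matrix)
        assert part.label == {"c1": "core", "c2": "accessory", "c3": "specific", "c4": "core"}
        assert part.single_copy_core == {"c1"}
        assert part.per_strain_accessory.tolist() == [1, 1, 0]
        assert part.per_strain_specific.tolist() == [1, 0, 0]

    def test_label_counts_sum_to_total(self, worked_matrix):
        part = pv.partition_clusters(worked_matrix)
        assert sum(part.counts.values()) == worked_matrix.shape[1]

    def test_all_ones_matrix_everything_single_copy_core(self):
        m = pd.DataFrame(np.ones((4, 6), dtype=int), index=list("ABCD"),
                         columns=[f"c{i}" for i in range(6)])
        part = pv.partition_clusters(m)
        assert set(part.label.values()) == {"core"}
        assert part.single_copy_core == set(m.columns)

    def test_multicopy_single_strain_is_specific_not_accessory(self):
        m = pd.DataFrame({"c1": [3, 0], "c2": [1, 1]}, index=["A", "B"])
        assert pv.partition_clusters(m).label["c1"] == "specific"

    def test_empty_matrix_empty_partition(self):
        part = pv.partition_clusters(pd.DataFrame())
        assert part.label == {}

    def test_core_percentage_on_reported_cluster_counts(self):
        # replaying the published panel arithmetic: 1,512 core of 2,065
        summary = pv.summarize_partition({"core": 1512, "accessory": 540, "specific": 13})
        assert summary.loc["core", "percent"] == 73.22
        assert summary.attrs["total"] == 2065


class TestAccumulation:
    def test_exhaustive_mean_pairwise_pan_size(self, worked_matrix):
        curve = pv.accumulation_curves(worked_matrix, n_permutations=1)
        assert curve.exhaustive and curve.n_permutations == 6
        # pairs (A,B): 4, (A,C): 4, (B,C): 3 clusters; each ordering twice
        assert curve.pan_sizes[:, 1].mean() == pytest.approx(11 / 3)

    def test_full_subset_endpoints_constant(self, worked_matrix):
        curve = pv.accumulation_curves(worked_matrix, n_permutations=1)
        part = pv.partition_clusters(worked_matrix)
        assert (curve.pan_sizes[:, -1] == worked_matrix.shape[1]).all()
        assert (curve.core_sizes[:, -1] == part.counts["core"]).all()

    def test_single_strain_pan_equals_presence_count(self, worked_matrix):
        curve = pv.accumulation_curves(worked_matrix, n_permutations=1)
        presence = (worked_matrix >= 1).sum(axis=1)
        assert set(curve.pan_sizes[:, 0]) <= set(presence.values)

    def test_monotone_within_every_permutation(self, rng):
        m = pd.DataFrame((rng.random((9, 40)) < 0.6).astype(int),
                         index=[f"S{i}" for i in range(9)],
                         columns=[f"c{i}" for i in range(40)])
        m = m.loc[:, m.sum() > 0]
        curve = pv.accumulation_curves(m, n_permutations=200, seed=5)
        assert not curve.exhaustive
        assert (np.diff(curve.pan_sizes, axis=1) >= 0).all()
        assert (np.diff(curve.core_sizes, axis=1) <= 0).all()

    def test_sampled_curves_reproducible_with_seed(self, rng):
        m = pd.DataFrame((rng.random((8, 30)) < 0.5).astype(int) + 1)
        a = pv.accumulation_curves(m, n_permutations=50, seed=9)
        b = pv.accumulation_curves(m, n_permutations=50, seed=9)
        assert (a.pan_sizes == b.pan_sizes).all()


def _curve_from_pan(pan_row: np.ndarray) -> AccumulationCurve:
    pan = np.asarray(pan_row, dtype=float)[None, :]
    return AccumulationCurve(np.arange(1, pan.shape[1] + 1), pan, pan.copy(), True)


class TestHeaps:
    def test_recovers_exact_power_law_exponent(self):
        k = np.arange(2, 10)
        pan = np.concatenate([[100.0], 100.0 + np.cumsum(100.0 * k**-0.7)])
        fit = pv.fit_heaps(_curve_from_pan(pan))
        assert fit.alpha == pytest.approx(0.7, abs=1e-6)
        assert fit.openness_verdict == "open"
        assert fit.gamma == pytest.approx(0.3, abs=1e-6)

    def test_flat_discovery_rate_is_open_with_zero_exponent(self):
        pan = 100.0 + 10.0 * np.arange(9)
        fit = pv.fit_heaps(_curve_from_pan(pan))
        assert fit.alpha == pytest.approx(0.0, abs=1e-9)
        assert fit.openness_verdict == "open"

    def test_saturated_curve_is_closed(self):
        pan = np.full(9, 120.0)
        fit = pv.fit_heaps(_curve_from_pan(pan))
        assert fit.openness_verdict == "closed"
        assert fit.gamma == 0.0 and fit.kappa > 0

    def test_exponent_recovered_under_multiplicative_noise(self, rng):
        k = np.arange(2, 10)
        for alpha_true in (0.5, 0.8):
            new = 80.0 * k**-alpha_true * (1 + 0.05 * rng.standard_normal((25, k.size)))
            pan = np.concatenate([np.full((25, 1), 80.0), 80.0 + np.cumsum(new, axis=1)], axis=1)
            curve = AccumulationCurve(np.arange(1, 10), pan, pan.copy(), False)
            fit = pv.fit_heaps(curve)
            assert fit.alpha == pytest.approx(alpha_true, abs=0.05)


class TestProteomeSummary:
    def test_reported_strain_panel_total(self):
        counts = {"KON": 1903, "CMW7756B": 1973, "ACS-049-V-Sch6": 1840,
                  "ACS-134-V-Col7a": 1903, "KON_ATCC_17744": 1832, "NCTC11830": 1957,
                  "AF36-15BH": 1781, "KHUD_V1": 1969, "OK5": 1790}
        table, total = pv.proteome_summary(counts)
        assert total == 16948
        assert table.loc["OK5", "n_proteins"] == 1790

    def test_empty_input_totals_zero(self):
        _, total = pv.proteome_summary([])
        assert total == 0

    def test_simulated_panel(self, small_panel):
        _, proteomes, truth = small_panel
        table, total = pv.proteome_summary(proteomes)
        assert total == len(truth.cluster_assignment)
        assert len(table) == 3
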