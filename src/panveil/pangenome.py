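"""Pan-genome accounting: partition, accumulation curves and openness.

The presence/absence matrix (strains × clusters, integer copy numbers) is
the unit of accounting.  A cluster is **core** when every strain carries at
least one copy, **specific** when exactly one strain does, and
**accessory** otherwise (≥2 strains but not all) — note that a cluster
found in a single strain with several copies is specific, not accessory.
Single-copy core clusters (exactly one copy in every strain) are the basis
of concatenated phylogenies.

Openness is judged Tettelin-style from the gene-accumulation curve: the
median number of new clusters contributed by the k-th genome is fitted as
``n_new(k) = kappa * k**(-alpha)`` (log–log least squares) and the
pan-genome is called *open* when ``alpha < 1``.
"""

from __future__ import annotations

import json

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import ClusterSet
from .records import StrainProteome, strain_of


def build_presence_matrix(cluster_set: ClusterSet, strain_list: list[str] | None = None,
                          strain_lookup=strain_of) -> pd.DataFrame:
    """Strains × clusters copy-number DataFrame from a cluster set.

    Cluster column order follows cluster id order; the result is
    deterministic.  Every clustered protein must belong to a strain in
    ``strain_list`` when one is given.
    """
    clusters = cluster_set.clusters
    cluster_ids = sorted(clusters, key=lambda c: (len(c), c))
    if strain_list is None:
        strain_list = sorted({strain_lookup(p) for members in clusters.values() for p in members})
    counts = pd.DataFrame(0, index=pd.Index(strain_list, name="Strain"), columns=cluster_ids, dtype=int)
    for cid in cluster_ids:
        for pid in clusters[cid]:
            s = strain_lookup(pid)
            if s not in counts.index:
                raise ValueError(f"protein {pid} maps to unknown strain {s}")
            counts.loc[s, cid] += 1
    return counts


@dataclass
class PanPartition:
    """Core/accessory/specific labels plus derived per-strain counts."""

    label: dict[str, str]
    per_strain_accessory: pd.Series
    per_strain_specific: pd.Series
    single_copy_core: set[str] = field(default_factory=set)

    @property
    def counts(self) -> dict[str, int]:
        out = {"core": 0, "accessory": 0, "specific": 0}
        for v in self.label.values():
            out[v] += 1
        return out

    def clusters_with(self, partition: str) -> list[str]:
        return [c for c, v in self.label.items() if v == partition]


def partition_clusters(matrix: pd.DataFrame) -> PanPartition:
    """Apply the core/accessory/specific rules to a presence matrix."""
    if matrix.empty:
        return PanPartition({}, pd.Series(dtype=int), pd.Series(dtype=int), set())
    if len(matrix.index) < 2:
        raise ValueError("partitioning requires at least 2 strains")
    present = matrix.to_numpy() >= 1
    n_strains = present.shape[0]
    n_present = present.sum(axis=0)
    labels: dict[str, str] = {}
    single_copy_core: set[str] = set()
    for j, cid in enumerate(matrix.columns):
        if n_present[j] == 0:
            raise ValueError(f"cluster {cid} is present in no strain")
        if n_present[j] == n_strains:
            labels[cid] = "core"
            if (matrix.iloc[:, j] == 1).all():
                single_copy_core.add(cid)
        elif n_present[j] == 1:
            labels[cid] = "specific"
        else:
            labels[cid] = "accessory"
    acc_cols = [c for c, v in labels.items() if v == "accessory"]
    spec_cols = [c for c, v in labels.items() if v == "specific"]
    per_acc = (matrix[acc_cols] >= 1).sum(axis=1) if acc_cols else pd.Series(0, index=matrix.index)
    per_spec = (matrix[spec_cols] >= 1).sum(axis=1) if spec_cols else pd.Series(0, index=matrix.index)
    return PanPartition(labels, per_acc, per_spec, single_copy_core)


def summarize_partition(counts: dict[str, int] | PanPartition) -> pd.DataFrame:
    """Cluster counts and percentages per partition stratum.

    Accepts either a :class:`PanPartition` or a plain ``{stratum: count}``
    mapping (e.g. counts read off a published figure), so the arithmetic
    can be replayed on reported numbers.  Percentages are of the total
    cluster count, rounded to two decimals.
    """
    if isinstance(counts, PanPartition):
        counts = counts.counts
    total = sum(counts.values())
    rows = []
    for stratum in ("core", "accessory", "specific"):
        if stratum in counts:
            n = counts[stratum]
            rows.append((stratum, n, round(100.0 * n / total, 2) if total else 0.0))
    df = pd.DataFrame(rows, columns=["partition", "n_clusters", "percent"]).set_index("partition")
    df.attrs["total"] = total
    return df


@dataclass
class AccumulationCurve:
    """Pan/core sizes for growing strain subsets, one row per permutation."""

    subset_sizes: np.ndarray
    pan_sizes: np.ndarray   # (n_permutations, N)
    core_sizes: np.ndarray  # (n_permutations, N)
    exhaustive: bool
    seed: int | None = None

    @property
    def n_permutations(self) -> int:
        return self.pan_sizes.shape[0]

    def median_new_clusters(self) -> pd.Series:
        """Median count of clusters first seen with the k-th strain, k >= 2."""
        new = np.diff(self.pan_sizes, axis=1)
        med = np.median(new, axis=0)
        return pd.Series(med, index=self.subset_sizes[1:], name="n_new")

    def summary(self) -> pd.DataFrame:
        q = lambda a, p: np.percentile(a, p, axis=0)
        return pd.DataFrame(
            {
                "k": self.subset_sizes,
                "pan_median": np.median(self.pan_sizes, axis=0),
                "pan_q1": q(self.pan_sizes, 25),
                "pan_q3": q(self.pan_sizes, 75),
                "core_median": np.median(self.core_sizes, axis=0),
                "core_q1": q(self.core_sizes, 25),
                "core_q3": q(self.core_sizes, 75),
            }
        )


def accumulation_curves(matrix: pd.DataFrame, n_permutations: int = 1000, seed: int | None = None,
                        exhaustive_limit: int = 7) -> AccumulationCurve:
    """Pan- and core-genome sizes over random strain orderings.

    For each ordering, ``pan(k)`` counts clusters present in at least one of
    the first k strains and ``core(k)`` clusters present in all of them.
    All N! orderings are enumerated when N <= ``exhaustive_limit``;
    otherwise ``n_permutations`` seeded random orderings are sampled.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    present = matrix.to_numpy() >= 1
    n = present.shape[0]
    if n <= exhaustive_limit:
        orders = np.array(list(permutations(range(n))))
        exhaustive = True
    else:
        rng = np.random.default_rng(seed)
        orders = np.array([rng.permutation(n) for _ in range(n_permutations)])
        exhaustive = False
    pan = np.empty((orders.shape[0], n), dtype=int)
    core = np.empty_like(pan)
    for r, order in enumerate(orders):
        rows = present[order]
        pan[r] = np.logical_or.accumulate(rows, axis=0).sum(axis=1)
        core[r] = np.logical_and.accumulate(rows, axis=0).sum(axis=1)
    return AccumulationCurve(np.arange(1, n + 1), pan, core, exhaustive, seed)


@dataclass
class HeapsFit:
    """Power-law fit of new-cluster discovery; alpha < 1 means open."""

    kappa: float
    alpha: float

    @property
    def gamma(self) -> float:
        return 1.0 - self.alpha

    @property
    def openness_verdict(self) -> str:
        return "open" if self.alpha < 1.0 else "closed"


def fit_heaps(curve: AccumulationCurve) -> HeapsFit:
    """Least-squares log–log fit of median new-cluster counts vs k (k >= 2).

    Zero medians are excluded from the fit; if every median is zero the
    pan-genome is saturated and the verdict is closed (gamma 0, kappa a
    tiny positive sentinel).
    """
    med = curve.median_new_clusters()
    if len(med) < 2:
        raise ValueError("need at least 3 subset sizes to fit")
    positive = med[med > 0]
    if positive.empty:
        return HeapsFit(kappa=1e-12, alpha=1.0)
    x = np.log(positive.index.to_numpy(dtype=float))
    y = np.log(positive.to_numpy(dtype=float))
    if len(positive) == 1 or np.allclose(x, x[0]):
        return HeapsFit(kappa=float(positive.iloc[0]), alpha=0.0)
    fit = stats.linregress(x, y)
    return HeapsFit(kappa=float(np.exp(fit.intercept)), alpha=float(-fit.slope))


def proteome_summary(proteomes) -> tuple[pd.DataFrame, int]:
    """Per-strain protein counts and the grand total.

    Accepts a list of :class:`StrainProteome` or a ``{strain: count}``
    mapping (e.g. counts from a published strain table).
    """
    if isinstance(proteomes, dict):
        items = list(proteomes.items())
    else:
        items = [(p.strain_id, len(p)) for p in proteomes]
    df = pd.DataFrame(items, columns=["strain", "n_proteins"]).set_index("strain")
    total = int(df["n_proteins"].sum())
    return df, total


# ---------------------------------------------------------------------------
# serialisation

def write_presence_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="Strain")


def read_presence_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_partition(partition: PanPartition, matrix: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tlabel\tn_strains\tn_genes\n")
        for cid in matrix.columns:
            col = matrix[cid]
            fh.write(f"{cid}\t{partition.label[cid]}\t{int((col >= 1).sum())}\t{int(col.sum())}\n")


def write_curves(curve: AccumulationCurve, path) -> None:
    with open(path, "w") as fh:
        fh.write("k\tpermutation\tpan\tcore\n")
        for r in range(curve.n_permutations):
            for j, k in enumerate(curve.subset_sizes):
                fh.write(f"{k}\t{r}\t{curve.pan_sizes[r, j]}\t{curve.core_sizes[r, j]}\n")


def write_summary_json(path, **quantities) -> None:
    with open(path, "w") as fh:
        json.dump(quantities, fh, indent=2, sort_keys=True)
        fh.write("\n")
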