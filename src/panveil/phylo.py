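"""Phylogenies: progressive alignment, distance trees, bootstrap, comparison.

Two trees summarise a strain panel here, mirroring the two-track design of
the study this package reproduces:

* a **single-copy-core tree** — one protein per strain per single-copy core
  family, aligned per family (progressive profile alignment with a UPGMA
  guide tree), divergent/gappy columns removed, families concatenated, and
  a distance tree built from Poisson-corrected p-distances.  Distance
  methods (NJ) stand in for full maximum-likelihood inference: the object
  of interest is topology recovery, for which NJ on corrected distances is
  consistent and orders of magnitude cheaper.
* a **pan-genome tree** — UPGMA on Manhattan distances between the strains'
  presence/absence profiles (binary by default).

Support values come from column (or cluster-column) bootstrap resampling.
Trees are `skbio.TreeNode` objects, Newick-serialisable; all tie-breaks are
lexicographic so every builder is deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from ._dp import nw_affine
from .scoring import AA_INDEX, blosum62_array_x, DEFAULT_GAP_OPEN, DEFAULT_GAP_EXTEND

GAP = "-"
GAP_INDEX = 21  # after the 20 amino acids and X
#: Distance assigned when sequences share no (or only mismatching) columns.
MAX_DISTANCE = 23.0


@dataclass
class MultipleAlignment:
    """Equal-length gapped rows with a record of column filtering."""

    labels: list[str]
    rows: list[str]
    column_mask: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise ValueError("labels and rows differ in count")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows must have equal length")
        if self.column_mask is None:
            self.column_mask = np.ones(self.length, dtype=bool)

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, label: str) -> str:
        return self.rows[self.labels.index(label)]

    def columns(self) -> list[str]:
        return ["".join(col) for col in zip(*self.rows)]


def _encode_gapped(row: str) -> np.ndarray:
    return np.fromiter(
        (GAP_INDEX if c == GAP else AA_INDEX[c] for c in row), dtype=np.int64, count=len(row)
    )


def _profile(rows: list[str]) -> np.ndarray:
    """(L, 22) column frequency profile over 20 aa + X + gap."""
    L = len(rows[0])
    prof = np.zeros((L, 22))
    for row in rows:
        idx = _encode_gapped(row)
        prof[np.arange(L), idx] += 1.0
    return prof / len(rows)


def _profile_score_matrix() -> np.ndarray:
    out = np.zeros((22, 22))
    out[:21, :21] = blosum62_array_x()
    return out


def _merge_profiles(rows_a: list[str], rows_b: list[str], gap_open: float, gap_extend: float
                    ) -> tuple[list[str], list[str]]:
    pa, pb = _profile(rows_a), _profile(rows_b)
    S = pa @ _profile_score_matrix() @ pb.T
    _, ai, aj = nw_affine(S, float(gap_open), float(gap_extend))
    out_a = ["".join(r[i] if i >= 0 else GAP for i in ai) for r in rows_a]
    out_b = ["".join(r[j] if j >= 0 else GAP for j in aj) for r in rows_b]
    return out_a, out_b


def _pairwise_identity_distance(seq_a: str, seq_b: str, gap_open: float, gap_extend: float) -> float:
    ia = np.fromiter((AA_INDEX[c] for c in seq_a), dtype=np.int64)
    ib = np.fromiter((AA_INDEX[c] for c in seq_b), dtype=np.int64)
    S = blosum62_array_x()[ia[:, None], ib[None, :]]
    _, ai, aj = nw_affine(S, float(gap_open), float(gap_extend))
    both = (ai >= 0) & (aj >= 0)
    if not both.any():
        return 1.0
    matches = int((ia[ai[both]] == ib[aj[both]]).sum())
    return 1.0 - matches / int(both.sum())


def align_family(sequences: Mapping[str, str] | Sequence[tuple[str, str]],
                 gap_open: float = DEFAULT_GAP_OPEN, gap_extend: float = DEFAULT_GAP_EXTEND
                 ) -> MultipleAlignment:
    """Progressive multiple alignment of one protein family.

    Pairwise NW identity distances feed a UPGMA guide tree; profiles are
    merged child-first with affine-gap NW.  Identical inputs come back
    gap-free, and two sequences reduce to their pairwise NW alignment.
    """
    items = list(sequences.items()) if isinstance(sequences, Mapping) else list(sequences)
    if len(items) < 2:
        raise ValueError("align_family requires at least 2 sequences")
    labels = [lbl for lbl, _ in items]
    seqs = {lbl: seq for lbl, seq in items}

    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _pairwise_identity_distance(
                seqs[labels[i]], seqs[labels[j]], gap_open, gap_extend
            )
    guide = upgma(DistanceMatrix(d, ids=labels))

    def build(node) -> tuple[list[str], list[str]]:
        if node.is_tip():
            return [node.name], [seqs[node.name]]
        (la, ra) = build(node.children[0])
        (lb, rb) = build(node.children[1])
        ra, rb = _merge_profiles(ra, rb, gap_open, gap_extend)
        return la + lb, ra + rb

    out_labels, out_rows = build(guide)
    order = [out_labels.index(lbl) for lbl in labels]
    return MultipleAlignment(labels, [out_rows[i] for i in order])


def filter_columns(alignment: MultipleAlignment, max_gap_fraction: float = 0.2,
                   min_identity_fraction: float = 0.5) -> MultipleAlignment:
    """Drop gappy or divergent columns (Gblocks-style two-threshold rule).

    A column is dropped when its gap fraction exceeds ``max_gap_fraction``
    or its modal (non-gap) residue frequency, over all rows, falls below
    ``min_identity_fraction``.  The returned ``column_mask`` records the
    decision per input column.
    """
    n_rows = len(alignment.rows)
    mask = np.zeros(alignment.length, dtype=bool)
    for j, col in enumerate(alignment.columns()):
        gaps = col.count(GAP)
        if gaps / n_rows > max_gap_fraction:
            continue
        residues = [c for c in col if c != GAP]
        modal = max(residues.count(c) for c in set(residues)) if residues else 0
        if modal / n_rows < min_identity_fraction:
            continue
        mask[j] = True
    rows = ["".join(r[j] for j in range(alignment.length) if mask[j]) for r in alignment.rows]
    return MultipleAlignment(list(alignment.labels), rows, column_mask=mask)


def concatenate(alignments: Sequence[MultipleAlignment], strain_order: Sequence[str]) -> MultipleAlignment:
    """Row-wise concatenation of per-family alignments in fixed family order."""
    strain_order = list(strain_order)
    parts = {s: [] for s in strain_order}
    for k, aln in enumerate(alignments):
        if sorted(aln.labels) != sorted(strain_order):
            raise ValueError(f"family {k} does not have exactly one row per strain")
        for s in strain_order:
            parts[s].append(aln.row(s))
    rows = ["".join(parts[s]) for s in strain_order]
    return MultipleAlignment(strain_order, rows)


def protein_distance(alignment: MultipleAlignment, correction: str = "p") -> DistanceMatrix:
    """Pairwise p-distance over mutually ungapped columns.

    ``correction='poisson'`` applies -ln(1-p); saturated pairs (p -> 1)
    are capped at :data:`MAX_DISTANCE`.
    """
    if correction not in ("p", "poisson"):
        raise ValueError("correction must be 'p' or 'poisson'")
    if len(alignment.rows) < 2:
        raise ValueError("need at least 2 rows")
    enc = [_encode_gapped(r) for r in alignment.rows]
    n = len(enc)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = (enc[i] != GAP_INDEX) & (enc[j] != GAP_INDEX)
            total = int(both.sum())
            if total == 0:
                dist = MAX_DISTANCE
            else:
                p = float((enc[i][both] != enc[j][both]).sum()) / total
                if correction == "p":
                    dist = p
                else:
                    dist = min(-np.log(max(1.0 - p, 1e-10)), MAX_DISTANCE)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(d, ids=list(alignment.labels))


# ---------------------------------------------------------------------------
# tree builders

def _cluster_key(node: TreeNode) -> str:
    """Lexicographically smallest leaf label; the deterministic tie-break key."""
    return min(t.name for t in node.tips()) if not node.is_tip() else node.name


def upgma(dist: DistanceMatrix) -> TreeNode:
    """Average-linkage agglomeration; merge height = half the inter-cluster
    average distance, so the output is ultrametric by construction."""
    labels = list(dist.ids)
    if len(labels) < 2:
        raise ValueError("need at least 2 taxa")
    nodes: dict[str, TreeNode] = {lbl: TreeNode(name=lbl) for lbl in labels}
    heights: dict[str, float] = {lbl: 0.0 for lbl in labels}
    sizes: dict[str, int] = {lbl: 1 for lbl in labels}
    d: dict[frozenset, float] = {
        frozenset((a, b)): dist[a, b] for i, a in enumerate(labels) for b in labels[i + 1 :]
    }
    active = sorted(labels)
    while len(active) > 1:
        best = min(
            (d[frozenset((a, b))], a, b)
            for i, a in enumerate(active)
            for b in active[i + 1 :]
        )
        dd, a, b = best
        height = dd / 2.0
        na, nb = nodes.pop(a), nodes.pop(b)
        na.length = height - heights[a]
        nb.length = height - heights[b]
        parent = TreeNode(children=[na, nb])
        key = min(a, b)
        new_size = sizes[a] + sizes[b]
        for c in active:
            if c in (a, b):
                continue
            dc = (sizes[a] * d[frozenset((a, c))] + sizes[b] * d[frozenset((b, c))]) / new_size
            d[frozenset((key, c))] = dc
        active = sorted([c for c in active if c not in (a, b)] + [key])
        nodes[key] = parent
        heights[key] = height
        sizes[key] = new_size
    root = nodes[active[0]]
    root.length = None
    return root


def neighbor_joining(dist: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining; exact on additive matrices.

    Negative branch lengths are clamped to zero with a warning.  The
    unrooted result is returned as a trifurcating root.
    """
    labels = list(dist.ids)
    if len(labels) < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    nodes: dict[str, TreeNode] = {lbl: TreeNode(name=lbl) for lbl in labels}
    d: dict[frozenset, float] = {
        frozenset((a, b)): dist[a, b] for i, a in enumerate(labels) for b in labels[i + 1 :]
    }
    active = sorted(labels)
    clamped = False

    def get(a, b):
        return d[frozenset((a, b))]

    counter = 0
    while len(active) > 3:
        n = len(active)
        r = {a: sum(get(a, b) for b in active if b != a) for a in active}
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1 :]:
                q = (n - 2) * get(a, b) - r[a] - r[b]
                key = (q, min(a, b), max(a, b))
                if best is None or key < best:
                    best = key
        _, a, b = best
        dab = get(a, b)
        la = dab / 2.0 + (r[a] - r[b]) / (2.0 * (n - 2))
        lb = dab - la
        if la < 0 or lb < 0:
            clamped = True
        la, lb = max(la, 0.0), max(lb, 0.0)
        na, nb = nodes.pop(a), nodes.pop(b)
        na.length = la
        nb.length = lb
        counter += 1
        new_key = min(a, b)
        parent = TreeNode(children=[na, nb])
        for c in active:
            if c in (a, b):
                continue
            d[frozenset((new_key, c))] = (get(a, c) + get(b, c) - dab) / 2.0
        active = sorted([c for c in active if c not in (a, b)] + [new_key])
        nodes[new_key] = parent

    a, b, c = active
    la = (get(a, b) + get(a, c) - get(b, c)) / 2.0
    lb = (get(a, b) + get(b, c) - get(a, c)) / 2.0
    lc = (get(a, c) + get(b, c) - get(a, b)) / 2.0
    if min(la, lb, lc) < 0:
        clamped = True
    for key, ln in ((a, la), (b, lb), (c, lc)):
        nodes[key].length = max(ln, 0.0)
    if clamped:
        warnings.warn("negative NJ branch length(s) clamped to 0")
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return root


def manhattan_tree(matrix: pd.DataFrame, binarize: bool = True) -> TreeNode:
    """UPGMA on Manhattan distances between strain presence profiles.

    With ``binarize`` (default) the copy-number matrix is reduced to 0/1
    presence, so the distance equals the count of differing clusters.
    """
    data = (matrix.to_numpy() >= 1).astype(float) if binarize else matrix.to_numpy(dtype=float)
    n = data.shape[0]
    d = np.abs(data[:, None, :] - data[None, :, :]).sum(axis=2)
    np.fill_diagonal(d, 0.0)
    return upgma(DistanceMatrix(d, ids=list(matrix.index)))


# ---------------------------------------------------------------------------
# comparison & support

def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial splits, each canonicalised to the side away from the
    lexicographically smallest leaf (rooting-invariant)."""
    leaves = frozenset(t.name for t in tree.tips())
    ref = min(leaves)
    out: set[frozenset] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = leaves - side
        if 2 <= len(side) <= len(leaves) - 2:
            out.add(side)
    return out


def rf_distance(tree_a: TreeNode, tree_b: TreeNode) -> int:
    """Robinson–Foulds distance: splits present in exactly one tree."""
    la = {t.name for t in tree_a.tips()}
    lb = {t.name for t in tree_b.tips()}
    if la != lb:
        raise ValueError("trees must share an identical leaf set")
    return len(bipartitions(tree_a) ^ bipartitions(tree_b))


def bootstrap_support(data, tree_builder: Callable, n_replicates: int = 100,
                      seed: int | None = None) -> TreeNode:
    """Column-bootstrap support on the point-estimate tree.

    ``data`` is a :class:`MultipleAlignment` (residue columns resampled) or
    a presence/absence DataFrame (cluster columns resampled).  Internal
    nodes of the returned tree carry integer percent support as ``name``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)

    if isinstance(data, MultipleAlignment):
        n_cols = data.length

        def resample(idx):
            rows = ["".join(r[j] for j in idx) for r in data.rows]
            return MultipleAlignment(list(data.labels), rows)
    elif isinstance(data, pd.DataFrame):
        n_cols = data.shape[1]

        def resample(idx):
            return data.iloc[:, idx]
    else:
        raise TypeError("data must be a MultipleAlignment or DataFrame")

    point = tree_builder(data)
    split_counts: dict[frozenset, int] = {}
    for _ in range(n_replicates):
        idx = rng.integers(0, n_cols, size=n_cols)
        rep = tree_builder(resample(idx))
        for split in bipartitions(rep):
            split_counts[split] = split_counts.get(split, 0) + 1

    leaves = frozenset(t.name for t in point.tips())
    ref = min(leaves)
    for node in point.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = leaves - side
        if 2 <= len(side) <= len(leaves) - 2:
            support = round(100.0 * split_counts.get(side, 0) / n_replicates)
            node.name = str(int(support))
    return point


# ---------------------------------------------------------------------------
# pipeline convenience

def core_genome_tree(family_seqs: Sequence[Mapping[str, str]], strain_order: Sequence[str],
                     correction: str = "poisson", max_gap_fraction: float = 0.2,
                     min_identity_fraction: float = 0.5, method: str = "nj"
                     ) -> tuple[TreeNode, MultipleAlignment]:
    """Single-copy-core tree: align each family, filter, concatenate, build.

    ``family_seqs`` holds one {strain: sequence} mapping per single-copy
    core family.  Returns the tree and the concatenated filtered alignment.
    """
    if not family_seqs:
        raise ValueError("no single-copy core families supplied")
    alignments = []
    for fam in family_seqs:
        aln = align_family({s: fam[s] for s in strain_order})
        alignments.append(filter_columns(aln, max_gap_fraction, min_identity_fraction))
    concat = concatenate(alignments, strain_order)
    dist = protein_distance(concat, correction=correction)
    tree = neighbor_joining(dist) if method == "nj" else upgma(dist)
    return tree, concat
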