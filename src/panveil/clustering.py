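"""OrthoMCL-style ortholog graph construction and Markov Clustering.

From the thresholded hit table, protein pairs are weighted by the average
of ``-log10(E)`` over both directions (pairs hit in only one direction are
dropped) and classified as

* **ortholog** — inter-strain reciprocal best hits (ties within a small
  epsilon of the best weight all count as best),
* **in-paralog** — intra-strain pairs whose weight reaches both members'
  best inter-strain weight (genes without inter-strain hits always
  qualify, which is what lets recently duplicated strain-specific genes
  cluster),
* **co-ortholog** — inter-strain pairs with a direct hit that are connected
  through an ortholog edge between their in-paralog groups.

Weights are rescaled per class (per strain pair for orthologs) by the class
mean, then the symmetric graph is clustered with Markov Clustering (MCL):
expansion (matrix squaring), inflation (entrywise power + column
renormalisation) and pruning, iterated to convergence.  Inflation defaults
to 1.5, the granularity used for the nine-strain panel this package
reproduces.  Clusters are the connected components of the converged
attractor structure; single-member components are reported as singletons
and excluded from the pan-genome cluster count.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .records import strain_of
from .similarity import SimilarityHit

DEFAULT_INFLATION = 1.5
BEST_HIT_EPSILON = 1e-3  # float-safe reciprocal-best tie tolerance


@dataclass
class ClusterSet:
    """Disjoint clusters (>= 2 members each) plus unclustered singletons."""

    clusters: dict[str, list[str]] = field(default_factory=dict)
    singletons: list[str] = field(default_factory=list)
    converged: bool = True

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def all_proteins(self) -> set[str]:
        out = set(self.singletons)
        for members in self.clusters.values():
            out.update(members)
        return out

    def validate(self) -> None:
        seen: set[str] = set()
        for cid, members in self.clusters.items():
            if len(members) < 2:
                raise ValueError(f"cluster {cid} has fewer than 2 members")
            if seen & set(members):
                raise ValueError("clusters are not disjoint")
            seen.update(members)
        if seen & set(self.singletons):
            raise ValueError("singletons overlap clusters")


def _pair_weights(hits: list[SimilarityHit]) -> dict[tuple[str, str], float]:
    """Average -log10(E) over both directions; one-directional pairs dropped."""
    directed: dict[tuple[str, str], float] = {}
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        w = -math.log10(h.e_value)
        key = (h.query_id, h.subject_id)
        directed[key] = max(w, directed.get(key, -math.inf))
    weights: dict[tuple[str, str], float] = {}
    for (q, s), w in directed.items():
        if q < s and (s, q) in directed:
            weights[(q, s)] = (w + directed[(s, q)]) / 2.0
    return weights


def classify_edges(hits: list[SimilarityHit], strain_lookup=strain_of) -> nx.Graph:
    """Build the weighted ortholog graph from thresholded hits.

    Returns an undirected :class:`networkx.Graph`; nodes carry a ``strain``
    attribute, edges carry ``weight`` (normalised), ``raw_weight`` and
    ``eclass`` in {ortholog, inparalog, coortholog}.
    """
    graph = nx.Graph()
    weights = _pair_weights(hits)
    proteins = {p for h in hits for p in (h.query_id, h.subject_id)}
    for p in sorted(proteins):
        graph.add_node(p, strain=strain_lookup(p))

    # Best inter-strain weight per protein, overall and per partner strain.
    best_to_strain: dict[tuple[str, str], float] = {}
    best_inter: dict[str, float] = {}
    for (a, b), w in weights.items():
        sa, sb = strain_lookup(a), strain_lookup(b)
        if sa == sb:
            continue
        for prot, other in ((a, sb), (b, sa)):
            key = (prot, other)
            if w > best_to_strain.get(key, -math.inf):
                best_to_strain[key] = w
            if w > best_inter.get(prot, -math.inf):
                best_inter[prot] = w

    ortholog_edges: list[tuple[str, str, float]] = []
    inparalog_edges: list[tuple[str, str, float]] = []
    for (a, b), w in sorted(weights.items()):
        sa, sb = strain_lookup(a), strain_lookup(b)
        if sa != sb:
            if (w >= best_to_strain[(a, sb)] - BEST_HIT_EPSILON
                    and w >= best_to_strain[(b, sa)] - BEST_HIT_EPSILON):
                ortholog_edges.append((a, b, w))
        else:
            if (w >= best_inter.get(a, 0.0) - BEST_HIT_EPSILON
                    and w >= best_inter.get(b, 0.0) - BEST_HIT_EPSILON):
                inparalog_edges.append((a, b, w))

    # In-paralog groups (connected components over in-paralog edges).
    inpara = nx.Graph()
    inpara.add_nodes_from(proteins)
    inpara.add_edges_from((a, b) for a, b, _ in inparalog_edges)
    group_of = {}
    for comp in nx.connected_components(inpara):
        members = frozenset(comp)
        for p in members:
            group_of[p] = members

    ortho_set = {frozenset((a, b)) for a, b, _ in ortholog_edges}
    coortholog_edges: list[tuple[str, str, float]] = []
    seen_co: set[frozenset] = set()
    for a, b, _ in ortholog_edges:
        for x in group_of[a]:
            for y in group_of[b]:
                key = frozenset((x, y))
                if key in ortho_set or key in seen_co or x == y:
                    continue
                pair = (x, y) if x < y else (y, x)
                if pair in weights and strain_lookup(x) != strain_lookup(y):
                    seen_co.add(key)
                    coortholog_edges.append((pair[0], pair[1], weights[pair]))

    # Class-wise weight normalisation.
    def add_normalised(edges, eclass, key_func):
        sums: dict = {}
        counts: dict = {}
        for a, b, w in edges:
            k = key_func(a, b)
            sums[k] = sums.get(k, 0.0) + w
            counts[k] = counts.get(k, 0) + 1
        for a, b, w in edges:
            mean = sums[key_func(a, b)] / counts[key_func(a, b)]
            graph.add_edge(a, b, weight=w / mean if mean > 0 else 1.0, raw_weight=w, eclass=eclass)

    by_strain_pair = lambda a, b: frozenset((strain_lookup(a), strain_lookup(b)))
    add_normalised(ortholog_edges, "ortholog", by_strain_pair)
    add_normalised(inparalog_edges, "inparalog", lambda a, b: "inparalog")
    add_normalised(coortholog_edges, "coortholog", lambda a, b: "coortholog")
    return graph


def _inflate(m: np.ndarray, inflation: float, prune_threshold: float) -> np.ndarray:
    """Entrywise power, pruning, and column renormalisation.

    Always returns a column-stochastic matrix; a column emptied by pruning
    is revived as its own attractor (diagonal 1).
    """
    out = m ** inflation
    out[out < prune_threshold] = 0.0
    sums = out.sum(axis=0, keepdims=True)
    dead = np.where(sums[0] == 0)[0]
    if dead.size:
        out[dead, dead] = 1.0
        sums = out.sum(axis=0, keepdims=True)
    return out / sums


def _mcl_component(nodes: list[str], graph: nx.Graph, inflation: float, prune_threshold: float,
                   max_iter: int, tol: float) -> tuple[list[list[str]], bool]:
    """Run MCL on one connected component (dense; components are small)."""
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    m = np.zeros((n, n))
    for a, b, data in graph.edges(nodes, data=True):
        if a in idx and b in idx:
            m[idx[a], idx[b]] = m[idx[b], idx[a]] = data["weight"]
    # Self-loop = max incident edge weight (1.0 for isolated nodes).
    for i in range(n):
        incident = m[i].max()
        m[i, i] = incident if incident > 0 else 1.0
    m /= m.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(max_iter):
        inflated = _inflate(m @ m, inflation, prune_threshold)
        if np.abs(inflated - m).max() < tol:
            m = inflated
            converged = True
            break
        m = inflated

    support = nx.Graph()
    support.add_nodes_from(range(n))
    rows, cols = np.nonzero(m)
    support.add_edges_from(zip(rows.tolist(), cols.tolist()))
    comps = [sorted(nodes[i] for i in comp) for comp in nx.connected_components(support)]
    return comps, converged


def mcl(graph: nx.Graph, inflation: float = DEFAULT_INFLATION, prune_threshold: float = 1e-5,
        max_iter: int = 100, tol: float = 1e-6) -> ClusterSet:
    """Markov Clustering of the ortholog graph.

    Operates per connected component (MCL cannot merge disconnected
    subgraphs, and dense per-component iteration is fast at panel scale).
    Non-convergence at ``max_iter`` returns the current clustering with
    ``converged=False`` and a warning.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    all_groups: list[list[str]] = []
    all_converged = True
    for component in nx.connected_components(graph):
        nodes = sorted(component)
        groups, converged = _mcl_component(nodes, graph, inflation, prune_threshold, max_iter, tol)
        all_groups.extend(groups)
        all_converged = all_converged and converged
    if not all_converged:
        warnings.warn("MCL did not converge within max_iter; returning current clustering")

    all_groups.sort(key=lambda g: g[0])
    clusters: dict[str, list[str]] = {}
    singletons: list[str] = []
    n = 0
    for group in all_groups:
        if len(group) == 1:
            singletons.append(group[0])
        else:
            n += 1
            clusters[f"cluster{n}"] = group
    result = ClusterSet(clusters=clusters, singletons=sorted(singletons), converged=all_converged)
    result.validate()
    return result


# ---------------------------------------------------------------------------
# groups-file IO (OrthoMCL dialect: ``clusterN: strain|prot strain|prot ...``)

def write_groups(cluster_set: ClusterSet, path) -> None:
    with open(path, "w") as fh:
        for cid in sorted(cluster_set.clusters, key=lambda c: int(c.replace("cluster", ""))):
            fh.write(f"{cid}: " + " ".join(cluster_set.clusters[cid]) + "\n")


def write_singletons(cluster_set: ClusterSet, path) -> None:
    with open(path, "w") as fh:
        for p in cluster_set.singletons:
            fh.write(p + "\n")


def read_groups(path, singletons_path=None) -> ClusterSet:
    clusters: dict[str, list[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            if ":" not in line:
                raise ValueError(f"{path}:{ln}: malformed groups line (missing ':')")
            cid, _, rest = line.partition(":")
            members = rest.split()
            if not cid.strip() or len(members) < 2:
                raise ValueError(f"{path}:{ln}: cluster needs an id and >= 2 members")
            clusters[cid.strip()] = members
    singletons: list[str] = []
    if singletons_path is not None:
        with open(singletons_path) as fh:
            singletons = [line.strip() for line in fh if line.strip()]
    cs = ClusterSet(clusters=clusters, singletons=singletons)
    cs.validate()
    return cs
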