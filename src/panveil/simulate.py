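"""Synthetic strain sets with known ortholog, partition, tree and CRISPR truth.

The generator emulates the structure of a small bacterial strain panel
(by default nine strains, as in the *Veillonella atypica* study design this
package reproduces): gene families are drawn as core (present in every
strain), accessory (present in 2..N-1 strains) or strain-specific
(one strain, multi-copy by default), an ancestral protein per family is
evolved along a random ultrametric strain tree by i.i.d. substitutions
(no indels), and nucleotide genomes carry planted CRISPR repeat–spacer
arrays with optionally truncated terminal repeats.

Every downstream stage — similarity search, Markov clustering, pan-genome
partitioning, tree building, annotation lifting, array detection — can be
scored against the returned :class:`TruthTable`.

All randomness flows from a single integer seed through one
``numpy.random.Generator``; there is no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skbio import TreeNode

from .crispr import CrisprArray
from .records import AA20, ProteinRecord, StrainProteome
from .scoring import BACKGROUND_FREQS

DNA = "ACGT"

#: A compact CAZy-style vocabulary (families seen in oral/gut anaerobes),
#: COG category letters and opaque GO-style terms for label simulation.
DEFAULT_NAMESPACES: dict[str, list[str]] = {
    "CAZy": [
        "GT2", "GT4", "GT9", "GT19", "GT30", "GT45", "GT51", "GT83",
        "GH13", "GH23", "GH73", "GH25", "CE4", "CE9", "CE11",
        "CBM50", "AA3", "PL1", "SLH",
    ],
    "COG": list("CDEFGHIJKLMNOPTUV"),
    "GO": [
        "GO:0008150|biological_process",
        "GO:0009058|biosynthetic_process",
        "GO:0003674|molecular_function",
        "GO:0003824|catalytic_activity",
        "GO:0005575|cellular_component",
        "GO:0016020|membrane",
    ],
}


class PlacementError(RuntimeError):
    """Planted arrays could not be placed without overlap."""


@dataclass(frozen=True)
class ArraySpec:
    """Blueprint for one planted CRISPR array."""

    n_units: int = 4
    repeat_length: int = 30
    spacer_length: int = 35
    truncate_last: bool = False

    def __post_init__(self) -> None:
        if self.n_units < 2:
            raise ValueError("an array needs at least 2 repeat units")
        if not 23 <= self.repeat_length <= 55:
            raise ValueError("repeat_length must be within [23, 55] bp")
        if self.spacer_length < 1:
            raise ValueError("spacer_length must be positive")

    @property
    def footprint(self) -> int:
        """Total bp occupied by the array on the genome."""
        full = self.n_units * self.repeat_length + (self.n_units - 1) * self.spacer_length
        if self.truncate_last:
            full -= self.repeat_length // 2  # last unit kept at ceil(R/2)
        return full


def _default_array_specs() -> list[ArraySpec]:
    # 2-12 arrays per genome with 23-55 bp repeats is the real-data scale;
    # four heterogeneous arrays (one truncated) keep default runs light.
    return [
        ArraySpec(4, 30, 35, False),
        ArraySpec(5, 28, 40, True),
        ArraySpec(3, 36, 30, False),
        ArraySpec(6, 25, 42, False),
    ]


@dataclass
class SimulationConfig:
    """Parameters of one synthetic strain-set.

    ``divergence`` is the expected substitutions per site per unit branch
    length on the (height-1.0) strain tree; 0.05 yields ~90% identity
    between the most distant strains, comparable to within-species protein
    divergence.  Family counts default to a scaled-down panel (150 core /
    60 accessory / 5 specific) that preserves the real panel's ~73% core
    fraction at desk-scale runtime.
    """

    n_strains: int = 9
    n_core: int = 150
    n_accessory: int = 60
    n_specific: int = 5
    mean_protein_length: int = 300
    divergence: float = 0.05
    paralog_rate: float = 0.02
    specific_copies: int = 2
    paralog_divergence_scale: float = 0.1
    genome_length: int = 100_000
    gc_content: float = 0.39
    array_specs: list[ArraySpec] = field(default_factory=_default_array_specs)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strains < 2:
            raise ValueError("n_strains must be >= 2")
        if not 0.0 <= self.divergence <= 0.5:
            raise ValueError("divergence must be within [0, 0.5]")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be within (0, 1)")
        if min(self.n_core, self.n_accessory, self.n_specific) < 0:
            raise ValueError("family counts must be non-negative")
        if self.specific_copies < 1:
            raise ValueError("specific_copies must be >= 1")
        self.array_specs = [a if isinstance(a, ArraySpec) else ArraySpec(**a) for a in self.array_specs]

    @property
    def strain_ids(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_strains)]


@dataclass
class TruthTable:
    """Ground truth of one simulated strain-set."""

    cluster_assignment: dict[str, str]
    partition_label: dict[str, str]
    strain_tree: TreeNode | None = None
    planted_arrays: dict[str, list[CrisprArray]] = field(default_factory=dict)

    def members(self) -> dict[str, list[str]]:
        """Invert ``cluster_assignment``: true cluster id -> protein ids."""
        out: dict[str, list[str]] = {}
        for pid, cid in self.cluster_assignment.items():
            out.setdefault(cid, []).append(pid)
        return out


def simulate_strain_tree(n_strains: int, seed: int | None = None, rng: np.random.Generator | None = None,
                         labels: list[str] | None = None) -> TreeNode:
    """Random binary rooted ultrametric tree with root-to-tip height 1.0.

    Topology by uniform random joins; join heights are sorted uniforms
    rescaled so the root sits at exactly 1.0.
    """
    if n_strains < 2:
        raise ValueError("n_strains must be >= 2")
    if rng is None:
        rng = np.random.default_rng(seed)
    if labels is None:
        labels = [f"S{i + 1:02d}" for i in range(n_strains)]
    times = np.sort(rng.uniform(size=n_strains - 1))
    times = times / times[-1]
    nodes: list[tuple[TreeNode, float]] = [(TreeNode(name=lbl), 0.0) for lbl in labels]
    for t in times:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        (a, ha), (b, hb) = nodes[i], nodes[j]
        a.length = t - ha
        b.length = t - hb
        parent = TreeNode(children=[a, b])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append((parent, float(t)))
    root = nodes[0][0]
    root.length = None
    return root


def _mutate(seq: np.ndarray, p_sub: float, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. substitution: each site replaced w.p. p_sub by a background draw.

    The replacement may equal the original residue, which naturally models
    coincident/back substitution; there are no indels.
    """
    if p_sub <= 0:
        return seq.copy()
    out = seq.copy()
    mask = rng.random(seq.size) < p_sub
    n = int(mask.sum())
    if n:
        out[mask] = rng.choice(20, size=n, p=BACKGROUND_FREQS)
    return out


def _indices_to_protein(seq: np.ndarray) -> str:
    return "".join(AA20[i] for i in seq)


def simulate_pangenome(config: SimulationConfig, rng: np.random.Generator | None = None
                       ) -> tuple[list[StrainProteome], TruthTable]:
    """Simulate strain proteomes with a known family/partition structure.

    Core families get one member per strain, accessory families a uniform
    2..N-1 strain subset, specific families ``specific_copies`` members in
    a single strain; each present strain may gain one extra in-paralog copy
    with probability ``paralog_rate`` (core/accessory only).  Sequences
    evolve independently per family along the shared strain tree.
    """
    n_families = config.n_core + config.n_accessory + config.n_specific
    if n_families == 0:
        raise ValueError("at least one family is required")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    strains = config.strain_ids
    tree = simulate_strain_tree(config.n_strains, rng=rng, labels=strains)

    # Per-leaf path of (parent->child) branches, for sequence evolution.
    partitions = ["core"] * config.n_core + ["accessory"] * config.n_accessory + ["specific"] * config.n_specific
    proteins: dict[str, list[ProteinRecord]] = {s: [] for s in strains}
    assignment: dict[str, str] = {}
    labels: dict[str, str] = {}
    counters = {s: 0 for s in strains}

    for fam_idx, part in enumerate(partitions):
        cid = f"fam{fam_idx + 1:04d}"
        labels[cid] = part
        if part == "core":
            present = {s: 1 for s in strains}
        elif part == "accessory":
            k = int(rng.integers(2, config.n_strains))  # 2 .. N-1
            chosen = rng.choice(config.n_strains, size=k, replace=False)
            present = {strains[i]: 1 for i in sorted(chosen)}
        else:
            s = strains[int(rng.integers(config.n_strains))]
            present = {s: config.specific_copies}
        if part in ("core", "accessory") and config.paralog_rate > 0:
            for s in list(present):
                if rng.random() < config.paralog_rate:
                    present[s] += 1

        length = max(30, int(rng.poisson(config.mean_protein_length)))
        ancestral = rng.choice(20, size=length, p=BACKGROUND_FREQS)
        leaf_seqs: dict[str, np.ndarray] = {}
        stack = [(tree, ancestral)]
        while stack:
            node, seq = stack.pop()
            if node.is_tip():
                leaf_seqs[node.name] = seq
                continue
            for child in node.children:
                child_seq = _mutate(seq, config.divergence * (child.length or 0.0), rng)
                stack.append((child, child_seq))

        for s in strains:
            copies = present.get(s, 0)
            if not copies:
                continue
            base = leaf_seqs[s]
            for c in range(copies):
                seq = base if c == 0 else _mutate(base, config.divergence * config.paralog_divergence_scale, rng)
                counters[s] += 1
                pid = f"{s}|g{counters[s]:04d}"
                proteins[s].append(ProteinRecord(pid, s, _indices_to_protein(seq)))
                assignment[pid] = cid

    proteomes = [StrainProteome(s, proteins[s]) for s in strains]
    truth = TruthTable(cluster_assignment=assignment, partition_label=labels, strain_tree=tree)
    return proteomes, truth


def _random_dna(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p)


def simulate_genome_with_arrays(config: SimulationConfig, rng: np.random.Generator | None = None,
                                genome_id: str = "genome", max_tries: int = 1000
                                ) -> tuple[str, list[CrisprArray]]:
    """i.i.d. background genome with planted CRISPR arrays.

    Arrays are placed non-overlapping, at least 100 bp from either sequence
    end and at least 100 bp apart; truth coordinates are 0-based half-open.
    A truncated terminal repeat keeps its first ceil(R/2) bases.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    specs = config.array_specs
    footprints = [a.footprint for a in specs]
    if config.genome_length <= sum(footprints) + 200 * max(1, len(specs)):
        raise ValueError("genome_length too small for the requested arrays")
    genome = _random_dna(config.genome_length, config.gc_content, rng)

    margin = 100
    placed: list[tuple[int, int]] = []
    arrays: list[CrisprArray] = []
    for spec, fp in zip(specs, footprints):
        for _ in range(max_tries):
            start = int(rng.integers(margin, config.genome_length - margin - fp))
            span = (start - margin, start + fp + margin)
            if all(span[1] <= s or span[0] >= e for s, e in placed):
                placed.append((start, start + fp))
                break
        else:
            raise PlacementError("could not place arrays without overlap")

        repeat = _random_dna(spec.repeat_length, config.gc_content, rng)
        instances: list[tuple[int, int, bool]] = []
        spacers: list[tuple[int, int]] = []
        pos = start
        for u in range(spec.n_units):
            last = u == spec.n_units - 1
            if last and spec.truncate_last:
                unit = repeat[: spec.repeat_length - spec.repeat_length // 2]
                truncated = True
            else:
                unit = repeat
                truncated = False
            genome[pos : pos + unit.size] = unit
            instances.append((pos, pos + unit.size, truncated))
            pos += unit.size
            if not last:
                spacer = _random_dna(spec.spacer_length, config.gc_content, rng)
                genome[pos : pos + spacer.size] = spacer
                spacers.append((pos, pos + spacer.size))
                pos += spacer.size
        arrays.append(
            CrisprArray(
                genome_id=genome_id,
                start=start,
                end=pos,
                repeat_consensus="".join(DNA[i] for i in repeat),
                repeat_instances=instances,
                spacers=spacers,
            )
        )

    seq = "".join(DNA[i] for i in genome)
    for arr in arrays:
        arr.left_flank = seq[max(0, arr.start - 100) : arr.start]
        arr.right_flank = seq[arr.end : arr.end + 100]
        arr.validate(seq)
    return seq, sorted(arrays, key=lambda a: a.start)


def simulate_annotation_labels(truth: TruthTable, namespaces: dict[str, list[str]] | None = None,
                               label_rate: float = 0.3, seed: int | None = None,
                               rng: np.random.Generator | None = None):
    """Per-protein annotation table with cluster-consistent labels.

    Each true cluster receives, per namespace, a label with probability
    ``label_rate``; the label propagates to every member protein, so
    cluster-level annotation recovery is exact by construction.  Returns a
    DataFrame with columns (protein_id, namespace, label).
    """
    import pandas as pd

    if namespaces is None:
        namespaces = DEFAULT_NAMESPACES
    if not namespaces:
        raise ValueError("namespaces must be non-empty")
    if not 0.0 <= label_rate <= 1.0:
        raise ValueError("label_rate must be within [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    members = truth.members()
    rows = []
    for cid in sorted(members):
        for ns in sorted(namespaces):
            if rng.random() < label_rate:
                vocab = namespaces[ns]
                label = vocab[int(rng.integers(len(vocab)))]
                for pid in members[cid]:
                    rows.append((pid, ns, label))
    return pd.DataFrame(rows, columns=["protein_id", "namespace", "label"])


# ---------------------------------------------------------------------------
# serialisation

def write_proteomes(proteomes: list[StrainProteome], outdir) -> list[Path]:
    """One ``<strain>.faa`` per strain."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for prot in proteomes:
        path = outdir / f"{prot.strain_id}.faa"
        with open(path, "w") as fh:
            for rec in prot:
                fh.write(f">{rec.protein_id}\n{rec.sequence}\n")
        paths.append(path)
    return paths


def read_proteomes(paths) -> list[StrainProteome]:
    """Read ``<strain>.faa`` files written by :func:`write_proteomes`."""
    from Bio import SeqIO

    from .records import strain_of

    proteomes = []
    for path in paths:
        path = Path(path)
        records = []
        for rec in SeqIO.parse(str(path), "fasta"):
            sid = strain_of(rec.id) if "|" in rec.id else path.stem
            records.append(ProteinRecord(rec.id, sid, str(rec.seq)))
        proteomes.append(StrainProteome(path.stem, records))
    return proteomes


def write_genome_fasta(genome_id: str, sequence: str, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome_id}\n")
        for i in range(0, len(sequence), width):
            fh.write(sequence[i : i + width] + "\n")


def write_truth_tables(truth: TruthTable, outdir) -> None:
    """``truth_clusters.tsv``, ``truth_arrays.tsv`` and the strain tree."""
    from .records import strain_of

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "truth_clusters.tsv", "w") as fh:
        fh.write("protein_id\tstrain\tcluster_id\tpartition\n")
        for pid in sorted(truth.cluster_assignment):
            cid = truth.cluster_assignment[pid]
            fh.write(f"{pid}\t{strain_of(pid)}\t{cid}\t{truth.partition_label[cid]}\n")
    with open(outdir / "truth_arrays.tsv", "w") as fh:
        fh.write("genome\tstart\tend\trepeat_len\tn_units\ttruncated\n")
        for gid in sorted(truth.planted_arrays):
            for a in truth.planted_arrays[gid]:
                fh.write(
                    f"{gid}\t{a.start}\t{a.end}\t{a.repeat_length}\t{a.n_units}\t{int(a.has_truncated_unit)}\n"
                )
    if truth.strain_tree is not None:
        truth.strain_tree.write(str(outdir / "strain_tree.nwk"))


def read_truth_tables(outdir) -> TruthTable:
    """Reload cluster/partition truth (and the strain tree) written by
    :func:`write_truth_tables`; planted arrays are not reconstructed."""
    import pandas as pd

    outdir = Path(outdir)
    df = pd.read_csv(outdir / "truth_clusters.tsv", sep="\t")
    assignment = dict(zip(df["protein_id"], df["cluster_id"]))
    labels = df.drop_duplicates("cluster_id").set_index("cluster_id")["partition"].to_dict()
    tree_path = outdir / "strain_tree.nwk"
    tree = TreeNode.read(str(tree_path)) if tree_path.exists() else None
    return TruthTable(cluster_assignment=assignment, partition_label=labels, strain_tree=tree)
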