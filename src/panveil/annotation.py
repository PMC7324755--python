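"""Functional-annotation ingestion and partition-stratified summaries.

Database scans themselves (dbCAN hmmscan, COG BLASTP, eggnog-mapper) are
external: this module consumes their tabular outputs.  Per-protein hits are
reduced to one label per protein by the best-hit rule (E-value cutoff 1e-4,
then the single top bit-score hit — the filter used for COG assignment in
the study this package reproduces), lifted to clusters by a majority or
union rule, and summarised per pan-genome stratum (core/accessory/specific)
— the table structure behind per-strain CAZyme/COG/GO bar charts.

Labels are validated per namespace: CAZy family tokens (GT2, GH13, CE4,
PL1, CBM50, AA3, SLH…), single-letter COG categories; GO terms are carried
as opaque labels (no ontology traversal).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .clustering import ClusterSet
from .pangenome import PanPartition

DEFAULT_BEST_HIT_EVALUE = 1e-4

_CAZY_RE = re.compile(r"^(GT|GH|CE|PL|CBM|AA|SLH)\d*$")
_COG_RE = re.compile(r"^[A-Z]$")


def validate_labels(table: pd.DataFrame) -> pd.DataFrame:
    """Keep rows whose label fits the namespace grammar; raise on unknown namespace."""
    known = {"CAZy", "COG", "GO"}
    bad_ns = set(table["namespace"]) - known
    if bad_ns:
        raise ValueError(f"unknown namespace(s): {sorted(bad_ns)}")

    def ok(row) -> bool:
        if row.namespace == "CAZy":
            return bool(_CAZY_RE.match(row.label))
        if row.namespace == "COG":
            return bool(_COG_RE.match(row.label))
        return bool(row.label)  # GO terms are opaque
    if table.empty:
        return table
    return table[table.apply(ok, axis=1)].reset_index(drop=True)


def best_hit_filter(hit_table: pd.DataFrame, evalue_cutoff: float = DEFAULT_BEST_HIT_EVALUE) -> dict[str, str]:
    """One label per query: drop hits with E > cutoff, keep the top bit-score.

    Ties break by lower E-value, then lexicographic subject/label id.
    Idempotent: filtering an already-filtered table changes nothing.
    Expects columns (protein_id, label, e_value, bit_score).
    """
    if hit_table.empty:
        return {}
    kept = hit_table[hit_table["e_value"] <= evalue_cutoff]
    if kept.empty:
        return {}
    ordered = kept.sort_values(
        ["protein_id", "bit_score", "e_value", "label"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    best = ordered.drop_duplicates("protein_id", keep="first")
    return dict(zip(best["protein_id"], best["label"]))


@dataclass
class ClusterAnnotation:
    """Per-cluster labels with member-vote provenance."""

    labels: dict[str, list[str]] = field(default_factory=dict)
    ambiguous: dict[str, bool] = field(default_factory=dict)
    votes: dict[str, dict[str, int]] = field(default_factory=dict)

    def label_of(self, cluster_id: str) -> list[str]:
        return self.labels.get(cluster_id, [])


def lift_to_clusters(cluster_set: ClusterSet, protein_labels: dict[str, str], rule: str = "majority"
                     ) -> ClusterAnnotation:
    """Lift per-protein labels to clusters.

    ``any``: the union of member labels.  ``majority``: labels held by
    more than half of the *annotated* members; an exact tie reports all
    tied labels flagged ambiguous.
    """
    if rule not in ("any", "majority"):
        raise ValueError("rule must be 'any' or 'majority'")
    out = ClusterAnnotation()
    for cid, members in cluster_set.clusters.items():
        votes: dict[str, int] = {}
        for pid in members:
            label = protein_labels.get(pid)
            if label is not None:
                votes[label] = votes.get(label, 0) + 1
        if not votes:
            continue
        out.votes[cid] = votes
        if rule == "any":
            out.labels[cid] = sorted(votes)
            out.ambiguous[cid] = False
        else:
            annotated = sum(votes.values())
            majority = sorted(l for l, n in votes.items() if n > annotated / 2)
            if majority:
                out.labels[cid] = majority
                out.ambiguous[cid] = False
            else:
                top = max(votes.values())
                out.labels[cid] = sorted(l for l, n in votes.items() if n == top)
                out.ambiguous[cid] = True
    return out


@dataclass
class PartitionSummary:
    """The two tables behind stratified annotation figures."""

    stratum_label_counts: pd.DataFrame  # label x {core, accessory, specific}: cluster counts
    per_strain_gene_counts: pd.DataFrame  # strain x label: member-gene counts


def partition_counts(cluster_annotation: ClusterAnnotation, partition: PanPartition,
                     presence_matrix: pd.DataFrame) -> PartitionSummary:
    """Stratify annotated clusters by pan-genome partition.

    ``stratum_label_counts`` counts annotated clusters per (label, stratum);
    ``per_strain_gene_counts`` counts member gene copies per strain per
    label, over the clusters carrying that label.  When all core clusters
    are single-copy, core-derived label counts are identical across
    strains, by construction.
    """
    strata = ("core", "accessory", "specific")
    all_labels = sorted({l for labs in cluster_annotation.labels.values() for l in labs})
    counts = pd.DataFrame(0, index=all_labels, columns=list(strata))
    genes = pd.DataFrame(0, index=presence_matrix.index, columns=all_labels)
    for cid, labs in cluster_annotation.labels.items():
        stratum = partition.label.get(cid)
        if stratum is None:
            raise ValueError(f"cluster {cid} missing from the partition")
        for label in labs:
            counts.loc[label, stratum] += 1
            if cid in presence_matrix.columns:
                genes[label] += presence_matrix[cid]
    return PartitionSummary(counts, genes)


# ---------------------------------------------------------------------------
# annotation table IO

def read_annotation_tsv(path) -> pd.DataFrame:
    """Read a (protein_id, namespace, label[, e_value]) TSV and validate labels."""
    table = pd.read_csv(path, sep="\t")
    required = {"protein_id", "namespace", "label"}
    if not required <= set(table.columns):
        raise ValueError(f"annotation table needs columns {sorted(required)}")
    return validate_labels(table)


def write_partition_summary(summary: PartitionSummary, prefix) -> None:
    summary.stratum_label_counts.to_csv(f"{prefix}_stratum_counts.tsv", sep="\t", index_label="label")
    summary.per_strain_gene_counts.to_csv(f"{prefix}_per_strain_genes.tsv", sep="\t", index_label="strain")
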