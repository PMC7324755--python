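"""All-vs-all protein similarity search.

Every ordered protein pair is scored by optimal Smith–Waterman local
alignment (BLOSUM62, affine gaps 11/1, via Biopython's C aligner) and
converted to an E-value with the Karlin–Altschul formula
``E = K * m * n * exp(-lambda * S)`` in the gapped-BLOSUM62 regime
(K=0.041, lambda=0.267), with ``n`` the total residue count of the subject
database.  Hits below the E-value cutoff (default 1e-5, the ortholog-search
threshold of the study this package reproduces) feed the clustering stage.

An optional shared-k-mer prefilter skips alignment of pairs without any
exact k-mer in common; at the default k it is conservative for
within-species homologs, and its equivalence to the exhaustive search is
property-tested rather than assumed.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.Align import PairwiseAligner

from .records import ProteinRecord, StrainProteome, validate_protein_sequence
from .scoring import (
    DEFAULT_GAP_EXTEND,
    DEFAULT_GAP_OPEN,
    EVALUE_FLOOR,
    KARLIN_K,
    KARLIN_LAMBDA,
    blosum62,
)

DEFAULT_EVALUE_CUTOFF = 1e-5
DEFAULT_PREFILTER_K = 5


@dataclass(frozen=True)
class SimilarityHit:
    """One directed similarity hit (self-hits are never stored)."""

    query_id: str
    subject_id: str
    raw_score: float
    bit_score: float
    e_value: float
    identity_fraction: float
    aln_length: int


def _make_aligner(matrix=None, gap_open: float = DEFAULT_GAP_OPEN, gap_extend: float = DEFAULT_GAP_EXTEND) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = blosum62() if matrix is None else matrix
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def local_align(seq_a: str, seq_b: str, matrix=None, gap_open: float = DEFAULT_GAP_OPEN,
                gap_extend: float = DEFAULT_GAP_EXTEND) -> tuple[float, int, float]:
    """Optimal local alignment score, length and identity of two proteins.

    Returns ``(raw_score, aln_length, identity_fraction)``; identity is
    computed over aligned columns, gap columns excluded.  An all-negative
    scoring regime yields the empty alignment ``(0, 0, 0.0)``.
    """
    a = validate_protein_sequence(seq_a)
    b = validate_protein_sequence(seq_b)
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    score = aligner.score(a, b)
    if score <= 0:
        return 0.0, 0, 0.0
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    aligned_columns = counts.identities + counts.mismatches
    identity = counts.identities / aligned_columns if aligned_columns else 0.0
    return float(score), int(aln.length), float(identity)


def evalue(raw_score: float, m: int, n: int, k: float = KARLIN_K, lam: float = KARLIN_LAMBDA) -> float:
    """Karlin–Altschul expectation for a raw score against an (m, n) search space.

    Strictly decreasing in ``raw_score``; floored at 1e-300 so that
    ``-log10(E)`` edge weights stay finite.
    """
    if m <= 0 or n <= 0:
        raise ValueError("search-space sizes m and n must be positive")
    if k <= 0 or lam <= 0:
        raise ValueError("Karlin-Altschul parameters must be positive")
    e = k * m * n * math.exp(-lam * raw_score)
    return max(e, EVALUE_FLOOR)


def bit_score(raw_score: float, k: float = KARLIN_K, lam: float = KARLIN_LAMBDA) -> float:
    return (lam * raw_score - math.log(k)) / math.log(2)


def _kmer_candidate_pairs(records: Sequence[ProteinRecord], k: int) -> set[tuple[int, int]]:
    """Unordered index pairs sharing at least one exact k-mer."""
    index: dict[str, list[int]] = defaultdict(list)
    for i, rec in enumerate(records):
        for kmer in {rec.sequence[j : j + k] for j in range(len(rec.sequence) - k + 1)}:
            index[kmer].append(i)
    pairs: set[tuple[int, int]] = set()
    for hits in index.values():
        if len(hits) < 2:
            continue
        for x in range(len(hits)):
            for y in range(x + 1, len(hits)):
                pairs.add((hits[x], hits[y]))
    return pairs


def all_vs_all(proteomes: Iterable[StrainProteome], matrix=None, gap_open: float = DEFAULT_GAP_OPEN,
               gap_extend: float = DEFAULT_GAP_EXTEND, evalue_cutoff: float | None = DEFAULT_EVALUE_CUTOFF,
               prefilter_k: int | None = DEFAULT_PREFILTER_K) -> list[SimilarityHit]:
    """Directed similarity hits for every protein pair under the E cutoff.

    Alignment score, length and identity are symmetric, so each unordered
    pair is aligned once; the two directed E-values differ only through the
    query length ``m``.  ``evalue_cutoff=None`` retains all non-empty hits;
    ``prefilter_k=None`` disables the shared-k-mer prefilter.
    """
    records = [rec for prot in proteomes for rec in prot]
    if len(records) < 2:
        raise ValueError("all_vs_all requires at least two proteins")
    ids = [rec.protein_id for rec in records]
    if len(set(ids)) != len(ids):
        raise ValueError("protein ids must be unique across the run")
    n_db = sum(len(r) for r in records)
    aligner = _make_aligner(matrix, gap_open, gap_extend)

    if prefilter_k:
        pairs = sorted(_kmer_candidate_pairs(records, prefilter_k))
    else:
        pairs = [(i, j) for i in range(len(records)) for j in range(i + 1, len(records))]

    hits: list[SimilarityHit] = []
    for i, j in pairs:
        a, b = records[i], records[j]
        score = float(aligner.score(a.sequence, b.sequence))
        if score <= 0:
            continue
        e_ab = evalue(score, len(a), n_db)
        e_ba = evalue(score, len(b), n_db)
        if evalue_cutoff is not None and min(e_ab, e_ba) >= evalue_cutoff:
            continue
        aln = aligner.align(a.sequence, b.sequence)[0]
        counts = aln.counts()
        aligned_columns = counts.identities + counts.mismatches
        identity = counts.identities / aligned_columns if aligned_columns else 0.0
        bits = bit_score(score)
        if evalue_cutoff is None or e_ab < evalue_cutoff:
            hits.append(SimilarityHit(a.protein_id, b.protein_id, score, bits, e_ab, identity, aln.length))
        if evalue_cutoff is None or e_ba < evalue_cutoff:
            hits.append(SimilarityHit(b.protein_id, a.protein_id, score, bits, e_ba, identity, aln.length))
    return hits


# ---------------------------------------------------------------------------
# BLAST-outfmt-6-like hit table IO

_COLUMNS = (
    "query subject pct_identity aln_length mismatches gap_opens "
    "qstart qend sstart send e_value bit_score"
).split()


def write_hits_tsv(hits: Sequence[SimilarityHit], path) -> None:
    """BLAST tabular dialect; coordinate columns are not tracked (written 0)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{100 * h.identity_fraction:.2f}\t{h.aln_length}\t"
                f"0\t0\t0\t0\t0\t0\t{h.e_value:.3e}\t{h.bit_score:.1f}\n"
            )


def read_hits_tsv(path) -> list[SimilarityHit]:
    """Read the dialect of :func:`write_hits_tsv` (externally produced tables welcome)."""
    hits = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 12:
                raise ValueError(f"{path}:{ln}: expected 12 tab-separated columns")
            hits.append(
                SimilarityHit(
                    query_id=parts[0],
                    subject_id=parts[1],
                    raw_score=float("nan"),
                    bit_score=float(parts[11]),
                    e_value=float(parts[10]),
                    identity_fraction=float(parts[2]) / 100.0,
                    aln_length=int(parts[3]),
                )
            )
    return hits
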