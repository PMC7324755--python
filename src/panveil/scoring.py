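"""Protein scoring matrix and amino-acid background frequencies.

The similarity stage uses BLOSUM62 with affine gap penalties 11/1 — the de
facto defaults of protein database search — with one modification: the
unknown residue X scores 0 against everything, so unknowns neither reward
nor penalise an alignment.  Karlin–Altschul parameters for the gapped
BLOSUM62 regime convert raw scores into E-values.
"""

from __future__ import annotations

import functools

import numpy as np
from Bio.Align import substitution_matrices

from .records import AA20

#: Amino-acid background frequencies (Robinson–Robinson style composition
#: of a large protein database), in AA20 (alphabetical) order.  Embedded as
#: a constant so simulated proteomes are reproducible without external data.
BACKGROUND_FREQS = np.array(
    [
        0.0780,  # A
        0.0192,  # C
        0.0536,  # D
        0.0629,  # E
        0.0397,  # F
        0.0738,  # G
        0.0219,  # H
        0.0514,  # I
        0.0595,  # K
        0.0901,  # L
        0.0224,  # M
        0.0448,  # N
        0.0520,  # P
        0.0426,  # Q
        0.0512,  # R
        0.0712,  # S
        0.0584,  # T
        0.0661,  # V
        0.0132,  # W
        0.0321,  # Y
    ]
)
BACKGROUND_FREQS = BACKGROUND_FREQS / BACKGROUND_FREQS.sum()

#: Gapped BLOSUM62 Karlin–Altschul parameters (open 11, extend 1).
KARLIN_K = 0.041
KARLIN_LAMBDA = 0.267

DEFAULT_GAP_OPEN = 11
DEFAULT_GAP_EXTEND = 1

#: Smallest representable E-value; keeps -log10 weights finite downstream.
EVALUE_FLOOR = 1e-300


@functools.cache
def blosum62() -> substitution_matrices.Array:
    """BLOSUM62 with X scoring 0 against every residue (and itself)."""
    m = substitution_matrices.load("BLOSUM62").copy()
    for a in m.alphabet:
        m["X", a] = 0.0
        m[a, "X"] = 0.0
    return m


@functools.cache
def blosum62_array() -> np.ndarray:
    """BLOSUM62 over AA20 as a dense (20, 20) float array, AA20 order."""
    m = blosum62()
    out = np.empty((20, 20))
    for i, a in enumerate(AA20):
        for j, b in enumerate(AA20):
            out[i, j] = m[a, b]
    return out


#: Residue -> AA20 index; X maps to 20 (a zero-scoring extra row/column).
AA_INDEX = {a: i for i, a in enumerate(AA20)}
AA_INDEX["X"] = 20


@functools.cache
def blosum62_array_x() -> np.ndarray:
    """(21, 21) BLOSUM62 with index 20 = X scoring 0 everywhere."""
    out = np.zeros((21, 21))
    out[:20, :20] = blosum62_array()
    return out


def encode_protein(sequence: str) -> np.ndarray:
    """Encode a validated protein string as AA_INDEX integers."""
    return np.fromiter((AA_INDEX[c] for c in sequence), dtype=np.int64, count=len(sequence))
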