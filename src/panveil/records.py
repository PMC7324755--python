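"""Basic sequence records shared across the pipeline.

Protein identifiers are strain-qualified (``strain|gene``) so that a bare
id is globally unique across a multi-strain run, mirroring the convention
of OrthoMCL-style groups files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: The 20 standard amino acids, alphabetical one-letter codes.
AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Residues accepted in input proteins; X is the unknown-residue wildcard.
PROTEIN_ALPHABET = frozenset(AA20) | {"X"}

ID_SEPARATOR = "|"


class SequenceAlphabetError(ValueError):
    """Raised when a sequence contains residues outside the alphabet."""


def validate_protein_sequence(sequence: str) -> str:
    """Return ``sequence`` uppercased, or raise if empty/invalid."""
    if not sequence:
        raise SequenceAlphabetError("empty protein sequence")
    seq = sequence.upper()
    bad = set(seq) - PROTEIN_ALPHABET
    if bad:
        raise SequenceAlphabetError(
            f"invalid residue(s) {sorted(bad)}; allowed: 20 standard amino acids + X"
        )
    return seq


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with strain attribution.

    ``protein_id`` must be unique across the whole run; the conventional
    form is ``{strain_id}|{gene}``.
    """

    protein_id: str
    strain_id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", validate_protein_sequence(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)


def strain_of(protein_id: str) -> str:
    """Extract the strain from a strain-qualified protein id."""
    if ID_SEPARATOR not in protein_id:
        raise ValueError(f"protein id {protein_id!r} is not strain-qualified")
    return protein_id.split(ID_SEPARATOR, 1)[0]


@dataclass
class StrainProteome:
    """All proteins annotated on one strain's genome."""

    strain_id: str
    proteins: list[ProteinRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.proteins)

    def __iter__(self):
        return iter(self.proteins)

    @property
    def total_residues(self) -> int:
        return sum(len(p) for p in self.proteins)
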