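"""Genome container and strand arithmetic.

A mitogenome is modelled as an identified uppercase DNA string, optionally
circular (vertebrate mitochondrial DNA is a circular molecule of roughly
16-18 Kbp), optionally carrying taxonomy labels used for cohort grouping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

#: IUPAC nucleotide complements, ambiguity codes included.
IUPAC_COMPLEMENT: Mapping[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}

_COMPLEMENT_TABLE = str.maketrans(IUPAC_COMPLEMENT)
IUPAC_CODES = frozenset(IUPAC_COMPLEMENT)
UNAMBIGUOUS = frozenset("ACGT")


class InvalidAlphabetError(ValueError):
    """Raised when a sequence contains a character outside the IUPAC codes."""

    def __init__(self, char: str, position: int):
        self.char = char
        self.position = position
        super().__init__(
            f"invalid nucleotide {char!r} at position {position} "
            "(expected an IUPAC code)"
        )


def validate_sequence(sequence: str) -> str:
    """Uppercase ``sequence`` and verify every character is an IUPAC code.

    Returns the normalised sequence; raises :class:`InvalidAlphabetError`
    naming the first offending position otherwise.
    """
    seq = sequence.upper()
    for i, ch in enumerate(seq):
        if ch not in IUPAC_CODES:
            raise InvalidAlphabetError(ch, i)
    return seq


def reverse_complement(sequence: str) -> str:
    """Return the reverse complement of a DNA string.

    The complementary strand is built base by base (A<->T, C<->G, with
    ambiguity codes mapped to their IUPAC partners) and then reversed so the
    result reads 5'->3' again.
    """
    if not sequence:
        raise ValueError("cannot reverse-complement an empty sequence")
    seq = validate_sequence(sequence)
    return seq.translate(_COMPLEMENT_TABLE)[::-1]


@dataclass(frozen=True)
class Genome:
    """An identified DNA sequence with optional circularity and taxonomy.

    Parameters
    ----------
    id:
        Sequence identifier (e.g. an accession or species tag).
    sequence:
        DNA string; lowercased/soft-masked input is uppercased on ingest.
    circular:
        Whether the molecule is circular. When on, k-mer windows spanning
        the origin are included by the scanners.
    taxonomy:
        Optional labels such as ``{"order": "Anura", "species": ...}``.
    """

    id: str
    sequence: str
    circular: bool = False
    taxonomy: Optional[Mapping[str, str]] = field(default=None)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", validate_sequence(self.sequence))

    @property
    def length(self) -> int:
        return len(self.sequence)

    def reverse_complemented(self) -> "Genome":
        """The same molecule read from the complementary strand."""
        return Genome(
            id=self.id,
            sequence=reverse_complement(self.sequence),
            circular=self.circular,
            taxonomy=self.taxonomy,
        )

    def base_counts(self) -> dict[str, int]:
        return {b: self.sequence.count(b) for b in sorted(set(self.sequence))}

    def gc_content(self) -> float:
        if not self.sequence:
            return 0.0
        gc = self.sequence.count("G") + self.sequence.count("C")
        return gc / len(self.sequence)
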