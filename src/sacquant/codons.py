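"""Codon alphabet constants for the standard nuclear genetic code."""

from __future__ import annotations

BASES = "TCAG"

ALL_CODONS: tuple[str, ...] = tuple(
    a + b + c for a in BASES for b in BASES for c in BASES
)

STOP_CODONS: frozenset[str] = frozenset({"TAA", "TAG", "TGA"})

#: The 61 sense codons, in a fixed (T/C/A/G-major) order used for all
#: frequency vectors and CSC tables in this package.
SENSE_CODONS: tuple[str, ...] = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)

START_CODON = "ATG"

_SENSE_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}


def sense_index(codon: str) -> int:
    """Position of a sense codon in the canonical 61-codon order."""
    return _SENSE_INDEX[codon]


def is_valid_codon(codon: str) -> bool:
    return len(codon) == 3 and all(b in "ACGT" for b in codon)
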