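"""Nucleic-acid alphabet helpers shared across the toolkit.

DNA strings are uppercase over ``ACGT``, RNA over ``ACGU``.  All coordinates in
the package are 1-based; the utilities here are plain 0-based string helpers.
Ambiguity codes (N, R, Y, ...) are rejected rather than expanded.
"""

from __future__ import annotations

DNA_BASES = "ACGT"
RNA_BASES = "ACGU"

_DNA_COMP = str.maketrans("ACGT", "TGCA")
_RNA_COMP = str.maketrans("ACGU", "UGCA")
_TO_RNA = str.maketrans("T", "U")
_TO_DNA = str.maketrans("U", "T")


class AlphabetError(ValueError):
    """A sequence contains characters outside its declared alphabet."""


def ensure_dna(seq: str, name: str = "sequence", length: int | None = None) -> str:
    """Uppercase ``seq`` and check it is pure DNA (optionally of fixed length)."""
    s = seq.upper()
    bad = sorted(set(s) - set(DNA_BASES))
    if bad:
        raise AlphabetError(f"{name} contains non-DNA characters: {bad}")
    if length is not None and len(s) != length:
        raise ValueError(f"{name} must be {length} nt, got {len(s)} nt")
    return s


def ensure_rna(seq: str, name: str = "sequence", length: int | None = None) -> str:
    """Uppercase ``seq`` and check it is pure RNA (optionally of fixed length)."""
    s = seq.upper()
    bad = sorted(set(s) - set(RNA_BASES))
    if bad:
        raise AlphabetError(f"{name} contains non-RNA characters: {bad}")
    if length is not None and len(s) != length:
        raise ValueError(f"{name} must be {length} nt, got {len(s)} nt")
    return s


def comp_dna(seq: str) -> str:
    return seq.translate(_DNA_COMP)


def revcomp_dna(seq: str) -> str:
    return seq.translate(_DNA_COMP)[::-1]


def comp_rna(seq: str) -> str:
    return seq.translate(_RNA_COMP)


def dna_to_rna(seq: str) -> str:
    """Transliterate DNA to RNA (T -> U), preserving base identity."""
    return seq.translate(_TO_RNA)


def rna_to_dna(seq: str) -> str:
    return seq.translate(_TO_DNA)


def guide_base_for(dna_base: str) -> str:
    """The RNA base that Watson-Crick pairs a given DNA base (A->U, C->G, G->C, T->A)."""
    return dna_to_rna(comp_dna(dna_base))
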