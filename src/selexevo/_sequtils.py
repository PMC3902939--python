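"""Small shared sequence helpers (DNA/RNA alphabets, distances)."""

from __future__ import annotations

import edlib

_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_RNA_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")

IUPAC_DNA = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

IUPAC_RNA = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "R": "AG", "Y": "CU", "S": "CG", "W": "AU", "K": "GU", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG", "N": "ACGU",
}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence."""
    return seq.translate(_DNA_COMPLEMENT)[::-1]


def revcomp_rna(seq: str) -> str:
    return seq.translate(_RNA_COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    """Transcribe a DNA string to the RNA alphabet (T -> U); idempotent."""
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def levenshtein(a: str, b: str, max_dist: int | None = None) -> int:
    """Levenshtein edit distance via edlib.

    When ``max_dist`` is given, distances above it are reported as
    ``max_dist + 1`` (edlib's banded mode); callers that only test
    ``<= max_dist`` are unaffected and gain a large speedup.
    """
    k = -1 if max_dist is None else max_dist
    d = edlib.align(a, b, mode="NW", task="distance", k=k)["editDistance"]
    if d == -1:
        return (max_dist or 0) + 1
    return d
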