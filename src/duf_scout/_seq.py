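"""Small shared sequence helpers (thin wrappers over Biopython)."""

from __future__ import annotations

from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

DNA_ALPHABET = frozenset("ACGTN")
STANDARD_TABLE = unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(STANDARD_TABLE.stop_codons)  # TAA, TAG, TGA

# residue -> list of codons, standard table
CODONS_FOR = {}
for _codon, _aa in STANDARD_TABLE.forward_table.items():
    CODONS_FOR.setdefault(_aa, []).append(_codon)
for _aa in CODONS_FOR:
    CODONS_FOR[_aa].sort()


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate(seq: str) -> str:
    """Translate a frame-aligned DNA string; trailing partial codon dropped,
    stops rendered as '*'."""
    usable = len(seq) - len(seq) % 3
    return str(Seq(seq[:usable]).translate())


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def validate_dna(seq: str, name: str = "sequence") -> None:
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"{name} contains non-DNA characters: {sorted(bad)}")
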