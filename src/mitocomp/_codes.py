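"""Genetic-code lookups, keyed by NCBI translation table id.

The package defaults to table 5 (invertebrate mitochondrial: ATA=Met,
TGA=Trp, AGA/AGG=Ser), the code used for arthropod mitogenomes.
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Data import CodonTable

NT = "ACGT"

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N preserved)."""
    return seq.translate(COMPLEMENT)[::-1]


@lru_cache(maxsize=None)
def codon_table(code_id: int = 5) -> CodonTable.CodonTable:
    return CodonTable.unambiguous_dna_by_id[code_id]


@lru_cache(maxsize=None)
def stop_codons(code_id: int = 5) -> frozenset[str]:
    return frozenset(codon_table(code_id).stop_codons)


@lru_cache(maxsize=None)
def sense_codons(code_id: int = 5) -> tuple[str, ...]:
    """All non-stop codons of the code, in lexicographic order."""
    stops = stop_codons(code_id)
    return tuple(
        a + b + c
        for a in NT
        for b in NT
        for c in NT
        if a + b + c not in stops
    )


def translate_codon(codon: str, code_id: int = 5) -> str:
    """One-letter amino acid for a codon; '*' for a stop codon."""
    codon = codon.upper()
    if codon in stop_codons(code_id):
        return "*"
    return codon_table(code_id).forward_table[codon]


def is_stop(codon: str, code_id: int = 5) -> bool:
    return codon.upper() in stop_codons(code_id)
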