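"""Codon usage under the invertebrate mitochondrial code.

Covers codon splitting with incomplete-stop remnants (mitochondrial CDSs may
terminate in T or TA, completed to TAA by polyadenylation), verbatim
start/stop classification, relative synonymous codon usage (RSCU) and
amino-acid usage.

RSCU of a codon is its count divided by the mean count of its synonymous
family; families follow the amino acid under the chosen code, with Leu split
into leu1 (CUN) / leu2 (UUA, UUG) and Ser into ser1 (AGN) / ser2 (UCN) as is
conventional for mitogenome reports.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from functools import lru_cache

from ._codes import is_stop, sense_codons, translate_codon
from .mito_io import AnnotatedMitogenome, extract_gene_sequence

CANONICAL_STARTS = frozenset({"ATA", "ATT", "ATG", "ATC"})

_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}


@lru_cache(maxsize=None)
def codon_families(code_id: int = 5) -> dict[str, str]:
    """Map each sense codon to its synonymous-family label (leu/ser split)."""
    fam = {}
    for codon in sense_codons(code_id):
        aa = translate_codon(codon, code_id)
        label = _AA3[aa]
        if aa == "L":
            label = "Leu2" if codon in ("TTA", "TTG") else "Leu1"
        elif aa == "S":
            label = "Ser1" if codon.startswith("AG") else "Ser2"
        fam[codon] = label
    return fam


@dataclass
class CodonCall:
    gene: str
    start_codon: str
    stop_codon: str  # 3-mer, "TA", "T", or non-stop terminal reported verbatim
    is_canonical_start: bool
    is_incomplete_stop: bool
    has_internal_stop: bool = False


@dataclass
class CodonUsageTable:
    counts: dict[str, int]
    rscu: dict[str, float | None]  # None = family total zero, undefined
    aa_freq: dict[str, int]
    family_map: dict[str, str]


def split_codons(cds: str) -> tuple[list[str], str]:
    """Split a reading-direction CDS into triplets and a 0–2 nt remnant."""
    cds = cds.upper()
    if len(cds) < 3:
        raise ValueError("CDS shorter than one codon")
    n = len(cds) // 3 * 3
    return [cds[i:i + 3] for i in range(0, n, 3)], cds[n:]


def classify_start_stop(cds: str, gene: str = "", code_id: int = 5) -> CodonCall:
    """Classify start and stop codons of a CDS, verbatim.

    The start is the first triplet as annotated (never corrected to ATN).
    The stop is the final triplet if it is a stop under the code, else a
    trailing "T"/"TA" remnant (incomplete stop), else the terminal
    codon/remnant reported verbatim and flagged as non-stop.
    """
    if len(cds) < 6:
        raise ValueError("CDS shorter than two codons")
    codons, remnant = split_codons(cds)
    start = codons[0]
    internal = [c for c in codons[1:-1] if is_stop(c, code_id)]
    if internal:
        warnings.warn(f"{gene or 'CDS'}: internal stop codon(s) {internal}")
    if remnant:
        stop = remnant
        incomplete = remnant in ("T", "TA")
    else:
        stop = codons[-1]
        incomplete = False
    return CodonCall(gene=gene, start_codon=start, stop_codon=stop,
                     is_canonical_start=start in CANONICAL_STARTS,
                     is_incomplete_stop=incomplete,
                     has_internal_stop=bool(internal))


def genome_codon_calls(genome: AnnotatedMitogenome, code_id: int = 5) -> list[CodonCall]:
    return [classify_start_stop(extract_gene_sequence(genome, f), f.name, code_id)
            for f in genome.features if f.kind == "PCG"]


def count_codons(cds_list: list[str], code_id: int = 5,
                 exclude_stops: bool = True) -> Counter:
    """Codon counts over CDSs; trailing remnants and (by default) stops excluded."""
    counts: Counter = Counter()
    for cds in cds_list:
        codons, _ = split_codons(cds)
        for c in codons:
            if exclude_stops and is_stop(c, code_id):
                continue
            counts[c] += 1
    return counts


def rscu(counts: dict[str, int], code_id: int = 5) -> CodonUsageTable:
    fam = codon_families(code_id)
    bad = [c for c in counts if c not in fam]
    if bad:
        raise ValueError(f"non-sense codons in counts: {bad}")
    members: dict[str, list[str]] = {}
    for codon, label in fam.items():
        members.setdefault(label, []).append(codon)
    rscu_vals: dict[str, float | None] = {}
    aa_freq: Counter = Counter()
    for label, codons in members.items():
        total = sum(counts.get(c, 0) for c in codons)
        aa_freq[label] += total
        for c in codons:
            rscu_vals[c] = (counts.get(c, 0) * len(codons) / total
                            if total else None)
    return CodonUsageTable(counts=dict(counts), rscu=rscu_vals,
                           aa_freq=dict(aa_freq), family_map=fam)


def genome_rscu(genome: AnnotatedMitogenome, code_id: int = 5) -> CodonUsageTable:
    """RSCU over the concatenated PCGs of one genome."""
    cds_list = [extract_gene_sequence(genome, f)
                for f in genome.features if f.kind == "PCG"]
    return rscu(count_codons(cds_list, code_id), code_id)


def amino_acid_usage(genome_or_cds, code_id: int = 5) -> dict[str, int]:
    """Residue counts over all PCGs (or an explicit list of CDS strings);
    stops and incomplete remnants excluded."""
    if isinstance(genome_or_cds, AnnotatedMitogenome):
        cds_list = [extract_gene_sequence(genome_or_cds, f)
                    for f in genome_or_cds.features if f.kind == "PCG"]
    else:
        cds_list = list(genome_or_cds)
    usage: Counter = Counter()
    for cds in cds_list:
        codons, _ = split_codons(cds)
        for c in codons:
            if not is_stop(c, code_id):
                usage[_AA3[translate_codon(c, code_id)]] += 1
    return dict(usage)
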