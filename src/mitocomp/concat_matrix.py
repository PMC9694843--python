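"""Supermatrix preparation: per-gene harvest, column filtering, concatenation.

The package does not align (that is an external aligner's job) and its
column filter is a deliberately simple, logged rule — remove columns whose
gap fraction exceeds a threshold and, optionally, columns containing
ambiguity — not a re-implementation of heuristic trimming tools. Exports
aligned FASTA, NEXUS with per-gene charset lines, and relaxed PHYLIP.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .mito_io import AnnotatedMitogenome, extract_gene_sequence

#: fixed concatenation order (alphabetical by gene)
PCG_ORDER = ("atp6", "atp8", "cox1", "cox2", "cox3", "cytb", "nad1",
             "nad2", "nad3", "nad4", "nad4l", "nad5", "nad6")

GAP = "-"
AMBIGUOUS = set("NRYSWKMBDHV")


@dataclass
class SuperMatrix:
    taxa: list[str]
    rows: dict[str, str]
    charsets: dict[str, tuple[int, int]]  # gene -> 1-based inclusive columns
    filter_log: dict[str, list[int]] = field(default_factory=dict)

    @property
    def n_char(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0


def harvest_gene(genomes: list[AnnotatedMitogenome], gene: str) -> dict[str, str]:
    """Reading-direction CDS per taxon; taxa lacking the gene are omitted."""
    out = {}
    for g in genomes:
        f = g.get_feature(gene)
        if f is None:
            warnings.warn(f"{g.taxon}: {gene} missing")
            continue
        out[g.taxon] = extract_gene_sequence(g, f)
    return out


def filter_columns(alignment: dict[str, str], max_gap_frac: float = 0.0,
                   drop_ambiguous: bool = False) -> tuple[dict[str, str], list[int]]:
    """Drop columns by gap fraction (and optionally ambiguity).

    Returns (filtered alignment, 0-based indices of removed columns).
    Raises when nothing survives.
    """
    taxa = list(alignment)
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError("alignment is not rectangular")
    n = lengths.pop()
    removed = []
    keep = []
    for col in range(n):
        column = [alignment[t][col] for t in taxa]
        gap_frac = sum(c == GAP for c in column) / len(column)
        ambiguous = any(c.upper() in AMBIGUOUS for c in column)
        if gap_frac > max_gap_frac or (drop_ambiguous and ambiguous):
            removed.append(col)
        else:
            keep.append(col)
    if not keep:
        raise ValueError("no columns survive filtering")
    filtered = {t: "".join(alignment[t][c] for c in keep) for t in taxa}
    return filtered, removed


def _trim_to_codons(seq: str) -> str:
    return seq[: len(seq) // 3 * 3]


def concatenate(per_gene: dict[str, dict[str, str]],
                taxon_order: list[str] | None = None) -> SuperMatrix:
    """Concatenate per-gene alignments into a supermatrix with charsets.

    Genes are laid out in the fixed PCG_ORDER (others appended
    alphabetically); taxa missing from a gene are gap-filled with a warning.
    Per-gene lengths are trimmed to full codons first.
    """
    genes = [g for g in PCG_ORDER if g in per_gene]
    genes += sorted(set(per_gene) - set(genes))
    if taxon_order is None:
        taxon_order = sorted({t for aln in per_gene.values() for t in aln})
    if len(set(taxon_order)) != len(taxon_order):
        raise ValueError("duplicate taxon names")
    rows = {t: [] for t in taxon_order}
    charsets = {}
    pos = 1
    for gene in genes:
        aln = {t: _trim_to_codons(s) for t, s in per_gene[gene].items()}
        lengths = {len(s) for s in aln.values()}
        if len(lengths) != 1:
            raise ValueError(f"{gene}: unaligned (unequal lengths)")
        glen = lengths.pop()
        for t in taxon_order:
            if t in aln:
                rows[t].append(aln[t])
            else:
                warnings.warn(f"{t}: missing {gene}; gap-filled")
                rows[t].append(GAP * glen)
        charsets[gene] = (pos, pos + glen - 1)
        pos += glen
    sm = SuperMatrix(taxa=list(taxon_order),
                     rows={t: "".join(parts) for t, parts in rows.items()},
                     charsets=charsets)
    total = sm.n_char
    assert pos - 1 == total
    spans = sorted(charsets.values())
    assert spans[0][0] == 1 and spans[-1][1] == total
    assert all(spans[i][1] + 1 == spans[i + 1][0] for i in range(len(spans) - 1))
    return sm


def _safe(name: str) -> str:
    return name.replace(" ", "_")


def write_fasta(sm: SuperMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in sm.taxa:
            fh.write(f">{_safe(t)}\n{sm.rows[t]}\n")


def write_phylip(sm: SuperMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(sm.taxa)} {sm.n_char}\n")
        for t in sm.taxa:
            fh.write(f"{_safe(t)}  {sm.rows[t]}\n")


def write_nexus(sm: SuperMatrix, path: str | Path) -> None:
    """NEXUS with a DATA block and per-gene CHARSET lines."""
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN DATA;\n")
        fh.write(f"    DIMENSIONS NTAX={len(sm.taxa)} NCHAR={sm.n_char};\n")
        fh.write("    FORMAT DATATYPE=DNA MISSING=? GAP=-;\n    MATRIX\n")
        for t in sm.taxa:
            fh.write(f"    {_safe(t)}  {sm.rows[t]}\n")
        fh.write("    ;\nEND;\n\nBEGIN SETS;\n")
        for gene, (a, b) in sm.charsets.items():
            fh.write(f"    CHARSET {gene} = {a}-{b};\n")
        fh.write("END;\n")
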