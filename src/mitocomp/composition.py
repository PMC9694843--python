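"""Base composition, A+T content and strand-asymmetry skews.

AT skew = (A − T)/(A + T) and GC skew = (G − C)/(G + C), computed from raw
counts. N bases are excluded from all denominators; the reported length
still includes them. Whole-genome values refer to the deposited J-strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .mito_io import AnnotatedMitogenome, extract_gene_sequence


@dataclass
class CompositionSummary:
    label: str
    length: int
    n_count: int
    counts: dict[str, int]
    pct: dict[str, float]
    at_content: float
    gc_content: float
    at_skew: float | None  # None = undefined (zero denominator)
    gc_skew: float | None

    @property
    def gt_content(self) -> float:
        return self.pct["G"] + self.pct["T"]


def base_composition(seq: str, label: str = "seq") -> CompositionSummary:
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    n_count = len(seq) - sum(counts.values())
    total = sum(counts.values())
    if total == 0:
        return CompositionSummary(label, len(seq), n_count, counts,
                                  {b: float("nan") for b in "ACGT"},
                                  float("nan"), float("nan"), None, None)
    pct = {b: 100.0 * counts[b] / total for b in "ACGT"}
    a, c, g, t = counts["A"], counts["C"], counts["G"], counts["T"]
    at_skew = (a - t) / (a + t) if a + t else None
    gc_skew = (g - c) / (g + c) if g + c else None
    return CompositionSummary(label, len(seq), n_count, counts, pct,
                              pct["A"] + pct["T"], pct["G"] + pct["C"],
                              at_skew, gc_skew)


def skew(x: float, y: float) -> float | None:
    """(x − y)/(x + y); works on counts or printed percentages alike."""
    return (x - y) / (x + y) if x + y else None


def strand_class_composition(genome: AnnotatedMitogenome) -> list[CompositionSummary]:
    """Whole genome plus concatenated J- and N-strand PCG compositions.

    PCG concatenations are in reading direction. A strand with no PCGs is
    omitted with a warning.
    """
    out = [base_composition(genome.sequence, f"{genome.taxon}|genome")]
    for strand in ("J", "N"):
        parts = [extract_gene_sequence(genome, f)
                 for f in genome.features
                 if f.kind == "PCG" and f.strand == strand]
        if not parts:
            warnings.warn(f"{genome.taxon}: no PCGs on {strand}-strand")
            continue
        out.append(base_composition("".join(parts),
                                    f"{genome.taxon}|PCG-{strand}"))
    return out


def composition_table(genomes: list[AnnotatedMitogenome]) -> pd.DataFrame:
    """Per-genome composition report: size, base %, AT/GC/GT %, skews.

    Percentages are rounded to one decimal and skews to three, matching the
    conventional presentation of mitogenome composition tables.
    """
    if not genomes:
        raise ValueError("need at least one genome")
    rows = []
    for g in genomes:
        s = base_composition(g.sequence, g.taxon)
        rows.append({
            "Species": g.taxon,
            "Size (bp)": s.length,
            "T (%)": round(s.pct["T"], 1),
            "C (%)": round(s.pct["C"], 1),
            "A (%)": round(s.pct["A"], 1),
            "G (%)": round(s.pct["G"], 1),
            "AT (%)": round(s.at_content, 1),
            "GC (%)": round(s.gc_content, 1),
            "GT (%)": round(s.gt_content, 1),
            "AT skew": round(s.at_skew, 3) if s.at_skew is not None else None,
            "GC skew": round(s.gc_skew, 3) if s.gc_skew is not None else None,
        })
    return pd.DataFrame(rows)
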