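"""Overlap/spacer structure of adjacent genes on the circular genome.

Adjacent features either overlap, abut, or leave an intergenic spacer.
Overlaps are computed on genomic coordinates regardless of strand (the
conserved trnW/trnC overlap spans opposite-strand tRNAs) and all junction
sequences are reported on the J-strand. Conservation across a taxon panel
flags motifs shared identically by every genome (e.g. the lepidopteran
ATGATAA atp8/atp6 overlap and the ATACTAA trnS2/nad1 spacer).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from collections import Counter

from .composition import CompositionSummary, base_composition
from .mito_io import AnnotatedMitogenome, GeneFeature, circular_slice, sorted_features


@dataclass
class Junction:
    upstream_gene: str
    downstream_gene: str
    relation: str  # overlap | spacer | abutting
    length: int
    sequence: str  # J-strand; empty for abutting
    circular_wrap: bool = False


@dataclass
class ConservedJunction:
    gene_pair: tuple[str, str]
    relation: str
    motif: str
    taxa_supporting: list[str]
    is_universal: bool
    n_taxa: int


@dataclass
class ControlRegionHit:
    start: int
    end: int
    length: int
    upstream_flank: str
    downstream_flank: str
    canonical: bool  # flanked by rrnS and trnM


def _unwrapped(f: GeneFeature, n: int) -> tuple[int, int]:
    end = f.end if f.end >= f.start else f.end + n
    return f.start, end


def scan_junctions(genome: AnnotatedMitogenome) -> list[Junction]:
    """One Junction per adjacent feature pair around the circle.

    Nested (fully contained) features are reported as overlaps of the inner
    length with a warning, and the covering feature carries on to the next
    junction.
    """
    feats = sorted_features(genome)
    if not feats:
        return []
    n = genome.length
    out: list[Junction] = []
    cover = feats[0]  # feature with furthest reach so far
    for i in range(len(feats)):
        f = feats[(i + 1) % len(feats)] if i + 1 < len(feats) else feats[0]
        cs, ce = _unwrapped(cover, n)
        fs, fe = _unwrapped(f, n)
        if i + 1 == len(feats):  # wrap junction back to the first feature
            fs, fe = fs + n, fe + n
        gap = fs - ce - 1
        wrap = fs > n or ce > n
        if gap > 0:
            seq = circular_slice(genome.sequence, (ce % n) + 1, ((fs - 2) % n) + 1)
            out.append(Junction(cover.name, f.name, "spacer", gap, seq, wrap))
        elif gap == 0:
            out.append(Junction(cover.name, f.name, "abutting", 0, "", wrap))
        else:
            if fe <= ce:
                warnings.warn(f"{f.name} nested within {cover.name}")
                length = fe - fs + 1
            else:
                length = -gap
            seq = circular_slice(genome.sequence, (fs - 1) % n + 1,
                                 (min(ce, fe) - 1) % n + 1)
            out.append(Junction(cover.name, f.name, "overlap", length, seq, wrap))
        if i + 1 < len(feats) and fe > ce:
            cover = f
    return out


def conserved_junctions(genomes: list[AnnotatedMitogenome]) -> list[ConservedJunction]:
    """Cross-taxon conservation of junction sequences.

    A junction is universal when every input genome has the gene pair
    adjacent with an identical sequence (and the same relation). Otherwise
    the modal motif and its supporting taxa are reported.
    """
    if len(genomes) < 2:
        raise ValueError("need at least two genomes")
    per_pair: dict[tuple[str, str], list[tuple[str, str, str]]] = {}
    for g in genomes:
        for j in scan_junctions(g):
            key = (j.upstream_gene, j.downstream_gene)
            per_pair.setdefault(key, []).append((g.taxon, j.relation, j.sequence))
    out = []
    n_taxa = len(genomes)
    for pair in sorted(per_pair):
        hits = per_pair[pair]
        motif_counts = Counter((rel, seq) for _, rel, seq in hits)
        (relation, motif), support = motif_counts.most_common(1)[0]
        taxa = [t for t, rel, seq in hits if (rel, seq) == (relation, motif)]
        universal = len(hits) == n_taxa and support == n_taxa
        out.append(ConservedJunction(gene_pair=pair, relation=relation,
                                     motif=motif, taxa_supporting=taxa,
                                     is_universal=universal, n_taxa=n_taxa))
    return out


def spacer_profile(genomes: list[AnnotatedMitogenome],
                   gene_pair: tuple[str, str]) -> dict[str, object]:
    """Per-taxon spacer lengths and composition for one gene pair.

    The pair is matched in either orientation. Returns per-taxon entries
    plus min/max length across taxa; empty when the pair is never adjacent.
    """
    entries: dict[str, tuple[int, CompositionSummary | None]] = {}
    keys = {gene_pair, gene_pair[::-1]}
    for g in genomes:
        for j in scan_junctions(g):
            if (j.upstream_gene, j.downstream_gene) in keys:
                comp = base_composition(j.sequence, g.taxon) if j.sequence else None
                entries[g.taxon] = (j.length, comp)
    if not entries:
        return {"pair": gene_pair, "per_taxon": {}, "min": None, "max": None}
    lengths = [v[0] for v in entries.values()]
    return {"pair": gene_pair, "per_taxon": entries,
            "min": min(lengths), "max": max(lengths)}


def locate_control_regions(genome: AnnotatedMitogenome,
                           min_len: int = 200) -> list[ControlRegionHit]:
    """Unannotated stretches of the circle ≥ min_len, with flanking genes.

    The canonical lepidopteran control region is flanked by rrnS and trnM;
    hits with those flanks are marked canonical.
    """
    n = genome.length
    feats = sorted_features(genome)
    if not feats:
        return []
    covered = bytearray(n)
    for f in feats:
        s, e = _unwrapped(f, n)
        for pos in range(s - 1, e):
            covered[pos % n] = 1
    hits = []
    intervals = []
    pos = 0
    # find circular runs of uncovered positions
    if all(covered):
        return []
    # start scanning from a covered position to keep runs contiguous
    start0 = covered.index(1)
    run_start = None
    for k in range(n + 1):
        p = (start0 + k) % n
        if k < n and not covered[p]:
            if run_start is None:
                run_start = p
        else:
            if run_start is not None:
                length = (p - run_start) % n or n
                intervals.append((run_start, length))
                run_start = None
    for run_start, length in intervals:
        if length < min_len:
            continue
        start1 = run_start + 1
        end1 = (run_start + length - 1) % n + 1
        before = min(feats, key=lambda f: (start1 - 1 - _unwrapped(f, n)[1]) % n)
        after = min(feats, key=lambda f: (f.start - end1 - 1) % n)
        canonical = {before.name, after.name} == {"rrnS", "trnM"}
        hits.append(ControlRegionHit(start1, end1, length,
                                     before.name, after.name, canonical))
    hits.sort(key=lambda h: h.start)
    return hits
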