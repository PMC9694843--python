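"""Signed gene orders on the circular mitogenome and adjacency comparison.

Lepidopteran mitogenomes carry the derived trnM-trnI-trnQ block where
ancestral insects have trnI-trnQ-trnM (a tandem duplication–random loss
rearrangement); a chironomid trnI-trnM-trnQ variant is shipped as a third
reference. Orders are compared on the multiset of strand-aware circular
adjacencies (breakpoints), not by inversion distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .mito_io import AnnotatedMitogenome, sorted_features

Token = tuple[str, str]  # (gene name, strand)

# shared downstream block of the insect mitogenome, nad2 .. control region
_COMMON = [
    ("nad2", "J"), ("trnW", "J"), ("trnC", "N"), ("trnY", "N"),
    ("cox1", "J"), ("trnL2", "J"), ("cox2", "J"), ("trnK", "J"),
    ("trnD", "J"), ("atp8", "J"), ("atp6", "J"), ("cox3", "J"),
    ("trnG", "J"), ("nad3", "J"), ("trnA", "J"), ("trnR", "J"),
    ("trnN", "J"), ("trnS1", "J"), ("trnE", "J"), ("trnF", "N"),
    ("nad5", "N"), ("trnH", "N"), ("nad4", "N"), ("nad4l", "N"),
    ("trnT", "J"), ("trnP", "N"), ("nad6", "J"), ("cytb", "J"),
    ("trnS2", "J"), ("nad1", "N"), ("trnL1", "N"), ("rrnL", "N"),
    ("trnV", "N"), ("rrnS", "N"), ("CR", "J"),
]

LEPIDOPTERA_TYPICAL: tuple[Token, ...] = tuple(
    [("trnM", "J"), ("trnI", "J"), ("trnQ", "N")] + _COMMON)
ANCESTRAL_INSECT: tuple[Token, ...] = tuple(
    [("trnI", "J"), ("trnQ", "N"), ("trnM", "J")] + _COMMON)
CHIRONOMID_VARIANT: tuple[Token, ...] = tuple(
    [("trnI", "J"), ("trnM", "J"), ("trnQ", "N")] + _COMMON)

REFERENCE_ORDERS: dict[str, tuple[Token, ...]] = {
    "ancestral_insect": ANCESTRAL_INSECT,
    "lepidoptera_typical": LEPIDOPTERA_TYPICAL,
    "chironomid_variant": CHIRONOMID_VARIANT,
}


@dataclass
class GeneOrder:
    taxon: str
    order: tuple[Token, ...]


@dataclass
class OrderComparison:
    identical: bool
    breakpoints: int
    differing_blocks: list[list[str]]


def _canonical_rotation(tokens: list[Token], anchor: str = "cox1") -> tuple[Token, ...]:
    names = [t[0] for t in tokens]
    if anchor in names:
        i = names.index(anchor)
    else:
        warnings.warn(f"anchor {anchor} missing; falling back to smallest gene")
        i = names.index(min(names))
    return tuple(tokens[i:] + tokens[:i])


def order_string(genome: AnnotatedMitogenome, anchor: str = "cox1") -> GeneOrder:
    """Gene-order tokens in genomic order, rotated to start at the anchor."""
    tokens = [(f.name, f.strand) for f in sorted_features(genome)]
    return GeneOrder(taxon=genome.taxon, order=_canonical_rotation(tokens, anchor))


def from_template(name_or_tokens, taxon: str = "reference") -> GeneOrder:
    tokens = (REFERENCE_ORDERS[name_or_tokens]
              if isinstance(name_or_tokens, str) else tuple(name_or_tokens))
    return GeneOrder(taxon=taxon, order=_canonical_rotation(list(tokens)))


def _flip(token: Token) -> Token:
    return token[0], ("J" if token[1] == "N" else "N")


def _adjacencies(order: GeneOrder, include_cr: bool) -> set[tuple[Token, Token]]:
    """Strand-aware circular adjacencies, canonicalized against reading the
    circle on the opposite strand (so (a+,b+) ≡ (b−,a−))."""
    toks = [t for t in order.order
            if include_cr or not t[0].startswith("CR")]
    adj = set()
    for i in range(len(toks)):
        a, b = toks[i], toks[(i + 1) % len(toks)]
        forward = (a, b)
        reverse = (_flip(b), _flip(a))
        adj.add(min(forward, reverse))
    return adj


def compare_orders(a: GeneOrder, b: GeneOrder,
                   include_cr: bool = False) -> OrderComparison:
    """Breakpoints = adjacencies of ``a`` absent from ``b``.

    Genes present in only one order are dropped pairwise (with a warning);
    fully disjoint gene sets are an error.
    """
    names_a = {t[0] for t in a.order}
    names_b = {t[0] for t in b.order}
    common = names_a & names_b
    if not common:
        raise ValueError("orders share no genes")
    if names_a != names_b:
        warnings.warn("gene sets differ; comparing on the intersection")
        a = GeneOrder(a.taxon, tuple(t for t in a.order if t[0] in common))
        b = GeneOrder(b.taxon, tuple(t for t in b.order if t[0] in common))
    adj_a = _adjacencies(a, include_cr)
    adj_b = _adjacencies(b, include_cr)
    missing = adj_a - adj_b
    breakpoints = len(missing)

    # maximal runs of a's tokens chained by non-shared adjacencies
    toks = [t for t in a.order if include_cr or not t[0].startswith("CR")]
    n = len(toks)
    blocks: list[list[str]] = []
    current: list[str] = []
    for i in range(n):
        pair = (toks[i], toks[(i + 1) % n])
        shared = min(pair, (_flip(pair[1]), _flip(pair[0]))) in adj_b
        if not shared:
            if not current:
                current = [toks[i][0]]
            current.append(toks[(i + 1) % n][0])
        else:
            if current:
                blocks.append(current)
                current = []
    if current:
        blocks.append(current)
    return OrderComparison(identical=not missing and names_a == names_b,
                           breakpoints=breakpoints, differing_blocks=blocks)


def classify_against_references(
        genome_or_order, references: dict[str, GeneOrder] | None = None,
) -> tuple[str, OrderComparison, bool]:
    """Best-matching reference by breakpoint count.

    Returns (reference name, comparison, tie flag); ties break alphabetically.
    """
    if isinstance(genome_or_order, GeneOrder):
        order = genome_or_order
    else:
        order = order_string(genome_or_order)
    if references is None:
        references = {name: from_template(name, name)
                      for name in REFERENCE_ORDERS}
    results = {name: compare_orders(order, ref)
               for name, ref in sorted(references.items())}
    best = min(results, key=lambda k: (results[k].breakpoints, k))
    tie = sum(1 for r in results.values()
              if r.breakpoints == results[best].breakpoints) > 1
    return best, results[best], tie
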