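"""Synthetic annotated mitogenomes and divergence scenarios with known truth.

The generator emulates the structure of lepidopteran mitogenomes: a
circular ~15 kb molecule with 37 genes (13 PCGs, 22 tRNAs, 2 rRNAs) plus at
least one A+T-rich control region, strongly A+T-biased composition with
negative GC skew, the derived trnM-trnI-trnQ tRNA block, conserved junction
motifs (ATGATAA at atp8/atp6, TCTAA at cox1/trnL2, AAGCCTTA at trnW/trnC,
the ATACTAA trnS2/nad1 spacer), a variable-length A+T-rich trnQ/nad2
spacer, and Table-3-style start/stop codons including incomplete T/TA
stops. Every planted property is recorded in a truth record and re-checked
against the emitted genome before it is returned.

Nucleotide composition is achieved by biased sampling; because PCG bodies
reject stop codons, the sampling distribution is calibrated against the
exact non-stop conditional frequencies so realized composition matches the
target (declared tolerance: A+T ±1 percentage point, skews ±0.03).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._codes import NT, is_stop, revcomp, sense_codons, stop_codons, translate_codon
from .codon_usage import classify_start_stop, split_codons
from .composition import base_composition
from .gene_order import REFERENCE_ORDERS
from .junction_scan import scan_junctions
from .mito_io import AnnotatedMitogenome, GeneFeature

# --------------------------------------------------------------------------
# plans and specs
# --------------------------------------------------------------------------

#: full-codon counts per PCG (start + body [+ stop]); realistic moth sizes
DEFAULT_PCG_CODONS = {
    "nad2": 341, "cox1": 512, "cox2": 229, "atp8": 54, "atp6": 226,
    "cox3": 262, "nad3": 117, "nad5": 574, "nad4": 446, "nad4l": 98,
    "nad6": 175, "cytb": 379, "nad1": 314,
}

#: per-gene (start codon, stop codon or T/TA remnant); a typical Table-3 row
DEFAULT_START_STOP = {
    "nad2": ("ATT", "TAA"), "cox1": ("CGA", "TAA"), "cox2": ("ATG", "T"),
    "atp8": ("ATT", "TAA"), "atp6": ("ATG", "TAA"), "cox3": ("ATG", "TAA"),
    "nad3": ("ATT", "TAA"), "nad5": ("ATT", "TAA"), "nad4": ("ATG", "TA"),
    "nad4l": ("ATG", "TAA"), "nad6": ("ATG", "TAA"), "cytb": ("ATG", "TAA"),
    "nad1": ("ATG", "TAG"),
}


@dataclass
class JunctionPlan:
    relation: str          # overlap | spacer | abutting
    length: int = 0
    motif: str | None = None   # exact sequence (J-strand); None = random
    at_content: float | None = None  # spacer A+T target when random


#: conserved lepidopteran junction structure (J-strand motifs)
DEFAULT_JUNCTIONS = {
    ("atp8", "atp6"): JunctionPlan("overlap", 7, "ATGATAA"),
    ("cox1", "trnL2"): JunctionPlan("overlap", 5, "TCTAA"),
    ("trnW", "trnC"): JunctionPlan("overlap", 8, "AAGCCTTA"),
    ("trnS2", "nad1"): JunctionPlan("spacer", 7, "ATACTAA"),
    ("trnQ", "nad2"): JunctionPlan("spacer", 60, None, at_content=92.0),
}

DEFAULT_RRN_LENGTHS = {"rrnL": 1350, "rrnS": 780}


@dataclass
class GenomeSpec:
    taxon: str = "synthetic"
    template: str = "lepidoptera_typical"
    at_content: float = 80.0
    at_skew: float = 0.01
    gc_skew: float = -0.20
    length_target: int | None = None
    junction_plan: dict[tuple[str, str], JunctionPlan] = field(default_factory=dict)
    start_stop_plan: dict[str, tuple[str, str]] = field(default_factory=dict)
    pcg_codon_counts: dict[str, int] = field(default_factory=dict)
    cr_plan: tuple[tuple[str, str, int], ...] = (("rrnS", "CR", 400),)
    cr_at_bonus: float = 8.0
    trna_len_range: tuple[int, int] = (62, 72)
    rrn_lengths: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_RRN_LENGTHS))
    seed: int = 0
    code_id: int = 5

    def __post_init__(self):
        if not (50.0 <= self.at_content <= 95.0):
            raise ValueError("at_content target outside [50, 95]")
        for s in (self.at_skew, self.gc_skew):
            if not (-1.0 < s < 1.0):
                raise ValueError("skew targets must lie in (−1, 1)")

    def resolved_start_stop(self) -> dict[str, tuple[str, str]]:
        plan = dict(DEFAULT_START_STOP)
        plan.update(self.start_stop_plan)
        missing = set(DEFAULT_PCG_CODONS) - set(plan)
        if missing:
            raise ValueError(f"start/stop plan missing PCGs: {missing}")
        return plan

    def resolved_codon_counts(self) -> dict[str, int]:
        counts = dict(DEFAULT_PCG_CODONS)
        counts.update(self.pcg_codon_counts)
        return counts


TOLERANCE = {"at_content": 1.0, "skew": 0.03}


# --------------------------------------------------------------------------
# composition machinery
# --------------------------------------------------------------------------

def _target_freqs(at_content: float, at_skew: float, gc_skew: float) -> np.ndarray:
    """Nucleotide frequencies (A,C,G,T order) from AT%, AT skew, GC skew."""
    at = at_content / 100.0
    gc = 1.0 - at
    return np.array([
        at * (1.0 + at_skew) / 2.0,
        gc * (1.0 - gc_skew) / 2.0,
        gc * (1.0 + gc_skew) / 2.0,
        at * (1.0 - at_skew) / 2.0,
    ])


def _complement_freqs(freqs: np.ndarray) -> np.ndarray:
    a, c, g, t = freqs
    return np.array([t, g, c, a])


def _nonstop_expected_freqs(q: np.ndarray, code_id: int) -> np.ndarray:
    """Exact nucleotide frequencies of codons sampled iid from q, conditional
    on the codon not being a stop."""
    idx = {b: i for i, b in enumerate(NT)}
    total = 0.0
    nt_mass = np.zeros(4)
    for codon in sense_codons(code_id):
        p = q[idx[codon[0]]] * q[idx[codon[1]]] * q[idx[codon[2]]]
        total += p
        for b in codon:
            nt_mass[idx[b]] += p / 3.0
    return nt_mass / total


def _calibrate_codon_freqs(target: np.ndarray, code_id: int,
                           iters: int = 25) -> np.ndarray:
    """Sampling distribution whose non-stop conditional matches the target."""
    q = target.copy()
    for _ in range(iters):
        e = _nonstop_expected_freqs(q, code_id)
        q = q * target / np.maximum(e, 1e-12)
        q = q / q.sum()
    return q


def _sample_bases(rng: np.random.Generator, n: int, freqs: np.ndarray) -> str:
    idx = rng.choice(4, size=n, p=freqs / freqs.sum())
    return "".join(NT[i] for i in idx)


def _sample_sense_codons(rng: np.random.Generator, n: int, freqs: np.ndarray,
                         code_id: int) -> list[str]:
    stops = stop_codons(code_id)
    out: list[str] = []
    p = freqs / freqs.sum()
    while len(out) < n:
        draw = rng.choice(4, size=(n - len(out) + 8, 3), p=p)
        for row in draw:
            codon = NT[row[0]] + NT[row[1]] + NT[row[2]]
            if codon not in stops:
                out.append(codon)
                if len(out) == n:
                    break
    return out


# --------------------------------------------------------------------------
# genome construction
# --------------------------------------------------------------------------

def _balance_composition(seq: list[str], eligible: set[int],
                         target: np.ndarray, rng) -> None:
    """Flip surplus bases to deficit bases at eligible positions until the
    sequence matches the target counts (to integer rounding)."""
    L = len(seq)
    t = target / target.sum()
    want = np.floor(t * L).astype(int)
    frac = t * L - want
    for i in np.argsort(-frac)[: L - want.sum()]:
        want[i] += 1
    idx = {b: k for k, b in enumerate(NT)}
    counts = np.zeros(4, dtype=int)
    for ch in seq:
        counts[idx[ch]] += 1
    delta = counts - want
    pools: dict[str, list[int]] = {b: [] for b in NT}
    for i in eligible:
        pools[seq[i]].append(i)
    for b in NT:
        pools[b].sort()
        rng.shuffle(pools[b])
    for sb in NT:
        while delta[idx[sb]] > 0 and pools[sb]:
            db = NT[int(np.argmin(delta))]
            if delta[idx[db]] >= 0:
                break
            i = pools[sb].pop()
            seq[i] = db
            delta[idx[sb]] -= 1
            delta[idx[db]] += 1


def _pcg_length(gene: str, counts: dict[str, int], stop: str) -> int:
    if stop in ("TAA", "TAG"):
        return 3 * counts[gene]
    return 3 * counts[gene] + len(stop)


def _build_cds(rng, gene: str, n_codons: int, start: str, stop: str,
               freqs: np.ndarray, code_id: int) -> str:
    if stop in ("TAA", "TAG"):
        body = _sample_sense_codons(rng, n_codons - 2, freqs, code_id)
        return start + "".join(body) + stop
    body = _sample_sense_codons(rng, n_codons - 1, freqs, code_id)
    return start + "".join(body) + stop


class _Gene:
    __slots__ = ("name", "kind", "strand", "seq", "constrained")

    def __init__(self, name, kind, strand, seq):
        self.name = name
        self.kind = kind
        self.strand = strand
        self.seq = list(seq)          # genomic orientation (J-strand)
        self.constrained: set[int] = set()

    def overwrite(self, genomic_index: int, base: str) -> None:
        self.seq[genomic_index] = base
        self.constrained.add(genomic_index)


def _repair_pcg(gene: _Gene, plan_start: str, plan_stop: str,
                reading_freqs: np.ndarray, rng, code_id: int) -> None:
    """Resample unconstrained bases of any in-frame stop introduced by motif
    overwrites; verify the planned start/stop survived."""
    L = len(gene.seq)

    def reading() -> str:
        s = "".join(gene.seq)
        return revcomp(s) if gene.strand == "N" else s

    def genomic_index(ri: int) -> int:
        return L - 1 - ri if gene.strand == "N" else ri

    r = reading()
    if r[:3] != plan_start:
        raise ValueError(f"{gene.name}: junction plan clobbers start codon")
    terminal = r[-len(plan_stop):] if plan_stop in ("T", "TA") else r[-3:]
    if terminal != plan_stop:
        raise ValueError(f"{gene.name}: junction plan clobbers stop codon")
    n_full = L // 3
    last_full = n_full - 1 if plan_stop in ("TAA", "TAG") else n_full
    p = reading_freqs / reading_freqs.sum()
    for j in range(1, last_full):
        for _ in range(200):
            r = reading()
            codon = r[3 * j:3 * j + 3]
            if not is_stop(codon, code_id):
                break
            free = [k for k in range(3)
                    if genomic_index(3 * j + k) not in gene.constrained]
            if not free:
                raise ValueError(f"{gene.name}: fully constrained stop codon "
                                 f"at codon {j}; junction plan infeasible")
            for k in free:
                b = NT[rng.choice(4, p=p)]
                if gene.strand == "N":
                    b = revcomp(b)
                gene.seq[genomic_index(3 * j + k)] = b
        else:
            raise ValueError(f"{gene.name}: cannot repair codon {j}")


def make_genome(spec: GenomeSpec) -> tuple[AnnotatedMitogenome, dict]:
    """Generate one annotated mitogenome plus its ground-truth record.

    Deterministic given the spec's seed; the emitted genome is self-validated
    against every planted property before being returned.
    """
    rng = np.random.default_rng(spec.seed)
    code_id = spec.code_id
    template = [t for t in REFERENCE_ORDERS[spec.template]
                if not t[0].startswith("CR")]
    # insert control regions after their upstream flanks
    tokens: list[tuple[str, str]] = []
    cr_after = {flank: (name, length) for flank, name, length in spec.cr_plan}
    cr_lengths = {name: length for _, name, length in spec.cr_plan}
    for tok in template:
        tokens.append(tok)
        if tok[0] in cr_after:
            tokens.append((cr_after[tok[0]][0], "J"))
    start_stop = spec.resolved_start_stop()
    counts = spec.resolved_codon_counts()

    junctions = {k: replace(v) for k, v in DEFAULT_JUNCTIONS.items()}
    junctions.update({k: replace(v) for k, v in spec.junction_plan.items()})
    adjacent = {(tokens[i][0], tokens[(i + 1) % len(tokens)][0])
                for i in range(len(tokens))}
    junctions = {k: v for k, v in junctions.items() if k in adjacent}

    # ---- length plan --------------------------------------------------
    trna_lens = {name: int(rng.integers(spec.trna_len_range[0],
                                        spec.trna_len_range[1] + 1))
                 for name, _ in tokens if name.startswith("trn")}

    def gene_length(name: str) -> int:
        if name in counts:
            return _pcg_length(name, counts, start_stop[name][1])
        if name.startswith("trn"):
            return trna_lens[name]
        if name in spec.rrn_lengths:
            return spec.rrn_lengths[name]
        return cr_lengths[name]

    spacer_total = sum(p.length for p in junctions.values()
                       if p.relation == "spacer")
    overlap_total = sum(p.length for p in junctions.values()
                        if p.relation == "overlap")
    base_total = (sum(gene_length(n) for n, _ in tokens)
                  + spacer_total - overlap_total)
    if spec.length_target is not None:
        canonical = spec.cr_plan[0][1]
        adjusted = cr_lengths[canonical] + spec.length_target - base_total
        cr_lengths[canonical] = max(200, adjusted)

    # ---- composition targets per region -------------------------------
    target = _target_freqs(spec.at_content, spec.at_skew, spec.gc_skew)
    total_len = (sum(gene_length(n) for n, _ in tokens)
                 + spacer_total - overlap_total)
    # A+T enrichment of CRs and A+T-rich spacers is compensated elsewhere
    # so the whole-genome target is preserved in expectation
    cr_at = min(95.0, spec.at_content + spec.cr_at_bonus)
    rich_mass = sum(cr_lengths.values()) * cr_at
    rich_len = sum(cr_lengths.values())
    for p in junctions.values():
        if p.relation == "spacer" and p.motif is None and p.at_content:
            rich_mass += p.length * p.at_content
            rich_len += p.length
    rest_len = total_len - rich_len
    rest_at = (spec.at_content * total_len - rich_mass) / rest_len
    rest_at = min(95.0, max(50.0, rest_at))
    rest = _target_freqs(rest_at, spec.at_skew, spec.gc_skew)
    cr_freqs = _target_freqs(cr_at, spec.at_skew, spec.gc_skew)
    body_j = _calibrate_codon_freqs(rest, code_id)
    body_n = _calibrate_codon_freqs(_complement_freqs(rest), code_id)

    # ---- per-gene sequences -------------------------------------------
    genes: dict[str, _Gene] = {}
    for name, strand in tokens:
        if name in counts:
            freqs = body_j if strand == "J" else body_n
            cds = _build_cds(rng, name, counts[name], start_stop[name][0],
                             start_stop[name][1], freqs, code_id)
            seq = revcomp(cds) if strand == "N" else cds
            genes[name] = _Gene(name, "PCG", strand, seq)
        else:
            kind = ("control_region" if name in cr_lengths
                    else "rRNA" if name.startswith("rrn") else "tRNA")
            freqs = cr_freqs if kind == "control_region" else rest
            seq = _sample_bases(rng, gene_length(name), freqs)
            genes[name] = _Gene(name, kind, strand, seq)

    # ---- junction constraints -----------------------------------------
    resolved_junctions = []
    for (up, down), plan in sorted(junctions.items()):
        if plan.relation == "overlap":
            k = plan.length
            if k > min(len(genes[up].seq), len(genes[down].seq)):
                raise ValueError(f"overlap {up}/{down} longer than a gene")
            motif = plan.motif or _sample_bases(rng, k, rest)
            if len(motif) != k:
                raise ValueError(f"overlap {up}/{down}: motif length != {k}")
            gu, gd = genes[up], genes[down]
            for i, b in enumerate(motif):
                gu.overwrite(len(gu.seq) - k + i, b)
                gd.overwrite(i, b)
        elif plan.relation == "spacer" and plan.motif is not None:
            if len(plan.motif) != plan.length:
                raise ValueError(f"spacer {up}/{down}: motif length mismatch")
        resolved_junctions.append((up, down, plan))

    for name in counts:
        freqs = body_j if genes[name].strand == "J" else body_n
        _repair_pcg(genes[name], start_stop[name][0], start_stop[name][1],
                    freqs, rng, code_id)

    # ---- assembly ------------------------------------------------------
    plan_for = {(up, down): plan for up, down, plan in resolved_junctions}
    parts: list[str] = []
    features: list[GeneFeature] = []
    cursor = 1
    spacer_record = {}
    for i, (name, strand) in enumerate(tokens):
        g = genes[name]
        seq = "".join(g.seq)
        if i == 0:
            parts.append(seq)
            start = cursor
        else:
            prev = tokens[i - 1][0]
            plan = plan_for.get((prev, name), JunctionPlan("abutting"))
            if plan.relation == "overlap":
                k = plan.length
                assert parts[-1][-k:] == seq[:k]
                parts.append(seq[k:])
                start = cursor - k
            else:
                if plan.relation == "spacer":
                    if plan.motif is not None:
                        spacer = plan.motif
                    else:
                        sf = (_target_freqs(plan.at_content, spec.at_skew,
                                            spec.gc_skew)
                              if plan.at_content else rest)
                        spacer = _sample_bases(rng, plan.length, sf)
                    parts.append(spacer)
                    cursor += len(spacer)
                    spacer_record[(prev, name)] = spacer
                parts.append(seq)
                start = cursor
        end = start + len(seq) - 1
        features.append(GeneFeature(name, g.kind, start, end, strand))
        cursor = end + 1
    sequence = list("".join(parts))

    # balance whole-genome composition to the exact target counts by
    # flipping surplus bases at free (non-PCG, non-motif) positions of
    # tRNA/rRNA/CR genes; sampling noise would otherwise dominate the
    # declared tolerances
    eligible = set()
    for f, (name, _) in zip(features, tokens):
        if genes[name].kind == "PCG":
            continue
        constrained_genomic = {f.start - 1 + i for i in genes[name].constrained}
        eligible.update(set(range(f.start - 1, f.end)) - constrained_genomic)
    _balance_composition(sequence, eligible, target, rng)
    sequence = "".join(sequence)

    genome = AnnotatedMitogenome(taxon=spec.taxon, sequence=sequence,
                                 features=features)
    truth = {
        "taxon": spec.taxon,
        "seed": spec.seed,
        "template": spec.template,
        "targets": {"at_content": spec.at_content, "at_skew": spec.at_skew,
                    "gc_skew": spec.gc_skew},
        "tolerance": dict(TOLERANCE),
        "start_stop": {g: list(start_stop[g]) for g in counts},
        "junctions": [[up, down, p.relation, p.length,
                       p.motif or spacer_record.get((up, down))]
                      for up, down, p in resolved_junctions],
        "control_regions": [[flank, name, cr_lengths[name]]
                            for flank, name, _ in spec.cr_plan],
        "gene_order": [[n, s] for n, s in tokens],
        "length": len(sequence),
    }
    validate_genome(genome, truth, code_id)
    return genome, truth


def validate_genome(genome: AnnotatedMitogenome, truth: dict,
                    code_id: int = 5) -> None:
    """Machine-check every planted property against the emitted genome."""
    from .mito_io import extract_gene_sequence, sorted_features

    order = [(f.name, f.strand) for f in sorted_features(genome)]
    assert order == [tuple(t) for t in truth["gene_order"]], "gene order mismatch"
    kinds = {"PCG": 0, "tRNA": 0, "rRNA": 0, "control_region": 0}
    for f in genome.features:
        kinds[f.kind] += 1
    assert (kinds["PCG"], kinds["tRNA"], kinds["rRNA"]) == (13, 22, 2)
    assert kinds["control_region"] >= 1

    for f in genome.features:
        if f.kind != "PCG":
            continue
        call = classify_start_stop(extract_gene_sequence(genome, f), f.name,
                                   code_id)
        want_start, want_stop = truth["start_stop"][f.name]
        assert call.start_codon == want_start, f"{f.name} start"
        assert call.stop_codon == want_stop, f"{f.name} stop"
        assert not call.has_internal_stop, f"{f.name} internal stop"

    observed = {(j.upstream_gene, j.downstream_gene): j
                for j in scan_junctions(genome)}
    for up, down, relation, length, motif in truth["junctions"]:
        j = observed[(up, down)]
        assert j.relation == relation and j.length == length, (up, down)
        if motif:
            assert j.sequence == motif, (up, down, j.sequence)

    comp = base_composition(genome.sequence)
    t = truth["targets"]
    tol = truth["tolerance"]
    assert abs(comp.at_content - t["at_content"]) <= tol["at_content"], \
        f"AT {comp.at_content:.2f} vs {t['at_content']}"
    assert abs(comp.at_skew - t["at_skew"]) <= tol["skew"]
    assert abs(comp.gc_skew - t["gc_skew"]) <= tol["skew"]


def make_clade(n: int = 17, base: GenomeSpec | None = None, seed: int = 0,
               at_range: tuple[float, float] = (76.0, 81.7),
               spacer_pair: tuple[str, str] = ("trnQ", "nad2"),
               spacer_range: tuple[int, int] = (48, 87),
               motif_overrides: dict[int, dict[tuple[str, str], str]] | None = None,
               taxon_prefix: str = "taxon",
               ) -> list[tuple[AnnotatedMitogenome, dict]]:
    """A panel of genomes sharing the conserved junction plan.

    Per-taxon variation mirrors the study conditions: A+T drawn uniformly
    in ``at_range`` (the observed 76.0–81.7% span), the trnQ/nad2 spacer
    length uniform in ``spacer_range`` (48–87 bp), and optional per-taxon
    motif overrides (e.g. one taxon's trnS2/nad1 spacer mutated) to break
    universality on purpose.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    base = base or GenomeSpec()
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        at = float(rng.uniform(*at_range))
        spacer_len = int(rng.integers(spacer_range[0], spacer_range[1] + 1))
        sub_seed = int(rng.integers(2 ** 31))
        plan = dict(base.junction_plan)
        default_spacer = DEFAULT_JUNCTIONS.get(spacer_pair,
                                               JunctionPlan("spacer", 60))
        plan[spacer_pair] = replace(default_spacer, length=spacer_len)
        for pair, motif in (motif_overrides or {}).get(i, {}).items():
            prev = plan.get(pair) or DEFAULT_JUNCTIONS.get(pair)
            if prev is None:
                raise ValueError(f"no junction to override at {pair}")
            plan[pair] = replace(prev, motif=motif, length=len(motif))
        spec = replace(base, taxon=f"{taxon_prefix}{i:02d}", seed=sub_seed,
                       at_content=at, junction_plan=plan)
        out.append(make_genome(spec))
    return out


# --------------------------------------------------------------------------
# divergence scenarios
# --------------------------------------------------------------------------

@dataclass
class DivergenceSpec:
    """Parameters for codon- or nucleotide-level divergence simulation.

    Codon mode: ``ks``/``ka`` are expected substitutions per synonymous /
    nonsynonymous site over ``n_codons`` codons. Nucleotide mode: ``d`` is
    the expected substitutions per site between adjacent taxa in a chain of
    ``n_taxa`` sequences of ``length`` bp under a TN93 process with
    transition/transversion rate ratios ``kappa1`` (A↔G) and ``kappa2``
    (C↔T) and stationary ``base_freqs`` (A,C,G,T).
    """
    n_codons: int = 500
    ks: float = 0.2
    ka: float = 0.02
    replicates: int = 1
    seed: int = 0
    code_id: int = 5
    length: int = 10000
    d: float = 0.1
    kappa1: float = 4.0
    kappa2: float = 4.0
    base_freqs: tuple[float, float, float, float] = (0.40, 0.10, 0.10, 0.40)
    n_taxa: int = 2


@dataclass
class CodonPairTruth:
    seq_a: str
    seq_b: str
    syn_events: int
    nonsyn_events: int
    syn_sites: float
    nonsyn_sites: float


from functools import lru_cache


@lru_cache(maxsize=None)
def _codon_mutations(codon: str, code_id: int):
    """(synonymous, nonsynonymous) single-nt changes that avoid stops."""
    aa = translate_codon(codon, code_id)
    syn, non = [], []
    for pos in range(3):
        for alt in NT:
            if alt == codon[pos]:
                continue
            mutated = codon[:pos] + alt + codon[pos + 1:]
            if is_stop(mutated, code_id):
                continue
            (syn if translate_codon(mutated, code_id) == aa else non).append(
                (pos, alt))
    return tuple(syn), tuple(non)


def evolve_codons(spec: DivergenceSpec) -> list[CodonPairTruth]:
    """Codon pairs diverged by Poisson-sampled syn/nonsyn events.

    Events are single-nucleotide changes that never create stops; the truth
    records realized event counts and the ancestor's NG86 site counts.
    """
    from .mol_evol import ng86_sites

    out = []
    freqs = _calibrate_codon_freqs(_target_freqs(80.0, 0.0, 0.0), spec.code_id)
    for rep in range(spec.replicates):
        rng = np.random.default_rng([spec.seed, rep])
        ancestor = _sample_sense_codons(rng, spec.n_codons, freqs, spec.code_id)
        syn_sites = sum(ng86_sites(c, spec.code_id)[0] for c in ancestor)
        nonsyn_sites = 3.0 * spec.n_codons - syn_sites
        n_syn = int(rng.poisson(spec.ks * syn_sites))
        n_non = int(rng.poisson(spec.ka * nonsyn_sites))
        derived = list(ancestor)
        events = ["s"] * n_syn + ["n"] * n_non
        rng.shuffle(events)
        weights = np.array([[len(m) for m in _codon_mutations(c, spec.code_id)]
                            for c in derived], dtype=float)
        for kind in events:
            col = 0 if kind == "s" else 1
            # uniform over all candidate mutations of this class
            i = int(rng.choice(len(derived), p=weights[:, col] / weights[:, col].sum()))
            options = _codon_mutations(derived[i], spec.code_id)[col]
            pos, alt = options[rng.integers(len(options))]
            derived[i] = derived[i][:pos] + alt + derived[i][pos + 1:]
            weights[i] = [len(m) for m in _codon_mutations(derived[i], spec.code_id)]
        out.append(CodonPairTruth("".join(ancestor), "".join(derived),
                                  n_syn, n_non, syn_sites, nonsyn_sites))
    return out


def _tn93_generator_matrix(freqs: np.ndarray, kappa1: float,
                           kappa2: float) -> np.ndarray:
    """TN93 rate matrix (A,C,G,T order) scaled to one expected substitution
    per site per unit time."""
    a, c, g, t = freqs
    Q = np.zeros((4, 4))
    rate = {(0, 2): kappa1, (2, 0): kappa1, (1, 3): kappa2, (3, 1): kappa2}
    for i in range(4):
        for j in range(4):
            if i != j:
                Q[i, j] = rate.get((i, j), 1.0) * freqs[j]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(freqs * np.diag(Q)).sum()
    return Q / mu


def evolve_tn93(spec: DivergenceSpec) -> list[dict]:
    """Chains of sequences under a TN93 process.

    Each replicate yields ``n_taxa`` sequences where consecutive taxa are
    separated by expected distance ``d``; truth is the expected pairwise
    distance |i − j|·d.
    """
    from scipy.linalg import expm

    freqs = np.asarray(spec.base_freqs, dtype=float)
    freqs = freqs / freqs.sum()
    Q = _tn93_generator_matrix(freqs, spec.kappa1, spec.kappa2)
    P = expm(Q * spec.d)
    cum = P.cumsum(axis=1)
    out = []
    for rep in range(spec.replicates):
        rng = np.random.default_rng([spec.seed, rep])
        seqs_idx = [rng.choice(4, size=spec.length, p=freqs)]
        for _ in range(spec.n_taxa - 1):
            parent = seqs_idx[-1]
            child = np.empty_like(parent)
            u = rng.random(spec.length)
            for state in range(4):
                mask = parent == state
                child[mask] = np.searchsorted(cum[state], u[mask])
            seqs_idx.append(child)
        seqs = ["".join(NT[i] for i in row) for row in seqs_idx]
        out.append({"taxa": seqs, "d_step": spec.d})
    return out
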