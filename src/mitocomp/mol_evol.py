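"""Pairwise molecular-evolution statistics: NG86 Ka/Ks and TN93 distances.

Ka/Ks follows Nei & Gojobori (1986): synonymous/nonsynonymous site counts
per codon (stop-creating single mutations excluded from the denominator),
substitution counting by equal-weight averaging over minimal mutational
pathways that avoid stop codons, and Jukes–Cantor correction
d = −(3/4)·ln(1 − (4/3)p). Ka/Ks < 1 indicates purifying selection.

TN93 (Tamura & Nei 1993) distinguishes the two transition classes (A↔G,
C↔T) from transversions with empirical base frequencies, and is the
distance against which transition/transversion proportions are plotted to
assess substitution saturation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations, permutations

import numpy as np
import pandas as pd
from scipy import stats

from ._codes import NT, is_stop, sense_codons, translate_codon
from .mito_io import AnnotatedMitogenome, extract_gene_sequence


@dataclass
class PairwiseDivergence:
    label: str
    taxon_a: str
    taxon_b: str
    ka: float | None = None
    ks: float | None = None
    omega: float | None = None  # None when Ks = 0 or saturated
    tn93: float | None = None
    p_transition: float | None = None
    p_transversion: float | None = None
    sites_used: int = 0
    flags: list[str] = field(default_factory=list)


def ng86_sites(codon: str, code_id: int = 5) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts of one sense codon.

    Each position contributes the fraction of its possible single-nucleotide
    mutations that are synonymous; mutations to stop codons are excluded
    from the denominator, so syn + nonsyn = 3 always.
    """
    codon = codon.upper()
    if is_stop(codon, code_id):
        raise ValueError(f"stop codon {codon}")
    aa = translate_codon(codon, code_id)
    syn = 0.0
    for pos in range(3):
        syn_count = 0
        valid = 0
        for alt in NT:
            if alt == codon[pos]:
                continue
            mutated = codon[:pos] + alt + codon[pos + 1:]
            if is_stop(mutated, code_id):
                continue
            valid += 1
            if translate_codon(mutated, code_id) == aa:
                syn_count += 1
        if valid:
            syn += syn_count / valid
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def _sites_table(code_id: int) -> dict[str, tuple[float, float]]:
    return {c: ng86_sites(c, code_id) for c in sense_codons(code_id)}


@lru_cache(maxsize=None)
def _pair_diffs(codon_a: str, codon_b: str, code_id: int) -> tuple[float, float] | None:
    """Mean (synonymous, nonsynonymous) differences between two sense codons.

    Averages with equal weight over all minimal mutational pathways that do
    not pass through a stop codon; None when every pathway does.
    """
    positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not positions:
        return 0.0, 0.0
    path_counts = []
    for perm in permutations(positions):
        current = codon_a
        sd = nd = 0
        ok = True
        for pos in perm:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            if is_stop(nxt, code_id):
                ok = False
                break
            if translate_codon(current, code_id) == translate_codon(nxt, code_id):
                sd += 1
            else:
                nd += 1
            current = nxt
        if ok:
            path_counts.append((sd, nd))
    if not path_counts:
        return None
    sd = sum(p[0] for p in path_counts) / len(path_counts)
    nd = sum(p[1] for p in path_counts) / len(path_counts)
    return sd, nd


def jukes_cantor(p: float) -> float | None:
    """JC69 multiple-hit correction; None when p ≥ 3/4 (saturated)."""
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def _clean_codon_pairs(cds_a: str, cds_b: str, code_id: int):
    if len(cds_a) != len(cds_b):
        raise ValueError("aligned CDSs differ in length")
    n = len(cds_a) // 3 * 3
    pairs = []
    for i in range(0, n, 3):
        ca, cb = cds_a[i:i + 3].upper(), cds_b[i:i + 3].upper()
        if set(ca + cb) - set(NT):
            continue  # gaps / ambiguity
        if is_stop(ca, code_id) or is_stop(cb, code_id):
            continue
        pairs.append((ca, cb))
    return pairs


def pairwise_kaks(cds_a: str, cds_b: str, label: str = "",
                  taxon_a: str = "A", taxon_b: str = "B",
                  code_id: int = 5) -> PairwiseDivergence:
    """NG86 Ka, Ks and omega for an aligned codon pair of sequences.

    Codons containing gaps, ambiguity or stops are excluded; site counts are
    averaged over the two sequences.
    """
    sites = _sites_table(code_id)
    pairs = _clean_codon_pairs(cds_a, cds_b, code_id)
    res = PairwiseDivergence(label=label, taxon_a=taxon_a, taxon_b=taxon_b)
    s_sites = n_sites = sd_total = nd_total = 0.0
    used = 0
    for ca, cb in pairs:
        diffs = _pair_diffs(ca, cb, code_id)
        if diffs is None:
            warnings.warn(f"codon pair {ca}/{cb}: all pathways cross stops; excluded")
            continue
        s_sites += (sites[ca][0] + sites[cb][0]) / 2.0
        n_sites += (sites[ca][1] + sites[cb][1]) / 2.0
        sd_total += diffs[0]
        nd_total += diffs[1]
        used += 1
    res.sites_used = used
    if used == 0:
        res.flags.append("no_usable_codons")
        return res
    ps = sd_total / s_sites if s_sites else 0.0
    pn = nd_total / n_sites if n_sites else 0.0
    res.ks = jukes_cantor(ps)
    res.ka = jukes_cantor(pn)
    if res.ks is None or res.ka is None:
        res.flags.append("saturated")
        res.omega = None
        return res
    if res.ks == 0.0:
        res.flags.append("ks_zero")
        res.omega = None
    else:
        res.omega = res.ka / res.ks
    return res


def gene_panel_kaks(genomes: list[AnnotatedMitogenome], gene: str,
                    code_id: int = 5):
    """All-pairs NG86 summary for one PCG across a taxon panel.

    Equal-length CDSs are stacked in frame (the synthetic generator keeps
    per-gene lengths constant across a clade); unequal pairs are truncated
    to the common codon count with a warning. Returns (summary dict,
    per-pair list).
    """
    carriers = [(g.taxon, extract_gene_sequence(genome=g, feature=f))
                for g in genomes
                for f in [g.get_feature(gene)] if f is not None]
    if len(carriers) < 2:
        return {"gene": gene, "n_pairs": 0, "mean_ka": None,
                "mean_ks": None, "mean_omega": None}, []
    results = []
    for (ta, sa), (tb, sb) in combinations(carriers, 2):
        if len(sa) != len(sb):
            warnings.warn(f"{gene}: unequal CDS lengths for {ta}/{tb}; truncating")
            m = min(len(sa), len(sb)) // 3 * 3
            sa, sb = sa[:m], sb[:m]
        results.append(pairwise_kaks(sa, sb, gene, ta, tb, code_id))
    kas = [r.ka for r in results if r.ka is not None]
    kss = [r.ks for r in results if r.ks is not None]
    oms = [r.omega for r in results if r.omega is not None]
    summary = {
        "gene": gene, "n_pairs": len(results),
        "mean_ka": float(np.mean(kas)) if kas else None,
        "mean_ks": float(np.mean(kss)) if kss else None,
        "mean_omega": float(np.mean(oms)) if oms else None,
    }
    return summary, results


_ACGT_ARR = np.frombuffer(b"ACGT", dtype="S1")


def tn93_distance(seq_a: str, seq_b: str, taxon_a: str = "A",
                  taxon_b: str = "B", label: str = "tn93") -> PairwiseDivergence:
    """Tamura–Nei 1993 distance with transition/transversion proportions.

    Base frequencies are averaged over the two sequences (pairwise-deletion
    convention); sites containing anything but A/C/G/T in either sequence
    are excluded. Log arguments ≤ 0 flag the pair as saturated/undefined.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences differ in length")
    a = np.frombuffer(seq_a.upper().encode(), dtype="S1")
    b = np.frombuffer(seq_b.upper().encode(), dtype="S1")
    valid = np.isin(a, _ACGT_ARR) & np.isin(b, _ACGT_ARR)
    a, b = a[valid], b[valid]
    n = a.size
    res = PairwiseDivergence(label=label, taxon_a=taxon_a, taxon_b=taxon_b,
                             sites_used=int(n))
    if n == 0:
        res.flags.append("no_sites")
        return res
    ai = np.searchsorted(_ACGT_ARR, a)
    bi = np.searchsorted(_ACGT_ARR, b)
    # averaged empirical frequencies, order A C G T
    freq = (np.bincount(ai, minlength=4) + np.bincount(bi, minlength=4)) / (2.0 * n)
    gA, gC, gG, gT = freq
    gR, gY = gA + gG, gC + gT
    pair = ai * 4 + bi
    counts = np.bincount(pair, minlength=16).reshape(4, 4)
    p1 = (counts[0, 2] + counts[2, 0]) / n          # A<->G
    p2 = (counts[1, 3] + counts[3, 1]) / n          # C<->T
    diff = counts.sum() - np.trace(counts)
    q = (diff / n) - p1 - p2                        # transversions
    res.p_transition = float(p1 + p2)
    res.p_transversion = float(q)
    try:
        if gA * gG == 0 or gC * gT == 0 or gR * gY == 0:
            raise ValueError
        w1 = 1.0 - gR * p1 / (2.0 * gA * gG) - q / (2.0 * gR)
        w2 = 1.0 - gY * p2 / (2.0 * gC * gT) - q / (2.0 * gY)
        w3 = 1.0 - q / (2.0 * gR * gY)
        if w1 <= 0 or w2 <= 0 or w3 <= 0:
            raise ValueError
        d = (-(2.0 * gA * gG / gR) * math.log(w1)
             - (2.0 * gC * gT / gY) * math.log(w2)
             - 2.0 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY) * math.log(w3))
    except ValueError:
        res.flags.append("saturated")
        return res
    res.tn93 = float(d)
    return res


def saturation_table(alignment: dict[str, str]):
    """Per-pair transition/transversion proportions vs TN93 distance.

    Returns (DataFrame of per-pair rows, regression dict). Saturated /
    undefined pairs are excluded from the regressions and flagged in the
    table; regressions report slope, intercept and Pearson r of s and v
    against d, supporting (or not) the linearity expected of unsaturated
    data.
    """
    taxa = list(alignment)
    if len(taxa) < 2:
        raise ValueError("need at least two taxa")
    rows = []
    for ta, tb in combinations(taxa, 2):
        r = tn93_distance(alignment[ta], alignment[tb], ta, tb)
        rows.append({"taxon_a": ta, "taxon_b": tb,
                     "s": r.p_transition, "v": r.p_transversion,
                     "tn93": r.tn93, "flagged": "saturated" in r.flags})
    df = pd.DataFrame(rows)
    usable = df[~df["flagged"] & df["tn93"].notna()]
    regression = {}
    if len(usable) >= 3 and usable["tn93"].nunique() > 1:
        for var in ("s", "v"):
            fit = stats.linregress(usable["tn93"], usable[var])
            regression[var] = {"slope": fit.slope, "intercept": fit.intercept,
                               "r": fit.rvalue}
    return df, regression


def p_distance(seq_a: str, seq_b: str) -> float:
    """Proportion of differing sites among pairwise-valid positions."""
    a = np.frombuffer(seq_a.upper().encode(), dtype="S1")
    b = np.frombuffer(seq_b.upper().encode(), dtype="S1")
    valid = np.isin(a, _ACGT_ARR) & np.isin(b, _ACGT_ARR)
    if not valid.any():
        return 0.0
    return float((a[valid] != b[valid]).mean())
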