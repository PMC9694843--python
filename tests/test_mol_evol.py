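import itertools
import math

import numpy as np
import pytest
from Bio.Seq import Seq

from mitocomp._codes import sense_codons
from mitocomp.mol_evol import (jukes_cantor, ng86_sites, p_distance,
                               pairwise_kaks, gene_panel_kaks,
                               saturation_table, tn93_distance)
from mitocomp.synthetic_data import DivergenceSpec, evolve_codons, evolve_tn93


# --- independent NG86 oracle (Biopython translation, path enumeration) ------

def oracle_path_diffs(c1, c2):
    stops = {"TAA", "TAG"}

    def tr(codon):
        return str(Seq(codon).translate(table=5))

    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0
    results = []
    for perm in itertools.permutations(diffs):
        cur, sd, nd = c1, 0, 0
        for pos in perm:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in stops:
                break
            if tr(cur) == tr(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        else:
            results.append((sd, nd))
    if not results:
        return None
    return (sum(r[0] for r in results) / len(results),
            sum(r[1] for r in results) / len(results))


def test_site_conservation_all_sense_codons():
    for codon in sense_codons(5):
        s, n = ng86_sites(codon)
        assert s + n == pytest.approx(3.0)
        assert s >= 0 and n >= 0


def test_fourfold_and_trp_sites():
    s, _ = ng86_sites("GGG")  # Gly: all third-position changes synonymous
    assert s >= 1.0
    s, _ = ng86_sites("TGG")  # Trp in code 5: only TGA synonymous at pos 3
    assert s == pytest.approx(1.0 / 3.0)


def test_stop_codon_input_rejected():
    with pytest.raises(ValueError):
        ng86_sites("TAA")


def test_pathway_counts_match_oracle_up_to_two_diffs():
    from mitocomp.mol_evol import _pair_diffs
    codons = sense_codons(5)
    checked = 0
    for c1 in codons:
        for c2 in codons:
            ndiff = sum(a != b for a, b in zip(c1, c2))
            if ndiff > 2:
                continue
            assert _pair_diffs(c1, c2, 5) == pytest.approx(oracle_path_diffs(c1, c2))
            checked += 1
    assert checked > 1000


def test_identical_sequences_zero_divergence():
    cds = "ATGAAATTTGGG" * 25
    r = pairwise_kaks(cds, cds)
    assert r.ka == 0.0 and r.ks == 0.0
    assert r.omega is None and "ks_zero" in r.flags


def test_single_synonymous_change_matches_hand_value():
    # one third-position GGA->GGG change (Gly, synonymous) in 3 codons
    a, b = "ATGGGACAT", "ATGGGGCAT"
    r = pairwise_kaks(a, b)
    sites = [ng86_sites(c) for c in ("ATG", "GGA", "CAT", "GGG")]
    s_sites = (sites[0][0] + sites[1][0] / 2 + sites[3][0] / 2 + sites[2][0])
    expected_ks = jukes_cantor(1.0 / s_sites)
    assert r.ks == pytest.approx(expected_ks)
    assert r.ka == 0.0


def test_gap_and_stop_codons_excluded():
    a = "ATG---AAATAA" + "CCT"
    b = "ATGTTTAAATAA" + "CCT"
    r = pairwise_kaks(a, b)
    assert r.sites_used == 3  # gap codon and stop codon dropped


def test_length_mismatch_error():
    with pytest.raises(ValueError):
        pairwise_kaks("ATGAAA", "ATGAAATTT")


def test_purifying_selection_simulation():
    pairs = evolve_codons(DivergenceSpec(n_codons=500, ks=0.2, ka=0.02,
                                         replicates=100, seed=101))
    omegas = [pairwise_kaks(p.seq_a, p.seq_b).omega for p in pairs]
    defined = [o for o in omegas if o is not None]
    assert len(defined) >= 95
    assert np.mean([o < 1.0 for o in defined]) >= 0.95
    assert abs(np.mean(defined) - 0.1) / 0.1 < 0.25


def test_gene_panel_ranking_reflects_selection():
    # a toy panel whose cox1 evolved under tight constraint and atp8 under
    # loose constraint must rank atp8's mean omega above cox1's
    from mitocomp.mito_io import AnnotatedMitogenome, GeneFeature
    low = evolve_codons(DivergenceSpec(n_codons=200, ks=0.3, ka=0.01,
                                       replicates=9, seed=5))
    high = evolve_codons(DivergenceSpec(n_codons=50, ks=0.3, ka=0.15,
                                        replicates=9, seed=6))
    seqs_low = [low[0].seq_a] + [p.seq_b for p in low]     # ancestor + derived
    seqs_high = [high[0].seq_a] + [p.seq_b for p in high]
    panel = []
    for i in range(10):
        seq = seqs_low[i] + seqs_high[i]
        feats = [GeneFeature("cox1", "PCG", 1, 600, "J"),
                 GeneFeature("atp8", "PCG", 601, 750, "J")]
        panel.append(AnnotatedMitogenome(f"t{i}", seq, features=feats))
    sum_cox1, _ = gene_panel_kaks(panel, "cox1")
    sum_atp8, _ = gene_panel_kaks(panel, "atp8")
    assert sum_atp8["mean_omega"] > sum_cox1["mean_omega"]


def test_identical_panel_all_zero(clade17):
    g = clade17[0]
    import dataclasses
    twin = dataclasses.replace(g, taxon="twin")
    summary, results = gene_panel_kaks([g, twin], "cox1")
    assert summary["n_pairs"] == 1
    assert results[0].ka == 0.0 and results[0].ks == 0.0


def test_tn93_identical_zero():
    s = "ACGT" * 100
    r = tn93_distance(s, s)
    assert r.tn93 == 0.0
    assert r.p_transition == 0.0 and r.p_transversion == 0.0


def test_tn93_recovery_at_point_one():
    reps = evolve_tn93(DivergenceSpec(length=10000, d=0.1, replicates=20, seed=42))
    errors = [abs(tn93_distance(r["taxa"][0], r["taxa"][1]).tn93 - 0.1)
              for r in reps]
    assert np.median(errors) < 0.01


def test_tn93_recovery_relative_error():
    for d in (0.05, 0.2):
        reps = evolve_tn93(DivergenceSpec(length=10000, d=d, replicates=50,
                                          seed=int(d * 1000)))
        errors = [abs(tn93_distance(r["taxa"][0], r["taxa"][1]).tn93 - d)
                  for r in reps]
        assert np.median(errors) < 0.1 * d


def _k2p(P, Q):
    return -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)


def _jc(p):
    return -0.75 * math.log(1 - 4 * p / 3)


def test_tn93_reduces_to_k2p_and_jc_limits():
    n = 600
    a = "A" * n + "C" * n + "G" * n + "T" * n
    # K2P limit: equal frequencies, both transition classes equal
    x, y = 30, 12  # transitions per block, transversions (2y) per block
    b = ("G" * x + "C" * y + "T" * y + "A" * (n - x - 2 * y)
         + "T" * x + "A" * y + "G" * y + "C" * (n - x - 2 * y)
         + "A" * x + "T" * y + "C" * y + "G" * (n - x - 2 * y)
         + "C" * x + "G" * y + "A" * y + "T" * (n - x - 2 * y))
    r = tn93_distance(a, b)
    P, Q = 4 * x / (4 * n), 8 * y / (4 * n)
    assert r.p_transition == pytest.approx(P)
    assert r.p_transversion == pytest.approx(Q)
    assert r.tn93 == pytest.approx(_k2p(P, Q), abs=1e-9)
    # JC limit: all twelve substitution types equally frequent
    z = 15
    def block(keep, others):
        return others[0] * z + others[1] * z + others[2] * z + keep * (n - 3 * z)
    b2 = (block("A", "CGT") + block("C", "AGT") + block("G", "ACT")
          + block("T", "ACG"))
    r2 = tn93_distance(a, b2)
    p = 12 * z / (4 * n)
    assert r2.tn93 == pytest.approx(_jc(p), abs=1e-9)


def test_tn93_at_least_p_distance():
    for rep in evolve_tn93(DivergenceSpec(length=3000, d=0.15, replicates=20,
                                          seed=9)):
        a, b = rep["taxa"][:2]
        r = tn93_distance(a, b)
        assert r.tn93 is not None
        assert r.tn93 >= p_distance(a, b) - 1e-12


def test_tn93_saturated_flagged():
    a = "A" * 2000
    b = "G" * 2000
    r = tn93_distance(a, b)
    assert r.tn93 is None and "saturated" in r.flags


def test_saturation_table_linearity_and_flags():
    chain = evolve_tn93(DivergenceSpec(length=3000, d=0.02, n_taxa=10,
                                       replicates=1, seed=13))[0]
    aln = {f"t{i}": s for i, s in enumerate(chain["taxa"])}
    df, reg = saturation_table(aln)
    assert len(df) == 45
    assert reg["s"]["r"] > 0.95
    assert reg["v"]["r"] > 0.95
    # identical taxa give a (0, 0, 0) row
    df2, _ = saturation_table({"a": "ACGT" * 50, "b": "ACGT" * 50})
    row = df2.iloc[0]
    assert (row["s"], row["v"], row["tn93"]) == (0.0, 0.0, 0.0)


def test_saturated_rows_excluded_from_regression():
    chain = evolve_tn93(DivergenceSpec(length=2000, d=0.02, n_taxa=6,
                                       replicates=1, seed=14))[0]
    aln = {f"t{i}": s for i, s in enumerate(chain["taxa"])}
    aln["sat"] = "G" * 2000  # hopeless outlier
    df, reg = saturation_table(aln)
    assert df["flagged"].sum() >= 1
    assert reg["s"]["r"] > 0.9  # regression unharmed by flagged rows
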