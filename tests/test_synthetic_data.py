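import numpy as np
import pytest

from mitocomp.mol_evol import ng86_sites, pairwise_kaks, tn93_distance
from mitocomp.synthetic_data import (DivergenceSpec, GenomeSpec, JunctionPlan,
                                     evolve_codons, evolve_tn93, make_clade,
                                     make_genome, validate_genome)


def test_deterministic_given_seed():
    a, ta = make_genome(GenomeSpec(seed=123))
    b, tb = make_genome(GenomeSpec(seed=123))
    assert a.sequence == b.sequence
    assert a.features == b.features
    assert ta == tb
    c, _ = make_genome(GenomeSpec(seed=124))
    assert c.sequence != a.sequence


def test_gene_inventory_and_order(genome_with_truth):
    g, truth = genome_with_truth
    kinds = {}
    for f in g.features:
        kinds[f.kind] = kinds.get(f.kind, 0) + 1
    assert kinds == {"PCG": 13, "tRNA": 22, "rRNA": 2, "control_region": 1}
    names = [f.name for f in g.features]
    block = names[names.index("trnM"):][:3]
    assert block == ["trnM", "trnI", "trnQ"]
    # canonical CR between rrnS and (wrapping) trnM
    assert names[-1] == "CR" and names[-2] == "rrnS"


def test_truth_record_is_self_validating(genome_with_truth):
    g, truth = genome_with_truth
    validate_genome(g, truth)  # must not raise
    # corrupting a planted region (a PCG start codon) must break validation
    import dataclasses
    f = next(x for x in g.features if x.name == "nad2")
    broken = g.sequence[:f.start - 1] + "GGG" + g.sequence[f.start + 2:]
    with pytest.raises(AssertionError):
        validate_genome(dataclasses.replace(g, sequence=broken), truth)


def test_spec_validation():
    with pytest.raises(ValueError):
        GenomeSpec(at_content=40.0)
    with pytest.raises(ValueError):
        GenomeSpec(at_skew=1.5)


def test_infeasible_overlap_errors():
    plan = {("atp8", "atp6"): JunctionPlan("overlap", 400, "A" * 400)}
    with pytest.raises(ValueError, match="longer than a gene"):
        make_genome(GenomeSpec(seed=1, junction_plan=plan))


def test_length_target_adjusts_control_region():
    g, truth = make_genome(GenomeSpec(seed=2, length_target=15500))
    assert abs(g.length - 15500) <= 3
    assert 14000 <= g.length <= 16000


def test_at_content_81_7_recovered():
    from mitocomp.composition import base_composition
    g, _ = make_genome(GenomeSpec(seed=17, at_content=81.7))
    at = base_composition(g.sequence).at_content
    assert 80.7 <= at <= 82.7


def test_clade_spacer_lengths_within_range(clade17):
    from mitocomp.junction_scan import spacer_profile
    prof = spacer_profile(clade17, ("trnQ", "nad2"))
    assert 48 <= prof["min"] and prof["max"] <= 87


def test_clade_identical_specs_give_zero_divergence():
    clade = make_clade(n=2, seed=3, at_range=(80.0, 80.0),
                       spacer_range=(60, 60))
    a, b = clade[0][0], clade[1][0]
    # same spec but different sub-seeds: sequences differ
    assert a.sequence != b.sequence
    # forcing the same seed reproduces the genome exactly
    from dataclasses import replace
    g1, _ = make_genome(GenomeSpec(seed=99))
    g2, _ = make_genome(GenomeSpec(seed=99, taxon="other"))
    assert g1.sequence == g2.sequence


def test_evolve_codons_zero_rates_identical():
    pairs = evolve_codons(DivergenceSpec(n_codons=100, ks=0.0, ka=0.0,
                                         replicates=3, seed=1))
    for p in pairs:
        assert p.seq_a == p.seq_b
        assert p.syn_events == 0 and p.nonsyn_events == 0


def test_evolve_codons_syn_only_gives_zero_ka():
    pairs = evolve_codons(DivergenceSpec(n_codons=300, ks=0.1, ka=0.0,
                                         replicates=5, seed=2))
    for p in pairs:
        r = pairwise_kaks(p.seq_a, p.seq_b)
        assert r.ka == 0.0
        assert p.nonsyn_events == 0


def test_evolve_codons_no_stops_created():
    from mitocomp._codes import is_stop
    pairs = evolve_codons(DivergenceSpec(n_codons=200, ks=0.5, ka=0.2,
                                         replicates=3, seed=4))
    for p in pairs:
        for i in range(0, len(p.seq_b), 3):
            assert not is_stop(p.seq_b[i:i + 3])


def test_evolve_codons_event_counts_near_expectation():
    spec = DivergenceSpec(n_codons=500, ks=0.2, ka=0.02, replicates=50, seed=8)
    pairs = evolve_codons(spec)
    syn = np.mean([p.syn_events for p in pairs])
    expected = 0.2 * np.mean([p.syn_sites for p in pairs])
    assert abs(syn - expected) / expected < 0.15


def test_evolve_tn93_zero_distance_identical():
    reps = evolve_tn93(DivergenceSpec(length=500, d=0.0, replicates=2, seed=5))
    for r in reps:
        assert r["taxa"][0] == r["taxa"][1]


def test_evolve_tn93_deterministic():
    a = evolve_tn93(DivergenceSpec(length=500, d=0.1, replicates=1, seed=6))
    b = evolve_tn93(DivergenceSpec(length=500, d=0.1, replicates=1, seed=6))
    assert a[0]["taxa"] == b[0]["taxa"]


def test_evolve_tn93_transition_heavy():
    reps = evolve_tn93(DivergenceSpec(length=3000, d=0.1, replicates=20,
                                      seed=7, kappa1=4.0, kappa2=4.0))
    heavy = 0
    for r in reps:
        res = tn93_distance(r["taxa"][0], r["taxa"][1])
        heavy += res.p_transition > res.p_transversion
    assert heavy >= 19  # >=95% of replicates
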