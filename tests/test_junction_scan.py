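import dataclasses

import pytest

from mitocomp.junction_scan import (conserved_junctions, locate_control_regions,
                                    scan_junctions, spacer_profile)
from mitocomp.mito_io import AnnotatedMitogenome, GeneFeature, rotate_genome
from mitocomp.synthetic_data import GenomeSpec, JunctionPlan, make_clade, make_genome


def _toy(features, length=40):
    seq = ("ACGT" * (length // 4 + 1))[:length]
    return AnnotatedMitogenome("toy", seq, features=list(features))


def test_overlap_abutting_spacer_relations():
    g = _toy([GeneFeature("a", "tRNA", 1, 10, "J"),
              GeneFeature("b", "tRNA", 8, 20, "J"),
              GeneFeature("c", "tRNA", 21, 30, "J"),
              GeneFeature("d", "tRNA", 36, 40, "J")])
    juncs = {(j.upstream_gene, j.downstream_gene): j for j in scan_junctions(g)}
    assert juncs[("a", "b")].relation == "overlap"
    assert juncs[("a", "b")].length == 3
    assert juncs[("a", "b")].sequence == g.sequence[7:10]
    assert juncs[("b", "c")].relation == "abutting"
    assert juncs[("b", "c")].length == 0
    assert juncs[("c", "d")].relation == "spacer"
    assert juncs[("c", "d")].length == 5


def test_nested_feature_reported_with_warning():
    g = _toy([GeneFeature("big", "rRNA", 1, 30, "J"),
              GeneFeature("inner", "tRNA", 5, 12, "J"),
              GeneFeature("z", "tRNA", 33, 40, "J")])
    with pytest.warns(UserWarning, match="nested"):
        juncs = scan_junctions(g)
    j = next(x for x in juncs if x.downstream_gene == "inner")
    assert j.relation == "overlap" and j.length == 8
    # the covering feature, not the nested one, flanks the next junction
    assert any(x.upstream_gene == "big" and x.downstream_gene == "z"
               for x in juncs)


def test_empty_feature_list_gives_empty_report():
    assert scan_junctions(_toy([])) == []


def test_planted_overlap_motif_recovered(genome):
    juncs = {(j.upstream_gene, j.downstream_gene): j for j in scan_junctions(genome)}
    j = juncs[("atp8", "atp6")]
    assert (j.relation, j.length, j.sequence) == ("overlap", 7, "ATGATAA")
    assert juncs[("cox1", "trnL2")].sequence == "TCTAA"
    assert juncs[("trnW", "trnC")].sequence == "AAGCCTTA"
    assert juncs[("trnS2", "nad1")].relation == "spacer"
    assert juncs[("trnS2", "nad1")].sequence == "ATACTAA"


def test_length_accounting_identity(clade17):
    for g in clade17:
        juncs = scan_junctions(g)
        total = (sum(f.length(g.length) for f in g.features)
                 + sum(j.length for j in juncs if j.relation == "spacer")
                 - sum(j.length for j in juncs if j.relation == "overlap"))
        assert total == g.length


@pytest.mark.parametrize("offset", [1, 500, 7777])
def test_rotation_invariance(genome, offset):
    def key(juncs):
        return sorted((j.upstream_gene, j.downstream_gene, j.relation,
                       j.length, j.sequence) for j in juncs)
    assert key(scan_junctions(genome)) == key(scan_junctions(rotate_genome(genome, offset)))


def test_conserved_junctions_universal_motifs(clade17):
    cons = conserved_junctions(clade17)
    universal = {c.gene_pair: c for c in cons if c.is_universal}
    overlaps = [c for c in universal.values()
                if c.relation == "overlap" and c.motif]
    spacers = [c for c in universal.values()
               if c.relation == "spacer" and c.motif]
    assert {(c.gene_pair, c.motif) for c in overlaps} == {
        (("atp8", "atp6"), "ATGATAA"),
        (("cox1", "trnL2"), "TCTAA"),
        (("trnW", "trnC"), "AAGCCTTA"),
    }
    assert [(c.gene_pair, c.motif) for c in spacers] == [
        (("trnS2", "nad1"), "ATACTAA")]


def test_single_mutation_breaks_universality(clade17_one_mutant):
    cons = conserved_junctions(clade17_one_mutant)
    c = next(x for x in cons if x.gene_pair == ("trnS2", "nad1"))
    assert not c.is_universal
    assert len(c.taxa_supporting) == 16
    assert c.motif == "ATACTAA"  # modal motif still the conserved one


def test_conserved_requires_two_genomes(genome):
    with pytest.raises(ValueError):
        conserved_junctions([genome])


def test_spacer_profile_range_and_composition(clade17):
    prof = spacer_profile(clade17, ("trnQ", "nad2"))
    assert len(prof["per_taxon"]) == 17
    assert 48 <= prof["min"] <= prof["max"] <= 87
    for length, comp in prof["per_taxon"].values():
        assert comp.at_content > 80.0  # planted A+T-rich spacer


def test_spacer_profile_planted_at_content():
    motif = "A" * 29 + "T" * 28 + "GCG"  # 57/60 = 95% A+T
    plan = {("trnQ", "nad2"): JunctionPlan("spacer", 60, motif)}
    g, _ = make_genome(GenomeSpec(seed=3, junction_plan=plan))
    prof = spacer_profile([g], ("trnQ", "nad2"))
    length, comp = prof["per_taxon"][g.taxon]
    assert length == 60
    assert comp.at_content == pytest.approx(95.0)


def test_spacer_profile_absent_pair(clade17):
    prof = spacer_profile(clade17, ("cox1", "nad5"))
    assert prof["per_taxon"] == {} and prof["min"] is None


def test_locate_control_regions_canonical(genome):
    bare = dataclasses.replace(
        genome, features=[f for f in genome.features
                          if f.kind != "control_region"])
    hits = locate_control_regions(bare, min_len=200)
    assert len(hits) == 1
    h = hits[0]
    assert h.canonical
    assert {h.upstream_flank, h.downstream_flank} == {"rrnS", "trnM"}
    assert h.length >= 200


def test_locate_dual_control_regions():
    spec = GenomeSpec(taxon="dual-CR", seed=9,
                      cr_plan=(("rrnS", "CR", 400), ("rrnL", "CR2", 300)))
    g, _ = make_genome(spec)
    bare = dataclasses.replace(
        g, features=[f for f in g.features if f.kind != "control_region"])
    hits = locate_control_regions(bare, min_len=200)
    flank_sets = {frozenset((h.upstream_flank, h.downstream_flank)) for h in hits}
    assert flank_sets == {frozenset({"rrnS", "trnM"}), frozenset({"rrnL", "trnV"})}
    assert sum(h.canonical for h in hits) == 1


def test_locate_control_regions_fully_tiled(genome):
    # with the CR annotated, nothing unannotated remains above threshold
    assert locate_control_regions(genome, min_len=200) == []
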