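import pytest

from mitocomp.synthetic_data import GenomeSpec, make_clade, make_genome


@pytest.fixture(scope="session")
def genome_with_truth():
    """One deterministic lepidopteran-style genome plus its truth record."""
    return make_genome(GenomeSpec(taxon="fixture", seed=42))


@pytest.fixture(scope="session")
def genome(genome_with_truth):
    return genome_with_truth[0]


@pytest.fixture(scope="session")
def clade17():
    """17-taxon panel under the study conditions (all motifs conserved)."""
    return [g for g, _ in make_clade(n=17, seed=11, taxon_prefix="moth")]


@pytest.fixture(scope="session")
def clade17_one_mutant():
    """Same panel size, but one taxon's trnS2/nad1 spacer motif mutated."""
    clade = make_clade(n=17, seed=11, taxon_prefix="moth",
                       motif_overrides={16: {("trnS2", "nad1"): "TTACTAA"}})
    return [g for g, _ in clade]


@pytest.fixture(scope="session")
def small_clade():
    """Five genomes for fast plumbing tests."""
    return make_clade(n=5, seed=7, taxon_prefix="sp")
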