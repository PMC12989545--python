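import pytest

from strainmark.synth import generate_pangenome, random_genome

# a clean 20-mer used to plant primer sites in fixtures:
# GC 55%, self-complementarity 2, no long palindromes
PLANT_PRIMER = "ACAGCACCGAGAGCAAACCT"


@pytest.fixture(scope="session")
def pangenome42():
    """The documented seed-42 pangenome: 4 background strains, 50 core
    families at 95% identity, 5 planted focal-only genes."""
    return generate_pangenome(
        n_background=4, n_core=50, core_identity=0.95,
        n_planted_singletons=5, seed=42,
    )


@pytest.fixture(scope="session")
def target_genome_with_sites():
    """A 5-kb random genome carrying a planted convergent primer-site
    pair: PLANT_PRIMER forward at 1000, its reverse complement ending at
    1400 — a 400-bp product for (PLANT_PRIMER, PLANT_PRIMER)."""
    from strainmark.seqio import GenomeRecord, revcomp

    g = random_genome(5000, seed=11, gid="target")
    seq = list(g.sequence)
    seq[1000:1020] = list(PLANT_PRIMER)
    seq[1380:1400] = list(revcomp(PLANT_PRIMER))
    return GenomeRecord(id="target", sequence="".join(seq))


def assert_no_accidental_sites(genome, primer):
    """Guard helper: fixture genomes must not contain extra near-matches."""
    from strainmark.insilico import find_binding_sites

    return find_binding_sites(primer, genome)
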