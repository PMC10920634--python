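import pytest

from paleocacao import simulate as sim


@pytest.fixture(scope="session")
def cacao_genome():
    """Focal genome: one 20 kb AT-rich chromosome."""
    return {"chr1": sim.synthetic_genome(20000, gc=0.38, seed=101)}


@pytest.fixture(scope="session")
def taxa_genomes(cacao_genome):
    """Multi-taxon genome set: focal, a 5%-diverged sister, two unrelated
    contaminants."""
    herrania = {"h1": sim.related_genome(cacao_genome["chr1"], 0.05, seed=102)}
    return {
        "Theobroma_cacao": cacao_genome,
        "Herrania": herrania,
        "Zea_mays": {"z1": sim.synthetic_genome(5000, gc=0.45, seed=103)},
        "Musa": {"m1": sim.synthetic_genome(5000, gc=0.40, seed=104)},
    }


@pytest.fixture(scope="session")
def taxon_db(taxa_genomes):
    from paleocacao.taxassign import TaxonRecord

    return [
        TaxonRecord(f"{taxon}:{chrom}", taxon, seq)
        for taxon, genome in taxa_genomes.items()
        for chrom, seq in genome.items()
    ]


@pytest.fixture(scope="session")
def small_panel(cacao_genome):
    """3 groups x 100 loci placed on the focal genome."""
    return sim.build_panel(
        n_groups=3, n_loci=100, divergence=0.2, seed=11, genome=cacao_genome
    )


@pytest.fixture(scope="session")
def cacao_panel():
    """The 11-group, 76-accession reference collection shape (no genome)."""
    return sim.build_panel(n_groups=11, n_loci=460, divergence=0.15, seed=12)
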