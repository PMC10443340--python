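import pytest

from microdiv.records import Gene, GenomeRecord, GeneFamilyTable
from microdiv.simulate import SimulationConfig, simulate_pangenome


def make_genome(genome_id: str, genes: dict[str, str], spacer: str = "T" * 60,
                products: dict[str, str] | None = None) -> GenomeRecord:
    """One-contig genome from gene_id -> sequence, spacer-separated."""
    products = products or {}
    contig_id = f"{genome_id}_c1"
    parts, features, pos = [], [], 0
    for gene_id, seq in genes.items():
        parts.append(spacer)
        pos += len(spacer)
        features.append(
            Gene(
                gene_id=gene_id,
                contig_id=contig_id,
                start=pos,
                end=pos + len(seq),
                product=products.get(gene_id, "hypothetical protein"),
            )
        )
        parts.append(seq)
        pos += len(seq)
    parts.append(spacer)
    return GenomeRecord(
        genome_id=genome_id, contigs={contig_id: "".join(parts)}, genes=features
    )


def table_from_truth(truth) -> GeneFamilyTable:
    members = {
        fam: {s: [f"{s}_{fam}"] for s in carriers}
        for fam, carriers in truth.gene_family_truth.items()
    }
    genomes = sorted({s for c in truth.gene_family_truth.values() for s in c})
    return GeneFamilyTable(genome_ids=genomes, members=members)


@pytest.fixture(scope="session")
def small_sim():
    """Five strains, twenty core genes, default rates."""
    cfg = SimulationConfig(
        n_strains=5,
        n_core_genes=20,
        gene_length_range=(300, 600),
        n_unique_genes_per_strain=3,
        seed=11,
    )
    return cfg, *simulate_pangenome(cfg)


@pytest.fixture(scope="session")
def zero_rate_sim():
    """Identical core genes across strains (no substitutions, no accessory)."""
    cfg = SimulationConfig(
        n_strains=4,
        n_core_genes=12,
        gene_length_range=(200, 400),
        base_subst_rate=0.0,
        gain_loss_rate=0.0,
        n_unique_genes_per_strain=0,
        seed=7,
    )
    return cfg, *simulate_pangenome(cfg)


@pytest.fixture
def toy_table():
    """Five families over three genomes: patterns 111, 111, 110, 100, 010."""
    patterns = {
        "fam1": ["g1", "g2", "g3"],
        "fam2": ["g1", "g2", "g3"],
        "fam3": ["g1", "g2"],
        "fam4": ["g1"],
        "fam5": ["g2"],
    }
    members = {
        fam: {g: [f"{g}_{fam}"] for g in carriers}
        for fam, carriers in patterns.items()
    }
    return GeneFamilyTable(genome_ids=["g1", "g2", "g3"], members=members)
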