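import pytest

from imprintscan.design import reciprocal_pair
from imprintscan.genome import Gene, GenomeModel
from imprintscan.synthetic import simulate_dataset


@pytest.fixture(scope="session")
def toy_genome() -> GenomeModel:
    """Ten unit genes on two chromosomes, fixed layout."""
    genes = [Gene(f"g{i}", "chr1" if i <= 6 else "chr2", i * 100, i * 100 + 50) for i in range(1, 11)]
    return GenomeModel([("chr1", 2000), ("chr2", 2000)], genes)


@pytest.fixture(scope="session")
def pair_design():
    return reciprocal_pair("P1", "P2")


@pytest.fixture(scope="session")
def small_dataset():
    """200-gene fully detectable synthetic study (every gene has a SNP and
    reads), reciprocal pair, endosperm + embryo."""
    return simulate_dataset(
        n_chromosomes=2,
        genes_per_chromosome=100,
        n_meg=20,
        n_peg=5,
        n_cluster_pairs=2,
        p_gene_has_snp=1.0,
        p_no_asr_given_snp=0.0,
        seed=11,
    )
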