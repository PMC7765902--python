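"""The synthetic-data generator: determinism, planted structure, and the
statistical contracts downstream stages rely on."""

import numpy as np
import pytest
from scipy import stats

from imprintscan.caller import call_all_genes
from imprintscan.design import reciprocal_pair
from imprintscan.synthetic import (
    generate_genome,
    generate_variants,
    plant_truth,
    simulate_asr_counts,
    simulate_dataset,
    uniform_ordered_genome,
)


def test_generate_genome_structure():
    g = generate_genome(2, 5, 1000, 500, seed=1)
    assert g.n_genes == 10
    for name, _ in g.chromosomes:
        genes = g.genes_on(name)
        assert len(genes) == 5
        for a, b in zip(genes, genes[1:]):
            assert a.end <= b.start  # sorted, non-overlapping


def test_generate_genome_deterministic():
    a = generate_genome(2, 5, 1000, 500, seed=1)
    b = generate_genome(2, 5, 1000, 500, seed=1)
    assert a.chromosomes == b.chromosomes and a.genes == b.genes
    c = generate_genome(2, 5, 1000, 500, seed=2)
    assert a.genes != c.genes


def test_generate_genome_single_gene():
    g = generate_genome(1, 1, 1000, 500, seed=7)
    assert g.n_genes == 1
    assert g.rank(g.genes[0].gene_id) == ("chr1", 0)


@pytest.mark.parametrize("bad", [(0, 5), (2, 0)])
def test_generate_genome_rejects_nonpositive(bad):
    with pytest.raises(ValueError):
        generate_genome(*bad, 1000, 500, seed=1)


def test_variants_p_zero_and_one():
    g = generate_genome(1, 50, 1000, 500, seed=3)
    assert len(generate_variants(g, p_gene_has_snp=0.0, seed=1)) == 0
    vs = generate_variants(g, p_gene_has_snp=1.0, mean_snps_per_informative_gene=2, seed=1)
    covered = vs.genes_with_variants(g)
    assert covered == {gene.gene_id for gene in g.genes}


def test_variants_positions_inside_gene_bodies():
    g = generate_genome(2, 30, 1000, 500, seed=5)
    vs = generate_variants(g, p_gene_has_snp=0.8, indel_rate=0.5, seed=5)
    for v in list(vs.snps) + list(vs.indels):
        gene = g.gene_containing(v.chrom, v.pos)
        assert gene is not None and gene.start <= v.pos < gene.end


def test_snpless_gene_count_within_binomial_interval():
    """With p_gene_has_snp=0.3 on 10,000 genes the SNP-less count must fall
    inside the exact central 99% binomial(10000, 0.7) interval."""
    g = uniform_ordered_genome(10_000, 4)
    vs = generate_variants(g, p_gene_has_snp=0.3, mean_snps_per_informative_gene=1, seed=9)
    snpless = g.n_genes - len(vs.genes_with_variants(g))
    lo, hi = stats.binom.ppf([0.005, 0.995], 10_000, 0.7)
    assert lo <= snpless <= hi


def test_plant_truth_counts_and_baselines():
    g = generate_genome(2, 50, 1000, 500, seed=2)
    t = plant_truth(g, n_meg=5, n_peg=2, n_cluster_pairs=1, seed=3)
    classes = list(t.planted_class.values())
    assert classes.count("MEG") == 5 and classes.count("PEG") == 2
    off_baseline = [gid for gid, f in t.maternal_fraction_endosperm.items() if f != 2 / 3]
    assert len(off_baseline) == 7
    for gid, klass in t.planted_class.items():
        fe = t.maternal_fraction_endosperm[gid]
        if klass == "MEG":
            assert fe > 2 / 3
        elif klass == "PEG":
            assert fe < 2 / 3
        else:
            assert fe == 2 / 3 and t.maternal_fraction_embryo[gid] == 0.5
    # at least one adjacent planted pair exists
    clustered = [gid for gid, flag in t.in_planted_cluster.items() if flag]
    assert len(clustered) == 2
    (c1, r1), (c2, r2) = sorted(g.rank(gid) for gid in clustered)
    assert c1 == c2 and r2 == r1 + 1


def test_plant_truth_none_planted():
    g = generate_genome(1, 10, 1000, 500, seed=1)
    t = plant_truth(g, 0, 0, seed=1)
    assert set(t.planted_class.values()) == {"none"}


def test_plant_truth_infeasible_cluster_demand():
    g = generate_genome(1, 10, 1000, 500, seed=1)
    with pytest.raises(ValueError):
        plant_truth(g, n_meg=2, n_peg=0, n_cluster_pairs=2, seed=1)


def _pooled_share(records, cross_id, tissue, genes):
    m = sum(r.m for r in records if r.cross_id == cross_id and r.tissue == tissue and r.gene_id in genes)
    t = sum(r.m + r.p for r in records if r.cross_id == cross_id and r.tissue == tissue and r.gene_id in genes)
    return m / t


def test_simulated_counts_conservation_and_determinism(small_dataset):
    ds = small_dataset
    for r in ds.records:
        assert r.m >= 0 and r.p >= 0
    again = simulate_asr_counts(
        ds.genome, ds.variants, ds.truth, ds.design,
        mean_depth=100.0, p_no_asr_given_snp=0.0, seed=11,
    )
    assert again == ds.records


def test_baseline_shares_converge(small_dataset):
    """Pooled over many genes, non-imprinted maternal share approaches
    2/3 in endosperm and 1/2 in embryo, in both reciprocal crosses."""
    ds = small_dataset
    background = {g for g, c in ds.truth.planted_class.items() if c == "none"}
    for cross in ds.design.cross_ids():
        assert _pooled_share(ds.records, cross, "endosperm", background) == pytest.approx(2 / 3, abs=0.01)
        assert _pooled_share(ds.records, cross, "embryo", background) == pytest.approx(0.5, abs=0.01)


def test_meg_share_follows_truth_fraction_in_both_crosses(small_dataset):
    """Maternal orientation follows each cross's female parent: a planted
    MEG is maternal-biased in BOTH reciprocal crosses."""
    ds = small_dataset
    megs = {g for g, c in ds.truth.planted_class.items() if c == "MEG"}
    for cross in ds.design.cross_ids():
        assert _pooled_share(ds.records, cross, "endosperm", megs) == pytest.approx(0.95, abs=0.02)


def test_expected_maternal_count_at_depth():
    """MEG with maternal fraction 0.95 at Poisson depth 100: mean maternal
    count ~ 95 over replicates."""
    g = uniform_ordered_genome(1, 1)
    t = plant_truth(g, 1, 0, meg_maternal_fraction=0.95, seed=1)
    design = reciprocal_pair("A", "B", tissues=("endosperm",), replicates=200)
    vs = generate_variants(g, p_gene_has_snp=1.0, seed=1)
    recs = simulate_asr_counts(g, vs, t, design, mean_depth=100, p_no_asr_given_snp=0.0,
                               dispersion=float("inf"), seed=4)
    ms = [r.m for r in recs]
    assert np.mean(ms) == pytest.approx(95, rel=0.05)


def test_full_detectability_when_all_genes_informative(small_dataset):
    """p_gene_has_snp=1 and p_no_asr=0 leaves no ledger losses: every gene
    has positive total ASR in the pooled pair."""
    ds = small_dataset
    totals = {}
    for r in ds.records:
        totals[r.gene_id] = totals.get(r.gene_id, 0) + r.m + r.p
    assert all(v > 0 for v in totals.values())


def test_no_asr_genes_emit_zero_everywhere():
    ds = simulate_dataset(n_chromosomes=1, genes_per_chromosome=200, n_meg=0, n_peg=0,
                          p_gene_has_snp=0.6, p_no_asr_given_snp=0.3, seed=7)
    totals = {}
    for r in ds.records:
        totals[r.gene_id] = totals.get(r.gene_id, 0) + r.m + r.p
    silent = [g for g, v in totals.items() if v == 0]
    assert 0 < len(silent) < ds.genome.n_genes  # both loss modes present


def test_dataset_write_is_deterministic(tmp_path):
    a = simulate_dataset(seed=5, genes_per_chromosome=40)
    b = simulate_dataset(seed=5, genes_per_chromosome=40)
    a.write(tmp_path / "a")
    b.write(tmp_path / "b")
    for name in ("genes.bed", "genes.gff3", "variants.vcf", "truth.tsv", "design.tsv", "asr.tsv"):
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()
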