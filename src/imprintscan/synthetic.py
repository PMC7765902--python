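"""Synthetic data with the statistical structure the analysis assumes.

The generator emulates a reciprocal-cross allele-specific expression
experiment in a cereal seed: a triploid endosperm where non-imprinted genes
show a 2 maternal : 1 paternal read ratio and a diploid embryo with 1:1;
planted MEGs/PEGs with extreme maternal fractions; a fraction of genes with
no parental SNP (undetectable in principle) and a fraction with SNPs but no
covering reads; and optional adjacency clustering of the planted imprinted
genes. Per-gene total allele-specific depth is negative binomial
(configurable dispersion, Poisson in the limit), the maternal/paternal
split binomial at the gene's tissue-specific maternal fraction.

All randomness flows from one seed; each stage derives its own child
generator deterministically, so a fixed seed yields bit-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .asr import GeneASRRecord, write_asr_tsv
from .design import CrossDesign
from .genome import Gene, GenomeModel, write_fasta
from .pseudogenome import Indel, Snp, VariantSet

ENDOSPERM_BASELINE = 2.0 / 3.0
EMBRYO_BASELINE = 0.5
_ALPHABET = "ACGT"


@dataclass
class TruthTable:
    """Ground-truth imprinting status per gene.

    Non-imprinted genes carry the genomic baselines exactly (2/3 endosperm,
    1/2 embryo); planted MEGs have endosperm maternal fractions above 2/3,
    PEGs below.
    """

    planted_class: dict[str, str]  # gene_id -> MEG | PEG | none
    maternal_fraction_endosperm: dict[str, float]
    maternal_fraction_embryo: dict[str, float]
    in_planted_cluster: dict[str, bool] = field(default_factory=dict)

    def fraction(self, gene_id: str, tissue: str) -> float:
        table = (
            self.maternal_fraction_endosperm
            if tissue == "endosperm"
            else self.maternal_fraction_embryo
        )
        return table[gene_id]

    def imprinted_ids(self) -> dict[str, str]:
        return {g: c for g, c in self.planted_class.items() if c != "none"}

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "gene_id\tplanted_class\tmaternal_fraction_endosperm\t"
                "maternal_fraction_embryo\tin_planted_cluster\n"
            )
            for g in sorted(self.planted_class):
                fh.write(
                    f"{g}\t{self.planted_class[g]}\t"
                    f"{self.maternal_fraction_endosperm[g]:.10g}\t"
                    f"{self.maternal_fraction_embryo[g]:.10g}\t"
                    f"{int(self.in_planted_cluster.get(g, False))}\n"
                )


def _child(seed: int | None, stage: int) -> np.random.Generator:
    return np.random.default_rng(None if seed is None else [seed, stage])


def generate_genome(
    n_chromosomes: int,
    genes_per_chromosome: int,
    mean_gene_length: int = 2000,
    mean_intergenic_gap: int = 1000,
    seed: int | None = None,
) -> GenomeModel:
    """Random gene models: exponential-ish gene lengths and gaps laid end
    to end, deterministic for a fixed seed."""
    if n_chromosomes < 1 or genes_per_chromosome < 1:
        raise ValueError("counts must be >= 1")
    if mean_gene_length < 1 or mean_intergenic_gap < 1:
        raise ValueError("sizes must be positive")
    rng = _child(seed, 0)
    chromosomes: list[tuple[str, int]] = []
    genes: list[Gene] = []
    for ci in range(1, n_chromosomes + 1):
        name = f"chr{ci}"
        pos = 0
        for gi in range(1, genes_per_chromosome + 1):
            gap = 1 + rng.poisson(mean_intergenic_gap - 1)
            length = 50 + rng.poisson(max(mean_gene_length - 50, 1))
            start = pos + gap
            end = start + length
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(Gene(f"g{ci:02d}_{gi:05d}", name, start, end, strand))
            pos = end
        chromosomes.append((name, pos + 1 + rng.poisson(mean_intergenic_gap - 1)))
    return GenomeModel(chromosomes, genes)


def uniform_ordered_genome(n_genes: int, n_chromosomes: int = 12) -> GenomeModel:
    """Deterministic ordered genome: ``n_genes`` unit-spaced genes split as
    evenly as possible across chromosomes. Only gene order matters for
    adjacency statistics, so intervals are schematic (1 kb genes, 1 kb gaps).
    """
    if n_genes < 1 or n_chromosomes < 1:
        raise ValueError("counts must be >= 1")
    n_chromosomes = min(n_chromosomes, n_genes)
    base, extra = divmod(n_genes, n_chromosomes)
    chromosomes: list[tuple[str, int]] = []
    genes: list[Gene] = []
    gid = 0
    for ci in range(1, n_chromosomes + 1):
        k = base + (1 if ci <= extra else 0)
        for i in range(k):
            start = 2000 * i + 1000
            genes.append(Gene(f"g{gid:06d}", f"chr{ci}", start, start + 1000))
            gid += 1
        chromosomes.append((f"chr{ci}", 2000 * k + 1000))
    return GenomeModel(chromosomes, genes)


def generate_sequences(genome: GenomeModel, seed: int | None = None) -> dict[str, str]:
    """Uniform-random nucleotide sequence for each chromosome."""
    rng = _child(seed, 5)
    return {
        name: "".join(rng.choice(list(_ALPHABET), size=length))
        for name, length in genome.chromosomes
    }


def generate_variants(
    genome: GenomeModel,
    p_gene_has_snp: float = 0.95,
    mean_snps_per_informative_gene: float = 3.0,
    indel_rate: float = 0.2,
    seed: int | None = None,
    reference: dict[str, str] | None = None,
) -> VariantSet:
    """Parental variants: each gene is informative (carries >= 1 SNP) with
    probability ``p_gene_has_snp``; informative genes get 1 + Poisson extra
    SNPs and Poisson(``indel_rate``) short indels, all inside the gene body.

    When ``reference`` sequences are given, ref alleles match them;
    otherwise a fixed placeholder alphabet is used.
    """
    if not 0.0 <= p_gene_has_snp <= 1.0:
        raise ValueError("p_gene_has_snp must be a probability")
    if mean_snps_per_informative_gene < 0 or indel_rate < 0:
        raise ValueError("rates must be non-negative")
    rng = _child(seed, 1)
    snps: list[Snp] = []
    indels: list[Indel] = []
    for g in genome.genes:
        if rng.random() >= p_gene_has_snp:
            continue
        n_snp = 1 + rng.poisson(max(mean_snps_per_informative_gene - 1, 0.0))
        n_snp = min(n_snp, g.length)
        positions = sorted(rng.choice(g.length, size=n_snp, replace=False) + g.start)
        used = set()
        for pos in positions:
            ref = reference[g.chrom][pos] if reference else "A"
            alt = _ALPHABET[(rng.integers(1, 4) + _ALPHABET.index(ref)) % 4]
            snps.append(Snp(g.chrom, int(pos), ref, alt))
            used.add(int(pos))
        n_indel = rng.poisson(indel_rate)
        for _ in range(n_indel):
            pos = int(rng.integers(g.start, g.end - 2))
            span = {pos, pos + 1}
            if span & used:
                continue
            used |= span
            ref2 = reference[g.chrom][pos : pos + 2] if reference else "AA"
            if rng.random() < 0.5:
                indels.append(Indel(g.chrom, pos, ref2, ref2[0]))  # 1-bp deletion
            else:
                ins = _ALPHABET[rng.integers(0, 4)]
                indels.append(Indel(g.chrom, pos, ref2[0], ref2[0] + ins))
    return VariantSet(snps=snps, indels=indels)


def plant_truth(
    genome: GenomeModel,
    n_meg: int,
    n_peg: int,
    n_cluster_pairs: int = 0,
    meg_maternal_fraction: float = 0.95,
    peg_maternal_fraction: float = 0.10,
    seed: int | None = None,
) -> TruthTable:
    """Plant imprinted genes into a genome's truth table.

    ``n_cluster_pairs`` disjoint adjacent pairs of same-class imprinted
    genes are placed first (maternal-only pairs unless MEGs run out), the
    remaining MEGs/PEGs at random non-adjacent-constraint-free positions.
    Embryo fractions of planted genes are pulled toward the same parent
    (midpoint between the 1/2 baseline and the endosperm fraction).
    """
    n_genes = genome.n_genes
    if n_meg < 0 or n_peg < 0:
        raise ValueError("counts must be non-negative")
    if n_meg + n_peg > n_genes:
        raise ValueError("more imprinted genes requested than genes available")
    if not (peg_maternal_fraction < ENDOSPERM_BASELINE < meg_maternal_fraction):
        raise ValueError("need peg fraction < 2/3 < meg fraction")
    if n_cluster_pairs * 2 > n_meg + n_peg:
        raise ValueError("cluster demand exceeds planted imprinted genes")
    order = genome.gene_ids_in_order()
    # adjacency in rank order, respecting chromosome boundaries
    rank_of = {g: genome.rank(g) for g in order}
    rng = _child(seed, 2)

    remaining = {"MEG": n_meg, "PEG": n_peg}
    chosen: dict[str, str] = {}
    clustered: set[str] = set()
    # place cluster pairs on adjacent index pairs, disjoint
    if n_cluster_pairs:
        candidates = [
            i
            for i in range(len(order) - 1)
            if rank_of[order[i]][0] == rank_of[order[i + 1]][0]
        ]
        rng.shuffle(candidates)
        used_idx: set[int] = set()
        placed = 0
        for i in candidates:
            if placed == n_cluster_pairs:
                break
            if i in used_idx or i + 1 in used_idx:
                continue
            klass = "MEG" if remaining["MEG"] >= 2 else "PEG"
            if remaining[klass] < 2:
                break
            for j in (i, i + 1):
                chosen[order[j]] = klass
                clustered.add(order[j])
                used_idx.update({j - 1, j, j + 1})
            remaining[klass] -= 2
            placed += 1
        if placed < n_cluster_pairs:
            raise ValueError(
                f"could only place {placed} of {n_cluster_pairs} cluster pairs"
            )
    free = [g for g in order if g not in chosen]
    picks = rng.choice(len(free), size=remaining["MEG"] + remaining["PEG"], replace=False)
    for k, idx in enumerate(picks):
        chosen[free[int(idx)]] = "MEG" if k < remaining["MEG"] else "PEG"

    klass = {g: chosen.get(g, "none") for g in order}
    f_endo = {}
    f_emb = {}
    for g in order:
        if klass[g] == "MEG":
            f_endo[g] = meg_maternal_fraction
            f_emb[g] = (EMBRYO_BASELINE + meg_maternal_fraction) / 2
        elif klass[g] == "PEG":
            f_endo[g] = peg_maternal_fraction
            f_emb[g] = (EMBRYO_BASELINE + peg_maternal_fraction) / 2
        else:
            f_endo[g] = ENDOSPERM_BASELINE
            f_emb[g] = EMBRYO_BASELINE
    return TruthTable(klass, f_endo, f_emb, {g: g in clustered for g in order})


def simulate_asr_counts(
    genome: GenomeModel,
    variants: VariantSet,
    truth: TruthTable,
    design: CrossDesign,
    mean_depth: float = 100.0,
    p_no_asr_given_snp: float = 0.07,
    dispersion: float = 10.0,
    seed: int | None = None,
) -> list[GeneASRRecord]:
    """Simulate per-gene maternal/paternal ASR counts for every sample.

    Genes without a parental SNP, and a ``p_no_asr_given_snp`` fraction of
    SNP-bearing genes (no read covered the SNP), emit zero ASR; for the
    rest, each sample's total is NB(mean ``mean_depth``, dispersion k;
    variance mu + mu^2/k, Poisson as k -> inf) and the maternal count is
    binomial at the gene's tissue-specific truth fraction, oriented by the
    cross's female parent.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if not 0.0 <= p_no_asr_given_snp <= 1.0:
        raise ValueError("p_no_asr_given_snp must be a probability")
    if not design.samples:
        raise ValueError("design has no samples")
    for g in truth.planted_class:
        if g not in genome:
            raise ValueError(f"truth table gene {g} absent from genome")
    rng = _child(seed, 3)
    informative = variants.genes_with_variants(genome)
    order = genome.gene_ids_in_order()
    # no-ASR is a gene property (e.g. SNPs sit in an unexpressed region)
    no_asr = {
        g
        for g in order
        if g in informative and rng.random() < p_no_asr_given_snp
    }
    records: list[GeneASRRecord] = []
    for s in design.samples:
        for g in order:
            if g not in informative or g in no_asr:
                records.append(GeneASRRecord(g, s.sample_id, s.cross_id, s.tissue, 0, 0))
                continue
            if math.isinf(dispersion):
                total = int(rng.poisson(mean_depth))
            else:
                total = int(
                    rng.negative_binomial(dispersion, dispersion / (dispersion + mean_depth))
                )
            frac = truth.fraction(g, s.tissue)
            m = int(rng.binomial(total, frac)) if total else 0
            records.append(GeneASRRecord(g, s.sample_id, s.cross_id, s.tissue, m, total - m))
    return records


@dataclass
class SyntheticDataset:
    genome: GenomeModel
    sequences: dict[str, str] | None
    variants: VariantSet
    truth: TruthTable
    design: CrossDesign
    records: list[GeneASRRecord]

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        if self.sequences is not None:
            write_fasta(self.sequences.items(), out / "genome.fa")
        self.genome.write_bed(out / "genes.bed")
        self.genome.write_gff3(out / "genes.gff3")
        from .pseudogenome import write_vcf

        write_vcf(self.variants, out / "variants.vcf", contigs=self.genome.chromosomes)
        self.truth.write_tsv(out / "truth.tsv")
        self.design.write_tsv(out / "design.tsv")
        write_asr_tsv(self.records, out / "asr.tsv")


def simulate_dataset(
    n_chromosomes: int = 2,
    genes_per_chromosome: int = 500,
    n_meg: int = 50,
    n_peg: int = 10,
    n_cluster_pairs: int = 0,
    meg_maternal_fraction: float = 0.95,
    peg_maternal_fraction: float = 0.10,
    p_gene_has_snp: float = 0.95,
    p_no_asr_given_snp: float = 0.07,
    mean_depth: float = 100.0,
    dispersion: float = 10.0,
    design: CrossDesign | None = None,
    seed: int | None = None,
    with_sequences: bool = False,
) -> SyntheticDataset:
    """One call building every piece of a synthetic study."""
    from .design import reciprocal_pair

    genome = generate_genome(n_chromosomes, genes_per_chromosome, seed=seed)
    sequences = generate_sequences(genome, seed=seed) if with_sequences else None
    variants = generate_variants(
        genome, p_gene_has_snp=p_gene_has_snp, seed=seed, reference=sequences
    )
    truth = plant_truth(
        genome,
        n_meg,
        n_peg,
        n_cluster_pairs,
        meg_maternal_fraction,
        peg_maternal_fraction,
        seed=seed,
    )
    if design is None:
        design = reciprocal_pair("P1", "P2")
    records = simulate_asr_counts(
        genome,
        variants,
        truth,
        design,
        mean_depth=mean_depth,
        p_no_asr_given_snp=p_no_asr_given_snp,
        dispersion=dispersion,
        seed=seed,
    )
    return SyntheticDataset(genome, sequences, variants, truth, design, records)
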