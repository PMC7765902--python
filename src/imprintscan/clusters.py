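"""Mini clusters of imprinted genes and the neighbor-permutation null.

A mini cluster is a maximal run of two or more imprinted genes occupying
consecutive positions in a chromosome's gene order — tandemly located with
no intervening annotated gene. The null asks how often randomly selected
genes would sit next to each other by chance: draw n genes uniformly
without replacement from the ordered genome, record the fraction of drawn
genes having at least one drawn immediate rank-neighbor, repeat.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .genome import GenomeModel
from .nulls import NullDistribution

MATERNAL_ONLY = "maternal_only"
PATERNAL_ONLY = "paternal_only"
MATERNAL_PATERNAL = "maternal_paternal"


@dataclass(frozen=True)
class MiniCluster:
    members: tuple[str, ...]  # gene ids in genomic order
    chrom: str
    cluster_type: str

    @property
    def size(self) -> int:
        return len(self.members)


def _cluster_type(classes: Iterable[str]) -> str:
    kinds = set(classes)
    if kinds == {"MEG"}:
        return MATERNAL_ONLY
    if kinds == {"PEG"}:
        return PATERNAL_ONLY
    return MATERNAL_PATERNAL


def find_mini_clusters(
    imprinted: Mapping[str, str], genome: GenomeModel
) -> list[MiniCluster]:
    """Maximal runs of rank-consecutive imprinted genes (>= 2 members).

    ``imprinted`` maps gene_id -> class ("MEG" or "PEG"). Chromosome
    boundaries break adjacency; singleton imprinted genes form no cluster.
    """
    ranked: dict[str, list[tuple[int, str]]] = {}
    for gene_id in imprinted:
        chrom, rank = genome.rank(gene_id)  # raises KeyError for unknown genes
        ranked.setdefault(chrom, []).append((rank, gene_id))
    clusters: list[MiniCluster] = []
    for chrom in sorted(ranked):
        run: list[str] = []
        prev_rank = None
        for rank, gene_id in sorted(ranked[chrom]):
            if prev_rank is not None and rank == prev_rank + 1:
                run.append(gene_id)
            else:
                if len(run) >= 2:
                    clusters.append(
                        MiniCluster(tuple(run), chrom, _cluster_type(imprinted[g] for g in run))
                    )
                run = [gene_id]
            prev_rank = rank
        if len(run) >= 2:
            clusters.append(
                MiniCluster(tuple(run), chrom, _cluster_type(imprinted[g] for g in run))
            )
    return clusters


def clustered_fraction(clusters: Iterable[MiniCluster], n_imprinted: int) -> float:
    """Fraction of imprinted genes that sit in a mini cluster."""
    if n_imprinted <= 0:
        raise ValueError("n_imprinted must be positive")
    return sum(c.size for c in clusters) / n_imprinted


def _chrom_offsets(genome: GenomeModel) -> tuple[np.ndarray, np.ndarray]:
    """Global rank per gene and the chromosome index of each global rank."""
    chrom_idx = []
    for ci, (name, _) in enumerate(genome.chromosomes):
        chrom_idx.extend([ci] * len(genome.genes_on(name)))
    chrom_of = np.asarray(chrom_idx, dtype=np.int64)
    return np.arange(chrom_of.size), chrom_of


def neighbor_fraction(selected_ranks: np.ndarray, chrom_of: np.ndarray) -> float:
    """Fraction of selected genes with a selected immediate rank-neighbor
    on the same chromosome (the statistic the null distributes)."""
    n = selected_ranks.size
    if n == 0:
        raise ValueError("empty selection")
    if n == 1:
        return 0.0
    s = np.sort(selected_ranks)
    adj = (np.diff(s) == 1) & (chrom_of[s[:-1]] == chrom_of[s[1:]])
    in_pair = np.zeros(n, dtype=bool)
    in_pair[:-1] |= adj
    in_pair[1:] |= adj
    return in_pair.sum() / n


def neighbor_null(
    genome: GenomeModel, n_select: int, reps: int = 10_000, seed: int | None = None
) -> NullDistribution:
    """Null distribution of the clustered fraction for random gene draws."""
    n_genes = genome.n_genes
    if n_select < 1 or n_select > n_genes:
        raise ValueError(f"n_select must be in [1, {n_genes}]")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    _, chrom_of = _chrom_offsets(genome)
    rng = np.random.default_rng(seed)
    vals = np.empty(reps)
    for i in range(reps):
        sel = rng.choice(n_genes, n_select, replace=False)
        vals[i] = neighbor_fraction(sel, chrom_of)
    return NullDistribution(vals, seed=seed, meta={"n_select": n_select, "n_genes": n_genes})


def excess_test(
    observed_fraction: float, null: NullDistribution, level: float = 0.95
) -> dict:
    """Does the observed clustered fraction exceed the null's upper bound?"""
    bound = null.upper_bound(level)
    return {
        "observed": observed_fraction,
        "null_upper_bound": bound,
        "level": level,
        "exceeds": observed_fraction > bound,
    }


def write_clusters_tsv(clusters: Iterable[MiniCluster], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tchrom\tmembers\ttype\n")
        for i, c in enumerate(clusters, 1):
            fh.write(f"cluster{i}\t{c.chrom}\t{','.join(c.members)}\t{c.cluster_type}\n")
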