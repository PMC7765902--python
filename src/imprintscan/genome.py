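"""Genome and gene-model containers.

Coordinates are 0-based half-open internally; GFF3 output converts to
1-based closed, BED6 stays 0-based half-open.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeModel:
    """Ordered chromosomes plus sorted, non-overlapping gene intervals.

    Genes carry a per-chromosome rank (their index in start order); rank
    adjacency on the same chromosome is the "no intervening gene" relation
    used by the mini-cluster detector.
    """

    chromosomes: list[tuple[str, int]]
    genes: list[Gene]
    _by_id: dict[str, Gene] = field(init=False, repr=False)
    _rank: dict[str, tuple[str, int]] = field(init=False, repr=False)
    _per_chrom: dict[str, list[Gene]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        chrom_len = dict(self.chromosomes)
        if len(chrom_len) != len(self.chromosomes):
            raise ValueError("duplicate chromosome names")
        per_chrom: dict[str, list[Gene]] = {name: [] for name, _ in self.chromosomes}
        by_id: dict[str, Gene] = {}
        for g in self.genes:
            if g.gene_id in by_id:
                raise ValueError(f"duplicate gene_id {g.gene_id}")
            if g.chrom not in chrom_len:
                raise ValueError(f"gene {g.gene_id}: unknown chromosome {g.chrom}")
            if g.end > chrom_len[g.chrom]:
                raise ValueError(f"gene {g.gene_id} extends past chromosome end")
            by_id[g.gene_id] = g
            per_chrom[g.chrom].append(g)
        rank: dict[str, tuple[str, int]] = {}
        for name, gs in per_chrom.items():
            gs.sort(key=lambda g: g.start)
            prev_end = -1
            for i, g in enumerate(gs):
                if g.start < prev_end:
                    raise ValueError(f"overlapping genes on {name} at {g.gene_id}")
                prev_end = g.end
                rank[g.gene_id] = (name, i)
        object.__setattr__(self, "_by_id", by_id)
        object.__setattr__(self, "_rank", rank)
        object.__setattr__(self, "_per_chrom", per_chrom)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def gene(self, gene_id: str) -> Gene:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene {gene_id}") from None

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def rank(self, gene_id: str) -> tuple[str, int]:
        """(chromosome, rank-in-start-order) for a gene."""
        if gene_id not in self._rank:
            raise KeyError(f"unknown gene {gene_id}")
        return self._rank[gene_id]

    def genes_on(self, chrom: str) -> list[Gene]:
        return list(self._per_chrom[chrom])

    def gene_ids_in_order(self) -> list[str]:
        """All gene ids, chromosome by chromosome in start order."""
        out: list[str] = []
        for name, _ in self.chromosomes:
            out.extend(g.gene_id for g in self._per_chrom[name])
        return out

    def gene_containing(self, chrom: str, pos: int) -> Gene | None:
        gs = self._per_chrom.get(chrom)
        if not gs:
            return None
        starts = [g.start for g in gs]
        i = bisect.bisect_right(starts, pos) - 1
        if i >= 0 and gs[i].start <= pos < gs[i].end:
            return gs[i]
        return None

    # ------------------------------------------------------------------ I/O

    def write_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, _ in self.chromosomes:
                for g in self._per_chrom[name]:
                    fh.write(
                        f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n"
                    )

    def write_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for name, length in self.chromosomes:
                fh.write(f"##sequence-region {name} 1 {length}\n")
            for name, _ in self.chromosomes:
                for g in self._per_chrom[name]:
                    fh.write(
                        f"{g.chrom}\timprintscan\tgene\t{g.start + 1}\t{g.end}\t.\t"
                        f"{g.strand}\t.\tID={g.gene_id}\n"
                    )


def read_bed(path: str | Path, chromosomes: Sequence[tuple[str, int]] | None = None) -> GenomeModel:
    """Load gene models from BED6 (or BED4+). Chromosome lengths default to
    the maximal gene end seen per chromosome when not supplied."""
    genes: list[Gene] = []
    seen: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end, gene_id = parts[0], int(parts[1]), int(parts[2]), parts[3]
            strand = parts[5] if len(parts) > 5 else "+"
            genes.append(Gene(gene_id, chrom, start, end, strand))
            seen[chrom] = max(seen.get(chrom, 0), end)
    if chromosomes is None:
        chromosomes = [(c, L) for c, L in seen.items()]
    return GenomeModel(list(chromosomes), genes)


def write_fasta(sequences: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    import pyfaidx

    fa = pyfaidx.Fasta(str(path), as_raw=True, read_ahead=10_000_000)
    return {name: str(fa[name][:]) for name in fa.keys()}
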