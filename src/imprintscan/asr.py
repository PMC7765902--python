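"""Allele-specific read (ASR) accounting.

An ASR is a read whose parental origin is unambiguous given the informative
SNPs it covers. This module turns allele observations into per-gene
maternal/paternal counts, computes FPKM with the expressed-gene filter
(FPKM > 0.5, strict), and classifies why each gene was or was not callable:
the detectability ledger with categories imprinted / non-significant /
no-SNP (no informative site between the parents) / no-ASR (sites exist but
no read covers them).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .caller import ImprintCall
from .design import CrossDesign

EXPRESSED_FPKM_THRESHOLD = 0.5

#: Detectability ledger categories.
IMPRINTED = "imprinted"
NON_SIGNIFICANT = "non_significant"
NO_SNP = "no_SNP"
NO_ASR = "no_ASR"
LEDGER_CATEGORIES = (IMPRINTED, NON_SIGNIFICANT, NO_SNP, NO_ASR)

ASR_TSV_COLUMNS = ["gene_id", "sample_id", "cross_id", "tissue", "maternal_asr", "paternal_asr"]


@dataclass(frozen=True)
class GeneASRRecord:
    """Maternal (m) and paternal (p) allele-specific read counts for one
    gene in one sample."""

    gene_id: str
    sample_id: str
    cross_id: str
    tissue: str
    m: int
    p: int

    def __post_init__(self) -> None:
        if self.m < 0 or self.p < 0:
            raise ValueError("ASR counts must be non-negative")


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    sample_id: str
    fragment_count: int
    gene_length: int
    fpkm: float


def compute_fpkm(fragment_count: int, gene_length: int, library_size: int) -> float:
    """Fragments per kilobase of exon model per million mapped fragments."""
    if gene_length <= 0:
        raise ValueError("gene_length must be positive")
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    if fragment_count < 0:
        raise ValueError("fragment_count must be non-negative")
    return fragment_count / (gene_length / 1000.0) / (library_size / 1e6)


def filter_expressed(
    records: Iterable[ExpressionRecord], threshold: float = EXPRESSED_FPKM_THRESHOLD
) -> dict[str, set[str]]:
    """Per-sample sets of expressed genes: FPKM strictly above threshold."""
    out: dict[str, set[str]] = {}
    for r in records:
        out.setdefault(r.sample_id, set())
        if r.fpkm > threshold:
            out[r.sample_id].add(r.gene_id)
    return out


def assign_reads(
    observations: Sequence[tuple[str, str, int, str]],
    parent_of_allele: Mapping[int, Mapping[str, str]],
) -> tuple[dict[str, Counter], Counter]:
    """Assign reads to parents from per-site allele observations.

    ``observations`` are ``(read_id, gene_id, snp_position, observed_allele)``
    tuples, one per informative site a read covers. ``parent_of_allele`` maps
    a SNP position to ``{allele: parent_name}``. A read counts for a parent
    only when every covered informative site supports that parent; reads
    supporting both parents are discarded as ``conflicting``, reads with an
    allele matching neither parent as ``other``, and reads covering no
    informative site as ``uninformative``.

    Returns ``(per-gene Counter of parent -> ASR count, discard tallies)``.
    """
    by_read: dict[str, tuple[str, set[str], bool]] = {}
    for read_id, gene_id, pos, allele in observations:
        if pos not in parent_of_allele:
            raise KeyError(f"SNP position {pos} absent from the variant table")
        gene, parents, bad = by_read.get(read_id, (gene_id, set(), False))
        parent = parent_of_allele[pos].get(allele)
        if parent is None:
            bad = True
        else:
            parents.add(parent)
        by_read[read_id] = (gene, parents, bad)

    counts: dict[str, Counter] = {}
    discarded: Counter = Counter()
    for gene, parents, bad in by_read.values():
        if bad:
            discarded["other"] += 1
        elif len(parents) == 1:
            counts.setdefault(gene, Counter())[next(iter(parents))] += 1
        elif len(parents) > 1:
            discarded["conflicting"] += 1
        else:
            discarded["uninformative"] += 1
    return counts, discarded


def tabulate_asr(
    parent_counts: Mapping[tuple[str, str], Mapping[str, int]],
    design: CrossDesign,
    sample_tissue: Mapping[str, str] | None = None,
) -> list[GeneASRRecord]:
    """Orient per-parent counts into maternal/paternal GeneASRRecords.

    ``parent_counts`` maps ``(gene_id, sample_id)`` to per-parent-cultivar
    counts; the sample's cross determines which cultivar is maternal (the
    female parent of the cross).
    """
    sample_cross = {s.sample_id: s for s in design.samples}
    records: list[GeneASRRecord] = []
    for (gene_id, sample_id), by_parent in sorted(parent_counts.items()):
        if sample_id not in sample_cross:
            raise KeyError(f"unknown sample {sample_id!r}")
        s = sample_cross[sample_id]
        cross = design.cross(s.cross_id)
        m = by_parent.get(cross.female_parent, 0)
        p = by_parent.get(cross.male_parent, 0)
        tissue = sample_tissue[sample_id] if sample_tissue else s.tissue
        records.append(GeneASRRecord(gene_id, sample_id, s.cross_id, tissue, m, p))
    return records


def classify_detectability(
    gene_id: str,
    has_variants: bool,
    records: Sequence[GeneASRRecord],
    call: ImprintCall | None,
) -> str:
    """One ledger category per gene per reciprocal pair.

    No informative SNP dominates; then no ASR anywhere in the pair; else the
    caller's verdict decides imprinted vs non-significant. A gene the caller
    left untestable for depth counts as non-significant (it had reads but no
    adequate evidence).
    """
    if not has_variants:
        return NO_SNP
    if all(r.m + r.p == 0 for r in records) or not records:
        return NO_ASR
    if call is not None and call.is_imprinted:
        return IMPRINTED
    return NON_SIGNIFICANT


@dataclass
class DetectabilityLedger:
    """Per-pair partition of assessed genes into the four categories."""

    pair_id: str
    status: dict[str, str]

    def counts(self) -> dict[str, int]:
        c = Counter(self.status.values())
        return {cat: c.get(cat, 0) for cat in LEDGER_CATEGORIES}

    @property
    def n_assessed(self) -> int:
        return len(self.status)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\tpair_id\tstatus\n")
            for gene_id, status in sorted(self.status.items()):
                fh.write(f"{gene_id}\t{self.pair_id}\t{status}\n")


def build_ledger(
    pair_id: str,
    gene_ids: Iterable[str],
    genes_with_snp: set[str],
    records: Sequence[GeneASRRecord],
    calls: Mapping[str, ImprintCall],
) -> DetectabilityLedger:
    by_gene: dict[str, list[GeneASRRecord]] = {}
    for r in records:
        by_gene.setdefault(r.gene_id, []).append(r)
    status = {
        g: classify_detectability(g, g in genes_with_snp, by_gene.get(g, []), calls.get(g))
        for g in gene_ids
    }
    return DetectabilityLedger(pair_id, status)


# ------------------------------------------------------------------ TSV I/O

def read_asr_tsv(path: str | Path) -> list[GeneASRRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "sample_id": str})
    missing = set(ASR_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"ASR table missing columns: {sorted(missing)}")
    return [
        GeneASRRecord(
            r.gene_id, r.sample_id, r.cross_id, r.tissue, int(r.maternal_asr), int(r.paternal_asr)
        )
        for r in df.itertuples(index=False)
    ]


def write_asr_tsv(records: Iterable[GeneASRRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(ASR_TSV_COLUMNS) + "\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{r.sample_id}\t{r.cross_id}\t{r.tissue}\t{r.m}\t{r.p}\n")
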