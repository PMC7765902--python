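"""Pseudo-genome construction and coordinate liftover.

A pseudo-genome is the reference with one parent's homozygous SNPs and
InDels substituted in, so reads from either parent map comparably. The
builder also returns a bidirectional liftover map so positions found on the
pseudo-genome can be transferred back to reference coordinates.

Internally all coordinates are 0-based half-open; VCF I/O converts to and
from the 1-based convention. Heterozygous input is not supported: variants
are taken as fixed differences between the two parental genomes.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

DELETED = "deleted"  #: sentinel returned by lift() for positions with no image


@dataclass(frozen=True)
class Snp:
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str


@dataclass(frozen=True)
class Indel:
    chrom: str
    pos: int  # 0-based start of the replaced reference slice
    ref: str  # replaced reference sequence ("" for pure insertion)
    alt: str  # replacement sequence ("" for pure deletion)

    @property
    def end(self) -> int:
        return self.pos + len(self.ref)


class VariantValidationError(ValueError):
    pass


@dataclass
class VariantSet:
    """Sorted, non-overlapping parental SNPs and InDels.

    Positions are validated against a reference when one is supplied to
    :func:`apply_variants`; construction only checks ordering and overlap.
    """

    snps: list[Snp] = field(default_factory=list)
    indels: list[Indel] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.snps = sorted(self.snps, key=lambda v: (v.chrom, v.pos))
        self.indels = sorted(self.indels, key=lambda v: (v.chrom, v.pos))
        for v in self.snps:
            if len(v.ref) != 1 or len(v.alt) != 1:
                raise VariantValidationError(
                    f"SNP at {v.chrom}:{v.pos} must have single-base alleles"
                )
        last: dict[str, int] = {}
        for chrom, pos, end in sorted(
            [(v.chrom, v.pos, v.pos + 1) for v in self.snps]
            + [(v.chrom, v.pos, max(v.end, v.pos + 1)) for v in self.indels]
        ):
            if pos < last.get(chrom, 0):
                raise VariantValidationError(f"overlapping variants on {chrom} at {pos}")
            last[chrom] = end

    def __len__(self) -> int:
        return len(self.snps) + len(self.indels)

    def by_chrom(self) -> dict[str, list[Snp | Indel]]:
        out: dict[str, list[Snp | Indel]] = {}
        for v in self.snps:
            out.setdefault(v.chrom, []).append(v)
        for v in self.indels:
            out.setdefault(v.chrom, []).append(v)
        for vs in out.values():
            vs.sort(key=lambda v: v.pos)
        return out

    def genes_with_variants(self, genome) -> set[str]:
        """Gene ids whose interval contains at least one variant position."""
        hit: set[str] = set()
        for v in list(self.snps) + list(self.indels):
            g = genome.gene_containing(v.chrom, v.pos)
            if g is not None:
                hit.add(g.gene_id)
        return hit


@dataclass
class _Block:
    ref_start: int
    ref_end: int
    pseudo_start: int

    @property
    def pseudo_end(self) -> int:
        return self.pseudo_start + (self.ref_end - self.ref_start)


@dataclass
class LiftoverMap:
    """Piecewise-constant-offset map between reference and pseudo coordinates.

    Matched blocks tile the preserved reference; deleted reference intervals
    and inserted pseudo intervals have no image and lift to ``DELETED``.
    """

    blocks: dict[str, list[_Block]]
    deleted_ref: dict[str, list[tuple[int, int]]]
    inserted_pseudo: dict[str, list[tuple[int, int]]]
    ref_lengths: dict[str, int]
    pseudo_lengths: dict[str, int]

    def lift(self, chrom: str, pos: int, direction: str = "ref_to_pseudo") -> int | str:
        """Transfer one position between coordinate systems.

        Returns the lifted coordinate, or ``DELETED`` when the position lies
        in a deleted reference interval (forward) or an inserted pseudo
        interval (reverse). Out-of-bounds positions raise ``ValueError``.
        """
        if direction not in ("ref_to_pseudo", "pseudo_to_ref"):
            raise ValueError(f"unknown direction {direction!r}")
        if chrom not in self.blocks:
            raise ValueError(f"unknown chromosome {chrom!r}")
        forward = direction == "ref_to_pseudo"
        bound = (self.ref_lengths if forward else self.pseudo_lengths)[chrom]
        if not (0 <= pos < bound):
            raise ValueError(f"position {pos} outside {chrom} [0, {bound})")
        blocks = self.blocks[chrom]
        if forward:
            starts = [b.ref_start for b in blocks]
            i = bisect.bisect_right(starts, pos) - 1
            if i >= 0 and blocks[i].ref_start <= pos < blocks[i].ref_end:
                return blocks[i].pseudo_start + (pos - blocks[i].ref_start)
            return DELETED
        starts = [b.pseudo_start for b in blocks]
        i = bisect.bisect_right(starts, pos) - 1
        if i >= 0 and blocks[i].pseudo_start <= pos < blocks[i].pseudo_end:
            return blocks[i].ref_start + (pos - blocks[i].pseudo_start)
        return DELETED

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tref_start\tref_end\tpseudo_start\tpseudo_end\n")
            for chrom, blocks in self.blocks.items():
                for b in blocks:
                    fh.write(
                        f"{chrom}\t{b.ref_start}\t{b.ref_end}\t"
                        f"{b.pseudo_start}\t{b.pseudo_end}\n"
                    )


def apply_variants(
    reference: dict[str, str], variants: VariantSet
) -> tuple[dict[str, str], LiftoverMap]:
    """Substitute SNPs and InDels into a reference, producing the pseudo
    sequence and its liftover map.

    Every variant's ref allele is checked against the reference; a mismatch
    raises :class:`VariantValidationError` naming the chromosome and 1-based
    position. For an InDel the common prefix of ref and alt (the VCF anchor
    base) keeps a 1:1 coordinate mapping; the remainder of ref is recorded
    as deleted and the remainder of alt as inserted.
    """
    per_chrom = variants.by_chrom()
    for chrom in per_chrom:
        if chrom not in reference:
            raise VariantValidationError(f"variant on unknown chromosome {chrom!r}")
    pseudo: dict[str, str] = {}
    blocks: dict[str, list[_Block]] = {}
    deleted: dict[str, list[tuple[int, int]]] = {}
    inserted: dict[str, list[tuple[int, int]]] = {}
    ref_lengths = {c: len(s) for c, s in reference.items()}
    pseudo_lengths: dict[str, int] = {}

    for chrom, ref_seq in reference.items():
        out: list[str] = []
        chrom_blocks: list[_Block] = []
        chrom_del: list[tuple[int, int]] = []
        chrom_ins: list[tuple[int, int]] = []
        ref_cursor = 0  # next unconsumed reference base
        pseudo_cursor = 0
        block_ref_start = 0  # start of the open matched block

        def close_block(upto: int) -> None:
            nonlocal pseudo_cursor, block_ref_start
            if upto > block_ref_start:
                chrom_blocks.append(
                    _Block(block_ref_start, upto, pseudo_cursor - (upto - block_ref_start))
                )

        for v in per_chrom.get(chrom, []):
            if isinstance(v, Snp):
                if ref_seq[v.pos] != v.ref:
                    raise VariantValidationError(
                        f"ref mismatch at {chrom}:{v.pos + 1}: "
                        f"expected {v.ref}, reference has {ref_seq[v.pos]}"
                    )
                out.append(ref_seq[ref_cursor : v.pos])
                out.append(v.alt)
                pseudo_cursor += v.pos + 1 - ref_cursor
                ref_cursor = v.pos + 1
                continue
            if ref_seq[v.pos : v.end] != v.ref:
                raise VariantValidationError(
                    f"ref mismatch at {chrom}:{v.pos + 1}: "
                    f"expected {v.ref!r}, reference has {ref_seq[v.pos:v.end]!r}"
                )
            k = 0  # shared prefix length (VCF anchor)
            while k < len(v.ref) and k < len(v.alt) and v.ref[k] == v.alt[k]:
                k += 1
            out.append(ref_seq[ref_cursor : v.pos + k])
            pseudo_cursor += v.pos + k - ref_cursor
            ref_cursor = v.pos + k
            close_block(ref_cursor)
            del_len = len(v.ref) - k
            ins = v.alt[k:]
            if del_len:
                chrom_del.append((ref_cursor, ref_cursor + del_len))
                ref_cursor += del_len
            if ins:
                chrom_ins.append((pseudo_cursor, pseudo_cursor + len(ins)))
                out.append(ins)
                pseudo_cursor += len(ins)
            block_ref_start = ref_cursor

        out.append(ref_seq[ref_cursor:])
        pseudo_cursor += len(ref_seq) - ref_cursor
        close_block(len(ref_seq))
        pseudo[chrom] = "".join(out)
        blocks[chrom] = chrom_blocks
        deleted[chrom] = chrom_del
        inserted[chrom] = chrom_ins
        pseudo_lengths[chrom] = pseudo_cursor
        assert pseudo_cursor == len(pseudo[chrom])

    lift = LiftoverMap(blocks, deleted, inserted, ref_lengths, pseudo_lengths)
    return pseudo, lift


# ------------------------------------------------------------------ VCF I/O

_VCF_HEADER = """##fileformat=VCFv4.2
##source=imprintscan
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(variants: VariantSet, path: str | Path, contigs: Iterable[tuple[str, int]] = ()) -> None:
    """Write SNPs and InDels as minimal VCF 4.2 (1-based)."""
    lines = ["##fileformat=VCFv4.2", "##source=imprintscan"]
    for name, length in contigs:
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    records = [(v.chrom, v.pos, v.ref, v.alt, "SNP") for v in variants.snps] + [
        (v.chrom, v.pos, v.ref, v.alt, "INDEL") for v in variants.indels
    ]
    for chrom, pos, ref, alt, kind in sorted(records):
        # VCF cannot represent empty alleles; this writer requires anchored
        # indels (shared leading base), which VariantSet I/O round-trips.
        if not ref or not alt:
            raise VariantValidationError(
                f"{chrom}:{pos + 1}: VCF output requires anchored (non-empty) alleles"
            )
        lines.append(f"{chrom}\t{pos + 1}\t.\t{ref}\t{alt}\t.\tPASS\tTYPE={kind}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> VariantSet:
    """Read a VCF 4.2 file into a VariantSet (first ALT allele only)."""
    snps: list[Snp] = []
    indels: list[Indel] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, pos, _id, ref, alt = line.split("\t")[:5]
            alt = alt.split(",")[0]
            p = int(pos) - 1
            if len(ref) == 1 and len(alt) == 1:
                snps.append(Snp(chrom, p, ref, alt))
            else:
                indels.append(Indel(chrom, p, ref, alt))
    return VariantSet(snps=snps, indels=indels)
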