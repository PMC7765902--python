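"""Reciprocal-cross experimental design.

A reciprocal pair is two crosses A x B and B x A with the female and male
roles swapped; the female parent is listed first. Samples attach a tissue
(endosperm or embryo) and replicate number to a cross.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

TISSUES = ("endosperm", "embryo")


@dataclass(frozen=True)
class Cross:
    cross_id: str
    female_parent: str
    male_parent: str
    pair_id: str


@dataclass(frozen=True)
class Sample:
    sample_id: str
    cross_id: str
    tissue: str
    replicate: int = 1


@dataclass
class CrossDesign:
    crosses: list[Cross]
    samples: list[Sample]

    def __post_init__(self) -> None:
        by_id = {c.cross_id: c for c in self.crosses}
        if len(by_id) != len(self.crosses):
            raise ValueError("duplicate cross_id")
        pairs: dict[str, list[Cross]] = {}
        for c in self.crosses:
            pairs.setdefault(c.pair_id, []).append(c)
        for pid, cs in pairs.items():
            if len(cs) != 2:
                raise ValueError(f"pair {pid} must contain exactly two crosses")
            a, b = cs
            if not (a.female_parent == b.male_parent and a.male_parent == b.female_parent):
                raise ValueError(f"pair {pid} is not reciprocal")
        for s in self.samples:
            if s.cross_id not in by_id:
                raise ValueError(f"sample {s.sample_id}: unknown cross {s.cross_id}")
            if s.tissue not in TISSUES:
                raise ValueError(f"sample {s.sample_id}: unknown tissue {s.tissue!r}")
        self._by_id = by_id
        self._pairs = pairs

    def cross(self, cross_id: str) -> Cross:
        try:
            return self._by_id[cross_id]
        except KeyError:
            raise KeyError(f"unknown cross {cross_id!r}") from None

    def cross_ids(self) -> list[str]:
        return [c.cross_id for c in self.crosses]

    def pair_ids(self) -> list[str]:
        return list(self._pairs)

    def pair(self, pair_id: str) -> list[Cross]:
        return list(self._pairs[pair_id])

    def samples_of(self, cross_id: str) -> list[Sample]:
        return [s for s in self.samples if s.cross_id == cross_id]

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\tcross_id\tfemale_parent\tmale_parent\tpair_id\ttissue\treplicate\n")
            for s in self.samples:
                c = self.cross(s.cross_id)
                fh.write(
                    f"{s.sample_id}\t{c.cross_id}\t{c.female_parent}\t{c.male_parent}\t"
                    f"{c.pair_id}\t{s.tissue}\t{s.replicate}\n"
                )


def read_design_tsv(path: str | Path) -> CrossDesign:
    crosses: dict[str, Cross] = {}
    samples: list[Sample] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            cid = f[idx["cross_id"]]
            crosses.setdefault(
                cid,
                Cross(cid, f[idx["female_parent"]], f[idx["male_parent"]], f[idx["pair_id"]]),
            )
            samples.append(
                Sample(f[idx["sample_id"]], cid, f[idx["tissue"]], int(f[idx.get("replicate", -1)]) if "replicate" in idx else 1)
            )
    return CrossDesign(list(crosses.values()), samples)


def reciprocal_pair(
    parent_a: str, parent_b: str, pair_id: str = "pair1", tissues: tuple[str, ...] = TISSUES, replicates: int = 1
) -> CrossDesign:
    """Convenience constructor: the standard two-cross reciprocal design."""
    crosses = [
        Cross(f"{parent_a}x{parent_b}", parent_a, parent_b, pair_id),
        Cross(f"{parent_b}x{parent_a}", parent_b, parent_a, pair_id),
    ]
    samples = [
        Sample(f"{c.cross_id}_{t}_r{r}", c.cross_id, t, r)
        for c in crosses
        for t in tissues
        for r in range(1, replicates + 1)
    ]
    return CrossDesign(crosses, samples)
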