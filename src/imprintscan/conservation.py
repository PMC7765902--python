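"""Conservation of imprinted-gene sets.

Two questions: (1) do independently derived imprinted-gene sets share more
genes than random draws from the annotated background would (overlap
permutation null, default background 37,852 annotated genes)? (2) which
imprinted genes have orthologs in another species, scored by the
bidirectional hit rate BHR = Rf x Rr, the product of forward and reverse
best-hit-normalized similarity-score ratios, with conserved pairs defined
by BHR >= 0.95?
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .nulls import NullDistribution

RICE_BACKGROUND_N = 37_852  # genes annotated in the reference annotation
DEFAULT_BHR_THRESHOLD = 0.95


# ------------------------------------------------------------- gene-ID maps

@dataclass
class IdMap:
    """Functional mapping of assembly-specific or legacy gene ids onto the
    canonical annotation's ids; unmapped inputs are reported, not dropped
    silently."""

    table: dict[str, str]

    def canonicalize(self, ids: Iterable[str]) -> tuple[set[str], set[str]]:
        """Returns (canonical ids, inputs with no mapping)."""
        mapped: set[str] = set()
        unmapped: set[str] = set()
        for i in ids:
            if i in self.table:
                mapped.add(self.table[i])
            else:
                unmapped.add(i)
        return mapped, unmapped

    @classmethod
    def from_tsv(cls, path: str | Path) -> "IdMap":
        df = pd.read_csv(path, sep="\t", header=None, names=["source_id", "canonical_id"], dtype=str, comment="#")
        dup = df["source_id"].duplicated()
        if dup.any():
            raise ValueError(f"id map not functional: duplicated source ids {df.loc[dup, 'source_id'].tolist()[:5]}")
        return cls(dict(zip(df["source_id"], df["canonical_id"])))


# ------------------------------------------------------------ set overlaps

def overlap_counts(
    sets: Mapping[str, Iterable[str]], id_map: IdMap | None = None
) -> dict[str, int]:
    """Exact pairwise and k-way intersection counts for 2-3 labeled sets.

    Duplicate ids within a set are collapsed with a warning; keys are
    "label1&label2" for pairs and "&"-joined labels for the k-way count.
    """
    labels = list(sets)
    if not 2 <= len(labels) <= 3:
        raise ValueError("overlap_counts takes two or three sets")
    clean: dict[str, set[str]] = {}
    for lab in labels:
        ids = list(sets[lab])
        if id_map is not None:
            mapped, unmapped = id_map.canonicalize(ids)
            if unmapped:
                warnings.warn(f"set {lab}: {len(unmapped)} ids had no canonical mapping")
            clean[lab] = mapped
        else:
            s = set(ids)
            if len(s) < len(ids):
                warnings.warn(f"set {lab}: {len(ids) - len(s)} duplicate ids collapsed")
            clean[lab] = s
    out: dict[str, int] = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            out[f"{labels[i]}&{labels[j]}"] = len(clean[labels[i]] & clean[labels[j]])
    if len(labels) == 3:
        out["&".join(labels)] = len(clean[labels[0]] & clean[labels[1]] & clean[labels[2]])
    return out


def overlap_null(
    set_sizes: Sequence[int],
    background_n: int,
    reps: int = 10_000,
    seed: int | None = None,
    statistic: str = "pairwise",
    fix_first: bool = False,
) -> NullDistribution:
    """Permutation null of the overlap among random gene sets.

    Each replicate draws the sets independently, uniformly without
    replacement from a background of ``background_n`` genes and records the
    requested statistic: ``pairwise`` (two sets; their intersection size) or
    ``k_way`` (all sets; size of the common intersection). ``fix_first``
    holds the first set constant across replicates and redraws the others —
    statistically near-identical, provided for comparison.
    """
    sizes = list(set_sizes)
    if statistic not in ("pairwise", "k_way"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if statistic == "pairwise" and len(sizes) != 2:
        raise ValueError("pairwise statistic needs exactly two set sizes")
    if len(sizes) < 2:
        raise ValueError("need at least two sets")
    for s in sizes:
        if not 0 < s <= background_n:
            raise ValueError(f"set size {s} not in (0, background {background_n}]")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    vals = np.empty(reps, dtype=np.int64)
    hits = np.zeros(background_n, dtype=np.int16)
    first = rng.choice(background_n, sizes[0], replace=False) if fix_first else None
    for i in range(reps):
        draws = []
        for j, size in enumerate(sizes):
            if fix_first and j == 0:
                draws.append(first)
            else:
                draws.append(rng.choice(background_n, size, replace=False))
        for d in draws:
            hits[d] += 1
        vals[i] = int((hits[draws[0]] == len(sizes)).sum())
        for d in draws:
            hits[d] = 0
    return NullDistribution(
        vals,
        seed=seed,
        meta={"set_sizes": sizes, "background_n": background_n, "statistic": statistic},
    )


def conservation_verdict(
    observed: int, null: NullDistribution, level: float = 0.95
) -> dict:
    """Strict comparison of an observed overlap against the null's
    one-sided upper percentile bound."""
    bound = null.upper_bound(level)
    return {
        "observed": observed,
        "null_upper_bound": bound,
        "level": level,
        "exceeds": observed > bound,
    }


# ------------------------------------------------------------ BHR orthologs

@dataclass(frozen=True)
class BhrPair:
    gene_a: str
    gene_b: str
    rf: float
    rr: float

    @property
    def bhr(self) -> float:
        return self.rf * self.rr


def _score_table(df: pd.DataFrame) -> dict[tuple[str, str], float]:
    """Best score per directed (query, subject) pair."""
    scores: dict[tuple[str, str], float] = {}
    for q, s, sc in zip(df["query"], df["subject"], df["score"]):
        sc = float(sc)
        if sc <= 0:
            raise ValueError(f"non-positive score for {q}->{s}")
        key = (str(q), str(s))
        if sc > scores.get(key, 0.0):
            scores[key] = sc
    return scores


def bhr_match(
    forward_scores: pd.DataFrame,
    reverse_scores: pd.DataFrame,
    threshold: float = DEFAULT_BHR_THRESHOLD,
) -> list[BhrPair]:
    """Conserved gene pairs by bidirectional hit rate.

    ``forward_scores`` holds similarity scores A->B, ``reverse_scores``
    B->A, as DataFrames with columns query/subject/score (BLAST
    outfmt-6-style). For a pair (a, b):

        Rf(a,b) = score_f(a,b) / max_b' score_f(a,b')
        Rr(a,b) = score_r(b,a) / max_a' score_r(b,a')
        BHR     = Rf x Rr, kept iff BHR >= threshold.

    A pair missing from either direction is excluded (a gene with no hits
    in one direction cannot be scored).
    """
    fwd = _score_table(forward_scores)
    rev = _score_table(reverse_scores)
    best_f: dict[str, float] = {}
    for (a, _), sc in fwd.items():
        best_f[a] = max(best_f.get(a, 0.0), sc)
    best_r: dict[str, float] = {}
    for (b, _), sc in rev.items():
        best_r[b] = max(best_r.get(b, 0.0), sc)
    pairs: list[BhrPair] = []
    for (a, b), sc in sorted(fwd.items()):
        rev_sc = rev.get((b, a))
        if rev_sc is None:
            continue
        rf = sc / best_f[a]
        rr = rev_sc / best_r[b]
        if rf * rr >= threshold:
            pairs.append(BhrPair(a, b, rf, rr))
    return pairs


def read_score_tsv(path: str | Path) -> pd.DataFrame:
    """3-column TSV `query subject score` (header optional)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.iloc[0, 0] == "query":
        df = df.iloc[1:]
    df = df.iloc[:, :3]
    df.columns = ["query", "subject", "score"]
    df["score"] = df["score"].astype(float)
    return df


def write_bhr_tsv(pairs: Iterable[BhrPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tRf\tRr\tBHR\n")
        for p in pairs:
            fh.write(f"{p.gene_a}\t{p.gene_b}\t{p.rf:.6g}\t{p.rr:.6g}\t{p.bhr:.6g}\n")
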