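"""Set-overlap permutation nulls and BHR ortholog matching."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from imprintscan.conservation import (
    IdMap,
    bhr_match,
    conservation_verdict,
    overlap_counts,
    overlap_null,
    read_score_tsv,
)
from imprintscan.nulls import NullDistribution


def test_overlap_counts_pairwise_and_triple():
    sets = {"a": ["x", "y", "z"], "b": ["y", "z", "w"], "c": ["z", "w", "v"]}
    out = overlap_counts(sets)
    assert out["a&b"] == 2 and out["a&c"] == 1 and out["b&c"] == 2
    assert out["a&b&c"] == 1


def test_overlap_counts_identical_and_disjoint():
    five = [f"g{i}" for i in range(5)]
    out = overlap_counts({"a": five, "b": five, "c": five})
    assert out["a&b&c"] == 5
    out = overlap_counts({"a": ["1"], "b": ["2"]})
    assert out["a&b"] == 0


def test_overlap_counts_duplicates_warn():
    with pytest.warns(UserWarning):
        out = overlap_counts({"a": ["x", "x", "y"], "b": ["x"]})
    assert out["a&b"] == 1


def test_overlap_counts_with_id_map():
    idmap = IdMap({"legacy1": "G1", "legacy2": "G2"})
    with pytest.warns(UserWarning):  # one unmapped id
        out = overlap_counts({"a": ["legacy1", "junk"], "b": ["legacy1", "legacy2"]}, id_map=idmap)
    assert out["a&b"] == 1


def test_overlap_null_mean_is_hypergeometric():
    """Simulated pairwise-overlap mean within 3 SE of a*b/N."""
    for a, b, n in [(10, 10, 100), (50, 80, 1000)]:
        null = overlap_null([a, b], n, reps=3000, seed=1)
        se = null.values.std(ddof=1) / math.sqrt(null.reps)
        assert abs(null.mean - a * b / n) < 3 * se


def test_overlap_null_full_background_is_degenerate():
    null = overlap_null([20, 20], 20, reps=10, seed=1)
    assert np.all(null.values == 20)


def test_overlap_null_reproducible_and_validated():
    a = overlap_null([5, 5], 50, reps=100, seed=3)
    b = overlap_null([5, 5], 50, reps=100, seed=3)
    assert np.array_equal(a.values, b.values)
    with pytest.raises(ValueError):
        overlap_null([60, 5], 50, reps=10, seed=1)


def test_overlap_null_fix_first_variant_agrees():
    """Fixing the first set and redrawing the others gives the same mean
    (conditional distribution is identical)."""
    a = overlap_null([30, 30], 300, reps=3000, seed=5)
    b = overlap_null([30, 30], 300, reps=3000, seed=5, fix_first=True)
    se = a.values.std(ddof=1) / math.sqrt(a.reps)
    assert abs(a.mean - b.mean) < 4 * se


def test_conservation_verdict_strict():
    null = NullDistribution(np.arange(100))
    bound = null.upper_bound()
    assert conservation_verdict(int(bound), null)["exceeds"] is False
    assert conservation_verdict(int(bound) + 1, null)["exceeds"] is True
    assert conservation_verdict(0, null)["exceeds"] is False


# ------------------------------------------------------------------- BHR

def _table(rows):
    return pd.DataFrame(rows, columns=["query", "subject", "score"])


def test_bhr_mutual_best_hits_kept():
    fwd = _table([("a", "b", 100.0), ("a", "c", 50.0)])
    rev = _table([("b", "a", 200.0), ("b", "c", 40.0)])
    pairs = bhr_match(fwd, rev)
    assert [(p.gene_a, p.gene_b) for p in pairs] == [("a", "b")]
    assert pairs[0].rf == pairs[0].rr == pairs[0].bhr == 1.0


def test_bhr_threshold_arithmetic():
    fwd = _table([("a", "b", 100.0)])
    rev = _table([("b", "a", 90.0), ("b", "z", 100.0)])  # Rr = 0.9
    assert bhr_match(fwd, rev, threshold=0.95) == []
    kept = bhr_match(fwd, rev, threshold=0.9)
    assert len(kept) == 1 and kept[0].bhr == pytest.approx(0.9)


def test_bhr_missing_direction_excluded():
    fwd = _table([("a", "b", 100.0)])
    rev = _table([("c", "a", 100.0)])  # b never queried in reverse
    assert bhr_match(fwd, rev) == []


def _brute_force(fwd, rev, threshold):
    best_f = fwd.groupby("query")["score"].max()
    best_r = rev.groupby("query")["score"].max()
    f = {(q, s): sc for q, s, sc in fwd.itertuples(index=False)}
    r = {(q, s): sc for q, s, sc in rev.itertuples(index=False)}
    kept = set()
    for (a, b), sc in f.items():
        if (b, a) in r:
            bhr = (sc / best_f[a]) * (r[(b, a)] / best_r[b])
            if bhr >= threshold:
                kept.add((a, b))
    return kept


def test_bhr_matches_brute_force_on_3x3():
    """Kept set equals an exhaustive check of all 9 directed pairs, for a
    grid of score matrices and thresholds."""
    rng = np.random.default_rng(12)
    genes_a, genes_b = ["a1", "a2", "a3"], ["b1", "b2", "b3"]
    for trial in range(20):
        fwd = _table([(a, b, float(rng.integers(1, 200))) for a in genes_a for b in genes_b])
        rev = _table([(b, a, float(rng.integers(1, 200))) for b in genes_b for a in genes_a])
        for thr in (0.5, 0.8, 0.95, 1.0):
            ours = {(p.gene_a, p.gene_b) for p in bhr_match(fwd, rev, threshold=thr)}
            assert ours == _brute_force(fwd, rev, thr)


def test_bhr_species_exchange_symmetry():
    rng = np.random.default_rng(3)
    fwd = _table([(f"a{i}", f"b{j}", float(rng.integers(1, 100))) for i in range(3) for j in range(3)])
    rev = _table([(f"b{j}", f"a{i}", float(rng.integers(1, 100))) for j in range(3) for i in range(3)])
    ab = {(p.gene_a, p.gene_b) for p in bhr_match(fwd, rev)}
    ba = {(p.gene_b, p.gene_a) for p in bhr_match(rev, fwd)}
    assert ab == ba


def test_bhr_threshold_monotone():
    rng = np.random.default_rng(7)
    fwd = _table([(f"a{i}", f"b{j}", float(rng.integers(1, 100))) for i in range(4) for j in range(4)])
    rev = _table([(f"b{j}", f"a{i}", float(rng.integers(1, 100))) for j in range(4) for i in range(4)])
    prev: set = set()
    for thr in (1.0, 0.95, 0.8, 0.5, 0.1):
        cur = {(p.gene_a, p.gene_b) for p in bhr_match(fwd, rev, threshold=thr)}
        assert prev <= cur
        prev = cur


def test_score_tsv_reader(tmp_path):
    p = tmp_path / "s.tsv"
    p.write_text("query\tsubject\tscore\na\tb\t12.5\n")
    df = read_score_tsv(p)
    assert list(df.itertuples(index=False)) == [("a", "b", 12.5)]


def test_id_map_rejects_non_functional(tmp_path):
    p = tmp_path / "map.tsv"
    p.write_text("x\tG1\nx\tG2\n")
    with pytest.raises(ValueError):
        IdMap.from_tsv(p)
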