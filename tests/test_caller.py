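"""The chi-square ratio caller: statistic, folds, and reciprocal-pair rules."""

import math

import pytest
from scipy import stats

from imprintscan.asr import GeneASRRecord
from imprintscan.caller import (
    CHI2_CRITICAL,
    call_all_genes,
    call_gene,
    chi_square_ratio_test,
    fold_change,
    summarize_calls,
)


def test_critical_value_is_df1_alpha05_quantile():
    assert CHI2_CRITICAL == pytest.approx(3.84, abs=0.005)
    assert stats.chi2.sf(CHI2_CRITICAL, df=1) == pytest.approx(0.05)


@pytest.mark.parametrize(
    "m,p,share,expected_chi2,expected_sig",
    [
        (200, 100, 2 / 3, 0.0, False),  # exactly the 2m:1p expectation
        (100, 100, 2 / 3, 25.0, True),  # hand formula: (100-400/3)^2/(400/3)+(100-200/3)^2/(200/3)
        (50, 50, 1 / 2, 0.0, False),
    ],
)
def test_chi_square_known_values(m, p, share, expected_chi2, expected_sig):
    chi2, sig = chi_square_ratio_test(m, p, share)
    assert chi2 == pytest.approx(expected_chi2)
    assert sig is expected_sig


def test_chi_square_matches_pearson_exhaustively():
    """Statistic equals scipy's textbook Pearson chi-square for every
    (m, p) with 0 < m+p <= 50, both tissue expectations."""
    for share in (2 / 3, 1 / 2):
        for n in range(1, 51):
            for m in range(n + 1):
                ours, _ = chi_square_ratio_test(m, n - m, share)
                ref = stats.chisquare([m, n - m], f_exp=[n * share, n * (1 - share)]).statistic
                assert ours == pytest.approx(ref, rel=1e-12, abs=1e-12)


def test_chi_square_zero_total_raises():
    with pytest.raises(ValueError):
        chi_square_ratio_test(0, 0, 2 / 3)


@pytest.mark.parametrize(
    "m,p,fmp,fpm",
    [(80, 10, 8.0, 0.125), (10, 0, math.inf, 0.0), (10, 10, 1.0, 1.0), (0, 10, 0.0, math.inf)],
)
def test_fold_change(m, p, fmp, fpm):
    assert fold_change(m, p) == (fmp, fpm)


def _records(gene, per_cross_tissue):
    """per_cross_tissue: {(cross_id, tissue): (m, p)}"""
    return [
        GeneASRRecord(gene, f"{c}_{t}", c, t, m, p)
        for (c, t), (m, p) in per_cross_tissue.items()
    ]


CROSSES = ["AxB", "BxA"]


@pytest.mark.parametrize(
    "counts,expected_class",
    [
        # strong maternal bias both crosses: folds 9 and ~7.3, chi2 significant
        ({("AxB", "endosperm"): (90, 10), ("BxA", "endosperm"): (88, 12)}, "MEG"),
        # exactly the 2:1 expectation in both crosses
        ({("AxB", "endosperm"): (200, 100), ("BxA", "endosperm"): (200, 100)}, "none"),
        # paternal excess: fold_pm = 4 > 1 and chi2 significant
        ({("AxB", "endosperm"): (20, 80), ("BxA", "endosperm"): (20, 80)}, "PEG"),
        # significant in only one cross: no call
        ({("AxB", "endosperm"): (95, 5), ("BxA", "endosperm"): (200, 100)}, "none"),
        # embryo-only maternal evidence (fold > 2, chi2 significant both)
        ({("AxB", "embryo"): (80, 20), ("BxA", "embryo"): (78, 22)}, "MEG"),
    ],
)
def test_call_gene_rules(counts, expected_class):
    call = call_gene("g", _records("g", counts), CROSSES)
    assert call.klass == expected_class


def test_call_requires_both_crosses():
    """No call is ever made from a single cross."""
    call = call_gene("g", _records("g", {("AxB", "endosperm"): (95, 5)}), CROSSES)
    assert call.klass == "none" and not call.testable


def test_call_below_min_depth_untestable():
    counts = {("AxB", "endosperm"): (5, 0), ("BxA", "endosperm"): (4, 1)}
    call = call_gene("g", _records("g", counts), CROSSES, min_total_asr=10)
    assert not call.testable


def test_replicates_pooled_before_testing():
    """Two replicates of (45,5) test as one (90,10) pool."""
    recs = [
        GeneASRRecord("g", f"{c}_r{r}", c, "endosperm", 45, 5)
        for c in CROSSES
        for r in (1, 2)
    ]
    call = call_gene("g", recs, CROSSES)
    assert call.klass == "MEG"
    assert call.stats["AxB"]["endosperm"].m == 90


def test_label_swap_symmetry():
    """Swapping maternal/paternal labels turns a MEG into a PEG-side
    deviation; embryo significance is unchanged (symmetric expectation)."""
    counts = {("AxB", "embryo"): (80, 20), ("BxA", "embryo"): (78, 22)}
    fwd = call_gene("g", _records("g", counts), CROSSES)
    swapped = {k: (p, m) for k, (m, p) in counts.items()}
    rev = call_gene("g", _records("g", swapped), CROSSES)
    assert fwd.klass == "MEG" and rev.klass == "PEG"
    for c in CROSSES:
        assert fwd.stats[c]["embryo"].chi2 == pytest.approx(rev.stats[c]["embryo"].chi2)


def test_endosperm_significance_not_symmetric_under_swap():
    counts = {("AxB", "endosperm"): (200, 100), ("BxA", "endosperm"): (200, 100)}
    fwd = call_gene("g", _records("g", counts), CROSSES)
    swapped = call_gene("g", _records("g", {k: (p, m) for k, (m, p) in counts.items()}), CROSSES)
    assert fwd.stats["AxB"]["endosperm"].chi2 == pytest.approx(0.0)
    assert swapped.stats["AxB"]["endosperm"].chi2 > CHI2_CRITICAL


def test_summarize_calls():
    recs = []
    for g, (m, p) in {"a": (90, 10), "b": (95, 5), "c": (88, 12), "d": (20, 80)}.items():
        recs += _records(g, {("AxB", "endosperm"): (m, p), ("BxA", "endosperm"): (m, p)})
    recs += _records("e", {("AxB", "endosperm"): (200, 100), ("BxA", "endosperm"): (200, 100)})
    calls = call_all_genes(recs, CROSSES)
    summary = summarize_calls(calls.values())
    assert summary["endosperm"] == {"total": 4, "MEG": 3, "PEG": 1}
    assert summary["embryo"] == {"total": 0, "MEG": 0, "PEG": 0}


def test_summarize_no_calls_is_zeros():
    assert summarize_calls([]) == {
        "endosperm": {"total": 0, "MEG": 0, "PEG": 0},
        "embryo": {"total": 0, "MEG": 0, "PEG": 0},
    }
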