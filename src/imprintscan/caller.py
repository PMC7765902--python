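"""The imprinting caller.

Per gene and tissue, allele-specific reads pooled over replicates of each
cross are tested against the genomic expectation — 2 maternal : 1 paternal
in the triploid endosperm, 1:1 in the diploid embryo — with a one-degree
Pearson chi-square goodness-of-fit test. A gene is called a MEG
(maternally expressed gene) when, in BOTH crosses of a reciprocal pair, the
deviation is significant (chi2 > 3.84, p < 0.05) and the maternal:paternal
fold change exceeds 4 in endosperm or 2 in embryo; a PEG when the
paternal:maternal fold change exceeds 1 in endosperm or 2 in embryo with
the same significance requirement. Requiring both reciprocal crosses
separates imprinting from cis-regulatory (genotype-linked) allelic bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from scipy import stats

#: Exact chi-square df=1, alpha=0.05 critical value (~3.8415); calls use
#: strict ">" so a statistic of exactly 3.84 is not significant.
CHI2_CRITICAL: float = float(stats.chi2.ppf(0.95, df=1))

ENDOSPERM_MATERNAL_SHARE = 2.0 / 3.0  # 2 maternal : 1 paternal genome copies
EMBRYO_MATERNAL_SHARE = 0.5

#: Expected maternal share of allele-specific reads per tissue.
EXPECTED_SHARE: dict[str, float] = {
    "endosperm": ENDOSPERM_MATERNAL_SHARE,
    "embryo": EMBRYO_MATERNAL_SHARE,
}

#: Fold-change thresholds (strict ">") per tissue.
MEG_FOLD = {"endosperm": 4.0, "embryo": 2.0}
PEG_FOLD = {"endosperm": 1.0, "embryo": 2.0}

DEFAULT_MIN_TOTAL_ASR = 10


def chi_square_ratio_test(
    m: int, p: int, expected_m_share: float, critical: float = CHI2_CRITICAL
) -> tuple[float, bool]:
    """Pearson chi-square of observed (m, p) against an expected maternal
    share, df=1, no continuity correction.

    Returns ``(chi2, significant)``. ``m + p == 0`` is not testable and
    raises ``ValueError`` — callers route such genes to the no-ASR ledger
    category instead of testing them.
    """
    n = m + p
    if n <= 0:
        raise ValueError("chi-square ratio test requires m + p > 0")
    if not (0.0 < expected_m_share < 1.0):
        raise ValueError("expected maternal share must be in (0, 1)")
    em = n * expected_m_share
    ep = n - em
    chi2 = (m - em) ** 2 / em + (p - ep) ** 2 / ep
    return chi2, chi2 > critical


def fold_change(m: int, p: int) -> tuple[float, float]:
    """(m/p, p/m) with ``math.inf`` standing in for division by zero, so a
    parent with zero reads passes any finite threshold on the other side."""
    if m + p <= 0:
        raise ValueError("fold change requires m + p > 0")
    fold_mp = math.inf if p == 0 else m / p
    fold_pm = math.inf if m == 0 else p / m
    return fold_mp, fold_pm


@dataclass(frozen=True)
class TissueStats:
    """Test results for one cross x tissue (replicates pooled)."""

    m: int
    p: int
    chi2: float
    significant: bool
    fold_mp: float
    fold_pm: float


@dataclass
class ImprintCall:
    gene_id: str
    klass: str  # MEG | PEG | none
    tissue_evidence: str | None  # endosperm | embryo | both | None
    stats: dict[str, dict[str, TissueStats]]  # cross_id -> tissue -> stats
    testable: bool = True
    conflict: bool = False  # MEG and PEG rules both satisfied (via different tissues)

    @property
    def is_imprinted(self) -> bool:
        return self.klass in ("MEG", "PEG")


def _pool(records: Iterable, design) -> dict[tuple[str, str], tuple[int, int]]:
    """Sum replicate counts to (cross_id, tissue) -> (m, p)."""
    pooled: dict[tuple[str, str], tuple[int, int]] = {}
    for r in records:
        key = (r.cross_id, r.tissue)
        m0, p0 = pooled.get(key, (0, 0))
        pooled[key] = (m0 + r.m, p0 + r.p)
    return pooled


def call_gene(
    gene_id: str,
    records: Iterable,
    design,
    min_total_asr: int = DEFAULT_MIN_TOTAL_ASR,
    critical: float = CHI2_CRITICAL,
    meg_fold: Mapping[str, float] = MEG_FOLD,
    peg_fold: Mapping[str, float] = PEG_FOLD,
) -> ImprintCall:
    """Classify one gene from its ASR records across a reciprocal pair.

    ``records`` are maternal/paternal-oriented counts (any object with
    ``cross_id``, ``tissue``, ``m``, ``p``); ``design`` supplies the two
    cross ids of the pair. A tissue is testable only when both crosses have
    at least ``min_total_asr`` reads in it; a gene with no testable tissue
    is returned untestable (class ``none``).
    """
    cross_ids = design.cross_ids() if hasattr(design, "cross_ids") else list(design)
    if len(cross_ids) != 2:
        raise ValueError("a reciprocal pair must contain exactly two crosses")
    pooled = _pool(records, design)
    stats_by_cross: dict[str, dict[str, TissueStats]] = {c: {} for c in cross_ids}
    meg_tissues: list[str] = []
    peg_tissues: list[str] = []
    any_testable = False
    for tissue, share in EXPECTED_SHARE.items():
        per_cross = []
        for c in cross_ids:
            mp = pooled.get((c, tissue))
            if mp is None or mp[0] + mp[1] < min_total_asr:
                per_cross = []
                break
            per_cross.append((c, mp))
        if not per_cross:
            continue
        any_testable = True
        meg_ok = peg_ok = True
        for c, (m, p) in per_cross:
            chi2, sig = chi_square_ratio_test(m, p, share, critical)
            fmp, fpm = fold_change(m, p)
            stats_by_cross[c][tissue] = TissueStats(m, p, chi2, sig, fmp, fpm)
            meg_ok &= sig and fmp > meg_fold[tissue]
            peg_ok &= sig and fpm > peg_fold[tissue]
        if meg_ok:
            meg_tissues.append(tissue)
        if peg_ok:
            peg_tissues.append(tissue)

    if not any_testable:
        return ImprintCall(gene_id, "none", None, stats_by_cross, testable=False)

    def evidence(tissues: list[str]) -> str:
        return "both" if len(tissues) == 2 else tissues[0]

    if meg_tissues and peg_tissues:
        # opposite-direction evidence in different tissues: no call
        return ImprintCall(gene_id, "none", None, stats_by_cross, conflict=True)
    if meg_tissues:
        return ImprintCall(gene_id, "MEG", evidence(meg_tissues), stats_by_cross)
    if peg_tissues:
        return ImprintCall(gene_id, "PEG", evidence(peg_tissues), stats_by_cross)
    return ImprintCall(gene_id, "none", None, stats_by_cross)


def call_all_genes(
    records: Iterable,
    design,
    min_total_asr: int = DEFAULT_MIN_TOTAL_ASR,
    **kwargs,
) -> dict[str, ImprintCall]:
    """Group records by gene and call each one."""
    by_gene: dict[str, list] = {}
    for r in records:
        by_gene.setdefault(r.gene_id, []).append(r)
    return {
        g: call_gene(g, rs, design, min_total_asr=min_total_asr, **kwargs)
        for g, rs in sorted(by_gene.items())
    }


def summarize_calls(calls: Iterable[ImprintCall]) -> dict[str, dict[str, int]]:
    """Per-tissue counts of imprinted genes: total, MEG, PEG.

    A gene with evidence in both tissues counts in both; total = MEG + PEG
    within each tissue.
    """
    out = {t: {"total": 0, "MEG": 0, "PEG": 0} for t in EXPECTED_SHARE}
    for call in calls:
        if not call.is_imprinted:
            continue
        tissues = list(EXPECTED_SHARE) if call.tissue_evidence == "both" else [call.tissue_evidence]
        for t in tissues:
            out[t][call.klass] += 1
            out[t]["total"] += 1
    return out
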