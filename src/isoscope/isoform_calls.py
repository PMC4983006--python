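"""Tumor-specific isoform inference and the canonical/principal consistency census.

Two candidate classes are screened per cohort:

* type1 — expressed in tumor (median TPM above a small floor) and absent in the
  matched normal group; "strong" when tumor median TPM >= 1.0 and the isoform
  carries >= 10 % of the gene's tumor expression, otherwise "weak".
* type2 — major in the tumor group but not in the normal group, with a
  median-TPM fold change strictly greater than 2 (infinite passes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

from .errors import DomainError, EligibilityError, ValidationError
from .expression_stats import (
    NORMAL,
    TUMOR,
    GroupKey,
    MajorIsoformCall,
    StudySummaries,
    call_major,
    expression_percentage,
)
from .gene_models import CanonicalSet, GeneEntry, GeneRegistry


@dataclass(frozen=True)
class Thresholds:
    """Screening constants; defaults follow the published analysis."""

    expressed_min_tpm: float = 1e-6
    strong_min_tpm: float = 1.0
    strong_min_pct: float = 10.0
    type2_min_fold: float = 2.0
    min_normal_samples: int = 10

    def __post_init__(self) -> None:
        for name in ("expressed_min_tpm", "strong_min_tpm", "strong_min_pct", "type2_min_fold"):
            if getattr(self, name) <= 0:
                raise DomainError(f"threshold {name} must be strictly positive")
        if self.min_normal_samples <= 0:
            raise DomainError("min_normal_samples must be strictly positive")


@dataclass(frozen=True)
class TumorSpecificCall:
    isoform_id: str
    gene_symbol: str
    cohort: str
    call: str  # type1 | type2 | none
    subclass: str  # strong | weak | not_applicable
    tumor_mtpm: float
    normal_mtpm: float
    fold_change: float  # may be inf; nan when both groups are silent
    tumor_pct: float
    normal_pct: float


@dataclass(frozen=True)
class ConsistencyCounts:
    """Partition of genes by major-vs-canonical agreement in one group.

    The ``*_hi`` fields repeat the expressed buckets restricted to genes whose
    major isoform has median TPM >= 1.
    """

    cohort: str
    sample_class: str
    n_total_genes: int
    n_mtpm_zero: int
    n_matched: int
    n_notmatched_kcanon: int
    n_nokcanon: int
    n_matched_hi: int
    n_notmatched_kcanon_hi: int
    n_nokcanon_hi: int

    def __post_init__(self) -> None:
        total = self.n_mtpm_zero + self.n_matched + self.n_notmatched_kcanon + self.n_nokcanon
        if total != self.n_total_genes:
            raise ValidationError(
                f"consistency buckets sum to {total}, expected {self.n_total_genes}"
            )


def ratio_percent(numerator: float, denominator: float) -> float:
    """100·numerator/denominator rounded to one decimal (exact for int inputs)."""
    if denominator == 0:
        raise DomainError("percentage denominator must be nonzero")
    return float(
        (Decimal(numerator) * 100 / Decimal(denominator)).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )


def fold_change(tumor_mtpm: float, normal_mtpm: float) -> float:
    """tumor/normal median-TPM ratio; inf when only the tumor is expressed,
    nan when both are zero."""
    if tumor_mtpm < 0 or normal_mtpm < 0:
        raise DomainError("median TPM values must be non-negative")
    if normal_mtpm == 0:
        return math.inf if tumor_mtpm > 0 else math.nan
    return tumor_mtpm / normal_mtpm


def classify_type1(
    tumor_mtpm: float,
    normal_mtpm: float,
    tumor_pct: float,
    th: Thresholds = Thresholds(),
) -> tuple[bool, str]:
    """Expressed-in-tumor / absent-in-normal test with the strong/weak split.

    Both strong gates are inclusive (>= 1.0 TPM, >= 10 %).
    """
    is_type1 = tumor_mtpm > th.expressed_min_tpm and normal_mtpm <= th.expressed_min_tpm
    if not is_type1:
        return False, "not_applicable"
    strong = tumor_mtpm >= th.strong_min_tpm and tumor_pct >= th.strong_min_pct
    return True, ("strong" if strong else "weak")


def classify_type2(
    isoform_id: str,
    tumor_major: MajorIsoformCall,
    normal_major: MajorIsoformCall,
    fc: float,
    th: Thresholds = Thresholds(),
) -> bool:
    """Major-isoform switch test: tumor-major, not normal-major, fold change
    strictly above the gate (infinite passes, nan fails)."""
    if tumor_major.gene_symbol != normal_major.gene_symbol:
        raise ValidationError(
            f"major calls compare different genes: {tumor_major.gene_symbol} "
            f"vs {normal_major.gene_symbol}"
        )
    if tumor_major.cohort != normal_major.cohort:
        raise ValidationError("major calls compare different cohorts")
    if isoform_id != tumor_major.isoform_id or isoform_id == normal_major.isoform_id:
        return False
    return bool(fc > th.type2_min_fold)  # nan > x is False


def screen_gene(
    gene: GeneEntry,
    cohort: str,
    summaries: StudySummaries,
    th: Thresholds = Thresholds(),
) -> list[TumorSpecificCall]:
    """One TumorSpecificCall per isoform of ``gene`` in ``cohort``.

    An isoform satisfying both definitions is reported as type1 (its fold
    change to an absent normal is infinite, so type2's gate is vacuous).
    """
    tumor_group: GroupKey = (cohort, TUMOR)
    normal_group: GroupKey = (cohort, NORMAL)
    normal_n = summaries.group(cohort, NORMAL).n_patients
    if normal_n < th.min_normal_samples:
        raise EligibilityError(
            f"cohort {cohort} has {normal_n} normal patients; "
            f">= {th.min_normal_samples} required"
        )
    tumor_major = call_major(gene, tumor_group, summaries)
    normal_major = call_major(gene, normal_group, summaries)
    tumor_pcts = expression_percentage(gene, tumor_group, summaries)
    normal_pcts = expression_percentage(gene, normal_group, summaries)
    calls = []
    for iso in gene.isoform_ids:
        t_mtpm = summaries.summary(iso, *tumor_group).median_tpm
        n_mtpm = summaries.summary(iso, *normal_group).median_tpm
        fc = fold_change(t_mtpm, n_mtpm)
        is_t1, subclass = classify_type1(t_mtpm, n_mtpm, tumor_pcts[iso], th)
        if is_t1:
            call = "type1"
        elif classify_type2(iso, tumor_major, normal_major, fc, th):
            call, subclass = "type2", "not_applicable"
        else:
            call, subclass = "none", "not_applicable"
        calls.append(
            TumorSpecificCall(
                isoform_id=iso,
                gene_symbol=gene.symbol,
                cohort=cohort,
                call=call,
                subclass=subclass,
                tumor_mtpm=t_mtpm,
                normal_mtpm=n_mtpm,
                fold_change=fc,
                tumor_pct=tumor_pcts[iso],
                normal_pct=normal_pcts[iso],
            )
        )
    return calls


def consistency_check(
    cohort: str,
    sample_class: str,
    summaries: StudySummaries,
    registry: GeneRegistry,
    canonical: Mapping[str, CanonicalSet] | None = None,
) -> ConsistencyCounts:
    """Census of major-vs-canonical agreement over every registered gene.

    Buckets: silent (no isoform with median TPM > 0), expressed without any
    canonical/principal definition, matched (major equals at least one of the
    three definitions), and mismatched.
    """
    canon = registry.canonical if canonical is None else canonical
    group: GroupKey = (cohort, sample_class)
    n_zero = n_matched = n_not = n_nokc = 0
    hi_matched = hi_not = hi_nokc = 0
    for symbol in sorted(registry.genes):
        gene = registry.genes[symbol]
        per_iso = {
            iso: summaries.summary(iso, *group).median_tpm for iso in gene.isoform_ids
        }
        if all(m <= 0 for m in per_iso.values()):
            n_zero += 1
            continue
        major = call_major(gene, group, summaries)
        hi = per_iso[major.isoform_id] >= 1.0
        cset = canon.get(symbol)
        if cset is None or not cset.members():
            n_nokc += 1
            hi_nokc += hi
        elif major.isoform_id in cset.members():
            n_matched += 1
            hi_matched += hi
        else:
            n_not += 1
            hi_not += hi
    return ConsistencyCounts(
        cohort=cohort,
        sample_class=sample_class,
        n_total_genes=len(registry.genes),
        n_mtpm_zero=n_zero,
        n_matched=n_matched,
        n_notmatched_kcanon=n_not,
        n_nokcanon=n_nokc,
        n_matched_hi=hi_matched,
        n_notmatched_kcanon_hi=hi_not,
        n_nokcanon_hi=hi_nokc,
    )


def percent_increase(normal_count: int, tumor_count: int) -> float:
    """Percent change normal→tumor, one decimal, half away from zero."""
    if normal_count == 0:
        raise DomainError("normal_count must be nonzero")
    return float(
        (Decimal(tumor_count - normal_count) * 100 / Decimal(normal_count)).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )
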