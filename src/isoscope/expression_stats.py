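"""RSEM-style fraction matrices: replicate collapsing, boxplot summaries,
median TPM and major-isoform calling.

Expression values are fraction-of-transcripts estimates in [0, 1]; median TPM
is the group median multiplied by 1e6. Quantiles use linear interpolation
between order statistics (numpy's default, "type 7").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, LookupError_, ValidationError
from .gene_models import GeneEntry

logger = logging.getLogger(__name__)

TUMOR = "tumor"
NORMAL = "normal"

GroupKey = tuple[str, str]  # (cohort, sample_class)


class ExpressionTable:
    """Isoform x sample matrix of fraction estimates plus the isoform→gene map."""

    def __init__(self, values: pd.DataFrame, gene_ids: pd.Series):
        if not values.index.equals(gene_ids.index):
            raise ValidationError("expression values and gene_ids must share an index")
        bad = values.to_numpy()
        if np.any((bad < 0) | (bad > 1)):
            raise ValidationError("expression fractions must lie in [0, 1]")
        self.values = values
        self.gene_ids = gene_ids

    @property
    def isoform_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ExpressionTable":
        df = pd.read_csv(path, sep="\t", dtype={"isoform_id": str, "gene_id": str})
        df = df.set_index("isoform_id")
        gene_ids = df.pop("gene_id")
        return cls(df.astype(float), gene_ids)

    def write_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.insert(0, "gene_id", self.gene_ids)
        out.to_csv(path, sep="\t", index_label="isoform_id", float_format="%.10g")

    def flag_unknown(self, known_isoforms: set[str]) -> list[str]:
        unknown = [i for i in self.isoform_ids if i not in known_isoforms]
        if unknown:
            logger.warning("%d isoform ids absent from the gene-model registry", len(unknown))
        return unknown


class SampleSheet:
    """sample_id → (patient_id, cohort, sample_class)."""

    def __init__(self, df: pd.DataFrame):
        required = {"patient_id", "cohort", "sample_class"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"sample sheet missing columns: {sorted(missing)}")
        bad = set(df["sample_class"]) - {TUMOR, NORMAL}
        if bad:
            raise ValidationError(f"unknown sample_class values: {sorted(bad)}")
        self.df = df

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SampleSheet":
        df = pd.read_csv(path, sep="\t", dtype=str).set_index("sample_id")
        return cls(df)

    def write_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index_label="sample_id")

    def key_of(self, sample_id: str) -> tuple[str, str, str]:
        row = self.df.loc[sample_id]
        return (row["patient_id"], row["cohort"], row["sample_class"])


@dataclass
class GroupSummary:
    """Boxplot statistics of one isoform in one (cohort, sample_class) group."""

    isoform_id: str
    cohort: str
    sample_class: str
    n_patients: int
    lower_outliers: tuple[float, ...]
    whisker_min: float
    q1: float
    median: float
    q3: float
    whisker_max: float
    upper_outliers: tuple[float, ...]

    @property
    def median_tpm(self) -> float:
        return self.median * 1e6

    @property
    def group(self) -> GroupKey:
        return (self.cohort, self.sample_class)


@dataclass(frozen=True)
class MajorIsoformCall:
    gene_symbol: str
    cohort: str
    sample_class: str
    isoform_id: str
    basis: str  # median | q3_tiebreak | lexicographic
    expression_percentage: float


@dataclass
class GroupData:
    cohort: str
    sample_class: str
    n_patients: int
    isoforms: dict[str, GroupSummary] = field(default_factory=dict)


class StudySummaries:
    """Per-group, per-isoform summaries for a whole study."""

    def __init__(self, groups: dict[GroupKey, GroupData]):
        self.groups = groups

    def group(self, cohort: str, sample_class: str) -> GroupData:
        try:
            return self.groups[(cohort, sample_class)]
        except KeyError:
            raise LookupError_(f"no ({cohort}, {sample_class}) group summarized") from None

    def summary(self, isoform_id: str, cohort: str, sample_class: str) -> GroupSummary:
        gd = self.group(cohort, sample_class)
        try:
            return gd.isoforms[isoform_id]
        except KeyError:
            raise LookupError_(
                f"isoform {isoform_id} not summarized for ({cohort}, {sample_class})"
            ) from None


# ---------------------------------------------------------------------------
# core statistics
# ---------------------------------------------------------------------------

def collapse_replicates(table: ExpressionTable, sheet: SampleSheet) -> pd.DataFrame:
    """Average replicate samples per (patient, cohort, sample_class).

    Returns a DataFrame with a 3-level column MultiIndex keyed by that triple.
    """
    unmapped = [s for s in table.sample_ids if s not in sheet.df.index]
    if unmapped:
        raise ValidationError(f"expression columns missing from sample sheet: {unmapped}")
    keys = [sheet.key_of(s) for s in table.sample_ids]
    cols = pd.MultiIndex.from_tuples(keys, names=["patient_id", "cohort", "sample_class"])
    df = table.values.copy()
    df.columns = cols
    return df.T.groupby(level=["patient_id", "cohort", "sample_class"]).mean().T


def group_summary(
    values: Sequence[float],
    isoform_id: str = "",
    cohort: str = "",
    sample_class: str = "",
) -> GroupSummary:
    """Tukey boxplot statistics: type-7 quartiles, 1.5·IQR fences, whiskers at
    the extreme non-outlier points."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise DomainError("cannot summarize an empty value vector")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    lower = np.sort(arr[arr < lo_fence])
    upper = np.sort(arr[arr > hi_fence])
    inliers = arr[(arr >= lo_fence) & (arr <= hi_fence)]
    return GroupSummary(
        isoform_id=isoform_id,
        cohort=cohort,
        sample_class=sample_class,
        n_patients=int(arr.size),
        lower_outliers=tuple(float(x) for x in lower),
        whisker_min=float(min(inliers.min(), q1)),  # never above the box edge
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        whisker_max=float(max(inliers.max(), q3)),
        upper_outliers=tuple(float(x) for x in upper),
    )


def median_tpm(values: Sequence[float]) -> float:
    """Group median of fraction estimates scaled to transcripts per million."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise DomainError("cannot take the median of an empty value vector")
    return float(np.median(arr)) * 1e6


def summarize_study(table: ExpressionTable, sheet: SampleSheet) -> StudySummaries:
    """Collapse replicates, then summarize every isoform in every group."""
    collapsed = collapse_replicates(table, sheet)
    groups: dict[GroupKey, GroupData] = {}
    group_cols = collapsed.columns.to_frame(index=False)
    for (cohort, cls), sub in group_cols.groupby(["cohort", "sample_class"], sort=True):
        patients = list(sub["patient_id"])
        block = collapsed.loc[:, [(p, cohort, cls) for p in patients]]
        gd = GroupData(cohort=cohort, sample_class=cls, n_patients=len(patients))
        for iso in block.index:
            gd.isoforms[iso] = group_summary(
                block.loc[iso].to_numpy(), isoform_id=iso, cohort=cohort, sample_class=cls
            )
        groups[(cohort, cls)] = gd
    return StudySummaries(groups)


# ---------------------------------------------------------------------------
# gene-level calls
# ---------------------------------------------------------------------------

def _gene_summaries(
    gene: GeneEntry, group: GroupKey, summaries: StudySummaries
) -> dict[str, GroupSummary]:
    cohort, cls = group
    gd = summaries.group(cohort, cls)
    out = {}
    for iso in gene.isoform_ids:
        if iso not in gd.isoforms:
            raise LookupError_(
                f"isoform {iso} of {gene.symbol} not summarized for {group}"
            )
        out[iso] = gd.isoforms[iso]
    return out


def expression_percentage(
    gene: GeneEntry, group: GroupKey, summaries: StudySummaries
) -> dict[str, float]:
    """Each isoform's share (%) of the gene's total median TPM in the group;
    all-zero genes yield all-zero percentages."""
    per_iso = _gene_summaries(gene, group, summaries)
    total = sum(s.median_tpm for s in per_iso.values())
    if total <= 0:
        return {iso: 0.0 for iso in per_iso}
    return {iso: 100.0 * s.median_tpm / total for iso, s in per_iso.items()}


def call_major(
    gene: GeneEntry, group: GroupKey, summaries: StudySummaries
) -> MajorIsoformCall:
    """Highest median TPM wins; all-zero medians fall back to Q3; residual
    exact ties break to the lexicographically smallest transcript id."""
    per_iso = _gene_summaries(gene, group, summaries)
    if not per_iso:
        raise DomainError(f"gene {gene.symbol} has no isoforms")
    max_mtpm = max(s.median_tpm for s in per_iso.values())
    if max_mtpm > 0:
        cands = sorted(i for i, s in per_iso.items() if s.median_tpm == max_mtpm)
        basis = "median" if len(cands) == 1 else "lexicographic"
    else:
        max_q3 = max(s.q3 for s in per_iso.values())
        cands = sorted(i for i, s in per_iso.items() if s.q3 == max_q3)
        basis = "q3_tiebreak" if len(cands) == 1 and max_q3 > 0 else "lexicographic"
    winner = cands[0]
    pct = expression_percentage(gene, group, summaries)[winner]
    return MajorIsoformCall(
        gene_symbol=gene.symbol,
        cohort=group[0],
        sample_class=group[1],
        isoform_id=winner,
        basis=basis,
        expression_percentage=pct,
    )


# ---------------------------------------------------------------------------
# tidy output
# ---------------------------------------------------------------------------

def summaries_to_frame(
    summaries: StudySummaries, gene_ids: Optional[Mapping[str, str]] = None
) -> pd.DataFrame:
    """One row per isoform x group — the downloadable expression-view table."""
    rows = []
    for (cohort, cls), gd in sorted(summaries.groups.items()):
        for iso in sorted(gd.isoforms):
            s = gd.isoforms[iso]
            rows.append(
                {
                    "isoform_id": iso,
                    "gene_id": (gene_ids or {}).get(iso, ""),
                    "cohort": cohort,
                    "sample_class": cls,
                    "n_patients": gd.n_patients,
                    "lower_outliers": ",".join(f"{x:.10g}" for x in s.lower_outliers),
                    "whisker_min": s.whisker_min,
                    "q1": s.q1,
                    "median": s.median,
                    "q3": s.q3,
                    "whisker_max": s.whisker_max,
                    "upper_outliers": ",".join(f"{x:.10g}" for x in s.upper_outliers),
                    "median_tpm": s.median_tpm,
                }
            )
    return pd.DataFrame(rows)
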