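"""Expression-prioritized VCF annotation.

Maps variants onto transcript structure (E#/I#/5U/3U/OTR, numbered from the
transcription start site), predicts SNV consequences against a chosen
transcript backbone, emits the nine IE_* VCF fields, and tallies how
interpretation changes between canonical and major backbones.

VCF handling is deliberately line-based: records must round-trip
byte-identically with only INFO keys appended, which rules out re-serializing
through a normalizing parser. Output validity is checked against pysam in the
test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from Bio.Seq import Seq

from .errors import (
    DomainError,
    LookupError_,
    ReferenceMismatchError,
    UsageError,
    ValidationError,
)
from .expression_stats import StudySummaries
from .gene_models import (
    NON_CODING,
    PROTEIN_CODING,
    GeneEntry,
    GeneRegistry,
    TranscriptModel,
    cds_index,
    exon_ordinal,
    reverse_complement,
    spliced_cds,
)
from .isoform_calls import ratio_percent

logger = logging.getLogger(__name__)

IE_HEADER_KEYS = ("IE_TS", "IE_CA", "IE_SA", "IE_SN")
IE_RECORD_KEYS = ("IE_GE", "IE_UP", "IE_UC", "IE_AP", "IE_IS")

_COMPLEMENT_BASE = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


# ---------------------------------------------------------------------------
# element location
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ElementLocation:
    """Where a genomic position falls on one transcript.

    ``ordinal`` is the 1-based exon/intron number in transcription order and is
    set only for E and I; ``containing_exon_ordinal`` additionally records the
    host exon for UTR positions (used when comparing backbones).
    """

    category: str  # E | I | 5U | 3U | OTR
    ordinal: Optional[int] = None
    containing_exon_ordinal: Optional[int] = None

    def __post_init__(self) -> None:
        if self.category in ("E", "I") and self.ordinal is None:
            raise ValidationError(f"{self.category} location requires an ordinal")
        if self.category not in ("E", "I") and self.ordinal is not None:
            raise ValidationError(f"{self.category} location must not carry an ordinal")

    @property
    def label(self) -> str:
        if self.category in ("E", "I"):
            return f"{self.category}{self.ordinal}"
        return self.category

    @property
    def is_coding(self) -> bool:
        return self.category == "E"


def locate(t: TranscriptModel, pos: int, chrom: Optional[str] = None) -> ElementLocation:
    """Classify genomic position ``pos`` (0-based) against transcript ``t``."""
    if chrom is not None and chrom != t.chrom:
        raise ValidationError(
            f"position on {chrom} cannot be located on {t.transcript_id} ({t.chrom})"
        )
    if pos < 0:
        raise DomainError("genomic position must be >= 0")
    if pos < t.tx_start or pos >= t.tx_end:
        return ElementLocation("OTR")
    for i, (s, e) in enumerate(t.exons):
        if s <= pos < e:
            host = exon_ordinal(t, i)
            if t.biotype == NON_CODING:
                return ElementLocation("E", host, host)
            if t.cds_start <= pos < t.cds_end:
                return ElementLocation("E", host, host)
            if pos < t.cds_start:
                cat = "5U" if t.strand == "+" else "3U"
            else:
                cat = "5U" if t.strand == "-" else "3U"
            return ElementLocation(cat, None, host)
        if pos < s:
            # in the intron between genomic exons i-1 and i
            if t.strand == "+":
                return ElementLocation("I", i)
            return ElementLocation("I", t.exon_count - i)
    raise AssertionError("unreachable: position inside tx bounds but unclassified")


# ---------------------------------------------------------------------------
# consequences
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Consequence:
    kind: str  # synonymous | missense | nonsense | stop_lost | noncoding_position | unsupported_allele
    ref_aa: str = ""
    alt_aa: str = ""
    aa_pos: int = 0  # 1-based codon index
    codon_change: str = ""


@dataclass(frozen=True)
class VariantRecord:
    """One VCF variant; ``pos`` retains the 1-based VCF coordinate, ``pos0`` is
    the package-internal 0-based coordinate."""

    chrom: str
    pos: int
    ref: str
    alt: str
    vcf_line: str = ""

    def __post_init__(self) -> None:
        if not self.ref:
            raise ValidationError("REF allele must be non-empty")

    @property
    def pos0(self) -> int:
        return self.pos - 1

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 == len(self.alt) and self.alt in "ACGT"


def consequence(
    t: TranscriptModel, genome: Mapping[str, str], v: VariantRecord
) -> Consequence:
    """Predict the protein-level effect of an SNV on backbone ``t``.

    Codons are read from the spliced CDS with the variant base substituted
    (complemented for minus-strand transcripts) and translated with the
    standard nuclear code.
    """
    if not v.is_snv:
        return Consequence(kind="unsupported_allele")
    if t.biotype != PROTEIN_CODING:
        return Consequence(kind="noncoding_position")
    seq = genome.get(t.chrom)
    if seq is None:
        raise LookupError_(f"chromosome {t.chrom!r} absent from genome")
    if seq[v.pos0] != v.ref.upper():
        raise ReferenceMismatchError(
            f"{v.chrom}:{v.pos}: REF {v.ref} disagrees with genome base {seq[v.pos0]}"
        )
    idx = cds_index(t, v.pos0)
    if idx is None:
        return Consequence(kind="noncoding_position")
    cds = spliced_cds(t, genome)
    if idx >= len(cds):
        logger.warning(
            "%s: variant falls in a trimmed partial codon; effect not predicted",
            t.transcript_id,
        )
        return Consequence(kind="unsupported_allele")
    alt_base = v.alt.upper() if t.strand == "+" else _COMPLEMENT_BASE[v.alt.upper()]
    codon_i = idx // 3
    within = idx % 3
    ref_codon = cds[codon_i * 3 : codon_i * 3 + 3]
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        kind = "synonymous"
    elif alt_aa == "*":
        kind = "nonsense"
    elif ref_aa == "*":
        kind = "stop_lost"
    else:
        kind = "missense"
    return Consequence(
        kind=kind,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        aa_pos=codon_i + 1,
        codon_change=f"{ref_codon}>{alt_codon}",
    )


# ---------------------------------------------------------------------------
# expression-prioritized isoform ranking
# ---------------------------------------------------------------------------

def rank_isoforms(
    gene: GeneEntry, cohort: str, sample_class: str, summaries: StudySummaries
) -> list[str]:
    """All isoforms of ``gene`` sorted by descending median TPM, then
    descending Q3, then transcript id."""
    gd = summaries.group(cohort, sample_class)
    keyed = []
    for iso in gene.isoform_ids:
        if iso not in gd.isoforms:
            raise LookupError_(f"isoform {iso} not summarized for ({cohort}, {sample_class})")
        s = gd.isoforms[iso]
        keyed.append((-s.median_tpm, -s.q3, iso))
    return [iso for _, _, iso in sorted(keyed)]


# ---------------------------------------------------------------------------
# VCF annotation
# ---------------------------------------------------------------------------

class AnnotatedVCF:
    """Annotated VCF held as text lines (no trailing newlines)."""

    def __init__(self, lines: list[str]):
        self.lines = lines

    @property
    def header_lines(self) -> list[str]:
        return [l for l in self.lines if l.startswith("#")]

    @property
    def record_lines(self) -> list[str]:
        return [l for l in self.lines if l and not l.startswith("#")]

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for line in self.lines:
                fh.write(line + "\n")

    def serialize(self) -> str:
        return "".join(line + "\n" for line in self.lines)


def _read_vcf_lines(vcf_in) -> list[str]:
    if isinstance(vcf_in, (str, Path)):
        return Path(vcf_in).read_text().splitlines()
    return [line.rstrip("\n") for line in vcf_in]


def _format_mtpm(x: float) -> str:
    return f"{x:.6g}"


def _isoform_entry(
    tid: str,
    registry: GeneRegistry,
    element: ElementLocation,
    mtpm: float,
) -> str:
    t = registry.models[tid]
    x = registry.xrefs.get(tid)
    xref_part = "&".join(
        f"{label}:{val or '.'}"
        for label, val in (
            ("UniProt", x.uniprot_id if x else None),
            ("RefSeq", x.refseq_id if x else None),
            ("Ensembl", x.ensembl_tx_id if x else None),
            ("CCDS", x.ccds_id if x else None),
        )
    )
    return "|".join([tid, t.biotype, element.label, _format_mtpm(mtpm), xref_part])


def _canonical_field(registry: GeneRegistry, gene: GeneEntry, which: str) -> str:
    cs = registry.canonical.get(gene.symbol)
    val = getattr(cs, which, None) if cs else None
    return val or "."


def annotate_vcf(
    vcf_in,
    registry: GeneRegistry,
    summaries: StudySummaries,
    cohort: str,
    sample_class: str,
    tissue: Optional[str] = None,
    genome: Optional[Mapping[str, str]] = None,
) -> AnnotatedVCF:
    """Append the nine IE_* fields to a VCF.

    Four run-level fields go into the header (IE_TS/IE_CA/IE_SA/IE_SN); five
    per-variant keys are appended to INFO. Original records are preserved
    byte-for-byte apart from the appended keys. Intergenic variants get
    ``IE_GE=.`` and no isoform list.
    """
    group = summaries.group(cohort, sample_class)  # raises if absent
    lines = _read_vcf_lines(vcf_in)
    if not lines or not lines[0].startswith("##fileformat=VCF"):
        raise UsageError("input does not look like a VCF (missing ##fileformat header)")
    out: list[str] = []
    chrom_line_seen = False
    meta = [
        f"##IE_TS={tissue or cohort}",
        f"##IE_CA={cohort}",
        f"##IE_SA={sample_class}",
        f"##IE_SN={group.n_patients}",
        '##INFO=<ID=IE_GE,Number=.,Type=String,Description="Gene symbol(s) at the variant position">',
        '##INFO=<ID=IE_UP,Number=.,Type=String,Description="UniProt-based canonical isoform per gene">',
        '##INFO=<ID=IE_UC,Number=.,Type=String,Description="UCSC-based canonical isoform per gene">',
        '##INFO=<ID=IE_AP,Number=.,Type=String,Description="APPRIS principal isoform per gene">',
        '##INFO=<ID=IE_IS,Number=.,Type=String,Description="Isoforms sorted by group median TPM: '
        'id|biotype|element|medianTPM|UniProt:x&RefSeq:x&Ensembl:x&CCDS:x">',
    ]
    for line in lines:
        if line.startswith("##"):
            out.append(line)
            continue
        if line.startswith("#CHROM"):
            out.extend(meta)
            out.append(line)
            chrom_line_seen = True
            continue
        if not line.strip():
            continue
        if not chrom_line_seen:
            raise UsageError("VCF record encountered before the #CHROM header line")
        out.append(
            _annotate_record(line, registry, summaries, cohort, sample_class, genome)
        )
    if not chrom_line_seen:
        raise UsageError("VCF lacks a #CHROM header line")
    return AnnotatedVCF(out)


def _annotate_record(
    line: str,
    registry: GeneRegistry,
    summaries: StudySummaries,
    cohort: str,
    sample_class: str,
    genome: Optional[Mapping[str, str]],
) -> str:
    cols = line.split("\t")
    if len(cols) < 8:
        raise UsageError(f"VCF record has {len(cols)} columns; at least 8 required")
    chrom, pos_s, _, ref = cols[0], cols[1], cols[2], cols[3]
    pos0 = int(pos_s) - 1  # the single 1-based -> 0-based conversion point
    if genome is not None and chrom in genome and pos0 >= len(genome[chrom]):
        logger.warning(
            "%s:%s lies beyond the chromosome end (%d); annotated as intergenic",
            chrom,
            pos_s,
            len(genome[chrom]),
        )
    end0 = pos0 + max(1, len(ref))
    genes = registry.genes_overlapping(chrom, pos0, end0)
    if not genes:
        additions = {"IE_GE": "."}
    else:
        ge, up, uc, ap, is_ = [], [], [], [], []
        for gene in genes:
            ge.append(gene.symbol)
            up.append(_canonical_field(registry, gene, "uniprot_canonical"))
            uc.append(_canonical_field(registry, gene, "ucsc_canonical"))
            ap.append(_canonical_field(registry, gene, "appris_principal"))
            ranked = rank_isoforms(gene, cohort, sample_class, summaries)
            entries = []
            for tid in ranked:
                element = locate(registry.models[tid], pos0)
                mtpm = summaries.summary(tid, cohort, sample_class).median_tpm
                entries.append(_isoform_entry(tid, registry, element, mtpm))
            is_.append(",".join(entries))
        additions = {
            "IE_GE": "&".join(ge),
            "IE_UP": "&".join(up),
            "IE_UC": "&".join(uc),
            "IE_AP": "&".join(ap),
            "IE_IS": "&".join(is_),
        }
    added = ";".join(f"{k}={v}" for k, v in additions.items())
    info = cols[7]
    cols[7] = added if info in (".", "") else f"{info};{added}"
    return "\t".join(cols)


def strip_ie_fields(lines: Iterable[str]) -> list[str]:
    """Inverse of annotate_vcf: drop IE_* header lines and INFO keys."""
    out = []
    ie_meta = tuple(f"##{k}=" for k in IE_HEADER_KEYS) + tuple(
        f"##INFO=<ID={k}," for k in IE_RECORD_KEYS
    )
    for line in lines:
        if line.startswith(ie_meta):
            continue
        if line.startswith("#"):
            out.append(line)
            continue
        cols = line.split("\t")
        if len(cols) >= 8:
            kept = [
                kv
                for kv in cols[7].split(";")
                if not kv.startswith(tuple(f"{k}=" for k in IE_RECORD_KEYS))
            ]
            cols[7] = ";".join(kept) if kept else "."
        out.append("\t".join(cols))
    return out


def parse_records(lines: Iterable[str]) -> list[VariantRecord]:
    """Extract VariantRecord objects from VCF text lines (first ALT only for
    location purposes; multi-allelic sites share a position)."""
    records = []
    for line in lines:
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        records.append(
            VariantRecord(
                chrom=cols[0],
                pos=int(cols[1]),
                ref=cols[3],
                alt=cols[4].split(",")[0],
                vcf_line=line,
            )
        )
    return records


# ---------------------------------------------------------------------------
# backbone comparison
# ---------------------------------------------------------------------------

CASE_CONCORDANT = "concordant_coding"
CASE_AA_CHANGED = "coding_coding_aa_changed"
CASE_VS_INTRON = "coding_vs_intron"
CASE_VS_5U = "coding_vs_5U"
CASE_VS_3U = "coding_vs_3U"
CASE_VS_OTR = "coding_vs_OTR"
CASE_CANON_NONCODING = "canonical_noncoding"

_RELOCATION_CASES = {"I": CASE_VS_INTRON, "5U": CASE_VS_5U, "3U": CASE_VS_3U, "OTR": CASE_VS_OTR}


@dataclass(frozen=True)
class BackboneComparison:
    variant: VariantRecord
    major_id: str
    canonical_id: str
    major_location: ElementLocation
    canonical_location: ElementLocation
    case: str
    major_consequence: Optional[Consequence] = None
    canonical_consequence: Optional[Consequence] = None
    exon_ordinal_changed: Optional[bool] = None
    aa_interpretation_changed: Optional[bool] = None

    @property
    def major_is_canonical(self) -> bool:
        return self.major_id == self.canonical_id


def compare_backbones(
    v: VariantRecord,
    major_t: TranscriptModel,
    canonical_t: TranscriptModel,
    genome: Mapping[str, str],
) -> BackboneComparison:
    """How does interpretation of ``v`` change between the canonical and the
    (expression-chosen) major backbone of the same gene?"""
    if major_t.gene_symbol != canonical_t.gene_symbol:
        raise ValidationError(
            f"backbones annotate different genes: {major_t.gene_symbol} vs "
            f"{canonical_t.gene_symbol}"
        )
    loc_major = locate(major_t, v.pos0)
    loc_canon = locate(canonical_t, v.pos0)
    canon_coding = loc_canon.is_coding and canonical_t.biotype == PROTEIN_CODING
    major_coding = loc_major.is_coding and major_t.biotype == PROTEIN_CODING
    cons_major = cons_canon = None
    exon_changed = aa_changed = None
    if not canon_coding:
        case = CASE_CANON_NONCODING
    elif major_coding:
        exon_changed = loc_major.ordinal != loc_canon.ordinal
        if v.is_snv:
            cons_major = consequence(major_t, genome, v)
            cons_canon = consequence(canonical_t, genome, v)
            aa_changed = (cons_major.ref_aa, cons_major.alt_aa) != (
                cons_canon.ref_aa,
                cons_canon.alt_aa,
            )
        case = CASE_AA_CHANGED if aa_changed else CASE_CONCORDANT
    else:
        case = _RELOCATION_CASES[loc_major.category]
        if v.is_snv:
            cons_canon = consequence(canonical_t, genome, v)
    return BackboneComparison(
        variant=v,
        major_id=major_t.transcript_id,
        canonical_id=canonical_t.transcript_id,
        major_location=loc_major,
        canonical_location=loc_canon,
        case=case,
        major_consequence=cons_major,
        canonical_consequence=cons_canon,
        exon_ordinal_changed=exon_changed,
        aa_interpretation_changed=aa_changed,
    )


@dataclass(frozen=True)
class DiscordanceSummary:
    """Counts of how mutation interpretation shifts major-vs-canonical.

    Partition identities: the four relocation buckets plus still-coding sum to
    ``n_coding_in_canonical``; same/changed exon numbers sum to
    ``n_still_coding_in_major``.
    """

    canonical_definition: str
    n_total: int
    n_noncanonical_major: int
    n_coding_in_canonical: int
    n_still_coding_in_major: int
    n_intron: int
    n_5U: int
    n_3U: int
    n_OTR: int
    n_same_exon_number: int
    n_exon_number_changed: int
    n_aa_interpretation_changed: int

    def __post_init__(self) -> None:
        relocated = self.n_intron + self.n_5U + self.n_3U + self.n_OTR
        if self.n_still_coding_in_major + relocated != self.n_coding_in_canonical:
            raise ValidationError(
                "relocation buckets do not partition the canonical-coding mutations"
            )
        if self.n_same_exon_number + self.n_exon_number_changed != self.n_still_coding_in_major:
            raise ValidationError(
                "exon-number split does not partition the still-coding mutations"
            )

    @property
    def n_relocated(self) -> int:
        return self.n_intron + self.n_5U + self.n_3U + self.n_OTR

    def percentages(self) -> dict[str, float]:
        """Display percentages at one decimal, each over its stated denominator;
        keys whose denominator is zero are omitted."""
        out: dict[str, float] = {}
        if self.n_noncanonical_major:
            out["coding_in_canonical"] = ratio_percent(
                self.n_coding_in_canonical, self.n_noncanonical_major
            )
        if self.n_coding_in_canonical:
            den = self.n_coding_in_canonical
            out["still_coding"] = ratio_percent(self.n_still_coding_in_major, den)
            out["relocated"] = ratio_percent(self.n_relocated, den)
            out["intron"] = ratio_percent(self.n_intron, den)
            out["utr5"] = ratio_percent(self.n_5U, den)
            out["utr3"] = ratio_percent(self.n_3U, den)
            out["otr"] = ratio_percent(self.n_OTR, den)
        if self.n_still_coding_in_major:
            den = self.n_still_coding_in_major
            out["same_exon_number"] = ratio_percent(self.n_same_exon_number, den)
            out["exon_number_changed"] = ratio_percent(self.n_exon_number_changed, den)
        if self.n_exon_number_changed:
            out["aa_interpretation_changed"] = ratio_percent(
                self.n_aa_interpretation_changed, self.n_exon_number_changed
            )
        return out


def summarize_discordance(
    comparisons: Sequence[BackboneComparison], canonical_definition: str = "ucsc"
) -> DiscordanceSummary:
    """Tally BackboneComparison results into the discordance census."""
    if canonical_definition not in ("ucsc", "uniprot", "appris"):
        raise UsageError(f"unknown canonical definition {canonical_definition!r}")
    n_total = len(comparisons)
    mism = [c for c in comparisons if not c.major_is_canonical]
    coding = [c for c in mism if c.case != CASE_CANON_NONCODING]
    still = [c for c in coding if c.case in (CASE_CONCORDANT, CASE_AA_CHANGED)]
    by_case = lambda case: sum(1 for c in coding if c.case == case)  # noqa: E731
    same_exon = sum(1 for c in still if c.exon_ordinal_changed is False)
    changed_exon = len(still) - same_exon
    aa_changed = sum(
        1 for c in still if c.exon_ordinal_changed and c.aa_interpretation_changed
    )
    return DiscordanceSummary(
        canonical_definition=canonical_definition,
        n_total=n_total,
        n_noncanonical_major=len(mism),
        n_coding_in_canonical=len(coding),
        n_still_coding_in_major=len(still),
        n_intron=by_case(CASE_VS_INTRON),
        n_5U=by_case(CASE_VS_5U),
        n_3U=by_case(CASE_VS_3U),
        n_OTR=by_case(CASE_VS_OTR),
        n_same_exon_number=same_exon,
        n_exon_number_changed=changed_exon,
        n_aa_interpretation_changed=aa_changed,
    )
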