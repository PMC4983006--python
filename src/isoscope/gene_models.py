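"""Transcript/gene structures, cross-references and canonical assignments.

Coordinates are 0-based half-open throughout (genePred convention); the only
1-based surface in the package is VCF ingestion, which converts exactly once.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from Bio import SeqIO

from .errors import (
    DomainError,
    GenePredParseError,
    LookupError_,
    ModelValidationError,
    UsageError,
    ValidationError,
)

logger = logging.getLogger(__name__)

PROTEIN_CODING = "protein_coding"
NON_CODING = "non_coding"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_LOCUS_RE = re.compile(r"^(?P<chrom>[\w.]+):(?P<start>[\d,]+)-(?P<end>[\d,]+)$")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TranscriptModel:
    """Genomic exon/CDS structure of one isoform.

    ``biotype`` is derived: an empty CDS interval (``cds_start == cds_end``)
    means non-coding.
    """

    transcript_id: str
    gene_symbol: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exon_starts: tuple[int, ...]
    exon_ends: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ModelValidationError(
                f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if len(self.exon_starts) != len(self.exon_ends) or not self.exon_starts:
            raise ModelValidationError(
                f"{self.transcript_id}: exon start/end lists must be equal-length and non-empty"
            )
        prev_end = None
        for s, e in zip(self.exon_starts, self.exon_ends):
            if s >= e:
                raise ModelValidationError(
                    f"{self.transcript_id}: empty exon [{s}, {e})"
                )
            if prev_end is not None and s < prev_end:
                raise ModelValidationError(
                    f"{self.transcript_id}: exons unsorted or overlapping at {s}"
                )
            prev_end = e
        if self.exon_starts[0] < self.tx_start or self.exon_ends[-1] > self.tx_end:
            raise ModelValidationError(
                f"{self.transcript_id}: exons extend outside [tx_start, tx_end)"
            )
        if not (self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end):
            raise ModelValidationError(
                f"{self.transcript_id}: CDS [{self.cds_start}, {self.cds_end}) "
                f"outside transcript bounds"
            )

    @property
    def exon_count(self) -> int:
        return len(self.exon_starts)

    @property
    def biotype(self) -> str:
        return PROTEIN_CODING if self.cds_start < self.cds_end else NON_CODING

    @property
    def exons(self) -> tuple[tuple[int, int], ...]:
        return tuple(zip(self.exon_starts, self.exon_ends))


@dataclass
class GeneEntry:
    """One gene: a symbol grouping isoforms that share a chromosome."""

    symbol: str
    chrom: str
    start: int
    end: int
    isoform_ids: list[str]
    full_name: str = ""
    gene_xrefs: dict[str, str] = field(default_factory=dict)

    @property
    def locus(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass(frozen=True)
class IsoformXref:
    transcript_id: str
    uniprot_id: Optional[str] = None
    refseq_id: Optional[str] = None
    ensembl_tx_id: Optional[str] = None
    ccds_id: Optional[str] = None
    peptide_available: bool = False


@dataclass(frozen=True)
class CanonicalSet:
    gene_symbol: str
    uniprot_canonical: Optional[str] = None
    ucsc_canonical: Optional[str] = None
    appris_principal: Optional[str] = None

    def members(self) -> set[str]:
        return {
            t
            for t in (self.uniprot_canonical, self.ucsc_canonical, self.appris_principal)
            if t
        }


# ---------------------------------------------------------------------------
# genePred I/O
# ---------------------------------------------------------------------------

_GENEPRED_NCOLS = 11


def _parse_block_list(text: str, lineno: int, what: str) -> tuple[int, ...]:
    try:
        return tuple(int(x) for x in text.rstrip(",").split(",") if x != "")
    except ValueError as exc:
        raise GenePredParseError(f"line {lineno}: bad {what} block list {text!r}") from exc


def load_models(path: str | Path, format: str = "genepred") -> list[TranscriptModel]:
    """Parse a genePred TSV into validated transcript models, row order preserved."""
    if format != "genepred":
        raise UsageError(f"unknown gene-model format {format!r} (only 'genepred')")
    models: list[TranscriptModel] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != _GENEPRED_NCOLS:
                raise GenePredParseError(
                    f"line {lineno}: expected {_GENEPRED_NCOLS} columns, got {len(cols)}"
                )
            (name, chrom, strand, tx_s, tx_e, cds_s, cds_e, n_ex, ex_s, ex_e, sym) = cols
            try:
                exon_count = int(n_ex)
            except ValueError as exc:
                raise GenePredParseError(f"line {lineno}: bad exonCount {n_ex!r}") from exc
            starts = _parse_block_list(ex_s, lineno, "exonStarts")
            ends = _parse_block_list(ex_e, lineno, "exonEnds")
            if len(starts) != exon_count or len(ends) != exon_count:
                raise GenePredParseError(
                    f"line {lineno}: exonCount={exon_count} but "
                    f"{len(starts)} starts / {len(ends)} ends listed"
                )
            try:
                model = TranscriptModel(
                    transcript_id=name,
                    gene_symbol=sym,
                    chrom=chrom,
                    strand=strand,
                    tx_start=int(tx_s),
                    tx_end=int(tx_e),
                    cds_start=int(cds_s),
                    cds_end=int(cds_e),
                    exon_starts=starts,
                    exon_ends=ends,
                )
            except (ValueError, ModelValidationError) as exc:
                raise GenePredParseError(f"line {lineno}: {exc}") from exc
            models.append(model)
    return models


def write_models(models: Iterable[TranscriptModel], path: str | Path) -> None:
    """Serialize models back to genePred TSV (block lists comma-terminated)."""
    with open(path, "w") as fh:
        for t in models:
            fh.write(
                "\t".join(
                    [
                        t.transcript_id,
                        t.chrom,
                        t.strand,
                        str(t.tx_start),
                        str(t.tx_end),
                        str(t.cds_start),
                        str(t.cds_end),
                        str(t.exon_count),
                        "".join(f"{s}," for s in t.exon_starts),
                        "".join(f"{e}," for e in t.exon_ends),
                        t.gene_symbol,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# FASTA helpers
# ---------------------------------------------------------------------------

def load_genome(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into a chrom -> uppercase sequence mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_genome(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# coordinate primitives
# ---------------------------------------------------------------------------

def exon_ordinal(t: TranscriptModel, genomic_index: int) -> int:
    """1-based exon number in transcription order for the exon at ``genomic_index``
    (ascending genomic order)."""
    if not 0 <= genomic_index < t.exon_count:
        raise IndexError(
            f"exon index {genomic_index} out of range for {t.transcript_id} "
            f"({t.exon_count} exons)"
        )
    if t.strand == "+":
        return genomic_index + 1
    return t.exon_count - genomic_index


def spliced_cds(t: TranscriptModel, genome: Mapping[str, str]) -> str:
    """Coding sequence of ``t`` in transcription orientation.

    Exon/CDS intersections are concatenated in genomic order and
    reverse-complemented for minus-strand transcripts. A trailing partial codon
    is dropped with a warning.
    """
    if t.biotype != PROTEIN_CODING:
        raise DomainError(f"{t.transcript_id} is non-coding; it has no spliced CDS")
    if t.chrom not in genome:
        raise LookupError_(f"chromosome {t.chrom!r} absent from genome")
    seq = genome[t.chrom]
    if len(seq) < t.tx_end:
        raise LookupError_(
            f"genome sequence for {t.chrom} too short for {t.transcript_id}"
        )
    parts = []
    for s, e in t.exons:
        lo, hi = max(s, t.cds_start), min(e, t.cds_end)
        if lo < hi:
            parts.append(seq[lo:hi])
    cds = "".join(parts)
    if t.strand == "-":
        cds = reverse_complement(cds)
    if len(cds) % 3:
        logger.warning(
            "%s: CDS length %d not a multiple of 3; dropping trailing partial codon",
            t.transcript_id,
            len(cds),
        )
        cds = cds[: len(cds) - len(cds) % 3]
    return cds


def cds_length(t: TranscriptModel) -> int:
    """Sum of exon∩CDS interval lengths (before any partial-codon trim)."""
    return sum(
        max(0, min(e, t.cds_end) - max(s, t.cds_start)) for s, e in t.exons
    )


def cds_index(t: TranscriptModel, pos: int) -> Optional[int]:
    """0-based index of genomic position ``pos`` within the spliced CDS, in
    transcription orientation; ``None`` when the position is not coding."""
    if not (t.cds_start <= pos < t.cds_end):
        return None
    offset = 0
    plus_index = None
    for s, e in t.exons:
        lo, hi = max(s, t.cds_start), min(e, t.cds_end)
        if lo >= hi:
            continue
        if lo <= pos < hi:
            plus_index = offset + (pos - lo)
            break
        offset += hi - lo
    if plus_index is None:
        return None  # intronic position inside the CDS span
    if t.strand == "+":
        return plus_index
    return cds_length(t) - 1 - plus_index


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

class GeneRegistry:
    """Gene/transcript registry with canonical sets, xrefs and query resolution.

    Transcripts are grouped into genes by symbol; a symbol spanning several
    chromosomes is split into distinct genes with ``_2``, ``_3``... suffixes.
    """

    def __init__(self, models: Sequence[TranscriptModel]):
        self.models: dict[str, TranscriptModel] = {}
        for t in models:
            if t.transcript_id in self.models:
                raise ValidationError(f"duplicate transcript id {t.transcript_id}")
            self.models[t.transcript_id] = t
        self.genes: dict[str, GeneEntry] = {}
        self._gene_of_tx: dict[str, str] = {}
        self._build_genes(models)
        self.canonical: dict[str, CanonicalSet] = {}
        self.xrefs: dict[str, IsoformXref] = {}

    def _build_genes(self, models: Sequence[TranscriptModel]) -> None:
        by_symbol: dict[str, list[TranscriptModel]] = {}
        for t in models:
            by_symbol.setdefault(t.gene_symbol, []).append(t)
        for symbol, txs in by_symbol.items():
            chroms = sorted({t.chrom for t in txs})
            for i, chrom in enumerate(chroms):
                name = symbol if i == 0 else f"{symbol}_{i + 1}"
                members = [t for t in txs if t.chrom == chrom]
                entry = GeneEntry(
                    symbol=name,
                    chrom=chrom,
                    start=min(t.tx_start for t in members),
                    end=max(t.tx_end for t in members),
                    isoform_ids=[t.transcript_id for t in members],
                )
                self.genes[name] = entry
                for t in members:
                    self._gene_of_tx[t.transcript_id] = name

    # -- loading side tables ------------------------------------------------

    def add_gene_info(self, rows: Iterable[dict]) -> None:
        """Attach full names / gene-level xrefs (rows with 'gene_symbol' keys)."""
        for row in rows:
            sym = row["gene_symbol"]
            if sym not in self.genes:
                logger.warning("gene info for unknown symbol %s ignored", sym)
                continue
            entry = self.genes[sym]
            entry.full_name = row.get("full_name", "") or ""
            for key in ("refseq_id", "uniprot_id", "ensembl_gene_id"):
                val = row.get(key)
                if val:
                    entry.gene_xrefs[key] = val

    def add_canonical(self, sets: Iterable[CanonicalSet]) -> None:
        for cs in sets:
            if cs.gene_symbol not in self.genes:
                raise ValidationError(f"canonical set for unknown gene {cs.gene_symbol}")
            members = set(self.genes[cs.gene_symbol].isoform_ids)
            for tid in cs.members():
                if tid not in members:
                    raise ValidationError(
                        f"{tid} named canonical for {cs.gene_symbol} but is not one "
                        f"of its isoforms"
                    )
            self.canonical[cs.gene_symbol] = cs

    def add_xrefs(self, xrefs: Iterable[IsoformXref]) -> None:
        for x in xrefs:
            t = self.models.get(x.transcript_id)
            if t is None:
                raise ValidationError(f"xref for unknown transcript {x.transcript_id}")
            if x.peptide_available and t.biotype != PROTEIN_CODING:
                raise ValidationError(
                    f"{x.transcript_id}: peptide_available on a non-coding transcript"
                )
            self.xrefs[x.transcript_id] = x

    # -- queries ------------------------------------------------------------

    def gene_of(self, transcript_id: str) -> GeneEntry:
        try:
            return self.genes[self._gene_of_tx[transcript_id]]
        except KeyError:
            raise LookupError_(f"unknown transcript {transcript_id}") from None

    def is_protein_coding(self, transcript_id: str) -> bool:
        """Peptide-availability flag wins; fall back to CDS-length inference."""
        t = self.models.get(transcript_id)
        if t is None:
            raise LookupError_(f"unknown transcript {transcript_id}")
        x = self.xrefs.get(transcript_id)
        if x is not None:
            return bool(x.peptide_available)
        return t.cds_start < t.cds_end

    def genes_overlapping(self, chrom: str, start: int, end: int) -> list[GeneEntry]:
        """Genes whose span overlaps [start, end) on ``chrom``, in symbol order."""
        hits = [
            g
            for g in self.genes.values()
            if g.chrom == chrom and g.start < end and g.end > start
        ]
        return sorted(hits, key=lambda g: g.symbol)

    def resolve_query(self, q: str, mode: str = "exact") -> list[GeneEntry]:
        if mode not in ("exact", "keyword"):
            raise UsageError(f"unknown query mode {mode!r}")
        q = q.strip()
        if not q:
            raise UsageError("empty query")
        if mode == "keyword":
            needle = q.lower()
            return sorted(
                (
                    g
                    for g in self.genes.values()
                    if needle in g.symbol.lower() or needle in g.full_name.lower()
                ),
                key=lambda g: g.symbol,
            )
        # exact mode: symbol, transcript id, gene/isoform xref ids, or locus
        m = _LOCUS_RE.match(q)
        if m:
            chrom = m.group("chrom")
            start = int(m.group("start").replace(",", ""))
            end = int(m.group("end").replace(",", ""))
            return self.genes_overlapping(chrom, start, end)
        hits: dict[str, GeneEntry] = {}
        ql = q.lower()
        for g in self.genes.values():
            if g.symbol.lower() == ql or ql in {v.lower() for v in g.gene_xrefs.values()}:
                hits[g.symbol] = g
        if q in self.models:
            g = self.gene_of(q)
            hits[g.symbol] = g
        for x in self.xrefs.values():
            ids = {x.uniprot_id, x.refseq_id, x.ensembl_tx_id, x.ccds_id}
            if q in {i for i in ids if i}:
                g = self.gene_of(x.transcript_id)
                hits[g.symbol] = g
        return [hits[k] for k in sorted(hits)]


# ---------------------------------------------------------------------------
# side-table TSV loaders
# ---------------------------------------------------------------------------

def _opt(value: str) -> Optional[str]:
    value = value.strip()
    return None if value in ("", ".") else value


def load_canonical_sets(path: str | Path) -> list[CanonicalSet]:
    """Header-bearing TSV: gene_symbol, uniprot_canonical, ucsc_canonical,
    appris_principal ('.' = undefined)."""
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            out.append(
                CanonicalSet(
                    gene_symbol=cols[idx["gene_symbol"]],
                    uniprot_canonical=_opt(cols[idx["uniprot_canonical"]]),
                    ucsc_canonical=_opt(cols[idx["ucsc_canonical"]]),
                    appris_principal=_opt(cols[idx["appris_principal"]]),
                )
            )
    return out


def load_xrefs(path: str | Path) -> list[IsoformXref]:
    """Header-bearing TSV: transcript_id, uniprot_id, refseq_id, ensembl_tx_id,
    ccds_id, peptide_available (0/1)."""
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            out.append(
                IsoformXref(
                    transcript_id=cols[idx["transcript_id"]],
                    uniprot_id=_opt(cols[idx["uniprot_id"]]),
                    refseq_id=_opt(cols[idx["refseq_id"]]),
                    ensembl_tx_id=_opt(cols[idx["ensembl_tx_id"]]),
                    ccds_id=_opt(cols[idx["ccds_id"]]),
                    peptide_available=cols[idx["peptide_available"]].strip() in ("1", "true", "True"),
                )
            )
    return out


def write_canonical_sets(sets: Iterable[CanonicalSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_symbol\tuniprot_canonical\tucsc_canonical\tappris_principal\n")
        for cs in sets:
            fh.write(
                "\t".join(
                    [
                        cs.gene_symbol,
                        cs.uniprot_canonical or ".",
                        cs.ucsc_canonical or ".",
                        cs.appris_principal or ".",
                    ]
                )
                + "\n"
            )


def write_xrefs(xrefs: Iterable[IsoformXref], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "transcript_id\tuniprot_id\trefseq_id\tensembl_tx_id\tccds_id\tpeptide_available\n"
        )
        for x in xrefs:
            fh.write(
                "\t".join(
                    [
                        x.transcript_id,
                        x.uniprot_id or ".",
                        x.refseq_id or ".",
                        x.ensembl_tx_id or ".",
                        x.ccds_id or ".",
                        "1" if x.peptide_available else "0",
                    ]
                )
                + "\n"
            )


def write_gene_info(rows: Iterable[dict], path: str | Path) -> None:
    cols = ["gene_symbol", "full_name", "refseq_id", "uniprot_id", "ensembl_gene_id"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(row.get(c) or "." for c in cols) + "\n")


def load_gene_info(path: str | Path) -> list[dict]:
    """Header-bearing TSV with gene_symbol, full_name and optional gene xrefs."""
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            row = dict(zip(header, cols))
            for k, v in list(row.items()):
                if v == ".":
                    row[k] = ""
            rows.append(row)
    return rows
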