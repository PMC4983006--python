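"""Deterministic synthetic inputs: genome, gene models, canonical/xref tables,
expression matrices, sample sheets and VCFs.

The transcript catalog is designed, not sampled: it bakes in the structural
situations the rest of the package must handle — a gene whose two isoforms put
one position in exon 3 vs exon 4 with a shifted reading frame, a gene where a
coding position becomes 3'-UTR under the alternative isoform, plus/minus
strand genes, a non-coding isoform, genes without canonical assignments, a
silent gene, a Q3-tiebreak gene, and a five-isoform gene with a designed
tumor-only isoform (0.40 TPM) and a 29.3-fold major-isoform switch.

Only the genome sequence and the expression jitter depend on the seed; the
coordinates are fixed so tests can reason about them exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .errors import GenerationError
from .expression_stats import ExpressionTable, SampleSheet
from .gene_models import CanonicalSet, IsoformXref, TranscriptModel

_BASES = np.array(list("ACGT"))
_NEXT_BASE = {"A": "C", "C": "G", "G": "T", "T": "A", "N": "A"}


@dataclass
class FixtureDesign:
    """Knobs for the generators; defaults give the full designed study."""

    seed: int = 0
    cohort: str = "LUAD"
    n_tumor_patients: int = 11
    n_normal_patients: int = 11
    replicate_patient_index: int = 0  # this tumor patient gets two aliquots
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 12000, "chr2": 12000}
    )

    def __post_init__(self) -> None:
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise GenerationError(f"chromosome {chrom} has non-positive length")
        for n, what in (
            (self.n_tumor_patients, "tumor"),
            (self.n_normal_patients, "normal"),
        ):
            if n < 1 or n % 2 == 0:
                raise GenerationError(
                    f"{what} patient count must be odd and positive (exact designed "
                    f"medians require an odd n); got {n}"
                )


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def make_genome(design: FixtureDesign) -> dict[str, str]:
    """Random ACGT sequence per chromosome, deterministic for a given seed."""
    rng = np.random.default_rng(design.seed)
    return {
        chrom: "".join(rng.choice(_BASES, size=length))
        for chrom, length in sorted(design.chrom_lengths.items())
    }


# ---------------------------------------------------------------------------
# designed transcript catalog
# ---------------------------------------------------------------------------

def _tx(tid, sym, chrom, strand, exons, cds):
    starts = tuple(s for s, _ in exons)
    ends = tuple(e for _, e in exons)
    return TranscriptModel(
        transcript_id=tid,
        gene_symbol=sym,
        chrom=chrom,
        strand=strand,
        tx_start=starts[0],
        tx_end=ends[-1],
        cds_start=cds[0],
        cds_end=cds[1],
        exon_starts=starts,
        exon_ends=ends,
    )


_CATALOG = [
    # ALPHA: frame-shift exon-renumbering pair (position 1430 is E3 in tA1,
    # E4 in tA2, with differing CDS phase).
    _tx("tA1.1", "ALPHA", "chr1", "+",
        [(1000, 1060), (1200, 1260), (1400, 1460), (1600, 1660)], (1010, 1649)),
    _tx("tA2.1", "ALPHA", "chr1", "+",
        [(1000, 1060), (1100, 1120), (1200, 1260), (1400, 1460), (1600, 1660)],
        (1010, 1650)),
    # BRAVO: coding-vs-3U pair (position 3250 is E2 in tB1, 3U in tB2).
    _tx("tB1.1", "BRAVO", "chr1", "+", [(3000, 3090), (3200, 3290)], (3010, 3279)),
    _tx("tB2.1", "BRAVO", "chr1", "+", [(3000, 3090), (3200, 3290)], (3010, 3070)),
    # CHARLIE: minus-strand multi-exon gene with an exon-skipping isoform.
    _tx("tC1.1", "CHARLIE", "chr1", "-",
        [(5000, 5060), (5200, 5260), (5400, 5460)], (5010, 5449)),
    _tx("tC2.1", "CHARLIE", "chr1", "-", [(5000, 5060), (5400, 5460)], (5010, 5449)),
    # DELTA: coding isoform plus a non-coding twin.
    _tx("tD1.1", "DELTA", "chr2", "+", [(1000, 1100)], (1010, 1091)),
    _tx("tD2.1", "DELTA", "chr2", "+", [(1000, 1100)], (1000, 1000)),
    # ECHO: minus-strand gene with no canonical assignment (nokCanon bucket).
    _tx("tE1.1", "ECHO", "chr2", "-", [(3000, 3200)], (3010, 3190)),
    # FOXT1: five isoforms; tF5 spans only the second exon block, so upstream
    # positions are OTR for it.
    _tx("tF1.1", "FOXT1", "chr2", "+", [(5000, 5300), (5600, 5900)], (5010, 5889)),
    _tx("tF2.1", "FOXT1", "chr2", "+", [(5000, 5300), (5600, 5900)], (5010, 5889)),
    _tx("tF3.1", "FOXT1", "chr2", "+", [(5000, 5300), (5600, 5900)], (5010, 5889)),
    _tx("tF4.1", "FOXT1", "chr2", "+", [(5000, 5300), (5600, 5900)], (5010, 5889)),
    _tx("tF5.1", "FOXT1", "chr2", "+", [(5600, 5900)], (5610, 5889)),
    # GOLF: silent in every group (mTPM-zero bucket).
    _tx("tG1.1", "GOLF", "chr2", "+", [(8000, 8100)], (8010, 8070)),
    # INDIA: all-zero medians; tI2 wins the tumor major call on Q3.
    _tx("tI1.1", "INDIA", "chr2", "+", [(9000, 9100)], (9010, 9070)),
    _tx("tI2.1", "INDIA", "chr2", "+", [(9000, 9100)], (9010, 9070)),
]

_CANONICAL = [
    CanonicalSet("ALPHA", uniprot_canonical="tA1.1", ucsc_canonical="tA1.1",
                 appris_principal="tA1.1"),
    CanonicalSet("BRAVO", uniprot_canonical="tB1.1"),
    CanonicalSet("CHARLIE", appris_principal="tC1.1"),
    CanonicalSet("DELTA", ucsc_canonical="tD1.1", appris_principal="tD1.1"),
    CanonicalSet("FOXT1", uniprot_canonical="tF2.1", ucsc_canonical="tF2.1",
                 appris_principal="tF2.1"),
    CanonicalSet("GOLF", ucsc_canonical="tG1.1"),
    CanonicalSet("INDIA", ucsc_canonical="tI1.1"),
]

_GENE_INFO = [
    {"gene_symbol": "ALPHA", "full_name": "alpha-1 sample antigen",
     "ensembl_gene_id": "ENSG00000000001"},
    {"gene_symbol": "BRAVO", "full_name": "bravo receptor 2",
     "ensembl_gene_id": "ENSG00000000002"},
    {"gene_symbol": "CHARLIE", "full_name": "charlie kinase",
     "ensembl_gene_id": "ENSG00000000003"},
    {"gene_symbol": "DELTA", "full_name": "delta binding protein",
     "ensembl_gene_id": "ENSG00000000004"},
    {"gene_symbol": "ECHO", "full_name": "echo homolog",
     "ensembl_gene_id": "ENSG00000000005"},
    {"gene_symbol": "FOXT1", "full_name": "forkhead box test 1",
     "ensembl_gene_id": "ENSG00000000006", "uniprot_id": "Q99999"},
    {"gene_symbol": "GOLF", "full_name": "golf associated factor",
     "ensembl_gene_id": "ENSG00000000007"},
    {"gene_symbol": "INDIA", "full_name": "india channel",
     "ensembl_gene_id": "ENSG00000000008"},
]

# Designed group median fractions (tumor, normal). 2.93e-4 vs 1e-5 gives the
# 29.3-fold switch; 4e-7 is the 0.40-TPM tumor-only isoform.
DESIGNED_MEDIANS: dict[str, tuple[float, float]] = {
    "tA1.1": (2e-5, 5e-5),
    "tA2.1": (8e-5, 1e-5),
    "tB1.1": (1e-5, 3e-5),
    "tB2.1": (6e-5, 1e-5),
    "tC1.1": (4e-5, 4e-5),
    "tC2.1": (1e-5, 1e-5),
    "tD1.1": (3e-5, 3e-5),
    "tD2.1": (1e-6, 1e-6),
    "tE1.1": (2e-5, 2e-5),
    "tF1.1": (4e-7, 0.0),
    "tF2.1": (2.93e-4, 1e-5),
    "tF3.1": (3e-5, 6.2e-6),
    "tF4.1": (1e-4, 7.76e-5),
    "tF5.1": (1.78e-5, 6.2e-6),
    "tG1.1": (0.0, 0.0),
    "tI1.1": (0.0, 0.0),
    "tI2.1": (0.0, 0.0),
}

# tI2 tumor: zero median but four top-rank patients at this fraction, so the
# tumor major call must fall back to Q3.
_Q3_SPECIAL = {"tI2.1": ("tumor", 2e-6, 4)}

# Designed variant placements: (chrom, pos0, expected element label per
# transcript). Labels are re-derived in tests via locate().
DESIGNED_PLACEMENTS: list[tuple[str, int, dict[str, str]]] = [
    ("chr1", 1430, {"tA1.1": "E3", "tA2.1": "E4"}),      # case-2 analogue
    ("chr1", 3250, {"tB1.1": "E2", "tB2.1": "3U"}),      # case-3 analogue
    ("chr1", 3005, {"tB1.1": "5U", "tB2.1": "5U"}),
    ("chr1", 5050, {"tC1.1": "E3", "tC2.1": "E2"}),      # minus-strand coding
    ("chr1", 5100, {"tC1.1": "I2", "tC2.1": "I1"}),
    ("chr2", 1095, {"tD1.1": "3U", "tD2.1": "E1"}),
    ("chr2", 3195, {"tE1.1": "5U"}),                     # minus-strand 5U
    ("chr2", 5100, {"tF1.1": "E1", "tF2.1": "E1", "tF3.1": "E1",
                    "tF4.1": "E1", "tF5.1": "OTR"}),
    ("chr2", 5700, {"tF1.1": "E2", "tF2.1": "E2", "tF3.1": "E2",
                    "tF4.1": "E2", "tF5.1": "E1"}),
    ("chr2", 11000, {}),                                  # intergenic
]


def make_gene_models(
    design: FixtureDesign, genome: Mapping[str, str]
) -> tuple[list[TranscriptModel], list[CanonicalSet], list[IsoformXref], list[dict]]:
    """The designed catalog plus its canonical sets, xrefs and gene info."""
    for t in _CATALOG:
        if t.chrom not in genome:
            raise GenerationError(f"design lacks chromosome {t.chrom}")
        if len(genome[t.chrom]) < t.tx_end:
            raise GenerationError(
                f"chromosome {t.chrom} too short for {t.transcript_id} "
                f"(needs {t.tx_end} bp)"
            )
    xrefs = []
    for i, t in enumerate(_CATALOG, start=1):
        if t.transcript_id == "tI1.1":
            continue  # deliberately no xref row: exercises the CDS fallback
        coding = t.cds_start < t.cds_end
        xrefs.append(
            IsoformXref(
                transcript_id=t.transcript_id,
                uniprot_id=f"UP{i:05d}" if coding else None,
                refseq_id=f"NM_{i:06d}" if coding else f"NR_{i:06d}",
                ensembl_tx_id=f"ENST{i:011d}",
                ccds_id=f"CCDS{i}" if coding else None,
                peptide_available=coding,
            )
        )
    return list(_CATALOG), list(_CANONICAL), xrefs, [dict(r) for r in _GENE_INFO]


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def _group_vector(rng: np.random.Generator, median: float, n: int) -> np.ndarray:
    """n values whose sample median is exactly ``median`` (n odd): the lower
    half jitters in [0.8m, 0.97m], the upper half in [1.03m, 1.2m]."""
    if median == 0.0:
        return np.zeros(n)
    half = (n - 1) // 2
    lower = median * rng.uniform(0.80, 0.97, size=half)
    upper = median * rng.uniform(1.03, 1.20, size=half)
    return np.concatenate([np.sort(lower), [median], np.sort(upper)])


def make_expression(
    design: FixtureDesign, models: Optional[list[TranscriptModel]] = None
) -> tuple[ExpressionTable, SampleSheet]:
    """Expression matrix + sample sheet realizing DESIGNED_MEDIANS exactly.

    Tumor patient ``replicate_patient_index`` contributes two aliquot columns
    whose mean is the assigned value.
    """
    if models is None:
        models = list(_CATALOG)
    rng = np.random.default_rng(design.seed + 1)
    cohort = design.cohort
    patients_t = [f"{cohort}-P{i + 1:02d}" for i in range(design.n_tumor_patients)]
    patients_n = [f"{cohort}-P{i + 1:02d}" for i in range(design.n_normal_patients)]

    sheet_rows = []
    columns: list[str] = []
    rep_idx = design.replicate_patient_index
    if not 0 <= rep_idx < design.n_tumor_patients:
        raise GenerationError("replicate_patient_index out of range")
    for i, p in enumerate(patients_t):
        sids = [f"S-{p}-T"] if i != rep_idx else [f"S-{p}-Ta", f"S-{p}-Tb"]
        for sid in sids:
            sheet_rows.append({"sample_id": sid, "patient_id": p, "cohort": cohort,
                               "sample_class": "tumor"})
            columns.append(sid)
    for p in patients_n:
        sid = f"S-{p}-N"
        sheet_rows.append({"sample_id": sid, "patient_id": p, "cohort": cohort,
                           "sample_class": "normal"})
        columns.append(sid)

    iso_ids = [t.transcript_id for t in models]
    gene_ids = pd.Series({t.transcript_id: t.gene_symbol for t in models})
    data = pd.DataFrame(0.0, index=iso_ids, columns=columns)

    for tid in iso_ids:
        m_t, m_n = DESIGNED_MEDIANS.get(tid, (0.0, 0.0))
        vec_t = _group_vector(rng, m_t, design.n_tumor_patients)
        vec_n = _group_vector(rng, m_n, design.n_normal_patients)
        special = _Q3_SPECIAL.get(tid)
        if special is not None:
            which, value, count = special
            vec = np.zeros(design.n_tumor_patients if which == "tumor"
                           else design.n_normal_patients)
            vec[-count:] = value
            if which == "tumor":
                vec_t = vec
            else:
                vec_n = vec
        # rank i -> patient i; the replicate patient holds a lower-half rank
        # whenever possible so aliquot jitter cannot disturb the median.
        for i, p in enumerate(patients_t):
            v = float(vec_t[i])
            if i == rep_idx:
                data.loc[tid, f"S-{p}-Ta"] = v * 0.98
                data.loc[tid, f"S-{p}-Tb"] = v * 1.02
            else:
                data.loc[tid, f"S-{p}-T"] = v
        for i, p in enumerate(patients_n):
            data.loc[tid, f"S-{p}-N"] = float(vec_n[i])

    table = ExpressionTable(data, gene_ids)
    sheet = SampleSheet(pd.DataFrame(sheet_rows).set_index("sample_id"))
    return table, sheet


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def make_vcf(
    design: FixtureDesign,
    models: list[TranscriptModel],
    genome: Mapping[str, str],
    include_indel: bool = True,
) -> list[str]:
    """VCF text lines covering every designed element category; REF alleles are
    read from the genome, so annotation never reports a reference mismatch."""
    for chrom, pos0, _ in DESIGNED_PLACEMENTS:
        if chrom not in genome or pos0 >= len(genome[chrom]):
            raise GenerationError(f"designed placement {chrom}:{pos0} outside genome")
    lines = ["##fileformat=VCFv4.2"]
    for chrom, length in sorted(design.chrom_lengths.items()):
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    records = []
    for chrom, pos0, _ in DESIGNED_PLACEMENTS:
        ref = genome[chrom][pos0]
        alt = _NEXT_BASE[ref]
        records.append((chrom, pos0 + 1, ref, alt))
    if include_indel:
        # 2-bp deletion inside ALPHA's third exon: location still reported,
        # consequence must come back unsupported_allele.
        pos0 = 1432
        ref = genome["chr1"][pos0 : pos0 + 2]
        records.append(("chr1", pos0 + 1, ref, ref[0]))
    records.sort(key=lambda r: (r[0], r[1]))
    for chrom, pos, ref, alt in records:
        lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.")
    return lines


# ---------------------------------------------------------------------------
# random structures for property tests
# ---------------------------------------------------------------------------

def make_random_models(
    rng: np.random.Generator,
    n: int,
    chrom: str = "chrR",
    max_exons: int = 6,
) -> tuple[list[TranscriptModel], dict[str, str]]:
    """n random valid transcripts tiled along one synthetic chromosome, with a
    genome covering them; used by brute-force property suites."""
    models = []
    cursor = 50
    for k in range(n):
        n_exons = int(rng.integers(1, max_exons + 1))
        exons = []
        pos = cursor
        for _ in range(n_exons):
            length = int(rng.integers(5, 61))
            exons.append((pos, pos + length))
            pos += length + int(rng.integers(5, 41))
        tx_start, tx_end = exons[0][0], exons[-1][1]
        strand = "+" if rng.random() < 0.5 else "-"
        if rng.random() < 0.2:
            cds = (tx_start, tx_start)  # non-coding
        else:
            a, b = sorted(int(x) for x in rng.integers(tx_start, tx_end + 1, size=2))
            cds = (a, b)
        models.append(
            _tx(f"tR{k:04d}.1", f"RGENE{k:04d}", chrom, strand, exons, cds)
        )
        cursor = tx_end + int(rng.integers(20, 80))
    genome_len = cursor + 100
    genome = {chrom: "".join(rng.choice(_BASES, size=genome_len))}
    return models, genome
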