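"""Shared fixtures: one designed study (seed 7) built once per session, plus
independent brute-force oracles used by multiple test modules."""

from __future__ import annotations

import numpy as np
import pytest

from isoscope import expression_stats as es
from isoscope import fixtures as fx
from isoscope import gene_models as gm


@pytest.fixture(scope="session")
def design():
    return fx.FixtureDesign(seed=7)


@pytest.fixture(scope="session")
def genome(design):
    return fx.make_genome(design)


@pytest.fixture(scope="session")
def catalog(design, genome):
    models, canonical, xrefs, gene_info = fx.make_gene_models(design, genome)
    return models, canonical, xrefs, gene_info


@pytest.fixture(scope="session")
def registry(catalog):
    models, canonical, xrefs, gene_info = catalog
    reg = gm.GeneRegistry(models)
    reg.add_canonical(canonical)
    reg.add_xrefs(xrefs)
    reg.add_gene_info(gene_info)
    return reg


@pytest.fixture(scope="session")
def study(design, catalog):
    models = catalog[0]
    table, sheet = fx.make_expression(design, models)
    return table, sheet


@pytest.fixture(scope="session")
def summaries(study):
    table, sheet = study
    return es.summarize_study(table, sheet)


@pytest.fixture(scope="session")
def vcf_lines(design, catalog, genome):
    return fx.make_vcf(design, catalog[0], genome)


@pytest.fixture(scope="session")
def random_models():
    rng = np.random.default_rng(20240901)
    return fx.make_random_models(rng, 200)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def quantile_oracle(values, q):
    """Linear interpolation between order statistics, written from the
    definition (not via numpy)."""
    xs = sorted(values)
    n = len(xs)
    if n == 1:
        return xs[0]
    h = (n - 1) * q
    lo = int(h)
    if lo == h:
        return xs[lo]
    frac = h - lo
    return xs[lo] + frac * (xs[lo + 1] - xs[lo])


def brute_force_elements(t):
    """Per-base element labels for every position in [tx_start-5, tx_end+5),
    derived by walking the transcript base-by-base in transcription order."""
    tx_positions = []  # genomic positions of transcript bases, transcription order
    for s, e in t.exons:
        tx_positions.extend(range(s, e))
    intron_positions = [
        p
        for p in range(t.tx_start, t.tx_end)
        if not any(s <= p < e for s, e in t.exons)
    ]
    if t.strand == "-":
        tx_positions = tx_positions[::-1]
    index_of = {p: i for i, p in enumerate(tx_positions)}
    cds_positions = {p for p in tx_positions if t.cds_start <= p < t.cds_end}
    cds_indices = sorted(index_of[p] for p in cds_positions)

    # exon ordinal per base: count exon boundaries crossed in transcription order
    exon_of = {}
    ordinal = 0
    prev = None
    for i, p in enumerate(tx_positions):
        if prev is None or abs(p - prev) != 1:
            ordinal += 1
        exon_of[p] = ordinal
        prev = p

    labels = {}
    for p in range(t.tx_start - 5, t.tx_end + 5):
        if p < t.tx_start or p >= t.tx_end:
            labels[p] = "OTR"
        elif p in index_of:
            if t.cds_start == t.cds_end:
                labels[p] = f"E{exon_of[p]}"
            elif p in cds_positions:
                labels[p] = f"E{exon_of[p]}"
            elif not cds_indices:
                # coding interval declared but intron-only: transcript bases
                # fall before/after it in transcription order
                labels[p] = _utr_side_no_cds(t, index_of[p], index_of)
            elif index_of[p] < cds_indices[0]:
                labels[p] = "5U"
            else:
                labels[p] = "3U"
        else:
            # intron: number of complete exons already transcribed
            upstream_exons = {
                exon_of[q]
                for q in tx_positions
                if (q < p if t.strand == "+" else q > p)
            }
            labels[p] = f"I{len(upstream_exons)}"
    return labels


def _utr_side_no_cds(t, idx, index_of):
    # order the declared (empty-overlap) CDS interval against transcript bases
    before = [
        i
        for p, i in index_of.items()
        if (p < t.cds_start if t.strand == "+" else p >= t.cds_end)
    ]
    return "5U" if idx in before else "3U"


COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def spliced_cds_oracle(t, genome_map):
    """Per-base reconstruction of the spliced CDS (untrimmed)."""
    seq = genome_map[t.chrom]
    positions = [
        p
        for s, e in t.exons
        for p in range(s, e)
        if t.cds_start <= p < t.cds_end
    ]
    if t.strand == "+":
        return "".join(seq[p] for p in positions)
    return "".join(COMPLEMENT[seq[p]] for p in reversed(positions))
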