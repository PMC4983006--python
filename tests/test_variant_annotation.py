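import numpy as np
import pytest

from isoscope import fixtures as fx
from isoscope import gene_models as gm
from isoscope import variant_annotation as va
from isoscope.errors import ReferenceMismatchError, UsageError, ValidationError

from conftest import brute_force_elements

TOY_GENOME = {"chr1": "NN" + "ATGTTGTAA" + "NNNN"}  # CDS at [2, 11)


def _toy_tx(strand="+"):
    return gm.TranscriptModel("toy.1", "TOY", "chr1", strand, 0, 13, 2, 11,
                              (0,), (13,))


class TestLocate:
    def test_otr_upstream(self):
        t = _toy_tx()
        assert va.locate(t, 20).label == "OTR"

    @pytest.mark.parametrize("tid,pos,label", [
        ("tA1.1", 1430, "E3"),
        ("tA2.1", 1430, "E4"),
        ("tB1.1", 3250, "E2"),
        ("tB2.1", 3250, "3U"),
        ("tC1.1", 5100, "I2"),
        ("tC2.1", 5100, "I1"),
        ("tE1.1", 3195, "5U"),   # minus strand: past cds_end is 5'
        ("tF5.1", 5100, "OTR"),
        ("tD2.1", 1095, "E1"),   # non-coding transcript: exonic is E
    ])
    def test_designed_positions(self, registry, tid, pos, label):
        assert va.locate(registry.models[tid], pos).label == label

    def test_intron_ordinal_transcription_order(self):
        # 8 exons on the minus strand: the gap after exon 7 (transcription
        # order) lies between genomic exons 0 and 1
        starts = tuple(range(0, 800, 100))
        ends = tuple(s + 50 for s in starts)
        t = gm.TranscriptModel("t", "g", "chr1", "-", 0, 750, 0, 0, starts, ends)
        assert va.locate(t, 60).label == "I7"

    def test_chrom_mismatch(self):
        with pytest.raises(ValidationError):
            va.locate(_toy_tx(), 5, chrom="chr2")

    def test_exhaustive_per_base_oracle_on_catalog(self, registry):
        for t in registry.models.values():
            expected = brute_force_elements(t)
            for pos, label in expected.items():
                assert va.locate(t, pos).label == label, (t.transcript_id, pos)

    def test_exhaustive_per_base_oracle_on_random_transcripts(self):
        models, _ = fx.make_random_models(np.random.default_rng(5), 60)
        for t in models:
            expected = brute_force_elements(t)
            for pos, label in expected.items():
                assert va.locate(t, pos).label == label, (t.transcript_id, pos)


class TestConsequence:
    def _v(self, pos0, ref, alt):
        return va.VariantRecord(chrom="chr1", pos=pos0 + 1, ref=ref, alt=alt)

    def test_missense(self):
        # codon 2 TTG -> TCG: Leu -> Ser
        c = va.consequence(_toy_tx(), TOY_GENOME, self._v(6, "T", "C"))
        assert (c.kind, c.ref_aa, c.alt_aa, c.aa_pos) == ("missense", "L", "S", 2)

    def test_synonymous(self):
        c = va.consequence(_toy_tx(), TOY_GENOME, self._v(5, "T", "C"))
        assert (c.kind, c.ref_aa, c.alt_aa) == ("synonymous", "L", "L")

    def test_nonsense(self):
        c = va.consequence(_toy_tx(), TOY_GENOME, self._v(6, "T", "A"))
        assert c.kind == "nonsense" and c.alt_aa == "*"

    def test_stop_lost(self):
        c = va.consequence(_toy_tx(), TOY_GENOME, self._v(9, "A", "C"))
        assert c.kind == "stop_lost"

    def test_minus_strand_twin_identical_call(self):
        # genome holds the reverse complement; mirrored SNV gives the same
        # amino-acid result (checked against a hand-derived oracle)
        cds = "ATGTTGTAA"
        genome = {"chr1": "NN" + gm.reverse_complement(cds) + "NN"}
        t = gm.TranscriptModel("m.1", "M", "chr1", "-", 0, 13, 2, 11, (0,), (13,))
        # codon2 TTG -> TCG means transcript index 4 T->C; transcript index i
        # maps to genomic position cds_end-1-i + nothing: pos = 10 - 4 = 6
        v = va.VariantRecord(chrom="chr1", pos=7, ref=genome["chr1"][6], alt="G")
        c = va.consequence(t, genome, v)
        assert (c.kind, c.ref_aa, c.alt_aa) == ("missense", "L", "S")

    def test_reference_mismatch(self):
        with pytest.raises(ReferenceMismatchError, match="7"):
            va.consequence(_toy_tx(), TOY_GENOME, self._v(6, "G", "C"))

    def test_non_snv_unsupported(self):
        c = va.consequence(_toy_tx(), TOY_GENOME, self._v(6, "TG", "T"))
        assert c.kind == "unsupported_allele"

    def test_noncoding_position(self):
        c = va.consequence(_toy_tx(), TOY_GENOME, self._v(11, "N", "A"))
        assert c.kind == "noncoding_position"

    def test_strand_symmetry_on_random_cds(self):
        rng = np.random.default_rng(17)
        codons = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                  if a + b + c not in ("TAA", "TAG", "TGA")]
        for _ in range(25):
            body = "".join(rng.choice(codons) for _ in range(8))
            cds = "ATG" + body + "TAA"
            L = len(cds)
            genome = {"c": cds + gm.reverse_complement(cds)}
            plus = gm.TranscriptModel("p.1", "P", "c", "+", 0, L, 0, L,
                                      (0,), (L,))
            minus = gm.TranscriptModel("n.1", "N", "c", "-", L, 2 * L, L, 2 * L,
                                       (L,), (2 * L,))
            k = int(rng.integers(0, L))
            ref = cds[k]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            vp = va.VariantRecord("c", k + 1, ref, alt)
            mpos = 2 * L - 1 - k
            vm = va.VariantRecord(
                "c", mpos + 1, genome["c"][mpos], va._COMPLEMENT_BASE[alt]
            )
            cp = va.consequence(plus, genome, vp)
            cm = va.consequence(minus, genome, vm)
            assert (cp.kind, cp.ref_aa, cp.alt_aa, cp.aa_pos) == (
                cm.kind, cm.ref_aa, cm.alt_aa, cm.aa_pos
            )


class TestRankIsoforms:
    def test_by_median_tpm(self, registry, summaries):
        ranked = va.rank_isoforms(registry.genes["FOXT1"], "LUAD", "tumor", summaries)
        assert ranked == ["tF2.1", "tF4.1", "tF3.1", "tF5.1", "tF1.1"]

    def test_zero_medians_fall_back_to_q3(self, registry, summaries):
        ranked = va.rank_isoforms(registry.genes["INDIA"], "LUAD", "tumor", summaries)
        assert ranked == ["tI2.1", "tI1.1"]

    def test_single_isoform(self, registry, summaries):
        assert va.rank_isoforms(registry.genes["ECHO"], "LUAD", "tumor", summaries) == ["tE1.1"]


@pytest.fixture(scope="module")
def annotated(vcf_lines, registry, summaries, genome):
    return va.annotate_vcf(vcf_lines, registry, summaries, "LUAD", "tumor",
                           genome=genome)


class TestAnnotateVcf:
    def test_all_nine_keys_declared(self, annotated):
        header = "\n".join(annotated.header_lines)
        for key in va.IE_HEADER_KEYS:
            assert f"##{key}=" in header
        for key in va.IE_RECORD_KEYS:
            assert f"##INFO=<ID={key}," in header

    def test_genic_records_carry_all_five_keys(self, annotated):
        for line in annotated.record_lines:
            info = line.split("\t")[7]
            if "IE_GE=." in info:
                assert "IE_IS" not in info
            else:
                for key in va.IE_RECORD_KEYS:
                    assert f"{key}=" in info

    def test_intergenic_record(self, annotated):
        hits = [l for l in annotated.record_lines if l.startswith("chr2\t11001\t")]
        assert len(hits) == 1
        assert hits[0].split("\t")[7] == "IE_GE=."

    def test_ie_is_sorted_and_sized(self, annotated, registry, summaries):
        line = next(l for l in annotated.record_lines if l.startswith("chr2\t5701\t"))
        info = dict(kv.split("=", 1) for kv in line.split("\t")[7].split(";"))
        entries = info["IE_IS"].split(",")
        assert len(entries) == 5
        ids = [e.split("|")[0] for e in entries]
        assert ids == va.rank_isoforms(registry.genes["FOXT1"], "LUAD", "tumor", summaries)
        mtpms = [float(e.split("|")[3]) for e in entries]
        assert mtpms == sorted(mtpms, reverse=True)

    def test_round_trip_idempotent(self, annotated, tmp_path):
        p = tmp_path / "out.vcf"
        annotated.write(p)
        reparsed = va.AnnotatedVCF(p.read_text().splitlines())
        assert reparsed.serialize() == annotated.serialize()

    def test_strip_recovers_input(self, annotated, vcf_lines):
        assert va.strip_ie_fields(annotated.lines) == list(vcf_lines)

    def test_rerun_deterministic(self, vcf_lines, registry, summaries, genome):
        a = va.annotate_vcf(vcf_lines, registry, summaries, "LUAD", "tumor", genome=genome)
        b = va.annotate_vcf(vcf_lines, registry, summaries, "LUAD", "tumor", genome=genome)
        assert a.serialize() == b.serialize()

    def test_output_is_valid_vcf_per_pysam(self, annotated, tmp_path):
        pysam = pytest.importorskip("pysam")
        p = tmp_path / "out.vcf"
        annotated.write(p)
        with pysam.VariantFile(str(p)) as vf:
            records = list(vf)
        assert len(records) == len(annotated.record_lines)
        genic = [r for r in records if r.info["IE_GE"][0] != "."]
        assert genic and all("IE_IS" in r.info for r in genic)

    def test_header_values(self, annotated, summaries):
        header = annotated.header_lines
        assert "##IE_CA=LUAD" in header
        assert "##IE_SA=tumor" in header
        n = summaries.group("LUAD", "tumor").n_patients
        assert f"##IE_SN={n}" in header

    def test_missing_fileformat_rejected(self, registry, summaries):
        with pytest.raises(UsageError):
            va.annotate_vcf(["#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"],
                            registry, summaries, "LUAD", "tumor")

    def test_existing_info_preserved(self, registry, summaries):
        lines = [
            "##fileformat=VCFv4.2",
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
            "chr1\t1431\trs1\tA\tC\t50\tPASS\tDP=10;AF=0.5",
        ]
        out = va.annotate_vcf(lines, registry, summaries, "LUAD", "tumor")
        info = out.record_lines[0].split("\t")[7]
        assert info.startswith("DP=10;AF=0.5;IE_GE=")


class TestCompareBackbones:
    def test_case1_concordant(self, registry, genome):
        # same structure isoforms: identical interpretation
        ref = genome["chr2"][5700]
        v = va.VariantRecord("chr2", 5701, ref, "A" if ref != "A" else "C")
        c = va.compare_backbones(v, registry.models["tF1.1"], registry.models["tF2.1"], genome)
        assert c.case == va.CASE_CONCORDANT
        assert c.exon_ordinal_changed is False

    def test_case2_exon_renumbered(self, registry, genome, vcf_lines):
        recs = va.parse_records(vcf_lines)
        v = next(r for r in recs if r.chrom == "chr1" and r.pos == 1431)
        c = va.compare_backbones(v, registry.models["tA2.1"], registry.models["tA1.1"], genome)
        assert c.exon_ordinal_changed is True
        assert c.major_location.label == "E4"
        assert c.canonical_location.label == "E3"
        assert c.case in (va.CASE_CONCORDANT, va.CASE_AA_CHANGED)
        # the designed frame shift makes the interpretations differ
        assert c.aa_interpretation_changed is True
        assert c.case == va.CASE_AA_CHANGED

    def test_case3_relocated_to_3u(self, registry, genome, vcf_lines):
        recs = va.parse_records(vcf_lines)
        v = next(r for r in recs if r.chrom == "chr1" and r.pos == 3251)
        c = va.compare_backbones(v, registry.models["tB2.1"], registry.models["tB1.1"], genome)
        assert c.case == va.CASE_VS_3U
        assert c.canonical_consequence is not None

    def test_gene_mismatch_rejected(self, registry, genome):
        v = va.VariantRecord("chr1", 1431, genome["chr1"][1430], "A")
        with pytest.raises(ValidationError):
            va.compare_backbones(v, registry.models["tA1.1"], registry.models["tB1.1"], genome)

    def test_shared_cds_utr_only_difference_is_concordant(self, genome):
        # same CDS, different 3'-UTR extent: every coding SNV concordant
        seq = genome["chr1"]
        a = gm.TranscriptModel("w1.1", "W", "chr1", "+", 1000, 1200, 1010, 1091,
                               (1000,), (1200,))
        b = gm.TranscriptModel("w2.1", "W", "chr1", "+", 1000, 1150, 1010, 1091,
                               (1000,), (1150,))
        for pos0 in range(1010, 1091):
            ref = seq[pos0]
            alt = "A" if ref != "A" else "G"
            v = va.VariantRecord("chr1", pos0 + 1, ref, alt)
            c = va.compare_backbones(v, a, b, genome)
            assert c.case == va.CASE_CONCORDANT


class TestDiscordanceSummary:
    def _published_counts(self):
        return va.DiscordanceSummary(
            canonical_definition="ucsc",
            n_total=147540,
            n_noncanonical_major=27655,
            n_coding_in_canonical=25544,
            n_still_coding_in_major=21599,
            n_intron=1308,
            n_5U=492,
            n_3U=2145,
            n_OTR=0,
            n_same_exon_number=9373,
            n_exon_number_changed=12226,
            n_aa_interpretation_changed=743,
        )

    def test_percentages_from_printed_counts(self):
        pct = self._published_counts().percentages()
        assert pct["coding_in_canonical"] == 92.4
        assert pct["still_coding"] == 84.6
        assert pct["relocated"] == 15.4
        assert pct["intron"] == 5.1
        assert pct["utr5"] == 1.9
        assert pct["utr3"] == 8.4
        assert pct["same_exon_number"] == 43.4

    def test_partition_enforced(self):
        with pytest.raises(ValidationError):
            va.DiscordanceSummary(
                canonical_definition="ucsc", n_total=10, n_noncanonical_major=10,
                n_coding_in_canonical=10, n_still_coding_in_major=5,
                n_intron=1, n_5U=1, n_3U=1, n_OTR=1,
                n_same_exon_number=3, n_exon_number_changed=2,
                n_aa_interpretation_changed=0,
            )

    def test_empty_summary(self):
        s = va.summarize_discordance([], "ucsc")
        assert s.n_total == 0 and s.percentages() == {}

    def test_unknown_definition_rejected(self):
        with pytest.raises(UsageError):
            va.summarize_discordance([], "refseq")

    def test_synthetic_tally_matches_brute_force(self, registry, summaries, genome):
        # 100 SNVs scattered over ALPHA/BRAVO: summary equals a direct recount
        rng = np.random.default_rng(23)
        comparisons = []
        pairs = [("tA2.1", "tA1.1"), ("tB2.1", "tB1.1")]
        for _ in range(100):
            major_id, canon_id = pairs[int(rng.integers(0, 2))]
            major, canon = registry.models[major_id], registry.models[canon_id]
            pos0 = int(rng.integers(major.tx_start - 10, major.tx_end + 10))
            ref = genome["chr1"][pos0]
            alt = "A" if ref != "A" else "T"
            v = va.VariantRecord("chr1", pos0 + 1, ref, alt)
            comparisons.append(va.compare_backbones(v, major, canon, genome))
        s = va.summarize_discordance(comparisons, "ucsc")
        coding = [c for c in comparisons if c.canonical_location.is_coding]
        assert s.n_coding_in_canonical == len(coding)
        assert s.n_still_coding_in_major == sum(
            1 for c in coding if c.major_location.is_coding
        )
        assert s.n_intron == sum(
            1 for c in coding if c.major_location.category == "I"
        )
        assert s.n_3U == sum(
            1 for c in coding if c.major_location.category == "3U"
        )
        assert s.n_5U == sum(
            1 for c in coding if c.major_location.category == "5U"
        )
        assert s.n_OTR == sum(
            1 for c in coding if c.major_location.category == "OTR"
        )
        # partition identities
        assert s.n_still_coding_in_major + s.n_relocated == s.n_coding_in_canonical
        assert s.n_same_exon_number + s.n_exon_number_changed == s.n_still_coding_in_major
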