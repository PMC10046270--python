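"""Readers/writers: TSV round-trips, SNV filtering, signature layout checks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twm.formats_io import (
    BASES,
    CHANNELS,
    CnvSegment,
    ReadReport,
    SignatureMatrix,
    VariantRecord,
    extract_context,
    read_segments,
    read_signature_matrix,
    read_variant_table,
    write_signature_matrix,
    write_variant_table,
)

VARIANT_HEADER = "case_id\tchrom\tpos\tref\talt\tvaf\tgene\tpathogenic\tctx5\tctx3\n"


class TestVariantRecord:
    @pytest.mark.parametrize(
        "kw",
        [
            {"ref": "C", "alt": "C"},
            {"vaf": 1.5},
            {"vaf": -0.1},
            {"pos": 0},
            {"ref": "N"},
        ],
    )
    def test_invariants_rejected(self, variant_factory, kw):
        with pytest.raises(ValueError):
            variant_factory(**kw)

    def test_context_flag(self, variant_factory):
        assert variant_factory().has_context
        assert not variant_factory(ctx5="N").has_context


class TestVariantTable:
    def test_empty_table(self, tmp_path):
        p = tmp_path / "v.tsv"
        p.write_text(VARIANT_HEADER)
        rep = ReadReport()
        assert read_variant_table(p, report=rep) == []
        assert rep.n_skipped_non_snv == 0

    def test_identity_row(self, tmp_path):
        p = tmp_path / "v.tsv"
        p.write_text(VARIANT_HEADER + "case1\tchr1\t100\tC\tT\t0.50\tTERT\ttrue\tA\tA\n")
        (rec,) = read_variant_table(p)
        assert rec == VariantRecord("case1", "chr1", 100, "C", "T", 0.5, "TERT", True, "A", "A")

    def test_insertion_skipped(self, tmp_path):
        p = tmp_path / "v.tsv"
        p.write_text(
            VARIANT_HEADER
            + "case1\tchr1\t100\tC\tT\t0.5\tTERT\tfalse\tA\tA\n"
            + "case1\tchr1\t200\tC\tCAT\t0.4\t\tfalse\tA\tA\n"
            + "case1\tchr2\t300\tG\tA\t0.3\tTTN\tfalse\tT\tG\n"
        )
        rep = ReadReport()
        recs = read_variant_table(p, report=rep)
        assert len(recs) == 2
        assert rep.n_skipped_non_snv == 1

    def test_bad_vaf_rejected_and_counted(self, tmp_path):
        p = tmp_path / "v.tsv"
        p.write_text(VARIANT_HEADER + "case1\tchr1\t100\tC\tT\t1.7\tTERT\tfalse\tA\tA\n")
        rep = ReadReport()
        assert read_variant_table(p, report=rep) == []
        assert rep.n_rejected == 1

    def test_missing_file_fatal(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_variant_table(tmp_path / "absent.tsv")

    @settings(max_examples=25, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(BASES),
                st.sampled_from(BASES),
                st.floats(0, 1),
                st.sampled_from(BASES + ("N",)),
                st.sampled_from(BASES + ("N",)),
                st.booleans(),
            ),
            max_size=20,
        )
    )
    def test_roundtrip_and_invariants(self, tmp_path_factory, rows):
        """Written tables re-read identically; emitted records always valid."""
        variants = [
            VariantRecord("c1", "chrX", i + 1, ref, alt, vaf, "G1", patho, c5, c3)
            for i, (ref, alt, vaf, c5, c3, patho) in enumerate(rows)
            if ref != alt
        ]
        p = tmp_path_factory.mktemp("rt") / "v.tsv"
        write_variant_table(variants, p)
        back = read_variant_table(p)
        assert back == variants
        for rec in back:
            assert 0 <= rec.vaf <= 1 and rec.ref != rec.alt and rec.pos >= 1


class TestVcfDialect:
    VCF = (
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=chr1,length=1000000>\n"
        '##INFO=<ID=GENE,Number=1,Type=String,Description="g">\n'
        '##FORMAT=<ID=AF,Number=A,Type=Float,Description="af">\n'
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="ad">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR\n"
        "chr1\t100\t.\tC\tT\t.\t.\tGENE=TERT\tAF:AD\t0.5:30,30\n"
        "chr1\t200\t.\tG\tA\t.\t.\tGENE=TTN\tAD\t45,15\n"
        "chr1\t300\t.\tG\tGA\t.\t.\t.\tAD\t40,20\n"
    )

    def test_vcf_reading(self, tmp_path):
        p = tmp_path / "case1.vcf"
        p.write_text(self.VCF)
        rep = ReadReport()
        recs = read_variant_table(p, dialect="vcf", case_id="case1", report=rep)
        assert [r.pos for r in recs] == [100, 200]
        assert recs[0].vaf == pytest.approx(0.5)  # FORMAT AF wins
        assert recs[1].vaf == pytest.approx(0.25)  # falls back to AD
        assert recs[1].gene == "TTN"
        assert rep.n_skipped_non_snv == 1  # the insertion


class TestSignatureMatrix:
    def test_uniform_single_signature(self, tmp_path):
        p = tmp_path / "s.tsv"
        pd.DataFrame({"Type": list(CHANNELS), "SBSU": [1 / 96] * 96}).to_csv(
            p, sep="\t", index=False
        )
        m = read_signature_matrix(p)
        assert m.k == 1
        np.testing.assert_allclose(m.probs[0], 1 / 96)

    def test_missing_channel_named(self, tmp_path):
        p = tmp_path / "s.tsv"
        pd.DataFrame({"Type": list(CHANNELS[:-1]), "S1": [1 / 95] * 95}).to_csv(
            p, sep="\t", index=False
        )
        with pytest.raises(ValueError, match=r"T\[T>G\]T"):
            read_signature_matrix(p)

    def test_two_signature_roundtrip_preserves_order(self, tmp_path):
        rng = np.random.default_rng(0)
        probs = rng.dirichlet(np.ones(96), size=2)
        m = SignatureMatrix(["SBS7a", "SBS5"], probs)
        p = tmp_path / "s.tsv"
        write_signature_matrix(m, p)
        back = read_signature_matrix(p)
        assert back.signature_ids == ("SBS7a", "SBS5")
        np.testing.assert_allclose(back.probs, m.probs, atol=1e-12)

    def test_bad_row_sum_fatal(self, tmp_path):
        p = tmp_path / "s.tsv"
        pd.DataFrame({"Type": list(CHANNELS), "SBAD": [0.02] * 96}).to_csv(
            p, sep="\t", index=False
        )
        with pytest.raises(ValueError, match="SBAD"):
            read_signature_matrix(p)

    def test_shuffled_channels_reordered_canonically(self, tmp_path):
        rng = np.random.default_rng(3)
        perm = rng.permutation(96)
        probs = rng.dirichlet(np.ones(96))
        df = pd.DataFrame({"Type": [CHANNELS[i] for i in perm], "S1": probs[perm]})
        p = tmp_path / "s.tsv"
        df.to_csv(p, sep="\t", index=False)
        np.testing.assert_allclose(read_signature_matrix(p).probs[0], probs, atol=1e-12)


class TestSegments:
    def test_read_with_one_bad_row(self, tmp_path):
        p = tmp_path / "seg.tsv"
        p.write_text(
            "chrom\tstart\tend\tcn_total\tcn_minor\n"
            "chr5\t1\t1000000\t2\t1\n"
            "chr5\t10\t5\t2\t1\n"  # start > end
            "chr5\t2000000\t3000000\t3\t1\n"
            "chr5\t4000000\t5000000\t2\t0\n"
        )
        rep = ReadReport()
        segs = read_segments(p, report=rep)
        assert len(segs) == 3
        assert rep.n_rejected == 1

    def test_minor_exceeding_major_rejected(self):
        with pytest.raises(ValueError):
            CnvSegment("chr1", 1, 10, 2, 2)

    def test_zero_based_shift(self, tmp_path):
        p = tmp_path / "seg.tsv"
        p.write_text("chrom\tstart\tend\tcn_total\tcn_minor\nchr1\t0\t100\t2\t1\n")
        (seg,) = read_segments(p, zero_based=True)
        assert (seg.start, seg.end, seg.length) == (1, 100, 100)


class TestExtractContext:
    def test_middle_and_edges(self):
        ref = {"chr1": "GACAT"}
        assert extract_context("chr1", 3, ref) == ("A", "A")
        assert extract_context("chr1", 1, ref) == ("N", "A")
        assert extract_context("chr1", 5, ref) == ("A", "N")

    def test_derived_lookup(self):
        assert extract_context("c", 3, {"c": "TTGGC"}) == ("T", "G")

    def test_absent_contig_fatal(self):
        with pytest.raises(KeyError):
            extract_context("chr9", 1, {"chr1": "ACGT"})
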