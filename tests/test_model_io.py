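"""Coordinate model and on-disk format round trips."""

import pytest

from snopipe.io import (
    AlignmentParseError,
    load_annotations,
    read_alignment_table,
    write_alignment_table,
    write_annotations,
    write_candidates_gff,
)
from snopipe.detect import detect_cd_candidates
from snopipe.model import (
    AlignedRead,
    GenomicInterval,
    Library,
    SnoRNAAnnotation,
    Substitution,
)
from snopipe.simulate import make_mini_snorna


class TestGenomicInterval:
    def test_rejects_empty_and_negative(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 5)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 0, 5, strand=".")

    def test_transcript_mapping_is_involutive_on_both_strands(self):
        for strand in "+-":
            iv = GenomicInterval("chr1", 100, 120, strand)
            for t in range(iv.length):
                assert iv.to_transcript(iv.to_genomic(t)) == t

    def test_minus_strand_five_prime_is_genomic_right_end(self):
        read = AlignedRead(GenomicInterval("chr1", 50, 70, "-"))
        assert read.five_prime == 69
        assert read.three_prime == 50


class TestAlignmentTable:
    def test_row_parses_to_read(self, tmp_path):
        p = tmp_path / "lib.tsv"
        p.write_text("chr1\t100\t120\tr1\t3\t+\tT:5:C\n")
        lib = read_alignment_table(p)
        (read,) = lib.reads
        assert read.interval == GenomicInterval("chr1", 100, 120, "+")
        assert read.copies == 3
        assert read.substitutions == (Substitution(5, "T", "C"),)
        assert lib.total_mapped == 3

    def test_dot_means_no_substitutions(self, tmp_path):
        p = tmp_path / "lib.tsv"
        p.write_text("chr1\t0\t20\tr1\t1\t-\t.\n")
        assert read_alignment_table(p).reads[0].substitutions == ()

    def test_header_overrides_total_mapped(self, tmp_path):
        p = tmp_path / "lib.tsv"
        p.write_text("#total_mapped=1000\nchr1\t0\t20\tr1\t1\t+\t.\n")
        assert read_alignment_table(p).total_mapped == 1000

    @pytest.mark.parametrize(
        "row",
        [
            "chr1\t120\t100\tr1\t1\t+\t.",  # end <= start
            "chr1\t100\t120\tr1\t1\t+",  # too few fields
            "chr1\t100\t120\tr1\t1\t+\tT:25:C",  # offset outside read
            "chr1\t100\t120\tr1\t1\t+\tT5C",  # malformed substitution
        ],
    )
    def test_malformed_rows_raise_located_errors(self, tmp_path, row):
        p = tmp_path / "lib.tsv"
        p.write_text(row + "\n")
        with pytest.raises(AlignmentParseError, match="line 1"):
            read_alignment_table(p)

    def test_write_read_round_trip(self, tmp_path):
        lib = Library(
            "x",
            "parclip",
            [
                AlignedRead(GenomicInterval("chr1", 5, 30, "-"), 4,
                            (Substitution(2, "A", "G"),)),
                AlignedRead(GenomicInterval("chr2", 0, 18, "+"), 1),
            ],
        )
        p = tmp_path / "lib.tsv"
        write_alignment_table(lib, p)
        back = read_alignment_table(p)
        assert back.reads == lib.reads
        assert back.total_mapped == lib.total_mapped


class TestAnnotationsGFF:
    def make_annotation(self, strand="+"):
        if strand == "+":
            boxes = {
                "C": GenomicInterval("chr1", 104, 111, "+"),
                "D": GenomicInterval("chr1", 150, 154, "+"),
            }
            return SnoRNAAnnotation(
                "SNO1", "CD", GenomicInterval("chr1", 100, 170, "+"), boxes
            )
        boxes = {
            "C": GenomicInterval("chr1", 159, 166, "-"),
            "D": GenomicInterval("chr1", 116, 120, "-"),
        }
        return SnoRNAAnnotation(
            "SNO1", "CD", GenomicInterval("chr1", 100, 170, "-"), boxes
        )

    def test_gff_round_trip_is_identity(self, tmp_path):
        ann = self.make_annotation()
        p = tmp_path / "ann.gff3"
        write_annotations([ann], p)
        (back,) = load_annotations(p)
        assert back == ann

    def test_one_based_conversion(self, tmp_path):
        p = tmp_path / "ann.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t101\t170\t.\t+\t.\tID=G1;sno_class=CD\n"
            "chr1\tsrc\tC_box\t105\t111\t.\t+\t.\tID=G1_C;Parent=G1\n"
            "chr1\tsrc\tD_box\t151\t154\t.\t+\t.\tID=G1_D;Parent=G1\n"
        )
        (ann,) = load_annotations(p)
        assert ann.interval == GenomicInterval("chr1", 100, 170, "+")
        assert ann.boxes["C"] == GenomicInterval("chr1", 104, 111, "+")

    def test_cd_gene_without_d_box_is_invalid(self, tmp_path):
        p = tmp_path / "ann.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t101\t170\t.\t+\t.\tID=G1;sno_class=CD\n"
            "chr1\tsrc\tC_box\t105\t111\t.\t+\t.\tID=G1_C;Parent=G1\n"
        )
        with pytest.raises(ValueError, match="requires C and D"):
            load_annotations(p)

    def test_minus_strand_box_order_checked_in_transcript_orientation(self, tmp_path):
        # C box genomically 3'-most is correct on the minus strand
        ann = self.make_annotation(strand="-")
        p = tmp_path / "ann.gff3"
        write_annotations([ann], p)
        (back,) = load_annotations(p)
        assert back == ann
        # the mirrored (wrong) order is rejected
        with pytest.raises(ValueError, match="5' of D box"):
            SnoRNAAnnotation(
                "BAD",
                "CD",
                GenomicInterval("chr1", 100, 170, "-"),
                {
                    "C": GenomicInterval("chr1", 104, 111, "-"),
                    "D": GenomicInterval("chr1", 150, 154, "-"),
                },
            )

    def test_unknown_box_label_dropped_with_warning(self, tmp_path):
        p = tmp_path / "ann.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t101\t170\t.\t+\t.\tID=G1;sno_class=CD\n"
            "chr1\tsrc\tC_box\t105\t111\t.\t+\t.\tID=G1_C;Parent=G1\n"
            "chr1\tsrc\tD_box\t151\t154\t.\t+\t.\tID=G1_D;Parent=G1\n"
            "chr1\tsrc\tQ_box\t120\t124\t.\t+\t.\tID=G1_Q;Parent=G1\n"
        )
        with pytest.warns(UserWarning, match="unknown box"):
            (ann,) = load_annotations(p)
        assert set(ann.boxes) == {"C", "D"}


class TestCandidateGFF:
    def test_write_then_load_recovers_boxes(self, tmp_path):
        _, seq = make_mini_snorna(7)
        anchor = GenomicInterval("chr9", 500, 500 + len(seq), "+")
        (cand,) = detect_cd_candidates(seq, genomic_anchor=anchor, source="m")
        p = tmp_path / "cand.gff3"
        write_candidates_gff([cand], p)
        text = p.read_text()
        assert text.startswith("##gff-version 3")
        (back,) = load_annotations(p)
        assert back.interval == cand.mature_interval
        assert back.boxes["C"] == cand.genomic_box("C")
        assert back.boxes["D"] == cand.genomic_box("D")

    def test_empty_candidate_set_still_valid_gff(self, tmp_path):
        p = tmp_path / "cand.gff3"
        write_candidates_gff([], p)
        assert p.read_text() == "##gff-version 3\n"
        assert load_annotations(p) == []


class TestSamAdapter:
    SAM = (
        "@HD\tVN:1.6\n"
        "@SQ\tSN:chr1\tLN:1000\n"
        "r1\t0\tchr1\t101\t60\t10M\t*\t0\t0\tACGTCCGTAC\t*\tMD:Z:4T5\n"
        "r2\t16\tchr1\t201\t60\t8M\t*\t0\t0\tGGGGCCCC\t*\tMD:Z:8\n"
        "r3\t4\t*\t0\t0\t*\t*\t0\t0\tAAAA\t*\n"
    )

    def test_sam_records_convert_to_read_model(self, tmp_path):
        from snopipe.io import read_sam

        p = tmp_path / "reads.sam"
        p.write_text(self.SAM)
        lib = read_sam(p)
        assert len(lib.reads) == 2  # unmapped r3 skipped
        r1, r2 = lib.reads
        # SAM is 1-based: POS 101 -> internal start 100
        assert r1.interval == GenomicInterval("chr1", 100, 110, "+")
        assert r1.substitutions == (Substitution(4, "T", "C"),)
        assert r2.interval == GenomicInterval("chr1", 200, 208, "-")
        assert r2.substitutions == ()


class TestBedgraph:
    def test_runs_collapse_and_minus_strand_flips(self, tmp_path):
        from snopipe.io import write_bedgraph

        iv = GenomicInterval("chr1", 100, 106, "-")
        p = tmp_path / "cov.bedgraph"
        write_bedgraph([5, 5, 2, 2, 2, 0], iv, p)
        lines = p.read_text().splitlines()
        assert lines[0].startswith("track type=bedGraph")
        # transcript orientation reversed back to genomic order
        assert lines[1:] == [
            "chr1\t100\t101\t0",
            "chr1\t101\t104\t2",
            "chr1\t104\t106\t5",
        ]
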