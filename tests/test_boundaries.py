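"""Box-relative boundary histograms, modal boundaries, origin classification."""

from collections import Counter

import pytest

from snopipe.boundaries import (
    BoundaryProfile,
    classify_library_origins,
    classify_read_origin,
    end_histograms,
    export_boundary_matrix,
    long_short_agreement,
    mature_boundaries,
    modal_boundary,
)
from snopipe.model import AlignedRead, GenomicInterval, Library, SnoRNAAnnotation


def annotation(strand="+", chrom="chr1"):
    if strand == "+":
        boxes = {
            "C": GenomicInterval(chrom, 110, 117, "+"),
            "D": GenomicInterval(chrom, 150, 154, "+"),
        }
        iv = GenomicInterval(chrom, 105, 158, "+")
    else:
        boxes = {
            "C": GenomicInterval(chrom, 143, 150, "-"),
            "D": GenomicInterval(chrom, 106, 110, "-"),
        }
        iv = GenomicInterval(chrom, 102, 155, "-")
    return SnoRNAAnnotation("SNO", "CD", iv, boxes)


def lib(reads, assay="srna", name="L"):
    return Library(name, assay, reads)


class TestEndHistograms:
    def test_plus_strand_offsets(self):
        # 5' end 4 nt upstream of C box start (110), 3' end 2 nt past D end
        ann = annotation()
        reads = [AlignedRead(GenomicInterval("chr1", 106, 156, "+"), 5)]
        prof = end_histograms(ann, lib(reads))
        assert prof.start_hist == Counter({-4: 5})
        assert prof.end_hist == Counter({2: 5})

    def test_minus_strand_offsets_mirror(self):
        ann = annotation("-")
        # C box [143,150): 5' end 4 nt upstream = genomic 153; D box [106,110):
        # 3' end 2 nt downstream = genomic 104
        reads = [AlignedRead(GenomicInterval("chr1", 104, 154, "-"), 3)]
        prof = end_histograms(ann, lib(reads))
        assert prof.start_hist == Counter({-4: 3})
        assert prof.end_hist == Counter({2: 3})

    def test_histogram_mass_equals_overlapping_copies(self):
        ann = annotation()
        reads = [
            AlignedRead(GenomicInterval("chr1", 106, 156, "+"), 5),
            AlignedRead(GenomicInterval("chr1", 120, 140, "+"), 2),
            AlignedRead(GenomicInterval("chr1", 500, 520, "+"), 9),  # far away
        ]
        prof = end_histograms(ann, lib(reads))
        assert sum(prof.start_hist.values()) == 7
        assert sum(prof.end_hist.values()) == 7

    def test_mixture_modal_end(self):
        ann = annotation()
        reads = [
            AlignedRead(GenomicInterval("chr1", 106, 156, "+"), 6),  # end +2
            AlignedRead(GenomicInterval("chr1", 106, 159, "+"), 4),  # end +5
        ]
        prof = end_histograms(ann, lib(reads))
        assert prof.modal_end == 2


class TestModalBoundary:
    def test_plain_argmax(self):
        prof = BoundaryProfile("S", Counter({-4: 10, -5: 3}), Counter({2: 1}))
        assert modal_boundary(prof) == (-4, 2)

    def test_tie_breaks_toward_canonical_then_zero(self):
        prof = BoundaryProfile("S", Counter({-4: 5, -5: 5}), Counter({2: 2, 9: 2}))
        assert modal_boundary(prof) == (-4, 2)

    def test_empty_histogram_is_an_error(self):
        prof = BoundaryProfile("S")
        with pytest.raises(ValueError, match="empty"):
            modal_boundary(prof)


class TestAgreement:
    def test_identical_boundary_model_agrees_fully(self):
        ann = annotation()
        reads = [AlignedRead(GenomicInterval("chr1", 106, 156, "+"), 10)]
        start, end = long_short_agreement([ann], lib(reads), lib(reads), top_n=1)
        assert (start, end) == (1.0, 1.0)

    def test_jittered_short_library_halves_end_agreement(self):
        anns = [annotation(chrom=f"chr{i}") for i in range(4)]
        long_reads, short_reads = [], []
        for i, ann in enumerate(anns):
            long_reads.append(AlignedRead(GenomicInterval(f"chr{i}", 106, 156, "+"), 10))
            # 3' ends shifted +2 for half of the snoRNAs in the short library
            end = 156 if i < 2 else 158
            short_reads.append(AlignedRead(GenomicInterval(f"chr{i}", 106, end, "+"), 10))
        start, end = long_short_agreement(anns, lib(long_reads), lib(short_reads), top_n=4)
        assert start == 1.0
        assert end == 0.5

    def test_top_n_zero_rejected(self):
        with pytest.raises(ValueError):
            long_short_agreement([annotation()], lib([]), lib([]), top_n=0)

    def test_top_n_above_available_warns(self):
        ann = annotation()
        reads = [AlignedRead(GenomicInterval("chr1", 106, 156, "+"), 1)]
        with pytest.warns(UserWarning, match="using all"):
            long_short_agreement([ann], lib(reads), lib(reads), top_n=50)

    def test_recovers_generator_boundaries(
        self, sim_annotations, long_srna_library, short_srna_library, sim_config
    ):
        """Libraries simulated from one boundary model agree on modal ends for
        nearly all top snoRNAs."""
        start, end = long_short_agreement(
            sim_annotations, long_srna_library, short_srna_library,
            top_n=len(sim_annotations),
        )
        assert start >= 0.9
        assert end >= 0.9


class TestOriginClassification:
    mature = GenomicInterval("chr1", 106, 156, "+")

    def test_five_prime_derived(self):
        read = AlignedRead(GenomicInterval("chr1", 106, 130, "+"))
        assert classify_read_origin(read, self.mature) == "five_prime_derived"

    def test_spanning_full_length_read(self):
        read = AlignedRead(GenomicInterval("chr1", 106, 156, "+"))
        assert classify_read_origin(read, self.mature) == "spanning"

    def test_tolerance_boundary(self):
        inside = AlignedRead(GenomicInterval("chr1", 108, 130, "+"))
        beyond = AlignedRead(GenomicInterval("chr1", 109, 130, "+"))
        assert classify_read_origin(inside, self.mature, tolerance=2) == "five_prime_derived"
        assert classify_read_origin(beyond, self.mature, tolerance=2) == "internal"

    def test_minus_strand_five_prime_is_right_end(self):
        mature = GenomicInterval("chr1", 106, 156, "-")
        read = AlignedRead(GenomicInterval("chr1", 130, 156, "-"))
        assert classify_read_origin(read, mature) == "five_prime_derived"

    def test_fractions_match_generator_mixture(
        self, sim_config, sim_annotations, long_srna_library, short_srna_library
    ):
        """Origin-class fractions on terminus-derived synthetic sdRNA reads
        recover the generator mixture within 3 binomial standard errors,
        after accounting for end offsets beyond the classification window."""
        mature = {
            ann.id: mature_boundaries(ann, end_histograms(ann, long_srna_library))
            for ann in sim_annotations
        }
        fractions = classify_library_origins(
            sim_annotations, short_srna_library, mature
        )
        mix = sim_config.origin_mixture
        # 3'-derived reads with end offsets > tolerance away from the modal
        # end are classified internal by design
        end_dist = sim_config.end_offset_dist
        within = sum(p for off, p in end_dist.items() if abs(off - 2) <= 2)
        expected = {
            "five_prime_derived": mix["five_prime_derived"],
            "three_prime_derived": mix["three_prime_derived"] * within,
        }
        n = sum(r.copies for r in short_srna_library.reads)
        for label, exp in expected.items():
            se = (exp * (1 - exp) / n) ** 0.5
            assert abs(fractions[label] - exp) <= 3 * se + 0.01, label


class TestBoundaryMatrix:
    def test_round_trip_reconstructs_histograms(self):
        profs = [
            BoundaryProfile("A", Counter({-4: 3, -5: 1}), Counter({2: 4})),
            BoundaryProfile("B", Counter({-4: 2}), Counter({3: 1, 5: 1})),
        ]
        table = export_boundary_matrix(profs, {"A": ({-4, -5}, {2}), "B": (set(), set())})
        assert list(table["sno_id"].unique()) == ["A", "B"]
        a_start = table[(table.sno_id == "A") & (table.end == "five_prime")]
        assert Counter(dict(zip(a_start.offset, a_start["count"]))) == profs[0].start_hist
        assert a_start.stem_paired.all()
        b_rows = table[table.sno_id == "B"]
        assert not b_rows.stem_paired.any()
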