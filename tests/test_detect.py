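"""C/D box detector: motif scans, stem search, candidate calling, filters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracle_detect import candidate_tuple, oracle_detect
from snopipe.detect import (
    conservation_filter,
    detect_cd_candidates,
    evaluate_specificity,
    filter_expression,
    find_terminal_stem,
    scan_c_box,
    scan_d_box,
)
from snopipe.model import AlignedRead, GenomicInterval, Library
from snopipe.seq import revcomp
from snopipe.simulate import make_mini_snorna

# 5-nt G/C flank, C box, clean 7-nt guide, D box, complementary flank
TOY = "GGCGC" + "ATGATGA" + "CCGTACC" + "CTGA" + "GCGCC"


class TestBoxScans:
    def test_c_box_exact_consensus(self):
        (hit,) = scan_c_box("AUGAUGA")
        assert (hit.start, hit.mismatches) == (0, 0)

    def test_c_box_one_mismatch_at_last_position(self):
        (hit,) = scan_c_box("GUGAUGU")
        assert hit.mismatches == 1

    def test_c_box_two_mismatches_rejected(self):
        assert scan_c_box("CUGCUGA") == []

    def test_r_position_counts_a_or_g_as_match(self):
        assert scan_c_box("AUGAUGA")[0].mismatches == 0
        assert scan_c_box("GUGAUGA")[0].mismatches == 0
        assert scan_c_box("CUGAUGA")[0].mismatches == 1

    def test_n_never_matches(self):
        assert scan_c_box("NUGAUGN") == []
        assert scan_c_box("AUGAUGN")[0].mismatches == 1

    def test_too_short_sequence_yields_nothing(self):
        assert scan_c_box("AUGAUG") == []

    @pytest.mark.parametrize(
        "motif,expected", [("CUGA", 1), ("AUGA", 1), ("GUGA", 0), ("UUGA", 0)]
    )
    def test_d_box_motifs(self, motif, expected):
        assert len(scan_d_box(motif)) == expected

    def test_dna_input_equivalent_to_rna(self):
        assert scan_c_box("ATGATGA") == scan_c_box("AUGAUGA")
        assert scan_d_box("CTGA") == scan_d_box("CUGA")


class TestTerminalStem:
    def test_gc_rich_windows_pair(self):
        stem = find_terminal_stem("UAGGCG", "CGCCUA")
        assert stem is not None
        assert stem.n_pairs >= 4
        assert stem.n_gc >= 2

    def test_all_au_stem_rejected_for_gc_minimum(self):
        assert find_terminal_stem("AAAUUU", "AAAUUU") is None

    def test_empty_window_gives_no_stem(self):
        assert find_terminal_stem("", "GCGC") is None

    def test_gu_wobble_only_with_flag(self):
        # duplex needs one G-U pair: G-C, G-U, U-A, G-C reading antiparallel
        up, down = "GGUG", "CAUC"
        assert find_terminal_stem(up, down, min_pairs=4) is None
        stem = find_terminal_stem(up, down, min_pairs=4, allow_gu=True)
        assert stem is not None and stem.n_pairs == 4

    def test_relaxing_thresholds_is_monotone(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            up = "".join(rng.choice(list("ACGU"), size=10))
            down = "".join(rng.choice(list("ACGU"), size=10))
            strict = find_terminal_stem(up, down, min_pairs=5, min_gc=3)
            loose = find_terminal_stem(up, down, min_pairs=4, min_gc=2)
            if strict is not None:
                assert loose is not None


class TestDetect:
    def test_toy_sequence_single_candidate(self):
        (cand,) = detect_cd_candidates(TOY)
        assert cand.guide_len == 7
        assert cand.stem.n_pairs >= 4
        assert cand.stem.n_gc >= 2
        assert cand.mature_span == (0, len(TOY))

    def test_mutated_d_box_kills_candidate(self):
        broken = TOY.replace("CTGA", "GTGA")
        assert detect_cd_candidates(broken) == []

    def test_mini_snorna_structures(self):
        """Synthetic mini-snoRNA stand-ins: shortest one has a 27-nt mature
        form with a 7-nt guide; the longer two have 14- and 15-nt guides."""
        results = {}
        for g in (7, 14, 15):
            _, seq = make_mini_snorna(g)
            (cand,) = detect_cd_candidates(seq)
            results[g] = (cand.mature_length, cand.guide_len)
        assert results[7] == (27, 7)
        assert results[14][1] == 14
        assert results[15][1] == 15

    @given(st.integers(0, 10_000))
    @settings(max_examples=80, deadline=None)
    def test_matches_bruteforce_oracle_on_random_sequences(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 61))
        seq = "".join(rng.choice(list("ACGU"), size=n))
        got = [candidate_tuple(c) for c in detect_cd_candidates(seq)]
        assert got == oracle_detect(seq)

    def test_strand_aware_detection_recovers_genomic_boxes(self, sim_genome):
        """Scanning the transcript-oriented sequence of either strand yields
        candidates whose genomic box coordinates match the embedded truth."""
        genome, truths = sim_genome
        chrom = genome["chr"]
        seen_strands = set()
        for truth in truths[:12]:
            lo, hi = truth.locus.start - 20, truth.locus.end + 20
            anchor = GenomicInterval("chr", lo, hi, truth.locus.strand)
            window = chrom[lo:hi]
            if truth.locus.strand == "-":
                window = revcomp(window)
            cands = detect_cd_candidates(window, genomic_anchor=anchor)
            assert any(
                c.genomic_box("C") == truth.boxes["C"]
                and c.genomic_box("D") == truth.boxes["D"]
                for c in cands
            ), truth.sno_id
            seen_strands.add(truth.locus.strand)
        assert seen_strands == {"+", "-"}

    def test_monotone_in_stem_thresholds(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            seq = "".join(rng.choice(list("ACGU"), size=60))
            strict = detect_cd_candidates(seq, min_pairs=5, min_gc=3)
            loose = detect_cd_candidates(seq, min_pairs=4, min_gc=2)
            strict_c = {c.c_box.start for c in strict}
            loose_c = {c.c_box.start for c in loose}
            assert strict_c <= loose_c


class TestFilters:
    def anchored_candidate(self):
        anchor = GenomicInterval("chr1", 1000, 1000 + len(TOY), "+")
        (cand,) = detect_cd_candidates(TOY, genomic_anchor=anchor)
        return cand

    def lib(self, reads, assay="srna"):
        return Library("L", assay, reads)

    def full_cover_read(self, cand, copies=1):
        return AlignedRead(cand.mature_interval, copies)

    def test_kept_at_threshold_equality(self):
        cand = self.anchored_candidate()
        srna = self.lib([self.full_cover_read(cand)])
        clip = self.lib([self.full_cover_read(cand)], "parclip")
        # single full-cover read in a one-read library = 1e6/29 TPM per nt >= 1
        assert filter_expression([cand], srna, [clip]) == [cand]

    def test_short_srna_read_ignored_by_half_coverage_rule(self):
        cand = self.anchored_candidate()
        iv = cand.mature_interval
        short = AlignedRead(
            GenomicInterval(iv.chrom, iv.start, iv.start + iv.length * 2 // 5, "+")
        )
        srna = self.lib([short])
        clip = self.lib([self.full_cover_read(cand)], "parclip")
        assert filter_expression([cand], srna, [clip]) == []

    def test_no_clip_support_drops_candidate(self):
        cand = self.anchored_candidate()
        srna = self.lib([self.full_cover_read(cand, copies=100)])
        far = AlignedRead(GenomicInterval("chr1", 0, 30, "+"))
        clip = self.lib([far], "parclip")
        assert filter_expression([cand], srna, [clip]) == []

    def test_no_libraries_is_an_error(self):
        with pytest.raises(ValueError):
            filter_expression([], self.lib([]), [])

    def test_conservation_mean_over_eleven_box_nucleotides(self):
        cand = self.anchored_candidate()
        c_box = cand.genomic_box("C")
        d_box = cand.genomic_box("D")
        ones = {p: 1.0 for p in range(c_box.start, c_box.end)}
        mean, passed = conservation_filter(cand, ones)
        assert mean == pytest.approx(7 / 11)
        assert passed
        boundary = {p: 0.25 for p in
                    list(range(c_box.start, c_box.end)) + list(range(d_box.start, d_box.end))}
        mean, passed = conservation_filter(cand, boundary)
        assert mean == pytest.approx(0.25)
        assert not passed  # strictly greater required

    def test_specificity_counts_detectable_sequences(self):
        rng = np.random.default_rng(0)
        neg = ["".join(rng.choice(list("ACGU"), size=40)) for _ in range(5)]
        counts = evaluate_specificity({"pos": [TOY, TOY], "neg": neg, "empty": []})
        assert counts["pos"] == 2
        assert counts["empty"] == 0
        assert 0 <= counts["neg"] <= 5
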