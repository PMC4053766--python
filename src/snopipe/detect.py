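"""C/D box snoRNA gene finder.

The detector searches a transcript-oriented sequence for a C box
(consensus RUGAUGA, R = A or G, allowing one mismatch) 5' of a D box
(MUGA, M = A or C, exact), then requires a compact terminal closing stem:
a contiguous antiparallel duplex of at least four canonical Watson-Crick
base pairs, at least two of them G-C/C-G, formed between the 10 nucleotides
immediately 5' of the C box and the 10 nucleotides immediately 3' of the
D box.  The mature candidate spans from the outermost paired nucleotide of
the 5' stem arm to the outermost paired nucleotide of the 3' arm.

G-U wobble pairs are excluded from "canonical" by default; ``allow_gu``
re-admits them.  U and T are treated as equivalent on input; candidate
sequences are reported as RNA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

from .model import GenomicInterval, Library
from .seq import as_rna, is_wc_pair

C_BOX_PATTERN = "RUGAUGA"
C_BOX_LEN = 7
D_BOX_MOTIFS = ("CUGA", "AUGA")
D_BOX_LEN = 4

DEFAULT_EXTENSION = 10
DEFAULT_MIN_PAIRS = 4
DEFAULT_MIN_GC = 2


@dataclass(frozen=True)
class BoxMotifHit:
    box_type: str  # "C" or "D"
    start: int  # 0-based offset in the scanned sequence
    length: int
    mismatches: int

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class TerminalStem:
    """Contiguous antiparallel duplex closing the snoRNA.

    ``pairs`` holds (upstream-window offset, downstream-window offset) tuples;
    offsets are relative to the start of each 10-nt search window.
    """

    pairs: tuple[tuple[int, int], ...]
    n_pairs: int
    n_gc: int
    up_window_len: int
    down_window_len: int

    @property
    def up_arm(self) -> tuple[int, int]:
        """Half-open span of the 5' arm within the upstream window."""
        offs = [p[0] for p in self.pairs]
        return min(offs), max(offs) + 1

    @property
    def down_arm(self) -> tuple[int, int]:
        offs = [p[1] for p in self.pairs]
        return min(offs), max(offs) + 1


@dataclass(frozen=True)
class CDBoxCandidate:
    """A detected C/D box snoRNA candidate.

    Box hit offsets and ``mature_span`` are relative to the scanned sequence;
    ``mature_interval`` and ``genomic_box``/``genomic_stem_arm`` give genomic
    coordinates when the scan was anchored.
    """

    id: str
    sequence: str  # mature candidate sequence (RNA)
    c_box: BoxMotifHit
    d_box: BoxMotifHit
    stem: TerminalStem
    mature_span: tuple[int, int]  # half-open, in scanned-sequence coordinates
    mature_interval: GenomicInterval | None = None
    source: str = ""

    @property
    def guide_len(self) -> int:
        """Nucleotides between the C box end and the D box start."""
        return self.d_box.start - self.c_box.end

    @property
    def mature_length(self) -> int:
        return self.mature_span[1] - self.mature_span[0]

    def _local_box_span(self, label: str) -> tuple[int, int]:
        hit = self.c_box if label == "C" else self.d_box
        return hit.start, hit.end

    def _local_arm_span(self, which: str) -> tuple[int, int]:
        if which == "up":
            lo, hi = self.stem.up_arm
            base = self.c_box.start - self.stem.up_window_len
        else:
            lo, hi = self.stem.down_arm
            base = self.d_box.end
        return base + lo, base + hi

    def _anchor_to_genomic(self, lo: int, hi: int) -> GenomicInterval:
        anchor = self.mature_interval
        if anchor is None:
            raise ValueError("candidate has no genomic anchor")
        # mature_interval covers mature_span; map scanned-sequence offsets.
        m_lo, m_hi = self.mature_span
        if anchor.strand == "+":
            start = anchor.start + (lo - m_lo)
            return GenomicInterval(anchor.chrom, start, start + (hi - lo), "+")
        start = anchor.end - (hi - m_lo)
        return GenomicInterval(anchor.chrom, start, start + (hi - lo), "-")

    def genomic_box(self, label: str) -> GenomicInterval:
        return self._anchor_to_genomic(*self._local_box_span(label))

    def genomic_stem_arm(self, which: str) -> GenomicInterval:
        return self._anchor_to_genomic(*self._local_arm_span(which))


def scan_c_box(sequence: str, max_mismatches: int = 1) -> list[BoxMotifHit]:
    """All offsets whose 7-mer is within ``max_mismatches`` of RUGAUGA.

    A or G at the degenerate first position counts as zero mismatches;
    N never matches any pattern position.
    """
    seq = as_rna(sequence)
    hits = []
    for i in range(len(seq) - C_BOX_LEN + 1):
        window = seq[i : i + C_BOX_LEN]
        mm = 0
        for pos, base in enumerate(window):
            allowed = "AG" if C_BOX_PATTERN[pos] == "R" else C_BOX_PATTERN[pos]
            if base not in allowed:  # N is never in the allowed set
                mm += 1
                if mm > max_mismatches:
                    break
        if mm <= max_mismatches:
            hits.append(BoxMotifHit("C", i, C_BOX_LEN, mm))
    return hits


def scan_d_box(sequence: str) -> list[BoxMotifHit]:
    """All exact CUGA/AUGA occurrences."""
    seq = as_rna(sequence)
    return [
        BoxMotifHit("D", i, D_BOX_LEN, 0)
        for i in range(len(seq) - D_BOX_LEN + 1)
        if seq[i : i + D_BOX_LEN] in D_BOX_MOTIFS
    ]


def find_terminal_stem(
    upstream_window: str,
    downstream_window: str,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    min_gc: int = DEFAULT_MIN_GC,
    allow_gu: bool = False,
) -> TerminalStem | None:
    """Best compact closing stem between the two flanking windows, or None.

    All contiguous antiparallel duplex placements are enumerated; upstream
    offset ``i + k`` pairs downstream offset ``j + L - 1 - k``.  Among valid
    stems the winner maximises pair count, then G-C count, then minimises the
    summed distance of the arms to the boxes (upstream arm to the window's 3'
    end, downstream arm to the window's 5' end), with remaining ties broken
    toward the smaller downstream offset.
    """
    up = as_rna(upstream_window)
    down = as_rna(downstream_window)
    if not up or not down:
        return None
    best: tuple | None = None
    best_stem: TerminalStem | None = None
    max_len = min(len(up), len(down))
    for length in range(min_pairs, max_len + 1):
        for i in range(len(up) - length + 1):
            for j in range(len(down) - length + 1):
                pairs = []
                gc = 0
                ok = True
                for k in range(length):
                    a, b = up[i + k], down[j + length - 1 - k]
                    if not is_wc_pair(a, b, allow_gu):
                        ok = False
                        break
                    pairs.append((i + k, j + length - 1 - k))
                    if {a, b} == {"G", "C"}:
                        gc += 1
                if not ok or gc < min_gc:
                    continue
                up_gap = len(up) - (i + length)  # nts between 5' arm and C box
                down_gap = j  # nts between D box and 3' arm
                score = (-length, -gc, up_gap + down_gap, j, i)
                if best is None or score < best:
                    best = score
                    best_stem = TerminalStem(
                        tuple(pairs), length, gc, len(up), len(down)
                    )
    return best_stem


def _candidate_rank(cand: CDBoxCandidate) -> tuple:
    return (
        -cand.stem.n_pairs,
        -cand.stem.n_gc,
        cand.mature_length,
        cand.d_box.start,
    )


def detect_cd_candidates(
    sequence: str,
    genomic_anchor: GenomicInterval | None = None,
    extension: int = DEFAULT_EXTENSION,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    min_gc: int = DEFAULT_MIN_GC,
    allow_gu: bool = False,
    c_max_mismatches: int = 1,
    source: str = "",
) -> list[CDBoxCandidate]:
    """Detect C/D box snoRNA candidates in a transcript-oriented sequence.

    Every (C box, D box) pair with the C box entirely 5' of the D box is
    tested for a closing stem in the ``extension``-nt flanking windows.
    Candidates sharing a C box are reduced to the best-stem one; candidates
    with distinct C boxes are all reported.

    When ``genomic_anchor`` is given it must be the genomic interval of
    ``sequence`` (whose strand defines the transcript orientation);
    candidates then carry genomic mature intervals.
    """
    seq = as_rna(sequence)
    c_hits = scan_c_box(seq, c_max_mismatches)
    d_hits = scan_d_box(seq)
    per_c_best: dict[int, CDBoxCandidate] = {}
    for c in c_hits:
        for d in d_hits:
            if d.start < c.end:
                continue
            up = seq[max(0, c.start - extension) : c.start]
            down = seq[d.end : d.end + extension]
            stem = find_terminal_stem(up, down, min_pairs, min_gc, allow_gu)
            if stem is None:
                continue
            up_lo, _ = stem.up_arm
            _, down_hi = stem.down_arm
            mature_lo = (c.start - len(up)) + up_lo
            mature_hi = d.end + down_hi
            cand = CDBoxCandidate(
                id="",
                sequence=seq[mature_lo:mature_hi],
                c_box=c,
                d_box=d,
                stem=stem,
                mature_span=(mature_lo, mature_hi),
                source=source,
            )
            prev = per_c_best.get(c.start)
            if prev is None or _candidate_rank(cand) < _candidate_rank(prev):
                per_c_best[c.start] = cand

    out = []
    for idx, (c_start, cand) in enumerate(sorted(per_c_best.items())):
        mature_interval = None
        if genomic_anchor is not None:
            lo, hi = cand.mature_span
            if genomic_anchor.strand == "+":
                g_lo = genomic_anchor.start + lo
                g_hi = genomic_anchor.start + hi
            else:
                g_hi = genomic_anchor.end - lo
                g_lo = genomic_anchor.end - hi
            mature_interval = GenomicInterval(
                genomic_anchor.chrom, g_lo, g_hi, genomic_anchor.strand
            )
        name = source or "cand"
        out.append(
            CDBoxCandidate(
                id=f"{name}_{idx}",
                sequence=cand.sequence,
                c_box=cand.c_box,
                d_box=cand.d_box,
                stem=cand.stem,
                mature_span=cand.mature_span,
                mature_interval=mature_interval,
                source=source,
            )
        )
    return out


def _mean_tpm_per_nt(
    candidate: CDBoxCandidate,
    library: Library,
    min_cover_frac: float | None,
) -> float:
    """Mean per-nucleotide TPM coverage of the candidate's mature interval.

    With ``min_cover_frac`` set, only reads covering at least that fraction of
    the candidate are counted (the small-RNA-seq expression rule).
    """
    iv = candidate.mature_interval
    if iv is None:
        raise ValueError("expression filter requires genomically anchored candidates")
    total = 0.0
    for read in library.reads:
        if not read.interval.overlaps(iv):
            continue
        overlap = read.interval.overlap_length(iv)
        if min_cover_frac is not None and overlap < min_cover_frac * iv.length:
            continue
        total += read.copies * library.tpm_per_copy * overlap
    return total / iv.length


def filter_expression(
    candidates: Sequence[CDBoxCandidate],
    srna_lib: Library,
    clip_libs: Sequence[Library],
    min_tpm: float = 1.0,
    min_cover_frac: float = 0.5,
) -> list[CDBoxCandidate]:
    """Expression filter: mean coverage of at least ``min_tpm`` TPM per
    nucleotide in the small-RNA library (counting only reads covering at least
    ``min_cover_frac`` of the candidate) and in at least one CLIP library."""
    if srna_lib is None or not clip_libs:
        raise ValueError("need a small-RNA library and at least one CLIP library")
    kept = []
    for cand in candidates:
        srna_cov = _mean_tpm_per_nt(cand, srna_lib, min_cover_frac)
        if srna_cov < min_tpm:
            continue
        if any(
            _mean_tpm_per_nt(cand, lib, None) >= min_tpm for lib in clip_libs
        ):
            kept.append(cand)
    return kept


def conservation_filter(
    candidate: CDBoxCandidate,
    scores: Mapping[int, float],
    threshold: float = 0.25,
) -> tuple[float, bool]:
    """Mean conservation over the 11 C + D box nucleotides; pass iff the mean
    is strictly greater than the threshold.  Missing positions score 0."""
    positions = []
    for label in ("C", "D"):
        box = candidate.genomic_box(label)
        positions.extend(range(box.start, box.end))
    mean = sum(scores.get(p, 0.0) for p in positions) / len(positions)
    return mean, mean > threshold


def evaluate_specificity(
    sequence_sets: Mapping[str, Iterable[str]],
    detector: Callable[[str], list[CDBoxCandidate]] | None = None,
    **detector_kwargs,
) -> dict[str, int]:
    """Number of sequences per set in which the detector reports >= 1 candidate.

    Sets are typically positive control clusters (overlapping known C/D
    snoRNAs), negative clusters (mRNA exons or shuffles) and random sequence,
    each already extended by 25 nt per side.
    """
    if detector is None:
        detector = lambda s: detect_cd_candidates(s, **detector_kwargs)
    return {
        name: sum(1 for seq in seqs if detector(seq))
        for name, seqs in sequence_sets.items()
    }
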