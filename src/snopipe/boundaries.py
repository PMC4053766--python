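"""Box-relative processing-boundary analysis of snoRNA-derived reads.

Read 5' ends are histogrammed relative to the first nucleotide of the C box
and 3' ends relative to the last nucleotide of the D box, both in transcript
orientation with upstream/inside-of-box negative and downstream positive.
Mature C/D box snoRNAs typically start 4-5 nt upstream of the C box
(offsets -4/-5) and end 2-5 nt downstream of the D box (offsets +2..+5).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model import AlignedRead, GenomicInterval, Library, SnoRNAAnnotation

#: Canonical mature-boundary windows used for tie-breaking modal offsets.
CANONICAL_START_OFFSETS = frozenset({-4, -5})
CANONICAL_END_OFFSETS = frozenset({2, 3, 4, 5})

DEFAULT_FLANK = 20
DEFAULT_TOLERANCE = 2


@dataclass
class BoundaryProfile:
    sno_id: str
    start_hist: Counter = field(default_factory=Counter)
    end_hist: Counter = field(default_factory=Counter)

    @property
    def modal_start(self) -> int:
        return _modal_offset(self.start_hist, CANONICAL_START_OFFSETS)

    @property
    def modal_end(self) -> int:
        return _modal_offset(self.end_hist, CANONICAL_END_OFFSETS)


def _modal_offset(hist: Counter, canonical: frozenset[int]) -> int:
    if not hist:
        raise ValueError("empty boundary histogram has no modal offset")
    # Argmax; ties prefer offsets inside the canonical mature window, then
    # offsets closer to zero, then the numerically larger offset.
    return max(hist, key=lambda off: (hist[off], off in canonical, -abs(off), off))


def _read_end_offsets(
    read: AlignedRead, annotation: SnoRNAAnnotation
) -> tuple[int, int]:
    """Signed (5' offset vs C box start, 3' offset vs D box end) for one read."""
    c_box = annotation.boxes["C"]
    d_box = annotation.boxes["D"]
    if annotation.interval.strand == "+":
        start_off = read.interval.start - c_box.start
        end_off = (read.interval.end - 1) - (d_box.end - 1)
    else:
        start_off = (c_box.end - 1) - (read.interval.end - 1)
        end_off = d_box.start - read.interval.start
    return start_off, end_off


def end_histograms(
    annotation: SnoRNAAnnotation,
    library: Library,
    flank: int = DEFAULT_FLANK,
    weight_by_copies: bool = True,
) -> BoundaryProfile:
    """Copies-weighted histograms of read 5'/3' ends around one snoRNA.

    Reads overlapping the locus padded by ``flank`` nt are counted.
    """
    iv = annotation.interval
    window = GenomicInterval(
        iv.chrom, max(0, iv.start - flank), iv.end + flank, iv.strand
    )
    profile = BoundaryProfile(annotation.id)
    for read in library.reads:
        if not read.interval.overlaps(window):
            continue
        start_off, end_off = _read_end_offsets(read, annotation)
        weight = read.copies if weight_by_copies else 1
        profile.start_hist[start_off] += weight
        profile.end_hist[end_off] += weight
    return profile


def modal_boundary(profile: BoundaryProfile) -> tuple[int, int]:
    """Most prominent (5', 3') end offsets; error on empty histograms."""
    return profile.modal_start, profile.modal_end


def long_short_agreement(
    annotations: Sequence[SnoRNAAnnotation],
    long_lib: Library,
    short_lib: Library,
    top_n: int = 50,
    flank: int = DEFAULT_FLANK,
) -> tuple[float, float]:
    """Fraction of the top expressed snoRNAs whose modal 5' (respectively 3')
    offset agrees exactly between the long (20-200 nt) and short (18-30 nt)
    libraries.  snoRNAs are ranked by long-library expression."""
    if top_n < 1:
        raise ValueError(f"top_n must be >= 1, got {top_n}")

    def expression(ann: SnoRNAAnnotation) -> int:
        return sum(
            r.copies for r in long_lib.reads if r.interval.overlaps(ann.interval)
        )

    ranked = sorted(annotations, key=lambda a: (-expression(a), a.id))
    ranked = [a for a in ranked if expression(a) > 0]
    if top_n > len(ranked):
        warnings.warn(
            f"top_n={top_n} exceeds {len(ranked)} expressed snoRNAs; using all"
        )
    selected = ranked[:top_n]
    start_agree = end_agree = 0
    n_used = 0
    for ann in selected:
        long_prof = end_histograms(ann, long_lib, flank)
        short_prof = end_histograms(ann, short_lib, flank)
        if not (long_prof.start_hist and short_prof.start_hist):
            continue
        n_used += 1
        if long_prof.modal_start == short_prof.modal_start:
            start_agree += 1
        if long_prof.modal_end == short_prof.modal_end:
            end_agree += 1
    if n_used == 0:
        raise ValueError("no snoRNA had reads in both libraries")
    return start_agree / n_used, end_agree / n_used


def mature_boundaries(
    annotation: SnoRNAAnnotation,
    profile: BoundaryProfile | None = None,
    stem_interval: GenomicInterval | None = None,
) -> GenomicInterval:
    """Genomic mature interval: modal read boundaries when available, else the
    stem-derived candidate span, else the annotated interval."""
    iv = annotation.interval
    if profile is not None and profile.start_hist and profile.end_hist:
        c_box = annotation.boxes["C"]
        d_box = annotation.boxes["D"]
        s_off, e_off = profile.modal_start, profile.modal_end
        if iv.strand == "+":
            return GenomicInterval(
                iv.chrom, c_box.start + s_off, d_box.end + e_off, "+"
            )
        return GenomicInterval(
            iv.chrom, d_box.start - e_off, c_box.end - s_off, "-"
        )
    if stem_interval is not None:
        return stem_interval
    return iv


def classify_read_origin(
    read: AlignedRead,
    mature: GenomicInterval,
    tolerance: int = DEFAULT_TOLERANCE,
) -> str:
    """Classify a read as five_prime_derived / three_prime_derived / spanning /
    internal by whether its transcript 5'/3' ends fall within ``tolerance`` nt
    of the mature snoRNA boundaries."""
    if mature.strand == "+":
        mature5, mature3 = mature.start, mature.end - 1
    else:
        mature5, mature3 = mature.end - 1, mature.start
    at5 = abs(read.five_prime - mature5) <= tolerance
    at3 = abs(read.three_prime - mature3) <= tolerance
    if at5 and at3:
        return "spanning"
    if at5:
        return "five_prime_derived"
    if at3:
        return "three_prime_derived"
    return "internal"


def classify_library_origins(
    annotations: Iterable[SnoRNAAnnotation],
    library: Library,
    mature_by_sno: Mapping[str, GenomicInterval] | None = None,
    tolerance: int = DEFAULT_TOLERANCE,
) -> dict[str, float]:
    """Copies-weighted origin-class fractions of reads overlapping snoRNAs."""
    counts: Counter = Counter()
    for ann in annotations:
        mature = (
            mature_by_sno[ann.id]
            if mature_by_sno is not None
            else mature_boundaries(ann)
        )
        for read in library.reads:
            if read.interval.overlaps(ann.interval):
                counts[classify_read_origin(read, mature, tolerance)] += read.copies
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no reads overlap the snoRNA annotations")
    return {label: counts[label] / total for label in
            ("five_prime_derived", "three_prime_derived", "spanning", "internal")}


def export_boundary_matrix(
    profiles: Sequence[BoundaryProfile],
    stem_offsets: Mapping[str, tuple[set[int], set[int]]] | None = None,
) -> pd.DataFrame:
    """Tidy per-snoRNA boundary table: one row per (snoRNA, end, offset) with
    its read count and a stem-paired flag.

    ``stem_offsets`` maps sno_id to (start-offset set, end-offset set) of
    nucleotides predicted paired in the terminal stem.  Histograms are exactly
    reconstructable from the table.
    """
    rows = []
    for prof in sorted(profiles, key=lambda p: p.sno_id):
        stems = stem_offsets.get(prof.sno_id, (set(), set())) if stem_offsets else (set(), set())
        for end_label, hist, paired in (
            ("five_prime", prof.start_hist, stems[0]),
            ("three_prime", prof.end_hist, stems[1]),
        ):
            for offset in sorted(hist):
                rows.append(
                    {
                        "sno_id": prof.sno_id,
                        "end": end_label,
                        "offset": offset,
                        "count": hist[offset],
                        "stem_paired": offset in paired,
                    }
                )
    return pd.DataFrame(rows, columns=["sno_id", "end", "offset", "count", "stem_paired"])
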