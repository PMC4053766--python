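"""Core coordinate and read model shared by every analysis stage.

Internal coordinates are 0-based half-open on the genomic forward strand.
GFF3 input/output converts to/from 1-based inclusive; BED stays 0-based
half-open.  Substitution offsets on reads are relative to the read's genomic
interval start regardless of strand; strand-aware interpretation (a T>C
conversion on a minus-strand read appears as genomic A>G) is applied by
consumers, keeping the on-disk format orientation-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

VALID_STRANDS = ("+", "-")

#: RNA classes recognised by C/D and H/ACA snoRNA annotations.
SNO_CLASSES = ("CD", "HACA", "scaRNA")

#: Box sub-feature labels; Cp/Dp are the internal C'/D' copies.
BOX_LABELS = ("C", "D", "Cp", "Dp", "H", "ACA")

ASSAYS = ("parclip", "sdrna", "srna", "ago2ip")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on one strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty interval: [{self.start}, {self.end})")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", *, stranded: bool = True) -> bool:
        if self.chrom != other.chrom:
            return False
        if stranded and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def to_transcript(self, genomic_pos: int) -> int:
        """Map a genomic position inside the interval to a transcript-oriented
        offset (0 = 5'-most nucleotide of the feature)."""
        if not self.start <= genomic_pos < self.end:
            raise ValueError(f"{genomic_pos} outside {self}")
        if self.strand == "+":
            return genomic_pos - self.start
        return self.end - 1 - genomic_pos

    def to_genomic(self, transcript_pos: int) -> int:
        if not 0 <= transcript_pos < self.length:
            raise ValueError(f"transcript offset {transcript_pos} outside {self}")
        if self.strand == "+":
            return self.start + transcript_pos
        return self.end - 1 - transcript_pos


@dataclass(frozen=True, order=True)
class Substitution:
    """One observed mismatch: offset from interval start, reference and read base."""

    offset: int
    ref: str
    alt: str


@dataclass(frozen=True)
class AlignedRead:
    interval: GenomicInterval
    copies: int = 1
    substitutions: tuple[Substitution, ...] = ()

    def __post_init__(self) -> None:
        if self.copies < 1:
            raise ValueError(f"copies must be >= 1, got {self.copies}")
        for sub in self.substitutions:
            if not 0 <= sub.offset < self.interval.length:
                raise ValueError(
                    f"substitution offset {sub.offset} outside read of length "
                    f"{self.interval.length}"
                )

    @property
    def five_prime(self) -> int:
        """Genomic position of the read's 5' end (transcript orientation)."""
        iv = self.interval
        return iv.start if iv.strand == "+" else iv.end - 1

    @property
    def three_prime(self) -> int:
        iv = self.interval
        return iv.end - 1 if iv.strand == "+" else iv.start

    def tc_count(self) -> int:
        """Copies-weighted number of strand-aware T>C conversions.

        On the minus strand the cross-link diagnostic appears as genomic A>G.
        """
        if self.interval.strand == "+":
            n = sum(1 for s in self.substitutions if s.ref in "Tt" and s.alt in "Cc")
        else:
            n = sum(1 for s in self.substitutions if s.ref in "Aa" and s.alt in "Gg")
        return n * self.copies

    def tc_positions(self) -> list[int]:
        """Genomic positions of strand-aware T>C conversions (unweighted)."""
        if self.interval.strand == "+":
            return [
                self.interval.start + s.offset
                for s in self.substitutions
                if s.ref in "Tt" and s.alt in "Cc"
            ]
        return [
            self.interval.start + s.offset
            for s in self.substitutions
            if s.ref in "Aa" and s.alt in "Gg"
        ]


@dataclass
class Library:
    """A sequencing library: collapsed aligned reads plus the normalization
    denominator (total mapped reads) used for tags-per-million scaling."""

    name: str
    assay: str
    reads: list[AlignedRead] = field(default_factory=list)
    total_mapped: int | None = None

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}; expected one of {ASSAYS}")
        if self.total_mapped is None:
            self.total_mapped = sum(r.copies for r in self.reads)

    @property
    def tpm_per_copy(self) -> float:
        """TPM contributed by a single read copy (library scaled to 1,000,000)."""
        if not self.total_mapped:
            raise ValueError(f"library {self.name!r} has total_mapped = 0")
        return 1_000_000.0 / self.total_mapped


@dataclass(frozen=True)
class SnoRNAAnnotation:
    """A snoRNA gene with its box sub-features (genomic coordinates)."""

    id: str
    sno_class: str
    interval: GenomicInterval
    boxes: Mapping[str, GenomicInterval]

    def __post_init__(self) -> None:
        if self.sno_class not in SNO_CLASSES:
            raise ValueError(f"unknown snoRNA class {self.sno_class!r}")
        for label, box in self.boxes.items():
            if label not in BOX_LABELS:
                raise ValueError(f"unknown box label {label!r}")
            if not self.interval.contains(box):
                raise ValueError(f"box {label} {box} outside snoRNA {self.interval}")
        if self.sno_class == "CD":
            if "C" not in self.boxes or "D" not in self.boxes:
                raise ValueError(f"C/D snoRNA {self.id} requires C and D boxes")
            c, d = self.boxes["C"], self.boxes["D"]
            # Box order is checked in transcript orientation: C box 5' of D box.
            if self.interval.strand == "+" and not c.start < d.start:
                raise ValueError(f"{self.id}: C box must lie 5' of D box")
            if self.interval.strand == "-" and not c.start > d.start:
                raise ValueError(f"{self.id}: C box must lie 5' of D box")

    def box_transcript_span(self, label: str) -> tuple[int, int]:
        """Transcript-oriented half-open span of a box within the snoRNA."""
        box = self.boxes[label]
        iv = self.interval
        a = iv.to_transcript(box.start)
        b = iv.to_transcript(box.end - 1)
        lo, hi = min(a, b), max(a, b)
        return lo, hi + 1


@dataclass(frozen=True)
class Feature:
    """A generic annotated feature used for cluster/read classification."""

    interval: GenomicInterval
    category: str
    name: str = ""


def annotations_to_features(annotations: Iterable[SnoRNAAnnotation]) -> list[Feature]:
    """Convert snoRNA annotations to classification features.

    C/D -> ``CD_snoRNA``, H/ACA -> ``HACA_snoRNA``, scaRNA -> ``scaRNA``.
    """
    mapping = {"CD": "CD_snoRNA", "HACA": "HACA_snoRNA", "scaRNA": "scaRNA"}
    return [Feature(a.interval, mapping[a.sno_class], a.id) for a in annotations]
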