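"""Per-snoRNA PAR-CLIP coverage/conversion profiles and summary statistics:
pairwise profile correlations, per-region coverage z-scores and the
guide-with-target versus orphan-guide comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .model import Library, SnoRNAAnnotation

GUIDE_WINDOW = 9  # nucleotides upstream of the D / D' box taken as guide region


@dataclass
class CoverageProfile:
    """Per-position read coverage and T>C conversion counts along one snoRNA,
    in transcript orientation (position 0 = snoRNA 5' end)."""

    sno_id: str
    coverage: np.ndarray
    tc: np.ndarray
    library: str = ""

    def __post_init__(self) -> None:
        if len(self.coverage) != len(self.tc):
            raise ValueError("coverage and tc arrays differ in length")

    @property
    def is_constant(self) -> bool:
        return bool(np.all(self.coverage == self.coverage[0]))


@dataclass(frozen=True)
class RegionZScore:
    sno_id: str
    region: str
    mean_z: float


def build_profile(annotation: SnoRNAAnnotation, library: Library) -> CoverageProfile:
    """Copies-weighted coverage and strand-aware T>C counts over the snoRNA.

    Minus-strand profiles are reported in transcript orientation; a genomic
    A>G conversion on a minus-strand read counts as T>C.
    """
    iv = annotation.interval
    coverage = np.zeros(iv.length, dtype=np.int64)
    tc = np.zeros(iv.length, dtype=np.int64)
    for read in library.reads:
        if not read.interval.overlaps(iv):
            continue
        lo = max(read.interval.start, iv.start) - iv.start
        hi = min(read.interval.end, iv.end) - iv.start
        coverage[lo:hi] += read.copies
        for pos in read.tc_positions():
            if iv.start <= pos < iv.end:
                tc[pos - iv.start] += read.copies
    if iv.strand == "-":
        coverage = coverage[::-1].copy()
        tc = tc[::-1].copy()
    return CoverageProfile(annotation.id, coverage, tc, library.name)


def profile_correlation(a: CoverageProfile, b: CoverageProfile) -> float | None:
    """Pearson correlation of two coverage profiles of the same snoRNA.

    Returns None (undefined, to be excluded from summaries) when either
    profile is constant.
    """
    if len(a.coverage) != len(b.coverage):
        raise ValueError(
            f"profile length mismatch: {len(a.coverage)} vs {len(b.coverage)}"
        )
    if a.is_constant or b.is_constant:
        return None
    return float(np.corrcoef(a.coverage, b.coverage)[0, 1])


def correlation_summary(
    correlations: Iterable[float | None], cutoff: float = 0.9
) -> float:
    """Fraction of snoRNAs with correlation >= cutoff, over defined values."""
    defined = [r for r in correlations if r is not None and not math.isnan(r)]
    if not defined:
        raise ValueError("no defined correlations")
    return sum(1 for r in defined if r >= cutoff) / len(defined)


def default_regions(annotation: SnoRNAAnnotation) -> dict[str, list[int]]:
    """Transcript-position sets for box regions, 9-nt guide windows upstream of
    D/D' boxes, and the remainder of the snoRNA."""
    length = annotation.interval.length
    regions: dict[str, list[int]] = {}
    used: set[int] = set()
    for label in ("C", "D", "Cp", "Dp"):
        if label in annotation.boxes:
            lo, hi = annotation.box_transcript_span(label)
            regions[label] = list(range(lo, hi))
            used.update(regions[label])
    for box, guide in (("D", "guide_D"), ("Dp", "guide_Dp")):
        if box in annotation.boxes:
            lo, _ = annotation.box_transcript_span(box)
            window = [p for p in range(lo - GUIDE_WINDOW, lo) if 0 <= p < length]
            if window:
                regions[guide] = window
                used.update(window)
    regions["rest"] = [p for p in range(length) if p not in used]
    return regions


def region_zscores(
    profile: CoverageProfile,
    annotation: SnoRNAAnnotation,
    regions: Mapping[str, Sequence[int]] | None = None,
) -> list[RegionZScore] | None:
    """Mean per-position coverage z-score of each region.

    z is computed over the whole snoRNA with the population (n) standard
    deviation; a constant profile has no defined z-scores and yields None.
    """
    if regions is None:
        regions = default_regions(annotation)
    cov = profile.coverage.astype(float)
    sd = cov.std()  # population sd: z over a fixed profile is descriptive
    if sd == 0:
        return None
    z = (cov - cov.mean()) / sd
    return [
        RegionZScore(profile.sno_id, name, float(np.mean(z[list(pos)])))
        for name, pos in regions.items()
        if len(pos)
    ]


def guide_orphan_comparison(
    guide_scores: Iterable[tuple[float, bool]],
) -> dict[str, dict]:
    """Fraction of guide regions with strictly positive mean z, per group.

    ``guide_scores`` yields (mean_z, has_known_target) pairs.  Returns, per
    group, the positive fraction and the full empirical distribution for
    cumulative plots; a group with no members is reported as undefined (None).
    """
    groups: dict[str, list[float]] = {"target": [], "orphan": []}
    for mean_z, targeted in guide_scores:
        groups["target" if targeted else "orphan"].append(mean_z)
    out = {}
    for name, values in groups.items():
        if values:
            frac = sum(1 for v in values if v > 0) / len(values)
        else:
            frac = None
        out[name] = {"fraction_positive": frac, "values": sorted(values)}
    return out
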