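"""Read clustering, TPM normalization, ranking and annotation of PAR-CLIP
binding regions.

Reads whose loci are at most ``max_gap`` nucleotides apart (default 25) on the
same chromosome and strand are merged into one cluster.  The gap is measured
between the genomic end (exclusive) of the earlier read and the start of the
next, so touching or overlapping reads always merge.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .model import AlignedRead, Feature, GenomicInterval, Library

DEFAULT_MAX_GAP = 25

#: Annotation priority used when a cluster overlaps features of several
#: categories, mimicking a snoRNA-first annotation hierarchy.  Configurable.
DEFAULT_PRIORITY = (
    "CD_snoRNA",
    "HACA_snoRNA",
    "scaRNA",
    "miRNA",
    "tRNA",
    "snRNA",
    "rRNA",
    "repeat",
    "mRNA_exon",
    "other",
)


@dataclass(frozen=True)
class ReadCluster:
    interval: GenomicInterval
    reads: tuple[AlignedRead, ...]
    read_count: int
    tpm: float
    tc_count: int

    @property
    def density(self) -> float:
        """TPM per nucleotide of cluster length."""
        return self.tpm / self.interval.length


def tpm_normalize(library: Library) -> Library:
    """Validate and return the library for tags-per-million scaling.

    Each read's TPM is ``copies * 1,000,000 / total_mapped``; the factor is
    exposed as :attr:`Library.tpm_per_copy`.
    """
    if not library.total_mapped:
        raise ValueError(f"library {library.name!r} has total_mapped = 0")
    return library


def read_tpm(library: Library, read: AlignedRead) -> float:
    return read.copies * library.tpm_per_copy


def cluster_reads(
    library: Library, max_gap: int = DEFAULT_MAX_GAP
) -> list[ReadCluster]:
    """Partition the library's reads into strand-contiguous clusters.

    Two consecutive reads on the same chromosome and strand fall in the same
    cluster iff ``next.start - prev_end <= max_gap``.
    """
    tpm_normalize(library)
    factor = library.tpm_per_copy
    by_locus: dict[tuple[str, str], list[AlignedRead]] = {}
    for read in library.reads:
        by_locus.setdefault((read.interval.chrom, read.interval.strand), []).append(read)

    clusters: list[ReadCluster] = []
    for (chrom, strand), reads in sorted(by_locus.items()):
        reads.sort(key=lambda r: (r.interval.start, r.interval.end))
        group: list[AlignedRead] = []
        group_end = -1
        for read in reads:
            if group and read.interval.start - group_end > max_gap:
                clusters.append(_make_cluster(chrom, strand, group, factor))
                group = []
            group.append(read)
            group_end = max(group_end, read.interval.end)
        if group:
            clusters.append(_make_cluster(chrom, strand, group, factor))
    return clusters


def _make_cluster(
    chrom: str, strand: str, reads: list[AlignedRead], tpm_factor: float
) -> ReadCluster:
    start = min(r.interval.start for r in reads)
    end = max(r.interval.end for r in reads)
    count = sum(r.copies for r in reads)
    return ReadCluster(
        GenomicInterval(chrom, start, end, strand),
        tuple(reads),
        count,
        count * tpm_factor,
        sum(r.tc_count() for r in reads),
    )


def rank_clusters(
    clusters: Iterable[ReadCluster], metric: str = "density", n: int = 200
) -> list[ReadCluster]:
    """Top-``n`` clusters by read count or read density per nucleotide.

    Ties break on higher T>C support (the cross-link evidence), then leftmost
    genomic coordinate, so output order is deterministic.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if metric == "count":
        key = lambda c: c.read_count
    elif metric == "density":
        key = lambda c: c.density
    else:
        raise ValueError(f"unknown metric {metric!r}; use 'count' or 'density'")
    ordered = sorted(
        clusters,
        key=lambda c: (-key(c), -c.tc_count, c.interval.chrom, c.interval.start),
    )
    return ordered[:n]


def annotate_clusters(
    clusters: Sequence[ReadCluster],
    features: Iterable[Feature],
    priority: Sequence[str] = DEFAULT_PRIORITY,
) -> dict[ReadCluster, str]:
    """Assign each cluster the highest-priority category it overlaps by >= 1 nt
    on the same strand, or ``"none"``."""
    trees: dict[tuple[str, str], IntervalTree] = {}
    for feat in features:
        key = (feat.interval.chrom, feat.interval.strand)
        trees.setdefault(key, IntervalTree()).addi(
            feat.interval.start, feat.interval.end, feat.category
        )
    rank = {cat: i for i, cat in enumerate(priority)}
    result: dict[ReadCluster, str] = {}
    for cluster in clusters:
        iv = cluster.interval
        tree = trees.get((iv.chrom, iv.strand))
        hits = {h.data for h in tree.overlap(iv.start, iv.end)} if tree else set()
        if not hits:
            result[cluster] = "none"
        else:
            result[cluster] = min(hits, key=lambda c: rank.get(c, len(rank)))
    return result


def select_novel_clusters(
    clusters: Sequence[ReadCluster],
    features: Iterable[Feature],
    n: int = 500,
    metric: str = "count",
    priority: Sequence[str] = DEFAULT_PRIORITY,
) -> list[ReadCluster]:
    """Top-``n`` clusters that do not overlap any annotated feature."""
    categories = annotate_clusters(clusters, features, priority)
    novel = [c for c in clusters if categories[c] == "none"]
    if not novel:
        return []
    return rank_clusters(novel, metric=metric, n=n)


def extend_cluster(
    cluster: ReadCluster, pad: int = 25, chrom_length: int | None = None
) -> GenomicInterval:
    """Cluster span padded on both sides (detector input uses pad = 25)."""
    start = max(0, cluster.interval.start - pad)
    end = cluster.interval.end + pad
    if chrom_length is not None:
        end = min(end, chrom_length)
    return replace(cluster.interval, start=start, end=end)
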