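"""End-to-end convenience workflows over the library modules.

These functions wire the stages together the way the analysis scripts and
validation checks run them: cluster a CLIP library, extend the clusters,
run the C/D box detector on the cluster sequences, and compare against
known loci or generator truth.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .boundaries import end_histograms
from .clusters import ReadCluster, cluster_reads, extend_cluster
from .detect import CDBoxCandidate, detect_cd_candidates, evaluate_specificity
from .model import GenomicInterval, Library
from .seq import revcomp
from .simulate import SimulationConfig, TruthRecord


def cluster_sequence(
    cluster: ReadCluster, genome: Mapping[str, str], pad: int = 25
) -> tuple[str, GenomicInterval]:
    """Transcript-oriented sequence of a cluster extended by ``pad`` nt."""
    chrom_seq = genome[cluster.interval.chrom]
    iv = extend_cluster(cluster, pad, len(chrom_seq))
    seq = chrom_seq[iv.start : iv.end]
    if iv.strand == "-":
        seq = revcomp(seq)
    return seq, iv


def detect_from_library(
    library: Library,
    genome: Mapping[str, str],
    max_gap: int = 25,
    pad: int = 25,
    **detector_kwargs,
) -> list[CDBoxCandidate]:
    """Cluster a library and run the detector on every extended cluster."""
    candidates = []
    for cluster in cluster_reads(library, max_gap=max_gap):
        seq, anchor = cluster_sequence(cluster, genome, pad)
        candidates.extend(
            detect_cd_candidates(
                seq,
                genomic_anchor=anchor,
                source=f"{cluster.interval.chrom}:{cluster.interval.start}",
                **detector_kwargs,
            )
        )
    return candidates


def recovery_fraction(
    truths: Sequence[TruthRecord], candidates: Sequence[CDBoxCandidate]
) -> float:
    """Fraction of truth loci recovered with exact C and D box coordinates."""
    if not truths:
        raise ValueError("no truth records")
    found = 0
    for truth in truths:
        found += any(
            c.mature_interval is not None
            and c.genomic_box("C") == truth.boxes["C"]
            and c.genomic_box("D") == truth.boxes["D"]
            for c in candidates
        )
    return found / len(truths)


def modal_recovery(
    truths: Sequence[TruthRecord],
    library: Library,
    config: SimulationConfig,
) -> tuple[float, float]:
    """Fraction of snoRNAs whose modal 5' (3') read offset equals the mode of
    the generator's start (end) offset distribution."""
    exp_start = max(config.start_offset_dist, key=config.start_offset_dist.get)
    exp_end = max(config.end_offset_dist, key=config.end_offset_dist.get)
    ok_start = ok_end = 0
    for truth in truths:
        prof = end_histograms(truth.annotation(), library)
        if not prof.start_hist:
            continue
        ok_start += prof.modal_start == exp_start
        ok_end += prof.modal_end == exp_end
    return ok_start / len(truths), ok_end / len(truths)


def specificity_on_truth(
    truths: Sequence[TruthRecord],
    genome: Mapping[str, str],
    seed: int,
    pad: int = 25,
) -> dict[str, int]:
    """Detector specificity: embedded intact loci (each extended ``pad`` nt
    per side) versus length- and composition-matched shuffled negatives."""
    chrom_seq = genome["chr"]
    rng = np.random.default_rng(seed)
    positives, negatives = [], []
    for truth in truths:
        lo = max(0, truth.locus.start - pad)
        hi = min(len(chrom_seq), truth.locus.end + pad)
        seq = chrom_seq[lo:hi]
        if truth.locus.strand == "-":
            seq = revcomp(seq)
        positives.append(seq)
        negatives.append("".join(rng.permutation(list(seq))))
    return evaluate_specificity({"positive": positives, "negative": negatives})
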