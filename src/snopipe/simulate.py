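"""Synthetic data emulating C/D box snoRNA loci and the sequencing libraries
the pipeline consumes, with full ground truth.

The generator embeds intact C/D box snoRNA loci into i.i.d. uniform-random
background sequence.  Each locus carries, in transcript order: a 5' stem arm,
the C box (RUGAUGA with R drawn at random), a guide/internal region that by
default contains a degenerate C' box, a D' box and two 9-nt guide windows, the
D box, and a 3' closing stem arm complementary to the 5' arm.  Loci are placed
on a random strand and validated against the detector in their genomic
context, so every truth record is detectable with exact box coordinates.

Simulated libraries:

* PAR-CLIP reads whose anchors follow configurable per-region coverage
  weights (default D' > C ~ C' > D > rest, the empirical core-protein
  preference) with T>C conversions at covered uridines;
* long (20-200 nt) small-RNA reads spanning mature boundaries drawn from the
  box-relative offset distributions (5' end 4-5 nt upstream of the C box,
  3' end 2-5 nt downstream of the D box);
* short (18-30 nt) terminus-derived fragments mixing 5'-derived, 3'-derived
  and internal reads;
* paired total / Argonaute-IP class-mixture libraries for loading analysis.

All randomness flows through one ``numpy`` Generator seeded from the
mandatory config seed, so outputs are byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from . import detect
from .model import (
    AlignedRead,
    Feature,
    GenomicInterval,
    Library,
    SnoRNAAnnotation,
    Substitution,
)
from .seq import as_rna, revcomp

DNA = np.array(list("ACGT"))

#: Degenerate C' box: two mismatches from the C consensus, so the detector
#: does not treat it as an alternative C box.
CP_BOX = "ATGACGT"
DP_BOX = "CTGA"
GUIDE_WINDOW = 9
#: Internal region needs guide' + D' + C' + guide to plant internal boxes.
MIN_INTERNAL = 2 * GUIDE_WINDOW + len(DP_BOX) + len(CP_BOX)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic genome and libraries."""

    seed: int
    genome_length: int = 60_000
    n_snornas: int = 30
    guide_len_range: tuple[int, int] = (35, 55)  # nt between C box end and D box start
    stem_len: int = 5  # bp in the closing stem
    stem_gc_min: int = 3
    clip_region_weights: Mapping[str, float] = field(
        default_factory=lambda: {
            "Dp": 6.0, "C": 3.0, "Cp": 3.0, "D": 1.5,
            "guide_D": 3.0, "guide_Dp": 3.0, "rest": 1.0,
        }
    )
    tc_rate: float = 0.15  # P(T>C) per covered uridine per read
    start_offset_dist: Mapping[int, float] = field(
        default_factory=lambda: {-4: 0.7, -5: 0.3}
    )
    end_offset_dist: Mapping[int, float] = field(
        default_factory=lambda: {2: 0.4, 3: 0.3, 4: 0.2, 5: 0.1}
    )
    reads_per_sno: int = 500
    clip_read_len: tuple[int, int] = (12, 20)  # nuclease-trimmed fragments
    background_reads: int = 1000
    sdrna_len_range: tuple[int, int] = (18, 30)
    origin_mixture: Mapping[str, float] = field(
        default_factory=lambda: {
            "five_prime_derived": 0.39,
            "three_prime_derived": 0.46,
            "internal": 0.15,
        }
    )
    plant_internal_boxes: bool = True
    targeted_fraction: float = 0.5  # snoRNAs whose guide has a "known target"
    targeted_guide_boost: float = 3.0
    ago_pool: Mapping[str, float] = field(
        default_factory=lambda: {
            "miRNA": 0.183, "tRNA": 0.097, "snRNA": 0.053,
            "CD_snoRNA": 0.0175, "HACA_snoRNA": 0.0032, "none": 0.6463,
        }
    )
    ago_class_weights: Mapping[str, float] = field(
        default_factory=lambda: {
            "miRNA": 31.7, "tRNA": 0.136, "snRNA": 0.036,
            "CD_snoRNA": 0.0185, "HACA_snoRNA": 0.526, "none": 1.0,
        }
    )

    def __post_init__(self) -> None:
        for name in ("start_offset_dist", "end_offset_dist", "origin_mixture"):
            dist = getattr(self, name)
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} probabilities must sum to 1")
        if self.n_snornas < 0 or self.genome_length <= 0 or self.reads_per_sno <= 0:
            raise ValueError("counts must be positive")
        if any(w < 0 for w in self.ago_class_weights.values()):
            raise ValueError("ago class weights must be >= 0")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one embedded snoRNA locus."""

    sno_id: str
    locus: GenomicInterval  # stem-bounded snoRNA span
    boxes: Mapping[str, GenomicInterval]
    stem_len: int
    mature: GenomicInterval  # locus span (stem arm to stem arm)
    targeted: bool  # guide region has a planted "known target"
    guide_seq: str  # 8-mer immediately upstream of the D box
    sequence: str  # transcript-oriented locus sequence

    def annotation(self) -> SnoRNAAnnotation:
        return SnoRNAAnnotation(self.sno_id, "CD", self.locus, dict(self.boxes))


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(DNA, size=n))


def _contains_motif(seq: str, from_pos: int = 0, with_c_box: bool = True) -> bool:
    """Any D-box or C-box motif hit ending after ``from_pos``?"""
    rna = as_rna(seq)
    for motif in ("CUGA", "AUGA"):
        idx = rna.find(motif)
        while idx != -1:
            if idx + len(motif) > from_pos:
                return True
            idx = rna.find(motif, idx + 1)
    if with_c_box:
        return any(h.end > from_pos for h in detect.scan_c_box(rna))
    return False


def _clean_dna(rng: np.random.Generator, n: int, context: str = "") -> str:
    """Random DNA such that no D-box / C-box motif lies in the fragment or
    spans the junction with the context (keeps planted motifs unambiguous)."""
    if n == 0:
        return ""
    tail = context[-6:]
    for _ in range(200):
        frag = _random_dna(rng, n)
        if not _contains_motif(tail + frag, from_pos=len(tail)):
            return frag
    raise RuntimeError("could not sample a motif-free fragment")


def _stem_arm(rng: np.random.Generator, length: int, min_gc: int) -> str:
    while True:
        arm = _random_dna(rng, length)
        if sum(1 for b in arm if b in "GC") >= min_gc and not _contains_motif(arm):
            return arm


def _build_locus(rng: np.random.Generator, config: SimulationConfig) -> dict:
    """One transcript-oriented locus: sequence plus local feature offsets."""
    g_lo, g_hi = config.guide_len_range
    guide_len = int(rng.integers(g_lo, g_hi + 1))
    plant_internal = config.plant_internal_boxes and guide_len >= MIN_INTERNAL

    arm5 = _stem_arm(rng, config.stem_len, config.stem_gc_min)
    c_box = ("A" if rng.random() < 0.5 else "G") + "TGATGA"
    parts = [arm5, c_box]
    local = {}
    pos = len(arm5)
    local["C"] = (pos, pos + 7)
    pos += 7
    if plant_internal:
        guide_dp = _clean_dna(rng, GUIDE_WINDOW, "".join(parts))
        parts.append(guide_dp)
        pos += GUIDE_WINDOW
        local["Dp"] = (pos, pos + 4)
        parts.append(DP_BOX)
        pos += 4
        local["Cp"] = (pos, pos + 7)
        parts.append(CP_BOX)
        pos += 7
        filler = guide_len - MIN_INTERNAL
        parts.append(_clean_dna(rng, filler, "".join(parts)))
        pos += filler
    else:
        inner = guide_len - GUIDE_WINDOW
        parts.append(_clean_dna(rng, max(0, inner), "".join(parts)))
        pos += max(0, inner)
    guide_d = _clean_dna(rng, min(GUIDE_WINDOW, guide_len), "".join(parts))
    parts.append(guide_d)
    pos += len(guide_d)
    local["D"] = (pos, pos + 4)
    parts.append("CTGA" if rng.random() < 0.7 else "ATGA")
    pos += 4
    # 3' arm: reverse complement of the 5' arm (DNA alphabet, no U).
    arm3 = revcomp(arm5).replace("U", "T")
    parts.append(arm3)
    pos += config.stem_len
    seq = "".join(parts)
    guide8 = seq[local["D"][0] - 8 : local["D"][0]]
    return {"sequence": seq, "boxes": local, "guide8": as_rna(guide8)}


def _locus_is_clean(genome: str, start: int, length: int, strand: str,
                    boxes: Mapping[str, tuple[int, int]]) -> bool:
    """Detector check in genomic context: the candidate reported for the
    planted C box must carry exactly the planted C/D boxes and mature span."""
    lo = max(0, start - 30)
    hi = min(len(genome), start + length + 30)
    context = genome[lo:hi]
    anchor = GenomicInterval("chr", lo, hi, strand)
    if strand == "-":
        context = revcomp(context).replace("U", "T")
    cands = detect.detect_cd_candidates(context, genomic_anchor=anchor)
    if strand == "+":
        c_local = (start - lo) + boxes["C"][0]
        d_local = (start - lo) + boxes["D"][0]
        mature_span = (start - lo, start - lo + length)
    else:
        c_local = (hi - (start + length)) + boxes["C"][0]
        d_local = (hi - (start + length)) + boxes["D"][0]
        mature_span = (hi - (start + length), hi - start)
    for cand in cands:
        if cand.c_box.start == c_local:
            return cand.d_box.start == d_local and cand.mature_span == mature_span
    return False


def make_genome(config: SimulationConfig) -> tuple[dict[str, str], list[TruthRecord]]:
    """Uniform-random background genome with embedded intact snoRNA loci.

    Returns ``({chrom: sequence}, truth records)``; sequences are DNA, truth
    records carry transcript-oriented RNA sequences.  Deterministic under the
    config seed.
    """
    rng = np.random.default_rng([config.seed, 0])
    genome = list(_random_dna(rng, config.genome_length))
    max_locus = 2 * config.stem_len + 7 + 4 + config.guide_len_range[1]
    spacing = config.genome_length // max(1, config.n_snornas)
    if spacing < max_locus + 100:
        raise ValueError("genome too short for the requested snoRNA count")
    truths = []
    for k in range(config.n_snornas):
        slot_lo = k * spacing + 40
        strand = "+" if rng.random() < 0.5 else "-"
        targeted = rng.random() < config.targeted_fraction
        for _attempt in range(60):
            locus = _build_locus(rng, config)
            seq = locus["sequence"]
            start = slot_lo + int(rng.integers(0, spacing - len(seq) - 80))
            embedded = seq if strand == "+" else revcomp(seq).replace("U", "T")
            saved = genome[start : start + len(seq)]
            genome[start : start + len(seq)] = list(embedded)
            if _locus_is_clean("".join(genome), start, len(seq), strand, locus["boxes"]):
                break
            genome[start : start + len(seq)] = saved  # back out failed embedding
        else:
            raise RuntimeError(f"could not embed a clean locus for snoRNA {k}")
        interval = GenomicInterval("chr", start, start + len(seq), strand)
        boxes = {}
        for label, (lo, hi) in locus["boxes"].items():
            if strand == "+":
                boxes[label] = GenomicInterval("chr", start + lo, start + hi, "+")
            else:
                boxes[label] = GenomicInterval(
                    "chr", interval.end - hi, interval.end - lo, "-"
                )
        truths.append(
            TruthRecord(
                sno_id=f"syn{k:03d}",
                locus=interval,
                boxes=boxes,
                stem_len=config.stem_len,
                mature=interval,
                targeted=targeted,
                guide_seq=locus["guide8"],
                sequence=as_rna(seq),
            )
        )
    return {"chr": "".join(genome)}, truths


def _region_weights(truth: TruthRecord, config: SimulationConfig) -> np.ndarray:
    """Per-transcript-position anchor weights over the locus."""
    ann = truth.annotation()
    length = truth.locus.length
    weights = np.full(length, config.clip_region_weights.get("rest", 1.0))
    spans = {}
    for label in ("C", "D", "Cp", "Dp"):
        if label in truth.boxes:
            spans[label] = ann.box_transcript_span(label)
    for box, guide in (("D", "guide_D"), ("Dp", "guide_Dp")):
        if box in spans:
            lo = max(0, spans[box][0] - GUIDE_WINDOW)
            w = config.clip_region_weights.get(guide, 1.0)
            if truth.targeted:
                w *= config.targeted_guide_boost
            weights[lo : spans[box][0]] = w
    for label, (lo, hi) in spans.items():
        weights[lo:hi] = config.clip_region_weights.get(label, 1.0)
    return weights / weights.sum()


def _collapse(reads: list[tuple[GenomicInterval, tuple[Substitution, ...]]],
              name: str, assay: str) -> Library:
    counts: dict = {}
    for iv, subs in reads:
        key = (iv, subs)
        counts[key] = counts.get(key, 0) + 1
    collapsed = [
        AlignedRead(iv, copies, subs) for (iv, subs), copies in sorted(
            counts.items(), key=lambda kv: (kv[0][0], kv[0][1])
        )
    ]
    return Library(name, assay, collapsed)


def simulate_clip_reads(
    truths: Sequence[TruthRecord],
    genome: Mapping[str, str],
    config: SimulationConfig,
    name: str = "clip",
    stream: int = 1,
) -> Library:
    """PAR-CLIP library: box-biased anchors, T>C conversions, background reads."""
    rng = np.random.default_rng([config.seed, stream])
    chrom_seq = genome["chr"]
    raw: list[tuple[GenomicInterval, tuple[Substitution, ...]]] = []
    lo_len, hi_len = config.clip_read_len
    for truth in truths:
        weights = _region_weights(truth, config)
        anchors = rng.choice(truth.locus.length, size=config.reads_per_sno, p=weights)
        for anchor_t in anchors:
            length = int(rng.integers(lo_len, hi_len + 1))
            offset = int(rng.integers(0, length))  # anchor position within read
            anchor_g = truth.locus.to_genomic(int(anchor_t))
            if truth.locus.strand == "+":
                start = anchor_g - offset
            else:
                start = anchor_g - (length - 1 - offset)
            start = max(0, min(start, len(chrom_seq) - length))
            iv = GenomicInterval("chr", start, start + length, truth.locus.strand)
            raw.append((iv, _convert_ts(chrom_seq, iv, rng, config.tc_rate)))
    for _ in range(config.background_reads):
        length = int(rng.integers(lo_len, hi_len + 1))
        start = int(rng.integers(0, len(chrom_seq) - length))
        strand = "+" if rng.random() < 0.5 else "-"
        iv = GenomicInterval("chr", start, start + length, strand)
        raw.append((iv, ()))
    return _collapse(raw, name, "parclip")


def _convert_ts(
    chrom_seq: str, iv: GenomicInterval, rng: np.random.Generator, tc_rate: float
) -> tuple[Substitution, ...]:
    """T>C conversions in transcript orientation, stored as genomic-offset
    substitutions (T>C on plus reads, A>G on minus reads)."""
    if tc_rate <= 0:
        return ()
    ref, alt = ("T", "C") if iv.strand == "+" else ("A", "G")
    subs = []
    for off in range(iv.length):
        if chrom_seq[iv.start + off] == ref and rng.random() < tc_rate:
            subs.append(Substitution(off, ref, alt))
    return tuple(subs)


def _sample_offset(rng: np.random.Generator, dist: Mapping[int, float]) -> int:
    keys = sorted(dist)
    probs = np.array([dist[k] for k in keys])
    return int(rng.choice(keys, p=probs / probs.sum()))


def _mature_ends(truth: TruthRecord, start_off: int, end_off: int) -> tuple[int, int]:
    """Genomic (start, end) of a mature form with the given box-relative ends."""
    c_box, d_box = truth.boxes["C"], truth.boxes["D"]
    if truth.locus.strand == "+":
        return c_box.start + start_off, d_box.end + end_off
    return d_box.start - end_off, c_box.end - start_off


def simulate_srna_reads(
    truths: Sequence[TruthRecord],
    config: SimulationConfig,
    fraction: str = "long",
    name: str | None = None,
    stream: int = 2,
) -> Library:
    """Small-RNA library from snoRNA loci.

    ``fraction="long"`` (20-200 nt run): each read spans a mature form whose
    5'/3' ends are drawn from the box-relative offset distributions.
    ``fraction="short"`` (18-30 nt run): terminus-derived fragments whose
    outer ends equal sampled mature ends, mixed with internal fragments.
    """
    if fraction not in ("long", "short"):
        raise ValueError(f"fraction must be 'long' or 'short', got {fraction!r}")
    rng = np.random.default_rng([config.seed, stream])
    raw: list[tuple[GenomicInterval, tuple[Substitution, ...]]] = []
    classes = sorted(config.origin_mixture)
    probs = np.array([config.origin_mixture[c] for c in classes])
    lo_len, hi_len = config.sdrna_len_range
    for truth in truths:
        strand = truth.locus.strand
        for _ in range(config.reads_per_sno):
            s_off = _sample_offset(rng, config.start_offset_dist)
            e_off = _sample_offset(rng, config.end_offset_dist)
            m_start, m_end = _mature_ends(truth, s_off, e_off)
            if fraction == "long":
                raw.append((GenomicInterval("chr", m_start, m_end, strand), ()))
                continue
            origin = classes[int(rng.choice(len(classes), p=probs))]
            length = int(rng.integers(lo_len, hi_len + 1))
            if origin == "five_prime_derived":
                if strand == "+":
                    iv = GenomicInterval("chr", m_start, m_start + length, strand)
                else:
                    iv = GenomicInterval("chr", m_end - length, m_end, strand)
            elif origin == "three_prime_derived":
                if strand == "+":
                    iv = GenomicInterval("chr", m_end - length, m_end, strand)
                else:
                    iv = GenomicInterval("chr", m_start, m_start + length, strand)
            else:  # internal: both ends > tolerance away from mature boundaries
                margin = 4
                span = (m_end - m_start) - length - 2 * margin
                if span < 1:
                    continue
                start = m_start + margin + int(rng.integers(0, span))
                iv = GenomicInterval("chr", start, start + length, strand)
            raw.append((iv, ()))
    assay = "srna" if fraction == "long" else "sdrna"
    return _collapse(raw, name or f"{assay}_sim", assay)


AGO_LOCUS_LEN = 100


def ago_features() -> list[Feature]:
    """One synthetic locus per RNA class on a dedicated chromosome."""
    feats = []
    for i, cls in enumerate(("miRNA", "tRNA", "snRNA", "CD_snoRNA", "HACA_snoRNA")):
        start = i * 2 * AGO_LOCUS_LEN
        feats.append(
            Feature(GenomicInterval("ago_chr", start, start + AGO_LOCUS_LEN, "+"), cls)
        )
    return feats


def simulate_ago_ip(
    config: SimulationConfig,
    n_reads: int = 100_000,
    stream: int = 3,
) -> tuple[Library, Library, list[Feature]]:
    """Total and Argonaute-IP small-RNA libraries from a class mixture.

    The total library is multinomial over the class pool; the IP library is
    multinomial over pool proportions reweighted by the per-class inclusion
    weights, emulating class-biased Argonaute loading.
    """
    weights = config.ago_class_weights
    if all(w == 0 for w in weights.values()):
        raise ValueError("all ago class weights are zero")
    rng = np.random.default_rng([config.seed, stream])
    classes = sorted(config.ago_pool)
    pool = np.array([config.ago_pool[c] for c in classes], dtype=float)
    pool = pool / pool.sum()
    ip_p = pool * np.array([weights.get(c, 0.0) for c in classes])
    ip_p = ip_p / ip_p.sum()
    feats = ago_features()
    locus = {f.category: f.interval for f in feats}
    none_start = len(feats) * 2 * AGO_LOCUS_LEN

    def build(counts: np.ndarray, name: str) -> Library:
        reads = []
        for cls, count in zip(classes, counts):
            if count == 0:
                continue
            if cls == "none":
                iv = GenomicInterval("ago_chr", none_start, none_start + 30, "+")
            else:
                base = locus[cls]
                iv = GenomicInterval(base.chrom, base.start, base.start + 30, "+")
            reads.append(AlignedRead(iv, int(count)))
        return Library(name, "ago2ip", reads)

    total = build(rng.multinomial(n_reads, pool), "total_sim")
    ip = build(rng.multinomial(n_reads, ip_p), "ago2ip_sim")
    return total, ip, feats


def make_mini_snorna(guide_len: int, label: str = "mini") -> tuple[str, str]:
    """Synthetic stand-in mini-snoRNA sequence with a given guide length.

    Constructed (not a natural sequence): a 4-bp G/C closing stem whose 5' arm
    sits one nucleotide away from the C box and whose 3' arm abuts the D box,
    so the stem-bounded mature length is ``guide_len + 20``.  Guide fillers are
    fixed motif-free blocks.  Returns (name, sequence) with 10-nt flanks
    around the mature form, mirroring a detector input window.
    """
    filler = "CCGUACCGUACCGUACCGUA"  # motif-free
    if guide_len > len(filler):
        raise ValueError("guide too long for the fixed filler block")
    up_flank = "AAAAAGGCGA"  # last nt is the 1-nt gap before the C box
    down_flank = "CGCCAAAAAA"  # first 4 nt pair the GGCG arm
    seq = up_flank + "AUGAUGA" + filler[:guide_len] + "CUGA" + down_flank
    return f"{label}_synthetic", seq
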