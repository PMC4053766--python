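"""Guide-region extraction, antisense 8-mer target search with the D+5
methylation-site rule, shuffle-based enrichment testing, and a generic
percentile cutoff calibration for external duplex scorers.

The guide region is the antisense element immediately (offset 0) or one
nucleotide (offset 1) upstream of a D or D' box.  A target hit is an exact
Watson-Crick reverse-complement match of the 8-mer guide (G-U wobble excluded
by default).  The target nucleotide base-paired with the fifth snoRNA
nucleotide upstream of the box -- counting the nucleotide immediately 5' of
the box as position 1 -- is the predicted 2'-O-methylation site; for an
antiparallel duplex where target[t+i] pairs guide[7-i] this is
``t + 4 - offset``.  An alternative convention counting the adjacent
nucleotide as position 0 (site ``t + 5 - offset``) is available via
``counting="adjacent-is-zero"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .model import SnoRNAAnnotation
from .seq import as_rna, is_wc_pair, revcomp

GUIDE_LENGTH = 8
D_PLUS = 5  # the D+5 methylation rule


@dataclass(frozen=True)
class GuideRegion:
    sno_id: str
    box: str  # "D" or "Dp"
    sequence: str  # 8- or 9-nt, 5'->3', ending `offset` nt before the box
    offset: int  # 0 = immediately upstream of the box, 1 = one nt upstream


@dataclass(frozen=True)
class TargetHit:
    guide: GuideRegion
    target_id: str
    target_span: tuple[int, int]  # half-open, on the target RNA
    methyl_site: int  # 0-based target position predicted 2'-O-methylated


@dataclass(frozen=True)
class EnrichmentResult:
    observed: int
    shuffled_mean: float
    shuffled_counts: tuple[int, ...]
    n_shuffles: int
    seed: int


def extract_guides(
    annotation: SnoRNAAnnotation,
    sequence: str,
    length: int = GUIDE_LENGTH,
    offsets: Sequence[int] = (0, 1),
    boxes: Sequence[str] = ("D", "Dp"),
) -> list[GuideRegion]:
    """Guide regions upstream of the D (and D') boxes of one snoRNA.

    ``sequence`` is the transcript-oriented sequence of the snoRNA locus.
    A (box, offset) combination without enough upstream sequence is skipped
    with a warning.
    """
    guides = []
    for box in boxes:
        if box not in annotation.boxes:
            continue
        box_start, _ = annotation.box_transcript_span(box)
        for offset in offsets:
            lo = box_start - offset - length
            hi = box_start - offset
            if lo < 0:
                warnings.warn(
                    f"{annotation.id}: insufficient sequence upstream of {box} "
                    f"box for a {length}-mer at offset {offset}; skipped"
                )
                continue
            guides.append(
                GuideRegion(annotation.id, box, as_rna(sequence[lo:hi]), offset)
            )
    return guides


def methyl_site_for_match(
    target_start: int, offset: int, counting: str = "adjacent-is-one"
) -> int:
    """Predicted methylation position on the target for an 8-mer guide match
    starting at ``target_start``."""
    if counting == "adjacent-is-one":
        return target_start + (GUIDE_LENGTH - D_PLUS) + 1 - offset
    if counting == "adjacent-is-zero":
        return target_start + (GUIDE_LENGTH - D_PLUS) + 2 - offset
    raise ValueError(f"unknown counting convention {counting!r}")


def find_targets(
    guides: Iterable[GuideRegion],
    targets: Mapping[str, str],
    counting: str = "adjacent-is-one",
    allow_gu: bool = False,
) -> list[TargetHit]:
    """All exact antisense occurrences of each 8-mer guide in the target RNAs.

    With the default strict Watson-Crick mode a hit is simply an occurrence of
    the guide's reverse complement; ``allow_gu`` admits wobble pairs at each
    duplex position.
    """
    hits = []
    rna_targets = {tid: as_rna(seq) for tid, seq in targets.items()}
    for guide in guides:
        gseq = as_rna(guide.sequence)
        if len(gseq) != GUIDE_LENGTH:
            raise ValueError(
                f"target search requires {GUIDE_LENGTH}-mer guides, got {len(gseq)}"
            )
        for tid, tseq in rna_targets.items():
            for t in range(len(tseq) - GUIDE_LENGTH + 1):
                window = tseq[t : t + GUIDE_LENGTH]
                # antiparallel: target[t+i] pairs guide[7-i]
                if all(
                    is_wc_pair(window[i], gseq[GUIDE_LENGTH - 1 - i], allow_gu)
                    for i in range(GUIDE_LENGTH)
                ):
                    hits.append(
                        TargetHit(
                            guide,
                            tid,
                            (t, t + GUIDE_LENGTH),
                            methyl_site_for_match(t, guide.offset, counting),
                        )
                    )
    return hits


def _has_hit(sequence: str, complements: Sequence[str]) -> bool:
    return any(c in sequence for c in complements)


def shuffle_enrichment(
    cluster_sequences: Sequence[str],
    guides: Sequence[GuideRegion],
    n_shuffles: int = 100,
    seed: int = 0,
    dinucleotide: bool = False,
) -> EnrichmentResult:
    """Observed number of cluster sequences containing >= 1 guide complement,
    against the mean over mononucleotide shuffles of every cluster sequence.

    The shuffle permutes each sequence independently (composition preserved);
    ``dinucleotide`` swaps in a dinucleotide-preserving shuffle.
    """
    if not cluster_sequences:
        raise ValueError("empty cluster set")
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    seqs = [as_rna(s) for s in cluster_sequences]
    complements = sorted({revcomp(g.sequence) for g in guides})
    observed = sum(1 for s in seqs if _has_hit(s, complements))
    rng = np.random.default_rng(seed)
    counts = []
    for _ in range(n_shuffles):
        n = 0
        for s in seqs:
            shuffled = _shuffle_sequence(s, rng, dinucleotide)
            if _has_hit(shuffled, complements):
                n += 1
        counts.append(n)
    return EnrichmentResult(
        observed, float(np.mean(counts)), tuple(counts), n_shuffles, seed
    )


def _shuffle_sequence(seq: str, rng: np.random.Generator, dinucleotide: bool) -> str:
    if not dinucleotide:
        chars = np.array(list(seq))
        return "".join(rng.permutation(chars))
    # dinucleotide-preserving: random walk over the shuffled successor lists
    # of the dinucleotide multigraph; a uniformly shuffled ordering is not
    # always an Eulerian path, so retry a few times and fall back to the
    # original order (the identity walk always completes)
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    for _attempt in range(100):
        trial = {a: list(succ) for a, succ in edges.items()}
        for succ in trial.values():
            rng.shuffle(succ)
        out = [seq[0]]
        pos = {a: 0 for a in trial}
        for _ in range(len(seq) - 1):
            a = out[-1]
            if pos[a] >= len(trial[a]):
                break
            out.append(trial[a][pos[a]])
            pos[a] += 1
        if len(out) == len(seq):
            return "".join(out)
    return seq


def calibrate_score_cutoff(
    scorer: Callable[[str, str], float],
    query: str,
    n_random: int = 1000,
    random_len: int = 100,
    percentile: float = 90.0,
    seed: int = 0,
    alphabet: str = "ACGU",
) -> float:
    """Score cutoff such that a prediction passes iff it scores strictly lower
    (better) than at least ``percentile`` % of uniform-random targets.

    Emulates an energy-cutoff calibration on random sequences: the scorer maps
    (query, target) to a real value where lower is better.  ``percentile``
    100 makes the cutoff the minimum random score.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    rng = np.random.default_rng(seed)
    letters = np.array(list(alphabet))
    scores = np.sort(
        [
            scorer(query, "".join(rng.choice(letters, size=random_len)))
            for _ in range(n_random)
        ]
    )
    k = int(np.floor(n_random * (1.0 - percentile / 100.0)))
    k = min(k, n_random - 1)
    return float(scores[k])


def passes_cutoff(
    score: float,
    cutoff: float,
    side_pairs: tuple[int, int] | None = None,
    min_side_pairs: int = 3,
) -> bool:
    """Hit filter: strictly below the calibrated cutoff, and, when the scorer
    supplies per-side base-pair counts for the binding pocket, at least
    ``min_side_pairs`` canonical pairs on each side."""
    if score >= cutoff:
        return False
    if side_pairs is not None and min(side_pairs) < min_side_pairs:
        return False
    return True
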