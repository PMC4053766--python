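"""Small-RNA class composition and Argonaute-2 loading-efficiency analysis.

A :class:`ClassComposition` gives the percent of a library's reads assigned
to each small-RNA class (miRNA, tRNA, snRNA, C/D and H/ACA snoRNA) with an
explicit ``none`` category, so every row sums to 100%.  Loading efficiency of
class a relative to class b is the fold change of their abundance ratio
between the Argonaute-IP fraction and the total small-RNA pool.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .model import Feature, Library

LOADING_CLASSES = ("miRNA", "tRNA", "snRNA", "CD_snoRNA", "HACA_snoRNA", "none")

#: Priority when a read overlaps annotations of several classes.
LOADING_PRIORITY = ("miRNA", "tRNA", "snRNA", "CD_snoRNA", "HACA_snoRNA")


@dataclass(frozen=True)
class ClassComposition:
    library: str
    fractions: Mapping[str, float]  # percent per class, summing to 100

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 100.0) > 0.01:
            raise ValueError(f"class fractions sum to {total}, expected 100")
        if any(v < 0 for v in self.fractions.values()):
            raise ValueError("negative class fraction")


def compose_classes(
    library: Library,
    features: Iterable[Feature],
    priority: Sequence[str] = LOADING_PRIORITY,
    classes: Sequence[str] = LOADING_CLASSES,
) -> ClassComposition:
    """Copies-weighted percent of library reads per RNA class.

    Each read counts once, at the highest-priority class it overlaps;
    unannotated reads go to ``none``.
    """
    if not library.reads:
        raise ValueError(f"library {library.name!r} is empty")
    trees: dict[tuple[str, str], IntervalTree] = {}
    for feat in features:
        key = (feat.interval.chrom, feat.interval.strand)
        trees.setdefault(key, IntervalTree()).addi(
            feat.interval.start, feat.interval.end, feat.category
        )
    rank = {cat: i for i, cat in enumerate(priority)}
    counts: Counter = Counter()
    for read in library.reads:
        iv = read.interval
        tree = trees.get((iv.chrom, iv.strand))
        hits = {h.data for h in tree.overlap(iv.start, iv.end)} if tree else set()
        hits &= set(priority)
        label = min(hits, key=lambda c: rank[c]) if hits else "none"
        counts[label] += read.copies
    total = sum(counts.values())
    fractions = {cls: 100.0 * counts.get(cls, 0) / total for cls in classes}
    return ClassComposition(library.name, fractions)


def abundance_ratio(comp: ClassComposition, class_a: str, class_b: str) -> float:
    """fraction(a) / fraction(b) within one library."""
    b = comp.fractions[class_b]
    if b == 0:
        raise ValueError(f"class {class_b!r} has zero abundance in {comp.library!r}")
    return comp.fractions[class_a] / b


def loading_efficiency(
    total: ClassComposition,
    ip: ClassComposition,
    class_a: str,
    class_b: str,
) -> float:
    """Fold difference in Argonaute-incorporation efficiency of a vs b:
    (ip_a / ip_b) / (total_a / total_b).  Invariant to uniform rescaling of
    either composition."""
    for comp, cls in ((total, class_a), (total, class_b), (ip, class_a), (ip, class_b)):
        if comp.fractions[cls] == 0:
            raise ValueError(f"class {cls!r} has zero abundance in {comp.library!r}")
    return abundance_ratio(ip, class_a, class_b) / abundance_ratio(total, class_a, class_b)


def reference_compositions() -> dict[str, ClassComposition]:
    """Published-style reference class-composition table (HEK293 18-30 nt
    small-RNA pool; HeLa Ago2 IP, asynchronous and mitotic cells), as shipped
    with the package.  Percentages per column sum to 100 via ``none``."""
    path = resources.files("snopipe").joinpath("data/reference_class_composition.tsv")
    with resources.as_file(path) as p:
        table = pd.read_csv(p, sep="\t", index_col=0)
    return {
        column: ClassComposition(column, table[column].to_dict())
        for column in table.columns
    }


def composition_table(comps: Iterable[ClassComposition]) -> pd.DataFrame:
    """Compositions side by side, one column per library."""
    data = {c.library: pd.Series(dict(c.fractions)) for c in comps}
    return pd.DataFrame(data).reindex(LOADING_CLASSES)
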