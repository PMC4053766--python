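"""Readers and writers for the on-disk formats used across the pipeline.

Alignment dialect (canonical fixture format)
--------------------------------------------
Tab-separated, one mapped (collapsed) read per row::

    chrom  start  end  read_id  copies  strand  substitutions

``substitutions`` is ``.`` for none, else a comma-separated list of
``ref:offset:alt`` items such as ``T:5:C`` (offset relative to the read's
genomic interval start).  An optional header line ``#total_mapped=N``
overrides the normalization denominator; otherwise it is the sum of copies.

GFF3 carries snoRNA annotations (1-based inclusive, converted to internal
0-based half-open): a ``gene`` feature with ``ID`` and ``sno_class``
attributes and ``<label>_box`` child features.  FASTA goes through Biopython.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    AlignedRead,
    Feature,
    GenomicInterval,
    Library,
    SnoRNAAnnotation,
    Substitution,
)


class AlignmentParseError(ValueError):
    """Raised with the offending line number when the alignment TSV is malformed."""


_BOX_FEATURETYPES = {
    "C_box": "C",
    "D_box": "D",
    "Cp_box": "Cp",
    "Dp_box": "Dp",
    "H_box": "H",
    "ACA_box": "ACA",
}


def _parse_substitutions(field: str, line_no: int) -> tuple[Substitution, ...]:
    if field == "." or field == "":
        return ()
    subs = []
    for item in field.split(","):
        parts = item.split(":")
        if len(parts) != 3:
            raise AlignmentParseError(
                f"line {line_no}: bad substitution field {item!r} (want ref:offset:alt)"
            )
        ref, offset, alt = parts
        try:
            subs.append(Substitution(int(offset), ref, alt))
        except ValueError as exc:
            raise AlignmentParseError(f"line {line_no}: {exc}") from exc
    return tuple(subs)


def read_alignment_table(
    path: str | Path, name: str | None = None, assay: str = "parclip"
) -> Library:
    """Parse the alignment TSV dialect into a :class:`Library`.

    Every row either yields a read or raises a located error; rows are never
    silently dropped.
    """
    path = Path(path)
    reads: list[AlignedRead] = []
    total_mapped: int | None = None
    with path.open() as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#total_mapped="):
                    total_mapped = int(line.split("=", 1)[1])
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise AlignmentParseError(
                    f"line {line_no}: expected >= 7 tab-separated fields, got {len(fields)}"
                )
            chrom, start, end, _read_id, copies, strand, subs = fields[:7]
            try:
                interval = GenomicInterval(chrom, int(start), int(end), strand)
                read = AlignedRead(
                    interval, int(copies), _parse_substitutions(subs, line_no)
                )
            except AlignmentParseError:
                raise
            except ValueError as exc:
                raise AlignmentParseError(f"line {line_no}: {exc}") from exc
            reads.append(read)
    return Library(name or path.stem, assay, reads, total_mapped)


def write_alignment_table(library: Library, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as handle:
        handle.write(f"#total_mapped={library.total_mapped}\n")
        for i, read in enumerate(library.reads):
            subs = (
                ",".join(f"{s.ref}:{s.offset}:{s.alt}" for s in read.substitutions)
                or "."
            )
            iv = read.interval
            handle.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tr{i}\t{read.copies}\t{iv.strand}\t{subs}\n"
            )


def load_annotations(path: str | Path) -> list[SnoRNAAnnotation]:
    """Load snoRNA annotations with box children from a GFF3 file.

    Unknown box labels are dropped with a warning; a box outside its parent is
    a validation error.  A header-only file yields an empty list.
    """
    try:
        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except gffutils.exceptions.EmptyInputError:
        return []
    annotations = []
    for gene in db.features_of_type("gene"):
        interval = GenomicInterval(gene.seqid, gene.start - 1, gene.end, gene.strand)
        sno_class = gene.attributes.get("sno_class", ["CD"])[0]
        boxes: dict[str, GenomicInterval] = {}
        for child in db.children(gene):
            if child.featuretype == "stem_arm":
                continue  # structural annotation, not a box
            label = _BOX_FEATURETYPES.get(child.featuretype)
            if label is None:
                warnings.warn(
                    f"{gene.id}: unknown box feature type {child.featuretype!r}, dropped"
                )
                continue
            boxes[label] = GenomicInterval(
                child.seqid, child.start - 1, child.end, child.strand
            )
        annotations.append(SnoRNAAnnotation(gene.id, sno_class, interval, boxes))
    return annotations


def write_annotations(
    annotations: Iterable[SnoRNAAnnotation], path: str | Path, source: str = "snopipe"
) -> None:
    """Write snoRNA annotations (gene + box children) as GFF3, 1-based inclusive."""
    inverse = {v: k for k, v in _BOX_FEATURETYPES.items()}
    with Path(path).open("w") as handle:
        handle.write("##gff-version 3\n")
        for ann in annotations:
            iv = ann.interval
            handle.write(
                f"{iv.chrom}\t{source}\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t"
                f"ID={ann.id};sno_class={ann.sno_class}\n"
            )
            for label, box in sorted(ann.boxes.items()):
                handle.write(
                    f"{box.chrom}\t{source}\t{inverse[label]}\t{box.start + 1}\t{box.end}"
                    f"\t.\t{box.strand}\t.\tID={ann.id}_{label};Parent={ann.id}\n"
                )


def write_candidates_gff(candidates: Sequence, path: str | Path) -> None:
    """Write detected C/D box candidates as GFF3 (gene + C_box/D_box/stem_arm).

    Round-trips through :func:`load_annotations` losslessly for the boxes.
    """
    with Path(path).open("w") as handle:
        handle.write("##gff-version 3\n")
        for cand in candidates:
            if cand.mature_interval is None:
                raise ValueError(f"candidate {cand.id} has no genomic anchor")
            iv = cand.mature_interval
            handle.write(
                f"{iv.chrom}\tsnopipe\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t"
                f"ID={cand.id};sno_class=CD;guide_len={cand.guide_len}\n"
            )
            for label in ("C", "D"):
                box = cand.genomic_box(label)
                handle.write(
                    f"{box.chrom}\tsnopipe\t{label}_box\t{box.start + 1}\t{box.end}\t.\t"
                    f"{box.strand}\t.\tID={cand.id}_{label};Parent={cand.id}\n"
                )
            for arm_label, arm in (("up", cand.genomic_stem_arm("up")),
                                   ("down", cand.genomic_stem_arm("down"))):
                handle.write(
                    f"{arm.chrom}\tsnopipe\tstem_arm\t{arm.start + 1}\t{arm.end}\t.\t"
                    f"{arm.strand}\t.\tID={cand.id}_stem_{arm_label};Parent={cand.id}\n"
                )


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_sam(path: str | Path, name: str | None = None, assay: str = "parclip") -> Library:
    """Optional SAM/BAM adapter: convert mapped records to the same read model.

    Substitutions are reconstructed from the MD tag (records without one
    contribute no substitutions); each record counts one copy.  The tab
    dialect remains the canonical fixture format.
    """
    import pysam

    path = Path(path)
    reads: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as handle:
        for rec in handle:
            if rec.is_unmapped:
                continue
            strand = "-" if rec.is_reverse else "+"
            interval = GenomicInterval(
                rec.reference_name, rec.reference_start, rec.reference_end, strand
            )
            subs = []
            if rec.has_tag("MD") and rec.query_sequence:
                for qpos, rpos, ref in rec.get_aligned_pairs(with_seq=True):
                    if qpos is None or rpos is None or ref is None:
                        continue
                    if ref.islower():  # pysam marks mismatches lowercase
                        subs.append(
                            Substitution(
                                rpos - rec.reference_start,
                                ref.upper(),
                                rec.query_sequence[qpos].upper(),
                            )
                        )
            reads.append(AlignedRead(interval, 1, tuple(subs)))
    return Library(name or path.stem, assay, reads)


def write_bedgraph(
    coverage, interval: GenomicInterval, path: str | Path, name: str = "coverage"
) -> None:
    """Per-position coverage (transcript orientation) as genomic bedGraph."""
    values = list(coverage)
    if interval.strand == "-":
        values = values[::-1]
    with Path(path).open("w") as handle:
        handle.write(f'track type=bedGraph name="{name}"\n')
        run_start = 0
        for i in range(1, len(values) + 1):
            if i == len(values) or values[i] != values[run_start]:
                handle.write(
                    f"{interval.chrom}\t{interval.start + run_start}\t"
                    f"{interval.start + i}\t{values[run_start]}\n"
                )
                run_start = i


def read_bed6(path: str | Path) -> list[GenomicInterval]:
    intervals = []
    with Path(path).open() as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise AlignmentParseError(f"line {line_no}: BED6 needs 6 fields")
            intervals.append(
                GenomicInterval(fields[0], int(fields[1]), int(fields[2]), fields[5])
            )
    return intervals


def read_conservation_track(path: str | Path) -> dict[int, float]:
    """Two-column TSV (0-based position, score) -> sparse per-position scores."""
    scores: dict[int, float] = {}
    with Path(path).open() as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            pos, score = line.split("\t")[:2]
            scores[int(pos)] = float(score)
    return scores


def read_features_gff(path: str | Path) -> list[Feature]:
    """Read generic annotation features (any type) for cluster classification.

    The GFF3 ``category`` attribute takes precedence, else the feature type is
    used as the category label.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    feats = []
    for f in db.all_features():
        if f.attributes.get("Parent"):
            continue
        category = f.attributes.get("category", [f.featuretype])[0]
        feats.append(
            Feature(GenomicInterval(f.seqid, f.start - 1, f.end, f.strand), category, f.id or "")
        )
    return feats
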