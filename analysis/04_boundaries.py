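#!/usr/bin/env python
"""Box-relative processing-boundary analysis: 5'/3' end histograms of the
small-RNA reads, modal-boundary agreement between the long and short
libraries, and classification of short reads into terminus-derived classes.

Reads results/sim/; writes histogram and boundary tables under
results/boundaries/.
"""

import argparse
from pathlib import Path

import pandas as pd

from snopipe.boundaries import (
    classify_library_origins,
    end_histograms,
    export_boundary_matrix,
    long_short_agreement,
    mature_boundaries,
)
from snopipe.io import load_annotations, read_alignment_table


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--sim-dir", type=Path, default=Path("results/sim"))
    parser.add_argument("--out-dir", type=Path, default=Path("results/boundaries"))
    parser.add_argument("--top", type=int, default=50)
    args = parser.parse_args()
    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)

    annotations = load_annotations(args.sim_dir / "truth.gff3")
    long_lib = read_alignment_table(args.sim_dir / "srna_long.tsv", assay="srna")
    short_lib = read_alignment_table(args.sim_dir / "sdrna_short.tsv", assay="sdrna")

    profiles = [end_histograms(ann, long_lib) for ann in annotations]
    table = export_boundary_matrix(profiles)
    table.to_csv(out / "boundary_matrix_long.tsv", sep="\t", index=False)

    modal = pd.DataFrame(
        [{"sno_id": p.sno_id, "modal_start": p.modal_start,
          "modal_end": p.modal_end} for p in profiles if p.start_hist]
    )
    modal.to_csv(out / "modal_boundaries.tsv", sep="\t", index=False)
    print("modal 5' offsets:", modal.modal_start.value_counts().to_dict())
    print("modal 3' offsets:", modal.modal_end.value_counts().to_dict())

    top_n = min(args.top, len(annotations))
    start_agree, end_agree = long_short_agreement(
        annotations, long_lib, short_lib, top_n=top_n
    )
    print(f"long/short modal agreement over top {top_n}: "
          f"start {start_agree:.1%}, end {end_agree:.1%}")

    mature = {
        ann.id: mature_boundaries(ann, end_histograms(ann, long_lib))
        for ann in annotations
    }
    origins = classify_library_origins(annotations, short_lib, mature)
    print("short-read origin classes:",
          {k: f"{v:.1%}" for k, v in origins.items()})
    pd.Series(origins).to_csv(out / "read_origin_classes.tsv", sep="\t")


if __name__ == "__main__":
    main()
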