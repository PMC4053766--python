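#!/usr/bin/env python
"""Generate the default synthetic data set: a genome with 30 embedded C/D box
snoRNA loci, two replicate PAR-CLIP libraries, long (20-200 nt) and short
(18-30 nt) small-RNA libraries, and a total/Ago2-IP class-mixture pair.

Writes FASTA, truth GFF3 and alignment-dialect TSVs under results/sim/.
"""

import argparse
from pathlib import Path

from snopipe.io import write_alignment_table, write_annotations, write_fasta
from snopipe.simulate import (
    SimulationConfig,
    make_genome,
    simulate_ago_ip,
    simulate_clip_reads,
    simulate_srna_reads,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out-dir", type=Path, default=Path("results/sim"))
    args = parser.parse_args()
    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)

    cfg = SimulationConfig(seed=args.seed)
    genome, truths = make_genome(cfg)
    write_fasta(genome, out / "genome.fa")
    write_annotations([t.annotation() for t in truths], out / "truth.gff3")

    libraries = {
        "clip_repA.tsv": simulate_clip_reads(truths, genome, cfg, "clip_repA", stream=1),
        "clip_repB.tsv": simulate_clip_reads(truths, genome, cfg, "clip_repB", stream=11),
        "srna_long.tsv": simulate_srna_reads(truths, cfg, "long", stream=2),
        "sdrna_short.tsv": simulate_srna_reads(truths, cfg, "short", stream=5),
    }
    total, ip, _ = simulate_ago_ip(cfg, n_reads=100_000)
    libraries["ago_total.tsv"] = total
    libraries["ago_ip.tsv"] = ip
    for fname, lib in libraries.items():
        write_alignment_table(lib, out / fname)

    print(f"genome: {len(genome['chr'])} nt, {len(truths)} snoRNA loci "
          f"({sum(t.locus.strand == '-' for t in truths)} on the minus strand)")
    for fname, lib in libraries.items():
        print(f"  {fname}: {len(lib.reads)} collapsed reads, "
              f"{lib.total_mapped} mapped copies")


if __name__ == "__main__":
    main()
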