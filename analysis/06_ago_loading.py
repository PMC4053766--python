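#!/usr/bin/env python
"""Class composition of the simulated total and Ago2-IP small-RNA libraries,
the same ratios computed from the shipped reference composition table, and
recovery of the generator's inclusion weights as loading efficiencies.

Reads results/sim/; writes composition tables under results/loading/.
"""

import argparse
from pathlib import Path

from snopipe.io import read_alignment_table
from snopipe.loading import (
    abundance_ratio,
    compose_classes,
    composition_table,
    loading_efficiency,
    reference_compositions,
)
from snopipe.simulate import SimulationConfig, ago_features


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--sim-dir", type=Path, default=Path("results/sim"))
    parser.add_argument("--out-dir", type=Path, default=Path("results/loading"))
    args = parser.parse_args()
    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)

    ref = reference_compositions()
    total_ref = ref["hek293_srna_18_30"]
    ip_ref = ref["hela_ago2ip_async"]
    print("reference table ratios:")
    print(f"  C/D vs H/ACA in the total pool: "
          f"{abundance_ratio(total_ref, 'CD_snoRNA', 'HACA_snoRNA'):.1f}")
    print(f"  H/ACA vs C/D in the Ago2 IP:    "
          f"{abundance_ratio(ip_ref, 'HACA_snoRNA', 'CD_snoRNA'):.1f}")
    print(f"  tRNA vs C/D in the total pool:  "
          f"{abundance_ratio(total_ref, 'tRNA', 'CD_snoRNA'):.1f}")
    print(f"  tRNA vs C/D in the Ago2 IP:     "
          f"{abundance_ratio(ip_ref, 'tRNA', 'CD_snoRNA'):.1f}")
    print(f"  H/ACA vs C/D loading efficiency: "
          f"{loading_efficiency(total_ref, ip_ref, 'HACA_snoRNA', 'CD_snoRNA'):.1f}")

    feats = ago_features()
    total = compose_classes(
        read_alignment_table(args.sim_dir / "ago_total.tsv", assay="ago2ip"), feats
    )
    ip = compose_classes(
        read_alignment_table(args.sim_dir / "ago_ip.tsv", assay="ago2ip"), feats
    )
    table = composition_table([total, ip])
    table.to_csv(out / "simulated_composition.tsv", sep="\t")
    print("\nsimulated composition (% of reads):")
    print(table.round(3).to_string())

    cfg = SimulationConfig(seed=args.seed)
    eff = loading_efficiency(total, ip, "miRNA", "none")
    truth = cfg.ago_class_weights["miRNA"] / cfg.ago_class_weights["none"]
    print(f"\nmiRNA-vs-unannotated loading efficiency: {eff:.2f} "
          f"(generator weight ratio {truth:.2f}, "
          f"error {abs(eff - truth) / truth:.1%})")


if __name__ == "__main__":
    main()
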