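#!/usr/bin/env python
"""Classify cell-type selectivity and build the ligand->target network.

On the contamination-adjusted matrix: calls expression (median TPM > 2),
partitions genes into tumour-/host-selective and shared (FC > 5),
computes ligand->cell-type receptor scores, and assembles the edge list
for metastasis-flagged ligands.  Planted ligands should reappear as
exactly one edge each, from their producer to their planted target.
"""

import argparse
import json
import warnings
from pathlib import Path

from netkit import io, selectivity


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--sim", type=Path, default=Path("results/analysis/sim"))
    parser.add_argument("--adjusted", type=Path,
                        default=Path("results/analysis/adjust"))
    parser.add_argument("--out", type=Path, default=Path("results/analysis/network"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    matrix, meta = io.load_matrix(args.adjusted / "adjusted_matrix.tsv",
                                  args.adjusted / "meta_kept.tsv")
    lr_map = selectivity.LigandReceptorMap.from_tsv(args.sim / "lr_map.tsv")

    calls, counts = selectivity.classify_selectivity(matrix, meta)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scores = selectivity.receptor_target_scores(lr_map, matrix, meta)
        edges = selectivity.build_metastasis_network(calls, lr_map, matrix, meta)

    scores.to_csv(args.out / "receptor_target_scores.tsv", sep="\t",
                  index_label="ligand", float_format="%.10g", lineterminator="\n")
    edges.to_csv(args.out / "network_edges.tsv", sep="\t", index=False,
                 float_format="%.10g", lineterminator="\n")
    (args.out / "partition_counts.json").write_text(
        json.dumps(counts, indent=2, sort_keys=True) + "\n")

    print(f"expressed genes (median TPM > 2 in >=1 cell type): {counts['expressed']}")
    print(f"partition: {counts['tumour']} tumour-selective, {counts['host']} "
          f"host-selective ({counts['host_split']}), {counts['shared']} shared")
    print(f"stroma Venn: {counts['stroma_combinations']}")
    print(f"network: {len(edges)} edges for {len(lr_map.flagged('metastasis'))} "
          f"flagged ligands -> {args.out}")


if __name__ == "__main__":
    main()
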