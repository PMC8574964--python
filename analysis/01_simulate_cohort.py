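#!/usr/bin/env python
"""Generate the synthetic study data every later analysis step consumes.

Writes a contaminated sorted-cell cohort (TPM matrix + metadata + true
contamination fractions), a ligand/receptor annotation with planted
producer->target structure, and a two-timepoint LFQ proteomics table,
all under results/analysis/sim/.
"""

import argparse
from pathlib import Path

from netkit import io
from netkit.simulate import (
    SimulationConfig,
    generate_contaminated_cohort,
    generate_lr_annotation_and_secretome,
    generate_pure_profiles,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/analysis/sim"))
    args = parser.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    config = SimulationConfig(seed=args.seed)
    profiles, markers = generate_pure_profiles(config)
    matrix, meta, truth = generate_contaminated_cohort(profiles, config)
    lr_map, lfq, lr_truth = generate_lr_annotation_and_secretome(
        config, profiles, markers)

    io.write_matrix(matrix, out / "matrix.tsv")
    io.write_matrix(profiles, out / "pure_profiles.tsv")
    io.write_meta(meta, out / "meta.tsv")
    truth.to_csv(out / "contamination_truth.tsv", sep="\t", index=False,
                 lineterminator="\n")
    lr_map.to_frame().to_csv(out / "lr_map.tsv", sep="\t", index=False,
                             lineterminator="\n")
    lfq.to_csv(out / "lfq.tsv", sep="\t", index=False, float_format="%.10g",
               lineterminator="\n")

    n_cont = truth["sample_id"].nunique()
    print(f"cohort: {matrix.shape[0]} genes x {matrix.shape[1]} samples "
          f"({len(config.cell_types)} cell types, noise sigma {config.noise_sigma})")
    print(f"contaminated samples: {n_cont} at fractions "
          f"{sorted(set(truth['true_frac']))}")
    print(f"ligand-receptor annotation: {len(lr_map.ligands)} ligands, "
          f"planted single-target structure")
    print(f"LFQ table: {lfq['protein'].nunique()} proteins x "
          f"{lfq['sample'].nunique()} conditioned-medium samples")
    print(f"wrote inputs to {out}")


if __name__ == "__main__":
    main()
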