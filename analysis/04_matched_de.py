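#!/usr/bin/env python
"""Patient-matched compartment comparison with known planted truth.

Simulates six patient-matched omentum/ascites tumour-cell pairs twice:
once under the null (no planted effects) to verify that the paired t-test
is calibrated, and once with 200 planted 8-fold shifts to measure the
sensitivity of the combined FC > 3 / TPM > 3 / p < .05 call.  Also
reports the between-compartment profile correlation.
"""

import argparse
from pathlib import Path

from netkit import differential
from netkit.simulate import SimulationConfig, generate_matched_pairs


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/analysis/de"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    null_cfg = SimulationConfig(seed=args.seed, de_n_genes=1000, de_n_planted=0)
    matrix, _, pairs, _ = generate_matched_pairs(null_cfg)
    de_null = differential.paired_de(matrix, pairs)
    null_frac = float((de_null["p"] < 0.05).mean())

    power_cfg = SimulationConfig(seed=args.seed + 1, de_n_genes=1000,
                                 de_n_planted=200)
    matrix, _, pairs, truth = generate_matched_pairs(power_cfg)
    de = differential.paired_de(matrix, pairs)
    rho = differential.matched_correlation(matrix, pairs)
    planted = truth.index[truth["planted"]]
    sensitivity = float(de.loc[planted, "called"].mean())
    false_calls = int(de.loc[~de.index.isin(planted), "called"].sum())

    de.to_csv(args.out / "de_planted.tsv", sep="\t", index_label="gene",
              float_format="%.10g", lineterminator="\n")
    de_null.to_csv(args.out / "de_null.tsv", sep="\t", index_label="gene",
                   float_format="%.10g", lineterminator="\n")

    print(f"null calibration: {null_frac:.3f} of 1000 genes at p < .05 "
          f"(nominal 0.05, n = {len(pairs)} pairs)")
    print(f"power: sensitivity {sensitivity:.3f} on 200 planted 8-fold genes; "
          f"{false_calls} calls among unplanted genes")
    print(f"compartment profile correlation (Spearman): {rho:.3f}")
    print(f"called genes: {int(de['called'].sum())} "
          f"({int((de['called'] & (de['direction'] == 'up')).sum())} up, "
          f"{int((de['called'] & (de['direction'] == 'down')).sum())} down) "
          f"-> {args.out}")


if __name__ == "__main__":
    main()
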