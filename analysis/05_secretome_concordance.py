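#!/usr/bin/env python
"""Secretome calls from the LFQ table and concordance with RNA expression.

Calls the secretome (peptide detected and late > baseline median signal),
computes the secretome/transcriptome overlap at TPM > 0.3, the per-bin
detection fraction across RNA expression, and the RNA-protein rank
correlation over secreted proteins.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from netkit import io, secretome, selectivity


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--sim", type=Path, default=Path("results/analysis/sim"))
    parser.add_argument("--adjusted", type=Path,
                        default=Path("results/analysis/adjust"))
    parser.add_argument("--out", type=Path,
                        default=Path("results/analysis/secretome"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    matrix, meta = io.load_matrix(args.adjusted / "adjusted_matrix.tsv",
                                  args.adjusted / "meta_kept.tsv")
    lfq = pd.read_csv(args.sim / "lfq.tsv", sep="\t")

    calls = secretome.call_secretome(lfq)
    med = selectivity.medians_by_cell_type(matrix, meta)["CAF"]
    gene_list = sorted(set(calls.index) & set(med.index))
    overlap = secretome.secretome_transcriptome_overlap(med, calls, gene_list)
    rate = secretome.detection_rate_by_expression(
        med, calls, [0.0, 0.3, 2.0, 10.0, 50.0, 500.0, np.inf], gene_list)
    secreted = [g for g in calls.index[calls["in_secretome"]] if g in med.index]
    rho = secretome.rna_protein_correlation(
        med, calls.loc[secreted, "median_late"])

    calls.to_csv(args.out / "secretome_calls.tsv", sep="\t",
                 index_label="protein", float_format="%.10g", lineterminator="\n")
    rate.to_csv(args.out / "detection_rate.tsv", sep="\t", index=False,
                float_format="%.10g", lineterminator="\n")

    print(f"secretome: {overlap['secretome']} proteins; transcriptome "
          f"(TPM > 0.3): {overlap['transcriptome']}; overlap {overlap['overlap']}")
    frac = rate["fraction"]
    print("detection fraction per TPM bin:",
          ", ".join("-" if np.isnan(f) else f"{f:.2f}" for f in frac))
    print(f"RNA-protein Spearman over {len(secreted)} secreted proteins: {rho:.3f}")
    print(f"wrote calls and rates -> {args.out}")


if __name__ == "__main__":
    main()
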