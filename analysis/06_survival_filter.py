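#!/usr/bin/env python
"""Dual-significance survival filter on the stromal-ligand statistics table.

Applies the relapse-free-survival p < .05 and overall-survival |z| > 1.96
filter to the shipped 32-gene table of stroma-selective cytokine/growth-
factor genes and labels each retained gene by its survival direction.
"""

import argparse
from pathlib import Path

from netkit import differential


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--table", type=Path, default=None,
                        help="Alternative survival-statistics TSV "
                             "(gene, rfs_p, rfs_hr, os_z).")
    parser.add_argument("--out", type=Path,
                        default=Path("results/analysis/survival"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    if args.table:
        import pandas as pd

        table = pd.read_csv(args.table, sep="\t")
    else:
        table = differential.load_survival_table()
    out = differential.survival_filter(table, p_max=0.05, z_abs_min=1.96)
    out.to_csv(args.out / "survival_filtered.tsv", sep="\t", index=False,
               float_format="%.10g", lineterminator="\n")

    short = out[out["direction"] == "short survival"]
    long_ = out[out["direction"] == "long survival"]
    print(f"input rows: {len(table)}; retained: {len(out)}")
    print(f"short-survival-associated: {len(short)}; "
          f"long-survival-associated: {len(long_)} "
          f"({', '.join(long_['gene'])})")
    print(f"wrote filtered table -> {args.out}")


if __name__ == "__main__":
    main()
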