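"""Patient-matched differential expression and the survival-statistics filter.

The compartment comparison (omental vs ascites tumour cells, omental vs
ascites macrophages) is a per-gene two-sided paired t-test on
log2(TPM + 1), with a gene called regulated when additionally the
median-based fold change exceeds 3 (either direction) and the larger of
the two condition medians exceeds 3 TPM.  The nominal p-value drives the
call, exactly as in the published analysis; Benjamini-Hochberg q-values
are reported alongside for transparency.

The survival filter retains genes whose expression is dually significant:
relapse-free-survival p < .05 (Kaplan-Meier meta-analysis) and an
overall-survival |z| > 1.96 (pan-cancer meta-analysis), labelling each as
short- or long-survival-associated from the direction of both statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class MatchedPairSet:
    """Patient-matched sample pairs between two conditions (A vs B)."""

    patients: tuple[str, ...]
    a_ids: tuple[str, ...]
    b_ids: tuple[str, ...]
    label_a: str = "A"
    label_b: str = "B"

    def __post_init__(self) -> None:
        if not (len(self.patients) == len(self.a_ids) == len(self.b_ids)):
            raise ValueError("patients, a_ids and b_ids must align")
        if len(set(self.patients)) != len(self.patients):
            raise ValueError("each patient may appear only once")

    def __len__(self) -> int:
        return len(self.patients)

    def swapped(self) -> "MatchedPairSet":
        return MatchedPairSet(self.patients, self.b_ids, self.a_ids,
                              self.label_b, self.label_a)

    @classmethod
    def from_meta(cls, meta: pd.DataFrame, cell_type: str,
                  condition_a: str = "omentum",
                  condition_b: str = "ascites") -> "MatchedPairSet":
        """Pair samples of one cell type across compartments by patient."""
        sub = meta[meta["cell_type"] == cell_type]
        a = sub[sub["compartment"] == condition_a]
        b = sub[sub["compartment"] == condition_b]
        patients = sorted(set(a["patient_id"]) & set(b["patient_id"]))
        a_ids = tuple(sorted(a.index[a["patient_id"] == p])[0] for p in patients)
        b_ids = tuple(sorted(b.index[b["patient_id"] == p])[0] for p in patients)
        return cls(tuple(patients), a_ids, b_ids, condition_a, condition_b)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values for nominal p-values in (0, 1]."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def paired_de(
    matrix: pd.DataFrame,
    pairs: MatchedPairSet,
    fc_threshold: float = 3.0,
    tpm_threshold: float = 3.0,
    alpha: float = 0.05,
    log_offset: float = 1.0,
    fc_offset: float = 0.1,
) -> pd.DataFrame:
    """Per-gene paired differential-expression table (condition A over B).

    Fold change is the ratio of cross-pair medians with ``fc_offset``
    guarding zeros; the TPM filter applies to the larger of the two
    condition medians.  Genes with identical values in every pair get
    p = 1 and a ``zero_variance`` flag.
    """
    if len(pairs) < 3:
        raise ValueError(f"need >=3 matched pairs, got {len(pairs)}")
    a = matrix[list(pairs.a_ids)].to_numpy(dtype=float)
    b = matrix[list(pairs.b_ids)].to_numpy(dtype=float)
    la = np.log2(a + log_offset)
    lb = np.log2(b + log_offset)
    with np.errstate(all="ignore"):
        t_stat, p = stats.ttest_rel(la, lb, axis=1)
    zero_var = np.isclose(np.std(la - lb, axis=1), 0.0)
    p = np.where(zero_var, 1.0, p)
    t_stat = np.where(zero_var, 0.0, t_stat)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    med_a = np.median(a, axis=1)
    med_b = np.median(b, axis=1)
    fc = (med_a + fc_offset) / (med_b + fc_offset)
    fc_either = np.maximum(fc, 1.0 / fc)
    called = ((fc_either > fc_threshold)
              & (np.maximum(med_a, med_b) > tpm_threshold)
              & (p < alpha))
    return pd.DataFrame({
        "gene": matrix.index,
        f"median_{pairs.label_a}": med_a,
        f"median_{pairs.label_b}": med_b,
        "fc": fc,
        "t": t_stat,
        "p": p,
        "q": bh_adjust(p),
        "zero_variance": zero_var,
        "called": called,
        "direction": np.where(fc >= 1.0, "up", "down"),
    }).set_index("gene")


def matched_correlation(
    matrix: pd.DataFrame,
    pairs: MatchedPairSet,
    method: str = "spearman",
) -> float:
    """Correlation between the two conditions' median expression profiles.

    Restricted to genes with a positive median in at least one condition;
    returns NaN when either profile is constant (undefined correlation).
    """
    med_a = matrix[list(pairs.a_ids)].median(axis=1)
    med_b = matrix[list(pairs.b_ids)].median(axis=1)
    keep = (med_a > 0) | (med_b > 0)
    med_a, med_b = med_a[keep], med_b[keep]
    if len(med_a) < 2:
        raise ValueError("need >=2 genes passing the expression filter")
    if med_a.nunique() == 1 or med_b.nunique() == 1:
        return float("nan")
    if method == "spearman":
        return float(stats.spearmanr(med_a, med_b).statistic)
    if method == "pearson":
        return float(stats.pearsonr(med_a, med_b).statistic)
    raise ValueError(f"unknown method {method!r}")


def load_survival_table() -> pd.DataFrame:
    """The shipped survival-statistics table for stroma-selective ligands.

    32 cytokine/growth-factor genes with relapse-free-survival p-value and
    hazard ratio (serous ovarian cancer Kaplan-Meier meta-analysis) and
    overall-survival z-score (PRECOG), plus the main stromal expressor
    cell types.
    """
    path = resources.files("netkit.data").joinpath("stromal_ligand_survival.tsv")
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t")


def survival_filter(
    table: pd.DataFrame,
    p_max: float = 0.05,
    z_abs_min: float = 1.96,
) -> pd.DataFrame:
    """Keep dually significant genes and label the survival direction.

    Retains rows with ``rfs_p < p_max`` and ``|os_z| > z_abs_min``.
    Direction: ``short survival`` for HR > 1 with z > 0, ``long survival``
    for HR < 1 with z < 0, otherwise ``discordant``.
    """
    required = {"gene", "rfs_p", "rfs_hr", "os_z"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"survival table missing column(s): {', '.join(sorted(missing))}")
    kept = table[(table["rfs_p"] < p_max) & (table["os_z"].abs() > z_abs_min)].copy()
    kept["direction"] = np.select(
        [(kept["rfs_hr"] > 1) & (kept["os_z"] > 0),
         (kept["rfs_hr"] < 1) & (kept["os_z"] < 0)],
        ["short survival", "long survival"],
        default="discordant",
    )
    return kept
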