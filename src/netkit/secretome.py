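"""Secretome calls from conditioned-medium proteomics and RNA concordance.

Conditioned medium of cultured cells is profiled by label-free MS at a
baseline timepoint (t0, immediately after washing) and a late timepoint
(after ~20 h of secretion).  A protein's secretion signal is the late
minus baseline LFQ value (log-scale); a protein is "in secretome" when at
least one peptide was detected for it and its median late signal strictly
exceeds its median baseline signal.

Concordance with the transcriptome is quantified two ways: the fraction of
genes whose protein reaches the secretome as a function of RNA expression
(per-TPM-bin detection rate, expected to rise monotonically), and the
rank correlation between median TPM and median LFQ over secreted proteins.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

LFQ_COLUMNS = ("protein", "sample", "timepoint", "lfq", "peptide_detected")
TIMEPOINTS = ("t0", "late")

#: TPM above which a gene counts as transcriptome-present in the
#: secretome/transcriptome overlap accounting.
TRANSCRIPTOME_TPM = 0.3


def validate_lfq(table: pd.DataFrame) -> None:
    missing = [c for c in LFQ_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"LFQ table missing column(s): {', '.join(missing)}")
    bad = sorted(set(table["timepoint"]) - set(TIMEPOINTS))
    if bad:
        raise ValueError(f"unknown timepoint(s): {', '.join(map(str, bad))}")
    if table.duplicated(["protein", "sample", "timepoint"]).any():
        raise ValueError("duplicate (protein, sample, timepoint) rows")


def secretion_signal(lfq_t0: float | None, lfq_late: float) -> float:
    """Late-timepoint LFQ minus baseline LFQ; a missing baseline counts as 0."""
    if lfq_t0 is None or (isinstance(lfq_t0, float) and np.isnan(lfq_t0)):
        lfq_t0 = 0.0
    return float(lfq_late) - float(lfq_t0)


def call_secretome(table: pd.DataFrame) -> pd.DataFrame:
    """Per-protein secretome call from an LFQ long table.

    Returns a DataFrame indexed by protein with ``median_t0``,
    ``median_late``, ``secretion_signal`` (difference of medians),
    ``peptide_detected`` (any sample/timepoint) and ``in_secretome``
    (detected and median late strictly above median t0).
    """
    validate_lfq(table)
    med = (table.pivot_table(index="protein", columns="timepoint",
                             values="lfq", aggfunc="median")
           .reindex(columns=TIMEPOINTS).fillna(0.0))
    detected = table.groupby("protein")["peptide_detected"].any()
    out = pd.DataFrame({
        "median_t0": med["t0"],
        "median_late": med["late"],
        "peptide_detected": detected.reindex(med.index, fill_value=False),
    })
    out["secretion_signal"] = out["median_late"] - out["median_t0"]
    out["in_secretome"] = out["peptide_detected"] & (out["median_late"] > out["median_t0"])
    return out.sort_index()


def detection_rate_by_expression(
    tpm_medians: pd.Series,
    calls: pd.DataFrame,
    bin_edges: np.ndarray | list[float],
    gene_list: list[str] | None = None,
) -> pd.DataFrame:
    """Secretome detection fraction per TPM bin.

    ``tpm_medians`` maps genes to their median TPM in the secreting cell
    type; ``calls`` is the output of :func:`call_secretome` (gene-symbol
    mapped).  Genes outside ``gene_list`` (when given) are ignored; a gene
    without an LFQ record counts as not detected.  Empty bins report NaN.
    """
    genes = list(tpm_medians.index if gene_list is None
                 else [g for g in gene_list if g in tpm_medians.index])
    tpm = tpm_medians.loc[genes]
    in_sec = calls["in_secretome"].reindex(genes, fill_value=False)
    edges = np.asarray(bin_edges, dtype=float)
    idx = np.digitize(tpm.to_numpy(dtype=float), edges) - 1
    rows = []
    for b in range(len(edges) - 1):
        mask = idx == b
        n = int(mask.sum())
        detected = int(in_sec.to_numpy()[mask].sum())
        rows.append({
            "bin_low": edges[b], "bin_high": edges[b + 1],
            "n": n, "detected": detected,
            "fraction": detected / n if n else np.nan,
        })
    return pd.DataFrame(rows)


def rna_protein_correlation(
    tpm_medians: pd.Series,
    lfq_medians: pd.Series,
    method: str = "spearman",
) -> float:
    """Correlation between RNA (median TPM) and protein (median LFQ) levels.

    The caller restricts both series to secreted proteins; at least three
    matched points are required.  Ties are handled by average ranks.
    """
    common = sorted(set(tpm_medians.index) & set(lfq_medians.index))
    if len(common) < 3:
        raise ValueError(f"need >=3 matched gene/protein pairs, got {len(common)}")
    x = tpm_medians.loc[common].to_numpy(dtype=float)
    y = lfq_medians.loc[common].to_numpy(dtype=float)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    raise ValueError(f"unknown method {method!r}")


def secretome_transcriptome_overlap(
    tpm_medians: pd.Series,
    calls: pd.DataFrame,
    gene_list: list[str] | None = None,
    tpm_threshold: float = TRANSCRIPTOME_TPM,
) -> dict[str, int]:
    """Venn counts of secretome vs transcriptome presence.

    Returns counts of proteins in the secretome, genes in the transcriptome
    (median TPM > ``tpm_threshold``), and their overlap, over ``gene_list``
    (or the union of both inputs).
    """
    if gene_list is None:
        gene_list = sorted(set(tpm_medians.index) | set(calls.index))
    in_sec = calls["in_secretome"].reindex(gene_list, fill_value=False)
    in_rna = tpm_medians.reindex(gene_list).fillna(0.0) > tpm_threshold
    return {
        "secretome": int(in_sec.sum()),
        "transcriptome": int(in_rna.sum()),
        "overlap": int((in_sec & in_rna).sum()),
        "secretome_only": int((in_sec & ~in_rna).sum()),
    }
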