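"""Cell-type selectivity of cytokine/growth-factor genes and receptor scoring.

After contamination adjustment, each cytokine or growth-factor gene is
classified by where it is expressed (median TPM > 2 per cell type) and
whether that expression is *selective*: a compartment group (tumour /
immune / stroma) owns a gene when its best cell-type median exceeds
5-fold the best median outside the group.  Within a selective group, the
member cell types are those individually clearing the same 5-fold bar
against the outside — this yields the Venn-style partition counts used to
summarise the secretome of the microenvironment.

Ligand -> target-cell scoring aggregates a ligand's receptors: (i) each
receptor's per-cell-type median is scaled by its maximum across cell types,
(ii) the scaled values are summed over the ligand's receptor set, and
(iii) each ligand row is again scaled by its maximum, giving a 0-1 score of
how strongly each cell type listens to that ligand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .markers import samples_of_type

#: Compartment grouping used for the selectivity partition.
DEFAULT_GROUPING: Mapping[str, str] = {
    "TU": "tumour",
    "TAM": "immune", "TAT": "immune",
    "ADI": "stroma", "MESO": "stroma", "CAF": "stroma",
}

EXPRESSED_TPM = 2.0
SELECTIVE_FC = 5.0


@dataclass(frozen=True)
class LigandReceptorMap:
    """Many-to-many ligand -> receptor gene annotation.

    ``flags`` carries optional boolean per-ligand annotations such as
    ``metastasis`` (literature-curated metastasis association, supplied by
    the user) or ``wnt_family`` (scores for WNT ligands are unreliable
    because of the promiscuous WNT receptor usage and are flagged through
    to outputs).
    """

    receptors_by_ligand: Mapping[str, frozenset[str]]
    flags: Mapping[str, Mapping[str, bool]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [l for l, rs in self.receptors_by_ligand.items() if not rs]
        if empty:
            raise ValueError(f"ligand(s) without receptors: {', '.join(sorted(empty))}")

    @property
    def ligands(self) -> list[str]:
        return sorted(self.receptors_by_ligand)

    def flagged(self, flag: str) -> list[str]:
        return sorted(l for l in self.receptors_by_ligand
                      if self.flags.get(l, {}).get(flag, False))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LigandReceptorMap":
        """Read a TSV with columns ``ligand``, ``receptor`` and optional flag columns."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        flag_cols = [c for c in df.columns if c not in ("ligand", "receptor")]
        receptors: dict[str, set[str]] = {}
        flags: dict[str, dict[str, bool]] = {}
        for row in df.itertuples(index=False):
            receptors.setdefault(row.ligand, set()).add(row.receptor)
            for c in flag_cols:
                val = str(getattr(row, c)).lower() in ("true", "1", "yes")
                flags.setdefault(row.ligand, {})[c] = (
                    flags.get(row.ligand, {}).get(c, False) or val)
        return cls({l: frozenset(rs) for l, rs in receptors.items()}, flags)

    def to_frame(self) -> pd.DataFrame:
        flag_names = sorted({f for d in self.flags.values() for f in d})
        rows = []
        for ligand in self.ligands:
            for receptor in sorted(self.receptors_by_ligand[ligand]):
                row = {"ligand": ligand, "receptor": receptor}
                for f in flag_names:
                    row[f] = self.flags.get(ligand, {}).get(f, False)
                rows.append(row)
        return pd.DataFrame(rows)


def medians_by_cell_type(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    compartment: str | None = "omentum_preferred",
) -> pd.DataFrame:
    """Gene x cell-type matrix of median TPM.

    ``compartment`` restricts which samples summarise each cell type:
    ``None`` pools everything, a compartment name restricts strictly, and
    the default ``"omentum_preferred"`` uses omentum samples where a cell
    type has any and falls back to ascites otherwise (TAT, for instance, is
    typically only available from ascites).
    """
    cols = {}
    for cell_type in sorted(meta["cell_type"].unique()):
        samples = samples_of_type(meta, cell_type)
        if compartment == "omentum_preferred":
            om = [s for s in samples if meta.loc[s, "compartment"] == "omentum"]
            samples = om or samples
        elif compartment is not None:
            samples = [s for s in samples if meta.loc[s, "compartment"] == compartment]
        if samples:
            cols[cell_type] = matrix[samples].median(axis=1)
    return pd.DataFrame(cols)


def call_expressed(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    tpm_threshold: float = EXPRESSED_TPM,
    compartment: str | None = "omentum_preferred",
) -> pd.DataFrame:
    """Boolean gene x cell-type table: median TPM strictly above threshold."""
    return medians_by_cell_type(matrix, meta, compartment) > tpm_threshold


@dataclass(frozen=True)
class SelectivityCall:
    """Selectivity classification of one gene.

    ``category`` is ``"tumour"``, ``"host"`` or ``"shared"``;
    ``host_category`` refines host-selective genes into ``"stroma"``,
    ``"immune"`` or ``"both"``; ``selective_types`` are the member cell
    types clearing the fold-change bar within the selective group.
    """

    gene: str
    expressed_in: frozenset[str]
    category: str
    selective_types: frozenset[str] = frozenset()
    host_category: str | None = None


def classify_selectivity(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    grouping: Mapping[str, str] | None = None,
    fc: float = SELECTIVE_FC,
    tpm_threshold: float = EXPRESSED_TPM,
    genes: list[str] | None = None,
    compartment: str | None = "omentum_preferred",
) -> tuple[list[SelectivityCall], dict]:
    """Partition expressed genes into tumour-/host-selective and shared.

    Only genes expressed (median TPM > ``tpm_threshold``) in at least one
    cell type enter the partition.  A gene is selective for the tumour or
    host side when the best median on that side exceeds ``fc`` times the
    best median on the other side; otherwise it is shared.  Returns the
    calls and a nested dict of partition counts (top level, host split,
    stroma combination Venn).
    """
    grouping = dict(grouping or DEFAULT_GROUPING)
    med = medians_by_cell_type(matrix, meta, compartment)
    if genes is not None:
        med = med.loc[[g for g in genes if g in med.index]]
    present = [t for t in med.columns if t in grouping]
    med = med[present]
    tumour_types = [t for t in present if grouping[t] == "tumour"]
    host_types = [t for t in present if grouping[t] != "tumour"]
    stroma_types = [t for t in present if grouping[t] == "stroma"]

    calls: list[SelectivityCall] = []
    counts = {
        "expressed": 0, "tumour": 0, "host": 0, "shared": 0,
        "host_split": {"stroma": 0, "immune": 0, "both": 0},
        "stroma_combinations": {},
    }
    for gene, row in med.iterrows():
        expressed = frozenset(t for t in present if row[t] > tpm_threshold)
        if not expressed:
            continue
        counts["expressed"] += 1
        best_tumour = max((row[t] for t in tumour_types), default=0.0)
        best_host = max((row[t] for t in host_types), default=0.0)
        if best_tumour > fc * best_host:
            members = frozenset(t for t in tumour_types if row[t] > fc * best_host)
            calls.append(SelectivityCall(gene, expressed, "tumour", members))
            counts["tumour"] += 1
        elif best_host > fc * best_tumour:
            members = frozenset(t for t in host_types if row[t] > fc * best_tumour)
            in_stroma = members & set(stroma_types)
            in_immune = members - set(stroma_types)
            host_cat = ("both" if in_stroma and in_immune
                        else "stroma" if in_stroma else "immune")
            calls.append(SelectivityCall(gene, expressed, "host", members, host_cat))
            counts["host"] += 1
            counts["host_split"][host_cat] += 1
            if in_stroma and not in_immune:
                combo = "+".join(sorted(in_stroma))
                counts["stroma_combinations"][combo] = (
                    counts["stroma_combinations"].get(combo, 0) + 1)
        else:
            calls.append(SelectivityCall(gene, expressed, "shared"))
            counts["shared"] += 1
    return calls, counts


def receptor_target_scores(
    lr_map: LigandReceptorMap,
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    compartment: str | None = "omentum_preferred",
) -> pd.DataFrame:
    """Ligand x cell-type matrix of normalised receptor-expression scores.

    Three steps: (i) scale each receptor's per-cell-type median TPM by its
    maximum across cell types, (ii) per ligand, sum the scaled values over
    its receptor set, (iii) scale each ligand row by its maximum.  Rows are
    in [0, 1] with a 1 at the strongest target cell type; ligands whose
    receptors are all absent or unexpressed get an all-zero row with a
    warning.
    """
    med = medians_by_cell_type(matrix, meta, compartment)
    row_max = med.max(axis=1)
    norm = med.div(row_max.where(row_max > 0, 1.0), axis=0)

    rows = {}
    for ligand in lr_map.ligands:
        receptors = sorted(lr_map.receptors_by_ligand[ligand])
        present = [r for r in receptors if r in norm.index]
        missing = [r for r in receptors if r not in norm.index]
        if missing:
            warnings.warn(
                f"receptor(s) for {ligand} absent from matrix: {', '.join(missing)}")
        if not present:
            rows[ligand] = pd.Series(0.0, index=med.columns)
            warnings.warn(f"ligand {ligand} has no scorable receptor; zero row")
            continue
        summed = norm.loc[present].sum(axis=0)
        peak = summed.max()
        if peak > 0:
            rows[ligand] = summed / peak
        else:
            rows[ligand] = summed
            warnings.warn(f"ligand {ligand} receptors unexpressed everywhere; zero row")
    return pd.DataFrame(rows).T.reindex(columns=med.columns)


def build_metastasis_network(
    calls: list[SelectivityCall],
    lr_map: LigandReceptorMap,
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    receptor_tpm: float = EXPRESSED_TPM,
    ligand_tpm: float = EXPRESSED_TPM,
    flag: str = "metastasis",
    compartment: str | None = "omentum_preferred",
) -> pd.DataFrame:
    """Edge list of the metastasis-associated signalling network.

    For each ligand carrying the ``flag`` annotation and expressed by at
    least one cell type, an edge is emitted to every cell type on which a
    cognate receptor has median TPM strictly above ``receptor_tpm``.
    Producers are the ligand's selective member cell types when it is
    selective, otherwise all cell types expressing it.  Edges carry the
    ligand's receptor score for the target cell type.
    """
    med = medians_by_cell_type(matrix, meta, compartment)
    scores = receptor_target_scores(lr_map, matrix, meta, compartment)
    call_by_gene = {c.gene: c for c in calls}

    rows = []
    for ligand in lr_map.flagged(flag):
        if ligand not in med.index:
            continue
        expressed_in = [t for t in med.columns if med.loc[ligand, t] > ligand_tpm]
        if not expressed_in:
            continue
        call = call_by_gene.get(ligand)
        producers = (sorted(call.selective_types)
                     if call is not None and call.selective_types else expressed_in)
        receptors = [r for r in sorted(lr_map.receptors_by_ligand[ligand])
                     if r in med.index]
        for target in med.columns:
            hit = [r for r in receptors if med.loc[r, target] > receptor_tpm]
            if not hit:
                continue
            rows.append({
                "ligand": ligand,
                "source_cell_types": "+".join(producers),
                "target_cell_type": target,
                "receptor_score": float(scores.loc[ligand, target]),
                "receptors": ",".join(hit),
            })
    return pd.DataFrame(
        rows, columns=["ligand", "source_cell_types", "target_cell_type",
                       "receptor_score", "receptors"])
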