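"""Marker gene selection for sorted tumour-microenvironment populations.

Two flavours of marker set are produced from a TPM matrix:

* **identity markers** — genes highly and stably expressed in one cell type
  and at least 10-fold above every other cell type; used to pick reference
  samples and to verify purification.
* **contamination markers** — for an ordered (target, contaminant) pair,
  the top-25 genes most enriched in the contaminant (>50-fold median fold
  change, median >10 TPM in the contaminant); these drive the per-sample
  contamination-percentage estimator.

All thresholds are strict inequalities; fold changes are computed with a
0.001 TPM offset on both terms so that zero medians stay finite and
rankable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Median-TPM floors for identity-marker candidacy, per cell type.  The
#: stromal populations (ADI, MESO) have few, very highly expressed markers,
#: hence the higher floor; CAF markers are comparatively weak.
DEFAULT_MEDIAN_TPM_FLOOR: Mapping[str, float] = {
    "TU": 100.0, "TAM": 100.0, "TAT": 100.0,
    "ADI": 1000.0, "MESO": 1000.0, "CAF": 25.0,
}

#: Offset added to both terms of a median fold change to avoid division by 0.
FC_OFFSET = 0.001


@dataclass(frozen=True)
class MarkerCriteria:
    """Thresholds for identity-marker selection."""

    median_tpm_floor: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MEDIAN_TPM_FLOOR))
    max_within_spread: float = 10.0
    min_cross_ratio: float = 10.0

    def __post_init__(self) -> None:
        if self.max_within_spread <= 0 or self.min_cross_ratio <= 0:
            raise ValueError("marker criteria thresholds must be positive")
        if any(v <= 0 for v in self.median_tpm_floor.values()):
            raise ValueError("median TPM floors must be positive")


@dataclass(frozen=True)
class MarkerSet:
    """An ordered marker gene list for a target (and optional contaminant) type.

    ``scores`` holds the ranking statistic per gene: the worst-case
    cross-type ratio for identity markers, the offset median fold change for
    contamination markers.  Genes are ordered by descending score with
    lexicographic tie-break.
    """

    target: str
    genes: tuple[str, ...]
    scores: tuple[float, ...]
    contaminant: str | None = None

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores must align")

    def __len__(self) -> int:
        return len(self.genes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "target": self.target,
            "contaminant": self.contaminant or "",
            "rank": np.arange(1, len(self.genes) + 1),
            "gene": list(self.genes),
            "score": list(self.scores),
        })


def gene_family(symbol: str) -> str:
    """Maximal leading alphabetic prefix of a gene symbol (FCGR2A -> FCGR).

    A crude but deterministic stand-in for curated gene families, used only
    to diversify the top of the identity-marker ranking; a user-supplied
    family map overrides it.
    """
    i = 0
    while i < len(symbol) and symbol[i].isalpha():
        i += 1
    return symbol[:i] or symbol


def _rank(genes: Sequence[str], scores: Sequence[float]) -> list[int]:
    """Indices ordered by descending score, ties broken by gene symbol."""
    return sorted(range(len(genes)), key=lambda i: (-scores[i], genes[i]))


def samples_of_type(meta: pd.DataFrame, cell_type: str) -> list[str]:
    return list(meta.index[meta["cell_type"] == cell_type])


def select_identity_markers(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    target: str,
    criteria: MarkerCriteria | None = None,
    top_k: int | None = None,
    family_map: Mapping[str, str] | None = None,
) -> MarkerSet:
    """Select identity markers for ``target`` under the three criteria.

    A gene qualifies iff (i) its median TPM over target samples exceeds the
    cell-type floor, (ii) its max/min spread across target samples is at most
    ``max_within_spread``-fold, and (iii) the ratio between its minimum TPM
    in the target set and the minimum TPM of every other cell type's sample
    set exceeds ``min_cross_ratio``.  Genes are ranked by the worst-case
    criterion-(iii) ratio.  With ``top_k``, only the best gene per gene
    family is kept until ``top_k`` markers are collected.
    """
    criteria = criteria or MarkerCriteria()
    target_samples = samples_of_type(meta, target)
    if len(target_samples) < 2:
        raise ValueError(f"need >=2 samples of type {target}, found {len(target_samples)}")
    floor = criteria.median_tpm_floor.get(target)
    if floor is None:
        raise ValueError(f"no median TPM floor configured for cell type {target}")

    tvals = matrix[target_samples].to_numpy(dtype=float)
    med = np.median(tvals, axis=1)
    tmin = tvals.min(axis=1)
    tmax = tvals.max(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        spread = np.where(tmin > 0, tmax / tmin, np.where(tmax > 0, np.inf, 1.0))

    other_types = [t for t in meta["cell_type"].unique() if t != target]
    if not other_types:
        raise ValueError("need samples of at least one non-target cell type")
    # Worst case over other types of min-TPM within that type's sample set.
    other_min = np.max(
        np.stack([matrix[samples_of_type(meta, t)].to_numpy(dtype=float).min(axis=1)
                  for t in other_types]),
        axis=0,
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        cross = np.where(other_min > 0, tmin / other_min,
                         np.where(tmin > 0, np.inf, 0.0))

    ok = (med > floor) & (spread <= criteria.max_within_spread) & (cross > criteria.min_cross_ratio)
    genes = [g for g, keep in zip(matrix.index, ok) if keep]
    scores = [float(c) for c, keep in zip(cross, ok) if keep]
    if not genes:
        warnings.warn(f"no identity marker passes the criteria for {target}")
        return MarkerSet(target=target, genes=(), scores=())

    order = _rank(genes, scores)
    if top_k is not None:
        fam = family_map or {}
        picked: list[int] = []
        seen: set[str] = set()
        for i in order:
            f = fam.get(genes[i], gene_family(genes[i]))
            if f in seen:
                continue
            seen.add(f)
            picked.append(i)
            if len(picked) == top_k:
                break
        order = picked
    return MarkerSet(target=target,
                     genes=tuple(genes[i] for i in order),
                     scores=tuple(scores[i] for i in order))


def select_contamination_markers(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    target: str,
    contaminant: str,
    top_n: int = 25,
    min_fold: float = 50.0,
    min_contaminant_tpm: float = 10.0,
    offset: float = FC_OFFSET,
) -> MarkerSet:
    """Top-``top_n`` genes enriched in ``contaminant`` relative to ``target``.

    Candidates need an offset median fold change
    ``(median_contaminant + offset)/(median_target + offset)`` above
    ``min_fold`` and a contaminant median above ``min_contaminant_tpm``.
    Ranked by fold change descending; fewer than ``top_n`` candidates are
    returned in full with a warning.
    """
    t_samples = samples_of_type(meta, target)
    c_samples = samples_of_type(meta, contaminant)
    if not t_samples or not c_samples:
        raise ValueError(f"need samples of both {target} and {contaminant}")
    med_t = np.median(matrix[t_samples].to_numpy(dtype=float), axis=1)
    med_c = np.median(matrix[c_samples].to_numpy(dtype=float), axis=1)
    fc = (med_c + offset) / (med_t + offset)
    ok = (fc > min_fold) & (med_c > min_contaminant_tpm)
    genes = [g for g, keep in zip(matrix.index, ok) if keep]
    scores = [float(f) for f, keep in zip(fc, ok) if keep]
    if len(genes) < top_n:
        warnings.warn(
            f"only {len(genes)} contamination marker candidates for "
            f"{contaminant} in {target} (requested {top_n})")
    order = _rank(genes, scores)[:top_n]
    return MarkerSet(target=target, contaminant=contaminant,
                     genes=tuple(genes[i] for i in order),
                     scores=tuple(scores[i] for i in order))
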