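"""Contamination estimation, sample exclusion and linear unmixing.

Sorted cell populations are never perfectly pure: a TU sample carries a few
percent of macrophage RNA, an adipocyte sample a few percent of tumour RNA,
and so on.  This module implements the two-step correction:

1. **Estimation** — for every (target sample, contaminant type) pair the
   contamination percentage is estimated from a 25-gene marker set as the
   median over markers g of ``(TPM_sample,g - TPM_target_ref,g) /
   TPM_contaminant_ref,g * 100``, where the reference samples are the
   least-contaminated samples of each type.  Samples above a cell-type
   threshold (4% for TU/TAM/TAT, 6% for ADI) are excluded outright.

2. **Adjustment** — each kept sample is unmixed by the linear model
   ``(x - frac * contaminant_profile) / (1 - frac)``, applied iteratively
   per contaminant, negatives clamped to zero, and the whole matrix
   renormalised to TPM.

The model assumes the observed column is a convex combination of the pure
target profile and the contaminant profiles; for a single contaminant the
adjustment inverts the mixture exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import renormalize
from .markers import MarkerSet, samples_of_type

#: Contamination percentage at or above which a sample is excluded.
#: MESO and CAF samples are never excluded by default.
DEFAULT_EXCLUSION_THRESHOLD: Mapping[str, float] = {
    "TU": 4.0, "TAM": 4.0, "TAT": 4.0, "ADI": 6.0,
}


@dataclass(frozen=True)
class AdjustmentConfig:
    """Configuration of the estimate -> exclude -> adjust pipeline.

    ``contaminants_by_target`` names, per target cell type, the contaminant
    types assessed and removed.  ``minimum_assumed_percent`` lets the user
    assert a floor on specific (target, contaminant) estimates, reflecting
    that perfectly pure sorts do not exist; the default floor is 0.
    ``adjustment_order`` is either ``"descending_fraction"`` or an explicit
    contaminant ordering.
    """

    contaminants_by_target: Mapping[str, tuple[str, ...]]
    exclusion_threshold: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EXCLUSION_THRESHOLD))
    minimum_assumed_percent: Mapping[tuple[str, str], float] = field(default_factory=dict)
    contaminant_profile_source: str = "cohort_median"
    adjustment_order: str | tuple[str, ...] = "descending_fraction"

    def __post_init__(self) -> None:
        for t, thr in self.exclusion_threshold.items():
            if not (0 < thr <= 100):
                raise ValueError(f"exclusion threshold for {t} must be in (0, 100]")
        if self.contaminant_profile_source not in (
                "cohort_median", "patient_matched_if_available"):
            raise ValueError(f"unknown profile source {self.contaminant_profile_source!r}")


def choose_reference_sample(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    target: str,
    contaminant_marker_sets: Sequence[MarkerSet],
) -> str:
    """Pick the target sample with the least contaminant-marker signal.

    A pinned ``is_reference`` flag in the metadata wins; otherwise the
    sample minimising the sum, over marker sets, of the per-set median
    marker TPM is chosen, with ties broken by sample ID.
    """
    candidates = samples_of_type(meta, target)
    if not candidates:
        raise ValueError(f"no samples of type {target}")
    pinned = [s for s in candidates if bool(meta.loc[s, "is_reference"])]
    if pinned:
        return sorted(pinned)[0]
    if len(candidates) == 1 or not contaminant_marker_sets:
        return sorted(candidates)[0]

    def load(sample: str) -> float:
        total = 0.0
        for ms in contaminant_marker_sets:
            genes = [g for g in ms.genes if g in matrix.index]
            if genes:
                total += float(np.median(matrix.loc[genes, sample].to_numpy(dtype=float)))
        return total

    return min(sorted(candidates), key=lambda s: (load(s), s))


def estimate_contamination(
    sample_col: pd.Series,
    target_reference_col: pd.Series,
    contaminant_reference_col: pd.Series,
    marker_set: MarkerSet,
    floor_percent: float = 0.0,
) -> tuple[float, bool]:
    """Estimate the percentage of contaminant RNA in one sample.

    Per marker g the raw percentage is
    ``(sample_g - target_ref_g) / contaminant_ref_g * 100``; per-marker
    values are clamped to [0, 100] before taking the median so that noise
    below zero cannot bias the estimate downward.  Markers at which the
    contaminant reference is zero are dropped with a warning.  Returns the
    estimate (at least ``floor_percent``) and whether the floor bound.
    """
    if len(marker_set) == 0:
        raise ValueError("empty marker set")
    genes = list(marker_set.genes)
    s = sample_col.loc[genes].to_numpy(dtype=float)
    tref = target_reference_col.loc[genes].to_numpy(dtype=float)
    cref = contaminant_reference_col.loc[genes].to_numpy(dtype=float)
    usable = cref > 0
    if not usable.all():
        dropped = [g for g, u in zip(genes, usable) if not u]
        warnings.warn(
            f"dropping marker(s) with zero contaminant reference: {', '.join(dropped)}")
    if not usable.any():
        raise ValueError("all markers have zero contaminant reference expression")
    pct = (s[usable] - tref[usable]) / cref[usable] * 100.0
    estimate = float(np.median(np.clip(pct, 0.0, 100.0)))
    floored = floor_percent > estimate
    return (max(estimate, floor_percent), floored)


def estimate_cohort(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    marker_sets: Mapping[tuple[str, str], MarkerSet],
    config: AdjustmentConfig,
    references: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Build the per-sample contamination table for a whole cohort.

    Returns a DataFrame with columns ``sample_id, cell_type, contaminant,
    estimated_percent, floored`` and the mapping of cell type -> reference
    sample used.  References default to the pinned/auto choice of
    :func:`choose_reference_sample`.
    """
    refs = dict(references or {})
    needed = set(config.contaminants_by_target)
    for contams in config.contaminants_by_target.values():
        needed.update(contams)
    for cell_type in sorted(needed):
        if cell_type in refs:
            continue
        relevant = [ms for (t, _c), ms in marker_sets.items() if t == cell_type]
        refs[cell_type] = choose_reference_sample(matrix, meta, cell_type, relevant)

    rows = []
    for target, contaminants in config.contaminants_by_target.items():
        tref = matrix[refs[target]]
        for sample in samples_of_type(meta, target):
            for contaminant in contaminants:
                key = (target, contaminant)
                if key not in marker_sets:
                    raise KeyError(f"no marker set for pair {key}")
                pct, floored = estimate_contamination(
                    matrix[sample], tref, matrix[refs[contaminant]],
                    marker_sets[key],
                    floor_percent=config.minimum_assumed_percent.get(key, 0.0),
                )
                rows.append((sample, target, contaminant, pct, floored))
    table = pd.DataFrame(
        rows, columns=["sample_id", "cell_type", "contaminant",
                       "estimated_percent", "floored"])
    return table, refs


def apply_exclusion(
    table: pd.DataFrame, config: AdjustmentConfig, tolerance: float = 1e-9
) -> tuple[list[str], list[str]]:
    """Partition assessed samples into (kept, excluded).

    A sample is excluded iff any contaminant estimate is at or above its
    cell type's threshold (>=, matching the published rule); cell types
    without a configured threshold are never excluded.  ``tolerance`` (in
    percentage points) keeps the boundary decision stable against
    floating-point jitter from renormalisation: an estimate within one
    nano-percentage-point of the threshold counts as at the threshold.
    """
    kept, excluded = [], []
    for sample, group in table.groupby("sample_id", sort=True):
        cell_type = group["cell_type"].iloc[0]
        thr = config.exclusion_threshold.get(cell_type)
        if thr is not None and (group["estimated_percent"] >= thr - tolerance).any():
            excluded.append(str(sample))
        else:
            kept.append(str(sample))
    return kept, excluded


def adjust_sample(
    sample_col: pd.Series,
    fracs: Mapping[str, float],
    contaminant_profiles: Mapping[str, pd.Series],
    order: Sequence[str] | None = None,
) -> pd.Series:
    """Remove contaminant signal from one sample column by linear unmixing.

    For each contaminant in ``order`` (default: descending fraction, ties by
    name) the column is updated to ``(col - frac * profile) / (1 - frac)``;
    negatives are clamped to zero once after all contaminants.  The caller
    renormalises the full matrix afterwards.
    """
    for contaminant, frac in fracs.items():
        if not (0 <= frac < 1):
            raise ValueError(f"fraction for {contaminant} must be in [0, 1), got {frac}")
    if order is None:
        order = sorted(fracs, key=lambda c: (-fracs[c], c))
    col = sample_col.astype(float).copy()
    for contaminant in order:
        frac = fracs[contaminant]
        if frac == 0:
            continue
        profile = contaminant_profiles[contaminant].reindex(col.index)
        if profile.isna().any():
            missing = list(profile.index[profile.isna()])[:5]
            raise ValueError(f"contaminant profile missing gene(s): {', '.join(missing)}")
        col = (col - frac * profile) / (1.0 - frac)
    return col.clip(lower=0.0)


@dataclass
class AdjustmentResult:
    """Outcome of :func:`run_adjustment`."""

    adjusted: pd.DataFrame
    table: pd.DataFrame           # contamination estimates + 'excluded' column
    references: dict[str, str]
    excluded_samples: list[str]
    profiles_used: dict[str, dict[str, str]]  # sample -> contaminant -> source label


def _contaminant_profile(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    contaminant: str,
    kept: Sequence[str],
    sample: str,
    config: AdjustmentConfig,
) -> tuple[pd.Series, str]:
    """Profile used to model a contaminant inside ``sample``.

    Cohort median over kept contaminant samples, or the patient-matched
    contaminant sample when configured and available (same compartment
    preferred, then lexicographic).
    """
    pool = [s for s in kept if meta.loc[s, "cell_type"] == contaminant]
    if not pool:
        pool = samples_of_type(meta, contaminant)
    if not pool:
        raise ValueError(f"no samples of contaminant type {contaminant}")
    if config.contaminant_profile_source == "patient_matched_if_available":
        patient = meta.loc[sample, "patient_id"]
        compartment = meta.loc[sample, "compartment"]
        matched = [s for s in pool if meta.loc[s, "patient_id"] == patient]
        if matched:
            same_comp = [s for s in matched if meta.loc[s, "compartment"] == compartment]
            chosen = sorted(same_comp or matched)[0]
            return matrix[chosen], f"patient_matched:{chosen}"
    return matrix[sorted(pool)].median(axis=1), "cohort_median"


def run_adjustment(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    marker_sets: Mapping[tuple[str, str], MarkerSet],
    config: AdjustmentConfig,
    references: Mapping[str, str] | None = None,
) -> AdjustmentResult:
    """Full estimate -> exclude -> adjust -> renormalise pipeline."""
    table, refs = estimate_cohort(matrix, meta, marker_sets, config, references)
    _, excluded = apply_exclusion(table, config)
    table = table.assign(excluded=table["sample_id"].isin(excluded))
    kept = [s for s in matrix.columns if s not in excluded]

    fracs_by_sample: dict[str, dict[str, float]] = {}
    for row in table.itertuples(index=False):
        if row.sample_id in excluded:
            continue
        fracs_by_sample.setdefault(row.sample_id, {})[row.contaminant] = (
            row.estimated_percent / 100.0)

    adjusted_cols: dict[str, pd.Series] = {}
    profiles_used: dict[str, dict[str, str]] = {}
    for sample in kept:
        fracs = fracs_by_sample.get(sample, {})
        if not fracs:
            adjusted_cols[sample] = matrix[sample].astype(float)
            continue
        profiles: dict[str, pd.Series] = {}
        sources: dict[str, str] = {}
        for contaminant in fracs:
            profiles[contaminant], sources[contaminant] = _contaminant_profile(
                matrix, meta, contaminant, kept, sample, config)
        order = (None if config.adjustment_order == "descending_fraction"
                 else [c for c in config.adjustment_order if c in fracs])
        adjusted_cols[sample] = adjust_sample(matrix[sample], fracs, profiles, order)
        profiles_used[sample] = sources

    adjusted = renormalize(pd.DataFrame(adjusted_cols, index=matrix.index)[kept])
    return AdjustmentResult(adjusted=adjusted, table=table, references=refs,
                            excluded_samples=sorted(excluded),
                            profiles_used=profiles_used)
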