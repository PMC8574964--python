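"""Synthetic cohorts with known ground truth for every pipeline stage.

The generator emulates the statistical structure the pipeline assumes:

* per-cell-type TPM profiles with planted marker blocks — each cell type
  owns a block of genes expressed at a high, floor-clearing level in that
  type and at zero elsewhere, so the block doubles as identity markers for
  its own type and as contamination markers for any (target, this type)
  pair;
* cohorts of samples built as convex mixtures of pure profiles at known
  contamination fractions, with multiplicative log-normal noise and TPM
  renormalisation, mirroring how cross-contamination manifests in
  normalised data;
* patient-matched compartment pairs with planted per-gene fold changes on
  top of shared patient effects;
* ligand/receptor annotations with planted producer and target cell types,
  and LFQ proteomics whose detection probability follows a logistic curve
  in log RNA expression.

All generators are pure functions of (config, seed): TPM-level simulation,
not read-count simulation — the pipeline consumes normalised matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CELL_TYPES, TPM_TOTAL, renormalize
from .markers import MarkerSet
from .differential import MatchedPairSet
from .selectivity import LigandReceptorMap

#: Pre-normalisation marker expression level per cell type, chosen ~10x the
#: identity-marker median-TPM floor of that type so planted markers clear
#: the floors comfortably after renormalisation.
DEFAULT_MARKER_LEVEL: Mapping[str, float] = {
    "TU": 1000.0, "TAM": 1000.0, "TAT": 1000.0,
    "ADI": 10000.0, "MESO": 10000.0, "CAF": 250.0,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study; the defaults are the study conditions.

    Expression baselines are log-normal on the natural-log scale
    (``baseline_log_mean``/``sigma``); cell-type individuality of non-marker
    genes comes from a per-type log-normal modulation
    (``type_effect_sigma``).  Sample-level measurement noise is
    multiplicative log-normal with ``noise_sigma`` (0.2 by default, the
    regime in which the contamination estimator is expected to stay within
    one percentage point).  Matched-pair parameters mirror the six-patient
    compartment comparison with 8-fold planted shifts.
    """

    seed: int
    n_genes: int = 2000
    cell_types: tuple[str, ...] = CELL_TYPES
    samples_per_type: int = 6
    n_markers_per_type: int = 30
    marker_level: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MARKER_LEVEL))
    marker_low: float = 0.0
    baseline_log_mean: float = 3.0
    baseline_log_sigma: float = 1.2
    type_effect_sigma: float = 0.3
    noise_sigma: float = 0.2
    contamination_fracs: tuple[float, ...] = (0.02, 0.05)
    # matched-pair design
    n_pairs: int = 6
    de_n_genes: int = 1000
    de_n_planted: int = 50
    de_fold: float = 8.0
    de_noise_sigma: float = 0.3
    patient_sigma: float = 0.3
    de_min_planted_base: float = 10.0
    # ligand/receptor + secretome design
    n_ligands: int = 12
    receptors_per_ligand: int = 2
    secreting_cell_type: str = "CAF"
    n_secretome_extra_genes: int = 150
    n_secretome_samples: int = 3
    lfq_slope: float = 1.5
    lfq_intercept: float = 2.0
    lfq_noise_sigma: float = 0.05
    detect_midpoint_tpm: float = 10.0
    detect_slope: float = 3.0

    def __post_init__(self) -> None:
        needed = len(self.cell_types) * self.n_markers_per_type
        if needed > self.n_genes:
            raise ValueError(
                f"{needed} marker genes demanded but only {self.n_genes} genes configured")
        if sum(self.contamination_fracs) >= 1:
            raise ValueError("contamination fractions must sum below 1")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, stream))


def gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def generate_pure_profiles(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Pure per-cell-type TPM profiles plus the planted marker truth.

    Returns a gene x cell-type DataFrame (columns sum to 1e6) and a mapping
    cell type -> its planted marker genes (the block expressed at the
    marker level in that type and at ``marker_low`` in all others).
    """
    rng = config.rng(1)
    genes = gene_names(config.n_genes)
    base = rng.lognormal(config.baseline_log_mean, config.baseline_log_sigma,
                         size=config.n_genes)
    weights = {}
    for cell_type in config.cell_types:
        weights[cell_type] = base * rng.lognormal(
            0.0, config.type_effect_sigma, size=config.n_genes)
    profiles = pd.DataFrame(weights, index=genes)

    markers: dict[str, list[str]] = {}
    m = config.n_markers_per_type
    for i, cell_type in enumerate(config.cell_types):
        block = genes[i * m:(i + 1) * m]
        markers[cell_type] = block
        profiles.loc[block, :] = config.marker_low
        profiles.loc[block, cell_type] = config.marker_level[cell_type]
    return renormalize(profiles), markers


def marker_sets_from_truth(
    markers: Mapping[str, Sequence[str]],
    targets: Mapping[str, Sequence[str]],
    top_n: int = 25,
) -> dict[tuple[str, str], MarkerSet]:
    """Contamination marker sets taken directly from the planted truth.

    For a (target, contaminant) pair the contaminant's planted marker block
    is the ideal marker set (zero in the target, high in the contaminant);
    scores are placeholders since the ranking is not being tested here.
    """
    sets = {}
    for target, contaminants in targets.items():
        for contaminant in contaminants:
            genes = tuple(markers[contaminant][:top_n])
            sets[(target, contaminant)] = MarkerSet(
                target=target, contaminant=contaminant,
                genes=genes, scores=(float("nan"),) * len(genes))
    return sets


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    cell_type: str
    compartment: str
    patient_id: str
    fracs: Mapping[str, float] = field(default_factory=dict)
    is_reference: bool = False


def default_cohort_design(config: SimulationConfig) -> list[SampleSpec]:
    """Mostly-pure cohort with a contaminated minority per cell type.

    Sample ``j`` of every cell type belongs to patient ``P{j}`` (so
    patient-matched contaminant profiles exist).  The majority of each
    type's samples are uncontaminated — as in a real sorted cohort, where
    the type-level median of a foreign marker must stay at baseline for
    marker selection to work — while the last ``len(contamination_fracs)``
    samples carry a single contaminant (the next cell type, cyclically) at
    the configured fractions.  TAT samples sit in ascites, everything else
    in omentum, mirroring which compartments the populations are sorted
    from.
    """
    design = []
    types = list(config.cell_types)
    n_pure = config.samples_per_type - len(config.contamination_fracs)
    if n_pure <= config.samples_per_type // 2:
        raise ValueError("a majority of samples per type must stay uncontaminated")
    for i, cell_type in enumerate(types):
        contaminant = types[(i + 1) % len(types)]
        compartment = "ascites" if cell_type == "TAT" else "omentum"
        for j in range(config.samples_per_type):
            fracs = {}
            if j >= n_pure:
                fracs = {contaminant: config.contamination_fracs[j - n_pure]}
            design.append(SampleSpec(
                sample_id=f"{cell_type}_{j:02d}",
                cell_type=cell_type,
                compartment=compartment,
                patient_id=f"P{j:02d}",
                fracs=fracs,
            ))
    return design


def generate_contaminated_cohort(
    profiles: pd.DataFrame,
    config: SimulationConfig,
    design: Sequence[SampleSpec] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Mix pure profiles into a noisy cohort at known contamination fractions.

    Each sample is ``(1 - sum(frac)) * own + sum(frac_c * contaminant_c)``
    on the TPM simplex, then multiplicative log-normal noise, then
    renormalisation.  Returns (matrix, metadata, truth) where truth has one
    row per (sample, contaminant, true_frac).
    """
    design = list(design) if design is not None else default_cohort_design(config)
    rng = config.rng(2)
    cols = {}
    meta_rows = []
    truth_rows = []
    for spec in design:
        total_frac = sum(spec.fracs.values())
        if total_frac >= 1:
            raise ValueError(f"fractions for {spec.sample_id} sum to >=1")
        col = (1.0 - total_frac) * profiles[spec.cell_type]
        for contaminant, frac in spec.fracs.items():
            col = col + frac * profiles[contaminant]
            truth_rows.append((spec.sample_id, contaminant, frac))
        if config.noise_sigma > 0:
            col = col * rng.lognormal(0.0, config.noise_sigma, size=len(col))
        cols[spec.sample_id] = col
        meta_rows.append((spec.sample_id, spec.cell_type, spec.compartment,
                          spec.patient_id, spec.is_reference))
    matrix = renormalize(pd.DataFrame(cols, index=profiles.index))
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "cell_type", "compartment",
                            "patient_id", "is_reference"]).set_index("sample_id")
    truth = pd.DataFrame(truth_rows, columns=["sample_id", "contaminant", "true_frac"])
    return matrix, meta, truth


def generate_matched_pairs(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, MatchedPairSet, pd.DataFrame]:
    """Patient-matched two-condition cohort with planted fold changes.

    Condition A (omentum) and B (ascites) samples of each patient share a
    per-gene patient effect; the first ``de_n_planted`` genes carry the
    planted fold (alternating up in A / up in B) and are guaranteed a
    baseline above ``de_min_planted_base`` so they survive the TPM filter.
    Returns (matrix, metadata, pairs, truth).
    """
    rng = config.rng(3)
    genes = gene_names(config.de_n_genes)
    base = rng.lognormal(config.baseline_log_mean + 0.5, 1.0, size=config.de_n_genes)
    planted = np.arange(config.de_n_planted)
    base[planted] = np.maximum(base[planted], config.de_min_planted_base)
    direction = np.zeros(config.de_n_genes, dtype=int)
    direction[planted] = np.where(planted % 2 == 0, 1, -1)
    fold = np.where(direction == 0, 1.0,
                    np.where(direction > 0, config.de_fold, 1.0 / config.de_fold))

    cols = {}
    meta_rows = []
    patients, a_ids, b_ids = [], [], []
    for p in range(config.n_pairs):
        patient = f"P{p:02d}"
        shared = rng.lognormal(0.0, config.patient_sigma, size=config.de_n_genes)
        a = base * fold * shared
        b = base * shared
        if config.de_noise_sigma > 0:
            a = a * rng.lognormal(0.0, config.de_noise_sigma, size=config.de_n_genes)
            b = b * rng.lognormal(0.0, config.de_noise_sigma, size=config.de_n_genes)
        a_id, b_id = f"{patient}_om", f"{patient}_asc"
        cols[a_id], cols[b_id] = a, b
        meta_rows.append((a_id, "TU", "omentum", patient, False))
        meta_rows.append((b_id, "TU", "ascites", patient, False))
        patients.append(patient)
        a_ids.append(a_id)
        b_ids.append(b_id)

    matrix = renormalize(pd.DataFrame(cols, index=genes))
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "cell_type", "compartment",
                            "patient_id", "is_reference"]).set_index("sample_id")
    pairs = MatchedPairSet(tuple(patients), tuple(a_ids), tuple(b_ids),
                           "omentum", "ascites")
    truth = pd.DataFrame({
        "gene": genes,
        "planted": direction != 0,
        "direction": np.where(direction > 0, "up",
                              np.where(direction < 0, "down", "none")),
        "fold": fold,
    }).set_index("gene")
    return matrix, meta, pairs, truth


def generate_lr_annotation_and_secretome(
    config: SimulationConfig,
    profiles: pd.DataFrame,
    markers: Mapping[str, Sequence[str]],
) -> tuple[LigandReceptorMap, pd.DataFrame, dict]:
    """Ligand/receptor annotation with planted targets, plus an LFQ table.

    Ligand genes are drawn from the planted marker block of their producer
    cell type (hence selectively expressed there); receptor genes from the
    tail of the planted target type's block (hence expressed only on the
    target).  All ligands carry the ``metastasis`` flag.  The LFQ table
    covers the ligand genes plus random extra genes, with detection
    probability logistic in log10 of the secreting cell type's TPM and
    detected LFQ values affine in log10(TPM + 1).
    """
    rng = config.rng(4)
    types = list(config.cell_types)
    m = config.n_markers_per_type
    k = config.receptors_per_ligand
    per_type_capacity = (m // 2) // k
    receptors_by_ligand: dict[str, frozenset[str]] = {}
    flags: dict[str, dict[str, bool]] = {}
    truth_targets: dict[str, str] = {}
    truth_producers: dict[str, str] = {}
    for i in range(config.n_ligands):
        producer = types[i % len(types)]
        target = types[(i + 1) % len(types)]
        ligand = markers[producer][i // len(types)]
        slot = i // len(types)
        if slot >= per_type_capacity:
            raise ValueError("not enough planted marker genes for the receptor design")
        # receptors come from the back half of the target's marker block so
        # they never collide with genes used as ligands
        start = m - (slot + 1) * k
        receptor_genes = frozenset(markers[target][start:start + k])
        receptors_by_ligand[ligand] = receptor_genes
        flags[ligand] = {"metastasis": True}
        truth_targets[ligand] = target
        truth_producers[ligand] = producer
    lr_map = LigandReceptorMap(receptors_by_ligand, flags)

    secreting = config.secreting_cell_type
    ligand_genes = sorted(receptors_by_ligand)
    used = set(ligand_genes) | {g for rs in receptors_by_ligand.values() for g in rs}
    pool = [g for g in profiles.index if g not in used]
    extra = sorted(rng.choice(pool, size=config.n_secretome_extra_genes, replace=False))
    secretome_genes = ligand_genes + extra

    tpm = profiles.loc[secretome_genes, secreting].to_numpy(dtype=float)
    log_tpm = np.log10(tpm + 1e-3)
    midpoint = np.log10(config.detect_midpoint_tpm)
    detect_prob = 1.0 / (1.0 + np.exp(-config.detect_slope * (log_tpm - midpoint)))
    detected = rng.random(len(secretome_genes)) < detect_prob

    rows = []
    for g, gene in enumerate(secretome_genes):
        signal = config.lfq_slope * np.log10(tpm[g] + 1.0) + config.lfq_intercept
        for s in range(config.n_secretome_samples):
            sample = f"{secreting}_CM_{s:02d}"
            rows.append((gene, sample, "t0", 0.0, bool(detected[g])))
            late = (signal + rng.normal(0.0, config.lfq_noise_sigma)
                    if config.lfq_noise_sigma > 0 else signal)
            lfq = max(float(late), 0.0) if detected[g] else 0.0
            rows.append((gene, sample, "late", lfq, bool(detected[g])))
    lfq_table = pd.DataFrame(
        rows, columns=["protein", "sample", "timepoint", "lfq", "peptide_detected"])

    truth = {
        "targets": truth_targets,
        "producers": truth_producers,
        "secretome_genes": secretome_genes,
        "detect_prob": pd.Series(detect_prob, index=secretome_genes),
        "detected": pd.Series(detected, index=secretome_genes),
    }
    return lr_map, lfq_table, truth


def contamination_recovery(
    config: SimulationConfig,
    true_frac: float,
    n_replicates: int,
    target: str = "TU",
    contaminant: str = "TAM",
) -> np.ndarray:
    """Estimator-recovery experiment: estimates over noisy replicate mixtures.

    A single mixed sample ``(1 - f) * target + f * contaminant`` is drawn
    ``n_replicates`` times with fresh multiplicative noise, renormalised,
    and fed to the contamination estimator against the noise-free pure
    references.  Returns the array of estimated percentages.
    """
    from .contamination import estimate_contamination

    profiles, markers = generate_pure_profiles(config)
    marker_set = marker_sets_from_truth(
        markers, {target: [contaminant]})[(target, contaminant)]
    rng = config.rng(5)
    t_ref = profiles[target]
    c_ref = profiles[contaminant]
    mixed = (1.0 - true_frac) * t_ref + true_frac * c_ref
    estimates = np.empty(n_replicates)
    for r in range(n_replicates):
        noisy = mixed * rng.lognormal(0.0, config.noise_sigma, size=len(mixed))
        noisy = noisy * (TPM_TOTAL / noisy.sum())
        estimates[r], _ = estimate_contamination(noisy, t_ref, c_ref, marker_set)
    return estimates
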