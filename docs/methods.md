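# Methods

This note documents the models, conventions and numerical choices behind
`netkit`, the assumptions of its synthetic-data generator, and the limits
of what the test suite can demonstrate about real data.

## Data model

The central object is a gene × sample matrix of TPM values (pandas
DataFrame, gene symbols × sample IDs) with per-sample metadata: cell type
(`TU`, `TAM`, `TAT`, `ADI`, `MESO`, `CAF`), compartment (`ascites`,
`omentum`), patient ID and an optional reference-sample flag.  Every valid
matrix column sums to 10^6 (relative tolerance 1e-9); any operation that
removes genes or alters values ends with renormalisation so the contract
holds at every stage.  Gene identity is the case-sensitive symbol string;
no alias resolution is attempted.

The default gene-exclusion asset removes mitochondrially encoded genes,
mitochondrial and cytosolic ribosomal protein genes, MIR/LINC non-coding
families, histone genes, and a fixed list of genes known to quantify
discordantly between poly(A)-selected and total-RNA libraries.  Two
caveats: histone genes are included although protocols disagree only
partially about them, and the glob patterns `RPS[0-9]*`/`RPL[0-9]*`
unavoidably also match the RPS6K* kinase family — a user-supplied
exclusion file overrides the asset when that matters.

## Marker selection

Identity markers for a cell type must satisfy three strict criteria:
median TPM in the target above a per-type floor (100 for TU/TAM/TAT,
1000 for ADI/MESO, 25 for CAF — stromal markers are few but very strong,
CAF markers comparatively weak), at most a 10-fold min–max spread across
target samples, and a ratio above 10 between the minimum target TPM and
the minimum TPM of every other cell type's sample set.  Genes are ranked
by the worst-case cross-type ratio.  "Different gene families" for
top-k deduplication defaults to the maximal leading alphabetic prefix of
the symbol (FCGR2A → FCGR); a curated family map can be supplied.

Contamination marker sets for an ordered (target, contaminant) pair are
the top-25 genes by offset median fold change
`(median_contaminant + 0.001) / (median_target + 0.001)`, subject to
fold change > 50 and contaminant median > 10 TPM.  The 0.001 offset is
applied to both terms so zero medians stay finite and the ranking is
total; ties are broken lexicographically by symbol for determinism.

Marker selection is circular in one respect: it uses medians over the
very samples whose contamination is to be estimated.  If a majority of a
cell type's samples carry the *same* contaminant, genes of a third cell
type contaminating the contaminant can leak past the 10-TPM floor and
displace genuine markers.  The estimator guards against the downstream
symptom (markers at zero in the contaminant reference are dropped with a
warning; an all-zero set is an error), but the assumption remains that
most samples of each type are substantially pure — which holds for
sorted populations and is built into the synthetic cohort design.

## Contamination estimation, exclusion and adjustment

For each sample and contaminant, the per-marker percentage is

    (TPM_sample,g − TPM_target_ref,g) / TPM_contaminant_ref,g × 100

and the estimate is the median over the (≤25) markers.  Per-marker values
are clamped to [0, 100] before the median: noise can push individual
markers below zero, and unclamped negatives would bias the median
downward — the bias this method deliberately avoids.  Reference samples
are the pinned `is_reference` samples where provided, otherwise the
target sample minimising the summed per-set median contaminant-marker
TPM (ties by sample ID).  A configurable per-pair minimum assumed
percentage (default 0) can floor the estimate, reflecting that perfectly
pure sorts do not exist.

Samples are excluded when any contaminant estimate reaches the cell-type
threshold: 4% for TU/TAM/TAT, 6% for ADI, never for MESO/CAF by default.
The comparison is inclusive (≥) and applied with a 1e-9-percentage-point
tolerance so that a boundary case such as an exactly-4.0% mixture is not
flipped by floating-point jitter from renormalisation.

Kept samples are unmixed iteratively per contaminant:

    x ← (x − frac · contaminant_profile) / (1 − frac)

with the contaminant profile the cohort median over kept samples of that
type, or the patient-matched sample when configured and available (same
compartment preferred).  The default iteration order is descending
estimated fraction (configurable); negatives are clamped to zero once
after all contaminants, and the whole matrix is renormalised once at the
end.  For a single contaminant the adjustment inverts the mixture
exactly (up to floating point).  For several simultaneous contaminants
the sequential update leaves a cross term of order `frac_i × frac_j`
(≈0.25% signal at 5% + 5%), which is negligible in the post-exclusion
regime; this residual is why the exact-inversion guarantee is stated per
contaminant.  The reference sample itself is adjusted like any other
kept sample.

Precision of the estimator under the generator's noise model (25
markers, multiplicative log-normal noise σ = 0.2): the estimate is
`frac × median(ε_g)` with the log of the 25-marker median having
standard deviation ≈ 1.2533 · σ / √25 ≈ 0.05.  A ±1-percentage-point
window is therefore ≈3.6 σ at 5% contamination but only ≈2 σ at 10% and
≈1 σ at 20%.  The recovery experiments accordingly run at 1/2/5% — the
regime in which samples are adjusted at all, since estimates at ≥4–6%
trigger exclusion instead.

## Selectivity and receptor scoring

A gene is *expressed* in a cell type when its median TPM there strictly
exceeds 2.  Cell types are summarised by medians throughout, and by
default each cell type is summarised from its omentum samples where any
exist (falling back to ascites, e.g. for TAT); a compartment filter
exposes the alternatives.

Selectivity compares compartment groups (tumour = TU; immune = TAM, TAT;
stroma = ADI, MESO, CAF): a side owns a gene when its best cell-type
median exceeds 5 × the best median on the other side — the strictest
reading of "5-fold selective", using the maximum rather than the mean of
the competition.  Within a selective group, member cell types are those
individually exceeding 5 × the best outside median; host-selective genes
are subdivided into stroma/immune/both by their member set, and stromal
member sets produce the Venn combination counts.  The partition is
exhaustive and mutually exclusive over expressed genes.

Ligand→target scores follow three steps: (i) each receptor's per-type
median is divided by its maximum across cell types (making the score
invariant to uniform rescaling of any receptor, so weakly and strongly
expressed receptors contribute equally); (ii) scaled values are summed
over the ligand's receptor set; (iii) each ligand row is divided by its
maximum, giving scores in [0, 1] with a 1 at the strongest target.
Step (iii) is interpreted as ligand-wise max scaling across cell types;
the resulting row profile is relative, not an absolute expression level.
Scores for WNT-family ligands should be treated with caution — WNT
ligand–receptor usage is too promiscuous for this aggregation — and a
`wnt_family` annotation flag can be carried through to outputs; the
computation itself is unchanged.

Network assembly emits, for every metastasis-flagged ligand expressed by
at least one cell type, an edge to each cell type where a cognate
receptor's median TPM strictly exceeds 2.  Producers are the ligand's
selective member types when it is selective, otherwise all expressing
types.  Flags are user-supplied annotations; no literature mining is
performed.

## Matched differential expression

The compartment comparison is a two-sided paired t-test per gene on
log2(TPM + 1) — the log stabilises multiplicative variance and matches
the fold-change framing; the offset 1 is configurable.  A gene is called
when additionally the cross-pair median fold change (offset 0.1 against
zeros) exceeds 3 in either direction and the larger of the two condition
medians exceeds 3 TPM ("either condition" resolves the ambiguity of a
one-sided TPM filter; requiring both would drop genes switched fully
off in one compartment).  The nominal p-value drives the call;
Benjamini–Hochberg q-values (statsmodels step-up) are reported alongside
for transparency.  Zero-variance genes get p = 1 and a flag.  Profile
correlation between conditions is computed on cross-pair median profiles
(genes with positive median in either condition), not as an average of
per-pair correlations.

The survival filter keeps genes with relapse-free-survival p < .05 and
overall-survival |z| > 1.96 (both strict), labelling HR > 1 & z > 0 as
short-survival and HR < 1 & z < 0 as long-survival; disagreeing signs
are labelled discordant.  The shipped 32-row statistics table for
stroma-selective ligands is an input to this filter, not something the
package computes — the underlying meta-analyses are external resources.

## Secretome concordance

LFQ tables carry one row per (protein, sample, timepoint ∈ {t0, late});
both timepoints must be on one declared (log) scale.  The secretion
signal is late − baseline; a missing baseline counts as 0
(non-detection, the label-free convention; a drop-pair mode is the
alternative).  A protein is in the secretome when a peptide was detected
in any sample and the median late signal strictly exceeds the median
baseline signal — a rank-based rule, invariant under any strictly
increasing transform of the LFQ scale.  Concordance with RNA uses the
detection fraction per TPM bin (empty bins reported as missing) and the
Spearman correlation between median TPM and median LFQ over secreted
proteins.  The transcriptome-presence threshold for overlap counts is
TPM > 0.3, a named constant.

## Synthetic data

The generator is a pure function of (config, seed) and emulates, at TPM
level, the structure the pipeline assumes:

* **Pure profiles** — gene baselines log-normal (natural-log mean 3,
  σ 1.2, i.e. a median of ≈20 pre-normalisation units with a heavy right
  tail), modulated per cell type by log-normal factors (σ 0.3).  Each
  cell type owns a 30-gene marker block at ≈10× its identity floor in
  its own type and exactly zero elsewhere, so each block doubles as
  identity markers for its type and contamination markers for any pair
  with that type as contaminant.
* **Cohorts** — six samples per cell type, four pure and two carrying a
  single contaminant (the next type, cyclically) at 2% and 5%; mixing is
  convex on the TPM simplex, followed by multiplicative log-normal noise
  (σ 0.2) and renormalisation.  A majority of pure samples per type is
  enforced — see the marker-circularity note above.
* **Matched pairs** — six patients, two compartments, 1000 genes;
  per-gene patient effects (log-normal, σ 0.3) shared within a pair,
  per-sample noise σ 0.3, and planted 8-fold shifts (alternating
  direction) on genes guaranteed a baseline ≥10 so they survive the TPM
  filter.
* **Ligands/receptors/secretome** — ligand genes drawn from producer
  marker blocks, receptors from the planted target's block (single-target
  truth); LFQ = 1.5 · log10(TPM + 1) + 2 plus Gaussian noise (σ 0.05)
  for detected proteins, detection Bernoulli with logistic probability
  in log10 TPM (midpoint 10 TPM, slope 3).

Deliberately not emulated: read-count sampling (no Poisson/NB layer —
the pipeline consumes TPM), gene length and GC bias, correlated gene
modules, compositional competition beyond renormalisation, batch
effects, and isoform-level structure.  Passing tests therefore
demonstrate the correctness of the algorithms under their stated model,
not robustness to the full messiness of real cohorts; in particular the
estimator-recovery rates are statements about multiplicative log-normal
noise only.

## Problem sizes and numerics

Simulated experiments use 2000 genes × 36 samples for cohort work,
1000 genes × 6 pairs for matched DE (1000 genes under the null, 200
planted effects for power), 1000 replicates per fraction for estimator
recovery, and 1000 random p-vectors for the BH cross-check — sizes at
which every analysis is exact or Monte-Carlo-stable while the whole
suite runs in well under a minute.  All randomness flows from a single
integer seed through `numpy.random.default_rng`; pipeline outputs are
written with a fixed float format (`%.10g`) and sorted JSON keys so
reruns are byte-identical, which the manifest (SHA-256 per input and
output) makes checkable.

## Known limitations

* Marker selection assumes mostly-pure sample sets per cell type (see
  above); heavily and systematically contaminated cohorts require
  manual marker curation.
* Sequential unmixing of simultaneous multi-contaminant mixtures is
  approximate to O(frac²); the iteration order is configurable and
  order sensitivity should be checked when fractions are large.
* The assumed-minimum-contamination floors default to 0 and must be set
  by the user when replicating analyses that used nonzero floors.
* Selectivity calls depend on the compartment summarisation rule;
  pooled-compartment and omentum-only calls can differ for TU/TAM.
* The receptor score is a relative, within-ligand quantity; scores are
  not comparable across ligands, and WNT-family rows are unreliable by
  construction.
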