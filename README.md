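# netkit

Contamination-adjusted analysis of bulk RNA-seq from sorted
tumour-microenvironment cell populations, built around the
ovarian-cancer setting: tumour cells (TU), tumour-associated macrophages
(TAM) and T cells (TAT) from ascites, and adipocytes (ADI), mesothelial
cells (MESO) and cancer-associated fibroblasts (CAF) from omental
metastases.

Sorted populations are never perfectly pure, and because cell types
differ enormously in expression of their signature genes, a few percent
of foreign RNA is enough to produce false cell-type-selective calls.
`netkit` implements the computational workflow that deals with this and
builds on the corrected data:

* **TPM housekeeping** — gene-exclusion lists (mitochondrial, ribosomal,
  non-coding, protocol-discordant genes) with renormalisation to
  column sums of 10^6.
* **Marker selection** — identity markers per cell type (median TPM
  above a per-type floor, ≤10-fold within-type spread, >10-fold above
  all other types) and top-25 contamination marker sets per
  (target, contaminant) pair (>50-fold median fold change with a 0.001
  offset, >10 TPM in the contaminant).
* **Contamination estimation and unmixing** — per sample and
  contaminant, the estimate is the median over markers g of
  `(TPM_sample,g − TPM_target_ref,g) / TPM_contaminant_ref,g × 100`;
  samples at ≥4% (TU/TAM/TAT) or ≥6% (ADI) are excluded, the rest are
  unmixed by the linear model `(x − frac·profile) / (1 − frac)` applied
  iteratively per contaminant, clamped at zero and renormalised.
* **Cytokine/growth-factor selectivity** — expression calls at median
  TPM > 2 and a tumour/immune/stroma partition at 5-fold selectivity,
  with Venn-style combination counts.
* **Ligand→receptor target scoring** — per receptor, cell-type medians
  scaled by their maximum; summed over a ligand's receptor set; scaled
  again per ligand, yielding a 0–1 score of how strongly each cell type
  listens to each ligand, plus an edge list for metastasis-flagged
  ligands.
* **Matched compartment comparison** — paired t-tests on log2(TPM + 1)
  over patient-matched omentum/ascites samples with FC > 3, TPM > 3,
  nominal p < .05 calls and Benjamini–Hochberg q-values.
* **Secretome concordance** — secretome calls from two-timepoint LFQ
  proteomics of conditioned media and their agreement with RNA levels.
* **Survival filter** — dual-significance screen (relapse-free-survival
  p < .05 and overall-survival |z| > 1.96) on a shipped statistics table
  for 32 stroma-selective ligands.
* **Synthetic data** — generators for all of the above with known ground
  truth (planted markers, known mixing fractions, planted fold changes,
  planted ligand targets, logistic detection), so the whole pipeline is
  testable without any external download.

## Worked example

Generate a synthetic cohort and run the full pipeline:

```bash
netkit simulate --seed 7 --out sim/
netkit run --config config.yaml     # config points at sim/ (see below)
netkit report --run-dir run/
```

with `config.yaml`:

```yaml
matrix: sim/matrix.tsv
meta: sim/meta.tsv
lr_map: sim/lr_map.tsv
lfq: sim/lfq.tsv
out_dir: run/
seed: 7
```

The report (`run/report.json`) for this seed contains:

```
"excluded_samples": ["TAM_05", "TAT_05", "TU_05"],
"network_edge_count": 12,
"selectivity_counts": {"expressed": 2000, "tumour": 30, "host": 151,
                       "shared": 1819, ...},
"survival": {"retained": 32, "short_survival": 31, "long_survival": 1}
```

Reading this: the three samples simulated with 5% contamination of a
4%-threshold cell type were excluded (the 2% samples were kept and
unmixed); all 12 planted metastasis-flagged ligands reappear as exactly
one edge each from their producer to their planted target cell type;
each cell type's 30 planted markers are recovered as selective for it
(the tumour count is exactly the TU marker block); and the survival
filter retains all 32 genes of the shipped table, 31 of them associated
with short survival and one (BDNF) with long survival.

The same steps can be run as a narrated analysis sequence:

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_adjust_contamination.py
python analysis/03_selectivity_network.py
python analysis/04_matched_de.py --seed 1
python analysis/05_secretome_concordance.py
python analysis/06_survival_filter.py
```

Step 02, for instance, prints the estimator's accuracy against the
generator truth (`mean abs error 0.009 pp, max 0.342 pp over 180
assessments` at seed 1) and step 04 the calibration and power of the
matched test (`0.051 of 1000 genes at p < .05` under the null;
`sensitivity 1.000` on 200 planted 8-fold shifts).

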