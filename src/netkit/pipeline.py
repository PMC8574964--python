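"""End-to-end orchestration: load -> adjust -> selectivity -> network -> DE -> concordance.

A run is configured by a single YAML file whose defaults are the published
thresholds (TPM > 2 expression, FC > 5 selectivity, FC > 3 / TPM > 3 /
p < .05 matched DE, 4%/6% contamination exclusion, 25 contamination
markers at >50-fold and >10 TPM), so the zero-override configuration
reproduces the published analysis settings.  Every stage writes TSV
outputs plus an entry in ``manifest.json`` recording parameters and
SHA-256 hashes of inputs and outputs; identical config and inputs yield a
byte-identical manifest.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import contamination, differential, io, markers, secretome, selectivity


@dataclass
class PipelineConfig:
    """Paths, thresholds and seed for one pipeline run."""

    matrix: str
    meta: str
    out_dir: str
    lr_map: str | None = None
    lfq: str | None = None
    survival: str | None = "builtin"
    exclusions: str | None = "default"
    seed: int = 0
    # contamination
    contamination_pairs: list[list[str]] | None = None  # default: all ordered pairs
    exclusion_threshold: dict[str, float] = field(
        default_factory=lambda: dict(contamination.DEFAULT_EXCLUSION_THRESHOLD))
    minimum_assumed_percent: dict[str, float] = field(default_factory=dict)  # "TU:TAM" keys
    contaminant_profile_source: str = "cohort_median"
    marker_top_n: int = 25
    marker_min_fold: float = 50.0
    marker_min_contaminant_tpm: float = 10.0
    fc_offset: float = 0.001
    # selectivity / network
    expressed_tpm: float = 2.0
    selective_fc: float = 5.0
    receptor_tpm: float = 2.0
    compartment: str | None = "omentum_preferred"
    # matched DE
    de_cell_types: list[str] = field(default_factory=lambda: ["TU", "TAM"])
    de_fc: float = 3.0
    de_tpm: float = 3.0
    de_alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True,
               index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", index=index, index_label=index_label,
              float_format="%.10g", lineterminator="\n")


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages and write outputs plus manifest under ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "inputs": {}}
    report: dict = {}

    def record(stage: str, params: Mapping, outputs: list[Path],
               status: str = "completed") -> None:
        manifest["stages"][stage] = {
            "status": status,
            "params": dict(params),
            "outputs": {p.name: _sha256(p) for p in outputs},
        }

    # --- load + gene exclusion ------------------------------------------
    matrix, meta = io.load_matrix(config.matrix, config.meta)
    manifest["inputs"]["matrix"] = _sha256(Path(config.matrix))
    manifest["inputs"]["meta"] = _sha256(Path(config.meta))
    if config.exclusions == "default":
        excl = io.default_exclusions()
    elif config.exclusions:
        excl = io.GeneExclusionList.from_file(config.exclusions)
        manifest["inputs"]["exclusions"] = _sha256(Path(config.exclusions))
    else:
        excl = io.GeneExclusionList()
    matrix = io.exclude_genes(matrix, excl)
    p_norm = out / "matrix_renormalized.tsv"
    io.write_matrix(matrix, p_norm)
    record("load", {"exclusions": config.exclusions or "none",
                    "n_genes": len(matrix.index),
                    "n_samples": len(matrix.columns)}, [p_norm])

    # --- contamination markers ------------------------------------------
    present = sorted(meta["cell_type"].unique())
    if config.contamination_pairs is None:
        pairs = [(t, c) for t in present for c in present if t != c]
    else:
        pairs = [(t, c) for t, c in config.contamination_pairs
                 if t in present and c in present]
    marker_sets: dict[tuple[str, str], markers.MarkerSet] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for target, contam in pairs:
            marker_sets[(target, contam)] = markers.select_contamination_markers(
                matrix, meta, target, contam,
                top_n=config.marker_top_n,
                min_fold=config.marker_min_fold,
                min_contaminant_tpm=config.marker_min_contaminant_tpm,
                offset=config.fc_offset)
    p_markers = out / "contamination_markers.tsv"
    frames = [ms.to_frame() for ms in marker_sets.values() if len(ms)]
    _write_tsv(pd.concat(frames, ignore_index=True) if frames
               else pd.DataFrame(columns=["target", "contaminant", "rank", "gene", "score"]),
               p_markers, index=False)
    record("markers", {"pairs": len(pairs), "top_n": config.marker_top_n}, [p_markers])

    # --- estimate, exclude, adjust --------------------------------------
    contaminants_by_target: dict[str, tuple[str, ...]] = {}
    for target, contam in pairs:
        if len(marker_sets[(target, contam)]):
            contaminants_by_target.setdefault(target, ())
            contaminants_by_target[target] += (contam,)
    min_pct = {tuple(k.split(":")): v for k, v in config.minimum_assumed_percent.items()}
    adj_config = contamination.AdjustmentConfig(
        contaminants_by_target=contaminants_by_target,
        exclusion_threshold=config.exclusion_threshold,
        minimum_assumed_percent=min_pct,
        contaminant_profile_source=config.contaminant_profile_source)
    result = contamination.run_adjustment(matrix, meta, marker_sets, adj_config)
    kept_meta = meta.loc[result.adjusted.columns]
    p_adj = out / "adjusted_matrix.tsv"
    p_table = out / "contamination_table.tsv"
    p_meta = out / "meta_kept.tsv"
    io.write_matrix(result.adjusted, p_adj)
    _write_tsv(result.table, p_table, index=False)
    io.write_meta(kept_meta, p_meta)
    record("adjust", {"excluded": result.excluded_samples,
                      "references": result.references,
                      "profile_source": config.contaminant_profile_source},
           [p_adj, p_table, p_meta])
    report["excluded_samples"] = result.excluded_samples

    # --- selectivity -----------------------------------------------------
    calls, counts = selectivity.classify_selectivity(
        result.adjusted, kept_meta, fc=config.selective_fc,
        tpm_threshold=config.expressed_tpm, compartment=config.compartment)
    p_sel = out / "selectivity_calls.tsv"
    _write_tsv(pd.DataFrame([{
        "gene": c.gene,
        "category": c.category,
        "host_category": c.host_category or "",
        "selective_types": "+".join(sorted(c.selective_types)),
        "expressed_in": "+".join(sorted(c.expressed_in)),
    } for c in calls]), p_sel, index=False)
    record("selectivity", {"fc": config.selective_fc, "tpm": config.expressed_tpm},
           [p_sel])
    report["selectivity_counts"] = counts

    # --- metastasis network ----------------------------------------------
    if config.lr_map:
        manifest["inputs"]["lr_map"] = _sha256(Path(config.lr_map))
        lr_map = selectivity.LigandReceptorMap.from_tsv(config.lr_map)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            edges = selectivity.build_metastasis_network(
                calls, lr_map, result.adjusted, kept_meta,
                receptor_tpm=config.receptor_tpm,
                ligand_tpm=config.expressed_tpm,
                compartment=config.compartment)
            scores = selectivity.receptor_target_scores(
                lr_map, result.adjusted, kept_meta, compartment=config.compartment)
        p_edges = out / "network_edges.tsv"
        p_nodes = out / "network_nodes.tsv"
        p_scores = out / "receptor_target_scores.tsv"
        _write_tsv(edges, p_edges, index=False)
        nodes = sorted(set(edges["ligand"]) | set(edges["target_cell_type"])
                       | {t for s in edges["source_cell_types"] for t in s.split("+")})
        _write_tsv(pd.DataFrame({"node": nodes}), p_nodes, index=False)
        _write_tsv(scores, p_scores, index_label="ligand")
        record("network", {"receptor_tpm": config.receptor_tpm},
               [p_edges, p_nodes, p_scores])
        report["network_edge_count"] = int(len(edges))
    else:
        record("network", {}, [], status="skipped (no ligand-receptor map)")

    # --- matched differential expression ---------------------------------
    de_counts: dict[str, dict] = {}
    de_outputs: list[Path] = []
    for cell_type in config.de_cell_types:
        pairs_ct = differential.MatchedPairSet.from_meta(meta, cell_type)
        usable = [i for i, (a, b) in enumerate(zip(pairs_ct.a_ids, pairs_ct.b_ids))
                  if a in result.adjusted.columns and b in result.adjusted.columns]
        pairs_ct = differential.MatchedPairSet(
            tuple(pairs_ct.patients[i] for i in usable),
            tuple(pairs_ct.a_ids[i] for i in usable),
            tuple(pairs_ct.b_ids[i] for i in usable),
            pairs_ct.label_a, pairs_ct.label_b)
        if len(pairs_ct) < 3:
            de_counts[cell_type] = {"status": "skipped (<3 matched pairs)"}
            continue
        de = differential.paired_de(
            result.adjusted, pairs_ct, fc_threshold=config.de_fc,
            tpm_threshold=config.de_tpm, alpha=config.de_alpha)
        rho = differential.matched_correlation(result.adjusted, pairs_ct)
        p_de = out / f"de_{cell_type}.tsv"
        _write_tsv(de, p_de, index_label="gene")
        de_outputs.append(p_de)
        de_counts[cell_type] = {
            "n_pairs": len(pairs_ct),
            "n_called": int(de["called"].sum()),
            "n_up": int((de["called"] & (de["direction"] == "up")).sum()),
            "n_down": int((de["called"] & (de["direction"] == "down")).sum()),
            "spearman": round(float(rho), 6),
        }
    record("de", {"fc": config.de_fc, "tpm": config.de_tpm, "alpha": config.de_alpha,
                  "cell_types": list(config.de_cell_types)}, de_outputs,
           status="completed" if de_outputs else "skipped (no matched pairs)")
    report["de"] = de_counts

    # --- secretome concordance -------------------------------------------
    if config.lfq:
        manifest["inputs"]["lfq"] = _sha256(Path(config.lfq))
        lfq_table = pd.read_csv(config.lfq, sep="\t")
        if lfq_table["peptide_detected"].dtype != bool:
            lfq_table["peptide_detected"] = (
                lfq_table["peptide_detected"].astype(str).str.lower()
                .isin(("true", "1", "yes")))
        sec_calls = secretome.call_secretome(lfq_table)
        med = selectivity.medians_by_cell_type(result.adjusted, kept_meta,
                                               config.compartment)
        secreting = [t for t in ("CAF", *med.columns) if t in med.columns][0]
        tpm_med = med[secreting]
        overlap = secretome.secretome_transcriptome_overlap(
            tpm_med, sec_calls, gene_list=sorted(sec_calls.index))
        edges_tpm = [0.0, 0.3, 2.0, 10.0, 50.0, 500.0, np.inf]
        rate = secretome.detection_rate_by_expression(
            tpm_med, sec_calls, edges_tpm, gene_list=sorted(sec_calls.index))
        secreted = sec_calls.index[sec_calls["in_secretome"]]
        rho_rp = (secretome.rna_protein_correlation(
            tpm_med, sec_calls.loc[secreted, "median_late"])
            if len(set(secreted) & set(tpm_med.index)) >= 3 else float("nan"))
        p_sec = out / "secretome_calls.tsv"
        p_rate = out / "detection_rate.tsv"
        _write_tsv(sec_calls, p_sec, index_label="protein")
        _write_tsv(rate, p_rate, index=False)
        record("concordance", {"secreting_cell_type": secreting}, [p_sec, p_rate])
        report["secretome"] = {
            "overlap": overlap,
            "rna_protein_spearman": round(float(rho_rp), 6),
        }
    else:
        record("concordance", {}, [], status="skipped (no LFQ table)")

    # --- survival filter ---------------------------------------------------
    if config.survival:
        if config.survival == "builtin":
            surv = differential.load_survival_table()
        else:
            manifest["inputs"]["survival"] = _sha256(Path(config.survival))
            surv = pd.read_csv(config.survival, sep="\t")
        filtered = differential.survival_filter(surv)
        p_surv = out / "survival_filtered.tsv"
        _write_tsv(filtered, p_surv, index=False)
        record("survival", {"p_max": 0.05, "z_abs_min": 1.96}, [p_surv])
        report["survival"] = {
            "retained": int(len(filtered)),
            "short_survival": int((filtered["direction"] == "short survival").sum()),
            "long_survival": int((filtered["direction"] == "long survival").sum()),
        }
    else:
        record("survival", {}, [], status="skipped (no survival table)")

    # --- report + manifest -------------------------------------------------
    p_report = out / "report.json"
    p_report.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    manifest["stages"]["report"] = {
        "status": "completed", "params": {},
        "outputs": {p_report.name: _sha256(p_report)},
    }
    manifest["seed"] = config.seed
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out


def load_report(run_dir: str | Path) -> dict:
    """Load the machine-readable summary of a finished run."""
    path = Path(run_dir) / "report.json"
    if not path.exists():
        raise FileNotFoundError(f"no report.json under {run_dir}; incomplete run")
    return json.loads(path.read_text())
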