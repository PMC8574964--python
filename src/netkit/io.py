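"""Reading, validation and normalisation of TPM expression matrices.

The central object of the pipeline is a gene x sample matrix of TPM
(transcripts-per-million) values held as a :class:`pandas.DataFrame` with
gene symbols as the index and sample IDs as columns.  Sample annotations
(cell type, compartment, patient, reference flag) travel alongside in a
second DataFrame indexed by sample ID.  Every column of a valid matrix sums
to 1e6; gene exclusion is always followed by renormalisation so that the
TPM contract holds at every stage.
"""

from __future__ import annotations

import fnmatch
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: TPM column total: transcripts per million.
TPM_TOTAL = 1e6

#: Sorted cell populations of the tumour microenvironment handled here:
#: tumour cells, tumour-associated macrophages / T cells, adipocytes,
#: mesothelial cells and cancer-associated fibroblasts.
CELL_TYPES = ("TU", "TAM", "TAT", "ADI", "MESO", "CAF")

COMPARTMENTS = ("ascites", "omentum")

META_COLUMNS = ("cell_type", "compartment", "patient_id", "is_reference")


class ExpressionDataError(ValueError):
    """Raised when an expression matrix or its metadata violate the contract."""


def validate_matrix(matrix: pd.DataFrame) -> None:
    """Check the ExpressionMatrix invariants (non-negative, finite, unique labels)."""
    if matrix.index.has_duplicates:
        dupes = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ExpressionDataError(f"duplicate gene symbol(s): {', '.join(map(str, dupes))}")
    if matrix.columns.has_duplicates:
        dupes = matrix.columns[matrix.columns.duplicated()].unique().tolist()
        raise ExpressionDataError(f"duplicate sample ID(s): {', '.join(map(str, dupes))}")
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ExpressionDataError("expression matrix contains non-finite values")
    if (values < 0).any():
        raise ExpressionDataError("expression matrix contains negative values")


def validate_meta(meta: pd.DataFrame, matrix: pd.DataFrame | None = None) -> None:
    """Check sample metadata and, if given, its agreement with a matrix."""
    missing_cols = [c for c in META_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ExpressionDataError(f"metadata missing column(s): {', '.join(missing_cols)}")
    if meta.index.has_duplicates:
        dupes = meta.index[meta.index.duplicated()].unique().tolist()
        raise ExpressionDataError(f"duplicate metadata record(s) for: {', '.join(map(str, dupes))}")
    bad_types = sorted(set(meta["cell_type"]) - set(CELL_TYPES))
    if bad_types:
        raise ExpressionDataError(f"unknown cell type(s): {', '.join(bad_types)}")
    bad_comp = sorted(set(meta["compartment"]) - set(COMPARTMENTS))
    if bad_comp:
        raise ExpressionDataError(f"unknown compartment(s): {', '.join(bad_comp)}")
    if matrix is not None:
        missing = [s for s in matrix.columns if s not in meta.index]
        if missing:
            raise ExpressionDataError(f"missing metadata for sample(s): {', '.join(missing)}")


def renormalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Rescale every sample column so it sums to 1e6 (TPM).

    Preserves within-sample gene proportions; idempotent up to floating point.
    Raises for all-zero samples, which have no TPM representation.
    """
    totals = matrix.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ExpressionDataError(
            f"cannot renormalize all-zero sample(s): {', '.join(map(str, zero.index))}"
        )
    return matrix * (TPM_TOTAL / totals)


def load_matrix(path: str | Path, meta_path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load a TPM matrix and its sample metadata from TSV, cross-validated.

    The matrix TSV has gene symbols in the first column and sample IDs in the
    header; the metadata TSV has columns ``sample_id``, ``cell_type``,
    ``compartment``, ``patient_id``, ``is_reference``.
    """
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    matrix.index = matrix.index.astype(str)
    matrix.columns = matrix.columns.astype(str)
    validate_matrix(matrix)
    meta = pd.read_csv(meta_path, sep="\t", dtype={"sample_id": str, "patient_id": str})
    if "sample_id" not in meta.columns:
        raise ExpressionDataError("metadata missing column(s): sample_id")
    meta = meta.set_index("sample_id")
    if meta["is_reference"].dtype != bool:
        meta["is_reference"] = (
            meta["is_reference"].astype(str).str.lower().isin(("true", "1", "yes"))
        )
    validate_meta(meta, matrix)
    return matrix, meta


def write_matrix(matrix: pd.DataFrame, path: str | Path, index_label: str = "gene") -> None:
    """Write a matrix as TSV with a deterministic float representation."""
    matrix.to_csv(path, sep="\t", index_label=index_label, float_format="%.10g",
                  lineterminator="\n")


def write_meta(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id", lineterminator="\n")


@dataclass(frozen=True)
class GeneExclusionList:
    """Gene symbols and glob-style symbol patterns to drop before analysis.

    Patterns use :mod:`fnmatch` syntax (``MT-*`` drops all mitochondrially
    encoded genes).  Matching is case-sensitive and deterministic.
    """

    patterns: tuple[str, ...] = field(default_factory=tuple)

    @classmethod
    def from_lines(cls, lines: Iterable[str]) -> "GeneExclusionList":
        pats = []
        for line in lines:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            pats.append(line)
        return cls(tuple(pats))

    @classmethod
    def from_file(cls, path: str | Path) -> "GeneExclusionList":
        return cls.from_lines(Path(path).read_text().splitlines())

    def matches(self, gene: str) -> bool:
        return any(fnmatch.fnmatchcase(gene, p) for p in self.patterns)

    def filter(self, genes: Sequence[str]) -> list[str]:
        """Return the genes that survive (do not match any pattern)."""
        return [g for g in genes if not self.matches(g)]


def default_exclusions() -> GeneExclusionList:
    """The shipped default exclusion list.

    Covers mitochondrial genes, mitochondrial ribosomal genes, cytosolic
    ribosomal (40S/60S) genes, non-protein-coding gene families (MIR/LINC),
    histone genes, and a fixed list of genes with discordant quantification
    between poly(A)-selected and total-RNA library protocols.
    """
    text = resources.files("netkit.data").joinpath("default_gene_exclusions.txt").read_text()
    return GeneExclusionList.from_lines(text.splitlines())


def exclude_genes(matrix: pd.DataFrame, excl: GeneExclusionList) -> pd.DataFrame:
    """Drop genes matching the exclusion list and renormalize to TPM."""
    keep = excl.filter(list(matrix.index))
    if not keep:
        raise ExpressionDataError("gene exclusion removed every gene")
    return renormalize(matrix.loc[keep])
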