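"""Input/output and preprocessing of expression matrices, gene annotation,
pathway sets, and the pipeline configuration.

Expression values are stored on a log scale, ``x = log2(TPM / f + 1)`` with a
recorded scale factor ``f`` (``transform_scale_factor``).  ``f = 1`` is the
plain log2(TPM+1) convention; ``f = 10`` reproduces the log2(TPM/10+1)
convention used by some published single-cell datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised when an input file violates a structural invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x cells log-scale expression matrix.

    Parameters
    ----------
    data:
        DataFrame with gene ids as index and cell ids as columns.  Values are
        ``log2(TPM / f + 1)``; nonnegative, no missing entries.
    transform_scale_factor:
        The positive ``f`` of the log transform, recorded so TPM values can be
        recovered exactly: ``TPM = f * (2**x - 1)``.
    """

    data: pd.DataFrame
    transform_scale_factor: float = 1.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.transform_scale_factor <= 0:
            raise ValueError("transform_scale_factor must be positive")
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise FormatError(f"duplicate gene identifier: {dup!r}")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise FormatError(f"duplicate cell identifier: {dup!r}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("expression matrix contains non-numeric values")
        if np.isnan(values).any():
            g, c = np.argwhere(np.isnan(values))[0]
            raise FormatError(
                f"missing value at gene {self.data.index[g]!r}, "
                f"cell {self.data.columns[c]!r}"
            )
        if (values < 0).any():
            g, c = np.argwhere(values < 0)[0]
            raise FormatError(
                f"negative expression value at gene {self.data.index[g]!r}, "
                f"cell {self.data.columns[c]!r}"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_cells(self) -> int:
        return self.data.shape[1]

    def tpm(self) -> pd.DataFrame:
        """Recover the TPM matrix from the stored log scale."""
        f = self.transform_scale_factor
        return f * (np.exp2(self.data) - 1.0)

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[gene_ids], self.transform_scale_factor)

    def subset_cells(self, cell_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[list(cell_ids)], self.transform_scale_factor)


@dataclass
class GeneAnnotation:
    """Genomic gene annotation: chromosome, arm, position, and within-chromosome
    order index.

    ``table`` columns: gene_id, chromosome, arm (``p``/``q``), start_bp, end_bp
    (1-based inclusive), order_index (1..n per chromosome, sorted by start_bp,
    ties broken lexicographically by gene_id).
    """

    table: pd.DataFrame

    REQUIRED = ("gene_id", "chromosome", "arm", "start_bp", "end_bp")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise FormatError(f"annotation missing columns: {missing}")
        t = self.table
        if t["gene_id"].duplicated().any():
            dup = t.loc[t["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise FormatError(f"duplicate gene in annotation: {dup!r}")
        bad_arm = set(t["arm"].unique()) - {"p", "q"}
        if bad_arm:
            raise FormatError(f"arm labels must be 'p' or 'q', got {sorted(bad_arm)}")
        if (t["start_bp"] > t["end_bp"]).any():
            raise FormatError("start_bp > end_bp for at least one gene")
        if "order_index" not in t.columns:
            self.table = _assign_order_index(t)
        self.table = self.table.reset_index(drop=True)

    def loc(self, gene_ids) -> pd.DataFrame:
        return self.table.set_index("gene_id").loc[gene_ids]

    @property
    def gene_ids(self) -> pd.Index:
        return pd.Index(self.table["gene_id"])

    def arm_genes(self, chromosome: str, arm: str) -> list[str]:
        t = self.table
        sel = (t["chromosome"] == chromosome) & (t["arm"] == arm)
        return list(t.loc[sel, "gene_id"])


def _assign_order_index(table: pd.DataFrame) -> pd.DataFrame:
    """Sort genes by (chromosome, start_bp, gene_id) and number them 1..n per
    chromosome.  The lexicographic gene_id tie-break makes the order
    deterministic when two genes share a start coordinate."""
    t = table.sort_values(
        ["chromosome", "start_bp", "gene_id"], kind="mergesort"
    ).reset_index(drop=True)
    t["order_index"] = t.groupby("chromosome", sort=False).cumcount() + 1
    return t


@dataclass
class PathwayAnnotation:
    """Pathway gene sets, each labeled ``signaling`` or ``immune``.

    ``table`` columns: pathway_id, pathway_class, members (frozenset of gene ids).
    """

    table: pd.DataFrame

    CLASSES = ("signaling", "immune")

    def __post_init__(self) -> None:
        t = self.table
        for col in ("pathway_id", "pathway_class", "members"):
            if col not in t.columns:
                raise FormatError(f"pathway table missing column {col!r}")
        bad = set(t["pathway_class"].unique()) - set(self.CLASSES)
        if bad:
            raise FormatError(f"unknown pathway class(es): {sorted(bad)}")
        if (t["members"].map(len) == 0).any():
            empty = t.loc[t["members"].map(len) == 0, "pathway_id"].iloc[0]
            raise FormatError(f"pathway {empty!r} has no members")
        dup = t.duplicated(subset=["pathway_id", "pathway_class"])
        if dup.any():
            raise FormatError(
                f"duplicate pathway id within class: "
                f"{t.loc[dup, 'pathway_id'].iloc[0]!r}"
            )

    def class_union(self, pathway_class: str) -> set[str]:
        """Union of member genes of all pathways of one class."""
        sel = self.table["pathway_class"] == pathway_class
        out: set[str] = set()
        for members in self.table.loc[sel, "members"]:
            out |= set(members)
        return out


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline, with the study defaults."""

    expr_filter_threshold: float = 4.0   # log2 units, aggregate-expression gene filter
    clip_bound: float = 3.0              # relative-expression clipping for CNV
    window_halfwidth: int = 25           # 25 genes each side -> 51-gene windows
    reference_p_threshold: float = 0.99  # Welch p >= threshold -> reference cell
    zero_band: float = 0.2               # |CN| <= band set to 0
    variance_cutoff: float = 0.5         # network gene variance filter
    train_fraction: float = 2.0 / 3.0
    n_network_instances: int = 10
    n_random_networks_per_instance: int = 10
    predictor_q: float = 0.01
    enrichment_q: float = 0.05
    candidate_q: float = 0.1
    min_recurrence: int = 2
    de_q: float = 0.01
    de_abs_lfc: float = 2.0
    n_rank_permutations: int = 10000
    max_path_length: int = 5
    propagation_tolerance: float = 1e-8
    lasso_path_cap: int = 50             # max lasso path steps per gene model
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        for name in (
            "window_halfwidth", "n_network_instances",
            "n_random_networks_per_instance", "min_recurrence",
            "n_rank_permutations", "max_path_length", "lasso_path_cap",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        for name in ("predictor_q", "enrichment_q", "candidate_q", "de_q"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if not 0 <= self.reference_p_threshold <= 1:
            raise ValueError("reference_p_threshold must lie in [0, 1]")
        for name in ("clip_bound", "zero_band", "variance_cutoff",
                     "expr_filter_threshold", "de_abs_lfc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Read a YAML (or JSON, a YAML subset) config mirroring field names."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.as_dict(), sort_keys=False))

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_expression_matrix(
    path: str | Path,
    format: str | None = None,
    transform_scale_factor: float = 1.0,
) -> ExpressionMatrix:
    """Read an expression matrix from TSV/CSV (genes in rows, header = cell
    ids) or a MatrixMarket triplet with ``genes.tsv``/``cells.tsv`` sidecars.

    Absent entries of a sparse MTX file are dense zeros by convention.
    """
    path = Path(path)
    if format is None:
        format = {".tsv": "tsv", ".csv": "csv", ".mtx": "mtx-triplet"}.get(
            path.suffix, "tsv"
        )
    if format not in ("tsv", "csv", "mtx-triplet"):
        raise ValueError(f"unsupported format: {format!r}")
    if not path.exists():
        raise FileNotFoundError(path)

    if format == "mtx-triplet":
        from scipy.io import mmread

        matrix = np.asarray(mmread(path).todense(), dtype=float)
        genes = pd.read_csv(path.parent / "genes.tsv", sep="\t", header=None)[0]
        cells = pd.read_csv(path.parent / "cells.tsv", sep="\t", header=None)[0]
        data = pd.DataFrame(matrix, index=list(genes), columns=list(cells))
    else:
        sep = "\t" if format == "tsv" else ","
        data = pd.read_csv(path, sep=sep, index_col=0)
        try:
            data = data.astype(float)
        except ValueError as exc:
            raise FormatError(f"non-numeric expression value in {path}: {exc}")
    data.index = data.index.astype(str)
    data.columns = data.columns.astype(str)
    return ExpressionMatrix(data, transform_scale_factor)


def write_expression_matrix(
    X: ExpressionMatrix, path: str | Path, format: str = "tsv"
) -> None:
    path = Path(path)
    if format in ("tsv", "csv"):
        X.data.to_csv(path, sep="\t" if format == "tsv" else ",",
                      index_label="gene_id", float_format="%.10g")
    elif format == "mtx-triplet":
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        mmwrite(str(path), csr_matrix(X.data.to_numpy()))
        pd.Series(X.gene_ids).to_csv(path.parent / "genes.tsv", sep="\t",
                                     header=False, index=False)
        pd.Series(X.cell_ids).to_csv(path.parent / "cells.tsv", sep="\t",
                                     header=False, index=False)
    else:
        raise ValueError(f"unsupported format: {format!r}")


def read_gene_annotation(path: str | Path) -> GeneAnnotation:
    """Read a BED-like TSV with columns chrom, start, end, gene_id, arm.

    Coordinates are 1-based inclusive in this dialect.
    """
    t = pd.read_csv(path, sep="\t")
    rename = {"chrom": "chromosome", "start": "start_bp", "end": "end_bp"}
    t = t.rename(columns=rename)
    t["gene_id"] = t["gene_id"].astype(str)
    t["chromosome"] = t["chromosome"].astype(str)
    return GeneAnnotation(t[list(GeneAnnotation.REQUIRED)])


def write_gene_annotation(ann: GeneAnnotation, path: str | Path) -> None:
    out = ann.table.rename(
        columns={"chromosome": "chrom", "start_bp": "start", "end_bp": "end"}
    )
    out[["chrom", "start", "end", "gene_id", "arm"]].to_csv(
        path, sep="\t", index=False
    )


def read_pathways_gmt(path: str | Path) -> PathwayAnnotation:
    """Read pathway sets from GMT: ``pathway_id <TAB> class <TAB> gene ...``.

    The GMT description field carries the pathway class (signaling/immune).
    """
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
        pathway_id, pathway_class, *members = parts
        rows.append(
            {
                "pathway_id": pathway_id,
                "pathway_class": pathway_class.strip().lower(),
                "members": frozenset(m for m in members if m),
            }
        )
    return PathwayAnnotation(pd.DataFrame(rows))


def write_pathways_gmt(pathways: PathwayAnnotation, path: str | Path) -> None:
    lines = []
    for _, row in pathways.table.iterrows():
        lines.append(
            "\t".join([row["pathway_id"], row["pathway_class"]]
                      + sorted(row["members"]))
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Preprocessing operations
# ---------------------------------------------------------------------------


def filter_low_expression_genes(
    X: ExpressionMatrix, threshold: float = 4.0
) -> ExpressionMatrix:
    """Drop genes whose aggregate expression ``log2(mean TPM + 1)`` across all
    cells falls strictly below ``threshold`` (log2 units).

    The mean is taken on the TPM scale over all cells (zeros included); the
    boundary value is retained ("less than" excludes).  Pure row selection:
    retained values and the cell set are untouched.
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    aggregate = np.log2(X.tpm().mean(axis=1) + 1.0)
    keep = aggregate >= threshold
    if not keep.any():
        raise ValueError(
            f"no gene passes the aggregate-expression filter at threshold "
            f"{threshold}; review the threshold or the transform scale factor"
        )
    return ExpressionMatrix(X.data.loc[keep], X.transform_scale_factor)


def restrict_annotation(ann: GeneAnnotation, gene_ids) -> GeneAnnotation:
    """Annotation restricted to ``gene_ids`` with order_index recomputed so it
    is again a contiguous 1..n permutation per chromosome.

    Downstream window arithmetic (smoothing, local-predictor exclusion)
    measures distances in retained-gene positions, so the analysis annotation
    must be re-indexed after any gene filter.
    """
    keep = ann.table[ann.table["gene_id"].isin(set(gene_ids))]
    if len(keep) == 0:
        raise ValueError("annotation restriction removed every gene")
    return GeneAnnotation(_assign_order_index(keep.drop(columns="order_index")))


def order_genes_genomically(
    X: ExpressionMatrix, ann: GeneAnnotation
) -> ExpressionMatrix:
    """Sort the matrix rows by (chromosome, start_bp, gene_id).

    Genes absent from the annotation are dropped with a logged count; an
    annotation covering none of the matrix genes is an error.
    """
    annotated = ann.table[ann.table["gene_id"].isin(X.gene_ids)]
    n_dropped = X.n_genes - len(annotated)
    if len(annotated) == 0:
        raise ValueError("no expression gene has a genomic annotation")
    if n_dropped:
        logger.info("dropping %d gene(s) without genomic annotation", n_dropped)
    ordered = _assign_order_index(annotated)
    return ExpressionMatrix(
        X.data.loc[ordered["gene_id"]], X.transform_scale_factor
    )
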