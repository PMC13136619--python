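"""Expression-derived per-cell copy-number profiles.

The procedure treats smoothed relative expression along the genome as a
surrogate for DNA copy number: per-gene centering and clipping, a centered
rolling mean over 51 genomically ordered genes (25 each side), statistical
selection of reference (putatively non-deleted) cells by a per-cell one-sided
Welch test contrasting the affected arms against their unaffected sister arms,
baseline subtraction, and a zero band that flattens small fluctuations.
Values are relative log2 expression units; 0 means copy-number neutral.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

from codelnet.genomics_io import ExpressionMatrix, GeneAnnotation

logger = logging.getLogger(__name__)

Arm = tuple[str, str]  # (chromosome, "p"/"q")


@dataclass
class WindowProfile:
    """Per-cell windowed values along the genome.

    ``windows``: one row per window with chromosome, center_order_index,
    center_gene and the center gene's arm.  ``values``: windows x cells.
    Used both for the smoothed relative-expression profile and for the
    baseline-subtracted copy-number profile.
    """

    windows: pd.DataFrame
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.windows) != len(self.values):
            raise ValueError("window metadata and values disagree in length")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("window values must be finite")


def center_and_clip(X: ExpressionMatrix, bound: float = 3.0) -> pd.DataFrame:
    """Relative expression: per-gene mean over cells subtracted, then clipped
    to ``[-bound, +bound]`` to remove strong outliers."""
    values = X.data.to_numpy(dtype=float)
    rel = values - values.mean(axis=1, keepdims=True)
    np.clip(rel, -bound, bound, out=rel)
    return pd.DataFrame(rel, index=X.gene_ids, columns=X.cell_ids)


def rolling_mean_profile(
    relX: pd.DataFrame, ann: GeneAnnotation, halfwidth: int = 25
) -> WindowProfile:
    """Centered rolling mean over ``2*halfwidth + 1`` genes per chromosome.

    Genes must be genomically ordered.  Only full windows are emitted; a
    chromosome with fewer than ``2*halfwidth + 1`` annotated genes yields no
    windows (logged).
    """
    ann_t = ann.table.set_index("gene_id")
    meta = ann_t.loc[relX.index]
    width = 2 * halfwidth + 1
    win_rows, win_values = [], []
    for chrom, idx in meta.groupby("chromosome", sort=False).groups.items():
        sub = meta.loc[idx].sort_values("order_index")
        if len(sub) < width:
            logger.warning(
                "chromosome %s has %d genes (< %d); no windows emitted",
                chrom, len(sub), width,
            )
            continue
        block = relX.loc[sub.index].to_numpy(dtype=float)
        smoothed = sliding_window_view(block, width, axis=0).mean(axis=2)
        centers = sub.iloc[halfwidth: len(sub) - halfwidth]
        for row, (gene, grow) in enumerate(centers.iterrows()):
            win_rows.append(
                {
                    "chromosome": chrom,
                    "center_order_index": int(grow["order_index"]),
                    "center_gene": gene,
                    "arm": grow["arm"],
                }
            )
        win_values.append(smoothed)
    if not win_rows:
        raise ValueError("no chromosome is long enough for a smoothing window")
    windows = pd.DataFrame(win_rows)
    values = pd.DataFrame(
        np.vstack(win_values), index=range(len(windows)), columns=relX.columns
    )
    return WindowProfile(windows, values)


def codeletion_pvalue_per_cell(
    X: ExpressionMatrix,
    ann: GeneAnnotation,
    affected_arms: set[Arm],
    reference_arms: set[Arm],
) -> pd.Series:
    """Per-cell one-sided Welch test for the co-deletion.

    For each cell, the original (unclipped) expression values of genes on the
    affected arms are tested against those on the reference arms with a Welch
    two-sample statistic, lower tail (H1: affected mean < reference mean).
    A cell carrying the deletion yields p near 0; a cell without it sits in
    the nonsignificant upper tail.
    """
    aff_genes = _collect_arm_genes(X, ann, affected_arms, "affected")
    ref_genes = _collect_arm_genes(X, ann, reference_arms, "reference")
    a = X.data.loc[aff_genes].to_numpy(dtype=float)
    b = X.data.loc[ref_genes].to_numpy(dtype=float)
    na, nb = a.shape[0], b.shape[0]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va, vb = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    se2 = va / na + vb / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = np.where(
        se2 > 0,
        stats.t.cdf(t, np.where(se2 > 0, df, 1.0)),
        # both-sides-constant degenerate case: decide by the sign of the
        # mean difference, p = 1 for equal means
        np.where(ma == mb, 1.0, np.where(ma < mb, 0.0, 1.0)),
    )
    return pd.Series(p, index=X.cell_ids, name="p_value")


def _collect_arm_genes(X, ann, arms: set[Arm], which: str) -> list[str]:
    genes: list[str] = []
    present = set(X.gene_ids)
    for chrom, arm in sorted(arms):
        genes.extend(g for g in ann.arm_genes(chrom, arm) if g in present)
    if len(genes) < 2:
        raise ValueError(
            f"fewer than 2 measured genes on the {which} arms {sorted(arms)}"
        )
    return genes


def select_reference_cells(
    pvals: pd.Series, threshold: float = 0.99
) -> pd.DataFrame:
    """Mark cells with p >= threshold (inclusive) as reference cells."""
    is_ref = pvals >= threshold
    n = int(is_ref.sum())
    if n == 0:
        raise ValueError(
            f"no cell reaches the reference p-value threshold {threshold}; "
            f"consider relaxing reference_p_threshold"
        )
    logger.info("selected %d reference cell(s) of %d", n, len(pvals))
    return pd.DataFrame(
        {"p_value": pvals, "is_reference": is_ref}
    ).rename_axis("cell_id")


def baseline_subtract_and_threshold(
    profiles: WindowProfile,
    refs: pd.DataFrame,
    band: float = 0.2,
) -> WindowProfile:
    """Subtract the reference-cell average baseline per window and flatten the
    zero band: values with ``|v| <= band`` (inclusive) become exactly 0."""
    ref_cells = refs.index[refs["is_reference"]]
    if len(ref_cells) == 0:
        raise ValueError("at least one reference cell is required")
    missing = set(ref_cells) - set(profiles.values.columns)
    if missing:
        raise ValueError(f"reference cell(s) missing from profile: {sorted(missing)[:3]}")
    baseline = profiles.values[list(ref_cells)].mean(axis=1)
    cn = profiles.values.sub(baseline, axis=0)
    arr = cn.to_numpy()
    arr[np.abs(arr) <= band] = 0.0
    return WindowProfile(profiles.windows.copy(), pd.DataFrame(
        arr, index=cn.index, columns=cn.columns
    ))


def gene_copy_number(
    cn: WindowProfile, ann: GeneAnnotation, halfwidth: int = 25
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-gene per-cell copy-number estimates.

    A gene's estimate is the mean of all window values whose gene-index range
    ``[center - halfwidth, center + halfwidth]`` on the gene's chromosome
    contains the gene.  Genes covered by no window get 0 with a coverage flag
    of False.

    Returns ``(estimates genes x cells, covered flags per gene)``.
    """
    ann_t = ann.table
    est_blocks, covered_flags, gene_order = [], [], []
    win_meta = cn.windows
    values = cn.values.to_numpy()
    n_cells = cn.values.shape[1]
    for chrom, genes in ann_t.groupby("chromosome", sort=False):
        sel = win_meta["chromosome"] == chrom
        centers = win_meta.loc[sel, "center_order_index"].to_numpy()
        block = values[sel.to_numpy()]
        order = np.argsort(centers)
        centers, block = centers[order], block[order]
        for _, g in genes.iterrows():
            gene_order.append(g["gene_id"])
            if len(centers) == 0:
                est_blocks.append(np.zeros(n_cells))
                covered_flags.append(False)
                continue
            lo = np.searchsorted(centers, g["order_index"] - halfwidth, "left")
            hi = np.searchsorted(centers, g["order_index"] + halfwidth, "right")
            if hi > lo:
                est_blocks.append(block[lo:hi].mean(axis=0))
                covered_flags.append(True)
            else:
                est_blocks.append(np.zeros(n_cells))
                covered_flags.append(False)
    estimates = pd.DataFrame(
        np.vstack(est_blocks), index=gene_order, columns=cn.values.columns
    )
    covered = pd.Series(covered_flags, index=gene_order, name="covered")
    return estimates, covered


def arm_mean_summary(cn: WindowProfile) -> pd.DataFrame:
    """Mean copy-number window value per (cell, chromosome arm).

    Windows are attributed to the arm of their center gene.  Arms with no
    window are absent from the output (flagged by omission).  Long format:
    columns cell_id, chromosome, arm, mean_cn.
    """
    joined = cn.values.copy()
    joined["chromosome"] = cn.windows["chromosome"].to_numpy()
    joined["arm"] = cn.windows["arm"].to_numpy()
    long = joined.melt(
        id_vars=["chromosome", "arm"], var_name="cell_id", value_name="cn"
    )
    out = (
        long.groupby(["cell_id", "chromosome", "arm"], sort=False)["cn"]
        .mean()
        .reset_index()
        .rename(columns={"cn": "mean_cn"})
    )
    return out


def flag_codeleted_cells(
    arm_means: pd.DataFrame,
    deleted_arms: set[Arm],
    cutoff: float = -0.2,
) -> pd.Series:
    """Boolean per-cell flag: every listed deleted arm's mean CN < cutoff.

    A cross-check of tumor status against embedding-derived labels; arms
    without windows make the flag undefined (raises).
    """
    flags = None
    for chrom, arm in sorted(deleted_arms):
        sel = (arm_means["chromosome"] == chrom) & (arm_means["arm"] == arm)
        if not sel.any():
            raise ValueError(f"arm {chrom}{arm} has no copy-number windows")
        per_cell = arm_means.loc[sel].set_index("cell_id")["mean_cn"] < cutoff
        flags = per_cell if flags is None else (flags & per_cell)
    return flags.rename("is_codeleted")


def compute_cnv_profiles(
    X: ExpressionMatrix,
    ann: GeneAnnotation,
    affected_arms: set[Arm],
    reference_arms: set[Arm],
    clip_bound: float = 3.0,
    halfwidth: int = 25,
    reference_p_threshold: float = 0.99,
    zero_band: float = 0.2,
):
    """Full copy-number stage: returns (cn_windows, gene_estimates, covered,
    reference_selection)."""
    from codelnet.genomics_io import restrict_annotation

    ann = restrict_annotation(ann, X.gene_ids)
    rel = center_and_clip(X, bound=clip_bound)
    smoothed = rolling_mean_profile(rel, ann, halfwidth=halfwidth)
    pvals = codeletion_pvalue_per_cell(X, ann, affected_arms, reference_arms)
    refs = select_reference_cells(pvals, threshold=reference_p_threshold)
    cn = baseline_subtract_and_threshold(smoothed, refs, band=zero_band)
    estimates, covered = gene_copy_number(cn, ann, halfwidth=halfwidth)
    return cn, estimates, covered, refs


def write_copy_number(cn: WindowProfile, estimates: pd.DataFrame,
                      covered: pd.Series, prefix) -> None:
    """Window-level and gene-level TSV outputs."""
    win = cn.windows.copy()
    win_out = pd.concat([win, cn.values], axis=1)
    win_out.to_csv(f"{prefix}.windows.tsv", sep="\t", index=False)
    long = estimates.rename_axis("gene_id").reset_index().melt(
        id_vars="gene_id", var_name="cell_id", value_name="cn_estimate"
    )
    long["covered"] = covered.reindex(long["gene_id"]).to_numpy()
    long.to_csv(f"{prefix}.genes.tsv", sep="\t", index=False)
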