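"""Cell subpopulation assignment from a 2-D embedding.

The embedding itself is delegated to UMAP with default settings; all bespoke
logic lives in the coordinate standardization and the threshold rules that
split cells into a large tumor subpopulation (SP1), a small nontumor
subpopulation (SP2), and optionally a putative subclone (SP3).
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd

from codelnet.genomics_io import ExpressionMatrix

logger = logging.getLogger(__name__)

EMBEDDING_COLUMNS = ["cell_id", "x_raw", "y_raw"]


def standardize_embedding(emb: pd.DataFrame) -> pd.DataFrame:
    """Scale raw embedding coordinates to [0, 1] per axis.

    ``v' = (v - min) / (max - min)``; both extremes are attained.  A zero
    span on either axis makes the embedding degenerate and is an error.
    """
    if len(emb) < 2:
        raise ValueError("need at least 2 cells to standardize an embedding")
    out = emb.copy()
    for axis in ("x", "y"):
        v = out[f"{axis}_raw"].to_numpy(dtype=float)
        span = v.max() - v.min()
        if span == 0:
            raise ValueError(f"degenerate embedding: zero span on {axis} axis")
        out[f"{axis}_scaled"] = (v - v.min()) / span
    return out


def assign_subpopulations(
    emb: pd.DataFrame,
    use_sp3: bool = False,
    outlier_cells: Iterable[str] = (),
) -> pd.DataFrame:
    """Assign each cell to SP1/SP2/SP3 (or outlier) by threshold rules on the
    standardized coordinates.

    Cells with scaled y < 0.5 are SP1 and those with scaled y > 0.5 are SP2.
    With ``use_sp3``, cells with scaled y < 0.5 and scaled x > 0.5 are SP3,
    overriding SP1.  Cells exactly on a threshold go to the "greater" side
    (SP2, respectively SP3).  Cells in ``outlier_cells`` are labeled
    ``outlier`` regardless of position.
    """
    for col in ("x_scaled", "y_scaled"):
        if col not in emb.columns:
            raise ValueError("embedding must be standardized first")
    outliers = set(outlier_cells)
    x = emb["x_scaled"].to_numpy(dtype=float)
    y = emb["y_scaled"].to_numpy(dtype=float)
    label = np.where(y >= 0.5, "SP2", "SP1")
    if use_sp3:
        label = np.where((y < 0.5) & (x >= 0.5), "SP3", label)
    out = emb.copy()
    out["label"] = label
    if outliers:
        out.loc[out["cell_id"].isin(outliers), "label"] = "outlier"
    return out


def compute_embedding(
    X: ExpressionMatrix, seed: int = 123
) -> pd.DataFrame:
    """Embed cells into 2-D with UMAP under default settings and a fixed seed.

    Deterministic for a given input and seed; the geometry of the embedding
    itself is not asserted anywhere, only the downstream threshold rules.
    The study convention fixes ``seed = 123``.
    """
    if X.n_cells < 10:
        raise ValueError("need at least 10 cells for a meaningful embedding")
    import umap  # deferred: slow import

    reducer = umap.UMAP(random_state=seed)
    coords = reducer.fit_transform(X.data.to_numpy().T)
    return pd.DataFrame(
        {
            "cell_id": list(X.cell_ids),
            "x_raw": coords[:, 0].astype(float),
            "y_raw": coords[:, 1].astype(float),
        }
    )


def marker_panel_summary(
    de: pd.DataFrame,
    markers: Mapping[str, Iterable[str]],
    orientation: str = "B_vs_A",
) -> pd.DataFrame:
    """Mean and standard deviation of log2 fold changes for named marker sets.

    ``de`` is a per-gene differential-expression table with columns
    ``gene_id`` and ``log_fc`` oriented as group A minus group B (see
    :func:`codelnet.diffexp.moderated_de`).  With the default orientation
    ``"B_vs_A"`` the sign is flipped so that the summary reads as the second
    group versus the first (e.g., SP2 versus SP1 when A=SP1, B=SP2).  Markers
    missing from the table are reported and excluded; a marker set that is
    empty after filtering is an error.
    """
    if orientation not in ("A_vs_B", "B_vs_A"):
        raise ValueError("orientation must be 'A_vs_B' or 'B_vs_A'")
    sign = 1.0 if orientation == "A_vs_B" else -1.0
    lfc = de.set_index("gene_id")["log_fc"]
    rows = []
    for name, genes in markers.items():
        genes = list(genes)
        present = [g for g in genes if g in lfc.index]
        missing = sorted(set(genes) - set(present))
        if missing:
            logger.warning("marker set %r: %d gene(s) missing: %s",
                           name, len(missing), missing)
        if not present:
            raise ValueError(f"marker set {name!r} has no gene in the DE table")
        vals = sign * lfc.loc[present].to_numpy(dtype=float)
        rows.append(
            {
                "set": name,
                "mean_log_fc": float(vals.mean()),
                "sd_log_fc": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                "n_genes": len(present),
                "n_missing": len(missing),
            }
        )
    return pd.DataFrame(rows)


def write_assignment(assign: pd.DataFrame, path) -> None:
    cols = ["cell_id", "label", "x_raw", "y_raw", "x_scaled", "y_scaled"]
    assign[cols].to_csv(path, sep="\t", index=False)


def read_assignment(path) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t")
    if "cell_id" not in t.columns or "label" not in t.columns:
        raise ValueError("assignment file needs cell_id and label columns")
    t["cell_id"] = t["cell_id"].astype(str)
    return t
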