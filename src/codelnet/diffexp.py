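"""Moderated-t differential expression between cell groups and Fisher-exact
pathway enrichment.

Single-cell expression tables are zero-inflated, so each gene is tested only
on the cells in which it was measured (value > 0).  Per-gene variances are
shrunk toward a common prior by empirical Bayes: the prior degrees of freedom
``d0`` and prior variance ``s0^2`` are estimated by a method of moments on the
log sample variances (matching the standard moderated-t formulation), the
posterior variance is ``s~^2 = (d0*s0^2 + d*s^2) / (d0 + d)``, and the
moderated t statistic has ``d0 + d`` degrees of freedom.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from codelnet.genomics_io import ExpressionMatrix, PathwayAnnotation

logger = logging.getLogger(__name__)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Empirical-Bayes variance moderation
# ---------------------------------------------------------------------------


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration on 1/y scale)."""
    if x <= 0:
        return np.inf
    # standard initialization: trigamma(y) ~ 1/y for large y
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_variance_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F prior for gene variances.

    Given sample variances ``s2`` with degrees of freedom ``df``, returns
    ``(d0, s0_sq)``.  ``d0 = inf`` when the observed spread of log variances
    is no larger than expected from sampling alone (complete shrinkage).
    Zero variances are excluded from estimation.
    """
    ok = (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        return np.inf, float(np.median(s2[s2 > 0])) if (s2 > 0).any() else 1.0
    s2, df = s2[ok], df[ok]
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - np.mean(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(s0_sq)


def moderated_de(
    X: ExpressionMatrix,
    cells_A,
    cells_B,
    prior_df: float | None = None,
    min_cells: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-group moderated-t differential expression on nonzero cells.

    For each gene, only cells with expression > 0 enter; genes with fewer
    than ``min_cells`` usable cells in either group are omitted with a reason
    code.  ``log_fc`` is group A minus group B on the means of the used cells.
    ``prior_df`` overrides the estimated prior degrees of freedom; 0 disables
    moderation (ordinary pooled-variance t).

    Returns ``(results, omitted)``; results columns: gene_id, log_fc, t, p, q,
    n_used_A, n_used_B.
    """
    cells_A, cells_B = list(cells_A), list(cells_B)
    if not cells_A or not cells_B:
        raise ValueError("both cell groups must be nonempty")
    if set(cells_A) & set(cells_B):
        raise ValueError("cell groups must be disjoint")
    A = X.data[cells_A].to_numpy(dtype=float)
    B = X.data[cells_B].to_numpy(dtype=float)
    maskA, maskB = A > 0, B > 0
    nA, nB = maskA.sum(axis=1), maskB.sum(axis=1)

    sumA = np.where(maskA, A, 0.0).sum(axis=1)
    sumB = np.where(maskB, B, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        meanA, meanB = sumA / nA, sumB / nB
        ssA = (np.where(maskA, A, 0.0) ** 2).sum(axis=1) - nA * meanA**2
        ssB = (np.where(maskB, B, 0.0) ** 2).sum(axis=1) - nB * meanB**2
    testable = (nA >= min_cells) & (nB >= min_cells)
    if not testable.any():
        raise ValueError("no gene is measurable in both groups")

    df = (nA + nB - 2).astype(float)
    s2 = np.where(testable & (df > 0), np.maximum(ssA + ssB, 0.0) / np.maximum(df, 1), np.nan)

    if prior_df == 0:
        d0, s0_sq = 0.0, 0.0
    elif prior_df is None:
        d0, s0_sq = estimate_variance_prior(s2[testable], df[testable])
    else:
        d0 = float(prior_df)
        _, s0_sq = estimate_variance_prior(s2[testable], df[testable])

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.full_like(df, np.inf)
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df

    with np.errstate(invalid="ignore", divide="ignore"):
        log_fc = meanA - meanB
        se = np.sqrt(s2_post * (1.0 / nA + 1.0 / nB))
        t = log_fc / se
    p = np.where(
        np.isinf(df_total),
        2.0 * stats.norm.sf(np.abs(t)),
        2.0 * stats.t.sf(np.abs(t), np.where(np.isfinite(df_total), df_total, 1.0)),
    )
    # degenerate zero-variance genes: infinite t -> p = 0 unless no difference
    zero_se = testable & (se == 0)
    p[zero_se & (log_fc == 0)] = 1.0
    p[zero_se & (log_fc != 0)] = 0.0

    genes = np.asarray(X.gene_ids)
    res = pd.DataFrame(
        {
            "gene_id": genes[testable],
            "log_fc": log_fc[testable],
            "t": t[testable],
            "p": p[testable],
            "n_used_A": nA[testable],
            "n_used_B": nB[testable],
        }
    )
    res["q"] = bh_fdr(res["p"].to_numpy())
    res = res[["gene_id", "log_fc", "t", "p", "q", "n_used_A", "n_used_B"]]

    omitted = pd.DataFrame(
        {
            "gene_id": genes[~testable],
            "reason": np.where(
                nA[~testable] < min_cells, "too_few_nonzero_A", "too_few_nonzero_B"
            ),
        }
    )
    return res, omitted


def select_de_genes(
    de: pd.DataFrame, q_max: float = 0.01, abs_lfc_min: float = 2.0
) -> tuple[set[str], set[str]]:
    """Split differentially expressed genes into under/over sets.

    Both boundaries are inclusive: q <= q_max and |log_fc| >= abs_lfc_min.
    ``under`` holds genes with log_fc <= -abs_lfc_min (lower in group A),
    ``over`` those with log_fc >= +abs_lfc_min.
    """
    sig = de["q"] <= q_max
    under = set(de.loc[sig & (de["log_fc"] <= -abs_lfc_min), "gene_id"])
    over = set(de.loc[sig & (de["log_fc"] >= abs_lfc_min), "gene_id"])
    return under, over


def fisher_pathway_enrichment(
    gene_set: set[str],
    pathways: PathwayAnnotation,
    universe: set[str],
    significance_q: float = 0.05,
) -> pd.DataFrame:
    """One-sided Fisher enrichment of ``gene_set`` in each pathway.

    Pathway members are intersected with the universe; pathways with no
    overlap are omitted (logged).  The 2x2 table per pathway is
    (in-pathway & set, in-pathway \\ set, out-pathway & set, out-pathway \\ set);
    the p-value is the upper (enrichment) tail.  BH correction runs across the
    tested pathways; the significance flag uses strict ``q < significance_q``.
    """
    if not universe:
        raise ValueError("empty universe")
    if not gene_set <= universe:
        raise ValueError("gene_set must be a subset of the universe")
    rows = []
    for _, pw in pathways.table.iterrows():
        members = set(pw["members"]) & universe
        if not members:
            logger.info("pathway %r has no gene in the universe; omitted",
                        pw["pathway_id"])
            continue
        a = len(members & gene_set)
        b = len(members - gene_set)
        c = len(gene_set - members)
        d = len(universe) - a - b - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append(
            {
                "pathway_class": pw["pathway_class"],
                "pathway_id": pw["pathway_id"],
                "a": a, "b": b, "c": c, "d": d,
                "odds_ratio": odds,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_fdr(out["p"].to_numpy())
        out["significant"] = out["q"] < significance_q
    return out
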