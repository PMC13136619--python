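"""Network-propagation impact scoring and candidate-gene statistics.

The impact a source gene exerts on a target is the sum, over all directed
paths up to a length cap, of the product of absolute edge coefficients along
the path, each step weighted by the downstream gene's prediction quality
(the positive part of its test-set correlation).  Summed onto the measured
genes of a pathway class (signaling or immune), compared per source gene to
the mean impact under degree-preserving random networks, and aggregated over
network instances with a paired one-sided t-test, this yields the per-tumor
candidate statistics; candidates must recur across tumors with consistent
tumor-versus-nontumor expression direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from codelnet.diffexp import bh_fdr
from codelnet.genomics_io import GeneAnnotation, PathwayAnnotation
from codelnet.network import (
    RegulatoryNetwork,
    permute_network_degree_preserving,
    predict_expression,
    prediction_quality,
)

logger = logging.getLogger(__name__)


@dataclass
class ImpactMatrix:
    """Source x target propagated impact scores for one network instance."""

    instance_id: int
    genes: list[str]
    scores: np.ndarray
    max_len: int
    converged: bool

    def __post_init__(self) -> None:
        if (self.scores < 0).any():
            raise ValueError("impact scores must be nonnegative")

    def impact(self, source: str, target: str) -> float:
        i = self.genes.index(source)
        j = self.genes.index(target)
        return float(self.scores[i, j])


def quality_weights(quality: pd.DataFrame) -> pd.Series:
    """Per-gene propagation weight: max(0, r_test); undefined r maps to 0."""
    r = quality["r"].fillna(0.0)
    return r.clip(lower=0.0)


def impact_matrix(
    net: RegulatoryNetwork,
    quality: pd.DataFrame,
    max_len: int = 5,
    tol: float = 1e-8,
) -> ImpactMatrix:
    """Truncated path-sum impacts between all gene pairs.

    The weighted adjacency is ``A[u, v] = |coef(u->v)| * qhat_v`` over the
    expression edges (copy-number covariates do not propagate); the impact is
    ``sum_{k=1..L} (A^k)[s, t]``, accumulated by repeated multiplication and
    early-stopped once the largest entry increment falls below ``tol``.
    Entries are nonnegative and monotone nondecreasing in ``L``.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    genes = net.genes
    pos = {g: i for i, g in enumerate(genes)}
    qhat = quality_weights(quality).reindex(genes).fillna(0.0).to_numpy()
    A = np.zeros((len(genes), len(genes)))
    edges = net.expression_edges()
    for _, e in edges.iterrows():
        A[pos[e["source"]], pos[e["target"]]] = abs(e["coefficient"]) * qhat[pos[e["target"]]]
    total = A.copy()
    power = A
    converged = max_len == 1
    for _ in range(2, max_len + 1):
        power = power @ A
        inc = power.max(initial=0.0)
        total += power
        if inc < tol:
            converged = True
            break
    return ImpactMatrix(net.instance_id, genes, total, max_len, converged)


def pathway_impact(
    impacts: ImpactMatrix,
    sources: list[str],
    pathways: PathwayAnnotation,
    classes: tuple[str, ...] = ("signaling", "immune"),
) -> pd.DataFrame:
    """Total impact of each source gene on the measured genes of each pathway
    class (union of that class's member sets, target != source).

    Long format: source, pathway_class, instance_id, total_impact.
    """
    genes = impacts.genes
    pos = {g: i for i, g in enumerate(genes)}
    rows = []
    for cls in classes:
        members = sorted(g for g in pathways.class_union(cls) if g in pos)
        if not members:
            raise ValueError(f"pathway class {cls!r} has no measured gene")
        cols = np.array([pos[g] for g in members])
        for s in sources:
            if s not in pos:
                continue
            i = pos[s]
            total = impacts.scores[i, cols].sum()
            if s in members:
                total -= impacts.scores[i, i]
            rows.append(
                {
                    "source": s,
                    "pathway_class": cls,
                    "instance_id": impacts.instance_id,
                    "total_impact": float(total),
                }
            )
    return pd.DataFrame(rows)


def direct_impacts_only(
    net: RegulatoryNetwork,
    quality: pd.DataFrame,
    sources: list[str],
    pathways: PathwayAnnotation,
    classes: tuple[str, ...] = ("signaling", "immune"),
) -> pd.DataFrame:
    """Pathway impacts from direct edges only (path length cap 1)."""
    return pathway_impact(
        impact_matrix(net, quality, max_len=1), sources, pathways, classes
    )


def random_baseline_impacts(
    net: RegulatoryNetwork,
    ann: GeneAnnotation,
    X_test: pd.DataFrame,
    CN_test: pd.DataFrame | None,
    sources: list[str],
    pathways: PathwayAnnotation,
    n_random: int = 10,
    seed: int = 0,
    max_len: int = 5,
    tol: float = 1e-8,
    classes: tuple[str, ...] = ("signaling", "immune"),
) -> pd.DataFrame:
    """Mean pathway impact per source gene under degree-preserving random
    networks of identical complexity.

    For each permutation the prediction quality is recomputed on the
    instance's own test cells, so the baseline sees the same quality-weighting
    mechanism as the observed network.
    Columns: source, pathway_class, instance_id, baseline_impact.
    """
    seeds = np.random.SeedSequence(seed).generate_state(n_random) % (2**31)
    acc: pd.DataFrame | None = None
    for s in seeds:
        perm = permute_network_degree_preserving(net, ann, seed=int(s))
        pred = predict_expression(perm, X_test, CN_test)
        qual = prediction_quality(pred, X_test)
        imp = impact_matrix(perm, qual, max_len=max_len, tol=tol)
        tab = pathway_impact(imp, sources, pathways, classes)
        acc = tab if acc is None else acc.assign(
            total_impact=acc["total_impact"] + tab["total_impact"]
        )
    out = acc.rename(columns={"total_impact": "baseline_impact"})
    out["baseline_impact"] = out["baseline_impact"] / n_random
    return out


def candidate_test(observed: np.ndarray, baseline: np.ndarray):
    """Paired one-sided t-test: observed impacts greater than baseline.

    ``observed``/``baseline`` are the per-instance totals and the matching
    per-instance random-baseline means.  Returns (mean difference, t, p).
    Degenerate zero-spread differences: p = 1 for no difference, p = 0 (with
    log note) for a constant positive shift.
    """
    observed = np.asarray(observed, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if observed.shape != baseline.shape or observed.ndim != 1:
        raise ValueError("observed and baseline must be paired 1-D vectors")
    d = observed - baseline
    n = len(d)
    sd = d.std(ddof=1) if n > 1 else 0.0
    mean_d = float(d.mean())
    if sd == 0:
        if mean_d == 0:
            return mean_d, 0.0, 1.0
        logger.info("degenerate paired test: constant difference %g", mean_d)
        return mean_d, np.inf if mean_d > 0 else -np.inf, 0.0 if mean_d > 0 else 1.0
    t = mean_d / (sd / np.sqrt(n))
    p = float(stats.t.sf(t, df=n - 1))
    return mean_d, float(t), p


def impact_statistics(impact_table: pd.DataFrame) -> pd.DataFrame:
    """Per (source, pathway class) paired statistics over network instances.

    ``impact_table`` columns: source, pathway_class, instance_id,
    total_impact, baseline_impact.  BH correction runs within each pathway
    class across the source genes (one tumor at a time).
    """
    rows = []
    for (src, cls), sub in impact_table.groupby(["source", "pathway_class"], sort=False):
        sub = sub.sort_values("instance_id")
        mean_d, t, p = candidate_test(
            sub["total_impact"].to_numpy(), sub["baseline_impact"].to_numpy()
        )
        rows.append(
            {
                "source": src,
                "pathway_class": cls,
                "n_instances": len(sub),
                "mean_observed": sub["total_impact"].mean(),
                "mean_baseline": sub["baseline_impact"].mean(),
                "mean_difference": mean_d,
                "t": t,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    for cls, idx in out.groupby("pathway_class").groups.items():
        out.loc[idx, "q"] = bh_fdr(out.loc[idx, "p"].to_numpy())
    return out


def select_candidates(
    stats_per_tumor: dict[str, pd.DataFrame],
    de_directions: dict[str, pd.Series],
    ann: GeneAnnotation | None = None,
    q_max: float = 0.1,
    min_recurrence: int = 2,
) -> pd.DataFrame:
    """Recurrent candidate genes across tumors with consistent DE direction.

    A gene is selected for a pathway class iff its paired-impact q-value is
    <= ``q_max`` (inclusive) in at least ``min_recurrence`` tumors and the
    sign of its tumor-versus-nontumor log fold change is identical across
    every tumor where it is measured.  Genes missing a direction in some
    tumor are evaluated over the available tumors and flagged.  Output is
    invariant to the order of the tumors.
    """
    if len(stats_per_tumor) < 2:
        raise ValueError("need at least 2 tumors for recurrence filtering")
    tumors = sorted(stats_per_tumor)
    rows = []
    all_pairs = set()
    for tumor in tumors:
        s = stats_per_tumor[tumor]
        all_pairs |= set(zip(s["source"], s["pathway_class"]))
    arm_of = None
    if ann is not None:
        t = ann.table.set_index("gene_id")
        arm_of = (t["chromosome"].astype(str) + t["arm"]).to_dict()
    for gene, cls in sorted(all_pairs):
        qvals, hits = {}, 0
        for tumor in tumors:
            s = stats_per_tumor[tumor]
            row = s[(s["source"] == gene) & (s["pathway_class"] == cls)]
            if len(row):
                qvals[tumor] = float(row["q"].iloc[0])
                if qvals[tumor] <= q_max:
                    hits += 1
        dirs = {}
        for tumor in tumors:
            d = de_directions.get(tumor)
            if d is not None and gene in d.index and np.isfinite(d[gene]) and d[gene] != 0:
                dirs[tumor] = "up" if d[gene] > 0 else "down"
        consistent = len(set(dirs.values())) == 1 if dirs else False
        selected = hits >= min_recurrence and consistent
        rows.append(
            {
                "gene_id": gene,
                "arm": arm_of.get(gene, "") if arm_of else "",
                "pathway_class": cls,
                "recurrence": hits,
                "direction": next(iter(set(dirs.values()))) if consistent else "inconsistent" if dirs else "unavailable",
                "direction_missing_in": ",".join(t for t in tumors if t not in dirs),
                "selected": selected,
                **{f"q_{t}": qvals.get(t, np.nan) for t in tumors},
            }
        )
    return pd.DataFrame(rows)


def rank_permutation_test(
    de_region: pd.DataFrame,
    candidates: list[str],
    n_perm: int = 10000,
    seed: int = 0,
    plus_one: bool = False,
):
    """Are the candidate genes ranked unusually high in the region's
    differential-expression ordering?

    Region genes are ranked 1..N by ascending q, ties by ascending p, then by
    descending |log_fc|; the observed statistic is the mean rank of the
    candidates, the null draws equally many region genes uniformly without
    replacement.  p is the fraction of draws with mean rank <= observed
    (optionally with the +1 correction).
    Returns (observed mean rank, null mean rank, p).
    """
    missing = sorted(set(candidates) - set(de_region["gene_id"]))
    if missing:
        raise ValueError(f"candidate(s) not in the region gene list: {missing}")
    ranked = de_region.assign(abs_lfc=de_region["log_fc"].abs()).sort_values(
        ["q", "p", "abs_lfc"], ascending=[True, True, False], kind="mergesort"
    )
    rank = pd.Series(np.arange(1, len(ranked) + 1), index=ranked["gene_id"])
    observed = float(rank.loc[list(candidates)].mean())
    rng = np.random.default_rng(seed)
    k, N = len(candidates), len(rank)
    draws = np.empty(n_perm)
    ranks = rank.to_numpy()
    for i in range(n_perm):
        draws[i] = ranks[rng.choice(N, size=k, replace=False)].mean()
    hits = int((draws <= observed).sum())
    p = (hits + 1) / (n_perm + 1) if plus_one else hits / n_perm
    return observed, float(draws.mean()), float(p)


def group_impact_comparison(candidate_impacts, other_impacts):
    """One-sided Welch two-sample t-test: candidate impacts > other impacts.

    Returns (candidate mean, other mean, t, p).
    """
    a = np.asarray(candidate_impacts, dtype=float)
    b = np.asarray(other_impacts, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 genes")
    res = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
    return float(a.mean()), float(b.mean()), float(res.statistic), float(res.pvalue)
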