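"""Self-contained evaluation studies on synthetic data.

Each function generates its inputs from a seed, runs the relevant pipeline
stages, and measures recovery against the known ground truth.  The studies
back both the test suite and the reproduction script; problem sizes are the
generator defaults unless noted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from codelnet import cnv as cnv_mod
from codelnet import simulation as sim
from codelnet.genomics_io import PipelineConfig
from codelnet.network import (
    GeneModel,
    PREDICTOR_COLUMNS,
    RegulatoryNetwork,
    learn_network,
    predict_expression,
    prediction_quality,
    split_train_test,
)
from codelnet.propagation import (
    impact_matrix,
    impact_statistics,
    pathway_impact,
    random_baseline_impacts,
)

DELETED = {("chr1", "p"), ("chr4", "q")}
SISTERS = {("chr1", "q"), ("chr4", "p")}


# ---------------------------------------------------------------------------
# Propagation oracle
# ---------------------------------------------------------------------------


def enumerate_path_impacts(adjacency: np.ndarray, max_len: int) -> np.ndarray:
    """Brute-force oracle: sum over every directed path of length 1..L of the
    product of edge weights, by explicit depth-first path extension."""
    n = adjacency.shape[0]
    total = np.zeros((n, n))
    succ = [np.flatnonzero(adjacency[u]) for u in range(n)]

    def extend(start: int, node: int, weight: float, length: int) -> None:
        for v in succ[node]:
            w = weight * adjacency[node, v]
            total[start, v] += w
            if length + 1 < max_len:
                extend(start, v, w, length + 1)

    for s in range(n):
        extend(s, s, 1.0, 0)
    return total


def propagation_oracle_check(
    n_graphs: int = 200, n_nodes: int = 8, max_len: int = 5, seed: int = 0
) -> float:
    """Maximum absolute deviation between the impact-matrix computation and
    exhaustive path enumeration over random directed graphs."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    genes = [f"n{i}" for i in range(n_nodes)]
    for _ in range(n_graphs):
        density = rng.uniform(0.1, 0.5)
        A_mask = rng.random((n_nodes, n_nodes)) < density
        np.fill_diagonal(A_mask, False)
        coefs = rng.uniform(-1.0, 1.0, size=(n_nodes, n_nodes)) * A_mask
        qhat = rng.uniform(0.0, 1.0, size=n_nodes)
        net = _network_from_matrix(genes, coefs)
        quality = pd.DataFrame({"r": qhat, "defined": True}, index=genes)
        imp = impact_matrix(net, quality, max_len=max_len, tol=0.0)
        oracle = enumerate_path_impacts(np.abs(coefs) * qhat[None, :], max_len)
        worst = max(worst, float(np.max(np.abs(imp.scores - oracle))))
    return worst


def _network_from_matrix(
    genes: list[str],
    coefs: np.ndarray,
    train_cells=("c1", "c2"),
    test_cells=("c3",),
    instance_id: int = 0,
) -> RegulatoryNetwork:
    """Assemble a RegulatoryNetwork directly from a coefficient matrix
    (entry [u, v] = coefficient of edge u -> v)."""
    models = {}
    for j, g in enumerate(genes):
        rows = [
            {"predictor_id": genes[i], "kind": "expression",
             "coefficient": float(coefs[i, j]), "p": 0.0, "q": 0.0}
            for i in np.flatnonzero(coefs[:, j])
        ]
        models[g] = GeneModel(g, 0.0, pd.DataFrame(rows, columns=PREDICTOR_COLUMNS))
    unit = pd.Series(1.0, index=genes)
    return RegulatoryNetwork(
        instance_id=instance_id, seed=0,
        train_cells=list(train_cells), test_cells=list(test_cells),
        models=models,
        train_mean=pd.Series(0.0, index=genes), train_sd=unit,
        cn_mean=None, cn_sd=None,
    )


# ---------------------------------------------------------------------------
# CNV recovery
# ---------------------------------------------------------------------------


def cnv_recovery_study(seed: int = 0) -> dict:
    """Copy-number stage on a default simulation; ground-truth comparison.

    Returns deleted-arm negativity (fraction of tumor cells whose mean
    deleted-arm gene estimate is negative, and the fraction of deleted genes
    negative in >= 90% of tumor cells), the median absolute estimate on
    neutral arms, reference-selection specificity, and the tumor-flag
    agreement of the arm-mean summary.
    """
    ann = sim.simulate_genome(seed=seed)
    truth = sim.simulate_network(ann, seed=seed)
    ds = sim.simulate_cells(truth, seed=seed)
    cn, est, covered, refs = cnv_mod.compute_cnv_profiles(
        ds.expression, ann, DELETED, SISTERS
    )
    tumor = list(ds.labels.index[ds.labels == "tumor"])
    deleted = [g for g in ds.truth.deleted_genes if g in est.index]
    neutral = [g for g in est.index if g not in set(deleted)]

    sel = refs.index[refs["is_reference"]]
    specificity = float((ds.labels.loc[sel] == "normal").mean())
    cell_neg = float((est.loc[deleted, tumor].mean(axis=0) < 0).mean())
    gene_neg90 = float(((est.loc[deleted, tumor] < 0).mean(axis=1) >= 0.9).mean())
    neutral_med = float(np.median(np.abs(est.loc[neutral].to_numpy())))

    arm_means = cnv_mod.arm_mean_summary(cn)
    flag = cnv_mod.flag_codeleted_cells(arm_means, DELETED)
    agree = float(
        (flag.reindex(ds.labels.index) == (ds.labels == "tumor")).mean()
    )
    return {
        "reference_specificity": specificity,
        "tumor_cells_deleted_arm_negative": cell_neg,
        "deleted_genes_negative_in_90pct_cells": gene_neg90,
        "neutral_median_abs_cn": neutral_med,
        "tumor_flag_agreement": agree,
        "n_cells": int(ds.expression.n_cells),
    }


def null_welch_calibration(n_cells: int = 1000, n_genes_per_arm: int = 100,
                           seed: int = 0) -> float:
    """KS p-value for uniformity of the per-cell co-deletion test under the
    null: every gene shares one mean, noise i.i.d., no deletion."""
    from scipy import stats

    from codelnet.cnv import codeletion_pvalue_per_cell
    from codelnet.genomics_io import ExpressionMatrix, GeneAnnotation

    rng = np.random.default_rng(seed)
    rows = []
    for chrom in ("chr1", "chr4"):
        for i in range(2 * n_genes_per_arm):
            rows.append(
                {
                    "gene_id": f"{chrom}_g{i:03d}",
                    "chromosome": chrom,
                    "arm": "p" if i < n_genes_per_arm else "q",
                    "start_bp": (i + 1) * 1000,
                    "end_bp": (i + 1) * 1000 + 500,
                }
            )
    ann = GeneAnnotation(pd.DataFrame(rows))
    genes = list(ann.gene_ids)
    X = ExpressionMatrix(
        pd.DataFrame(
            rng.normal(5.0, 1.0, size=(len(genes), n_cells)).clip(min=0.0),
            index=genes,
            columns=[f"cell{i}" for i in range(n_cells)],
        )
    )
    p = codeletion_pvalue_per_cell(X, ann, DELETED, SISTERS)
    return float(stats.kstest(p.to_numpy(), "uniform").pvalue)


# ---------------------------------------------------------------------------
# Network recovery
# ---------------------------------------------------------------------------


def network_recovery_study(
    n_seeds: int = 10, seed: int = 0, config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Learn one network per seed on the default simulation and evaluate edge
    and dosage-covariate recovery against the ground truth.

    Learning uses all simulated cells with the true copy-number covariate,
    which is what gives the covariate the between-cell variation the dosage
    signal needs (see methods note).
    """
    config = config or PipelineConfig()
    rows = []
    base = np.random.SeedSequence(seed).generate_state(n_seeds) % (2**31)
    for s in base:
        s = int(s)
        ann = sim.simulate_genome(seed=s)
        truth = sim.simulate_network(ann, seed=s)
        ds = sim.simulate_cells(truth, seed=s)
        net = learn_network(ds.expression, ds.cn_true, ann, config, seed=s)
        rows.append({"seed": s, **sim.evaluate_recovery(truth, [net])})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Planted-impact recovery
# ---------------------------------------------------------------------------


def planted_impact_study(
    n_replicates: int = 10,
    seed: int = 0,
    n_instances: int = 10,
    n_random: int = 10,
    n_planted: int = 3,
    n_null_sources: int = 12,
    pathway_fraction: float = 0.3,
) -> dict:
    """Can the impact statistics recover sources wired into a pathway?

    Per replicate, a synthetic genome carries planted source genes on the
    deleted arm, each wired directly to ``pathway_fraction`` of the signaling
    pathway genes, plus unconnected null sources and background edges among
    other genes.  Network instances are assembled from the ground truth with
    per-instance coefficient jitter, cells are simulated from the same
    model, and the full observed-versus-random-baseline paired statistics are
    computed.  Returns the selection rates (q <= 0.1) for planted and null
    sources.
    """
    master = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    planted_hits = null_hits = planted_total = null_total = 0
    for rep_seed in map(int, master):
        rng = np.random.default_rng(rep_seed)
        ann = sim.simulate_genome(n_chrom=2, genes_per_arm=40, seed=rep_seed)
        genes = list(ann.gene_ids)
        arm_genes = ann.arm_genes("chr1", "p")
        planted = list(arm_genes[:n_planted])
        nulls = list(arm_genes[n_planted: n_planted + n_null_sources])

        other = [g for g in genes if g not in set(arm_genes)]
        pathway_genes = sorted(rng.choice(other, size=30, replace=False))
        pathways = _pathway_annotation(pathway_genes)
        k = max(1, int(round(pathway_fraction * len(pathway_genes))))

        edges = []
        for s in planted:
            targets = rng.choice(pathway_genes, size=k, replace=False)
            for t in targets:
                edges.append((s, t, rng.uniform(0.5, 0.9) * rng.choice([-1, 1])))
        gene_rank = {g: i for i, g in enumerate(genes)}
        for _ in range(40):  # background edges give the permutation material
            u, v = rng.choice(other, size=2, replace=False)
            if gene_rank[u] > gene_rank[v]:
                u, v = v, u  # orient low -> high rank: background stays acyclic
            edges.append((u, v, rng.uniform(0.3, 0.8) * rng.choice([-1, 1])))

        truth_edges = pd.DataFrame(edges, columns=["source", "target", "beta"])
        truth = sim.SyntheticGroundTruth(
            annotation=ann,
            edges=truth_edges.drop_duplicates(subset=["source", "target"]),
            alpha=pd.Series(0.0, index=genes),
            mu=pd.Series(5.0, index=genes),
            deleted_arms=frozenset({("chr1", "p")}),
            seed=rep_seed,
            exclusion=0,  # planted edges are intentionally local-free anyway
        )
        ds = sim.simulate_cells(truth, n_tumor=120, n_normal=0,
                                deletion_shift=0.0, sigma=0.3, seed=rep_seed)

        sources = planted + nulls
        tables = []
        for j in range(n_instances):
            inst_rng = np.random.default_rng(rep_seed * 1000 + j)
            jitter = truth_edges.copy()
            jitter["beta"] = jitter["beta"] * inst_rng.uniform(0.9, 1.1, len(jitter))
            train, test = split_train_test(
                list(ds.expression.cell_ids), 2 / 3, seed=rep_seed * 1000 + j
            )
            net = _network_from_truth(ds, jitter, train, test, instance_id=j)
            X_test = ds.expression.data[test]
            pred = predict_expression(net, X_test, None)
            quality = prediction_quality(pred, X_test)
            imp = impact_matrix(net, quality, max_len=5)
            observed = pathway_impact(imp, sources, pathways,
                                      classes=("signaling",))
            baseline = random_baseline_impacts(
                net, ann, X_test, None, sources, pathways,
                n_random=n_random, seed=rep_seed * 1000 + j,
                classes=("signaling",),
            )
            tables.append(
                observed.merge(baseline, on=["source", "pathway_class", "instance_id"])
            )
        stats = impact_statistics(pd.concat(tables, ignore_index=True))
        selected = set(stats.loc[stats["q"] <= 0.1, "source"])
        planted_hits += len(selected & set(planted))
        null_hits += len(selected & set(nulls))
        planted_total += len(planted)
        null_total += len(nulls)
    return {
        "planted_selection_rate": planted_hits / planted_total,
        "null_selection_rate": null_hits / null_total,
        "n_replicates": n_replicates,
    }


def _pathway_annotation(pathway_genes: list[str]):
    from codelnet.genomics_io import PathwayAnnotation

    half = len(pathway_genes) // 2
    return PathwayAnnotation(
        pd.DataFrame(
            [
                {"pathway_id": "signaling_1", "pathway_class": "signaling",
                 "members": frozenset(pathway_genes[:half])},
                {"pathway_id": "signaling_2", "pathway_class": "signaling",
                 "members": frozenset(pathway_genes[half:])},
                {"pathway_id": "immune_1", "pathway_class": "immune",
                 "members": frozenset(pathway_genes[:2])},
            ]
        )
    )


def _network_from_truth(ds, edges: pd.DataFrame, train, test, instance_id=0):
    """Network instance assembled from ground-truth edges; standardization
    statistics come from the training cells so predictions are well-scaled."""
    genes = list(ds.expression.gene_ids)
    data = ds.expression.data
    mean = data[train].mean(axis=1)
    sd = data[train].std(axis=1, ddof=0)
    models = {}
    by_target = edges.groupby("target")
    for g in genes:
        rows = []
        if g in by_target.groups:
            for _, e in by_target.get_group(g).iterrows():
                s_sd = sd[e["source"]]
                rows.append(
                    {
                        "predictor_id": e["source"], "kind": "expression",
                        # truth coefficients are per expression unit; models
                        # store units per predictor-sd
                        "coefficient": float(e["beta"] * (s_sd if s_sd > 0 else 1.0)),
                        "p": 0.0, "q": 0.0,
                    }
                )
        models[g] = GeneModel(g, float(mean[g]), pd.DataFrame(rows, columns=PREDICTOR_COLUMNS))
    return RegulatoryNetwork(
        instance_id=instance_id, seed=0,
        train_cells=list(train), test_cells=list(test),
        models=models,
        train_mean=mean, train_sd=sd.where(sd > 0, 1.0),
        cn_mean=None, cn_sd=None,
    )
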