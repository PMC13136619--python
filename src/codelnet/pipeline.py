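"""End-to-end pipeline orchestration.

Sequences the stages for one or more tumors: gene filtering and genomic
ordering, subpopulation labels (provided or embedding-derived), per-cell
copy-number profiles, differential expression and pathway enrichment,
variance filtering, repeated network inference with train/test splits,
degree-preserving baselines, propagation impact statistics, and recurrent
candidate selection.  Fully reproducible from the master seed; the manifest
records config, input digests, stage seeds, outputs, timings, and warnings.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from codelnet import cnv as cnv_mod
from codelnet import diffexp, genomics_io, network as net_mod, propagation
from codelnet import subpopulations as subpop
from codelnet.genomics_io import ExpressionMatrix, PipelineConfig

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


@dataclass
class RunManifest:
    config: dict
    inputs: dict = field(default_factory=dict)
    input_digests: dict = field(default_factory=dict)
    stage_seeds: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, default=str))


@dataclass
class TumorState:
    """In-memory artifacts of one tumor's run (for variants and inspection)."""

    name: str
    analysis: ExpressionMatrix          # filtered + ordered, all cells
    ann: genomics_io.GeneAnnotation     # analysis annotation
    labels: pd.Series
    cn_estimates: pd.DataFrame
    refs: pd.DataFrame
    de: pd.DataFrame
    network_X: ExpressionMatrix         # variance-filtered matrix used for learning
    networks: list = field(default_factory=list)
    qualities: list = field(default_factory=list)
    impact_table: pd.DataFrame | None = None
    stats: pd.DataFrame | None = None


@dataclass
class PipelineResult:
    manifest: RunManifest
    tumors: dict[str, TumorState]
    candidates: pd.DataFrame
    pathways: genomics_io.PathwayAnnotation
    full_ann: genomics_io.GeneAnnotation
    deleted_arms: set
    reference_arms: set


def _digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def derive_seed(master_seed: int, *keys: int) -> int:
    """Deterministic sub-seed from the master seed and stage keys (< 2^31)."""
    return int(np.random.SeedSequence([int(master_seed), *map(int, keys)])
               .generate_state(1)[0] % (2**31))


def _tumor_labels(inputs: dict, X: ExpressionMatrix, config: PipelineConfig,
                  manifest: RunManifest, tumor: str) -> pd.Series:
    if "labels" in inputs:
        assign = subpop.read_assignment(inputs["labels"])
        labels = assign.set_index("cell_id")["label"]
    else:
        seed = derive_seed(config.master_seed, 1)
        manifest.stage_seeds[f"{tumor}.embedding"] = seed
        emb = subpop.compute_embedding(X, seed=seed)
        emb = subpop.standardize_embedding(emb)
        assign = subpop.assign_subpopulations(emb)
        labels = assign.set_index("cell_id")["label"]
    missing = set(X.cell_ids) - set(labels.index)
    if missing:
        raise PipelineError("labels", f"cells without label: {sorted(missing)[:3]}")
    return labels.reindex(X.cell_ids)


def _run_tumor(
    tumor: str,
    t_index: int,
    inputs: dict,
    ann_full: genomics_io.GeneAnnotation,
    pathways: genomics_io.PathwayAnnotation,
    config: PipelineConfig,
    deleted_arms: set,
    reference_arms: set,
    manifest: RunManifest,
    out: Path,
    tumor_label: str = "SP1",
    nontumor_label: str = "SP2",
) -> TumorState:
    t0 = time.perf_counter()
    X = genomics_io.read_expression_matrix(inputs["expression"])
    X = genomics_io.filter_low_expression_genes(X, config.expr_filter_threshold)
    X = genomics_io.order_genes_genomically(X, ann_full)
    ann = genomics_io.restrict_annotation(ann_full, X.gene_ids)
    logger.info("%s: %d genes pass the aggregate filter (threshold %.3g)",
                tumor, X.n_genes, config.expr_filter_threshold)

    labels = _tumor_labels(inputs, X, config, manifest, tumor)

    cn_windows, cn_est, covered, refs = cnv_mod.compute_cnv_profiles(
        X, ann, deleted_arms, reference_arms,
        clip_bound=config.clip_bound,
        halfwidth=config.window_halfwidth,
        reference_p_threshold=config.reference_p_threshold,
        zero_band=config.zero_band,
    )
    cnv_mod.write_copy_number(cn_windows, cn_est, covered, out / f"{tumor}.cnv")

    cells_A = list(labels.index[labels == tumor_label])
    cells_B = list(labels.index[labels == nontumor_label])
    if not cells_A or not cells_B:
        raise PipelineError("diffexp", f"{tumor}: empty {tumor_label}/{nontumor_label} group")
    de, omitted = diffexp.moderated_de(X, cells_A, cells_B)
    de.to_csv(out / f"{tumor}.de.tsv", sep="\t", index=False)
    under, over = diffexp.select_de_genes(de, config.de_q, config.de_abs_lfc)
    universe = set(de["gene_id"])
    enrich = pd.concat(
        [
            diffexp.fisher_pathway_enrichment(s, pathways, universe,
                                              config.enrichment_q).assign(direction=d)
            for s, d in ((under, "under"), (over, "over"))
        ],
        ignore_index=True,
    )
    enrich.to_csv(out / f"{tumor}.enrichment.tsv", sep="\t", index=False)

    # network stage: tumor cells only, imputed matrix when provided
    if "imputed_expression" in inputs:
        Xnet = genomics_io.read_expression_matrix(inputs["imputed_expression"])
        Xnet = genomics_io.order_genes_genomically(
            Xnet.subset_genes([g for g in Xnet.gene_ids if g in set(X.gene_ids)]),
            ann_full,
        )
    else:
        Xnet = X
    Xnet = Xnet.subset_cells([c for c in Xnet.cell_ids if labels.get(c) == tumor_label])
    Xnet = net_mod.filter_variable_genes(Xnet, config.variance_cutoff)
    net_ann = genomics_io.restrict_annotation(ann_full, Xnet.gene_ids)
    logger.info("%s: %d genes, %d tumor cells enter network inference "
                "(variance cutoff %.3g)", tumor, Xnet.n_genes, Xnet.n_cells,
                config.variance_cutoff)
    CN = cn_est.loc[Xnet.gene_ids]

    sources = [
        g for chrom, arm in sorted(deleted_arms)
        for g in net_ann.arm_genes(chrom, arm)
    ]
    if not sources:
        raise PipelineError("propagation", f"{tumor}: no measured gene on the affected arms")

    state = TumorState(tumor, X, ann, labels, cn_est, refs, de, Xnet)
    tables = []
    for j in range(config.n_network_instances):
        seed = derive_seed(config.master_seed, 10, t_index, j)
        manifest.stage_seeds[f"{tumor}.instance{j}.split"] = seed
        net = net_mod.learn_network(Xnet, CN, net_ann, config, seed=seed,
                                    instance_id=j)
        pred = net_mod.predict_expression(
            net, Xnet.data[net.test_cells], CN[net.test_cells]
        )
        quality = net_mod.prediction_quality(pred, Xnet.data[net.test_cells])
        imp = propagation.impact_matrix(
            net, quality, config.max_path_length, config.propagation_tolerance
        )
        observed = propagation.pathway_impact(imp, sources, pathways)
        perm_seed = derive_seed(config.master_seed, 20, t_index, j)
        manifest.stage_seeds[f"{tumor}.instance{j}.permutations"] = perm_seed
        baseline = propagation.random_baseline_impacts(
            net, net_ann, Xnet.data[net.test_cells], CN[net.test_cells],
            sources, pathways,
            n_random=config.n_random_networks_per_instance,
            seed=perm_seed,
            max_len=config.max_path_length,
            tol=config.propagation_tolerance,
        )
        merged = observed.merge(baseline, on=["source", "pathway_class", "instance_id"])
        tables.append(merged)
        pred_train = net_mod.predict_expression(
            net, Xnet.data[net.train_cells], CN[net.train_cells]
        )
        quality_train = net_mod.prediction_quality(
            pred_train, Xnet.data[net.train_cells]
        )
        quality.assign(
            instance_id=j, r_train=quality_train["r"]
        ).rename(columns={"r": "r_test"}).rename_axis("gene_id").reset_index()[
            ["instance_id", "gene_id", "r_train", "r_test"]
        ].to_csv(out / f"{tumor}.network{j}.quality.tsv", sep="\t", index=False)
        state.networks.append(net)
        state.qualities.append(quality)
        net_mod.write_network(net, out / f"{tumor}.network{j}")

    state.impact_table = pd.concat(tables, ignore_index=True)
    state.impact_table.to_csv(out / f"{tumor}.impacts.tsv", sep="\t", index=False)
    state.stats = propagation.impact_statistics(state.impact_table)
    state.stats.to_csv(out / f"{tumor}.impact_stats.tsv", sep="\t", index=False)
    manifest.timings[tumor] = round(time.perf_counter() - t0, 3)
    return state


def run_pipeline(
    config: PipelineConfig,
    tumors: dict[str, dict],
    annotation_path,
    pathways_path,
    out_dir,
    deleted_arms: set,
    reference_arms: set,
) -> PipelineResult:
    """Run the full chain for every tumor and select recurrent candidates.

    ``tumors`` maps tumor name -> {"expression": path, optional "labels",
    optional "imputed_expression"}.  Halts at the first hard error, naming
    the failing stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.as_dict())
    manifest.inputs = {
        "annotation": str(annotation_path),
        "pathways": str(pathways_path),
        **{f"{t}.{k}": str(v) for t, ins in tumors.items() for k, v in ins.items()},
    }
    for name, path in manifest.inputs.items():
        if not Path(path).exists():
            raise PipelineError("inputs", f"missing input file {name}: {path}")
        manifest.input_digests[name] = _digest(path)

    ann_full = genomics_io.read_gene_annotation(annotation_path)
    pathways = genomics_io.read_pathways_gmt(pathways_path)

    states: dict[str, TumorState] = {}
    for t_index, (tumor, inputs) in enumerate(sorted(tumors.items())):
        try:
            states[tumor] = _run_tumor(
                tumor, t_index, inputs, ann_full, pathways, config,
                deleted_arms, reference_arms, manifest, out,
            )
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"tumor:{tumor}", str(exc)) from exc

    candidates = _select(states, ann_full, config)
    candidates.to_csv(out / "candidates.tsv", sep="\t", index=False)
    manifest.outputs["candidates"] = str(out / "candidates.tsv")
    for name, path in manifest.inputs.items():
        after = _digest(path)
        if after != manifest.input_digests[name]:
            manifest.warnings.append(f"input {name} changed during the run")
    manifest.save(out / "manifest.json")
    return PipelineResult(
        manifest, states, candidates, pathways, ann_full,
        set(deleted_arms), set(reference_arms),
    )


def _select(states: dict[str, TumorState], ann_full, config) -> pd.DataFrame:
    stats_per_tumor = {t: s.stats for t, s in states.items()}
    de_directions = {
        t: s.de.set_index("gene_id")["log_fc"] for t, s in states.items()
    }
    if len(states) >= 2:
        return propagation.select_candidates(
            stats_per_tumor, de_directions, ann_full,
            q_max=config.candidate_q, min_recurrence=config.min_recurrence,
        )
    # single-tumor runs fall back to the per-tumor significance list
    t, s = next(iter(states.items()))
    out = s.stats.copy()
    out["selected"] = out["q"] <= config.candidate_q
    out["tumor"] = t
    return out


# ---------------------------------------------------------------------------
# Robustness variants
# ---------------------------------------------------------------------------


def run_variant(
    result: PipelineResult,
    variant: str,
    config: PipelineConfig,
    out_dir,
    raw_expression: dict[str, str] | None = None,
    external_expression: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Re-score impacts with alternative test data, networks unchanged.

    ``nonimputed_test``: per tumor, quality and impacts are recomputed on the
    raw (zero-containing) expression of each instance's test cells
    (``raw_expression`` maps tumor -> path; defaults to the analysis matrix
    already loaded, which equals the network matrix when no imputation was
    used).  ``external_tumor``: cells of an independent tumor
    (``external_expression`` maps tumor -> path) serve as the test set for
    the learned networks.

    Returns (candidate table, per-tumor statistics).
    """
    if variant not in ("nonimputed_test", "external_tumor"):
        raise ValueError(f"unknown variant {variant!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stats_per_tumor: dict[str, pd.DataFrame] = {}
    for t_index, (tumor, state) in enumerate(sorted(result.tumors.items())):
        genes = list(state.network_X.gene_ids)
        if variant == "nonimputed_test":
            if raw_expression and tumor in raw_expression:
                raw = genomics_io.read_expression_matrix(raw_expression[tumor])
            else:
                raw = state.analysis
            missing = [g for g in genes if g not in set(raw.gene_ids)]
            if missing:
                raise ValueError(
                    f"{tumor}: network genes missing from raw matrix: {missing[:5]}"
                )
            data_source = raw.data.loc[genes]
            cn_source = state.cn_estimates.loc[genes]
        else:
            if not external_expression or tumor not in external_expression:
                raise ValueError("external_tumor variant needs external_expression")
            ext = genomics_io.read_expression_matrix(external_expression[tumor])
            missing = [g for g in genes if g not in set(ext.gene_ids)]
            if missing:
                raise ValueError(
                    f"{tumor}: network genes missing from external tumor: "
                    f"{missing[:5]} ({len(missing)} total)"
                )
            data_source = ext.data.loc[genes]
            cn_source = None

        net_ann = genomics_io.restrict_annotation(result.full_ann, genes)
        sources = [
            g for chrom, arm in sorted(result.deleted_arms)
            for g in net_ann.arm_genes(chrom, arm)
        ]
        tables = []
        for j, net in enumerate(state.networks):
            if variant == "nonimputed_test":
                cells = net.test_cells
            else:
                cells = list(data_source.columns)
            X_test = data_source[cells]
            if cn_source is not None:
                CN_test = cn_source[cells]
            else:
                # external tumor: neutral copy-number covariate
                CN_test = pd.DataFrame(0.0, index=genes, columns=cells)
            pred = net_mod.predict_expression(net, X_test, CN_test)
            quality = net_mod.prediction_quality(pred, X_test)
            imp = propagation.impact_matrix(
                net, quality, config.max_path_length, config.propagation_tolerance
            )
            observed = propagation.pathway_impact(imp, sources, result.pathways)
            perm_seed = derive_seed(config.master_seed, 20, t_index, j)
            baseline = propagation.random_baseline_impacts(
                net, net_ann, X_test, CN_test, sources, result.pathways,
                n_random=config.n_random_networks_per_instance,
                seed=perm_seed,
                max_len=config.max_path_length,
                tol=config.propagation_tolerance,
            )
            tables.append(
                observed.merge(baseline, on=["source", "pathway_class", "instance_id"])
            )
        table = pd.concat(tables, ignore_index=True)
        stats_per_tumor[tumor] = propagation.impact_statistics(table)
        stats_per_tumor[tumor].to_csv(
            out / f"{tumor}.{variant}.impact_stats.tsv", sep="\t", index=False
        )

    de_directions = {
        t: s.de.set_index("gene_id")["log_fc"] for t, s in result.tumors.items()
    }
    if len(stats_per_tumor) >= 2:
        candidates = propagation.select_candidates(
            stats_per_tumor, de_directions, result.full_ann,
            q_max=config.candidate_q, min_recurrence=config.min_recurrence,
        )
    else:
        t, s = next(iter(stats_per_tumor.items()))
        candidates = s.copy()
        candidates["selected"] = candidates["q"] <= config.candidate_q
        candidates["tumor"] = t
    candidates.to_csv(out / f"candidates.{variant}.tsv", sep="\t", index=False)
    return candidates, stats_per_tumor
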