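# codelnet

Network-based prioritization of driver-gene candidates inside recurrent
arm-level co-deletions, from single-cell tumor transcriptomes.

## The problem

Some tumors are defined by a recurrent co-deletion — in oligodendroglioma,
the joint monoallelic loss of chromosome arms 1p and 19q.  Because the
deletion lowers the expression of *hundreds* of genes on both arms in every
tumor, differential expression alone cannot separate the few genes whose
dosage loss drives disease biology from the many passengers.  `codelnet`
addresses this with a network strategy for users analyzing genes×cells
expression matrices: identify the tumor cells, learn how each gene's
expression depends on the rest of the transcriptome and on its own copy
number, and ask which co-deleted genes exert unusually strong influence on
signaling and immune pathways through the learned network.

## The method in brief

1. **Copy number from expression.**  Per-gene centered, ±3-clipped
   expression is smoothed along the genome with a 51-gene rolling window.
   Cells without the co-deletion are found by a per-cell one-sided Welch
   test of affected-arm vs. sister-arm expression (reference cells:
   p ≥ 0.99); subtracting their average profile and zeroing the ±0.2 band
   gives per-cell copy-number profiles CN<sub>g,c</sub>.
2. **Tumor cells.**  A UMAP embedding (min–max standardized) is split by
   threshold rules into a large tumor subpopulation (SP1) and a small
   nontumor subpopulation (SP2, plus an optional SP3 subclone); marker
   panels and moderated-t DE between SP1 and SP2 validate the labels.
3. **Per-gene regulatory models.**  For each gene *g* over training tumor
   cells, x<sub>g</sub> ≈ β₀ + Σ<sub>u∉local(g)</sub> β<sub>u</sub>x<sub>u</sub> +
   γ·CN<sub>g</sub>, fit by lasso; each predictor entering the path gets a
   covariance-test p-value (Exp(1) reference), predictors with BH q ≤ 0.01
   are kept and refit by OLS.  Genes within ±50 positions on the same
   chromosome are excluded as predictors so dosage neighborhoods cannot pose
   as regulation.  Ten instances with independent 2/3–1/3 splits are
   validated by predicted-vs-measured correlation r<sub>g</sub> on held-out
   cells, against degree-preserving random networks.
4. **Propagated impact.**  With edge weights |β<sub>u→v</sub>|·max(0, r<sub>v</sub>),
   the impact of a co-deleted source on a pathway class is the path-sum
   Σ<sub>k≤5</sub>(A<sup>k</sup>) summed over the class's genes.  Per gene,
   observed impacts are compared to random-network baselines with a paired
   one-sided t-test (BH per tumor and class); candidates must pass q ≤ 0.1
   in ≥ 2 tumors with consistent SP1-vs-SP2 expression direction.

A synthetic-data module generates genomes, regulatory ground truth,
co-deleted tumor cell populations, and dropout, so every stage is testable
without downloads.  See `docs/methods.md` for assumptions, parameter
defaults, and limitations.

## Worked example

```python
from codelnet import simulation as sim, cnv
from codelnet.network import learn_network
from codelnet.genomics_io import PipelineConfig

ann = sim.simulate_genome(seed=7)                      # 4 chromosomes x 100 genes
truth = sim.simulate_network(ann, seed=7)              # 60-edge regulatory DAG
ds = sim.simulate_cells(truth, seed=7)                 # 400 tumor + 60 normal cells
print(f"simulated {ds.expression.n_genes} genes x {ds.expression.n_cells} cells "
      f"({(ds.labels == 'tumor').sum()} tumor, {(ds.labels == 'normal').sum()} normal)")

cn_w, est, covered, refs = cnv.compute_cnv_profiles(
    ds.expression, ann,
    affected_arms={("chr1", "p"), ("chr4", "q")},
    reference_arms={("chr1", "q"), ("chr4", "p")},
)
n_ref = int(refs["is_reference"].sum())
spec = (ds.labels.loc[refs.index[refs["is_reference"]]] == "normal").mean()
tumor = ds.labels.index[ds.labels == "tumor"]
deleted_mean = est.loc[ds.truth.deleted_genes, tumor].mean().mean()
print(f"reference cells: {n_ref} ({100*spec:.0f}% truly normal); "
      f"mean deleted-arm CN in tumor cells: {deleted_mean:.2f}")

net = learn_network(ds.expression, ds.cn_true, ann, PipelineConfig(), seed=7)
rec = sim.evaluate_recovery(truth, [net])
print(f"learned {rec['n_learned_edges']:.0f} edges: precision {rec['precision']:.2f}, "
      f"recall {rec['recall']:.2f}, dosage detection {rec['dosage_detection_rate']:.2f}")
```

prints:

```
simulated 400 genes x 460 cells (400 tumor, 60 normal)
reference cells: 60 (100% truly normal); mean deleted-arm CN in tumor cells: -0.55
learned 125 edges: precision 0.94, recall 1.00, dosage detection 0.97
```

meaning: the Welch rule recovered exactly the 60 cells without the deletion
as the copy-number baseline; tumor cells show the expected negative
copy-number footprint on the deleted arms (−0.55 relative log2 units, i.e.
well past the ±0.2 zero band); and of the 125 recovered regulatory links 94%
connect truly linked gene pairs, all 60 true links are found, and the
copy-number covariate is detected for 97% of the genes with a ground-truth
dosage effect.

The same chain runs end-to-end from files:

```bash
codelnet simulate --preset fast --seed 0 --out data/T1
codelnet run-all --data-dir data --tumors T1 \
    --annotation data/T1/genes.annotation.tsv --pathways data/T1/pathways.gmt \
    --deleted-arms chr1p,chr4q --reference-arms chr1q,chr4p \
    --seed 0 --out results/run
```

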