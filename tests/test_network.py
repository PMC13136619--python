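import numpy as np
import pandas as pd
import pytest

from codelnet import network as nw
from codelnet.evaluation import _network_from_matrix
from codelnet.genomics_io import ExpressionMatrix, PipelineConfig

from conftest import make_annotation


def fit(y, Z, **kwargs):
    kinds = pd.Series("expression", index=Z.columns)
    return nw.fit_gene_model(y, Z, kinds, PipelineConfig(), **kwargs)


class TestVarianceFilterAndSplit:
    def test_variance_filter_closed_form(self):
        # alternating 0/2 has sample variance ~1 >= 0.5; constants removed
        n = 40
        data = pd.DataFrame(
            {
                f"c{i}": [0.0 if i % 2 else 2.0, 3.0, 5.0 * (i % 2)]
                for i in range(n)
            },
            index=["alternating", "constant", "high"],
        )
        out = nw.filter_variable_genes(ExpressionMatrix(data), cutoff=0.5)
        assert list(out.gene_ids) == ["alternating", "high"]

    def test_split_rounding_and_determinism(self):
        cells = [f"c{i}" for i in range(9)]
        tr1, te1 = nw.split_train_test(cells, 2 / 3, seed=5)
        tr2, te2 = nw.split_train_test(cells, 2 / 3, seed=5)
        assert (len(tr1), len(te1)) == (6, 3)
        assert tr1 == tr2 and te1 == te2
        assert sorted(tr1 + te1) == cells

    def test_split_frequency_across_seeds(self):
        cells = [f"c{i}" for i in range(30)]
        counts = {c: 0 for c in cells}
        n_seeds = 300
        for s in range(n_seeds):
            tr, _ = nw.split_train_test(cells, 2 / 3, seed=s)
            for c in tr:
                counts[c] += 1
        freqs = np.array(list(counts.values())) / n_seeds
        assert np.all(np.abs(freqs - 2 / 3) < 0.1)


class TestCandidatePredictors:
    @pytest.fixture(scope="class")
    def two_chrom_ann(self):
        return make_annotation(
            [(f"a{i:03d}", "chrA", "p", (i + 1) * 10) for i in range(200)]
            + [(f"b{i:03d}", "chrB", "p", (i + 1) * 10) for i in range(60)]
        )

    def test_window_arithmetic(self, two_chrom_ann):
        preds = set(nw.candidate_predictor_set("a059", two_chrom_ann))
        # target order_index 60: excluded genes are order 10..110 on chrA
        for i in range(200):
            gene = f"a{i:03d}"
            if 9 <= i <= 109:
                assert gene not in preds
            else:
                assert gene in preds

    def test_other_chromosome_never_excluded(self, two_chrom_ann):
        preds = set(nw.candidate_predictor_set("a059", two_chrom_ann))
        assert all(f"b{i:03d}" in preds for i in range(60))

    def test_matches_bruteforce_distance_scan(self, two_chrom_ann):
        t = two_chrom_ann.table.set_index("gene_id")
        for target in ["a000", "a150", "b030"]:
            expected = {
                g for g in t.index
                if g != target and not (
                    t.loc[g, "chromosome"] == t.loc[target, "chromosome"]
                    and abs(t.loc[g, "order_index"] - t.loc[target, "order_index"]) <= 50
                )
            }
            assert set(nw.candidate_predictor_set(target, two_chrom_ann)) == expected


class TestFitGeneModel:
    def test_noiseless_single_predictor_recovery(self, rng):
        n = 120
        Z = pd.DataFrame(rng.normal(size=(n, 25)),
                         columns=[f"z{i}" for i in range(25)])
        y = 2.0 * Z["z3"].to_numpy()
        model = fit(y, Z)
        assert list(model.predictors["predictor_id"]) == ["z3"]
        sd3 = Z["z3"].std(ddof=0)
        assert model.predictors["coefficient"].iloc[0] / sd3 == pytest.approx(2.0, rel=1e-6)

    def test_null_models_stay_empty_on_average(self, rng):
        retained = []
        for _ in range(60):
            Z = pd.DataFrame(rng.normal(size=(200, 100)),
                             columns=[f"z{i}" for i in range(100)])
            y = rng.normal(size=200)
            retained.append(len(fit(y, Z).predictors))
        assert np.mean(retained) < 1.0

    def test_two_predictor_recovery_with_noise(self, rng):
        hits = 0
        n_rep = 60
        for _ in range(n_rep):
            Z = pd.DataFrame(rng.normal(size=(300, 40)),
                             columns=[f"z{i}" for i in range(40)])
            y = (1.5 * Z["z0"] - 0.8 * Z["z1"] + rng.normal(0, 0.2, 300)).to_numpy()
            model = fit(y, Z)
            got = model.predictors.set_index("predictor_id")
            if {"z0", "z1"} <= set(got.index):
                sd0, sd1 = Z["z0"].std(ddof=0), Z["z1"].std(ddof=0)
                if (got.loc["z0", "coefficient"] / sd0 > 0
                        and got.loc["z1", "coefficient"] / sd1 < 0):
                    hits += 1
        assert hits / n_rep >= 0.95

    def test_degenerate_target_and_empty_predictors(self):
        Z = pd.DataFrame(np.random.default_rng(0).normal(size=(30, 5)),
                         columns=list("abcde"))
        model = fit(np.full(30, 2.0), Z)
        assert len(model.predictors) == 0
        assert "zero_variance_target" in model.flags
        model2 = fit(np.random.default_rng(1).normal(size=30),
                     pd.DataFrame(index=range(30)))
        assert len(model2.predictors) == 0

    @pytest.fixture(scope="class")
    def learned(self, default_truth, default_dataset):
        net = nw.learn_network(
            default_dataset.expression, default_dataset.cn_true,
            default_truth.annotation, PipelineConfig(), seed=3,
        )
        return net, default_dataset

    def test_retained_predictors_satisfy_q_threshold(self, default_truth, learned):
        cfg = PipelineConfig()
        net, _ = learned
        ann_t = default_truth.annotation.table.set_index("gene_id")
        for target, model in net.models.items():
            assert (model.predictors["q"] <= cfg.predictor_q).all()
            for _, r in model.expression_predictors.iterrows():
                assert r["predictor_id"] != target
                same = ann_t.loc[r["predictor_id"], "chromosome"] == \
                    ann_t.loc[target, "chromosome"]
                if same:
                    dist = abs(int(ann_t.loc[r["predictor_id"], "order_index"])
                               - int(ann_t.loc[target, "order_index"]))
                    assert dist > 50

    def test_train_quality_exceeds_test_quality_in_median(self, learned):
        net, ds = learned
        CN = ds.cn_true
        q = {}
        for cells in (net.train_cells, net.test_cells):
            X = ds.expression.data[cells]
            pred = nw.predict_expression(net, X, CN[cells])
            q[len(cells)] = nw.prediction_quality(pred, X)["r"]
        train_q, test_q = q[len(net.train_cells)], q[len(net.test_cells)]
        assert train_q.median() >= test_q.median()


class TestPrediction:
    def make_net(self):
        genes = ["a", "b", "c"]
        coefs = np.zeros((3, 3))
        coefs[0, 1] = 1.2   # a -> b
        coefs[2, 1] = -0.5  # c -> b
        net = _network_from_matrix(genes, coefs)
        net.train_mean = pd.Series({"a": 1.0, "b": 0.0, "c": 2.0})
        net.train_sd = pd.Series({"a": 2.0, "b": 1.0, "c": 0.5})
        net.models["b"].intercept = 3.0
        return net

    def test_hand_built_model_matches_manual_arithmetic(self):
        net = self.make_net()
        X = pd.DataFrame(
            {"c1": [3.0, 0.0, 2.5], "c2": [1.0, 0.0, 1.0],
             "c3": [5.0, 0.0, 2.0], "c4": [-1.0, 0.0, 3.0]},
            index=["a", "b", "c"],
        )
        pred = nw.predict_expression(net, X)
        # b_hat = 3 + 1.2*(a-1)/2 - 0.5*(c-2)/0.5
        for cell in X.columns:
            expected = 3.0 + 1.2 * (X.loc["a", cell] - 1.0) / 2.0 \
                - 0.5 * (X.loc["c", cell] - 2.0) / 0.5
            assert pred.loc["b", cell] == pytest.approx(expected)

    def test_intercept_only_is_constant(self):
        net = self.make_net()
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(3, 4)),
                         index=["a", "b", "c"],
                         columns=["c1", "c2", "c3", "c4"])
        pred = nw.predict_expression(net, X)
        assert pred.loc["a"].eq(0.0).all()  # model of 'a' has no predictors

    def test_missing_predictor_named(self):
        net = self.make_net()
        X = pd.DataFrame(np.zeros((2, 3)), index=["a", "b"],
                         columns=["c1", "c2", "c3"])
        with pytest.raises(KeyError, match="c"):
            nw.predict_expression(net, X)


class TestPredictionQuality:
    def test_perfect_and_inverted(self, rng):
        obs = pd.DataFrame(rng.normal(size=(4, 10)),
                           index=list("abcd"),
                           columns=[f"c{i}" for i in range(10)])
        q = nw.prediction_quality(obs, obs)
        np.testing.assert_allclose(q["r"], 1.0)
        q2 = nw.prediction_quality(-obs, obs)
        np.testing.assert_allclose(q2["r"], -1.0)

    def test_constant_prediction_flagged_undefined(self, rng):
        obs = pd.DataFrame(rng.normal(size=(1, 8)), index=["g"],
                           columns=[f"c{i}" for i in range(8)])
        pred = pd.DataFrame(np.full((1, 8), 2.0), index=["g"],
                            columns=obs.columns)
        q = nw.prediction_quality(pred, obs)
        assert not q["defined"].iloc[0]
        assert np.isnan(q["r"].iloc[0])

    def test_independent_vectors_have_small_median_r(self, rng):
        obs = pd.DataFrame(rng.normal(size=(100, 100)))
        pred = pd.DataFrame(rng.normal(size=(100, 100)))
        q = nw.prediction_quality(pred, obs)
        assert abs(q["r"].median()) < 0.2

    def test_too_few_cells_rejected(self):
        x = pd.DataFrame(np.ones((2, 2)))
        with pytest.raises(ValueError):
            nw.prediction_quality(x, x)


def random_network(rng, n_genes=30, n_edges=60):
    genes = [f"g{i:03d}" for i in range(n_genes)]
    coefs = np.zeros((n_genes, n_genes))
    while (coefs != 0).sum() < n_edges:
        i, j = rng.integers(0, n_genes, 2)
        if i != j:
            coefs[i, j] = rng.normal()
    return _network_from_matrix(genes, coefs), genes


def single_chrom_annotation(genes):
    # all genes far apart on distinct chromosomes: no local-exclusion
    # interference with the swap test
    return make_annotation(
        [(g, f"chr{i}", "p", 100) for i, g in enumerate(genes)]
    )


class TestDegreePreservingPermutation:
    def degree_seqs(self, net):
        edges = net.expression_edges()
        return (
            edges.groupby("source").size().to_dict(),
            edges.groupby("target").size().to_dict(),
        )

    def test_degrees_and_coefficients_preserved(self, rng):
        net, genes = random_network(rng)
        ann = single_chrom_annotation(genes)
        perm = nw.permute_network_degree_preserving(net, ann, seed=4)
        assert self.degree_seqs(net) == self.degree_seqs(perm)
        orig = sorted(net.expression_edges()["coefficient"])
        new = sorted(perm.expression_edges()["coefficient"])
        np.testing.assert_allclose(orig, new)

    def test_edges_actually_rewired(self, rng):
        net, genes = random_network(rng)
        ann = single_chrom_annotation(genes)
        perm = nw.permute_network_degree_preserving(net, ann, seed=4)
        e0 = set(map(tuple, net.expression_edges()[["source", "target"]].to_numpy()))
        e1 = set(map(tuple, perm.expression_edges()[["source", "target"]].to_numpy()))
        assert e0 != e1

    def test_two_edge_forced_swap(self):
        genes = ["a", "b", "c", "d"]
        coefs = np.zeros((4, 4))
        coefs[0, 1] = 0.5  # a -> b
        coefs[2, 3] = -0.7  # c -> d
        net = _network_from_matrix(genes, coefs)
        ann = single_chrom_annotation(genes)
        perm = nw.permute_network_degree_preserving(net, ann, seed=0, n_swaps=1)
        edges = set(map(tuple,
                        perm.expression_edges()[["source", "target"]].to_numpy()))
        assert edges == {("a", "d"), ("c", "b")}

    def test_coefficient_travels_with_source(self):
        genes = ["a", "b", "c", "d"]
        coefs = np.zeros((4, 4))
        coefs[0, 1] = 0.5
        coefs[2, 3] = -0.7
        net = _network_from_matrix(genes, coefs)
        ann = single_chrom_annotation(genes)
        perm = nw.permute_network_degree_preserving(net, ann, seed=0, n_swaps=1)
        edges = perm.expression_edges().set_index("source")
        assert edges.loc["a", "coefficient"] == 0.5
        assert edges.loc["c", "coefficient"] == -0.7

    def test_local_exclusion_respected_after_swap(self, rng):
        genes = [f"g{i:03d}" for i in range(40)]
        ann = make_annotation(
            [(g, "chrA", "p", (i + 1) * 10) for i, g in enumerate(genes)]
        )
        # only long-range edges are legal on one chromosome with +/-50:
        # no legal configuration exists, so test with exclusion 5 instead
        coefs = np.zeros((40, 40))
        placed = 0
        while placed < 30:
            i, j = rng.integers(0, 40, 2)
            if abs(i - j) > 5 and coefs[i, j] == 0:
                coefs[i, j] = rng.normal()
                placed += 1
        net = _network_from_matrix(genes, coefs)
        perm = nw.permute_network_degree_preserving(net, ann, seed=9, exclusion=5)
        t = ann.table.set_index("gene_id")
        for _, e in perm.expression_edges().iterrows():
            dist = abs(int(t.loc[e["source"], "order_index"])
                       - int(t.loc[e["target"], "order_index"]))
            assert dist > 5


class TestMedianComparison:
    def test_all_ties_convention(self):
        r = pd.Series([0.3, 0.5, 0.1])
        m1, m2, p, flag = nw.compare_median_correlations(r, r.copy())
        assert p == 1.0 and flag == "all_ties"

    def test_uniform_shift_is_significant(self, rng):
        r_rand = pd.Series(rng.uniform(-0.2, 0.2, size=100))
        r_orig = r_rand + 0.1
        m_o, m_r, p, _ = nw.compare_median_correlations(r_orig, r_rand)
        assert p < 1e-10
        assert m_o > m_r
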