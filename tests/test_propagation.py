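import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from codelnet import propagation as prop
from codelnet.evaluation import _network_from_matrix, enumerate_path_impacts
from codelnet.genomics_io import PathwayAnnotation


def quality_frame(genes, r=1.0):
    return pd.DataFrame({"r": r, "defined": True}, index=genes)


def pathway(genes, cls="signaling", pid="pw1"):
    return PathwayAnnotation(
        pd.DataFrame(
            [{"pathway_id": pid, "pathway_class": cls, "members": frozenset(genes)}]
        )
    )


class TestImpactMatrix:
    def chain(self):
        genes = ["a", "b", "c"]
        coefs = np.zeros((3, 3))
        coefs[0, 1] = 0.5
        coefs[1, 2] = -0.5  # sign must not matter: |beta| propagates
        return _network_from_matrix(genes, coefs), genes

    def test_chain_path_products(self):
        net, genes = self.chain()
        imp = prop.impact_matrix(net, quality_frame(genes), max_len=5)
        assert imp.impact("a", "b") == pytest.approx(0.5)
        assert imp.impact("a", "c") == pytest.approx(0.25)
        assert imp.impact("c", "a") == 0.0

    def test_len_one_is_direct_only(self):
        net, genes = self.chain()
        imp = prop.impact_matrix(net, quality_frame(genes), max_len=1)
        assert imp.impact("a", "c") == 0.0
        assert imp.impact("a", "b") == pytest.approx(0.5)

    def test_monotone_in_path_length_cap(self):
        rng = np.random.default_rng(3)
        genes = [f"n{i}" for i in range(8)]
        coefs = rng.normal(size=(8, 8)) * (rng.random((8, 8)) < 0.4)
        np.fill_diagonal(coefs, 0.0)
        net = _network_from_matrix(genes, coefs)
        q = quality_frame(genes, r=rng.uniform(0, 1, 8))
        prev = None
        for L in range(1, 6):
            imp = prop.impact_matrix(net, q, max_len=L, tol=0.0)
            assert (imp.scores >= 0).all()
            if prev is not None:
                assert (imp.scores >= prev - 1e-14).all()
            prev = imp.scores

    def test_matches_bruteforce_enumeration_on_random_graphs(self):
        rng = np.random.default_rng(17)
        genes = [f"n{i}" for i in range(7)]
        for _ in range(30):
            coefs = rng.normal(size=(7, 7)) * (rng.random((7, 7)) < 0.35)
            np.fill_diagonal(coefs, 0.0)
            qhat = rng.uniform(0, 1, 7)
            net = _network_from_matrix(genes, coefs)
            imp = prop.impact_matrix(net, quality_frame(genes, r=qhat),
                                     max_len=4, tol=0.0)
            oracle = enumerate_path_impacts(np.abs(coefs) * qhat[None, :], 4)
            np.testing.assert_allclose(imp.scores, oracle, atol=1e-10)

    def test_negative_quality_contributes_nothing(self):
        net, genes = self.chain()
        q = quality_frame(genes, r=[-0.5, -0.2, 1.0])
        imp = prop.impact_matrix(net, q, max_len=5)
        assert imp.impact("a", "b") == 0.0   # qhat_b = 0
        assert imp.impact("a", "c") == 0.0   # path through b carries weight 0

    def test_invalid_cap_rejected(self):
        net, genes = self.chain()
        with pytest.raises(ValueError):
            prop.impact_matrix(net, quality_frame(genes), max_len=0)


class TestPathwayImpact:
    def star(self):
        genes = ["hub", "t1", "t2", "t3", "other"]
        coefs = np.zeros((5, 5))
        coefs[0, 1], coefs[0, 2], coefs[0, 3] = 0.4, 0.6, 0.2
        return _network_from_matrix(genes, coefs), genes

    def test_star_totals_match_hand_sums(self):
        net, genes = self.star()
        imp = prop.impact_matrix(net, quality_frame(genes), max_len=5)
        out = prop.pathway_impact(imp, ["hub", "other"],
                                  pathway(["t1", "t2"]), classes=("signaling",))
        by = out.set_index("source")["total_impact"]
        assert by["hub"] == pytest.approx(1.0)  # 0.4 + 0.6
        assert by["other"] == 0.0

    def test_source_excluded_from_its_own_total(self):
        net, genes = self.star()
        imp = prop.impact_matrix(net, quality_frame(genes), max_len=5)
        out = prop.pathway_impact(imp, ["hub"], pathway(["hub", "t1"]),
                                  classes=("signaling",))
        assert out["total_impact"].iloc[0] == pytest.approx(0.4)

    def test_direct_only_equals_len_one(self):
        genes = ["a", "b", "c"]
        coefs = np.zeros((3, 3))
        coefs[0, 1] = 0.5
        coefs[1, 2] = 0.5
        net = _network_from_matrix(genes, coefs)
        q = quality_frame(genes)
        direct = prop.direct_impacts_only(net, q, ["a"], pathway(["c"]),
                                          classes=("signaling",))
        assert direct["total_impact"].iloc[0] == 0.0  # a->c needs 2 hops
        full = prop.pathway_impact(
            prop.impact_matrix(net, q, max_len=1), ["a"], pathway(["c"]),
            classes=("signaling",),
        )
        pd.testing.assert_frame_equal(direct, full)

    def test_missing_class_rejected(self):
        net, genes = self.star()
        imp = prop.impact_matrix(net, quality_frame(genes), max_len=2)
        with pytest.raises(ValueError, match="immune"):
            prop.pathway_impact(imp, ["hub"], pathway(["t1"]),
                                classes=("signaling", "immune"))


class TestCandidateTest:
    def test_identical_vectors_p_one(self):
        obs = np.array([1.0, 2.0, 3.0, 2.5])
        assert prop.candidate_test(obs, obs.copy())[2] == 1.0

    def test_matches_paired_t_oracle(self, rng):
        obs = rng.normal(2, 1, size=10)
        base = rng.normal(1, 1, size=10)
        mean_d, t, p = prop.candidate_test(obs, base)
        oracle = stats.ttest_rel(obs, base, alternative="greater")
        assert t == pytest.approx(oracle.statistic, rel=1e-12)
        assert p == pytest.approx(oracle.pvalue, rel=1e-12)

    def test_constant_positive_shift_with_noise_is_tiny_p(self, rng):
        d = 1.0 + rng.normal(0, 0.01, size=10)
        base = rng.normal(size=10)
        _, _, p = prop.candidate_test(base + d, base)
        assert p < 1e-8

    def test_degenerate_constant_difference(self):
        base = np.arange(10, dtype=float)
        mean_d, t, p = prop.candidate_test(base + 2.0, base)
        assert (mean_d, p) == (2.0, 0.0)


class TestSelectCandidates:
    def stats_frame(self, rows):
        return pd.DataFrame(
            [{"source": g, "pathway_class": c, "q": q, "mean_difference": 1.0}
             for g, c, q in rows]
        )

    def test_recurrence_and_direction_rules(self):
        stats_per_tumor = {
            "T1": self.stats_frame([("g1", "signaling", 0.05), ("g2", "signaling", 0.05)]),
            "T2": self.stats_frame([("g1", "signaling", 0.2), ("g2", "signaling", 0.05)]),
            "T3": self.stats_frame([("g1", "signaling", 0.08), ("g2", "signaling", 0.05)]),
        }
        directions = {
            "T1": pd.Series({"g1": -1.0, "g2": 1.0}),
            "T2": pd.Series({"g1": -2.0, "g2": -1.0}),
            "T3": pd.Series({"g1": -0.5, "g2": 1.0}),
        }
        out = prop.select_candidates(stats_per_tumor, directions).set_index("gene_id")
        assert out.loc["g1", "selected"]          # q<=0.1 in T1,T3; consistent down
        assert out.loc["g1", "recurrence"] == 2
        assert not out.loc["g2", "selected"]      # inconsistent directions
        assert out.loc["g2", "direction"] == "inconsistent"

    def test_invariant_to_tumor_ordering(self):
        stats_per_tumor = {
            "T1": self.stats_frame([("g1", "immune", 0.05)]),
            "T2": self.stats_frame([("g1", "immune", 0.09)]),
        }
        directions = {"T1": pd.Series({"g1": 1.0}), "T2": pd.Series({"g1": 2.0})}
        a = prop.select_candidates(stats_per_tumor, directions)
        b = prop.select_candidates(
            dict(reversed(list(stats_per_tumor.items()))),
            dict(reversed(list(directions.items()))),
        )
        pd.testing.assert_frame_equal(a, b)

    def test_missing_direction_flagged_not_fatal(self):
        stats_per_tumor = {
            "T1": self.stats_frame([("g1", "immune", 0.01)]),
            "T2": self.stats_frame([("g1", "immune", 0.01)]),
        }
        directions = {"T1": pd.Series({"g1": 1.0}), "T2": pd.Series(dtype=float)}
        out = prop.select_candidates(stats_per_tumor, directions)
        assert out["direction_missing_in"].iloc[0] == "T2"
        assert out["selected"].iloc[0]  # consistent over available tumors

    def test_fewer_than_two_tumors_rejected(self):
        with pytest.raises(ValueError):
            prop.select_candidates({"T1": self.stats_frame([])}, {})


class TestRankPermutation:
    def region(self, n=10):
        return pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n)],
                "q": np.linspace(0.001, 0.9, n),
                "p": np.linspace(0.0005, 0.8, n),
                "log_fc": np.linspace(3, -3, n),
            }
        )

    def test_top_candidates_give_minimal_p(self):
        de = self.region(60)
        obs, null, p = prop.rank_permutation_test(
            de, ["g0", "g1", "g2"], n_perm=2000, seed=1
        )
        assert obs == 2.0
        assert p <= 1 / 1000  # only the unique top combination reaches rank 2

    def test_null_mean_is_central_rank(self):
        de = self.region(12)
        _, null, _ = prop.rank_permutation_test(de, ["g3", "g7", "g11"],
                                                n_perm=4000, seed=2)
        assert null == pytest.approx((12 + 1) / 2, abs=0.15)

    def test_matches_exhaustive_enumeration(self):
        de = self.region(10)
        candidates = ["g1", "g4", "g6"]
        obs, _, p = prop.rank_permutation_test(de, candidates, n_perm=20000, seed=3)
        ranks = np.arange(1, 11)
        means = [np.mean(c) for c in itertools.combinations(ranks, 3)]
        exact = np.mean([m <= obs for m in means])
        assert p == pytest.approx(exact, abs=0.02)

    def test_unknown_candidate_named(self):
        with pytest.raises(ValueError, match="gX"):
            prop.rank_permutation_test(self.region(), ["gX"], n_perm=10, seed=0)


class TestGroupComparison:
    def test_identical_groups_symmetric(self, rng):
        vals = rng.normal(size=50)
        m1, m2, t, p = prop.group_impact_comparison(vals, vals.copy())
        assert p == pytest.approx(0.5, abs=1e-9)

    def test_shifted_candidates_significant(self, rng):
        other = rng.normal(0, 0.1, size=132)
        cand = rng.normal(1, 0.1, size=13)
        m1, m2, t, p = prop.group_impact_comparison(cand, other)
        assert p < 1e-10
        assert m1 > m2

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            prop.group_impact_comparison([1.0], [1.0, 2.0])


class TestRandomBaseline:
    def test_total_edge_mass_preserved_per_permutation(self, rng):
        from codelnet.network import permute_network_degree_preserving
        from conftest import make_annotation

        genes = [f"g{i:02d}" for i in range(20)]
        coefs = rng.normal(size=(20, 20)) * (rng.random((20, 20)) < 0.2)
        np.fill_diagonal(coefs, 0.0)
        net = _network_from_matrix(genes, coefs)
        ann = make_annotation([(g, f"chr{i}", "p", 100) for i, g in enumerate(genes)])
        perm = permute_network_degree_preserving(net, ann, seed=12)
        assert perm.expression_edges()["coefficient"].abs().sum() == pytest.approx(
            net.expression_edges()["coefficient"].abs().sum()
        )
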