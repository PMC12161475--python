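"""Footprint activity inference: weighted means, permutation NES, ssGSEA
projection (with an independent ECDF oracle) and expression preprocessing."""

import numpy as np
import pandas as pd
import pytest
from oracles import ssgsea_es_oracle
from scipy import stats

from crcprofiler import activity, synth
from crcprofiler.activity import SsgseaParams


def _net(edges):
    return pd.DataFrame(edges, columns=["source", "target", "weight"])


class TestFilterKinaseNetwork:
    def _edges(self, rows):
        return pd.DataFrame(rows, columns=["source", "target", "weight",
                                           "resources", "modification"])

    def test_protmapper_only_removed(self):
        edges = self._edges([("K1", "S1", 1.0, "ProtMapper",
                              "phosphorylation")])
        assert len(activity.filter_kinase_network(edges)) == 0

    def test_protmapper_confirmed_kept(self):
        edges = self._edges([("K1", "S1", 1.0, "ProtMapper;PhosphoSitePlus",
                              "phosphorylation")])
        assert len(activity.filter_kinase_network(edges)) == 1

    def test_non_phospho_modification_removed(self):
        edges = self._edges([("K1", "S1", 1.0, "SIGNOR", "ubiquitination"),
                             ("K1", "S2", 1.0, "SIGNOR", "dephosphorylation")])
        out = activity.filter_kinase_network(edges)
        assert out["target"].tolist() == ["S2"]

    def test_duplicates_removed(self):
        edges = self._edges([("K1", "S1", 1.0, "SIGNOR", "phosphorylation"),
                             ("K1", "S1", 1.0, "SIGNOR", "phosphorylation")])
        assert len(activity.filter_kinase_network(edges)) == 1


class TestWmean:
    def test_signed_example(self):
        stat = pd.Series({"g1": 2.0, "g2": -2.0})
        net = _net([("S", "g1", 1.0), ("S", "g2", -1.0)])
        out = activity.wmean(stat, net, min_size=1)
        assert out["S"] == pytest.approx(2.0)

    def test_zero_stats_zero_score(self):
        stat = pd.Series({"g1": 0.0, "g2": 0.0})
        net = _net([("S", "g1", 1.0), ("S", "g2", 1.0)])
        assert activity.wmean(stat, net, min_size=1)["S"] == 0.0

    def test_shift_linearity_with_unit_weights(self, rng):
        genes = [f"g{i}" for i in range(20)]
        stat = pd.Series(rng.normal(size=20), index=genes)
        net = _net([("S", g, 1.0) for g in genes[:8]])
        base = activity.wmean(stat, net, min_size=1)["S"]
        shifted = activity.wmean(stat + 3.0, net, min_size=1)["S"]
        assert shifted == pytest.approx(base + 3.0)

    def test_min_size_warning_empty(self):
        stat = pd.Series({"g1": 1.0})
        net = _net([("S", "g1", 1.0)])
        with pytest.warns(UserWarning, match="enough measured targets"):
            out = activity.wmean(stat, net, min_size=5)
        assert out.empty


class TestNormWmean:
    def test_same_seed_identical(self, rng):
        genes = [f"g{i}" for i in range(100)]
        stat = pd.Series(rng.normal(size=100), index=genes)
        net = _net([("S", g, 1.0) for g in genes[:20]])
        r1 = activity.norm_wmean(stat, net, n_perm=200, seed=9)
        r2 = activity.norm_wmean(stat, net, n_perm=200, seed=9)
        pd.testing.assert_frame_equal(r1, r2)

    def test_planted_shift_reaches_significance(self, rng):
        genes = [f"g{i}" for i in range(300)]
        stat = pd.Series(rng.normal(size=300), index=genes)
        targets = genes[:30]
        stat[targets] += 3.0
        net = _net([("S", g, 1.0) for g in targets])
        out = activity.norm_wmean(stat, net, n_perm=500, seed=0)
        assert out.loc[0, "nes"] >= 2.0
        assert out.loc[0, "p_perm"] <= 0.05

    def test_constant_stat_flags_unset_nes(self):
        genes = [f"g{i}" for i in range(30)]
        stat = pd.Series(1.0, index=genes)
        net = _net([("S", g, 1.0) for g in genes[:10]])
        with pytest.warns(UserWarning, match="zero-variance"):
            out = activity.norm_wmean(stat, net, n_perm=100, seed=0)
        assert np.isnan(out.loc[0, "nes"])


class TestPathwayScores:
    def test_top_n_covering_everything_matches_unrestricted(self, rng):
        genes = [f"g{i}" for i in range(50)]
        stat = pd.Series(rng.normal(size=50), index=genes)
        W = pd.DataFrame(rng.normal(size=(2, 50)),
                         index=["P1", "P2"], columns=genes)
        full = activity.pathway_scores(stat, W, top_n=50, n_perm=100, seed=3)
        unrestricted = activity.norm_wmean_matrix(stat, W, n_perm=100, seed=3)
        pd.testing.assert_frame_equal(full, unrestricted)

    def test_restriction_zeroes_small_weights(self, rng):
        genes = [f"g{i}" for i in range(40)]
        stat = pd.Series(rng.normal(size=40), index=genes)
        W = pd.DataFrame(np.concatenate([np.full(10, 5.0),
                                         np.full(30, 0.01)])[None, :],
                         index=["P"], columns=genes)
        out10 = activity.pathway_scores(stat, W, top_n=10, n_perm=50, seed=0,
                                        min_size=5)
        assert out10.loc[0, "n_targets_used"] == 10  # post-restriction
        exp = (stat[genes[:10]] * 5.0).sum() / (10 * 5.0)
        assert out10.loc[0, "score"] == pytest.approx(exp)

    def test_disjoint_pathways_independent(self, rng):
        genes = [f"g{i}" for i in range(40)]
        stat = pd.Series(rng.normal(size=40), index=genes)
        W1 = pd.DataFrame(0.0, index=["A", "B"], columns=genes)
        W1.loc["A", genes[:10]] = 1.0
        W1.loc["B", genes[20:30]] = 1.0
        W2 = W1.copy()
        W2.loc["B", genes[20:30]] = 2.5  # rescale the other pathway
        a1 = activity.pathway_scores(stat, W1, top_n=40, n_perm=50, seed=1)
        a2 = activity.pathway_scores(stat, W2, top_n=40, n_perm=50, seed=1)
        assert a1.loc[0, "score"] == pytest.approx(a2.loc[0, "score"])

    def test_top_n_below_min_size_rejected(self):
        with pytest.raises(ValueError):
            activity.pathway_scores(pd.Series(dtype=float),
                                    pd.DataFrame(), top_n=3, min_size=5)


class TestPerSampleActivities:
    def _setup(self, rng, n_samples=6):
        genes = [f"g{i}" for i in range(80)]
        expr = pd.DataFrame(rng.normal(size=(80, n_samples)), index=genes,
                            columns=[f"s{i}" for i in range(n_samples)])
        net = _net([("S", g, 1.0) for g in genes[:20]])
        return expr, net

    def test_duplicated_sample_columns_identical_nes(self, rng):
        expr, net = self._setup(rng)
        expr["s1"] = expr["s0"]
        nes, _ = activity.per_sample_activities(expr, net, n_perm=100, seed=0)
        assert nes["s0"].tolist() == nes["s1"].tolist()

    def test_constant_rows_dropped(self, rng):
        expr, net = self._setup(rng)
        expr.loc["g0"] = 5.0
        with pytest.warns(UserWarning, match="constant gene"):
            nes, _ = activity.per_sample_activities(expr, net, n_perm=100,
                                                    seed=0)
        assert nes.shape[1] == expr.shape[1]

    def test_too_few_samples_rejected(self, rng):
        expr, net = self._setup(rng, n_samples=2)
        with pytest.raises(ValueError, match="3 samples"):
            activity.per_sample_activities(expr, net)

    def test_planted_sample_group_recovered(self):
        net = synth.gen_regulon_network(n_sources=2, n_targets=30,
                                        n_genes=500, seed=4)
        counts, truth = synth.gen_expression_matrix(
            12, net, planted={"TF01": 2.0}, n_genes=500, seed=4)
        expr = activity.filter_normalize(counts)
        nes, mask = activity.per_sample_activities(expr, net, n_perm=300,
                                                   seed=4)
        in_group = nes.loc["TF01", truth["group"]]
        out_group = nes.loc["TF01", ~truth["group"]]
        assert in_group.mean() > 2.0
        assert out_group.mean() < 0.0


class TestSsgsea:
    def test_single_top_gene_worked_example(self):
        # 3 genes, set = {top gene}: P_in walks 1,1,1 and P_out 0,1/2,1,
        # so ES = 1 + 1/2 + 0 = 1.5 for any alpha
        expr = pd.DataFrame({"s1": [3.0, 2.0, 1.0]}, index=["a", "b", "c"])
        params = SsgseaParams(alpha=0.75, correction="none", n_perm=10,
                              min_size=1)
        scores, _ = activity.ssgsea(expr, {"top": ["a"]}, params, seed=0)
        assert scores.loc["top", "s1"] == pytest.approx(1.5)

    def test_small_overlap_skipped(self, rng):
        expr = pd.DataFrame(rng.normal(size=(30, 4)),
                            index=[f"g{i}" for i in range(30)],
                            columns=list("abcd"))
        with pytest.warns(UserWarning, match="min size"):
            scores, _ = activity.ssgsea(
                expr, {"tiny": ["g0", "g1"]},
                SsgseaParams(n_perm=10, min_size=10), seed=0)
        assert scores.empty

    def test_whole_matrix_set_skipped(self, rng):
        expr = pd.DataFrame(rng.normal(size=(12, 4)),
                            index=[f"g{i}" for i in range(12)],
                            columns=list("abcd"))
        with pytest.warns(UserWarning, match="every gene"):
            scores, _ = activity.ssgsea(
                expr, {"all": list(expr.index)},
                SsgseaParams(n_perm=10, min_size=10), seed=0)
        assert scores.empty

    def test_matches_bruteforce_oracle(self, rng):
        genes = [f"g{i}" for i in range(60)]
        expr = pd.DataFrame(rng.normal(size=(60, 3)), index=genes,
                            columns=["s1", "s2", "s3"])
        sets = {f"S{k}": list(rng.choice(genes, 15, replace=False))
                for k in range(5)}
        params = SsgseaParams(alpha=0.75, n_perm=10, min_size=10)
        scores, _ = activity.ssgsea(expr, sets, params, seed=0)
        # oracle works on the z-corrected values, like the implementation
        X = expr.to_numpy()
        Z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
        for j, s in enumerate(expr.columns):
            values = dict(zip(genes, Z[:, j]))
            for name, members in sets.items():
                expect = ssgsea_es_oracle(values, set(members), 0.75)
                assert scores.loc[name, s] == pytest.approx(expect,
                                                            abs=1e-9)

    def test_monotone_in_planted_shift(self, rng):
        genes = [f"g{i}" for i in range(50)]
        base = rng.normal(size=(50, 4))
        members = genes[:12]
        es = []
        for shift in (0.0, 1.0, 2.0):
            X = base.copy()
            X[:12, 0] += shift
            expr = pd.DataFrame(X, index=genes, columns=list("wxyz"))
            params = SsgseaParams(correction="none", n_perm=10, min_size=10)
            scores, _ = activity.ssgsea(expr, {"S": members}, params, seed=0)
            es.append(scores.loc["S", "w"])
        assert es[0] < es[1] < es[2]


class TestFilterNormalize:
    def test_boundary_five_vs_four_samples(self):
        df = pd.DataFrame([[10] * 5 + [0], [10] * 4 + [0, 0],
                           [100] * 6],
                          index=["keep", "drop", "high"],
                          columns=list("abcdef"))
        out = activity.filter_normalize(df)
        assert list(out.index) == ["keep", "high"]

    def test_all_pass_preserves_shape_and_cpm(self):
        df = pd.DataFrame([[100, 200], [300, 400], [600, 400]],
                          index=list("xyz"), columns=["a", "b"],
                          dtype=float)
        out = activity.filter_normalize(df, min_count=10, min_samples=2)
        assert out.shape == df.shape
        assert out.loc["x", "a"] == pytest.approx(np.log2(1e5 + 1))

    def test_zero_library_rejected(self):
        df = pd.DataFrame({"a": [0, 0], "b": [1, 2]})
        with pytest.raises(ValueError, match="zero library"):
            activity.filter_normalize(df, min_count=0, min_samples=0)


class TestContrastStatistic:
    def test_identical_means_zero(self):
        expr = pd.DataFrame([[1.0, 2.0, 1.0, 2.0]], index=["g"],
                            columns=list("abcd"))
        groups = pd.Series(["MSI", "MSI", "MSS", "MSS"], index=list("abcd"))
        assert activity.contrast_statistic(expr, groups)["g"] == 0.0

    def test_antisymmetric_under_group_swap(self, rng):
        expr = pd.DataFrame(rng.normal(size=(20, 8)),
                            index=[f"g{i}" for i in range(20)],
                            columns=list("abcdefgh"))
        g1 = pd.Series(["MSI"] * 4 + ["MSS"] * 4, index=expr.columns)
        g2 = pd.Series(["MSS"] * 4 + ["MSI"] * 4, index=expr.columns)
        t1 = activity.contrast_statistic(expr, g1)
        t2 = activity.contrast_statistic(expr, g2)
        np.testing.assert_allclose(t1, -t2, atol=1e-12)

    def test_matches_scipy_welch(self, rng):
        expr = pd.DataFrame(rng.normal(size=(15, 9)),
                            index=[f"g{i}" for i in range(15)],
                            columns=[f"s{i}" for i in range(9)])
        groups = pd.Series(["MSI"] * 4 + ["MSS"] * 5, index=expr.columns)
        mine = activity.contrast_statistic(expr, groups)
        ref = stats.ttest_ind(expr.iloc[:, :4], expr.iloc[:, 4:], axis=1,
                              equal_var=False).statistic
        np.testing.assert_allclose(mine, ref, atol=1e-10)

    def test_small_group_rejected(self, rng):
        expr = pd.DataFrame(rng.normal(size=(3, 4)), columns=list("abcd"))
        groups = pd.Series(["MSI", "MSS", "MSS", "MSS"],
                           index=expr.columns)
        with pytest.raises(ValueError, match=">= 2 samples"):
            activity.contrast_statistic(expr, groups)
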