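import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from netten.datasets import NetworkTensor
from netten.exceptions import DegenerateTableError, InvalidArgumentError
from netten.interpretation import (
    BinaryAdjacency,
    RegionSplit,
    binary_adjacency,
    differential_edge_score,
    expand_target_network,
    mean_re_summary,
    rec,
    rec_pca,
    regulatory_effect,
    split_samples,
    tissue_association_test,
    top_k_markers,
)


def series(vals, ids=None):
    ids = ids or [f"s{i}" for i in range(len(vals))]
    return pd.Series(np.asarray(vals, dtype=float), index=ids)


class TestSplitSamples:
    def test_top_bottom_by_rank(self):
        s = series(range(1, 11))
        sp = split_samples(s, mode="top_bottom_N", N=2)
        assert set(sp.high_ids) == {"s8", "s9"}
        assert set(sp.low_ids) == {"s0", "s1"}

    def test_median_split_of_distinct_values(self):
        s = series(range(1, 11))
        sp = split_samples(s, mode="median")
        assert set(sp.high_ids) == {f"s{i}" for i in range(5, 10)}
        assert set(sp.low_ids) == {f"s{i}" for i in range(5)}

    def test_boundary_ties_broken_by_sample_id(self):
        s = series([1, 2, 2, 2, 5], ids=["e", "d", "c", "b", "a"])
        sp = split_samples(s, mode="top_bottom_N", N=2)
        # ascending (score, id): e(1), b(2), c(2), d(2), a(5)
        assert sp.low_ids == ["e", "b"]
        assert sp.high_ids == ["a", "d"]
        # reproducible and disjoint even under broad ties
        sp2 = split_samples(s.sample(frac=1, random_state=0), mode="top_bottom_N", N=2)
        assert sp2.low_ids == sp.low_ids and sp2.high_ids == sp.high_ids
        assert set(sp.high_ids).isdisjoint(sp.low_ids)

    def test_partition_properties(self):
        rng = np.random.default_rng(0)
        s = series(rng.standard_normal(21))
        med = split_samples(s, mode="median")
        assert sorted(med.high_ids + med.low_ids) == sorted(s.index)
        top = split_samples(s, mode="top_bottom_N", N=5)
        assert len(top.high_ids) == len(top.low_ids) == 5

    def test_constant_scores_warn_all_low(self):
        s = series([1.0] * 6)
        with pytest.warns(UserWarning):
            sp = split_samples(s, mode="median")
        assert not sp.high_ids and len(sp.low_ids) == 6

    def test_oversized_n_rejected(self):
        with pytest.raises(InvalidArgumentError):
            split_samples(series(range(6)), mode="top_bottom_N", N=4)


class TestBinaryAdjacency:
    def test_all_zero_slices(self, toy_tensor):
        t = toy_tensor
        t.coefficients[:] = 0.0
        A = binary_adjacency(t, ["s0", "s1"])
        assert A.matrix.to_numpy().sum() == 0

    def test_singleton_union(self, toy_tensor):
        A = binary_adjacency(toy_tensor, ["s2"])
        m = A.matrix
        assert m.to_numpy().sum() == 2  # g1<-g2 (everywhere) and g2<-g0 (s2)
        assert m.loc["g2", "g0"] == 1 and m.loc["g1", "g2"] == 1

    def test_matches_brute_force_or(self):
        rng = np.random.default_rng(1)
        coeffs = rng.standard_normal((4, 3, 6)) * (rng.random((4, 3, 6)) < 0.2)
        t = NetworkTensor(
            coefficients=coeffs, intercepts=np.zeros((4, 6)),
            target_ids=[f"t{i}" for i in range(4)],
            regulator_ids=[f"r{j}" for j in range(3)],
            sample_ids=[f"s{a}" for a in range(6)],
        )
        ids = ["s1", "s3", "s4"]
        A = binary_adjacency(t, ids)
        for l, tg in enumerate(t.target_ids):
            for j, rg in enumerate(t.regulator_ids):
                expect = 0
                for a in (1, 3, 4):
                    if coeffs[l, j, a] != 0:
                        expect = 1
                assert A.matrix.loc[tg, rg] == expect

    def test_unknown_sample_rejected(self, toy_tensor):
        with pytest.raises(InvalidArgumentError):
            binary_adjacency(toy_tensor, ["nope"])


def adjacency_from(matrix, genes):
    return BinaryAdjacency(matrix=pd.DataFrame(matrix, index=genes, columns=genes))


class TestDifferentialEdges:
    genes = ["a", "b", "c", "d"]

    def test_identical_regions_score_zero(self):
        rng = np.random.default_rng(2)
        M = (rng.random((4, 4)) < 0.4).astype(int)
        A = adjacency_from(M, self.genes)
        scores = differential_edge_score(A, adjacency_from(M.copy(), self.genes))
        assert (scores == 0).all()

    def test_single_differing_edge(self):
        M = np.zeros((4, 4), dtype=int)
        A_low = adjacency_from(M, self.genes)
        M2 = M.copy()
        M2[1, 3] = 1  # edge target b <- regulator d
        A_high = adjacency_from(M2, self.genes)
        scores = differential_edge_score(A_high, A_low)
        assert scores["b"] == 1 and scores["d"] == 1
        assert scores[["a", "c"]].sum() == 0

    def test_matches_loop_based_count(self):
        rng = np.random.default_rng(3)
        M1 = (rng.random((4, 4)) < 0.5).astype(int)
        M2 = (rng.random((4, 4)) < 0.5).astype(int)
        scores = differential_edge_score(adjacency_from(M1, self.genes),
                                         adjacency_from(M2, self.genes))
        D = np.abs(M1 - M2)
        for g_idx, g in enumerate(self.genes):
            count = 0
            for other in range(4):
                count += D[g_idx, other]  # edges onto g
                if other != g_idx:
                    count += D[other, g_idx]  # edges out of g
            assert scores[g] == count

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(4)
        M1 = (rng.random((5, 5)) < 0.5).astype(int)
        M2 = (rng.random((5, 5)) < 0.5).astype(int)
        g = [f"g{i}" for i in range(5)]
        s12 = differential_edge_score(adjacency_from(M1, g), adjacency_from(M2, g))
        s21 = differential_edge_score(adjacency_from(M2, g), adjacency_from(M1, g))
        assert (s12 == s21).all()


class TestTopKMarkers:
    def test_planted_markers_recovered(self):
        scores = pd.Series({"a": 0, "b": 7, "c": 1, "d": 9, "e": 8, "f": 0})
        assert top_k_markers(scores, k=3) == ["d", "e", "b"]

    def test_all_equal_ties_by_gene_id(self):
        scores = pd.Series(2, index=["z", "m", "a", "k"])
        assert top_k_markers(scores, k=2) == ["a", "k"]

    def test_k_equals_gene_count(self):
        scores = pd.Series({"a": 1, "b": 3, "c": 2})
        assert top_k_markers(scores, k=3) == ["b", "c", "a"]

    def test_oversized_k_rejected(self):
        with pytest.raises(InvalidArgumentError):
            top_k_markers(pd.Series({"a": 1}), k=2)


class TestExpandTargetNetwork:
    def _tensor(self, edges, genes, n_samples=2):
        # edges: list of (regulator, target)
        coeffs = np.zeros((len(genes), len(genes), n_samples))
        for reg, tgt in edges:
            coeffs[genes.index(tgt), genes.index(reg), 0] = 1.0
        return NetworkTensor(
            coefficients=coeffs, intercepts=np.zeros((len(genes), n_samples)),
            target_ids=genes, regulator_ids=genes,
            sample_ids=[f"s{a}" for a in range(n_samples)],
        )

    def test_isolated_seed_empty(self):
        t = self._tensor([("b", "c")], ["a", "b", "c"])
        assert expand_target_network(["a"], t, ["s0"], hops=2) == []

    def test_chain_traversal(self):
        t = self._tensor([("a", "b"), ("b", "c")], ["a", "b", "c"])
        edges = expand_target_network(["a"], t, ["s0"], hops=2)
        assert set(edges) == {("a", "b"), ("b", "c")}

    def test_matches_bfs_oracle_on_random_dag(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(10)]
        edges = [(genes[i], genes[j]) for i in range(10) for j in range(i + 1, 10)
                 if rng.random() < 0.25]
        t = self._tensor(edges, genes)
        seeds = ["g0", "g1"]
        got = expand_target_network(seeds, t, ["s0"], hops=2)
        nodes = set(seeds) | {v for _, v in got}

        # plain BFS truncated at depth 2
        adj = {}
        for u, v in edges:
            adj.setdefault(u, set()).add(v)
        level = set(seeds)
        expect = set(seeds)
        for _ in range(2):
            level = {v for u in level for v in adj.get(u, ())}
            expect |= level
        assert nodes == expect

    def test_empty_seed_set_rejected(self, toy_tensor):
        with pytest.raises(InvalidArgumentError):
            expand_target_network([], toy_tensor, ["s0"])


class TestRegulatoryEffect:
    def test_zero_coefficient_annihilates(self, toy_tensor, toy_expression):
        re = regulatory_effect(toy_tensor, toy_expression)
        assert np.all(re[(toy_tensor.coefficients == 0)] == 0)

    def test_printed_product(self, toy_tensor, toy_expression):
        toy_tensor.coefficients[0, 1, 0] = 2.0
        toy_expression.values.loc["g1", "s0"] = 3.0
        re = regulatory_effect(toy_tensor, toy_expression)
        assert re[0, 1, 0] == pytest.approx(6.0)

    def test_matches_loop_oracle(self, toy_tensor, toy_expression):
        re = regulatory_effect(toy_tensor, toy_expression)
        for l in range(3):
            for j in range(3):
                for a in range(4):
                    reg = toy_tensor.regulator_ids[j]
                    sample = toy_tensor.sample_ids[a]
                    expect = (toy_tensor.coefficients[l, j, a]
                              * toy_expression.values.loc[reg, sample])
                    assert re[l, j, a] == pytest.approx(expect)

    def test_misaligned_samples_rejected(self, toy_tensor, toy_expression):
        toy_tensor.sample_ids = ["x0", "x1", "x2", "x3"]
        with pytest.raises(InvalidArgumentError):
            regulatory_effect(toy_tensor, toy_expression)


class TestREC:
    def test_constant_re_gives_zero(self):
        re = np.full((2, 2, 5), 3.0)
        np.testing.assert_array_equal(rec(re), np.zeros((2, 2)))

    def test_range_arithmetic(self):
        re = np.array([[[-1.0, 2.0, 0.5]]])
        assert rec(re)[0, 0] == pytest.approx(3.0)

    def test_matches_brute_force_range(self):
        rng = np.random.default_rng(6)
        re = rng.standard_normal((3, 4, 7))
        out = rec(re)
        for l in range(3):
            for j in range(4):
                assert out[l, j] == pytest.approx(re[l, j].max() - re[l, j].min())

    def test_nonnegative_and_zero_edge_annihilation(self):
        rng = np.random.default_rng(7)
        re = rng.standard_normal((4, 3, 6))
        re[1, 2, :] = 0.0
        out = rec(re)
        assert np.all(out >= 0)
        assert out[1, 2] == 0.0


class TestMeanRESummary:
    def test_exact_cancellation_pruned(self, toy_tensor):
        re = np.zeros((3, 3, 4))
        re[0, 1, :] = [1.0, -1.0, 2.0, -2.0]
        long = mean_re_summary(re, toy_tensor, toy_tensor.sample_ids,
                               prune_zero_mean=True)
        assert long.empty

    def test_singleton_mean(self, toy_tensor):
        rng = np.random.default_rng(8)
        re = rng.standard_normal((3, 3, 4))
        long = mean_re_summary(re, toy_tensor, ["s2"], prune_zero_mean=False)
        pivot = long.pivot(index="target", columns="regulator", values="mean_re")
        np.testing.assert_allclose(
            pivot.loc[toy_tensor.target_ids, toy_tensor.regulator_ids].to_numpy(),
            re[:, :, 2],
        )

    def test_matches_arithmetic_mean(self, toy_tensor):
        rng = np.random.default_rng(9)
        re = rng.standard_normal((3, 3, 4))
        ids = ["s0", "s3"]
        long = mean_re_summary(re, toy_tensor, ids, prune_zero_mean=False)
        pivot = long.pivot(index="target", columns="regulator", values="mean_re")
        np.testing.assert_allclose(
            pivot.loc[toy_tensor.target_ids, toy_tensor.regulator_ids].to_numpy(),
            re[:, :, [0, 3]].mean(axis=2),
        )


class TestRecPCA:
    def test_duplicate_columns_coincide(self):
        rng = np.random.default_rng(10)
        base = rng.standard_normal(20)
        df = pd.DataFrame({"m1": base, "m2": base, "m3": rng.standard_normal(20)},
                          index=[f"t{i}" for i in range(20)])
        out = rec_pca(df, ["m1", "m2", "m3"])
        np.testing.assert_allclose(out["loadings"].loc["m1"],
                                   out["loadings"].loc["m2"], atol=1e-10)

    def test_rank_one_matrix_first_fraction_one(self):
        u = np.arange(1.0, 11.0)
        v = np.array([1.0, -2.0, 0.5])
        df = pd.DataFrame(np.outer(u, v), columns=["a", "b", "c"])
        out = rec_pca(df, ["a", "b", "c"])
        assert out["variance_explained"][0] == pytest.approx(1.0, abs=1e-8)

    def test_planted_two_cluster_recovery(self):
        """Markers sharing target profiles should co-locate in the PC plane."""
        rng = np.random.default_rng(11)
        profile_a = rng.standard_normal(50) * 3
        profile_b = rng.standard_normal(50) * 3
        cols = {}
        cluster = {}
        for i in range(3):
            cols[f"a{i}"] = profile_a + 0.1 * rng.standard_normal(50)
            cluster[f"a{i}"] = 0
        for i in range(3):
            cols[f"b{i}"] = profile_b + 0.1 * rng.standard_normal(50)
            cluster[f"b{i}"] = 1
        df = pd.DataFrame(cols)
        out = rec_pca(df, list(cols))
        pts = out["loadings"].to_numpy()
        labels = np.array([cluster[g] for g in out["loadings"].index])
        cen0 = pts[labels == 0].mean(axis=0)
        cen1 = pts[labels == 1].mean(axis=0)
        for p, lab in zip(pts, labels):
            own, other = (cen0, cen1) if lab == 0 else (cen1, cen0)
            assert np.linalg.norm(p - own) < np.linalg.norm(p - other)

    def test_too_few_markers_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0]})
        with pytest.raises(InvalidArgumentError):
            rec_pca(df, ["a"])


class TestTissueAssociation:
    def _split(self, high, low):
        return RegionSplit(mode="median", high_ids=high, low_ids=low)

    def test_independent_table_statistic_zero(self):
        ids = [f"s{i}" for i in range(20)]
        tissue = pd.Series(["lung"] * 5 + ["skin"] * 5 + ["lung"] * 5 + ["skin"] * 5,
                           index=ids)
        split = self._split(ids[:10], ids[10:])
        stat, p, stars = tissue_association_test(tissue, split, "lung")
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)
        assert stars == ""

    def test_diagonal_table_statistic_sixty(self):
        ids = [f"s{i:02d}" for i in range(60)]
        tissue = pd.Series(["brain"] * 30 + ["other"] * 30, index=ids)
        split = self._split(ids[:30], ids[30:])
        stat, p, stars = tissue_association_test(tissue, split, "brain")
        assert stat == pytest.approx(60.0)
        assert stars == "****"

    def test_matches_pearson_formula_on_random_tables(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            n_high, n_low = rng.integers(5, 30, size=2)
            ids = [f"s{i:03d}" for i in range(n_high + n_low)]
            labels = rng.choice(["lung", "other"], size=len(ids), p=[0.4, 0.6])
            while len(set(labels)) < 2:  # avoid empty tissue margin
                labels = rng.choice(["lung", "other"], size=len(ids), p=[0.4, 0.6])
            tissue = pd.Series(labels, index=ids)
            split = self._split(ids[:n_high], ids[n_high:])
            stat, p, _ = tissue_association_test(tissue, split, "lung")
            # textbook Pearson chi-squared by explicit loops
            O = np.zeros((2, 2))
            for s in ids:
                r = 0 if tissue[s] == "lung" else 1
                c = 0 if s in split.high_ids else 1
                O[r, c] += 1
            E = np.outer(O.sum(1), O.sum(0)) / O.sum()
            expect = ((O - E) ** 2 / E).sum()
            assert stat == pytest.approx(expect, abs=1e-10)
            assert p == pytest.approx(float(chi2.sf(expect, 1)), abs=1e-12)

    def test_empty_margin_rejected(self):
        ids = ["a", "b", "c", "d"]
        tissue = pd.Series(["lung"] * 4, index=ids)
        split = self._split(ids[:2], ids[2:])
        with pytest.raises(DegenerateTableError):
            tissue_association_test(tissue, split, "lung")

    def test_significance_stars_track_thresholds(self):
        ids = [f"s{i:03d}" for i in range(200)]
        tissue = pd.Series(["brain"] * 100 + ["other"] * 100, index=ids)
        split = self._split(ids[:100], ids[100:])
        _, p, stars = tissue_association_test(tissue, split, "brain")
        assert p < 1e-4 and stars == "****"
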