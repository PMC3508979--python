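import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mtubesim import stats


class TestMape:
    def test_exact_estimates_zero(self):
        assert stats.mape([1, 2, 3], [1, 2, 3]) == 0.0

    def test_formula(self):
        assert stats.mape([100], [110]) == pytest.approx(10.0)

    def test_matches_elementwise_oracle(self, rng):
        t = rng.random(50) + 0.5
        e = t + rng.normal(0, 0.2, 50)
        oracle = 100 * np.mean([abs(b - a) / abs(a) for a, b in zip(t, e)])
        assert stats.mape(t, e) == pytest.approx(oracle)

    def test_zero_true_raises(self):
        with pytest.raises(ValueError):
            stats.mape([0.0, 1.0], [1.0, 1.0])


class TestCoefficientOfVariation:
    def test_constant_vector(self):
        assert stats.coefficient_of_variation([3.0, 3.0, 3.0]) == 0.0

    def test_two_values(self):
        assert stats.coefficient_of_variation([1.0, 3.0]) == pytest.approx(
            np.sqrt(2) / 2
        )

    def test_scale_invariance(self, rng):
        x = rng.random(30) + 1
        assert stats.coefficient_of_variation(7.5 * x) == pytest.approx(
            stats.coefficient_of_variation(x)
        )


class TestPolymerizedTubulin:
    def test_product(self):
        assert stats.polymerized_tubulin(250, 30) == 7500.0
        assert stats.polymerized_tubulin(0, 25) == 0.0

    def test_matches_expected_total_length(self, open_geometry):
        # product n * mu approximates the expected sum of realized lengths
        from mtubesim.growth import GrowthParams, generate_distribution

        params = GrowthParams(n=100, mu_um=8.0, collinearity=0.98)
        mts = generate_distribution(
            open_geometry, params, np.random.default_rng(5)
        )
        total = sum(m.length_um for m in mts)
        assert abs(total - stats.polymerized_tubulin(100, 8.0)) < 0.10 * total


class TestHotellingT2:
    def test_identical_groups(self, rng):
        g = rng.normal(size=(20, 2))
        t2, p = stats.hotelling_t2(g, g)
        assert t2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_direct_formula(self, rng):
        a = rng.normal(size=(15, 2))
        b = rng.normal(loc=0.8, size=(12, 2))
        t2, p = stats.hotelling_t2(a, b)
        na, nb = 15, 12
        d = a.mean(0) - b.mean(0)
        sp = ((na - 1) * np.cov(a.T) + (nb - 1) * np.cov(b.T)) / (na + nb - 2)
        t2_ref = na * nb / (na + nb) * d @ np.linalg.inv(sp) @ d
        assert t2 == pytest.approx(t2_ref, abs=1e-8)
        f_ref = t2_ref * (na + nb - 3) / (2 * (na + nb - 2))
        assert p == pytest.approx(sps.f.sf(f_ref, 2, na + nb - 3), abs=1e-10)

    def test_cross_check_against_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        a = rng.normal(size=(20, 2))
        b = rng.normal(loc=0.5, size=(25, 2))
        t2, p = stats.hotelling_t2(a, b)
        ref = pingouin.multivariate_ttest(a, b)
        assert t2 == pytest.approx(float(ref["T2"].iloc[0]), rel=1e-9)
        assert p == pytest.approx(float(ref["pval"].iloc[0]), rel=1e-9)

    def test_type_one_error_calibrated(self):
        # reduced-replication null calibration; full 2000-rep version runs
        # in the acceptance suite
        rng = np.random.default_rng(99)
        rejections = 0
        reps = 500
        for _ in range(reps):
            a = rng.normal(size=(35, 2))
            b = rng.normal(size=(35, 2))
            _, p = stats.hotelling_t2(a, b)
            rejections += p < 0.05
        assert abs(rejections / reps - 0.05) < 0.03


class TestBoxM:
    def test_identical_groups_zero(self, rng):
        g = rng.normal(size=(15, 2))
        m, p = stats.box_m_test([g, g.copy(), g.copy()])
        assert m == pytest.approx(0.0, abs=1e-10)

    def test_matches_log_determinant_formula(self, rng):
        groups = [rng.normal(size=(n, 3)) for n in (10, 14, 12)]
        m, p = stats.box_m_test(groups)
        v = np.array([9, 13, 11])
        covs = [np.cov(g.T) for g in groups]
        sp = sum(vi * c for vi, c in zip(v, covs)) / v.sum()
        m_ref = v.sum() * np.log(np.linalg.det(sp)) - sum(
            vi * np.log(np.linalg.det(c)) for vi, c in zip(v, covs)
        )
        assert m == pytest.approx(m_ref, abs=1e-8)

    def test_cross_check_against_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        groups = [rng.normal(size=(n, 2)) for n in (20, 25, 30)]
        m, p = stats.box_m_test(groups)
        df = pd.DataFrame(
            np.vstack(groups), columns=["x", "y"]
        )
        df["g"] = np.repeat([0, 1, 2], [20, 25, 30])
        ref = pingouin.box_m(df, dvs=["x", "y"], group="g")
        assert p == pytest.approx(float(ref["pval"].iloc[0]), abs=1e-6)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(4)
        pvals = [
            stats.box_m_test([rng.normal(size=(20, 2)) for _ in range(3)])[1]
            for _ in range(300)
        ]
        assert sps.kstest(pvals, "uniform").pvalue > 0.001


def _toy_table(rng, k=3, n=60, shift=0.0):
    rows = []
    for gi in range(k):
        x = rng.normal(loc=gi * shift, size=(n, 2))
        for r in x:
            rows.append({"group": f"g{gi}", "n_hat": r[0], "mu_hat": r[1]})
    return pd.DataFrame(rows)


class TestPairwiseCompare:
    def test_null_p_near_one(self):
        high = 0
        for s in range(5):
            table = _toy_table(np.random.default_rng(100 + s), k=2)
            (res,) = stats.pairwise_compare(table, repeats=20, seed=s)
            high += res.p_adjusted > 0.5
        assert high >= 4

    def test_separated_means_detected(self):
        table = _toy_table(np.random.default_rng(0), k=2, shift=3.0)
        (res,) = stats.pairwise_compare(table, repeats=20, seed=0)
        assert res.p_adjusted < 0.05

    def test_eleven_groups_give_55_pairs(self):
        table = _toy_table(np.random.default_rng(1), k=11, n=40)
        results = stats.pairwise_compare(table, repeats=3, seed=0)
        assert len(results) == 55
        assert all(0 <= r.p_adjusted <= 1 for r in results)

    def test_symmetric_in_group_block_order(self):
        # presenting the groups in the opposite block order (same rows,
        # same within-group order) must not change the result
        table = _toy_table(np.random.default_rng(2), k=2)
        swapped = pd.concat(
            [table[table.group == "g1"], table[table.group == "g0"]],
            ignore_index=True,
        )
        (a,) = stats.pairwise_compare(table, repeats=5, seed=3)
        (b,) = stats.pairwise_compare(swapped, repeats=5, seed=3)
        assert {a.group_a, a.group_b} == {b.group_a, b.group_b}
        assert a.p_adjusted == pytest.approx(b.p_adjusted)
        assert a.t2_statistic == pytest.approx(b.t2_statistic)

    def test_small_group_raises(self):
        table = _toy_table(np.random.default_rng(3), k=2, n=10)
        with pytest.raises(ValueError, match="g0"):
            stats.pairwise_compare(table, repeats=2, seed=0)


class TestClusterTree:
    def test_closest_pair_merges_first(self):
        d = np.array([[0.0, 1.0, 9.0], [1.0, 0.0, 8.0], [9.0, 8.0, 0.0]])
        nwk = stats.cluster_tree(d, labels=["A", "B", "C"])
        assert "(A:" in nwk or "(B:" in nwk
        assert nwk.count("A") == 1 and nwk.count("C") == 1
        # A and B form the innermost clade
        inner = nwk[nwk.rfind("(") :]
        assert "A" in inner and "B" in inner and "C" not in inner

    def test_matches_brute_force_upgma(self, rng):
        from scipy.cluster import hierarchy
        from scipy.spatial.distance import squareform

        for _ in range(5):
            k = 5
            m = rng.random((k, k)) * 10
            d = (m + m.T) / 2
            np.fill_diagonal(d, 0.0)
            link = hierarchy.linkage(squareform(d, checks=False), "average")
            # brute-force agglomeration oracle
            clusters = {i: [i] for i in range(k)}
            dist = {(i, j): d[i, j] for i in range(k) for j in range(i + 1, k)}
            merges = []
            next_id = k
            while len(clusters) > 1:
                (i, j), dm = min(dist.items(), key=lambda kv: kv[1])
                merges.append(dm)
                merged = clusters.pop(i) + clusters.pop(j)
                new_dists = {}
                for c, members in clusters.items():
                    dd = np.mean([d[a, b] for a in merged for b in members])
                    new_dists[(min(c, next_id), max(c, next_id))] = dd
                clusters[next_id] = merged
                dist = {
                    key: v
                    for key, v in dist.items()
                    if i not in key and j not in key
                }
                dist.update(new_dists)
                next_id += 1
            assert np.allclose(sorted(link[:, 2]), sorted(merges))

    def test_newick_parses_with_one_leaf_per_group(self):
        import io

        from Bio import Phylo

        d = np.array(
            [[0, 2.0, 5.0, 6.0], [2.0, 0, 4.0, 7.0], [5.0, 4.0, 0, 3.0], [6.0, 7.0, 3.0, 0]]
        )
        labels = ["w", "x", "y", "z"]
        nwk = stats.cluster_tree(d, labels)
        tree = Phylo.read(io.StringIO(nwk), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == sorted(labels)

    def test_asymmetric_raises(self):
        d = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            stats.cluster_tree(d)


class TestPca:
    def test_rank_two_plane_fractions(self, rng):
        basis = rng.random((2, 5))
        coords = rng.normal(size=(40, 2))
        x = coords @ basis
        scores, fracs = stats.pca_first_two(x)
        assert fracs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_scores_preserve_plane_distances(self, rng):
        basis = np.linalg.qr(rng.normal(size=(5, 2)))[0].T
        coords = rng.normal(size=(30, 2))
        x = coords @ basis
        scores, _ = stats.pca_first_two(x)
        d_orig = np.linalg.norm(
            x[:, None, :] - x[None, :, :], axis=-1
        )
        d_scores = np.linalg.norm(
            scores[:, None, :] - scores[None, :, :], axis=-1
        )
        assert np.allclose(d_orig, d_scores, atol=1e-6)

    def test_sign_deterministic(self, rng):
        x = rng.normal(size=(25, 4))
        s1, _ = stats.pca_first_two(x)
        s2, _ = stats.pca_first_two(x.copy())
        assert np.array_equal(s1, s2)

    def test_rank_one_raises(self):
        x = np.outer(np.arange(10.0), [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            stats.pca_first_two(x)


class TestCorrelate:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert stats.correlate(x, 2 * x + 1) == pytest.approx(1.0)
        assert stats.correlate(x, -x) == pytest.approx(-1.0)

    def test_matches_covariance_formula(self, rng):
        x = rng.random(40)
        y = rng.random(40)
        ref = np.cov(x, y)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
        assert stats.correlate(x, y) == pytest.approx(ref)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            stats.correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
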