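"""Ordination, permutation tests, NB differential abundance, enrichment."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from peatvirome.ecology import (
    accumulation_curve,
    bray_curtis,
    depth_groups,
    hellinger,
    mantel,
    nb_lrt,
    pcoa,
    permanova,
    size_factors,
    trait_enrichment,
    two_sample_t,
)

LEVELS4 = ["a"] * 5 + ["b"] * 5 + ["c"] * 5 + ["d"] * 5


def _nb_counts(rng, n_votu, n_samp=20, disp=0.3, mean_lo=5, mean_hi=50, lib=None):
    lib = np.ones(n_samp) if lib is None else lib
    M = np.zeros((n_votu, n_samp))
    size = 1 / disp
    for i in range(n_votu):
        mu = np.exp(rng.uniform(np.log(mean_lo), np.log(mean_hi))) * lib
        M[i] = rng.negative_binomial(size, size / (size + mu))
    return pd.DataFrame(
        M, index=[f"v{i}" for i in range(n_votu)], columns=[f"s{j}" for j in range(n_samp)]
    )


class TestHellinger:
    def test_single_votu_sample_is_one(self):
        m = pd.DataFrame([[7.0]], index=["s1"], columns=["v1"])
        assert hellinger(m).iloc[0, 0] == 1.0

    def test_hand_case(self):
        m = pd.DataFrame([[1.0, 1.0, 2.0]], index=["s1"], columns=list("xyz"))
        out = hellinger(m).iloc[0].tolist()
        assert out == pytest.approx([0.5, 0.5, math.sqrt(0.5)])

    def test_zero_sample_stays_zero_with_warning(self, caplog):
        import logging

        m = pd.DataFrame([[0.0, 0.0], [1.0, 3.0]], index=["s1", "s2"], columns=["x", "y"])
        with caplog.at_level(logging.WARNING):
            out = hellinger(m)
        assert (out.loc["s1"] == 0).all()
        assert "all-zero" in caplog.text


class TestBrayCurtis:
    def test_identical_and_disjoint_samples(self):
        m = pd.DataFrame(
            [[1.0, 2.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 5.0]],
            index=["s1", "s2", "s3"],
        )
        d = bray_curtis(m)
        assert d["s1", "s2"] == 0.0
        assert d["s1", "s3"] == 1.0

    def test_hand_case(self):
        m = pd.DataFrame([[2.0, 1.0], [1.0, 1.0]], index=["a", "b"])
        assert bray_curtis(m)["a", "b"] == pytest.approx(0.2)

    def test_unit_interval_after_hellinger(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.poisson(5, (6, 30)).astype(float))
        d = bray_curtis(hellinger(m)).condensed_form()
        assert ((d >= 0) & (d <= 1)).all()


class TestPcoa:
    def test_two_points_half_coordinates(self):
        dm = DistanceMatrix([[0, 1], [1, 0]], ids=["a", "b"])
        coords, rel = pcoa(dm)
        assert sorted(coords.iloc[:, 0].tolist()) == pytest.approx([-0.5, 0.5])

    def test_identical_points_give_zeros(self):
        dm = DistanceMatrix(np.zeros((3, 3)), ids=list("abc"))
        coords, rel = pcoa(dm)
        assert coords.shape[1] == 0 or np.allclose(coords.to_numpy(), 0)

    def test_planar_configuration_recovered(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(7, 2))
        dm = DistanceMatrix(squareform(pdist(X)), ids=[str(i) for i in range(7)])
        coords, rel = pcoa(dm)
        from scipy.spatial import procrustes

        _, _, disparity = procrustes(X, coords.to_numpy()[:, :2])
        assert disparity < 1e-8


class TestMantel:
    def test_self_correlation_floor_p(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.poisson(8, (8, 25)).astype(float))
        d = bray_curtis(hellinger(m))
        res = mantel(d, d, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 100)

    def test_statistic_matches_naive_oracle(self):
        """Observed r equals the plain Pearson correlation of condensed
        distances, and the permutation p agrees with a hand-rolled
        permutation loop to Monte-Carlo accuracy."""
        rng = np.random.default_rng(3)
        a = pd.DataFrame(rng.poisson(8, (9, 30)).astype(float))
        b = a + rng.normal(0, 2, a.shape).clip(-3, 3)
        d1, d2 = bray_curtis(a), bray_curtis(b.clip(lower=0))
        res = mantel(d1, d2, n_perm=999, seed=0)
        r_direct = stats.pearsonr(d1.condensed_form(), d2.condensed_form())[0]
        assert res.r == pytest.approx(r_direct, rel=1e-12)

        arr2 = d2.data
        count = 0
        n_perm = 999
        prng = np.random.default_rng(42)
        for _ in range(n_perm):
            idx = prng.permutation(arr2.shape[0])
            rp = stats.pearsonr(
                d1.condensed_form(), squareform(arr2[np.ix_(idx, idx)], checks=False)
            )[0]
            if rp >= res.r:
                count += 1
        p_naive = (count + 1) / (n_perm + 1)
        assert abs(res.p - p_naive) < 0.05

    def test_constant_matrix_rejected(self):
        d = DistanceMatrix(np.ones((5, 5)) - np.eye(5), ids=list("abcde"))
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.poisson(8, (5, 10)).astype(float), index=list("abcde"))
        with pytest.raises(ValueError, match="variance"):
            mantel(bray_curtis(m), d, n_perm=9)

    def test_type_one_error_near_nominal(self):
        """Independent random matrices: rejection rate ~5% over 200 sims."""
        rng = np.random.default_rng(4)
        hits = 0
        n_sim = 200
        for i in range(n_sim):
            a = pd.DataFrame(rng.poisson(8, (9, 15)).astype(float))
            b = pd.DataFrame(rng.poisson(8, (9, 15)).astype(float))
            res = mantel(bray_curtis(a), bray_curtis(b), n_perm=99, seed=int(i))
            hits += res.p < 0.05
        assert 0.02 <= hits / n_sim <= 0.09


class TestPermanova:
    def test_separated_clouds_floor_p(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 0.1, (5, 4)), rng.normal(5, 0.1, (5, 4))])
        dm = DistanceMatrix(squareform(pdist(X)), ids=[str(i) for i in range(10)])
        res = permanova(dm, ["a"] * 5 + ["b"] * 5, n_perm=99, seed=0)
        # the all-swap permutation reproduces the observed F exactly, so
        # the attainable floor with balanced groups is 2/(n_perm+1)
        assert res.p <= 2 / 100

    def test_statistic_matches_gower_oracle(self):
        """Pseudo-F equals the within/between sums-of-squares formula
        computed directly from squared distances."""
        rng = np.random.default_rng(6)
        X = rng.normal(size=(9, 5))
        dm = DistanceMatrix(squareform(pdist(X)), ids=[str(i) for i in range(9)])
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = permanova(dm, groups, n_perm=9, seed=0)
        d2 = dm.data**2
        n, a = 9, 3
        sst = d2[np.triu_indices(n, 1)].sum() / n
        ssw = 0.0
        for g in ("a", "b", "c"):
            idx = [i for i, x in enumerate(groups) if x == g]
            sub = d2[np.ix_(idx, idx)]
            ssw += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
        f_oracle = ((sst - ssw) / (a - 1)) / (ssw / (n - a))
        assert res.pseudo_f == pytest.approx(f_oracle, rel=1e-9)

    def test_single_group_rejected(self):
        dm = DistanceMatrix(np.ones((4, 4)) - np.eye(4), ids=list("abcd"))
        with pytest.raises(ValueError, match="two groups"):
            permanova(dm, ["x"] * 4, n_perm=9)

    def test_no_residual_df_rejected(self):
        dm = DistanceMatrix([[0, 1], [1, 0]], ids=["a", "b"])
        with pytest.raises(ValueError, match="residual"):
            permanova(dm, ["x", "y"], n_perm=9)

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(7)
        hits = 0
        n_sim = 200
        for i in range(n_sim):
            X = rng.normal(size=(12, 5))
            dm = DistanceMatrix(squareform(pdist(X)), ids=[str(k) for k in range(12)])
            labels = ["a"] * 6 + ["b"] * 6
            res = permanova(dm, labels, n_perm=99, seed=int(i))
            hits += res.p < 0.05
        assert 0.02 <= hits / n_sim <= 0.09


class TestAccumulation:
    def test_single_sample_curve_is_its_richness(self):
        m = pd.DataFrame([[1, 0, 2, 0]], index=["s1"])
        mean, curves = accumulation_curve(m, n_perm=10, seed=0)
        assert mean.tolist() == [2.0]

    def test_identical_samples_flat_curve(self):
        m = pd.DataFrame([[1, 1, 0]] * 4)
        mean, _ = accumulation_curve(m, n_perm=20, seed=0)
        assert mean.tolist() == [2.0, 2.0, 2.0, 2.0]

    def test_disjoint_samples_linear_curve(self):
        m = pd.DataFrame(np.eye(4))
        mean, _ = accumulation_curve(m, n_perm=20, seed=0)
        assert mean.tolist() == [1.0, 2.0, 3.0, 4.0]


class TestSizeFactorsAndLrt:
    def test_duplicated_identical_columns_give_unit_factors(self):
        rng = np.random.default_rng(8)
        col = rng.poisson(20, 50) + 1
        counts = pd.DataFrame({f"s{j}": col for j in range(6)})
        assert np.allclose(size_factors(counts), 1.0)

    def test_all_zero_rows_dropped(self):
        rng = np.random.default_rng(9)
        counts = _nb_counts(rng, 30)
        counts.iloc[5] = 0
        res = nb_lrt(counts, LEVELS4)
        assert "v5" not in res.table.index
        assert len(res.table) == 29

    def test_too_few_levels_rejected(self):
        rng = np.random.default_rng(10)
        with pytest.raises(ValueError):
            nb_lrt(_nb_counts(rng, 5), ["a"] * 20)

    def test_null_lrt_matches_chi2_asymptotics(self):
        """QQ agreement of null LRT statistics with chi-square(df):
        Kolmogorov distance below 0.08 at 2000 simulated vOTUs."""
        rng = np.random.default_rng(11)
        counts = _nb_counts(rng, 2000, lib=rng.uniform(0.8, 1.2, 20))
        res = nb_lrt(counts, LEVELS4)
        ks = stats.ks_1samp(res.table["lrt"], stats.chi2(3).cdf).statistic
        assert ks < 0.08

    def test_planted_effect_detected(self):
        rng = np.random.default_rng(12)
        counts = _nb_counts(rng, 60)
        # plant a strong 6-fold surface effect in the first five vOTUs
        boost = np.ones(20)
        boost[:5] = 6.0
        counts.iloc[:5] = (counts.iloc[:5] * boost).round()
        res = nb_lrt(counts, LEVELS4)
        assert np.mean([f"v{i}" in res.significant for i in range(5)]) >= 0.8


class TestDepthGroups:
    def test_archetypal_profiles_recovered(self):
        """Surface-only, mid-only and deep-only vOTUs (10 each, noise
        sigma=0.1) are perfectly separated and labeled shallow-to-deep."""
        rng = np.random.default_rng(13)
        rows = {}
        for i in range(30):
            base = np.full(20, 5.0)
            if i < 10:
                base[:5] = 50.0
            elif i < 20:
                base[5:10] = 50.0
            else:
                base[10:] = 50.0
            rows[f"v{i}"] = np.maximum(0, base + rng.normal(0, 0.1, 20)).round(2)
        counts = pd.DataFrame.from_dict(rows, orient="index")
        counts.columns = [f"s{j}" for j in range(20)]
        groups = depth_groups(list(rows), counts, LEVELS4, k=3)
        assert all(groups[f"v{i}"] == 1 for i in range(10))
        assert all(groups[f"v{i}"] == 2 for i in range(10, 20))
        assert all(groups[f"v{i}"] == 3 for i in range(20, 30))

    def test_k_equals_one_single_group(self):
        rng = np.random.default_rng(14)
        counts = _nb_counts(rng, 6)
        groups = depth_groups(list(counts.index), counts, LEVELS4, k=1)
        assert set(groups.values()) == {1}

    def test_constant_profile_assigned_by_zero_vector_convention(self):
        # the two varied rows straddle the flat row in every sample, so
        # the median-of-ratios size factors are all equal and the flat
        # vOTU's Z profile is exactly the zero vector
        counts = pd.DataFrame(
            {
                f"s{j}": [7, 3 if j < 10 else 14, 14 if j < 10 else 3]
                for j in range(20)
            },
            index=["flat", "up", "down"],
        )
        groups = depth_groups(["flat", "up", "down"], counts, LEVELS4, k=3)
        assert "flat" in groups and set(groups) == {"flat", "up", "down"}

    def test_empty_significant_set(self):
        counts = pd.DataFrame(np.ones((2, 20)), columns=[f"s{j}" for j in range(20)])
        assert depth_groups([], counts, LEVELS4) == {}


class TestEnrichment:
    def test_extreme_case_closed_form(self):
        # all 10 draws are successes: p = C(10,10)C(90,0)/C(100,10)
        res = trait_enrichment(
            {1: {f"t{i}" for i in range(10)}},
            {f"t{i}" for i in range(10)},
            {f"t{i}" for i in range(10)} | {f"u{i}" for i in range(90)},
        )[0]
        assert res.p == pytest.approx(1 / math.comb(100, 10), rel=1e-9)
        assert res.significant

    def test_expected_value_not_significant(self):
        universe = {f"x{i}" for i in range(100)}
        trait = {f"x{i}" for i in range(20)}
        group = {f"x{i}" for i in range(15, 25)}  # k=5 hits of n=10, E=2: mild
        res = trait_enrichment({1: group}, trait, universe)[0]
        group_expected = {f"x{i}" for i in range(18, 28)}  # k=2 = E exactly
        res2 = trait_enrichment({1: group_expected}, trait, universe)[0]
        assert not res2.significant
        assert 0.2 < res2.p <= 1.0

    def test_empty_trait_gives_p_one(self):
        universe = {f"x{i}" for i in range(50)}
        res = trait_enrichment({1: set(list(universe)[:10])}, set(), universe)[0]
        assert res.K == 0 and res.k == 0 and res.p == 1.0


class TestTwoSampleT:
    def test_identical_samples_zero_t(self):
        t, p = two_sample_t([1, 2, 3, 4], [1, 2, 3, 4])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_textbook_case_matches_closed_form(self):
        x = np.array([5.1, 4.9, 6.0, 5.5, 5.3])
        y = np.array([4.0, 4.2, 3.9, 4.5, 4.1])
        nx_, ny = len(x), len(y)
        sp2 = ((nx_ - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx_ + ny - 2)
        t_hand = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / nx_ + 1 / ny))
        p_hand = 2 * stats.t.sf(abs(t_hand), nx_ + ny - 2)
        t, p = two_sample_t(x, y)
        assert t == pytest.approx(t_hand) and p == pytest.approx(p_hand)

    def test_single_observation_group_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [2.0, 3.0])
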