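"""Distribution summaries, correlation/chi-square statistics and PCA against
independent brute-force oracles."""

import math

import numpy as np
import pytest

from orientfilm import anglestats as an
from orientfilm.roiorient import AngleSeries


def brute_pearson(x, y):
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = math.sqrt(n * sxx - sx * sx) * math.sqrt(n * syy - sy * sy)
    return num / den


def brute_ranks(x):
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    return ranks


class TestSummarizeDistribution:
    def test_small_sample_quartiles(self):
        s = an.summarize_distribution([10, 20, 30, 40, 50])
        assert (s.median, s.q25, s.q75) == (30.0, 20.0, 40.0)
        assert len(s.outliers) == 0
        assert (s.whisker_low, s.whisker_high) == (10.0, 50.0)

    def test_zero_iqr_flags_lone_point_as_outlier(self):
        angles = [90.0] * 59 + [0.0]
        s = an.summarize_distribution(angles)
        assert list(s.outliers) == [0.0]
        assert s.median == 90.0

    def test_quartiles_match_sort_based_oracle(self):
        rng = np.random.default_rng(0)
        a = np.concatenate([rng.normal(40, 5, 30), rng.normal(120, 10, 30)]) % 180
        s = an.summarize_distribution(a)
        assert s.q25 == np.percentile(a, 25)
        assert s.median == np.percentile(a, 50)
        assert s.q75 == np.percentile(a, 75)
        assert s.kde_curve is not None
        grid, dens = s.kde_curve
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=0.02)

    def test_identical_angles_degenerate(self):
        s = an.summarize_distribution([45.0] * 10)
        assert s.degenerate and s.kde_curve is None and len(s.outliers) == 0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            an.summarize_distribution([1.0, 2.0, 3.0])


class TestPairwiseStats:
    def test_identity_series(self):
        a = AngleSeries("a", np.linspace(5, 170, 20))
        ps = an.pairwise_stats(a, a)
        assert ps.pearson_r == pytest.approx(1.0)
        assert ps.spearman_rho == pytest.approx(1.0)
        assert ps.chi2_stat == 0.0

    def test_reversed_strictly_increasing_spearman_minus_one(self):
        b = np.linspace(1, 179, 15)
        ps = an.pairwise_stats(b[::-1], b)
        assert ps.spearman_rho == pytest.approx(-1.0)

    def test_matches_brute_force_formulas(self):
        x = [12.0, 45.0, 33.0, 78.0, 90.0, 101.0, 150.0, 20.0, 67.0, 5.0]
        y = [100.0, 40.0, 31.0, 80.0, 95.0, 120.0, 140.0, 25.0, 60.0, 15.0]
        ps = an.pairwise_stats(x, y)
        assert ps.pearson_r == pytest.approx(brute_pearson(x, y), abs=1e-12)
        rho = brute_pearson(brute_ranks(x), brute_ranks(y))
        assert ps.spearman_rho == pytest.approx(rho, abs=1e-12)
        sa, sb = sorted(x), sorted(y)
        chi2 = sum((a - b) ** 2 / b for a, b in zip(sa, sb))
        assert ps.chi2_stat == pytest.approx(chi2, abs=1e-12)
        assert ps.chi2_df == 9

    def test_zero_variance_gives_nan_sentinels(self):
        ps = an.pairwise_stats([5.0] * 6, [1, 2, 3, 4, 5, 6])
        assert math.isnan(ps.pearson_r) and math.isnan(ps.spearman_rho)
        assert ps.notes

    def test_binned_mode_uses_sturges_bins(self):
        rng = np.random.default_rng(1)
        a, b = rng.uniform(0, 180, 60), rng.uniform(0, 180, 60)
        ps = an.pairwise_stats(a, b, chi2_mode="binned")
        from orientfilm.shapestats import sturges_bins
        assert ps.chi2_df == sturges_bins(60) - 1
        assert ps.chi2_stat >= 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            an.pairwise_stats([1.0, 2.0], [1.0, 2.0, 3.0])


class TestPca:
    def test_two_perfectly_correlated_variables(self):
        x = np.linspace(0, 1, 10)
        res = an.pca_angles(np.column_stack([x, 3 * x + 1]))
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_explained_ratios_sum_to_one_nonincreasing(self):
        rng = np.random.default_rng(2)
        res = an.pca_angles(rng.normal(size=(30, 6)))
        r = res.explained_variance_ratio
        assert r.sum() == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(r) <= 1e-12).all()

    def test_independent_variables_near_equal_ratios(self):
        rng = np.random.default_rng(3)
        res = an.pca_angles(rng.normal(size=(4000, 4)))
        np.testing.assert_allclose(res.explained_variance_ratio, 0.25, atol=0.03)

    def test_eigenvalues_match_sklearn_oracle(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(4, 6)) * [1, 2, 3, 1, 5, 1] + rng.normal(size=6)
        res = an.pca_angles(x)
        from sklearn.decomposition import PCA
        from sklearn.preprocessing import StandardScaler
        z = StandardScaler().fit_transform(x)
        skl = PCA().fit(z)
        np.testing.assert_allclose(res.explained_variance_ratio[:3],
                                   skl.explained_variance_ratio_[:3], atol=1e-9)
        # scores agree up to component sign
        for k in range(3):
            ours, theirs = res.scores[:, k], skl.transform(z)[:, k]
            assert (np.allclose(ours, theirs, atol=1e-8)
                    or np.allclose(ours, -theirs, atol=1e-8))

    def test_loadings_orthonormal_and_sign_convention(self):
        rng = np.random.default_rng(5)
        res = an.pca_angles(rng.normal(size=(20, 5)))
        np.testing.assert_allclose(res.loadings @ res.loadings.T, np.eye(5),
                                   atol=1e-9)
        for row in res.loadings:
            assert row[np.argmax(np.abs(row))] > 0

    def test_zero_variance_column_dropped(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(10, 3))
        x[:, 1] = 7.0
        with pytest.warns(UserWarning):
            res = an.pca_angles(x)
        assert res.dropped_columns == [1]
        assert res.loadings.shape == (2, 2)

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError):
            an.pca_angles(np.array([[1.0, np.nan], [2.0, 3.0]]))


class TestSeparationReport:
    def test_identical_samples_zero_distance(self):
        a = AngleSeries("a", np.linspace(10, 170, 12))
        rep = an.separation_report({"s1": a, "s2": AngleSeries("b", a.angles.copy())})
        assert rep["min_between_distance"] == pytest.approx(0.0, abs=1e-9)

    def test_distances_symmetric_in_construction(self):
        rng = np.random.default_rng(7)
        series = {f"s{i}": [AngleSeries(f"s{i}", rng.uniform(0, 180, 20))
                            for _ in range(2)] for i in range(3)}
        rep = an.separation_report(series)
        for (s1, s2), d in rep["centroid_distances"].items():
            assert d >= 0 and (s2, s1) not in rep["centroid_distances"]

    def test_disjoint_angle_regimes_separate(self):
        rng = np.random.default_rng(8)
        series = {}
        for name, center in [("a", 20), ("b", 60), ("c", 100), ("d", 140)]:
            series[name] = [AngleSeries(name, (center + rng.normal(0, 3, 60)) % 180)
                            for _ in range(3)]
        rep = an.separation_report(series)
        assert rep["min_between_distance"] > 2 * rep["mean_within_sample_distance"]
        assert rep["silhouette"] > 0

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            an.separation_report({"only": AngleSeries("x", np.arange(10.0))})
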