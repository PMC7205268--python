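import numpy as np
import pytest

from yamm import (
    BenchmarkConfig,
    breakdown_probe,
    cluster_fixture,
    laplace_cloud,
    mse,
    run_mse_benchmark,
    sample_mean,
    spatial_median,
    symmetric_laplace_cloud,
)


class TestGenerators:
    def test_laplace_variance_and_symmetry(self):
        X = laplace_cloud(100000, 2, scale=1.0, seed=1)
        np.testing.assert_allclose(X.var(axis=0), 2.0, atol=0.05)
        np.testing.assert_allclose(np.median(X, axis=0), 0.0, atol=0.02)

    def test_symmetric_laplace_variance(self):
        X = symmetric_laplace_cloud(200000, 2, scale=1.0, seed=2)
        np.testing.assert_allclose(X.var(axis=0), 2.0, atol=0.06)

    def test_symmetric_laplace_is_rotation_invariant_in_law(self):
        # kurtosis of any projection of the elliptical variant matches the
        # marginal kurtosis; for iid marginals a 45-degree projection differs
        X = symmetric_laplace_cloud(200000, 2, scale=1.0, seed=3)
        u = np.array([1.0, 1.0]) / np.sqrt(2)
        proj = X @ u

        def kurt(v):
            return np.mean((v - v.mean()) ** 4) / np.var(v) ** 2

        assert abs(kurt(proj) - kurt(X[:, 0])) < 0.3

    def test_seed_reproducibility(self):
        np.testing.assert_array_equal(
            laplace_cloud(50, 2, seed=7), laplace_cloud(50, 2, seed=7)
        )
        np.testing.assert_array_equal(
            symmetric_laplace_cloud(50, 2, seed=7), symmetric_laplace_cloud(50, 2, seed=7)
        )


class TestClusterFixture:
    def test_row_count(self):
        X = cluster_fixture(
            [((0, 0), 1.0, 33), ((5, 5), 1.0, 33), ((0, 5), 1.0, 33)],
            outliers=[(100, 100), (-100, 100)],
            seed=1,
        )
        assert X.shape == (101, 2)

    def test_identical_seed_identical_fixture(self):
        spec = [((0, 0), 1.0, 10), ((4, 0), 0.5, 10)]
        np.testing.assert_array_equal(
            cluster_fixture(spec, seed=3), cluster_fixture(spec, seed=3)
        )

    def test_medians_robust_to_outliers_mean_is_not(self):
        spec = [((0, 0), 0.5, 33), ((6, 0), 0.5, 33), ((3, 5), 0.5, 33)]
        clean = cluster_fixture(spec, seed=5)
        dirty = cluster_fixture(spec, outliers=[(1000, 1000), (1000, -1000)], seed=5)
        med_shift = np.linalg.norm(
            spatial_median(dirty).location - spatial_median(clean).location
        )
        mean_shift = np.linalg.norm(
            sample_mean(dirty).location - sample_mean(clean).location
        )
        assert mean_shift >= 10 * max(med_shift, 1e-12)


class TestMse:
    @pytest.mark.parametrize(
        "estimates, truth, expected",
        [
            ([[1.0, 1.0]], [0.0, 0.0], 1.0),
            ([[0.5, -0.5]], [0.5, -0.5], 0.0),
            ([[2.0, 0.0], [0.0, 2.0]], [0.0, 0.0], 2.0),
        ],
    )
    def test_hand_values(self, estimates, truth, expected):
        assert mse(estimates, truth) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mse(np.empty((0, 2)), [0.0, 0.0])


class TestBenchmark:
    def test_mean_mse_matches_analytic_value(self):
        # MSE(sample mean) = 2 b^2 / k for either Laplace variant
        cfg = BenchmarkConfig(sample_sizes=(200,), reps=400,
                              estimators=("mean",), seed=11)
        rep = run_mse_benchmark(cfg)
        cell = rep.table.iloc[0]
        analytic = 2 * cfg.scale**2 / 200
        assert abs(cell.mse - analytic) <= 3 * cell.se

    def test_medians_beat_mean_on_laplace(self):
        cfg = BenchmarkConfig(sample_sizes=(50,), reps=300,
                              estimators=("spatial", "componentwise",
                                          "pmed_trapz", "mean"), seed=12)
        rep = run_mse_benchmark(cfg)
        mean_mse = rep.cell("mean", 50)
        for e in ("spatial", "componentwise", "pmed_trapz"):
            assert rep.cell(e, 50) < mean_mse

    def test_mse_scales_inversely_with_k(self):
        cfg = BenchmarkConfig(sample_sizes=(10, 40, 160), reps=300,
                              estimators=("componentwise", "mean"), seed=13)
        rep = run_mse_benchmark(cfg)
        for e in cfg.estimators:
            sub = rep.table[rep.table.estimator == e].sort_values("k")
            slope = np.polyfit(np.log(sub.k), np.log(sub.mse), 1)[0]
            assert abs(slope + 1.0) < 0.15

    def test_reproducible_from_seed(self):
        cfg = BenchmarkConfig(sample_sizes=(20,), reps=50,
                              estimators=("spatial",), seed=21)
        a = run_mse_benchmark(cfg).table
        b = run_mse_benchmark(cfg).table
        assert a.equals(b)

    def test_unknown_estimator_listed(self):
        with pytest.raises(ValueError, match="valid tags"):
            BenchmarkConfig(estimators=("oja",))


class TestBreakdown:
    def test_projection_median_bounded_below_half(self):
        flags = breakdown_probe(k=100, fractions=(0.1, 0.49, 0.51), seed=31)
        assert flags[0.1] is True and flags[0.49] is True and flags[0.51] is False

    def test_mean_breaks_immediately(self):
        flags = breakdown_probe(k=100, fractions=(0.02,), estimator="mean", seed=32)
        assert flags[0.02] is False
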