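import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from yamm import (
    MixtureConfig,
    influence_curve_numeric,
    projected_median_root,
    projected_median_taylor,
    projected_mixture_cdf,
    projected_shift,
    yamm_approx_axis,
    yamm_approx_general,
)
from yamm.influence import approx_validity


def bessel_i_series(n, z, terms=60):
    """Independent oracle: power series I_n(z) = sum (z/2)^(2k+n) / (k! (k+n)!)."""
    from math import factorial

    return sum(
        (z / 2.0) ** (2 * k + n) / (factorial(k) * factorial(k + n))
        for k in range(terms)
    )


class TestProjectedShift:
    def test_zero_when_shift_equals_bulk_mean(self):
        mix = MixtureConfig(nu1=(1.0, 2.0), nu2=(3.0, -1.0))
        for th in (0.0, 0.7, 2.0):
            s1, _ = projected_shift(th, mix, mu=(1.0, 2.0))
            assert s1 == pytest.approx(0.0, abs=1e-12)

    def test_axis_aligned_quarter_turn(self):
        mix = MixtureConfig(nu1=(0.0, 0.0), nu2=(0.0, 3.0))
        _, s2 = projected_shift(np.pi / 2, mix, mu=(0.0, 0.0))
        assert s2 == pytest.approx(-3.0)

    def test_difference_identity(self, rng):
        mix = MixtureConfig(nu1=rng.standard_normal(2), nu2=rng.standard_normal(2))
        d1, d2 = mix.delta
        for th in rng.uniform(0, 2 * np.pi, 5):
            s1, s2 = projected_shift(th, mix, mu=rng.standard_normal(2))
            assert s2 - s1 == pytest.approx(d1 * np.cos(th) - d2 * np.sin(th))


class TestProjectedCdf:
    def test_uncontaminated_median_at_bulk(self):
        mix = MixtureConfig(nu1=(0.5, -0.5), eps=0.0)
        assert projected_mixture_cdf(0.0, 0.3, mix, mu=(0.5, -0.5)) == pytest.approx(0.5)

    def test_balanced_symmetric_mixture(self):
        # s1 = -1, s2 = 1 under theta=0, mu=0 with these means
        mix = MixtureConfig(nu1=(-1.0, 0.0), nu2=(1.0, 0.0), eps=0.5)
        assert projected_mixture_cdf(0.0, 0.0, mix) == pytest.approx(0.5)

    def test_limits(self):
        mix = MixtureConfig(nu2=(0.0, 2.0), eps=0.1)
        assert projected_mixture_cdf(50.0, 1.0, mix) == pytest.approx(1.0)
        assert projected_mixture_cdf(-50.0, 1.0, mix) == pytest.approx(0.0, abs=1e-12)

    @settings(deadline=None, max_examples=40)
    @given(
        eps=st.floats(0.0, 1.0),
        theta=st.floats(0.0, 2 * np.pi),
        d=st.floats(-5.0, 5.0),
    )
    def test_monotone_in_y(self, eps, theta, d):
        mix = MixtureConfig(nu2=(d, -d / 2), eps=eps)
        y = np.linspace(-8, 8, 100)
        F = projected_mixture_cdf(y, theta, mix)
        assert np.all(np.diff(F) >= -1e-12)


class TestProjectedMedian:
    def test_root_equals_s1_without_contamination(self):
        mix = MixtureConfig(nu1=(0.7, 0.1), nu2=(5.0, 5.0), eps=0.0)
        s1, _ = projected_shift(0.4, mix)
        assert projected_median_root(0.4, mix) == pytest.approx(s1, abs=1e-10)

    def test_root_satisfies_half_mass(self):
        mix = MixtureConfig(nu2=(0.0, 2.0), eps=0.05)
        y = projected_median_root(np.pi / 2, mix)
        assert projected_mixture_cdf(y, np.pi / 2, mix) == pytest.approx(0.5, abs=1e-9)

    def test_taylor_tracks_root(self):
        mix = MixtureConfig(nu2=(0.0, 2.0), eps=0.05)
        root = projected_median_root(np.pi / 2, mix)
        tay = projected_median_taylor(np.pi / 2, mix)
        assert abs(root - tay) < 0.01

    def test_taylor_reduces_to_s1(self):
        mix0 = MixtureConfig(nu2=(1.0, 1.0), eps=0.0)
        s1, _ = projected_shift(0.2, mix0)
        assert projected_median_taylor(0.2, mix0) == pytest.approx(s1)
        mix_same = MixtureConfig(nu1=(1.0, 1.0), nu2=(1.0, 1.0), eps=0.3)
        s1b, _ = projected_shift(0.9, mix_same)
        assert projected_median_taylor(0.9, mix_same) == pytest.approx(s1b)

    def test_taylor_error_second_order_in_eps(self):
        mix = lambda e: MixtureConfig(nu2=(1.5, -0.5), eps=e)
        errs = []
        for e in (0.1, 0.05, 0.025):
            errs.append(
                abs(
                    projected_median_root(0.8, mix(e))
                    - projected_median_taylor(0.8, mix(e))
                )
            )
        # halving eps should cut the error by ~4
        assert errs[1] < errs[0] / 2.5 and errs[2] < errs[1] / 2.5


class TestClosedForms:
    def test_axis_value_against_bessel_series_oracle(self):
        d, eps = 2.0, 0.05
        z = d * d / 8.0
        expected = eps * d / np.sqrt(2.0) * np.exp(-z) * (
            bessel_i_series(0, z) + bessel_i_series(1, z)
        )
        got = yamm_approx_axis(d, eps)
        assert got[0] == 0.0
        assert got[1] == pytest.approx(expected, abs=1e-10)
        assert got[1] == pytest.approx(0.0567, abs=5e-4)

    def test_axis_large_d_limit(self):
        eps = 0.05
        limit = 2.0**1.5 * eps / np.sqrt(np.pi)
        assert yamm_approx_axis(1e4, eps)[1] == pytest.approx(limit, rel=0.01)

    def test_axis_zero_distance(self):
        np.testing.assert_array_equal(yamm_approx_axis(0.0, 0.05), [0.0, 0.0])

    def test_axis_sign_symmetry(self):
        v = yamm_approx_axis(np.array([3.0, -3.0]), 0.05)
        assert v[0] == pytest.approx(-v[1])

    def test_general_reduces_to_bulk_mean(self):
        assert np.allclose(
            yamm_approx_general(MixtureConfig(nu1=(1.0, 2.0), nu2=(1.0, 2.0), eps=0.3)),
            [1.0, 2.0],
        )
        assert np.allclose(
            yamm_approx_general(MixtureConfig(nu1=(1.0, 2.0), nu2=(4.0, 5.0), eps=0.0)),
            [1.0, 2.0],
        )

    def test_general_vs_axis_same_order_at_small_R(self):
        # the cosine density approximation behind the general form costs
        # ~sqrt(pi/2) at small R, so agreement is to ~20%, not exact
        mix = MixtureConfig(nu1=(0.0, 0.0), nu2=(0.0, 1.0), eps=0.05)
        g = yamm_approx_general(mix)[1]
        a = yamm_approx_axis(1.0, 0.05)[1]
        assert abs(g - a) / a < 0.25
        assert yamm_approx_general(mix)[0] == pytest.approx(0.0, abs=1e-12)

    def test_validity_thresholds_reported(self):
        v = approx_validity(MixtureConfig(nu2=(5.0, 0.0)))
        assert v["R"] == pytest.approx(5.0)
        assert v["valid_R_lt_2pi"] is True and v["valid_R_lt_sqrt2_pi"] is False

    def test_cosine_density_approximation_integrates_to_one(self):
        val, _ = quad(lambda z: (1 + np.cos(z)) / (2 * np.pi), -np.pi, np.pi)
        assert val == pytest.approx(1.0, abs=1e-10)


class TestNumericCurve:
    def test_uncontaminated_curve_is_flat_zero(self):
        res = influence_curve_numeric([0.0, 3.0], eps=0.0, reps=8, nprojs=300,
                                      sample_size=60, seed=1)
        assert np.all(np.abs(res.numeric) <= 3 * res.numeric_se + 1e-6)

    def test_tracks_axis_closed_form_at_moderate_d(self):
        res = influence_curve_numeric([2.0], eps=0.05, reps=30, nprojs=500,
                                      sample_size=100, seed=2)
        assert abs(res.numeric[0] - res.approx_axis[0]) <= 4 * res.numeric_se[0]

    def test_result_table_shape(self):
        res = influence_curve_numeric([0.0, 1.0, 2.0], eps=0.05, reps=3,
                                      nprojs=200, sample_size=40, seed=3)
        df = res.to_frame()
        assert list(df.columns) == ["d", "numeric", "numeric_se",
                                    "approx_general", "approx_axis"]
        assert len(df) == 3 and np.all(np.isfinite(df.numeric))
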