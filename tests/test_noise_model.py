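import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from psnlm import Mask, NoiseEstimate, Volume, estimate_sigma, squared_magnitude, unbias_squared


def rician_samples(r, sigma, n, seed):
    rng = np.random.default_rng(seed)
    return np.hypot(r + sigma * rng.standard_normal(n), sigma * rng.standard_normal(n))


class TestSquaredMagnitude:
    def test_definition(self):
        v = Volume(np.array([[[0.0, 2.0]], [[3.0, 1.5]]]).reshape(2, 1, 2))
        assert np.array_equal(squared_magnitude(v).data.ravel(), [0.0, 4.0, 9.0, 2.25])

    def test_rejects_negative(self):
        with pytest.raises(ValueError, match="negative"):
            squared_magnitude(Volume(np.full((2, 2, 2), -1.0)))

    @pytest.mark.parametrize("r,expected", [(0.0, 200.0), (50.0, 2700.0)])
    def test_second_moment_monte_carlo(self, r, expected):
        # E|z|^2 = r^2 + 2 sigma^2
        z = rician_samples(r, 10.0, 10 ** 6, seed=42)
        assert np.mean(z ** 2) == pytest.approx(expected, rel=0.01)


class TestEstimateSigma:
    def test_mean_200_gives_sigma_10(self):
        sq = Volume(np.full((4, 4, 4), 200.0))
        mask = Mask(np.ones((4, 4, 4), dtype=bool))
        est = estimate_sigma(sq, mask)
        assert est.sigma == pytest.approx(10.0)
        assert est.background_mean == pytest.approx(200.0)
        assert est.n_background == 64

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty background"):
            estimate_sigma(Volume(np.ones((3, 3, 3))), Mask(np.zeros((3, 3, 3), dtype=bool)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape mismatch"):
            estimate_sigma(Volume(np.ones((3, 3, 3))), Mask(np.ones((4, 3, 3), dtype=bool)))

    def test_foreground_content_irrelevant(self, rng):
        sq = rng.random((6, 6, 6)) * 100
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[:3] = True
        a = estimate_sigma(Volume(sq), Mask(mask))
        sq2 = sq.copy()
        sq2[~mask] = 1e6  # arbitrary foreground rewrite
        b = estimate_sigma(Volume(sq2), Mask(mask))
        assert a.sigma == b.sigma


class TestUnbiasSquared:
    def test_arithmetic_and_clamp(self):
        v = Volume(np.array([300.0, 100.0, 200.0]).reshape(1, 1, 3))
        out = unbias_squared(v, 10.0)
        assert out.data.ravel() == pytest.approx([10.0, 0.0, 0.0])

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            unbias_squared(Volume(np.ones((2, 2, 2))), -1.0)

    def test_output_non_negative(self, rng):
        v = Volume(rng.random((5, 5, 5)) * 50)
        assert np.all(unbias_squared(v, 6.0).data >= 0)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(r=st.floats(0, 1e6), sigma=st.floats(0, 1e3))
    def test_composition_recovers_clean_signal(self, r, sigma):
        # unbias(square(r) + 2 sigma^2) == r exactly for noiseless r
        biased = Volume(np.full((2, 2, 2), r * r + 2 * sigma ** 2))
        assert unbias_squared(biased, sigma).data.ravel()[0] == pytest.approx(r, rel=1e-12, abs=1e-9)

    @pytest.mark.parametrize("r", [0.0, 20.0, 50.0])
    def test_monte_carlo_recovery(self, r):
        sigma = 10.0
        z2_mean = np.mean(rician_samples(r, sigma, 10 ** 6, seed=7) ** 2)
        rec = unbias_squared(Volume(np.full((1, 1, 1), z2_mean)), sigma).data.ravel()[0]
        if r == 0:
            assert rec < 0.1 * sigma  # sqrt amplifies the MC noise of a clamped zero
        else:
            assert rec == pytest.approx(r, rel=0.01)


def test_noise_estimate_invariants():
    with pytest.raises(ValueError):
        NoiseEstimate(sigma=-1.0, background_mean=2.0, n_background=5)
    with pytest.raises(ValueError):
        NoiseEstimate(sigma=1.0, background_mean=2.0, n_background=0)
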