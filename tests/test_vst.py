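import numpy as np
import pytest
from scipy.integrate import quad

from psnlm import Volume, VSTConfig, VSTTable, build_vst, forward_vst, inverse_vst, rician_moments
from psnlm.vst import rician_pdf


class TestRicianMoments:
    def test_rayleigh_limit(self):
        mean, std = rician_moments(0.0)
        assert mean == pytest.approx(np.sqrt(np.pi / 2), abs=1e-12)
        assert std == pytest.approx(np.sqrt(2 - np.pi / 2), abs=1e-12)

    def test_gaussian_asymptote(self):
        mean, std = rician_moments(100.0)
        assert abs(std - 1.0) < 1e-3
        assert mean - 100.0 == pytest.approx(0.005, abs=5e-4)  # ~ 1/(2 nu)

    def test_monte_carlo_nu_1(self):
        rng = np.random.default_rng(11)
        n = 10 ** 7
        z = np.hypot(1.0 + rng.standard_normal(n), rng.standard_normal(n))
        mean, std = rician_moments(1.0)
        assert z.mean() == pytest.approx(mean, abs=1e-3)
        assert z.std() == pytest.approx(std, abs=1e-3)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            rician_moments(-0.5)

    def test_pdf_normalized(self):
        for nu in (0.0, 1.0, 5.0):
            mass = quad(lambda z: rician_pdf(z, nu), 0, nu + 15)[0]
            assert mass == pytest.approx(1.0, abs=1e-8)


class TestBuildVst:
    def test_strictly_increasing(self, vst_table):
        assert np.all(np.diff(vst_table.f_values) > 0)
        assert np.all(np.diff(vst_table.inverse_grid) > 0)

    def test_affine_asymptote(self, vst_table):
        # f(x) - x settles to a constant in the high-SNR Gaussian regime
        x = vst_table.grid
        offset = vst_table.f_values - x
        tail = offset[x >= 50]
        assert tail.max() - tail.min() < 1e-2

    @pytest.mark.parametrize("nu", [0.0, 0.5, 1.0, 2.0, 4.0, 8.0])
    def test_stabilizes_noise_std(self, vst_table, nu):
        rng = np.random.default_rng(int(nu * 10) + 5)
        z = np.hypot(nu + rng.standard_normal(10 ** 6), rng.standard_normal(10 ** 6))
        assert 0.9 <= vst_table.forward_values(z).std() <= 1.1

    def test_coarse_grid_rejected(self):
        with pytest.raises(ValueError):
            VSTConfig(n_points=10)


class TestForward:
    def test_constant_maps_to_constant(self, vst_table):
        out = forward_vst(Volume(np.full((3, 3, 3), 40.0)), 10.0, vst_table)
        assert np.ptp(out.data) == 0.0

    def test_order_preserved(self, vst_table, rng):
        v = rng.random((4, 4, 4)) * 300
        out = forward_vst(Volume(v), 7.0, vst_table).data
        a, b = v.ravel(), out.ravel()
        idx = np.argsort(a)
        assert np.all(np.diff(b[idx]) >= 0)

    def test_beyond_grid_uses_affine_extension(self, vst_table):
        sigma = 1.0
        x_max = vst_table.grid[-1]
        out = forward_vst(Volume(np.full((1, 1, 1), x_max + 50.0)), sigma, vst_table)
        assert out.data.ravel()[0] == pytest.approx(vst_table.f_values[-1] + 50.0)

    def test_sigma_must_be_positive(self, vst_table):
        with pytest.raises(ValueError, match="sigma"):
            forward_vst(Volume(np.ones((2, 2, 2))), 0.0, vst_table)


class TestInverse:
    @pytest.mark.filterwarnings("ignore::scipy.integrate.IntegrationWarning")
    def test_exact_unbiased_against_quadrature(self, vst_table):
        # independent oracle: E[f(z)|nu] via adaptive quadrature
        sigma = 1.0
        for nu in (2.0, 4.0, 8.0):
            ef = quad(lambda z: float(vst_table.forward_values(np.array([z]))[0])
                      * rician_pdf(z, nu), max(0.0, nu - 12), nu + 12)[0]
            rec = inverse_vst(Volume(np.full((1, 1, 1), ef)), sigma, vst_table).data.ravel()[0]
            assert abs(rec - nu) <= 0.01 * sigma

    def test_below_table_minimum_maps_to_zero(self, vst_table):
        low = vst_table.inverse_grid[0] - 1.0
        out = inverse_vst(Volume(np.full((2, 2, 2), max(low, 0.0))), 5.0, vst_table)
        assert np.all(out.data == 0.0)

    def test_high_snr_roundtrip(self, vst_table):
        sigma = 2.0
        r = 100.0 * sigma
        ft = forward_vst(Volume(np.full((2, 2, 2), r)), sigma, vst_table)
        back = inverse_vst(ft, sigma, vst_table)
        assert np.allclose(back.data, r, atol=0.005 * sigma)

    def test_order_preserved(self, vst_table, rng):
        y = np.sort(rng.random(20) * 50)
        rec = vst_table.inverse_values(y)
        assert np.all(np.diff(rec) >= 0)


class TestSerialization:
    def test_json_roundtrip(self, vst_table, tmp_path):
        path = tmp_path / "table.json"
        vst_table.save(path)
        back = VSTTable.load(path)
        assert np.array_equal(back.grid, vst_table.grid)
        assert np.array_equal(back.f_values, vst_table.f_values)
        assert np.array_equal(back.inverse_grid, vst_table.inverse_grid)
        assert back.config == vst_table.config

    def test_version_checked(self, vst_table, tmp_path):
        path = tmp_path / "table.json"
        vst_table.save(path)
        payload = path.read_text().replace('"format_version": 1', '"format_version": 99')
        path.write_text(payload)
        with pytest.raises(ValueError, match="version"):
            VSTTable.load(path)
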