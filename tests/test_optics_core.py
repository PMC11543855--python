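"""Wave-optics layer: metalens phase, chromatic focal law, Fresnel propagation,
transport-equation rates."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromatie import (
    ComplexField,
    SampledGrid,
    chromatic_focal_shift,
    focal_at_wavelength,
    fresnel_propagate,
    hyperboloid_phase,
    refocus_stack,
    tie_rhs,
    tpe_rhs,
)
from chromatie.optics_core import AliasingWarning

from conftest import band_limited_field


class TestHyperboloidPhase:
    def test_on_axis_zero_and_exact_value(self):
        grid = SampledGrid(16, 16, 62.5)  # puts r = 250 µm on the grid
        phase = hyperboloid_phase(grid, focal_length=1000.0, wavelength=0.530)
        assert phase[8, 8] == 0.0  # r = 0
        r = 250.0
        expected = 2 * math.pi / 0.530 * (math.hypot(r, 1000.0) - 1000.0)
        col = 8 + int(250.0 / 62.5)
        assert phase[8, col] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(364.9, abs=0.1)

    def test_paraxial_expansion_within_two_percent_at_quarter_aperture(self):
        exact = 2 * math.pi / 0.530 * (math.hypot(250.0, 1000.0) - 1000.0)
        paraxial = 2 * math.pi / 0.530 * 250.0**2 / (2 * 1000.0)
        assert paraxial == pytest.approx(370.5, abs=0.1)
        assert abs(paraxial - exact) / exact < 0.02

    def test_rejects_nonpositive_parameters(self):
        grid = SampledGrid(16, 16, 1.0)
        with pytest.raises(ValueError):
            hyperboloid_phase(grid, -1.0, 0.53)
        with pytest.raises(ValueError):
            hyperboloid_phase(grid, 1000.0, 0.0)


class TestChromaticFocalLaw:
    def test_identity_at_reference_wavelength(self):
        assert focal_at_wavelength(1150.0, 530.0, 530.0) == 1150.0

    def test_product_conservation_value(self):
        # λ·f conserved: 530 nm × 1150 µm → 625 nm focus at 975.2 µm
        assert focal_at_wavelength(1150.0, 530.0, 625.0) == pytest.approx(975.2, abs=0.05)

    @pytest.mark.parametrize("lam", [400.0, 455.0, 530.0, 625.0, 700.0])
    def test_product_exactly_conserved(self, lam):
        f = focal_at_wavelength(1000.0, 530.0, lam)
        assert lam * f == pytest.approx(530.0 * 1000.0, rel=1e-12)

    def test_linearized_red_green_shift_matches_measured_180um(self):
        # λδf = −fδλ at f = 1 mm, λ = 530 nm, δλ = 95 nm
        shift = chromatic_focal_shift(1000.0, 530.0, 95.0)
        assert shift == pytest.approx(179.2, abs=0.1)
        assert round(shift, -1) == 180.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        f_ref=st.floats(50.0, 5000.0),
        lam_ref=st.floats(400.0, 700.0),
        lam=st.floats(400.0, 700.0),
    )
    def test_focal_law_is_involutive_and_monotone(self, f_ref, lam_ref, lam):
        f = focal_at_wavelength(f_ref, lam_ref, lam)
        assert focal_at_wavelength(f, lam, lam_ref) == pytest.approx(f_ref, rel=1e-12)
        if lam > lam_ref:
            assert f < f_ref  # longer wavelengths focus shorter
        elif lam < lam_ref:
            assert f > f_ref

    def test_measured_focal_triplet_conserves_product_within_4_percent(self):
        # red focuses first at 0.95 mm, green 1.15 mm, blue 1.35 mm
        products = [625 * 0.95, 530 * 1.15, 455 * 1.35]
        for a in products:
            for b in products:
                assert abs(a - b) / b < 0.04


class TestFresnelPropagate:
    def test_zero_distance_is_identity(self, grid128, rng):
        f = ComplexField(grid128, band_limited_field(grid128, rng), 0.53)
        out = fresnel_propagate(f, 0.0)
        np.testing.assert_array_equal(out.amplitude, f.amplitude)

    def test_plane_wave_eigenfunction(self, grid128):
        f = ComplexField(grid128, np.ones(grid128.shape, complex), 0.53)
        z = 100.0
        out = fresnel_propagate(f, z, pad=False)
        assert out.intensity().std() < 1e-12
        expected = (2 * np.pi / 0.53 * z) % (2 * np.pi)
        measured = np.angle(out.amplitude[0, 0]) % (2 * np.pi)
        assert measured == pytest.approx(expected, abs=1e-9)

    def test_energy_conservation_on_transfer_path(self, grid128, rng):
        f = ComplexField(grid128, band_limited_field(grid128, rng), 0.53)
        out = fresnel_propagate(f, 57.0, pad=False)
        e0, e1 = f.intensity().sum(), out.intensity().sum()
        assert abs(e1 - e0) / e0 < 1e-6

    def test_forward_backward_roundtrip(self, grid128, rng):
        f = ComplexField(grid128, band_limited_field(grid128, rng), 0.53)
        back = fresnel_propagate(fresnel_propagate(f, 50.0, pad=False), -50.0, pad=False)
        rms = np.sqrt(np.mean(np.abs(back.amplitude - f.amplitude) ** 2))
        assert rms / np.sqrt(np.mean(np.abs(f.amplitude) ** 2)) < 1e-8

    def test_group_property(self, grid128, rng):
        f = ComplexField(grid128, band_limited_field(grid128, rng), 0.53)
        two_steps = fresnel_propagate(fresnel_propagate(f, 30.0, pad=False), 20.0, pad=False)
        one_step = fresnel_propagate(f, 50.0, pad=False)
        assert np.sqrt(np.mean(np.abs(two_steps.amplitude - one_step.amplitude) ** 2)) < 1e-7

    def test_forced_kernel_outside_bound_warns(self, grid128, rng):
        f = ComplexField(grid128, band_limited_field(grid128, rng), 0.53)
        with pytest.warns(AliasingWarning):
            fresnel_propagate(f, 1e6, kernel="transfer", pad=False)
        with pytest.warns(AliasingWarning):
            fresnel_propagate(f, 1.0, kernel="impulse", pad=False)

    def test_tapered_tophat_matches_fresnel_quadrature(self):
        """Propagated aperture intensity vs direct quadrature of the Fresnel
        integral on a 16x finer source grid (converged to <1e-7)."""

        def taper(x, half=36.0, w=8.0):
            t = np.ones_like(x)
            a = np.abs(x)
            t[a > half] = 0.0
            edge = (a > half - w) & (a <= half)
            t[edge] = 0.5 * (1 + np.cos(np.pi * (a[edge] - (half - w)) / w))
            return t

        lam, z = 0.53, 500.0
        k = 2 * np.pi / lam
        grid = SampledGrid(256, 256, 1.0)
        x, y = grid.coordinates()
        aperture = taper(x[0])[None, :] * taper(y[:, 0])[:, None]
        field = ComplexField(grid, aperture.astype(complex), lam)
        numeric = fresnel_propagate(field, z, pad=True).intensity()

        fine = 16
        n = 64 * fine
        fine_grid = SampledGrid(n, n, 2.0 / fine)
        xf, yf = fine_grid.coordinates()
        src = taper(xf[0])[None, :] * taper(yf[:, 0])[:, None]
        xs, ys = xf[0], yf[:, 0]
        targets = (np.arange(64) - 32) * 2.0
        U = np.zeros(64, dtype=complex)
        for i, xt in enumerate(targets):
            phx = np.exp(1j * k * (xt - xs) ** 2 / (2 * z))
            phy = np.exp(1j * k * ys**2 / (2 * z))
            U[i] = np.sum((src * phy[:, None]) @ phx)
        U *= np.exp(1j * k * z) / (1j * lam * z) * (2.0 / fine) ** 2
        oracle = np.abs(U) ** 2

        row = numeric[128, 128 - 64 : 128 + 64 : 2]
        assert np.sqrt(np.mean((row - oracle) ** 2)) < 1e-4


class TestRefocusStack:
    def test_zero_defocus_returns_intensity(self, grid128, rng):
        f = ComplexField(grid128, band_limited_field(grid128, rng), 0.53)
        (out,) = refocus_stack(f, [(0.53, 0.0)])
        np.testing.assert_allclose(out, f.intensity())

    def test_zeta_product_invariance(self, grid128, rng):
        # λ·z is the only variable of the diffraction pattern
        f = ComplexField(grid128, band_limited_field(grid128, rng), 0.53)
        i1, i2 = refocus_stack(
            f, [(0.530, 400.0), (0.625, 0.530 * 400.0 / 0.625)], pad=False
        )
        rms = np.sqrt(np.mean((i1 / i1.sum() - i2 / i2.sum()) ** 2)) * i1.size
        assert rms < 1e-6


def _oracle_field(grid):
    """Smooth weak-phase field, confined so the periodic FFT sees no seam."""
    x, y = grid.coordinates()
    envelope = np.exp(-(x**2 + y**2) / (2 * 12.0**2))
    intensity = 1 + 0.05 * envelope * np.cos(2 * np.pi * x / 40.0)
    phase = 0.1 * envelope * np.sin(2 * np.pi * y / 48.0)
    return intensity, phase


class TestTransportRates:
    def test_uniform_phase_gives_zero_tie_rate(self, grid128):
        out = tie_rhs(np.ones(grid128.shape), np.full(grid128.shape, 0.7), 0.53, 1.0)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_cosine_phase_analytic_laplacian(self, grid128):
        x, _ = grid128.coordinates()
        kx = 2 * np.pi * 4 / 128
        phase = 0.05 * np.cos(kx * x) * np.ones(grid128.shape)
        rate = tie_rhs(np.ones(grid128.shape), phase, 0.53, 1.0)
        expected = (0.53 / (2 * np.pi)) * 0.05 * kx**2 * np.cos(kx * x) * np.ones(grid128.shape)
        interior = np.s_[8:-8, 8:-8]
        rel = np.sqrt(np.mean((rate[interior] - expected[interior]) ** 2))
        assert rel / np.sqrt(np.mean(expected[interior] ** 2)) < 0.02

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            tie_rhs(np.ones((16, 16)), np.ones((16, 17)), 0.53, 1.0)

    def test_uniform_field_gives_zero_tpe_rate(self, grid128):
        out = tpe_rhs(np.ones(grid128.shape), np.full(grid128.shape, 0.3), 0.53, 1.0)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_tilt_gives_constant_gradient_square_term(self, grid128):
        x, _ = grid128.coordinates()
        alpha = 0.05
        rate = tpe_rhs(np.ones(grid128.shape), alpha * x * np.ones(grid128.shape), 0.53, 1.0)
        # dφ/dz = −(λ/4π)|∇φ|² for a plane-wave tilt (Fresnel-consistent)
        expected = -0.53 * alpha**2 / (4 * np.pi)
        assert rate[64, 64] == pytest.approx(expected, rel=1e-9)

    def test_rates_match_fresnel_finite_differences(self, grid128):
        intensity, phase = _oracle_field(grid128)
        field = ComplexField.from_intensity_phase(grid128, intensity, phase, 0.53)
        dz = 1.0
        fp = fresnel_propagate(field, dz, pad=False)
        fm = fresnel_propagate(field, -dz, pad=False)
        k0 = 2 * np.pi / 0.53

        di_fd = (fp.intensity() - fm.intensity()) / (2 * dz)
        di_an = tie_rhs(intensity, phase, 0.53, 1.0)
        assert np.sqrt(np.mean((di_fd - di_an) ** 2)) / np.sqrt(np.mean(di_fd**2)) < 0.02

        dphi_fd = (
            np.angle(fp.amplitude * np.exp(-1j * k0 * dz))
            - np.angle(fm.amplitude * np.exp(1j * k0 * dz))
        ) / (2 * dz)
        dphi_an = tpe_rhs(intensity, phase, 0.53, 1.0)
        assert np.sqrt(np.mean((dphi_fd - dphi_an) ** 2)) / np.sqrt(np.mean(dphi_fd**2)) < 0.02
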