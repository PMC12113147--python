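"""Unit and property tests for the core-triple-shell forward model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lnpsaxs import (
    GaussianPeakParams,
    LNPModelParams,
    ScatteringCurve,
    ShellStack,
    amplitude,
    contrast_change,
    d_spacing,
    forward_amplitude,
    intensity_polydisperse,
    polydispersity_index,
    quasi_bragg_peak,
    size_distribution,
    sphere_shape,
    sphere_volume,
)


def uniform_sphere_intensity(q, R, contrast, scale, bg):
    """Closed-form monodisperse uniform-sphere intensity (independent oracle)."""
    v = 4.0 / 3.0 * math.pi * R**3
    j = 3.0 * (np.sin(q * R) - q * R * np.cos(q * R)) / (q * R) ** 3
    return scale * (contrast * v * j) ** 2 + bg


class TestSphereShape:
    @pytest.mark.parametrize(
        "x, expected, tol",
        [
            (1e-6, 1.0, 1e-9),          # continuous extension at 0
            (math.pi, 3.0 / math.pi**2, 1e-12),  # sin(pi)=0, cos(pi)=-1
            (4.4934095, 0.0, 1e-4),     # first root of tan x = x
        ],
    )
    def test_known_values(self, x, expected, tol):
        assert sphere_shape(x) == pytest.approx(expected, abs=tol)

    def test_series_matches_closed_form_at_the_switch(self):
        # the Taylor branch and the closed form must agree across the cutoff
        x = np.linspace(5e-3, 2e-2, 50)
        closed = 3.0 * (np.sin(x) - x * np.cos(x)) / x**3
        assert np.allclose(sphere_shape(x), closed, rtol=1e-10)

    @given(st.floats(min_value=0.0, max_value=500.0))
    @settings(derandomize=True, max_examples=200)
    def test_bounded_by_one(self, x):
        assert abs(sphere_shape(x)) <= 1.0 + 1e-12

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            sphere_shape(-1.0)


class TestSphereVolume:
    def test_unit_sphere(self):
        assert sphere_volume(1.0) == pytest.approx(4.0 * math.pi / 3.0)

    def test_zero_and_cubic_scaling(self):
        assert sphere_volume(0.0) == 0.0
        assert sphere_volume(2.0) / sphere_volume(1.0) == pytest.approx(8.0)


class TestAmplitude:
    def test_zero_contrast_gives_zero(self, base_params):
        sh = base_params.shells
        flat = ShellStack(
            Rc0=sh.Rc0, sigma=0, t1=sh.t1, t2=sh.t2, t3=sh.t3,
            rho_c=0.5, rho_1=0.5, rho_2=0.5, rho_3=0.5, rho_s=0.5,
        )
        q = np.linspace(0.07, 4.5, 64)
        assert np.allclose(amplitude(q, 25.0, flat), 0.0, atol=1e-10)

    def test_telescopes_to_uniform_sphere(self):
        # equal shell/solvent SLDs: only the core contrast survives
        sh = ShellStack(rho_c=0.013, rho_1=0.002, rho_2=0.002, rho_3=0.002, rho_s=0.002)
        q = np.linspace(0.07, 4.5, 64)
        a = amplitude(q, 25.0, sh)
        v = 4.0 / 3.0 * math.pi * 25.0**3
        j = 3.0 * (np.sin(q * 25) - q * 25 * np.cos(q * 25)) / (q * 25) ** 3
        assert np.allclose(a, (0.013 - 0.002) * v * j, rtol=1e-10)

    def test_forward_limit_by_direct_summation(self, base_params):
        # independent arithmetic: sum of contrast * volume over the 4 interfaces
        expected = 0.0
        radii = [25.0, 27.0, 27.3, 31.3]
        contrasts = [0.01 - (-0.01), -0.01 - 0.01, 0.01 - 0.001, 0.001 - 0.0]
        for dr, r in zip(contrasts, radii):
            expected += dr * 4.0 / 3.0 * math.pi * r**3
        got = amplitude(1e-6, 25.0, base_params.shells)[0]
        assert got == pytest.approx(expected, rel=1e-9)
        assert forward_amplitude(25.0, base_params.shells) == pytest.approx(
            expected, rel=1e-12
        )

    def test_q_nonpositive_rejected(self, base_params):
        with pytest.raises(ValueError):
            amplitude(0.0, 25.0, base_params.shells)


class TestSizeDistribution:
    def test_mode_and_one_sigma_point(self):
        n, r0, sig = 3.0, 22.0, 2.5
        assert size_distribution(r0, r0, sig, n) == pytest.approx(
            n / (sig * math.sqrt(2 * math.pi))
        )
        ratio = size_distribution(r0 + sig, r0, sig, n) / size_distribution(r0, r0, sig, n)
        assert ratio == pytest.approx(math.exp(-0.5))

    def test_normalization(self):
        r0, sig, n = 22.0, 2.5, 7.0
        r = np.linspace(r0 - 8 * sig, r0 + 8 * sig, 200001)
        total = np.trapezoid(size_distribution(r, r0, sig, n), r)
        assert total == pytest.approx(n, rel=1e-6)

    def test_zero_sigma_signals_monodisperse_path(self):
        with pytest.raises(ValueError):
            size_distribution(22.0, 22.0, 0.0)


class TestIntensityPolydisperse:
    def test_near_monodisperse_limit(self, base_params, q_grid):
        import dataclasses

        # sigma -> 0+; at 1e-5 nm the residual quadratic broadening near the
        # form-factor zeros is far below the tolerance
        sh = dataclasses.replace(base_params.shells, sigma=1e-5)
        params = LNPModelParams(shells=sh, scale=2.0, background=0.1)
        mono = 2.0 * amplitude(q_grid, sh.Rc0, sh) ** 2 + 0.1
        poly = intensity_polydisperse(q_grid, params)
        assert np.allclose(poly, mono, rtol=1e-5)

    def test_against_riemann_sum_oracle(self, base_params, q_grid):
        import dataclasses

        sigma = 2.5
        sh = dataclasses.replace(base_params.shells, sigma=sigma)
        params = LNPModelParams(shells=sh, scale=1.0, background=0.0)
        # brute-force oracle: 1e5 equally spaced nodes over R0 +- 6 sigma
        nodes = np.linspace(sh.Rc0 - 6 * sigma, sh.Rc0 + 6 * sigma, 100000)
        pdf = np.exp(-((nodes - sh.Rc0) ** 2) / (2 * sigma**2)) / (
            sigma * math.sqrt(2 * math.pi)
        )
        oracle = np.empty_like(q_grid)
        for i in range(0, q_grid.size, 25):  # chunked to bound memory
            a = amplitude(q_grid[i : i + 25], nodes, sh)
            oracle[i : i + 25] = np.trapezoid(pdf[:, None] * a**2, nodes, axis=0)
        got = intensity_polydisperse(q_grid, params)
        assert np.allclose(got, oracle, rtol=1e-4)

    def test_uniform_sphere_reduction(self, q_grid):
        sh = ShellStack(Rc0=20.0, sigma=0.0, rho_c=0.02, rho_1=0.0, rho_2=0.0,
                        rho_3=0.0, rho_s=0.0)
        params = LNPModelParams(shells=sh, scale=3.0, background=0.05)
        expected = uniform_sphere_intensity(q_grid, 20.0, 0.02, 3.0, 0.05)
        assert np.allclose(intensity_polydisperse(q_grid, params), expected, rtol=1e-6)

    def test_contrast_scaling_is_quadratic(self, q_grid):
        import dataclasses

        k = 3.0
        sh = ShellStack(Rc0=22.0, sigma=2.2)
        scaled = dataclasses.replace(
            sh,
            rho_c=k * sh.rho_c, rho_1=k * sh.rho_1, rho_2=k * sh.rho_2,
            rho_3=k * sh.rho_3, rho_s=k * sh.rho_s,
        )
        bg = 0.7
        i1 = intensity_polydisperse(q_grid, LNPModelParams(shells=sh, background=bg))
        i2 = intensity_polydisperse(q_grid, LNPModelParams(shells=scaled, background=bg))
        assert np.allclose(i2 - bg, k**2 * (i1 - bg), rtol=1e-12)

    def test_peak_additivity(self, mrna_params, q_grid):
        import dataclasses

        with_peak = intensity_polydisperse(q_grid, mrna_params)
        without = intensity_polydisperse(
            q_grid, dataclasses.replace(mrna_params, peak=None)
        )
        assert np.allclose(
            with_peak - without, quasi_bragg_peak(q_grid, mrna_params.peak), rtol=0,
            atol=1e-15 * with_peak.max(),
        )

    def test_positive_with_background(self, mrna_params, q_grid):
        assert np.all(intensity_polydisperse(q_grid, mrna_params) > 0)


class TestQuasiBraggPeak:
    def test_center_height_and_one_sigma(self):
        peak = GaussianPeakParams(amplitude=0.05, center=1.27, width=0.28)
        assert quasi_bragg_peak(1.27, peak) == pytest.approx(0.05)
        assert quasi_bragg_peak(1.27 + 0.28, peak) == pytest.approx(
            0.05 * math.exp(-0.5)
        )
        assert quasi_bragg_peak(1.27 - 0.28, peak) == pytest.approx(
            0.05 * math.exp(-0.5)
        )

    def test_integral(self):
        peak = GaussianPeakParams(amplitude=0.05, center=1.27, width=0.28)
        q = np.linspace(1.27 - 8 * 0.28, 1.27 + 8 * 0.28, 200001)
        integral = np.trapezoid(quasi_bragg_peak(q, peak), q)
        assert integral == pytest.approx(0.05 * 0.28 * math.sqrt(2 * math.pi), rel=1e-6)


class TestDerivedMetrics:
    def test_d_spacing(self):
        assert d_spacing(1.27) == pytest.approx(4.947, abs=5e-3)
        assert d_spacing(2 * math.pi) == pytest.approx(1.0)
        assert d_spacing(1.21) == pytest.approx(5.193, abs=5e-3)

    def test_polydispersity_index(self):
        assert polydispersity_index(2.65, 22.01) == pytest.approx(0.120, abs=5e-4)
        assert polydispersity_index(0.0, 30.0) == 0.0
        assert polydispersity_index(2.50, 22.94) == pytest.approx(0.109, abs=5e-4)

    def test_contrast_change(self):
        assert contrast_change(2.77, 2.19) == pytest.approx(20.94, abs=0.01)
        assert contrast_change(1.3, 1.3) == 0.0
        assert contrast_change(0.22, 0.55) == pytest.approx(-150.0)
        with pytest.raises(ValueError):
            contrast_change(0.0, 1.0)


class TestScatteringCurve:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            ScatteringCurve(q=[0.1], intensity=[1.0])  # too short
        with pytest.raises(ValueError):
            ScatteringCurve(q=[0.2, 0.1], intensity=[1.0, 1.0])  # not increasing
        with pytest.raises(ValueError):
            ScatteringCurve(q=[-0.1, 0.2], intensity=[1.0, 1.0])  # q <= 0
        with pytest.raises(ValueError):
            ScatteringCurve(q=[0.1, 0.2], intensity=[1.0, -1.0])  # negative I
        with pytest.raises(ValueError):
            ScatteringCurve(
                q=[0.1, 0.2], intensity=[1.0, 1.0], uncertainty=[0.1, 0.0]
            )  # nonpositive error
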