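"""Centerline extraction, the deviation metric, and bending-strain kinematics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from axonmech.errors import (
    DegenerateGeometryError,
    InsufficientDataError,
    TopologyError,
)
from axonmech.shape import (
    Centerline,
    bending_strain,
    defect_spacing,
    detrend_centerline,
    extract_centerline,
    fit_deviation,
    msd_profile,
    neuron_strain,
)
from axonmech.synthetic import gen_centerline, gen_worm_posture


def brute_force_msd(points: np.ndarray) -> np.ndarray:
    """Independent double-loop evaluation of the windowed MSD."""
    N = len(points)
    out = np.empty(N - 2)
    for n in range(1, N - 1):
        acc = 0.0
        for i in range(N - n):
            dx = points[i + n, 0] - points[i, 0]
            dy = points[i + n, 1] - points[i, 1]
            acc += dx * dx + dy * dy
        out[n - 1] = acc / (N - n)
    return out


class TestMsdProfile:
    def test_straight_unit_spaced_line_equals_n_squared(self):
        pts = np.column_stack([np.arange(50.0), np.zeros(50)])
        ns, msd = msd_profile(Centerline(points=pts))
        assert np.allclose(msd, ns.astype(float) ** 2, rtol=0, atol=1e-12)

    def test_three_collinear_points_spacing_two(self):
        pts = np.array([[0.0, 0.0], [2.0, 0.0], [4.0, 0.0]])
        ns, msd = msd_profile(Centerline(points=pts))
        assert ns.tolist() == [1]
        assert msd[0] == pytest.approx(4.0)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(5, 120))
        pts = np.cumsum(rng.normal(0, 1, (N, 2)), axis=0)
        _, msd = msd_profile(Centerline(points=pts))
        assert np.allclose(msd, brute_force_msd(pts), rtol=1e-12, atol=1e-9)

    def test_transverse_only_drops_longitudinal_term(self):
        pts = np.column_stack([np.arange(30.0), np.zeros(30)])
        _, msd = msd_profile(Centerline(points=pts), transverse_only=True)
        assert np.allclose(msd, 0.0)


class TestDeviationFit:
    def test_straight_line_gives_zero_deviation_unit_persistence(self):
        pts = np.column_stack([np.arange(200.0), np.zeros(200)])
        fit = fit_deviation(msd_profile(Centerline(points=pts)))
        assert abs(fit.Ddev) < 1e-8
        assert fit.S == pytest.approx(1.0, rel=1e-9)

    def test_constructed_quadratic_recovered_exactly(self):
        n = np.arange(1, 40)
        fit = fit_deviation((n, 4.0 * n**2 + 3.0 * n))
        assert fit.S == pytest.approx(2.0, rel=1e-9)
        assert fit.Ddev == pytest.approx(3.0, rel=1e-9)

    def test_plectoneme_shape_scores_higher_than_straight(self):
        straight, _ = gen_centerline(60, "straight", px_per_um=5)
        coiled, _ = gen_centerline(60, "plectoneme_like", wavelength_um=13, px_per_um=5)
        d_straight = fit_deviation(msd_profile(straight)).Ddev
        d_coiled = fit_deviation(msd_profile(coiled)).Ddev
        assert d_coiled > d_straight

    def test_invariant_under_translation_and_reflection(self):
        cl, _ = gen_centerline(40, "sinusoid", amplitude_um=1.0, wavelength_um=10, px_per_um=5)
        fit0 = fit_deviation(msd_profile(cl))
        shifted = Centerline(points=cl.points + [120.0, -55.0], scale=cl.scale)
        reflected = Centerline(points=cl.points * [1.0, -1.0], scale=cl.scale)
        for variant in (shifted, reflected):
            fit = fit_deviation(msd_profile(variant))
            assert fit.Ddev == pytest.approx(fit0.Ddev, rel=1e-9, abs=1e-12)
            assert fit.S == pytest.approx(fit0.S, rel=1e-9)

    def test_deviation_monotone_in_perturbation_amplitude(self):
        ds = []
        for amp in [0.1, 0.3, 0.6, 1.0, 1.5]:
            cl, _ = gen_centerline(60, "sinusoid", amplitude_um=amp, wavelength_um=13, px_per_um=5)
            ds.append(fit_deviation(msd_profile(cl)).Ddev)
        assert all(b > a for a, b in zip(ds, ds[1:]))

    def test_too_few_points_in_range_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_deviation((np.array([1, 2]), np.array([1.0, 4.0])))


class TestDetrend:
    def test_tilted_line_order_one_residual_zero(self):
        x = np.arange(50.0)
        cl = Centerline(points=np.column_stack([x, 0.3 * x + 7.0]))
        out = detrend_centerline(cl, poly_order=1)
        assert np.allclose(out.points[:, 1], 0.0, atol=1e-9)

    def test_parabola_order_two_residual_zero(self):
        x = np.arange(50.0)
        cl = Centerline(points=np.column_stack([x, 0.05 * x**2 - x + 3.0]))
        out = detrend_centerline(cl, poly_order=2)
        assert np.allclose(out.points[:, 1], 0.0, atol=1e-8)

    def test_sinusoid_on_parabolic_trend_recovered(self):
        # many whole periods: the wave's projection onto the quadratic trend
        # basis shrinks as 1/(number of periods)
        x = np.linspace(0, 520, 4160)
        wave = 1.5 * np.sin(2 * np.pi * x / 13.0)
        trend = 0.02 * x**2 + 0.5 * x
        cl = Centerline(points=np.column_stack([x, wave + trend]))
        out = detrend_centerline(cl, poly_order=2)
        rms = np.sqrt(np.mean((out.points[:, 1] - wave) ** 2))
        assert rms < 0.02 * np.sqrt(np.mean(wave**2))

    def test_degenerate_longitudinal_coordinate_rejected(self):
        pts = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.raises(DegenerateGeometryError):
            detrend_centerline(Centerline(points=pts), poly_order=2)


class TestDefectSpacing:
    def test_sinusoid_spacing_matches_wavelength(self):
        cl, _ = gen_centerline(60, "sinusoid", amplitude_um=1.5, wavelength_um=13, px_per_um=10)
        mean_sp, _ = defect_spacing(cl)
        assert mean_sp == pytest.approx(13.0, rel=0.05)

    def test_straight_line_has_no_defects(self):
        cl, _ = gen_centerline(50, "straight")
        with pytest.raises(InsufficientDataError):
            defect_spacing(cl)

    def test_threshold_above_amplitude_finds_nothing(self):
        cl, _ = gen_centerline(60, "sinusoid", amplitude_um=1.0, wavelength_um=13)
        with pytest.raises(InsufficientDataError):
            defect_spacing(cl, amplitude_threshold_px=1e6)


class TestExtraction:
    def test_rasterized_diagonal_line(self):
        img = np.zeros((80, 80), dtype=bool)
        for i in range(70):
            img[5 + i, 5 + i] = True
        cl = extract_centerline(img, scale=0.5)
        # collinear with the diagonal
        d = np.diff(cl.points, axis=0)
        assert np.allclose(d[:, 0], d[:, 1])
        assert cl.length_um == pytest.approx(69 * np.sqrt(2) * 0.5, rel=0.02)

    def test_rasterized_sinusoid_arclength(self):
        x = np.arange(300)
        y = np.round(20 * np.sin(2 * np.pi * x / 100.0)).astype(int) + 40
        img = np.zeros((80, 300), dtype=bool)
        img[y, x] = True
        from skimage.morphology import dilation, footprint_rectangle

        img = dilation(img, footprint_rectangle((3, 3)))
        cl = extract_centerline(img, scale=1.0)
        # analytic quadrature of the arclength of y = 20 sin(2 pi x / 100)
        xs = np.linspace(0, 299, 20000)
        dy = 20 * (2 * np.pi / 100.0) * np.cos(2 * np.pi * xs / 100.0)
        arclen = np.trapezoid(np.sqrt(1 + dy**2), xs)
        assert cl.length_um == pytest.approx(arclen, rel=0.02)

    def test_blank_image_rejected(self):
        with pytest.raises(InsufficientDataError):
            extract_centerline(np.zeros((20, 20), dtype=bool), scale=1.0)

    def test_closed_loop_rejected(self):
        img = np.zeros((40, 40), dtype=bool)
        rr = 15
        t = np.linspace(0, 2 * np.pi, 400)
        img[(20 + rr * np.sin(t)).astype(int), (20 + rr * np.cos(t)).astype(int)] = True
        with pytest.raises(TopologyError):
            extract_centerline(img, scale=1.0)


class TestStrainKinematics:
    def test_zero_curvature_zero_strain(self):
        assert bending_strain(0.0, 21.1) == 0.0

    def test_avm_alm_fold_difference(self):
        # equal curvature, offsets 21.1 vs 5.5 um: ratio ~ 3.84 (four-fold)
        ratio = bending_strain(0.01, 21.1) / bending_strain(0.01, 5.5)
        assert ratio == pytest.approx(21.1 / 5.5, rel=1e-12)
        assert round(ratio) == 4

    def test_strain_arithmetic(self):
        assert bending_strain(0.01, 21.1) == pytest.approx(0.211)

    def test_static_frames_zero_strain(self):
        cl, _ = gen_centerline(50, "straight")
        series = neuron_strain([cl, cl, cl])
        assert np.allclose(series.neuron_strain, 0.0)

    def test_generator_strain_recovered(self):
        frames, truth = gen_worm_posture([0.0, 0.025], z_offset_um=20.0, neuron_rest_length_um=100.0)
        series = neuron_strain([f["neuron"] for f in frames])
        assert series.neuron_strain[1] == pytest.approx(0.5, rel=0.02)

    def test_unit_slope_against_bending_strain(self):
        cs = [0.0, 0.005, 0.01, 0.015]
        frames, _ = gen_worm_posture(cs, z_offset_um=21.1, neuron_rest_length_um=100.0)
        series = neuron_strain(
            [f["neuron"] for f in frames], curvature_series=cs, z_um=21.1
        )
        slope = np.polyfit(series.bending_strain, series.neuron_strain, 1)[0]
        assert slope == pytest.approx(1.0, rel=0.02)
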