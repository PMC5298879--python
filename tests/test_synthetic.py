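"""Generator contracts: determinism, finiteness, and structural ground truth."""

import numpy as np
import pytest

from axonmech.errors import InvalidParameterError
from axonmech.synthetic import (
    SyntheticSpec,
    gen_bundle_stack,
    gen_centerline,
    gen_force_curve,
    gen_frap_kymograph,
    gen_periodic_profile,
    gen_worm_posture,
)


class TestDeterminismAndValidity:
    @pytest.mark.parametrize(
        "kind,params,getter",
        [
            ("centerline", dict(length_um=30, mode="sinusoid", noise_um=0.2), lambda o: o[0].points),
            ("frap_kymograph", dict(D_um2_s=0.5, mobile_fraction=0.7, noise_sd=0.05, n_frames=10), lambda o: o[0]),
            ("force_curve", dict(E_axon_pa=5000.0, noise_n=1e-11), lambda o: o[0].force),
            ("bundle_stack", dict(n_mts=12, jitter_nm=2.0, n_sections=2), lambda o: o[0][0].centers),
            ("periodic_profile", dict(period_nm=200.0, noise_sd=0.1), lambda o: o[1]),
            ("worm_posture", dict(curvature_series=[0.01], z_offset_um=10.0, noise_um=0.1), lambda o: o[0][0]["neuron"].points),
        ],
    )
    def test_same_seed_bit_identical(self, kind, params, getter):
        a = getter(SyntheticSpec(kind=kind, params=params, seed=7).generate())
        b = getter(SyntheticSpec(kind=kind, params=params, seed=7).generate())
        c = getter(SyntheticSpec(kind=kind, params=params, seed=8).generate())
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)
        assert np.all(np.isfinite(a))

    def test_unknown_kind_rejected(self):
        with pytest.raises(InvalidParameterError):
            SyntheticSpec(kind="nope").generate()

    def test_intensities_nonnegative(self):
        _, y, _ = gen_periodic_profile(200.0, noise_sd=1.0, seed=0)
        assert np.all(y >= 0)


class TestCenterlines:
    def test_straight_noiseless_transverse_zero(self):
        cl, _ = gen_centerline(50, "straight", noise_um=0.0)
        assert np.all(cl.points[:, 1] == 0.0)

    def test_nonpositive_dimensions_rejected(self):
        with pytest.raises(InvalidParameterError):
            gen_centerline(-5, "straight")
        with pytest.raises(InvalidParameterError):
            gen_centerline(50, "sinusoid", wavelength_um=0.0)

    def test_plectoneme_like_loop_spacing(self):
        cl, truth = gen_centerline(80, "plectoneme_like", wavelength_um=13, amplitude_um=1.0)
        centers = np.array(truth["loop_centers_arclength_um"])
        assert len(centers) >= 4
        assert np.diff(centers).mean() == pytest.approx(13.0, abs=0.5)


class TestFrapGenerator:
    def test_zero_diffusion_width_constant(self):
        stack, tru = gen_frap_kymograph(0.0, 1.0, n_frames=10)
        from axonmech.frap import fit_bleach_profile

        x = (np.arange(stack.shape[1]) + 0.5) * tru["um_per_px"]
        widths = [fit_bleach_profile(x, f)[2] for f in stack[tru["bleach_frame"] :]]
        assert np.ptp(widths) < 1e-9

    def test_greens_function_area_and_width(self):
        # mobile fraction 1, noiseless: dip area conserved, w^2 linear 2Dt
        D = 0.4
        stack, tru = gen_frap_kymograph(D, 1.0, n_frames=20, frame_dt_s=0.5)
        from axonmech.frap import fit_bleach_profile

        x = (np.arange(stack.shape[1]) + 0.5) * tru["um_per_px"]
        post = stack[tru["bleach_frame"] :]
        areas, w2 = [], []
        for f in post:
            A, _, w = fit_bleach_profile(x, f)
            areas.append(A * w)
            w2.append(w**2)
        assert np.ptp(areas) / np.mean(areas) < 1e-3
        slope = np.polyfit(np.arange(20) * 0.5, w2, 1)[0]
        assert slope == pytest.approx(2 * D, rel=1e-3)

    def test_negative_noise_rejected(self):
        with pytest.raises(InvalidParameterError):
            gen_frap_kymograph(0.1, 0.5, noise_sd=-1.0)


class TestForceCurveGenerator:
    def test_log_log_slope_is_three_halves(self):
        curve, _ = gen_force_curve(5000.0)
        d, F = curve.indentation[1:], curve.force[1:]
        slope = np.polyfit(np.log(d), np.log(F), 1)[0]
        assert slope == pytest.approx(1.5, rel=1e-9)

    def test_force_starts_at_zero_and_increases(self):
        curve, _ = gen_force_curve(5000.0)
        assert curve.force[0] == 0.0
        assert np.all(np.diff(curve.force) > 0)

    def test_prefactor_monotone_in_modulus(self):
        _, t1 = gen_force_curve(3000.0)
        _, t2 = gen_force_curve(6000.0)
        assert t2["a"] > t1["a"]

    def test_nonpositive_indent_rejected(self):
        with pytest.raises(InvalidParameterError):
            gen_force_curve(5000.0, max_indent_m=0.0)


class TestBundleGenerator:
    def test_perfect_lattice_angles(self):
        from axonmech.bundle import triplet_angles

        secs, _ = gen_bundle_stack(19, 35.0, 0.0, 0.0)
        ang = triplet_angles(secs[0])
        assert set(np.round(ang).astype(int)) <= {60, 120, 180}

    def test_perfect_lattice_edge_distances(self):
        from axonmech.bundle import edge_distances

        secs, truth = gen_bundle_stack(19, 35.0, 0.0, 0.0, mt_radius_nm=12.5)
        d = edge_distances(secs[0])
        assert np.allclose(d, truth["edge_to_edge_nm"])
        assert truth["edge_to_edge_nm"] == pytest.approx(10.0)

    def test_sections_are_rigid_rotations(self):
        secs, truth = gen_bundle_stack(12, 35.0, 3.0, 4.0, n_sections=3, seed=2)
        c = np.array(truth["centroid_nm"])
        a = secs[0].centers - c
        b = secs[1].centers - c
        ang = np.radians(4.0)
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        assert np.allclose(a @ rot.T, b, atol=1e-9)

    def test_overlap_rejected(self):
        with pytest.raises(InvalidParameterError):
            gen_bundle_stack(7, 20.0, mt_radius_nm=12.5)


class TestPeriodicProfileGenerator:
    def test_dominant_frequency_matches_period(self):
        x, y, tru = gen_periodic_profile(200.0, length_um=10, noise_sd=0.0)
        spec = np.abs(np.fft.rfft(y - y.mean()))
        freq = np.fft.rfftfreq(len(y), d=tru["sample_nm"])
        assert 1.0 / freq[np.argmax(spec)] == pytest.approx(200.0, rel=0.05)

    def test_psf_attenuates_peak(self):
        _, y0, tru = gen_periodic_profile(200.0, psf_fwhm_nm=0.0)
        _, y1, _ = gen_periodic_profile(200.0, psf_fwhm_nm=250.0)

        def peak(y):
            s = np.abs(np.fft.rfft(y - y.mean()))
            return s.max()

        assert peak(y1) < 0.5 * peak(y0)

    def test_nyquist_violation_rejected(self):
        with pytest.raises(InvalidParameterError):
            gen_periodic_profile(30.0, sample_nm=20.0)


class TestWormPosture:
    def test_zero_curvature_zero_strain(self):
        frames, truth = gen_worm_posture([0.0], 21.1)
        assert truth["neuron_strain"] == [0.0]
        n = frames[0]["neuron"].points
        assert np.allclose(np.diff(n[:, 1]), 0.0)

    def test_offset_ratio_sets_strain_ratio(self):
        _, t_avm = gen_worm_posture([0.01], 21.1)
        _, t_alm = gen_worm_posture([0.01], 5.5)
        ratio = t_avm["neuron_strain"][0] / t_alm["neuron_strain"][0]
        assert ratio == pytest.approx(21.1 / 5.5)

    def test_arclength_matches_euler_beam(self):
        frames, _ = gen_worm_posture([0.025], 20.0, neuron_rest_length_um=100.0)
        L = frames[0]["neuron"].length_um
        assert L == pytest.approx(100.0 * 1.5, rel=1e-4)

    def test_unphysical_strain_rejected(self):
        with pytest.raises(InvalidParameterError):
            gen_worm_posture([0.06], 21.1)
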