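"""MT-bundle morphometrics: spacings, angles, lengths, PIV pitch."""

import numpy as np
import pytest

from axonmech.bundle import (
    BundleSection,
    contact_fraction,
    edge_distances,
    is_bimodal,
    lognormal_summary,
    mt_length,
    pitch_profile,
    piv_displacement,
    rotation_sense,
    triplet_angles,
    twist_from_field,
)
from axonmech.errors import (
    InsufficientDataError,
    InvalidParameterError,
    InvalidSizeError,
    NoSignalError,
)
from axonmech.synthetic import gen_bundle_stack, render_section_image


class TestEdgeDistances:
    def test_two_profiles_arithmetic(self):
        sec = BundleSection(centers=np.array([[0.0, 0.0], [50.0, 0.0]]), radii=np.array([12.5, 12.5]))
        assert edge_distances(sec).tolist() == [25.0]

    def test_hexagonal_lattice_uniform_spacing(self):
        secs, _ = gen_bundle_stack(19, 35.0, 0.0, 0.0)
        d = edge_distances(secs[0])
        assert np.allclose(d, 10.0)

    def test_touching_profiles_floor_at_zero(self):
        sec = BundleSection(centers=np.array([[0.0, 0.0], [25.0, 0.0]]), radii=np.array([12.5, 12.5]))
        assert edge_distances(sec).tolist() == [0.0]

    def test_rigid_motion_invariance(self):
        secs, _ = gen_bundle_stack(19, 35.0, 2.0, 0.0, seed=3)
        d0 = np.sort(edge_distances(secs[0]))
        ang = 0.7
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        moved = BundleSection(centers=secs[0].centers @ rot.T + [500.0, -200.0])
        assert np.allclose(np.sort(edge_distances(moved)), d0, atol=1e-9)
        a0 = np.sort(triplet_angles(secs[0]))
        assert np.allclose(np.sort(triplet_angles(moved)), a0, atol=1e-9)


class TestLognormalSummary:
    def test_constant_distances(self):
        gm, var = lognormal_summary(np.full(50, 10.0))
        assert gm == pytest.approx(10.0)
        assert var == pytest.approx(0.0)

    def test_lognormal_sampling_oracle(self):
        # sample from log-normal with geometric mean 9.8 nm and raw-scale
        # variance ~32 nm^2 (sigma_log solved from the log-normal moments)
        gm_true, var_true = 9.8, 32.0
        mu = np.log(gm_true)
        # var = gm^2 e^{s2} (e^{s2} - 1) with mean = gm e^{s2/2}
        from scipy.optimize import brentq

        s2 = brentq(lambda s2: gm_true**2 * np.exp(s2) * (np.exp(s2) - 1.0) - var_true, 1e-6, 2.0)
        rng = np.random.default_rng(42)
        d = rng.lognormal(mu, np.sqrt(s2), 10_000)
        gm, var = lognormal_summary(d)
        assert gm == pytest.approx(gm_true, rel=0.02)
        assert var == pytest.approx(var_true, rel=0.10)

    def test_consistency_error_shrinks_with_n(self):
        rng = np.random.default_rng(0)
        errs = []
        for n in (100, 1000, 10_000):
            reps = [abs(lognormal_summary(rng.lognormal(np.log(9.8), 0.5, n))[0] - 9.8) for _ in range(8)]
            errs.append(np.mean(reps))
        assert errs[0] > errs[1] > errs[2]

    def test_zeros_excluded_and_reported(self):
        d = np.array([0.0, 0.0, 10.0, 10.0])
        gm, _ = lognormal_summary(d)
        assert gm == pytest.approx(10.0)
        assert contact_fraction(d) == pytest.approx(0.5)

    def test_empty_rejected(self):
        with pytest.raises(InsufficientDataError):
            lognormal_summary(np.array([]))

    def test_bimodal_mixture_flagged(self):
        rng = np.random.default_rng(1)
        uni = rng.lognormal(np.log(10.0), 0.3, 400)
        mix = np.concatenate(
            [rng.lognormal(np.log(4.0), 0.25, 200), rng.lognormal(np.log(20.0), 0.25, 200)]
        )
        assert not is_bimodal(uni)
        assert is_bimodal(mix)


class TestTripletAngles:
    def test_jittered_lattice_keeps_hex_modes(self):
        secs, _ = gen_bundle_stack(19, 35.0, 2.0, 0.0, seed=5)
        ang = triplet_angles(secs[0])
        hist, edges = np.histogram(ang, bins=np.arange(0, 181, 15))
        top_bins = edges[:-1][np.argsort(hist)[-3:]]
        assert set(top_bins) <= {45.0, 60.0, 105.0, 120.0, 165.0, 180.0}

    def test_random_points_no_dominant_mode(self):
        rng = np.random.default_rng(2)
        sec = BundleSection(centers=rng.uniform(0, 300, (40, 2)))
        ang = triplet_angles(sec)
        hist, _ = np.histogram(ang, bins=np.arange(0, 181, 15))
        # chi-square heuristic: no bin more than 4x the uniform expectation
        assert hist.max() < 4.0 * hist.mean()

    def test_too_few_centers_rejected(self):
        with pytest.raises(InsufficientDataError):
            triplet_angles(BundleSection(centers=np.array([[0.0, 0.0], [30.0, 0.0]])))


class TestMtLength:
    def test_arithmetic(self):
        assert mt_length(10, 3.0, 6) == pytest.approx(10.0)

    def test_control_alm_magnitude(self):
        # N = 31, a = 3 um with ~11.6 terminations gives ~16 um
        assert mt_length(31, 3.0, 11.6) == pytest.approx(16.0, rel=0.01)

    def test_zero_terminations_rejected(self):
        with pytest.raises(InvalidParameterError):
            mt_length(10, 3.0, 0)

    def test_endpoint_counting_simulation(self):
        # rods of known length scattered in a window: the 2Na/T estimator
        # should recover the true length within 15%
        rng = np.random.default_rng(7)
        L_true, window, n_rods = 12.0, 3.0, 3000
        starts = rng.uniform(-L_true, window, n_rods)
        ends = starts + L_true
        covered = (ends > 0) & (starts < window)
        n_sections = 60
        zs = np.linspace(0, window, n_sections)
        counts = [(np.sum((starts[covered] <= z) & (ends[covered] >= z))) for z in zs]
        terminations = np.sum((starts > 0) & (starts < window) & covered) + np.sum(
            (ends > 0) & (ends < window) & covered
        )
        est = mt_length(np.mean(counts), window, terminations)
        assert est == pytest.approx(L_true, rel=0.15)


class TestPiv:
    def _textured_pair(self, shift):
        rng = np.random.default_rng(0)
        from scipy.ndimage import gaussian_filter

        img = gaussian_filter(rng.normal(0, 1, (256, 256)), 2)
        return img, np.roll(img, shift, axis=1)

    def test_pure_translation(self):
        imgA, imgB = self._textured_pair(3)
        vf = piv_displacement(imgA, imgB)
        ok = ~vf.masked
        assert ok.all()
        assert np.allclose(vf.dx[ok], 3.0, atol=0.1)
        assert np.allclose(vf.dy[ok], 0.0, atol=0.1)

    def test_uncorrelated_noise_masked(self):
        rng = np.random.default_rng(1)
        from scipy.ndimage import gaussian_filter

        a = gaussian_filter(rng.normal(0, 1, (256, 256)), 1)
        b = gaussian_filter(rng.normal(0, 1, (256, 256)), 1)
        vf = piv_displacement(a, b)
        assert vf.masked.mean() >= 0.9

    def test_too_small_images_rejected(self):
        with pytest.raises(InvalidSizeError):
            piv_displacement(np.zeros((50, 50)), np.zeros((50, 50)))

    def test_rotation_recovered(self):
        secs, truth = gen_bundle_stack(37, 35.0, 3.0, 5.0, n_sections=2, seed=4)
        c = tuple(truth["centroid_nm"])
        A = render_section_image(secs[0], px_size_nm=2.0, image_px=256, center_nm=c)
        B = render_section_image(secs[1], px_size_nm=2.0, image_px=256, center_nm=c)
        vf = piv_displacement(A, B)
        assert abs(twist_from_field(vf, (127.5, 127.5))) == pytest.approx(5.0, rel=0.10)


class TestPitchProfile:
    def _field(self, dx, dy, x=(100.0,), y=(100.0,)):
        n = len(x)
        return type(
            "VF",
            (),
            dict(
                x=np.array(x),
                y=np.array(y),
                dx=np.full(n, dx),
                dy=np.full(n, dy),
                corr=np.ones(n),
                masked=np.zeros(n, dtype=bool),
            ),
        )()

    def test_forty_five_degrees(self):
        vf = self._field(100.0, 0.0)
        _, th = pitch_profile(vf, (0.0, 0.0), z_nm=100.0, px_size_nm=1.0, n_bins=1)
        assert th[0] == pytest.approx(45.0)

    def test_zero_displacement_zero_pitch(self):
        vf = self._field(0.0, 0.0)
        _, th = pitch_profile(vf, (0.0, 0.0), z_nm=100.0, px_size_nm=1.0, n_bins=1)
        assert th[0] == pytest.approx(0.0)

    def test_all_masked_rejected(self):
        vf = self._field(1.0, 0.0)
        vf.masked[:] = True
        with pytest.raises(NoSignalError):
            pitch_profile(vf, (0.0, 0.0))

    def test_twisted_stack_pitch_increases_with_radius(self):
        twist = 3.0
        secs, truth = gen_bundle_stack(37, 35.0, 3.0, twist, n_sections=2, seed=4)
        c = tuple(truth["centroid_nm"])
        A = render_section_image(secs[0], px_size_nm=2.0, image_px=256, center_nm=c)
        B = render_section_image(secs[1], px_size_nm=2.0, image_px=256, center_nm=c)
        vf = piv_displacement(A, B, search_px=64)
        r, th = pitch_profile(vf, (127.5, 127.5), z_nm=100.0, px_size_nm=2.0, n_bins=5)
        # analytic rigid rotation: |d| = 2 r sin(delta/2)
        th_an = np.degrees(np.arctan2(2 * r * np.sin(np.radians(twist / 2)), 100.0))
        sel = r > 50.0  # inner annuli have near-zero displacement
        assert np.all(np.diff(th) > -1.0)  # increasing within tolerance
        assert np.allclose(th[sel], th_an[sel], rtol=0.25, atol=0.6)

    def test_handedness_flips_with_stack_order(self):
        secs, truth = gen_bundle_stack(37, 35.0, 3.0, 4.0, n_sections=2, seed=4)
        c = tuple(truth["centroid_nm"])
        A = render_section_image(secs[0], px_size_nm=2.0, image_px=256, center_nm=c)
        B = render_section_image(secs[1], px_size_nm=2.0, image_px=256, center_nm=c)
        s_fwd = rotation_sense(piv_displacement(A, B), (127.5, 127.5))
        s_rev = rotation_sense(piv_displacement(B, A), (127.5, 127.5))
        assert s_fwd == -s_rev != 0
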