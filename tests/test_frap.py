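"""FRAP width-widening diffusion estimates and mobile-fraction recovery."""

import warnings

import numpy as np
import pytest

from axonmech.errors import InsufficientDataError, LowSignalError
from axonmech.frap import (
    FrapSeries,
    diffusion_from_widths,
    fit_bleach_profile,
    mobile_fraction,
    series_from_kymograph,
)
from axonmech.synthetic import gen_frap_kymograph


class TestBleachProfileFit:
    def test_noiseless_gaussian_self_fit(self):
        x = np.linspace(0, 20, 400)
        y = 1.0 - 0.5 * np.exp(-((x - 10) ** 2) / (2 * 1.0**2))
        A, c, w = fit_bleach_profile(x, y)
        assert w == pytest.approx(1.0, abs=1e-6)
        assert A == pytest.approx(0.5, abs=1e-6)
        assert c == pytest.approx(10.0, abs=1e-6)

    def test_width_follows_greens_function(self):
        D, w0 = 0.8, 1.0
        stack, tru = gen_frap_kymograph(D, 1.0, bleach_width_um=w0, n_frames=15, frame_dt_s=0.5)
        x = (np.arange(stack.shape[1]) + 0.5) * tru["um_per_px"]
        t_check = 10
        _, _, w = fit_bleach_profile(x, stack[tru["bleach_frame"] + t_check])
        assert w**2 == pytest.approx(w0**2 + 2 * D * t_check * 0.5, rel=0.02)

    def test_flat_profile_low_signal(self):
        x = np.linspace(0, 20, 200)
        with pytest.raises(LowSignalError):
            fit_bleach_profile(x, np.ones_like(x))


class TestDiffusionFromWidths:
    def test_constructed_line_gives_exact_D(self):
        t = np.linspace(0.5, 20, 40)
        series = FrapSeries(
            times=t,
            widths_sq=0.1 + 0.24 * t,
            amplitudes=np.ones_like(t),
            I_pre=1.0,
            I0=0.5,
        )
        assert diffusion_from_widths(series) == pytest.approx(0.12, rel=1e-12)

    def test_generator_recovery_noiseless(self):
        stack, tru = gen_frap_kymograph(1.0, 1.0, n_frames=40, frame_dt_s=0.25)
        ser = series_from_kymograph(stack, tru["frame_dt_s"], tru["um_per_px"], tru["bleach_frame"])
        assert diffusion_from_widths(ser) == pytest.approx(1.0, rel=0.02)

    def test_zero_diffusion_reports_zero(self):
        stack, tru = gen_frap_kymograph(0.0, 1.0, n_frames=20)
        ser = series_from_kymograph(stack, tru["frame_dt_s"], tru["um_per_px"], tru["bleach_frame"])
        assert diffusion_from_widths(ser) == pytest.approx(0.0, abs=1e-9)

    def test_too_few_frames_rejected(self):
        series = FrapSeries(
            times=np.array([1.0, 2.0]),
            widths_sq=np.array([1.0, 1.5]),
            amplitudes=np.array([1.0, 1.0]),
            I_pre=1.0,
            I0=0.5,
        )
        with pytest.raises(InsufficientDataError):
            diffusion_from_widths(series, fit_range=(0, 10))


class TestMobileFraction:
    def test_full_recovery_limit(self):
        stack, tru = gen_frap_kymograph(0.5, 1.0, n_frames=80, frame_dt_s=0.5)
        ser = series_from_kymograph(stack, tru["frame_dt_s"], tru["um_per_px"], tru["bleach_frame"])
        f, tau = mobile_fraction(ser)
        assert f == pytest.approx(1.0, rel=0.02)
        assert tau > 0

    def test_partial_recovery_at_snr20(self):
        # dip depth 0.6, noise 0.03 -> SNR 20
        stack, tru = gen_frap_kymograph(
            0.5, 0.6, noise_sd=0.03, n_frames=80, frame_dt_s=0.5, seed=11
        )
        ser = series_from_kymograph(stack, tru["frame_dt_s"], tru["um_per_px"], tru["bleach_frame"])
        f, _ = mobile_fraction(ser)
        assert f == pytest.approx(0.6, rel=0.05)

    def test_no_recovery_immobile(self):
        stack, tru = gen_frap_kymograph(0.0, 0.0, n_frames=20)
        ser = series_from_kymograph(
            stack, tru["frame_dt_s"], tru["um_per_px"], tru["bleach_frame"], two_component=False
        )
        f, _ = mobile_fraction(ser)
        assert f == pytest.approx(0.0, abs=0.05)


class TestInvariances:
    def test_intensity_rescaling_leaves_D_unchanged(self):
        stack, tru = gen_frap_kymograph(0.7, 0.8, noise_sd=0.0, n_frames=30)
        ser1 = series_from_kymograph(stack, tru["frame_dt_s"], tru["um_per_px"], tru["bleach_frame"])
        ser2 = series_from_kymograph(
            5.0 * stack, tru["frame_dt_s"], tru["um_per_px"], tru["bleach_frame"]
        )
        assert diffusion_from_widths(ser2) == pytest.approx(
            diffusion_from_widths(ser1), rel=1e-6
        )

    def test_parameter_recovery_grid(self):
        # median relative error of (D, f) over the printed D range at SNR 20
        errs = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for D in (0.05, 0.5, 3.0):
                for f in (0.3, 0.6, 1.0):
                    for seed in range(3):
                        stack, tru = gen_frap_kymograph(
                            D, f, noise_sd=0.03, n_frames=60, frame_dt_s=0.5, seed=seed
                        )
                        ser = series_from_kymograph(
                            stack, tru["frame_dt_s"], tru["um_per_px"], tru["bleach_frame"]
                        )
                        D_hat = diffusion_from_widths(ser)
                        f_hat, _ = mobile_fraction(ser)
                        errs.append(abs(D_hat - D) / D)
                        errs.append(abs(f_hat - f) / f)
        assert np.median(errs) < 0.10
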