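"""FRAP analysis: diffusion constants and mobile fractions from kymographs.

Recovery after photobleaching is modeled as one-dimensional diffusion of
fluorophores along the axon. The bleach profile is an inverted Gaussian
whose dispersion obeys the Green's-function relation

    w(t)^2 = w0^2 + 2 D t

so an ordinary least-squares line through w^2(t) has slope 2D. The
intercept is left free: a real bleach spot has finite width at t = 0,
although the ideal point-release solution passes through the origin.

The mobile fraction comes from the normalized region-of-interest recovery

    I_norm(t) = (I_t - I_0) / (I_pre - I_0)

fitted to the single-exponential f (1 - exp(-t/tau)); the plateau f is the
fraction of fluorophores free to exchange.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import (
    FitFailureError,
    InsufficientDataError,
    InvalidParameterError,
    LowSignalError,
)


@dataclass
class FrapSeries:
    """Bleach-profile observables over post-bleach time."""

    times: np.ndarray  # s since bleach
    widths_sq: np.ndarray  # w^2, um^2
    amplitudes: np.ndarray  # dip depth per frame
    I_pre: float  # mean pre-bleach ROI intensity
    I0: float  # ROI intensity at t = 0
    I_t: np.ndarray | None = None  # ROI intensity per frame

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.widths_sq = np.asarray(self.widths_sq, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise InvalidParameterError("times must be strictly increasing")
        if np.any(self.widths_sq <= 0):
            raise InvalidParameterError("widths_sq must be positive")
        if self.I_pre < self.I0:
            raise InvalidParameterError("pre-bleach intensity must be >= bleached intensity")


def fit_bleach_profile(
    x_um: np.ndarray,
    intensity: np.ndarray,
    baseline: float | None = None,
    noise_floor: float | None = None,
) -> tuple[float, float, float]:
    """Fit an inverted Gaussian dip; returns (amplitude, center, w).

    ``w`` is the Gaussian dispersion (sigma). ``baseline`` defaults to the
    mean of the outer quarter of the profile; a dip amplitude below
    ``noise_floor`` (3x the outer-region standard deviation by default)
    raises :class:`LowSignalError`.
    """
    x = np.asarray(x_um, dtype=float)
    y = np.asarray(intensity, dtype=float)
    k = max(len(y) // 8, 2)
    outer = np.concatenate([y[:k], y[-k:]])
    if baseline is None:
        baseline = float(outer.mean())
    if noise_floor is None:
        noise_floor = 3.0 * float(outer.std())
    depth0 = baseline - y.min()
    if depth0 <= noise_floor:
        raise LowSignalError(
            f"dip amplitude {depth0:.3g} below noise floor {noise_floor:.3g}"
        )
    c0 = float(x[np.argmin(y)])
    # moment-based width seed
    dip = np.clip(baseline - y, 0.0, None)
    w0 = float(np.sqrt(np.sum(dip * (x - c0) ** 2) / np.sum(dip)))

    def model(x, A, c, w):
        return baseline - A * np.exp(-((x - c) ** 2) / (2.0 * w**2))

    try:
        popt, _ = curve_fit(
            model, x, y, p0=[depth0, c0, max(w0, np.diff(x).mean())], maxfev=10000
        )
    except RuntimeError as exc:
        raise FitFailureError(f"bleach-profile fit did not converge: {exc}") from exc
    A, c, w = float(popt[0]), float(popt[1]), abs(float(popt[2]))
    return A, c, w


def _fit_two_component(
    x: np.ndarray,
    y: np.ndarray,
    baseline: float,
    center: float,
    w0: float,
) -> tuple[float, float, float]:
    """Decompose a dip into frozen (width w0) + spreading Gaussian components.

    Returns (A_immobile, A_mobile, w_mobile). The immobile pool keeps the
    initial bleach width; only the mobile component widens, so the mobile
    width is the right observable for the w^2 = w0^2 + 2Dt line even when
    a large immobile fraction would otherwise pin a single-Gaussian fit
    near w0.
    """

    def model(x, a_im, a_m, w):
        g0 = np.exp(-((x - center) ** 2) / (2.0 * w0**2))
        g = np.exp(-((x - center) ** 2) / (2.0 * w**2))
        return baseline - a_im * g0 - a_m * g

    depth = baseline - y.min()
    try:
        popt, _ = curve_fit(
            model,
            x,
            y,
            p0=[depth / 2.0, depth / 2.0, 1.5 * w0],
            bounds=([0.0, 0.0, 0.8 * w0], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise FitFailureError(f"two-component profile fit failed: {exc}") from exc
    return float(popt[0]), float(popt[1]), float(popt[2])


def series_from_kymograph(
    stack: np.ndarray,
    frame_dt_s: float,
    um_per_px: float,
    bleach_frame: int,
    roi_halfwidth_um: float | None = None,
    two_component: bool = True,
) -> FrapSeries:
    """Extract a :class:`FrapSeries` from a kymograph (rows = frames).

    The first post-bleach frame fixes the bleach center and initial width
    w0. Later frames are decomposed into a frozen immobile dip plus a
    spreading mobile dip (see :func:`_fit_two_component`); ``widths_sq``
    tracks the mobile component. With ``two_component=False`` each frame
    gets the plain single-Gaussian fit.
    """
    stack = np.asarray(stack, dtype=float)
    x = np.arange(stack.shape[1]) * um_per_px
    pre = stack[:bleach_frame]
    post = stack[bleach_frame:]
    I_pre_profile = pre.mean(axis=0)
    baseline = float(I_pre_profile.mean())
    amp0, c0, w0 = fit_bleach_profile(x, post[0], baseline=baseline)
    if roi_halfwidth_um is None:
        # a narrow ROI (half the initial bleach sigma) makes the normalized
        # recovery close to 1 - w0/w(t), which the plateau fit extrapolates
        # reliably even when the window ends before full recovery
        roi_halfwidth_um = 0.5 * w0
    roi = np.abs(x - c0) <= roi_halfwidth_um
    times, widths_sq, amps, roi_int = [], [], [], []
    for i, prof in enumerate(post):
        t = i * frame_dt_s
        roi_int.append(float(prof[roi].mean()))
        try:
            if two_component and i > 0:
                a_im, a_m, w = _fit_two_component(x, prof, baseline, c0, w0)
                A = a_im + a_m
            else:
                A, _, w = fit_bleach_profile(x, prof, baseline=baseline)
        except (LowSignalError, FitFailureError):
            continue
        times.append(t)
        widths_sq.append(w**2)
        amps.append(A)
    if len(times) < 3:
        raise InsufficientDataError("fewer than 3 usable post-bleach frames")
    return FrapSeries(
        times=np.array(times),
        widths_sq=np.array(widths_sq),
        amplitudes=np.array(amps),
        I_pre=float(I_pre_profile[roi].mean()),
        I0=float(roi_int[0]),
        I_t=np.array(roi_int),
    )


def diffusion_from_widths(
    series: FrapSeries,
    fit_range: tuple[float, float] | None = None,
    t_min_s: float = 0.5,
) -> float:
    """Apparent diffusion constant D = slope/2 of w^2 against t (um^2/s).

    Frames earlier than ``t_min_s`` after the bleach are excluded by
    default (the fresh bleach profile is not yet Gaussian). A negative
    slope beyond tolerance yields D = 0 with a warning.
    """
    t, w2 = series.times, series.widths_sq
    if fit_range is not None:
        m = (t >= fit_range[0]) & (t <= fit_range[1])
    else:
        m = t >= t_min_s
        if m.sum() < 3:
            m = np.ones_like(t, dtype=bool)
    if m.sum() < 3:
        raise InsufficientDataError("need >= 3 frames in the fit range")
    coeffs = np.polyfit(t[m], w2[m], 1)
    slope = float(coeffs[0])
    if slope < 0:
        scale = float(np.std(w2[m])) / max(float(t[m].max() - t[m].min()), 1e-12)
        if abs(slope) > 0.05 * max(scale, 1e-12):
            warnings.warn("w^2(t) slope negative; no measurable recovery, D set to 0")
        return 0.0
    return slope / 2.0


def mobile_fraction(series: FrapSeries, model: str = "auto") -> tuple[float, float]:
    """Mobile fraction and recovery time from normalized ROI recovery.

    The normalized trace I_norm(t) = (I_t - I_0)/(I_pre - I_0) is fitted to
    a saturating recovery with plateau f:

    - ``exponential``: f (1 - exp(-t/tau)), the conventional single-
      exponential recovery;
    - ``diffusive``: f (1 - 1/sqrt(1 + t/tau)), the shape of 1-D diffusive
      refilling of the bleach region, whose slow tail an exponential
      truncates (biasing f low when the window is short);
    - ``auto`` (default): both, keeping the lower-residual fit.

    Returns (f, tau). If tau exceeds the observation window a wide-
    confidence warning is emitted.
    """
    if series.I_t is None:
        raise InsufficientDataError("series carries no ROI intensity trace")
    if len(series.I_t) < 5:
        raise InsufficientDataError("need >= 5 post-bleach frames")
    if series.I_pre <= series.I0:
        raise InvalidParameterError("I_pre must exceed I0 for normalization")
    dt = float(np.median(np.diff(series.times)))
    t = np.arange(len(series.I_t)) * dt
    norm = (series.I_t - series.I0) / (series.I_pre - series.I0)
    t_span = float(t[-1]) if t[-1] > 0 else 1.0

    shapes = {
        "exponential": lambda t, f, tau: f * (1.0 - np.exp(-t / tau)),
        "diffusive": lambda t, f, tau: f * (1.0 - 1.0 / np.sqrt(1.0 + t / tau)),
    }
    if model != "auto":
        if model not in shapes:
            raise InvalidParameterError(f"unknown recovery model {model!r}")
        candidates = [model]
    else:
        candidates = list(shapes)
    best = None
    for name in candidates:
        fn = shapes[name]
        try:
            popt, _ = curve_fit(
                fn,
                t,
                norm,
                p0=[min(max(norm[-1], 0.1), 1.0), t_span / 5.0],
                bounds=([0.0, 1e-9], [1.05, np.inf]),
                maxfev=10000,
            )
        except RuntimeError:
            continue
        ssr = float(np.sum((norm - fn(t, *popt)) ** 2))
        if best is None or ssr < best[0]:
            best = (ssr, float(popt[0]), float(popt[1]))
    if best is None:
        raise FitFailureError("recovery fit did not converge for any model")
    _, f, tau = best
    if tau > t_span:
        warnings.warn("recovery time exceeds observation window; plateau uncertain")
    return f, tau
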