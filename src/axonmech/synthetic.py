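"""Seeded synthetic-data generators for every pipeline stage.

Each generator is a pure function of its parameters and a seed, and
returns the observable (centerline, kymograph, force curve, bundle stack,
intensity profile, worm posture) together with a ground-truth record
containing exactly the parameters the paired analysis stage estimates, so
every stage supports parameter-recovery tests without any external data.

Noise models are deliberately simple and match the least-squares
assumptions of the fitters: additive Gaussian noise on intensities and
forces, isotropic Gaussian jitter on coordinates.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from .afm import ForceCurve, TipModel, invert_modulus
from .bundle import DEFAULT_MT_RADIUS_NM, BundleSection
from .errors import InvalidParameterError
from .shape import Centerline


@dataclass
class SyntheticSpec:
    """A reproducible recipe: (kind, params, seed) -> identical output."""

    kind: str  # centerline | frap_kymograph | force_curve | bundle_stack | periodic_profile | worm_posture
    params: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def generate(self):
        try:
            fn = _GENERATORS[self.kind]
        except KeyError:
            raise InvalidParameterError(
                f"unknown synthetic kind {self.kind!r}; options: {sorted(_GENERATORS)}"
            ) from None
        return fn(seed=self.seed, **self.params)


# ---------------------------------------------------------------------------
# centerlines


def gen_centerline(
    length_um: float,
    mode: str = "straight",
    amplitude_um: float = 1.0,
    wavelength_um: float = 13.0,
    noise_um: float = 0.0,
    px_per_um: float = 10.0,
    seed: int = 0,
) -> tuple[Centerline, dict]:
    """Synthetic 2-D axon centerline spanning ``length_um`` of arclength.

    Modes: ``straight``; ``sinusoid`` (transverse wave of the given
    amplitude/wavelength); ``helix_projection`` (sinusoid with the
    foreshortened longitudinal coordinate of a projected helix);
    ``plectoneme_like`` (straight backbone with self-crossing loops of
    radius ``amplitude_um`` inserted every ``wavelength_um`` of backbone).
    """
    if length_um <= 0:
        raise InvalidParameterError("length_um must be > 0")
    if mode in ("sinusoid", "helix_projection", "plectoneme_like") and wavelength_um <= 0:
        raise InvalidParameterError("wavelength_um must be > 0 for periodic modes")
    if noise_um < 0 or px_per_um <= 0:
        raise InvalidParameterError("noise_um >= 0 and px_per_um > 0 required")
    rng = np.random.default_rng(seed)
    scale = 1.0 / px_per_um  # um per px
    ds = scale  # sample spacing along arclength, um
    truth: dict[str, Any] = {
        "mode": mode,
        "length_um": length_um,
        "amplitude_um": amplitude_um,
        "wavelength_um": wavelength_um,
        "noise_um": noise_um,
    }
    if mode == "straight":
        n = int(round(length_um / ds)) + 1
        x = np.arange(n) * ds
        y = np.zeros(n)
    elif mode == "sinusoid":
        # wave parameterized by arclength: y = A sin(2 pi s / lambda), so
        # crest-to-crest spacing equals the wavelength measured along the
        # contour (the convention of the defect-spacing statistic)
        k = 2 * np.pi / wavelength_um
        if amplitude_um * k >= 1.0:
            raise InvalidParameterError(
                "sinusoid slope A*2pi/lambda must be < 1 for an arclength wave"
            )
        n = int(round(length_um / ds)) + 1
        s = np.arange(n) * ds
        y = amplitude_um * np.sin(k * s)
        dx = np.sqrt(np.clip(ds**2 - np.diff(y) ** 2, 1e-12 * ds**2, None))
        x = np.concatenate([[0.0], np.cumsum(dx)])
    elif mode == "helix_projection":
        # planar projection of a circular helix of unit-speed arclength s:
        # (c s, A sin(w s)) with c^2 + (A w)^2 = 1
        w = 2 * np.pi / wavelength_um
        if amplitude_um * w >= 1.0:
            raise InvalidParameterError(
                "helix amplitude*2pi/wavelength must be < 1 (pitch angle < 90 deg)"
            )
        c = np.sqrt(1.0 - (amplitude_um * w) ** 2)
        s = np.arange(0.0, length_um + ds / 2, ds)
        x = c * s
        y = amplitude_um * np.sin(w * s)
    elif mode == "plectoneme_like":
        loop_r = amplitude_um
        circ = 2 * np.pi * loop_r
        gap = wavelength_um - circ  # straight backbone between loop centers
        if gap <= 0:
            raise InvalidParameterError(
                f"loop circumference {circ:.1f} um exceeds wavelength {wavelength_um} um"
            )
        pts = [np.array([0.0, 0.0])]
        loop_centers = []  # arclength of each loop's crossing point
        s_arc = 0.0
        next_loop = wavelength_um / 2.0
        while s_arc < length_um:
            if s_arc >= next_loop:
                x0, _ = pts[-1]
                n_loop = max(int(circ / ds), 12)
                t_loop = np.linspace(0.0, 2 * np.pi, n_loop, endpoint=False)[1:]
                loop = np.column_stack(
                    [x0 + loop_r * np.sin(t_loop), loop_r * (1.0 - np.cos(t_loop))]
                )
                pts.extend(list(loop))
                pts.append(np.array([x0 + ds, 0.0]))
                loop_centers.append(s_arc + circ / 2.0)
                next_loop += wavelength_um
                s_arc += circ + ds
            else:
                x0, _ = pts[-1]
                pts.append(np.array([x0 + ds, 0.0]))
                s_arc += ds
        arr = np.array(pts)
        x, y = arr[:, 0], arr[:, 1]
        truth["loop_centers_arclength_um"] = loop_centers
        truth["n_loops"] = len(loop_centers)
    else:
        raise InvalidParameterError(f"unknown centerline mode {mode!r}")
    y = y + rng.normal(0.0, noise_um, len(y))
    pts_px = np.column_stack([x, y]) / scale
    return Centerline(points=pts_px, scale=scale), truth


# ---------------------------------------------------------------------------
# FRAP kymographs


def gen_frap_kymograph(
    D_um2_s: float,
    mobile_fraction: float,
    bleach_width_um: float = 1.0,
    frame_dt_s: float = 0.5,
    n_frames: int = 60,
    noise_sd: float = 0.0,
    seed: int = 0,
    length_um: float = 30.0,
    px_per_um: float = 10.0,
    n_prebleach: int = 5,
    bleach_depth: float = 0.6,
) -> tuple[np.ndarray, dict]:
    """Kymograph (rows = frames) of 1-D diffusive recovery with an immobile pool.

    The mobile component of the bleach dip spreads with variance
    w0^2 + 2 D t while conserving its area; the immobile fraction is a
    frozen copy of the initial dip. Pre-bleach frames sit at the baseline.
    """
    if D_um2_s < 0:
        raise InvalidParameterError("D must be >= 0")
    if not 0.0 <= mobile_fraction <= 1.0:
        raise InvalidParameterError("mobile_fraction must be in [0, 1]")
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    nx = int(round(length_um * px_per_um))
    x = (np.arange(nx) + 0.5) / px_per_um
    c = length_um / 2.0
    w0 = bleach_width_um
    baseline = 1.0
    frames = []
    for _ in range(n_prebleach):
        frames.append(np.full(nx, baseline))
    for i in range(n_frames):
        t = i * frame_dt_s
        w_t = np.sqrt(w0**2 + 2.0 * D_um2_s * t)
        mobile_dip = (
            mobile_fraction
            * bleach_depth
            * (w0 / w_t)
            * np.exp(-((x - c) ** 2) / (2.0 * w_t**2))
        )
        immobile_dip = (1.0 - mobile_fraction) * bleach_depth * np.exp(
            -((x - c) ** 2) / (2.0 * w0**2)
        )
        frames.append(baseline - mobile_dip - immobile_dip)
    stack = np.array(frames)
    if noise_sd > 0:
        stack = stack + rng.normal(0.0, noise_sd, stack.shape)
    truth = {
        "D_um2_s": D_um2_s,
        "mobile_fraction": mobile_fraction,
        "bleach_width_um": bleach_width_um,
        "frame_dt_s": frame_dt_s,
        "bleach_frame": n_prebleach,
        "um_per_px": 1.0 / px_per_um,
        "bleach_depth": bleach_depth,
        "baseline": baseline,
    }
    return stack, truth


# ---------------------------------------------------------------------------
# AFM force curves


def gen_force_curve(
    E_axon_pa: float,
    tip_diameter_m: float = 60e-9,
    max_indent_m: float = 100e-9,
    noise_n: float = 0.0,
    seed: int = 0,
    n_points: int = 200,
    tip: TipModel | None = None,
) -> tuple[ForceCurve, dict]:
    """Hertzian F = a d^1.5 force-indentation curve for a given modulus.

    The prefactor is obtained by inverting the sphere-on-cylinder contact
    relation, so generator and fitter form an exact round trip at zero
    noise.
    """
    if E_axon_pa <= 0:
        raise InvalidParameterError("E_axon_pa must be > 0")
    if max_indent_m <= 0:
        raise InvalidParameterError("max_indent_m must be > 0")
    if noise_n < 0:
        raise InvalidParameterError("noise_n must be >= 0")
    rng = np.random.default_rng(seed)
    tip = tip or TipModel(tip_diameter=tip_diameter_m)
    a = invert_modulus(E_axon_pa, tip)
    d = np.linspace(0.0, max_indent_m, n_points)
    F = a * d**1.5
    if noise_n > 0:
        F = F + rng.normal(0.0, noise_n, len(F))
    truth = {"E_axon_pa": E_axon_pa, "a": a, "tip_diameter_m": tip.tip_diameter}
    return ForceCurve(indentation=d, force=F), truth


# ---------------------------------------------------------------------------
# MT bundle stacks


def _hex_lattice(n: int, spacing: float) -> np.ndarray:
    """First ``n`` sites of a hexagonal lattice, sorted radially."""
    m = int(np.ceil(np.sqrt(n))) + 2
    pts = []
    for i in range(-m, m + 1):
        for j in range(-m, m + 1):
            pts.append((spacing * (i + 0.5 * j), spacing * (np.sqrt(3) / 2.0) * j))
    pts = np.array(pts)
    order = np.argsort((pts**2).sum(axis=1), kind="stable")
    return pts[order[:n]]


def gen_bundle_stack(
    n_mts: int,
    lattice_spacing_nm: float = 35.0,
    jitter_nm: float = 0.0,
    twist_deg_per_section: float = 0.0,
    section_thickness_nm: float = 50.0,
    n_sections: int = 1,
    seed: int = 0,
    mt_radius_nm: float = DEFAULT_MT_RADIUS_NM,
) -> tuple[list[BundleSection], dict]:
    """Serial sections of a (possibly twisted) jittered hexagonal MT bundle.

    Section 0 is a hexagonal packing with isotropic Gaussian jitter;
    section i+1 is section i rotated rigidly by ``twist_deg_per_section``
    about the bundle centroid.
    """
    if n_mts < 3:
        raise InvalidParameterError("n_mts must be >= 3")
    if lattice_spacing_nm <= 2.0 * mt_radius_nm:
        raise InvalidParameterError(
            f"lattice spacing {lattice_spacing_nm} nm <= MT diameter "
            f"{2 * mt_radius_nm} nm; profiles would overlap"
        )
    rng = np.random.default_rng(seed)
    base = _hex_lattice(n_mts, lattice_spacing_nm)
    base = base + rng.normal(0.0, jitter_nm, base.shape)
    centroid = base.mean(axis=0)
    sections = []
    ang = np.radians(twist_deg_per_section)
    for k in range(n_sections):
        rot = np.array(
            [[np.cos(k * ang), -np.sin(k * ang)], [np.sin(k * ang), np.cos(k * ang)]]
        )
        pts = (base - centroid) @ rot.T + centroid
        sections.append(
            BundleSection(
                centers=pts,
                radii=np.full(n_mts, mt_radius_nm),
                section_index=k,
                thickness_nm=section_thickness_nm,
            )
        )
    truth = {
        "n_mts": n_mts,
        "lattice_spacing_nm": lattice_spacing_nm,
        "jitter_nm": jitter_nm,
        "twist_deg_per_section": twist_deg_per_section,
        "section_thickness_nm": section_thickness_nm,
        "centroid_nm": centroid.tolist(),
        "edge_to_edge_nm": lattice_spacing_nm - 2.0 * mt_radius_nm,
    }
    return sections, truth


def render_section_image(
    section: BundleSection,
    px_size_nm: float = 4.0,
    image_px: int = 256,
    spot_sigma_nm: float = 10.0,
    center_nm: tuple[float, float] | None = None,
) -> np.ndarray:
    """Rasterize a section as bright Gaussian spots (for PIV analysis)."""
    img = np.zeros((image_px, image_px))
    if center_nm is None:
        center_nm = tuple(section.centers.mean(axis=0))
    half = image_px / 2.0
    yy, xx = np.mgrid[0:image_px, 0:image_px]
    for cx, cy in section.centers:
        px = (cx - center_nm[0]) / px_size_nm + half
        py = (cy - center_nm[1]) / px_size_nm + half
        s = spot_sigma_nm / px_size_nm
        img += np.exp(-((xx - px) ** 2 + (yy - py) ** 2) / (2.0 * s**2))
    return img


# ---------------------------------------------------------------------------
# periodic intensity profiles


def gen_periodic_profile(
    period_nm: float,
    length_um: float = 10.0,
    psf_fwhm_nm: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    sample_nm: float = 20.0,
    amplitude: float = 1.0,
    baseline: float = 2.0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Spectrin-like periodic intensity profile with PSF blur and noise.

    Returns (positions_nm, intensity, truth). ``period_nm`` of 0 or None
    generates a structureless (noise-only) profile for null tests.
    """
    if noise_sd < 0 or sample_nm <= 0 or length_um <= 0:
        raise InvalidParameterError("invalid profile parameters")
    has_period = bool(period_nm)
    if has_period and period_nm <= 2.0 * sample_nm:
        raise InvalidParameterError(
            f"period {period_nm} nm violates Nyquist for {sample_nm} nm sampling"
        )
    rng = np.random.default_rng(seed)
    n = int(round(length_um * 1000.0 / sample_nm))
    x = np.arange(n) * sample_nm
    y = np.full(n, float(baseline))
    if has_period:
        y = y + amplitude * np.cos(2 * np.pi * x / period_nm)
    if psf_fwhm_nm > 0:
        from scipy.ndimage import gaussian_filter1d

        y = gaussian_filter1d(y, sigma=psf_fwhm_nm / 2.3548 / sample_nm, mode="reflect")
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, n)
    y = np.clip(y, 0.0, None)
    truth = {
        "period_nm": period_nm if has_period else None,
        "psf_fwhm_nm": psf_fwhm_nm,
        "noise_sd": noise_sd,
        "sample_nm": sample_nm,
        "amplitude": amplitude,
    }
    return x, y, truth


# ---------------------------------------------------------------------------
# worm posture


def gen_worm_posture(
    curvature_series,
    z_offset_um: float,
    neuron_rest_length_um: float = 100.0,
    seed: int = 0,
    n_points: int = 200,
    noise_um: float = 0.0,
) -> tuple[list[dict], dict]:
    """Per-frame body and neuron centerlines under Euler-beam bending.

    The body midline is an arc of the given curvature per frame; the
    neuron runs parallel at signed offset ``z`` from the neutral axis, so
    its arclength is rest_length * (1 + c z) exactly.
    """
    c_series = np.atleast_1d(np.asarray(curvature_series, dtype=float))
    if np.any(np.abs(c_series) * abs(z_offset_um) >= 1.0):
        raise InvalidParameterError("|curvature| * z must be < 1 (physical strain)")
    rng = np.random.default_rng(seed)
    L = neuron_rest_length_um
    frames = []
    for c in c_series:
        s = np.linspace(0.0, L, n_points)
        if abs(c) < 1e-12:
            body = np.column_stack([s, np.zeros_like(s)])
            neuron = np.column_stack([s, np.full_like(s, -z_offset_um)])
        else:
            R = 1.0 / c
            phi = s / R
            body = np.column_stack([R * np.sin(phi), R * (1.0 - np.cos(phi))])
            # neuron offset z on the outer (convex) side: radius R + z
            Rn = R + z_offset_um
            neuron = np.column_stack([Rn * np.sin(phi), R - Rn * np.cos(phi)])
        if noise_um > 0:
            neuron = neuron + rng.normal(0.0, noise_um, neuron.shape)
        frames.append(
            {
                "body": Centerline(points=body, scale=1.0),
                "neuron": Centerline(points=neuron, scale=1.0),
                "curvature_per_um": float(c),
            }
        )
    truth = {
        "curvature_series": c_series.tolist(),
        "z_offset_um": z_offset_um,
        "neuron_rest_length_um": neuron_rest_length_um,
        "neuron_strain": (c_series * z_offset_um).tolist(),
    }
    return frames, truth


_GENERATORS = {
    "centerline": gen_centerline,
    "frap_kymograph": gen_frap_kymograph,
    "force_curve": gen_force_curve,
    "bundle_stack": gen_bundle_stack,
    "periodic_profile": gen_periodic_profile,
    "worm_posture": gen_worm_posture,
}


def write_truth_sidecar(path: str | Path, truth: dict) -> Path:
    """Write the ground-truth record as <output>.truth.json next to a file."""
    path = Path(path)
    sidecar = path.with_name(path.name + ".truth.json")
    sidecar.write_text(json.dumps(truth, indent=2, default=float))
    return sidecar
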