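"""Axon shape quantification from centerlines.

The deviation of a neurite from the straightest possible path is scored by
a mean-squared-displacement statistic over the ordered centerline points:

    <x^2>(n) = (1/(N-n)) sum_i [ (x_{i+n} - x_i)^2 + (y_{i+n} - y_i)^2 ]

which for a perfectly straight, unit-spaced line equals n^2 (the square of
the contour). Fitting

    <x^2> = S^2 n^2 + D n

separates the directed component (persistence S) from the random
transverse component: D is zero for a straight neuron and grows with local
shape disorder. Bending kinematics follow the Euler beam relation
eps = c * z: axial strain is the product of body curvature and distance
from the neutral bending axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateGeometryError,
    InsufficientDataError,
    InvalidParameterError,
    TopologyError,
)


@dataclass
class Centerline:
    """Ordered centerline points in pixel convention with physical scale.

    ``points`` are (x, y[, z]) coordinates, 0-based, row = y; ``scale``
    converts pixels to micrometers.
    """

    points: np.ndarray
    scale: float = 1.0  # um per pixel

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or len(self.points) < 2:
            raise InvalidParameterError("centerline needs >= 2 ordered points")
        if np.any(np.all(np.diff(self.points, axis=0) == 0, axis=1)):
            raise InvalidParameterError("consecutive centerline points must be distinct")

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def step_lengths_px(self) -> np.ndarray:
        return np.sqrt((np.diff(self.points, axis=0) ** 2).sum(axis=1))

    @property
    def arclength_px(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(self.step_lengths_px)])

    @property
    def length_um(self) -> float:
        return float(self.step_lengths_px.sum() * self.scale)

    @property
    def points_um(self) -> np.ndarray:
        return self.points * self.scale


@dataclass
class DeviationFit:
    """Result of the <x^2> = S^2 n^2 + D n fit (pixel convention)."""

    S: float
    Ddev: float
    msd_curve: np.ndarray
    fit_range: tuple[int, int]
    residual: float


@dataclass
class StrainSeries:
    """Per-frame neuron strain paired with Euler-beam bending strain."""

    times: np.ndarray
    neuron_strain: np.ndarray
    bending_strain: np.ndarray | None = None
    curvature: np.ndarray | None = None
    offset: float | None = None
    rest_length_um: float = field(default=np.nan)


# ---------------------------------------------------------------------------
# centerline extraction


def extract_centerline(
    binary_image: np.ndarray, scale: float, smooth_px: int = 5
) -> Centerline:
    """Skeletonize a binary axon image and return the ordered main path.

    The image must contain a single curvilinear 8-connected foreground
    component; side branches are discarded by taking the longest
    endpoint-to-endpoint geodesic through the skeleton. A light moving
    average (``smooth_px`` samples) removes the pixel staircase, which
    would otherwise inflate arclength by several percent.
    """
    import networkx as nx
    from skimage.measure import label
    from skimage.morphology import skeletonize

    img = np.asarray(binary_image) > 0
    if not img.any():
        raise InsufficientDataError("blank image: no foreground")
    lab = label(img, connectivity=2)
    sizes = np.bincount(lab.ravel())[1:]
    if len(sizes) > 1:
        order = np.sort(sizes)[::-1]
        if order[1] >= 0.9 * order[0]:
            raise TopologyError(
                "multiple comparable foreground components; ambiguous input"
            )
        img = lab == (int(np.argmax(sizes)) + 1)
    skel = skeletonize(img)
    rr, cc = np.nonzero(skel)
    coords = list(zip(rr.tolist(), cc.tolist()))
    index = {p: i for i, p in enumerate(coords)}
    G = nx.Graph()
    G.add_nodes_from(range(len(coords)))
    for (r, c) in coords:
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                q = (r + dr, c + dc)
                if q in index:
                    G.add_edge(index[(r, c)], index[q], weight=float(np.hypot(dr, dc)))
    degrees = dict(G.degree())
    endpoints = [v for v, d in degrees.items() if d == 1]
    if not endpoints:
        raise TopologyError("skeleton has no endpoints (closed loop?)")
    # farthest-pair geodesic: two sweeps of Dijkstra from an arbitrary endpoint
    import networkx.algorithms.shortest_paths.weighted as spw

    def farthest_from(src):
        dist = spw.single_source_dijkstra_path_length(G, src)
        v = max(dist, key=dist.get)
        return v, dist[v]

    a, _ = farthest_from(endpoints[0])
    b, _ = farthest_from(a)
    path = nx.dijkstra_path(G, a, b)
    if len(path) < 2:
        raise InsufficientDataError("degenerate skeleton")
    pts = np.array([(coords[i][1], coords[i][0]) for i in path], dtype=float)  # (x, y)
    if smooth_px and len(pts) > smooth_px:
        k = np.ones(smooth_px) / smooth_px
        pad = smooth_px // 2
        sm = np.column_stack(
            [
                np.convolve(np.pad(pts[:, c], pad, mode="edge"), k, mode="valid")
                for c in (0, 1)
            ]
        )
        keep = np.any(np.abs(np.diff(sm, axis=0)) > 1e-12, axis=1)
        pts = sm[np.concatenate([[True], keep])]
    return Centerline(points=pts, scale=scale)


def detrend_centerline(cl: Centerline, poly_order: int = 2) -> Centerline:
    """Remove the smooth body-curvature trend from the transverse coordinate.

    The transverse (y) coordinate is replaced by its residual from a
    least-squares polynomial of the stated order in the longitudinal (x)
    coordinate.
    """
    if cl.n_points < poly_order + 2:
        raise InsufficientDataError(
            f"need >= {poly_order + 2} points for order-{poly_order} detrending"
        )
    x, y = cl.points[:, 0], cl.points[:, 1]
    if len(np.unique(x)) < poly_order + 1:
        raise DegenerateGeometryError("longitudinal coordinate is rank-deficient")
    # scale x for conditioning
    x0, xs = x.mean(), max(x.std(), 1e-12)
    coeffs = np.polynomial.polynomial.polyfit((x - x0) / xs, y, poly_order)
    trend = np.polynomial.polynomial.polyval((x - x0) / xs, coeffs)
    out = cl.points.copy()
    out[:, 1] = y - trend
    return Centerline(points=out, scale=cl.scale)


# ---------------------------------------------------------------------------
# deviation metric


def msd_profile(cl: Centerline, transverse_only: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Windowed mean-squared displacement <x^2>(n) for n = 1 .. N-2.

    Averages (x_{i+n}-x_i)^2 + (y_{i+n}-y_i)^2 over all N-n windows. With
    ``transverse_only`` the longitudinal term is dropped (deviation
    perpendicular to the long axis only).
    """
    pts = cl.points
    N = len(pts)
    if N < 3:
        raise InsufficientDataError("need >= 3 points for an MSD profile")
    ns = np.arange(1, N - 1)
    msd = np.empty(len(ns))
    cols = pts[:, 1:2] if transverse_only else pts[:, :2]
    for idx, n in enumerate(ns):
        d = cols[n:] - cols[:-n]
        msd[idx] = float(np.mean((d**2).sum(axis=1)))
    return ns, msd


def fit_deviation(
    msd: tuple[np.ndarray, np.ndarray] | np.ndarray,
    fit_range: tuple[int, int] | None = None,
) -> DeviationFit:
    """Fit <x^2> = S^2 n^2 + D n and return persistence S and deviation D.

    ``msd`` is the (n, <x^2>) pair from :func:`msd_profile` (or a bare
    <x^2> array for n = 1, 2, ...). The default fit range is n = 1 .. N/4;
    unconstrained least squares may return a tiny negative quadratic or
    linear coefficient for a perfectly straight input, so both are clipped
    at zero.
    """
    if isinstance(msd, tuple):
        ns, vals = msd
    else:
        vals = np.asarray(msd, dtype=float)
        ns = np.arange(1, len(vals) + 1)
    ns = np.asarray(ns, dtype=float)
    if fit_range is None:
        n_max = max(int(len(ns) // 4), 3)
        fit_range = (1, int(ns[min(n_max, len(ns) - 1)]))
    lo, hi = fit_range
    mask = (ns >= lo) & (ns <= hi)
    if mask.sum() < 3:
        raise InsufficientDataError("need >= 3 points in the fit range")
    n_f, y_f = ns[mask], vals[mask]
    X = np.column_stack([n_f**2, n_f])
    try:
        coef, res, rank, _ = np.linalg.lstsq(X, y_f, rcond=None)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise DegenerateGeometryError(f"deviation fit failed: {exc}") from exc
    a, b = float(coef[0]), float(coef[1])
    fitted = X @ coef
    residual = float(np.sum((y_f - fitted) ** 2))
    S = float(np.sqrt(max(a, 0.0)))
    D = max(b, 0.0)
    # clip sub-rounding negatives only; flag D=0 when |b| is numerically zero
    if abs(b) < 1e-8 * max(vals.max(), 1.0):
        D = 0.0
    return DeviationFit(S=S, Ddev=D, msd_curve=vals, fit_range=(int(lo), int(hi)), residual=residual)


def defect_spacing(
    cl: Centerline,
    amplitude_threshold_px: float | None = None,
) -> tuple[float, np.ndarray]:
    """Arclength spacings (um) between transverse-deviation maxima.

    Defects are local maxima of the (detrended) transverse coordinate that
    exceed an amplitude threshold, 3x the median absolute transverse
    deviation by default. Returns (mean spacing, per-interval spacings).
    """
    from scipy.signal import find_peaks

    y = cl.points[:, 1]
    if amplitude_threshold_px is None:
        # 3x MAD for sparse defects on a quiet baseline, capped at half the
        # largest excursion so dense regular undulations are still counted
        mad = float(np.median(np.abs(y - np.median(y))))
        amplitude_threshold_px = min(3.0 * mad, 0.5 * float(np.max(y, initial=0.0)))
    # prominence keeps pixel-noise wiggles on a defect crest from being
    # counted as separate defects
    peaks, _ = find_peaks(
        y, height=amplitude_threshold_px, prominence=0.5 * amplitude_threshold_px
    )
    if len(peaks) < 2:
        raise InsufficientDataError(
            f"found {len(peaks)} defects above threshold; need >= 2 for spacings"
        )
    s = cl.arclength_px[peaks] * cl.scale
    intervals = np.diff(s)
    return float(intervals.mean()), intervals


# ---------------------------------------------------------------------------
# bending-strain kinematics


def bending_strain(c_per_um, z_um):
    """Euler-beam axial strain eps = c * z (elementwise)."""
    return np.asarray(c_per_um, dtype=float) * z_um


def _mean_abs_curvature(cl: Centerline) -> float:
    p = cl.points_um[:, :2]
    t = np.diff(p, axis=0)
    lengths = np.sqrt((t**2).sum(axis=1))
    t = t / lengths[:, None]
    cross = t[:-1, 0] * t[1:, 1] - t[:-1, 1] * t[1:, 0]
    dot = np.clip((t[:-1] * t[1:]).sum(axis=1), -1.0, 1.0)
    ang = np.arctan2(cross, dot)
    return float(np.sum(np.abs(ang)) / np.sum(lengths))


def neuron_strain(
    frames: list[Centerline],
    rest_length_rule: str = "min_curvature",
    times=None,
    curvature_series=None,
    z_um: float | None = None,
) -> StrainSeries:
    """Normalized length change dL/L per frame, optionally paired with c*z.

    The rest length is the arclength at the frame of minimum mean absolute
    curvature (``min_curvature``, default) or the first frame (``first``).
    """
    if len(frames) < 2:
        raise InsufficientDataError("need >= 2 frames")
    for i, f in enumerate(frames):
        if f.n_points < 2:
            raise InvalidParameterError(f"frame {i} has fewer than 2 points")
    lengths = np.array([f.length_um for f in frames])
    if rest_length_rule == "first":
        rest = lengths[0]
    elif rest_length_rule == "min_curvature":
        curv = [_mean_abs_curvature(f) for f in frames]
        rest = lengths[int(np.argmin(curv))]
    else:
        raise InvalidParameterError(f"unknown rest_length_rule {rest_length_rule!r}")
    strain = (lengths - rest) / rest
    t = np.arange(len(frames), dtype=float) if times is None else np.asarray(times, float)
    bend = None
    curv_arr = None
    if curvature_series is not None and z_um is not None:
        curv_arr = np.asarray(curvature_series, dtype=float)
        bend = bending_strain(curv_arr, z_um)
    return StrainSeries(
        times=t,
        neuron_strain=strain,
        bending_strain=bend,
        curvature=curv_arr,
        offset=z_um,
        rest_length_um=float(rest),
    )
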