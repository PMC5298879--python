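"""Microtubule-bundle morphometrics from serial EM sections.

Cross-sections through a touch-receptor neuron show a bundle of 15-
protofilament microtubules (MT) packed approximately hexagonally. From the
per-section MT center coordinates this module measures:

- edge-to-edge distances between adjacent MTs (Delaunay adjacency with
  long-edge pruning), summarized by the geometric mean of a log-normal
  distribution and the raw-scale variance in nm^2;
- inter-MT angles subtended at each MT by pairs of adjacent neighbors
  (hexagonal order shows modes at 60, 120 and 180 degrees);
- average MT length from counts and terminations, L = 2 N a / T;
- the helical pitch of twisted bundles via particle image velocimetry
  between section pairs: theta(r) = atan(|d|(r) / z) with z the section
  separation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import (
    InsufficientDataError,
    InvalidParameterError,
    InvalidSizeError,
    NoSignalError,
)

DEFAULT_MT_RADIUS_NM = 12.5


@dataclass
class BundleSection:
    """MT profile centers (nm) of one EM cross-section."""

    centers: np.ndarray  # (n, 2) nm
    radii: np.ndarray | None = None  # nm
    section_index: int = 0
    thickness_nm: float = 50.0
    oblique: np.ndarray | None = None  # bool flags; oblique profiles excluded

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        if self.radii is None:
            self.radii = np.full(len(self.centers), DEFAULT_MT_RADIUS_NM)
        else:
            self.radii = np.asarray(self.radii, dtype=float)
        if np.any(self.radii <= 0):
            raise InvalidParameterError("radii must be > 0")
        if self.oblique is not None:
            keep = ~np.asarray(self.oblique, dtype=bool)
            self.centers = self.centers[keep]
            self.radii = self.radii[keep]
            self.oblique = None

    @property
    def n_mts(self) -> int:
        return len(self.centers)


@dataclass
class BundleSummary:
    geometric_mean_nm: float
    variance_nm2: float
    contact_fraction: float
    angle_histogram: np.ndarray
    angle_bins_deg: np.ndarray
    n_mts_per_section: float
    mt_length_um: float | None = None
    pitch_r_nm: np.ndarray | None = None
    pitch_theta_deg: np.ndarray | None = None


# ---------------------------------------------------------------------------
# adjacency and spacing


def _adjacent_pairs(section: BundleSection, prune_factor: float = 2.5) -> np.ndarray:
    """Delaunay-adjacent index pairs, long edges pruned.

    Edges longer than ``prune_factor`` times the median edge length are
    removed; degenerate (collinear) configurations fall back to
    nearest-neighbor pairs with a warning.
    """
    pts = section.centers
    n = len(pts)
    if n < 2:
        raise InsufficientDataError("need >= 2 MT centers")
    if n == 2:
        return np.array([[0, 1]])
    try:
        from scipy.spatial import Delaunay, QhullError

        tri = Delaunay(pts)
        edges = set()
        for simplex in tri.simplices:
            for a in range(3):
                i, j = int(simplex[a]), int(simplex[(a + 1) % 3])
                edges.add((min(i, j), max(i, j)))
        pairs = np.array(sorted(edges))
    except (QhullError, ValueError):
        warnings.warn("degenerate triangulation; falling back to nearest neighbors")
        from scipy.spatial import cKDTree

        tree = cKDTree(pts)
        _, idx = tree.query(pts, k=2)
        pairs = np.unique(np.sort(np.column_stack([np.arange(n), idx[:, 1]]), axis=1), axis=0)
    lengths = np.sqrt(((pts[pairs[:, 0]] - pts[pairs[:, 1]]) ** 2).sum(axis=1))
    keep = lengths <= prune_factor * np.median(lengths)
    return pairs[keep]


def edge_distances(section: BundleSection, prune_factor: float = 2.5) -> np.ndarray:
    """Edge-to-edge distances (nm) between adjacent MTs, floored at 0."""
    pairs = _adjacent_pairs(section, prune_factor)
    pts, r = section.centers, section.radii
    d = np.sqrt(((pts[pairs[:, 0]] - pts[pairs[:, 1]]) ** 2).sum(axis=1))
    return np.clip(d - r[pairs[:, 0]] - r[pairs[:, 1]], 0.0, None)


def lognormal_summary(distances: np.ndarray) -> tuple[float, float]:
    """(geometric mean nm, raw-scale variance nm^2) of edge distances.

    Exact zeros (touching MTs) are excluded from the geometric mean, whose
    log is undefined there; report them separately via
    :func:`contact_fraction`. The variance is the arithmetic variance of
    the distances in nm^2, matching how bundle-spacing spreads are quoted.
    """
    d = np.asarray(distances, dtype=float)
    d = d[d > 0]
    if len(d) == 0:
        raise InsufficientDataError("no positive distances")
    gm = float(np.exp(np.mean(np.log(d))))
    var = float(np.var(d, ddof=1)) if len(d) > 1 else 0.0
    return gm, var


def contact_fraction(distances: np.ndarray) -> float:
    """Fraction of adjacent pairs in direct contact (zero edge distance)."""
    d = np.asarray(distances, dtype=float)
    if len(d) == 0:
        raise InsufficientDataError("no distances")
    return float(np.mean(d <= 0))


def is_bimodal(distances: np.ndarray, min_delta_bic: float = 10.0) -> bool:
    """Heuristic bimodality flag for an edge-distance distribution.

    Compares 1- vs 2-component Gaussian mixtures on log-distances by BIC
    and requires the two components to be genuinely separated (mean gap
    exceeding the pooled standard deviation).
    """
    from sklearn.mixture import GaussianMixture

    d = np.asarray(distances, dtype=float)
    d = np.log(d[d > 0])[:, None]
    if len(d) < 10:
        return False
    g1 = GaussianMixture(1, random_state=0, n_init=1).fit(d)
    g2 = GaussianMixture(2, random_state=0, n_init=3).fit(d)
    if g1.bic(d) - g2.bic(d) < min_delta_bic:
        return False
    mu = np.sort(g2.means_.ravel())
    sd = float(np.sqrt(g2.covariances_.ravel().mean()))
    return bool(mu[1] - mu[0] > sd)


def triplet_angles(section: BundleSection, prune_factor: float = 2.5) -> np.ndarray:
    """Angles (deg, in [0, 180]) at each MT between pairs of its neighbors.

    Uses the same adjacency as :func:`edge_distances`; a hexagonal lattice
    concentrates the histogram at 60, 120 and 180 degrees.
    """
    if section.n_mts < 3:
        raise InsufficientDataError("need >= 3 MT centers for angles")
    pairs = _adjacent_pairs(section, prune_factor)
    pts = section.centers
    neighbors: dict[int, list[int]] = {}
    for i, j in pairs:
        neighbors.setdefault(int(i), []).append(int(j))
        neighbors.setdefault(int(j), []).append(int(i))
    angles = []
    for v, nbrs in neighbors.items():
        for a_i in range(len(nbrs)):
            for b_i in range(a_i + 1, len(nbrs)):
                u = pts[nbrs[a_i]] - pts[v]
                w = pts[nbrs[b_i]] - pts[v]
                cosang = np.dot(u, w) / (np.linalg.norm(u) * np.linalg.norm(w))
                angles.append(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    return np.asarray(angles)


def mt_length(
    mean_count_per_section: float, series_length_um: float, n_terminations: float
) -> float:
    """Average MT length L = 2 N a / T (um).

    N: mean MTs per cross-section, a: series length, T: MT terminations
    observed in the series.
    """
    if series_length_um <= 0:
        raise InvalidParameterError("series length must be > 0")
    if n_terminations <= 0:
        raise InvalidParameterError(
            "no MT terminations observed; length undefined for this series"
        )
    return 2.0 * mean_count_per_section * series_length_um / n_terminations


# ---------------------------------------------------------------------------
# PIV and helical pitch


@dataclass
class VectorField:
    """PIV displacement field on a regular window grid (pixel units)."""

    x: np.ndarray  # window centers
    y: np.ndarray
    dx: np.ndarray
    dy: np.ndarray
    corr: np.ndarray
    masked: np.ndarray  # True where peak correlation < threshold


def _subpixel_peak(c: np.ndarray, i: int, j: int) -> tuple[float, float]:
    """3-point parabolic interpolation of a correlation peak."""

    def refine(m1, m0, p1):
        denom = m1 - 2 * m0 + p1
        if denom >= 0:
            return 0.0
        return 0.5 * (m1 - p1) / denom

    di = dj = 0.0
    if 0 < i < c.shape[0] - 1:
        di = refine(c[i - 1, j], c[i, j], c[i + 1, j])
    if 0 < j < c.shape[1] - 1:
        dj = refine(c[i, j - 1], c[i, j], c[i, j + 1])
    return di, dj


def piv_displacement(
    imgA: np.ndarray,
    imgB: np.ndarray,
    interrogation_px: int = 32,
    search_px: int = 96,
    corr_threshold: float = 0.6,
) -> VectorField:
    """Normalized cross-correlation PIV between two aligned images.

    Each ``interrogation_px`` window of ``imgA`` is matched within the
    concentric ``search_px`` window of ``imgB``; the displacement maximizes
    the normalized cross-correlation, with sub-pixel parabolic refinement.
    Windows whose peak correlation falls below ``corr_threshold`` (or with
    no texture) are masked. MT profiles must be bright on dark; invert the
    contrast of raw EM images first.
    """
    from skimage.feature import match_template

    A = np.asarray(imgA, dtype=float)
    B = np.asarray(imgB, dtype=float)
    if A.shape != B.shape or A.ndim != 2:
        raise InvalidSizeError("images must be same-size single-channel arrays")
    if min(A.shape) < search_px:
        raise InvalidSizeError(
            f"images smaller than the search window ({search_px} px)"
        )
    half = (search_px - interrogation_px) // 2
    xs, ys, dxs, dys, corrs, masks = [], [], [], [], [], []
    for r0 in range(half, A.shape[0] - half - interrogation_px + 1, interrogation_px):
        for c0 in range(half, A.shape[1] - half - interrogation_px + 1, interrogation_px):
            template = A[r0 : r0 + interrogation_px, c0 : c0 + interrogation_px]
            search = B[r0 - half : r0 + interrogation_px + half, c0 - half : c0 + interrogation_px + half]
            # assign the vector to the window's intensity centroid: that is
            # where the tracked features actually sit, which matters for
            # radius-dependent quantities like the pitch profile
            tsum = template.sum()
            if tsum > 0:
                wy, wx = np.mgrid[0:interrogation_px, 0:interrogation_px]
                cy = r0 + float((template * wy).sum() / tsum)
                cx = c0 + float((template * wx).sum() / tsum)
            else:
                cy = r0 + interrogation_px / 2.0 - 0.5
                cx = c0 + interrogation_px / 2.0 - 0.5
            xs.append(cx)
            ys.append(cy)
            # featureless windows (e.g. background outside the bundle) would
            # correlate spuriously; require real texture relative to the image
            if template.std() < 0.05 * A.std() or search.std() < 0.05 * B.std():
                dxs.append(0.0), dys.append(0.0), corrs.append(0.0), masks.append(True)
                continue
            cc = match_template(search, template)
            i, j = np.unravel_index(int(np.argmax(cc)), cc.shape)
            peak = float(cc[i, j])
            di, dj = _subpixel_peak(cc, i, j)
            dys.append(i + di - half)
            dxs.append(j + dj - half)
            corrs.append(peak)
            masks.append(peak < corr_threshold)
    return VectorField(
        x=np.array(xs),
        y=np.array(ys),
        dx=np.array(dxs),
        dy=np.array(dys),
        corr=np.array(corrs),
        masked=np.array(masks, dtype=bool),
    )


def pitch_profile(
    field: VectorField,
    center_px: tuple[float, float],
    z_nm: float = 100.0,
    px_size_nm: float = 1.0,
    n_bins: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Helical pitch angle theta(r) = atan(|d|(r)/z) from a PIV field.

    Displacement magnitudes are binned radially about the bundle center;
    ``z_nm`` is the axial separation of the two sections. Returns
    (bin-center radii in nm, pitch angles in degrees).
    """
    ok = ~field.masked
    if not np.any(ok):
        raise NoSignalError("all PIV windows are masked")
    rx = (field.x[ok] - center_px[0]) * px_size_nm
    ry = (field.y[ok] - center_px[1]) * px_size_nm
    r = np.hypot(rx, ry)
    mag = np.hypot(field.dx[ok], field.dy[ok]) * px_size_nm
    edges = np.linspace(0.0, r.max() * 1.0001, n_bins + 1)
    idx = np.digitize(r, edges) - 1
    radii, thetas = [], []
    for b in range(n_bins):
        sel = idx == b
        if not np.any(sel):
            continue
        radii.append(float((edges[b] + edges[b + 1]) / 2))
        # median magnitude per annulus: robust to occasional windows that
        # lock onto a lattice vector instead of the true displacement
        thetas.append(float(np.degrees(np.arctan2(np.median(mag[sel]), z_nm))))
    return np.array(radii), np.array(thetas)


def twist_from_field(field: VectorField, center_px: tuple[float, float]) -> float:
    """Rigid rotation angle (deg) between the two sections of a PIV pair.

    Each unmasked window provides an angle estimate
    theta_i = atan2(r x (r + d), r . (r + d)); the median over windows is
    robust against occasional lattice-locked outliers.
    """
    ok = ~field.masked
    if not np.any(ok):
        raise NoSignalError("all PIV windows are masked")
    rx = field.x[ok] - center_px[0]
    ry = field.y[ok] - center_px[1]
    px = rx + field.dx[ok]
    py = ry + field.dy[ok]
    cross = rx * py - ry * px
    dot = rx * px + ry * py
    angles = np.degrees(np.arctan2(cross, dot))
    r2 = rx**2 + ry**2
    # windows at tiny radius carry no angular information
    good = r2 > np.percentile(r2, 20)
    return float(np.median(angles[good]))


def rotation_sense(field: VectorField, center_px: tuple[float, float]) -> float:
    """Sign of the mean tangential displacement about the bundle center.

    Positive = counter-clockwise in image coordinates; a sign change along
    a stack marks a helical perversion.
    """
    ok = ~field.masked
    if not np.any(ok):
        raise NoSignalError("all PIV windows are masked")
    rx = field.x[ok] - center_px[0]
    ry = field.y[ok] - center_px[1]
    tangential = rx * field.dy[ok] - ry * field.dx[ok]
    return float(np.sign(tangential.mean()))
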