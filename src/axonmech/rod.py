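"""Discrete elastic rod (Kirchhoff) representation of an axon.

The rod is a polyline of vertices with a material frame attached to every
edge. Frames are kept adapted to the centerline by parallel transport; the
per-edge angle ``theta`` rotates the reference frame into the material
frame, so twist lives in scalar degrees of freedom while the centerline
carries bend and stretch. The elastic energy is

    H = E_bend + E_twist + E_tension

with a quadratic bend term built on the discrete curvature binormal

    (kappa b)_j = 2 e_{j-1} x e_j / (|e_{j-1}||e_j| + e_{j-1} . e_j),

a quadratic twist term on the junction material twists, a Hookean stretch
term per edge, and a soft quadratic self-contact penalty that activates
when non-adjacent segments approach closer than a multiple of the rod
diameter (plectonemes require contact).

Internally all mechanics run in micrometers, piconewtons and seconds for
numerical conditioning; the public API is SI.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DiscretizationError, InvalidParameterError
from .params import MechParams

# unit conversions SI <-> internal (um, pN, s)
M_TO_UM = 1e6
N_TO_PN = 1e12
NM2_TO_PNUM2 = 1e24  # N m^2 -> pN um^2
J_TO_PNUM = 1e18  # J -> pN um


# ---------------------------------------------------------------------------
# geometry helpers


def _norm(v: np.ndarray) -> np.ndarray:
    return np.sqrt(np.einsum("ij,ij->i", v, v))


def _cross3(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise cross product of (n, 3) arrays (np.cross without overhead)."""
    out = np.empty_like(a)
    a0, a1, a2 = a[:, 0], a[:, 1], a[:, 2]
    b0, b1, b2 = b[:, 0], b[:, 1], b[:, 2]
    out[:, 0] = a1 * b2 - a2 * b1
    out[:, 1] = a2 * b0 - a0 * b2
    out[:, 2] = a0 * b1 - a1 * b0
    return out


def parallel_transport(u: np.ndarray, t_from: np.ndarray, t_to: np.ndarray) -> np.ndarray:
    """Rotate vectors ``u`` by the rotation taking unit tangent t_from to t_to.

    Vectorized over the leading axis. The rotation axis is t_from x t_to
    (Rodrigues); for (anti)parallel tangents the identity is used.
    """
    axis = _cross3(t_from, t_to)
    cos = np.einsum("ij,ij->i", t_from, t_to)
    # u_rot = u cos + (axis x u) + axis (axis.u) / (1 + cos); stable for cos > -1
    denom = np.where(1.0 + cos > 1e-12, 1.0 + cos, 1.0)
    dot_au = np.einsum("ij,ij->i", axis, u)
    u_rot = (
        u * cos[:, None]
        + _cross3(axis, u)
        + axis * (dot_au / denom)[:, None]
    )
    return np.where((1.0 + cos > 1e-12)[:, None], u_rot, u)


def curvature_binormals(verts: np.ndarray) -> np.ndarray:
    """Discrete curvature binormal at each interior vertex, shape (n-2, 3)."""
    e = np.diff(verts, axis=0)
    ea, eb = e[:-1], e[1:]
    chi = _norm(ea) * _norm(eb) + np.einsum("ij,ij->i", ea, eb)
    return 2.0 * _cross3(ea, eb) / chi[:, None]


def signed_angle(v1: np.ndarray, v2: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Signed angle from v1 to v2 about unit axis, vectorized."""
    s = np.einsum("ij,ij->i", _cross3(v1, v2), axis)
    c = np.einsum("ij,ij->i", v1, v2)
    return np.arctan2(s, c)


# ---------------------------------------------------------------------------
# rod state


@dataclass
class RodState:
    """Discretized elastic rod state (SI units).

    Attributes
    ----------
    vertices : (n, 3) float array, m
    theta : (n-1,) float array
        Material-frame rotation angle per edge, rad. The difference across a
        junction (plus the reference twist from parallel transport) is the
        material twist.
    rest_lengths : (n-1,) float array, m
    rest_twist : float
        Natural twist rate tau0, rad/m (0 for a naturally untwisted axon;
        imposed boundary twist is carried by ``theta``).
    reference_frames : (n-1, 3) float array
        First reference director d1 per edge (unit, orthogonal to the edge).
    time : float, s
    """

    vertices: np.ndarray
    theta: np.ndarray
    rest_lengths: np.ndarray
    rest_twist: float = 0.0
    reference_frames: np.ndarray | None = None
    time: float = 0.0

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        self.rest_lengths = np.asarray(self.rest_lengths, dtype=float)
        if self.reference_frames is None:
            self.reference_frames = self._space_parallel_frames()

    # -- derived geometry -------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return len(self.vertices) - 1

    @property
    def edges(self) -> np.ndarray:
        return np.diff(self.vertices, axis=0)

    @property
    def lengths(self) -> np.ndarray:
        return _norm(self.edges)

    @property
    def tangents(self) -> np.ndarray:
        e = self.edges
        return e / _norm(e)[:, None]

    @property
    def total_rest_length(self) -> float:
        return float(self.rest_lengths.sum())

    @property
    def arclength(self) -> np.ndarray:
        """Cumulative arclength at vertices (current configuration), m."""
        return np.concatenate([[0.0], np.cumsum(self.lengths)])

    def _space_parallel_frames(self) -> np.ndarray:
        t = self.tangents
        # seed director: any unit vector orthogonal to the first tangent
        seed = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(seed, t[0])) > 0.9:
            seed = np.array([0.0, 1.0, 0.0])
        d1 = np.empty_like(t)
        d1[0] = seed - np.dot(seed, t[0]) * t[0]
        d1[0] /= np.linalg.norm(d1[0])
        for j in range(1, len(t)):
            d1[j] = parallel_transport(d1[None, j - 1], t[None, j - 1], t[None, j])[0]
            d1[j] -= np.dot(d1[j], t[j]) * t[j]
            d1[j] /= np.linalg.norm(d1[j])
        return d1

    def reference_twists(self) -> np.ndarray:
        """Reference twist at each interior junction, shape (n-2,), rad."""
        t = self.tangents
        d1 = self.reference_frames
        transported = parallel_transport(d1[:-1], t[:-1], t[1:])
        return signed_angle(transported, d1[1:], t[1:])

    def material_twists(self) -> np.ndarray:
        """Material twist at each interior junction, rad."""
        return np.diff(self.theta) + self.reference_twists()

    def total_twist(self) -> float:
        """Total material twist accumulated along the rod, rad."""
        return float(self.material_twists().sum())

    def displaced(self, dx: np.ndarray) -> "RodState":
        """Return a copy displaced by ``dx`` with frames parallel-transported.

        This defines the elastic energy as a function of vertex positions
        alone (the map used for finite-difference force checks).
        """
        new_verts = self.vertices + dx
        t_old = self.tangents
        e_new = np.diff(new_verts, axis=0)
        t_new = e_new / _norm(e_new)[:, None]
        d1 = parallel_transport(self.reference_frames, t_old, t_new)
        # re-orthonormalize against drift
        d1 -= np.einsum("ij,ij->i", d1, t_new)[:, None] * t_new
        d1 /= _norm(d1)[:, None]
        return replace(self, vertices=new_verts, reference_frames=d1)


def build_rod(
    n_vertices: int,
    length_m: float,
    params: MechParams,
    twist_rate_rad_per_m: float = 0.0,
) -> RodState:
    """Build a straight rod along +x with uniformly distributed imposed twist.

    The imposed twist (total angle ``twist_rate * length``) is written into
    the per-edge ``theta`` as a uniform ramp, the configuration produced by
    clamped ends with the stated end-to-end rotation.
    """
    if n_vertices < 3:
        raise InvalidParameterError("n_vertices must be >= 3")
    if length_m <= 0:
        raise InvalidParameterError("length must be > 0")
    seg = length_m / (n_vertices - 1)
    if seg <= 2.0 * params.radius:
        raise DiscretizationError(
            f"segment length {seg:.3g} m <= rod diameter "
            f"{2 * params.radius:.3g} m; increase length or reduce n_vertices"
        )
    x = np.linspace(0.0, length_m, n_vertices)
    verts = np.column_stack([x, np.zeros(n_vertices), np.zeros(n_vertices)])
    rest = np.full(n_vertices - 1, seg)
    total = twist_rate_rad_per_m * length_m
    # theta at edge j corresponds to arclength at the edge midpoint
    mid = (x[:-1] + x[1:]) / 2.0
    theta = total * mid / length_m
    return RodState(vertices=verts, theta=theta, rest_lengths=rest)


# ---------------------------------------------------------------------------
# energies


@dataclass
class EnergyBreakdown:
    """Elastic energy decomposition, J."""

    bend: float
    twist: float
    stretch: float
    contact_penalty: float = 0.0
    total: float = field(init=False)

    def __post_init__(self) -> None:
        self.total = self.bend + self.twist + self.stretch + self.contact_penalty


def _segment_pair_distances(
    p: np.ndarray, pairs_i: np.ndarray, pairs_j: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Closest distance between segment pairs (i, i+1)-(j, j+1).

    Returns (distance, unit vector from point on j to point on i, s, t) where
    s, t in [0, 1] are the barycentric locations of the closest points.
    Vectorized implementation of the standard segment-segment algorithm.
    """
    p1 = p[pairs_i]
    q1 = p[pairs_j]
    d1 = p[pairs_i + 1] - p1
    d2 = p[pairs_j + 1] - q1
    r = p1 - q1
    a = np.einsum("ij,ij->i", d1, d1)
    e = np.einsum("ij,ij->i", d2, d2)
    f = np.einsum("ij,ij->i", d2, r)
    c = np.einsum("ij,ij->i", d1, r)
    b = np.einsum("ij,ij->i", d1, d2)
    denom = a * e - b * b
    s = np.where(denom > 1e-30, (b * f - c * e) / np.where(denom > 1e-30, denom, 1.0), 0.0)
    s = np.clip(s, 0.0, 1.0)
    t = np.where(e > 1e-30, (b * s + f) / np.where(e > 1e-30, e, 1.0), 0.0)
    # clamp t then recompute s
    t_cl = np.clip(t, 0.0, 1.0)
    need = t_cl != t
    s = np.where(need, np.clip((b * t_cl - c) / np.where(a > 1e-30, a, 1.0), 0.0, 1.0), s)
    t = t_cl
    cp1 = p1 + s[:, None] * d1
    cp2 = q1 + t[:, None] * d2
    diff = cp1 - cp2
    dist = _norm(diff)
    unit = diff / np.where(dist > 1e-30, dist, 1.0)[:, None]
    return dist, unit, s, t


class RodCore:
    """Scaled-unit workhorse evaluating energies and analytic forces.

    Holds the immutable discretization constants; operates on plain arrays
    in um / pN / s so the simulator can iterate without reconverting.
    """

    def __init__(
        self,
        rod: RodState,
        params: MechParams,
        *,
        stretch_stiffness_n: float | None = None,
        axial_mode: str = "hookean",
        axial_tension_n: float = 0.0,
        contact_stiffness_pn_um: float = 2000.0,
        contact_activation_factor: float = 1.1,
        contact_model: str = "vertex",
    ):
        self.B = params.B * NM2_TO_PNUM2
        self.C = params.C * NM2_TO_PNUM2
        ea = params.k * params.A if stretch_stiffness_n is None else stretch_stiffness_n
        self.EA = ea * N_TO_PN
        self.rest = rod.rest_lengths * M_TO_UM
        self._rest0 = self.rest.copy()
        self.lbar = (self.rest[:-1] + self.rest[1:]) / 2.0  # junction Voronoi, um
        self.L_tw = float(self.lbar.sum())
        self.diameter = params.diameter * M_TO_UM
        self.kc = contact_stiffness_pn_um
        # self-contact: "vertex" model acts between vertex spheres (smooth
        # landscape, sphere radius inflated to cover the tube between
        # vertices so strands cannot thread the gaps); "segment" model uses
        # exact segment-segment distances at the physical diameter (sharper
        # geometry, but closest-point switching makes the landscape rough
        # and the descent slow in winding regions)
        seg = float(self.rest.mean())
        self.contact_model = contact_model
        if contact_model == "vertex":
            self.d_act = max(
                contact_activation_factor * self.diameter,
                np.hypot(self.diameter, 0.8 * seg),
            )
        else:
            self.d_act = contact_activation_factor * self.diameter
        # axial term: quadratic Hookean (default) or constant-tension, the
        # linear |l - l0| form smoothed by a small Huber core so forces
        # stay bounded; in that mode arclength costs a fixed force T and
        # coils can recruit length without quadratic arrest
        self.axial_mode = axial_mode
        self.T_ax = axial_tension_n * N_TO_PN
        self.huber_delta = 0.02 * seg
        # contact candidate pairs (rebuilt lazily by the simulator)
        self._pairs: tuple[np.ndarray, np.ndarray] | None = None
        ne = len(self.rest)
        # exclude pairs closer than ~1.5 um along the strand (loops are larger)
        self.min_sep_segments = max(2, int(np.ceil(1.5 / self.rest.mean())))
        self._ne = ne

    def set_rest_scale(self, scale: float) -> None:
        """Uniformly rescale rest lengths (time-ramped slack injection)."""
        self.rest = self._rest0 * scale
        self.lbar = (self.rest[:-1] + self.rest[1:]) / 2.0
        self.L_tw = float(self.lbar.sum())

    # -- contact neighbor list -------------------------------------------
    def rebuild_pairs(self, x_um: np.ndarray, margin_um: float = 1.0) -> None:
        """Refresh the contact neighbor list (vertex or segment pairs)."""
        from scipy.spatial.distance import pdist, squareform

        if self.contact_model == "vertex":
            dm = squareform(pdist(x_um))
            ii, jj = np.triu_indices(len(x_um), k=self.min_sep_segments)
        else:
            mid = (x_um[:-1] + x_um[1:]) / 2.0
            dm = squareform(pdist(mid))
            ii, jj = np.triu_indices(len(mid), k=self.min_sep_segments)
        cutoff = self.d_act + margin_um
        keep = dm[ii, jj] < cutoff
        self._pairs = (ii[keep], jj[keep])

    # -- energy terms (scaled units: um, pN) ------------------------------
    def energies(self, x: np.ndarray, phi: np.ndarray):
        """Return (bend, twist, stretch, contact) in pN um.

        ``phi`` is the per-junction material twist (rad) relative to the
        natural twist.
        """
        e = np.diff(x, axis=0)
        le = _norm(e)
        kb = curvature_binormals(x)
        bend = float(np.sum(self.B * np.einsum("ij,ij->i", kb, kb) / (2.0 * self.lbar)))
        twist = float(np.sum(0.5 * self.C * phi**2 / self.lbar))
        dl = le - self.rest
        if self.axial_mode == "hookean":
            stretch = float(np.sum(0.5 * self.EA * dl**2 / self.rest))
        else:  # constant tension, Huber-smoothed |dl|
            d = self.huber_delta
            core = np.abs(dl) < d
            stretch = float(
                self.T_ax
                * np.sum(np.where(core, dl**2 / (2.0 * d), np.abs(dl) - d / 2.0))
            )
        contact = self._contact_energy(x)
        return bend, twist, stretch, contact

    def _contact_terms(self, x: np.ndarray):
        if self._pairs is None or len(self._pairs[0]) == 0:
            return None
        ii, jj = self._pairs
        if self.contact_model == "vertex":
            diff = x[ii] - x[jj]
            dist = _norm(diff)
            pen = self.d_act - dist
            active = pen > 0
            if not np.any(active):
                return None
            unit = diff[active] / dist[active][:, None]
            return ii[active], jj[active], pen[active], unit, None, None
        dist, unit, s, t = _segment_pair_distances(x, ii, jj)
        pen = self.d_act - dist
        active = pen > 0
        if not np.any(active):
            return None
        return ii[active], jj[active], pen[active], unit[active], s[active], t[active]

    def _contact_energy(self, x: np.ndarray) -> float:
        terms = self._contact_terms(x)
        if terms is None:
            return 0.0
        return float(np.sum(0.5 * self.kc * terms[2] ** 2))

    # -- forces -----------------------------------------------------------
    def forces(self, x: np.ndarray, phi: np.ndarray) -> np.ndarray:
        """Analytic force -dH/dx, pN, shape (n, 3)."""
        n = len(x)
        F = np.zeros((n, 3))
        e = np.diff(x, axis=0)
        le = _norm(e)
        ea, eb = e[:-1], e[1:]
        la, lb = le[:-1], le[1:]
        chi = la * lb + np.einsum("ij,ij->i", ea, eb)
        kb = 2.0 * _cross3(ea, eb) / chi[:, None]
        kb2 = np.einsum("ij,ij->i", kb, kb)

        # bend: gradient of sum B |kb|^2 / (2 lbar)
        w = self.B / self.lbar  # per junction
        g_a = (2.0 * _cross3(eb, kb) - kb2[:, None] * ((lb / la)[:, None] * ea + eb)) / chi[:, None]
        g_b = (-2.0 * _cross3(ea, kb) - kb2[:, None] * ((la / lb)[:, None] * eb + ea)) / chi[:, None]
        F[:-2] += w[:, None] * g_a
        F[1:-1] += w[:, None] * (g_b - g_a)
        F[2:] -= w[:, None] * g_b
        # note: F accumulates -dE/dx, so signs above already flipped:
        # dE/dx_{j-1} = -w g_a  -> F_{j-1} += w g_a, etc.

        # twist: E = sum C phi_j^2/(2 lbar_j); d(phi_j)/dx via the holonomy
        # gradient of the junction reference twist: -kb/(2|e_{j-1}|) at
        # x_{j-1}, +kb/(2|e_j|) at x_{j+1}, minus the sum at x_j
        m_j = (self.C * phi / self.lbar)[:, None]  # junction torque, pN um
        if np.any(m_j != 0.0):
            ga_t = -kb / (2.0 * la)[:, None]
            gb_t = kb / (2.0 * lb)[:, None]
            F[:-2] -= m_j * ga_t
            F[1:-1] -= m_j * (-(ga_t + gb_t))
            F[2:] -= m_j * gb_t

        # stretch
        dl = le - self.rest
        if self.axial_mode == "hookean":
            tension_edge = self.EA * dl / self.rest
        else:
            tension_edge = self.T_ax * np.clip(dl / self.huber_delta, -1.0, 1.0)
        f_edge = tension_edge[:, None] * (e / le[:, None])
        F[:-1] += f_edge
        F[1:] -= f_edge

        # contact penalty
        terms = self._contact_terms(x)
        if terms is not None:
            ii, jj, pen, unit, s, t = terms
            fvec = (self.kc * pen)[:, None] * unit  # pushes i away from j
            if self.contact_model == "vertex":
                np.add.at(F, ii, fvec)
                np.add.at(F, jj, -fvec)
            else:
                np.add.at(F, ii, fvec * (1.0 - s)[:, None])
                np.add.at(F, ii + 1, fvec * s[:, None])
                np.add.at(F, jj, -fvec * (1.0 - t)[:, None])
                np.add.at(F, jj + 1, -fvec * t[:, None])
        return F


def elastic_energy(
    rod: RodState,
    params: MechParams,
    *,
    contact_stiffness_pn_um: float = 2000.0,
    contact_activation_factor: float = 1.1,
) -> EnergyBreakdown:
    """Elastic energy of a rod state, J.

    Bend from the curvature binormal at interior vertices, twist from the
    departure of total material twist from the natural twist, Hookean
    stretch per edge, and the self-contact penalty.
    """
    core = RodCore(
        rod,
        params,
        contact_stiffness_pn_um=contact_stiffness_pn_um,
        contact_activation_factor=contact_activation_factor,
    )
    x = rod.vertices * M_TO_UM
    core.rebuild_pairs(x)
    phi = rod.material_twists() - (rod.rest_twist / M_TO_UM) * core.lbar
    b, tw, s, c = core.energies(x, phi)
    return EnergyBreakdown(
        bend=b / J_TO_PNUM,
        twist=tw / J_TO_PNUM,
        stretch=s / J_TO_PNUM,
        contact_penalty=c / J_TO_PNUM,
    )
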