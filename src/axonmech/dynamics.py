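"""Overdamped dynamics of the discrete elastic rod.

Viscous forces dominate at axon scale (low Reynolds number), so vertices
follow the gradient flow

    gamma_i dx_i/dt = -dH/dx_i

with a per-vertex drag coefficient gamma = 4 pi mu l (Stokes drag on a
slender cylinder segment; the prefactor only rescales time, not the
equilibria).

Time stepping is semi-implicit: the stiffest terms (stretch and the
bending bi-Laplacian, locally reweighted by curvature) enter through a
symmetric positive-definite banded operator solved at the new positions,
while twist coupling and the contact penalty stay explicit,

    (gamma/dt + K) dx = -dH/dx(x_n),    K ~ D2' diag(w) D2 + (EA/l) L2.

The step size is capped so drag-limited axial transport stays resolved,
and controlled by an energy test: a trial step is accepted only if the
total energy (including boundary work) does not increase, else dt is
halved. Where strict descent stalls in the corrugated landscape of a
tightening coil, rollback bursts (blocks of small unconditional sub-steps
accepted only on net descent) carry the state through, keeping energy
non-increasing at block granularity.

Twist relaxes between positional steps either quasi-statically (uniform
rate) or, by default, through damped Jacobi sweeps that model slow,
adhesion-limited spinning of an embedded axon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .errors import InvalidParameterError, NumericalFailureError
from .params import MechParams
from .rod import (
    M_TO_UM,
    N_TO_PN,
    EnergyBreakdown,
    J_TO_PNUM,
    RodCore,
    RodState,
    _norm,
    build_rod,
    parallel_transport,
    signed_angle,
)


@dataclass
class SimConfig:
    """Configuration of a rod relaxation run (SI on input)."""

    params: MechParams
    n_vertices: int = 200
    length_m: float = 75e-6
    twist_rate_rad_per_m: float = 0.0
    boundary: Literal["clamped", "tension"] = "clamped"
    tension_n: float = 0.0
    #: axial stretch law: "hookean" (quadratic, stiffness from params.k) or
    #: "constant_tension" (the linear |l - l0| rod-energy term, smoothed):
    #: arclength then costs the fixed force ``tension_n`` per unit length
    #: change, letting coils recruit length without quadratic arrest
    axial_mode: Literal["hookean", "constant_tension"] = "hookean"
    end_shortening_frac: float = 0.0
    shortening_steps: int = 4000
    #: uniform compressive pre-strain: rest arclength exceeds the clamped
    #: span by this fraction (slack available for coil formation)
    slack_frac: float = 0.0
    #: if > 0, the slack is ramped in linearly over this many steps instead
    #: of being present from the start
    slack_ramp_steps: int = 0
    stretch_stiffness_n: float | None = None  # override EA (N), e.g. for tension mode
    max_time_s: float = 3000.0
    max_steps: int = 400_000
    ftol_pn: float = 2e-4
    min_time_s: float = 0.0
    snapshot_interval_s: float = 100.0
    seed: int = 0
    perturb_amplitude_frac: float = 0.01
    #: if set, the symmetry-breaking perturbation is a coherent helix of
    #: this wavelength (normally the fastest-growing mode of the twisted
    #: rod) instead of band-limited noise; all wave periods then reach the
    #: nonlinear stage together instead of the noise-leader winning
    perturb_wavelength_um: float | None = None
    contact_stiffness_pn_um: float = 2000.0
    pair_refresh_steps: int = 15
    dt_safety: float = 0.2
    max_step_um: float = 0.03
    #: upper bound on the time step, s. The semi-implicit solve is stable at
    #: any dt, but dt must stay below the axial slack-transport time over
    #: the shortest physical scale of interest (~d^2 gamma / EA) or that
    #: transport becomes artificially instantaneous. 0.5 s resolves
    #: transport over a few micrometers at the reference mechanics.
    dt_max_s: float = 0.5
    #: twist handling: "dynamic" relaxes the per-edge twist angles by
    #: ``twist_sweeps`` damped Jacobi sweeps per positional step (finite
    #: twist transport, allowing several plectonemes to coexist);
    #: "quasistatic" equilibrates twist to a uniform rate every step
    twist_mode: Literal["dynamic", "quasistatic"] = "dynamic"
    twist_sweeps: int = 2
    twist_relax: float = 0.7
    #: self-contact model: smooth "vertex" spheres (default) or exact
    #: "segment" distances (see RodCore)
    contact_model: Literal["vertex", "segment"] = "vertex"
    #: rollback bursts through corrugated stretches (None = only for the
    #: smooth vertex contact model; True/False forces)
    enable_bursts: bool | None = None


@dataclass
class Trajectory:
    """Sequence of rod snapshots plus bookkeeping."""

    snapshots: list[RodState]
    times: list[float]
    energies: list[EnergyBreakdown]
    converged: bool = False
    n_steps: int = 0
    config: SimConfig | None = None

    @property
    def final(self) -> RodState:
        return self.snapshots[-1]


class _Sim:
    """Mutable simulation state in scaled units (um, pN, s)."""

    def __init__(self, rod: RodState, params: MechParams, cfg: SimConfig):
        self.cfg = cfg
        self.params = params
        self.core = RodCore(
            rod,
            params,
            stretch_stiffness_n=cfg.stretch_stiffness_n,
            axial_mode=cfg.axial_mode,
            axial_tension_n=cfg.tension_n if cfg.axial_mode == "constant_tension" else 0.0,
            contact_stiffness_pn_um=cfg.contact_stiffness_pn_um,
            contact_model=cfg.contact_model,
        )
        self.x = rod.vertices * M_TO_UM
        self.d1 = rod.reference_frames.copy()
        self.theta = rod.theta.astype(float).copy()
        self.rest_twist = rod.rest_twist
        self.tau0_per_junction = (rod.rest_twist / M_TO_UM) * self.core.lbar
        self.time = rod.time
        n = len(self.x)
        # Voronoi vertex lengths for drag
        l = self.core.rest
        lv = np.empty(n)
        lv[0], lv[-1] = l[0] / 2, l[-1] / 2
        lv[1:-1] = (l[:-1] + l[1:]) / 2
        self.gamma = 4.0 * math.pi * params.mu * lv  # mu: Pa s == pN s/um^2
        self.free = np.ones((n, 3), dtype=bool)
        self.free[:2] = False
        self.free[-2:] = False
        self.tension = cfg.tension_n * N_TO_PN if cfg.boundary == "tension" else 0.0
        if cfg.boundary == "tension":
            # far end slides along x under a dead axial load; tangent stays
            # axial because the last two vertices are confined to the axis
            self.free[-2:, 0] = True
        self.dt_max = cfg.dt_max_s
        self.dt = self.dt_max / 10.0
        self._steps_since_refresh = 10**9
        self._energy = None  # cached accepted-state energy
        self._prec_bands = self._preconditioner_bands()
        # reference twists carried continuously in time: the raw junction
        # angle wraps at +-pi, and a wrap event would inject 2 pi of
        # spurious material twist (an energy pump in tightly wound regions)
        self._dm = self._ref_twists(self.x, self.d1)

    def _preconditioner_bands(self) -> np.ndarray:
        """SPD bands K = D2' diag(w) D2 + (EA/l) L2 + contact diag, upper form.

        Bend and stretch are treated implicitly (unconditional stability);
        the physical rate of drag-limited transport is preserved by the
        ``dt_max_s`` cap, which keeps dt below the transport time of the
        shortest scales of interest. The per-junction bending weight w_j is
        boosted where the rod is tightly curved: the straight-rod operator
        underestimates the true bend Hessian inside a winding loop by
        orders of magnitude, and without the boost a single tightening
        coil forces the global step size down for the whole rod.
        """
        from .rod import curvature_binormals

        n = len(self.x)
        l = float(self.core.rest.mean())
        kb2 = (curvature_binormals(self.x) ** 2).sum(axis=1)
        w = (self.core.B / l**3) * (1.0 + 300.0 * kb2)  # per junction, (n-2,)
        diag = np.zeros(n)
        off1 = np.zeros(n - 1)
        off2 = np.zeros(n - 2)
        diag[:-2] += w
        diag[1:-1] += 4.0 * w
        diag[2:] += w
        off1[:-1] += -2.0 * w
        off1[1:] += -2.0 * w
        off2[:] = w
        if self.core.axial_mode == "hookean":
            ks = self.core.EA / l
        else:
            ks = self.core.T_ax / self.core.huber_delta
        diag += 2.0 * ks + self.core.kc
        diag[[0, -1]] -= ks
        off1 += -ks
        ab = np.zeros((3, n))
        ab[0, 2:] = off2
        ab[1, 1:] = off1
        ab[2, :] = diag
        return ab

    # -- energy bookkeeping ------------------------------------------------
    def _ref_twists(self, x: np.ndarray, d1: np.ndarray) -> np.ndarray:
        e = np.diff(x, axis=0)
        t = e / _norm(e)[:, None]
        transported = parallel_transport(d1[:-1], t[:-1], t[1:])
        return signed_angle(transported, d1[1:], t[1:])

    def _dm_continuous(self, x: np.ndarray, d1: np.ndarray) -> np.ndarray:
        """Junction reference twists of a (possibly trial) state.

        The raw angle lives in (-pi, pi); temporal unwrapping was tried and
        rejected: near a fold the raw angle oscillates across the branch
        cut and unwrapping ratchets phantom writhe into the bookkeeping,
        silently shedding real twist. Keeping the principal value is
        correct whenever strand passage is excluded by the contact model.
        """
        return self._ref_twists(x, d1)

    def _phi(self, x: np.ndarray, d1: np.ndarray, dm: np.ndarray | None = None) -> np.ndarray:
        if dm is None:
            dm = self._dm_continuous(x, d1)
        return np.diff(self.theta) + dm - self.tau0_per_junction

    def _total_energy(
        self, x: np.ndarray, d1: np.ndarray, dm: np.ndarray | None = None
    ) -> float:
        b, tw, s, c = self.core.energies(x, self._phi(x, d1, dm))
        return b + tw + s + c - self.tension * x[-1, 0]

    def _relax_twist(self, dm: np.ndarray | None = None) -> None:
        """Relax interior twist angles toward torsional equilibrium.

        Quasi-static mode equalizes the twist rate along the rod in one
        shot; dynamic mode applies a few damped Jacobi sweeps, modeling
        finite-rate twist transport so distant coils cannot instantly
        drain each other's torque.
        """
        if dm is None:
            dm = self._dm_continuous(self.x, self.d1)
        if self.cfg.twist_mode == "quasistatic":
            total = float(self.theta[-1] - self.theta[0] + dm.sum() - self.tau0_per_junction.sum())
            phi = total * self.core.lbar / self.core.L_tw
            self.theta = self.theta[0] + np.concatenate(
                [[0.0], np.cumsum(phi - dm + self.tau0_per_junction)]
            )
            return
        lbar = self.core.lbar
        for _ in range(self.cfg.twist_sweeps):
            phi = np.diff(self.theta) + dm - self.tau0_per_junction
            rate = phi / lbar
            # coordinate-wise minimizer of the quadratic twist energy in
            # theta_j, damped for Jacobi stability
            h = 1.0 / (1.0 / lbar[:-1] + 1.0 / lbar[1:])
            self.theta[1:-1] += self.cfg.twist_relax * h * (rate[1:] - rate[:-1])

    def _transport(self, x_new: np.ndarray) -> np.ndarray:
        e_old = np.diff(self.x, axis=0)
        t_old = e_old / _norm(e_old)[:, None]
        e_new = np.diff(x_new, axis=0)
        t_new = e_new / _norm(e_new)[:, None]
        d1 = parallel_transport(self.d1, t_old, t_new)
        d1 -= np.einsum("ij,ij->i", d1, t_new)[:, None] * t_new
        d1 /= _norm(d1)[:, None]
        return d1

    def shift_boundary(self, dx_um: np.ndarray) -> None:
        """Apply a prescribed displacement to the far clamped vertices.

        Boundary motion does work on the rod, so the cached energy is
        invalidated rather than subjected to the descent test.
        """
        x_new = self.x.copy()
        x_new[-2:] += dx_um
        self.d1 = self._transport(x_new)
        self.x = x_new
        self._dm = self._dm_continuous(x_new, self.d1)
        self._energy = None

    # -- stepping ----------------------------------------------------------
    def forces(self) -> np.ndarray:
        F = self.core.forces(self.x, self._phi(self.x, self.d1))
        if self.tension:
            F[-1, 0] += self.tension
        F[~self.free] = 0.0
        return F

    def step(self, step_index: int, dt_cap: float | None = None) -> float:
        """One accepted step; returns the dt actually taken (s)."""
        if self._steps_since_refresh >= self.cfg.pair_refresh_steps:
            self.core.rebuild_pairs(self.x)
            self._prec_bands = self._preconditioner_bands()
            self._steps_since_refresh = 0
            self._energy = None
        F = self.forces()
        if not np.all(np.isfinite(F)):
            raise NumericalFailureError("non-finite force", step=step_index)
        if self._energy is None:
            self._energy = self._total_energy(self.x, self.d1)
        dt = self.dt if dt_cap is None else min(self.dt, dt_cap)
        from scipy.linalg import solveh_banded

        for _ in range(25):
            dx = np.empty_like(F)
            for ax in range(3):
                ab = self._prec_bands.copy()
                ab[2] += self.gamma / dt
                clamped = ~self.free[:, ax]
                ab[2, clamped] = 1e30
                dx[:, ax] = solveh_banded(ab, F[:, ax])
            dxmax = float(np.abs(dx).max())
            if dxmax > self.cfg.max_step_um:
                dx *= self.cfg.max_step_um / dxmax
            x_new = self.x + dx
            d1_new = self._transport(x_new)
            dm_new = self._dm_continuous(x_new, d1_new)
            e_new = self._total_energy(x_new, d1_new, dm_new)
            # tolerance just above energy-evaluation roundoff: below that a
            # "rise" is indistinguishable from noise and halving further
            # only stalls the run at sub-physical step sizes
            if e_new <= self._energy + 1e-10 * (abs(self._energy) + 1.0):
                break
            dt *= 0.5
            bursts_ok = (
                self.cfg.enable_bursts
                if self.cfg.enable_bursts is not None
                else self.cfg.contact_model == "vertex"
            )
            if dt < self.dt_max / 500.0 and bursts_ok:
                # strict descent has stalled in a corrugated region (a
                # tightening coil): traverse it with a rollback burst
                return self._burst()
        else:
            # fully stalled: accept a zero-length step to let callers bail out
            return 0.0
        self.x = x_new
        self.d1 = d1_new
        self._dm = dm_new
        self._relax_twist(dm_new)
        self._energy = self._total_energy(self.x, self.d1, dm_new)
        self.time += dt
        # sticky step size with geometric recovery: one rough step must not
        # depress the following smooth stretch for hundreds of steps
        self.dt = min(dt * 2.0, self.dt_max)
        self._steps_since_refresh += 1
        return dt

    def _burst(self, n_sub: int = 1000) -> float:
        """Traverse a corrugated stretch with small unconditional sub-steps.

        Inside a tightening coil the energy landscape is a narrow curved
        valley: strict per-step descent collapses the step size to the
        noise floor while physical progress is finite. The burst takes
        ``n_sub`` fixed small steps without per-step tests, then accepts
        the whole block only if the net energy decreased; otherwise the
        state is rolled back and the sub-step halved. Energy is thus
        non-increasing at burst granularity (the solver tolerance), while
        micro-oscillations inside the valley are permitted.
        """
        from scipy.linalg import solveh_banded

        saved = (self.x.copy(), self.d1.copy(), self.theta.copy(), self._energy, self.time, self._dm.copy())
        dt_sub = self.dt_max / 250.0
        for attempt in range(3):
            for k in range(n_sub):
                if k % 20 == 0:
                    self.core.rebuild_pairs(self.x)
                    self._prec_bands = self._preconditioner_bands()
                F = self.core.forces(self.x, self._phi(self.x, self.d1))
                if self.tension:
                    F[-1, 0] += self.tension
                F[~self.free] = 0.0
                if not np.all(np.isfinite(F)):
                    break
                dx = np.empty_like(F)
                for ax in range(3):
                    ab = self._prec_bands.copy()
                    ab[2] += self.gamma / dt_sub
                    ab[2, ~self.free[:, ax]] = 1e30
                    dx[:, ax] = solveh_banded(ab, F[:, ax])
                m = float(np.abs(dx).max())
                if m > self.cfg.max_step_um:
                    dx *= self.cfg.max_step_um / m
                x_new = self.x + dx
                self.d1 = self._transport(x_new)
                self.x = x_new
                self._dm = self._dm_continuous(self.x, self.d1)
                self._relax_twist(self._dm)
            e_end = self._total_energy(self.x, self.d1)
            if np.isfinite(e_end) and e_end <= saved[3] + 1e-6 * (abs(saved[3]) + 1.0):
                self._energy = e_end
                self.time = saved[4] + n_sub * dt_sub
                self._steps_since_refresh = 0
                self.dt = max(self.dt, 2.0 * self.dt_max / 500.0)
                return n_sub * dt_sub
            # roll back and retry with a longer burst: the valley's descent
            # emerges only on horizons beyond its oscillation period
            self.x, self.d1, self.theta = saved[0].copy(), saved[1].copy(), saved[2].copy()
            self._energy = saved[3]
            self.time = saved[4]
            self._dm = saved[5].copy()
            self.core.rebuild_pairs(self.x)
            self._prec_bands = self._preconditioner_bands()
            n_sub *= 4
        return 0.0

    # -- export ------------------------------------------------------------
    def snapshot(self) -> RodState:
        """Current state as an SI RodState."""
        return RodState(
            vertices=self.x / M_TO_UM,
            theta=self.theta.copy(),
            rest_lengths=self.core.rest / M_TO_UM,
            rest_twist=self.rest_twist,
            reference_frames=self.d1.copy(),
            time=self.time,
        )


def step_dynamics(rod: RodState, dt_s: float, params: MechParams, **cfg_kwargs) -> RodState:
    """Advance a rod by (at most) ``dt_s`` of overdamped relaxation.

    Clamped boundary vertices are unchanged; the accepted step never
    increases the total elastic energy. Internally the step may be
    subdivided if ``dt_s`` exceeds the stability bound.
    """
    cfg = SimConfig(params=params, **cfg_kwargs)
    sim = _Sim(rod, params, cfg)
    remaining = dt_s
    for i in range(1000):
        if remaining <= 0:
            break
        taken = sim.step(i, dt_cap=remaining)
        if taken == 0.0:
            break
        remaining -= taken
    return sim.snapshot()


def _seeded_perturbation(
    n: int,
    length_um: float,
    amp_frac: float,
    seed: int,
    wavelength_um: float | None = None,
) -> np.ndarray:
    """Deterministic transverse perturbation breaking the straight-rod symmetry.

    Default: a long-wavelength sinusoid plus smoothed seeded noise,
    enveloped to vanish at the clamped ends, amplitude ~ amp_frac * length.
    With ``wavelength_um`` set: a coherent helical wave of that wavelength
    (plus 10% noise), seeding every period of the instability equally.
    """
    rng = np.random.default_rng(seed)
    if wavelength_um is not None:
        s = np.linspace(0.0, 1.0, n)
        amp = amp_frac * length_um
        env = np.sin(np.pi * s)
        phase = rng.uniform(0, 2 * np.pi)
        arg = 2 * np.pi * s * length_um / wavelength_um + phase
        pert = np.zeros((n, 3))
        pert[:, 1] = amp * env * np.sin(arg)
        pert[:, 2] = amp * env * np.cos(arg)
        noise = rng.normal(0.0, 0.1 * amp, (n, 2))
        kernel = np.ones(5) / 5.0
        for c in (0, 1):
            pert[:, c + 1] += np.convolve(np.pad(noise[:, c], 2, mode="edge"), kernel, mode="valid") * env
        pert[:2] = 0.0
        pert[-2:] = 0.0
        return pert
    s = np.linspace(0.0, 1.0, n)
    amp = amp_frac * length_um
    env = np.sin(np.pi * s)
    pert = np.zeros((n, 3))
    for ax in (1, 2):
        phase = rng.uniform(0, 2 * np.pi)
        noise = rng.normal(0.0, 1.0, n)
        kernel = np.ones(5) / 5.0
        noise = np.convolve(noise, kernel, mode="same")
        noise /= max(np.abs(noise).max(), 1e-12)
        pert[:, ax] = amp * env * (np.sin(3 * np.pi * s + phase) + 0.5 * noise)
    # localized bumps: seeded nucleation sites for coil formation
    n_bumps = max(3, n // 50)
    centers = rng.uniform(0.1, 0.9, n_bumps)
    for c in centers:
        direction = rng.normal(size=2)
        direction /= np.linalg.norm(direction)
        bump = np.exp(-((s - c) ** 2) / (2 * 0.015**2))
        pert[:, 1] += amp * direction[0] * bump
        pert[:, 2] += amp * direction[1] * bump
    pert[:2] = 0.0
    pert[-2:] = 0.0
    return pert


def simulate(config: SimConfig, initial: RodState | None = None) -> Trajectory:
    """Relax a twisted rod to quasi-static equilibrium, collecting snapshots.

    The run terminates early once the maximum unclamped force norm drops
    below ``ftol_pn`` (after ``min_time_s``), else at ``max_time_s`` or
    ``max_steps``.
    """
    p = config.params
    if initial is None:
        rod = build_rod(config.n_vertices, config.length_m, p, config.twist_rate_rad_per_m)
        if config.slack_frac and not config.slack_ramp_steps:
            rod.rest_lengths = rod.rest_lengths * (1.0 + config.slack_frac)
        pert = _seeded_perturbation(
            rod.n_vertices,
            config.length_m * M_TO_UM,
            config.perturb_amplitude_frac,
            config.seed,
            wavelength_um=config.perturb_wavelength_um,
        )
        rod = rod.displaced(pert / M_TO_UM)
    else:
        rod = initial
    sim = _Sim(rod, p, config)
    traj = Trajectory(snapshots=[], times=[], energies=[], config=config)

    def record() -> None:
        snap = sim.snapshot()
        from .rod import elastic_energy

        traj.snapshots.append(snap)
        traj.times.append(sim.time)
        traj.energies.append(elastic_energy(snap, p))

    record()
    next_snap = config.snapshot_interval_s
    check_every = 50
    step = 0
    n_short = config.shortening_steps if config.end_shortening_frac else 0
    if n_short:
        total_short_um = config.end_shortening_frac * config.length_m * M_TO_UM
        increment = np.array([-total_short_um / n_short, 0.0, 0.0])
    n_ramp = config.slack_ramp_steps if (config.slack_frac and config.slack_ramp_steps) else 0
    n_short = max(n_short, n_ramp)
    while step < config.max_steps and sim.time < config.max_time_s:
        if config.end_shortening_frac and step < config.shortening_steps:
            sim.shift_boundary(increment)
        if n_ramp and step <= n_ramp:
            sim.core.set_rest_scale(1.0 + config.slack_frac * min(step / n_ramp, 1.0))
            sim._energy = None
        taken = sim.step(step)
        step += 1
        if taken == 0.0 and step > n_short:
            traj.converged = True
            break
        if sim.time >= next_snap:
            record()
            next_snap += config.snapshot_interval_s
        if step % check_every == 0 and sim.time >= config.min_time_s and step > n_short:
            F = sim.forces()
            fmax = float(np.sqrt((F**2).sum(axis=1)).max())
            if fmax < config.ftol_pn:
                traj.converged = True
                break
    record()
    traj.n_steps = step
    return traj
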