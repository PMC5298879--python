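"""Parameter-space sweeps: coil counts over mechanics grids (phase diagrams).

Each grid vertex runs a full rod relaxation and counts the resulting
self-contact coils; the analytic stability boundary k_crit = C^2 tau^2/(4B)
is overlaid where the swept axes permit. In the constant-tension boundary
mode the linear theory applies exactly, so the simulated coil/no-coil
boundary should track the analytic curve.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .dynamics import SimConfig, simulate
from .errors import AxonMechError, InvalidParameterError
from .params import MechParams
from .plectoneme import detect_plectonemes
from .stability import critical_stiffness

_AXES = ("tension_n", "axial_stiffness_pa", "B", "G", "E", "twist_rate_rad_per_m")


@dataclass
class PhaseDiagram:
    axis1_name: str
    axis1_values: np.ndarray
    axis2_name: str
    axis2_values: np.ndarray
    coil_count: np.ndarray  # shape (len(axis2), len(axis1))
    failed: np.ndarray
    boundary_analytic: np.ndarray | None  # (m, 2): critical axis1 value per axis2


def _rebuild_params(p: MechParams, **overrides) -> MechParams:
    """New MechParams with selected fields replaced and derived ones updated."""
    fields = dict(E=p.E, nu=p.nu, radius=p.radius, G=p.G, B=p.B, C=p.C, k=p.k, mu=p.mu)
    if "E" in overrides and len(overrides) == 1:
        # re-derive everything from the new Young's modulus
        return MechParams(E=overrides["E"], nu=p.nu, radius=p.radius, mu=p.mu)
    if "G" in overrides:
        fields["C"] = None  # C follows the swept shear modulus: C = 2 G I
    fields.update(overrides)
    return MechParams(**fields)


def _apply_axis(cfg: SimConfig, name: str, value: float) -> SimConfig:
    if name == "tension_n":
        if cfg.axial_mode == "constant_tension":
            return replace(cfg, tension_n=value)
        return replace(cfg, boundary="tension", tension_n=value)
    if name == "axial_stiffness_pa":
        if cfg.boundary == "tension":
            return replace(cfg, tension_n=value * cfg.params.A)
        return replace(cfg, params=_rebuild_params(cfg.params, k=value))
    if name == "B":
        return replace(cfg, params=_rebuild_params(cfg.params, B=value))
    if name == "G":
        return replace(cfg, params=_rebuild_params(cfg.params, G=value))
    if name == "E":
        return replace(cfg, params=_rebuild_params(cfg.params, E=value))
    if name == "twist_rate_rad_per_m":
        return replace(cfg, twist_rate_rad_per_m=value)
    raise InvalidParameterError(f"unknown sweep axis {name!r}; options: {_AXES}")


def _critical_axis1(axis1: str, cfg: SimConfig) -> float | None:
    """Critical value of axis1 from k_crit = C^2 tau^2 / (4B), if expressible."""
    p = cfg.params
    tau = cfg.twist_rate_rad_per_m
    if tau == 0:
        return None
    try:
        k_crit = critical_stiffness(p.C, tau, p.B)  # tension, N
    except AxonMechError:
        return None
    if axis1 == "tension_n":
        return k_crit
    if axis1 == "axial_stiffness_pa":
        return k_crit / p.A
    if axis1 == "B":
        # B_crit below which the rod coils at the configured tension
        if cfg.boundary == "tension" or cfg.axial_mode == "constant_tension":
            T = cfg.tension_n
        else:
            T = p.k * p.A
        if T <= 0:
            return None
        return p.C**2 * tau**2 / (4.0 * T)
    return None


def _run_cell(cfg: SimConfig, contact_factor, cluster_gap_um, early_stop, chunk_steps):
    """Simulate one grid vertex, optionally stopping once a coil exists."""
    if not early_stop:
        traj = simulate(cfg)
        return detect_plectonemes(
            traj.final,
            diameter_um=cfg.params.diameter * 1e6,
            contact_factor=contact_factor,
            cluster_gap_um=cluster_gap_um,
        ).count
    done = 0
    state = None
    count = 0
    while done < cfg.max_steps:
        step_budget = min(chunk_steps, cfg.max_steps - done)
        traj = simulate(replace(cfg, max_steps=step_budget), initial=state)
        state = traj.final
        done += traj.n_steps
        count = detect_plectonemes(
            state,
            diameter_um=cfg.params.diameter * 1e6,
            contact_factor=contact_factor,
            cluster_gap_um=cluster_gap_um,
        ).count
        if count > 0 or traj.converged:
            break
    return count


def phase_diagram(
    axis1: tuple[str, np.ndarray],
    axis2: tuple[str, np.ndarray],
    base_config: SimConfig,
    contact_factor: float = 1.5,
    cluster_gap_um: float = 2.0,
    early_stop_on_coil: bool = True,
    chunk_steps: int = 4000,
) -> PhaseDiagram:
    """Coil count over a 2-D parameter grid, with the analytic boundary.

    Each vertex simulates to quasi-static convergence and counts coils by
    self-contact clustering; with ``early_stop_on_coil`` a vertex finishes
    as soon as the first coil appears (sufficient for the coil/no-coil
    boundary). Failed vertices are flagged rather than aborting the sweep.
    """
    name1, vals1 = axis1
    name2, vals2 = axis2
    vals1 = np.asarray(vals1, dtype=float)
    vals2 = np.asarray(vals2, dtype=float)
    if len(vals1) < 3 or len(vals2) < 3:
        raise InvalidParameterError("each sweep axis needs >= 3 points")
    counts = np.zeros((len(vals2), len(vals1)), dtype=int)
    failed = np.zeros_like(counts, dtype=bool)
    boundary = []
    for i2, v2 in enumerate(vals2):
        cfg_row = _apply_axis(base_config, name2, v2)
        crit = _critical_axis1(name1, cfg_row)
        if crit is not None:
            boundary.append((crit, v2))
        for i1, v1 in enumerate(vals1):
            cfg = _apply_axis(cfg_row, name1, v1)
            try:
                counts[i2, i1] = _run_cell(
                    cfg, contact_factor, cluster_gap_um, early_stop_on_coil, chunk_steps
                )
            except AxonMechError:
                failed[i2, i1] = True
    return PhaseDiagram(
        axis1_name=name1,
        axis1_values=vals1,
        axis2_name=name2,
        axis2_values=vals2,
        coil_count=counts,
        failed=failed,
        boundary_analytic=np.array(boundary) if boundary else None,
    )
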