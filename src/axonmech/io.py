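"""File I/O: trajectories (HDF5), tables (CSV), image stacks (TIFF).

All physical quantities are written with explicit unit suffixes in column
names or dataset attributes.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .rod import RodState


def save_trajectory(path: str | Path, snapshots: list[RodState], energies=None) -> Path:
    """Write rod snapshots (vertices, theta, times, energies) to HDF5."""
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["n_snapshots"] = len(snapshots)
        f.attrs["units"] = "vertices: m, theta: rad, time: s, energies: J"
        verts = np.stack([s.vertices for s in snapshots])
        f.create_dataset("vertices_m", data=verts)
        f.create_dataset("theta_rad", data=np.stack([s.theta for s in snapshots]))
        f.create_dataset("time_s", data=np.array([s.time for s in snapshots]))
        f.create_dataset("rest_lengths_m", data=snapshots[0].rest_lengths)
        if energies is not None:
            for name in ("bend", "twist", "stretch", "contact_penalty", "total"):
                f.create_dataset(
                    f"energy_{name}_j", data=np.array([getattr(e, name) for e in energies])
                )
    return path


def load_trajectory(path: str | Path) -> list[RodState]:
    import h5py

    out = []
    with h5py.File(path, "r") as f:
        verts = f["vertices_m"][...]
        theta = f["theta_rad"][...]
        times = f["time_s"][...]
        rest = f["rest_lengths_m"][...]
    for v, th, t in zip(verts, theta, times):
        out.append(RodState(vertices=v, theta=th, rest_lengths=rest, time=float(t)))
    return out


def save_table(path: str | Path, rows: list[dict]) -> Path:
    import pandas as pd

    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def save_stack_tiff(path: str | Path, stack: np.ndarray) -> Path:
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))
    return path


def load_stack_tiff(path: str | Path) -> np.ndarray:
    import tifffile

    return tifffile.imread(path)


def read_centerline_csv(path: str | Path, scale_um_per_px: float = 1.0):
    """Centerline from a CSV with x_um,y_um (or x,y in pixels) columns."""
    import pandas as pd

    from .shape import Centerline

    df = pd.read_csv(path)
    if {"x_um", "y_um"} <= set(df.columns):
        pts = df[["x_um", "y_um"]].to_numpy()
        return Centerline(points=pts, scale=1.0)
    pts = df[["x", "y"]].to_numpy()
    return Centerline(points=pts, scale=scale_um_per_px)


def read_force_curve(path: str | Path):
    """Force curve from a two-column CSV/TSV with unit-suffixed headers.

    Accepts (indentation_m, force_n) or (indentation_nm, force_pn).
    """
    import pandas as pd

    from .afm import ForceCurve
    from .errors import InvalidParameterError

    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    cols = {c.lower(): c for c in df.columns}
    if "indentation_m" in cols and "force_n" in cols:
        d = df[cols["indentation_m"]].to_numpy()
        F = df[cols["force_n"]].to_numpy()
    elif "indentation_nm" in cols and "force_pn" in cols:
        d = df[cols["indentation_nm"]].to_numpy() * 1e-9
        F = df[cols["force_pn"]].to_numpy() * 1e-12
    else:
        raise InvalidParameterError(
            "expected columns (indentation_m, force_n) or (indentation_nm, force_pn); "
            f"got {list(df.columns)}"
        )
    return ForceCurve(indentation=d, force=F)


def read_bundle_sections(path: str | Path):
    """BundleSections from CSV (section_index, x_nm, y_nm[, radius_nm, oblique])."""
    import pandas as pd

    from .bundle import DEFAULT_MT_RADIUS_NM, BundleSection

    df = pd.read_csv(path)
    sections = []
    for idx, grp in df.groupby("section_index"):
        radii = grp["radius_nm"].to_numpy() if "radius_nm" in grp else None
        oblique = grp["oblique"].to_numpy().astype(bool) if "oblique" in grp else None
        sections.append(
            BundleSection(
                centers=grp[["x_nm", "y_nm"]].to_numpy(),
                radii=radii,
                section_index=int(idx),
                oblique=oblique,
            )
        )
    return sections


def save_json(path: str | Path, obj) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, default=_json_default))
    return path


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    return str(o)
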