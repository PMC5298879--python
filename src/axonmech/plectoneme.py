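"""Plectoneme (coil) detection and spacing statistics.

A plectoneme is a localized self-contacting supercoil: two portions of the
rod that are distant along the contour approach each other in space. Coils
are detected as clusters of such self-contacts along arclength: every
non-neighboring segment pair closer than ``contact_factor`` rod diameters
is a contact event located at the arclength midpoint of the two strands
(the tip of the loop); events closer than ``cluster_gap_um`` along the
contour are merged into one coil.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import InsufficientDataError
from .rod import RodState, _segment_pair_distances


@dataclass
class CoilCluster:
    """One detected coil: arclength centroid and extent, um."""

    centroid_um: float
    extent_um: float
    n_contacts: int


@dataclass
class PlectonemeSet:
    clusters: list[CoilCluster]
    count: int
    total_arclength_um: float


def _as_points_um(obj) -> np.ndarray:
    if isinstance(obj, RodState):
        return obj.vertices * 1e6
    pts = np.asarray(obj, dtype=float)
    if pts.ndim != 2 or pts.shape[1] not in (2, 3):
        raise InsufficientDataError("expected (n, 2) or (n, 3) point array or RodState")
    if pts.shape[1] == 2:
        pts = np.column_stack([pts, np.zeros(len(pts))])
    return pts


def detect_plectonemes(
    rod_or_points_um,
    *,
    diameter_um: float = 0.2,
    contact_factor: float = 1.5,
    cluster_gap_um: float = 2.0,
    min_arclength_sep_um: float = 2.0,
) -> PlectonemeSet:
    """Find self-contact coil clusters along a rod or centerline.

    Parameters
    ----------
    rod_or_points_um
        A :class:`RodState` (SI) or an (n, 2|3) array of points in um.
    diameter_um
        Rod diameter; contact threshold is ``contact_factor * diameter_um``.
    cluster_gap_um
        Contacts closer than this along the contour merge into one coil.
    min_arclength_sep_um
        Pairs closer than this along the contour are ignored (a smooth bend
        is not a self-contact; loops are larger than this).
    """
    pts = _as_points_um(rod_or_points_um)
    seg = np.diff(pts, axis=0)
    seg_len = np.sqrt((seg**2).sum(axis=1))
    s_mid = np.concatenate([[0.0], np.cumsum(seg_len)])[:-1] + seg_len / 2.0
    total = float(seg_len.sum())
    threshold = contact_factor * diameter_um

    mids = (pts[:-1] + pts[1:]) / 2.0
    ne = len(mids)
    ii, jj = np.triu_indices(ne, k=1)
    far_enough = (s_mid[jj] - s_mid[ii]) >= min_arclength_sep_um
    ii, jj = ii[far_enough], jj[far_enough]
    if len(ii):
        # cheap midpoint prefilter before the exact segment-segment distance
        md = np.sqrt(((mids[ii] - mids[jj]) ** 2).sum(axis=1))
        margin = seg_len.max()
        cand = md < threshold + 2 * margin
        ii, jj = ii[cand], jj[cand]
    if len(ii):
        dist, _, _, _ = _segment_pair_distances(pts, ii, jj)
        hit = dist < threshold
        ii, jj = ii[hit], jj[hit]

    clusters: list[CoilCluster] = []
    if len(ii):
        centers = (s_mid[ii] + s_mid[jj]) / 2.0
        order = np.argsort(centers)
        centers = centers[order]
        lo = s_mid[ii][order]
        hi = s_mid[jj][order]
        breaks = np.where(np.diff(centers) > cluster_gap_um)[0]
        bounds = np.concatenate([[0], breaks + 1, [len(centers)]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            clusters.append(
                CoilCluster(
                    centroid_um=float(centers[a:b].mean()),
                    extent_um=float(hi[a:b].max() - lo[a:b].min()),
                    n_contacts=int(b - a),
                )
            )
    return PlectonemeSet(clusters=clusters, count=len(clusters), total_arclength_um=total)


def plectoneme_spacing(clusters) -> tuple[float, np.ndarray]:
    """Mean and per-interval centroid-to-centroid arclength spacings, um.

    Accepts a :class:`PlectonemeSet`, a list of :class:`CoilCluster`, or a
    sequence of centroid arclengths.
    """
    if isinstance(clusters, PlectonemeSet):
        clusters = clusters.clusters
    cents = np.sort(
        np.array(
            [c.centroid_um if isinstance(c, CoilCluster) else float(c) for c in clusters]
        )
    )
    if len(cents) < 2:
        raise InsufficientDataError(
            f"need >= 2 coils to measure spacing, got {len(cents)}"
        )
    intervals = np.diff(cents)
    return float(intervals.mean()), intervals
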