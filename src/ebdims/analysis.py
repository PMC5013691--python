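"""Pathway scoring against crystallographic intermediates.

Three diagnostics mirror the validation workflow: per-intermediate approach
profiles (rMSD and PC1-2 distance along the path), a forward/reverse
asymmetry score in the PC1-2 plane, and free-energy-landscape-style
projection histograms (−k_BT·ln density).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import KB
from .pca import PCABasis, ProjectionSet, pc_distance, project, project_set
from .structures import CAModel, Trajectory, rmsd

__all__ = [
    "PathScore",
    "approach_profile",
    "asymmetry_score",
    "projection_histogram",
]


@dataclass
class PathScore:
    """Closest-approach summary of a pathway to a list of intermediates."""

    labels: list
    min_rmsd: np.ndarray           # Å, per intermediate
    min_rmsd_frame: np.ndarray     # frame index of closest rMSD approach
    min_pc_distance: np.ndarray    # Å in PC1-2, per intermediate
    min_pc_frame: np.ndarray
    rmsd_profiles: np.ndarray      # (n_frames, n_intermediates)
    pc_profiles: np.ndarray
    asymmetry: float | None = None


def approach_profile(path, intermediates: list[CAModel],
                     basis: PCABasis) -> PathScore:
    """Per-frame rMSD and PC1-2 distance to each intermediate.

    ``path`` is a Trajectory or anything with a ``.trajectory`` attribute
    (a PathResult).  rMSD is computed after optimal superposition of each
    frame onto the intermediate; PC distances are Euclidean in the PC1-2
    plane of ``basis``.
    """
    traj: Trajectory = getattr(path, "trajectory", path)
    if len(traj) == 0:
        raise ValueError("empty path")
    if not intermediates:
        raise ValueError("no intermediates given")
    inter_pc = np.asarray([project(basis, m.coords, 2) for m in intermediates])
    frame_pc = project_set(basis, traj, k_components=2).coords_pc
    n_f, n_i = len(traj), len(intermediates)
    rmsd_prof = np.empty((n_f, n_i))
    pc_prof = np.empty((n_f, n_i))
    for f in range(n_f):
        for m in range(n_i):
            rmsd_prof[f, m] = rmsd(traj.frames[f], intermediates[m].coords)
            pc_prof[f, m] = pc_distance(frame_pc[f], inter_pc[m])
    return PathScore(
        labels=[m.id for m in intermediates],
        min_rmsd=rmsd_prof.min(axis=0),
        min_rmsd_frame=rmsd_prof.argmin(axis=0),
        min_pc_distance=pc_prof.min(axis=0),
        min_pc_frame=pc_prof.argmin(axis=0),
        rmsd_profiles=rmsd_prof,
        pc_profiles=pc_prof,
    )


def asymmetry_score(forward: ProjectionSet, reverse: ProjectionSet,
                    anchors=None, n_bins: int = 20) -> float:
    """Forward/reverse pathway divergence in the PC1-2 plane, in [0, 1].

    The two paths bound a loop between the end-states.  The frame is
    rotated so the start→target axis (``anchors``; by default the first and
    last forward points) lies along x, then the loop's semi-minor axis is
    taken as half the largest gap between the binned mean forward and
    reverse PC2 profiles, and the semi-major axis as half the pooled extent
    along the transition.  The score is their ratio: 0 for coincident
    routes, approaching 1 for a loop as wide as the transition is long.
    Symmetric in its arguments and invariant to rotations of the PC plane.
    """
    f = np.asarray(forward.coords_pc, dtype=float)[:, :2]
    r = np.asarray(reverse.coords_pc, dtype=float)[:, :2]
    if anchors is None:
        anchors = (f[0], f[-1])
    a0, a1 = (np.asarray(a, dtype=float)[:2] for a in anchors)
    axis = a1 - a0
    pooled = np.vstack([f, r])
    if np.allclose(pooled, pooled[0]) or np.linalg.norm(axis) == 0:
        raise ValueError("degenerate projections: no transition extent")
    axis = axis / np.linalg.norm(axis)
    rot = np.array([[axis[0], axis[1]], [-axis[1], axis[0]]])
    fx = (f - a0) @ rot.T
    rx = (r - a0) @ rot.T
    lo = min(fx[:, 0].min(), rx[:, 0].min())
    hi = max(fx[:, 0].max(), rx[:, 0].max())
    if hi == lo:
        raise ValueError("degenerate projections: no transition extent")
    edges = np.linspace(lo, hi, n_bins + 1)
    gap = 0.0
    for b in range(n_bins):
        in_f = (fx[:, 0] >= edges[b]) & (fx[:, 0] <= edges[b + 1])
        in_r = (rx[:, 0] >= edges[b]) & (rx[:, 0] <= edges[b + 1])
        if in_f.any() and in_r.any():
            gap = max(gap, abs(fx[in_f, 1].mean() - rx[in_r, 1].mean()))
    semi_minor = gap / 2.0
    semi_major = (hi - lo) / 2.0
    return float(min(semi_minor / semi_major, 1.0))


def projection_histogram(sets: list[ProjectionSet], bins: int = 40,
                         temperature: float = 300.0):
    """Free-energy-style landscape −k_BT·ln(density) over the PC1-2 plane.

    Pools the points of all sets, normalizes the 2-D histogram, masks empty
    bins with NaN and shifts the minimum to zero.  Returns
    ``(grid, x_edges, y_edges)`` with grid indexed [ix, iy].
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if not sets:
        raise ValueError("no projection sets given")
    pts = np.vstack([np.asarray(s.coords_pc)[:, :2] for s in sets])
    counts, xe, ye = np.histogram2d(pts[:, 0], pts[:, 1], bins=bins)
    density = counts / counts.sum()
    with np.errstate(divide="ignore"):
        grid = -KB * temperature * np.log(density)
    grid[counts == 0] = np.nan
    grid -= np.nanmin(grid)
    return grid, xe, ye
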