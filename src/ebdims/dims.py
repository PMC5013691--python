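"""Dynamic importance sampling: a Maxwell demon on top of Langevin dynamics.

Transitions between two conformations are generated by running stretches of
k unbiased thermostatted steps and letting a demon accept a stretch only if
the structure moved closer to the target, as measured by the progress
variable

    Γ = Σ_{(i,j)} (d_ij − d_ij^target)²

over corresponded residue pairs.  Γ depends only on internal distances, so
no superposition is needed and the bias never applies external forces: the
demon merely filters spontaneous thermal moves.  Iteration stops when the
structure reaches the target basin, i.e. an rMSD to the target within the
range of thermal oscillations (1–3 Å depending on system size).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .bd_engine import BDParams, SimState, integrate, kinetic_temperature, \
    maxwell_velocities
from .enm import ENMParams, build_ed_enm
from .structures import CAModel, Trajectory, rmsd

__all__ = [
    "DIMSParams",
    "PathResult",
    "progress_variable",
    "demon_accept",
    "run_transition",
    "asymmetry_inputs",
]


@dataclass
class DIMSParams:
    """Demon parameters.

    k_unbiased : unbiased Langevin steps per demon evaluation cycle.
        Larger k gives slower but wider sampling; small k approaches a
        Cartesian interpolation.  The default gives the overdamped soft
        modes enough time to diffuse between demon evaluations, which the
        ratchet needs to make steady progress.
    convergence_rmsd : Å; target-basin radius.  ``None`` selects 1.5 Å,
        widened to 3.0 Å for systems above 1000 residues.
    max_cycles : demon cycles before giving up (non-convergence is
        reported, not raised).
    pair_subset : optional (P, 2) residue-index pairs restricting Γ, for
        partial targets with unresolved regions.
    """

    k_unbiased: int = 300
    convergence_rmsd: float | None = None
    max_cycles: int = 5000
    pair_subset: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        if self.k_unbiased < 1:
            raise ValueError("k_unbiased must be >= 1")
        if self.convergence_rmsd is not None and not (
                0 < self.convergence_rmsd <= 5):
            raise ValueError("convergence_rmsd must be in (0, 5] Å")
        if self.max_cycles < 1:
            raise ValueError("max_cycles must be >= 1")

    def resolved_convergence(self, n_residues: int) -> float:
        if self.convergence_rmsd is not None:
            return self.convergence_rmsd
        return 3.0 if n_residues > 1000 else 1.5


@dataclass
class PathResult:
    """A biased pathway: one frame per accepted demon checkpoint."""

    trajectory: Trajectory
    gamma_series: np.ndarray      # Å² at each accepted checkpoint
    rmsd_to_target: np.ndarray    # Å at each accepted checkpoint
    converged: bool
    n_rejections: int
    n_cycles: int
    log: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self):
        if not (len(self.trajectory) == len(self.gamma_series)
                == len(self.rmsd_to_target)):
            raise ValueError("series lengths differ")
        if np.any(np.diff(self.gamma_series) >= 0):
            raise ValueError("gamma_series must be strictly decreasing")


def _pair_distances(coords: np.ndarray, pair_subset) -> np.ndarray:
    if pair_subset is None:
        return pdist(coords)
    ps = np.asarray(pair_subset, dtype=int)
    return np.linalg.norm(coords[ps[:, 0]] - coords[ps[:, 1]], axis=1)


def progress_variable(coords: np.ndarray, target, pair_subset=None) -> float:
    """Γ in Å²: squared pairwise-distance mismatch with the target.

    ``target`` may be a CAModel or a coordinate array; by default every
    corresponded pair contributes, or only ``pair_subset``.  Rigid motions
    of either structure leave Γ unchanged.
    """
    tcoords = target.coords if isinstance(target, CAModel) else np.asarray(target)
    coords = np.asarray(coords, dtype=float)
    if coords.shape != tcoords.shape:
        raise ValueError("coords and target are not corresponded")
    d_now = _pair_distances(coords, pair_subset)
    d_tgt = _pair_distances(tcoords, pair_subset)
    if len(d_now) == 0:
        raise ValueError("empty pair set")
    return float(np.sum((d_now - d_tgt) ** 2))


def demon_accept(gamma_now: float, gamma_prev: float) -> bool:
    """Accept iff Γ strictly decreased (equality rejected to avoid
    stagnation at plateaus)."""
    if not (np.isfinite(gamma_now) and np.isfinite(gamma_prev)):
        raise ValueError("non-finite progress variable")
    return gamma_now < gamma_prev


def run_transition(start: CAModel, target: CAModel,
                   enm_params: ENMParams | None = None,
                   bd_params: BDParams | None = None,
                   dims_params: DIMSParams | None = None) -> PathResult:
    """Generate a biased pathway from ``start`` towards ``target``.

    The spring network is built from the start structure only; the target
    enters exclusively through Γ (and the convergence rMSD), so it may be
    partial via ``pair_subset``.  On rejection both coordinates and
    velocities revert to the last accepted checkpoint while the noise
    stream keeps advancing, so each retry explores a fresh random branch.
    The reverse pathway is the same call with the roles swapped.
    """
    enm_params = enm_params or ENMParams()
    bd_params = bd_params or BDParams()
    dims_params = dims_params or DIMSParams()
    if start.n_residues != target.n_residues and dims_params.pair_subset is None:
        raise ValueError("start/target not corresponded; supply pair_subset")
    topo = build_ed_enm(start, enm_params)
    conv = dims_params.resolved_convergence(start.n_residues)
    ps = dims_params.pair_subset
    if ps is not None:
        ps = np.asarray(ps, dtype=int)
        restrained = np.unique(ps)
    else:
        restrained = None
    d_tgt = _pair_distances(target.coords, ps)

    rng = np.random.default_rng(dims_params.seed)
    state = SimState(start.coords.copy(),
                     maxwell_velocities(start.n_residues, bd_params, rng),
                     0, rng)

    def gamma_of(coords):
        d = _pair_distances(coords, ps)
        return float(np.sum((d - d_tgt) ** 2))

    def rmsd_of(coords):
        return rmsd(coords, target.coords, subset=restrained)

    g = gamma_of(state.coords)
    r = rmsd_of(state.coords)
    frames = [state.coords.copy()]
    gammas = [g]
    rmsds = [r]
    checkpoint = state.copy()
    rows = [(0, True, g, r, kinetic_temperature(state.velocities, bd_params.mass))]
    converged = r <= conv
    n_rej = 0
    cycle = 0
    while not converged and cycle < dims_params.max_cycles:
        cycle += 1
        integrate(state, topo, bd_params, dims_params.k_unbiased)
        g_now = gamma_of(state.coords)
        accepted = demon_accept(g_now, g)
        if accepted:
            g = g_now
            r = rmsd_of(state.coords)
            frames.append(state.coords.copy())
            gammas.append(g)
            rmsds.append(r)
            checkpoint = state.copy()
            converged = r <= conv
        else:
            n_rej += 1
            state.coords[:] = checkpoint.coords
            state.velocities[:] = checkpoint.velocities
        rows.append((cycle, accepted, g_now, r,
                     kinetic_temperature(state.velocities, bd_params.mass)))
    log = pd.DataFrame(rows, columns=["cycle", "accepted", "gamma",
                                      "rmsd_to_target", "temperature"])
    return PathResult(Trajectory(np.asarray(frames)),
                      np.asarray(gammas), np.asarray(rmsds),
                      bool(converged), n_rej, cycle, log)


def asymmetry_inputs(forward: PathResult,
                     reverse: PathResult) -> tuple[Trajectory, Trajectory]:
    """Bundle forward and reverse pathways (in that order) for projection."""
    if forward is None or reverse is None:
        raise ValueError("both forward and reverse paths are required")
    return forward.trajectory, reverse.trajectory
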