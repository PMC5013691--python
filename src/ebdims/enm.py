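"""Elastic network model with essential-dynamics calibrated springs.

Each Cα pair interacts through a hookean potential.  The potential
convention used throughout the package is

    V = Σ_pairs K_ij (d_ij − d⁰_ij)²     (no ½ factor),

so a pair stretched by δ pulls each bead with force 2Kδ.  Spring constants
follow the two-regime rule: the first ``n_seq`` chain neighbours get stiff,
distance-graded constants ``c_seq/s²`` (s = sequence separation) that
preserve backbone stereochemistry, while every other pair within the cutoff
gets an inverse-power, distance-decaying constant
``energy_scale·(c_cart/d⁰)^power``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .constants import KB
from .structures import CAModel, Trajectory

__all__ = [
    "ENMParams",
    "ENMTopology",
    "NormalModes",
    "build_ed_enm",
    "forces",
    "potential_energy",
    "hessian",
    "normal_modes",
    "mode_overlap",
    "mc_sample_along_modes",
]


@dataclass
class ENMParams:
    """Spring-network parameters.

    c_seq : kcal·mol⁻¹·Å⁻², scale of the sequential springs (K = c_seq/s²)
    n_seq : number of chain neighbours treated as sequential
    energy_scale : kcal·mol⁻¹·Å⁻², prefactor of the long-range rule
    c_cart : Å, length scale of the long-range decay
    power : long-range decay exponent
    cutoff : Å, interaction cutoff for non-sequential pairs
    """

    c_seq: float = 60.0
    n_seq: int = 3
    energy_scale: float = 6.0
    c_cart: float = 6.0
    power: float = 6.0
    cutoff: float = 12.0

    def __post_init__(self):
        if min(self.c_seq, self.energy_scale, self.c_cart, self.power,
               self.cutoff) <= 0:
            raise ValueError("ENM parameters must be positive")
        if self.n_seq < 1:
            raise ValueError("n_seq must be >= 1")
        if self.cutoff <= 3.8:
            raise ValueError("cutoff must exceed the Cα-Cα bond length")


@dataclass
class ENMTopology:
    """Spring list defining the network potential.

    ``pairs[p] = (i, j)`` with i < j, spring constant ``K[p]`` and
    equilibrium length ``d0[p]`` taken from the build structure, whose
    coordinates are kept in ``ref_coords``.
    """

    pairs: np.ndarray        # (P, 2) int
    K: np.ndarray            # (P,) kcal·mol⁻¹·Å⁻²
    d0: np.ndarray           # (P,) Å
    ref_coords: np.ndarray   # (N, 3) Å

    def __post_init__(self):
        self.pairs = np.asarray(self.pairs, dtype=int)
        self.K = np.asarray(self.K, dtype=float)
        self.d0 = np.asarray(self.d0, dtype=float)
        self.ref_coords = np.asarray(self.ref_coords, dtype=float)
        if np.any(self.d0 <= 0):
            raise ValueError("equilibrium lengths must be positive")
        keys = {tuple(p) for p in self.pairs}
        if len(keys) != len(self.pairs):
            raise ValueError("duplicate pairs")

    @property
    def n_residues(self) -> int:
        return len(self.ref_coords)

    def is_connected(self) -> bool:
        n = self.n_residues
        adj = coo_matrix((np.ones(len(self.pairs)),
                          (self.pairs[:, 0], self.pairs[:, 1])), shape=(n, n))
        return connected_components(adj, directed=False)[0] == 1


@dataclass
class NormalModes:
    """Low-frequency normal modes of the network Hessian.

    ``eigenvalues`` are ascending stiffnesses (kcal·mol⁻¹·Å⁻²) of the
    retained non-rigid modes; ``modes[k]`` is the corresponding orthonormal
    3N displacement vector.  ``n_zero`` counts the discarded near-zero
    (rigid-body) eigenvalues.  Residue masses are uniform, so mass-weighting
    is a scalar and the Hessian eigenvectors are the modes directly.
    """

    eigenvalues: np.ndarray
    modes: np.ndarray        # (n_modes, 3N)
    n_zero: int
    origin: np.ndarray       # (N, 3) build coordinates

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)


def build_ed_enm(model: CAModel, params: ENMParams | None = None) -> ENMTopology:
    """Build the spring network from a Cα structure.

    Sequential constants require an unbroken backbone: a pair counts as
    sequential only if both residues share a chain and their author numbers
    differ by exactly the sequence separation.  Pairs across chain breaks or
    numbering gaps fall back to the long-range rule (springs across a break
    should not inherit backbone stiffness).
    """
    if params is None:
        params = ENMParams()
    coords = model.coords
    n = len(coords)
    dist = squareform(pdist(coords))
    seq_pairs = {}
    for s in range(1, params.n_seq + 1):
        for i in range(n - s):
            j = i + s
            if (model.chain_ids[i] == model.chain_ids[j]
                    and model.res_ids[j] - model.res_ids[i] == s
                    and model.ins_codes[i] == model.ins_codes[j]):
                seq_pairs[(i, j)] = params.c_seq / s ** 2
    pairs, ks, d0s = [], [], []
    for (i, j), k in seq_pairs.items():
        pairs.append((i, j))
        ks.append(k)
        d0s.append(dist[i, j])
    iu, ju = np.triu_indices(n, k=1)
    within = dist[iu, ju] <= params.cutoff
    for i, j in zip(iu[within], ju[within]):
        if (i, j) in seq_pairs:
            continue
        d = dist[i, j]
        pairs.append((i, j))
        ks.append(params.energy_scale * (params.c_cart / d) ** params.power)
        d0s.append(d)
    topo = ENMTopology(np.asarray(pairs), np.asarray(ks), np.asarray(d0s),
                       coords.copy())
    if not topo.is_connected():
        warnings.warn("elastic network is not a single connected component",
                      stacklevel=2)
    return topo


def _pair_geometry(topology: ENMTopology, coords: np.ndarray):
    i, j = topology.pairs[:, 0], topology.pairs[:, 1]
    vec = coords[i] - coords[j]
    d = np.linalg.norm(vec, axis=1)
    return i, j, vec, d


def potential_energy(topology: ENMTopology, coords: np.ndarray) -> float:
    """V = Σ K (d − d0)² in kcal·mol⁻¹; zero at the build geometry."""
    _, _, _, d = _pair_geometry(topology, np.asarray(coords, dtype=float))
    return float(np.sum(topology.K * (d - topology.d0) ** 2))


def forces(topology: ENMTopology, coords: np.ndarray) -> np.ndarray:
    """−∇V at ``coords``; (N, 3) in kcal·mol⁻¹·Å⁻¹."""
    coords = np.asarray(coords, dtype=float)
    i, j, vec, d = _pair_geometry(topology, coords)
    if np.any(d == 0):
        raise ValueError("coincident bonded pair: force undefined")
    f_pair = (-2.0 * topology.K * (d - topology.d0) / d)[:, None] * vec
    out = np.zeros_like(coords)
    np.add.at(out, i, f_pair)
    np.add.at(out, j, -f_pair)
    return out


def hessian(topology: ENMTopology) -> np.ndarray:
    """Analytic 3N×3N second-derivative matrix of V at the build geometry.

    At d = d0 the tangential term vanishes, leaving rank-one blocks
    2K·ûûᵀ along each spring direction.
    """
    coords = topology.ref_coords
    n = len(coords)
    h = np.zeros((3 * n, 3 * n))
    i, j, vec, d = _pair_geometry(topology, coords)
    u = vec / d[:, None]
    for p in range(len(topology.pairs)):
        block = 2.0 * topology.K[p] * np.outer(u[p], u[p])
        a, b = 3 * i[p], 3 * j[p]
        h[a:a + 3, a:a + 3] += block
        h[b:b + 3, b:b + 3] += block
        h[a:a + 3, b:b + 3] -= block
        h[b:b + 3, a:a + 3] -= block
    return h


def normal_modes(topology: ENMTopology, n_modes: int,
                 zero_tol: float = 1e-8) -> NormalModes:
    """Lowest ``n_modes`` non-rigid modes of the network.

    Rigid-body modes are identified by eigenvalue magnitude relative to the
    stiffest mode (collinear toy systems have 5 rather than 6), then
    discarded.
    """
    h = hessian(topology)
    evals, evecs = np.linalg.eigh(h)
    n_zero = int(np.sum(evals < zero_tol * max(evals[-1], 1.0)))
    available = len(evals) - n_zero
    if n_modes > available:
        raise ValueError(f"only {available} non-rigid modes available")
    sel = slice(n_zero, n_zero + n_modes)
    return NormalModes(evals[sel].copy(), evecs[:, sel].T.copy(), n_zero,
                       topology.ref_coords.copy())


def mode_overlap(mode: np.ndarray, delta: np.ndarray) -> float:
    """|cosine| between a mode and a conformational difference vector."""
    mode = np.ravel(np.asarray(mode, dtype=float))
    delta = np.ravel(np.asarray(delta, dtype=float))
    nd = np.linalg.norm(delta)
    if nd == 0:
        raise ValueError("zero difference vector")
    return float(abs(mode @ delta) / (np.linalg.norm(mode) * nd))


def mc_sample_along_modes(modes: NormalModes, temperature: float,
                          n_samples: int, seed: int) -> Trajectory:
    """Monte-Carlo ensemble along normal modes at thermal amplitudes.

    Mode amplitudes are independent Gaussians with equipartition variance
    k_B·T/λ_k (the Hessian curvature along mode k is λ_k, giving energy
    ½λa², hence ⟨a²⟩ = k_BT/λ).
    """
    if modes.n_modes == 0:
        raise ValueError("no modes supplied")
    if np.any(modes.eigenvalues <= 0):
        raise ValueError("non-positive eigenvalue among selected modes")
    rng = np.random.default_rng(seed)
    sd = np.sqrt(KB * temperature / modes.eigenvalues)
    amps = rng.standard_normal((n_samples, modes.n_modes)) * sd
    disp = amps @ modes.modes                      # (n_samples, 3N)
    frames = modes.origin[None] + disp.reshape(n_samples, -1, 3)
    return Trajectory(frames)
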