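"""Synthetic structures for testing and demonstration: no downloads needed.

The central fixture is a toy two-domain "hinge" protein — two helical-
lattice domains joined by a 3-residue extended linker — whose conformers
interpolate a rigid hinge rotation between an open and a closed state,
emulating the domain-closure motions of periplasmic binding proteins.  The
helical lattice (2.0 Å rise, 100° twist, radius chosen for ~3.8 Å
consecutive Cα spacing) keeps sequential springs realistic; degenerate
straight chains would have pathological zero modes.  The open state is
already bent at the hinge: a pre-bent joint splits the two otherwise
degenerate bending directions, making in-plane hinge closure the single
softest normal mode, and keeps the hinge stiff enough that its thermal
oscillations stay protein-like.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .structures import CAModel, Ensemble

__all__ = ["HingeSpec", "make_hinge_models", "make_pca_ensemble"]

_SPACING = 3.8   # Å consecutive Cα distance
_RISE = 2.0      # Å per residue along the helix axis
_TWIST = 100.0   # degrees per residue
_RADIUS = np.sqrt(_SPACING ** 2 - _RISE ** 2) / (2 * np.sin(np.deg2rad(_TWIST / 2)))


@dataclass
class HingeSpec:
    """Toy hinge protein: two ``n_per_domain`` domains + 3-residue linker.

    Conformers rotate domain 2 about a hinge axis through the linker
    midpoint, at angles linearly interpolated between
    ``hinge_angle_open`` and ``hinge_angle_closed`` (degrees).
    """

    n_per_domain: int = 28
    hinge_angle_open: float = 30.0
    hinge_angle_closed: float = 60.0
    n_intermediates: int = 0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_per_domain < 10:
            raise ValueError("n_per_domain must be >= 10")
        if self.hinge_angle_open == self.hinge_angle_closed:
            raise ValueError("open and closed angles must differ")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def n_residues(self) -> int:
        return 2 * self.n_per_domain + 3


def _helix(n: int) -> np.ndarray:
    t = np.arange(n)
    ang = np.deg2rad(_TWIST) * t
    return np.column_stack([_RADIUS * np.cos(ang), _RADIUS * np.sin(ang),
                            _RISE * t])


def make_hinge_models(spec: HingeSpec) -> list[CAModel]:
    """Deterministic hinge conformers, ordered open → intermediates → closed.

    ``n_intermediates=0`` gives just the two end-states.  Gaussian
    coordinate noise (``noise_sd``) is reproducible from ``seed``.
    """
    n = spec.n_residues
    nd = spec.n_per_domain
    dom1 = _helix(nd)
    # extended linker continues along the helix axis; its low contact
    # density makes the joint the soft spot of the network
    linker = dom1[-1] + np.outer(np.arange(1, 4), [0.0, 0.0, _SPACING])
    dom2 = _helix(nd) - _helix(1)[0] + linker[-1] + [0.0, 0.0, _SPACING]
    base = np.vstack([dom1, linker, dom2])
    pivot_idx = nd + 1                         # middle linker residue
    pivot = base[pivot_idx]
    moving = np.arange(n) > pivot_idx
    angles = np.linspace(spec.hinge_angle_open, spec.hinge_angle_closed,
                         spec.n_intermediates + 2)
    rng = np.random.default_rng(spec.seed)
    names = (["hinge_open"]
             + [f"hinge_mid{i + 1}" for i in range(spec.n_intermediates)]
             + ["hinge_closed"])
    models = []
    for name, ang in zip(names, angles):
        coords = base.copy()
        rot = Rotation.from_rotvec(np.deg2rad(ang) * np.array([1.0, 0.0, 0.0]))
        coords[moving] = rot.apply(coords[moving] - pivot) + pivot
        if spec.noise_sd > 0:
            coords = coords + rng.normal(0.0, spec.noise_sd, coords.shape)
        models.append(CAModel(name, np.full(n, "A"), np.arange(1, n + 1),
                              np.full(n, ""), np.full(n, "ALA"), coords))
    return models


def make_pca_ensemble(mean_model: CAModel, basis_vectors, amplitudes_sd,
                      n: int, seed: int = 0) -> Ensemble:
    """Gaussian ensemble with known principal axes, for PCA ground truth.

    Members are ``mean + Σ_k a_k v_k`` with independent ``a_k ~
    N(0, sd_k²)`` along orthonormal 3N ``basis_vectors``; reproducible from
    ``seed``.
    """
    v = np.atleast_2d(np.asarray(basis_vectors, dtype=float))
    gram = v @ v.T
    if not np.allclose(gram, np.eye(len(v)), atol=1e-8):
        raise ValueError("basis vectors must be orthonormal")
    sd = np.asarray(amplitudes_sd, dtype=float)
    if len(sd) != len(v):
        raise ValueError("one amplitude per basis vector required")
    rng = np.random.default_rng(seed)
    amps = rng.standard_normal((n, len(v))) * sd
    disp = (amps @ v).reshape(n, -1, 3)
    members = [mean_model.with_coords(mean_model.coords + disp[i])
               for i in range(n)]
    for i, m in enumerate(members):
        m.id = f"synth_{i:04d}"
    return Ensemble(members, reference_index=0)
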