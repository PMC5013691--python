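"""Principal component analysis of structural ensembles.

All members are superposed once onto the designated reference (the
inactive/apo state); the covariance of Cα coordinates is taken about the
ensemble mean and diagonalized.  Projections, however, subtract the
REFERENCE structure rather than the mean, so a structure's PC coordinates
measure its deformation relative to a real conformation instead of a
geometric average — consequently the reference itself projects to the
origin while the centred cloud is generally offset from it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structures import CAModel, Ensemble, Trajectory, superposed

__all__ = [
    "PCABasis",
    "ProjectionSet",
    "fit_pca",
    "project",
    "project_set",
    "transition_coverage",
    "pc_distance",
    "save_basis",
    "load_basis",
]


@dataclass
class PCABasis:
    """Reference-aligned principal components of an ensemble.

    ``components`` are orthonormal 3N row vectors in descending eigenvalue
    order; eigenvalues are coordinate variances (Å²).
    """

    reference_coords: np.ndarray     # (N, 3)
    mean_coords: np.ndarray          # (N, 3)
    components: np.ndarray           # (n_comp, 3N)
    eigenvalues: np.ndarray          # (n_comp,)
    variance_fractions: np.ndarray   # (n_comp,) summing to 1

    @property
    def n_residues(self) -> int:
        return len(self.reference_coords)

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


@dataclass
class ProjectionSet:
    """PC-space coordinates of a set of structures or frames."""

    labels: list
    coords_pc: np.ndarray            # (M, k) Å

    def __post_init__(self):
        self.coords_pc = np.atleast_2d(np.asarray(self.coords_pc, dtype=float))
        if len(self.labels) != len(self.coords_pc):
            raise ValueError("labels/coords length mismatch")
        if not np.isfinite(self.coords_pc).all():
            raise ValueError("non-finite projections")

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{k + 1}" for k in range(self.coords_pc.shape[1])]
        df = pd.DataFrame(self.coords_pc, columns=cols)
        df.insert(0, "label", self.labels)
        return df


def fit_pca(ensemble: Ensemble, about: str = "mean") -> PCABasis:
    """Fit principal components to a corresponded ensemble (≥3 members).

    ``about`` selects the centring convention for the covariance: the
    ensemble ``"mean"`` (standard PCA, default) or the ``"reference"``
    structure; variance fractions can shift a few percent between the two.
    Component signs are fixed deterministically (largest-magnitude
    coefficient positive).
    """
    if len(ensemble) < 3:
        raise ValueError("need at least 3 ensemble members")
    if about not in ("mean", "reference"):
        raise ValueError("about must be 'mean' or 'reference'")
    ref = ensemble.reference.coords
    aligned = np.asarray([superposed(m.coords, ref) for m in ensemble.members])
    flat = aligned.reshape(len(ensemble), -1)
    mean = flat.mean(axis=0)
    centre = mean if about == "mean" else ref.ravel()
    x = flat - centre
    # economy SVD: at most M-1 (or M for reference centring) non-null PCs
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    denom = max(len(ensemble) - 1, 1)
    evals = s ** 2 / denom
    keep = evals > max(evals[0], 1e-300) * 1e-12
    evals, vt = evals[keep], vt[keep]
    signs = np.sign(vt[np.arange(len(vt)), np.argmax(np.abs(vt), axis=1)])
    vt = vt * signs[:, None]
    fractions = evals / evals.sum()
    return PCABasis(ref.copy(), mean.reshape(-1, 3), vt.copy(), evals,
                    fractions)


def project(basis: PCABasis, coords: np.ndarray, k_components: int = 2) -> np.ndarray:
    """Project one structure onto the first ``k_components`` PCs.

    The structure is superposed onto the reference first, then the
    difference to the REFERENCE coordinates is dotted with each component;
    the reference itself therefore maps to the origin.
    """
    if k_components > basis.n_components:
        raise ValueError(f"basis holds only {basis.n_components} components")
    aligned = superposed(np.asarray(coords, dtype=float), basis.reference_coords)
    diff = (aligned - basis.reference_coords).ravel()
    return basis.components[:k_components] @ diff


def project_set(basis: PCABasis, items, labels=None,
                k_components: int = 2) -> ProjectionSet:
    """Project an Ensemble, Trajectory, or list of CAModels/coord arrays."""
    if isinstance(items, Ensemble):
        coords = [m.coords for m in items.members]
        labels = labels or [m.id for m in items.members]
    elif isinstance(items, Trajectory):
        coords = list(items.frames)
        labels = labels or [f"frame{int(s)}" for s in items.frame_meta]
    else:
        coords = [it.coords if isinstance(it, CAModel) else np.asarray(it)
                  for it in items]
        labels = labels or [getattr(it, "id", f"item{i}")
                            for i, it in enumerate(items)]
    pcs = np.asarray([project(basis, c, k_components) for c in coords])
    return ProjectionSet(list(labels), pcs)


def transition_coverage(basis: PCABasis, start: CAModel, target: CAModel,
                        k: int = 2) -> float:
    """Fraction of the end-state difference captured by the first k PCs.

    With Δ the aligned target-minus-start vector,
    coverage_k = Σ_{j≤k} (Δ·PC_j)² / |Δ|².
    """
    if k > basis.n_components:
        raise ValueError(f"basis holds only {basis.n_components} components")
    a = superposed(start.coords, basis.reference_coords)
    b = superposed(target.coords, basis.reference_coords)
    delta = (b - a).ravel()
    norm2 = float(delta @ delta)
    if norm2 == 0:
        raise ValueError("start and target coincide")
    dots = basis.components[:k] @ delta
    return float(np.sum(dots ** 2) / norm2)


def pc_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two points in PC space (Å)."""
    a = np.ravel(np.asarray(a, dtype=float))
    b = np.ravel(np.asarray(b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("dimension mismatch")
    return float(np.linalg.norm(a - b))


def save_basis(basis: PCABasis, path) -> None:
    np.savez(path, reference_coords=basis.reference_coords,
             mean_coords=basis.mean_coords, components=basis.components,
             eigenvalues=basis.eigenvalues,
             variance_fractions=basis.variance_fractions)


def load_basis(path) -> PCABasis:
    with np.load(path) as z:
        return PCABasis(z["reference_coords"], z["mean_coords"],
                        z["components"], z["eigenvalues"],
                        z["variance_fractions"])
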