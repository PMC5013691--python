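"""Cα structure handling: PDB I/O, ensemble correspondence, superposition.

Proteins are reduced to one particle per residue (the α-carbon).  All
coordinates are in Å.  Residues are addressed internally by 0-based array
position; author chain/residue numbering (including insertion codes) is kept
as metadata for reporting and for matching residues across crystal forms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "CAModel",
    "Ensemble",
    "Trajectory",
    "DegenerateGeometryWarning",
    "read_pdb_ca",
    "write_multimodel_pdb",
    "residue_correspondence",
    "superpose",
    "superposed",
    "rmsd",
]


class DegenerateGeometryWarning(UserWarning):
    """Raised when a superposition target is collinear or coincident."""


@dataclass
class CAModel:
    """One structure reduced to Cα particles.

    Parameters
    ----------
    id : str
        Label, e.g. a PDB code.
    chain_ids, res_ids, ins_codes, res_names :
        Per-residue author chain label, residue number, insertion code
        (``""`` if none) and 3-letter residue name.
    coords : (N, 3) float array
        Cα positions in Å.
    """

    id: str
    chain_ids: np.ndarray
    res_ids: np.ndarray
    ins_codes: np.ndarray
    res_names: np.ndarray
    coords: np.ndarray

    def __post_init__(self):
        self.chain_ids = np.asarray(self.chain_ids, dtype="U4")
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        self.ins_codes = np.asarray(self.ins_codes, dtype="U1")
        self.res_names = np.asarray(self.res_names, dtype="U3")
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.coords)
        if n < 2:
            raise ValueError("a CAModel needs at least 2 residues")
        if self.coords.shape != (n, 3):
            raise ValueError("coords must be (N, 3)")
        if not np.isfinite(self.coords).all():
            raise ValueError("coords must be finite")
        for arr in (self.chain_ids, self.res_ids, self.ins_codes, self.res_names):
            if len(arr) != n:
                raise ValueError("metadata arrays must match coords length")
        if len(set(self.residue_keys())) != n:
            raise ValueError("duplicate (chain, res_id, ins_code) residue keys")

    @property
    def n_residues(self) -> int:
        return len(self.coords)

    def residue_keys(self) -> list[tuple[str, int, str]]:
        """Unique per-residue keys used for cross-structure matching."""
        return list(zip(self.chain_ids.tolist(), self.res_ids.tolist(),
                        self.ins_codes.tolist()))

    def subset(self, indices: np.ndarray) -> "CAModel":
        idx = np.asarray(indices, dtype=int)
        return CAModel(self.id, self.chain_ids[idx], self.res_ids[idx],
                       self.ins_codes[idx], self.res_names[idx],
                       self.coords[idx])

    def with_coords(self, coords: np.ndarray) -> "CAModel":
        return CAModel(self.id, self.chain_ids, self.res_ids,
                       self.ins_codes, self.res_names, coords)


@dataclass
class Ensemble:
    """Structures over a common residue correspondence.

    ``members[reference_index]`` is the designated reference (the inactive,
    resting or apo-like state) used for alignment and as projection origin.
    """

    members: list[CAModel]
    reference_index: int = 0

    def __post_init__(self):
        if not self.members:
            raise ValueError("empty ensemble")
        n = self.members[0].n_residues
        if any(m.n_residues != n for m in self.members):
            raise ValueError("ensemble members differ in residue count")
        if not 0 <= self.reference_index < len(self.members):
            raise ValueError("reference_index out of range")

    @property
    def reference(self) -> CAModel:
        return self.members[self.reference_index]

    @property
    def n_residues(self) -> int:
        return self.members[0].n_residues

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class Trajectory:
    """Ordered coordinate frames belonging to one CAModel topology."""

    frames: np.ndarray                      # (F, N, 3) Å
    frame_meta: np.ndarray = field(default=None)  # per-frame step index

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must be (F, N, 3)")
        if self.frame_meta is None:
            self.frame_meta = np.arange(len(self.frames))
        self.frame_meta = np.asarray(self.frame_meta, dtype=int)
        if len(self.frame_meta) != len(self.frames):
            raise ValueError("frame_meta length mismatch")

    def __len__(self) -> int:
        return len(self.frames)


# ---------------------------------------------------------------------------
# PDB I/O

def read_pdb_ca(path, model_index: int = 1,
                altloc_policy: str = "occupancy") -> CAModel:
    """Read one model of a PDB file and keep one Cα per residue.

    ``altloc_policy`` is one of ``"occupancy"`` (highest occupancy, ties to
    the first listed), ``"first"`` or ``"strict"`` (any alternate Cα
    location is an error).  Residues without a Cα (ligands, waters) are
    skipped.
    """
    if altloc_policy not in ("occupancy", "first", "strict"):
        raise ValueError(f"unknown altloc policy {altloc_policy!r}")
    pdb = PDBFile.read(path)
    if not 1 <= model_index <= pdb.get_model_count():
        raise ValueError(f"model {model_index} not in file "
                         f"({pdb.get_model_count()} models)")
    altloc = "all" if altloc_policy == "strict" else altloc_policy
    atoms = pdb.get_structure(model=model_index, altloc=altloc,
                              extra_fields=["occupancy"] if altloc == "all" else [])
    ca = atoms[(atoms.atom_name == "CA") & (atoms.element == "C")]
    if ca.array_length() == 0:
        raise ValueError(f"no Cα atoms in {path}")
    keys = list(zip(ca.chain_id.tolist(), ca.res_id.tolist(),
                    ca.ins_code.tolist()))
    if altloc_policy == "strict" and len(set(keys)) != len(keys):
        raise ValueError("alternate Cα locations present under strict policy")
    # under altloc="all" (strict) keys are unique if we got here
    name = str(path)
    label = name.rsplit("/", 1)[-1].rsplit(".", 1)[0]
    return CAModel(label, np.asarray(ca.chain_id), np.asarray(ca.res_id),
                   np.asarray(ca.ins_code), np.asarray(ca.res_name),
                   np.asarray(ca.coord, dtype=float))


def write_multimodel_pdb(model: CAModel, traj: Trajectory, path) -> None:
    """Write a trajectory as a multi-model PDB (one MODEL per frame)."""
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    n = model.n_residues
    if traj.frames.shape[1] != n:
        raise ValueError("frame size does not match model")
    stack = struc.AtomArrayStack(len(traj), n)
    stack.coord = np.asarray(traj.frames, dtype=np.float32)
    stack.chain_id = model.chain_ids
    stack.res_id = model.res_ids
    stack.ins_code = model.ins_codes
    stack.res_name = model.res_names
    stack.atom_name = np.full(n, "CA")
    stack.element = np.full(n, "C")
    stack.hetero = np.zeros(n, dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(path)


# ---------------------------------------------------------------------------
# Correspondence

def residue_correspondence(models: list[CAModel],
                           min_identity: float = 0.95) -> Ensemble:
    """Match residues across crystal forms of the same protein.

    Keeps the intersection of residues resolved in every member, matched by
    (chain, author residue number, insertion code); rejects the set if any
    pairwise sequence identity over the matched positions falls below
    ``min_identity``.  Same-protein crystal forms share numbering, so no
    alignment algorithm is needed.
    """
    if len(models) < 2:
        raise ValueError("need at least 2 models")
    n_chains = [len(dict.fromkeys(m.chain_ids.tolist())) for m in models]
    if len(set(n_chains)) != 1:
        raise ValueError("members differ in chain count")
    common = set(models[0].residue_keys())
    for m in models[1:]:
        common &= set(m.residue_keys())
    if not common:
        raise ValueError("no residues shared by all members")
    trimmed = []
    for m in models:
        keys = m.residue_keys()
        idx = [i for i, k in enumerate(keys) if k in common]
        trimmed.append(m.subset(np.asarray(idx)))
    # order within each member follows its own file; align to the first
    ref_keys = trimmed[0].residue_keys()
    order_maps = []
    for m in trimmed[1:]:
        pos = {k: i for i, k in enumerate(m.residue_keys())}
        order_maps.append(np.asarray([pos[k] for k in ref_keys]))
    trimmed = [trimmed[0]] + [m.subset(o) for m, o in zip(trimmed[1:], order_maps)]
    for i in range(len(trimmed)):
        for j in range(i + 1, len(trimmed)):
            ident = float(np.mean(trimmed[i].res_names == trimmed[j].res_names))
            if ident < min_identity:
                raise ValueError(
                    f"sequence identity {ident:.2f} between "
                    f"{trimmed[i].id} and {trimmed[j].id} below {min_identity}")
    return Ensemble(trimmed, reference_index=0)


# ---------------------------------------------------------------------------
# Superposition

def superpose(mobile: np.ndarray, target: np.ndarray, subset=None):
    """Least-squares rigid superposition (Kabsch) of ``mobile`` onto ``target``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``target`` over
    ``subset`` (all residues by default); the RMSD is computed over the
    subset after the transform.  A proper rotation (det = +1) is enforced.
    Coincident or collinear subsets are flagged with
    :class:`DegenerateGeometryWarning` and fitted by translation only.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape:
        raise ValueError("shape mismatch")
    if subset is None:
        subset = np.arange(len(mobile))
    subset = np.asarray(subset, dtype=int)
    if len(subset) == 0:
        raise ValueError("empty subset")
    x = mobile[subset]
    y = target[subset]
    xc = x.mean(axis=0)
    yc = y.mean(axis=0)
    h = (x - xc).T @ (y - yc)
    u, s, vt = np.linalg.svd(h)
    if len(subset) < 3 or s[1] <= 1e-10 * max(s[0], 1e-300):
        warnings.warn("degenerate geometry: translation-only superposition",
                      DegenerateGeometryWarning, stacklevel=2)
        rot = np.eye(3)
    else:
        d = np.sign(np.linalg.det(vt.T @ u.T))
        rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = yc - xc @ rot.T
    fitted = x @ rot.T + trans
    value = float(np.sqrt(np.mean(np.sum((fitted - y) ** 2, axis=1))))
    return rot, trans, value


def superposed(mobile: np.ndarray, target: np.ndarray, subset=None) -> np.ndarray:
    """``mobile`` after optimal superposition onto ``target``."""
    rot, trans, _ = superpose(mobile, target, subset)
    return np.asarray(mobile, dtype=float) @ rot.T + trans


def rmsd(a: np.ndarray, b: np.ndarray, subset=None, fit: bool = True) -> float:
    """Cα RMSD in Å, after optimal superposition unless ``fit=False``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if fit:
        return superpose(a, b, subset)[2]
    if subset is not None:
        idx = np.asarray(subset, dtype=int)
        a, b = a[idx], b[idx]
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
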