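"""Shared test utilities: oracles and tiny structure builders.

The oracles here are deliberately independent of the library code they
check (numerical minimisation instead of the closed-form Kabsch solution,
exhaustive scans instead of vectorised matrix algebra).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from conformens.core import StructureModel


def brute_force_rigid_rmsd(
    mobile: np.ndarray, target: np.ndarray, seed: int = 0, restarts: int = 6
) -> float:
    """Minimum RMSD over rigid motions by direct numerical minimisation.

    Parametrises the rotation as a rotation vector and minimises with
    Nelder-Mead from several random starts; independent of the SVD-based
    closed form.
    """
    rng = np.random.default_rng(seed)

    def cost(p: np.ndarray) -> float:
        rot = Rotation.from_rotvec(p[:3]).as_matrix()
        d = mobile @ rot.T + p[3:] - target
        return float(np.sqrt((d**2).sum(axis=1).mean()))

    best = np.inf
    for _ in range(restarts):
        p0 = np.concatenate([rng.normal(size=3), rng.normal(size=3)])
        res = minimize(
            cost,
            p0,
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-13, "maxiter": 20000, "maxfev": 20000},
        )
        best = min(best, res.fun)
    return best


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A uniform random proper rotation matrix."""
    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()


def ca_model(coords: np.ndarray, model_id: str = "m", chain: str = "A") -> StructureModel:
    """Cα-only model with residues numbered 1..n."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    return StructureModel(
        model_id, ["CA"] * n, ["ALA"] * n, np.arange(1, n + 1), [chain] * n, coords
    )


def backbone_model(
    n_res: int, model_id: str = "m", chain: str = "A", seed: int = 0
) -> StructureModel:
    """Model with N, CA, C, O per residue at jittered helical-ish positions."""
    rng = np.random.default_rng(seed)
    names, resnames, resnums, chains, coords = [], [], [], [], []
    offsets = {"N": (0.0, 0.0, 0.0), "CA": (1.5, 0.0, 0.0),
               "C": (2.5, 1.0, 0.0), "O": (2.5, 2.2, 0.0)}
    for r in range(1, n_res + 1):
        base = np.array([3.8 * r, 0.5 * (r % 3), 0.3 * r])
        for name, off in offsets.items():
            names.append(name)
            resnames.append("ALA")
            resnums.append(r)
            chains.append(chain)
            coords.append(base + np.array(off) + rng.normal(scale=0.01, size=3))
    return StructureModel(model_id, names, resnames, resnums, chains, np.array(coords))


def pdb_line(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resnum: int,
    xyz: tuple[float, float, float],
    occupancy: float = 1.0,
    altloc: str = " ",
    hetatm: bool = False,
    element: str | None = None,
    icode: str = " ",
) -> str:
    """One fixed-width ATOM/HETATM record."""
    record = "HETATM" if hetatm else "ATOM  "
    padded = name if len(name) >= 4 else f" {name:<3}"
    if element is None:
        element = name.lstrip("0123456789")[0]
    x, y, z = xyz
    return (
        f"{record}{serial:>5} {padded}{altloc}{resname:<3} {chain}{resnum:>4}{icode}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occupancy:6.2f}{0.0:6.2f}          {element:>2}"
    )


def equidistant_blob_coords(
    base: np.ndarray, n_per: int, n_blobs: int, sep: float, noise: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Well-separated blobs of conformations with equal pairwise separation.

    Blob centres sit at the vertices of a regular simplex in a random
    subspace of conformation space, ``sep`` Å RMSD apart, with isotropic
    per-atom noise inside each blob.  Returns (coords, true_labels).
    """
    rng = np.random.default_rng(seed)
    n_atoms = base.shape[0]
    dim = base.size
    # orthonormal directions spanning the simplex
    dirs = rng.normal(size=(n_blobs - 1, dim))
    q, _ = np.linalg.qr(dirs.T)
    q = q.T[: n_blobs - 1]
    # regular simplex vertices in (n_blobs-1) dims with unit edge
    verts = np.zeros((n_blobs, n_blobs - 1))
    if n_blobs == 2:
        verts[1, 0] = 1.0
    elif n_blobs == 3:
        verts[1] = [1.0, 0.0]
        verts[2] = [0.5, np.sqrt(3) / 2]
    else:
        raise ValueError("only 2 or 3 blobs supported")
    scale = sep * np.sqrt(n_atoms)  # Euclidean displacement giving ~sep Å RMSD
    coords, labels = [], []
    for b in range(n_blobs):
        center = (verts[b] @ q).reshape(n_atoms, 3) * scale
        for _ in range(n_per):
            coords.append(base + center + rng.normal(scale=noise, size=base.shape))
            labels.append(b)
    return np.array(coords), np.array(labels)
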