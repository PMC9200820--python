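"""Rigid-body superposition, RMSD matrices, ensemble alignment and RMSF.

Superposition uses the Kabsch solution (via
:func:`scipy.spatial.transform.Rotation.align_vectors`), which minimises the
weighted RMSD over proper rotations — reflections are excluded so chirality
is preserved.  Pairwise RMSD matrices are computed with a vectorised batch
of Kabsch fits (singular values of the 3x3 cross-covariance per pair), which
is algebraically identical to fitting each pair separately.

All coordinates are in Å.  RMSF values are reported in nm (Å/10), the
customary unit for per-residue fluctuation profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .core import Ensemble

__all__ = [
    "Superposition",
    "RMSDMatrix",
    "RMSFProfile",
    "kabsch_superpose",
    "rmsd_to_reference",
    "pairwise_rmsd_matrix",
    "align_to_mean",
    "rmsf_profile",
]


@dataclass(frozen=True)
class Superposition:
    """Optimal rigid transform of a mobile onto a target coordinate set.

    ``apply(x) = x @ rotation.T + translation`` maps mobile coordinates into
    the target frame; ``rmsd`` is the minimised (weighted) RMSD in Å.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        if r.shape != (3, 3) or not np.allclose(r.T @ r, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be a 3x3 orthonormal matrix")
        if np.linalg.det(r) < 0:
            raise ValueError("rotation must be proper (det +1)")
        if self.rmsd < 0:
            raise ValueError("rmsd must be >= 0")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


def kabsch_superpose(
    mobile: np.ndarray,
    target: np.ndarray,
    weights: np.ndarray | None = None,
) -> Superposition:
    """Least-squares rigid superposition of *mobile* onto *target*.

    Parameters
    ----------
    mobile, target
        Matched coordinate sets of shape ``(n_atoms, 3)``, n_atoms >= 3.
    weights
        Optional non-negative per-atom weights (default: unweighted).

    Returns
    -------
    Superposition
        Proper rotation + translation minimising the weighted RMSD, with the
        minimised RMSD value.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape:
        raise ValueError(
            f"atom count mismatch: mobile {mobile.shape} vs target {target.shape}"
        )
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise ValueError("need matched (n>=3, 3) coordinate sets")
    n = mobile.shape[0]
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0):
            raise ValueError("weights must be a non-negative length-n vector")
        if not w.sum() > 0:
            raise ValueError("weights must not be all zero")
    mob_center = np.average(mobile, axis=0, weights=w)
    tgt_center = np.average(target, axis=0, weights=w)
    mob_c = mobile - mob_center
    tgt_c = target - tgt_center
    if np.max(np.linalg.norm(mob_c, axis=1)) < 1e-12:
        raise ValueError("all mobile points coincident; superposition undefined")
    rot, rssd = Rotation.align_vectors(tgt_c, mob_c, weights=w)
    rmsd = float(rssd) / np.sqrt(w.sum())
    rotation = rot.as_matrix()
    translation = tgt_center - rotation @ mob_center
    return Superposition(rotation, translation, rmsd)


def rmsd_to_reference(coords: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Minimised RMSD of each conformation in *coords* to one *reference*.

    *coords* has shape ``(n_models, n_atoms, 3)``; vectorised Kabsch.
    """
    coords = np.asarray(coords, dtype=float)
    reference = np.asarray(reference, dtype=float)
    x = coords - coords.mean(axis=1, keepdims=True)
    r = reference - reference.mean(axis=0)
    n_atoms = r.shape[0]
    g_x = np.einsum("mia,mia->m", x, x)
    g_r = np.einsum("ia,ia->", r, r)
    h = np.einsum("mia,ib->mab", x, r)
    traces = _proper_singular_trace(h)
    msd = np.maximum(0.0, (g_x + g_r - 2.0 * traces) / n_atoms)
    return np.sqrt(msd)


def _proper_singular_trace(h: np.ndarray) -> np.ndarray:
    """max trace(R H) over proper rotations, for a batch of 3x3 matrices."""
    u, s, vt = np.linalg.svd(h)
    det = np.linalg.det(u) * np.linalg.det(vt)
    return s[..., 0] + s[..., 1] + np.sign(det) * s[..., 2]


@dataclass
class RMSDMatrix:
    """Symmetric matrix of pairwise minimised RMSDs (Å) between models."""

    model_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.model_ids)
        if v.shape != (n, n):
            raise ValueError(f"values shape {v.shape} does not match {n} ids")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("RMSD matrix must be symmetric")
        if np.any(np.abs(np.diag(v)) > 1e-9) or np.any(v < -1e-12):
            raise ValueError("RMSD matrix needs zero diagonal, entries >= 0")
        v = np.maximum(v, 0.0)
        np.fill_diagonal(v, 0.0)
        self.values = (v + v.T) / 2.0

    @property
    def n(self) -> int:
        return len(self.model_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.model_ids, columns=self.model_ids)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="model_id")

    @classmethod
    def from_csv(cls, path) -> "RMSDMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls([str(c) for c in df.columns], df.to_numpy(dtype=float))


def pairwise_rmsd_matrix(
    ensemble: Ensemble | np.ndarray,
    model_ids: list[str] | None = None,
    chunk: int = 256,
) -> RMSDMatrix:
    """All-against-all minimised RMSD between models of an ensemble.

    Each entry ``(i, j)`` equals an independent Kabsch fit of model *i* onto
    model *j*.  The computation is vectorised over pairs in chunks (3x3
    cross-covariance SVD per pair), so 1000-model decoy sets are tractable.
    """
    if isinstance(ensemble, Ensemble):
        coords = ensemble.coords()
        ids = ensemble.model_ids
    else:
        coords = np.asarray(ensemble, dtype=float)
        ids = model_ids if model_ids is not None else [str(i) for i in range(len(coords))]
    n, n_atoms, _ = coords.shape
    if n < 2:
        raise ValueError("pairwise RMSD needs at least 2 models")
    x = coords - coords.mean(axis=1, keepdims=True)
    g = np.einsum("mia,mia->m", x, x)
    out = np.zeros((n, n))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        # cross-covariances of the chunk against all models
        h = np.einsum("mia,nib->mnab", x[start:stop], x)
        traces = _proper_singular_trace(h)
        msd = np.maximum(0.0, (g[start:stop, None] + g[None, :] - 2.0 * traces) / n_atoms)
        out[start:stop] = np.sqrt(msd)
    out = (out + out.T) / 2.0
    np.fill_diagonal(out, 0.0)
    return RMSDMatrix(list(ids), out)


def align_to_mean(
    ensemble: Ensemble,
    tol: float = 1e-6,
    max_iter: int = 10,
) -> tuple[Ensemble, np.ndarray]:
    """Iteratively superpose all models onto their evolving mean structure.

    Starting from the first model as reference, every model is superposed
    onto the current reference and the mean of the superposed coordinates
    becomes the next reference, until the mean shifts by less than *tol*
    (plain RMSD between successive means) or *max_iter* is reached
    (non-convergence is a warning, not an error).

    Returns
    -------
    (aligned, mean)
        Transformed copy of the ensemble and the converged mean coordinates
        (``(n_atoms, 3)``, Å).
    """
    if ensemble.n_models < 2:
        raise ValueError("alignment needs at least 2 models")
    coords = ensemble.coords()
    reference = coords[0].copy()
    aligned = coords.copy()
    converged = False
    for _ in range(max_iter):
        for i in range(len(aligned)):
            sup = kabsch_superpose(aligned[i], reference)
            aligned[i] = sup.apply(aligned[i])
        new_mean = aligned.mean(axis=0)
        shift = np.sqrt(np.mean(np.sum((new_mean - reference) ** 2, axis=1)))
        reference = new_mean
        if shift < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"align_to_mean did not converge below tol={tol} within "
            f"{max_iter} iterations",
            stacklevel=2,
        )
    return ensemble.with_coords(aligned), reference


@dataclass
class RMSFProfile:
    """Per-residue root-mean-square fluctuation about the ensemble mean, nm."""

    residue_keys: list[tuple[str, int]]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.residue_keys),) or np.any(v < 0):
            raise ValueError("RMSF values must be >= 0, one per residue")
        self.values = v

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chain": [c for c, _ in self.residue_keys],
                "residue_number": [r for _, r in self.residue_keys],
                "rmsf_nm": self.values,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def rmsf_profile(aligned: Ensemble, selection: str = "calpha") -> RMSFProfile:
    """Per-residue RMSF of a pre-aligned ensemble, in nm.

    The per-residue position is the Cα atom (``selection="calpha"``) or the
    centroid of the residue's backbone atoms (``selection="backbone"``).  The
    fluctuation is the root of the mean (over models) squared displacement of
    that position from its ensemble-mean location.  The ensemble must already
    be aligned (see :func:`align_to_mean`); no superposition is applied here.
    """
    if aligned.n_models < 2:
        raise ValueError("RMSF undefined for a single-model ensemble")
    first = aligned.models[0]
    if selection == "calpha":
        atom_mask = first.atom_names.astype(str) == "CA"
    elif selection == "backbone":
        atom_mask = np.isin(first.atom_names.astype(str), ("N", "CA", "C", "O"))
    else:
        raise ValueError(f"unknown selection {selection!r}")
    if not atom_mask.any():
        raise ValueError(f"no atoms match selection {selection!r}")
    coords = aligned.coords()[:, atom_mask]
    chains = first.chain_ids[atom_mask]
    resnums = first.residue_numbers[atom_mask]
    residue_keys: list[tuple[str, int]] = []
    positions = []
    seen = set()
    for c, r in zip(chains, resnums):
        key = (str(c), int(r))
        if key not in seen:
            seen.add(key)
            residue_keys.append(key)
    for key in residue_keys:
        sel = (chains == key[0]) & (resnums == key[1])
        positions.append(coords[:, sel].mean(axis=1))
    pos = np.stack(positions, axis=1)  # (n_models, n_residues, 3)
    mean_pos = pos.mean(axis=0)
    sq = np.sum((pos - mean_pos) ** 2, axis=2).mean(axis=0)
    return RMSFProfile(residue_keys, np.sqrt(sq) / 10.0)
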