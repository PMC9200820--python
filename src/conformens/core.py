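"""Core containers for conformational-ensemble analysis.

A :class:`StructureModel` is one conformer (one decoy, one trajectory frame,
or one reference structure) stored as parallel per-atom arrays.  An
:class:`Ensemble` is an ordered, topology-consistent collection of models:
every model carries exactly the same atoms, identified by
``(chain_id, residue_number, atom_name)`` keys in the same order, so that
coordinate arrays can be stacked and compared atom-by-atom.  Energies from an
external rescoring step are carried in an :class:`EnergyTable`, and residue
ranges of interest (hinge, lids, domains) in :class:`RegionSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "StructureModel",
    "Ensemble",
    "EnergyTable",
    "RegionSpec",
    "AtomKey",
    "TopologyError",
]

#: identity of one atom within a model: (chain_id, residue_number, atom_name)
AtomKey = tuple[str, int, str]


class TopologyError(ValueError):
    """Raised when models in an ensemble do not share the same atom set."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a conformer, author numbering, coordinates in Å."""

    atom_name: str
    residue_name: str
    residue_number: int
    chain_id: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError(f"coords must be a finite 3-vector, got {self.coords!r}")
        object.__setattr__(self, "coords", coords)

    @property
    def key(self) -> AtomKey:
        return (self.chain_id, int(self.residue_number), self.atom_name)


class StructureModel:
    """A single conformer: labelled atoms with Cartesian coordinates (Å).

    Atom identity and coordinates are stored as parallel arrays; atom order
    is stable and significant (it defines the correspondence used by RMSD,
    RMSF and PCA).
    """

    def __init__(
        self,
        model_id: str,
        atom_names: Sequence[str],
        residue_names: Sequence[str],
        residue_numbers: Sequence[int],
        chain_ids: Sequence[str],
        coords: np.ndarray,
    ) -> None:
        self.model_id = str(model_id)
        self.atom_names = np.asarray(atom_names, dtype=object)
        self.residue_names = np.asarray(residue_names, dtype=object)
        self.residue_numbers = np.asarray(residue_numbers, dtype=int)
        self.chain_ids = np.asarray(chain_ids, dtype=object)
        self.coords = np.asarray(coords, dtype=float)
        n = len(self.atom_names)
        if self.coords.shape != (n, 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match {n} atoms"
            )
        for arr, name in (
            (self.residue_names, "residue_names"),
            (self.residue_numbers, "residue_numbers"),
            (self.chain_ids, "chain_ids"),
        ):
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != {n}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"model {model_id!r}: non-finite coordinates")
        keys = self.atom_keys
        if len(set(keys)) != len(keys):
            raise ValueError(f"model {model_id!r}: duplicate atom keys")

    @classmethod
    def from_atom_records(cls, model_id: str, atoms: Iterable[AtomRecord]) -> "StructureModel":
        atoms = list(atoms)
        if not atoms:
            raise ValueError("empty atom list")
        return cls(
            model_id,
            [a.atom_name for a in atoms],
            [a.residue_name for a in atoms],
            [a.residue_number for a in atoms],
            [a.chain_id for a in atoms],
            np.array([a.coords for a in atoms], dtype=float),
        )

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def atom_keys(self) -> list[AtomKey]:
        return [
            (c, int(r), a)
            for c, r, a in zip(self.chain_ids, self.residue_numbers, self.atom_names)
        ]

    def with_coords(self, coords: np.ndarray, model_id: str | None = None) -> "StructureModel":
        """Copy of this model with replaced coordinates (same topology)."""
        return StructureModel(
            model_id if model_id is not None else self.model_id,
            self.atom_names,
            self.residue_names,
            self.residue_numbers,
            self.chain_ids,
            coords,
        )

    def subset(self, mask: np.ndarray) -> "StructureModel":
        mask = np.asarray(mask, dtype=bool)
        return StructureModel(
            self.model_id,
            self.atom_names[mask],
            self.residue_names[mask],
            self.residue_numbers[mask],
            self.chain_ids[mask],
            self.coords[mask],
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"StructureModel({self.model_id!r}, {self.n_atoms} atoms)"


class Ensemble:
    """Ordered collection of topology-consistent :class:`StructureModel`.

    Every model must contain exactly the shared ``atom_keys`` in the same
    order; violating models raise :class:`TopologyError` naming them.
    """

    def __init__(self, models: Sequence[StructureModel]) -> None:
        models = list(models)
        if not models:
            raise ValueError("an Ensemble needs at least one model")
        ref_keys = models[0].atom_keys
        bad = [m.model_id for m in models[1:] if m.atom_keys != ref_keys]
        if bad:
            raise TopologyError(
                "models with atom sets inconsistent with the first model: "
                + ", ".join(bad)
            )
        ids = [m.model_id for m in models]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate model_ids in ensemble")
        self.models = models
        self.atom_keys: list[AtomKey] = ref_keys

    @property
    def n_models(self) -> int:
        return len(self.models)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_keys)

    @property
    def model_ids(self) -> list[str]:
        return [m.model_id for m in self.models]

    def coords(self) -> np.ndarray:
        """Stacked coordinates, shape ``(n_models, n_atoms, 3)``, Å."""
        return np.stack([m.coords for m in self.models])

    def with_coords(self, coords: np.ndarray) -> "Ensemble":
        """Same models/topology with replaced stacked coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_models, self.n_atoms, 3):
            raise ValueError(f"expected shape {(self.n_models, self.n_atoms, 3)}")
        return Ensemble([m.with_coords(c) for m, c in zip(self.models, coords)])

    def subset_models(self, model_ids: Sequence[str]) -> "Ensemble":
        by_id = {m.model_id: m for m in self.models}
        missing = [i for i in model_ids if i not in by_id]
        if missing:
            raise KeyError(f"model_ids not in ensemble: {missing}")
        return Ensemble([by_id[i] for i in model_ids])

    def __iter__(self) -> Iterator[StructureModel]:
        return iter(self.models)

    def __len__(self) -> int:
        return self.n_models

    def __getitem__(self, i: int) -> StructureModel:
        return self.models[i]

    def __repr__(self) -> str:  # pragma: no cover
        return f"Ensemble({self.n_models} models, {self.n_atoms} atoms)"


@dataclass
class EnergyTable:
    """Per-model scalar energies (kcal/mol) from an external rescoring step."""

    entries: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for mid, e in self.entries.items():
            if not np.isfinite(e):
                raise ValueError(f"non-finite energy for model {mid!r}")

    def __getitem__(self, model_id: str) -> float:
        return self.entries[model_id]

    def __contains__(self, model_id: str) -> bool:
        return model_id in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def for_models(self, model_ids: Sequence[str]) -> np.ndarray:
        missing = [i for i in model_ids if i not in self.entries]
        if missing:
            raise KeyError(f"model_ids missing from energy table: {missing}")
        return np.array([self.entries[i] for i in model_ids], dtype=float)


@dataclass(frozen=True)
class RegionSpec:
    """Inclusive author-numbered residue range on one chain.

    Used to name functional regions such as hinge lids or helices, e.g.
    the adenylate-kinase ATP lid (chain A, residues 26-78).
    """

    name: str
    chain_id: str
    first_residue: int
    last_residue: int

    def __post_init__(self) -> None:
        if self.first_residue > self.last_residue:
            raise ValueError(
                f"region {self.name!r}: first_residue > last_residue"
            )

    def contains(self, chain_id: str, residue_number: int) -> bool:
        return (
            chain_id == self.chain_id
            and self.first_residue <= residue_number <= self.last_residue
        )

    def mask(self, model: StructureModel) -> np.ndarray:
        return (model.chain_ids == self.chain_id) & (
            (model.residue_numbers >= self.first_residue)
            & (model.residue_numbers <= self.last_residue)
        )
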