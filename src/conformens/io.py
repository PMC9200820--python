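"""Reading and writing of structural ensembles and energy tables.

PDB parsing/writing is delegated to :mod:`biotite`; this module layers the
ensemble contract on top: one :class:`~conformens.core.StructureModel` per
``MODEL``/``ENDMDL`` block (or per file when a directory of single-model
files is given), altloc resolution by occupancy, optional removal of
heteroatoms and waters, and strict topology consistency with offending
models named in the error.

Energies produced by an external rescoring step (e.g. a coarse-grained
force-field evaluation of each decoy) are ingested from a two-column CSV
``model_id,energy_kcal_mol``.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .core import Ensemble, EnergyTable, RegionSpec, StructureModel, TopologyError

__all__ = [
    "read_pdb_models",
    "write_pdb_models",
    "read_energy_table",
    "write_energy_table",
    "extract_atoms",
    "read_region_file",
    "BACKBONE_ATOMS",
    "BACKBONE_ATOMS_NO_O",
]

#: protein backbone heavy atoms, including the carbonyl oxygen
BACKBONE_ATOMS = ("N", "CA", "C", "O")
#: backbone without the carbonyl oxygen
BACKBONE_ATOMS_NO_O = ("N", "CA", "C")

_WATER_NAMES = {"HOH", "WAT", "H2O", "DOD", "TIP", "TIP3", "SOL"}

HetPolicy = Literal["strip", "keep"]
Selection = Literal["backbone", "calpha"]


def _resolve_altloc(atoms: struc.AtomArray) -> struc.AtomArray:
    """Keep one altloc per atom site: highest occupancy, blank wins ties."""
    alt = atoms.get_annotation("altloc_id")
    if np.all((alt == "") | (alt == " ") | (alt == ".")):
        return atoms
    occ = atoms.occupancy
    keep = np.ones(atoms.array_length(), dtype=bool)
    sites: dict[tuple, list[int]] = {}
    for i in range(atoms.array_length()):
        key = (atoms.chain_id[i], int(atoms.res_id[i]), atoms.atom_name[i])
        sites.setdefault(key, []).append(i)
    for idx in sites.values():
        if len(idx) == 1:
            continue
        # best = max occupancy; on a tie prefer the blank altloc, then the
        # alphabetically first altloc id (deterministic)
        def rank(i: int) -> tuple:
            a = alt[i].strip(". ")
            return (-occ[i], 0 if a == "" else 1, a)

        best = min(idx, key=rank)
        for i in idx:
            if i != best:
                keep[i] = False
    return atoms[keep]


def _clean_model(atoms: struc.AtomArray, het_policy: HetPolicy, origin: str) -> struc.AtomArray:
    if het_policy == "strip":
        is_water = np.isin(atoms.res_name, list(_WATER_NAMES))
        atoms = atoms[~(atoms.hetero | is_water)]
    elif het_policy != "keep":
        raise ValueError(f"unknown het_policy {het_policy!r}")
    atoms = _resolve_altloc(atoms)
    ins = atoms.get_annotation("ins_code")
    if np.any(ins != ""):
        bad = sorted({f"{c}{r}{i}" for c, r, i in
                      zip(atoms.chain_id[ins != ""], atoms.res_id[ins != ""],
                          ins[ins != ""])})
        raise ValueError(
            f"{origin}: insertion codes are not supported "
            f"(residues {', '.join(bad[:5])}{'...' if len(bad) > 5 else ''})"
        )
    return atoms


def _to_structure_model(atoms: struc.AtomArray, model_id: str) -> StructureModel:
    return StructureModel(
        model_id,
        atoms.atom_name.tolist(),
        atoms.res_name.tolist(),
        atoms.res_id.tolist(),
        atoms.chain_id.tolist(),
        np.asarray(atoms.coord, dtype=float),
    )


def _model_serials(pdb_file: PDBFile) -> list[str]:
    serials = []
    for line in pdb_file.lines:
        if line.startswith("MODEL"):
            serials.append(line[5:].strip() or str(len(serials) + 1))
    return serials


def _read_single_file(path: Path, het_policy: HetPolicy) -> list[StructureModel]:
    try:
        pdb_file = PDBFile.read(str(path))
    except OSError as exc:
        raise OSError(f"cannot read PDB file {path}: {exc}") from exc
    n_models = pdb_file.get_model_count()
    if n_models == 0:
        raise ValueError(f"{path}: no ATOM records")
    serials = _model_serials(pdb_file)
    models = []
    for i in range(1, n_models + 1):
        atoms = pdb_file.get_structure(
            model=i, altloc="all", extra_fields=["occupancy"]
        )
        if serials:
            model_id = serials[i - 1] if i - 1 < len(serials) else str(i)
        else:
            model_id = path.stem
        atoms = _clean_model(atoms, het_policy, f"{path} model {model_id}")
        if atoms.array_length() == 0:
            raise ValueError(f"{path} model {model_id}: zero protein atoms")
        models.append(_to_structure_model(atoms, model_id))
    return models


def read_pdb_models(
    path: str | Path,
    het_policy: HetPolicy = "strip",
    on_inconsistent: Literal["raise", "drop"] = "raise",
) -> Ensemble:
    """Read a multi-model PDB file (or a directory of single-model files).

    Parameters
    ----------
    path
        A PDB file, in which case each ``MODEL``/``ENDMDL`` block becomes one
        model (identified by its MODEL serial; a single implicit model takes
        the file stem), or a directory, in which case every ``*.pdb`` file is
        read as one model identified by its file stem.
    het_policy
        ``"strip"`` (default) removes all HETATM records and waters, matching
        the usual preprocessing of experimental structures; ``"keep"`` keeps
        them.
    on_inconsistent
        Models whose atom set differs from the first model's are an error by
        default (``"raise"``, the error names the offending model ids);
        ``"drop"`` discards them with a warning instead.

    Returns
    -------
    Ensemble
        Topology-consistent ensemble; ``atom_keys`` come from the first model.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.pdb"))
        if not files:
            raise FileNotFoundError(f"no .pdb files in directory {path}")
        models: list[StructureModel] = []
        for f in files:
            models.extend(_read_single_file(f, het_policy))
    elif path.exists():
        models = _read_single_file(path, het_policy)
    else:
        raise FileNotFoundError(f"no such file or directory: {path}")

    ref_keys = models[0].atom_keys
    bad = [m.model_id for m in models[1:] if m.atom_keys != ref_keys]
    if bad:
        if on_inconsistent == "raise":
            raise TopologyError(
                "inconsistent atom sets across models (relative to the "
                f"first): {', '.join(bad)}"
            )
        warnings.warn(
            f"dropping {len(bad)} topology-inconsistent models: "
            + ", ".join(bad),
            stacklevel=2,
        )
        models = [m for m in models if m.model_id not in set(bad)]
    return Ensemble(models)


_ELEMENT_GUESS = {"CA": "C", "CB": "C", "CD": "C", "CE": "C", "CG": "C",
                  "CZ": "C", "CH": "C"}


def _guess_element(atom_name: str) -> str:
    if atom_name in _ELEMENT_GUESS:
        return _ELEMENT_GUESS[atom_name]
    stripped = atom_name.lstrip("0123456789")
    return stripped[:1].upper() if stripped else "C"


def write_pdb_models(ensemble: Ensemble, path: str | Path) -> None:
    """Write an ensemble as a multi-model PDB file (MODEL/ENDMDL blocks).

    Coordinates are written in the fixed PDB format (three decimals), so a
    write/read round trip preserves coordinates to 1e-3 Å and atom keys
    exactly.  Model ids beyond the MODEL serial are not representable in the
    format and are replaced by serial numbers on write.
    """
    first = ensemble.models[0]
    n = first.n_atoms
    template = struc.AtomArray(n)
    template.chain_id = first.chain_ids.astype("U4")
    template.res_id = first.residue_numbers
    template.res_name = first.residue_names.astype("U5")
    template.atom_name = first.atom_names.astype("U6")
    template.element = np.array(
        [_guess_element(a) for a in first.atom_names], dtype="U2"
    )
    template.hetero = np.zeros(n, dtype=bool)
    stack = struc.from_template(template, ensemble.coords())
    pdb_file = PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


def read_energy_table(path: str | Path) -> EnergyTable:
    """Read a per-model energy CSV with header ``model_id,energy_kcal_mol``."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"model_id": str})
    expected = ["model_id", "energy_kcal_mol"]
    if list(df.columns) != expected:
        raise ValueError(
            f"{path}: expected header {','.join(expected)}, "
            f"got {','.join(map(str, df.columns))}"
        )
    if len(df) == 0:
        raise ValueError(f"{path}: no entries")
    energies = pd.to_numeric(df["energy_kcal_mol"], errors="coerce")
    bad = df.index[~np.isfinite(energies)]
    if len(bad):
        rows = ", ".join(
            f"row {i + 2} (model_id={df['model_id'][i]!r})" for i in bad[:5]
        )
        raise ValueError(f"{path}: non-finite or non-numeric energy at {rows}")
    dup = df["model_id"][df["model_id"].duplicated()].unique()
    if len(dup):
        raise ValueError(f"{path}: duplicate model_id(s): {', '.join(dup)}")
    return EnergyTable(dict(zip(df["model_id"], energies.astype(float))))


def write_energy_table(table: EnergyTable, path: str | Path) -> None:
    pd.DataFrame(
        {"model_id": list(table.entries), "energy_kcal_mol": list(table.entries.values())}
    ).to_csv(path, index=False)


def extract_atoms(
    ensemble: Ensemble,
    selection: Selection = "backbone",
    regions: Sequence[RegionSpec] | None = None,
    include_carbonyl_o: bool = True,
) -> Ensemble:
    """Restrict an ensemble to backbone or Cα atoms, optionally to regions.

    ``backbone`` keeps N, CA, C and (by default) the carbonyl O; models that
    carry only Cα atoms degrade gracefully to the Cα subset.  With *regions*,
    only atoms whose ``(chain, residue_number)`` fall inside one of the
    inclusive ranges are kept.  Atom order is preserved.
    """
    if selection == "backbone":
        names = BACKBONE_ATOMS if include_carbonyl_o else BACKBONE_ATOMS_NO_O
    elif selection == "calpha":
        names = ("CA",)
    else:
        raise ValueError(f"unknown selection {selection!r}")
    first = ensemble.models[0]
    mask = np.isin(first.atom_names.astype(str), names)
    if regions is not None:
        chains = {str(c) for c in first.chain_ids}
        missing = [r.name for r in regions if r.chain_id not in chains]
        if missing:
            raise ValueError(
                f"region chain absent from structure: {', '.join(missing)}"
            )
        region_mask = np.zeros(first.n_atoms, dtype=bool)
        for r in regions:
            region_mask |= r.mask(first)
        mask &= region_mask
    if not mask.any():
        raise ValueError(
            f"empty selection ({selection}"
            + (f", regions {[r.name for r in regions]}" if regions else "")
            + ")"
        )
    return Ensemble([m.subset(mask) for m in ensemble.models])


def read_region_file(path: str | Path) -> list[RegionSpec]:
    """Read regions from a flat text file with lines ``name chain first last``."""
    regions = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(
                f"{path}:{lineno}: expected 'name chain first last', got {raw!r}"
            )
        name, chain, first, last = parts
        regions.append(RegionSpec(name, chain, int(first), int(last)))
    if not regions:
        raise ValueError(f"{path}: no regions")
    return regions
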