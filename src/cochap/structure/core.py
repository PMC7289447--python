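"""Molecular structures with coordinates in nm.

A :class:`Structure` is a flat, array-backed atom table — the minimal
container the geometric detectors need.  PDB files are read and written
through biotite (fixed-width, Angstrom); coordinates are converted to nm
on read and back to Angstrom on write.  Multi-model PDB files are treated
as frame lists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

__all__ = ["Structure", "read_pdb", "read_pdb_frames", "write_pdb"]

_WATER_NAMES = {"HOH", "WAT", "SOL", "TIP3", "TIP"}
A_PER_NM = 10.0


@dataclass
class Structure:
    """Array-backed atom table; one model."""

    chain_ids: np.ndarray
    res_ids: np.ndarray
    res_names: np.ndarray
    atom_names: np.ndarray
    elements: np.ndarray
    coords: np.ndarray  # (n, 3), nm
    model_id: int = 1

    def __post_init__(self):
        n = len(self.coords)
        for name in ("chain_ids", "res_ids", "res_names", "atom_names", "elements"):
            arr = np.asarray(getattr(self, name))
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != {n} atoms")
            setattr(self, name, arr)
        self.coords = np.asarray(self.coords, dtype=float).reshape(n, 3)
        if n and not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        keys = list(zip(self.chain_ids, self.res_ids, self.atom_names))
        if len(set(keys)) != n:
            raise ValueError("(chain, residue number, atom name) must be unique")

    # -- convenience -------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.asarray([e.upper() != "H" for e in self.elements])

    def chains(self) -> list[str]:
        seen: dict = {}
        for c in self.chain_ids:
            seen.setdefault(str(c), None)
        return list(seen)

    def mask(
        self,
        chain: Optional[str] = None,
        residues: Optional[Iterable[int]] = None,
        heavy_only: bool = False,
    ) -> np.ndarray:
        m = np.ones(self.n_atoms, dtype=bool)
        if chain is not None:
            m &= self.chain_ids == chain
        if residues is not None:
            rset = set(int(r) for r in residues)
            m &= np.asarray([int(r) in rset for r in self.res_ids])
        if heavy_only:
            m &= self.heavy_mask
        return m

    def subset(self, mask: np.ndarray) -> "Structure":
        return Structure(
            self.chain_ids[mask],
            self.res_ids[mask],
            self.res_names[mask],
            self.atom_names[mask],
            self.elements[mask],
            self.coords[mask],
            self.model_id,
        )

    def residues(self, chain: Optional[str] = None) -> list[tuple[str, int, str]]:
        """Ordered unique (chain, res_id, res_name) triples."""
        out, seen = [], set()
        for c, r, n in zip(self.chain_ids, self.res_ids, self.res_names):
            if chain is not None and c != chain:
                continue
            key = (str(c), int(r))
            if key not in seen:
                seen.add(key)
                out.append((str(c), int(r), str(n)))
        return out

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        new = self.subset(np.ones(self.n_atoms, dtype=bool))
        new.coords = self.coords @ np.asarray(rotation).T + np.asarray(translation)
        return new


def _from_atom_array(arr, model_id: int, exclude_waters: bool) -> Structure:
    if exclude_waters and len(arr):
        keep = ~np.isin(arr.res_name, list(_WATER_NAMES))
        arr = arr[keep]
    return Structure(
        chain_ids=arr.chain_id.astype(str),
        res_ids=arr.res_id.astype(int),
        res_names=arr.res_name.astype(str),
        atom_names=arr.atom_name.astype(str),
        elements=arr.element.astype(str),
        coords=arr.coord / A_PER_NM,
        model_id=model_id,
    )


def _locate_bad_coordinate_line(path) -> Optional[int]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    try:
                        float(line[lo:hi])
                    except ValueError:
                        return lineno
    return None


def _read_pdb_file(path) -> PDBFile:
    try:
        return PDBFile.read(str(path))
    except Exception as exc:
        bad = _locate_bad_coordinate_line(path)
        where = f" (line {bad})" if bad else ""
        raise ValueError(f"PDB parse error in {path}{where}: {exc}") from exc


def _empty_structure() -> Structure:
    return Structure(
        chain_ids=np.empty(0, dtype="U4"),
        res_ids=np.empty(0, dtype=int),
        res_names=np.empty(0, dtype="U5"),
        atom_names=np.empty(0, dtype="U6"),
        elements=np.empty(0, dtype="U2"),
        coords=np.empty((0, 3)),
    )


def read_pdb(path, exclude_waters: bool = True) -> Structure:
    """Read the first model of a PDB file (alternate locations resolved to
    highest occupancy; waters excluded by default)."""
    pdb = _read_pdb_file(path)
    if pdb.get_model_count() == 0:
        warnings.warn(f"{path}: no atoms read")
        return _empty_structure()
    try:
        arr = pdb.get_structure(model=1, altloc="occupancy")
    except Exception as exc:
        bad = _locate_bad_coordinate_line(path)
        where = f" (line {bad})" if bad else ""
        raise ValueError(f"PDB parse error in {path}{where}: {exc}") from exc
    structure = _from_atom_array(arr, 1, exclude_waters)
    if structure.n_atoms == 0:
        warnings.warn(f"{path}: no atoms read")
    return structure


def read_pdb_frames(path, exclude_waters: bool = True) -> list[Structure]:
    """All models of a (multi-model) PDB file as a frame list."""
    pdb = _read_pdb_file(path)
    n_models = pdb.get_model_count()
    return [
        _from_atom_array(
            pdb.get_structure(model=m, altloc="occupancy"), m, exclude_waters
        )
        for m in range(1, n_models + 1)
    ]


def _to_atom_array(s: Structure):
    arr = bst.AtomArray(s.n_atoms)
    arr.chain_id = s.chain_ids.astype("U4")
    arr.res_id = s.res_ids.astype(int)
    arr.res_name = s.res_names.astype("U5")
    arr.atom_name = s.atom_names.astype("U6")
    arr.element = np.char.upper(s.elements.astype("U2"))
    arr.hetero = np.zeros(s.n_atoms, dtype=bool)
    arr.coord = (s.coords * A_PER_NM).astype(np.float32)
    return arr


def write_pdb(structures, path) -> None:
    """Write one Structure or a frame list as a (multi-model) PDB file."""
    if isinstance(structures, Structure):
        structures = [structures]
    pdb = PDBFile()
    if len(structures) == 1:
        pdb.set_structure(_to_atom_array(structures[0]))
    else:
        stack = bst.stack([_to_atom_array(s) for s in structures])
        pdb.set_structure(stack)
    pdb.write(str(path))
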