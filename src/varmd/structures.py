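"""Shared molecular containers: static structures and multi-frame trajectories.

A :class:`StructureModel` is a flat atom table plus one coordinate set; a
:class:`Trajectory` shares the atom table across an ordered stack of frames
(the multi-model PDB convention).  Residues are addressed by the authored
``(chain_id, residue_number, insertion_code)`` key — no renumbering is ever
applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.PDB import PDBParser

__all__ = [
    "Atom",
    "ResidueKey",
    "StructureModel",
    "Trajectory",
    "PDBFormatError",
    "read_models",
    "write_pdb",
]

#: (chain_id, residue_number, insertion_code)
ResidueKey = tuple[str, int, str]


class PDBFormatError(ValueError):
    """Raised for structurally inconsistent coordinate files."""


@dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    res_name: str
    chain_id: str
    res_seq: int
    i_code: str = ""
    element: str = ""
    hetero: bool = False

    @property
    def residue_key(self) -> ResidueKey:
        return (self.chain_id, self.res_seq, self.i_code)

    @property
    def identity(self) -> tuple:
        """Atom identity used for cross-model consistency checks."""
        return (self.chain_id, self.res_seq, self.i_code, self.res_name, self.name)


def _residue_index(atoms: list[Atom]) -> dict[ResidueKey, list[int]]:
    idx: dict[ResidueKey, list[int]] = {}
    for i, a in enumerate(atoms):
        idx.setdefault(a.residue_key, []).append(i)
    return idx


@dataclass
class StructureModel:
    """One conformation of a molecular system as a flat atom table."""

    atoms: list[Atom]
    coords: np.ndarray  # (n_atoms, 3), Å

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.atoms), 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        seen: set[tuple] = set()
        for a in self.atoms:
            key = a.identity[:3] + (a.name,)
            if key in seen:
                raise ValueError(f"duplicate atom {key} in model")
            seen.add(key)

    # -- residue-level access -------------------------------------------------

    @property
    def residue_table(self) -> dict[ResidueKey, list[int]]:
        return _residue_index(self.atoms)

    def residue_keys(self) -> list[ResidueKey]:
        return list(self.residue_table)

    def residue_name(self, key: ResidueKey) -> str:
        return self.atoms[self.residue_table[key][0]].res_name

    def atom_indices(self, key: ResidueKey, names: set[str] | None = None) -> list[int]:
        idx = self.residue_table.get(key, [])
        if names is None:
            return idx
        return [i for i in idx if self.atoms[i].name in names]

    def find_atom(self, key: ResidueKey, name: str) -> int:
        for i in self.residue_table.get(key, []):
            if self.atoms[i].name == name:
                return i
        raise KeyError(f"atom {name} not found in residue {key}")

    def subset(self, indices: list[int]) -> "StructureModel":
        return StructureModel([self.atoms[i] for i in indices], self.coords[indices])


@dataclass
class Trajectory:
    """Ordered coordinate frames over a shared atom table."""

    atoms: list[Atom]
    frames: np.ndarray  # (n_frames, n_atoms, 3), Å
    timestep_ps: float = 8.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1] != len(self.atoms):
            raise ValueError(
                f"frames shape {self.frames.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        if self.n_frames < 1:
            raise ValueError("trajectory needs at least one frame")
        if self.timestep_ps <= 0:
            raise ValueError("timestep_ps must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def residue_table(self) -> dict[ResidueKey, list[int]]:
        return _residue_index(self.atoms)

    def model(self, frame: int) -> StructureModel:
        return StructureModel(self.atoms, self.frames[frame])

    def tail(self, n: int) -> "Trajectory":
        """Last ``n`` frames (the equilibrated analysis window)."""
        if n < 1:
            raise ValueError("tail length must be >= 1")
        return replace(self, frames=self.frames[-n:])

    def subset(self, indices: list[int]) -> "Trajectory":
        return replace(
            self,
            atoms=[self.atoms[i] for i in indices],
            frames=self.frames[:, indices, :],
        )


def frame_count(duration_ns: float, snapshot_ps: float) -> int:
    """Number of snapshots produced by a run of ``duration_ns`` sampled every
    ``snapshot_ps`` (e.g. 40 ns at 8 ps -> 5000)."""
    if duration_ns <= 0 or snapshot_ps <= 0:
        raise ValueError("duration and snapshot interval must be positive")
    n = duration_ns * 1000.0 / snapshot_ps
    if abs(n - round(n)) > 1e-9:
        raise ValueError("snapshot interval does not divide the run duration")
    return int(round(n))


# -- PDB reading / writing ----------------------------------------------------


def _atoms_coords_from_biopdb_model(model, first_serials=None):
    atoms: list[Atom] = []
    xyz: list[np.ndarray] = []
    for chain in model:
        for residue in chain:
            het, resseq, icode = residue.id
            hetero = het.strip() != ""
            for at in residue:
                if at.is_disordered():
                    at = at.disordered_get()  # keep highest-occupancy altloc
                atoms.append(
                    Atom(
                        serial=at.serial_number or len(atoms) + 1,
                        name=at.get_name(),
                        res_name=residue.get_resname().strip(),
                        chain_id=chain.id,
                        res_seq=resseq,
                        i_code=icode.strip(),
                        element=(at.element or "").strip(),
                        hetero=hetero,
                    )
                )
                xyz.append(at.get_coord())
    return atoms, np.asarray(xyz, dtype=float)


def read_models(path) -> StructureModel | Trajectory:
    """Read a (possibly multi-model) PDB file.

    A single MODEL yields a :class:`StructureModel`; several MODELs yield a
    :class:`Trajectory` in MODEL order.  All models must share the same atom
    table; the first divergent atom is reported otherwise.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("m", str(path))
    models = list(structure)
    if not models:
        raise PDBFormatError(f"{path}: no models found")
    atoms0, coords0 = _atoms_coords_from_biopdb_model(models[0])
    if not atoms0:
        raise PDBFormatError(f"{path}: no atoms found")
    if len(models) == 1:
        return StructureModel(atoms0, coords0)
    ref_ids = [a.identity for a in atoms0]
    frames = [coords0]
    for m_i, model in enumerate(models[1:], start=2):
        atoms_i, coords_i = _atoms_coords_from_biopdb_model(model)
        ids_i = [a.identity for a in atoms_i]
        if ids_i != ref_ids:
            for k in range(min(len(ids_i), len(ref_ids))):
                if ids_i[k] != ref_ids[k]:
                    raise PDBFormatError(
                        f"{path}: model {m_i} diverges at atom {ref_ids[k]} "
                        f"(found {ids_i[k]})"
                    )
            raise PDBFormatError(
                f"{path}: model {m_i} has {len(ids_i)} atoms, expected {len(ref_ids)}"
            )
        frames.append(coords_i)
    return Trajectory(atoms0, np.stack(frames))


def _pdb_atom_line(a: Atom, serial: int, x: float, y: float, z: float) -> str:
    record = "HETATM" if a.hetero else "ATOM  "
    name = a.name
    # PDB column rule: 1-letter elements start in column 14 unless 4 chars long
    if len(name) < 4 and len(a.element) < 2:
        name = " " + name
    return (
        f"{record}{serial:>5} {name:<4} {a.res_name:>3} {a.chain_id:1}"
        f"{a.res_seq:>4}{a.i_code or ' ':1}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
        f"{a.element:>2}"
    )


def write_pdb(obj: StructureModel | Trajectory, path) -> None:
    """Serialize to PDB; trajectories are written as MODEL/ENDMDL blocks."""
    if isinstance(obj, StructureModel):
        frames = obj.coords[None]
    else:
        frames = obj.frames
    multi = frames.shape[0] > 1
    with open(path, "w") as fh:
        for m, frame in enumerate(frames, start=1):
            if multi:
                fh.write(f"MODEL     {m:>4}\n")
            for serial, (a, (x, y, z)) in enumerate(zip(obj.atoms, frame), start=1):
                fh.write(_pdb_atom_line(a, serial, x, y, z) + "\n")
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")
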