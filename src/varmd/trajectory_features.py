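"""Active-site feature extraction from structures and trajectories.

Given a reference complex with a bound damaged nucleoside, the active site is
defined by a distance cutoff (default 5 Å) around the ligand.  From the
residues so selected we enumerate torsion angles (φ/ψ/χ for amino acids,
α…ζ/χ for nucleotides) and compute per-frame torsion and catalytic-geometry
time series.  A solvent-stripping rule keeps only waters that actually visit
the ligand for a minimum fraction of the trajectory.

All angles are reported in degrees; torsions lie in (−180°, 180°] following
the usual signed two-plane convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .residues import (CHI_ATOMS, ION_NAMES_DEFAULT, WATER_NAMES_DEFAULT,
                       glycosidic_atoms, is_amino_acid, is_nucleotide)
from .structures import (PDBFormatError, ResidueKey, StructureModel,
                         Trajectory, frame_count, read_models)

__all__ = [
    "TorsionDefinition",
    "GeometrySpec",
    "read_models",
    "frame_count",
    "select_active_site",
    "enumerate_torsions",
    "compute_dihedral_series",
    "compute_geometry_series",
    "strip_solvent",
    "dihedral_angles",
    "ANALYSIS_TAIL_DEFAULT",
]

log = logging.getLogger(__name__)

#: analysis window: number of trailing (equilibrated) frames kept downstream
ANALYSIS_TAIL_DEFAULT = 2500

_NUC_BACKBONE = {
    "alpha": (("-1", "O3'"), ("0", "P"), ("0", "O5'"), ("0", "C5'")),
    "beta": (("0", "P"), ("0", "O5'"), ("0", "C5'"), ("0", "C4'")),
    "gamma": (("0", "O5'"), ("0", "C5'"), ("0", "C4'"), ("0", "C3'")),
    "delta": (("0", "C5'"), ("0", "C4'"), ("0", "C3'"), ("0", "O3'")),
    "epsilon": (("0", "C4'"), ("0", "C3'"), ("0", "O3'"), ("+1", "P")),
    "zeta": (("0", "C3'"), ("0", "O3'"), ("+1", "P"), ("+1", "O5'")),
}


@dataclass(frozen=True)
class TorsionDefinition:
    """A named torsion: four ordered atom indices into the shared atom table."""

    residue_key: ResidueKey
    name: str  # phi/psi/chi1../alpha..zeta/chi
    atom_indices: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if len(set(self.atom_indices)) != 4:
            raise ValueError(f"{self.label}: four distinct atoms required")

    @property
    def label(self) -> str:
        c, n, ic = self.residue_key
        return f"{c}:{n}{ic}:{self.name}"


@dataclass(frozen=True)
class GeometrySpec:
    """A named scalar geometric observable.

    kind ``distance``: atoms = (a, b) -> |a-b| in Å.
    kind ``min_distance``: atoms = ((d1, d2, ...), b) -> min_i |d_i - b|.
    kind ``angle``: atoms = (a, b, c) -> a-b-c angle in degrees.

    Atom references are ``(residue_key, atom_name)`` pairs.
    """

    name: str
    kind: str
    atoms: tuple

    def __post_init__(self) -> None:
        if self.kind not in ("distance", "min_distance", "angle"):
            raise ValueError(f"unknown geometry kind {self.kind!r}")


def _is_residue_key(x) -> bool:
    return (isinstance(x, tuple) and len(x) in (2, 3)
            and isinstance(x[0], str) and isinstance(x[1], (int, np.integer)))


def _ligand_residues(model, ligand) -> list[ResidueKey]:
    """Resolve a ligand selector: residue name, residue key (chain, number[,
    icode]), or an iterable of either."""
    keys = model.residue_table
    if isinstance(ligand, str) or _is_residue_key(ligand):
        sels = [ligand]
    else:
        sels = list(ligand)
    out: list[ResidueKey] = []
    for sel in sels:
        if isinstance(sel, str):
            out.extend(k for k in keys if model.residue_name(k) == sel)
        elif _is_residue_key(sel):
            sel = (sel[0], sel[1], "") if len(sel) == 2 else tuple(sel)
            if sel in keys:
                out.append(sel)
        else:
            raise TypeError(f"unrecognized ligand selector {sel!r}")
    return out


def select_active_site(
    model: StructureModel,
    ligand,
    cutoff: float = 5.0,
    *,
    heavy_only: bool = True,
    include_ligand: bool = False,
    exclude_phosphate: bool = True,
    include_solvent: bool = False,
) -> set[ResidueKey]:
    """Protein/nucleic residues with at least one atom within ``cutoff`` Å of
    the ligand.

    The ligand is taken as the nucleoside heavy atoms by default: hydrogens
    are ignored and the phosphate moiety (P, OP1/OP2/O1P/O2P and the 5'
    bridging O) is excluded, matching an active site defined around the
    damaged 2'-deoxynucleoside itself.  Waters and counter-ions are excluded
    unless ``include_solvent`` is set.  All toggles are exposed.
    """
    lig_keys = _ligand_residues(model, ligand)
    if not lig_keys:
        raise ValueError(f"ligand selector {ligand!r} matched no residue")
    lig_set = set(lig_keys)
    phosphate = {"P", "OP1", "OP2", "OP3", "O1P", "O2P", "O3P", "O5'"}

    def _is_h(i: int) -> bool:
        a = model.atoms[i]
        el = a.element or a.name[:1]
        return el.upper().startswith("H")

    lig_idx = [
        i
        for k in lig_keys
        for i in model.atom_indices(k)
        if not (heavy_only and _is_h(i))
        and not (exclude_phosphate and model.atoms[i].name in phosphate)
    ]
    if not lig_idx:
        raise ValueError("ligand selection left no atoms")
    solvent = WATER_NAMES_DEFAULT | ION_NAMES_DEFAULT
    other_idx = [
        i
        for i, a in enumerate(model.atoms)
        if a.residue_key not in lig_set
        and not (heavy_only and _is_h(i))
        and (include_solvent or a.res_name not in solvent)
    ]
    selected: set[ResidueKey] = set()
    if cutoff > 0 and other_idx:
        tree = cKDTree(model.coords[lig_idx])
        dmin, _ = tree.query(model.coords[other_idx], k=1)
        for i, d in zip(other_idx, dmin):
            if d <= cutoff:
                selected.add(model.atoms[i].residue_key)
    if include_ligand:
        selected |= lig_set
    return selected


def _chain_residue_order(model) -> dict[str, list[ResidueKey]]:
    chains: dict[str, list[ResidueKey]] = {}
    for key in model.residue_keys():
        chains.setdefault(key[0], []).append(key)
    return chains


def enumerate_torsions(
    model: StructureModel,
    residues: set[ResidueKey],
    *,
    include_nucleic: bool = True,
) -> list[TorsionDefinition]:
    """Standard torsions for the selected residues.

    Amino acids contribute φ, ψ and side-chain χ1…χn (ω is deliberately
    excluded — it is near-constant and only inflates the dimensionality);
    nucleotides contribute the backbone α…ζ and the glycosidic χ.  Torsions
    reaching into a neighbouring residue use that neighbour's atoms even if
    it is not itself selected; torsions with missing atoms (chain termini,
    truncated models) are dropped with a log entry.
    """
    chains = _chain_residue_order(model)
    defs: list[TorsionDefinition] = []

    def _try_add(key: ResidueKey, name: str, refs: list[tuple[ResidueKey, str]]):
        try:
            idx = tuple(model.find_atom(rk, an) for rk, an in refs)
        except KeyError:
            log.debug("torsion %s of %s dropped: missing atom", name, key)
            return
        defs.append(TorsionDefinition(key, name, idx))

    for key in sorted(residues, key=lambda k: (k[0], k[1], k[2])):
        if key not in model.residue_table:
            continue
        res_name = model.residue_name(key)
        order = chains[key[0]]
        pos = order.index(key)
        prev_key = order[pos - 1] if pos > 0 else None
        next_key = order[pos + 1] if pos + 1 < len(order) else None
        if is_amino_acid(res_name):
            if prev_key is not None and is_amino_acid(model.residue_name(prev_key)):
                _try_add(key, "phi", [(prev_key, "C"), (key, "N"), (key, "CA"), (key, "C")])
            if next_key is not None and is_amino_acid(model.residue_name(next_key)):
                _try_add(key, "psi", [(key, "N"), (key, "CA"), (key, "C"), (next_key, "N")])
            for i, quad in enumerate(CHI_ATOMS.get(res_name, []), start=1):
                _try_add(key, f"chi{i}", [(key, a) for a in quad])
        elif include_nucleic and is_nucleotide(res_name):
            for name, refs in _NUC_BACKBONE.items():
                resolved = []
                ok = True
                for rel, atom in refs:
                    rk = {"-1": prev_key, "0": key, "+1": next_key}[rel]
                    if rk is None:
                        ok = False
                        break
                    resolved.append((rk, atom))
                if ok:
                    _try_add(key, name, resolved)
                else:
                    log.debug("torsion %s of %s dropped: chain terminus", name, key)
            glyc = glycosidic_atoms(res_name)
            _try_add(key, "chi", [(key, a) for a in glyc])
        else:
            log.warning("residue %s (%s): no torsion template, skipped", key, res_name)
    return defs


def dihedral_angles(p1, p2, p3, p4) -> np.ndarray:
    """Signed dihedral (degrees, in (−180, 180]) between the plane of atoms
    1-2-3 and 2-3-4, sign by the right-hand rule about the 2–3 bond.

    Inputs broadcast over a leading frame axis.  Frames with collinear
    central atoms yield NaN.
    """
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b3 = np.asarray(p4) - np.asarray(p3)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.cross(b2 / b2n, n1)
        x = (n1 * n2).sum(axis=-1)
        y = (m * n2).sum(axis=-1)
        theta = np.degrees(np.arctan2(y, x))
    bad = (np.linalg.norm(n1, axis=-1) < 1e-10) | (np.linalg.norm(n2, axis=-1) < 1e-10)
    theta = np.where(bad, np.nan, theta)
    # fold the closed end of the interval onto +180
    theta = np.where(theta <= -180.0, theta + 360.0, theta)
    return theta


def compute_dihedral_series(
    traj: Trajectory | StructureModel, defs: list[TorsionDefinition]
) -> pd.DataFrame:
    """Per-frame torsion angles: DataFrame of shape (n_frames, n_torsions)
    with torsion labels as columns, degrees in (−180, 180]."""
    frames = traj.coords[None] if isinstance(traj, StructureModel) else traj.frames
    data = {}
    for d in defs:
        i, j, k, l = d.atom_indices
        vals = dihedral_angles(frames[:, i], frames[:, j], frames[:, k], frames[:, l])
        n_bad = int(np.isnan(vals).sum())
        if n_bad:
            log.warning("torsion %s: %d frame(s) with collinear atoms -> NA",
                        d.label, n_bad)
        data[d.label] = vals
    return pd.DataFrame(data)


def _resolve(model_atoms_lookup, ref):
    key, name = ref
    key = tuple(key)
    if len(key) == 2:
        key = (key[0], key[1], "")
    return model_atoms_lookup(key, name)


def compute_geometry_series(
    traj: Trajectory | StructureModel, specs: list[GeometrySpec]
) -> pd.DataFrame:
    """Per-frame geometric observables (Å / degrees), one column per spec."""
    if isinstance(traj, StructureModel):
        frames = traj.coords[None]
        finder = traj.find_atom
    else:
        frames = traj.frames
        finder = StructureModel(traj.atoms, traj.frames[0]).find_atom
    data = {}
    for spec in specs:
        try:
            if spec.kind == "distance":
                a, b = (_resolve(finder, r) for r in spec.atoms)
                data[spec.name] = np.linalg.norm(frames[:, a] - frames[:, b], axis=-1)
            elif spec.kind == "min_distance":
                donors, target = spec.atoms
                t = _resolve(finder, target)
                ds = [
                    np.linalg.norm(frames[:, _resolve(finder, d)] - frames[:, t], axis=-1)
                    for d in donors
                ]
                data[spec.name] = np.min(np.stack(ds), axis=0)
            else:  # angle
                a, b, c = (_resolve(finder, r) for r in spec.atoms)
                v1 = frames[:, a] - frames[:, b]
                v2 = frames[:, c] - frames[:, b]
                cosang = (v1 * v2).sum(axis=-1) / (
                    np.linalg.norm(v1, axis=-1) * np.linalg.norm(v2, axis=-1)
                )
                data[spec.name] = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        except KeyError as exc:
            raise KeyError(f"geometry spec {spec.name!r}: {exc}") from exc
    return pd.DataFrame(data)


def strip_solvent(
    traj: Trajectory,
    ligand,
    cutoff: float = 5.0,
    min_fraction: float = 0.10,
    *,
    water_names: frozenset = WATER_NAMES_DEFAULT,
    ion_names: frozenset = ION_NAMES_DEFAULT,
) -> Trajectory:
    """Remove bulk solvent and counter-ions.

    A water is kept iff it has at least one atom within ``cutoff`` Å of the
    ligand in at least ``min_fraction`` of the frames; everything that is not
    water or ion is kept unconditionally.  Frame count is unchanged and the
    operation is idempotent.
    """
    model0 = StructureModel(traj.atoms, traj.frames[0])
    lig_keys = _ligand_residues(model0, ligand)
    if not lig_keys:
        raise ValueError(f"ligand selector {ligand!r} matched no residue")
    lig_idx = [i for k in lig_keys for i in model0.atom_indices(k)]
    table = traj.residue_table
    keep_idx: list[int] = []
    for key, idx in table.items():
        name = traj.atoms[idx[0]].res_name
        if name in ion_names:
            continue
        if name not in water_names:
            keep_idx.extend(idx)
            continue
        if min_fraction <= 0:
            keep_idx.extend(idx)
            continue
        # fraction of frames with any water atom within cutoff of any ligand atom
        w = traj.frames[:, idx, :]  # (F, nw, 3)
        l = traj.frames[:, lig_idx, :]  # (F, nl, 3)
        d2 = ((w[:, :, None, :] - l[:, None, :, :]) ** 2).sum(axis=-1)
        near = (d2.min(axis=(1, 2)) <= cutoff**2)
        if near.mean() >= min_fraction:
            keep_idx.extend(idx)
    keep_idx.sort()
    return traj.subset(keep_idx)
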