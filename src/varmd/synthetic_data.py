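"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

Real inputs are solvated MD trajectories; those are far outside desk scale,
so this module generates the two kinds of per-variant time series the
analysis actually consumes, with planted ground truth:

* torsion-angle series — hidden metastable states evolving under a Markov
  switch matrix, each state emitting von Mises-distributed angles per
  torsion (circular data with clustered conformational populations);
* catalytic-geometry series — Gaussian-mixture draws of (d1, d2, a1) around
  conformational cluster centres, where wild-type-like variants populate a
  dense "optimal" cluster heavily and impaired variants barely visit it;
* a toy structural complex — a small peptide, three nucleotides, a damaged
  nucleoside ligand and choreographed waters/ions, with analytically known
  active-site membership, torsion values and geometry, as a fixture for the
  structure-handling code.

Everything is a pure function of (spec, n_frames, seed); truth is recorded
alongside the data so tests never re-derive it from generator internals.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structures import Atom, StructureModel, Trajectory

__all__ = [
    "GeometryCluster",
    "VariantSpec",
    "gen_torsion_set",
    "gen_geometry_set",
    "gen_toy_complex",
    "ogg1_like_preset",
    "GEOMETRY_COLUMNS",
]

#: catalytic dyad observables: two distances (Å) and one angle (degrees)
GEOMETRY_COLUMNS = ("d1", "d2", "a1")


def _substream(seed: int, tag: str) -> np.random.Generator:
    """Independent, reproducible substream for one variant."""
    return np.random.default_rng([int(seed), zlib.crc32(tag.encode()) & 0x7FFFFFFF])


@dataclass(frozen=True)
class GeometryCluster:
    center: tuple[float, float, float]  # (d1 Å, d2 Å, a1 deg)
    cov: tuple  # 3×3 covariance

    def __post_init__(self) -> None:
        cov = np.asarray(self.cov, dtype=float)
        if cov.shape != (3, 3):
            raise ValueError("covariance must be 3×3")
        if np.linalg.eigvalsh(cov).min() <= 0:
            raise ValueError("covariance must be positive definite")


@dataclass(frozen=True)
class VariantSpec:
    """Generative description of one variant's conformational behaviour."""

    variant_id: str
    planted: str  # "wt-like" | "impaired"
    # circular part: k metastable states; per torsion, per-state von Mises
    torsion_means: dict = field(default_factory=dict)  # label -> (k,) degrees
    torsion_kappas: dict = field(default_factory=dict)  # label -> (k,) > 0
    switch: tuple = ()  # (k, k) row-stochastic state-switch matrix
    # geometric part: Gaussian mixture over conformational clusters
    geometry_clusters: tuple = ()  # GeometryCluster, ...
    geometry_weights: tuple = ()  # mixture weights, sum 1

    def __post_init__(self) -> None:
        if self.planted not in ("wt-like", "impaired"):
            raise ValueError(f"unknown planted label {self.planted!r}")
        if self.torsion_means:
            k = len(next(iter(self.torsion_means.values())))
            P = np.asarray(self.switch, dtype=float)
            if P.shape != (k, k) or not np.allclose(P.sum(axis=1), 1.0):
                raise ValueError("switch matrix rows must sum to 1")
            for lab, means in self.torsion_means.items():
                kap = np.asarray(self.torsion_kappas[lab], dtype=float)
                if len(means) != k or len(kap) != k:
                    raise ValueError(f"state count mismatch for torsion {lab!r}")
                if (kap <= 0).any():
                    raise ValueError("von Mises concentrations must be > 0")
        if self.geometry_clusters:
            w = np.asarray(self.geometry_weights, dtype=float)
            if len(w) != len(self.geometry_clusters) or not np.isclose(w.sum(), 1.0):
                raise ValueError("mixture weights must match clusters and sum to 1")

    @property
    def n_states(self) -> int:
        return len(next(iter(self.torsion_means.values())))


def _sample_states(P: np.ndarray, n: int, rng) -> np.ndarray:
    k = P.shape[0]
    # start from the stationary distribution of the switch chain
    w, v = np.linalg.eig(P.T)
    pi = np.real(v[:, np.argmin(np.abs(w - 1.0))])
    pi = np.abs(pi) / np.abs(pi).sum()
    states = np.empty(n, dtype=int)
    states[0] = rng.choice(k, p=pi)
    u = rng.random(n)
    cum = P.cumsum(axis=1)
    for t in range(1, n):
        states[t] = np.searchsorted(cum[states[t - 1]], u[t])
    return states


def gen_torsion_set(
    specs: list[VariantSpec], n_frames: int = 2500, seed: int = 0
) -> dict[str, pd.DataFrame]:
    """Per-variant torsion tables (frames × labels, degrees in (−180, 180])."""
    labels = list(specs[0].torsion_means)
    for s in specs:
        if list(s.torsion_means) != labels:
            raise ValueError(f"variant {s.variant_id!r}: torsion labels differ")
    out: dict[str, pd.DataFrame] = {}
    for s in specs:
        rng = _substream(seed, "torsion:" + s.variant_id)
        states = _sample_states(np.asarray(s.switch, dtype=float), n_frames, rng)
        data = {}
        for lab in labels:
            mu = np.radians(np.asarray(s.torsion_means[lab], dtype=float))[states]
            kap = np.asarray(s.torsion_kappas[lab], dtype=float)[states]
            ang = np.degrees(rng.vonmises(mu, kap))
            ang = np.where(ang <= -180.0, ang + 360.0, ang)
            data[lab] = ang
        out[s.variant_id] = pd.DataFrame(data)
    return out


def gen_geometry_set(
    specs: list[VariantSpec], n_frames: int = 2500, seed: int = 0
) -> dict[str, pd.DataFrame]:
    """Per-variant geometry tables with columns (d1, d2, a1).

    Distances are kept strictly positive and the angle inside [0, 180]."""
    out: dict[str, pd.DataFrame] = {}
    for s in specs:
        if not s.geometry_clusters:
            raise ValueError(f"variant {s.variant_id!r} has no geometry clusters")
        rng = _substream(seed, "geometry:" + s.variant_id)
        comp = rng.choice(len(s.geometry_clusters), size=n_frames,
                          p=np.asarray(s.geometry_weights, dtype=float))
        X = np.empty((n_frames, 3))
        for ci, cl in enumerate(s.geometry_clusters):
            m = comp == ci
            if m.any():
                X[m] = rng.multivariate_normal(cl.center, np.asarray(cl.cov), size=int(m.sum()))
        X[:, 0] = np.maximum(X[:, 0], 1e-2)
        X[:, 1] = np.maximum(X[:, 1], 1e-2)
        X[:, 2] = np.clip(X[:, 2], 0.0, 180.0)
        out[s.variant_id] = pd.DataFrame(X, columns=list(GEOMETRY_COLUMNS))
    return out


# -- OGG1-like preset ---------------------------------------------------------

_OPTIMAL = GeometryCluster((3.2, 2.8, 160.0), np.diag([0.09, 0.09, 64.0]))
_DISPLACED = GeometryCluster((6.5, 5.5, 100.0), np.diag([0.25, 0.25, 144.0]))

_TORSION_LABELS = ("A:249:chi1", "A:249:chi4", "A:268:chi2",
                   "C:7:chi", "C:8:zeta", "A:267:psi")


def ogg1_like_preset(
    n_variants: int = 21, n_impaired: int = 3, seed: int = 0
) -> tuple[list[VariantSpec], dict]:
    """Study-sized synthetic cohort: one wild type plus mutants, a few of
    them planted as impaired.

    Wild-type-like variants put ~90 % of their frames in the dense "optimal"
    catalytic-geometry cluster; a second wt-like group samples a broader
    secondary conformation as well (mirroring the second cluster of
    unaffected variants real cohorts show); impaired variants barely visit
    the optimal cluster (weight 0.05) and their shifted torsional states
    move two active-site torsions by ~90°.  Cluster centres sit more than
    3σ apart in every coordinate.
    """
    if n_variants < n_impaired + 2:
        raise ValueError("need at least one WT and one unaffected mutant")
    rng = np.random.default_rng(seed)
    mutant_ids = [f"M{i:02d}" for i in range(1, n_variants)]
    impaired = sorted(rng.choice(mutant_ids, size=n_impaired, replace=False).tolist())
    # split the remaining mutants into the tight WT-like group and the
    # broader secondary group
    rest = [m for m in mutant_ids if m not in impaired]
    n_b = max(1, len(rest) * 2 // 5)
    group_b = sorted(rng.choice(rest, size=n_b, replace=False).tolist())

    base_means = {lab: np.array([-60.0 + 25.0 * i, 60.0 + 25.0 * i])
                  for i, lab in enumerate(_TORSION_LABELS)}
    switch = ((0.97, 0.03), (0.10, 0.90))

    def _spec(vid: str) -> VariantSpec:
        r = _substream(seed, "preset:" + vid)
        means = {lab: m.copy() for lab, m in base_means.items()}
        kappas = {lab: np.array([25.0, 25.0]) for lab in _TORSION_LABELS}
        if vid in impaired:
            planted = "impaired"
            for lab in _TORSION_LABELS[:2]:
                means[lab] = means[lab] + 90.0
            w_opt = float(np.clip(0.05 + r.normal(0, 0.01), 0.01, 0.10))
        elif vid in group_b:
            planted = "wt-like"
            w_opt = float(np.clip(0.35 + r.normal(0, 0.03), 0.25, 0.45))
        else:
            planted = "wt-like"
            w_opt = float(np.clip(0.90 + r.normal(0, 0.02), 0.85, 0.95))
        for lab in _TORSION_LABELS:
            means[lab] = means[lab] + r.normal(0, 3.0, size=2)
        return VariantSpec(
            variant_id=vid,
            planted=planted,
            torsion_means=means,
            torsion_kappas=kappas,
            switch=switch,
            geometry_clusters=(_OPTIMAL, _DISPLACED),
            geometry_weights=(w_opt, 1.0 - w_opt),
        )

    specs = [
        VariantSpec(
            variant_id="WT",
            planted="wt-like",
            torsion_means={lab: m.copy() for lab, m in base_means.items()},
            torsion_kappas={lab: np.array([25.0, 25.0]) for lab in _TORSION_LABELS},
            switch=switch,
            geometry_clusters=(_OPTIMAL, _DISPLACED),
            geometry_weights=(0.9, 0.1),
        )
    ] + [_spec(v) for v in mutant_ids]
    truth = {
        "wt": "WT",
        "impaired": impaired,
        "secondary_group": group_b,
        "shifted_torsions": list(_TORSION_LABELS[:2]),
    }
    return specs, truth


# -- toy structural complex ---------------------------------------------------


def _nerf(a, b, c, r, theta_deg, phi_deg) -> np.ndarray:
    """Place atom D given three predecessors: |CD| = r, angle B-C-D = theta,
    dihedral A-B-C-D = phi (natural extension reference frame)."""
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    theta, phi = np.radians(theta_deg), np.radians(phi_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [-r * np.cos(theta), r * np.sin(theta) * np.cos(phi), r * np.sin(theta) * np.sin(phi)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _aa_template(res_name: str, chi: list[float]) -> dict[str, np.ndarray]:
    """Local-coordinate amino acid with scripted side-chain dihedrals."""
    atoms = {
        "N": np.array([0.0, 0.0, 0.0]),
        "CA": np.array([1.458, 0.0, 0.0]),
    }
    atoms["CB"] = _nerf([0.0, 1.0, 0.0], atoms["N"], atoms["CA"], 1.53, 110.5, 122.0)
    atoms["C"] = _nerf(atoms["CB"], atoms["N"], atoms["CA"], 1.525, 111.2, -122.0)
    atoms["O"] = _nerf(atoms["N"], atoms["CA"], atoms["C"], 1.23, 120.5, 0.0)
    chains = {
        "SER": ["OG"],
        "LEU": ["CG", "CD1"],
        "LYS": ["CG", "CD", "CE", "NZ"],
        "ASP": ["CG", "OD1"],
        "CYS": ["SG"],
        "ALA": [],
        "GLY": [],
    }[res_name]
    prev = ["N", "CA", "CB"]
    for i, name in enumerate(chains):
        phi = chi[i] if i < len(chi) else 180.0
        atoms[name] = _nerf(atoms[prev[-3]], atoms[prev[-2]], atoms[prev[-1]],
                            1.52, 112.0, phi)
        prev.append(name)
    if res_name == "ASP":
        atoms["OD2"] = _nerf(atoms["CA"], atoms["CB"], atoms["CG"], 1.25, 118.0,
                             (chi[1] if len(chi) > 1 else 180.0) + 180.0)
    if res_name == "GLY":
        del atoms["CB"]
    return atoms


def gen_toy_complex(seed: int = 0, n_frames: int = 24) -> tuple[Trajectory, dict]:
    """A small protein–DNA–ligand complex with choreographed solvent.

    Returns a trajectory (≥ 20 frames of rigid global motion, so all
    internal coordinates are frame-invariant) and a truth record holding the
    planted active-site membership, the scripted side-chain/backbone torsion
    values, the catalytic-geometry values, and which waters visit the ligand
    often enough to survive solvent stripping.
    """
    rng = np.random.default_rng(seed)
    atoms: list[Atom] = []
    xyz: list[np.ndarray] = []

    def _add(name, res_name, chain, res_seq, pos, hetero=False):
        el = name.strip("0123456789'")[:1]
        atoms.append(Atom(len(atoms) + 1, name, res_name, chain, res_seq,
                          "", el, hetero))
        xyz.append(np.asarray(pos, dtype=float))

    # ligand: 8-oxoguanine 2'-deoxynucleoside fragment at the origin
    lig = {
        "C1'": np.array([0.0, 0.0, 0.0]),
        "O4'": np.array([1.41, 0.0, 0.0]),
        "N9": np.array([-0.70, 1.25, 0.0]),
        "C4": np.array([-2.05, 1.30, 0.10]),
        "C8": np.array([-0.20, 2.50, -0.10]),
        "O8": np.array([0.95, 2.95, -0.20]),
    }
    for n, p in lig.items():
        _add(n, "8OG", "B", 1, p, hetero=True)

    # protein chain A: scripted chi1 (and deeper) dihedrals per residue
    protein = [
        ("ALA", []), ("SER", [-65.0]), ("LEU", [-60.0, 175.0]), ("ALA", []),
        ("LYS", [-62.0, 178.0, -170.0, 65.0]), ("ASP", [-70.0, -15.0]),
        ("GLY", []), ("CYS", [-55.0]),
    ]
    # anchor atom of each residue is translated to a planted global position;
    # margins to the 5 Å cutoff are ≥ 1 Å on either side
    anchors = {
        1: ("CA", np.array([9.0, -6.0, 3.0])),
        2: ("CB", np.array([0.5, -3.8, 1.0])),     # in (≈3.9 Å from C1')
        3: ("CA", np.array([-8.0, 6.0, -4.0])),
        4: ("CA", np.array([10.0, 5.0, -6.0])),
        5: ("NZ", np.array([0.8, -1.6, 2.4])),     # in (3.0 Å from C1')
        6: ("OD1", np.array([3.2, 1.3, 1.6])),     # in (≈2.6 Å from O4')
        7: ("CA", np.array([-9.0, -7.0, 5.0])),
        8: ("CA", np.array([12.0, 0.0, 8.0])),
    }
    chi_truth: dict[str, list[float]] = {}
    for i, (res_name, chi) in enumerate(protein, start=1):
        local = _aa_template(res_name, chi)
        anchor_name, target = anchors[i]
        shift = target - local[anchor_name]
        for n in local:
            local[n] = local[n] + shift
        for n, p in local.items():
            _add(n, res_name, "A", i, p)
        if chi:
            chi_truth[f"A:{i}:chi1"] = chi[0]

    # DNA chain C: one continuous placement chain so every backbone torsion
    # of the middle nucleotide equals its scripted value
    nuc_names = ["DC", "DG", "DA"]
    base_atoms = {"DC": ("N1", "C2"), "DG": ("N9", "C4"), "DA": ("N9", "C4")}
    bb_torsions = {  # scripted dihedrals, keyed by (res, atom)
        (1, "C4'"): 175.0, (1, "C3'"): 140.0, (1, "O3'"): 80.0,
        (2, "P"): -95.0, (2, "O5'"): -70.0, (2, "C5'"): -60.0,  # zeta(1)/alpha(2)/beta(2)
        (2, "C4'"): 175.0, (2, "C3'"): 55.0, (2, "O3'"): 82.0,  # gamma/delta(2)
        (3, "P"): -85.0, (3, "O5'"): -68.0, (3, "C5'"): -58.0,
        (3, "C4'"): 170.0, (3, "C3'"): 60.0, (3, "O3'"): 85.0,
    }
    start = np.array([4.5, 3.5, -1.5])
    chain_pts = [start + np.array([-1.5, -1.0, 0.0]),
                 start + np.array([-0.8, 0.3, 0.0])]
    placed: dict[tuple[int, str], np.ndarray] = {}
    seq = []
    for r, name in enumerate(nuc_names, start=1):
        for atom in ("P", "O5'", "C5'", "C4'", "C3'", "O3'"):
            if r == 1 and atom == "P":
                pos = start
            else:
                phi = bb_torsions.get((r, atom), 170.0)
                pos = _nerf(chain_pts[-3], chain_pts[-2], chain_pts[-1], 1.55, 110.0, phi)
            chain_pts.append(pos)
            placed[(r, atom)] = pos
            seq.append((r, atom))
    glyco_truth: dict[str, float] = {}
    for r, name in enumerate(nuc_names, start=1):
        c5, c4, c3 = placed[(r, "C5'")], placed[(r, "C4'")], placed[(r, "C3'")]
        o4 = _nerf(c5, c3, c4, 1.45, 105.0, -120.0)
        c1 = _nerf(c3, c4, o4, 1.42, 109.0, 100.0)
        n_at, c_at = base_atoms[name]
        n9 = _nerf(c4, o4, c1, 1.47, 108.0, -140.0)
        chi_val = -110.0 + 15.0 * r
        cb = _nerf(o4, c1, n9, 1.37, 126.0, chi_val)
        glyco_truth[f"C:{r}:chi"] = chi_val
        for an, p in [("P", placed[(r, "P")]), ("O5'", placed[(r, "O5'")]),
                      ("C5'", c5), ("C4'", c4), ("C3'", c3),
                      ("O3'", placed[(r, "O3'")]), ("O4'", o4), ("C1'", c1),
                      (n_at, n9), (c_at, cb)]:
            _add(an, name, "C", r, p)

    # waters: two frequent visitors, two rare, one never close; two Na+ ions
    water_far = np.array([25.0, 25.0, 25.0])
    water_near_offsets = {
        "W1": np.array([0.0, 0.0, 3.0]),
        "W2": np.array([0.0, 3.2, 0.0]),
        "W3": np.array([3.0, 0.0, -1.0]),
        "W4": np.array([-2.5, -2.0, 0.5]),
        "W5": None,
    }
    near_frames = {
        "W1": set(range(n_frames)),                       # 100 %
        "W2": set(range(0, n_frames, 2)),                 # 50 %
        "W3": {0} if n_frames >= 20 else set(),           # < 10 %
        "W4": set(),                                      # never
        "W5": set(),
    }
    for wi, wname in enumerate(water_near_offsets, start=1):
        _add("O", "HOH", "W", wi, water_far + wi * 3.0, hetero=True)
    _add("NA", "NA", "I", 1, np.array([-20.0, 15.0, 0.0]), hetero=True)
    _add("NA", "NA", "I", 2, np.array([20.0, -15.0, 0.0]), hetero=True)

    coords0 = np.stack(xyz)
    model0 = StructureModel(list(atoms), coords0)

    # planted active-site membership by direct distance check with margin
    lig_idx = [i for i, a in enumerate(atoms) if a.res_name == "8OG"]
    members: set = set()
    for key, idx in model0.residue_table.items():
        if key[0] in ("B", "W", "I"):
            continue
        d = np.linalg.norm(
            coords0[idx][:, None, :] - coords0[lig_idx][None, :, :], axis=-1
        ).min()
        if d <= 4.0:
            members.add(key)
        elif d <= 6.0:
            raise AssertionError(f"toy residue {key} too close to the cutoff ({d:.2f} Å)")

    # scripted geometry truth (ligand frame)
    nz = anchors[5][1]
    od1 = anchors[6][1]
    c1p, o4p, n9 = lig["C1'"], lig["O4'"], lig["N9"]
    od2 = coords0[model0.find_atom(("A", 6, ""), "OD2")]
    v1, v2 = nz - c1p, n9 - c1p
    truth_geometry = {
        "d1": float(np.linalg.norm(nz - c1p)),
        "d2": float(min(np.linalg.norm(od1 - o4p), np.linalg.norm(od2 - o4p))),
        "a1": float(np.degrees(np.arccos(
            np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))))),
    }

    # frames: rigid global motion; waters choreographed relative to the ligand
    from scipy.spatial.transform import Rotation

    frames = np.empty((n_frames, len(atoms), 3))
    water_rows = {f"W{i}": model0.residue_table[("W", i, "")] for i in range(1, 6)}
    for f in range(n_frames):
        rot = Rotation.from_rotvec(np.radians(9.0 * f) * np.array([1.0, 1.0, 0.0]) / np.sqrt(2))
        shift = f * np.array([0.3, 0.1, -0.2])
        frames[f] = rot.apply(coords0) + shift
        lig_c1 = frames[f][model0.find_atom(("B", 1, ""), "C1'")]
        for wname, rows in water_rows.items():
            if f in near_frames[wname]:
                frames[f][rows[0]] = lig_c1 + water_near_offsets[wname]
            else:
                frames[f][rows[0]] = rot.apply(water_far + int(wname[1]) * 3.0) + shift
    # sub-numerical jitter: frames are distinct objects but all scripted
    # values stay exact to well below 1e-6 degrees / Å
    frames += rng.normal(0.0, 1e-9, size=frames.shape)

    traj = Trajectory(list(atoms), frames, timestep_ps=8.0)
    truth = {
        "active_site": sorted(members),
        "chi1": chi_truth,
        "glycosidic": glyco_truth,
        # canonical names of the scripted backbone dihedrals of the middle
        # nucleotide: each equals the NeRF placement angle of its last atom
        "backbone_middle": {
            "C:2:alpha": bb_torsions[(2, "C5'")],
            "C:2:beta": bb_torsions[(2, "C4'")],
            "C:2:gamma": bb_torsions[(2, "C3'")],
            "C:2:delta": bb_torsions[(2, "O3'")],
            "C:2:epsilon": bb_torsions[(3, "P")],
            "C:2:zeta": bb_torsions[(3, "O5'")],
        },
        "geometry": truth_geometry,
        "waters_kept": ["W1", "W2"],
        "waters_removed": ["W3", "W4", "W5"],
        "n_frames": n_frames,
    }
    return traj, truth
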