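"""Structure/trajectory IO, active-site selection, torsions, geometry,
solvent stripping — validated against the toy complex's planted truth."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from varmd import trajectory_features as tf
from varmd.structures import (PDBFormatError, StructureModel, Trajectory,
                              frame_count, read_models, write_pdb)

from conftest import make_model


# -- PDB round trips ----------------------------------------------------------


def test_read_models_single_and_multi(tmp_path, toy):
    traj, _ = toy
    f1 = tmp_path / "single.pdb"
    write_pdb(traj.model(0), f1)
    m = read_models(f1)
    assert isinstance(m, StructureModel)
    assert len(m.atoms) == len(traj.atoms)
    assert np.allclose(m.coords, traj.frames[0], atol=5e-4)  # PDB is 3-decimal

    f2 = tmp_path / "multi.pdb"
    write_pdb(Trajectory(traj.atoms, traj.frames[:5]), f2)
    t = read_models(f2)
    assert isinstance(t, Trajectory)
    assert t.n_frames == 5
    assert [a.identity for a in t.atoms] == [a.identity for a in traj.atoms]


def test_read_models_reports_divergent_model(tmp_path, toy):
    traj, _ = toy
    f = tmp_path / "broken.pdb"
    write_pdb(Trajectory(traj.atoms, traj.frames[:4]), f)
    lines = f.read_text().splitlines()
    # delete one atom from the third MODEL block
    model_starts = [i for i, l in enumerate(lines) if l.startswith("MODEL")]
    del lines[model_starts[2] + 3]
    f.write_text("\n".join(lines) + "\n")
    with pytest.raises(PDBFormatError, match="model 3"):
        read_models(f)


def test_frame_count_bookkeeping():
    assert frame_count(40, 8) == 5000
    assert frame_count(1, 2) == 500
    with pytest.raises(ValueError):
        frame_count(-1, 8)


def test_trajectory_tail():
    atoms_model = make_model([("A", 1, "ALA", [("CA", np.zeros(3))])])
    frames = np.arange(30.0).reshape(10, 1, 3)
    traj = Trajectory(atoms_model.atoms, frames)
    assert traj.tail(4).n_frames == 4
    assert np.array_equal(traj.tail(4).frames, frames[-4:])


# -- active-site selection ----------------------------------------------------


def test_select_active_site_by_construction():
    model = make_model([
        ("B", 1, "8OG", [("C1'", np.zeros(3))]),
        ("A", 1, "ALA", [("CA", np.array([4.9, 0, 0]))]),
        ("A", 2, "ALA", [("CA", np.array([5.1, 0, 0]))]),
    ])
    assert tf.select_active_site(model, "8OG", 5.0) == {("A", 1, "")}
    assert tf.select_active_site(model, "8OG", 0.0) == set()


def test_select_active_site_matches_toy_truth(toy):
    traj, truth = toy
    site = tf.select_active_site(traj.model(0), "8OG", 5.0)
    assert sorted(site) == [tuple(k) for k in truth["active_site"]]


def test_select_active_site_monotone_in_cutoff(toy):
    traj, _ = toy
    model = traj.model(0)
    sites = [tf.select_active_site(model, "8OG", c) for c in (2.0, 5.0, 8.0, 15.0)]
    for small, big in zip(sites, sites[1:]):
        assert small <= big


def test_select_active_site_missing_ligand(toy):
    traj, _ = toy
    with pytest.raises(ValueError):
        tf.select_active_site(traj.model(0), "XYZ", 5.0)


# -- torsion enumeration ------------------------------------------------------


def test_enumerate_torsions_mid_chain(tripeptide):
    mid_ala = tf.enumerate_torsions(tripeptide, {("A", 3, "")})
    # C-terminal Ala: psi needs the next N -> dropped; phi present
    assert {d.name for d in mid_ala} == {"phi"}
    arg = tf.enumerate_torsions(tripeptide, {("A", 2, "")})
    assert {d.name for d in arg} == {"phi", "psi", "chi1", "chi2", "chi3", "chi4", "chi5"}


def test_enumerate_torsions_terminal_drops_phi(tripeptide):
    nterm = tf.enumerate_torsions(tripeptide, {("A", 1, "")})
    assert {d.name for d in nterm} == {"psi"}  # no preceding C, Ala has no chi


def test_enumerate_torsions_nucleotide_middle(toy):
    traj, _ = toy
    defs = tf.enumerate_torsions(traj.model(0), {("C", 2, "")})
    assert {d.name for d in defs} == {"alpha", "beta", "gamma", "delta",
                                      "epsilon", "zeta", "chi"}


# -- dihedral computation -----------------------------------------------------


def _dihedral_single(p1, p2, p3, p4):
    return float(tf.dihedral_angles(*(np.asarray(p)[None] for p in (p1, p2, p3, p4)))[0])


def test_dihedral_cis_trans():
    assert _dihedral_single([1, 1, 0], [0, 1, 0], [0, 0, 0], [1, 0, 0]) == pytest.approx(0.0)
    assert _dihedral_single([-1, 1, 0], [0, 1, 0], [0, 0, 0], [1, 0, 0]) == pytest.approx(180.0)


def test_dihedral_staggered_sign_matches_independent_formula():
    """Butane-like ±60° conformers, cross-checked against MDAnalysis."""
    from MDAnalysis.lib.distances import calc_dihedrals

    rng = np.random.default_rng(4)
    for _ in range(20):
        pts = rng.normal(size=(4, 3)) * 3
        mine = _dihedral_single(*pts)
        ref = float(
            np.degrees(calc_dihedrals(*(p[None].astype(np.float64) for p in pts)))[0]
        )
        assert mine == pytest.approx(ref, abs=1e-4)  # reference runs in float32


def test_dihedral_reversal_symmetry():
    rng = np.random.default_rng(5)
    pts = rng.normal(size=(4, 3))
    fwd = _dihedral_single(*pts)
    rev = _dihedral_single(*pts[::-1])
    assert rev == pytest.approx(fwd, abs=1e-10)  # θ(4321) = θ(1234)


def test_dihedral_rigid_motion_invariance(toy):
    traj, _ = toy
    model = traj.model(0)
    site = {k for k in model.residue_keys() if k[0] in ("A", "C")}
    defs = tf.enumerate_torsions(model, site)
    base = tf.compute_dihedral_series(model, defs)
    R = Rotation.from_euler("xyz", [31.0, -47.0, 113.0], degrees=True).as_matrix()
    moved = StructureModel(model.atoms, model.coords @ R.T + np.array([5.0, -3.0, 11.0]))
    shifted = tf.compute_dihedral_series(moved, defs)
    assert np.allclose(base.to_numpy(), shifted.to_numpy(), atol=1e-8)


def test_dihedral_collinear_yields_na():
    vals = tf.dihedral_angles(
        np.array([[0.0, 0, 0]]), np.array([[1.0, 0, 0]]),
        np.array([[2.0, 0, 0]]), np.array([[3.0, 1, 0]]),
    )
    assert np.isnan(vals[0])


def test_toy_scripted_torsions(toy):
    traj, truth = toy
    model = traj.model(0)
    site = {k for k in model.residue_keys() if k[0] in ("A", "C")}
    series = tf.compute_dihedral_series(traj, tf.enumerate_torsions(model, site))
    scripted = {**truth["chi1"], **truth["glycosidic"], **truth["backbone_middle"]}
    for label, expected in scripted.items():
        got = series[label].iloc[0]
        assert got == pytest.approx(expected, abs=1e-6), label


# -- geometry -----------------------------------------------------------------


def test_geometry_trivial_cases():
    model = make_model([
        ("A", 1, "ALA", [("CA", np.zeros(3)), ("CB", np.array([3.0, 0, 0]))]),
        ("A", 2, "ALA", [("CA", np.array([0.0, 2.5, 0])), ("CB", np.array([0.0, 4.0, 0]))]),
    ])
    traj = Trajectory(model.atoms, model.coords[None])
    specs = [
        tf.GeometrySpec("d", "distance", ((("A", 1), "CA"), (("A", 1), "CB"))),
        tf.GeometrySpec("dmin", "min_distance",
                        ((((("A", 2), "CA")), (("A", 2), "CB")), (("A", 1), "CA"))),
        tf.GeometrySpec("ang", "angle",
                        ((("A", 1), "CB"), (("A", 1), "CA"), (("A", 2), "CA"))),
    ]
    out = tf.compute_geometry_series(traj, specs)
    assert out["d"].iloc[0] == pytest.approx(3.0)
    assert out["dmin"].iloc[0] == pytest.approx(2.5)
    assert out["ang"].iloc[0] == pytest.approx(90.0)


def test_geometry_matches_toy_truth(toy):
    traj, truth = toy
    specs = [
        tf.GeometrySpec("d1", "distance", ((("A", 5), "NZ"), (("B", 1), "C1'"))),
        tf.GeometrySpec("d2", "min_distance",
                        (((("A", 6), "OD1"), (("A", 6), "OD2")), (("B", 1), "O4'"))),
        tf.GeometrySpec("a1", "angle",
                        ((("A", 5), "NZ"), (("B", 1), "C1'"), (("B", 1), "N9"))),
    ]
    out = tf.compute_geometry_series(traj, specs)
    for name, val in truth["geometry"].items():
        assert out[name].iloc[0] == pytest.approx(val, abs=1e-6)
        # rigid global motion: constant over frames
        assert out[name].std() < 1e-6


def test_geometry_unknown_atom():
    model = make_model([("A", 1, "ALA", [("CA", np.zeros(3)), ("CB", np.ones(3))])])
    traj = Trajectory(model.atoms, model.coords[None])
    spec = tf.GeometrySpec("d", "distance", ((("A", 1), "CA"), (("A", 1), "XX")))
    with pytest.raises(KeyError, match="d"):
        tf.compute_geometry_series(traj, [spec])


# -- solvent stripping --------------------------------------------------------


def test_strip_solvent_occupancy_rule(toy):
    traj, truth = toy
    stripped = tf.strip_solvent(traj, "8OG", cutoff=5.0, min_fraction=0.10)
    waters = sorted({a.residue_key for a in stripped.atoms if a.res_name == "HOH"})
    assert [k[1] for k in waters] == [int(w[1]) for w in truth["waters_kept"]]
    # ions removed, solute intact, frame count unchanged
    assert not any(a.res_name == "NA" for a in stripped.atoms)
    assert stripped.n_frames == traj.n_frames
    n_solute = sum(a.res_name not in ("HOH", "NA") for a in traj.atoms)
    assert sum(a.res_name not in ("HOH", "NA") for a in stripped.atoms) == n_solute


def test_strip_solvent_idempotent(toy):
    traj, _ = toy
    once = tf.strip_solvent(traj, "8OG")
    twice = tf.strip_solvent(once, "8OG")
    assert [a.identity for a in twice.atoms] == [a.identity for a in once.atoms]
    assert np.array_equal(twice.frames, once.frames)


def test_strip_solvent_zero_fraction_keeps_all(toy):
    traj, _ = toy
    kept = tf.strip_solvent(traj, "8OG", min_fraction=0.0)
    waters = {a.residue_key for a in kept.atoms if a.res_name == "HOH"}
    assert len(waters) == 5
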