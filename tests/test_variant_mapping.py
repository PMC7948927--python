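"""Variant parsing, structure mapping, sampling and superposition."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from varmd import variant_mapping as vm
from varmd.structures import Atom, StructureModel

from conftest import make_model


# -- protein-change parsing ---------------------------------------------------


@pytest.mark.parametrize(
    "text,expected",
    [
        ("p.I145M", ("I", 145, "M")),
        ("I145M", ("I", 145, "M")),
        ("p.Arg229Gln", ("R", 229, "Q")),
        ("p.Val267Met", ("V", 267, "M")),
        (" p.E92D ", ("E", 92, "D")),
    ],
)
def test_parse_missense(text, expected):
    assert vm.parse_protein_change(text) == expected


@pytest.mark.parametrize(
    "text",
    ["p.K249K", "p.Arg229Arg", "p.R229*", "p.Trp151Ter", "p.S33fs", "p.S33Afs*12",
     "p.Met1del", "p.E92="],
)
def test_parse_rejects_non_missense(text):
    with pytest.raises(vm.NotMissenseError):
        vm.parse_protein_change(text)


@pytest.mark.parametrize("text", ["", "145M", "p.X145M", "p.I145Z", "nonsense"])
def test_parse_rejects_malformed(text):
    with pytest.raises(vm.ProteinChangeError):
        vm.parse_protein_change(text)


# -- catalogue loading --------------------------------------------------------


def _write_tsv(path, rows):
    lines = ["Gene name\tMutation AA\tMutation ID"]
    lines += [f"{g}\t{c}\t{i}" for g, c, i in rows]
    path.write_text("\n".join(lines) + "\n")


def test_load_variant_table_counts_and_dedup(tmp_path):
    f = tmp_path / "cosmic.tsv"
    _write_tsv(f, [
        ("OGG1", "p.I145M", "COSM1"),
        ("OGG1", "p.G202C", "COSM2"),
        ("OGG1", "p.R229*", "COSM3"),   # nonsense, skipped
        ("OGG1", "p.I145M", "COSM4"),   # duplicate
        ("UNG", "p.A10V", "COSM5"),     # other gene
    ])
    records = vm.load_variant_table(f, "OGG1")
    assert sorted(r.label for r in records) == ["G202C", "I145M"]


def test_load_variant_table_cohort_size(tmp_path):
    # a 39-variant cohort loads completely
    rows = [("OGG1", f"p.A{i}V", f"COSM{i}") for i in range(1, 40)]
    f = tmp_path / "cosmic.tsv"
    _write_tsv(f, rows)
    assert len(vm.load_variant_table(f, "OGG1")) == 39


def test_load_variant_table_missing_column(tmp_path):
    f = tmp_path / "bad.tsv"
    f.write_text("foo\tbar\n1\t2\n")
    with pytest.raises(KeyError):
        vm.load_variant_table(f, "OGG1")


# -- alignment-based mapping --------------------------------------------------


def _positions(seq, chain="A", start=1):
    return [((chain, start + i, ""), aa) for i, aa in enumerate(seq)]


def test_map_variant_identity_alignment():
    seq = "MAHIKLMNPQRSTVWY" * 10  # no alignment surprises
    iso = vm.build_alignment_map(seq, seq)
    v = vm.VariantRecord("G1", seq[144], 145, "M" if seq[144] != "M" else "W")
    assert vm.map_variant(v, iso, _positions(seq)) == ("A", 145, "")


def test_map_variant_nterminal_extension_offset():
    core = "ACDEFGHIKLMNPQRSTVWY" * 3
    ref = "MGSSHHHHHH" + core  # 10-residue tag on the reference isoform
    iso = vm.build_alignment_map(ref, core)
    v = vm.VariantRecord("G1", ref[14], 15, "A" if ref[14] != "A" else "G")
    assert vm.map_variant(v, iso, _positions(core)) == ("A", 5, "")


def test_map_variant_gap_is_unmapped():
    core = "ACDEFGHIKLMNPQRSTVWY"
    ref = core[:10] + "GGGGG" + core[10:]  # 5-residue insertion in reference
    iso = vm.build_alignment_map(ref, core)
    v = vm.VariantRecord("G1", "G", 12, "A")  # inside the insertion
    assert vm.map_variant(v, iso, _positions(core)) is None


def test_map_variant_reference_mismatch():
    seq = "ACDEFGHIKLMNPQRSTVWY"
    iso = vm.build_alignment_map(seq, seq)
    v = vm.VariantRecord("G1", "W", 1, "R")  # structure has A at 1
    with pytest.raises(vm.ReferenceMismatchError):
        vm.map_variant(v, iso, _positions(seq))


# -- sampling -----------------------------------------------------------------


def _records(n):
    alts = "ACDEFGHIKLMNPQRSTVWY"
    return [vm.VariantRecord("G", "A", i + 1, alts[i % 20] if alts[i % 20] != "A" else "V")
            for i in range(n)]


def test_sample_variants_is_seed_determined():
    recs = _records(39)
    s1 = vm.sample_variants(recs, 20, seed=1)
    s2 = vm.sample_variants(recs, 20, seed=1)
    s3 = vm.sample_variants(recs, 20, seed=2)
    assert s1 == s2
    assert len(s1) == len(set(s1)) == 20
    assert s1 != s3


def test_sample_variants_order_normalized():
    recs = _records(15)
    shuffled = list(reversed(recs))
    assert vm.sample_variants(recs, 7, seed=3) == vm.sample_variants(shuffled, 7, seed=3)


def test_sample_variants_full_and_oversize():
    recs = _records(5)
    assert set(vm.sample_variants(recs, 5, seed=0)) == set(recs)
    with pytest.raises(ValueError):
        vm.sample_variants(recs, 6, seed=0)


# -- structure mutation -------------------------------------------------------


def _residue(chain, seq, name, atom_names, offset=0.0):
    return (chain, seq, name,
            [(a, np.array([i + offset, 0.0, 0.0])) for i, a in enumerate(atom_names)])


def test_mutate_ala_to_val_keeps_atoms():
    model = make_model([_residue("A", 1, "ALA", ["N", "CA", "C", "O", "CB"])])
    out = vm.mutate_structure(model, ("A", 1), "V")
    assert [a.res_name for a in out.atoms] == ["VAL"] * 5
    assert [a.name for a in out.atoms] == ["N", "CA", "C", "O", "CB"]


def test_mutate_arg_to_lys_truncates_to_cb():
    arg = ["N", "CA", "C", "O", "CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"]
    model = make_model([_residue("A", 1, "ARG", arg)])
    out = vm.mutate_structure(model, ("A", 1), "K")
    assert [a.name for a in out.atoms] == ["N", "CA", "C", "O", "CB"]
    assert out.atoms[0].res_name == "LYS"


def test_mutate_ile_to_gly_removes_cb():
    ile = ["N", "CA", "C", "O", "CB", "CG1", "CG2", "CD1"]
    model = make_model([_residue("A", 1, "ILE", ile)])
    out = vm.mutate_structure(model, ("A", 1), "G")
    assert [a.name for a in out.atoms] == ["N", "CA", "C", "O"]


def test_mutate_leaves_other_residues_bitwise_identical():
    model = make_model([
        _residue("A", 1, "ALA", ["N", "CA", "C", "O", "CB"]),
        _residue("A", 2, "SER", ["N", "CA", "C", "O", "CB", "OG"], offset=10.0),
    ])
    out = vm.mutate_structure(model, ("A", 2), "A")
    kept = [a for a in out.atoms if a.res_seq == 1]
    assert kept == model.atoms[:5]
    assert np.array_equal(out.coords[:5], model.coords[:5])
    # backbone coordinates of the mutated residue are untouched too
    for name in ("N", "CA", "C", "O", "CB"):
        i_old = model.find_atom(("A", 2, ""), name)
        i_new = out.find_atom(("A", 2, ""), name)
        assert np.array_equal(out.coords[i_new], model.coords[i_old])


def test_mutate_errors():
    model = make_model([
        _residue("A", 1, "ALA", ["N", "CA", "C", "O", "CB"]),
        ("B", 1, "8OG", [("C1'", np.array([20.0, 0, 0]))]),
    ])
    with pytest.raises(KeyError):
        vm.mutate_structure(model, ("A", 9), "V")
    with pytest.raises(TypeError):
        vm.mutate_structure(model, ("B", 1), "V")


# -- Kabsch superposition -----------------------------------------------------


def _random_points(rng, n=8):
    return rng.normal(size=(n, 3))


def test_kabsch_identity():
    pts = _random_points(np.random.default_rng(0))
    R, t, rmsd = vm.kabsch_superpose(pts, pts)
    assert np.allclose(R, np.eye(3), atol=1e-10)
    assert np.allclose(t, 0.0, atol=1e-10)
    assert rmsd < 1e-12


def test_kabsch_recovers_known_transform():
    rng = np.random.default_rng(1)
    A = _random_points(rng)
    R_true = Rotation.from_euler("z", 90, degrees=True).as_matrix()
    B = A @ R_true.T + np.array([1.0, -2.0, 3.0])
    R, t, rmsd = vm.kabsch_superpose(A, B)
    assert rmsd <= 1e-8
    assert np.allclose(R, R_true, atol=1e-8)
    assert np.isclose(np.linalg.det(R), 1.0)


def test_kabsch_matches_numeric_minimum():
    """Perturbed triangle: the analytic RMSD equals an independent numeric
    minimization over rotations and translations."""
    from scipy.optimize import minimize

    A = np.array([[0.0, 0, 0], [1.0, 0, 0], [0.5, np.sqrt(3) / 2, 0]])
    B = A.copy()
    B[2] += np.array([0.0, 0.0, 0.3])
    _, _, rmsd = vm.kabsch_superpose(A, B)

    def cost(p):
        R = Rotation.from_rotvec(p[:3]).as_matrix()
        return np.sqrt(((A @ R.T + p[3:] - B) ** 2).sum() / len(A))

    best = min(
        minimize(cost, x0, method="Nelder-Mead",
                 options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000}).fun
        for x0 in (np.zeros(6), np.r_[0.1, -0.2, 0.3, 0.1, 0.1, -0.1])
    )
    assert rmsd == pytest.approx(best, abs=1e-6)


def test_kabsch_never_returns_reflection():
    # mirror-image point sets force the sign-correction branch
    rng = np.random.default_rng(2)
    A = _random_points(rng)
    B = A * np.array([1.0, 1.0, -1.0])
    R, _, _ = vm.kabsch_superpose(A, B)
    assert np.isclose(np.linalg.det(R), 1.0)


@given(st.integers(0, 10_000))
def test_kabsch_rmsd_rigid_invariance(seed):
    rng = np.random.default_rng(seed)
    A, B = _random_points(rng), _random_points(rng)
    _, _, rmsd0 = vm.kabsch_superpose(A, B)
    Rr = Rotation.random(random_state=np.random.RandomState(seed)).as_matrix()
    A2 = A @ Rr.T + rng.normal(size=3)
    _, _, rmsd1 = vm.kabsch_superpose(A2, B)
    assert rmsd1 == pytest.approx(rmsd0, abs=1e-8)


def test_kabsch_input_validation():
    pts = _random_points(np.random.default_rng(3))
    with pytest.raises(ValueError):
        vm.kabsch_superpose(pts[:4], pts[:5])
    line = np.outer(np.arange(5.0), np.array([1.0, 0, 0]))
    with pytest.raises(ValueError):
        vm.kabsch_superpose(line, line)
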