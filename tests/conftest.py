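import numpy as np
import pytest
from hypothesis import settings

from varmd.structures import Atom, StructureModel
from varmd.synthetic_data import gen_toy_complex

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy():
    """Toy protein–DNA–ligand trajectory with planted ground truth."""
    traj, truth = gen_toy_complex(seed=0)
    return traj, truth


def make_model(residues):
    """Build a StructureModel from [(chain, resseq, resname, [(atom, xyz)...])]."""
    atoms, xyz = [], []
    for chain, resseq, resname, atom_list in residues:
        for name, pos in atom_list:
            atoms.append(
                Atom(len(atoms) + 1, name, resname, chain, resseq, "",
                     name[:1], resname in ("HOH", "NA", "8OG"))
            )
            xyz.append(pos)
    return StructureModel(atoms, np.asarray(xyz, dtype=float))


@pytest.fixture
def tripeptide():
    """Ala–Arg–Ala with full Arg side chain; coordinates are arbitrary but
    distinct (torsion enumeration only needs atom presence)."""
    rng = np.random.default_rng(7)

    def res(chain, seq, name, atom_names):
        return (chain, seq, name, [(a, rng.normal(size=3)) for a in atom_names])

    ala = ["N", "CA", "C", "O", "CB"]
    arg = ["N", "CA", "C", "O", "CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"]
    return make_model([
        res("A", 1, "ALA", ala),
        res("A", 2, "ARG", arg),
        res("A", 3, "ALA", ala),
    ])
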