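import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from ufsrat import FixtureSpec, Molecule3D, random_molecule, read_sd


def mol_from_smiles(smiles: str, seed: int = 7, name: str = "mol") -> Molecule3D:
    """Embed a SMILES in 3D and round it through SD parsing (explicit H kept)."""
    rdmol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    if AllChem.EmbedMolecule(rdmol, randomSeed=seed) != 0:
        raise RuntimeError(f"embedding failed for {smiles}")
    block = Chem.MolToMolBlock(rdmol)
    block = name + block[block.index("\n") :]
    mols = read_sd(block + "$$$$\n")
    assert len(mols) == 1
    return mols[0]


def random_rigid_transform(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """A uniform random rotation matrix and a translation vector."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    return rot, rng.uniform(-20, 20, size=3)


def transform_molecule(mol: Molecule3D, rot: np.ndarray, shift: np.ndarray) -> Molecule3D:
    from dataclasses import replace

    coords = mol.coords @ rot.T + shift
    atoms = [replace(a, coords=tuple(coords[a.index])) for a in mol.atoms]
    return Molecule3D(id=mol.id, atoms=atoms, bonds=list(mol.bonds))


@pytest.fixture(scope="session")
def phenol() -> Molecule3D:
    return mol_from_smiles("c1ccccc1O", name="phenol")


@pytest.fixture(scope="session")
def benzene() -> Molecule3D:
    return mol_from_smiles("c1ccccc1", name="benzene")


@pytest.fixture()
def random_molecules():
    spec = FixtureSpec(seed=11)
    rng = np.random.default_rng(11)
    return [random_molecule(spec, f"m{i:03d}", rng) for i in range(30)]
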