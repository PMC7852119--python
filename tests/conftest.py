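import random

import pytest
from rdkit import Chem

from molsetcomp import fixtures, molio
from molsetcomp.molgraph import parse_smiles


@pytest.fixture
def smiles_file(tmp_path):
    """Factory writing a SMILES file from a list of lines."""

    def write(lines, name="set.smi"):
        p = tmp_path / name
        p.write_text("\n".join(lines) + "\n", encoding="utf-8")
        return p

    return write


@pytest.fixture
def paired_fixture(tmp_path):
    """Factory: generate a paired fixture run and return the PairedSet."""

    def make(n_pairs=100, rate=0.3, seed=0, **kw):
        spec = fixtures.FixtureSpec(
            n_pairs=n_pairs, perturbation_rate=rate, seed=seed, **kw
        )
        a, b = tmp_path / "a.smi", tmp_path / "b.smi"
        fixtures.generate_paired_sets(spec, a, b)
        return molio.pair_sets(molio.read_set(a), molio.read_set(b))

    return make


def random_carbon_smiles(rng: random.Random, n_max: int = 12, extra_edges: int = 2) -> str:
    """A random connected all-carbon molecule of <= n_max heavy atoms.

    Built as a random tree (uniform attachment, degree capped at 4) plus up
    to ``extra_edges`` random ring-closing bonds; used to exercise the
    topological descriptors against independent graph oracles.
    """
    n = rng.randint(1, n_max)
    mol = Chem.RWMol()
    for _ in range(n):
        mol.AddAtom(Chem.Atom(6))
    deg = [0] * n
    for i in range(1, n):
        parents = [j for j in range(i) if deg[j] < 4]
        j = rng.choice(parents)
        mol.AddBond(i, j, Chem.BondType.SINGLE)
        deg[i] += 1
        deg[j] += 1
    for _ in range(rng.randint(0, extra_edges)):
        cands = [
            (i, j)
            for i in range(n)
            for j in range(i + 1, n)
            if deg[i] < 4 and deg[j] < 4 and mol.GetBondBetweenAtoms(i, j) is None
        ]
        if not cands:
            break
        i, j = rng.choice(cands)
        mol.AddBond(i, j, Chem.BondType.SINGLE)
        deg[i] += 1
        deg[j] += 1
    m = mol.GetMol()
    Chem.SanitizeMol(m)
    return Chem.MolToSmiles(m)


def shuffled_spelling(smiles: str, rng: random.Random) -> str:
    """A different SMILES spelling of the same molecule (atom-order shuffle)."""
    mol = Chem.MolFromSmiles(smiles)
    perm = list(range(mol.GetNumAtoms()))
    rng.shuffle(perm)
    return Chem.MolToSmiles(Chem.RenumberAtoms(mol, perm), canonical=False)


@pytest.fixture
def parse():
    return parse_smiles
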