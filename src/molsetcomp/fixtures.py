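"""Deterministic generator of paired original/predicted molecule sets.

Real inputs to this package are the outputs of molecular-recognition
models: file A holds the original structures, file B the model's
prediction for each line.  This module emulates that situation without any
external data: originals are drawn from a bundled list of small drug-like
molecules, and each "prediction" is either

* a *perturbed* copy (with probability ``perturbation_rate``): one randomly
  chosen structural edit — C<->N element swap, single<->double bond-order
  change, appended methyl group, or deleted terminal atom — every one of
  which is guaranteed to produce a *different* molecule while preserving
  valence validity, or
* an *exact* copy spelled differently (atom-order shuffled SMILES), so that
  a correct prediction still exercises canonicalisation rather than string
  equality.

Consequently the expected fraction of canonical-equality hits is exactly
``1 - perturbation_rate``, which is what the recovery tests assert.  An
optional ``invalid_rate`` injects syntactically broken SMILES to exercise
the parse-failure policies.  Identical specs produce byte-identical files.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from rdkit import Chem

DEFAULT_OPS = ("element_swap", "bond_order", "append_methyl", "delete_terminal")

_INVALID_SMILES = "C1CC("  # unclosed ring + paren: never parses


@dataclass(frozen=True)
class FixtureSpec:
    n_pairs: int
    perturbation_rate: float = 0.3
    seed: int = 0
    ops: tuple[str, ...] = DEFAULT_OPS
    invalid_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be positive")
        if not 0.0 <= self.perturbation_rate <= 1.0:
            raise ValueError("perturbation_rate must lie in [0, 1]")
        unknown = set(self.ops) - set(DEFAULT_OPS)
        if unknown:
            raise ValueError(f"unknown perturbation ops: {sorted(unknown)}")


def seed_molecules() -> list[str]:
    """The bundled drug-like seed SMILES (structure token per line)."""
    text = resources.files("molsetcomp.data").joinpath("seed_molecules.smi").read_text()
    return [line.split()[0] for line in text.splitlines() if line.strip()]


def _shuffled_spelling(mol: Chem.Mol, rng: random.Random) -> str:
    perm = list(range(mol.GetNumAtoms()))
    rng.shuffle(perm)
    return Chem.MolToSmiles(Chem.RenumberAtoms(mol, perm), canonical=False)


def _try_element_swap(mol: Chem.Mol, rng: random.Random) -> Chem.Mol | None:
    rw = Chem.RWMol(mol)
    candidates = []
    for a in rw.GetAtoms():
        if a.GetSymbol() == "C" and a.GetDegree() <= 3 and a.GetFormalCharge() == 0:
            candidates.append((a.GetIdx(), 7))
        elif a.GetSymbol() == "N" and a.GetFormalCharge() == 0:
            candidates.append((a.GetIdx(), 6))
    if not candidates:
        return None
    idx, z = rng.choice(candidates)
    atom = rw.GetAtomWithIdx(idx)
    atom.SetAtomicNum(z)
    atom.SetNumExplicitHs(0)
    atom.SetNoImplicit(False)
    return rw.GetMol()


def _try_bond_order(mol: Chem.Mol, rng: random.Random) -> Chem.Mol | None:
    rw = Chem.RWMol(mol)
    ups, downs = [], []
    for b in rw.GetBonds():
        if b.GetIsAromatic() or b.IsInRing():
            continue
        a1, a2 = b.GetBeginAtom(), b.GetEndAtom()
        if b.GetBondType() == Chem.BondType.SINGLE:
            if (a1.GetSymbol() == a2.GetSymbol() == "C"
                    and a1.GetTotalNumHs() >= 1 and a2.GetTotalNumHs() >= 1):
                ups.append(b.GetIdx())
        elif b.GetBondType() == Chem.BondType.DOUBLE:
            downs.append(b.GetIdx())
    pool = [("up", i) for i in ups] + [("down", i) for i in downs]
    if not pool:
        return None
    kind, bidx = rng.choice(pool)
    bond = rw.GetBondWithIdx(bidx)
    bond.SetBondType(Chem.BondType.DOUBLE if kind == "up" else Chem.BondType.SINGLE)
    for a in (bond.GetBeginAtom(), bond.GetEndAtom()):
        a.SetNumExplicitHs(0)
        a.SetNoImplicit(False)
    return rw.GetMol()


def _try_append_methyl(mol: Chem.Mol, rng: random.Random) -> Chem.Mol | None:
    rw = Chem.RWMol(mol)
    candidates = [a.GetIdx() for a in rw.GetAtoms() if a.GetTotalNumHs() >= 1]
    if not candidates:
        return None
    idx = rng.choice(candidates)
    new_idx = rw.AddAtom(Chem.Atom(6))
    rw.AddBond(idx, new_idx, Chem.BondType.SINGLE)
    rw.GetAtomWithIdx(idx).SetNumExplicitHs(0)
    rw.GetAtomWithIdx(idx).SetNoImplicit(False)
    return rw.GetMol()


def _try_delete_terminal(mol: Chem.Mol, rng: random.Random) -> Chem.Mol | None:
    if mol.GetNumAtoms() < 2:
        return None
    rw = Chem.RWMol(mol)
    candidates = [a.GetIdx() for a in rw.GetAtoms() if a.GetDegree() == 1]
    if not candidates:
        return None
    idx = rng.choice(candidates)
    neighbor = rw.GetAtomWithIdx(idx).GetNeighbors()[0].GetIdx()
    rw.RemoveAtom(idx)
    if neighbor > idx:
        neighbor -= 1
    a = rw.GetAtomWithIdx(neighbor)
    a.SetNumExplicitHs(0)
    a.SetNoImplicit(False)
    return rw.GetMol()


_OP_FUNCS = {
    "element_swap": _try_element_swap,
    "bond_order": _try_bond_order,
    "append_methyl": _try_append_methyl,
    "delete_terminal": _try_delete_terminal,
}

_MAX_ATTEMPTS = 50


def perturb(smiles: str, rng: random.Random, ops: tuple[str, ...] = DEFAULT_OPS) -> str:
    """Apply one random valence-preserving edit; the result is always a
    different molecule (every operator changes the molecular formula or
    bond-order multiset).  Edits that fail sanitisation are resampled."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"seed molecule does not parse: {smiles!r}")
    original_canonical = Chem.MolToSmiles(mol)
    for _ in range(_MAX_ATTEMPTS):
        op = rng.choice(ops)
        candidate = _OP_FUNCS[op](Chem.Mol(mol), rng)
        if candidate is None:
            continue
        try:
            Chem.SanitizeMol(candidate)
        except Exception:
            continue
        out = Chem.MolToSmiles(candidate)
        if out and out != original_canonical and Chem.MolFromSmiles(out) is not None:
            return out
    raise RuntimeError(f"could not perturb {smiles!r} with ops {ops}")


def generate_pairs(spec: FixtureSpec) -> tuple[list[str], list[str]]:
    """In-memory generation: (original lines, predicted lines)."""
    rng = random.Random(spec.seed)
    seeds = seed_molecules()
    lines_a, lines_b = [], []
    for _ in range(spec.n_pairs):
        smiles = rng.choice(seeds)
        mol = Chem.MolFromSmiles(smiles)
        lines_a.append(_shuffled_spelling(mol, rng))
        if spec.invalid_rate > 0 and rng.random() < spec.invalid_rate:
            lines_b.append(_INVALID_SMILES)
        elif rng.random() < spec.perturbation_rate:
            lines_b.append(perturb(smiles, rng, spec.ops))
        else:
            lines_b.append(_shuffled_spelling(mol, rng))
    return lines_a, lines_b


def generate_paired_sets(spec: FixtureSpec, out_a: str | Path, out_b: str | Path) -> None:
    """Write the paired sets as two SMILES files (one record per line)."""
    lines_a, lines_b = generate_pairs(spec)
    Path(out_a).write_text("\n".join(lines_a) + "\n", encoding="utf-8")
    Path(out_b).write_text("\n".join(lines_b) + "\n", encoding="utf-8")
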