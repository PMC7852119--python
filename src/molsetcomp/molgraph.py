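"""Hydrogen-suppressed molecular graph model.

Every descriptor and fingerprint in this package is a pure function of the
:class:`MolGraph` defined here.  Lexical SMILES/molfile parsing, aromaticity
perception, implicit-hydrogen assignment, SSSR ring perception and canonical
SMILES generation are delegated to RDKit; the graph itself (atoms, bonds,
adjacency, topological distances, eccentricities) is materialised into plain
Python structures so that descriptor code never touches the toolkit directly.

Conventions pinned here and used uniformly downstream:

* hydrogen-suppressed graphs: explicit hydrogens are folded into per-atom
  implicit H counts at parse time;
* RDKit's default aromaticity model decides all ``aromatic`` flags;
* topological distance is the bond count of a shortest path; atoms in
  different fragments of a dot-disconnected input are at distance
  :data:`UNREACHABLE`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")  # parse failures are a status, not console noise

#: Sentinel distance between atoms of different connected fragments.
UNREACHABLE = -1

_HYBRID_MAP = {
    Chem.HybridizationType.SP: "sp",
    Chem.HybridizationType.SP2: "sp2",
    Chem.HybridizationType.SP3: "sp3",
}


@dataclass(frozen=True)
class Atom:
    idx: int
    element: str
    formal_charge: int
    aromatic: bool
    implicit_h: int
    hybridization: str  # one of {"sp", "sp2", "sp3", "other"}


@dataclass(frozen=True)
class Bond:
    a1: int
    a2: int
    order: int  # 1..4; aromatic bonds carry order 1 plus the aromatic flag
    aromatic: bool
    in_ring: bool


@dataclass
class RingSet:
    """Smallest set of smallest rings (SSSR), as atom-index cycles."""

    rings: list[tuple[int, ...]]
    ring_sizes: list[int] = field(init=False)

    def __post_init__(self) -> None:
        self.ring_sizes = sorted(len(r) for r in self.rings)

    def __len__(self) -> int:
        return len(self.rings)


class DistanceMatrix:
    """All-pairs topological distances with derived eccentricity statistics.

    ``diameter``/``radius`` are taken over the largest connected fragment so
    that they stay finite for dot-disconnected inputs.
    """

    def __init__(self, d: list[list[int]], largest_fragment: Sequence[int]):
        self.d = d
        self.largest_fragment = tuple(largest_fragment)
        ecc = []
        for i in range(len(d)):
            reach = [x for x in d[i] if x != UNREACHABLE]
            ecc.append(max(reach) if reach else 0)
        self.eccentricity = ecc
        frag_ecc = [ecc[i] for i in self.largest_fragment]
        self.diameter = max(frag_ecc) if frag_ecc else 0
        self.radius = min(frag_ecc) if frag_ecc else 0

    def __getitem__(self, ij: tuple[int, int]) -> int:
        i, j = ij
        return self.d[i][j]


class MolGraph:
    """Hydrogen-suppressed molecular graph.

    Constructed via :func:`parse_structure`; do not mutate after creation.
    Expensive derived views (distance matrix, rings, canonical form) are
    computed lazily and cached on the instance.
    """

    def __init__(self, atoms: list[Atom], bonds: list[Bond], rdmol: Chem.Mol):
        self.atoms = atoms
        self.bonds = bonds
        self._rdmol = rdmol
        self.adjacency: list[list[int]] = [[] for _ in atoms]
        self._bond_lookup: dict[tuple[int, int], Bond] = {}
        for b in bonds:
            self.adjacency[b.a1].append(b.a2)
            self.adjacency[b.a2].append(b.a1)
            self._bond_lookup[(b.a1, b.a2)] = b
            self._bond_lookup[(b.a2, b.a1)] = b
        self._dm: Optional[DistanceMatrix] = None
        self._rings: Optional[RingSet] = None
        self._canonical: Optional[str] = None

    # -- basic accessors -------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def degree(self, idx: int) -> int:
        return len(self.adjacency[idx])

    def bond_between(self, i: int, j: int) -> Optional[Bond]:
        return self._bond_lookup.get((i, j))

    def neighbors(self, idx: int) -> list[int]:
        return self.adjacency[idx]

    @property
    def rdmol(self) -> Chem.Mol:
        """Underlying toolkit molecule (for SMARTS matching and weights)."""
        return self._rdmol

    # -- fragments -------------------------------------------------------

    def fragments(self) -> list[list[int]]:
        """Connected components as sorted atom-index lists, largest first."""
        seen = [False] * self.n_atoms
        comps: list[list[int]] = []
        for start in range(self.n_atoms):
            if seen[start]:
                continue
            comp = [start]
            seen[start] = True
            stack = [start]
            while stack:
                u = stack.pop()
                for v in self.adjacency[u]:
                    if not seen[v]:
                        seen[v] = True
                        comp.append(v)
                        stack.append(v)
            comps.append(sorted(comp))
        comps.sort(key=lambda c: (-len(c), c))
        return comps

    @property
    def n_fragments(self) -> int:
        return len(self.fragments())

    # -- derived views ---------------------------------------------------

    @property
    def distances(self) -> DistanceMatrix:
        if self._dm is None:
            self._dm = distance_matrix(self)
        return self._dm

    @property
    def rings(self) -> RingSet:
        if self._rings is None:
            self._rings = perceive_rings(self)
        return self._rings

    def molecular_weight(self) -> float:
        """Average molecular weight in g/mol, implicit hydrogens included.

        Summed with :func:`math.fsum` (correctly rounded), so the result is
        bit-identical for every atom ordering of the same molecule —
        plain left-to-right accumulation is not.  Standard atomic weights;
        isotope labels are not distinguished.
        """
        pt = Chem.GetPeriodicTable()
        masses = [pt.GetAtomicWeight(a.element) for a in self.atoms]
        n_h = sum(a.implicit_h for a in self.atoms)
        masses.append(n_h * pt.GetAtomicWeight(1))
        return math.fsum(sorted(masses))


class ParseError(ValueError):
    """Raised by parse_structure when a structure cannot be interpreted."""


def _from_rdmol(mol: Chem.Mol) -> MolGraph:
    mol = Chem.RemoveHs(mol)
    atoms = []
    for a in mol.GetAtoms():
        atoms.append(
            Atom(
                idx=a.GetIdx(),
                element=a.GetSymbol(),
                formal_charge=a.GetFormalCharge(),
                aromatic=a.GetIsAromatic(),
                implicit_h=a.GetTotalNumHs(),
                hybridization=_HYBRID_MAP.get(a.GetHybridization(), "other"),
            )
        )
    ring_info = mol.GetRingInfo()
    bonds = []
    for b in mol.GetBonds():
        if b.GetIsAromatic():
            order = 1
        else:
            order = int(b.GetBondTypeAsDouble())
            if order < 1:
                order = 1
            order = min(order, 4)
        bonds.append(
            Bond(
                a1=b.GetBeginAtomIdx(),
                a2=b.GetEndAtomIdx(),
                order=order,
                aromatic=b.GetIsAromatic(),
                in_ring=ring_info.NumBondRings(b.GetIdx()) > 0,
            )
        )
    return MolGraph(atoms, bonds, mol)


def parse_smiles(smiles: str) -> MolGraph:
    """Parse a SMILES string into a MolGraph.

    Raises :class:`ParseError` on syntactically or chemically invalid input;
    batch drivers catch this and mark the record instead of aborting.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"invalid SMILES: {smiles!r}")
    return _from_rdmol(mol)


def parse_molblock(molblock: str) -> MolGraph:
    """Parse one MDL molfile (V2000/V3000) record into a MolGraph."""
    mol = Chem.MolFromMolBlock(molblock, sanitize=True)
    if mol is None:
        raise ParseError("invalid molfile record")
    return _from_rdmol(mol)


def distance_matrix(g: MolGraph) -> DistanceMatrix:
    """All-pairs shortest path lengths via BFS from every atom."""
    n = g.n_atoms
    d = [[UNREACHABLE] * n for _ in range(n)]
    for src in range(n):
        row = d[src]
        row[src] = 0
        frontier = [src]
        dist = 0
        while frontier:
            dist += 1
            nxt = []
            for u in frontier:
                for v in g.adjacency[u]:
                    if row[v] == UNREACHABLE:
                        row[v] = dist
                        nxt.append(v)
            frontier = nxt
    frags = g.fragments()
    return DistanceMatrix(d, frags[0] if frags else [])


def perceive_rings(g: MolGraph) -> RingSet:
    """SSSR ring perception; the ring count equals the circuit rank.

    Uses the toolkit's non-symmetrized SSSR (the symmetrized variant can
    return an extra ring on symmetric cages, breaking the circuit-rank
    identity that ring-count descriptors rely on).
    """
    rings = [tuple(r) for r in Chem.GetSSSR(Chem.Mol(g.rdmol))]
    return RingSet(rings=rings)


def canonical_form(g: MolGraph) -> str:
    """Canonical SMILES; invariant under input atom ordering."""
    if g._canonical is None:
        g._canonical = Chem.MolToSmiles(g.rdmol)
    return g._canonical


def circuit_rank(g: MolGraph) -> int:
    """bonds - atoms + components; equals the SSSR ring count."""
    return g.n_bonds - g.n_atoms + g.n_fragments
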