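"""Molecular descriptors computed on the hydrogen-suppressed graph.

Each descriptor is a pure function of a :class:`~molsetcomp.molgraph.MolGraph`
returning a :class:`DescriptorValue`.  The registry at the bottom maps the
canonical descriptor names used throughout the package (CLI, comparison
engine, persistence) to their implementations.

Pinned conventions (the field knows several variants of most of these
quantities; one definition per name is frozen here and documented in
``docs/methods.md``):

* "all atoms" counts heavy atoms; implicit hydrogens can be included via a
  flag but are excluded from every registered descriptor;
* distance-based indices (Wiener numbers, eccentric connectivity, Petitjean
  number) are evaluated on the largest connected fragment;
* kappa shape indices follow Kier's path-count formulas on the
  hydrogen-suppressed graph, with the parity-dependent third-order form;
* undefined cases (Petitjean number of a single atom, sp3 fraction of a
  carbon-free molecule, path counts of zero) yield ``defined=False`` rather
  than raising — batch runs over large sets must never abort on one molecule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Callable, Iterable

from rdkit import Chem

from .molgraph import MolGraph, canonical_form

# ---------------------------------------------------------------------------
# value & spec types


@dataclass(frozen=True)
class DescriptorValue:
    name: str
    value: float
    defined: bool = True


@dataclass(frozen=True)
class DescriptorSpec:
    name: str
    category: str  # atom_count | bond_count | group_count | logp | misc | equality
    arity: str = "single_molecule"  # or "pair"


# ---------------------------------------------------------------------------
# SMARTS pattern lists (bundled plain-text data files)


@dataclass(frozen=True)
class SmartsPattern:
    smarts: str
    label: str
    query: Chem.Mol


class SmartsFileError(ValueError):
    """An invalid SMARTS in a bundled or user-supplied pattern file."""


def load_smarts_list(lines: Iterable[str], source: str = "<smarts>") -> list[SmartsPattern]:
    """Parse a pattern list: one ``SMARTS<whitespace>label`` per line, '#' comments."""
    patterns = []
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        smarts = parts[0]
        label = parts[1].strip() if len(parts) > 1 else smarts
        query = Chem.MolFromSmarts(smarts)
        if query is None:
            raise SmartsFileError(f"{source}:{lineno}: invalid SMARTS {smarts!r}")
        patterns.append(SmartsPattern(smarts, label, query))
    return patterns


@lru_cache(maxsize=None)
def bundled_smarts(name: str) -> tuple[SmartsPattern, ...]:
    """Load one of the shipped pattern files (acidic, basic, hba, hbd, substructure)."""
    text = resources.files("molsetcomp.data").joinpath(f"{name}.smarts").read_text()
    return tuple(load_smarts_list(text.splitlines(), source=f"{name}.smarts"))


def count_smarts_matches(g: MolGraph, patterns: Iterable[SmartsPattern]) -> int:
    """Total number of unique matches summed over a pattern list."""
    return sum(
        len(g.rdmol.GetSubstructMatches(p.query, uniquify=True)) for p in patterns
    )


# ---------------------------------------------------------------------------
# atom counts

_ELEMENT_SELECTORS = {"C": "C", "O": "O", "S": "S", "N": "N", "P": "P"}


def _spiro_atoms(g: MolGraph) -> set[int]:
    """Atoms shared by two SSSR rings whose intersection is exactly that atom."""
    rings = [frozenset(r) for r in g.rings.rings]
    spiro = set()
    for i in range(len(rings)):
        for j in range(i + 1, len(rings)):
            inter = rings[i] & rings[j]
            if len(inter) == 1:
                spiro |= inter
    return spiro


def _cnspm(g: MolGraph, n_carbon_neighbors: int, hybrid: str) -> int:
    """Carbons of a given hybridisation bonded to exactly n other carbons."""
    count = 0
    for a in g.atoms:
        if a.element != "C" or a.hybridization != hybrid:
            continue
        ncarbons = sum(1 for v in g.neighbors(a.idx) if g.atoms[v].element == "C")
        if ncarbons == n_carbon_neighbors:
            count += 1
    return count


ATOM_SELECTORS = (
    "all", "C", "O", "S", "N", "P", "aromatic", "spiro",
    "C1SP1", "C2SP1", "C1SP2", "C2SP2", "C3SP2",
    "C1SP3", "C2SP3", "C3SP3", "C4SP3",
)


def count_atoms(g: MolGraph, selector: str, include_implicit_h: bool = False) -> int:
    """Atom counts: total, per element, aromatic, spiro and CnSPm classes.

    ``include_implicit_h`` extends the ``all`` selector to the
    hydrogen-filled atom count; every other selector ignores it.
    """
    if selector == "all":
        n = g.n_atoms
        if include_implicit_h:
            n += sum(a.implicit_h for a in g.atoms)
        return n
    if selector in _ELEMENT_SELECTORS:
        return sum(1 for a in g.atoms if a.element == selector)
    if selector == "aromatic":
        return sum(1 for a in g.atoms if a.aromatic)
    if selector == "spiro":
        return len(_spiro_atoms(g))
    if len(selector) == 5 and selector.startswith("C") and "SP" in selector:
        n = int(selector[1])
        hybrid = {"1": "sp", "2": "sp2", "3": "sp3"}[selector[4]]
        return _cnspm(g, n, hybrid)
    raise ValueError(f"unknown atom selector: {selector!r}")


# ---------------------------------------------------------------------------
# bond counts

BOND_SELECTORS = ("all", "aromatic", "single", "double", "triple", "quadruple", "rotatable")

_ORDER_NAMES = {"single": 1, "double": 2, "triple": 3, "quadruple": 4}


def _is_amide_cn(g: MolGraph, a1: int, a2: int) -> bool:
    """C-N bond where the carbon carries a double-bonded oxygen."""
    for c, n in ((a1, a2), (a2, a1)):
        if g.atoms[c].element == "C" and g.atoms[n].element == "N":
            for v in g.neighbors(c):
                b = g.bond_between(c, v)
                if g.atoms[v].element == "O" and b is not None and b.order == 2:
                    return True
    return False


def count_bonds(g: MolGraph, selector: str) -> int:
    """Bond counts; aromatic bonds count only under ``aromatic``/``all``.

    ``rotatable``: non-ring single bonds between two heavy atoms of
    heavy-degree >= 2 each, excluding amide C-N bonds.
    """
    if selector == "all":
        return g.n_bonds
    if selector == "aromatic":
        return sum(1 for b in g.bonds if b.aromatic)
    if selector in _ORDER_NAMES:
        order = _ORDER_NAMES[selector]
        return sum(1 for b in g.bonds if not b.aromatic and b.order == order)
    if selector == "rotatable":
        count = 0
        for b in g.bonds:
            if b.aromatic or b.in_ring or b.order != 1:
                continue
            if g.degree(b.a1) < 2 or g.degree(b.a2) < 2:
                continue
            if _is_amide_cn(g, b.a1, b.a2):
                continue
            count += 1
        return count
    raise ValueError(f"unknown bond selector: {selector!r}")


# ---------------------------------------------------------------------------
# group counts

GROUP_SELECTORS = (
    "acidic", "basic", "hba", "hbd",
    "rings_all", "rings_aromatic", "rings_small",
    *(f"rings_size_{k}" for k in range(3, 10)),
)


def _ring_is_aromatic(g: MolGraph, ring: tuple[int, ...]) -> bool:
    n = len(ring)
    for k in range(n):
        b = g.bond_between(ring[k], ring[(k + 1) % n])
        if b is None or not b.aromatic:
            return False
    return True


def count_groups(g: MolGraph, selector: str) -> int:
    """Functional-group and ring counts.

    Acidic/basic/HBA/HBD groups are counted by the bundled SMARTS lists
    (``data/*.smarts``); ring selectors count SSSR rings, with ``small``
    meaning size <= 9.
    """
    if selector in ("acidic", "basic", "hba", "hbd"):
        return count_smarts_matches(g, bundled_smarts(selector))
    rings = g.rings.rings
    if selector == "rings_all":
        return len(rings)
    if selector == "rings_aromatic":
        return sum(1 for r in rings if _ring_is_aromatic(g, r))
    if selector == "rings_small":
        return sum(1 for r in rings if len(r) <= 9)
    if selector.startswith("rings_size_"):
        k = int(selector.rsplit("_", 1)[1])
        if not 3 <= k <= 9:
            raise ValueError(f"ring size out of range: {k}")
        return sum(1 for r in rings if len(r) == k)
    raise ValueError(f"unknown group selector: {selector!r}")


# ---------------------------------------------------------------------------
# logP and weight


def mannhold_logp(g: MolGraph) -> float:
    """Mannhold's heavy-atom logP estimate: 1.46 + 0.11*nC - 0.11*nHet."""
    n_c = sum(1 for a in g.atoms if a.element == "C")
    n_het = g.n_atoms - n_c
    return 1.46 + 0.11 * n_c - 0.11 * n_het


def molecular_weight(g: MolGraph) -> float:
    """Average molecular weight (g/mol), implicit hydrogens included."""
    return g.molecular_weight()


# ---------------------------------------------------------------------------
# topological indices

TOPO_INDICES = (
    "wiener_path", "wiener_polarity", "zagreb", "eccentric_connectivity",
    "petitjean", "kappa1", "kappa2", "kappa3", "vertex_adjacency",
    "sp3_fraction", "largest_chain", "longest_aliphatic_chain",
    "largest_pi_system",
)

#: Induced subsets larger than this are not searched exhaustively for a
#: longest simple path; the descriptor comes back undefined instead of
#: letting an exponential search stall a million-pair run.
LONGEST_PATH_ATOM_GUARD = 60


def _path_counts(g: MolGraph) -> tuple[int, int, int]:
    """Simple-path counts P1, P2, P3 (paths of 1, 2, 3 bonds).

    P2 is the number of 2-paths through each centre vertex; P3 uses the
    edge-product form corrected for triangles (a triangle's three edges
    would otherwise each contribute a closed walk that is not a path).
    """
    p1 = g.n_bonds
    degs = [g.degree(i) for i in range(g.n_atoms)]
    p2 = sum(d * (d - 1) // 2 for d in degs)
    neigh = [set(g.adjacency[i]) for i in range(g.n_atoms)]
    p3 = 0
    for b in g.bonds:
        u, v = b.a1, b.a2
        # (d(u)-1)(d(v)-1) counts walks w-u-v-x; w == x (a common neighbour)
        # closes a triangle and is not a path, so subtract those.
        p3 += (degs[u] - 1) * (degs[v] - 1) - len(neigh[u] & neigh[v])
    return p1, p2, p3


def _longest_simple_path(g: MolGraph, subset: set[int]) -> int:
    """Atom count of the longest simple path within an induced subgraph."""
    if not subset:
        return 0
    adj = {u: [v for v in g.adjacency[u] if v in subset] for u in subset}
    best = 1

    def dfs(u: int, visited: set[int], length: int) -> None:
        nonlocal best
        if length > best:
            best = length
        for v in adj[u]:
            if v not in visited:
                visited.add(v)
                dfs(v, visited, length + 1)
                visited.remove(v)

    for start in sorted(subset):
        dfs(start, {start}, 1)
    return best


def _has_pi_electrons(g: MolGraph, idx: int) -> bool:
    if g.atoms[idx].aromatic:
        return True
    for v in g.neighbors(idx):
        b = g.bond_between(idx, v)
        if b is not None and (b.aromatic or b.order >= 2):
            return True
    return False


def topo_index(g: MolGraph, which: str) -> DescriptorValue:
    """Topological indices; see module docstring for the pinned definitions."""
    if which not in TOPO_INDICES:
        raise ValueError(f"unknown topological index: {which!r}")

    if which in ("wiener_path", "wiener_polarity", "eccentric_connectivity", "petitjean"):
        dm = g.distances
        frag = dm.largest_fragment
        if which == "wiener_path":
            total = sum(
                dm[i, j] for ai, i in enumerate(frag) for j in frag[ai + 1:]
            )
            return DescriptorValue(which, float(total))
        if which == "wiener_polarity":
            total = sum(
                1 for ai, i in enumerate(frag) for j in frag[ai + 1:] if dm[i, j] == 3
            )
            return DescriptorValue(which, float(total))
        if which == "eccentric_connectivity":
            total = sum(g.degree(i) * dm.eccentricity[i] for i in frag)
            return DescriptorValue(which, float(total))
        # petitjean
        if dm.radius == 0:
            return DescriptorValue(which, float("nan"), defined=False)
        return DescriptorValue(which, (dm.diameter - dm.radius) / dm.radius)

    if which == "zagreb":
        return DescriptorValue(which, float(sum(g.degree(i) ** 2 for i in range(g.n_atoms))))

    if which.startswith("kappa"):
        a = g.n_atoms
        p1, p2, p3 = _path_counts(g)
        if which == "kappa1":
            if p1 == 0:
                return DescriptorValue(which, float("nan"), defined=False)
            return DescriptorValue(which, a * (a - 1) ** 2 / p1**2)
        if which == "kappa2":
            if p2 == 0:
                return DescriptorValue(which, float("nan"), defined=False)
            return DescriptorValue(which, (a - 1) * (a - 2) ** 2 / p2**2)
        if p3 == 0:
            return DescriptorValue(which, float("nan"), defined=False)
        if a % 2 == 1:
            return DescriptorValue(which, (a - 1) * (a - 3) ** 2 / p3**2)
        return DescriptorValue(which, (a - 3) * (a - 2) ** 2 / p3**2)

    if which == "vertex_adjacency":
        m = g.n_bonds
        return DescriptorValue(which, 1.0 + math.log2(m) if m > 0 else 0.0)

    if which == "sp3_fraction":
        carbons = [a for a in g.atoms if a.element == "C"]
        if not carbons:
            return DescriptorValue(which, float("nan"), defined=False)
        sp3 = sum(1 for a in carbons if a.hybridization == "sp3")
        return DescriptorValue(which, sp3 / len(carbons))

    # longest-simple-path family
    if which == "largest_chain":
        ring_atoms = {i for r in g.rings.rings for i in r}
        subset = {a.idx for a in g.atoms} - ring_atoms
    elif which == "longest_aliphatic_chain":
        subset = {
            a.idx for a in g.atoms
            if a.element == "C" and not a.aromatic and a.hybridization == "sp3"
        }
    else:  # largest_pi_system
        subset = {a.idx for a in g.atoms if _has_pi_electrons(g, a.idx)}
    if len(subset) > LONGEST_PATH_ATOM_GUARD:
        return DescriptorValue(which, float("nan"), defined=False)
    return DescriptorValue(which, float(_longest_simple_path(g, subset)))


# ---------------------------------------------------------------------------
# pair-arity descriptor


def equality(a: MolGraph, b: MolGraph) -> float:
    """1.0 if the canonical forms match (same molecule), else 0.0."""
    return 1.0 if canonical_form(a) == canonical_form(b) else 0.0


# ---------------------------------------------------------------------------
# registry


def _dv(name: str, fn: Callable[[MolGraph], float]) -> Callable[[MolGraph], DescriptorValue]:
    def wrapped(g: MolGraph) -> DescriptorValue:
        return DescriptorValue(name, float(fn(g)))
    return wrapped


DESCRIPTORS: dict[str, Callable[[MolGraph], DescriptorValue]] = {}
DESCRIPTOR_SPECS: dict[str, DescriptorSpec] = {}


def _register(name: str, category: str, fn: Callable[[MolGraph], DescriptorValue]) -> None:
    if name in DESCRIPTORS:
        raise ValueError(f"duplicate descriptor name: {name}")
    DESCRIPTORS[name] = fn
    DESCRIPTOR_SPECS[name] = DescriptorSpec(name, category)


for _sel in ATOM_SELECTORS:
    _name = "atoms_all" if _sel == "all" else (
        f"atoms_{_sel.lower()}" if _sel.isupper() or len(_sel) > 1 else f"atoms_{_sel}"
    )
    _name = {
        "atoms_c": "atoms_carbon", "atoms_o": "atoms_oxygen",
        "atoms_s": "atoms_sulfur", "atoms_n": "atoms_nitrogen",
        "atoms_p": "atoms_phosphorus",
    }.get(_name, _name)
    _register(_name, "atom_count", _dv(_name, lambda g, s=_sel: count_atoms(g, s)))

for _sel in BOND_SELECTORS:
    _name = f"bonds_{_sel}"
    _register(_name, "bond_count", _dv(_name, lambda g, s=_sel: count_bonds(g, s)))

for _sel in GROUP_SELECTORS:
    _name = _sel if _sel.startswith("rings") else f"groups_{_sel}"
    _name = {"groups_hba": "hba", "groups_hbd": "hbd"}.get(_name, _name)
    _register(_name, "group_count", _dv(_name, lambda g, s=_sel: count_groups(g, s)))

_register("mannhold_logp", "logp", _dv("mannhold_logp", mannhold_logp))
_register("molecular_weight", "misc", _dv("molecular_weight", molecular_weight))

for _which in TOPO_INDICES:
    _register(_which, "misc", lambda g, w=_which: topo_index(g, w))

DESCRIPTOR_SPECS["equality"] = DescriptorSpec("equality", "equality", arity="pair")


def list_descriptors() -> list[str]:
    """All registered single-molecule descriptor names, sorted."""
    return sorted(DESCRIPTORS)


def compute(g: MolGraph, name: str) -> DescriptorValue:
    """Evaluate one registered descriptor by name."""
    try:
        fn = DESCRIPTORS[name]
    except KeyError:
        raise KeyError(
            f"unknown descriptor {name!r}; valid names: {', '.join(list_descriptors())}"
        ) from None
    return fn(g)
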