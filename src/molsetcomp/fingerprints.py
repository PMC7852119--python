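"""Fingerprints and Tanimoto similarity.

Four fingerprint families are provided for original/predicted pair scoring:

``path``
    Hashed linear atom-bond paths of 0..max_depth bonds (default 7), folded
    into a fixed-length bit vector — behaviour-compatible with classic
    hashed-path fingerprints, but with a pinned portable hash (32-bit
    FNV-1a) so bit positions are identical on every platform.
``shortest_path``
    One canonical string per atom pair encoding a shortest topological path
    between them (plus one string per atom), hashed the same way.
``substructure``
    One bit per SMARTS pattern of a bundled functional-group key; no hashing.
``lingo``
    Not a bit vector: the multiset of length-q substrings (q-grams, q=4) of
    the canonical SMILES with ring-closure digits normalised to '0',
    compared with the multiset form of the Tanimoto coefficient.

All similarities lie in [0, 1]; two identical molecules score 1.0.  The
degenerate all-zero-vs-all-zero comparison is defined as 1.0 (identical
objects) and all-zero vs anything else as 0.0.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .descriptors import SmartsPattern, bundled_smarts
from .molgraph import MolGraph, canonical_form

_BOND_SYMBOL = {1: "-", 2: "=", 3: "#", 4: "$"}

DEFAULT_MAX_DEPTH = 7
DEFAULT_N_BITS = 1024
DEFAULT_LINGO_Q = 4


@dataclass(frozen=True)
class BitFingerprint:
    bits: int  # bitmask; bit i set <=> feature hashed to position i
    length: int
    kind: str  # path | shortest_path | substructure

    @property
    def popcount(self) -> int:
        return self.bits.bit_count()

    def on_bits(self) -> list[int]:
        return [i for i in range(self.length) if self.bits >> i & 1]


@dataclass(frozen=True)
class LingoProfile:
    qgrams: tuple[tuple[str, int], ...]  # sorted (gram, count) pairs
    q: int

    @property
    def total(self) -> int:
        return sum(c for _, c in self.qgrams)


def fnv1a_32(s: str) -> int:
    """32-bit FNV-1a over the UTF-8 bytes; the pinned fingerprint hash."""
    h = 0x811C9DC5
    for byte in s.encode("utf-8"):
        h ^= byte
        h = (h * 0x01000193) & 0xFFFFFFFF
    return h


def _bond_symbol(g: MolGraph, a1: int, a2: int) -> str:
    b = g.bond_between(a1, a2)
    assert b is not None
    return ":" if b.aromatic else _BOND_SYMBOL[b.order]


def _path_string(g: MolGraph, path: Sequence[int]) -> str:
    """Canonical string of an atom path, direction-normalised."""
    parts = [g.atoms[path[0]].element]
    for prev, cur in zip(path, path[1:]):
        parts.append(_bond_symbol(g, prev, cur))
        parts.append(g.atoms[cur].element)
    forward = "".join(parts)
    backward = "".join(reversed(parts))
    return min(forward, backward)


def enumerate_path_strings(g: MolGraph, max_depth: int = DEFAULT_MAX_DEPTH) -> Counter:
    """Multiset of canonical strings of all linear paths of 0..max_depth bonds.

    Each path is counted once regardless of traversal direction.  The
    multiset (rather than the hashed bit vector) is what structural
    sub-multiset properties are stated on.
    """
    counts: Counter = Counter()
    for a in g.atoms:
        counts[a.element] += 1
    # DFS from every atom; count each undirected path once via endpoint order
    stack_path: list[int] = []

    def dfs(u: int) -> None:
        stack_path.append(u)
        if 2 <= len(stack_path) <= max_depth + 1:
            if stack_path[0] < stack_path[-1]:
                counts[_path_string(g, stack_path)] += 1
        if len(stack_path) <= max_depth:
            for v in g.adjacency[u]:
                if v not in stack_path:
                    dfs(v)
        stack_path.pop()

    for start in range(g.n_atoms):
        dfs(start)
    return counts


def path_fingerprint(
    g: MolGraph, max_depth: int = DEFAULT_MAX_DEPTH, n_bits: int = DEFAULT_N_BITS
) -> BitFingerprint:
    """Hashed linear-path fingerprint (the 'basic' fingerprint family)."""
    bits = 0
    for s in enumerate_path_strings(g, max_depth):
        bits |= 1 << (fnv1a_32(s) % n_bits)
    return BitFingerprint(bits, n_bits, "path")


def _all_shortest_paths(g: MolGraph, src: int) -> tuple[list[int], list[list[int]]]:
    """BFS distances and predecessor lists from one source."""
    dist = [-1] * g.n_atoms
    preds: list[list[int]] = [[] for _ in range(g.n_atoms)]
    dist[src] = 0
    frontier = [src]
    d = 0
    while frontier:
        d += 1
        nxt = []
        for u in frontier:
            for v in g.adjacency[u]:
                if dist[v] == -1:
                    dist[v] = d
                    preds[v].append(u)
                    nxt.append(v)
                elif dist[v] == d:
                    preds[v].append(u)
        frontier = nxt
    return dist, preds


def _expand_paths(preds: list[list[int]], src: int, dst: int) -> Iterable[list[int]]:
    if dst == src:
        yield [src]
        return
    for p in preds[dst]:
        for sub in _expand_paths(preds, src, p):
            yield sub + [dst]


def shortest_path_fingerprint(g: MolGraph, n_bits: int = DEFAULT_N_BITS) -> BitFingerprint:
    """Fingerprint of one canonical shortest-path string per atom pair.

    Among equal-length shortest paths between a pair, the lexicographically
    smallest canonical string is the pair's representative.  Cross-fragment
    pairs (unreachable) contribute nothing.
    """
    strings: set[str] = {a.element for a in g.atoms}
    for src in range(g.n_atoms):
        dist, preds = _all_shortest_paths(g, src)
        for dst in range(src + 1, g.n_atoms):
            if dist[dst] <= 0:
                continue
            best = min(
                _path_string(g, path) for path in _expand_paths(preds, src, dst)
            )
            strings.add(best)
    bits = 0
    for s in strings:
        bits |= 1 << (fnv1a_32(s) % n_bits)
    return BitFingerprint(bits, n_bits, "shortest_path")


def normalize_smiles_for_lingo(smiles: str) -> str:
    """Replace ring-closure digits (outside brackets) with '0'."""
    out = []
    in_bracket = False
    for ch in smiles:
        if ch == "[":
            in_bracket = True
        elif ch == "]":
            in_bracket = False
        if ch.isdigit() and not in_bracket:
            out.append("0")
        else:
            out.append(ch)
    return "".join(out)


def lingo_profile(g: MolGraph, q: int = DEFAULT_LINGO_Q) -> LingoProfile:
    """q-gram multiset of the normalised canonical SMILES."""
    s = normalize_smiles_for_lingo(canonical_form(g))
    grams = Counter(s[i : i + q] for i in range(max(len(s) - q + 1, 0)))
    return LingoProfile(tuple(sorted(grams.items())), q)


def lingo_similarity(a: LingoProfile, b: LingoProfile) -> float:
    """Multiset Tanimoto over q-gram counts; 1.0 for two empty profiles."""
    if a.q != b.q:
        raise ValueError(f"LINGO q mismatch: {a.q} vs {b.q}")
    ca, cb = dict(a.qgrams), dict(b.qgrams)
    mins = maxs = 0
    for gram in set(ca) | set(cb):
        x, y = ca.get(gram, 0), cb.get(gram, 0)
        mins += min(x, y)
        maxs += max(x, y)
    if maxs == 0:
        return 1.0
    return mins / maxs


def substructure_fingerprint(
    g: MolGraph, patterns: Optional[Sequence[SmartsPattern]] = None
) -> BitFingerprint:
    """One bit per SMARTS pattern; defaults to the bundled functional-group key."""
    if patterns is None:
        patterns = bundled_smarts("substructure")
    bits = 0
    for i, p in enumerate(patterns):
        if g.rdmol.HasSubstructMatch(p.query):
            bits |= 1 << i
    return BitFingerprint(bits, len(patterns), "substructure")


def tanimoto(a: BitFingerprint, b: BitFingerprint) -> float:
    """|intersection| / |union| of the set bits.

    Comparable only for matching kind and length; 1.0 when both vectors are
    all-zero (identical objects).
    """
    if a.kind != b.kind or a.length != b.length:
        raise ValueError(
            f"incomparable fingerprints: {a.kind}/{a.length} vs {b.kind}/{b.length}"
        )
    if a.length == 0:
        raise ValueError("zero-length fingerprints cannot be compared")
    union = (a.bits | b.bits).bit_count()
    if union == 0:
        return 1.0
    return (a.bits & b.bits).bit_count() / union
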