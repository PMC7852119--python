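import math
import random

import networkx as nx
import pytest

from molsetcomp import descriptors as D
from molsetcomp.molgraph import parse_smiles

from conftest import random_carbon_smiles, shuffled_spelling


def to_networkx(g):
    G = nx.Graph()
    G.add_nodes_from(range(g.n_atoms))
    G.add_edges_from((b.a1, b.a2) for b in g.bonds)
    return G


def count_simple_paths(G, length):
    """Brute-force count of simple paths with exactly `length` edges."""
    total = 0
    for src in G.nodes:
        stack = [(src, {src})]
        while stack:
            node, seen = stack.pop()
            if len(seen) == length + 1:
                total += 1
                continue
            for nbr in G.neighbors(node):
                if nbr not in seen:
                    stack.append((nbr, seen | {nbr}))
    return total // 2  # each undirected path visited from both ends


class TestAtomCounts:
    @pytest.mark.parametrize(
        "smiles,selector,expected",
        [
            ("CCC", "C", 3),
            ("CCC", "all", 3),
            ("C1CCC2(C1)CCCC2", "spiro", 1),
            ("CC(C)C", "C3SP3", 1),
            ("CC(C)C", "C1SP3", 3),
            ("C#C", "C1SP1", 2),
            ("c1ccccc1", "aromatic", 6),
            ("c1ccccc1", "C2SP2", 6),
            ("NCCS(=O)(=O)O", "S", 1),
            ("NCCS(=O)(=O)O", "N", 1),
        ],
    )
    def test_selectors(self, smiles, selector, expected):
        assert D.count_atoms(parse_smiles(smiles), selector) == expected

    def test_all_atoms_with_implicit_h(self):
        g = parse_smiles("CCO")
        assert D.count_atoms(g, "all") == 3
        assert D.count_atoms(g, "all", include_implicit_h=True) == 9

    def test_unknown_selector(self):
        with pytest.raises(ValueError):
            D.count_atoms(parse_smiles("C"), "X")


class TestBondCounts:
    @pytest.mark.parametrize(
        "smiles,selector,expected",
        [
            ("CCCC", "rotatable", 1),
            ("c1ccccc1", "aromatic", 6),
            ("c1ccccc1", "single", 0),
            ("C#C", "triple", 1),
            ("C=C", "double", 1),
            ("CC(=O)NC", "rotatable", 0),  # amide C-N excluded, others terminal
            ("CCOCC", "rotatable", 2),
        ],
    )
    def test_selectors(self, smiles, selector, expected):
        assert D.count_bonds(parse_smiles(smiles), selector) == expected

    def test_all_equals_sum_of_kinds_plus_aromatic(self):
        g = parse_smiles("CC(=O)Oc1ccccc1C(=O)O")
        total = sum(
            D.count_bonds(g, s) for s in ("single", "double", "triple", "quadruple", "aromatic")
        )
        assert D.count_bonds(g, "all") == total


class TestGroupCounts:
    @pytest.mark.parametrize(
        "smiles,selector,expected",
        [
            ("CC(=O)O", "acidic", 1),
            ("CC(=O)O", "hbd", 1),
            ("CC(=O)O", "hba", 2),
            ("c1ccncc1", "basic", 1),
            ("c1ccncc1", "rings_aromatic", 1),
            ("C1CC1", "rings_size_3", 1),
            ("C1CC1", "rings_size_4", 0),
            ("c1ccc2ccccc2c1", "rings_all", 2),
            ("C1CCCCCCCCCC1", "rings_small", 0),  # 11-ring exceeds small cutoff
            ("CCN", "basic", 1),
            ("CC(=O)N", "basic", 0),  # amide nitrogen is not basic
        ],
    )
    def test_selectors(self, smiles, selector, expected):
        assert D.count_groups(parse_smiles(smiles), selector) == expected


class TestLogPAndWeight:
    @pytest.mark.parametrize(
        "smiles,expected",
        [("c1ccccc1", 2.12), ("O", 1.35), ("CCO", 1.57)],
    )
    def test_mannhold_formula(self, smiles, expected):
        assert D.mannhold_logp(parse_smiles(smiles)) == pytest.approx(expected)

    @pytest.mark.parametrize("smiles,mw", [("C", 16.04), ("CCO", 46.07)])
    def test_molecular_weight(self, smiles, mw):
        assert D.molecular_weight(parse_smiles(smiles)) == pytest.approx(mw, abs=0.01)


class TestTopoIndices:
    @pytest.mark.parametrize("n", range(2, 11))
    def test_wiener_closed_form_on_alkanes(self, n):
        g = parse_smiles("C" * n)
        dv = D.topo_index(g, "wiener_path")
        assert dv.value == n * (n**2 - 1) / 6

    @pytest.mark.parametrize(
        "smiles,which,expected",
        [
            ("C1CCCCC1", "zagreb", 24.0),
            ("CCC", "eccentric_connectivity", 6.0),
            ("CCC", "kappa1", 3.0),
            ("CCCC", "wiener_polarity", 1.0),
            ("c1ccccc1", "petitjean", 0.0),
            ("CCCCCC", "largest_chain", 6.0),
            ("CC(C)CC", "largest_chain", 4.0),
            ("c1ccccc1CCC", "longest_aliphatic_chain", 3.0),
            ("c1ccccc1C=C", "largest_pi_system", 8.0),
            ("C", "vertex_adjacency", 0.0),
            ("CC", "vertex_adjacency", 1.0),
        ],
    )
    def test_pinned_examples(self, smiles, which, expected):
        dv = D.topo_index(parse_smiles(smiles), which)
        assert dv.defined
        assert dv.value == pytest.approx(expected)

    @pytest.mark.parametrize(
        "smiles,which",
        [("C", "petitjean"), ("O=S=O", "sp3_fraction")],
    )
    def test_undefined_cases_flagged_not_raised(self, smiles, which):
        dv = D.topo_index(parse_smiles(smiles), which)
        assert not dv.defined and math.isnan(dv.value)

    def test_sp3_fraction(self):
        assert D.topo_index(parse_smiles("CC=C"), "sp3_fraction").value == pytest.approx(1 / 3)

    def test_indices_match_graph_oracles_on_random_molecules(self):
        rng = random.Random(42)
        for _ in range(120):
            g = parse_smiles(random_carbon_smiles(rng))
            G = to_networkx(g)
            sp = dict(nx.all_pairs_shortest_path_length(G))
            n = g.n_atoms
            wiener = sum(sp[i][j] for i in range(n) for j in range(i + 1, n))
            polarity = sum(
                1 for i in range(n) for j in range(i + 1, n) if sp[i][j] == 3
            )
            zagreb = sum(d * d for _, d in G.degree)
            ecc = nx.eccentricity(G)
            ecc_conn = sum(G.degree(i) * ecc[i] for i in range(n))
            assert D.topo_index(g, "wiener_path").value == wiener
            assert D.topo_index(g, "wiener_polarity").value == polarity
            assert D.topo_index(g, "zagreb").value == zagreb
            assert D.topo_index(g, "eccentric_connectivity").value == ecc_conn
            p1, p2, p3 = (count_simple_paths(G, k) for k in (1, 2, 3))
            for which, expected in [
                ("kappa1", n * (n - 1) ** 2 / p1**2 if p1 else None),
                ("kappa2", (n - 1) * (n - 2) ** 2 / p2**2 if p2 else None),
                (
                    "kappa3",
                    (
                        ((n - 1) * (n - 3) ** 2 if n % 2 else (n - 3) * (n - 2) ** 2)
                        / p3**2
                        if p3
                        else None
                    ),
                ),
            ]:
                dv = D.topo_index(g, which)
                if expected is None:
                    assert not dv.defined
                else:
                    assert dv.value == pytest.approx(expected)

    def test_largest_chain_matches_longest_path_oracle_on_trees(self):
        rng = random.Random(5)
        for _ in range(60):
            g = parse_smiles(random_carbon_smiles(rng, extra_edges=0))
            G = to_networkx(g)
            # in a tree the longest simple path is the diameter path
            sp = dict(nx.all_pairs_shortest_path_length(G))
            longest = max(sp[i][j] for i in sp for j in sp[i]) + 1
            assert D.topo_index(g, "largest_chain").value == longest

    def test_zagreb_lower_bound(self):
        rng = random.Random(9)
        for _ in range(30):
            g = parse_smiles(random_carbon_smiles(rng))
            assert D.topo_index(g, "zagreb").value >= 2 * g.n_bonds


class TestEquality:
    @pytest.mark.parametrize(
        "a,b,expected",
        [("CCO", "OCC", 1.0), ("CCO", "CCN", 0.0), ("c1ccccc1", "C1=CC=CC=C1", 1.0)],
    )
    def test_pairs(self, a, b, expected):
        assert D.equality(parse_smiles(a), parse_smiles(b)) == expected


class TestRegistry:
    def test_counts_are_nonnegative_integers(self):
        g = parse_smiles("CC(=O)Oc1ccccc1C(=O)O")
        for name, spec in D.DESCRIPTOR_SPECS.items():
            if spec.category.endswith("_count") and spec.arity == "single_molecule":
                dv = D.compute(g, name)
                assert dv.value >= 0 and dv.value == int(dv.value)

    def test_unknown_name_lists_candidates(self):
        with pytest.raises(KeyError, match="mannhold_logp"):
            D.compute(parse_smiles("C"), "nope")

    def test_every_descriptor_permutation_invariant(self):
        rng = random.Random(17)
        for smiles in ["CC(=O)Oc1ccccc1C(=O)O", "CN1CCCC1c1cccnc1"]:
            ref = {n: D.compute(parse_smiles(smiles), n) for n in D.list_descriptors()}
            alt = parse_smiles(shuffled_spelling(smiles, rng))
            for name, dv in ref.items():
                other = D.compute(alt, name)
                assert other.defined == dv.defined
                if dv.defined:
                    assert other.value == pytest.approx(dv.value), name
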