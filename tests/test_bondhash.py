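"""Bond-environment hashing: definitions, symmetry, and orbit soundness."""
import itertools

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bondbreak import atom_hash, bond_hash, parse_molecule, rn_atom_hash, unique_bonds
from bondbreak.bondhash import classify_bonds, shell_atom_hash, unique_bonds_across
from bondbreak.structures import MoleculeRecord


def relabel(record: MoleculeRecord, perm) -> MoleculeRecord:
    """Apply an atom permutation to a record (perm[i] = new index of atom i)."""
    inv = sorted(range(len(perm)), key=lambda i: perm[i])
    bonds = []
    for a, b, order, ar in record.bonds:
        x, y = perm[a], perm[b]
        x, y = (x, y) if x < y else (y, x)
        bonds.append((x, y, order, ar))
    return MoleculeRecord(
        identifier=record.identifier,
        smiles=record.smiles,
        elements=tuple(record.elements[i] for i in inv),
        bonds=tuple(sorted(bonds)),
        explicit_h_counts=tuple(record.explicit_h_counts[i] for i in inv),
        valences=tuple(record.valences[i] for i in inv),
        formal_charges=tuple(record.formal_charges[i] for i in inv),
    )


class TestAtomHash:
    def test_methane_carbon(self, methane):
        assert atom_hash(methane, 0) == (6, 4, 4, 4, 0)

    def test_methane_hydrogen(self, methane):
        assert atom_hash(methane, 1) == (1, 0, 1, 1, 0)

    def test_benzene_carbon_aromatic_flag(self):
        benzene = parse_molecule("c1ccccc1", "benzene")
        carbons = [i for i, e in enumerate(benzene.elements) if e == "C"]
        assert all(atom_hash(benzene, i)[4] == 1 for i in carbons)

    def test_invalid_index_raises(self, methane):
        with pytest.raises(IndexError):
            atom_hash(methane, 99)


class TestRnAtomHash:
    def test_radius_zero_equals_atom_hash(self, ethane):
        for i in range(ethane.n_atoms):
            assert rn_atom_hash(ethane, i, 0) == atom_hash(ethane, i)

    def test_methane_carbon_radius_one(self, methane):
        assert rn_atom_hash(methane, 0, 1) == (10, 4, 8, 8, 0)

    def test_large_radius_equals_whole_molecule_sum(self):
        # propane's central carbon sees the whole molecule within 3 bonds
        propane = parse_molecule("CCC", "propane")
        center = 1
        brute = tuple(
            sum(atom_hash(propane, i)[k] for i in range(propane.n_atoms))
            for k in range(5)
        )
        assert rn_atom_hash(propane, center, 3) == brute

    def test_shell_hash_sums_to_rn_hash(self, ethane):
        for i in range(ethane.n_atoms):
            shells = shell_atom_hash(ethane, i, 3)
            collapsed = tuple(sum(s[k] for s in shells) for k in range(5))
            assert collapsed == rn_atom_hash(ethane, i, 3)


class TestBondHash:
    def test_methane_ch_bonds_identical(self, methane):
        hashes = {bond_hash(methane, pair) for pair in methane.bond_pairs}
        assert len(hashes) == 1

    def test_ethane_cc_differs_from_ch(self, ethane):
        cc = next(p for p in ethane.bond_pairs
                  if ethane.elements[p[0]] == ethane.elements[p[1]] == "C")
        ch = next(p for p in ethane.bond_pairs if p != cc)
        assert bond_hash(ethane, cc) != bond_hash(ethane, ch)

    def test_symmetric_in_bond_atoms(self, ethane):
        for a, b in ethane.bond_pairs:
            assert bond_hash(ethane, (a, b)) == bond_hash(ethane, (b, a))

    def test_nonbonded_pair_raises(self, ethane):
        with pytest.raises(ValueError, match="not bonded"):
            bond_hash(ethane, (2, 3))  # two hydrogens

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_relabeling_invariance(self, seed):
        """The multiset of bond hashes is unchanged by atom relabeling."""
        import numpy as np

        rec = parse_molecule("CC(N)O", "aminoethanol")
        rng = np.random.default_rng(seed)
        perm = list(rng.permutation(rec.n_atoms))
        shuffled = relabel(rec, perm)
        original = sorted(bond_hash(rec, p) for p in rec.bond_pairs)
        relabeled = sorted(bond_hash(shuffled, p) for p in shuffled.bond_pairs)
        assert original == relabeled


def automorphism_bond_orbits(record: MoleculeRecord):
    """Oracle: partition bonds into orbits of the colored-graph automorphisms."""
    g = nx.Graph()
    for i, el in enumerate(record.elements):
        g.add_node(i, element=el)
    for a, b, order, _ar in record.bonds:
        g.add_edge(a, b, order=order)
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        g, g,
        node_match=lambda x, y: x["element"] == y["element"],
        edge_match=lambda x, y: x["order"] == y["order"],
    )
    bonds = [tuple(sorted(p)) for p in record.bond_pairs]
    parent = {b: b for b in bonds}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for iso in matcher.isomorphisms_iter():
        for a, b in bonds:
            image = tuple(sorted((iso[a], iso[b])))
            ra, rb = find((a, b)), find(image)
            if ra != rb:
                parent[ra] = rb
    return {find(b) for b in bonds}


class TestUniqueBonds:
    def test_methane_single_class_of_four(self, methane):
        classes = classify_bonds(methane)
        assert len(classes) == 1
        assert len(next(iter(classes.values()))) == 4

    def test_ethane_two_classes(self, ethane):
        assert len(unique_bonds(ethane)) == 2

    @pytest.mark.parametrize("smiles", ["CC(C)(C)CC", "CCC", "CC(N)O", "c1ccccc1"])
    def test_class_count_matches_automorphism_orbits(self, smiles):
        rec = parse_molecule(smiles, smiles)
        orbits = automorphism_bond_orbits(rec)
        assert len(unique_bonds(rec)) == len(orbits)

    @pytest.mark.parametrize("smiles", ["CC(C)(C)CC", "CC(N)O", "CCO"])
    def test_orbit_equivalent_bonds_always_share_hash(self, smiles):
        # soundness (forward direction only): same orbit => same hash
        rec = parse_molecule(smiles, smiles)
        g = nx.Graph()
        for i, el in enumerate(rec.elements):
            g.add_node(i, element=el)
        for a, b, order, _ar in rec.bonds:
            g.add_edge(a, b, order=order)
        matcher = nx.algorithms.isomorphism.GraphMatcher(
            g, g,
            node_match=lambda x, y: x["element"] == y["element"],
            edge_match=lambda x, y: x["order"] == y["order"],
        )
        for iso in itertools.islice(matcher.isomorphisms_iter(), 50):
            for pair in rec.bond_pairs:
                image = (iso[pair[0]], iso[pair[1]])
                assert bond_hash(rec, pair) == bond_hash(rec, image)

    def test_representative_is_lexicographically_smallest(self, methane):
        classes = classify_bonds(methane)
        for key, members in classes.items():
            rep = unique_bonds(methane)[key]
            assert rep == min(members)

    def test_cross_molecule_dedup_merges_shared_environments(self, methane, ethane):
        # methane's C-H class is distinct from ethane's, but dedup across a
        # doubled input collapses exact duplicates
        twice = unique_bonds_across([methane, methane])
        once = unique_bonds_across([methane])
        assert len(twice) == len(once) == 1
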