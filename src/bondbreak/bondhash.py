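"""Bond-environment hashing and chemically-equivalent-bond deduplication.

Each atom gets a 5-integer descriptor (atomic number, bonded hydrogens,
neighbor count, total valence, aromatic flag).  The radius-``R`` atom hash is
the component-wise sum of these descriptors over all atoms within ``R`` bonds
(breadth-first over the bond graph, atom included).  A bond's hash is the sum
of the two radius-3 atom hashes of its endpoints — an order-independent,
relabeling-invariant key, conceptually a bond-centred cousin of a Morgan
fingerprint.  Bonds sharing a hash are treated as chemically equivalent, and
the stretching workflow runs once per equivalence class.

The hash is deliberately weaker than full graph canonical labeling: bonds in
the same automorphism orbit always collide, but distinct orbits may also
collide.  That is acceptable — the goal is removing redundant sampling work,
not exact symmetry detection.
"""
from __future__ import annotations

from collections import deque
from typing import Dict, List, Sequence, Tuple

from .structures import ATOMIC_NUMBERS, Bond, MoleculeRecord

AtomHash = Tuple[int, int, int, int, int]
#: Bond key: per-shell sums of the two endpoint descriptors, flattened.
BondHashKey = Tuple[int, ...]

DEFAULT_RADIUS = 3


def atom_hash(record: MoleculeRecord, atom_index: int) -> AtomHash:
    """5-integer atomic descriptor for one atom.

    Components: atomic number, number of bonded hydrogens, number of bonded
    neighbors, total valence, aromatic indicator (0/1).
    """
    if not (0 <= atom_index < record.n_atoms):
        raise IndexError(
            f"atom index {atom_index} out of range for {record.n_atoms} atoms"
        )
    aromatic = 0
    for a, b, _order, ar in record.bonds:
        if ar and (a == atom_index or b == atom_index):
            aromatic = 1
            break
    return (
        ATOMIC_NUMBERS[record.elements[atom_index]],
        record.explicit_h_counts[atom_index],
        len(record.neighbors(atom_index)),
        record.valences[atom_index],
        aromatic,
    )


def _atoms_within(record: MoleculeRecord, atom_index: int, radius: int) -> List[int]:
    """Closed radius-neighborhood by BFS over the bond graph."""
    seen = {atom_index}
    frontier = deque([(atom_index, 0)])
    while frontier:
        node, d = frontier.popleft()
        if d == radius:
            continue
        for nb in record.neighbors(node):
            if nb not in seen:
                seen.add(nb)
                frontier.append((nb, d + 1))
    return sorted(seen)


def rn_atom_hash(record: MoleculeRecord, atom_index: int, radius: int = DEFAULT_RADIUS) -> AtomHash:
    """Component-wise sum of atom hashes over the closed radius neighborhood."""
    if radius < 0:
        raise ValueError("radius must be non-negative")
    total = [0, 0, 0, 0, 0]
    for idx in _atoms_within(record, atom_index, radius):
        h = atom_hash(record, idx)
        for k in range(5):
            total[k] += h[k]
    return tuple(total)  # type: ignore[return-value]


def shell_atom_hash(
    record: MoleculeRecord, atom_index: int, radius: int = DEFAULT_RADIUS
) -> Tuple[AtomHash, ...]:
    """Shell-resolved neighborhood descriptor: one summed 5-vector per shell.

    Entry ``d`` is the component-wise sum of atom hashes over atoms at
    topological distance exactly ``d``; summing the tuple reproduces
    :func:`rn_atom_hash`.  Keeping shells separate prevents the bond key
    from degenerating on small molecules, where every atom's collapsed
    radius-3 sum equals the whole-molecule total (e.g. ethane, whose C–C
    and C–H bonds must land in different classes).
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    shells = [[0, 0, 0, 0, 0] for _ in range(radius + 1)]
    seen = {atom_index: 0}
    frontier = deque([(atom_index, 0)])
    while frontier:
        node, d = frontier.popleft()
        h = atom_hash(record, node)
        for k in range(5):
            shells[d][k] += h[k]
        if d == radius:
            continue
        for nb in record.neighbors(node):
            if nb not in seen:
                seen[nb] = d + 1
                frontier.append((nb, d + 1))
    return tuple(tuple(s) for s in shells)  # type: ignore[return-value]


def bond_hash(record: MoleculeRecord, bond: Bond, radius: int = DEFAULT_RADIUS) -> BondHashKey:
    """Environment hash of a bond: shell-wise sum of the two endpoint hashes.

    The two endpoints' shell-resolved radius-3 descriptors are added
    component-wise within each shell and the result flattened into one
    integer tuple.  The key is symmetric in the two atoms and invariant
    under atom relabeling.  Component values are never collapsed into a
    scalar (and shells are kept separate), so distinct environments cannot
    alias through accidental sums; bonds related by a graph automorphism
    still always collide, which is the equivalence the workflow needs.
    """
    a, b = bond
    if not record.has_bond(a, b):
        raise ValueError(f"atoms ({a},{b}) are not bonded in {record.identifier!r}")
    ha = shell_atom_hash(record, a, radius)
    hb = shell_atom_hash(record, b, radius)
    key: List[int] = []
    for sa, sb in zip(ha, hb):
        key.extend(x + y for x, y in zip(sa, sb))
    return tuple(key)


def classify_bonds(
    record: MoleculeRecord, radius: int = DEFAULT_RADIUS
) -> Dict[BondHashKey, List[Bond]]:
    """Group all bonds of a molecule by their hash."""
    classes: Dict[BondHashKey, List[Bond]] = {}
    for pair in record.bond_pairs:
        classes.setdefault(bond_hash(record, pair, radius), []).append(pair)
    for members in classes.values():
        members.sort()
    return classes


def unique_bonds(record: MoleculeRecord, radius: int = DEFAULT_RADIUS) -> Dict[BondHashKey, Bond]:
    """One representative bond per distinct hash.

    The representative is the lexicographically smallest normalized ``(a, b)``
    pair in its class, making the output deterministic.
    """
    return {key: members[0] for key, members in classify_bonds(record, radius).items()}


def unique_bonds_across(
    records: Sequence[MoleculeRecord], radius: int = DEFAULT_RADIUS
) -> Dict[BondHashKey, Tuple[str, Bond]]:
    """Deduplicate bonds across a whole molecule set (cross-molecule mode).

    Returns one ``(molecule identifier, bond)`` representative per hash,
    chosen from the first molecule (in input order) containing the class and
    the lexicographically smallest bond within it.
    """
    out: Dict[BondHashKey, Tuple[str, Bond]] = {}
    for record in records:
        for key, rep in unique_bonds(record, radius).items():
            out.setdefault(key, (record.identifier, rep))
    return out
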