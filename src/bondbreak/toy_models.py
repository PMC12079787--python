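"""Analytic toy calculator and mock orbital spectra for exercising the workflow.

The real workflow labels conformers with finite-temperature DFT; that is far
outside desk scale, so this module provides two deliberately simple stand-ins
that satisfy the calculator contract exactly:

* :class:`ToyForceField` — a smooth molecular-mechanics-style potential
  (harmonic bonds and angles plus an exponential repulsion between atoms at
  graph distance >= 3) with analytic forces.  It is non-reactive by design:
  the bond topology is frozen at construction, so rearrangement chemistry is
  out of its scope.  Parameters are tuned so equilibrium bond lengths sit
  close to distance-geometry-embedded lengths, keeping the constraint forces
  modest at the first elongation step.

* :class:`ToySpectrumModel` — a mock spin-orbital spectrum whose HOMO–LUMO
  gap decays exponentially as a designated reference bond stretches,
  emulating homolytic biradical formation: at large stretch the four
  frontier spin levels collapse onto the Fermi energy and share two
  electrons, driving N_FOD toward 2.

Both are fixtures with physically sensible *shapes*, not quantitative
chemistry.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Dict, Optional, Tuple

import numpy as np
from rdkit import Chem

from .structures import (
    Bond,
    CalculationFailed,
    CalculatorContract,
    EvalResult,
    Geometry,
    MoleculeRecord,
    VALENCE_ELECTRONS,
)
from . import chem_prep

# Equilibrium lengths (Å) for single bonds between sorted element pairs.
BOND_R0 = {
    ("C", "H"): 1.09, ("C", "C"): 1.53, ("C", "N"): 1.46, ("C", "O"): 1.42,
    ("H", "N"): 1.01, ("H", "O"): 0.96, ("H", "H"): 0.74,
    ("N", "N"): 1.44, ("N", "O"): 1.42, ("O", "O"): 1.46,
}
# Per-unit-order contraction of r0 for multiple/aromatic bonds.
ORDER_CONTRACTION = 0.13

# Bond stiffness (eV/Å²): softer for X–H so a 0.5 fs velocity-Verlet step
# resolves the fastest oscillation with comfortably bounded energy error.
K_BOND_H = 15.0
K_BOND_HEAVY = 25.0
K_ANGLE = 3.0            # eV/rad²
REPULSION_A = 1.0        # eV
REPULSION_RHO = 0.4      # Å

TETRAHEDRAL = math.acos(-1.0 / 3.0)  # exact tetrahedral angle, ~109.4712°
TRIGONAL = math.radians(120.0)

# Fixed per-element partial charges (e) for the toy dipole; shifted to
# neutrality per molecule before use.
PARTIAL_CHARGES = {"H": 0.06, "C": -0.02, "N": -0.30, "O": -0.40}


def _pair_key(e1: str, e2: str) -> Tuple[str, str]:
    return (e1, e2) if e1 <= e2 else (e2, e1)


def bond_rest_length(e1: str, e2: str, order: float = 1.0) -> float:
    r0 = BOND_R0.get(_pair_key(e1, e2), 1.5)
    return r0 * (1.0 - ORDER_CONTRACTION * max(0.0, order - 1.0))


@dataclass
class ToySpectrumModel:
    """Mock spin-orbital spectrum with a gap that closes on bond stretch.

    gap(r) = g0 * exp(-(r - r0) / w): continuous and strictly decreasing in
    the reference-bond length r.  The level ladder holds, from bottom to
    top: (n_electrons - 2) filled core levels, two degenerate HOMO levels at
    -gap/2, two degenerate LUMO levels at +gap/2, and four virtual levels.
    Energies in eV.
    """

    n_electrons: int
    r0: float
    g0: float = 8.0     # eV, gap at the rest length
    w: float = 0.3      # Å, gap decay length
    core_top: float = -7.5
    core_spacing: float = 1.5
    virtual_bottom: float = 7.5
    virtual_spacing: float = 1.5
    n_virtual_extra: int = 4

    def gap(self, r: float) -> float:
        return self.g0 * math.exp(-(r - self.r0) / self.w)

    def levels(self, r: float) -> np.ndarray:
        g = self.gap(r)
        n_core = self.n_electrons - 2
        core = self.core_top - self.core_spacing * np.arange(n_core)[::-1]
        frontier = np.array([-g / 2.0, -g / 2.0, g / 2.0, g / 2.0])
        virt = self.virtual_bottom + self.virtual_spacing * np.arange(self.n_virtual_extra)
        return np.concatenate([core, frontier, virt])


class ToyForceField(CalculatorContract):
    """Smooth analytic force field over a fixed bond topology.

    Energy terms:

    * bonds: ``1/2 k (r - r0)^2`` per bonded pair,
    * angles: ``1/2 k_a (theta - theta0)^2`` for every bonded triple, with
      ``theta0`` = 120° at unsaturated centers and 109.47° otherwise,
    * repulsion: ``A exp(-r / rho)`` between pairs at graph distance >= 3.

    At a geometry with every bond at its rest length and every angle at its
    rest angle (and no >=3-separated pairs, e.g. methane) the energy and all
    forces are exactly zero.  Forces are the analytic negative gradient.

    Parameters
    ----------
    record : MoleculeRecord
        Connectivity defining the (frozen) term list.
    reference_bond : (int, int), optional
        Bond whose length drives the mock orbital spectrum.  When set, the
        calculator reports orbital energies and an electron count.
    fail_predicate : callable, optional
        Failure injector for exercising the discard path: when it returns
        true for a geometry, :class:`CalculationFailed` is raised.
    """

    provides_dipole = True

    def __init__(
        self,
        record: MoleculeRecord,
        reference_bond: Optional[Bond] = None,
        fail_predicate: Optional[Callable[[Geometry], bool]] = None,
    ) -> None:
        self.record = record
        self.fail_predicate = fail_predicate
        n = record.n_atoms
        self._bond_terms = []
        for a, b, order, aromatic in record.bonds:
            eff_order = 1.5 if aromatic else order
            r0 = bond_rest_length(record.elements[a], record.elements[b], eff_order)
            k = K_BOND_H if "H" in (record.elements[a], record.elements[b]) else K_BOND_HEAVY
            self._bond_terms.append((a, b, k, r0))
        self._angle_terms = []
        unsaturated = set()
        for a, b, order, aromatic in record.bonds:
            if aromatic or order > 1.0:
                unsaturated.update((a, b))
        for j in range(n):
            nbrs = record.neighbors(j)
            theta0 = TRIGONAL if j in unsaturated else TETRAHEDRAL
            for x in range(len(nbrs)):
                for y in range(x + 1, len(nbrs)):
                    self._angle_terms.append((nbrs[x], j, nbrs[y], K_ANGLE, theta0))
        # graph distances for the repulsion pair list
        dist = _all_pairs_bond_distance(record)
        self._rep_pairs = [
            (i, j)
            for i in range(n)
            for j in range(i + 1, n)
            if dist[i][j] >= 3
        ]
        q = np.array([PARTIAL_CHARGES.get(e, 0.0) for e in record.elements])
        self._charges = q - q.mean() if n else q

        self.spectrum_model: Optional[ToySpectrumModel] = None
        if reference_bond is not None:
            a, b = reference_bond
            if not record.has_bond(a, b):
                raise ValueError(f"reference bond ({a},{b}) not in {record.identifier!r}")
            order = next(o for x, y, o, _ar in record.bonds if (x, y) == tuple(sorted((a, b))))
            n_elec = sum(VALENCE_ELECTRONS[e] for e in record.elements)
            self.reference_bond: Optional[Bond] = (min(a, b), max(a, b))
            self.spectrum_model = ToySpectrumModel(
                n_electrons=n_elec,
                r0=bond_rest_length(record.elements[a], record.elements[b], order),
            )
            self.provides_orbital_energies = True
        else:
            self.reference_bond = None

    # -- energetics -----------------------------------------------------

    def energy_and_gradient(self, coords: np.ndarray) -> Tuple[float, np.ndarray]:
        coords = np.asarray(coords, dtype=float)
        energy = 0.0
        grad = np.zeros_like(coords)
        for a, b, k, r0 in self._bond_terms:
            rij = coords[a] - coords[b]
            d = np.linalg.norm(rij)
            if d < 1e-12:
                raise CalculationFailed(f"coincident bonded atoms {a},{b}")
            energy += 0.5 * k * (d - r0) ** 2
            g = k * (d - r0) * rij / d
            grad[a] += g
            grad[b] -= g
        for i, j, k_, ka, theta0 in self._angle_terms:
            u = coords[i] - coords[j]
            v = coords[k_] - coords[j]
            nu, nv = np.linalg.norm(u), np.linalg.norm(v)
            if nu < 1e-12 or nv < 1e-12:
                continue
            c = float(np.dot(u, v) / (nu * nv))
            c = max(-1.0, min(1.0, c))
            theta = math.acos(c)
            s = math.sqrt(max(1e-12, 1.0 - c * c))
            dE = ka * (theta - theta0)
            energy += 0.5 * ka * (theta - theta0) ** 2
            # dtheta/dx = -dcos/dx / sin(theta)
            dcos_di = v / (nu * nv) - c * u / (nu * nu)
            dcos_dk = u / (nu * nv) - c * v / (nv * nv)
            gi = dE * (-dcos_di / s)
            gk = dE * (-dcos_dk / s)
            grad[i] += gi
            grad[k_] += gk
            grad[j] -= gi + gk
        for i, j in self._rep_pairs:
            rij = coords[i] - coords[j]
            d = np.linalg.norm(rij)
            if d < 1e-12:
                raise CalculationFailed(f"coincident nonbonded atoms {i},{j}")
            e = REPULSION_A * math.exp(-d / REPULSION_RHO)
            energy += e
            g = -(e / REPULSION_RHO) * rij / d
            grad[i] += g
            grad[j] -= g
        return float(energy), grad

    def evaluate(self, geometry: Geometry) -> EvalResult:
        if geometry.n_atoms != self.record.n_atoms:
            raise ValueError("geometry does not match the calculator's molecule")
        if self.fail_predicate is not None and self.fail_predicate(geometry):
            raise CalculationFailed(
                f"injected evaluation failure for {geometry.provenance.molecule_id}"
            )
        energy, grad = self.energy_and_gradient(geometry.coordinates)
        dipole = self._charges @ geometry.coordinates
        orbital_energies = None
        n_electrons = None
        if self.spectrum_model is not None:
            a, b = self.reference_bond  # type: ignore[misc]
            orbital_energies = self.spectrum_model.levels(geometry.distance(a, b))
            n_electrons = self.spectrum_model.n_electrons
        return EvalResult(
            energy=energy,
            forces=-grad,
            dipole=dipole,
            orbital_energies=orbital_energies,
            n_electrons=n_electrons,
        )


def _all_pairs_bond_distance(record: MoleculeRecord):
    """Topological distances by repeated BFS (molecules here are tiny)."""
    from collections import deque

    n = record.n_atoms
    dist = [[10 ** 9] * n for _ in range(n)]
    for src in range(n):
        dist[src][src] = 0
        q = deque([src])
        while q:
            node = q.popleft()
            for nb in record.neighbors(node):
                if dist[src][nb] > dist[src][node] + 1:
                    dist[src][nb] = dist[src][node] + 1
                    q.append(nb)
    return dist


# -- fixture suite -------------------------------------------------------

NAMED_SPECIES = {
    "methane": "C",
    "ethane": "CC",
    "2,2-dimethylbutane": "CC(C)(C)CC",
    "1-aminoethanol": "CC(N)O",
    "ethanamine": "CCN",
    "ethanimine": "CC=N",
    "benzene": "c1ccccc1",
}

_MAX_DEGREE = {"C": 4, "N": 3, "O": 2}


@dataclass
class FixtureBundle:
    """Deterministic set of molecule records plus embedded geometries."""

    records: Dict[str, MoleculeRecord]
    geometries: Dict[str, Geometry]


def _random_smiles(rng: np.random.Generator) -> str:
    """Random neutral H/C/N/O molecule with 2–7 heavy atoms (single-bond tree)."""
    n_heavy = int(rng.integers(2, 8))
    symbols = [str(rng.choice(["C", "C", "C", "N", "O"])) for _ in range(n_heavy)]
    mol = Chem.RWMol()
    for s in symbols:
        mol.AddAtom(Chem.Atom(s))
    degree = [0] * n_heavy
    for i in range(1, n_heavy):
        candidates = [
            j for j in range(i) if degree[j] < _MAX_DEGREE[symbols[j]]
        ]
        j = int(rng.choice(candidates)) if candidates else 0
        mol.AddBond(i, j, Chem.BondType.SINGLE)
        degree[i] += 1
        degree[j] += 1
    m = mol.GetMol()
    Chem.SanitizeMol(m)
    return Chem.MolToSmiles(m)


def make_fixture_suite(seed: int = 0, n_random: int = 5) -> FixtureBundle:
    """Deterministic fixture set: the named worked species plus random ones.

    All molecules pass the default H/C/N/O, <=7 heavy-atom filter, and every
    record comes with a seeded embedded geometry.
    """
    rng = np.random.default_rng(seed)
    records: Dict[str, MoleculeRecord] = {}
    for name, smi in NAMED_SPECIES.items():
        records[name] = chem_prep.parse_molecule(smi, name)
    for i in range(n_random):
        smi = _random_smiles(rng)
        name = f"random-{i}"
        records[name] = chem_prep.parse_molecule(smi, name)
    geometries = {
        name: chem_prep.embed_geometry(rec, seed=seed) for name, rec in records.items()
    }
    return FixtureBundle(records=records, geometries=geometries)
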