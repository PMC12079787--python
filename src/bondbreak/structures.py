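"""Shared domain containers: molecules, geometries, provenance.

A :class:`MoleculeRecord` is a connectivity-level description of a molecule
(elements, bonds, valences) decoupled from any cheminformatics toolkit, so the
hashing and sampling layers never touch RDKit objects directly.  A
:class:`Geometry` is a single Cartesian conformer tagged with enough
provenance (molecule, bond, elongation step, opt/MD origin) to trace every
sampled frame back to the workflow step that produced it.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np

#: Atomic numbers for the supported element alphabet.
ATOMIC_NUMBERS = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18, "Br": 35, "I": 53,
}

#: Atomic masses in amu (unified atomic mass units), used by the MD integrator.
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "S": 32.06, "Cl": 35.45,
}

#: Valence-electron counts for the toy spectrum model.
VALENCE_ELECTRONS = {"H": 1, "C": 4, "N": 5, "O": 6}


class ParseError(ValueError):
    """A SMILES string could not be parsed or sanitized."""


class EmbedError(RuntimeError):
    """3D embedding failed for a molecule."""


class CalculationFailed(RuntimeError):
    """A calculator evaluation did not converge / could not be completed.

    The sampling layer catches this and marks the affected geometry as
    discarded rather than aborting the run, mirroring the discard-on-failure
    policy applied to non-converged electronic-structure labels.
    """


Bond = Tuple[int, int]


@dataclass(frozen=True)
class MoleculeRecord:
    """Connectivity-level molecule description with explicit hydrogens.

    Attributes
    ----------
    identifier : str
        User-supplied name for error messages and provenance.
    smiles : str
        The input SMILES the record was built from.
    elements : tuple of str
        Element symbol per atom.
    bonds : tuple of (int, int, float, bool)
        Normalized bonds ``(a, b, order, aromatic)`` with ``a < b``.
    explicit_h_counts : tuple of int
        Number of hydrogen neighbors per atom.
    valences : tuple of int
        Total valence (including hydrogens) per atom.
    formal_charges : tuple of int
        Formal charge per atom.
    """

    identifier: str
    smiles: str
    elements: Tuple[str, ...]
    bonds: Tuple[Tuple[int, int, float, bool], ...]
    explicit_h_counts: Tuple[int, ...]
    valences: Tuple[int, ...]
    formal_charges: Tuple[int, ...]

    def __post_init__(self) -> None:
        n = len(self.elements)
        for a, b, _order, aromatic in self.bonds:
            if not (0 <= a < b < n):
                raise ValueError(
                    f"{self.identifier}: bond ({a},{b}) has invalid or "
                    f"unnormalized indices for {n} atoms"
                )
            if not isinstance(aromatic, (bool, np.bool_)):
                raise ValueError(f"{self.identifier}: aromatic flag must be boolean")
        for sym in self.elements:
            if sym not in ATOMIC_NUMBERS:
                raise ValueError(f"{self.identifier}: unknown element {sym!r}")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def bond_pairs(self) -> Tuple[Bond, ...]:
        """Bonds as bare ``(a, b)`` index pairs."""
        return tuple((a, b) for a, b, _o, _ar in self.bonds)

    def neighbors(self, atom_index: int) -> Tuple[int, ...]:
        """Indices bonded to ``atom_index``."""
        out = []
        for a, b, _o, _ar in self.bonds:
            if a == atom_index:
                out.append(b)
            elif b == atom_index:
                out.append(a)
        return tuple(sorted(out))

    def has_bond(self, a: int, b: int) -> bool:
        a, b = (a, b) if a < b else (b, a)
        return any(x == a and y == b for x, y, _o, _ar in self.bonds)

    def heavy_atom_count(self) -> int:
        return sum(1 for e in self.elements if e != "H")


@dataclass(frozen=True)
class Provenance:
    """Workflow origin of a sampled conformer."""

    molecule_id: str
    bond_id: str            # "a-b" of the stretched bond; "" before sampling
    step_index: int         # elongation step (−1 for the embedded equilibrium)
    origin: str             # "embed" | "opt" | "md"
    snapshot_index: int = 0

    def __post_init__(self) -> None:
        if self.origin not in ("embed", "opt", "md"):
            raise ValueError(f"unknown origin tag {self.origin!r}")


@dataclass
class Geometry:
    """A Cartesian conformer (coordinates in Å) with provenance tags."""

    elements: Tuple[str, ...]
    coordinates: np.ndarray
    provenance: Provenance

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (len(self.elements), 3):
            raise ValueError(
                f"coordinate shape {self.coordinates.shape} does not match "
                f"{len(self.elements)} atoms"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def distance(self, a: int, b: int) -> float:
        return float(np.linalg.norm(self.coordinates[a] - self.coordinates[b]))

    def with_coordinates(self, coords: np.ndarray, **prov_updates) -> "Geometry":
        """Copy with new coordinates and optionally updated provenance."""
        prov = replace(self.provenance, **prov_updates) if prov_updates else self.provenance
        return Geometry(self.elements, np.array(coords, dtype=float), prov)

    def copy(self) -> "Geometry":
        return Geometry(self.elements, self.coordinates.copy(), self.provenance)


@dataclass
class EvalResult:
    """Output of one calculator evaluation."""

    energy: float
    forces: np.ndarray
    dipole: Optional[np.ndarray] = None
    orbital_energies: Optional[np.ndarray] = None
    n_electrons: Optional[int] = None


class CalculatorContract:
    """Abstract energy/force provider the sampling loop is written against.

    Implementations declare capabilities and must raise
    :class:`CalculationFailed` on non-convergence rather than returning NaNs.
    Forces are the negative Cartesian gradient of the energy in the declared
    unit system (default eV and eV/Å).
    """

    provides_energy: bool = True
    provides_forces: bool = True
    provides_dipole: bool = False
    provides_orbital_energies: bool = False
    energy_unit: str = "eV"
    length_unit: str = "Angstrom"

    def evaluate(self, geometry: Geometry) -> EvalResult:  # pragma: no cover
        raise NotImplementedError
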