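"""Finite-temperature occupation analysis (Fermi smearing).

Forced homolytic bond stretching produces biradical-like species whose
frontier orbitals become degenerate.  Rather than attempting open-shell
treatments geometry-by-geometry, every conformer is treated as closed shell
with fractionally occupied frontier levels: occupations follow the
Fermi–Dirac distribution at an electronic temperature ``T_el``, with the
Fermi level solved so that the occupations sum to the electron count.

The degree of open-shell / multireference character is summarized by the
fractional-orbital-density number

    N_FOD = Σ_{ε_i < E_F} (1 − f_i)  +  Σ_{ε_i ≥ E_F} f_i ,

the occupation-space reduction of the spatial FOD integral for orthonormal
orbitals.  A closed-shell gapped spectrum gives N_FOD → 0 as T_el → 0; a
homolytically dissociated bond (two degenerate frontier levels sharing two
electrons) gives N_FOD = 2.

Conventions: levels are spin orbitals (occupancy in [0, 1]); ``n_electrons``
counts electrons, not pairs; energies are in a declared unit (eV by default,
set ``kb`` accordingly for other units); temperatures in kelvin.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
from scipy.special import expit

from .structures import CalculatorContract, CalculationFailed, Geometry

#: Boltzmann constant in eV/K (energies default to eV).
KB_EV = 8.617333262e-5

#: Energy tolerance for deciding a level sits exactly at the Fermi energy.
AT_FERMI_TOL = 1e-9

#: Electron-count convergence target for the Fermi-level solve.
CHARGE_TOL = 1e-10

DEFAULT_TEMPERATURES = (0.0, 1000.0, 5000.0)


@dataclass(frozen=True)
class Spectrum:
    """Spin-orbital energy levels plus the number of electrons filling them."""

    orbital_energies: np.ndarray
    n_electrons: int

    def __post_init__(self) -> None:
        energies = np.asarray(self.orbital_energies, dtype=float)
        object.__setattr__(self, "orbital_energies", energies)
        if not np.all(np.isfinite(energies)):
            raise ValueError("orbital energies must be finite")
        if not (0 <= self.n_electrons <= energies.size):
            raise ValueError(
                f"{self.n_electrons} electrons infeasible for "
                f"{energies.size} spin-orbital levels"
            )


@dataclass
class OccupationResult:
    """Fermi level and fractional occupations at one electronic temperature."""

    fermi_energy: float
    occupations: np.ndarray
    energies: np.ndarray
    t_el: float
    n_fod: Optional[float] = None


def fermi_occupations(spectrum: Spectrum, t_el: float, kb: float = KB_EV) -> OccupationResult:
    """Solve Fermi–Dirac occupations at electronic temperature ``t_el`` (K).

    The Fermi energy is found by bisection so that the occupations sum to
    the electron count to 1e-10.  At ``t_el = 0`` the occupation is a step
    function, with levels degenerate at the Fermi energy sharing the
    remaining electrons equally.
    """
    if t_el < 0:
        raise ValueError("electronic temperature must be non-negative")
    eps = spectrum.orbital_energies
    n_elec = spectrum.n_electrons
    n_lev = eps.size

    if n_elec == 0:
        return OccupationResult(float(eps.min() - 1.0) if n_lev else 0.0,
                                np.zeros(n_lev), eps.copy(), t_el)
    if n_elec == n_lev:
        # fully filled: the Fermi level sits above every state
        return OccupationResult(float(eps.max() + 1.0), np.ones(n_lev), eps.copy(), t_el)

    if t_el == 0.0:
        e_sorted = np.sort(eps, kind="stable")
        e_homo = float(e_sorted[n_elec - 1])
        e_lumo = float(e_sorted[n_elec])
        f = np.zeros(n_lev)
        if e_lumo - e_homo > AT_FERMI_TOL:
            # gapped: Fermi level mid-gap, occupations a clean step
            e_f = 0.5 * (e_homo + e_lumo)
            f[eps < e_f] = 1.0
        else:
            # levels degenerate at the Fermi cut share the remaining electrons
            e_f = e_homo
            below = eps < e_f - AT_FERMI_TOL
            at = np.abs(eps - e_f) <= AT_FERMI_TOL
            f[below] = 1.0
            f[at] = (n_elec - int(below.sum())) / int(at.sum())
        return OccupationResult(e_f, f, eps.copy(), 0.0)

    kt = kb * t_el

    def total(mu: float) -> float:
        return float(expit((mu - eps) / kt).sum())

    lo = float(eps.min()) - 60.0 * kt
    hi = float(eps.max()) + 60.0 * kt
    # total() is monotone increasing in mu; bisect until the electron count
    # converges (interval width no longer moves the sum).
    for _ in range(500):
        mu = 0.5 * (lo + hi)
        t = total(mu)
        if abs(t - n_elec) <= CHARGE_TOL * 0.1 or hi - lo < 1e-16 * max(1.0, abs(mu)):
            break
        if t < n_elec:
            lo = mu
        else:
            hi = mu
    f = expit((mu - eps) / kt)
    if abs(f.sum() - n_elec) > CHARGE_TOL:
        raise RuntimeError(
            f"Fermi-level solve failed to conserve electrons: "
            f"sum f = {f.sum()!r}, expected {n_elec}"
        )
    return OccupationResult(float(mu), f, eps.copy(), t_el)


def n_fod(occ: OccupationResult, tol: float = AT_FERMI_TOL) -> float:
    """Occupation-sum FOD number for a solved occupation pattern.

    Levels below the Fermi energy contribute ``1 − f_i``; levels at or above
    it contribute ``f_i``.  Levels within ``tol`` of the Fermi energy count
    as "not below", which makes the degenerate biradical limit evaluate to
    exactly 2.
    """
    below = occ.energies < occ.fermi_energy - tol
    return float(np.sum(1.0 - occ.occupations[below]) + np.sum(occ.occupations[~below]))


def occupation_analysis(spectrum: Spectrum, t_el: float, kb: float = KB_EV) -> OccupationResult:
    """Occupations plus the FOD number in one call."""
    occ = fermi_occupations(spectrum, t_el, kb=kb)
    occ.n_fod = n_fod(occ)
    return occ


def recommended_t_el(a_x: float) -> float:
    """Optimal Fermi-smearing temperature (K) for a hybrid functional.

    Follows the empirical linear convention ``T_el = 5000 K + 20000 K · a_x``
    where ``a_x`` is the fraction of nonlocal Fock exchange; a pure GGA-type
    functional (``a_x = 0``) gets 5000 K.
    """
    if not 0.0 <= a_x <= 1.0:
        raise ValueError(f"Fock-exchange fraction must be in [0, 1], got {a_x}")
    return 5000.0 + 20000.0 * a_x


@dataclass
class ConformerLabel:
    """Per-conformer property labels attached to a sampled geometry."""

    energy: float
    forces: np.ndarray
    dipole: Optional[np.ndarray] = None
    n_fod_by_temperature: Dict[float, float] = field(default_factory=dict)


def label_geometry(
    geometry: Geometry,
    calc: CalculatorContract,
    temperatures: Sequence[float] = DEFAULT_TEMPERATURES,
    kb: float = KB_EV,
) -> ConformerLabel:
    """Evaluate a calculator on one geometry and build its property label.

    N_FOD is computed at every requested electronic temperature (default
    0, 1000 and 5000 K) when the calculator exposes orbital energies;
    otherwise the map is left empty with a warning.  Calculator failures
    propagate as :class:`CalculationFailed` so batch drivers can discard the
    geometry, mirroring the policy of dropping non-converged labels.
    """
    result = calc.evaluate(geometry)
    label = ConformerLabel(energy=result.energy, forces=result.forces, dipole=result.dipole)
    if result.orbital_energies is None or result.n_electrons is None:
        warnings.warn(
            "calculator provides no orbital energies; N_FOD labels skipped",
            stacklevel=2,
        )
        return label
    spectrum = Spectrum(result.orbital_energies, result.n_electrons)
    for t in temperatures:
        label.n_fod_by_temperature[float(t)] = n_fod(fermi_occupations(spectrum, t, kb=kb))
    return label


def label_geometries(
    geometries: Sequence[Geometry],
    calc: CalculatorContract,
    temperatures: Sequence[float] = DEFAULT_TEMPERATURES,
    kb: float = KB_EV,
):
    """Label a batch, discarding geometries whose evaluation fails.

    Returns ``(labels, kept_indices, discarded_indices)``.
    """
    labels, kept, discarded = [], [], []
    for i, geom in enumerate(geometries):
        try:
            labels.append(label_geometry(geom, calc, temperatures, kb=kb))
            kept.append(i)
        except CalculationFailed:
            discarded.append(i)
    return labels, kept, discarded
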