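"""Staged bond-elongation sampling: displace, relax, shake, collect.

For one selected bond the workflow walks a staged schedule of absolute
target distances (default: equilibrium length to 2x in 10 steps, then to 3x
in 5 more).  At each step the two bond atoms are displaced symmetrically
along the bond axis to the target distance, the rest of the molecule is
relaxed with the bond atoms held at fixed Cartesian positions, and a short
constrained NVT trajectory is run from the relaxed structure; a diversity
cap keeps up to ``snapshot_cap`` maximally spread MD frames per segment.
With the defaults (15 steps, 1 ps of MD dumped every 10 fs, cap 10) a bond
yields 15 optimization conformers and 150 MD conformers — 165 in total.

The optimizer is L-BFGS-B over the free-atom coordinates only, so the
constraint is exact by construction; the integrator is BAOAB Langevin
(velocity Verlet when the thermostat is disabled) with fixed atoms carrying
zero velocity and force.  Units: Å, fs, eV, amu, kelvin.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Set, Tuple, Union

import numpy as np
from scipy.optimize import minimize

from . import bondhash, chem_prep, diversity
from .structures import (
    ATOMIC_MASSES,
    Bond,
    CalculationFailed,
    CalculatorContract,
    Geometry,
    MoleculeRecord,
)

#: (eV/Å)/amu expressed in Å/fs² — converts force/mass to acceleration.
ACCEL_CONV = 9.648533212e-3
#: Boltzmann constant, eV/K.
KB_EV = 8.617333262e-5

DEFAULT_STAGES: Tuple[Tuple[float, int], ...] = ((2.0, 10), (3.0, 5))


@dataclass(frozen=True)
class ElongationSchedule:
    """Absolute bond-length targets (Å) for a staged stretching run."""

    l0: float
    targets: Tuple[float, ...]
    stage_boundaries: Tuple[int, ...]  # cumulative step counts per stage

    def stage_of(self, step_index: int) -> int:
        for s, bound in enumerate(self.stage_boundaries):
            if step_index < bound:
                return s
        raise IndexError(step_index)


def build_schedule(
    l0: float, stages: Sequence[Tuple[float, int]] = DEFAULT_STAGES
) -> ElongationSchedule:
    """Equally spaced targets within each stage of a multi-stage stretch.

    Each stage ``(multiplier, step_count)`` extends the bond from the
    previous stage's endpoint to ``multiplier * l0`` in ``step_count`` equal
    increments.  The default reaches twice the equilibrium length after step
    10 and three times after step 15, weighting sampling toward the 1–2
    bond-length range where rearrangements concentrate.
    """
    if l0 <= 0:
        raise ValueError("equilibrium bond length must be positive")
    if not stages:
        raise ValueError("at least one stage is required")
    targets: List[float] = []
    boundaries: List[int] = []
    prev_mult = 1.0
    for mult, count in stages:
        if mult <= prev_mult:
            raise ValueError(
                f"stage multipliers must be strictly increasing (got {mult} after {prev_mult})"
            )
        if count < 1:
            raise ValueError("stage step counts must be >= 1")
        start = prev_mult * l0
        end = mult * l0
        step = (end - start) / count
        targets.extend(start + step * (i + 1) for i in range(count))
        targets[-1] = end  # land stage endpoints exactly
        boundaries.append(len(targets))
        prev_mult = mult
    return ElongationSchedule(l0=l0, targets=tuple(targets), stage_boundaries=tuple(boundaries))


@dataclass
class SamplerConfig:
    """Tunable knobs of the per-bond sampling loop.

    Times are fs except ``t_md`` (ps); forces are in the calculator's unit
    system (eV/Å for the toy force field).  ``constraint_mode`` is
    ``"positions"`` (both bond atoms fully fixed, the default) or
    ``"distance"`` (only the bond length constrained).  ``continue_from``
    selects which structure seeds the next elongation step: the relaxed
    geometry (``"opt"``, deterministic default) or the final MD frame
    (``"md"``).
    """

    stages: Tuple[Tuple[float, int], ...] = DEFAULT_STAGES
    t_md: float = 1.0            # ps
    dt: float = 0.5              # fs
    t_dump: float = 10.0         # fs
    snapshot_cap: int = 10
    md_temperature: float = 300.0  # K
    thermostat: str = "langevin"   # "langevin" | "none"
    friction: float = 0.01         # fs^-1, Langevin friction
    opt_fmax: float = 0.05         # max |force| on free atoms at convergence
    opt_max_iter: int = 500
    rng_seed: int = 0
    constraint_mode: str = "positions"
    continue_from: str = "opt"

    def __post_init__(self) -> None:
        if self.t_md < 0 or self.dt <= 0 or self.t_dump <= 0:
            raise ValueError("times must be positive (t_md may be 0 to disable MD)")
        if self.t_md > 0:
            if abs(self.t_dump / self.dt - round(self.t_dump / self.dt)) > 1e-9:
                raise ValueError("dt must divide t_dump")
            n_dumps = self.t_md * 1000.0 / self.t_dump
            if abs(n_dumps - round(n_dumps)) > 1e-9:
                raise ValueError("t_dump must divide t_md")
        if self.snapshot_cap < 0:
            raise ValueError("snapshot_cap must be >= 0")
        if self.thermostat not in ("langevin", "none"):
            raise ValueError(f"unknown thermostat {self.thermostat!r}")
        if self.constraint_mode not in ("positions", "distance"):
            raise ValueError(f"unknown constraint mode {self.constraint_mode!r}")
        if self.continue_from not in ("opt", "md"):
            raise ValueError(f"continue_from must be 'opt' or 'md'")
        mults = [m for m, _c in self.stages]
        if any(b <= a for a, b in zip(mults, mults[1:])) or (mults and mults[0] <= 1.0):
            raise ValueError("stage multipliers must be strictly increasing and > 1")

    @property
    def md_steps(self) -> int:
        return int(round(self.t_md * 1000.0 / self.dt))

    @property
    def dump_interval(self) -> int:
        return int(round(self.t_dump / self.dt))


@dataclass
class StepOutcome:
    """Per-elongation-step bookkeeping."""

    step_index: int
    target: float
    stage: int
    opt_converged: bool = False
    opt_discarded: bool = False
    md_failed: bool = False
    n_md_snapshots: int = 0


@dataclass
class TrajectoryResult:
    """All conformers and bookkeeping from one bond's stretching run."""

    molecule_id: str
    bond: Bond
    schedule: ElongationSchedule
    opt_geometries: List[Geometry] = field(default_factory=list)
    md_geometries: List[Geometry] = field(default_factory=list)
    steps: List[StepOutcome] = field(default_factory=list)
    discarded_count: int = 0

    @property
    def bond_id(self) -> str:
        return f"{self.bond[0]}-{self.bond[1]}"

    @property
    def n_conformers(self) -> int:
        return len(self.opt_geometries) + len(self.md_geometries)

    def all_geometries(self) -> List[Geometry]:
        """Saved conformers in workflow order (per step: opt, then MD)."""
        by_step: Dict[int, List[Geometry]] = {}
        for g in self.opt_geometries + self.md_geometries:
            by_step.setdefault(g.provenance.step_index, []).append(g)
        out: List[Geometry] = []
        for step in sorted(by_step):
            frames = by_step[step]
            frames.sort(key=lambda g: (g.provenance.origin != "opt", g.provenance.snapshot_index))
            out.extend(frames)
        return out


def elongate(geometry: Geometry, bond: Bond, target: float) -> Geometry:
    """Move the two bond atoms apart symmetrically to ``target`` Å.

    Both atoms shift by ``(target - d)/2`` along the bond axis, preserving
    the bond midpoint; every other coordinate is copied bit-identically.
    """
    a, b = bond
    if target <= 0:
        raise ValueError("target distance must be positive")
    coords = geometry.coordinates.copy()
    rab = coords[b] - coords[a]
    d = float(np.linalg.norm(rab))
    if d < 1e-12:
        raise ValueError(f"atoms {a} and {b} are coincident; bond axis undefined")
    u = rab / d
    delta = 0.5 * (target - d)
    coords[a] -= delta * u
    coords[b] += delta * u
    return geometry.with_coordinates(coords)


@dataclass
class OptimizeOutcome:
    geometry: Geometry
    converged: bool
    discarded: bool = False


def constrained_optimize(
    geometry: Geometry,
    fixed_atoms: Set[int],
    calc: CalculatorContract,
    config: SamplerConfig,
    target_distance: Optional[float] = None,
) -> OptimizeOutcome:
    """Relax all non-fixed atoms; fixed atoms stay bit-identical.

    In ``"positions"`` mode (default) the fixed atoms are simply excluded
    from the optimization variables.  In ``"distance"`` mode only the
    distance between the two atoms in ``fixed_atoms`` is constrained (SLSQP
    equality constraint); ``target_distance`` must then be given.
    Convergence means the largest per-atom force magnitude on the free atoms
    is at most ``config.opt_fmax``.  A calculator failure mid-optimization
    flags the outcome as discarded instead of raising.
    """
    if not fixed_atoms:
        raise ValueError("fixed_atoms must be nonempty")
    n = geometry.n_atoms
    coords0 = geometry.coordinates

    if config.constraint_mode == "distance":
        return _distance_constrained_optimize(geometry, fixed_atoms, calc, config, target_distance)

    free = np.array(sorted(set(range(n)) - set(fixed_atoms)), dtype=int)
    if free.size == 0:
        return OptimizeOutcome(geometry.with_coordinates(coords0, origin="opt"), True)

    def assemble(x: np.ndarray) -> np.ndarray:
        coords = coords0.copy()
        coords[free] = x.reshape(-1, 3)
        return coords

    def fun(x: np.ndarray):
        res = calc.evaluate(geometry.with_coordinates(assemble(x)))
        return res.energy, (-res.forces[free]).ravel()

    try:
        opt = minimize(
            fun,
            coords0[free].ravel(),
            jac=True,
            method="L-BFGS-B",
            options={
                "maxiter": config.opt_max_iter,
                "gtol": config.opt_fmax / 10.0,
                "ftol": 1e-14,
            },
        )
        final_coords = assemble(opt.x)
        res = calc.evaluate(geometry.with_coordinates(final_coords))
    except CalculationFailed:
        return OptimizeOutcome(geometry.with_coordinates(coords0, origin="opt"), False, discarded=True)
    fmax = float(np.linalg.norm(res.forces[free], axis=1).max()) if free.size else 0.0
    converged = fmax <= config.opt_fmax
    return OptimizeOutcome(geometry.with_coordinates(final_coords, origin="opt"), converged)


def _distance_constrained_optimize(
    geometry: Geometry,
    bond_atoms: Set[int],
    calc: CalculatorContract,
    config: SamplerConfig,
    target_distance: Optional[float],
) -> OptimizeOutcome:
    if len(bond_atoms) != 2 or target_distance is None:
        raise ValueError("distance mode needs exactly two bond atoms and a target distance")
    a, b = sorted(bond_atoms)
    x0 = geometry.coordinates.ravel().copy()

    def fun(x: np.ndarray):
        res = calc.evaluate(geometry.with_coordinates(x.reshape(-1, 3)))
        return res.energy, (-res.forces).ravel()

    def constraint(x: np.ndarray) -> float:
        c = x.reshape(-1, 3)
        return float(np.linalg.norm(c[a] - c[b]) - target_distance)

    try:
        opt = minimize(
            fun,
            x0,
            jac=True,
            method="SLSQP",
            constraints=[{"type": "eq", "fun": constraint}],
            options={"maxiter": config.opt_max_iter, "ftol": 1e-12},
        )
        coords = opt.x.reshape(-1, 3)
        res = calc.evaluate(geometry.with_coordinates(coords))
    except CalculationFailed:
        return OptimizeOutcome(geometry.with_coordinates(geometry.coordinates, origin="opt"),
                               False, discarded=True)
    others = np.array([i for i in range(geometry.n_atoms) if i not in (a, b)], dtype=int)
    fmax = float(np.linalg.norm(res.forces[others], axis=1).max()) if others.size else 0.0
    converged = bool(opt.success) and fmax <= config.opt_fmax and abs(constraint(opt.x)) < 1e-6
    return OptimizeOutcome(geometry.with_coordinates(coords, origin="opt"), converged)


@dataclass
class MDOutcome:
    snapshots: List[Geometry]
    failed: bool = False


def maxwell_boltzmann_velocities(
    geometry: Geometry,
    temperature: float,
    rng: np.random.Generator,
    fixed_atoms: Set[int] = frozenset(),
) -> np.ndarray:
    """Thermal velocities (Å/fs) with fixed atoms zeroed."""
    masses = np.array([ATOMIC_MASSES[e] for e in geometry.elements])
    std = np.sqrt(KB_EV * temperature * ACCEL_CONV / masses)
    v = rng.standard_normal((geometry.n_atoms, 3)) * std[:, None]
    v[list(fixed_atoms)] = 0.0
    return v


def kinetic_energy(velocities: np.ndarray, elements: Sequence[str]) -> float:
    """Kinetic energy in eV for velocities in Å/fs."""
    masses = np.array([ATOMIC_MASSES[e] for e in elements])
    return float(0.5 * (masses * (velocities ** 2).sum(axis=1)).sum() / ACCEL_CONV)


def constrained_md(
    geometry: Geometry,
    fixed_atoms: Set[int],
    calc: CalculatorContract,
    config: SamplerConfig,
    rng: Optional[np.random.Generator] = None,
) -> MDOutcome:
    """NVT dynamics with fixed atoms pinned; snapshots every ``t_dump`` fs.

    BAOAB Langevin splitting; with ``thermostat="none"`` (or zero friction)
    it reduces to plain velocity Verlet.  Defaults (1 ps, dump every 10 fs)
    give exactly 100 snapshots.  A calculator failure mid-run drops the
    remainder of the segment and flags the outcome.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    fixed = np.array(sorted(fixed_atoms), dtype=int)
    coords = geometry.coordinates.copy()
    fixed_ref = coords[fixed].copy()
    masses = np.array([ATOMIC_MASSES[e] for e in geometry.elements])[:, None]
    v = maxwell_boltzmann_velocities(geometry, config.md_temperature, rng, set(fixed_atoms))
    dt = config.dt
    gamma = config.friction if config.thermostat == "langevin" else 0.0
    c1 = math.exp(-gamma * dt)
    c2 = math.sqrt(max(0.0, 1.0 - c1 * c1))
    vstd = np.sqrt(KB_EV * config.md_temperature * ACCEL_CONV / masses)

    def accel(c: np.ndarray) -> np.ndarray:
        res = calc.evaluate(geometry.with_coordinates(c))
        a = res.forces / masses * ACCEL_CONV
        a[fixed] = 0.0
        return a

    snapshots: List[Geometry] = []
    try:
        a = accel(coords)
        for step in range(1, config.md_steps + 1):
            v += 0.5 * dt * a
            coords += 0.5 * dt * v
            if gamma > 0.0:
                v = c1 * v + c2 * vstd * rng.standard_normal(v.shape)
                v[fixed] = 0.0
            coords += 0.5 * dt * v
            coords[fixed] = fixed_ref  # pinned atoms never move
            a = accel(coords)
            v += 0.5 * dt * a
            v[fixed] = 0.0
            if step % config.dump_interval == 0:
                snap = geometry.with_coordinates(
                    coords.copy(),
                    origin="md",
                    snapshot_index=step // config.dump_interval - 1,
                )
                snapshots.append(snap)
    except CalculationFailed:
        return MDOutcome(snapshots, failed=True)
    return MDOutcome(snapshots, failed=False)


def run_bond_trajectory(
    record: MoleculeRecord,
    start: Geometry,
    bond: Bond,
    calc: CalculatorContract,
    config: SamplerConfig = SamplerConfig(),
) -> TrajectoryResult:
    """Full staged elongation of one bond from an embedded equilibrium.

    Per schedule target: elongate, relax with the bond atoms fixed (save the
    relaxed frame), run constrained MD and keep up to ``snapshot_cap``
    diverse frames.  The next step continues from the relaxed geometry by
    default.  With the default configuration and no calculator failures the
    result holds 15 + 150 = 165 conformers.
    """
    a, b = min(bond), max(bond)
    if not record.has_bond(a, b):
        raise ValueError(f"({a},{b}) is not a bond of {record.identifier!r}")
    l0 = start.distance(a, b)
    schedule = build_schedule(l0, config.stages)
    result = TrajectoryResult(molecule_id=record.identifier, bond=(a, b), schedule=schedule)
    bond_id = f"{a}-{b}"
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed & 0x7FFFFFFF, a, b]))
    fixed = {a, b}
    current = start

    for i, target in enumerate(schedule.targets):
        stage = schedule.stage_of(i)
        outcome = StepOutcome(step_index=i, target=target, stage=stage)
        stretched = elongate(current, (a, b), target)
        stretched = stretched.with_coordinates(
            stretched.coordinates, bond_id=bond_id, step_index=i
        )
        opt = constrained_optimize(stretched, fixed, calc, config, target_distance=target)
        outcome.opt_converged = opt.converged
        outcome.opt_discarded = opt.discarded
        if opt.discarded:
            result.discarded_count += 1
            result.steps.append(outcome)
            current = stretched
            continue
        opt_geom = opt.geometry.with_coordinates(
            opt.geometry.coordinates, bond_id=bond_id, step_index=i, origin="opt",
            snapshot_index=0,
        )
        result.opt_geometries.append(opt_geom)

        next_start = opt_geom
        if config.t_md > 0 and config.snapshot_cap > 0:
            md = constrained_md(opt_geom, fixed, calc, config, rng)
            outcome.md_failed = md.failed
            if md.snapshots:
                picks = diversity.select_geometries(md.snapshots, config.snapshot_cap)
                for idx in picks:
                    result.md_geometries.append(md.snapshots[idx])
                outcome.n_md_snapshots = len(picks)
                if config.continue_from == "md":
                    next_start = md.snapshots[-1]
        result.steps.append(outcome)
        current = next_start
    return result


CalcFactory = Union[CalculatorContract, Callable[[MoleculeRecord, Bond], CalculatorContract]]


def run_molecule(
    record: MoleculeRecord,
    calc: CalcFactory,
    config: SamplerConfig = SamplerConfig(),
    start: Optional[Geometry] = None,
    radius: int = bondhash.DEFAULT_RADIUS,
) -> List[TrajectoryResult]:
    """Run the bond-stretching workflow once per chemically unique bond.

    Bonds are deduplicated by their environment hash; every trajectory
    starts from the same embedded equilibrium geometry.  ``calc`` is either
    a calculator instance shared across bonds or a factory
    ``(record, bond) -> calculator`` (useful when the calculator tracks the
    stretched bond, as the toy spectrum model does).
    """
    if not chem_prep.passes_filter(record):
        raise ValueError(f"molecule {record.identifier!r} fails the element/size filter")
    if start is None:
        start = chem_prep.embed_geometry(record, seed=config.rng_seed)
    results = []
    for rep in bondhash.unique_bonds(record, radius).values():
        bond_calc = calc(record, rep) if callable(calc) else calc
        results.append(run_bond_trajectory(record, start, rep, bond_calc, config))
    return results
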