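"""Elongation schedule, constrained optimization/MD, and the per-bond loop."""
import numpy as np
import pytest

from bondbreak import (
    SamplerConfig,
    build_schedule,
    constrained_md,
    constrained_optimize,
    elongate,
    parse_molecule,
    run_bond_trajectory,
    run_molecule,
)
from bondbreak.sampler import kinetic_energy, maxwell_boltzmann_velocities
from bondbreak.structures import Geometry, Provenance
from bondbreak.toy_models import ToyForceField


class TestBuildSchedule:
    def test_default_fifteen_targets(self):
        sched = build_schedule(1.0)
        np.testing.assert_allclose(
            sched.targets,
            [1.1, 1.2, 1.3, 1.4, 1.5, 1.6, 1.7, 1.8, 1.9, 2.0,
             2.2, 2.4, 2.6, 2.8, 3.0],
        )

    def test_stage_endpoints_exact(self):
        for l0 in (0.96, 1.09, 1.54):
            sched = build_schedule(l0)
            assert sched.targets[9] / l0 == pytest.approx(2.0, abs=1e-12)
            assert sched.targets[14] / l0 == 3.0  # exact landing

    def test_single_step_stage(self):
        assert build_schedule(1.0, [(2.0, 1)]).targets == (2.0,)

    def test_targets_strictly_increasing(self):
        sched = build_schedule(1.23)
        assert all(b > a for a, b in zip(sched.targets, sched.targets[1:]))
        assert sched.targets[0] > sched.l0

    def test_non_increasing_multipliers_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            build_schedule(1.0, [(2.0, 5), (1.5, 5)])


def _diatomic(d=1.0):
    prov = Provenance("dia", "0-1", 0, "embed")
    return Geometry(("C", "C"), np.array([[0.0, 0.0, 0.0], [0.0, 0.0, d]]), prov)


class TestElongate:
    def test_symmetric_displacement(self):
        out = elongate(_diatomic(1.0), (0, 1), 1.5)
        np.testing.assert_allclose(out.coordinates[0], [0, 0, -0.25])
        np.testing.assert_allclose(out.coordinates[1], [0, 0, 1.25])

    def test_identity_when_target_equals_current(self):
        g = _diatomic(1.2)
        out = elongate(g, (0, 1), 1.2)
        np.testing.assert_array_equal(out.coordinates, g.coordinates)

    def test_midpoint_preserved_and_spectators_untouched(self, ethane, ethane_geometry):
        out = elongate(ethane_geometry, (0, 1), 2.5)
        mid_before = ethane_geometry.coordinates[[0, 1]].mean(axis=0)
        mid_after = out.coordinates[[0, 1]].mean(axis=0)
        np.testing.assert_allclose(mid_after, mid_before, atol=1e-12)
        others = [i for i in range(ethane_geometry.n_atoms) if i not in (0, 1)]
        np.testing.assert_array_equal(
            out.coordinates[others], ethane_geometry.coordinates[others]
        )
        assert out.distance(0, 1) == pytest.approx(2.5, abs=1e-12)

    def test_coincident_atoms_rejected(self):
        with pytest.raises(ValueError, match="coincident"):
            elongate(_diatomic(0.0), (0, 1), 1.0)


class TestConstrainedOptimize:
    def test_harmonic_triatomic_free_atom_lands_at_analytic_minimum(self):
        # water-like toy molecule: hold both H, relax O.  The toy energy for
        # O is two harmonic bonds + one angle; with the two H pinned
        # symmetrically the minimizer is computable by 1-D search along the
        # symmetry axis, which we do here to 1e-10 as the oracle.
        water = parse_molecule("O", "water")
        calc = ToyForceField(water)
        # place H symmetric about z axis, O displaced
        coords = np.array([[0.3, 0.2, 0.8], [0.76, 0.0, -0.2], [-0.76, 0.0, -0.2]])
        geom = Geometry(tuple(water.elements), coords, Provenance("water", "", 0, "embed"))
        fixed = {1, 2}
        cfg = SamplerConfig(opt_fmax=1e-6)
        out = constrained_optimize(geom, fixed, calc, cfg)
        assert out.converged

        # oracle: scan O on its symmetry plane (x=0 by symmetry of the H)
        def energy_at(y, z):
            c = coords.copy()
            c[0] = [0.0, y, z]
            return calc.energy_and_gradient(c)[0]

        from scipy.optimize import minimize as sp_min

        oracle = sp_min(lambda v: energy_at(*v), [0.0, 0.6], method="Nelder-Mead",
                        options={"xatol": 1e-12, "fatol": 1e-14})
        e_opt = calc.energy_and_gradient(out.geometry.coordinates)[0]
        assert e_opt == pytest.approx(oracle.fun, abs=1e-8)

    def test_fixed_atoms_bit_identical(self, ethane, ethane_geometry, ethane_calc):
        stretched = elongate(ethane_geometry, (0, 1), 2.0)
        out = constrained_optimize(stretched, {0, 1}, ethane_calc, SamplerConfig())
        np.testing.assert_array_equal(
            out.geometry.coordinates[[0, 1]], stretched.coordinates[[0, 1]]
        )

    def test_already_optimal_input_returned_converged(self, ethane, ethane_geometry, ethane_calc):
        cfg = SamplerConfig()
        first = constrained_optimize(ethane_geometry, {0, 1}, ethane_calc, cfg)
        again = constrained_optimize(first.geometry, {0, 1}, ethane_calc, cfg)
        assert again.converged
        np.testing.assert_allclose(
            again.geometry.coordinates, first.geometry.coordinates, atol=1e-4
        )

    def test_calculator_failure_flags_discard_not_fatal(self, ethane, ethane_geometry):
        calc = ToyForceField(ethane, fail_predicate=lambda g: True)
        out = constrained_optimize(ethane_geometry, {0, 1}, calc, SamplerConfig())
        assert out.discarded and not out.converged

    def test_distance_mode_preserves_bond_length_only(self, ethane, ethane_geometry, ethane_calc):
        cfg = SamplerConfig(constraint_mode="distance")
        stretched = elongate(ethane_geometry, (0, 1), 2.2)
        out = constrained_optimize(
            stretched, {0, 1}, ethane_calc, cfg, target_distance=2.2
        )
        assert out.geometry.distance(0, 1) == pytest.approx(2.2, abs=1e-6)


class TestConstrainedMD:
    def test_default_snapshot_count(self, ethane, ethane_geometry, ethane_calc):
        cfg = SamplerConfig(t_md=0.1, t_dump=10.0)  # 100 fs -> 10 dumps
        out = constrained_md(ethane_geometry, {0, 1}, ethane_calc, cfg)
        assert len(out.snapshots) == 10 and not out.failed

    def test_fixed_atoms_never_move(self, ethane, ethane_geometry, ethane_calc):
        cfg = SamplerConfig(t_md=0.05, t_dump=5.0, rng_seed=11)
        out = constrained_md(ethane_geometry, {0, 1}, ethane_calc, cfg)
        for snap in out.snapshots:
            np.testing.assert_array_equal(
                snap.coordinates[[0, 1]], ethane_geometry.coordinates[[0, 1]]
            )

    def test_energy_drift_below_one_percent_without_thermostat(
        self, ethane, ethane_geometry, ethane_calc
    ):
        # symplectic check: thermal kick at t=0, no thermostat, 1 ps at
        # 0.5 fs; total-energy drift stays under 1% of the initial kinetic
        # energy
        cfg = SamplerConfig(thermostat="none", t_md=1.0, dt=0.5, t_dump=10.0, rng_seed=5)
        rng = np.random.default_rng(cfg.rng_seed)
        start = constrained_optimize(
            ethane_geometry, {0, 1}, ethane_calc, SamplerConfig(opt_fmax=1e-4)
        ).geometry
        v0 = maxwell_boltzmann_velocities(start, cfg.md_temperature, rng, {0, 1})
        ke0 = kinetic_energy(v0, start.elements)

        # re-run the integrator manually to track the conserved energy
        from bondbreak.sampler import ACCEL_CONV
        from bondbreak.structures import ATOMIC_MASSES

        masses = np.array([ATOMIC_MASSES[e] for e in start.elements])[:, None]
        coords = start.coordinates.copy()
        v = v0.copy()
        fixed = np.array([0, 1])

        def force(c):
            return ethane_calc.evaluate(start.with_coordinates(c)).forces

        def accel(c):
            a = force(c) / masses * ACCEL_CONV
            a[fixed] = 0.0
            return a

        e_init = ethane_calc.evaluate(start.with_coordinates(coords)).energy + ke0
        a = accel(coords)
        for _ in range(cfg.md_steps):
            v += 0.5 * cfg.dt * a
            coords += cfg.dt * v
            coords[fixed] = start.coordinates[fixed]
            a = accel(coords)
            v += 0.5 * cfg.dt * a
            v[fixed] = 0.0
        e_end = ethane_calc.evaluate(start.with_coordinates(coords)).energy + kinetic_energy(
            v, start.elements
        )
        assert abs(e_end - e_init) < 0.01 * ke0

    def test_failure_mid_run_truncates_and_flags(self, ethane, ethane_geometry):
        calls = {"n": 0}

        def fail_late(geom):
            calls["n"] += 1
            return calls["n"] > 50

        calc = ToyForceField(ethane, fail_predicate=fail_late)
        cfg = SamplerConfig(t_md=0.1, t_dump=5.0, rng_seed=2)
        out = constrained_md(ethane_geometry, {0, 1}, calc, cfg)
        assert out.failed
        assert len(out.snapshots) < 20


class TestRunBondTrajectory:
    def test_conformer_accounting_short_run(self, ethane, ethane_geometry, ethane_calc, fast_config):
        res = run_bond_trajectory(ethane, ethane_geometry, (0, 1), ethane_calc, fast_config)
        assert len(res.opt_geometries) == 2
        assert len(res.md_geometries) == 2 * fast_config.snapshot_cap
        assert res.n_conformers == 8

    def test_md_disabled_gives_opt_only(self, ethane, ethane_geometry, ethane_calc):
        cfg = SamplerConfig(t_md=0.0)
        res = run_bond_trajectory(ethane, ethane_geometry, (0, 1), ethane_calc, cfg)
        assert len(res.opt_geometries) == 15
        assert res.md_geometries == []

    def test_constraint_exact_through_opt_and_md(self, ethane, ethane_geometry, ethane_calc, fast_config):
        res = run_bond_trajectory(ethane, ethane_geometry, (0, 1), ethane_calc, fast_config)
        for g in res.opt_geometries + res.md_geometries:
            target = res.schedule.targets[g.provenance.step_index]
            assert g.distance(0, 1) == pytest.approx(target, abs=1e-6)

    def test_provenance_fully_populated(self, ethane, ethane_geometry, ethane_calc, fast_config):
        res = run_bond_trajectory(ethane, ethane_geometry, (0, 1), ethane_calc, fast_config)
        for g in res.all_geometries():
            p = g.provenance
            assert p.molecule_id == "ethane"
            assert p.bond_id == "0-1"
            assert p.origin in ("opt", "md")
            assert 0 <= p.step_index < len(res.schedule.targets)

    def test_full_run_determinism(self, ethane, ethane_geometry, ethane_calc, fast_config):
        r1 = run_bond_trajectory(ethane, ethane_geometry, (0, 1), ethane_calc, fast_config)
        r2 = run_bond_trajectory(ethane, ethane_geometry, (0, 1), ethane_calc, fast_config)
        assert r1.n_conformers == r2.n_conformers
        for g1, g2 in zip(r1.all_geometries(), r2.all_geometries()):
            np.testing.assert_array_equal(g1.coordinates, g2.coordinates)

    def test_discarded_steps_counted(self, ethane, ethane_geometry, fast_config):
        calls = {"n": 0}

        def fail_often(geom):
            calls["n"] += 1
            return calls["n"] % 37 == 0

        calc = ToyForceField(ethane, fail_predicate=fail_often)
        res = run_bond_trajectory(ethane, ethane_geometry, (0, 1), calc, fast_config)
        assert res.discarded_count + len(res.opt_geometries) == 2


class TestRunMolecule:
    def test_methane_single_trajectory(self, methane, fast_config):
        results = run_molecule(methane, ToyForceField, fast_config)
        assert len(results) == 1

    def test_ethane_two_trajectories_conserving_counts(self, ethane, fast_config):
        results = run_molecule(ethane, ToyForceField, fast_config)
        assert len(results) == 2
        total = sum(r.n_conformers for r in results)
        assert total == sum(
            len(r.opt_geometries) + len(r.md_geometries) for r in results
        )

    def test_filtered_molecule_rejected(self, fast_config):
        big = parse_molecule("CCCCCCCC", "octane")
        with pytest.raises(ValueError, match="filter"):
            run_molecule(big, ToyForceField, fast_config)
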