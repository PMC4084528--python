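"""Engine: schedule validity, conservation laws, decomposition equivalence."""

import numpy as np
import pytest

from socmd import (EwaldParams, PipelineConfig, SimulationConfig, StepSchedule,
                   compute_forces, generate_system, leapfrog_step, run,
                   run_step)
from socmd.engine import STAGES


class TestSchedule:
    def test_default_order_is_valid(self):
        StepSchedule()       # must not raise

    def test_update_before_gather_rejected(self):
        bad = list(STAGES)
        bad.remove("update")
        bad.insert(0, "update")
        with pytest.raises(ValueError):
            StepSchedule(tuple(bad))

    def test_missing_stage_rejected(self):
        with pytest.raises(ValueError):
            StepSchedule(STAGES[:-1])

    def test_alternative_topological_order_accepted(self):
        StepSchedule(("distribute", "bonded", "nonbonded", "charge_assign",
                      "poisson", "back_interp", "gather", "update"))


class TestLeapfrog:
    def test_zero_force_is_uniform_motion(self, lj_system):
        s = generate_system("lj_fluid", 8, 0.01, seed=0)
        v0 = s.velocities.copy()
        x0 = s.positions.copy()
        leapfrog_step(s, np.zeros((s.n, 3)), dt=0.1)
        assert np.allclose(s.velocities, v0)
        assert np.allclose(np.mod(x0 + v0 * 0.1, s.box), s.positions)

    def test_constant_force_quadratic_trajectory(self):
        s = generate_system("lj_fluid", 8, 0.01, seed=0)
        s.velocities[:] = 0.0
        x0 = s.positions.copy()
        f = np.zeros((s.n, 3))
        f[:, 0] = 0.5
        dt, n_steps = 0.01, 100
        for _ in range(n_steps):
            leapfrog_step(s, f, dt)
        t = n_steps * dt
        # leap-frog from rest: x(t) = x0 + (a t / 2)(t + dt)
        expected = x0[:, 0] + 0.25 * t * (t + dt)
        assert np.allclose(s.positions[:, 0], expected, atol=1e-12)

    def test_harmonic_oscillator_energy_bounded(self):
        """1-D oscillator integrated 1000 steps at dt = T/100: the energy
        error stays bounded (no drift beyond O(dt^2))."""
        m = k = 1.0
        period = 2 * np.pi
        dt = period / 100
        x, v = 1.0, 0.0            # v at t - dt/2
        v -= 0.5 * dt * x          # half-step offset init
        energies = []
        for _ in range(1000):
            v += -k * x / m * dt
            x += v * dt
            # synchronize: v(t+dt) = v(t+dt/2) + a(x(t+dt)) * dt/2
            v_on = v - 0.5 * k * x / m * dt
            energies.append(0.5 * m * v_on ** 2 + 0.5 * k * x ** 2)
        energies = np.array(energies)
        assert np.abs(energies - 0.5).max() <= 0.5 * dt ** 2 * 10


class TestConservation:
    def test_total_fixed_point_force_is_zero_word_every_step(self, lj_config):
        s = generate_system("lj_fluid", 64, 0.5, seed=4)
        for step in range(5):
            s, _, bank = run_step(s, lj_config, step=step)
            assert np.array_equal(bank.total_word(), np.zeros(3, dtype=np.int64))

    def test_polymer_bonded_forces_sum_to_zero_word(self):
        s = generate_system("toy_polymer", 12, 0.05, seed=9)
        config = SimulationConfig(cutoff=3.0,
                                  pipeline=PipelineConfig(cutoff_radius=3.0))
        bank, energies = compute_forces(s, config)
        assert np.array_equal(bank.total_word(), np.zeros(3, dtype=np.int64))
        assert energies["bonded"] > 0.0

    def test_microcanonical_lj_drift_below_1e3(self):
        """500-step LJ-fluid NVE run: |E(t) - E(0)| / |E(0)| <= 1e-3."""
        s = generate_system("lj_fluid", 64, 0.5, seed=1)
        config = SimulationConfig(dt=0.004, n_steps=500, cutoff=2.5,
                                  pipeline=PipelineConfig(cutoff_radius=2.5))
        _, records = run(s, config)
        energies = np.array([r.total for r in records])
        drift = np.abs(energies - energies[0]).max() / abs(energies[0])
        assert drift <= 1e-3

    def test_decomposed_forces_bit_identical_to_flat(self):
        s = generate_system("lj_fluid", 216, 0.4, seed=6)
        config = SimulationConfig(cutoff=2.0,
                                  pipeline=PipelineConfig(cutoff_radius=2.0))
        bank_cells, e_cells = compute_forces(s, config)
        bank_flat, e_flat = compute_forces(s, config, flat=True)
        assert np.array_equal(bank_cells.words, bank_flat.words)
        assert e_cells["short_range"] == pytest.approx(e_flat["short_range"],
                                                       rel=1e-12)


class TestChargedRun:
    def test_salt_lattice_step_runs_with_ewald(self):
        s = generate_system("salt_lattice", 64, 1.0)
        L = float(s.box[0])
        alpha = 6.0 / 1.9
        from socmd import AtomTypeTable
        config = SimulationConfig(
            dt=0.001, cutoff=1.9,
            pipeline=PipelineConfig(alpha=alpha, cutoff_radius=1.9),
            type_table=AtomTypeTable([0.0], [1.0]),   # pure Coulomb lattice
            ewald=EwaldParams(alpha=alpha, box=(L,) * 3, mesh_dims=(32,) * 3))
        s2, record, bank = run_step(s, config)
        # long-range energy recovers most of the Madelung energy
        assert record.long_range < 0.0
        assert record.potential == pytest.approx(-1.747565 * 32, rel=1e-3)

    def test_alpha_mismatch_between_modules_rejected(self):
        s = generate_system("salt_lattice", 64, 1.0)
        L = float(s.box[0])
        config = SimulationConfig(
            dt=0.001, cutoff=1.9,
            pipeline=PipelineConfig(alpha=3.0, cutoff_radius=1.9),
            ewald=EwaldParams(alpha=3.2, box=(L,) * 3, mesh_dims=(32,) * 3))
        with pytest.raises(ValueError):
            compute_forces(s, config)
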