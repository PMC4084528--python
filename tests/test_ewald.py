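"""Gaussian-split Ewald mesh vs the direct Ewald summation oracle."""

import numpy as np
import pytest

from socmd import (EwaldParams, back_interpolate, real_space_correction,
                   reciprocal_energy, self_energy, solve_poisson,
                   spread_charges, total_coulomb_energy)
from oracles import (MADELUNG_NACL, direct_ewald_energy, direct_ewald_forces)


@pytest.fixture
def params():
    L = 6.0
    return EwaldParams(alpha=6.0 / 2.9, box=(L, L, L), mesh_dims=(32, 32, 32))


@pytest.fixture
def neutral_random(rng):
    L = 6.0
    pos = rng.uniform(0, L, size=(8, 3))
    q = np.array([1.0, -1.0] * 4)
    return pos, q, L


class TestSpreading:
    def test_single_unit_charge_sums_to_one(self, params):
        mesh = spread_charges([[3.0, 3.0, 3.0]], [1.0], params)
        assert mesh.values.sum() == pytest.approx(1.0, abs=1e-10)

    def test_charge_at_mesh_node_has_octahedral_symmetry(self, params):
        h = params.cell_spacing
        node = np.array([8 * h[0], 8 * h[1], 8 * h[2]])
        mesh = spread_charges([node], [1.0], params).values
        # reflections through the node map the mesh onto itself
        rolled = np.roll(mesh[::-1], 2 * 8 + 1, axis=0)
        assert np.allclose(rolled, mesh, atol=1e-14)
        assert np.allclose(mesh.transpose(1, 0, 2), mesh, atol=1e-14)

    def test_opposite_charges_at_same_point_cancel(self, params):
        pos = [[2.2, 3.3, 4.4], [2.2, 3.3, 4.4]]
        mesh = spread_charges(pos, [1.0, -1.0], params)
        assert np.abs(mesh.values).max() == pytest.approx(0.0, abs=1e-15)

    def test_total_charge_conserved_on_mesh(self, neutral_random, params):
        pos, q, _ = neutral_random
        mesh = spread_charges(pos, q, params)
        assert mesh.values.sum() == pytest.approx(q.sum(), abs=1e-10)

    def test_oversized_support_rejected(self):
        with pytest.raises(ValueError):
            EwaldParams(alpha=2.0, box=(6.0,) * 3, mesh_dims=(32,) * 3,
                        sigma_spread=0.15, r_spread_cut=3.5)


class TestPoisson:
    def test_zero_charge_mesh_gives_zero_potential(self, params):
        from socmd.ewald import ChargeMesh
        mesh = ChargeMesh(np.zeros(params.mesh_dims), params)
        phi = solve_poisson(mesh, params)
        assert np.abs(phi.values).max() == 0.0

    def test_single_fourier_mode_is_eigenfunction(self, params):
        from socmd.ewald import ChargeMesh, _greens_function
        nx = params.mesh_dims[0]
        x = np.arange(nx) * params.cell_spacing[0]
        mode = np.cos(2 * np.pi * 2 * x / params.box[0])
        values = np.broadcast_to(mode[:, None, None], params.mesh_dims).copy()
        phi = solve_poisson(ChargeMesh(values, params), params)
        # eigenfunction: output proportional to input with the Green's factor
        mask = np.abs(values) > 0.1
        ratio = phi.values[mask] / values[mask]
        assert np.allclose(ratio, ratio.flat[0], rtol=1e-9)
        g = _greens_function(params)[2, 0, 0]
        assert ratio.flat[0] == pytest.approx(
            g * np.prod(params.mesh_dims) / params.volume, rel=1e-6)

    def test_parseval_energy_identity(self, rng):
        """Mesh-space and reciprocal-space energies agree to 1e-10."""
        params = EwaldParams(alpha=1.5, box=(4.0,) * 3, mesh_dims=(16,) * 3)
        pos = rng.uniform(0, 4.0, size=(6, 3))
        q = np.array([1.0, -1.0] * 3)
        mesh = spread_charges(pos, q, params)
        phi = solve_poisson(mesh, params)
        e_mesh = 0.5 * np.sum(mesh.values * phi.values)
        e_k = reciprocal_energy(mesh, params)
        assert e_mesh == pytest.approx(e_k, rel=1e-10)

    def test_shape_mismatch_rejected(self, params):
        from socmd.ewald import ChargeMesh
        with pytest.raises(ValueError):
            solve_poisson(ChargeMesh(np.zeros((8, 8, 8)), params), params)


class TestBackInterpolation:
    def test_uniform_potential_gives_zero_forces(self, neutral_random, params):
        from socmd.ewald import PotentialMesh
        pos, q, _ = neutral_random
        phi = PotentialMesh(np.full(params.mesh_dims, 2.5), params)
        forces, _ = back_interpolate(phi, pos, q, params)
        assert np.abs(forces).max() <= 1e-12

    def test_net_reciprocal_force_vanishes(self, neutral_random, params):
        pos, q, _ = neutral_random
        mesh = spread_charges(pos, q, params)
        phi = solve_poisson(mesh, params)
        forces, _ = back_interpolate(phi, pos, q, params)
        rms = np.sqrt(np.mean(forces ** 2))
        assert np.abs(forces.sum(axis=0)).max() <= 1e-8 * rms

    def test_two_ion_force_matches_direct_ewald(self, params):
        pos = np.array([[2.0, 3.0, 3.0], [4.5, 3.0, 3.0]])
        q = np.array([1.0, -1.0])
        mesh = spread_charges(pos, q, params)
        phi = solve_poisson(mesh, params)
        f_mesh, _ = back_interpolate(phi, pos, q, params)
        f_real, _ = real_space_correction(pos, q, params, 2.9)
        f_direct = direct_ewald_forces(pos, q, 6.0, params.alpha)
        scale = np.abs(f_direct).max()
        assert np.abs(f_mesh + f_real - f_direct).max() / scale <= 1e-4

    def test_parameter_mismatch_rejected(self, neutral_random, params):
        from socmd.ewald import PotentialMesh
        other = EwaldParams(alpha=params.alpha, box=params.box,
                            mesh_dims=params.mesh_dims,
                            sigma_spread=0.5 * params.sigma_spread)
        phi = PotentialMesh(np.zeros(other.mesh_dims), other)
        with pytest.raises(ValueError):
            back_interpolate(phi, *neutral_random[:2], params)


class TestTotalEnergy:
    def test_matches_direct_ewald_on_random_neutral_system(self, neutral_random,
                                                           params):
        pos, q, L = neutral_random
        e_mesh = total_coulomb_energy(pos, q, params, cutoff=2.9)
        e_direct = direct_ewald_energy(pos, q, L, params.alpha)
        assert e_mesh == pytest.approx(e_direct, rel=1e-4)

    def test_rock_salt_madelung_energy(self):
        """64-ion rock-salt lattice recovers the Madelung constant."""
        m, a = 4, 1.0
        L = m * a
        ijk = np.array([(i, j, k) for i in range(m) for j in range(m)
                        for k in range(m)])
        pos = (ijk + 0.5) * a
        q = np.where(ijk.sum(axis=1) % 2 == 0, 1.0, -1.0)
        params = EwaldParams(alpha=6.0 / 1.9, box=(L,) * 3,
                             mesh_dims=(32,) * 3)
        energy = total_coulomb_energy(pos, q, params, cutoff=1.9)
        per_pair = energy / (len(q) // 2)
        assert per_pair == pytest.approx(-MADELUNG_NACL / a, rel=1e-3)

    def test_isolated_pair_in_large_box_approaches_bare_coulomb(self):
        L, r = 20.0, 1.0
        pos = np.array([[10.0, 10.0, 10.0], [10.0 + r, 10.0, 10.0]])
        q = np.array([1.0, -1.0])
        params = EwaldParams(alpha=6.0 / 8.0, box=(L,) * 3,
                             mesh_dims=(32,) * 3)
        energy = total_coulomb_energy(pos, q, params, cutoff=8.0)
        assert energy == pytest.approx(-1.0 / r, rel=1e-3)

    def test_empty_system_gives_zero(self):
        params = EwaldParams(alpha=2.0, box=(6.0,) * 3)
        assert total_coulomb_energy(np.empty((0, 3)), [], params, 2.9) == 0.0

    def test_non_neutral_system_rejected(self, params):
        with pytest.raises(ValueError):
            total_coulomb_energy([[1, 1, 1], [3, 3, 3]], [1.0, 1.0],
                                 params, 2.9)

    def test_alpha_invariance(self, neutral_random):
        """Doubling alpha with a matched mesh moves the energy < 1e-4.

        Fixed accuracy settings: the spreading width is 0.9 mesh cells
        in both configurations (the mesh is refined with alpha)."""
        pos, q, L = neutral_random
        e1 = total_coulomb_energy(
            pos, q, EwaldParams(alpha=6.0 / 2.9, box=(L,) * 3,
                                mesh_dims=(32,) * 3,
                                sigma_spread=0.9 * L / 32), cutoff=2.9)
        e2 = total_coulomb_energy(
            pos, q, EwaldParams(alpha=12.0 / 2.9, box=(L,) * 3,
                                mesh_dims=(64,) * 3,
                                sigma_spread=0.9 * L / 64), cutoff=2.9)
        assert e2 == pytest.approx(e1, rel=1e-4)

    def test_inconsistent_cutoff_rejected(self, neutral_random, params):
        pos, q, _ = neutral_random
        with pytest.raises(ValueError):
            real_space_correction(pos, q, params, cutoff=1.0)
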