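"""Bonded terms: analytic gradients, invariances, and the FLOP model."""

import numpy as np
import pytest

from socmd import (Angle, Bond, BondTypeCost, FlopWeights, Torsion, Topology,
                   angle_force, bond_force, flops_per_interaction,
                   per_atom_flops, torsion_force, PROTEIN_RICH_COSTS)


def _numerical_gradient(func, coords, term, h=1e-6):
    grad = np.zeros_like(coords)
    for a in range(coords.shape[0]):
        for c in range(3):
            up, dn = coords.copy(), coords.copy()
            up[a, c] += h
            dn[a, c] -= h
            grad[a, c] = (func(up, term)[0] - func(dn, term)[0]) / (2 * h)
    return grad


TERMS = [
    (bond_force, Bond(0, 1, 100.0, 1.1), 2),
    (angle_force, Angle(0, 1, 2, 50.0, 1.9), 3),
    (torsion_force, Torsion(0, 1, 2, 3, 2.5, 3, 0.7), 4),
]


class TestForces:
    def test_bond_at_equilibrium_is_force_free(self):
        coords = np.array([[0.0, 0, 0], [1.1, 0, 0]])
        e, f = bond_force(coords, Bond(0, 1, 100.0, 1.1))
        assert e == pytest.approx(0.0, abs=1e-12)
        assert np.abs(f[0]).max() == pytest.approx(0.0, abs=1e-12)

    def test_bond_energy_convention_without_half_factor(self):
        coords = np.array([[0.0, 0, 0], [2.1, 0, 0]])
        e, _ = bond_force(coords, Bond(0, 1, 100.0, 1.1))
        assert e == pytest.approx(100.0)   # K (r - r0)^2 with r - r0 = 1

    def test_angle_at_equilibrium_is_force_free(self):
        theta0 = 1.9
        coords = np.array([[np.cos(theta0), np.sin(theta0), 0.0],
                           [0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        e, f = angle_force(coords, Angle(0, 1, 2, 50.0, theta0))
        assert e == pytest.approx(0.0, abs=1e-12)
        for v in f.values():
            assert np.abs(v).max() == pytest.approx(0.0, abs=1e-9)

    def test_torsion_zero_barrier_is_zero_everywhere(self, rng):
        coords = rng.normal(size=(4, 3))
        e, f = torsion_force(coords, Torsion(0, 1, 2, 3, 0.0, 2, 0.3))
        assert e == 0.0
        for v in f.values():
            assert np.abs(v).max() == 0.0

    def test_torsion_energy_vanishes_at_cosine_minimum(self):
        # planar trans geometry: phi = pi, so 1 + cos(phi - 0) = 0
        coords = np.array([[1.0, 1.0, 0.0], [1.0, 0.0, 0.0],
                           [2.0, 0.0, 0.0], [2.0, -1.0, 0.0]])
        e, _ = torsion_force(coords, Torsion(0, 1, 2, 3, 2.5, 1, 0.0))
        assert e == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("func,term,n_atoms", TERMS)
    def test_forces_are_negative_gradients(self, rng, func, term, n_atoms):
        """Central-difference check at 1e-8 relative on random geometries."""
        for _ in range(8):
            coords = rng.normal(size=(n_atoms, 3)) * 1.5
            _, forces = func(coords, term)
            grad = _numerical_gradient(func, coords, term)
            scale = max(np.abs(grad).max(), 1.0)
            for idx, f in forces.items():
                assert np.abs(f + grad[idx]).max() / scale <= 1e-7

    @pytest.mark.parametrize("func,term,n_atoms", TERMS)
    def test_net_force_and_torque_vanish(self, rng, func, term, n_atoms):
        for _ in range(5):
            coords = rng.normal(size=(n_atoms, 3)) * 1.5
            _, forces = func(coords, term)
            net = sum(forces.values())
            torque = sum(np.cross(coords[i], f) for i, f in forces.items())
            assert np.abs(net).max() <= 1e-10
            assert np.abs(torque).max() <= 1e-10

    def test_coincident_bond_atoms_rejected(self):
        coords = np.zeros((2, 3))
        with pytest.raises(ValueError):
            bond_force(coords, Bond(0, 1, 1.0, 1.0))

    def test_collinear_torsion_rejected(self):
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0],
                           [3.0, 0, 0]])
        with pytest.raises(ValueError):
            torsion_force(coords, Torsion(0, 1, 2, 3, 1.0, 1, 0.0))


class TestTopology:
    def test_term_index_validation(self):
        with pytest.raises(ValueError):
            Topology(n_particles=3, bonds=[Bond(0, 5, 1.0, 1.0)])
        with pytest.raises(ValueError):
            Bond(2, 2, 1.0, 1.0)
        with pytest.raises(ValueError):
            Torsion(0, 1, 2, 3, 1.0, 0, 0.0)

    def test_excluded_pairs_cover_12_and_13(self):
        topo = Topology(n_particles=4,
                        bonds=[Bond(0, 1, 1, 1), Bond(1, 2, 1, 1),
                               Bond(2, 3, 1, 1)],
                        angles=[Angle(0, 1, 2, 1, 1), Angle(1, 2, 3, 1, 1)],
                        torsions=[Torsion(0, 1, 2, 3, 1, 1, 0)])
        excl = topo.excluded_pairs()
        assert frozenset((0, 1)) in excl and frozenset((0, 2)) in excl
        assert frozenset((0, 3)) not in excl
        assert frozenset((0, 3)) in topo.excluded_pairs(include_14=True)


class TestFlopModel:
    def test_bond_stretching_row(self):
        assert flops_per_interaction({"add": 12, "mul": 9, "rsqrt": 1}) == 31

    def test_angle_bending_row(self):
        counts = {"add": 34, "mul": 42, "rsqrt": 4, "cos": 1, "acos": 1}
        assert flops_per_interaction(counts) == 136

    def test_zero_tallies_give_zero(self):
        assert flops_per_interaction({}) == 0.0
        assert flops_per_interaction({"add": 0, "cos": 0}) == 0.0

    def test_negative_tally_rejected(self):
        with pytest.raises(ValueError):
            flops_per_interaction({"add": -1})

    def test_unknown_operation_rejected(self):
        with pytest.raises(KeyError):
            flops_per_interaction({"fma": 3})

    def test_weights_must_be_positive(self):
        with pytest.raises(ValueError):
            FlopWeights(add=0.0)

    def test_per_atom_contributions_round_to_one_decimal(self):
        assert BondTypeCost("angle", 136.0, 1.8).per_atom_contribution == 244.8
        assert BondTypeCost("torsion", 183.84, 3.9).per_atom_contribution == 717.0
        assert BondTypeCost("x", 5.0, 0.0).per_atom_contribution == 0.0

    def test_protein_rich_total_per_atom(self):
        contributions, total = per_atom_flops()
        assert contributions == {"bond stretching": 31.0,
                                 "angle bending": 244.8,
                                 "torsion": 717.0}
        assert total == 992.8

    def test_tabulated_totals_follow_from_tallies(self):
        by_name = {c.name: c for c in PROTEIN_RICH_COSTS}
        assert by_name["bond stretching"].flops_per_interaction == 31
        assert by_name["angle bending"].flops_per_interaction == 136
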