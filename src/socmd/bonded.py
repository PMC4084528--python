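"""Amber-form bonded interactions and the operation-weighted FLOP model.

Bonded terms follow the Amber conventions without 1/2 factors:

* bond stretch   ``U = K_b (r - r0)^2``
* angle bend     ``U = K_theta (theta - theta0)^2``
* torsion        ``U = sum_n V_n (1 + cos(n*phi - gamma))``

All forces are analytic gradients; each term's forces sum to zero
(translation invariance) and exert no net torque (rotation invariance).
Near-collinear angle/torsion geometries are regularized by clamping
cosine arguments to [-1+eps, 1-eps] with eps = 1e-12, which keeps
forces bounded.

The FLOP model reproduces the accounting used when sizing the on-chip
general-purpose cores: per-interaction operation tallies are weighted
(add/mul = 1; rsqrt, cos, acos = 10), multiplied by per-atom
multiplicities from a protein-rich domain composition, rounded to one
decimal per bond type, and summed to a per-atom total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Bond",
    "Angle",
    "Torsion",
    "Topology",
    "FlopWeights",
    "BondTypeCost",
    "bond_force",
    "angle_force",
    "torsion_force",
    "topology_energy_forces",
    "flops_per_interaction",
    "per_atom_flops",
    "PROTEIN_RICH_COSTS",
]

_CLAMP_EPS = 1e-12


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    k_b: float      # energy / length^2
    r0: float       # length

    def __post_init__(self):
        if self.i == self.j:
            raise ValueError("bond endpoints must be distinct")
        if not self.r0 > 0:
            raise ValueError("equilibrium bond length must be positive")


@dataclass(frozen=True)
class Angle:
    i: int
    j: int          # vertex
    k: int
    k_theta: float  # energy / rad^2
    theta0: float   # rad

    def __post_init__(self):
        if len({self.i, self.j, self.k}) != 3:
            raise ValueError("angle atoms must be distinct")


@dataclass(frozen=True)
class Torsion:
    i: int
    j: int
    k: int
    l: int
    v_n: float      # energy (barrier height)
    n: int          # periodicity, >= 1
    gamma: float    # phase, rad

    def __post_init__(self):
        if len({self.i, self.j, self.k, self.l}) != 4:
            raise ValueError("torsion atoms must be distinct")
        if self.n < 1:
            raise ValueError("torsion periodicity must be >= 1")


@dataclass
class Topology:
    """Bonded-term lists for a particle system."""

    n_particles: int
    bonds: list = field(default_factory=list)
    angles: list = field(default_factory=list)
    torsions: list = field(default_factory=list)

    def __post_init__(self):
        for term in (*self.bonds, *self.angles, *self.torsions):
            idx = [term.i, term.j, term.k] if isinstance(term, Angle) else (
                [term.i, term.j, term.k, term.l] if isinstance(term, Torsion)
                else [term.i, term.j])
            if any(a < 0 or a >= self.n_particles for a in idx):
                raise ValueError("bonded term references a particle outside the system")

    def excluded_pairs(self, include_14: bool = False) -> set:
        """1-2 and 1-3 pairs (optionally 1-4) excluded from non-bonded forces."""
        pairs = set()
        for b in self.bonds:
            pairs.add(frozenset((b.i, b.j)))
        for a in self.angles:
            pairs.add(frozenset((a.i, a.k)))
            pairs.add(frozenset((a.i, a.j)))
            pairs.add(frozenset((a.j, a.k)))
        if include_14:
            for t in self.torsions:
                pairs.add(frozenset((t.i, t.l)))
        return pairs


def bond_force(coords: np.ndarray, bond: Bond):
    """Energy and forces of one harmonic bond.

    Returns ``(energy, {i: f_i, j: f_j})`` with f_j = -f_i exactly.
    """
    rij = coords[bond.i] - coords[bond.j]
    r = np.linalg.norm(rij)
    if r == 0.0:
        raise ValueError("coincident bonded atoms")
    delta = r - bond.r0
    energy = bond.k_b * delta * delta
    f_i = -2.0 * bond.k_b * delta * rij / r
    return float(energy), {bond.i: f_i, bond.j: -f_i}


def angle_force(coords: np.ndarray, angle: Angle):
    """Energy and forces of one harmonic angle (vertex at j)."""
    r_ji = coords[angle.i] - coords[angle.j]
    r_jk = coords[angle.k] - coords[angle.j]
    a = np.linalg.norm(r_ji)
    b = np.linalg.norm(r_jk)
    if a == 0.0 or b == 0.0:
        raise ValueError("zero-length angle arm")
    cos_t = np.clip(np.dot(r_ji, r_jk) / (a * b),
                    -1.0 + _CLAMP_EPS, 1.0 - _CLAMP_EPS)
    theta = np.arccos(cos_t)
    delta = theta - angle.theta0
    energy = angle.k_theta * delta * delta

    # dU/dtheta, and dtheta/dr via the standard geometric gradients
    dU = 2.0 * angle.k_theta * delta
    sin_t = np.sqrt(1.0 - cos_t * cos_t)
    f_i = -dU * (r_jk / (a * b) - cos_t * r_ji / (a * a)) / (-sin_t)
    f_k = -dU * (r_ji / (a * b) - cos_t * r_jk / (b * b)) / (-sin_t)
    f_j = -(f_i + f_k)
    return float(energy), {angle.i: f_i, angle.j: f_j, angle.k: f_k}


def dihedral_angle(coords: np.ndarray, i: int, j: int, k: int, l: int) -> float:
    """Signed dihedral angle phi about the j-k axis, in radians."""
    b1 = coords[j] - coords[i]
    b2 = coords[k] - coords[j]
    b3 = coords[l] - coords[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.arctan2(y, x))


def torsion_force(coords: np.ndarray, torsion: Torsion):
    """Energy and forces of one periodic torsion term."""
    i, j, k, l = torsion.i, torsion.j, torsion.k, torsion.l
    b1 = coords[j] - coords[i]
    b2 = coords[k] - coords[j]
    b3 = coords[l] - coords[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    n1_sq = np.dot(n1, n1)
    n2_sq = np.dot(n2, n2)
    b2_len = np.linalg.norm(b2)
    if n1_sq < _CLAMP_EPS or n2_sq < _CLAMP_EPS or b2_len == 0.0:
        raise ValueError("collinear torsion geometry")

    phi = dihedral_angle(coords, i, j, k, l)
    arg = torsion.n * phi - torsion.gamma
    energy = torsion.v_n * (1.0 + np.cos(arg))
    dU_dphi = -torsion.v_n * torsion.n * np.sin(arg)

    # analytic dihedral gradient: dphi/dr for the end atoms points along
    # the plane normals; the inner atoms follow from lever-arm projections
    dphi_i = b2_len / n1_sq * n1
    dphi_l = -b2_len / n2_sq * n2
    s1 = np.dot(b1, b2) / (b2_len ** 2)
    s2 = np.dot(b3, b2) / (b2_len ** 2)
    dphi_j = -(1.0 + s1) * dphi_i + s2 * dphi_l
    f_i = -dU_dphi * dphi_i
    f_j = -dU_dphi * dphi_j
    f_l = -dU_dphi * dphi_l
    f_k = -(f_i + f_j + f_l)
    return float(energy), {i: f_i, j: f_j, k: f_k, l: f_l}


def topology_energy_forces(coords: np.ndarray, topology: Topology):
    """Total bonded energy and per-particle force array."""
    forces = np.zeros((topology.n_particles, 3))
    energy = 0.0
    for term, func in ((topology.bonds, bond_force),
                       (topology.angles, angle_force),
                       (topology.torsions, torsion_force)):
        for t in term:
            e, fdict = func(coords, t)
            energy += e
            for idx, f in fdict.items():
                forces[idx] += f
    return energy, forces


# --------------------------------------------------------------------------
# FLOP-cost model


@dataclass(frozen=True)
class FlopWeights:
    """Operation costs used by the bonded-force FLOP accounting."""

    add: float = 1.0
    mul: float = 1.0
    rsqrt: float = 10.0
    cos: float = 10.0
    acos: float = 10.0

    def __post_init__(self):
        if any(w <= 0 for w in (self.add, self.mul, self.rsqrt, self.cos, self.acos)):
            raise ValueError("all operation weights must be positive")


@dataclass(frozen=True)
class BondTypeCost:
    """Per-interaction FLOP total and per-atom multiplicity of a bond type."""

    name: str
    flops_per_interaction: float
    per_atom_multiplicity: float

    @property
    def per_atom_contribution(self) -> float:
        """Contribution rounded to one decimal, as tabulated."""
        return round(self.flops_per_interaction * self.per_atom_multiplicity, 1)


def flops_per_interaction(counts: dict, weights: FlopWeights | None = None) -> float:
    """Weighted FLOP total of one bonded interaction.

    ``counts`` maps operation names (add, mul, rsqrt, cos, acos) to
    tallies; fractional tallies are allowed (torsion rows are averaged
    over periods).
    """
    if weights is None:
        weights = FlopWeights()
    total = 0.0
    for op, count in counts.items():
        if count < 0:
            raise ValueError(f"negative operation tally for {op!r}")
        try:
            w = getattr(weights, op)
        except AttributeError:
            raise KeyError(f"unknown operation {op!r}") from None
        total += count * w
    return total


#: Bonded-force cost table for a protein-rich spatial domain: operation
#: tallies for bond stretching (add 12, mul 9, rsqrt 1 -> 31 FLOP) and
#: angle bending (add 34, mul 42, rsqrt 4, cos 1, acos 1 -> 136 FLOP),
#: with per-atom multiplicities 1 and 1.8; the torsion entry carries its
#: period-averaged totals (183.84 FLOP, multiplicity 3.9) directly.
PROTEIN_RICH_COSTS = (
    BondTypeCost("bond stretching",
                 flops_per_interaction({"add": 12, "mul": 9, "rsqrt": 1}), 1.0),
    BondTypeCost("angle bending",
                 flops_per_interaction({"add": 34, "mul": 42, "rsqrt": 4,
                                        "cos": 1, "acos": 1}), 1.8),
    BondTypeCost("torsion", 183.84, 3.9),
)


def per_atom_flops(costs=PROTEIN_RICH_COSTS):
    """Per-bond-type per-atom FLOP contributions and their total.

    Each contribution is rounded to one decimal before summation (the
    tabulation convention); the default protein-rich composition yields
    31.0 + 244.8 + 717.0 = 992.8 FLOP per atom.
    """
    contributions = {c.name: c.per_atom_contribution for c in costs}
    return contributions, round(sum(contributions.values()), 1)
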