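"""Particle systems, synthetic generators and spatial decomposition.

The synthetic generators provide the three study systems used
throughout the tests and examples:

* ``lj_fluid`` — a neutral Lennard-Jones fluid in reduced units
  (epsilon = sigma = mass = 1), placed on a jittered cubic lattice with
  Maxwell-Boltzmann velocities; the workhorse for microcanonical
  energy-conservation checks.
* ``salt_lattice`` — a rock-salt arrangement of alternating +1/-1 point
  charges, whose exact Madelung energy makes it the standard oracle for
  Ewald implementations.
* ``toy_polymer`` — a single chain with bonds, angles and torsions plus
  the matching 1-2/1-3 non-bonded exclusions.

All generation is reproducible from an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bonded import Bond, Angle, Torsion, Topology

__all__ = ["System", "generate_system", "DomainDecomposition", "decompose"]


@dataclass
class System:
    """A periodic particle system with optional bonded topology."""

    positions: np.ndarray          # (n, 3), length units
    velocities: np.ndarray         # (n, 3)
    masses: np.ndarray             # (n,)
    charges: np.ndarray            # (n,)
    types: np.ndarray              # (n,) int indices into an AtomTypeTable
    box: np.ndarray                # (3,) orthorhombic box lengths
    groups: np.ndarray | None = None
    exclusions: set = field(default_factory=set)   # frozensets of index pairs
    topology: Topology | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.velocities = np.asarray(self.velocities, dtype=np.float64)
        self.masses = np.asarray(self.masses, dtype=np.float64)
        self.charges = np.asarray(self.charges, dtype=np.float64)
        self.types = np.asarray(self.types, dtype=np.int64)
        self.box = np.asarray(self.box, dtype=np.float64)
        n = len(self.positions)
        for name in ("velocities", "masses", "charges", "types"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match positions")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")
        self.wrap()

    @property
    def n(self) -> int:
        return len(self.positions)

    def wrap(self) -> None:
        """Wrap all positions into [0, box)."""
        self.positions = np.mod(self.positions, self.box)

    def kinetic_energy(self) -> float:
        return float(0.5 * np.sum(self.masses[:, None] * self.velocities ** 2))


def _maxwell_velocities(rng, n, masses, temperature):
    v = rng.normal(size=(n, 3)) * np.sqrt(temperature / masses)[:, None]
    v -= v.mean(axis=0)      # zero net momentum
    return v


def _jittered_lattice(rng, n, box, jitter):
    per_axis = int(np.ceil(n ** (1.0 / 3.0)))
    spacing = box / per_axis
    sites = np.array([(i, j, k) for i in range(per_axis)
                      for j in range(per_axis) for k in range(per_axis)])
    sites = (sites[:n] + 0.5) * spacing
    return sites + rng.uniform(-jitter, jitter, size=(n, 3)) * spacing


def generate_system(kind: str, n_particles: int, density: float,
                    seed: int = 0, temperature: float = 0.7,
                    min_separation: float = 0.85) -> System:
    """Build one of the synthetic study systems (reproducible by seed)."""
    if n_particles < 2:
        raise ValueError("need at least two particles")
    if not density > 0:
        raise ValueError("density must be positive")
    rng = np.random.default_rng(seed)

    if kind == "lj_fluid":
        volume = n_particles / density
        box = np.full(3, volume ** (1.0 / 3.0))
        pos = np.mod(_jittered_lattice(rng, n_particles, box[0], 0.15), box)
        _check_separation(pos, box, min_separation)
        masses = np.ones(n_particles)
        return System(positions=pos,
                      velocities=_maxwell_velocities(rng, n_particles, masses,
                                                     temperature),
                      masses=masses, charges=np.zeros(n_particles),
                      types=np.zeros(n_particles, dtype=np.int64), box=box)

    if kind == "salt_lattice":
        per_axis = round(n_particles ** (1.0 / 3.0))
        if per_axis ** 3 != n_particles or per_axis % 2 != 0:
            raise ValueError("salt_lattice needs n = m^3 with even m "
                             "(charge neutrality)")
        a = density ** (-1.0 / 3.0)      # nearest-neighbour spacing
        box = np.full(3, per_axis * a)
        ijk = np.array([(i, j, k) for i in range(per_axis)
                        for j in range(per_axis) for k in range(per_axis)])
        pos = (ijk + 0.5) * a
        charges = np.where(ijk.sum(axis=1) % 2 == 0, 1.0, -1.0)
        return System(positions=pos, velocities=np.zeros((n_particles, 3)),
                      masses=np.ones(n_particles), charges=charges,
                      types=np.zeros(n_particles, dtype=np.int64), box=box)

    if kind == "toy_polymer":
        # zig-zag chain along x with small random perturbations
        bond_r0 = 1.0
        volume = max(n_particles / density, (1.5 * n_particles * bond_r0) ** 3 / 64)
        box = np.full(3, max(volume ** (1.0 / 3.0), 1.2 * n_particles * bond_r0 * 0.6))
        pos = np.zeros((n_particles, 3))
        pos[:, 0] = np.arange(n_particles) * bond_r0 * 0.8
        pos[:, 1] = np.where(np.arange(n_particles) % 2 == 0, 0.0, bond_r0 * 0.6)
        pos += rng.normal(scale=0.03, size=pos.shape)
        pos += box / 2 - pos.mean(axis=0)
        topo = Topology(
            n_particles=n_particles,
            bonds=[Bond(i, i + 1, 300.0, bond_r0)
                   for i in range(n_particles - 1)],
            angles=[Angle(i, i + 1, i + 2, 40.0, np.deg2rad(110.0))
                    for i in range(n_particles - 2)],
            torsions=[Torsion(i, i + 1, i + 2, i + 3, 1.5, 3, 0.0)
                      for i in range(n_particles - 3)],
        )
        masses = np.ones(n_particles)
        return System(positions=pos,
                      velocities=_maxwell_velocities(rng, n_particles, masses,
                                                     temperature),
                      masses=masses, charges=np.zeros(n_particles),
                      types=np.zeros(n_particles, dtype=np.int64), box=box,
                      exclusions=topo.excluded_pairs(), topology=topo)

    raise ValueError(f"unknown system kind: {kind!r}")


def _check_separation(pos, box, min_separation):
    n = len(pos)
    if n > 512:      # generator lattice guarantees separation at scale
        return
    ii, jj = np.triu_indices(n, k=1)
    dr = pos[ii] - pos[jj]
    dr -= box * np.round(dr / box)
    r = np.linalg.norm(dr, axis=1)
    if r.min() < min_separation:
        raise ValueError(
            f"density too high: minimum separation {r.min():.3f} below "
            f"{min_separation}")


# -- spatial decomposition -------------------------------------------------

#: the 13 half-stencil neighbour-cell offsets (one of each +/- pair of the
#: 26 Chebyshev-1 offsets), lexicographically positive
HALF_STENCIL = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)


@dataclass
class DomainDecomposition:
    """Cell grid over the box mapped to virtual chips.

    ``cell_of`` assigns each particle to exactly one home cell
    (half-open intervals); ``pair_arrays`` enumerates every
    within-cutoff pair exactly once via the half stencil.
    """

    grid: tuple
    cell_size: np.ndarray
    cells: dict                   # cell index tuple -> particle index array
    box: np.ndarray
    cutoff: float

    def pair_arrays(self):
        """(i, j) index arrays covering each candidate pair exactly once."""
        out_i, out_j = [], []
        gx, gy, gz = self.grid
        single = (gx == 1 and gy == 1 and gz == 1)
        done_cell_pairs = set()
        for cell, members in self.cells.items():
            if len(members) > 1:
                ii, jj = np.triu_indices(len(members), k=1)
                out_i.append(members[ii])
                out_j.append(members[jj])
            if single:
                continue
            for off in HALF_STENCIL:
                ncell = ((cell[0] + off[0]) % gx, (cell[1] + off[1]) % gy,
                         (cell[2] + off[2]) % gz)
                key = frozenset((cell, ncell))
                if ncell == cell or key in done_cell_pairs:
                    continue     # wrapped onto self/duplicate on tiny grids
                done_cell_pairs.add(key)
                others = self.cells.get(ncell)
                if others is None or len(others) == 0 or len(members) == 0:
                    continue
                ii, jj = np.meshgrid(members, others, indexing="ij")
                out_i.append(ii.ravel())
                out_j.append(jj.ravel())
        if not out_i:
            return (np.empty(0, dtype=np.int64),) * 2
        return np.concatenate(out_i), np.concatenate(out_j)


def decompose(system: System, cell_size: float,
              grid: tuple | None = None) -> DomainDecomposition:
    """Bin particles into cells of at least the cut-off size."""
    if grid is None:
        grid = tuple(max(1, int(b // cell_size)) for b in system.box)
    grid = tuple(int(g) for g in grid)
    cell_len = system.box / np.asarray(grid, dtype=np.float64)
    if np.any(cell_len < cell_size - 1e-12):
        raise ValueError("cells smaller than the requested cell size "
                         "(must be >= the cut-off)")
    idx = np.floor(system.positions / cell_len).astype(np.int64)
    idx = np.minimum(idx, np.asarray(grid) - 1)   # guard exact upper edge
    cells: dict = {}
    for p, c in enumerate(map(tuple, idx)):
        cells.setdefault(c, []).append(p)
    cells = {c: np.asarray(m, dtype=np.int64) for c, m in cells.items()}
    return DomainDecomposition(grid=grid, cell_size=cell_len, cells=cells,
                               box=system.box, cutoff=cell_size)
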