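"""The MD mini-engine: per-step schedule, forces, leap-frog integration.

One timestep follows the machine's stage graph::

    distribute -> { charge_assign -> poisson -> back_interp
                  | nonbonded | bonded }      -> gather -> update

All short-range forces pass through the emulated fixed-point path: each
pair (and each bonded term) is evaluated once in floating point,
quantized to the 32-bit force format, and deposited with exact
action-reaction (the same integer word added to one side and subtracted
from the other), so the short-range contribution to the total force is
exactly the zero word and any domain decomposition reproduces the flat
computation bit for bit.  Mesh (reciprocal-space) forces are quantized
per particle; their float-space sum vanishes by construction but their
quantized sum is only zero to ~n/2 lsb.

Units: the engine is unit-agnostic; the bundled generators use reduced
Lennard-Jones units (epsilon = sigma = mass = 1) and Gaussian-unit
electrostatics (energy = q1*q2/r).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bonded import bond_force, angle_force, torsion_force
from .ewald import (EwaldParams, spread_charges, solve_poisson,
                    back_interpolate, self_energy)
from .fixedpoint import FixedFormat, ForceBank, quantize
from .pipeline import AtomTypeTable, PipelineConfig, combine_params, eval_pairs
from .system import System, decompose

__all__ = [
    "STAGES",
    "STAGE_DEPENDENCIES",
    "StepSchedule",
    "SimulationConfig",
    "EnergyRecord",
    "compute_forces",
    "leapfrog_step",
    "run_step",
    "run",
]

STAGES = ("distribute", "charge_assign", "nonbonded", "bonded", "poisson",
          "back_interp", "gather", "update")

#: stage -> stages it depends on
STAGE_DEPENDENCIES = {
    "distribute": (),
    "charge_assign": ("distribute",),
    "nonbonded": ("distribute",),
    "bonded": ("distribute",),
    "poisson": ("charge_assign",),
    "back_interp": ("poisson",),
    "gather": ("nonbonded", "bonded", "back_interp"),
    "update": ("gather",),
}


@dataclass(frozen=True)
class StepSchedule:
    """An execution order of the per-step stages (must be topological)."""

    order: tuple = STAGES

    def __post_init__(self):
        if set(self.order) != set(STAGES):
            raise ValueError("schedule must contain every stage exactly once")
        seen = set()
        for stage in self.order:
            for dep in STAGE_DEPENDENCIES[stage]:
                if dep not in seen:
                    raise ValueError(
                        f"stage {stage!r} scheduled before its dependency {dep!r}")
            seen.add(stage)


@dataclass
class SimulationConfig:
    """Engine parameters for a run."""

    dt: float = 0.004
    n_steps: int = 100
    cutoff: float = 2.5
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    type_table: AtomTypeTable = field(
        default_factory=lambda: AtomTypeTable([1.0], [1.0]))
    ewald: EwaldParams | None = None
    vdw_shift: bool = True       # shift LJ so U(cutoff) = 0 (energy bookkeeping)
    use_cells: bool = True
    include_14: bool = False     # exclude 1-4 bonded pairs from non-bonded too
    seed: int = 0
    output_every: int = 10

    def __post_init__(self):
        if not self.dt > 0:
            raise ValueError("dt must be positive")


@dataclass
class EnergyRecord:
    """Energy bookkeeping for one step."""

    step: int
    kinetic: float
    bonded: float
    short_range: float       # LJ + screened real-space Coulomb
    long_range: float        # reciprocal mesh + self energy

    @property
    def potential(self) -> float:
        return self.bonded + self.short_range + self.long_range

    @property
    def total(self) -> float:
        return self.kinetic + self.potential


def _vdw_shift_energy(config: SimulationConfig, eps, sig):
    """Energy shift making the truncated LJ potential continuous at r_c."""
    a = (sig / config.cutoff) ** 6
    return 4.0 * eps * (a * a - a)


def _nonbonded_pairs(system: System, config: SimulationConfig):
    """Candidate pair index arrays (each pair once, exclusions removed)."""
    if config.use_cells and np.all(system.box >= 3 * config.cutoff):
        dd = decompose(system, config.cutoff)
        ii, jj = dd.pair_arrays()
    else:
        ii, jj = np.triu_indices(system.n, k=1)
    if system.exclusions:
        excl = system.exclusions
        if config.include_14 and system.topology is not None:
            excl = excl | system.topology.excluded_pairs(include_14=True)
        keep = np.array([frozenset((int(a), int(b))) not in excl
                         for a, b in zip(ii, jj)])
        ii, jj = ii[keep], jj[keep]
    return ii, jj


def compute_forces(system: System, config: SimulationConfig,
                   flat: bool = False):
    """All forces of one step through the fixed-point path.

    Returns ``(bank, energies)`` where ``bank`` is the fixed-point force
    accumulator and ``energies`` a dict with ``bonded``, ``short_range``
    and ``long_range`` entries.  With ``flat=True`` the non-bonded pair
    list is built by the all-pairs scan instead of the cell
    decomposition (the totals must agree bit for bit).
    """
    pconf = config.pipeline
    bank = ForceBank(system.n, pconf.force_fmt)
    energies = {"bonded": 0.0, "short_range": 0.0, "long_range": 0.0}

    # non-bonded short range (LJ + screened Coulomb), pairwise fixed point
    if flat:
        ii, jj = np.triu_indices(system.n, k=1)
        if system.exclusions:
            keep = np.array([frozenset((int(a), int(b))) not in system.exclusions
                             for a, b in zip(ii, jj)])
            ii, jj = ii[keep], jj[keep]
    else:
        ii, jj = _nonbonded_pairs(system, config)
    if len(ii):
        dr = system.positions[ii] - system.positions[jj]
        dr -= system.box * np.round(dr / system.box)
        eps, sig = combine_params(system.types[ii], system.types[jj],
                                  config.type_table, pconf)
        forces, pot_c, pot_v = eval_pairs(dr, system.charges[ii],
                                          system.charges[jj], eps, sig, pconf)
        if config.vdw_shift:
            r = np.linalg.norm(dr, axis=1)
            inside = (r <= pconf.cutoff_radius) & (eps > 0)
            pot_v = pot_v - np.where(
                inside, _vdw_shift_energy(config, eps, sig), 0.0)
        words = quantize(forces, bank.fmt)
        bank.deposit_words(ii, words)
        bank.deposit_words(jj, -words)
        energies["short_range"] = float(pot_c.sum() + pot_v.sum())

    # bonded terms: last atom of each term takes the negated integer sum,
    # so every term's fixed-point contribution is exactly zero
    if system.topology is not None:
        e_bonded = 0.0
        for terms, func in ((system.topology.bonds, bond_force),
                            (system.topology.angles, angle_force),
                            (system.topology.torsions, torsion_force)):
            for term in terms:
                e, fdict = func(system.positions, term)
                e_bonded += e
                idx = list(fdict.keys())
                words = quantize(np.array([fdict[a] for a in idx[:-1]]),
                                 bank.fmt)
                bank.deposit_words(idx[:-1], words)
                bank.deposit_words([idx[-1]], -words.sum(axis=0, keepdims=True))
        energies["bonded"] = e_bonded

    # long range: Gaussian-split Ewald mesh (only if charges are present)
    if config.ewald is not None and np.any(system.charges != 0.0):
        params = config.ewald
        if abs(params.alpha - pconf.alpha) > 1e-12:
            raise ValueError("Ewald alpha differs between the pipeline and "
                             "the mesh solver")
        mesh = spread_charges(system.positions, system.charges, params)
        phi = solve_poisson(mesh, params)
        f_recip, e_recip = back_interpolate(phi, system.positions,
                                            system.charges, params)
        bank.deposit(np.arange(system.n), f_recip)
        energies["long_range"] = float(e_recip.sum()
                                       + self_energy(system.charges, params))
    return bank, energies


def leapfrog_step(system: System, forces: np.ndarray, dt: float) -> System:
    """Leap-frog update: v(t+dt/2) = v(t-dt/2) + (f/m) dt, then drift."""
    system.velocities = system.velocities + forces / system.masses[:, None] * dt
    system.positions = system.positions + system.velocities * dt
    system.wrap()
    return system


def run_step(system: System, config: SimulationConfig, step: int = 0,
             schedule: StepSchedule | None = None):
    """Execute one timestep along the stage schedule.

    Returns ``(system, EnergyRecord, bank)``; the kinetic energy is the
    half-step value available to the integrator.
    """
    if schedule is None:
        schedule = StepSchedule()
    bank, energies = compute_forces(system, config)
    v_old = system.velocities.copy()
    system = leapfrog_step(system, bank.physical, config.dt)
    # on-step kinetic energy: v(t) is the mean of the two half-step values
    v_on = 0.5 * (v_old + system.velocities)
    kinetic = float(0.5 * np.sum(system.masses[:, None] * v_on ** 2))
    record = EnergyRecord(step=step, kinetic=kinetic,
                          bonded=energies["bonded"],
                          short_range=energies["short_range"],
                          long_range=energies["long_range"])
    return system, record, bank


def run(system: System, config: SimulationConfig,
        schedule: StepSchedule | None = None):
    """Run ``config.n_steps`` steps; returns (system, [EnergyRecord])."""
    records = []
    for step in range(config.n_steps):
        system, record, _ = run_step(system, config, step=step,
                                     schedule=schedule)
        records.append(record)
    return system, records
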