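"""Emulation of the non-bonded force-calculation pipeline.

Each pipeline evaluates one Coulomb + van der Waals pair interaction per
clock: both potentials and the force in a single pass, with the Coulomb
term screened by a cut-off factor (the Ewald real-space ``erfc`` kernel,
or a compactly supported polynomial taper), Lennard-Jones 12-6 van der
Waals with per-pair parameters built from an atom-type table by
combination rules, optional soft-core vdW and particle-group cut-offs.

Forces are deposited into fixed-point accumulators with action-reaction
symmetry: the pair is evaluated once and the *same integer word* is
added to particle i and subtracted from particle j, so the pair's
contribution to the total force is exactly the zero word.

Pair evaluation itself is done in double precision (the hardware's
mixed-precision datapath is single-precision-grade; the emulator's
fidelity model is the 32-bit coordinate quantization on input and the
32-bit fixed-point force quantization on output, both of which are
modelled exactly).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .fixedpoint import FixedFormat, ForceBank, quantize

__all__ = [
    "MAX_ATOM_TYPES",
    "BLOCK_PARTICLE_LIMIT",
    "AtomTypeTable",
    "SoftCoreParams",
    "PipelineConfig",
    "PairResult",
    "combine_params",
    "coulomb_cutoff_phi",
    "coulomb_cutoff_g",
    "eval_pair",
    "eval_pairs",
    "eval_block",
    "softcore_vdw",
    "group_cutoff_filter",
    "minimum_image",
]

MAX_ATOM_TYPES = 64          # type-table depth of the modelled hardware
BLOCK_PARTICLE_LIMIT = 16    # double-buffered register depth per block

_TWO_OVER_SQRT_PI = 2.0 / np.sqrt(np.pi)


class AtomTypeTable:
    """Lennard-Jones (epsilon, sigma) lookup table, at most 64 entries."""

    def __init__(self, epsilon, sigma):
        self.epsilon = np.asarray(epsilon, dtype=np.float64)
        self.sigma = np.asarray(sigma, dtype=np.float64)
        if self.epsilon.shape != self.sigma.shape or self.epsilon.ndim != 1:
            raise ValueError("epsilon and sigma must be 1-D and equal length")
        if len(self.epsilon) > MAX_ATOM_TYPES:
            raise ValueError(f"at most {MAX_ATOM_TYPES} atom types supported")
        if np.any(self.epsilon < 0):
            raise ValueError("epsilon must be non-negative")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive")

    def __len__(self) -> int:
        return len(self.epsilon)


@dataclass(frozen=True)
class SoftCoreParams:
    """Soft-core vdW: r^6 -> r^6 + alpha_sc*(1-lambda)*sigma^6."""

    lambda_: float = 1.0
    alpha_sc: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda_ <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")


@dataclass(frozen=True)
class PipelineConfig:
    """Cut-off kernel, combination rules and accumulation format."""

    alpha: float = 0.0                     # Ewald splitting constant (1/length)
    kernel: str = "gaussian"               # "gaussian" (erfc) | "finite_support"
    combination_rule_sigma: str = "arithmetic"
    combination_rule_epsilon: str = "geometric"
    cutoff_radius: float = 10.0
    softcore: SoftCoreParams | None = None
    group_exclusions: frozenset = frozenset()   # set of frozenset group pairs
    exclude_same_group: bool = False
    force_fmt: FixedFormat = field(default_factory=lambda: FixedFormat(32, 2.0 ** -20))

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if not self.cutoff_radius > 0:
            raise ValueError("cutoff_radius must be positive")
        if self.kernel not in ("gaussian", "finite_support"):
            raise ValueError(f"unknown kernel: {self.kernel!r}")
        for rule in (self.combination_rule_sigma, self.combination_rule_epsilon):
            if rule not in ("arithmetic", "geometric"):
                raise ValueError(f"unknown combination rule: {rule!r}")


@dataclass(frozen=True)
class PairResult:
    """One pair interaction: force on i (force on j is exactly -force_on_i)."""

    force_on_i: np.ndarray
    coulomb_potential: float
    vdw_potential: float


def minimum_image(dr, box):
    """Minimum-image displacement in an orthorhombic periodic box."""
    dr = np.asarray(dr, dtype=np.float64)
    box = np.asarray(box, dtype=np.float64)
    return dr - box * np.round(dr / box)


def combine_params(type_i, type_j, table: AtomTypeTable, config: PipelineConfig):
    """Per-pair (epsilon_ij, sigma_ij) from the type table by the
    configured combination rule (default Lorentz-Berthelot)."""
    type_i = np.asarray(type_i)
    type_j = np.asarray(type_j)
    n = len(table)
    if np.any(type_i < 0) or np.any(type_i >= n) or np.any(type_j < 0) or np.any(type_j >= n):
        raise IndexError("atom type index outside the type table")
    ei, si = table.epsilon[type_i], table.sigma[type_i]
    ej, sj = table.epsilon[type_j], table.sigma[type_j]
    if config.combination_rule_epsilon == "arithmetic":
        eps = 0.5 * (ei + ej)
    else:
        eps = np.sqrt(ei * ej)
    if config.combination_rule_sigma == "arithmetic":
        sig = 0.5 * (si + sj)
    else:
        sig = np.sqrt(si * sj)
    return eps, sig


def _quintic_taper(s):
    """Quintic in s = (r/r_c)^2: 1 at s=0, 0 at s=1 with two vanishing
    derivatives at the cut-off (and at the origin)."""
    s = np.asarray(s, dtype=np.float64)
    return 1.0 - s ** 3 * (10.0 - 15.0 * s + 6.0 * s ** 2)


def _quintic_taper_ds(s):
    s = np.asarray(s, dtype=np.float64)
    return -30.0 * s ** 2 * (1.0 - s) ** 2


def coulomb_cutoff_phi(t, kernel: str = "gaussian", t_cut: float | None = None):
    """Potential cut-off factor g_phi(t), t = alpha*r.

    ``gaussian`` returns erfc(t) (the Ewald real-space screen);
    ``finite_support`` returns the quintic taper in (t/t_cut)^2, exactly
    zero beyond t_cut.
    """
    t_arr = np.asarray(t, dtype=np.float64)
    if np.any(t_arr < 0):
        raise ValueError("cut-off argument must be non-negative")
    if kernel == "gaussian":
        out = special.erfc(t_arr)
    elif kernel == "finite_support":
        if t_cut is None or not t_cut > 0:
            raise ValueError("finite_support kernel needs a positive t_cut")
        s = np.clip((t_arr / t_cut) ** 2, 0.0, 1.0)
        out = _quintic_taper(s)
    else:
        raise ValueError(f"unknown kernel: {kernel!r}")
    return float(out) if np.ndim(t) == 0 else out


def coulomb_cutoff_g(t, kernel: str = "gaussian", t_cut: float | None = None):
    """Force cut-off factor g(t) with f = q_i q_j g(alpha*r)/r^2 * r_hat,
    consistent with f = -grad(phi) for the matching g_phi."""
    t_arr = np.asarray(t, dtype=np.float64)
    if np.any(t_arr < 0):
        raise ValueError("cut-off argument must be non-negative")
    if kernel == "gaussian":
        out = special.erfc(t_arr) + _TWO_OVER_SQRT_PI * t_arr * np.exp(-t_arr ** 2)
    elif kernel == "finite_support":
        if t_cut is None or not t_cut > 0:
            raise ValueError("finite_support kernel needs a positive t_cut")
        s = np.clip((t_arr / t_cut) ** 2, 0.0, 1.0)
        # phi = g_phi(s)/r; -r^2 dphi/dr = g_phi(s) - 2 s g_phi'(s)
        out = _quintic_taper(s) - 2.0 * s * _quintic_taper_ds(s)
    else:
        raise ValueError(f"unknown kernel: {kernel!r}")
    return float(out) if np.ndim(t) == 0 else out


def softcore_vdw(r2, lambda_, epsilon, sigma, alpha_sc: float = 0.5):
    """Soft-core Lennard-Jones at squared distance r2.

    Returns ``(dU_dr, potential)`` where dU_dr is the radial derivative
    (force magnitude along -r_hat is -dU_dr).  At lambda=1 this is plain
    LJ 12-6; for lambda<1 the effective r^6 is shifted by
    alpha_sc*(1-lambda)*sigma^6, keeping the potential finite at r=0.
    """
    if not 0.0 <= lambda_ <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    r2 = np.asarray(r2, dtype=np.float64)
    sig6 = np.asarray(sigma, dtype=np.float64) ** 6
    r6_eff = r2 ** 3 + alpha_sc * (1.0 - lambda_) * sig6
    a = sig6 / r6_eff
    pot = 4.0 * np.asarray(epsilon) * (a * a - a)
    # dU/dr = dU/dr6_eff * 6 r^5
    dU_dr6 = 4.0 * np.asarray(epsilon) * (-2.0 * a * a + a) / r6_eff
    dU_dr = dU_dr6 * 6.0 * r2 ** 2 * np.sqrt(r2)
    return dU_dr, pot


def _pair_terms(r, q_i, q_j, eps, sig, config: PipelineConfig):
    """Coulomb/vdW potential and radial derivative at distance r (arrays ok)."""
    t = config.alpha * r
    t_cut = config.alpha * config.cutoff_radius
    if config.kernel == "gaussian":
        g_phi = special.erfc(t)
        g_f = g_phi + _TWO_OVER_SQRT_PI * t * np.exp(-t * t)
    else:
        s = np.clip((r / config.cutoff_radius) ** 2, 0.0, 1.0)
        g_phi = _quintic_taper(s)
        g_f = g_phi - 2.0 * s * _quintic_taper_ds(s)
    qq = np.asarray(q_i) * np.asarray(q_j)
    pot_c = qq * g_phi / r
    # f = qq g_f / r^2 along +r_hat on i  =>  dphi/dr = -qq g_f / r^2
    dU_dr_c = -qq * g_f / (r * r)

    if config.softcore is not None:
        sc = config.softcore
        dU_dr_v, pot_v = softcore_vdw(r * r, sc.lambda_, eps, sig, sc.alpha_sc)
    else:
        a = (np.asarray(sig) / r) ** 6
        pot_v = 4.0 * np.asarray(eps) * (a * a - a)
        dU_dr_v = 4.0 * np.asarray(eps) * (-12.0 * a * a + 6.0 * a) / r
    return pot_c, dU_dr_c, pot_v, dU_dr_v


def eval_pairs(r_ij, q_i, q_j, eps, sig, config: PipelineConfig):
    """Vectorized pair evaluation on minimum-image displacements.

    Parameters are per-pair arrays; ``r_ij`` has shape (n, 3) and points
    from j to i.  Returns ``(forces_on_i, coulomb_pot, vdw_pot)`` with
    all outputs exactly zero beyond the cut-off radius.
    """
    r_ij = np.atleast_2d(np.asarray(r_ij, dtype=np.float64))
    r = np.linalg.norm(r_ij, axis=1)
    if np.any(r == 0.0):
        raise ValueError("coincident particles in pair evaluation")
    pot_c, dU_dr_c, pot_v, dU_dr_v = _pair_terms(
        r, q_i, q_j, eps, sig, config)
    inside = r <= config.cutoff_radius
    dU_dr = np.where(inside, dU_dr_c + dU_dr_v, 0.0)
    pot_c = np.where(inside, pot_c, 0.0)
    pot_v = np.where(inside, pot_v, 0.0)
    forces = -dU_dr[:, None] * r_ij / r[:, None]
    return forces, pot_c, pot_v


def eval_pair(r_i, r_j, q_i, q_j, type_i, type_j, table: AtomTypeTable,
              config: PipelineConfig, box=None) -> PairResult:
    """Evaluate one pair (Coulomb and vdW force + potentials in one pass)."""
    dr = np.asarray(r_i, dtype=np.float64) - np.asarray(r_j, dtype=np.float64)
    if box is not None:
        dr = minimum_image(dr, box)
    eps, sig = combine_params(type_i, type_j, table, config)
    forces, pot_c, pot_v = eval_pairs(dr[None, :], [q_i], [q_j],
                                      [eps], [sig], config)
    return PairResult(force_on_i=forces[0],
                      coulomb_potential=float(pot_c[0]),
                      vdw_potential=float(pot_v[0]))


def group_cutoff_filter(group_i, group_j, config: PipelineConfig) -> bool:
    """True if the pair is kept, False if its group pair is excluded."""
    if group_i is None or group_j is None:
        raise ValueError("particle-group cut-offs need a group label per particle")
    if config.exclude_same_group and group_i == group_j:
        return False
    return frozenset((group_i, group_j)) not in config.group_exclusions


def eval_block(i_indices, j_indices, positions, charges, types,
               table: AtomTypeTable, config: PipelineConfig,
               bank: ForceBank, box=None, skip_same_index: bool = False):
    """Evaluate every (i, j) pair of two register batches and accumulate.

    Models one pipeline-block pass: at most 16 i-particles and 16
    j-particles are resident at once; every cross pair is evaluated
    once and the quantized force word is added to i and subtracted
    from j (action-reaction), with per-particle partial sums reduced
    before the write to the accumulator bank.  With
    ``skip_same_index=True`` (self-block), pairs with i == j are
    skipped and each unordered pair is evaluated once.

    Returns ``(coulomb_energy, vdw_energy)`` for the evaluated pairs.
    """
    i_idx = np.asarray(i_indices, dtype=np.int64)
    j_idx = np.asarray(j_indices, dtype=np.int64)
    if len(i_idx) > BLOCK_PARTICLE_LIMIT or len(j_idx) > BLOCK_PARTICLE_LIMIT:
        raise ValueError(f"batch exceeds the {BLOCK_PARTICLE_LIMIT}-particle register limit")
    if len(i_idx) == 0 or len(j_idx) == 0:
        return 0.0, 0.0

    ii, jj = np.meshgrid(i_idx, j_idx, indexing="ij")
    ii, jj = ii.ravel(), jj.ravel()
    if skip_same_index:
        keep = ii < jj          # each unordered pair once, no self pairs
    else:
        keep = np.ones(len(ii), dtype=bool)
    ii, jj = ii[keep], jj[keep]
    if len(ii) == 0:
        return 0.0, 0.0

    positions = np.asarray(positions, dtype=np.float64)
    charges = np.asarray(charges, dtype=np.float64)
    types = np.asarray(types)
    dr = positions[ii] - positions[jj]
    if box is not None:
        dr = minimum_image(dr, box)
    eps, sig = combine_params(types[ii], types[jj], table, config)
    forces, pot_c, pot_v = eval_pairs(dr, charges[ii], charges[jj], eps, sig, config)

    words = quantize(forces, bank.fmt)
    bank.deposit_words(ii, words)
    bank.deposit_words(jj, -words)    # bit-exact negation
    return float(pot_c.sum()), float(pot_v.sum())
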