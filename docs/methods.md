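# Methods

This note records the models implemented by `socmd`, the parameter
choices that matter, and the places where the design was genuinely
open.

## Mixed-precision force path

Coordinates are modelled as 32-bit box-relative fixed point: one lsb is
`L/2³²` per axis, the finest uniform resolution a 32-bit word affords
over a periodic box, with the unsigned-fraction convention (the box
midpoint maps to word 2³¹). Encoding rounds half-to-even, so the
round-trip error is at most one lsb everywhere.

Pair interactions are evaluated in double precision on the quantized
coordinates (the real hardware datapath is single-precision-grade; what
the emulator reproduces exactly is the quantization at both ends, which
is what determines reproducibility). The resulting force is quantized
to a 32-bit force format — default lsb 2⁻²⁰ in the engine's force
units, configurable; at that setting the pipeline path agrees with a
pure double-precision evaluation to ~2·10⁻⁸ RMS relative on random
pairs, far inside the 10⁻⁶ single-precision-grade target — and
deposited with action–reaction symmetry: the identical integer word is
added on one side and subtracted on the other. Accumulation is
two's-complement integer addition with a sticky overflow flag (no
saturation), so any permutation or partition of the deposit stream
yields bit-identical totals. This is also what the accumulate-on-write
memory port and the reducing gather packets model: integer-only
summation whose result is arrival-order independent.

Consequences used by the tests: the total short-range force is exactly
the zero word every step; a cell decomposition reproduces the flat
all-pairs computation bit for bit. For bonded terms the last atom of
each term is assigned the negated integer sum of the other atoms'
words, so bonded contributions are exactly momentum-free as well. Mesh
(reciprocal-space) forces are quantized per particle; their float sum
vanishes by a k ↔ −k parity argument (see below) but their quantized
sum is only zero to ~n/2 lsb — the exact-zero guarantee is a property
of the pairwise paths.

ROM-table function evaluation is modelled as segmented least-squares
polynomials evaluated by Horner's rule. `erfc` is tabulated as a
quadratic fit of `log erfc` on [0, 6] (512 segments), which holds
~6·10⁻⁹ relative error over the function's 17 decades; inverse powers
are tabulated log–log, where a power law is exactly linear. The
single-precision tolerance (1.2·10⁻⁷) is asserted by tests.

## Non-bonded kernels

Coulomb: `φ = q_i q_j g_φ(αr)/r` with `g_φ = erfc` for the Gaussian
(Ewald) kernel, and a quintic taper `g(s) = 1 - s³(10 - 15s + 6s²)`,
`s = (r/r_c)²`, for the finite-support kernel — value and two
derivatives vanish at the cut-off, so force and potential are
continuous there. The force factor `g` is derived analytically from
`g_φ` so that `f = -∇φ` holds to central-difference accuracy (10⁻⁸).

Van der Waals: 12-6 Lennard-Jones with per-pair parameters from a
≤64-entry type table by arithmetic or geometric combination rules
(default Lorentz–Berthelot: arithmetic σ, geometric ε). The soft-core
variant substitutes `r⁶ → r⁶ + α_sc(1-λ)σ⁶` (Beutler-style), reducing
exactly to plain LJ at λ = 1 and staying finite at r = 0. The engine
optionally shifts the truncated LJ potential to zero at the cut-off for
energy bookkeeping (forces unchanged); this is on by default because
the microcanonical drift measure is otherwise dominated by potential
jumps at cut-off crossings.

Block semantics mirror the hardware: at most 16 i- and 16 j-particles
resident per pass, every cross pair evaluated once, per-particle
partial sums reduced before the bank write. Block partitioning is
bit-equivalent to a flat pass by the fixed-point argument above.

## Gaussian-split Ewald mesh

The Ewald split assigns `erfc(αr)/r` to the pairwise path (cut-off
validated so `erfc(α r_c) < 10⁻⁷`) and the remainder to the mesh:

1. charges spread with a truncated spherical Gaussian of width σ_s,
   discretely renormalized per particle so mesh charge is conserved to
   10⁻¹⁰;
2. FFT, multiplication by `(4π/k²)·exp(-k²/4α² + σ_s²k²)` — the
   remaining Ewald Gaussian applied and both spreading convolutions
   deconvolved in reciprocal space; k = 0 dropped (tinfoil boundary);
3. back interpolation with the same Gaussian weights (adjoint pair);
   forces interpolate the ik-differentiated field meshes.

Because the field route makes the net reciprocal force
`Σ_k ik G(k) |ρ̂(k)|²`, which cancels pairwise between k and −k, the
reciprocal forces sum to zero at machine rounding regardless of mesh
resolution.

Parameter defaults: σ_s = 0.8 mesh cells (capped at 0.45/α so the
reciprocal-space exponent stays decaying), support radius 6σ_s. The
support is the accuracy-critical choice: the truncated Gaussian tail is
amplified by the deconvolution, and 6σ (tail mass ~4·10⁻⁸) is what
brings the energy to ~10⁻⁵ relative agreement with a direct Ewald
summation oracle; at 5σ the error sits at the 10⁻⁴ boundary. With the
defaults, a 32³ mesh recovers the rock-salt Madelung constant to
2·10⁻⁴ and random neutral systems to ~10⁻⁵ against brute-force Ewald.

The self term is `-α/√π Σq²`; non-neutral systems are rejected rather
than silently background-corrected.

## Bonded forces and the FLOP model

Energy conventions (no ½ factors): `K_b(r-r₀)²`, `K_θ(θ-θ₀)²`,
`ΣV_n(1+cos(nφ-γ))`. All gradients are analytic and tested against
central differences at 10⁻⁸ and for vanishing net force and torque.
Near-collinear geometries clamp cosine arguments to ±(1 - 10⁻¹²);
exactly collinear torsions are rejected.

The FLOP model weights operation tallies (add/mul 1; rsqrt/cos/acos 10)
and multiplies by per-atom multiplicities of a protein-rich domain:
bond 31 × 1.0, angle 136 × 1.8 = 244.8, torsion 183.84 × 3.9 = 717.0
(per-row products rounded to one decimal before summation — the
tabulation convention; without that rounding the total is 992.776
rather than 992.8). The torsion row's per-operation tallies are carried
as period-averaged totals.

## Torus network

Type I packets route dimension-ordered (X→Y→Z) with per-axis shortest
wraparound; hop counts equal BFS distances on the torus graph. Type II
scatter uses a programmable per-(stage, inbound-direction) forwarding
table; the default is an axis chain — stage 1 fans out on all six
links, stage 2 forwards x→y, y→z, z→x, stage 3 completes the vertices
from the x-y edges plus one extra rule — chosen because, under
per-direction keying (the table cannot distinguish nodes positionally),
it reaches exactly the 26 Chebyshev-distance-1 neighbours in stages of
6/12/8 with exactly two redundant receptions, matching the published
pattern's cardinalities and redundancy. Type III gather forwards along
a line with a decrementing hop counter and reduces 32-bit integer
payloads through the accumulate-on-write port, so the terminal value is
arrival-order independent.

Link bandwidth is `lanes × rate × 0.8 (8b/10b) / 8` = 7.2 GB/s at the
default 12 × 6 Gbps; packet timing is the measured affine model
`T(ns) = 600 + 450·N_hop + 200·D/128` (D in 4-byte words). Packet
contention is not modelled (the measurements behind the latency model
do not include it).

## Performance estimator

Stage times: pipeline stages are `count / (64 × 0.8 GHz × 30 %)`;
GP-core stages are `FLOP / (0.6 GFLOPS × 20 %)`. The FFT cost model is
`2.5·N·log₂N` — the real-transform convention, adopted because it
reproduces the published 400 FLOP at N = 32 (the complex convention
gives 800). The Poisson stage composes three FFT rounds and two
four-hop transposes per direction, forward and inverse, plus the charge
gather and potential distribution, landing at 35 µs on the default 32³
mesh over 64 nodes. Particle distribution and force gathering are
modelled as three sequential scatter stages carrying the full per-node
payload (≈6.0/4.6 µs) — the published 5/4 µs figures exceed any single
latency-model evaluation, so the number of sequential transfers is a
modelling choice.

Two published figures are reported rather than reproduced: the
non-bonded stage (100×100×63 interactions at 30 % evaluates to 41 µs,
not the quoted ~30 µs) and the bonded stage (the quoted 8.3 µs matches
one atom per core, not the quoted two; the per-atom reading is the
default and both are exposed). The critical path composes
distribute → max(long-range chain, non-bonded, overlapped bonded) →
gather → update and exceeds 50 µs on the default 50 k-atom workload.

## Synthetic systems

The generators define the test conditions: a Lennard-Jones fluid in
reduced units (jittered lattice at density 0.5, Maxwell–Boltzmann
velocities at T = 0.7, zero net momentum) for microcanonical
conservation checks (64 particles, dt = 0.004τ, 500 steps — small
enough to run in well under a second, large enough for hundreds of
cut-off crossings); a rock-salt ±1 lattice whose exact Madelung energy
anchors the Ewald solver; and a toy polymer chain (bonds 300/1.0,
angles 40/110°, torsions V = 1.5, n = 3) with 1-2/1-3 exclusions
(1-4 exclusion is a flag). All generation is seed-reproducible.

What these do not emulate: real force-field heterogeneity (water
models, constraint networks), pressure/temperature coupling (the engine
is microcanonical only), and system sizes where neighbour-list
maintenance dominates. Passing tests therefore demonstrate numerical
fidelity of the force path and the network/cost models, not
biomolecular realism.

## Known limitations

- The mesh force quantization breaks the exact-zero total force at the
  ~n/2 lsb level (pairwise paths are exact).
- The finite-support Coulomb kernel truncates the true 1/r interaction;
  it models the hardware option, not an approximation to Ewald.
- Packet contention and header bytes are absorbed into the latency
  intercept; the network model is analytic, not event-driven.
- Single orthorhombic boxes only; no bond constraints or multiple
  timestepping.
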