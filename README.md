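# socmd

A small molecular-dynamics engine coupled to a computational model of a
special-purpose MD machine: a system-on-chip design whose dedicated
pipelines evaluate non-bonded pair interactions in mixed fixed-point
precision, whose general-purpose cores handle bonded forces and FFTs,
and whose chips form a 3D torus with programmable packet routing.

The package is for people studying hardware/software co-design for
particle simulation: it makes the machine's numerical behaviour
(deterministic integer force accumulation, mesh Ewald electrostatics,
Amber-form bonded forces) and its performance model (interaction
counts, FLOP budgets, link latencies, per-step critical path)
executable and testable at desk scale.

## What it computes

**Forces and dynamics.** Newton's equations `m_i d²r_i/dt² = -∇_i U`
are integrated with a leap-frog scheme. The potential is Amber-form:

```
U = Σ K_b (r - r₀)² + Σ K_θ (θ - θ₀)² + Σ V_n (1 + cos(nφ - γ))
  + Σ_pairs [ q_i q_j g_φ(αr)/r + 4ε_ij ((σ_ij/r)¹² - (σ_ij/r)⁶) ]
```

The Coulomb term is split Ewald-style: the short-range part is screened
by `g_φ(αr) = erfc(αr)` (or a compactly supported quintic taper) and
evaluated pairwise; the long-range part spreads charges onto a mesh
with a spherically symmetric Gaussian, solves the Poisson equation by
FFT with the Gaussian-split Green's function
`(4π/k²)·exp(-k²/4α² + σ_s²k²)`, and interpolates potentials and fields
back with the same weights.

**The fixed-point pipeline.** Coordinates enter as 32-bit box-relative
fixed point; every pair is evaluated once and the same quantized force
word is added to one particle and subtracted from the other. Because
integer addition commutes bit-exactly, the total force is exactly the
zero word and any domain decomposition reproduces the flat computation
bit for bit.

**The machine model.** 64 pipelines/chip at 0.8 GHz (peak 51.2 G
interactions/s), 64 GP cores at 0.6 GHz, 12-lane 6 Gbps 8b/10b links
(7.2 GB/s), packet latency `T(ns) = 600 + 450·N_hop + 200·D/128`, a
three-stage scatter reaching all 26 torus neighbours, and an
operation-weighted bonded FLOP budget of 992.8 FLOP/atom, composed into
a per-timestep critical-path estimate.

## Worked example

```
$ python examples/perf_estimate.py
stage          time (us)
distribute          5.96
charge_assign      11.25
nonbonded          41.02
bonded             16.55
poisson            35.00
back_interp        11.25
gather              4.56
update              1.00
critical_path      69.02
```

Charge assignment evaluates 100×1728 particle–mesh interactions on 64
pipelines at 30 % efficiency (11.25 µs); the Poisson stage interleaves
32-point FFTs (400 FLOP each, 3.3 µs per round at 20 % GP efficiency)
with four-hop mesh transposes (2.5 µs each) for 35 µs; the critical
path — distribution, the long-range chain, force gathering and the
update — lands at 69 µs, consistent with the design point that a
simple timestep cannot go below ~50 µs.

```
$ python examples/ewald_madelung.py
total Coulomb energy of 64 ions: -55.912699
energy per ion pair:             -1.747272
exact Madelung value:            -1.747565
relative error:                  1.68e-04
```

The mesh solver recovers the rock-salt lattice sum to 2·10⁻⁴,
and `examples/lj_fluid_run.py` shows a 500-step microcanonical run with
total energy conserved to 5·10⁻⁴ while the total fixed-point force is
the exact zero word each step.

Other examples: `fixedpoint_determinism.py` (order-independent integer
accumulation), `bonded_flops.py` (the per-atom FLOP budget),
`torus_scatter.py` (the 6/12/8 neighbour scatter with 2 redundant
copies). A thin CLI mirrors them: `socmd generate | run | perf |
network-trace`.

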