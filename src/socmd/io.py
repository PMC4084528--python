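"""Trajectory, energy-log and topology file I/O.

XYZ frames are the four-line-per-atom-block standard: atom count,
comment line (carrying ``step=<n> box=<lx> <ly> <lz>``), then one
``<element> x y z`` line per atom.  PDB output (CRYST1 + ATOM records)
goes through biotite so the fixed-column layout is guaranteed.  Energy
logs and network traces are tab-separated text.

The topology schema is a small line-oriented text format::

    particles <n>
    bond <i> <j> <k_b> <r0>
    angle <i> <j> <k> <k_theta> <theta0>
    torsion <i> <j> <k> <l> <v_n> <n> <gamma>
"""

from __future__ import annotations

import numpy as np

from .bonded import Bond, Angle, Torsion, Topology
from .system import System

__all__ = [
    "write_xyz_frame",
    "read_xyz",
    "write_pdb",
    "write_trajectory_frame",
    "write_energies",
    "write_topology",
    "read_topology",
]


def write_xyz_frame(system: System, stream, step: int = 0,
                    element: str = "Ar") -> None:
    stream.write(f"{system.n}\n")
    box = system.box
    stream.write(f"step={step} box={box[0]:.6f} {box[1]:.6f} {box[2]:.6f}\n")
    for p in system.positions:
        stream.write(f"{element} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")


def read_xyz(stream):
    """Read all XYZ frames; returns list of (step, box, positions)."""
    frames = []
    lines = stream.read().splitlines()
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        n = int(lines[pos])
        comment = lines[pos + 1]
        fields = dict(kv.split("=", 1) for kv in comment.split(" ", 1))
        step = int(fields.get("step", 0))
        box = np.array([float(x) for x in fields["box"].split()])
        coords = np.array([[float(x) for x in lines[pos + 2 + i].split()[1:4]]
                           for i in range(n)])
        frames.append((step, box, coords))
        pos += 2 + n
    return frames


def write_pdb(system: System, path, element: str = "C") -> None:
    """Minimal PDB output (CRYST1 + ATOM records) via biotite."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    atoms = struc.AtomArray(system.n)
    atoms.coord = np.asarray(system.positions, dtype=np.float32)
    atoms.chain_id = np.full(system.n, "A")
    atoms.res_id = np.arange(1, system.n + 1)
    atoms.res_name = np.full(system.n, "UNK")
    atoms.atom_name = np.full(system.n, element)
    atoms.element = np.full(system.n, element)
    atoms.box = np.diag(system.box).astype(np.float32)
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(path)


def write_trajectory_frame(system: System, stream_or_path, fmt: str = "xyz",
                           step: int = 0) -> None:
    if fmt == "xyz":
        write_xyz_frame(system, stream_or_path, step=step)
    elif fmt == "pdb":
        write_pdb(system, stream_or_path)
    else:
        raise ValueError(f"unknown trajectory format: {fmt!r}")


def write_energies(records, stream) -> None:
    """Tab-separated energy log, one row per step."""
    stream.write("step\tkinetic\tbonded\tshort_range\tlong_range\ttotal\n")
    for r in records:
        stream.write(f"{r.step}\t{r.kinetic:.10g}\t{r.bonded:.10g}\t"
                     f"{r.short_range:.10g}\t{r.long_range:.10g}\t"
                     f"{r.total:.10g}\n")


def write_topology(topology: Topology, stream) -> None:
    stream.write(f"particles {topology.n_particles}\n")
    for b in topology.bonds:
        stream.write(f"bond {b.i} {b.j} {b.k_b:.10g} {b.r0:.10g}\n")
    for a in topology.angles:
        stream.write(f"angle {a.i} {a.j} {a.k} {a.k_theta:.10g} {a.theta0:.10g}\n")
    for t in topology.torsions:
        stream.write(f"torsion {t.i} {t.j} {t.k} {t.l} {t.v_n:.10g} "
                     f"{t.n} {t.gamma:.10g}\n")


def read_topology(stream) -> Topology:
    n_particles = None
    bonds, angles, torsions = [], [], []
    for raw in stream:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        kind, *rest = line.split()
        if kind == "particles":
            n_particles = int(rest[0])
        elif kind == "bond":
            bonds.append(Bond(int(rest[0]), int(rest[1]),
                              float(rest[2]), float(rest[3])))
        elif kind == "angle":
            angles.append(Angle(int(rest[0]), int(rest[1]), int(rest[2]),
                                float(rest[3]), float(rest[4])))
        elif kind == "torsion":
            torsions.append(Torsion(int(rest[0]), int(rest[1]), int(rest[2]),
                                    int(rest[3]), float(rest[4]),
                                    int(rest[5]), float(rest[6])))
        else:
            raise ValueError(f"unknown topology record {kind!r}")
    if n_particles is None:
        raise ValueError("topology file lacks a 'particles' line")
    return Topology(n_particles=n_particles, bonds=bonds, angles=angles,
                    torsions=torsions)
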