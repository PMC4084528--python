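"""3D-torus interconnect model: routing, scatter/gather packets, timing.

The modelled machine connects its chips in a periodic 8x8x8 torus with
six directed links per node.  Three packet classes are modelled:

* **type I** — point-to-point, dimension-ordered shortest-path routing
  with wraparound;
* **type II** — multi-stage scatter: a node's particle data is forwarded
  by the network interfaces themselves so that all 26 Chebyshev-
  distance-1 neighbours receive it in three stages (6 face, 12 edge,
  8 vertex neighbours), without per-hop processor involvement.  The
  per-stage forwarding table is programmable; the default table below
  reaches all 26 neighbours with exactly two redundant receptions;
* **type III** — hop-decremented gather along a line, optionally with
  integer reduction performed by the accumulate-on-write memory port at
  the terminal node (inheriting its order-independence).

The timing model is affine in hops and payload:
``T(ns) = 600 + 450*N_hop + 200*D/128`` with ``D`` in 4-byte words,
and the link bandwidth is ``lanes * lane_rate * 8b/10b-efficiency``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fixedpoint import FixedFormat, FixedAccumulator

__all__ = [
    "DIRECTIONS",
    "TorusTopology",
    "LinkSpec",
    "LatencyModel",
    "ForwardingConfig",
    "Packet",
    "ScatterResult",
    "route_type1",
    "scatter_type2",
    "gather_type3",
    "link_bandwidth",
    "transfer_time",
]

#: the six signed axis directions, as (axis, sign)
DIRECTIONS = tuple((axis, sign) for axis in range(3) for sign in (+1, -1))


def _step(node, direction, dims):
    axis, sign = direction
    out = list(node)
    out[axis] = (out[axis] + sign) % dims[axis]
    return tuple(out)


@dataclass(frozen=True)
class TorusTopology:
    """Periodic 3-D grid of nodes with six directed links each."""

    dims: tuple = (8, 8, 8)

    def __post_init__(self):
        dims = tuple(int(d) for d in self.dims)
        object.__setattr__(self, "dims", dims)
        if len(dims) != 3 or any(d < 1 for d in dims):
            raise ValueError("torus dims must be three positive integers")

    @property
    def n_nodes(self) -> int:
        return int(np.prod(self.dims))

    def wrap(self, node) -> tuple:
        return tuple(int(c) % d for c, d in zip(node, self.dims))

    def neighbors(self, node) -> list:
        return [_step(self.wrap(node), d, self.dims) for d in DIRECTIONS]

    def axis_distance(self, a: int, b: int, axis: int) -> int:
        d = abs(a - b) % self.dims[axis]
        return min(d, self.dims[axis] - d)

    def hop_distance(self, src, dst) -> int:
        return sum(self.axis_distance(src[a], dst[a], a) for a in range(3))


@dataclass(frozen=True)
class LinkSpec:
    """One inter-chip link: 12 SerDes lanes at 6 Gbps with 8b/10b coding."""

    lanes: int = 12
    lane_rate_gbps: float = 6.0
    encoding_efficiency: float = 0.8

    def __post_init__(self):
        if self.lanes <= 0 or self.lane_rate_gbps <= 0 or not (
                0 < self.encoding_efficiency <= 1):
            raise ValueError("link parameters must be positive")


def link_bandwidth(spec: LinkSpec) -> float:
    """Payload bandwidth in bytes per second (12 x 6 Gbps x 0.8 / 8 = 7.2 GB/s)."""
    return spec.lanes * spec.lane_rate_gbps * 1e9 * spec.encoding_efficiency / 8.0


@dataclass(frozen=True)
class LatencyModel:
    """Measured affine packet-transfer latency model (nanoseconds)."""

    base_ns: float = 600.0
    per_hop_ns: float = 450.0
    per_128_words_ns: float = 200.0


def transfer_time(n_hop: int, d_words: float, model: LatencyModel | None = None) -> float:
    """Packet transfer time in nanoseconds for ``d_words`` 4-byte words."""
    if model is None:
        model = LatencyModel()
    if n_hop < 0 or d_words < 0:
        raise ValueError("hop count and payload must be non-negative")
    return model.base_ns + model.per_hop_ns * n_hop + model.per_128_words_ns * d_words / 128.0


@dataclass(frozen=True)
class Packet:
    """A routed packet; payloads are counted in 4-byte words."""

    ptype: str                      # "I" | "II" | "III"
    payload_words: int = 0
    src: tuple | None = None
    dst: tuple | None = None
    direction: tuple | None = None  # for type III lines
    stage: int = 0                  # type II forwarding stage
    hop_count: int = 0              # type III decrementing hop counter
    reduce_flag: bool = False

    def __post_init__(self):
        if self.ptype not in ("I", "II", "III"):
            raise ValueError(f"unknown packet type {self.ptype!r}")
        if self.ptype == "II" and self.stage > 3:
            raise ValueError("type II packets traverse at most 3 stages")


# -- type I --------------------------------------------------------------


def route_type1(src, dst, topology: TorusTopology) -> list:
    """Dimension-ordered (X then Y then Z) shortest path with wraparound.

    Returns the hop path as a list of nodes, starting after ``src`` and
    ending at ``dst``; its length is the hop count.
    """
    src = topology.wrap(src)
    dst = topology.wrap(dst)
    if src == dst:
        raise ValueError("source and destination coincide")
    path = []
    cur = list(src)
    for axis in range(3):
        dim = topology.dims[axis]
        delta = (dst[axis] - cur[axis]) % dim
        if delta == 0:
            continue
        sign = 1 if delta <= dim - delta else -1
        steps = delta if sign == 1 else dim - delta
        for _ in range(steps):
            cur[axis] = (cur[axis] + sign) % dim
            path.append(tuple(cur))
    return path


# -- type II -------------------------------------------------------------


def _default_forwarding() -> dict:
    """Default programmable forwarding table for the three-stage scatter.

    Keyed by (stage, inbound direction) -> tuple of outbound directions.
    Stage 1 (source transmission) fans out on all six links; stage 2
    chains each axis to the next (x->y, y->z, z->x) reaching the 12 edge
    neighbours; stage 3 completes the 8 vertex neighbours from the x-y
    edges, plus one extra rule whose two receptions are redundant (the
    published routing pattern also delivers two duplicate copies).
    """
    XP, XM, YP, YM, ZP, ZM = DIRECTIONS
    table = {
        (2, XP): (YP, YM), (2, XM): (YP, YM),
        (2, YP): (ZP, ZM), (2, YM): (ZP, ZM),
        (2, ZP): (XP, XM), (2, ZM): (XP, XM),
        (3, YP): (ZP, ZM), (3, YM): (ZP, ZM),
        (3, ZP): (XP,),
    }
    return table


@dataclass(frozen=True)
class ForwardingConfig:
    """Per-(stage, inbound-direction) outbound-direction sets for type II."""

    table: dict = field(default_factory=_default_forwarding)
    first_stage_directions: tuple = DIRECTIONS


@dataclass
class ScatterResult:
    """Reception schedule of a type II scatter."""

    source: tuple
    stage_receivers: list          # list of sets: first-time receivers per stage
    receptions: dict               # node -> number of copies received

    @property
    def receivers(self) -> set:
        out = set()
        for s in self.stage_receivers:
            out |= s
        return out

    @property
    def duplicate_count(self) -> int:
        return sum(c - 1 for c in self.receptions.values() if c > 1)


def scatter_type2(src, topology: TorusTopology,
                  config: ForwardingConfig | None = None) -> ScatterResult:
    """Simulate the multi-stage type II scatter from one source node."""
    if any(d < 3 for d in topology.dims):
        raise ValueError("type II scatter needs dims >= 3 per axis "
                         "(otherwise the 26 neighbours alias)")
    if config is None:
        config = ForwardingConfig()
    src = topology.wrap(src)

    receptions: dict = {}
    stage_receivers: list = []
    seen = {src}
    # frontier: list of (node, inbound direction)
    frontier = [(_step(src, d, topology.dims), d)
                for d in config.first_stage_directions]
    stage = 1
    while frontier:
        new_this_stage = set()
        for node, _ in frontier:
            receptions[node] = receptions.get(node, 0) + 1
            if node not in seen:
                new_this_stage.add(node)
                seen.add(node)
        stage_receivers.append(new_this_stage)
        next_frontier = []
        for node, inbound in frontier:
            for out in config.table.get((stage + 1, inbound), ()):
                next_frontier.append((_step(node, out, topology.dims), out))
        frontier = next_frontier
        stage += 1
        if stage > 3:
            if frontier:
                raise ValueError("forwarding table exceeds the 3-stage limit")
            break
    return ScatterResult(source=src, stage_receivers=stage_receivers,
                         receptions=receptions)


# -- type III ------------------------------------------------------------


def gather_type3(line_nodes, payloads, reduce: bool = True,
                 fmt: FixedFormat | None = None):
    """Gather along a communication line with hop-decremented packets.

    ``line_nodes`` are the contributing nodes in line order; the last
    one is the terminal.  Each node sends its payload with a hop count
    equal to its distance from the terminal; intermediate nodes forward
    with a decremented counter and the packet is stored when it reaches
    zero.  With ``reduce=True`` the terminal's memory port accumulates
    the 32-bit integer payloads on write, so the result equals the
    plain integer sum for any arrival order.

    Returns the terminal value (int with reduction, list without).
    """
    payloads = list(payloads)
    if len(payloads) != len(line_nodes):
        raise ValueError("one payload per line node required")
    if not reduce:
        return payloads
    if fmt is None:
        fmt = FixedFormat(32, 1.0)
    for p in payloads:
        if not isinstance(p, (int, np.integer)):
            raise TypeError("type III reduction payloads must be integer words")
    acc = FixedAccumulator(fmt)
    n = len(payloads)
    for dist, p in enumerate(payloads):
        hops = n - 1 - dist     # decremented to 0 at the terminal
        assert hops >= 0
        acc.add_word(int(p))
    return acc.value
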