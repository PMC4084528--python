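"""Independent reference implementations used as test oracles.

These are deliberately brute-force and share no code with the package:
the Ewald oracle evaluates the lattice sum by explicit real-space image
loops plus an explicit reciprocal k-sum; the pair oracle is plain
double-precision arithmetic on exact coordinates.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erfc

#: Madelung constant of the rock-salt structure (energy per ion pair
#: is -MADELUNG_NACL / nearest-neighbour distance)
MADELUNG_NACL = 1.747565


def direct_ewald_energy(pos, q, box_length, alpha, nreal=1, kmax=16):
    """Ewald energy by explicit image/k-space summation (cubic box)."""
    pos = np.asarray(pos, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    n = len(q)
    L = float(box_length)
    V = L ** 3

    e_real = 0.0
    rng_s = range(-nreal, nreal + 1)
    for i in range(n):
        for j in range(n):
            for a in rng_s:
                for b in rng_s:
                    for c in rng_s:
                        if i == j and a == b == c == 0:
                            continue
                        r = np.linalg.norm(pos[i] - pos[j]
                                           + np.array([a, b, c]) * L)
                        e_real += 0.5 * q[i] * q[j] * erfc(alpha * r) / r

    ks = 2.0 * np.pi / L * np.arange(-kmax, kmax + 1)
    KX, KY, KZ = np.meshgrid(ks, ks, ks, indexing="ij")
    K2 = KX ** 2 + KY ** 2 + KZ ** 2
    S = sum(q[j] * np.exp(1j * (KX * pos[j, 0] + KY * pos[j, 1]
                                + KZ * pos[j, 2])) for j in range(n))
    with np.errstate(divide="ignore", invalid="ignore"):
        coef = np.where(K2 > 0,
                        4.0 * np.pi / np.where(K2 > 0, K2, 1.0)
                        * np.exp(-K2 / (4.0 * alpha ** 2)), 0.0)
    e_k = 0.5 / V * np.sum(coef * np.abs(S) ** 2)
    e_self = -alpha / np.sqrt(np.pi) * np.sum(q ** 2)
    return e_real + e_k + e_self


def direct_ewald_forces(pos, q, box_length, alpha, nreal=1, kmax=16):
    """Ewald forces by explicit image/k-space summation (cubic box)."""
    pos = np.asarray(pos, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    n = len(q)
    L = float(box_length)
    V = L ** 3
    F = np.zeros((n, 3))

    rng_s = range(-nreal, nreal + 1)
    for i in range(n):
        for j in range(n):
            for a in rng_s:
                for b in rng_s:
                    for c in rng_s:
                        if i == j and a == b == c == 0:
                            continue
                        d = pos[i] - pos[j] + np.array([a, b, c]) * L
                        r = np.linalg.norm(d)
                        g = (erfc(alpha * r) + 2.0 * alpha * r / np.sqrt(np.pi)
                             * np.exp(-(alpha * r) ** 2))
                        F[i] += q[i] * q[j] * g / r ** 3 * d

    ks = 2.0 * np.pi / L * np.arange(-kmax, kmax + 1)
    KX, KY, KZ = np.meshgrid(ks, ks, ks, indexing="ij")
    K2 = KX ** 2 + KY ** 2 + KZ ** 2
    S = sum(q[j] * np.exp(1j * (KX * pos[j, 0] + KY * pos[j, 1]
                                + KZ * pos[j, 2])) for j in range(n))
    with np.errstate(divide="ignore", invalid="ignore"):
        coef = np.where(K2 > 0,
                        4.0 * np.pi / np.where(K2 > 0, K2, 1.0)
                        * np.exp(-K2 / (4.0 * alpha ** 2)), 0.0)
    for i in range(n):
        phase = KX * pos[i, 0] + KY * pos[i, 1] + KZ * pos[i, 2]
        im = np.imag(np.conj(S) * np.exp(1j * phase))
        F[i, 0] += q[i] / V * np.sum(coef * KX * im)
        F[i, 1] += q[i] / V * np.sum(coef * KY * im)
        F[i, 2] += q[i] / V * np.sum(coef * KZ * im)
    return F


def brute_force_pairs_within_cutoff(positions, box, cutoff):
    """All unordered within-cutoff pairs by the O(N^2) minimum-image scan."""
    positions = np.asarray(positions)
    box = np.asarray(box)
    n = len(positions)
    ii, jj = np.triu_indices(n, k=1)
    dr = positions[ii] - positions[jj]
    dr -= box * np.round(dr / box)
    r = np.linalg.norm(dr, axis=1)
    keep = r <= cutoff
    return {frozenset((int(a), int(b))) for a, b in zip(ii[keep], jj[keep])}


def bfs_hop_distances(dims):
    """All-pairs hop distances on a torus grid by breadth-first search."""
    from collections import deque
    import itertools
    nodes = list(itertools.product(*(range(d) for d in dims)))
    dist = {}
    for src in nodes:
        d = {src: 0}
        queue = deque([src])
        while queue:
            cur = queue.popleft()
            for axis in range(3):
                for sign in (1, -1):
                    nxt = list(cur)
                    nxt[axis] = (nxt[axis] + sign) % dims[axis]
                    nxt = tuple(nxt)
                    if nxt not in d:
                        d[nxt] = d[cur] + 1
                        queue.append(nxt)
        dist[src] = d
    return dist
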