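"""Shared fixtures.

The expensive Langevin runs (a 10⁶-step topology-conservation run and the
matched MO/LB comparison runs) are session-scoped so the unit tests and the
acceptance tests share a single simulation each.
"""

import numpy as np
import pytest

from kdnatools import network as net
from kdnatools import simulate as sim
from kdnatools import enrichment as enr


def make_disk_mask(radius=50, pad=15):
    n = 2 * (radius + pad) + 1
    c = radius + pad
    yy, xx = np.mgrid[0:n, 0:n]
    return (xx - c) ** 2 + (yy - c) ** 2 <= radius ** 2


def make_ellipse_mask(a=60, b=35, pad=15):
    n = 2 * (a + pad) + 1
    c = a + pad
    yy, xx = np.mgrid[0:n, 0:n]
    return ((xx - c) / a) ** 2 + ((yy - c) / b) ** 2 <= 1.0


def make_crescent_mask(radius=55, pad=15):
    n = 2 * (radius + pad) + 1
    c = radius + pad
    yy, xx = np.mgrid[0:n, 0:n]
    disk = (xx - c) ** 2 + (yy - c) ** 2 <= radius ** 2
    bite = (xx - c - 30) ** 2 + (yy - c) ** 2 <= 40 ** 2
    return disk & ~bite


def icosphere(subdiv=3, radius=2.0):
    """Subdivided icosahedron: a closed, near-uniform sphere triangulation."""
    t = (1 + np.sqrt(5)) / 2
    verts = [np.array(v, float) for v in
             [(-1, t, 0), (1, t, 0), (-1, -t, 0), (1, -t, 0),
              (0, -1, t), (0, 1, t), (0, -1, -t), (0, 1, -t),
              (t, 0, -1), (t, 0, 1), (-t, 0, -1), (-t, 0, 1)]]
    verts = [v / np.linalg.norm(v) for v in verts]
    faces = [[0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
             [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
             [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
             [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1]]
    for _ in range(subdiv):
        cache = {}
        newf = []

        def midpoint(a, b):
            key = (min(a, b), max(a, b))
            if key not in cache:
                m = (verts[a] + verts[b]) / 2
                verts.append(m / np.linalg.norm(m))
                cache[key] = len(verts) - 1
            return cache[key]

        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            newf += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        faces = newf
    V = radius * np.array(verts)
    F = np.array(faces)
    e1 = V[F[:, 1]] - V[F[:, 0]]
    e2 = V[F[:, 2]] - V[F[:, 0]]
    flip = np.einsum("ij,ij->i", np.cross(e1, e2), V[F].mean(axis=1)) < 0
    F[flip] = F[flip][:, [0, 2, 1]]
    return V, F


def make_free_ring(n_beads=100, bond=0.95):
    """SimState of an isolated semiflexible ring."""
    theta = 2 * np.pi * np.arange(n_beads) / n_beads
    R = n_beads * bond / (2 * np.pi)
    pos = np.column_stack([R * np.cos(theta), R * np.sin(theta),
                           np.zeros(n_beads)])
    bonds = np.array([[i, (i + 1) % n_beads] for i in range(n_beads)],
                     dtype=np.int64)
    angles = np.array([[(i - 1) % n_beads, i, (i + 1) % n_beads]
                       for i in range(n_beads)], dtype=np.int64)
    return sim.SimState(positions=pos, velocities=np.zeros((n_beads, 3)),
                        bonds=bonds, angles=angles)


@pytest.fixture(scope="session")
def disk_region():
    return enr.KdnaRegion.from_mask(make_disk_mask())


@pytest.fixture(scope="session")
def mo48():
    """Scaled-down minicircle-only network (48 rings, valence-3 honeycomb)."""
    return net.build_mo(n_rings=48, seed=11)


@pytest.fixture(scope="session")
def mo48_longrun(mo48):
    """10⁶-step Langevin run of the 48-ring MO network.

    Serves the topology-conservation and thermostat checks (final state) and
    the flat-disk curvature statistics (dumped trajectory: the long window
    gives the time-averaged H̄ far more effective samples than the short
    matched comparison runs).
    """
    state = sim.SimState.from_network(mo48, seed=12)
    params = sim.SimParams(seed=13)
    sim.relax(state, params)
    traj = sim.run(state, params, 1_000_000, dump_every=10_000)
    return mo48, state, traj


@pytest.fixture(scope="session")
def matched_runs():
    """Matched MO and LB protocol runs for the topology-comparison checks.

    Same lattice size, equilibration, production length and dump stride for
    both topologies; only the maxicircles differ.
    """
    out = {}
    for mode, seed in (("MO", 21), ("LB", 31)):
        base = net.build_mo(n_rings=48, seed=seed)
        network = base if mode == "MO" else net.add_maxicircles(
            base, mode="LB", seed=seed + 1)
        # longer burn-in than production: shorter-equilibration pilots left
        # a relaxation transient in the Rg trend diagnostic
        params = sim.SimParams(seed=seed + 2, equil_steps=100_000,
                               prod_steps=150_000, dump_every=2_000)
        traj, report = sim.run_protocol(network, params)
        out[mode] = (network, traj, report)
    return out
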