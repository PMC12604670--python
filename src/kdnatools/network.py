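"""Construction of catenated ring-polymer (Olympic) networks.

Builds the three model kDNA topologies as bead-spring ring collections:

* **MO** (minicircle-only): minicircles on a honeycomb (valence-3) planar
  lattice, each pair of neighbours forming a Hopf link;
* **LD** (linked diffuse): three mutually interlinked maxicircles threaded
  through minicircles sampled uniformly over the disk;
* **LB** (linked border): the maxicircles threaded along the boundary cycle
  of the minicircle disk.

Minicircle geometry: each ring is a circle of radius 0.6·spacing around its
lattice node, with an out-of-plane height modulation z = ±h·cos(3θ) whose
sign alternates between the two honeycomb sublattices. At each of the six
rim crossings with its three neighbours the modulation puts the two strands
on opposite sides of the plane, so every lattice edge is realised as a Hopf
link (|Lk| = 1) while second neighbours stay unlinked. Ring traversal
orientations are drawn at random, which randomises the chirality signs of
the links; the recorded chirality of every edge is its realised Gauss
linking number, verified numerically at build time.

Maxicircles are closed waypoint curves that travel above (+z0) and below
(−z0) the disk plane and cross it only through the holes of the minicircles
they thread, alternating dive direction so the curve closes; mutual
maxi–maxi Hopf links are realised by wrap clasps in a rendezvous region
outside the disk. All intended linking numbers are verified with the exact
polygonal Gauss double sum and the construction retries with a fresh seed on
failure.

All lengths are in reduced units of the bead diameter σ.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
from numba import njit

__all__ = [
    "OlympicNetwork", "linking_number", "build_mo", "add_maxicircles",
    "compress_to_disk",
]

MINI_BEADS = 60          # beads per minicircle
RING_RADIUS_FACTOR = 0.6     # ring radius / lattice spacing
RING_HEIGHT_FACTOR = 0.2     # z-modulation amplitude / lattice spacing
TARGET_BOND = 0.95           # target initial bead spacing, σ


# ---------------------------------------------------------------------------
# Gauss linking number
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _gauss_double_sum(a, b):  # pragma: no cover - exercised via wrapper
    """Polygonal Gauss linking integral (Klenin–Langowski segment formula)."""
    n = a.shape[0]
    m = b.shape[0]
    total = 0.0
    degenerate = False
    for i in range(n):
        a1x, a1y, a1z = a[i, 0], a[i, 1], a[i, 2]
        i2 = (i + 1) % n
        a2x, a2y, a2z = a[i2, 0], a[i2, 1], a[i2, 2]
        for j in range(m):
            b1x, b1y, b1z = b[j, 0], b[j, 1], b[j, 2]
            j2 = (j + 1) % m
            b2x, b2y, b2z = b[j2, 0], b[j2, 1], b[j2, 2]

            r13x, r13y, r13z = b1x - a1x, b1y - a1y, b1z - a1z
            r14x, r14y, r14z = b2x - a1x, b2y - a1y, b2z - a1z
            r23x, r23y, r23z = b1x - a2x, b1y - a2y, b1z - a2z
            r24x, r24y, r24z = b2x - a2x, b2y - a2y, b2z - a2z

            n1x = r13y * r14z - r13z * r14y
            n1y = r13z * r14x - r13x * r14z
            n1z = r13x * r14y - r13y * r14x
            n2x = r14y * r24z - r14z * r24y
            n2y = r14z * r24x - r14x * r24z
            n2z = r14x * r24y - r14y * r24x
            n3x = r24y * r23z - r24z * r23y
            n3y = r24z * r23x - r24x * r23z
            n3z = r24x * r23y - r24y * r23x
            n4x = r23y * r13z - r23z * r13y
            n4y = r23z * r13x - r23x * r13z
            n4z = r23x * r13y - r23y * r13x

            l1 = (n1x * n1x + n1y * n1y + n1z * n1z) ** 0.5
            l2 = (n2x * n2x + n2y * n2y + n2z * n2z) ** 0.5
            l3 = (n3x * n3x + n3y * n3y + n3z * n3z) ** 0.5
            l4 = (n4x * n4x + n4y * n4y + n4z * n4z) ** 0.5
            if l1 < 1e-13 or l2 < 1e-13 or l3 < 1e-13 or l4 < 1e-13:
                degenerate = True
                continue

            d12 = (n1x * n2x + n1y * n2y + n1z * n2z) / (l1 * l2)
            d23 = (n2x * n3x + n2y * n3y + n2z * n3z) / (l2 * l3)
            d34 = (n3x * n4x + n3y * n4y + n3z * n4z) / (l3 * l4)
            d41 = (n4x * n1x + n4y * n1y + n4z * n1z) / (l4 * l1)
            d12 = min(1.0, max(-1.0, d12))
            d23 = min(1.0, max(-1.0, d23))
            d34 = min(1.0, max(-1.0, d34))
            d41 = min(1.0, max(-1.0, d41))
            omega = (np.arcsin(d12) + np.arcsin(d23)
                     + np.arcsin(d34) + np.arcsin(d41))

            # sign from (r34 x r12) . r13
            r34x, r34y, r34z = b2x - b1x, b2y - b1y, b2z - b1z
            r12x, r12y, r12z = a2x - a1x, a2y - a1y, a2z - a1z
            cx = r34y * r12z - r34z * r12y
            cy = r34z * r12x - r34x * r12z
            cz = r34x * r12y - r34y * r12x
            s = cx * r13x + cy * r13y + cz * r13z
            if s > 0:
                total += omega
            elif s < 0:
                total -= omega
    return total / (4.0 * np.pi), degenerate


def _resample_closed(curve: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polyline to n approximately equidistant vertices."""
    pts = np.vstack([curve, curve[:1]])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    targets = np.linspace(0, total, n, endpoint=False)
    out = np.empty((n, 3))
    for d in range(3):
        out[:, d] = np.interp(targets, s, pts[:, d])
    return out


def linking_number(ring_a: np.ndarray, ring_b: np.ndarray,
                   tol: float = 0.2, max_refine: int = 3) -> int:
    """Gauss linking number of two closed polylines, rounded to an integer.

    Antisymmetric under orientation reversal of either ring. If the double
    sum lands farther than ``tol`` from an integer (near-touching segments),
    both curves are resampled at double resolution and the computation
    retried up to ``max_refine`` times before raising.
    """
    a = np.ascontiguousarray(ring_a, dtype=np.float64)
    b = np.ascontiguousarray(ring_b, dtype=np.float64)
    for attempt in range(max_refine + 1):
        val, degenerate = _gauss_double_sum(a, b)
        rounded = int(round(val))
        if not degenerate and abs(val - rounded) <= tol:
            return rounded
        a = _resample_closed(a, 2 * len(a))
        b = _resample_closed(b, 2 * len(b))
    raise ValueError(
        f"Gauss linking integral did not converge to an integer (got {val:.3f})")


def gauss_linking_float(ring_a: np.ndarray, ring_b: np.ndarray) -> float:
    """Raw (unrounded) Gauss linking integral; mainly for diagnostics."""
    val, _ = _gauss_double_sum(np.ascontiguousarray(ring_a, np.float64),
                               np.ascontiguousarray(ring_b, np.float64))
    return val


# ---------------------------------------------------------------------------
# network container
# ---------------------------------------------------------------------------

@dataclass
class OlympicNetwork:
    """Bead-spring ring collection with verified catenation topology.

    ``coords`` holds all bead positions (N, 3) in σ units; ``ring_slices``
    maps ring index to its (start, n_beads) block; ``link_edges`` records
    (ring_i, ring_j, chirality) for every intended catenation, where the
    chirality is the realised Gauss linking number (±1). ``graph`` is the
    planar adjacency of the minicircles.
    """

    coords: np.ndarray
    ring_slices: list[tuple[int, int]]
    ring_class: list[str]                      # "mini" | "maxi" per ring
    link_edges: list[tuple[int, int, int]]
    graph: nx.Graph
    mode: str = "MO"
    spacing: float = 12.5

    @property
    def n_rings(self) -> int:
        return len(self.ring_slices)

    @property
    def n_beads(self) -> int:
        return self.coords.shape[0]

    @property
    def mini_rings(self) -> list[int]:
        return [i for i, c in enumerate(self.ring_class) if c == "mini"]

    @property
    def maxi_rings(self) -> list[int]:
        return [i for i, c in enumerate(self.ring_class) if c == "maxi"]

    def ring_coords(self, i: int) -> np.ndarray:
        start, n = self.ring_slices[i]
        return self.coords[start:start + n]

    def ring_centers(self, rings: list[int] | None = None) -> np.ndarray:
        rings = rings if rings is not None else range(self.n_rings)
        return np.array([self.ring_coords(i).mean(axis=0) for i in rings])

    def boundary_rings(self) -> list[int]:
        """Minicircles on the outer rim (catenation valence < 3), ordered by
        angle around the disk centroid."""
        mini = self.mini_rings
        deg = dict(self.graph.degree(mini))
        rim = [i for i in mini if deg.get(i, 0) < 3]
        centers = self.ring_centers(rim)
        c0 = self.ring_centers(mini).mean(axis=0)
        ang = np.arctan2(centers[:, 1] - c0[1], centers[:, 0] - c0[0])
        return [rim[k] for k in np.argsort(ang)]

    def bonds(self) -> np.ndarray:
        out = []
        for start, n in self.ring_slices:
            for k in range(n):
                out.append((start + k, start + (k + 1) % n))
        return np.array(out, dtype=np.int64)

    def angles(self) -> np.ndarray:
        out = []
        for start, n in self.ring_slices:
            for k in range(n):
                out.append((start + (k - 1) % n, start + k, start + (k + 1) % n))
        return np.array(out, dtype=np.int64)

    # -- topology bookkeeping ------------------------------------------------

    def linking_matrix(self, pairs: list[tuple[int, int]] | None = None) -> dict:
        """Gauss linking number per ring pair.

        With ``pairs=None``, all pairs whose bounding spheres overlap are
        evaluated (others are 0 by geometry and skipped). Returns a dict
        {(i, j): Lk} containing only non-zero entries plus every requested
        pair.
        """
        result = {}
        if pairs is None:
            centers = self.ring_centers()
            radii = np.array([
                np.linalg.norm(self.ring_coords(i) - centers[i], axis=1).max()
                for i in range(self.n_rings)])
            pairs = []
            for i in range(self.n_rings):
                for j in range(i + 1, self.n_rings):
                    if np.linalg.norm(centers[i] - centers[j]) < radii[i] + radii[j] + 1.0:
                        pairs.append((i, j))
        for i, j in pairs:
            lk = linking_number(self.ring_coords(i), self.ring_coords(j))
            result[(min(i, j), max(i, j))] = lk
        return result

    def intended_links(self) -> dict:
        return {(min(i, j), max(i, j)): s for i, j, s in self.link_edges}

    def verify_topology(self, full: bool = False) -> None:
        """Check realised linking numbers against intended ``link_edges``.

        With ``full=True`` every geometrically-possible pair is evaluated and
        spurious catenations raise too.
        """
        intended = self.intended_links()
        if full:
            realised = self.linking_matrix()
            realised = {k: v for k, v in realised.items() if v != 0}
        else:
            realised = {}
            for (i, j) in intended:
                realised[(i, j)] = linking_number(self.ring_coords(i),
                                                  self.ring_coords(j))
            realised = {k: v for k, v in realised.items() if v != 0}
        missing = {k: v for k, v in intended.items() if realised.get(k) != v}
        spurious = {k: v for k, v in realised.items() if k not in intended}
        if missing or spurious:
            raise ValueError(
                "topology verification failed: "
                f"unrealised/wrong edges {missing}, spurious links {spurious}")

    # -- I/O -------------------------------------------------------------

    def to_lammps_data(self, path) -> None:
        """Write a LAMMPS data file (atom_style angle/molecular layout)."""
        bonds = self.bonds()
        angles = self.angles()
        lo = self.coords.min(axis=0) - 10
        hi = self.coords.max(axis=0) + 10
        mol = np.empty(self.n_beads, dtype=np.int64)
        for r, (start, n) in enumerate(self.ring_slices):
            mol[start:start + n] = r + 1
        with open(path, "w") as fh:
            fh.write("kDNA Olympic network\n\n")
            fh.write(f"{self.n_beads} atoms\n{len(bonds)} bonds\n"
                     f"{len(angles)} angles\n\n")
            fh.write("2 atom types\n1 bond types\n1 angle types\n\n")
            for d, name in enumerate("xyz"):
                fh.write(f"{lo[d]:.6f} {hi[d]:.6f} {name}lo {name}hi\n")
            fh.write("\nMasses\n\n1 1.0\n2 1.0\n\nAtoms\n\n")
            for i, (x, y, z) in enumerate(self.coords):
                atype = 1 if self.ring_class[mol[i] - 1] == "mini" else 2
                fh.write(f"{i + 1} {mol[i]} {atype} {x:.6f} {y:.6f} {z:.6f}\n")
            fh.write("\nBonds\n\n")
            for k, (i, j) in enumerate(bonds):
                fh.write(f"{k + 1} 1 {i + 1} {j + 1}\n")
            fh.write("\nAngles\n\n")
            for k, (i, j, l) in enumerate(angles):
                fh.write(f"{k + 1} 1 {i + 1} {j + 1} {l + 1}\n")

    def topology_sidecar(self, path) -> None:
        """Write ring classes, link edges and mode as a JSON sidecar."""
        Path(path).write_text(json.dumps({
            "mode": self.mode,
            "spacing": self.spacing,
            "ring_class": self.ring_class,
            "ring_slices": self.ring_slices,
            "link_edges": [[int(i), int(j), int(s)] for i, j, s in self.link_edges],
            "mini_adjacency": sorted(map(sorted, self.graph.edges())),
        }, indent=1))


# ---------------------------------------------------------------------------
# minicircle-only construction
# ---------------------------------------------------------------------------

def _honeycomb_patch(n_rings: int, spacing: float):
    """Positions, sublattice signs and adjacency of a round honeycomb patch."""
    d = spacing
    a1 = np.array([np.sqrt(3) * d, 0.0])
    a2 = np.array([np.sqrt(3) * d / 2, 1.5 * d])
    off = np.array([0.0, d])
    extent = int(np.ceil(np.sqrt(n_rings))) + 3
    sites = {}
    for mi in range(-extent, extent + 1):
        for ni in range(-extent, extent + 1):
            base = mi * a1 + ni * a2
            sites[(mi, ni, 0)] = base               # sublattice A
            sites[(mi, ni, 1)] = base + off         # sublattice B
    # recentre on the mean of the candidate cloud and take the n closest
    keys = list(sites)
    pos = np.array([sites[k] for k in keys])
    center = pos.mean(axis=0)
    order = np.argsort(np.linalg.norm(pos - center, axis=1), kind="stable")
    chosen = [keys[i] for i in order[:n_rings]]
    index = {k: i for i, k in enumerate(chosen)}

    g = nx.Graph()
    g.add_nodes_from(range(n_rings))
    for (mi, ni, s) in chosen:
        if s != 0:
            continue
        i = index[(mi, ni, 0)]
        for nb in ((mi, ni, 1), (mi, ni - 1, 1), (mi + 1, ni - 1, 1)):
            if nb in index:
                g.add_edge(i, index[nb])
    if not nx.is_connected(g):
        raise ValueError("honeycomb patch is not connected; "
                         "increase n_rings or adjust spacing")
    coords = np.array([sites[k] for k in chosen])
    coords -= coords.mean(axis=0)
    sub = np.array([k[2] for k in chosen])
    return coords, sub, g


def _mini_ring(center_xy: np.ndarray, spacing: float, sub: int,
               orientation: int, n_beads: int) -> np.ndarray:
    R = RING_RADIUS_FACTOR * spacing
    h = RING_HEIGHT_FACTOR * spacing
    # dense analytic curve, then equal-arclength resampling for uniform bonds
    theta = orientation * 2 * np.pi * np.arange(8 * n_beads) / (8 * n_beads)
    x = center_xy[0] + R * np.cos(theta)
    y = center_xy[1] + R * np.sin(theta)
    z = (1 if sub == 0 else -1) * h * np.cos(3 * theta)
    return _resample_closed(np.column_stack([x, y, z]), n_beads)


def build_mo(n_rings: int = 604, beads_per_ring: int = MINI_BEADS,
             spacing: float | None = None, seed: int | None = None,
             verify: str = "edges") -> OlympicNetwork:
    """Build a minicircle-only Olympic network on a honeycomb patch.

    Every interior minicircle is catenated with exactly its 3 lattice
    neighbours as a Hopf link with random chirality (realised by random ring
    orientations). ``spacing`` defaults to the value giving an initial bead
    spacing of ~0.95 σ for the chosen ``beads_per_ring``. ``verify`` is
    "edges" (check every intended link) or "full" (also scan for spurious
    catenations).
    """
    if n_rings < 2:
        raise ValueError("need at least 2 rings")
    if spacing is None:
        # ring arclength ≈ 0.6·s · ∫ sqrt(1 + sin²3θ) dθ ≈ 4.58·s
        spacing = TARGET_BOND * beads_per_ring / 4.58
    rng = np.random.default_rng(seed)
    centers, sub, graph = _honeycomb_patch(n_rings, spacing)
    orientations = rng.choice([-1, 1], size=n_rings)

    coords = np.vstack([
        _mini_ring(centers[i], spacing, sub[i], orientations[i], beads_per_ring)
        for i in range(n_rings)])
    ring_slices = [(i * beads_per_ring, beads_per_ring) for i in range(n_rings)]
    net = OlympicNetwork(coords=coords, ring_slices=ring_slices,
                         ring_class=["mini"] * n_rings, link_edges=[],
                         graph=graph, mode="MO", spacing=spacing)

    edges = []
    for i, j in graph.edges():
        lk = linking_number(net.ring_coords(i), net.ring_coords(j))
        if abs(lk) != 1:
            raise ValueError(
                f"construction failed: rings {i}-{j} have Lk={lk}, expected ±1 "
                f"(spacing {spacing:.2f} σ not geometrically realisable)")
        edges.append((i, j, lk))
    net.link_edges = edges
    if verify == "full":
        net.verify_topology(full=True)
    return net


# ---------------------------------------------------------------------------
# maxicircles
# ---------------------------------------------------------------------------

def _maxi_waypoints(dive_points: np.ndarray, z_lo: float, z_hi: float) -> list:
    """Waypoints threading the given xy dive points with alternating direction.

    Starts above dive point 0, dives to the lower level, travels below to
    point 1, rises, travels above to point 2, and so on. Requires an even
    number of dive points so the curve closes on the upper level.
    """
    n = len(dive_points)
    if n % 2:
        raise ValueError("alternating threading needs an even number of holes")
    wp = []
    for k, (x, y) in enumerate(dive_points):
        if k % 2 == 0:        # dive down
            wp.append((x, y, z_hi))
            wp.append((x, y, z_lo))
        else:                 # rise up
            wp.append((x, y, z_lo))
            wp.append((x, y, z_hi))
    return wp


def _wrap_clasp(line_x: float, line_z: float, y: float, radius: float,
                z_top: float, from_x: float, from_z: float) -> list:
    """Waypoints taking a curve from its own line (from_x, from_z) around the
    line of another maxicircle running along y at (line_x, line_z)."""
    g = 3.0 * radius
    wp = [(from_x, y - 2 * g, from_z),
          (from_x, y - g, z_top),
          (line_x + radius, y - g / 2, z_top)]
    phis = np.linspace(0, 2 * np.pi, 13)
    ys = np.linspace(y - 0.3, y + 0.3, 13)
    for phi, yy in zip(phis, ys):
        wp.append((line_x + radius * np.cos(phi), yy,
                   line_z + radius * np.sin(phi)))
    wp += [(line_x + radius, y + g / 2, z_top),
           (from_x, y + g, z_top),
           (from_x, y + 2 * g, from_z)]
    return wp


def add_maxicircles(network: OlympicNetwork, n_maxi: int = 3,
                    beads: int | None = None, mode: str = "LD",
                    n_threaded: int | None = None,
                    seed: int | None = None,
                    max_retries: int = 3,
                    verify: str = "edges") -> OlympicNetwork:
    """Add mutually interlinked maxicircles threaded through the minicircle disk.

    mode "LB": each maxicircle threads the minicircles of the disk's boundary
    cycle. mode "LD": each maxicircle threads ``n_threaded`` minicircles
    sampled uniformly over the whole disk (default: as many as the boundary
    cycle, for comparability). The maxicircles are pairwise Hopf-linked via
    clasps outside the disk. All realised linkings are verified; on failure
    the construction retries with a fresh seed up to ``max_retries`` times.
    """
    if mode not in ("LD", "LB"):
        raise ValueError("mode must be 'LD' or 'LB'")
    if network.maxi_rings:
        raise ValueError("network already has maxicircles")
    last_err: Exception | None = None
    for attempt in range(max_retries + 1):
        attempt_seed = None if seed is None else seed + 104729 * attempt
        try:
            return _add_maxicircles_once(network, n_maxi, beads, mode,
                                         n_threaded, attempt_seed, verify)
        except ValueError as err:
            last_err = err
    raise ValueError(f"maxicircle construction failed after "
                     f"{max_retries + 1} attempts: {last_err}")


def _add_maxicircles_once(network, n_maxi, beads, mode, n_threaded, seed,
                          verify) -> OlympicNetwork:
    rng = np.random.default_rng(seed)
    boundary = network.boundary_rings()
    mini_centers = network.ring_centers(network.mini_rings)
    h = RING_HEIGHT_FACTOR * network.spacing
    xmax = network.coords[:, 0].max()
    ymin = network.coords[:, 1].min()
    ymax = network.coords[:, 1].max()

    threaded_sets = []
    for k in range(n_maxi):
        if mode == "LB":
            rings = list(boundary)
        else:
            count = n_threaded if n_threaded is not None else len(boundary)
            count = min(count, len(network.mini_rings))
            rings = list(rng.choice(network.mini_rings, size=count,
                                    replace=False))
            # order by angle around the disk centroid to keep the loop simple
            centers = network.ring_centers(rings)
            c0 = mini_centers.mean(axis=0)
            ang = np.arctan2(centers[:, 1] - c0[1], centers[:, 0] - c0[0])
            rings = [rings[i] for i in np.argsort(ang)]
        if len(rings) % 2:
            rings = rings[:-1]
        if len(rings) < 2:
            raise ValueError("not enough minicircles to thread")
        threaded_sets.append(rings)

    curves = []
    line_x = {}
    line_z = {}
    clasp_r = 2.0
    for k in range(n_maxi):
        z_hi = h + 1.5 + 1.2 * k
        z_lo = -z_hi
        line_x[k] = xmax + 12.0 + 8.0 * k
        line_z[k] = z_hi
        centers = network.ring_centers(threaded_sets[k])
        offset = np.array([0.8 * k, 0.0])       # avoid coincident dives (LB)
        dive_xy = centers[:, :2] + offset
        wp = _maxi_waypoints(dive_xy, z_lo, z_hi)
        # rendezvous line outside the disk, spliced into the closing upper
        # leg via axis-aligned detours that stay clear of the clasp slots
        px, py = dive_xy[-1]
        x0, y0 = dive_xy[0]
        wp.append((px, ymin - 10.0, z_hi))
        wp.append((line_x[k], ymin - 10.0, z_hi))
        wp.append((line_x[k], ymax + 10.0, z_hi))
        wp.append((x0, ymax + 10.0, z_hi))
        curves.append(wp)

    # Discretise, then add pairwise wrap clasps along the rendezvous lines
    # for any pair whose bead-level loops are still unlinked (the interior
    # dives of two loops can already realise a mutual link on their own).
    # The decision is taken on the discretised curves because corner-cutting
    # during resampling can change marginal crossings of the waypoint paths.
    def _discretise(wp):
        poly = np.array(wp, dtype=float)
        length = np.linalg.norm(np.diff(np.vstack([poly, poly[:1]]), axis=0),
                                axis=1).sum()
        n_b = beads if beads is not None else int(round(length / TARGET_BOND))
        if length / n_b > 1.3:
            raise ValueError(
                f"{n_b} beads cannot span a maxicircle of length "
                f"{length:.0f} σ without overstretching")
        return _resample_closed(poly, n_b)

    bead_curves = [_discretise(wp) for wp in curves]
    pair_list = [(i, j) for i in range(n_maxi) for j in range(i + 1, n_maxi)]
    span = (ymax + 10.0) - (ymin - 10.0)
    z_top = max(line_z.values()) + 5.0
    for s, (i, j) in enumerate(pair_list):
        if linking_number(bead_curves[i], bead_curves[j]) != 0:
            continue
        y_slot = ymin - 10.0 + span * (s + 1) / (len(pair_list) + 1)
        clasp = _wrap_clasp(line_x[j], line_z[j], y_slot, clasp_r, z_top,
                            from_x=line_x[i], from_z=line_z[i])
        # splice into curve i's line run (which goes ymin→ymax at line_x[i])
        wp = curves[i]
        idx = next(q for q in range(len(wp))
                   if wp[q][0] == line_x[i] and wp[q][1] == ymax + 10.0)
        curves[i] = wp[:idx] + clasp + wp[idx:]
        bead_curves[i] = _discretise(curves[i])

    # bead discretisation
    new_coords = [network.coords]
    ring_slices = list(network.ring_slices)
    ring_class = list(network.ring_class)
    start = network.n_beads
    maxi_ids = []
    for curve in bead_curves:
        new_coords.append(curve)
        ring_slices.append((start, len(curve)))
        ring_class.append("maxi")
        maxi_ids.append(len(ring_slices) - 1)
        start += len(curve)

    net = OlympicNetwork(coords=np.vstack(new_coords), ring_slices=ring_slices,
                         ring_class=ring_class,
                         link_edges=list(network.link_edges),
                         graph=network.graph, mode=mode,
                         spacing=network.spacing)

    # verify and record the realised maxi-mini and maxi-maxi linkings
    edges = list(network.link_edges)
    for k, mid in enumerate(maxi_ids):
        for ring in threaded_sets[k]:
            lk = linking_number(net.ring_coords(mid), net.ring_coords(ring))
            if abs(lk) != 1:
                raise ValueError(f"maxicircle {k} failed to thread minicircle "
                                 f"{ring} (Lk={lk})")
            edges.append((ring, mid, lk))
    for a in range(n_maxi):
        for b in range(a + 1, n_maxi):
            lk = linking_number(net.ring_coords(maxi_ids[a]),
                                net.ring_coords(maxi_ids[b]))
            if lk == 0:
                raise ValueError(f"maxicircles {a} and {b} are not interlinked")
            edges.append((maxi_ids[a], maxi_ids[b], lk))
    net.link_edges = edges
    if verify == "full":
        net.verify_topology(full=True)
    return net


# ---------------------------------------------------------------------------
# slit compression
# ---------------------------------------------------------------------------

def compress_to_disk(network: OlympicNetwork, slit_gap: float,
                     params=None, stage_steps: int = 20000,
                     n_stages: int = 5, seed: int = 0) -> OlympicNetwork:
    """Compress the network between slit walls down to ``slit_gap``.

    Runs the Langevin engine with harmonic walls whose half-gap narrows over
    ``n_stages`` stages to slit_gap/2, then verifies that every intended
    linking number survived (the run is aborted otherwise). Returns the
    network with updated coordinates.
    """
    from . import simulate as sim     # local import: simulate ← network cycle

    if params is None:
        params = sim.SimParams()
    extent = np.abs(network.coords[:, 2]).max()
    target = slit_gap / 2.0
    if extent <= target:
        gaps = [target]
    else:
        gaps = np.linspace(extent, target, n_stages + 1)[1:]
    state = sim.SimState.from_network(network, seed=seed)
    sim.relax(state, params)
    for i, gap in enumerate(gaps):
        p = sim.SimParams(**{**params.__dict__, "wall_gap": 2 * gap,
                             "seed": seed + i})
        state = sim.step(state, p, stage_steps)
    out = OlympicNetwork(coords=state.positions.copy(),
                         ring_slices=list(network.ring_slices),
                         ring_class=list(network.ring_class),
                         link_edges=list(network.link_edges),
                         graph=network.graph, mode=network.mode,
                         spacing=network.spacing)
    out.verify_topology(full=False)
    return out
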