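"""Underdamped Langevin dynamics for bead-spring ring networks.

Kremer–Grest-type model in reduced Lennard-Jones units (σ = ε = m = 1):

* FENE bonds between consecutive beads of each ring
  (U = −K R0²/2 · ln(1 − (r/R0)²), defaults K = 30, R0 = 1.5), combined with
* purely repulsive WCA excluded volume (ε = 1, cutoff 2^{1/6} σ) between all
  bead pairs — together these prevent strand crossing, so the catenation
  topology of the network is conserved by construction;
* cosine bending potential U = κ_bend (1 − cos θ); the default κ_bend is
  calibrated with the discrete Kratky–Porod relation so the chain's
  tangent-correlation persistence length is l_p = 4σ at T = 1 (the naive
  continuum identification l_p = κ_bend·σ overshoots at this stiffness);
* optional harmonic slit walls confining |z|;
* Grønbech-Jensen–Farago velocity-Verlet Langevin integration with
  γ = 0.1 /τ_LJ and dt = 0.01 τ_LJ by default.

Force kernels and the time-stepping loop are Numba-compiled; a cell-based
neighbour list with a 0.4 σ skin is rebuilt on a displacement criterion.
Runs are bitwise reproducible for a given (state, params, seed) on one
thread.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from numba import njit

from .dynamics import MsdCurve

__all__ = [
    "SimParams", "SimState", "Trajectory", "EquilibrationReport",
    "ObservableSet", "relax", "step", "run", "run_protocol",
    "potential_energy", "kinetic_temperature", "observables", "ring_msd",
    "radius_of_gyration", "rigid_transform", "align_to_reference",
    "AlignmentError", "SimulationError", "bend_constant_for_lp",
]


class SimulationError(RuntimeError):
    """Raised when the integrator detects a broken bond or non-finite state."""


class AlignmentError(ValueError):
    """Raised when rigid-body alignment would require a reflection."""


def bend_constant_for_lp(lp: float, bond_length: float = 0.965,
                         temperature: float = 1.0) -> float:
    """Cosine-bending constant giving persistence length ``lp`` (in σ).

    For the discrete Kratky–Porod chain, ⟨cos φ⟩ = coth(κ/T) − T/κ and
    l_p = −b / ln⟨cos φ⟩ with b the equilibrium bond length; this inverts
    that relation. At l_p = 4σ the result is ≈ 4.66 ε, noticeably above the
    continuum estimate κ ≈ l_p·k_BT/σ.
    """
    from scipy.optimize import brentq

    def lp_of(k):
        c = 1 / np.tanh(k / temperature) - temperature / k
        return -bond_length / np.log(c)

    return float(brentq(lambda k: lp_of(k) - lp, 0.5, 50.0))


#: bending constant calibrated so that l_p = 4σ for the discrete chain
DEFAULT_BEND_KAPPA = 4.661


# ---------------------------------------------------------------------------
# parameters and state
# ---------------------------------------------------------------------------

@dataclass
class SimParams:
    """Reduced-unit simulation parameters (Kremer–Grest defaults)."""

    gamma: float = 0.1          # damping, 1/τ_LJ
    dt: float = 0.01            # timestep, τ_LJ
    temperature: float = 1.0    # reduced k_B T
    fene_k: float = 30.0        # ε/σ²
    fene_r0: float = 1.5        # σ
    wca_epsilon: float = 1.0
    wca_sigma: float = 1.0
    bend_kappa: float = DEFAULT_BEND_KAPPA   # ε; calibrated for l_p = 4σ
    wall_gap: float | None = None   # full slit gap in σ; None = no walls
    wall_k: float = 100.0       # harmonic wall stiffness; stiff vs k_BT/σ²
                                # so thermal penetration stays well below σ
    skin: float = 0.4           # neighbour-list skin, σ
    equil_steps: int = 5_000_000
    prod_steps: int = 5_000_000
    dump_every: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0 or self.gamma <= 0:
            raise ValueError("dt and gamma must be positive")
        if self.fene_r0 <= self.wca_sigma:
            raise ValueError("FENE R0 must exceed the bead diameter")


@dataclass
class SimState:
    """Bead positions/velocities plus the bonded topology they evolve under."""

    positions: np.ndarray
    velocities: np.ndarray
    bonds: np.ndarray
    angles: np.ndarray
    time: float = 0.0
    kinetic_temp: float | None = None   # run-averaged, set after step()/run()

    @classmethod
    def from_network(cls, network, seed: int = 0,
                     temperature: float = 1.0) -> "SimState":
        rng = np.random.default_rng(seed)
        # always copy: the integrator advances positions in place and must
        # never mutate the network it was built from
        pos = np.array(network.coords, dtype=np.float64, order="C", copy=True)
        vel = rng.normal(0.0, np.sqrt(temperature), size=pos.shape)
        vel -= vel.mean(axis=0)
        return cls(positions=pos, velocities=vel,
                   bonds=np.ascontiguousarray(network.bonds()),
                   angles=np.ascontiguousarray(network.angles()))

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]


@dataclass
class Trajectory:
    """Dumped configurations at a fixed stride."""

    times: np.ndarray                 # τ_LJ
    positions: np.ndarray             # (frames, N, 3)

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def write_xyz(self, path, symbol: str = "C") -> None:
        with open(path, "w") as fh:
            for t, frame in zip(self.times, self.positions):
                fh.write(f"{frame.shape[0]}\nt={t}\n")
                for x, y, z in frame:
                    fh.write(f"{symbol} {x:.5f} {y:.5f} {z:.5f}\n")

    def write_lammps_dump(self, path, mol: np.ndarray | None = None) -> None:
        n = self.positions.shape[1]
        mol = mol if mol is not None else np.ones(n, dtype=int)
        with open(path, "w") as fh:
            for k, (t, frame) in enumerate(zip(self.times, self.positions)):
                lo = frame.min(axis=0) - 1
                hi = frame.max(axis=0) + 1
                fh.write("ITEM: TIMESTEP\n%d\n" % round(t))
                fh.write("ITEM: NUMBER OF ATOMS\n%d\n" % n)
                fh.write("ITEM: BOX BOUNDS ff ff ff\n")
                for d in range(3):
                    fh.write(f"{lo[d]:.4f} {hi[d]:.4f}\n")
                fh.write("ITEM: ATOMS id mol type x y z\n")
                for i, (x, y, z) in enumerate(frame):
                    fh.write(f"{i + 1} {mol[i]} 1 {x:.5f} {y:.5f} {z:.5f}\n")


@dataclass
class EquilibrationReport:
    """Radius-of-gyration stationarity diagnostic.

    The run counts as equilibrated when at least 95% of Rg samples fall
    within two standard deviations of the mean and there is no drift
    (|linear slope| × duration ≤ 0.5 SD).
    """

    rg_series: np.ndarray
    mean: float
    sd: float
    frac_within_2sd: float
    trend: float                      # slope × duration, in units of SD
    passed: bool

    @classmethod
    def from_series(cls, rg: np.ndarray) -> "EquilibrationReport":
        rg = np.asarray(rg, dtype=float)
        mean = float(rg.mean())
        sd = float(rg.std(ddof=1)) if len(rg) > 1 else 0.0
        if sd > 0:
            frac = float(np.mean(np.abs(rg - mean) <= 2 * sd))
            x = np.arange(len(rg), dtype=float)
            slope = float(np.polyfit(x, rg, 1)[0])
            trend = abs(slope) * len(rg) / sd
        else:
            frac, trend = 1.0, 0.0
        return cls(rg_series=rg, mean=mean, sd=sd, frac_within_2sd=frac,
                   trend=trend, passed=(frac >= 0.95 and trend <= 0.5))


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

# xorshift64* PRNG with Box-Muller, used instead of numpy's generator inside
# the hot loop (explicit uint64 constants avoid int64 promotion)
_U = np.uint64
_MASK = _U(0xFFFFFFFFFFFFFFFF)
_S12, _S25, _S27, _S11 = _U(12), _U(25), _U(27), _U(11)
_MULT = _U(0x2545F4914F6CDD1D)
_INV53 = 1.0 / 9007199254740992.0


@njit(cache=True, fastmath=True, inline="always")
def _rng_next(state):  # pragma: no cover
    x = state
    x ^= x >> _S12
    x ^= (x << _S25) & _MASK
    x ^= x >> _S27
    return x, (x * _MULT) & _MASK


@njit(cache=True, fastmath=True)
def _rng_seed(seed):  # pragma: no cover
    return (_U(seed) * _U(6364136223846793005)
            + _U(1442695040888963407)) | _U(1)


@njit(cache=True, fastmath=True)
def _fill_gaussian(state, buf):  # pragma: no cover
    """Fill a flat buffer with standard normals (Box-Muller pairs)."""
    m = buf.shape[0]
    k = 0
    while k < m:
        state, r1 = _rng_next(state)
        state, r2 = _rng_next(state)
        u1 = float(r1 >> _S11) * _INV53
        u2 = float(r2 >> _S11) * _INV53
        if u1 < 1e-300:
            u1 = 1e-300
        rad = np.sqrt(-2.0 * np.log(u1))
        buf[k] = rad * np.cos(6.283185307179586 * u2)
        if k + 1 < m:
            buf[k + 1] = rad * np.sin(6.283185307179586 * u2)
        k += 2
    return state


@njit(cache=True, fastmath=True)
def _build_pairs(pos, cutoff):  # pragma: no cover
    """All bead pairs closer than cutoff, via cell binning."""
    n = pos.shape[0]
    lo0 = pos[:, 0].min(); lo1 = pos[:, 1].min(); lo2 = pos[:, 2].min()
    cell = cutoff
    nx = max(1, int((pos[:, 0].max() - lo0) / cell) + 1)
    ny = max(1, int((pos[:, 1].max() - lo1) / cell) + 1)
    nz = max(1, int((pos[:, 2].max() - lo2) / cell) + 1)
    ncell = nx * ny * nz
    cidx = np.empty(n, dtype=np.int64)
    for i in range(n):
        cx = int((pos[i, 0] - lo0) / cell)
        cy = int((pos[i, 1] - lo1) / cell)
        cz = int((pos[i, 2] - lo2) / cell)
        cidx[i] = (cx * ny + cy) * nz + cz
    order = np.argsort(cidx)
    starts = np.zeros(ncell + 1, dtype=np.int64)
    for i in range(n):
        starts[cidx[i] + 1] += 1
    for c in range(ncell):
        starts[c + 1] += starts[c]

    cut2 = cutoff * cutoff
    cap = 64 * n
    pi = np.empty(cap, dtype=np.int64)
    pj = np.empty(cap, dtype=np.int64)
    cnt = 0
    for a in range(n):
        i = order[a]
        cx = int((pos[i, 0] - lo0) / cell)
        cy = int((pos[i, 1] - lo1) / cell)
        cz = int((pos[i, 2] - lo2) / cell)
        for dx in range(-1, 2):
            x = cx + dx
            if x < 0 or x >= nx:
                continue
            for dy in range(-1, 2):
                y = cy + dy
                if y < 0 or y >= ny:
                    continue
                for dz in range(-1, 2):
                    z = cz + dz
                    if z < 0 or z >= nz:
                        continue
                    c = (x * ny + y) * nz + z
                    for b in range(starts[c], starts[c + 1]):
                        j = order[b]
                        if j <= i:
                            continue
                        rx = pos[i, 0] - pos[j, 0]
                        ry = pos[i, 1] - pos[j, 1]
                        rz = pos[i, 2] - pos[j, 2]
                        r2 = rx * rx + ry * ry + rz * rz
                        if r2 < cut2:
                            if cnt >= cap:
                                cap2 = cap * 2
                                pi2 = np.empty(cap2, dtype=np.int64)
                                pj2 = np.empty(cap2, dtype=np.int64)
                                pi2[:cnt] = pi[:cnt]
                                pj2[:cnt] = pj[:cnt]
                                pi, pj, cap = pi2, pj2, cap2
                            pi[cnt] = i
                            pj[cnt] = j
                            cnt += 1
    return pi[:cnt], pj[:cnt]


@njit(cache=True, fastmath=True)
def _forces(pos, bonds, angles, pi, pj, fene_k, fene_r0, eps, sigma,
            bend_k, wall_gap, wall_k, forces):  # pragma: no cover
    """Total force; returns (E_fene, E_wca, E_bend, E_wall, ok_flag)."""
    n = pos.shape[0]
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0
    e_fene = 0.0
    e_wca = 0.0
    e_bend = 0.0
    e_wall = 0.0
    ok = True

    r02 = fene_r0 * fene_r0
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        rx = pos[i, 0] - pos[j, 0]
        ry = pos[i, 1] - pos[j, 1]
        rz = pos[i, 2] - pos[j, 2]
        r2 = rx * rx + ry * ry + rz * rz
        if r2 >= r02:
            ok = False
            r2 = 0.9999 * r02
        e_fene += -0.5 * fene_k * r02 * np.log(1.0 - r2 / r02)
        fmag = -fene_k / (1.0 - r2 / r02)
        forces[i, 0] += fmag * rx
        forces[i, 1] += fmag * ry
        forces[i, 2] += fmag * rz
        forces[j, 0] -= fmag * rx
        forces[j, 1] -= fmag * ry
        forces[j, 2] -= fmag * rz

    wca_cut2 = (2.0 ** (1.0 / 3.0)) * sigma * sigma
    s2 = sigma * sigma
    for p in range(pi.shape[0]):
        i = pi[p]
        j = pj[p]
        rx = pos[i, 0] - pos[j, 0]
        ry = pos[i, 1] - pos[j, 1]
        rz = pos[i, 2] - pos[j, 2]
        r2 = rx * rx + ry * ry + rz * rz
        if r2 < wca_cut2 and r2 > 1e-12:
            inv2 = s2 / r2
            inv6 = inv2 * inv2 * inv2
            e_wca += 4.0 * eps * (inv6 * inv6 - inv6) + eps
            fmag = 24.0 * eps * (2.0 * inv6 * inv6 - inv6) / r2
            forces[i, 0] += fmag * rx
            forces[i, 1] += fmag * ry
            forces[i, 2] += fmag * rz
            forces[j, 0] -= fmag * rx
            forces[j, 1] -= fmag * ry
            forces[j, 2] -= fmag * rz

    if bend_k > 0.0:
        for a in range(angles.shape[0]):
            i = angles[a, 0]
            j = angles[a, 1]
            k = angles[a, 2]
            # bond vectors j->i and j->k
            ax = pos[i, 0] - pos[j, 0]
            ay = pos[i, 1] - pos[j, 1]
            az = pos[i, 2] - pos[j, 2]
            bx = pos[k, 0] - pos[j, 0]
            by = pos[k, 1] - pos[j, 1]
            bz = pos[k, 2] - pos[j, 2]
            la2 = ax * ax + ay * ay + az * az
            lb2 = bx * bx + by * by + bz * bz
            la = la2 ** 0.5
            lb = lb2 ** 0.5
            if la < 1e-12 or lb < 1e-12:
                continue
            c = (ax * bx + ay * by + az * bz) / (la * lb)
            c = min(1.0, max(-1.0, c))
            # U = bend_k (1 + cos(angle)) is minimal for straight (cos=-1)
            e_bend += bend_k * (1.0 + c)
            # dU/d(cos) = bend_k ; F = -bend_k * d(cos)/dr
            inv_ab = 1.0 / (la * lb)
            fi_x = -bend_k * (bx * inv_ab - c * ax / la2)
            fi_y = -bend_k * (by * inv_ab - c * ay / la2)
            fi_z = -bend_k * (bz * inv_ab - c * az / la2)
            fk_x = -bend_k * (ax * inv_ab - c * bx / lb2)
            fk_y = -bend_k * (ay * inv_ab - c * by / lb2)
            fk_z = -bend_k * (az * inv_ab - c * bz / lb2)
            forces[i, 0] += fi_x
            forces[i, 1] += fi_y
            forces[i, 2] += fi_z
            forces[k, 0] += fk_x
            forces[k, 1] += fk_y
            forces[k, 2] += fk_z
            forces[j, 0] -= fi_x + fk_x
            forces[j, 1] -= fi_y + fk_y
            forces[j, 2] -= fi_z + fk_z

    if wall_gap > 0.0:
        half = wall_gap / 2.0
        for i in range(n):
            z = pos[i, 2]
            if z > half:
                e_wall += 0.5 * wall_k * (z - half) ** 2
                forces[i, 2] -= wall_k * (z - half)
            elif z < -half:
                e_wall += 0.5 * wall_k * (z + half) ** 2
                forces[i, 2] -= wall_k * (z + half)
    return e_fene, e_wca, e_bend, e_wall, ok


@njit(cache=True, fastmath=True)
def _relax_kernel(pos, bonds, angles, fene_k, fene_r0, eps, sigma, bend_k,
                  wall_gap, wall_k, skin, n_iter, max_disp):  # pragma: no cover
    """Capped-displacement steepest descent to remove construction overlaps."""
    n = pos.shape[0]
    cutoff = (2.0 ** (1.0 / 6.0)) * sigma + skin
    forces = np.zeros((n, 3))
    eta = 1e-4
    for it in range(n_iter):
        if it % 10 == 0:
            pi, pj = _build_pairs(pos, cutoff)
        _forces(pos, bonds, angles, pi, pj, fene_k, fene_r0, eps, sigma,
                bend_k, wall_gap, wall_k, forces)
        fmax = 0.0
        for i in range(n):
            f2 = (forces[i, 0] ** 2 + forces[i, 1] ** 2 + forces[i, 2] ** 2)
            if f2 > fmax:
                fmax = f2
        fmax = fmax ** 0.5
        if fmax < 1.0:
            break
        scale = eta if eta * fmax <= max_disp else max_disp / fmax
        for i in range(n):
            for d in range(3):
                pos[i, d] += scale * forces[i, d]
    return 0


@njit(cache=True, fastmath=True)
def _integrate(pos, vel, bonds, angles, n_steps, dt, gamma, temp,
               fene_k, fene_r0, eps, sigma, bend_k, wall_gap, wall_k,
               skin, seed, dump_every, dump_pos, dump_t):  # pragma: no cover
    """GJF Langevin velocity-Verlet loop. Returns (status, n_dumped).

    status 0 = ok, 1 = FENE bond reached R0, 2 = non-finite coordinates.
    The third return value is the accumulated squared half-step displacement,
    whose mean over steps gives the (finite-dt exact) kinetic temperature.
    """
    rng_state = _rng_seed(seed)
    n = pos.shape[0]
    cutoff = (2.0 ** (1.0 / 6.0)) * sigma + skin
    forces = np.zeros((n, 3))
    beta = np.empty(n * 3)
    pi, pj = _build_pairs(pos, cutoff)
    ref = pos.copy()

    b_coef = 1.0 / (1.0 + gamma * dt / 2.0)
    a_coef = (1.0 - gamma * dt / 2.0) / (1.0 + gamma * dt / 2.0)
    noise_sd = np.sqrt(2.0 * gamma * temp * dt)

    e1, e2, e3, e4, ok = _forces(pos, bonds, angles, pi, pj, fene_k, fene_r0,
                                 eps, sigma, bend_k, wall_gap, wall_k, forces)
    if not ok:
        return 1, 0, 0.0
    ndump = 0
    skin_half2 = (skin / 2.0) ** 2
    dx2_sum = 0.0      # half-step velocity statistic (2GJ): exact kinetic T
    for stp in range(n_steps):
        rng_state = _fill_gaussian(rng_state, beta)
        for i in range(n):
            for d in range(3):
                bnoise = beta[3 * i + d] * noise_sd
                dx = (b_coef * dt * vel[i, d]
                      + b_coef * dt * dt / 2.0 * forces[i, d]
                      + b_coef * dt / 2.0 * bnoise)
                pos[i, d] += dx
                dx2_sum += dx * dx
                # store half-step contribution in vel temporarily
                vel[i, d] = (a_coef * vel[i, d]
                             + dt / 2.0 * a_coef * forces[i, d]
                             + b_coef * bnoise)
        # neighbour-list displacement criterion
        maxd2 = 0.0
        for i in range(n):
            dx = pos[i, 0] - ref[i, 0]
            dy = pos[i, 1] - ref[i, 1]
            dz = pos[i, 2] - ref[i, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 > maxd2:
                maxd2 = d2
        if maxd2 > skin_half2:
            pi, pj = _build_pairs(pos, cutoff)
            ref = pos.copy()
        e1, e2, e3, e4, ok = _forces(pos, bonds, angles, pi, pj, fene_k,
                                     fene_r0, eps, sigma, bend_k, wall_gap,
                                     wall_k, forces)
        if not ok:
            return 1, ndump, dx2_sum
        for i in range(n):
            for d in range(3):
                vel[i, d] += dt / 2.0 * forces[i, d]
        if dump_every > 0 and (stp + 1) % dump_every == 0 and ndump < dump_pos.shape[0]:
            for i in range(n):
                for d in range(3):
                    dump_pos[ndump, i, d] = pos[i, d]
            dump_t[ndump] = (stp + 1) * dt
            ndump += 1
    if not np.isfinite(pos).all():
        return 2, ndump, dx2_sum
    return 0, ndump, dx2_sum


# ---------------------------------------------------------------------------
# python-facing operations
# ---------------------------------------------------------------------------

def _wall(params: SimParams) -> float:
    return params.wall_gap if params.wall_gap is not None else -1.0


def relax(state: SimState, params: SimParams, n_iter: int = 2000,
          max_disp: float = 0.05) -> SimState:
    """Capped-displacement energy relaxation of construction overlaps.

    Freshly built networks have slight excluded-volume overlaps at ring
    crossings; a few thousand steepest-descent iterations with displacements
    capped at ``max_disp`` σ remove them without letting beads pass through
    bonds, so the catenation topology is untouched.
    """
    _relax_kernel(state.positions, state.bonds, state.angles, params.fene_k,
                  params.fene_r0, params.wca_epsilon, params.wca_sigma,
                  params.bend_kappa, _wall(params), params.wall_k,
                  params.skin, n_iter, max_disp)
    return state


def step(state: SimState, params: SimParams, n_steps: int) -> SimState:
    """Advance the state by n_steps; raises SimulationError on blow-up."""
    dump = np.empty((0, state.n_beads, 3))
    dump_t = np.empty(0)
    status, _, dx2 = _integrate(state.positions, state.velocities, state.bonds,
                           state.angles, n_steps, params.dt, params.gamma,
                           params.temperature, params.fene_k, params.fene_r0,
                           params.wca_epsilon, params.wca_sigma,
                           params.bend_kappa, _wall(params), params.wall_k,
                           params.skin, params.seed % (2 ** 31), 0,
                           dump, dump_t)
    _raise_on(status, state)
    state.time += n_steps * params.dt
    state.kinetic_temp = _half_step_temp(dx2, state.n_beads, n_steps, params)
    return state


def run(state: SimState, params: SimParams, n_steps: int,
        dump_every: int | None = None) -> Trajectory:
    """Advance the state while dumping configurations at a fixed stride."""
    stride = dump_every or params.dump_every
    n_dumps = n_steps // stride
    dump = np.empty((n_dumps, state.n_beads, 3))
    dump_t = np.empty(n_dumps)
    status, nd, dx2 = _integrate(state.positions, state.velocities, state.bonds,
                            state.angles, n_steps, params.dt, params.gamma,
                            params.temperature, params.fene_k, params.fene_r0,
                            params.wca_epsilon, params.wca_sigma,
                            params.bend_kappa, _wall(params), params.wall_k,
                            params.skin, params.seed % (2 ** 31), stride,
                            dump, dump_t)
    _raise_on(status, state)
    t0 = state.time
    state.time += n_steps * params.dt
    state.kinetic_temp = _half_step_temp(dx2, state.n_beads, n_steps, params)
    return Trajectory(times=t0 + dump_t[:nd], positions=dump[:nd])


def _half_step_temp(dx2_sum: float, n_beads: int, n_steps: int,
                    params: SimParams) -> float:
    """Run-averaged kinetic temperature from half-step displacements.

    Uses the 2GJ half-step velocity u = Δx/(√b Δt), whose variance equals
    k_B T/m exactly for linear forces at any stable timestep — unlike the
    on-site velocity, which underestimates T at finite dt.
    """
    b = 1.0 / (1.0 + params.gamma * params.dt / 2.0)
    return dx2_sum / (b * params.dt ** 2) / (3 * n_beads * n_steps)


def _raise_on(status: int, state: SimState) -> None:
    if status == 1:
        raise SimulationError(
            "FENE bond extension reached R0; diagnostic snapshot in "
            "state.positions (reduce dt or relax the initial configuration)")
    if status == 2:
        raise SimulationError("non-finite coordinates encountered")


def potential_energy(state: SimState, params: SimParams) -> dict:
    """Per-term potential energies: fene, wca, bend, wall (reduced units)."""
    bond_vec = state.positions[state.bonds[:, 0]] - state.positions[state.bonds[:, 1]]
    ext = np.linalg.norm(bond_vec, axis=1)
    if (ext >= params.fene_r0).any():
        raise ValueError("FENE bond extension >= R0: energy undefined")
    cutoff = 2 ** (1 / 6) * params.wca_sigma + params.skin
    pi, pj = _build_pairs(state.positions, cutoff)
    forces = np.zeros_like(state.positions)
    e1, e2, e3, e4, _ = _forces(state.positions, state.bonds, state.angles,
                                pi, pj, params.fene_k, params.fene_r0,
                                params.wca_epsilon, params.wca_sigma,
                                params.bend_kappa, _wall(params),
                                params.wall_k, forces)
    return {"fene": e1, "wca": e2, "bend": e3, "wall": e4,
            "total": e1 + e2 + e3 + e4}


def kinetic_temperature(state: SimState) -> float:
    """Instantaneous kinetic temperature, ⟨v²⟩/3 per bead (m = 1)."""
    return float((state.velocities ** 2).sum() / (3 * state.n_beads))


def radius_of_gyration(positions: np.ndarray) -> float:
    com = positions.mean(axis=0)
    return float(np.sqrt(((positions - com) ** 2).sum(axis=1).mean()))


def run_protocol(network, params: SimParams,
                 verify_topology: bool = True) -> tuple[Trajectory, EquilibrationReport]:
    """Equilibrate, then run production with dumps and stationarity checks.

    Dumps configurations every ``params.dump_every`` steps during production,
    builds the radius-of-gyration series, and verifies that all intended
    linking numbers are conserved between the initial and final
    configuration (aborting with an error otherwise).
    """
    state = SimState.from_network(network, seed=params.seed,
                                  temperature=params.temperature)
    relax(state, params)
    if params.equil_steps:
        eq = replace(params, seed=params.seed + 1)
        step(state, eq, params.equil_steps)
    prod = replace(params, seed=params.seed + 2)
    traj = run(state, prod, params.prod_steps)
    rg = np.array([radius_of_gyration(f) for f in traj.positions])
    report = EquilibrationReport.from_series(rg)
    if verify_topology:
        final = _network_with_coords(network, state.positions)
        final.verify_topology(full=False)
    return traj, report


def _network_with_coords(network, coords):
    from .network import OlympicNetwork
    return OlympicNetwork(coords=np.asarray(coords), ring_slices=list(network.ring_slices),
                          ring_class=list(network.ring_class),
                          link_edges=list(network.link_edges),
                          graph=network.graph, mode=network.mode,
                          spacing=network.spacing)


# ---------------------------------------------------------------------------
# observables
# ---------------------------------------------------------------------------

def rigid_transform(coords: np.ndarray, ref: np.ndarray):
    """Optimal proper-rotation superposition (Kabsch) of coords onto ref.

    Returns ``(R, t)`` with ``aligned = coords @ R.T + t``. Only proper
    rotations are allowed: if the optimal orthogonal transform is a
    reflection, AlignmentError is raised. Degenerate (collinear) point sets
    fall back to translation-only alignment with a warning.
    """
    P = np.asarray(coords, dtype=float)
    Q = np.asarray(ref, dtype=float)
    Pm = P.mean(axis=0)
    Qm = Q.mean(axis=0)
    H = (P - Pm).T @ (Q - Qm)
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-10 * max(S[0], 1e-30):
        warnings.warn("degenerate (collinear) configuration: "
                      "translation-only alignment", stacklevel=2)
        R = np.eye(3)
    else:
        d = np.linalg.det(Vt.T @ U.T)
        if d < 0:
            raise AlignmentError("optimal superposition requires a reflection")
        R = Vt.T @ U.T
    return R, Qm - Pm @ R.T


def align_to_reference(coords: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Least-squares rigid superposition of coords onto ref (see
    :func:`rigid_transform` for the conventions and failure modes)."""
    R, t = rigid_transform(coords, ref)
    return np.asarray(coords, dtype=float) @ R.T + t


@dataclass
class ObservableSet:
    """Per-frame scalar observables and MSD-ready aligned ring tracks."""

    times: np.ndarray
    rg: np.ndarray
    ring_com: np.ndarray          # (frames, n_rings, 3), raw
    ring_com_aligned: np.ndarray  # (frames, n_rings, 3), roto-translation removed

    def rg_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "rg": self.rg})


def observables(traj: Trajectory, network,
                rings: list[int] | None = None) -> ObservableSet:
    """Per-frame Rg and (aligned) ring centre-of-mass tracks.

    The rigid-body transform (translation + proper rotation) of every frame
    is determined from the COMs of *all* rings of the network superposed
    onto the first frame, and then applied to the COM tracks of the
    requested ``rings`` subset — so small subsets (e.g. the three
    maxicircles) are carried along with the global frame rather than
    defining a degenerate alignment of their own.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    rings = list(rings) if rings is not None else list(range(network.n_rings))
    rg = np.array([radius_of_gyration(f) for f in traj.positions])

    all_coms = np.empty((traj.n_frames, network.n_rings, 3))
    for f, frame in enumerate(traj.positions):
        for r, (start, n) in enumerate(network.ring_slices):
            all_coms[f, r] = frame[start:start + n].mean(axis=0)
    coms = all_coms[:, rings, :]
    aligned = np.empty_like(coms)
    aligned[0] = coms[0]
    for f in range(1, traj.n_frames):
        try:
            R, t = rigid_transform(all_coms[f], all_coms[0])
        except AlignmentError:
            warnings.warn(f"frame {f}: reflection-optimal alignment; "
                          "translation-only applied", stacklevel=2)
            R = np.eye(3)
            t = all_coms[0].mean(axis=0) - all_coms[f].mean(axis=0)
        aligned[f] = coms[f] @ R.T + t
    return ObservableSet(times=traj.times, rg=rg, ring_com=coms,
                         ring_com_aligned=aligned)


def ring_msd(tracks_3d: np.ndarray, dt_frame: float) -> MsdCurve:
    """Ensemble MSD of aligned ring-COM tracks (frames, n_rings, 3)."""
    F = tracks_3d.shape[0]
    max_lag = F - 1
    sums = np.zeros(max_lag)
    counts = np.zeros(max_lag)
    for lag in range(1, max_lag + 1):
        diff = tracks_3d[lag:] - tracks_3d[:-lag]
        sq = (diff ** 2).sum(axis=2)
        sums[lag - 1] = sq.sum()
        counts[lag - 1] = sq.size
    lags = np.concatenate([[0.0], np.arange(1, max_lag + 1) * dt_frame])
    vals = np.concatenate([[0.0], sums / counts])
    cnts = np.concatenate([[tracks_3d.shape[1] * F], counts])
    return MsdCurve(lags=lags, values=vals, counts=cnts, kind="msd")
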