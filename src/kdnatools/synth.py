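"""Synthetic two-channel movies, spot tables and trajectories with ground truth.

This module generates the inputs the analysis chain expects — a DNA-stain
channel showing a ~4 μm disk/annulus-shaped network, a quantum-dot channel
with point emitters, and confined subdiffusive trajectories — together with
the ground truth needed to score every downstream estimator. Defaults mirror
the acquisition conditions of the experiments the pipeline targets: 70 nm
pixels, 8 fps, at least 500 frames per movie.

Emitter dynamics use an overdamped Ornstein–Uhlenbeck (OU) process in a
harmonic trap (closed-form stationary variance k_B T / κ per axis) and, for
exponent tests, fractional Brownian motion with Hurst index α/2 (closed-form
MSD ∝ t^α). Neither is a model of true kDNA dynamics; they are generators
with known targets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import enrichment as _enr
from .dynamics import TrackSet
from .units import kbt_pn_um, DEFAULT_TEMPERATURE

__all__ = [
    "RegionGeometry", "NoiseParams", "RadialLaw", "GroundTruth",
    "LabelledMovie", "make_kdna_image", "make_confined_tracks",
    "make_subdiffusive_tracks", "make_blinking", "fractional_gaussian_noise",
]

#: default drag coefficient of the OU emitter model, pN·s/μm per axis
DEFAULT_DRAG = 0.02


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class RegionGeometry:
    """Geometry of the synthetic DNA region: a filled ellipse with a soft,
    brighter annular rim (diameter ~4 μm by default)."""

    shape: tuple[int, int] = (128, 128)
    center: tuple[float, float] | None = None     # (x, y) px; default frame centre
    semi_axes: tuple[float, float] | None = None  # px; default from diameter_um
    diameter_um: float = 4.0
    pixel_size: float = 0.07                      # μm/px
    rim_fraction: float = 0.15                    # rim thickness as fraction of radius
    rim_boost: float = 0.8                        # extra rim intensity (relative)

    def resolved(self) -> tuple[tuple[float, float], tuple[float, float]]:
        c = self.center or ((self.shape[1] - 1) / 2, (self.shape[0] - 1) / 2)
        if self.semi_axes is not None:
            ax = self.semi_axes
        else:
            r = self.diameter_um / (2 * self.pixel_size)
            ax = (r, 0.85 * r)
        return c, ax


@dataclass
class NoiseParams:
    psf_sigma: float = 1.5        # px
    photons: float = 500.0        # expected photons per emitter
    background: float = 5.0       # expected background photons per pixel
    dna_amplitude: float = 200.0  # DNA channel peak intensity (photons)
    poisson: bool = True


@dataclass
class RadialLaw:
    """Radial placement law for emitters, parameterised on r/r0 (0 = rim).

    kinds: "uniform" (uniform over the mask area), "peripheral" (probability
    ``p_outer`` of landing uniformly within the shell r/r0 <= shell_fraction,
    otherwise uniform over the rest), "central" (uniform over r/r0 >=
    core_fraction).
    """

    kind: str = "uniform"
    p_outer: float = 1.0
    shell_fraction: float = 0.1
    core_fraction: float = 0.5

    @classmethod
    def uniform(cls) -> "RadialLaw":
        return cls("uniform")

    @classmethod
    def peripheral(cls, p_outer: float = 1.0, shell_fraction: float = 0.1) -> "RadialLaw":
        return cls("peripheral", p_outer=p_outer, shell_fraction=shell_fraction)

    @classmethod
    def central(cls, core_fraction: float = 0.5) -> "RadialLaw":
        return cls("central", core_fraction=core_fraction)


@dataclass
class GroundTruth:
    """True quantities behind a synthetic dataset, for scoring estimators."""

    emitter_positions: np.ndarray | None = None   # (frames, n, 2) in μm
    radial_law: RadialLaw | None = None
    kappa_true: float | None = None               # pN/μm per axis
    alpha_true: float | None = None               # subdiffusion exponent
    d_pairs: np.ndarray | None = None             # true pair distances, μm
    seed: int | None = None

    def __post_init__(self):
        if self.kappa_true is not None and self.kappa_true < 0:
            raise ValueError("kappa_true must be positive")
        if self.alpha_true is not None and not (0 < self.alpha_true <= 1):
            raise ValueError("alpha_true must lie in (0, 1]")


@dataclass
class LabelledMovie:
    """Two-channel pixel stack (frames × rows × cols) with calibration."""

    dna_channel: np.ndarray
    qd_channel: np.ndarray
    pixel_size: float          # μm/px
    frame_interval: float      # s

    def __post_init__(self):
        self.dna_channel = self._3d(self.dna_channel)
        self.qd_channel = self._3d(self.qd_channel)
        if self.dna_channel.shape != self.qd_channel.shape:
            raise ValueError("channels must share shape")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be positive")

    @staticmethod
    def _3d(arr):
        arr = np.asarray(arr)
        return arr[None] if arr.ndim == 2 else arr

    @property
    def n_frames(self) -> int:
        return self.dna_channel.shape[0]

    def to_tiff(self, path) -> None:
        """Write as ImageJ-compatible multi-page TIFF, axes TCYX, with a JSON
        calibration sidecar next to it."""
        stack = np.stack([self.dna_channel, self.qd_channel], axis=1)
        tifffile.imwrite(path, stack.astype(np.float32), imagej=True,
                         metadata={"axes": "TCYX"})
        sidecar = Path(path).with_suffix(".json")
        sidecar.write_text(json.dumps({"pixel_size_um": self.pixel_size,
                                       "frame_interval_s": self.frame_interval}))

    @classmethod
    def from_tiff(cls, path, pixel_size: float | None = None,
                  frame_interval: float | None = None) -> "LabelledMovie":
        stack = tifffile.imread(path)
        if stack.ndim == 3:       # single frame, CYX
            stack = stack[None]
        sidecar = Path(path).with_suffix(".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            pixel_size = pixel_size or meta["pixel_size_um"]
            frame_interval = frame_interval or meta["frame_interval_s"]
        return cls(dna_channel=stack[:, 0], qd_channel=stack[:, 1],
                   pixel_size=pixel_size or 0.07,
                   frame_interval=frame_interval or 0.125)


# ---------------------------------------------------------------------------
# image synthesis
# ---------------------------------------------------------------------------

def _dna_profile(geometry: RegionGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless DNA intensity image and its boolean support mask."""
    (cx, cy), (ax, ay) = geometry.resolved()
    h, w = geometry.shape
    yy, xx = np.mgrid[0:h, 0:w]
    rho = np.sqrt(((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2)
    mask = rho <= 1.0
    body = np.clip(1.0 - rho, 0, None) ** 0.3          # soft filled ellipse
    rim = np.exp(-0.5 * ((rho - 1.0) / (geometry.rim_fraction / 2)) ** 2)
    img = np.where(mask, body + geometry.rim_boost * rim * mask, 0.0)
    return img, mask


def _pixel_r_over_r0(region: _enr.KdnaRegion) -> tuple[np.ndarray, np.ndarray]:
    """(pixel coordinates (n,2) as (x,y), r/r0 per foreground pixel)."""
    rows, cols = np.nonzero(region.mask)
    pts = np.column_stack([cols, rows]).astype(float)
    d = _enr.distance_to_boundary(pts, region)
    return pts, d / region.r0


def sample_emitter_positions(region: _enr.KdnaRegion, n: int, law: RadialLaw,
                             rng: np.random.Generator) -> np.ndarray:
    """Sample n emitter positions (x, y in px) inside the mask per the law."""
    pts, rr = _pixel_r_over_r0(region)
    if law.kind == "uniform":
        weights = np.ones(len(pts))
    elif law.kind == "peripheral":
        shell = rr <= law.shell_fraction
        if not shell.any():
            raise ValueError("peripheral shell contains no pixels")
        weights = np.where(shell, law.p_outer / shell.sum(), 0.0)
        if law.p_outer < 1.0:
            rest = ~shell
            weights = weights + np.where(rest, (1 - law.p_outer) / rest.sum(), 0.0)
    elif law.kind == "central":
        core = rr >= law.core_fraction
        if not core.any():
            raise ValueError("central core contains no pixels")
        weights = core.astype(float)
    else:
        raise ValueError(f"unknown radial law {law.kind!r}")
    weights = weights / weights.sum()
    idx = rng.choice(len(pts), size=n, p=weights)
    jitter = rng.uniform(-0.5, 0.5, size=(n, 2))
    out = pts[idx] + jitter
    # keep jittered points on foreground pixels
    for k in range(n):
        while not region.contains(out[k, 0], out[k, 1])[0]:
            out[k] = pts[idx[k]] + rng.uniform(-0.5, 0.5, size=2)
    return out


def _render_emitters(shape, positions_px, psf_sigma, photons) -> np.ndarray:
    img = np.zeros(shape)
    if len(positions_px) == 0:
        return img
    yy = np.arange(shape[0])
    xx = np.arange(shape[1])
    for x, y in positions_px:
        gx = np.exp(-0.5 * ((xx - x) / psf_sigma) ** 2)
        gy = np.exp(-0.5 * ((yy - y) / psf_sigma) ** 2)
        img += photons * np.outer(gy, gx) / (2 * np.pi * psf_sigma ** 2)
    return img


def make_kdna_image(geometry: RegionGeometry | None = None,
                    n_emitters: int = 15,
                    radial_law: RadialLaw | None = None,
                    noise: NoiseParams | None = None,
                    n_frames: int = 1,
                    frame_interval: float = 0.125,
                    seed: int | None = None) -> tuple[LabelledMovie, GroundTruth]:
    """Synthesize a two-channel image/movie plus its ground truth.

    The DNA channel is a smooth elliptical blob with a brighter rim; the QD
    channel contains ``n_emitters`` static point emitters placed per
    ``radial_law``, convolved with a Gaussian PSF, with optional Poisson
    noise on both channels. The region must fit inside the frame with a
    margin of at least 5 pixels.
    """
    geometry = geometry or RegionGeometry()
    radial_law = radial_law or RadialLaw.uniform()
    noise = noise or NoiseParams()
    rng = np.random.default_rng(seed)

    (cx, cy), (ax, ay) = geometry.resolved()
    h, w = geometry.shape
    if (cx - ax < 5 or cx + ax > w - 6 or cy - ay < 5 or cy + ay > h - 6):
        raise ValueError(
            f"region (centre ({cx:.0f},{cy:.0f}), semi-axes ({ax:.0f},{ay:.0f})) "
            f"does not fit in frame {geometry.shape} with a 5-pixel margin")

    profile, mask = _dna_profile(geometry)
    region = _enr.KdnaRegion.from_mask(mask, pixel_size=geometry.pixel_size)
    pos_px = sample_emitter_positions(region, n_emitters, radial_law, rng) \
        if n_emitters else np.zeros((0, 2))

    dna_frames = np.empty((n_frames, h, w))
    qd_frames = np.empty((n_frames, h, w))
    qd_clean = _render_emitters((h, w), pos_px, noise.psf_sigma, noise.photons)
    for f in range(n_frames):
        dna = noise.dna_amplitude * profile + noise.background
        qd = qd_clean + noise.background
        if noise.poisson:
            dna = rng.poisson(dna).astype(float)
            qd = rng.poisson(qd).astype(float)
        dna_frames[f] = dna
        qd_frames[f] = qd

    movie = LabelledMovie(dna_channel=dna_frames, qd_channel=qd_frames,
                          pixel_size=geometry.pixel_size,
                          frame_interval=frame_interval)
    positions_um = np.broadcast_to(pos_px * geometry.pixel_size,
                                   (n_frames, len(pos_px), 2)).copy()
    truth = GroundTruth(emitter_positions=positions_um, radial_law=radial_law,
                        seed=seed)
    return movie, truth


# ---------------------------------------------------------------------------
# trajectory synthesis
# ---------------------------------------------------------------------------

def make_confined_tracks(n_qd: int = 5, kappa: float = 0.1,
                         temperature: float = DEFAULT_TEMPERATURE,
                         n_frames: int = 500, dt: float = 0.125,
                         drag: float = DEFAULT_DRAG,
                         centers: np.ndarray | None = None,
                         spread: float = 1.0,
                         drift_velocity: tuple[float, float] = (0.0, 0.0),
                         seed: int | None = None) -> tuple[TrackSet, GroundTruth]:
    """Overdamped OU motion of n_qd emitters in harmonic traps.

    Each axis follows dx = -(κ/γ) x dt + sqrt(2 k_B T/γ) dW, discretised
    exactly, so the stationary per-axis variance is k_B T/κ and the
    relaxation time is γ/κ. ``kappa`` is the per-axis trap stiffness in
    pN/μm (``kappa = 0`` gives free diffusion with D = k_B T/γ). A common
    linear drift can be superposed; it is removable by COM subtraction.
    Trap centres default to random points within ``spread`` μm of the origin.
    """
    if n_frames < 100:
        raise ValueError("n_frames must be >= 100")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    rng = np.random.default_rng(seed)
    kbt = kbt_pn_um(temperature)
    if centers is None:
        centers = rng.uniform(-spread, spread, size=(n_qd, 2))
    centers = np.asarray(centers, dtype=float)

    x = np.empty((n_frames, n_qd, 2))
    if kappa > 0:
        tau = drag / kappa
        var = kbt / kappa
        rho = np.exp(-dt / tau)
        x[0] = rng.normal(0.0, np.sqrt(var), size=(n_qd, 2))
        step_sd = np.sqrt(var * (1 - rho ** 2))
        for t in range(1, n_frames):
            x[t] = rho * x[t - 1] + step_sd * rng.normal(size=(n_qd, 2))
    else:
        D = kbt / drag
        steps = rng.normal(0.0, np.sqrt(2 * D * dt), size=(n_frames - 1, n_qd, 2))
        x[0] = 0.0
        x[1:] = np.cumsum(steps, axis=0)

    drift = np.outer(np.arange(n_frames) * dt, np.asarray(drift_velocity))
    pos = x + centers[None, :, :] + drift[:, None, :]

    frames = np.arange(n_frames)
    records = []
    for k in range(n_qd):
        for f in frames:
            records.append((k, f, pos[f, k, 0], pos[f, k, 1]))
    data = pd.DataFrame(records, columns=["track_id", "frame", "x_um", "y_um"])
    com = pd.DataFrame({"frame": frames,
                        "x_um": centers[:, 0].mean() + drift[:, 0],
                        "y_um": centers[:, 1].mean() + drift[:, 1]})
    tracks = TrackSet(data, frame_interval=dt, com=com)
    d_pairs = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=2)
    truth = GroundTruth(emitter_positions=pos, kappa_true=kappa,
                        d_pairs=d_pairs[np.triu_indices(n_qd, 1)], seed=seed)
    return tracks, truth


def fractional_gaussian_noise(n: int, hurst: float,
                              rng: np.random.Generator) -> np.ndarray:
    """Exact fGn sample of length n via Davies–Harte circulant embedding."""
    if not (0 < hurst < 1):
        raise ValueError("hurst must lie in (0, 1)")
    k = np.arange(n + 1, dtype=float)
    gamma = 0.5 * ((k + 1) ** (2 * hurst) - 2 * k ** (2 * hurst)
                   + np.abs(k - 1) ** (2 * hurst))
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    eig = np.fft.rfft(row).real
    eig = np.clip(eig, 0, None)          # numerical guard
    m = len(row)
    z = rng.normal(size=m // 2 + 1) + 1j * rng.normal(size=m // 2 + 1)
    z[0] = z[0].real * np.sqrt(2)
    z[-1] = z[-1].real * np.sqrt(2)
    coeff = np.sqrt(eig / (2 * m))
    sample = np.fft.irfft(coeff * z, n=m) * m
    return sample[:n]


def make_subdiffusive_tracks(n_tracks: int = 100, alpha: float = 0.25,
                             scale: float = 0.1, n_frames: int = 500,
                             dt: float = 0.125,
                             seed: int | None = None) -> tuple[TrackSet, GroundTruth]:
    """Fractional-Brownian tracks with per-axis MSD = scale²·(t/dt)^α.

    Each axis is the running sum of fractional Gaussian noise with Hurst
    index α/2, giving a 2D MSD ∝ t^α with exponent exactly α in expectation.
    """
    rng = np.random.default_rng(seed)
    records = []
    for k in range(n_tracks):
        x = np.concatenate([[0.0], np.cumsum(
            scale * fractional_gaussian_noise(n_frames - 1, alpha / 2, rng))])
        y = np.concatenate([[0.0], np.cumsum(
            scale * fractional_gaussian_noise(n_frames - 1, alpha / 2, rng))])
        for f in range(n_frames):
            records.append((k, f, x[f], y[f]))
    data = pd.DataFrame(records, columns=["track_id", "frame", "x_um", "y_um"])
    tracks = TrackSet(data, frame_interval=dt)
    return tracks, GroundTruth(alpha_true=alpha, seed=seed)


def make_blinking(tracks: TrackSet, off_prob: float,
                  seed: int | None = None) -> pd.DataFrame:
    """Spot table with localisations removed i.i.d. per frame (QD blinking).

    Returns a DataFrame (frame, x_um, y_um, id) where ``id`` retains the
    ground-truth track identity for scoring the linker.
    """
    if not (0 <= off_prob < 1) and off_prob != 1.0:
        raise ValueError("off_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    df = tracks.data.rename(columns={"track_id": "id"})[
        ["frame", "x_um", "y_um", "id"]].copy()
    keep = rng.random(len(df)) >= off_prob
    return df[keep].reset_index(drop=True)
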