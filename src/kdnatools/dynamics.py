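"""Single-particle-tracking statistics and equipartition stiffness estimates.

Implements the analysis chain applied to quantum-dot labels on a fluctuating
kDNA network:

* frame-to-frame linking of spot localisations into trajectories
  (nearest-neighbour assignment with a displacement cap and gap closing),
* tracking of the network centre of mass (COM) from the DNA channel,
* ``g2(t)``: the mean squared displacement of each label measured in the COM
  frame, g2(t) = ⟨[(r_i(t+t0) − r_CM(t+t0)) − (r_i(t0) − r_CM(t0))]²⟩,
  averaged over initial times t0 and labels,
* ``dMSD(t)``: the MSD of the pair distance vector d_ij = r_i − r_j, which is
  insensitive to rigid-body motion, optionally normalised per pair by ⟨d⟩²,
* power-law exponent fits on log-log MSD curves,
* plateau estimation and the two equipartition stiffness estimators
  κ = 2 k_B T / g2(∞) and κ = 2 k_B T / σ⟨d⟩².
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment

from . import enrichment as _enr
from .units import kbt_pn_um, DEFAULT_TEMPERATURE

__all__ = [
    "TrackSet", "MsdCurve", "PairDistanceStats", "StiffnessEstimate",
    "ExponentFit", "PlateauEstimate",
    "link_spots", "track_com", "g2", "dmsd", "fit_exponent", "plateau",
    "stiffness_from_plateau", "stiffness_from_pairs",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class TrackSet:
    """A set of 2D trajectories in physical units.

    ``data`` has columns ``track_id, frame, x_um, y_um`` with frames strictly
    increasing within each track (gaps from blinking allowed). ``com`` is an
    optional per-frame COM table with columns ``frame, x_um, y_um``.
    """

    data: pd.DataFrame
    frame_interval: float
    com: pd.DataFrame | None = None

    def __post_init__(self):
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        for tid, g in self.data.groupby("track_id"):
            f = g["frame"].to_numpy()
            if (np.diff(f) <= 0).any():
                raise ValueError(f"frames not strictly increasing in track {tid}")

    @property
    def track_ids(self) -> np.ndarray:
        return self.data["track_id"].unique()

    def __len__(self) -> int:
        return len(self.track_ids)

    def arrays(self) -> dict[int, tuple[np.ndarray, np.ndarray]]:
        """Per-track (frames, xy) arrays."""
        out = {}
        for tid, g in self.data.groupby("track_id"):
            out[tid] = (g["frame"].to_numpy(int),
                        g[["x_um", "y_um"]].to_numpy(float))
        return out

    def dense(self) -> tuple[np.ndarray, np.ndarray]:
        """Positions on a common frame axis: (frames, array (F, n, 2) with NaN gaps)."""
        fmin = int(self.data["frame"].min())
        fmax = int(self.data["frame"].max())
        frames = np.arange(fmin, fmax + 1)
        ids = list(self.track_ids)
        pos = np.full((len(frames), len(ids), 2), np.nan)
        for k, tid in enumerate(ids):
            g = self.data[self.data["track_id"] == tid]
            pos[g["frame"].to_numpy(int) - fmin, k] = g[["x_um", "y_um"]].to_numpy()
        return frames, pos

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, frame_interval: float) -> "TrackSet":
        return cls(pd.read_csv(path), frame_interval=frame_interval)


@dataclass
class MsdCurve:
    """Lag-time statistics of a squared-displacement observable."""

    lags: np.ndarray          # seconds, lag 0 included
    values: np.ndarray        # μm² (or dimensionless when normalised)
    counts: np.ndarray        # samples per lag
    kind: str                 # "g2" | "dmsd" | "dmsd_normalised" | "msd"

    def __post_init__(self):
        if self.lags[0] != 0 or self.values[0] != 0:
            raise ValueError("MSD curves must start at lag 0 with value 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag_s": self.lags, "value": self.values,
                             "n": self.counts})


@dataclass
class PairDistanceStats:
    """Per-pair distance statistics d_ij(t) = |r_i − r_j|."""

    pairs: pd.DataFrame       # columns i, j, mean_d, sd_d, n
    mean_distance: float      # pooled mean of per-pair ⟨d⟩, μm
    mean_sd: float            # pooled mean of per-pair σ(d), μm


@dataclass
class ExponentFit:
    alpha: float
    window: tuple[float, float]
    stderr: float
    r_squared: float
    n_points: int


@dataclass
class PlateauEstimate:
    value: float              # μm²
    se: float
    n_lags: int
    slope: float              # residual log-log slope over the window
    reliable: bool


@dataclass
class StiffnessEstimate:
    """Effective network stiffness κ from the equipartition theorem.

    κ is defined through κ = 2 k_B T / ⟨fluctuation²⟩ where the fluctuation
    is either the long-time g2 plateau (method "plateau") or the standard
    deviation of pair distances (method "pair_distance"). For a 2D harmonic
    trap of per-axis stiffness k this convention returns k/2: it is an
    effective 2D network stiffness, not a per-axis spring constant.
    """

    kappa: float              # pN/μm
    method: str
    kbt: float                # pN·μm
    temperature: float        # K
    fluct_input: float        # plateau (μm²) or σ⟨d⟩ (μm)


# ---------------------------------------------------------------------------
# linking
# ---------------------------------------------------------------------------

def link_spots(spots: pd.DataFrame, max_disp: float, memory: int = 3,
               frame_interval: float = 0.125) -> TrackSet:
    """Link per-frame localisations into trajectories.

    Nearest-neighbour frame-to-frame assignment (optimal, via the Hungarian
    algorithm on pairwise distances) with links longer than ``max_disp`` (μm
    per frame gap) forbidden, and gap closing across up to ``memory`` missing
    frames.

    ``spots`` needs columns ``frame, x_um, y_um``; rows with an ``inside``
    column set to False are ignored.
    """
    df = spots.copy()
    if "inside" in df.columns:
        df = df[df["inside"]]
    if df["frame"].nunique() < 2:
        raise ValueError("linking needs spots in at least 2 frames")

    next_id = 0
    # active track: id -> (last_frame, last_xy)
    active: dict[int, tuple[int, np.ndarray]] = {}
    rows: list[tuple[int, int, float, float]] = []

    for f in sorted(df["frame"].unique()):
        pts = df[df["frame"] == f][["x_um", "y_um"]].to_numpy(float)
        # drop tracks whose gap exceeds memory
        active = {tid: (lf, xy) for tid, (lf, xy) in active.items()
                  if f - lf <= memory + 1}
        tids = list(active.keys())
        assigned = set()
        if tids and len(pts):
            last = np.array([active[t][1] for t in tids])
            gaps = np.array([f - active[t][0] for t in tids], dtype=float)
            cost = np.linalg.norm(last[:, None, :] - pts[None, :, :], axis=2)
            limit = max_disp * gaps[:, None]
            big = 1e9
            cost = np.where(cost <= limit, cost, big)
            ri, ci = linear_sum_assignment(cost)
            for i, j in zip(ri, ci):
                if cost[i, j] >= big:
                    continue
                tid = tids[i]
                active[tid] = (f, pts[j])
                rows.append((tid, int(f), pts[j][0], pts[j][1]))
                assigned.add(j)
        for j in range(len(pts)):
            if j not in assigned:
                tid = next_id
                next_id += 1
                active[tid] = (f, pts[j])
                rows.append((tid, int(f), pts[j][0], pts[j][1]))

    data = pd.DataFrame(rows, columns=["track_id", "frame", "x_um", "y_um"])
    data = data.sort_values(["track_id", "frame"]).reset_index(drop=True)
    return TrackSet(data, frame_interval=frame_interval)


def track_com(dna_movie: np.ndarray, blur_sigma: float = 2.0,
              threshold_method: str = "otsu", pixel_size: float = 1.0,
              frame_interval: float = 0.125) -> pd.DataFrame:
    """Per-frame centroid of the segmented DNA signal, in μm.

    Frames where segmentation fails are interpolated from neighbouring frames
    with a warning.
    """
    movie = np.asarray(dna_movie, dtype=float)
    if movie.ndim == 2:
        movie = movie[None]
    xs = np.full(len(movie), np.nan)
    ys = np.full(len(movie), np.nan)
    for i, frame in enumerate(movie):
        try:
            region = _enr.segment_region(frame, blur_sigma=blur_sigma,
                                         threshold_method=threshold_method)
        except ValueError:
            continue
        xs[i], ys[i] = region.centroid
    bad = np.isnan(xs)
    if bad.all():
        raise ValueError("no frame could be segmented")
    if bad.any():
        warnings.warn(f"{bad.sum()} frame(s) unsegmentable; centroid interpolated",
                      stacklevel=2)
        idx = np.arange(len(movie))
        xs[bad] = np.interp(idx[bad], idx[~bad], xs[~bad])
        ys[bad] = np.interp(idx[bad], idx[~bad], ys[~bad])
    return pd.DataFrame({"frame": np.arange(len(movie)),
                         "x_um": xs * pixel_size, "y_um": ys * pixel_size})


# ---------------------------------------------------------------------------
# MSD statistics
# ---------------------------------------------------------------------------

def _msd_from_series(series: np.ndarray, max_lag: int) -> tuple[np.ndarray, np.ndarray]:
    """Overlapping-window MSD of one (F, d) series with NaN gaps.

    Returns (sum of squared displacements, counts) per integer lag 1..max_lag.
    """
    F = series.shape[0]
    sums = np.zeros(max_lag)
    counts = np.zeros(max_lag)
    for lag in range(1, min(max_lag, F - 1) + 1):
        diff = series[lag:] - series[:-lag]
        sq = np.einsum("ij,ij->i", diff, diff)
        ok = ~np.isnan(sq)
        sums[lag - 1] = np.nansum(sq)
        counts[lag - 1] = ok.sum()
    return sums, counts


def g2(tracks: TrackSet, com: pd.DataFrame | None = None,
       max_lag: int | None = None) -> MsdCurve:
    """MSD of each label in the COM frame, averaged over t0 and labels.

    ``com`` defaults to the TrackSet's own COM table; pass an explicit table
    (columns ``frame, x_um, y_um``) to override. If no COM is available the
    labels' ensemble centre of mass per frame is used.
    """
    frames, pos = tracks.dense()
    if com is None:
        com = tracks.com
    if com is not None:
        com_xy = np.full((len(frames), 2), np.nan)
        cf = com["frame"].to_numpy(int)
        sel = (cf >= frames[0]) & (cf <= frames[-1])
        com_xy[cf[sel] - frames[0]] = com.loc[sel, ["x_um", "y_um"]].to_numpy()
        if np.isnan(com_xy).any():
            raise ValueError("COM trajectory does not cover all track frames")
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            com_xy = np.nanmean(pos, axis=1)
    rel = pos - com_xy[:, None, :]

    F = len(frames)
    if max_lag is None:
        max_lag = F - 1
    sums = np.zeros(max_lag)
    counts = np.zeros(max_lag)
    for k in range(rel.shape[1]):
        s, c = _msd_from_series(rel[:, k, :], max_lag)
        sums += s
        counts += c
    keep = counts > 0
    lags = np.concatenate([[0.0], (np.arange(1, max_lag + 1)[keep])
                           * tracks.frame_interval])
    vals = np.concatenate([[0.0], sums[keep] / counts[keep]])
    cnts = np.concatenate([[rel.shape[1] * F], counts[keep]])
    return MsdCurve(lags=lags, values=vals, counts=cnts, kind="g2")


def dmsd(tracks: TrackSet, normalise: bool = False,
         max_lag: int | None = None) -> tuple[MsdCurve, PairDistanceStats]:
    """MSD of the pair-distance vector, averaged over t0 and pairs.

    Also returns per-pair mean distance ⟨d⟩ and its standard deviation σ(d),
    whose pooled averages feed the pair-route stiffness estimator. With
    ``normalise=True`` each pair's curve is divided by its ⟨d⟩² before
    pooling.
    """
    frames, pos = tracks.dense()
    n = pos.shape[1]
    if n < 2:
        raise ValueError("dmsd needs at least 2 concurrent tracks")
    F = len(frames)
    if max_lag is None:
        max_lag = F - 1
    sums = np.zeros(max_lag)
    counts = np.zeros(max_lag)
    pair_rows = []
    ids = list(tracks.track_ids)
    for a in range(n):
        for b in range(a + 1, n):
            d_vec = pos[:, a, :] - pos[:, b, :]
            valid = ~np.isnan(d_vec[:, 0])
            if valid.sum() < 2:
                logger.info("pair (%s, %s) skipped: no overlapping frames",
                            ids[a], ids[b])
                continue
            d_abs = np.linalg.norm(d_vec[valid], axis=1)
            mean_d = float(d_abs.mean())
            sd_d = float(d_abs.std(ddof=1)) if len(d_abs) > 1 else 0.0
            pair_rows.append((ids[a], ids[b], mean_d, sd_d, int(valid.sum())))
            s, c = _msd_from_series(d_vec, max_lag)
            if normalise:
                s = s / mean_d ** 2
            sums += s
            counts += c
    if not pair_rows:
        raise ValueError("no pair has overlapping frames")
    keep = counts > 0
    lags = np.concatenate([[0.0], np.arange(1, max_lag + 1)[keep]
                           * tracks.frame_interval])
    vals = np.concatenate([[0.0], sums[keep] / counts[keep]])
    cnts = np.concatenate([[len(pair_rows) * F], counts[keep]])
    pairs = pd.DataFrame(pair_rows, columns=["i", "j", "mean_d", "sd_d", "n"])
    stats_ = PairDistanceStats(pairs=pairs,
                               mean_distance=float(pairs["mean_d"].mean()),
                               mean_sd=float(pairs["sd_d"].mean()))
    kind = "dmsd_normalised" if normalise else "dmsd"
    return MsdCurve(lags=lags, values=vals, counts=cnts, kind=kind), stats_


# ---------------------------------------------------------------------------
# fits and stiffness
# ---------------------------------------------------------------------------

def fit_exponent(curve: MsdCurve, window: tuple[float, float]) -> ExponentFit:
    """Power-law exponent α from a log10-log10 least-squares fit in a window."""
    t_min, t_max = window
    sel = (curve.lags >= t_min) & (curve.lags <= t_max) & (curve.lags > 0)
    if sel.sum() < 4:
        raise ValueError("exponent fit needs >= 4 lag points in the window")
    vals = curve.values[sel]
    if (vals <= 0).any():
        raise ValueError("nonpositive MSD values in the fit window")
    res = stats.linregress(np.log10(curve.lags[sel]), np.log10(vals))
    return ExponentFit(alpha=float(res.slope), window=(t_min, t_max),
                       stderr=float(res.stderr),
                       r_squared=float(res.rvalue ** 2), n_points=int(sel.sum()))


def plateau(curve: MsdCurve, t_min: float = 10.0,
            slope_tol: float = 0.1) -> PlateauEstimate:
    """Long-time plateau: mean of curve values at lags > t_min.

    The estimate is flagged unreliable when the residual log-log slope over
    the window exceeds ``slope_tol`` (the curve is still rising, e.g. free
    diffusion).
    """
    sel = curve.lags > t_min
    if sel.sum() < 3:
        raise ValueError("plateau needs at least 3 lags beyond t_min")
    vals = curve.values[sel]
    value = float(vals.mean())
    se = float(vals.std(ddof=1) / np.sqrt(sel.sum()))
    slope = 0.0
    reliable = True
    if (vals > 0).all():
        res = stats.linregress(np.log10(curve.lags[sel]), np.log10(vals))
        slope = float(res.slope)
        reliable = abs(slope) <= slope_tol
    return PlateauEstimate(value=value, se=se, n_lags=int(sel.sum()),
                           slope=slope, reliable=reliable)


def stiffness_from_plateau(plateau_um2: float,
                           temperature: float = DEFAULT_TEMPERATURE) -> StiffnessEstimate:
    """κ = 2 k_B T / g2(∞): equipartition stiffness from the g2 plateau."""
    if plateau_um2 <= 0:
        raise ValueError("plateau must be positive")
    kbt = kbt_pn_um(temperature)
    return StiffnessEstimate(kappa=2.0 * kbt / plateau_um2, method="plateau",
                             kbt=kbt, temperature=temperature,
                             fluct_input=plateau_um2)


def stiffness_from_pairs(sigma_d_um: float,
                         temperature: float = DEFAULT_TEMPERATURE) -> StiffnessEstimate:
    """κ = 2 k_B T / σ⟨d⟩²: equipartition stiffness from pair-distance spread."""
    if sigma_d_um <= 0:
        raise ValueError("sigma_d must be positive")
    kbt = kbt_pn_um(temperature)
    return StiffnessEstimate(kappa=2.0 * kbt / sigma_d_um ** 2,
                             method="pair_distance", kbt=kbt,
                             temperature=temperature, fluct_input=sigma_d_um)
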