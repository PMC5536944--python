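"""Trajectory linking, mean-square displacement and diffusion estimates.

Detections are linked frame to frame by greedy nearest-neighbour
assignment; per-trajectory diffusion coefficients come from an ordinary
least-squares fit of the first MSD lags,

    MSD(nΔt) = 4·D·nΔt + b,

with a free intercept b that absorbs the localization-noise offset.
Mobility distributions are reported as log10(D) with a per-cell peak from
a normal fit, the standard representation for sptPALM data.

Coordinates are in nm; lag times in s; MSD in µm²; D in µm²/s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import norm

__all__ = [
    "LinkParams",
    "Trajectory",
    "MSDCurve",
    "DiffusionEstimate",
    "MobilityStats",
    "link_trajectories",
    "compute_msd",
    "fit_diffusion",
    "mobility_stats",
]


@dataclass(frozen=True)
class LinkParams:
    """Linking and length-selection parameters.

    ``min_len_map`` / ``min_len_msd`` are strict lower bounds in points for
    map rendering and MSD analysis (trajectories *longer than* the bound
    qualify).
    """

    max_disp: float = 500.0  # nm per frame transition
    max_gap: int = 0  # frames a trajectory may go dark
    min_len_map: int = 20
    min_len_msd: int = 15

    def __post_init__(self) -> None:
        if not self.max_disp > 0:
            raise ValueError("max_disp must be > 0")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")
        if self.min_len_map < 2 or self.min_len_msd < 2:
            raise ValueError("length thresholds must be >= 2")


@dataclass
class Trajectory:
    """One linked track: strictly increasing frames and (x, y) in nm."""

    id: int
    frames: np.ndarray
    xy: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, np.int64)
        self.xy = np.asarray(self.xy, float)
        if len(self.frames) != len(self.xy):
            raise ValueError("frames and xy lengths differ")
        if len(self.frames) > 1 and np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")

    @property
    def length(self) -> int:
        return len(self.frames)


def link_trajectories(table, params: LinkParams) -> list[Trajectory]:
    """Link detections into trajectories by greedy nearest neighbours.

    For every frame transition, candidate (track end, detection) pairs
    within ``max_disp`` are assigned one-to-one in ascending distance order
    (ties: lower track id, then input order).  Unmatched detections start
    new trajectories; tracks dark for more than ``max_gap`` frames are
    terminated.  Every detection ends up in exactly one trajectory.
    """
    if hasattr(table, "table"):  # MoleculeSet: track burst barycentres
        df = table.table.rename(columns={"first_frame": "frame"})
    else:
        df = table
    frames = df["frame"].to_numpy(np.int64)
    xy = df[["x", "y"]].to_numpy(float)
    order = np.argsort(frames, kind="stable")

    traj_frames: list[list[int]] = []
    traj_xy: list[list[np.ndarray]] = []
    traj_last: list[int] = []
    active: list[int] = []

    for f in np.unique(frames):
        rows = order[np.searchsorted(frames[order], f):
                     np.searchsorted(frames[order], f, side="right")]
        det = xy[rows]
        active = [t for t in active if f - traj_last[t] <= params.max_gap + 1]
        pairs = []
        if active and len(det):
            ends = np.asarray([traj_xy[t][-1] for t in active])
            tree = cKDTree(ends)
            for di, hits in enumerate(tree.query_ball_point(det, params.max_disp)):
                for h in hits:
                    d = float(np.hypot(*(det[di] - ends[h])))
                    pairs.append((d, active[h], di))
        pairs.sort()
        used_t: set[int] = set()
        used_d: set[int] = set()
        for d, t, di in pairs:
            if t in used_t or di in used_d:
                continue
            used_t.add(t)
            used_d.add(di)
            traj_frames[t].append(int(f))
            traj_xy[t].append(det[di])
            traj_last[t] = int(f)
        for di in range(len(det)):
            if di not in used_d:
                t = len(traj_frames)
                traj_frames.append([int(f)])
                traj_xy.append([det[di]])
                traj_last.append(int(f))
                active.append(t)

    return [Trajectory(id=i, frames=np.asarray(fr, np.int64),
                       xy=np.asarray(p))
            for i, (fr, p) in enumerate(zip(traj_frames, traj_xy))]


@dataclass
class MSDCurve:
    """Time-averaged MSD of one trajectory (or an ensemble mean).

    Lag 0 is included with MSD 0; ``n_pairs[n]`` counts the overlapping
    displacement pairs contributing to lag ``n``.
    """

    lags: np.ndarray  # s
    msd: np.ndarray  # µm²
    n_pairs: np.ndarray

    def __len__(self) -> int:
        return len(self.lags)


def compute_msd(traj: Trajectory, frame_interval: float) -> MSDCurve:
    """Time-averaged MSD over overlapping windows, lags up to length/2.

    MSD(nΔt) is the mean of |r(t+nΔt) − r(t)|² over all ordered position
    pairs separated by n frames, for n = 1..⌊length/2⌋ (plus the trivial
    lag 0).  Positions in nm, MSD returned in µm².
    """
    if traj.length < 2:
        raise ValueError("MSD needs at least 2 positions")
    if frame_interval <= 0:
        raise ValueError("frame_interval must be > 0")
    frames = traj.frames - traj.frames[0]
    span = int(frames[-1])
    max_lag = max(1, span // 2)
    lags = [0.0]
    msd = [0.0]
    npairs = [traj.length]
    xy_um = traj.xy * 1e-3
    # frame-difference matching also handles gapped tracks
    idx = {int(f): k for k, f in enumerate(frames)}
    for n in range(1, max_lag + 1):
        sq = [float(np.sum((xy_um[idx[int(f) + n]] - xy_um[k]) ** 2))
              for k, f in enumerate(frames) if int(f) + n in idx]
        lags.append(n * frame_interval)
        if sq:
            msd.append(float(np.mean(sq)))
            npairs.append(len(sq))
        else:
            msd.append(np.nan)
            npairs.append(0)
    return MSDCurve(lags=np.asarray(lags), msd=np.asarray(msd),
                    n_pairs=np.asarray(npairs, np.int64))


@dataclass
class DiffusionEstimate:
    """OLS fit MSD(t) = 4·D·t + b over the first lags."""

    D: float  # µm²/s (unclipped; may be negative for immobile noise)
    intercept: float  # µm²
    n_fit_points: int
    r_squared: float


def fit_diffusion(msd: MSDCurve, n_points: int = 4) -> DiffusionEstimate:
    """Fit D from the first ``n_points`` nonzero MSD lags.

    Ordinary least squares of MSD on lag time with a free intercept; the
    diffusion coefficient is slope/4.  Raises when fewer than ``n_points``
    lags (excluding lag 0) are available.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    mask = msd.lags > 0
    t = msd.lags[mask][:n_points]
    y = msd.msd[mask][:n_points]
    if len(t) < n_points or np.any(~np.isfinite(y)):
        raise ValueError(f"need {n_points} finite MSD lags, have {np.sum(np.isfinite(y))}")
    slope, intercept = np.polyfit(t, y, 1)
    pred = slope * t + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return DiffusionEstimate(D=float(slope) / 4.0, intercept=float(intercept),
                             n_fit_points=int(len(t)), r_squared=r2)


@dataclass
class MobilityStats:
    """Mobility readouts of one cell's trajectory set."""

    log10_D: np.ndarray  # per qualifying trajectory, floor-clipped
    hist_counts: np.ndarray
    hist_edges: np.ndarray
    peak_log10_D: float  # mean of a normal fit to log10 D
    sigma_log10_D: float
    ensemble_msd: pd.DataFrame  # lag_s, msd_um2, n_traj
    n_trajectories: int


def mobility_stats(trajectories: list[Trajectory], frame_interval: float,
                   params: LinkParams = LinkParams(), n_points: int = 4,
                   d_floor: float = 1e-5, bins: int = 40) -> MobilityStats:
    """log10(D) distribution, normal-fit peak and ensemble MSD.

    Only trajectories strictly longer than ``min_len_msd`` points enter.
    Per-trajectory D values are clipped at ``d_floor`` (µm²/s) before
    taking log10; the per-cell peak is the mean of a normal distribution
    fitted to the log10 D values.  The ensemble MSD is the lag-wise mean
    over the individual MSD curves.
    """
    qual = [t for t in trajectories if t.length > params.min_len_msd]
    if not qual:
        raise ValueError("no trajectory exceeds min_len_msd points")
    curves = [compute_msd(t, frame_interval) for t in qual]
    ds = []
    for c in curves:
        try:
            ds.append(fit_diffusion(c, n_points=n_points).D)
        except ValueError:
            continue
    if not ds:
        raise ValueError("no trajectory has enough MSD lags to fit")
    log_d = np.log10(np.maximum(np.asarray(ds), d_floor))
    mu, sigma = norm.fit(log_d)
    counts, edges = np.histogram(log_d, bins=bins)

    max_n = max(len(c) for c in curves)
    lag_s = np.arange(max_n) * frame_interval
    sums = np.zeros(max_n)
    cnts = np.zeros(max_n, int)
    for c in curves:
        m = np.isfinite(c.msd)
        sums[np.flatnonzero(m)] += c.msd[m]
        cnts[np.flatnonzero(m)] += 1
    with np.errstate(invalid="ignore"):
        mean_msd = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    ens = pd.DataFrame({"lag_s": lag_s, "msd_um2": mean_msd, "n_traj": cnts})
    return MobilityStats(log10_D=log_d, hist_counts=counts, hist_edges=edges,
                         peak_log10_D=float(mu), sigma_log10_D=float(sigma),
                         ensemble_msd=ens, n_trajectories=len(qual))
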