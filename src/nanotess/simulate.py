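"""Synthetic ground-truth generators for nanodomain analysis.

Every downstream stage of the pipeline (blinking correction, tessellation
segmentation, trajectory analysis, line-profile statistics) is exercised on
data produced here, with full bookkeeping of the ground truth so that
parameter-recovery tests have an exact oracle.

The single-molecule generator emulates a photoactivated-localization (PALM)
acquisition of a membrane protein that partitions into ~80-nm nanodomains:

* molecule positions: homogeneous Poisson background plus uniform-in-disk
  nanodomain members (non-overlapping disks, rejection-sampled);
* photophysics: each molecule emits ``1 + Geometric(p)`` bursts; burst
  on-times and the dark gaps between bursts are geometric with configurable
  means (the memoryless convention for fluorophore blinking);
* localization error: each detection is the true molecule position plus
  isotropic Gaussian noise.

Units: coordinates in nm, field size in µm, densities per µm², diffusion in
µm²/s, times in frames unless stated otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SmlmSimConfig",
    "GroundTruth",
    "TrajectorySimConfig",
    "SimulatedTrajectories",
    "LineProfile",
    "simulate_smlm",
    "simulate_trajectories",
    "simulate_profiles",
    "simulate_ratio_image",
]


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class SmlmSimConfig:
    """Parameters of a synthetic single-molecule localization acquisition.

    Defaults describe the study conditions used throughout the test suite:
    a 5×5 µm membrane patch at ≈317 molecules/µm² total density with 37% of
    molecules in 80-nm nanodomains at 2 domains/µm², 20-nm localization
    precision, and mEos-like blinking with a mean of 1/(1-0.3) ≈ 1.43
    bursts per molecule.
    """

    field_size: float = 5.0  # µm, square side
    background_density: float = 200.0  # background molecules / µm²
    domain_density: float = 2.0  # domains / µm²
    domain_diameter: float = 80.0  # nm
    fraction_in_domains: float = 0.37
    loc_precision_sigma: float = 20.0  # nm, per detection
    n_frames: int = 20_000
    blink_continue_prob: float = 0.3  # geometric extra-blink probability
    mean_on_frames: float = 3.0
    mean_off_frames: float = 5.0
    detection_prob: float = 1.0  # chance a scheduled on-frame yields a detection
    seed: int = 0

    def validate(self) -> None:
        for name in ("field_size", "background_density", "domain_density",
                     "domain_diameter", "loc_precision_sigma"):
            v = getattr(self, name)
            _check(np.isfinite(v) and v >= 0, f"{name} must be finite and >= 0")
        _check(self.field_size > 0, "field_size must be > 0")
        _check(0.0 <= self.fraction_in_domains <= 1.0,
               "fraction_in_domains must be in [0, 1]")
        _check(0.0 <= self.blink_continue_prob < 1.0,
               "blink_continue_prob must be in [0, 1)")
        _check(self.n_frames >= 1, "n_frames must be >= 1")
        _check(self.mean_on_frames >= 1.0, "mean_on_frames must be >= 1 frame")
        _check(self.mean_off_frames >= 1.0, "mean_off_frames must be >= 1 frame")
        _check(0.0 < self.detection_prob <= 1.0, "detection_prob must be in (0, 1]")
        if self.fraction_in_domains == 1.0 and self.background_density > 0:
            raise ValueError(
                "fraction_in_domains=1 with nonzero background is inconsistent; "
                "set background_density=0 or fraction_in_domains<1")


@dataclass
class GroundTruth:
    """Exact bookkeeping of a simulated acquisition.

    ``molecule_domain`` is -1 for background molecules, otherwise the index
    into ``domain_centers``/``domain_radii``.  ``detection_molecule`` maps
    every row of the localization table back to its emitting molecule.
    """

    molecule_xy: np.ndarray  # (n_mol, 2) nm, true positions
    molecule_domain: np.ndarray  # (n_mol,) int
    molecule_n_blinks: np.ndarray  # (n_mol,) int, bursts per molecule
    domain_centers: np.ndarray  # (n_dom, 2) nm
    domain_radii: np.ndarray  # (n_dom,) nm
    detection_molecule: np.ndarray  # (n_det,) int, aligned with the table rows

    @property
    def n_molecules(self) -> int:
        return len(self.molecule_xy)

    @property
    def fraction_in_domains(self) -> float:
        if self.n_molecules == 0:
            return 0.0
        return float(np.mean(self.molecule_domain >= 0))


def _sample_domains(rng: np.random.Generator, n: int, L: float, r: float,
                    max_tries: int = 10_000) -> np.ndarray:
    """Non-overlapping disk centres, fully inside the [0, L]² field (nm)."""
    if n == 0:
        return np.empty((0, 2))
    if 2 * r >= L:
        raise ValueError("domain diameter exceeds the field size")
    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < n:
        tries += 1
        if tries > max_tries * n:
            raise RuntimeError(
                "could not place non-overlapping domains; lower domain_density")
        c = rng.uniform(r, L - r, size=2)
        if all(np.hypot(*(c - o)) >= 2 * r for o in centers):
            centers.append(c)
    return np.asarray(centers)


def simulate_smlm(config: SmlmSimConfig) -> tuple[GroundTruth, pd.DataFrame]:
    """Simulate a blinking PALM acquisition of a clustered membrane protein.

    Returns the ground truth and a localization table with columns
    ``frame, x, y, sigma, intensity`` (nm), sorted by frame.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = config.field_size * 1000.0  # nm
    area = config.field_size ** 2  # µm²
    r_dom = config.domain_diameter / 2.0

    n_bg = rng.poisson(config.background_density * area)
    f = config.fraction_in_domains
    if f >= 1.0:
        lam_in = 0.0 if config.background_density == 0 else np.nan
        n_in = 0
    else:
        lam_in = config.background_density * area * f / (1.0 - f)
        n_in = rng.poisson(lam_in)
    n_dom = rng.poisson(config.domain_density * area)
    if n_dom == 0:
        n_in = 0
    centers = _sample_domains(rng, n_dom, L, r_dom)

    xy_bg = rng.uniform(0.0, L, size=(n_bg, 2))
    # uniform in disk: sqrt-radius sampling
    assign = rng.integers(0, n_dom, size=n_in) if n_dom else np.empty(0, int)
    rr = r_dom * np.sqrt(rng.uniform(size=n_in))
    th = rng.uniform(0.0, 2 * np.pi, size=n_in)
    xy_in = (centers[assign] if n_in else np.empty((0, 2))) + \
        np.c_[rr * np.cos(th), rr * np.sin(th)]

    mol_xy = np.vstack([xy_bg, xy_in])
    mol_dom = np.concatenate([np.full(n_bg, -1, int), assign.astype(int)])
    n_mol = len(mol_xy)

    # photophysics: bursts, on-times, off-times (all geometric, support >= 1)
    p = config.blink_continue_prob
    extra = rng.geometric(1.0 - p, size=n_mol) - 1 if p > 0 else np.zeros(n_mol, int)
    n_blinks = 1 + extra
    start = rng.integers(0, config.n_frames, size=n_mol)

    frames: list[int] = []
    det_mol: list[int] = []
    for i in range(n_mol):
        t = int(start[i])
        for b in range(n_blinks[i]):
            on = int(rng.geometric(1.0 / config.mean_on_frames))
            for k in range(on):
                fr = t + k
                if fr >= config.n_frames:
                    break
                if config.detection_prob >= 1.0 or rng.uniform() < config.detection_prob:
                    frames.append(fr)
                    det_mol.append(i)
            t += on
            if b < n_blinks[i] - 1:
                t += int(rng.geometric(1.0 / config.mean_off_frames))

    frames_a = np.asarray(frames, int)
    det_mol_a = np.asarray(det_mol, int)
    n_det = len(frames_a)
    noise = rng.normal(0.0, config.loc_precision_sigma, size=(n_det, 2)) \
        if config.loc_precision_sigma > 0 else np.zeros((n_det, 2))
    det_xy = mol_xy[det_mol_a] + noise if n_det else np.empty((0, 2))

    order = np.argsort(frames_a, kind="stable")
    table = pd.DataFrame({
        "frame": frames_a[order],
        "x": det_xy[order, 0],
        "y": det_xy[order, 1],
        "sigma": np.full(n_det, float(config.loc_precision_sigma)),
        "intensity": np.ones(n_det),
    })
    gt = GroundTruth(
        molecule_xy=mol_xy,
        molecule_domain=mol_dom,
        molecule_n_blinks=n_blinks,
        domain_centers=centers,
        domain_radii=np.full(n_dom, r_dom),
        detection_molecule=det_mol_a[order],
    )
    return gt, table


@dataclass(frozen=True)
class TrajectorySimConfig:
    """Brownian / confined trajectory simulation parameters.

    ``n_steps`` is the number of displacement steps; each trajectory has
    ``n_steps + 1`` positions.  When ``confinement_radius`` is set the walk
    is reflected at a circular corral of that radius centred at the origin
    and started from the stationary (uniform-in-disk) distribution.
    """

    D_true: float = 0.05  # µm²/s
    frame_interval: float = 0.02  # s
    n_steps: int = 50
    n_trajectories: int = 100
    confinement_radius: float | None = None  # nm
    loc_precision_sigma: float = 0.0  # nm
    seed: int = 0

    def validate(self) -> None:
        _check(np.isfinite(self.D_true) and self.D_true >= 0, "D_true must be >= 0")
        _check(self.frame_interval > 0, "frame_interval must be > 0")
        _check(self.n_steps >= 2, "n_steps must be >= 2")
        _check(self.n_trajectories >= 1, "n_trajectories must be >= 1")
        if self.confinement_radius is not None:
            _check(self.confinement_radius > 0, "confinement_radius must be > 0")
        _check(self.loc_precision_sigma >= 0, "loc_precision_sigma must be >= 0")


@dataclass
class SimulatedTrajectories:
    """True and noise-corrupted positions, shape (n_traj, n_steps+1, 2), nm."""

    true_xy: np.ndarray
    noisy_xy: np.ndarray
    frame_interval: float  # s

    def to_trajectories(self, noisy: bool = True) -> list:
        """Export as :class:`nanotess.tracking.Trajectory` objects."""
        from .tracking import Trajectory

        xy = self.noisy_xy if noisy else self.true_xy
        n_pos = xy.shape[1]
        frames = np.arange(n_pos)
        return [Trajectory(id=i, frames=frames.copy(), xy=xy[i].copy())
                for i in range(xy.shape[0])]


def _reflect_disk(pos: np.ndarray, R: float) -> np.ndarray:
    """Radial reflection of points at the circle |r| = R (in place safe)."""
    out = pos.copy()
    r = np.hypot(out[:, 0], out[:, 1])
    while np.any(r > R):
        idx = r > R
        # reflected radius is |2R - r|; may still exceed R for huge steps
        out[idx] *= ((2 * R - r[idx]) / r[idx])[:, None]
        r = np.hypot(out[:, 0], out[:, 1])
    return out


def simulate_trajectories(config: TrajectorySimConfig) -> SimulatedTrajectories:
    """Simulate 2-D Brownian (optionally corral-confined) trajectories.

    Free diffusion: per-axis step variance ``2 D Δt``.  Confined: the same
    steps with radial reflection at the corral boundary; the long-time
    position distribution is uniform in the disk, so the ensemble MSD
    plateaus at R² (mean squared distance of two uniform disk points).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, m = config.n_trajectories, config.n_steps
    step_sd = math.sqrt(2.0 * config.D_true * config.frame_interval) * 1000.0  # nm
    steps = rng.normal(0.0, step_sd, size=(n, m, 2)) if step_sd > 0 \
        else np.zeros((n, m, 2))

    R = config.confinement_radius
    if R is None:
        start = np.zeros((n, 2))
        true = np.concatenate([start[:, None, :],
                               start[:, None, :] + np.cumsum(steps, axis=1)], axis=1)
    else:
        rr = R * np.sqrt(rng.uniform(size=n))
        th = rng.uniform(0, 2 * np.pi, size=n)
        pos = np.c_[rr * np.cos(th), rr * np.sin(th)]
        true = np.empty((n, m + 1, 2))
        true[:, 0] = pos
        for k in range(m):
            pos = _reflect_disk(pos + steps[:, k], R)
            true[:, k + 1] = pos

    sig = config.loc_precision_sigma
    noisy = true + rng.normal(0.0, sig, size=true.shape) if sig > 0 else true.copy()
    return SimulatedTrajectories(true_xy=true, noisy_xy=noisy,
                                 frame_interval=config.frame_interval)


@dataclass
class LineProfile:
    """Fluorescence intensities sampled along a membrane line (a.u.).

    ``length_um`` is the physical line length (10 µm by convention for
    surface-view plasma-membrane profiles).
    """

    intensities: np.ndarray
    length_um: float = 10.0

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, float)
        if self.intensities.ndim != 1 or len(self.intensities) < 20:
            raise ValueError("a line profile needs >= 20 samples")
        if not np.all(np.isfinite(self.intensities)) or np.any(self.intensities < 0):
            raise ValueError("intensities must be finite and >= 0")
        if self.length_um <= 0:
            raise ValueError("length_um must be > 0")

    @property
    def spacing_um(self) -> float:
        return self.length_um / (len(self.intensities) - 1)


def simulate_profiles(n_samples: int = 100, spot_amplitude: float = 8.0,
                      spot_sigma: float = 0.15, n_spots: int = 8,
                      baseline: float = 1.0, noise_sigma: float = 0.1,
                      seed: int = 0, length_um: float = 10.0) -> LineProfile:
    """Synthetic line profile: baseline + Gaussian spots + noise (clipped at 0).

    ``spot_sigma`` is in µm along the line.  ``n_spots=0, noise_sigma=0``
    gives a constant profile at ``baseline``.
    """
    if n_samples < 20:
        raise ValueError("n_samples must be >= 20 (percentile slices undefined)")
    for name, v in [("spot_amplitude", spot_amplitude), ("spot_sigma", spot_sigma),
                    ("baseline", baseline), ("noise_sigma", noise_sigma)]:
        _check(np.isfinite(v) and v >= 0, f"{name} must be finite and >= 0")
    _check(n_spots >= 0, "n_spots must be >= 0")
    rng = np.random.default_rng(seed)
    x = np.linspace(0.0, length_um, n_samples)
    y = np.full(n_samples, float(baseline))
    centers = rng.uniform(0.0, length_um, size=n_spots)
    for c in centers:
        y += spot_amplitude * np.exp(-0.5 * ((x - c) / max(spot_sigma, 1e-12)) ** 2)
    if noise_sigma > 0:
        y += rng.normal(0.0, noise_sigma, size=n_samples)
    return LineProfile(intensities=np.clip(y, 0.0, None), length_um=length_um)


def simulate_ratio_image(shape: tuple[int, int] = (128, 128), n_spots: int = 12,
                         spot_sigma_px: float = 3.0, spot_amplitude: float = 8.0,
                         baseline: float = 1.0, ratio_inside: float = 0.5,
                         ratio_outside: float = 1.0, green_level: float = 100.0,
                         noise_sigma: float = 0.0, seed: int = 0,
                         pixel_size_um: float = 0.1):
    """Two-channel ratiometric image with a co-registered reference channel.

    The reference channel carries Gaussian spots (the protein marker); the
    red/green ratio equals ``ratio_inside`` at spot centres and relaxes to
    ``ratio_outside`` away from spots, emulating an ordered-lipid reporter
    that shifts spectrally inside protein-enriched domains.
    """
    from .profiles import RatioImagePair

    _check(n_spots >= 0, "n_spots must be >= 0")
    _check(green_level > 0, "green_level must be > 0")
    rng = np.random.default_rng(seed)
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    spots = np.zeros(shape, float)
    for _ in range(n_spots):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        spots += np.exp(-0.5 * (((yy - cy) ** 2 + (xx - cx) ** 2)
                                / spot_sigma_px ** 2))
    weight = np.clip(spots, 0.0, 1.0)
    reference = baseline + spot_amplitude * spots
    if noise_sigma > 0:
        reference = np.clip(reference + rng.normal(0, noise_sigma, shape), 0, None)
    ratio = ratio_outside + (ratio_inside - ratio_outside) * weight
    green = np.full(shape, float(green_level))
    red = green * ratio
    return RatioImagePair(reference=reference, green=green, red=red,
                          pixel_size_um=pixel_size_um)
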