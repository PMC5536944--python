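"""Localization-table I/O and blinking correction.

A photoactivatable fluorophore emits several temporally separated bursts
("blinks") before bleaching, so a raw localization table overcounts
molecules.  The correction merges detections that fall within a spatial
search radius ω and a blinking tolerance τ (frames) into single molecules,
replacing each molecule by the barycentre of its member detections:

* a *burst* is a maximal chain of detections in consecutive frames, each
  within ω of the burst's running barycentre;
* a *molecule* is a maximal chain of bursts whose dark gaps are ≤ τ frames
  and that stay within ω of the molecule's running barycentre.

ω defaults to 48 nm, appropriate when the per-frame density of active
fluorophores stays below ~0.5 molecules/µm².  τ is chosen from the measured
off-time distribution (see :func:`select_tau`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "MergeParams",
    "MoleculeSet",
    "PhotophysicsSummary",
    "read_localizations",
    "merge_molecules",
    "photophysics_summary",
    "consistency_check",
    "select_tau",
]


class FormatError(ValueError):
    """Raised when a localization file lacks a mandatory column."""


#: column aliases per dialect -> canonical names (coordinates in nm)
_DIALECTS = {
    "generic": {"frame": "frame", "x": "x", "y": "y", "x_nm": "x", "y_nm": "y",
                "sigma": "sigma", "sigma_nm": "sigma", "intensity": "intensity"},
    "thunderstorm": {"frame": "frame", "x [nm]": "x", "y [nm]": "y",
                     "sigma [nm]": "sigma", "uncertainty [nm]": "sigma",
                     "intensity [photon]": "intensity", "id": "id"},
}


def read_localizations(path, dialect: str = "generic") -> pd.DataFrame:
    """Read a localization CSV into the canonical table (frame, x, y [, ...]).

    Coordinates are mapped to nm column names ``x``/``y``.  Rows with
    non-finite coordinates are dropped (count logged).
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; use one of {sorted(_DIALECTS)}")
    raw = pd.read_csv(path)
    mapping = _DIALECTS[dialect]
    cols = {c: mapping[c] for c in raw.columns if c in mapping}
    table = raw.rename(columns=cols)
    for mandatory in ("frame", "x", "y"):
        if mandatory not in table.columns:
            raise FormatError(f"missing column {mandatory}")
    keep = ["frame", "x", "y"] + [c for c in ("sigma", "intensity")
                                  if c in table.columns]
    table = table[keep].copy()
    ok = np.isfinite(table["x"].to_numpy(float)) & np.isfinite(table["y"].to_numpy(float))
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("dropped %d rows with non-finite coordinates", n_bad)
        table = table[ok]
    table["frame"] = table["frame"].astype(np.int64)
    table = table.sort_values("frame", kind="stable").reset_index(drop=True)
    if len(table) == 0:
        raise ValueError("localization table is empty")
    return table


@dataclass(frozen=True)
class MergeParams:
    """ω (nm) and τ (frames) of the spatio-temporal merge."""

    omega: float = 48.0
    tau: int = 0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.omega) and self.omega >= 0):
            raise ValueError("omega must be finite and >= 0")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")


@dataclass
class MoleculeSet:
    """Blinking-merged molecules at burst barycentres.

    ``table`` columns: x, y (nm), first_frame, last_frame, n_detections,
    n_blinks.  ``members[i]`` holds the row indices of molecule *i*'s
    detections in the input table; ``burst_lengths``/``off_times`` record
    the photophysics of the merge graph.
    """

    table: pd.DataFrame
    members: list = field(default_factory=list)
    burst_lengths: list = field(default_factory=list)  # per molecule, frames
    off_times: list = field(default_factory=list)  # per molecule, frames
    params: MergeParams | None = None

    def __len__(self) -> int:
        return len(self.table)

    @property
    def xy(self) -> np.ndarray:
        return self.table[["x", "y"]].to_numpy(float)

    @property
    def n_bursts(self) -> int:
        return int(self.table["n_blinks"].sum())


def merge_molecules(table: pd.DataFrame, params: MergeParams) -> MoleculeSet:
    """Merge blinking detections into molecules (greedy, frame order).

    Detections are scanned frame by frame.  Each detection first tries to
    extend an *open* burst (one detected in the previous frame) whose
    running barycentre lies within ω, then to re-ignite a *dormant*
    molecule (dark for 1..τ frames) within ω of the molecule barycentre;
    otherwise it founds a new molecule.  Ties go to the nearest barycentre,
    then the lower molecule id; a molecule accepts at most one detection per
    frame.  With τ=0 molecules coincide with bursts.
    """
    if len(table) == 0:
        raise ValueError("cannot merge an empty table")
    frames = table["frame"].to_numpy(np.int64)
    if np.any(np.diff(frames) < 0):
        order = np.argsort(frames, kind="stable")
    else:
        order = np.arange(len(frames))
    xs = table["x"].to_numpy(float)
    ys = table["y"].to_numpy(float)
    omega, tau = params.omega, int(params.tau)

    # per-molecule accumulators
    msx: list[float] = []   # sum x over all detections
    msy: list[float] = []
    mn: list[int] = []      # total detections
    bsx: list[float] = []   # current-burst sums
    bsy: list[float] = []
    bn: list[int] = []
    first: list[int] = []
    last: list[int] = []
    bursts: list[list[int]] = []  # completed + running burst lengths
    gaps: list[list[int]] = []
    members: list[list[int]] = []

    # spatial hash over molecule barycentres; candidates come from the 3x3
    # cell neighbourhood so the scan stays O(local density) even for huge tau
    cell = max(omega, 1.0)
    grid: dict[tuple[int, int], list[int]] = {}
    cells_of: list[set] = []  # molecule registered under molecule- and
    #                           burst-barycentre cells (may differ)

    def _key(px: float, py: float) -> tuple[int, int]:
        return (int(np.floor(px / cell)), int(np.floor(py / cell)))

    def _reindex(m: int) -> None:
        want = {_key(msx[m] / mn[m], msy[m] / mn[m]),
                _key(bsx[m] / bn[m], bsy[m] / bn[m])}
        have = cells_of[m]
        for k in have - want:
            grid[k].remove(m)
        for k in want - have:
            grid.setdefault(k, []).append(m)
        cells_of[m] = want

    prev_frame = None
    claimed: set[int] = set()
    for row in order:
        f = int(frames[row])
        if f != prev_frame:
            claimed = set()
            prev_frame = f
        x, y = xs[row], ys[row]

        best = -1
        best_d = np.inf
        best_open = False
        kx, ky = _key(x, y)
        for gx in (kx - 1, kx, kx + 1):
            for gy in (ky - 1, ky, ky + 1):
                for m in grid.get((gx, gy), ()):
                    if m in claimed:
                        continue
                    gap = f - last[m] - 1
                    if gap == 0:  # open burst: use burst running barycentre
                        d = np.hypot(x - bsx[m] / bn[m], y - bsy[m] / bn[m])
                        is_open = True
                    elif 1 <= gap <= tau:  # dormant: molecule barycentre
                        d = np.hypot(x - msx[m] / mn[m], y - msy[m] / mn[m])
                        is_open = False
                    else:
                        continue
                    if d <= omega and \
                            (is_open, -d, -m) > (best_open, -best_d, -best):
                        # open-burst extension first, then nearest, lower id
                        best, best_d, best_open = m, d, is_open

        if best >= 0:
            m = best
            if best_open:
                bsx[m] += x; bsy[m] += y; bn[m] += 1
                bursts[m][-1] += 1
            else:
                gaps[m].append(f - last[m] - 1)
                bsx[m], bsy[m], bn[m] = x, y, 1
                bursts[m].append(1)
            msx[m] += x; msy[m] += y; mn[m] += 1
            last[m] = f
            members[m].append(int(row))
            claimed.add(m)
            _reindex(m)
        else:
            m = len(mn)
            msx.append(x); msy.append(y); mn.append(1)
            bsx.append(x); bsy.append(y); bn.append(1)
            first.append(f); last.append(f)
            bursts.append([1]); gaps.append([])
            members.append([int(row)])
            claimed.add(m)
            k = _key(x, y)
            cells_of.append({k})
            grid.setdefault(k, []).append(m)

    n_mol = len(mn)
    out = pd.DataFrame({
        "x": np.asarray(msx) / np.asarray(mn),
        "y": np.asarray(msy) / np.asarray(mn),
        "first_frame": np.asarray(first, np.int64),
        "last_frame": np.asarray(last, np.int64),
        "n_detections": np.asarray(mn, np.int64),
        "n_blinks": np.asarray([len(b) for b in bursts], np.int64),
    })
    assert int(out["n_detections"].sum()) == len(table)
    return MoleculeSet(table=out, members=[np.asarray(m) for m in members],
                       burst_lengths=bursts, off_times=gaps, params=params)


@dataclass
class PhotophysicsSummary:
    """Burst/blink statistics of a merged dataset.

    ``n_bursts_tau0`` is the burst count of the merge graph, i.e. the number
    of molecules a τ=0 merge of the same table yields.
    """

    on_times: np.ndarray  # frames, one entry per burst
    off_times: np.ndarray  # frames, one entry per dark gap
    blinks_per_molecule: np.ndarray
    n_bursts_tau0: int
    n_molecules: int

    @property
    def mean_on_time(self) -> float:
        return float(np.mean(self.on_times))

    @property
    def mean_off_time(self) -> float:
        return float(np.mean(self.off_times)) if len(self.off_times) else float("nan")

    @property
    def mean_blinks(self) -> float:
        return float(np.mean(self.blinks_per_molecule))

    def histogram(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        """(values, counts) histogram of 'on', 'off' or 'blinks' events."""
        data = {"on": self.on_times, "off": self.off_times,
                "blinks": self.blinks_per_molecule}[which]
        return np.unique(np.asarray(data, np.int64), return_counts=True)


def photophysics_summary(table: pd.DataFrame,
                         params: MergeParams) -> PhotophysicsSummary:
    """On-time, off-time and blinks-per-molecule distributions of a table.

    Runs the ω/τ merge and reports burst lengths (on-times), dark gaps
    between successive bursts of one molecule (off-times) and bursts per
    molecule, plus the τ=0 burst count of the same merge graph.
    """
    mols = merge_molecules(table, params)
    return summarize_photophysics(mols)


def summarize_photophysics(mols: MoleculeSet) -> PhotophysicsSummary:
    """Photophysics summary of an already-merged :class:`MoleculeSet`."""
    on = np.concatenate([np.asarray(b, np.int64) for b in mols.burst_lengths]) \
        if mols.burst_lengths else np.empty(0, np.int64)
    off = np.concatenate([np.asarray(g, np.int64) for g in mols.off_times
                          if len(g)]) if any(len(g) for g in mols.off_times) \
        else np.empty(0, np.int64)
    return PhotophysicsSummary(
        on_times=on, off_times=off,
        blinks_per_molecule=mols.table["n_blinks"].to_numpy(np.int64),
        n_bursts_tau0=mols.n_bursts, n_molecules=len(mols))


def consistency_check(summary: PhotophysicsSummary | None = None, *,
                      n_molecules: int | None = None,
                      n_bursts_tau0: int | None = None,
                      mean_blinks: float | None = None) -> float:
    """Percent difference between the molecule count and bursts/blinks.

    The expected molecule count is ``n_bursts_tau0 / mean_blinks``; the
    return value is ``100·|n_molecules − expected| / expected``.  A small
    percentage indicates the ω/τ merge and the photophysics are mutually
    consistent.  Accepts either a summary or the three raw numbers.
    """
    if summary is not None:
        n_molecules = summary.n_molecules
        n_bursts_tau0 = summary.n_bursts_tau0
        mean_blinks = summary.mean_blinks
    if not n_molecules or n_molecules <= 0:
        raise ValueError("n_molecules must be > 0")
    if not mean_blinks or mean_blinks <= 0:
        raise ValueError("mean blinks must be > 0")
    if not n_bursts_tau0 or n_bursts_tau0 <= 0:
        raise ValueError("n_bursts_tau0 must be > 0")
    expected = n_bursts_tau0 / mean_blinks
    return 100.0 * abs(n_molecules - expected) / expected


def select_tau(table: pd.DataFrame, omega: float = 48.0,
               quantile: float = 0.9, max_tau: int | None = None) -> int:
    """Choose τ as the smallest value covering a quantile of off-times.

    Off-times are measured with an effectively unlimited τ (all bursts
    within ω merge regardless of gap), then τ is the ``quantile``-level
    off-time, so a merge at that τ bridges the stated fraction of dark
    gaps.  Returns 0 when no blinking is observed.
    """
    if not 0 < quantile <= 1:
        raise ValueError("quantile must be in (0, 1]")
    frames = table["frame"].to_numpy(np.int64)
    span = int(frames.max() - frames.min()) + 1
    tau_all = span if max_tau is None else int(max_tau)
    summary = photophysics_summary(table, MergeParams(omega=omega, tau=tau_all))
    if len(summary.off_times) == 0:
        return 0
    return int(np.quantile(summary.off_times, quantile, method="inverted_cdf"))
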