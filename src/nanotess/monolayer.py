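"""Langmuir monolayer adsorption analysis: maximal insertion pressure.

Injecting a peptide under a lipid monolayer held at initial surface
pressure πᵢ raises the pressure by Δπ_max; Δπ_max decreases linearly with
πᵢ.  The x-intercept of the regression Δπ = slope·πᵢ + intercept is the
maximal insertion pressure (MIP), the monolayer pressure beyond which the
peptide can no longer insert; the synergy factor a = 1 + slope is positive
when lipid–peptide interactions favour insertion.  A series whose Δπ never
exceeds a significance floor is classified as non-penetrating instead of
being fitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["AdsorptionSeries", "MipResult", "fit_mip"]


@dataclass
class AdsorptionSeries:
    """(πᵢ, Δπ_max) pairs in mN/m for one lipid system."""

    pi_initial: np.ndarray
    delta_pi_max: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.pi_initial = np.asarray(self.pi_initial, float)
        self.delta_pi_max = np.asarray(self.delta_pi_max, float)
        if self.pi_initial.shape != self.delta_pi_max.shape \
                or self.pi_initial.ndim != 1:
            raise ValueError("pi_initial and delta_pi_max must be 1-D and equal length")
        if len(self.pi_initial) < 3:
            raise ValueError("need at least 3 (pi_initial, delta_pi_max) pairs")
        if not np.all(np.isfinite(self.pi_initial)) \
                or not np.all(np.isfinite(self.delta_pi_max)):
            raise ValueError("pressures must be finite")
        if np.any(self.pi_initial < 0):
            raise ValueError("pi_initial must be >= 0")
        if len(np.unique(self.pi_initial)) < 2:
            raise ValueError("pi_initial values must not all coincide")


@dataclass
class MipResult:
    """Regression summary: MIP = −intercept/slope, synergy = 1 + slope."""

    label: str
    slope: float
    intercept: float  # mN/m
    mip: float  # mN/m
    synergy: float
    r_squared: float
    mip_ci95: tuple[float, float]  # bootstrap percentile interval
    penetrating: bool = True


def fit_mip(series: AdsorptionSeries, n_boot: int = 1000, seed: int = 0,
            significance_floor: float = 1.0) -> MipResult:
    """Fit Δπ_max against πᵢ and extrapolate the maximal insertion pressure.

    Ordinary least squares with a pairs-resampling bootstrap 95% CI on the
    MIP.  If every Δπ_max lies below ``significance_floor`` (mN/m) the
    peptide is reported as non-penetrating (all fit fields NaN).  A
    non-negative slope raises, since no insertion limit can be
    extrapolated.
    """
    x, y = series.pi_initial, series.delta_pi_max
    if np.all(y < significance_floor):
        return MipResult(label=series.label, slope=np.nan, intercept=np.nan,
                         mip=np.nan, synergy=np.nan, r_squared=np.nan,
                         mip_ci95=(np.nan, np.nan), penetrating=False)
    fit = stats.linregress(x, y)
    if fit.slope >= 0:
        raise ValueError("no extrapolated insertion limit (slope >= 0)")
    mip = -fit.intercept / fit.slope
    rng = np.random.default_rng(seed)
    boots = []
    n = len(x)
    attempts = 0
    while len(boots) < n_boot and attempts < 20 * n_boot:
        attempts += 1
        idx = rng.integers(0, n, size=n)
        if len(np.unique(x[idx])) < 2:
            continue
        b = stats.linregress(x[idx], y[idx])
        if b.slope >= 0:
            continue  # degenerate resample carries no insertion limit
        boots.append(-b.intercept / b.slope)
    ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5))) \
        if boots else (np.nan, np.nan)
    return MipResult(label=series.label, slope=float(fit.slope),
                     intercept=float(fit.intercept), mip=float(mip),
                     synergy=1.0 + float(fit.slope),
                     r_squared=float(fit.rvalue) ** 2, mip_ci95=ci)
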