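"""Confocal quantifications: Spatial Clustering Index, ROI means and the
di-4-ANEPPDHQ red/green membrane-order ratio.

The Spatial Clustering Index (SCI) of a membrane line profile is the mean
of the 5% highest intensity samples divided by the mean of the 5% lowest;
1 means a homogeneous membrane, larger values indicate lateral segregation
into domains.  The red/green mean ratio (RGM) of the solvatochromic probe
di-4-ANEPPDHQ reports lipid order (lower ratio = more ordered) and is
evaluated over the brightest reference-channel pixels (global, 10, 5 or 2%
masks) to probe the environment of a protein marker.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .simulate import LineProfile

__all__ = ["LineProfile", "RatioImagePair", "spatial_clustering_index",
           "roi_mean", "rgm_ratio"]


@dataclass
class RatioImagePair:
    """Co-registered reference / green / red channels (a.u.).

    The reference channel is the protein marker used to build brightest-
    pixel masks; green and red are the 540–560 nm and 650–670 nm emission
    bands of the order-sensitive dye.
    """

    reference: np.ndarray
    green: np.ndarray
    red: np.ndarray
    pixel_size_um: float = 0.1

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, float)
        self.green = np.asarray(self.green, float)
        self.red = np.asarray(self.red, float)
        if not (self.reference.shape == self.green.shape == self.red.shape):
            raise ValueError("channel shapes differ")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")


def _top_bottom_k(n: int, frac: float) -> int:
    # round-half-up so .5 fractions behave predictably across platforms
    return max(1, int(math.floor(frac * n + 0.5)))


def spatial_clustering_index(profile, top_frac: float = 0.05,
                             bottom_frac: float = 0.05) -> float:
    """SCI = mean of the top-fraction samples / mean of the bottom fraction.

    ``profile`` is a :class:`LineProfile` or a plain intensity array with
    at least 20 samples.  k = max(1, round(frac·n)) samples enter each
    slice.  Raises when the bottom mean is zero (background-subtracted
    input; the index is undefined).
    """
    values = profile.intensities if isinstance(profile, LineProfile) \
        else np.asarray(profile, float)
    if values.ndim != 1 or len(values) < 20:
        raise ValueError("SCI needs a 1-D profile with >= 20 samples")
    if not np.all(np.isfinite(values)) or np.any(values < 0):
        raise ValueError("intensities must be finite and >= 0")
    if not (0 < top_frac <= 0.5 and 0 < bottom_frac <= 0.5):
        raise ValueError("fractions must be in (0, 0.5]")
    srt = np.sort(values)
    k_top = _top_bottom_k(len(values), top_frac)
    k_bot = _top_bottom_k(len(values), bottom_frac)
    bottom = float(np.mean(srt[:k_bot]))
    top = float(np.mean(srt[-k_top:]))
    if bottom == 0:
        raise ValueError("bottom mean is zero; SCI undefined "
                         "(was the background subtracted?)")
    return top / bottom


def roi_mean(image: np.ndarray, origin_um: tuple[float, float],
             pixel_size_um: float, size_um: float = 5.0) -> float:
    """Mean intensity over a square ROI (default 5×5 µm).

    ``origin_um`` is the (x, y) position of the ROI's lower corner in µm;
    pixels whose centres fall in [x0, x0+size) × [y0, y0+size) contribute.
    The ROI must lie fully inside the image.
    """
    img = np.asarray(image, float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    x0, y0 = origin_um
    h, w = img.shape
    if x0 < 0 or y0 < 0 or x0 + size_um > w * pixel_size_um \
            or y0 + size_um > h * pixel_size_um:
        raise ValueError("ROI exceeds image bounds")
    xc = (np.arange(w) + 0.5) * pixel_size_um
    yc = (np.arange(h) + 0.5) * pixel_size_um
    cols = (xc >= x0) & (xc < x0 + size_um)
    rows = (yc >= y0) & (yc < y0 + size_um)
    sel = img[np.ix_(rows, cols)]
    if sel.size == 0:
        raise ValueError("ROI contains no pixel centres")
    return float(sel.mean())


def rgm_ratio(pair: RatioImagePair, percent: float = 100.0,
              allowed=(100.0, 10.0, 5.0, 2.0)) -> float:
    """Mean red/green ratio over the brightest reference pixels.

    ``percent`` selects pixels with reference intensity at or above the
    (100−percent)th percentile; percent=100 uses every pixel.  The ratio is
    averaged per pixel (mean of red/green, not ratio of means).
    """
    if allowed is not None and percent not in allowed:
        raise ValueError(f"percent must be one of {allowed}")
    ref = pair.reference.ravel()
    red = pair.red.ravel()
    green = pair.green.ravel()
    if percent >= 100.0:
        mask = np.ones(ref.shape, bool)
    else:
        thr = np.percentile(ref, 100.0 - percent)
        mask = ref >= thr
    if not mask.any():
        raise ValueError("empty mask")
    if np.any(green[mask] == 0):
        raise ValueError("green channel contains zeros inside the mask")
    return float(np.mean(red[mask] / green[mask]))
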