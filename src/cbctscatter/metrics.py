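"""Image-quality metrics: CT number, contrast, CNR, percent cupping.

CT numbers are calibrated against a water-surrogate reference mean
(the soft-tissue background stands in for water when the spectrum
cannot separate the two):

    CT# = 1000 · (m_x − m_water) / m_water                       (HU)

Contrast and contrast-to-noise ratio between an insert and background:

    Contrast = m_x − m_bg,   CNR = (m_x − m_bg) / sqrt(σ_x² + σ_bg²)

Cupping is the percent depression of the center relative to the mean
of four peripheral ROIs in a uniform region:

    % cupping = (CT#_edge − CT#_center) · 100 / (CT#_edge + 1000).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.measure import profile_line

__all__ = [
    "ROIStats",
    "circular_roi_stats",
    "ct_number",
    "contrast_and_cnr",
    "percent_cupping",
    "extract_profile",
    "hu_difference_table",
]


@dataclass
class ROIStats:
    """Mean/STD over a region of interest."""

    mean: float
    std: float
    n: int = 0
    center: tuple[float, float] | None = None
    radius: float | None = None

    def __post_init__(self) -> None:
        if self.std < 0:
            raise ValueError("ROI standard deviation must be non-negative")
        if self.n < 0:
            raise ValueError("ROI pixel count must be non-negative")


def circular_roi_stats(
    image: np.ndarray, center: tuple[float, float], radius: float
) -> ROIStats:
    """Statistics over a circular ROI (pixel coordinates, axis order (i, j))."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2D")
    ii, jj = np.meshgrid(np.arange(img.shape[0]), np.arange(img.shape[1]), indexing="ij")
    mask = (ii - center[0]) ** 2 + (jj - center[1]) ** 2 <= radius**2
    if not np.any(mask):
        raise ValueError("ROI contains no pixels")
    vals = img[mask]
    return ROIStats(mean=float(vals.mean()), std=float(vals.std(ddof=0)),
                    n=int(vals.size), center=center, radius=radius)


def ct_number(m_x: float, m_water: float) -> float:
    """Hounsfield calibration: water maps to 0 HU, zero attenuation to −1000 HU."""
    if m_water <= 0:
        raise ValueError("water reference mean must be positive")
    return 1000.0 * (m_x - m_water) / m_water


def contrast_and_cnr(stats_x: ROIStats, stats_bg: ROIStats) -> tuple[float, float]:
    """Signed contrast and CNR between an insert ROI and the background ROI."""
    contrast = stats_x.mean - stats_bg.mean
    noise = float(np.hypot(stats_x.std, stats_bg.std))
    if noise == 0.0:
        if contrast == 0.0:
            return 0.0, 0.0
        warnings.warn("both ROI standard deviations are zero; CNR is infinite", stacklevel=2)
        return contrast, float(np.copysign(np.inf, contrast))
    return contrast, contrast / noise


def percent_cupping(edge_hu, center_hu: float) -> float:
    """Percent cupping from four peripheral CT numbers and the central one.

    ``edge_hu`` may be four HU values or four :class:`ROIStats` (their
    means are used).  A mean edge value of exactly −1000 HU leaves the
    metric undefined.
    """
    vals = [e.mean if isinstance(e, ROIStats) else float(e) for e in edge_hu]
    if len(vals) != 4:
        raise ValueError(f"exactly four peripheral ROIs are required, got {len(vals)}")
    center = center_hu.mean if isinstance(center_hu, ROIStats) else float(center_hu)
    edge = float(np.mean(vals))
    if edge == -1000.0:
        raise ValueError("edge CT number of −1000 HU makes percent cupping undefined")
    return (edge - center) * 100.0 / (edge + 1000.0)


def extract_profile(
    image: np.ndarray,
    start: tuple[float, float],
    end: tuple[float, float],
    interpolation: str = "nearest",
) -> np.ndarray:
    """Sample a line profile between two (row, col) points.

    Nearest-neighbour sampling by default ('linear' is also accepted).
    Endpoints must lie within the image bounds.
    """
    img = np.asarray(image, dtype=float)
    for name, pt in (("start", start), ("end", end)):
        if not (0 <= pt[0] <= img.shape[0] - 1 and 0 <= pt[1] <= img.shape[1] - 1):
            raise ValueError(f"profile {name} point {pt} lies outside the image {img.shape}")
    order = {"nearest": 0, "linear": 1}.get(interpolation)
    if order is None:
        raise ValueError("interpolation must be 'nearest' or 'linear'")
    return profile_line(img, start, end, order=order, mode="constant", cval=0.0,
                        reduce_func=None).ravel()


def hu_difference_table(corrected_means, reference_means) -> np.ndarray:
    """Per-insert absolute HU differences |corrected − reference|."""
    c = np.asarray(corrected_means, dtype=float)
    r = np.asarray(reference_means, dtype=float)
    if c.shape != r.shape:
        raise ValueError("corrected and reference insert lists must match")
    return np.abs(c - r)
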