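"""PMMA-equivalent thickness mapping and thickness-group partitioning.

Under a monoenergetic Beer's-law model the primary signal through ``t``
mm of PMMA is I_p = I_{p,0}·exp(−μ_PMMA·t), so the per-pixel equivalent
thickness is

    t_PMMA = (1 / μ_PMMA) · log(I_{p,0} / I_p).

Either this closed form or a measured log-signal lookup table (built
from calibration slabs) converts a primary-signal estimate into a
thickness map.  The projection is then partitioned into subprojections
by thickness group (default: five 40 mm groups, last group open-ended),
each of which is convolved with the kernel at its group's center
thickness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DEFAULT_MU_PMMA",
    "DEFAULT_GROUP_EDGES",
    "DEFAULT_MIN_SCATTER_THICKNESS_MM",
    "LogSignalLUT",
    "ThicknessGrouping",
    "estimate_thickness",
    "build_log_signal_lut",
    "partition_by_thickness",
    "group_representative_thicknesses",
]

#: Nominal effective linear attenuation coefficient of PMMA, mm^-1.
DEFAULT_MU_PMMA = 0.022

#: Lower edges of the default five 40 mm thickness groups (mm); the
#: last group is open-ended.
DEFAULT_GROUP_EDGES = (0.0, 40.0, 80.0, 120.0, 160.0)

#: Pixels thinner than this (mm) are treated as non-scattering by the
#: simulator and the correction.  A ray through (almost) no material
#: produces negligible scatter, and a strictly positive floor keeps the
#: scatter operator well-behaved around the flat field: without it, the
#: iteration admits a spurious self-consistent solution in which
#: near-flat-field pixels drift slightly below I0, acquire a tiny
#: apparent thickness, and then generate exactly the scatter that
#: sustains their own depression.  Sustaining such a halo requires an
#: apparent thickness of ≈ log(1 + A·SF)/μ ≈ 7 mm for the first group's
#: kernel mass, so a 10 mm floor rules it out.
DEFAULT_MIN_SCATTER_THICKNESS_MM = 10.0

#: Intensities below ``floor × I0`` are clipped before the log; the
#: closed form diverges at zero signal.
INTENSITY_FLOOR = 1e-6


@dataclass
class LogSignalLUT:
    """Monotone table mapping log-signal log(I0/I) to PMMA thickness (mm).

    Built from calibration pairs (thickness, primary signal); strictly
    increasing in log-signal and passing through (0, 0).  Queries below
    the first node clamp to 0 mm; queries above the last node clamp to
    the maximum calibrated thickness.
    """

    log_signal: np.ndarray
    thickness_mm: np.ndarray

    def __post_init__(self) -> None:
        self.log_signal = np.asarray(self.log_signal, dtype=float)
        self.thickness_mm = np.asarray(self.thickness_mm, dtype=float)
        if self.log_signal.shape != self.thickness_mm.shape or self.log_signal.ndim != 1:
            raise ValueError("log-signal and thickness arrays must be matching 1D arrays")
        if np.any(np.diff(self.log_signal) <= 0):
            raise ValueError("log-signal nodes must be strictly increasing")
        if np.any(np.diff(self.thickness_mm) <= 0):
            raise ValueError("thickness nodes must be strictly increasing")
        if abs(self.log_signal[0]) > 1e-12 or abs(self.thickness_mm[0]) > 1e-12:
            raise ValueError("LUT must pass through (0, 0)")

    def __call__(self, log_values: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(log_values, dtype=float), self.log_signal, self.thickness_mm)


def build_log_signal_lut(samples, flat_field: float) -> LogSignalLUT:
    """Build the log-signal transfer function from calibration slabs.

    Parameters
    ----------
    samples : sequence of (thickness_mm, signal) pairs
        At least two pairs with thicknesses strictly increasing and
        signals strictly decreasing (more material, less signal).  A
        zero-thickness node at the flat-field signal is prepended if
        absent.
    flat_field : float
        Unattenuated signal I0 (> 0).
    """
    if flat_field <= 0:
        raise ValueError("flat-field signal must be positive")
    pairs = [(float(t), float(s)) for t, s in samples]
    if len(pairs) < 2:
        raise ValueError("at least two calibration samples are required")
    for (t0, s0), (t1, s1) in zip(pairs, pairs[1:]):
        if t1 <= t0:
            raise ValueError(f"thicknesses must be strictly increasing (got {t0} then {t1})")
        if s1 >= s0:
            raise ValueError(
                f"signals must be strictly decreasing (thickness {t0}→{t1} mm "
                f"has signal {s0}→{s1})"
            )
    if pairs[0][0] > 0:
        if pairs[0][1] >= flat_field:
            raise ValueError(
                f"signal at {pairs[0][0]} mm (={pairs[0][1]}) must lie below "
                f"the flat field (={flat_field})"
            )
        pairs.insert(0, (0.0, flat_field))
    t = np.array([p[0] for p in pairs])
    logs = np.log(flat_field / np.array([p[1] for p in pairs]))
    return LogSignalLUT(log_signal=logs, thickness_mm=t)


def estimate_thickness(
    intensities: np.ndarray,
    flat_field: float,
    mu_pmma: float = DEFAULT_MU_PMMA,
    lut: LogSignalLUT | None = None,
    floor: float = INTENSITY_FLOOR,
) -> np.ndarray:
    """Per-pixel PMMA-equivalent thickness map (mm).

    Uses the Beer's-law closed form by default, or the calibration LUT
    when given.  Pixels at or above the flat field map to 0 mm;
    intensities below ``floor·I0`` are clipped before the log.
    """
    if flat_field <= 0:
        raise ValueError("flat-field intensity must be positive")
    if lut is None and mu_pmma <= 0:
        raise ValueError("mu_pmma must be positive")
    arr = np.asarray(intensities, dtype=float)
    clipped = np.clip(arr, floor * flat_field, None)
    logs = np.maximum(np.log(flat_field / clipped), 0.0)
    if lut is not None:
        return lut(logs)
    return logs / mu_pmma


def group_index(
    tmap: np.ndarray, edges=DEFAULT_GROUP_EDGES, min_thickness: float = 0.0
) -> np.ndarray:
    """Group index per pixel; −1 for non-scattering pixels.

    Membership is upper-edge inclusive: t in (edge_g, edge_{g+1}] maps
    to group g, and the last group is open-ended.  Pixels with t ≤ 0 or
    t below ``min_thickness`` carry index −1 (they belong to no group).
    """
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or edges.size < 1 or np.any(np.diff(edges) <= 0):
        raise ValueError("group edges must be strictly increasing")
    t = np.asarray(tmap, dtype=float)
    # searchsorted on inner edges with side='left' makes upper edges inclusive
    idx = np.searchsorted(edges[1:], t, side="left")
    idx = np.where((t > 0) & (t >= min_thickness), idx, -1)
    return idx


@dataclass
class ThicknessGrouping:
    """Partition of a projection's pixels into thickness groups.

    ``masks`` has shape ``(n_groups, rows, cols)``; masks are disjoint
    and jointly cover every scattering pixel (t > 0 and at or above the
    minimum scattering thickness).
    """

    edges: tuple[float, ...]
    masks: np.ndarray

    @property
    def n_groups(self) -> int:
        return len(self.edges)

    @classmethod
    def from_map(
        cls, tmap: np.ndarray, edges=DEFAULT_GROUP_EDGES, min_thickness: float = 0.0
    ) -> "ThicknessGrouping":
        idx = group_index(tmap, edges, min_thickness)
        g = np.arange(len(edges))
        masks = idx[None, :, :] == g[:, None, None]
        return cls(edges=tuple(float(e) for e in edges), masks=masks)

    def representative_thicknesses(self) -> np.ndarray:
        return group_representative_thicknesses(self.edges)


def group_representative_thicknesses(edges=DEFAULT_GROUP_EDGES) -> np.ndarray:
    """Center-of-bin thickness per group (mm).

    The open-ended last group uses last edge + half the nominal group
    width, giving 20/60/100/140/180 mm for the default edges.
    """
    e = np.asarray(edges, dtype=float)
    if e.size < 2:
        raise ValueError("need at least two edges to infer a group width")
    width = e[1] - e[0]
    reps = np.empty(e.size)
    reps[:-1] = (e[:-1] + e[1:]) / 2.0
    reps[-1] = e[-1] + width / 2.0
    return reps


def partition_by_thickness(
    primary: np.ndarray,
    tmap: np.ndarray,
    edges=DEFAULT_GROUP_EDGES,
    min_thickness: float = 0.0,
) -> np.ndarray:
    """Split a primary image into per-group subprojections.

    Returns an array ``(n_groups, rows, cols)`` where subprojection g
    equals the primary masked to its group's pixels and zero elsewhere.
    With the default ``min_thickness`` of zero, the subprojections sum
    to the primary exactly on pixels with t > 0; the scatter pipeline
    passes :data:`DEFAULT_MIN_SCATTER_THICKNESS_MM` so that near-air
    pixels are treated as non-scattering.
    """
    primary = np.asarray(primary, dtype=float)
    tmap = np.asarray(tmap, dtype=float)
    if primary.shape != tmap.shape:
        raise ValueError("primary image and thickness map shapes differ")
    grouping = ThicknessGrouping.from_map(tmap, edges, min_thickness)
    return np.where(grouping.masks, primary[None, :, :], 0.0)
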