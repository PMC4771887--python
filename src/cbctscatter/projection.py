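"""Projection-image containers.

A :class:`ProjectionSet` stacks one detector frame per view angle with a
shared flat-field (unattenuated) intensity and the acquisition geometry.
Intensities are detector counts in arbitrary units; the flat-field value
``I0`` is what an unattenuated ray records.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import AcquisitionGeometry

__all__ = ["ProjectionImage", "ProjectionSet"]


@dataclass
class ProjectionImage:
    """A single detector frame at one view angle."""

    intensities: np.ndarray
    angle_deg: float
    flat_field: float

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 2:
            raise ValueError("projection image must be 2D")
        if self.flat_field <= 0:
            raise ValueError("flat-field intensity must be positive")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")


@dataclass
class ProjectionSet:
    """Ordered stack of projection images over a full rotation.

    ``intensities`` has shape ``(n_views, n_rows, n_cols)``; every view
    shares the same flat-field convention.
    """

    intensities: np.ndarray
    angles_deg: np.ndarray
    flat_field: float
    geometry: AcquisitionGeometry | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError("projection stack must be 3D (views, rows, cols)")
        if self.angles_deg.shape != (self.intensities.shape[0],):
            raise ValueError("one view angle per projection image is required")
        if self.flat_field <= 0:
            raise ValueError("flat-field intensity must be positive")

    def __len__(self) -> int:
        return self.intensities.shape[0]

    def __getitem__(self, i: int) -> ProjectionImage:
        return ProjectionImage(self.intensities[i], float(self.angles_deg[i]), self.flat_field)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.intensities.shape[1:]

    def with_intensities(self, new: np.ndarray) -> "ProjectionSet":
        """Copy of the set with the same metadata but new intensities."""
        return replace(self, intensities=np.asarray(new, dtype=np.float64))

    def line_integrals(self, floor: float = 1e-12) -> np.ndarray:
        """Log-converted data ``p = log(I0 / I)`` per pixel, clipped at zero."""
        ratio = np.clip(self.intensities, floor * self.flat_field, None) / self.flat_field
        return np.maximum(-np.log(ratio), 0.0)
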