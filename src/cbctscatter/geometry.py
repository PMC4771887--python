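"""Cone-beam acquisition geometry.

The scanner is modelled as a point source and a flat-panel detector
rotating together around the isocenter over a full 360° circle.  The
source sits at distance DSO from the isocenter; the detector plane is
perpendicular to the source-isocenter axis at distance DSD from the
source.  Detector pixels are square with a single pitch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AcquisitionGeometry"]


@dataclass
class AcquisitionGeometry:
    """Circular cone-beam scan geometry.

    Parameters
    ----------
    dsd : float
        Source-to-detector distance in mm.
    dso : float
        Source-to-object (isocenter) distance in mm.  Must satisfy
        ``dsd > dso > 0`` (the detector is behind the isocenter).
    pixel_pitch_mm : float
        Detector pixel size in mm (square pixels).
    n_rows, n_cols : int
        Detector dimensions (rows index the rotation axis ``z``).
    angles_deg : numpy.ndarray
        View angles in degrees.  A full rotation is expected; use
        :meth:`with_views` for an evenly spaced set over [0°, 360°).
    """

    dsd: float
    dso: float
    pixel_pitch_mm: float
    n_rows: int
    n_cols: int
    angles_deg: np.ndarray = field(default_factory=lambda: np.linspace(0.0, 360.0, 360, endpoint=False))

    def __post_init__(self) -> None:
        self.angles_deg = np.atleast_1d(np.asarray(self.angles_deg, dtype=float))
        if not (self.dsd > self.dso > 0):
            raise ValueError(
                f"geometry requires DSD > DSO > 0, got DSD={self.dsd} mm, DSO={self.dso} mm"
            )
        if self.pixel_pitch_mm <= 0:
            raise ValueError(f"pixel pitch must be positive, got {self.pixel_pitch_mm}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("detector must have at least one row and one column")
        if self.angles_deg.ndim != 1 or self.angles_deg.size == 0:
            raise ValueError("angles_deg must be a non-empty 1D array")

    @classmethod
    def with_views(
        cls,
        n_views: int,
        *,
        dsd: float = 786.0,
        dso: float = 500.0,
        pixel_pitch_mm: float = 0.388,
        n_rows: int = 256,
        n_cols: int = 256,
    ) -> "AcquisitionGeometry":
        """Evenly spaced full-rotation scan with ``n_views`` views.

        Defaults use the reference scanner assignment DSO = 500 mm,
        DSD = 786 mm with 0.388 mm detector pitch.
        """
        angles = np.linspace(0.0, 360.0, n_views, endpoint=False)
        return cls(dsd=dsd, dso=dso, pixel_pitch_mm=pixel_pitch_mm,
                   n_rows=n_rows, n_cols=n_cols, angles_deg=angles)

    @property
    def n_views(self) -> int:
        return int(self.angles_deg.size)

    @property
    def magnification(self) -> float:
        """Geometric magnification DSD/DSO at the isocenter plane."""
        return self.dsd / self.dso

    def detector_u(self) -> np.ndarray:
        """Physical column coordinates (mm) on the detector, centered."""
        j = np.arange(self.n_cols, dtype=float)
        return (j - (self.n_cols - 1) / 2.0) * self.pixel_pitch_mm

    def detector_v(self) -> np.ndarray:
        """Physical row coordinates (mm) on the detector, centered."""
        i = np.arange(self.n_rows, dtype=float)
        return (i - (self.n_rows - 1) / 2.0) * self.pixel_pitch_mm
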