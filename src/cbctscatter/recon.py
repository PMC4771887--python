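"""Filtered backprojection for the circular cone-beam geometry.

Projections are log-converted to line integrals p = log(I0/I) and
reconstructed with the classical flat-detector fan-beam FBP for the
central slice (the default, used for benchmarking against fan-beam CT),
or with FDK weighting for a full volume.  Working on the virtual
detector through the isocenter (detector coordinates scaled by
DSO/DSD), the central-slice formula for a full 2π scan is

    f(x, y) = (π / N) Σ_β (DSO / L)² · Q_β(u(x, y)),

with L the source-to-point distance along the central-ray direction,
Q_β the ramp-filtered cosine-weighted projection row, and the factor
1/2 for the double coverage of each ray folded into π/N.

The ramp filter is applied in the frequency domain as the DFT of the
band-limited spatial ramp kernel, apodized by a Shepp-Logan (sinc) or
Hamming window.  "Cutoff 0.6" truncates the window at 0.6 × Nyquist.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import fft, ifft, next_fast_len
from scipy.ndimage import map_coordinates

from .geometry import AcquisitionGeometry
from .projection import ProjectionSet

__all__ = ["ReconFilter", "Volume", "fbp_reconstruct", "fbp_from_sinogram", "fdk_reconstruct"]

_FAMILIES = ("ramp", "shepp-logan", "hamming")


@dataclass(frozen=True)
class ReconFilter:
    """Apodized ramp filter: family and cutoff as a fraction of Nyquist."""

    family: str = "shepp-logan"
    cutoff: float = 0.6

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown filter family '{self.family}'; choose from {_FAMILIES}")
        if not (0.0 < self.cutoff <= 1.0):
            raise ValueError("cutoff must lie in (0, 1]")

    def response(self, n: int) -> np.ndarray:
        """Frequency response on an n-point DFT grid (unit sample spacing)."""
        # band-limited spatial ramp: h[0]=1/4, h[±k]=-1/(πk)² for odd k
        idx = np.minimum(np.arange(n), n - np.arange(n)).astype(float)
        h = np.zeros(n)
        h[0] = 0.25
        odd = (idx % 2 == 1)
        h[odd] = -1.0 / (np.pi * idx[odd]) ** 2
        ramp = np.real(fft(h))
        nu = idx / (n / 2.0)  # |frequency| as a fraction of Nyquist
        w = np.zeros(n)
        band = nu <= self.cutoff + 1e-12
        if self.family == "ramp":
            w[band] = 1.0
        elif self.family == "shepp-logan":
            w[band] = np.sinc(nu[band] / (2.0 * self.cutoff))
        else:  # hamming
            w[band] = 0.54 + 0.46 * np.cos(np.pi * nu[band] / self.cutoff)
        return ramp * w


@dataclass
class Volume:
    """Reconstructed attenuation grid (mm^-1 voxel values)."""

    values: np.ndarray
    voxel_size_mm: float
    orientation: str = "axial"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("reconstructed values must be finite")

    def central_slice(self) -> np.ndarray:
        if self.values.ndim == 2:
            return self.values
        return self.values[:, :, self.values.shape[2] // 2]


def _check_full_rotation(angles_deg: np.ndarray) -> None:
    a = np.sort(np.mod(angles_deg, 360.0))
    gaps = np.diff(np.concatenate([a, [a[0] + 360.0]]))
    nominal = 360.0 / a.size
    worst = float(gaps.max())
    if worst > 3.0 * nominal + 1e-9:
        raise ValueError(
            f"incomplete angular coverage: {worst:.1f}° gap after {a[np.argmax(gaps) % a.size]:.1f}° "
            f"(full-rotation scan expected)"
        )


def _filter_rows(rows: np.ndarray, du: float, recon_filter: ReconFilter) -> np.ndarray:
    """Ramp-filter each row (last axis), returning physical units (1/mm)."""
    n = rows.shape[-1]
    npad = next_fast_len(max(64, 2 * n))
    h = recon_filter.response(npad)
    padded = np.zeros(rows.shape[:-1] + (npad,))
    padded[..., :n] = rows
    filt = np.real(ifft(fft(padded, axis=-1) * h, axis=-1))[..., :n]
    return filt / du


def fbp_from_sinogram(
    sinogram: np.ndarray,
    angles_deg: np.ndarray,
    geometry: AcquisitionGeometry,
    recon_filter: ReconFilter = ReconFilter(),
    voxel_size_mm: float = 1.0,
    n_pixels: int | None = None,
) -> Volume:
    """Central-slice fan-beam FBP from line-integral data.

    ``sinogram`` has shape ``(n_views, n_cols)`` of line integrals
    (dimensionless).  This entry point is linear in the sinogram.
    """
    sino = np.asarray(sinogram, dtype=float)
    angles_deg = np.asarray(angles_deg, dtype=float)
    if sino.ndim != 2 or sino.shape[0] != angles_deg.size:
        raise ValueError("sinogram must be (n_views, n_cols) matching the angles")
    _check_full_rotation(angles_deg)
    dso, dsd = geometry.dso, geometry.dsd
    u_iso = geometry.detector_u() * (dso / dsd)
    du = geometry.pixel_pitch_mm * (dso / dsd)
    weighted = sino * (dso / np.sqrt(dso**2 + u_iso**2))[None, :]
    q = _filter_rows(weighted, du, recon_filter)

    if n_pixels is None:
        n_pixels = geometry.n_cols
    coords = (np.arange(n_pixels) - (n_pixels - 1) / 2.0) * voxel_size_mm
    xx, yy = np.meshgrid(coords, coords, indexing="ij")
    out = np.zeros((n_pixels, n_pixels))
    for k, ang in enumerate(np.deg2rad(angles_deg)):
        c, s = np.cos(ang), np.sin(ang)
        ell = dso - (xx * c + yy * s)
        t = -xx * s + yy * c
        u = dso * t / ell
        vals = np.interp(u, u_iso, q[k], left=0.0, right=0.0)
        out += (dso / ell) ** 2 * vals
    out *= np.pi / angles_deg.size
    return Volume(out, voxel_size_mm)


def _central_row(pset: ProjectionSet) -> np.ndarray:
    nr = pset.intensities.shape[1]
    if nr % 2 == 1:
        return pset.intensities[:, nr // 2, :]
    return 0.5 * (pset.intensities[:, nr // 2 - 1, :] + pset.intensities[:, nr // 2, :])


def fbp_reconstruct(
    projections: ProjectionSet,
    recon_filter: ReconFilter = ReconFilter(),
    voxel_size_mm: float = 1.0,
    n_pixels: int | None = None,
    geometry: AcquisitionGeometry | None = None,
) -> Volume:
    """Central-slice fan-beam FBP of a projection set.

    Intensities are log-converted internally (p = log(I0/I)); the
    central detector row (or the mean of the two middle rows for an
    even row count) forms the fan-beam sinogram.
    """
    geo = geometry or projections.geometry
    if geo is None:
        raise ValueError("an acquisition geometry is required")
    row = _central_row(projections)
    ratio = np.clip(row, 1e-12 * projections.flat_field, None) / projections.flat_field
    sino = np.maximum(-np.log(ratio), 0.0)
    return fbp_from_sinogram(sino, projections.angles_deg, geo, recon_filter,
                             voxel_size_mm, n_pixels)


def fdk_reconstruct(
    projections: ProjectionSet,
    recon_filter: ReconFilter = ReconFilter(),
    voxel_size_mm: float = 1.0,
    n_pixels: int | None = None,
    n_slices: int | None = None,
    geometry: AcquisitionGeometry | None = None,
) -> Volume:
    """FDK-weighted cone-beam reconstruction (small-volume variant).

    Rows are cosine-weighted by DSO/sqrt(DSO² + u² + v²) on the virtual
    detector, ramp-filtered along u, and backprojected with the fan
    weight (DSO/L)² and bilinear detector interpolation.  Intended for
    modest grids; the central slice reduces to :func:`fbp_reconstruct`.
    """
    geo = geometry or projections.geometry
    if geo is None:
        raise ValueError("an acquisition geometry is required")
    _check_full_rotation(projections.angles_deg)
    dso, dsd = geo.dso, geo.dsd
    scale = dso / dsd
    u_iso = geo.detector_u() * scale
    v_iso = geo.detector_v() * scale
    du = geo.pixel_pitch_mm * scale
    ratio = np.clip(projections.intensities, 1e-12 * projections.flat_field, None)
    sino = np.maximum(-np.log(ratio / projections.flat_field), 0.0)
    w = dso / np.sqrt(dso**2 + u_iso[None, :] ** 2 + v_iso[:, None] ** 2)
    q = _filter_rows(sino * w[None, :, :], du, recon_filter)

    if n_pixels is None:
        n_pixels = geo.n_cols
    if n_slices is None:
        n_slices = geo.n_rows
    coords = (np.arange(n_pixels) - (n_pixels - 1) / 2.0) * voxel_size_mm
    zc = (np.arange(n_slices) - (n_slices - 1) / 2.0) * voxel_size_mm
    xx, yy = np.meshgrid(coords, coords, indexing="ij")
    out = np.zeros((n_pixels, n_pixels, n_slices))
    for k, ang in enumerate(np.deg2rad(projections.angles_deg)):
        c, s = np.cos(ang), np.sin(ang)
        ell = dso - (xx * c + yy * s)
        t = -xx * s + yy * c
        u = dso * t / ell  # (nx, ny)
        uc = (u - u_iso[0]) / du
        wgt = (dso / ell) ** 2
        for iz, z in enumerate(zc):
            v = dso * z / ell
            vc = (v - v_iso[0]) / du
            vals = map_coordinates(q[k], [vc, uc], order=1, mode="constant", cval=0.0)
            out[:, :, iz] += wgt * vals
    out *= np.pi / projections.angles_deg.size
    return Volume(out, voxel_size_mm)
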