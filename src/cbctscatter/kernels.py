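"""Thickness-indexed scatter-kernel database.

The scatter reaching a detector pixel is modelled as the primary signal
convolved with a thickness-dependent kernel

    K_t(x, y) = A_t · SF_t · PSF_t(x, y),

where ``PSF_t`` is a unit-sum, radially symmetric point spread function
describing the spatial shape of scatter produced by a pencil beam
through ``t`` mm of PMMA, ``SF_t`` is the scatter fraction (scatter /
measured, linear in thickness, SF_t = a1·t + a2), and ``A_t`` is a
piecewise-constant compensating amplitude per thickness range.

Kernels live on a grid of 1 mm thickness increments.  They can be built
parametrically (two-component Gaussian-core + exponential-tail radial
model, widths affine in thickness) or loaded from an HDF5 file produced
by external photon-transport simulation.  In either case coarse kernels
are interpolated per-pixel to the 1 mm grid and re-normalized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_A1",
    "DEFAULT_A2",
    "DEFAULT_AMPLITUDE_TABLE",
    "SF_CLAMP",
    "PSFShape",
    "ScatterKernel",
    "KernelDatabase",
    "sf_of_thickness",
    "amplitude_of_thickness",
    "make_parametric_psf",
    "interpolate_kernels",
    "build_parametric_database",
    "save_kernels",
    "load_kernels",
]

#: Default scatter-fraction coefficients: SF(t) = a1·t + a2.
DEFAULT_A1 = 0.0038  # per mm
DEFAULT_A2 = 0.1

#: Compensating amplitude per thickness range, upper-edge inclusive;
#: the final range is open-ended.
DEFAULT_AMPLITUDE_TABLE: tuple[tuple[float, float], ...] = (
    (40.0, 1.0),
    (80.0, 1.0),
    (120.0, 1.75),
    (160.0, 1.75),
    (np.inf, 2.0),
)

#: The linear SF model crosses 1 near t ≈ 237 mm at the default
#: coefficients, which is unphysical; values are clamped here.
SF_CLAMP = 0.99


def sf_of_thickness(
    t: float | np.ndarray,
    a1: float = DEFAULT_A1,
    a2: float = DEFAULT_A2,
    clamp: float = SF_CLAMP,
) -> float | np.ndarray:
    """Scatter fraction SF(t) = a1·t + a2, clamped below 1.

    Parameters
    ----------
    t : float or array
        PMMA-equivalent thickness in mm, non-negative.
    a1, a2 : float
        Linear-fit coefficients (defaults 0.0038 / 0.1).
    clamp : float
        Upper bound; the linear model is unphysical past SF = 1, so any
        value ≥ ``clamp`` is replaced by ``clamp`` with a warning.
    """
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0):
        raise ValueError("thickness must be non-negative")
    sf = a1 * arr + a2
    if np.any(sf >= clamp):
        warnings.warn(
            f"scatter fraction clamped at {clamp} for thickness ≥ "
            f"{(clamp - a2) / a1:.1f} mm (linear SF model leaves its validity range)",
            stacklevel=2,
        )
        sf = np.minimum(sf, clamp)
    return float(sf) if np.isscalar(t) else sf


def amplitude_of_thickness(
    t: float, table: tuple[tuple[float, float], ...] = DEFAULT_AMPLITUDE_TABLE
) -> float:
    """Piecewise-constant compensating amplitude A(t).

    Ranges are upper-edge inclusive (a boundary thickness belongs to the
    lower range) and the final range is open-ended, so the lookup is
    total on t ≥ 0.
    """
    if t < 0:
        raise ValueError("thickness must be non-negative")
    for upper, a in table:
        if t <= upper:
            return float(a)
    raise ValueError("amplitude table does not cover the requested thickness")  # pragma: no cover


@dataclass(frozen=True)
class PSFShape:
    """Parametric radial PSF: (1-w)·Gaussian core + w·exponential tail.

    Widths are affine in thickness, in mm:
    σ(t) = core_sigma0 + core_sigma_slope·t,
    ρ(t) = tail_rho0 + tail_rho_slope·t.
    All widths must stay positive; monotone widths give a PSF whose
    radial spread grows with thickness.

    The defaults describe a mostly diffuse kernel: a small sharp core
    under a dominant exponential tail whose 1/e radius exceeds 100 mm
    at the detector.  Slab-scatter point spread functions on flat-panel
    detectors are of this broad-tailed kind — the scatter haze varies
    slowly across the detector, which is also what makes scatter
    manifest as the classic cupping artifact after log conversion.
    """

    core_sigma0: float = 4.0
    core_sigma_slope: float = 0.05
    tail_rho0: float = 120.0
    tail_rho_slope: float = 0.10
    tail_weight: float = 0.95

    def __post_init__(self) -> None:
        if not (0.0 <= self.tail_weight <= 1.0):
            raise ValueError("tail_weight must lie in [0, 1]")
        if min(self.core_sigma0, self.tail_rho0) <= 0:
            raise ValueError("width intercepts must be positive")
        if min(self.core_sigma_slope, self.tail_rho_slope) < 0:
            raise ValueError("width slopes must be non-negative")


@dataclass
class ScatterKernel:
    """One kernel of the database: K = A·SF·PSF at a single thickness."""

    thickness_mm: float
    psf: np.ndarray
    sf: float
    amplitude: float
    pitch_mm: float

    def __post_init__(self) -> None:
        self.psf = np.asarray(self.psf, dtype=np.float64)
        if self.psf.ndim != 2 or any(s % 2 == 0 for s in self.psf.shape):
            raise ValueError("PSF grid must be 2D with odd dimensions")
        if np.any(self.psf < 0):
            raise ValueError("PSF must be non-negative")
        if abs(self.psf.sum() - 1.0) > 1e-9:
            raise ValueError(f"PSF at t={self.thickness_mm} mm is not unit-sum")
        if not (0.0 <= self.sf < 1.0):
            raise ValueError("scatter fraction must lie in [0, 1)")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")

    @property
    def kernel(self) -> np.ndarray:
        """The full kernel A·SF·PSF (sums to A·SF)."""
        return self.amplitude * self.sf * self.psf


def make_parametric_psf(
    t: float,
    shape: PSFShape = PSFShape(),
    grid_size: int = 101,
    pitch_mm: float = 0.388,
) -> np.ndarray:
    """Radially symmetric PSF grid at thickness ``t``, normalized to unit sum.

    The two mixture components are normalized separately on the grid
    before mixing, so the result sums to 1 exactly (up to float error)
    regardless of truncation; truncation only reshapes the tail mass.
    """
    if grid_size % 2 == 0 or grid_size < 1:
        raise ValueError("PSF grid size must be odd and positive")
    if t < 0:
        raise ValueError("thickness must be non-negative")
    if pitch_mm <= 0:
        raise ValueError("pitch must be positive")
    if grid_size == 1:
        return np.array([[1.0]])
    half = grid_size // 2
    ax = np.arange(-half, half + 1, dtype=float) * pitch_mm
    xx, yy = np.meshgrid(ax, ax, indexing="ij")
    r = np.hypot(xx, yy)
    sigma = shape.core_sigma0 + shape.core_sigma_slope * t
    rho = shape.tail_rho0 + shape.tail_rho_slope * t
    core = np.exp(-0.5 * (r / sigma) ** 2)
    tail = np.exp(-r / rho)
    core /= core.sum()
    tail /= tail.sum()
    psf = (1.0 - shape.tail_weight) * core + shape.tail_weight * tail
    return psf / psf.sum()


@dataclass
class KernelDatabase:
    """Kernels at 1 mm thickness increments over [1, t_max] mm.

    ``psfs`` stacks the unit-sum PSF grids as ``(t_max, k, k)``; the
    scatter fraction and amplitude are evaluated from their own models
    (linear SF fit, amplitude table), never interpolated.
    """

    psfs: np.ndarray
    a1: float = DEFAULT_A1
    a2: float = DEFAULT_A2
    amplitude_table: tuple[tuple[float, float], ...] = DEFAULT_AMPLITUDE_TABLE
    pitch_mm: float = 0.388
    provenance: str = "parametric"
    _validate: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        self.psfs = np.asarray(self.psfs, dtype=np.float64)
        if self.psfs.ndim != 3:
            raise ValueError("psfs must be a 3D stack (thickness, rows, cols)")
        if self._validate:
            sums = self.psfs.reshape(self.psfs.shape[0], -1).sum(axis=1)
            bad = np.nonzero(np.abs(sums - 1.0) > 1e-6)[0]
            if bad.size:
                raise ValueError(
                    "non-normalized PSFs at thicknesses (mm): "
                    + ", ".join(str(int(i) + 1) for i in bad[:10])
                )

    @property
    def t_max(self) -> int:
        """Largest supported thickness in mm."""
        return int(self.psfs.shape[0])

    @property
    def thicknesses(self) -> np.ndarray:
        return np.arange(1, self.t_max + 1)

    def kernel_at(self, t: float) -> ScatterKernel:
        """Kernel at thickness ``t`` mm (nearest 1 mm entry).

        Raises ValueError if ``t`` exceeds the database range, reporting
        the maximum supported thickness.
        """
        if t <= 0:
            raise ValueError("thickness must be positive")
        idx = int(round(t))
        if idx > self.t_max:
            raise ValueError(
                f"thickness {t:.1f} mm exceeds kernel database range "
                f"(max supported thickness {self.t_max} mm)"
            )
        idx = max(idx, 1)
        return ScatterKernel(
            thickness_mm=float(idx),
            psf=self.psfs[idx - 1],
            sf=float(sf_of_thickness(idx, self.a1, self.a2)),
            amplitude=amplitude_of_thickness(idx, self.amplitude_table),
            pitch_mm=self.pitch_mm,
        )

    def zero_like(self) -> "KernelDatabase":
        """Database of identical shape whose kernels carry zero scatter.

        Implemented as SF coefficients a1 = a2 = 0 so that K_t ≡ 0 while
        PSFs stay valid; useful as a no-scatter control.
        """
        return KernelDatabase(
            psfs=self.psfs,
            a1=0.0,
            a2=0.0,
            amplitude_table=self.amplitude_table,
            pitch_mm=self.pitch_mm,
            provenance=self.provenance,
            _validate=False,
        )


def interpolate_kernels(
    coarse_thicknesses: np.ndarray,
    coarse_psfs: np.ndarray,
    t_max: int | None = None,
    *,
    a1: float = DEFAULT_A1,
    a2: float = DEFAULT_A2,
    amplitude_table: tuple[tuple[float, float], ...] = DEFAULT_AMPLITUDE_TABLE,
    pitch_mm: float = 0.388,
    provenance: str = "parametric",
) -> KernelDatabase:
    """Linear per-pixel interpolation of coarse PSFs onto the 1 mm grid.

    Each interpolated PSF is re-normalized to unit sum.  Requested
    thicknesses must lie inside the coarse range — no extrapolation.
    SF and amplitude are *not* interpolated; they come from their own
    models at lookup time.
    """
    ct = np.asarray(coarse_thicknesses, dtype=float)
    cp = np.asarray(coarse_psfs, dtype=np.float64)
    if ct.ndim != 1 or cp.ndim != 3 or cp.shape[0] != ct.size:
        raise ValueError("need one coarse PSF grid per coarse thickness")
    if np.any(np.diff(ct) <= 0):
        raise ValueError("coarse thicknesses must be strictly increasing")
    if t_max is None:
        t_max = int(np.floor(ct[-1]))
    targets = np.arange(1, t_max + 1, dtype=float)
    if targets[0] < ct[0] - 1e-9 or targets[-1] > ct[-1] + 1e-9:
        raise ValueError(
            f"requested thickness grid [1, {t_max}] mm lies outside the coarse "
            f"range [{ct[0]:g}, {ct[-1]:g}] mm; extrapolation is not supported"
        )
    idx = np.clip(np.searchsorted(ct, targets, side="right") - 1, 0, ct.size - 2)
    t0, t1 = ct[idx], ct[idx + 1]
    w = np.where(t1 > t0, (targets - t0) / (t1 - t0), 0.0)
    psfs = (1.0 - w)[:, None, None] * cp[idx] + w[:, None, None] * cp[idx + 1]
    psfs /= psfs.reshape(psfs.shape[0], -1).sum(axis=1)[:, None, None]
    return KernelDatabase(
        psfs=psfs, a1=a1, a2=a2, amplitude_table=amplitude_table,
        pitch_mm=pitch_mm, provenance=provenance,
    )


def build_parametric_database(
    t_max: int = 380,
    *,
    coarse_step: float = 38.0,
    shape: PSFShape = PSFShape(),
    grid_size: int = 101,
    pitch_mm: float = 0.388,
    a1: float = DEFAULT_A1,
    a2: float = DEFAULT_A2,
    amplitude_table: tuple[tuple[float, float], ...] = DEFAULT_AMPLITUDE_TABLE,
) -> KernelDatabase:
    """Build the default database from the parametric PSF family.

    Coarse kernels are generated at 1 mm and then every ``coarse_step``
    mm (mirroring slab-stack measurements at 38 mm increments) and
    interpolated down to 1 mm steps.
    """
    nodes = [1.0] + list(np.arange(coarse_step, t_max + 0.5 * coarse_step, coarse_step))
    nodes = [t for t in nodes if t <= t_max] + ([float(t_max)] if t_max % coarse_step else [])
    nodes = sorted(set(nodes))
    cp = np.stack([make_parametric_psf(t, shape, grid_size, pitch_mm) for t in nodes])
    return interpolate_kernels(
        np.asarray(nodes), cp, t_max,
        a1=a1, a2=a2, amplitude_table=amplitude_table, pitch_mm=pitch_mm,
        provenance="parametric",
    )


def save_kernels(db: KernelDatabase, path) -> None:
    """Write the database to HDF5 (``/kernels/t_<mm>`` datasets + attrs)."""
    import h5py

    with h5py.File(path, "w") as f:
        g = f.create_group("kernels")
        for t in db.thicknesses:
            g.create_dataset(f"t_{int(t):03d}", data=db.psfs[t - 1])
        f.attrs["a1"] = db.a1
        f.attrs["a2"] = db.a2
        f.attrs["pitch_mm"] = db.pitch_mm
        f.attrs["provenance"] = db.provenance
        f.attrs["amplitude_edges"] = [e for e, _ in db.amplitude_table]
        f.attrs["amplitude_values"] = [a for _, a in db.amplitude_table]


def load_kernels(path) -> KernelDatabase:
    """Read a database written by :func:`save_kernels`.

    Raises ValueError on missing metadata or non-normalized PSFs (the
    offending thicknesses are listed).
    """
    import h5py

    with h5py.File(path, "r") as f:
        required = ("a1", "a2", "pitch_mm", "amplitude_edges", "amplitude_values")
        missing = [k for k in required if k not in f.attrs]
        if missing:
            raise ValueError(f"kernel file '{path}' is missing metadata: {', '.join(missing)}")
        names = sorted(f["kernels"].keys())
        psfs = np.stack([f["kernels"][n][()] for n in names])
        table = tuple(zip((float(e) for e in f.attrs["amplitude_edges"]),
                          (float(a) for a in f.attrs["amplitude_values"])))
        return KernelDatabase(
            psfs=psfs,
            a1=float(f.attrs["a1"]),
            a2=float(f.attrs["a2"]),
            amplitude_table=table,
            pitch_mm=float(f.attrs["pitch_mm"]),
            provenance=str(f.attrs.get("provenance", "loaded")),
        )
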