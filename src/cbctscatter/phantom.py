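"""Digital phantoms: voxelized attenuation maps with labelled inserts.

The default test object mimics a cylindrical tissue-equivalent QA
phantom (160 mm diameter) with rod inserts of bone, air, water and soft
tissue running parallel to the rotation axis, plus a low-contrast
variant whose four inserts differ from background by small attenuation
offsets.  Attenuation values are monoenergetic effective-energy linear
attenuation coefficients in mm^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MATERIAL_MU",
    "Insert",
    "DigitalPhantom",
    "generate_qrm_like_phantom",
    "ct_number_insert_spec",
    "low_contrast_insert_spec",
    "slab_phantom",
]

#: Effective-energy linear attenuation coefficients, mm^-1 (≈60 keV).
MATERIAL_MU = {
    "air": 0.0,
    "water": 0.0206,
    "soft_tissue": 0.0210,
    "bone": 0.0573,
    "pmma": 0.0220,
}


@dataclass
class Insert:
    """Cylindrical rod insert, axis parallel to the rotation axis.

    ``center_mm`` is the in-plane (x, y) position of the rod axis in mm
    relative to the phantom axis.
    """

    center_mm: tuple[float, float]
    radius_mm: float
    mu: float
    label: str

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError(f"insert '{self.label}' has non-positive radius")
        if self.mu < 0:
            raise ValueError(f"insert '{self.label}' has negative attenuation")


@dataclass
class DigitalPhantom:
    """Voxel grid of linear attenuation plus geometric support metadata.

    ``mu`` is indexed ``[ix, iy, iz]`` with ``x``/``y`` the in-plane axes
    and ``z`` the rotation axis; voxels are cubes of ``voxel_size_mm``
    centered on the grid center.  ``cylinder_radius_mm``/``height_mm``
    describe the bounding support used for field-of-view checks; they are
    ``None`` for non-cylindrical objects (e.g. slabs), which disables the
    check.
    """

    mu: np.ndarray
    voxel_size_mm: float
    inserts: list[Insert] = field(default_factory=list)
    cylinder_radius_mm: float | None = None
    height_mm: float | None = None
    background_mu: float = 0.0

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=np.float64)
        if self.mu.ndim != 3:
            raise ValueError("attenuation grid must be 3D")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be positive")
        if np.any(self.mu < 0):
            raise ValueError("attenuation values must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mu.shape

    def axis_coords(self, axis: int) -> np.ndarray:
        """Voxel-center world coordinates (mm) along one axis."""
        n = self.mu.shape[axis]
        return (np.arange(n) - (n - 1) / 2.0) * self.voxel_size_mm

    def central_slice(self) -> np.ndarray:
        """Axial slice ``mu[:, :, nz//2]`` at (or nearest) z = 0."""
        return self.mu[:, :, self.mu.shape[2] // 2]


def ct_number_insert_spec(radius_mm: float = 9.0, offset_mm: float = 40.0) -> list[Insert]:
    """Four-material insert layout: bone, air, water, soft tissue.

    Inserts are placed on the ±x/±y axes at ``offset_mm`` from center.
    """
    mats = ["bone", "air", "water", "soft_tissue"]
    centers = [(offset_mm, 0.0), (-offset_mm, 0.0), (0.0, offset_mm), (0.0, -offset_mm)]
    return [Insert(c, radius_mm, MATERIAL_MU[m], m) for c, m in zip(centers, mats)]


def low_contrast_insert_spec(
    background_mu: float = MATERIAL_MU["soft_tissue"],
    offsets: tuple[float, ...] = (0.0004, 0.0008, 0.0012, 0.0016),
    radius_mm: float = 7.0,
    ring_radius_mm: float = 45.0,
) -> list[Insert]:
    """Low-contrast section: four inserts at small offsets from background."""
    out = []
    for k, d in enumerate(offsets):
        ang = 2.0 * np.pi * k / len(offsets) + np.pi / 4.0
        c = (ring_radius_mm * np.cos(ang), ring_radius_mm * np.sin(ang))
        out.append(Insert(c, radius_mm, background_mu + d, f"lc{k + 1}"))
    return out


def generate_qrm_like_phantom(
    diameter_mm: float = 160.0,
    inserts: list[Insert] | None = None,
    *,
    voxel_size_mm: float = 1.25,
    height_mm: float | None = None,
    background_mu: float = MATERIAL_MU["soft_tissue"],
    n_xy: int | None = None,
    n_z: int | None = None,
) -> DigitalPhantom:
    """Voxelize a cylindrical phantom with optional rod inserts.

    Parameters
    ----------
    diameter_mm : float
        Cylinder diameter (the reference QA phantom is 160 mm).
    inserts : list of Insert, optional
        Rod inserts; all must lie strictly inside the cylinder and must
        not overlap one another.
    voxel_size_mm : float
        Isotropic voxel size.
    height_mm : float, optional
        Cylinder height; defaults to the diameter.
    background_mu : float
        Attenuation of the cylinder body (soft tissue by default).

    Returns
    -------
    DigitalPhantom

    Raises
    ------
    ValueError
        If an insert pokes outside the cylinder (names the insert) or two
        inserts overlap (names the pair).
    """
    if diameter_mm <= 0:
        raise ValueError("diameter must be positive")
    radius = diameter_mm / 2.0
    if height_mm is None:
        height_mm = diameter_mm
    inserts = list(inserts) if inserts is not None else []

    for ins in inserts:
        if np.hypot(*ins.center_mm) + ins.radius_mm > radius:
            raise ValueError(
                f"insert '{ins.label}' extends outside the phantom cylinder "
                f"(|center| + radius = {np.hypot(*ins.center_mm) + ins.radius_mm:.1f} mm "
                f"> {radius:.1f} mm)"
            )
    for a in range(len(inserts)):
        for b in range(a + 1, len(inserts)):
            ia, ib = inserts[a], inserts[b]
            d = np.hypot(ia.center_mm[0] - ib.center_mm[0], ia.center_mm[1] - ib.center_mm[1])
            if d < ia.radius_mm + ib.radius_mm:
                raise ValueError(f"inserts '{ia.label}' and '{ib.label}' overlap")

    if n_xy is None:
        n_xy = int(np.ceil(diameter_mm / voxel_size_mm)) + 2
    if n_z is None:
        n_z = int(np.ceil(height_mm / voxel_size_mm))

    x = (np.arange(n_xy) - (n_xy - 1) / 2.0) * voxel_size_mm
    y = x.copy()
    xx, yy = np.meshgrid(x, y, indexing="ij")
    rr = np.hypot(xx, yy)

    slice2d = np.zeros((n_xy, n_xy), dtype=np.float64)
    slice2d[rr <= radius] = background_mu
    for ins in inserts:
        mask = np.hypot(xx - ins.center_mm[0], yy - ins.center_mm[1]) <= ins.radius_mm
        slice2d[mask] = ins.mu

    mu = np.repeat(slice2d[:, :, None], n_z, axis=2)
    return DigitalPhantom(
        mu=mu,
        voxel_size_mm=voxel_size_mm,
        inserts=inserts,
        cylinder_radius_mm=radius,
        height_mm=n_z * voxel_size_mm,
        background_mu=background_mu,
    )


def slab_phantom(
    thickness_mm: float,
    mu: float = MATERIAL_MU["pmma"],
    *,
    lateral_mm: float = 240.0,
    voxel_size_mm: float = 2.0,
) -> DigitalPhantom:
    """Uniform slab normal to the x axis (beam axis of the 0° view).

    Used for thickness-mapping calibration: a ray at normal incidence
    sees exactly ``thickness_mm`` of material.  The slab extends
    ``lateral_mm`` in y and z; no field-of-view support is declared so
    it may legitimately exceed the scan FOV.
    """
    if thickness_mm <= 0:
        raise ValueError("slab thickness must be positive")
    nx = max(3, int(np.ceil(thickness_mm / voxel_size_mm)) + 2)
    nyz = int(np.ceil(lateral_mm / voxel_size_mm))
    x = (np.arange(nx) - (nx - 1) / 2.0) * voxel_size_mm
    inside = np.abs(x) <= thickness_mm / 2.0
    # exact thickness via partial voxels: weight per voxel column
    lo = np.maximum(x - voxel_size_mm / 2.0, -thickness_mm / 2.0)
    hi = np.minimum(x + voxel_size_mm / 2.0, thickness_mm / 2.0)
    frac = np.clip((hi - lo) / voxel_size_mm, 0.0, 1.0)
    grid = np.zeros((nx, nyz, nyz), dtype=np.float64)
    grid[:] = (mu * frac)[:, None, None]
    del inside
    return DigitalPhantom(mu=grid, voxel_size_mm=voxel_size_mm, background_mu=0.0)
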