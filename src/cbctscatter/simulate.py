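"""Synthetic cone-beam projection simulator.

Primary projections follow monoenergetic Beer's law: each detector
pixel records I0·exp(−∫μ dl) along the ray from the point source to the
pixel center.  Line integrals use an exact radiological-path voxel
traversal (incremental Siddon/Amanatides-Woo stepping: the ray is
clipped to the grid, then voxels are visited in order of the parametric
boundary crossings, accumulating μ × intersection length).

Scatter is added with the same grouped-kernel forward model the
correction assumes: the primary is partitioned into thickness-group
subprojections, each convolved with the kernel at its group's center
thickness, and the results are summed,

    I_m = I_p + Σ_g (I_{p,g} ** K_{t_g}).

This deliberately commits the "inverse crime" — the simulated scatter
obeys the correction's own model exactly — which is what makes exact
primary-recovery testing possible.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy.signal import fftconvolve

from .geometry import AcquisitionGeometry
from .kernels import KernelDatabase
from .phantom import DigitalPhantom
from .projection import ProjectionSet
from .thickness import (
    DEFAULT_GROUP_EDGES,
    DEFAULT_MIN_SCATTER_THICKNESS_MM,
    DEFAULT_MU_PMMA,
    estimate_thickness,
    group_representative_thicknesses,
    partition_by_thickness,
)

__all__ = ["forward_project", "add_scatter", "add_poisson_noise", "check_field_of_view"]

DEFAULT_FLAT_FIELD = 1.0e4


@njit(cache=True)
def _ray_integrals(mu, vox, ox, oy, oz, sx, sy, sz, pts, out):  # pragma: no cover - jit
    nx, ny, nz = mu.shape
    for k in range(pts.shape[0]):
        px = pts[k, 0]
        py = pts[k, 1]
        pz = pts[k, 2]
        dx = px - sx
        dy = py - sy
        dz = pz - sz
        length = np.sqrt(dx * dx + dy * dy + dz * dz)
        tmin = 0.0
        tmax = 1.0
        ok = True
        for ax in range(3):
            if ax == 0:
                s0, d, o, n = sx, dx, ox, nx
            elif ax == 1:
                s0, d, o, n = sy, dy, oy, ny
            else:
                s0, d, o, n = sz, dz, oz, nz
            lo = o
            hi = o + n * vox
            if d == 0.0:
                if s0 <= lo or s0 >= hi:
                    ok = False
                    break
            else:
                t1 = (lo - s0) / d
                t2 = (hi - s0) / d
                if t1 > t2:
                    t1, t2 = t2, t1
                if t1 > tmin:
                    tmin = t1
                if t2 < tmax:
                    tmax = t2
        if (not ok) or tmin >= tmax:
            out[k] = 0.0
            continue
        # entry voxel
        exn = sx + tmin * dx
        eyn = sy + tmin * dy
        ezn = sz + tmin * dz
        ix = int((exn - ox) / vox)
        iy = int((eyn - oy) / vox)
        iz = int((ezn - oz) / vox)
        if ix < 0:
            ix = 0
        if ix > nx - 1:
            ix = nx - 1
        if iy < 0:
            iy = 0
        if iy > ny - 1:
            iy = ny - 1
        if iz < 0:
            iz = 0
        if iz > nz - 1:
            iz = nz - 1
        big = 1.0e300
        if dx > 0.0:
            tx = ((ox + (ix + 1) * vox) - sx) / dx
            dtx = vox / dx
            stx = 1
        elif dx < 0.0:
            tx = ((ox + ix * vox) - sx) / dx
            dtx = -vox / dx
            stx = -1
        else:
            tx = big
            dtx = big
            stx = 0
        if dy > 0.0:
            ty = ((oy + (iy + 1) * vox) - sy) / dy
            dty = vox / dy
            sty = 1
        elif dy < 0.0:
            ty = ((oy + iy * vox) - sy) / dy
            dty = -vox / dy
            sty = -1
        else:
            ty = big
            dty = big
            sty = 0
        if dz > 0.0:
            tz = ((oz + (iz + 1) * vox) - sz) / dz
            dtz = vox / dz
            stz = 1
        elif dz < 0.0:
            tz = ((oz + iz * vox) - sz) / dz
            dtz = -vox / dz
            stz = -1
        else:
            tz = big
            dtz = big
            stz = 0
        total = 0.0
        t = tmin
        while t < tmax - 1e-12:
            tnext = tx
            if ty < tnext:
                tnext = ty
            if tz < tnext:
                tnext = tz
            if tnext > tmax:
                tnext = tmax
            seg = (tnext - t) * length
            if seg > 0.0:
                total += mu[ix, iy, iz] * seg
            t = tnext
            if tx <= t:
                ix += stx
                tx += dtx
                if ix < 0 or ix >= nx:
                    break
            if ty <= t:
                iy += sty
                ty += dty
                if iy < 0 or iy >= ny:
                    break
            if tz <= t:
                iz += stz
                tz += dtz
                if iz < 0 or iz >= nz:
                    break
        out[k] = total


def check_field_of_view(phantom: DigitalPhantom, geometry: AcquisitionGeometry) -> None:
    """Raise if the phantom's declared cylinder support leaves the FOV.

    Uses the exact tangent half-fan for the in-plane extent,
    u_max = DSD·R/sqrt(DSO² − R²), and the worst-case axial
    magnification v_max = (H/2)·DSD/(DSO − R).  Phantoms without a
    declared cylinder support (slabs) skip the check.
    """
    r = phantom.cylinder_radius_mm
    if r is None:
        return
    if r >= geometry.dso:
        raise ValueError("phantom radius exceeds the source orbit radius")
    half_u = geometry.n_cols / 2.0 * geometry.pixel_pitch_mm
    half_v = geometry.n_rows / 2.0 * geometry.pixel_pitch_mm
    u_max = geometry.dsd * r / np.sqrt(geometry.dso**2 - r**2)
    h = phantom.height_mm if phantom.height_mm is not None else 0.0
    v_max = (h / 2.0) * geometry.dsd / (geometry.dso - r)
    if u_max > half_u or v_max > half_v:
        ang = float(geometry.angles_deg[0])
        raise ValueError(
            f"phantom exceeds the detector field of view at view angle {ang:.1f}° "
            f"(needs ±{u_max:.1f} mm × ±{v_max:.1f} mm on a "
            f"±{half_u:.1f} mm × ±{half_v:.1f} mm detector)"
        )


def forward_project(
    phantom: DigitalPhantom,
    geometry: AcquisitionGeometry,
    flat_field: float = DEFAULT_FLAT_FIELD,
    *,
    check_fov: bool = True,
) -> ProjectionSet:
    """Monoenergetic Beer's-law cone-beam projection of a phantom.

    Each pixel is I0·exp(−L) with L the exact radiological path through
    the voxel grid from the source to the pixel center.
    """
    if check_fov:
        check_field_of_view(phantom, geometry)
    mu = np.ascontiguousarray(phantom.mu)
    vox = phantom.voxel_size_mm
    # grid corner (lower edge of voxel (0,0,0))
    ox = -(mu.shape[0] * vox) / 2.0
    oy = -(mu.shape[1] * vox) / 2.0
    oz = -(mu.shape[2] * vox) / 2.0
    u = geometry.detector_u()
    v = geometry.detector_v()
    n_pix = geometry.n_rows * geometry.n_cols
    stack = np.empty((geometry.n_views, geometry.n_rows, geometry.n_cols))
    out = np.empty(n_pix)
    pts = np.empty((n_pix, 3))
    for k, ang in enumerate(np.deg2rad(geometry.angles_deg)):
        c, s = np.cos(ang), np.sin(ang)
        src = (geometry.dso * c, geometry.dso * s, 0.0)
        det_center = (-(geometry.dsd - geometry.dso) * c, -(geometry.dsd - geometry.dso) * s)
        # detector axes: e_u = (−sin, cos, 0), e_v = ẑ
        uu, vv = np.meshgrid(u, v, indexing="xy")  # (rows, cols)
        pts[:, 0] = (det_center[0] - uu * s).ravel()
        pts[:, 1] = (det_center[1] + uu * c).ravel()
        pts[:, 2] = vv.ravel()
        _ray_integrals(mu, vox, ox, oy, oz, src[0], src[1], src[2], pts, out)
        stack[k] = flat_field * np.exp(-out.reshape(geometry.n_rows, geometry.n_cols))
    return ProjectionSet(stack, geometry.angles_deg.copy(), flat_field, geometry)


def grouped_scatter_image(
    primary: np.ndarray,
    flat_field: float,
    kernels: KernelDatabase,
    edges=DEFAULT_GROUP_EDGES,
    mu_pmma: float = DEFAULT_MU_PMMA,
    min_thickness: float = DEFAULT_MIN_SCATTER_THICKNESS_MM,
) -> np.ndarray:
    """Scatter estimate Σ_g (I_{p,g} ** K_{t_g}) for one projection.

    The thickness map comes from the supplied primary via Beer's law,
    the primary is partitioned by group (pixels thinner than
    ``min_thickness`` do not scatter), and each subprojection is
    convolved (zero-padded, frequency domain) with its group kernel.
    """
    tmap = estimate_thickness(primary, flat_field, mu_pmma)
    reps = group_representative_thicknesses(edges)
    needed = max(float(tmap.max()), 0.0)
    if needed > kernels.t_max:
        raise ValueError(
            f"projection contains thickness {needed:.1f} mm beyond the kernel "
            f"database range (max supported thickness {kernels.t_max} mm)"
        )
    subs = partition_by_thickness(primary, tmap, edges, min_thickness)
    scatter = np.zeros_like(primary)
    for g, rep in enumerate(reps):
        if not np.any(subs[g]):
            continue
        k = kernels.kernel_at(float(rep)).kernel
        scatter += fftconvolve(subs[g], k, mode="same")
    return np.maximum(scatter, 0.0)


def add_scatter(
    primary: ProjectionSet,
    kernels: KernelDatabase,
    edges=DEFAULT_GROUP_EDGES,
    mu_pmma: float = DEFAULT_MU_PMMA,
    min_thickness: float = DEFAULT_MIN_SCATTER_THICKNESS_MM,
) -> ProjectionSet:
    """Measured-signal set I_m = I_p + Σ_g (I_{p,g} ** K_{t_g}).

    Output intensities are ≥ the input everywhere (scatter is additive
    and non-negative).  The same thickness partition rule the
    correction uses generates the scatter, so the true primary is by
    construction a fixed point of the MLEM iteration.
    """
    out = np.empty_like(primary.intensities)
    for i in range(len(primary)):
        s = grouped_scatter_image(primary.intensities[i], primary.flat_field,
                                  kernels, edges, mu_pmma, min_thickness)
        out[i] = primary.intensities[i] + s
    return primary.with_intensities(out)


def add_poisson_noise(pset: ProjectionSet, seed: int) -> ProjectionSet:
    """Poisson counting noise on measured intensities (mean = input).

    Off the default simulation path; the Poisson assumption underlies
    the MLEM derivation, so this switch exists for statistical tests.
    """
    rng = np.random.default_rng(seed)
    noisy = rng.poisson(pset.intensities).astype(np.float64)
    return pset.with_intensities(noisy)
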