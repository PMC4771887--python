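"""Readers/writers for projection sets and volumes (HDF5 and TIFF)."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .geometry import AcquisitionGeometry
from .projection import ProjectionSet
from .recon import Volume

__all__ = [
    "write_projections",
    "read_projections",
    "write_volume",
    "read_volume",
]

_GEO_FIELDS = ("dsd", "dso", "pixel_pitch_mm", "n_rows", "n_cols")


def _geometry_to_dict(geo: AcquisitionGeometry | None) -> dict | None:
    if geo is None:
        return None
    return {k: getattr(geo, k) for k in _GEO_FIELDS}


def _geometry_from_dict(d: dict | None, angles: np.ndarray) -> AcquisitionGeometry | None:
    if not d:
        return None
    return AcquisitionGeometry(angles_deg=angles, **{k: d[k] for k in _GEO_FIELDS})


def write_projections(pset: ProjectionSet, path) -> None:
    """Write a projection set; format chosen by extension (.h5/.hdf5 or .tif/.tiff)."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.attrs["flat_field"] = pset.flat_field
            f.attrs["angles_deg"] = pset.angles_deg
            geo = _geometry_to_dict(pset.geometry)
            if geo is not None:
                for k, v in geo.items():
                    f.attrs[f"geometry_{k}"] = v
            g = f.create_group("projections")
            for i in range(len(pset)):
                d = g.create_dataset(f"view_{i:04d}", data=pset.intensities[i])
                d.attrs["angle_deg"] = float(pset.angles_deg[i])
    elif path.suffix.lower() in (".tif", ".tiff"):
        meta = {
            "flat_field": pset.flat_field,
            "angles_deg": [float(a) for a in pset.angles_deg],
            "geometry": _geometry_to_dict(pset.geometry),
        }
        tifffile.imwrite(path, pset.intensities.astype(np.float32),
                         photometric="minisblack", description=json.dumps(meta))
    else:
        raise ValueError(f"unsupported projection format '{path.suffix}'")


def read_projections(path) -> ProjectionSet:
    """Read a projection set written by :func:`write_projections`."""
    path = Path(path)
    try:
        if path.suffix.lower() in (".h5", ".hdf5"):
            with h5py.File(path, "r") as f:
                if "flat_field" not in f.attrs:
                    raise ValueError(f"'{path}' is missing flat-field metadata")
                angles = np.asarray(f.attrs["angles_deg"], dtype=float)
                names = sorted(f["projections"].keys())
                stack = np.stack([f["projections"][n][()] for n in names])
                geo_d = {k: f.attrs[f"geometry_{k}"] for k in _GEO_FIELDS
                         if f"geometry_{k}" in f.attrs}
                geo = _geometry_from_dict(geo_d if len(geo_d) == len(_GEO_FIELDS) else None,
                                          angles)
                return ProjectionSet(stack, angles, float(f.attrs["flat_field"]), geo)
        elif path.suffix.lower() in (".tif", ".tiff"):
            with tifffile.TiffFile(path) as tf:
                stack = tf.asarray().astype(np.float64)
                desc = tf.pages[0].tags.get("ImageDescription")
                meta = json.loads(desc.value) if desc is not None else {}
            if "flat_field" not in meta:
                raise ValueError(f"'{path}' is missing flat-field metadata")
            angles = np.asarray(meta["angles_deg"], dtype=float)
            geo = _geometry_from_dict(meta.get("geometry"), angles)
            if stack.ndim == 2:
                stack = stack[None]
            return ProjectionSet(stack, angles, float(meta["flat_field"]), geo)
        raise ValueError(f"unsupported projection format '{path.suffix}'")
    except ValueError:
        raise
    except Exception as exc:
        raise IOError(f"could not read projection file '{path}': {exc}") from exc


def write_volume(vol: Volume, path) -> None:
    """Write a reconstructed volume (.h5/.hdf5 or .tif/.tiff)."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("volume", data=vol.values)
            f.attrs["voxel_size_mm"] = vol.voxel_size_mm
            f.attrs["orientation"] = vol.orientation
    elif path.suffix.lower() in (".tif", ".tiff"):
        meta = {"voxel_size_mm": vol.voxel_size_mm, "orientation": vol.orientation}
        tifffile.imwrite(path, vol.values.astype(np.float32),
                         photometric="minisblack", description=json.dumps(meta))
    else:
        raise ValueError(f"unsupported volume format '{path.suffix}'")


def read_volume(path) -> Volume:
    path = Path(path)
    try:
        if path.suffix.lower() in (".h5", ".hdf5"):
            with h5py.File(path, "r") as f:
                return Volume(f["volume"][()], float(f.attrs["voxel_size_mm"]),
                              str(f.attrs.get("orientation", "axial")))
        elif path.suffix.lower() in (".tif", ".tiff"):
            with tifffile.TiffFile(path) as tf:
                vals = tf.asarray().astype(np.float64)
                desc = tf.pages[0].tags.get("ImageDescription")
                meta = json.loads(desc.value) if desc is not None else {}
            return Volume(vals, float(meta.get("voxel_size_mm", 1.0)),
                          str(meta.get("orientation", "axial")))
        raise ValueError(f"unsupported volume format '{path.suffix}'")
    except ValueError:
        raise
    except Exception as exc:
        raise IOError(f"could not read volume file '{path}': {exc}") from exc
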