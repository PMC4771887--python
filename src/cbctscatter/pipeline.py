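"""End-to-end pipeline: simulate → correct → reconstruct → evaluate.

The pipeline is configured from a YAML/dict config with one block per
stage; :func:`validate_config` checks every stage's preconditions up
front so that a bad parameter aborts before any computation starts.
Identical config + seed reproduce bit-identical artifacts.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from .geometry import AcquisitionGeometry
from .io import write_projections, write_volume
from .kernels import (
    DEFAULT_A1,
    DEFAULT_A2,
    PSFShape,
    build_parametric_database,
    load_kernels,
)
from .metrics import circular_roi_stats, ct_number, percent_cupping
from .mlem import CorrectionConfig, run_scatter_correction
from .phantom import MATERIAL_MU, Insert, generate_qrm_like_phantom
from .recon import ReconFilter, fbp_reconstruct
from .simulate import add_poisson_noise, add_scatter, forward_project
from .thickness import DEFAULT_GROUP_EDGES, DEFAULT_MU_PMMA

__all__ = ["DEFAULT_CONFIG", "load_config", "validate_config", "run_pipeline"]

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "flat_field": 1.0e4,
    "noise": False,
    "phantom": {
        "diameter_mm": 160.0,
        "voxel_size_mm": 1.25,
        "height_mm": 60.0,
        "background": "soft_tissue",
        "inserts": [],  # list of {center_mm, radius_mm, material or mu, label}
    },
    "geometry": {
        "dso": 500.0,
        "dsd": 786.0,
        "pixel_pitch_mm": 1.2,
        "n_rows": 128,
        "n_cols": 224,
        "n_views": 120,
    },
    "kernels": {
        "path": None,
        "t_max": 200,
        "grid_size": 161,
        "a1": DEFAULT_A1,
        "a2": DEFAULT_A2,
    },
    "grouping": {"edges": list(DEFAULT_GROUP_EDGES), "mu_pmma": DEFAULT_MU_PMMA},
    "mlem": {"iterations": 5, "tolerance": 1e-4},
    "recon": {"filter": "shepp-logan", "cutoff": 0.6, "voxel_size_mm": 1.25, "n_pixels": 160},
    "evaluation": {"center_roi_radius_px": 6, "edge_roi_fraction": 0.6},
}


def _merged(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merged(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def load_config(path) -> dict:
    """Load a YAML config, filling unspecified values from the defaults."""
    with open(path) as f:
        user = yaml.safe_load(f) or {}
    return _merged(DEFAULT_CONFIG, user)


def validate_config(config: dict) -> None:
    """Check every stage's preconditions before computation starts."""
    g = config["geometry"]
    if not (g["dsd"] > g["dso"] > 0):
        raise ValueError("geometry: DSD > DSO > 0 is required")
    if g["pixel_pitch_mm"] <= 0:
        raise ValueError("geometry: pixel pitch must be positive")
    if min(g["n_rows"], g["n_cols"], g["n_views"]) < 1:
        raise ValueError("geometry: detector size and view count must be positive")
    p = config["phantom"]
    if p["diameter_mm"] <= 0 or p["voxel_size_mm"] <= 0:
        raise ValueError("phantom: diameter and voxel size must be positive")
    k = config["kernels"]
    if k["path"] is None:
        if k["t_max"] < 1 or k["grid_size"] % 2 == 0:
            raise ValueError("kernels: t_max ≥ 1 and an odd grid size are required")
    edges = config["grouping"]["edges"]
    if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("grouping: edges must be strictly increasing with ≥ 2 entries")
    if config["grouping"]["mu_pmma"] <= 0:
        raise ValueError("grouping: mu_pmma must be positive")
    m = config["mlem"]
    if m["iterations"] < 0 or m["tolerance"] <= 0:
        raise ValueError("mlem: iterations ≥ 0 and tolerance > 0 are required")
    r = config["recon"]
    ReconFilter(r["filter"], r["cutoff"])  # validates family and cutoff
    if r["voxel_size_mm"] <= 0 or r["n_pixels"] < 8:
        raise ValueError("recon: voxel size must be positive and grid at least 8 pixels")
    if config["flat_field"] <= 0:
        raise ValueError("flat_field must be positive")


def _build_phantom(cfg: dict):
    inserts = []
    for spec in cfg.get("inserts") or []:
        mu = spec.get("mu", MATERIAL_MU.get(spec.get("material", ""), None))
        if mu is None:
            raise ValueError(f"insert '{spec.get('label')}' needs a material or mu")
        inserts.append(Insert(tuple(spec["center_mm"]), spec["radius_mm"], mu,
                              spec.get("label", spec.get("material", "insert"))))
    return generate_qrm_like_phantom(
        cfg["diameter_mm"], inserts,
        voxel_size_mm=cfg["voxel_size_mm"],
        background_mu=MATERIAL_MU[cfg.get("background", "soft_tissue")],
        height_mm=cfg.get("height_mm"),
    )


def run_pipeline(config: dict, output_dir) -> dict:
    """Run simulate → correct → reconstruct → evaluate; write artifacts.

    Returns the metrics report (also written as ``metrics.json``).
    """
    validate_config(config)
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    gcfg = config["geometry"]
    geometry = AcquisitionGeometry.with_views(
        gcfg["n_views"], dsd=gcfg["dsd"], dso=gcfg["dso"],
        pixel_pitch_mm=gcfg["pixel_pitch_mm"], n_rows=gcfg["n_rows"], n_cols=gcfg["n_cols"],
    )
    kcfg = config["kernels"]
    if kcfg["path"]:
        kernels = load_kernels(kcfg["path"])
    else:
        kernels = build_parametric_database(
            t_max=kcfg["t_max"], grid_size=kcfg["grid_size"],
            pitch_mm=gcfg["pixel_pitch_mm"], a1=kcfg["a1"], a2=kcfg["a2"],
            shape=PSFShape(),
        )
    phantom = _build_phantom(config["phantom"])
    logger.info("simulating %d views (%.1fs elapsed)", geometry.n_views, time.time() - t0)
    primary = forward_project(phantom, geometry, config["flat_field"])
    edges = tuple(config["grouping"]["edges"])
    mu_pmma = config["grouping"]["mu_pmma"]
    measured = add_scatter(primary, kernels, edges, mu_pmma)
    if config["noise"]:
        measured = add_poisson_noise(measured, int(config["seed"]))
    write_projections(primary, out / "primary.h5")
    write_projections(measured, out / "measured.h5")

    logger.info("correcting (%.1fs elapsed)", time.time() - t0)
    cc = CorrectionConfig(
        kernels=kernels, max_iterations=config["mlem"]["iterations"],
        tolerance=config["mlem"]["tolerance"], group_edges=edges, mu_pmma=mu_pmma,
    )
    corrected, states, _ = run_scatter_correction(measured, cc)
    write_projections(corrected, out / "corrected.h5")
    with open(out / "diagnostics.csv", "w") as f:
        f.write("view,angle_deg,iterations,converged,log_likelihood\n")
        for i, st in enumerate(states):
            ll = st.log_likelihood_history[-1] if st.log_likelihood_history else ""
            f.write(f"{i},{measured.angles_deg[i]:.3f},{st.n},{st.converged},{ll}\n")

    logger.info("reconstructing (%.1fs elapsed)", time.time() - t0)
    rcfg = config["recon"]
    rf = ReconFilter(rcfg["filter"], rcfg["cutoff"])
    vols = {}
    for name, pset in [("uncorrected", measured), ("corrected", corrected),
                       ("reference", primary)]:
        vols[name] = fbp_reconstruct(pset, rf, rcfg["voxel_size_mm"], rcfg["n_pixels"])
        write_volume(vols[name], out / f"recon_{name}.h5")

    ecfg = config["evaluation"]
    n = rcfg["n_pixels"]
    c = (n - 1) / 2.0
    r_px = config["phantom"]["diameter_mm"] / 2.0 / rcfg["voxel_size_mm"]
    roi_r = ecfg["center_roi_radius_px"]
    off = ecfg["edge_roi_fraction"] * r_px
    report: dict = {"seed": config["seed"], "views": geometry.n_views}
    ref_bg = circular_roi_stats(vols["reference"].central_slice(), (c, c), roi_r)
    report["reference_background_mu"] = ref_bg.mean
    for name in ("uncorrected", "corrected", "reference"):
        sl = vols[name].central_slice()
        center = ct_number(circular_roi_stats(sl, (c, c), roi_r).mean, ref_bg.mean)
        edges_hu = [
            ct_number(circular_roi_stats(sl, (c + di * off, c + dj * off), roi_r).mean,
                      ref_bg.mean)
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1))
        ]
        report[f"{name}_center_hu"] = center
        report[f"{name}_percent_cupping"] = percent_cupping(edges_hu, center)
    report["mean_iterations"] = float(np.mean([s.n for s in states]))
    report["elapsed_s"] = time.time() - t0
    with open(out / "metrics.json", "w") as f:
        json.dump(report, f, indent=2)
    return report
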