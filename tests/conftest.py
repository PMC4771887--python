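"""Shared fixtures.

Small, fast objects are function-scoped; the full-size recovery fixture
(256×256 detector, 180 views, 160 mm cylinder with scatter generated by
the same kernel model the correction assumes) is session-scoped because
several end-to-end checks share it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pytest

from cbctscatter import (
    AcquisitionGeometry,
    CorrectionConfig,
    KernelDatabase,
    ProjectionSet,
    add_scatter,
    build_parametric_database,
    forward_project,
    generate_qrm_like_phantom,
    run_scatter_correction,
)

FLAT = 1.0e4
FIXTURE_PITCH = 1.2  # mm; detector pitch of the downscaled test scanner


@pytest.fixture(scope="session")
def small_kernel_db() -> KernelDatabase:
    return build_parametric_database(t_max=200, grid_size=61, pitch_mm=FIXTURE_PITCH)


@pytest.fixture(scope="session")
def small_cylinder_projections(small_kernel_db):
    """Primary + scattered projections of a uniform cylinder, 24 views."""
    phantom = generate_qrm_like_phantom(160.0, [], voxel_size_mm=2.0, height_mm=40.0)
    geometry = AcquisitionGeometry.with_views(
        24, pixel_pitch_mm=FIXTURE_PITCH, n_rows=64, n_cols=256)
    primary = forward_project(phantom, geometry, FLAT)
    measured = add_scatter(primary, small_kernel_db)
    return phantom, geometry, primary, measured


@dataclass
class RecoveryFixture:
    phantom: object
    geometry: AcquisitionGeometry
    kernels: KernelDatabase
    primary: ProjectionSet
    measured: ProjectionSet
    corrected: ProjectionSet
    states: list
    snapshots: dict[int, ProjectionSet]


@pytest.fixture(scope="session")
def recovery_fixture() -> RecoveryFixture:
    """Full-size inverse-crime fixture: simulate, scatter, correct.

    160 mm uniform soft-tissue cylinder, 180 views on a 256×256 detector,
    five 40 mm thickness groups, scatter-fraction fit SF = 0.0038·t + 0.1,
    five MLEM iterations with per-iteration snapshots.
    """
    kernels = build_parametric_database(t_max=200, grid_size=201, pitch_mm=FIXTURE_PITCH)
    phantom = generate_qrm_like_phantom(160.0, [], voxel_size_mm=1.25, height_mm=160.0)
    geometry = AcquisitionGeometry.with_views(
        180, pixel_pitch_mm=FIXTURE_PITCH, n_rows=256, n_cols=256)
    primary = forward_project(phantom, geometry, FLAT)
    measured = add_scatter(primary, kernels)
    config = CorrectionConfig(kernels=kernels, max_iterations=5, tolerance=1e-6)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        corrected, states, snapshots = run_scatter_correction(
            measured, config, snapshot_iters=range(6))
    return RecoveryFixture(phantom, geometry, kernels, primary, measured,
                           corrected, states, snapshots)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
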