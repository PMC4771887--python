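import warnings

import numpy as np
import pytest

from cbctscatter import (
    KernelDatabase,
    PSFShape,
    amplitude_of_thickness,
    build_parametric_database,
    interpolate_kernels,
    load_kernels,
    make_parametric_psf,
    save_kernels,
    sf_of_thickness,
)
from cbctscatter.kernels import DEFAULT_A1, DEFAULT_A2, SF_CLAMP


class TestScatterFraction:
    @pytest.mark.parametrize("t,expected", [(0.0, 0.1), (100.0, 0.48)])
    def test_linear_fit_values(self, t, expected):
        assert sf_of_thickness(t) == pytest.approx(expected)

    def test_negative_thickness_rejected(self):
        with pytest.raises(ValueError):
            sf_of_thickness(-1.0)

    def test_clamp_engages_past_validity_range(self):
        # a1·t + a2 crosses 1 at t = (1 - 0.1)/0.0038 ≈ 236.84 mm; the
        # clamp at 0.99 engages slightly earlier
        t_cross = (1.0 - DEFAULT_A2) / DEFAULT_A1
        assert t_cross == pytest.approx(236.84, abs=0.01)
        assert sf_of_thickness(230.0) < SF_CLAMP
        with pytest.warns(UserWarning, match="clamped"):
            val = sf_of_thickness(t_cross + 5.0)
        assert val == SF_CLAMP < 1.0


class TestAmplitudeTable:
    @pytest.mark.parametrize("t,expected", [
        (30.0, 1.0), (100.0, 1.75), (200.0, 2.0),
        (40.0, 1.0),   # boundary belongs to the lower range
        (80.0, 1.0), (120.0, 1.75), (160.0, 1.75),
        (1000.0, 2.0),  # final range is open-ended
    ])
    def test_piecewise_lookup(self, t, expected):
        assert amplitude_of_thickness(t) == expected


class TestParametricPSF:
    def test_unit_sum(self):
        for t in (1.0, 50.0, 200.0):
            psf = make_parametric_psf(t, grid_size=41, pitch_mm=1.2)
            assert abs(psf.sum() - 1.0) < 1e-9
            assert np.all(psf >= 0)

    def test_radial_spread_monotone_in_thickness(self):
        half = 50
        ax = np.arange(-half, half + 1) * 1.2
        xx, yy = np.meshgrid(ax, ax, indexing="ij")
        r2 = xx**2 + yy**2
        spreads = []
        for t in (1, 40, 80, 120, 160, 200, 300):
            psf = make_parametric_psf(float(t), grid_size=101, pitch_mm=1.2)
            spreads.append(float((psf * r2).sum()))
        assert all(b >= a for a, b in zip(spreads, spreads[1:]))

    def test_degenerate_1x1_grid(self):
        np.testing.assert_array_equal(make_parametric_psf(10.0, grid_size=1), [[1.0]])

    def test_even_grid_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            make_parametric_psf(10.0, grid_size=40)

    def test_radial_symmetry(self):
        psf = make_parametric_psf(80.0, grid_size=31, pitch_mm=1.0)
        np.testing.assert_allclose(psf, psf.T, rtol=1e-12)
        np.testing.assert_allclose(psf, psf[::-1, ::-1], rtol=1e-12)


class TestInterpolation:
    def test_at_coarse_node_returns_that_kernel(self):
        nodes = np.array([1.0, 38.0, 76.0])
        coarse = np.stack([make_parametric_psf(t, grid_size=21, pitch_mm=1.2)
                           for t in nodes])
        db = interpolate_kernels(nodes, coarse, 76)
        np.testing.assert_allclose(db.psfs[37], coarse[1], atol=1e-15)

    def test_equal_brackets_give_that_kernel(self):
        psf = make_parametric_psf(50.0, grid_size=21)
        db = interpolate_kernels(np.array([1.0, 99.0]), np.stack([psf, psf]), 99)
        np.testing.assert_allclose(db.psfs[49], psf, atol=1e-15)

    def test_ten_38mm_sets_span_380_entries(self):
        db = build_parametric_database(t_max=380, coarse_step=38.0, grid_size=11,
                                       pitch_mm=1.2)
        assert db.t_max == 380
        assert db.psfs.shape[0] == 380
        assert db.thicknesses[0] == 1 and db.thicknesses[-1] == 380

    def test_no_extrapolation_outside_coarse_range(self):
        nodes = np.array([10.0, 50.0])
        coarse = np.stack([make_parametric_psf(t, grid_size=11) for t in nodes])
        with pytest.raises(ValueError, match="extrapolation"):
            interpolate_kernels(nodes, coarse, 50)  # targets start at 1 < 10


class TestKernelDatabase:
    def test_energy_bookkeeping(self, small_kernel_db):
        for t in (20.0, 60.0, 100.0, 140.0, 180.0):
            k = small_kernel_db.kernel_at(t)
            assert k.kernel.sum() == pytest.approx(k.amplitude * k.sf, abs=1e-6)

    def test_thickness_beyond_range_reports_max(self, small_kernel_db):
        with pytest.raises(ValueError, match="max supported thickness 200"):
            small_kernel_db.kernel_at(250.0)

    def test_zero_like_carries_no_scatter(self, small_kernel_db):
        z = small_kernel_db.zero_like()
        assert np.all(z.kernel_at(60.0).kernel == 0.0)

    def test_save_load_round_trip_is_lossless(self, small_kernel_db, tmp_path):
        path = tmp_path / "kernels.h5"
        save_kernels(small_kernel_db, path)
        back = load_kernels(path)
        np.testing.assert_array_equal(back.psfs, small_kernel_db.psfs)
        assert back.a1 == small_kernel_db.a1
        assert back.a2 == small_kernel_db.a2
        assert back.pitch_mm == small_kernel_db.pitch_mm
        assert back.amplitude_table == small_kernel_db.amplitude_table

    def test_load_rejects_non_normalized_psfs(self, small_kernel_db, tmp_path):
        import h5py

        path = tmp_path / "bad.h5"
        save_kernels(small_kernel_db, path)
        with h5py.File(path, "a") as f:
            f["kernels/t_005"][...] = f["kernels/t_005"][()] * 2.0
        with pytest.raises(ValueError, match="non-normalized.*5"):
            load_kernels(path)

    def test_load_rejects_missing_metadata(self, small_kernel_db, tmp_path):
        import h5py

        path = tmp_path / "meta.h5"
        save_kernels(small_kernel_db, path)
        with h5py.File(path, "a") as f:
            del f.attrs["a1"]
        with pytest.raises(ValueError, match="a1"):
            load_kernels(path)


def test_psf_shape_validation():
    with pytest.raises(ValueError):
        PSFShape(tail_weight=1.5)
    with pytest.raises(ValueError):
        PSFShape(core_sigma0=-1.0)
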