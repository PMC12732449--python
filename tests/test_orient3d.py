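"""3D orientation: fields, heatmaps, nematic index, rotation rate."""

import numpy as np
import pytest

import hhgm_quant as hq
from hhgm_quant import orient3d
from hhgm_quant.orient3d import OrientationHeatmap
from hhgm_quant.synthstack import FiberSpec, render_fibers

from conftest import modal_theta


def fiber_field(theta_deg, shape=(7, 256, 256), voxel_xy=0.2, voxel_z=2.0,
                diameter=1.0, phi_deg=90.0):
    """Noiseless single fiber at mid-depth, returned as an OrientationField."""
    th = np.deg2rad(theta_deg)
    ph = np.deg2rad(phi_deg)
    d = np.array([np.cos(ph), -np.sin(ph) * np.sin(th), np.sin(ph) * np.cos(th)])
    zc = (shape[0] // 2) * voxel_z
    ctr = np.array([zc, shape[1] * voxel_xy / 2, shape[2] * voxel_xy / 2])
    spec = FiberSpec(np.stack([ctr - 40 * d, ctr + 40 * d]), diameter, 50.0,
                     theta_deg % 180.0, phi_deg)
    vol = render_fibers([spec], shape, voxel_xy, voxel_z)
    stack = hq.VolumeStack({"SHG": vol}, voxel_xy, voxel_z)
    return orient3d.orientation_field(stack, "SHG", 5.0)


class TestOrientationField:
    @pytest.mark.parametrize("theta", [0.0, 45.0, 90.0, 140.0])
    def test_in_plane_fiber_theta_and_phi(self, theta):
        f = fiber_field(theta)
        assert f.valid.sum() > 500
        diff = abs(modal_theta(f) - theta) % 180.0
        assert min(diff, 180.0 - diff) <= 3.0
        assert abs(np.nanmedian(f.phi_deg[f.valid]) - 90.0) <= 3.0

    def test_blank_stack_no_valid_voxels(self):
        stack = hq.VolumeStack({"SHG": np.zeros((4, 64, 64))}, 0.2, 2.0)
        f = orient3d.orientation_field(stack, "SHG", 1.0)
        assert f.valid.sum() == 0

    def test_anisotropic_voxels_need_physical_gradients(self):
        # fiber climbing at φ=45° in a stack with voxel_z = 10 × voxel_xy:
        # correct only because gradients are taken in µm, not voxels
        f = fiber_field(0.0, shape=(11, 256, 256), voxel_xy=0.1, voxel_z=1.0,
                        diameter=3.0, phi_deg=45.0)
        phi = np.nanmedian(f.phi_deg[f.valid])
        assert abs(phi - 45.0) <= 5.0

    def test_naive_voxel_gradients_fail_anisotropic_case(self):
        # regression guard: the same geometry analyzed pretending voxels are
        # isotropic puts the axis far from 45°
        th = 0.0
        d = np.array([np.cos(np.pi / 4), 0.0, np.sin(np.pi / 4)])
        ctr = np.array([5.0, 12.8, 12.8])
        spec = FiberSpec(np.stack([ctr - 8 * d, ctr + 8 * d]), 3.0, 50.0,
                         th, 45.0)
        vol = render_fibers([spec], (11, 256, 256), 0.1, 1.0)
        naive = hq.VolumeStack({"SHG": vol}, 0.1, 0.1)  # lies about voxel_z
        f = orient3d.orientation_field(naive, "SHG", 10.0)
        phi = np.nanmedian(f.phi_deg[f.valid])
        assert abs(phi - 45.0) > 5.0

    def test_two_layer_stack_uses_2d_fallback(self):
        vol = np.zeros((2, 64, 64))
        vol[:, 30:34, :] = 50.0
        stack = hq.VolumeStack({"SHG": vol}, 0.2, 2.0)
        f = orient3d.orientation_field(stack, "SHG", 5.0)
        assert f.mode_2d
        assert np.all(f.phi_deg[f.valid] == 90.0)
        with pytest.raises(ValueError):
            orient3d.orientation_field(stack, "SHG", 5.0,
                                       allow_2d_fallback=False)


class TestHeatmap:
    def _field_from_angles(self, theta_layers):
        nz = len(theta_layers)
        theta = np.stack([np.full((8, 8), t, dtype=float)
                          for t in theta_layers])
        valid = ~np.isnan(theta)
        return orient3d.OrientationField(theta, np.full_like(theta, 90.0),
                                         valid, "SHG", 0.2, 2.0)

    def test_delta_distribution(self):
        h = orient3d.orientation_heatmap(self._field_from_angles([45.0]))
        row = h.values[0]
        assert row[45] == pytest.approx(100.0)
        assert row.sum() == pytest.approx(100.0)

    def test_uniform_distribution(self):
        rng = np.random.default_rng(0)
        n = 10**6
        theta = rng.uniform(0, 180, n).reshape(1, 1000, 1000)
        field = orient3d.OrientationField(
            theta, np.full_like(theta, 90.0), np.ones_like(theta, bool),
            "SHG", 0.2, 2.0)
        h = orient3d.orientation_heatmap(field)
        expected = 100.0 / 180.0
        # binomial error at n=1e6: SD ≈ 100·√(p(1−p)/n) ≈ 0.0074 %
        assert np.abs(h.values[0] - expected).max() < 6 * 0.0074 + 1e-3

    def test_empty_layer_flagged(self):
        h = orient3d.orientation_heatmap(
            self._field_from_angles([30.0, np.nan, 60.0]))
        assert list(h.empty_layers) == [False, True, False]
        assert np.isnan(h.values[1]).all()

    def test_rows_sum_to_hundred(self, small_culture):
        stack, _ = small_culture
        f = orient3d.orientation_field(stack, "SHG", 12.0)
        h = orient3d.orientation_heatmap(f)
        sums = np.nansum(h.values[~h.empty_layers], axis=1)
        np.testing.assert_allclose(sums, 100.0, atol=1e-6)


class TestOrientationIndex:
    def test_parallel_field_is_one(self):
        assert orient3d.orientation_index_from_angles(
            np.full(100, 37.0), np.full(100, 90.0)) == pytest.approx(1.0)

    def test_isotropic_directions_near_zero(self):
        rng = np.random.default_rng(1)
        u = rng.normal(size=(10**6, 3))
        assert orient3d.orientation_index_from_directions(u) <= 0.01

    def test_two_population_brute_force_oracle(self):
        theta = np.concatenate([np.zeros(500), np.full(500, 90.0)])
        phi = np.full(1000, 90.0)
        # oracle: mean dyadic tensor assembled by hand
        th = np.deg2rad(theta)
        n = np.stack([np.sin(np.deg2rad(phi)) * np.cos(th),
                      np.sin(np.deg2rad(phi)) * np.sin(th),
                      np.cos(np.deg2rad(phi))], axis=1)
        T = n.T @ n / len(n)
        oracle = (3 * np.linalg.eigvalsh(T)[-1] - 1) / 2
        assert oracle == pytest.approx(0.25, abs=1e-12)
        got = orient3d.orientation_index_from_angles(theta, phi)
        assert got == pytest.approx(0.25, abs=1e-9)

    def test_invariant_to_voxel_order(self):
        rng = np.random.default_rng(2)
        theta = rng.uniform(0, 180, 5000)
        phi = np.full(5000, 90.0)
        a = orient3d.orientation_index_from_angles(theta, phi)
        p = rng.permutation(5000)
        b = orient3d.orientation_index_from_angles(theta[p], phi[p])
        assert a == pytest.approx(b, abs=1e-12)

    def test_global_rotation_leaves_index_unchanged(self):
        rng = np.random.default_rng(3)
        theta = rng.vonmises(0.5, 4.0, 3000)
        theta = np.degrees(theta) % 180.0
        phi = np.full(3000, 90.0)
        a = orient3d.orientation_index_from_angles(theta, phi)
        b = orient3d.orientation_index_from_angles((theta + 57.0) % 180.0, phi)
        assert a == pytest.approx(b, abs=1e-9)

    def test_no_valid_voxels_flagged(self):
        stack = hq.VolumeStack({"SHG": np.zeros((4, 64, 64))}, 0.2, 2.0)
        f = orient3d.orientation_field(stack, "SHG", 1.0)
        with pytest.raises(ValueError, match="undefined"):
            orient3d.orientation_index(f)


def synthetic_heatmap(dominant, spread_bins=4, nz=None):
    """Heatmap with a boxcar of weight around per-layer dominant angles."""
    dominant = np.asarray(dominant, dtype=float)
    nz = nz or len(dominant)
    values = np.zeros((nz, 180))
    for k, ang in enumerate(dominant):
        for b in range(-spread_bins, spread_bins + 1):
            values[k, int(round(ang) + b) % 180] = 1.0
        values[k] *= 100.0 / values[k].sum()
    return OrientationHeatmap(np.linspace(0, 180, 181),
                              np.arange(nz) * 2.0, values,
                              np.zeros(nz, dtype=bool))


class TestHeatmapCorrelation:
    def test_self_correlation_exactly_one(self):
        h = synthetic_heatmap(np.linspace(10, 40, 12))
        assert orient3d.heatmap_correlation(h, h) == pytest.approx(1.0)

    def test_affine_complement_anticorrelated(self):
        h = synthetic_heatmap(np.linspace(10, 40, 12))
        comp = OrientationHeatmap(h.bins_deg, h.layers_z_um,
                                  h.values.max() - h.values, h.empty_layers)
        assert orient3d.heatmap_correlation(h, comp) == pytest.approx(-1.0)

    def test_independent_random_maps_near_zero(self):
        rng = np.random.default_rng(4)
        a = OrientationHeatmap(np.linspace(0, 180, 181), np.arange(30) * 2.0,
                               rng.random((30, 180)), np.zeros(30, bool))
        b = OrientationHeatmap(np.linspace(0, 180, 181), np.arange(30) * 2.0,
                               rng.random((30, 180)), np.zeros(30, bool))
        assert abs(orient3d.heatmap_correlation(a, b)) < 0.05

    def test_zero_variance_flagged(self):
        flat = OrientationHeatmap(np.linspace(0, 180, 181), np.arange(4) * 2.0,
                                  np.full((4, 180), 100.0 / 180.0),
                                  np.zeros(4, bool))
        with pytest.warns(UserWarning):
            assert np.isnan(orient3d.heatmap_correlation(flat, flat))

    def test_mismatched_grids_rejected(self):
        a = synthetic_heatmap([10, 20, 30])
        b = synthetic_heatmap([10, 20])
        with pytest.raises(ValueError):
            orient3d.heatmap_correlation(a, b)


class TestRotationRate:
    def test_advancing_one_degree_per_layer(self):
        # 1°/layer at 2 µm steps = 0.5 °/µm
        h = synthetic_heatmap(20.0 + np.arange(15) * 1.0)
        rate, diag = orient3d.rotation_rate(h)
        assert rate == pytest.approx(0.5, rel=0.05)
        assert diag["n_layers_used"] == 15

    def test_constant_angle_zero_rate(self):
        h = synthetic_heatmap(np.full(12, 73.0))
        rate, _ = orient3d.rotation_rate(h)
        assert abs(rate) <= 0.02

    def test_unwrap_across_axial_boundary(self):
        # dominant angle crossing 180° → continues smoothly, not jumping
        h = synthetic_heatmap((170.0 + np.arange(15) * 1.0) % 180.0)
        rate, _ = orient3d.rotation_rate(h)
        assert rate == pytest.approx(0.5, rel=0.05)

    def test_disordered_layers_excluded(self):
        h = synthetic_heatmap(20.0 + np.arange(8) * 1.0)
        h.values[3] = 100.0 / 180.0  # uniform layer: circular variance ~1
        rate, diag = orient3d.rotation_rate(h)
        assert diag["n_layers_used"] == 7
        assert rate == pytest.approx(0.5, rel=0.05)

    def test_too_few_layers_undefined(self):
        h = synthetic_heatmap([10.0, 11.0])
        rate, _ = orient3d.rotation_rate(h)
        assert np.isnan(rate)
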