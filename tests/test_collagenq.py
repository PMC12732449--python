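"""Collagen amount and fiber diametry."""

import numpy as np
import pytest

import hhgm_quant as hq
from hhgm_quant import collagenq
from hhgm_quant.collagenq import FiberSite
from hhgm_quant.synthstack import FWHM_TO_SIGMA, FiberSpec, render_fibers


def make_stack(arr, voxel_xy=0.2, voxel_z=2.0):
    return hq.VolumeStack({"SHG": arr}, voxel_xy, voxel_z)


class TestPixelCount:
    def test_zero_channel(self):
        counts = collagenq.collagen_pixel_count(
            make_stack(np.zeros((3, 16, 16))), 0.0)
        assert counts["total"] == 0

    def test_exact_count_by_construction(self):
        arr = np.zeros((2, 32, 32))
        arr[0, :5, :7] = 10.0  # 35 pixels
        arr[1, 0, :8] = 10.0   # 8 pixels
        counts = collagenq.collagen_pixel_count(make_stack(arr), 5.0)
        assert list(counts["per_layer"]) == [35, 8]
        assert counts["total"] == 43

    def test_strict_inequality(self):
        arr = np.full((1, 8, 8), 5.0)
        assert collagenq.collagen_pixel_count(make_stack(arr), 5.0)["total"] == 0

    def test_monotone_in_threshold(self, fiber_stack):
        stack, _ = fiber_stack
        totals = [collagenq.collagen_pixel_count(stack, t)["total"]
                  for t in np.linspace(0, 60, 10)]
        assert all(a >= b for a, b in zip(totals, totals[1:]))


class TestPerCell:
    def test_ratio_definition(self):
        stack = make_stack(np.zeros((2, 16, 16)))
        shg = {"per_layer": np.array([600, 400])}
        cells = {"per_layer_counts": np.array([10])}
        summary = collagenq.collagen_per_cell(stack, shg, cells)
        assert summary.shg_per_cell == pytest.approx(100.0)

    def test_zero_cells_flagged_not_zero(self):
        stack = make_stack(np.zeros((2, 16, 16)))
        shg = {"per_layer": np.array([600, 400])}
        cells = {"per_layer_counts": np.array([0])}
        with pytest.warns(UserWarning, match="undefined"):
            summary = collagenq.collagen_per_cell(stack, shg, cells)
        assert np.isnan(summary.shg_per_cell)

    def test_homogeneity(self):
        stack = make_stack(np.zeros((2, 16, 16)))
        s1 = collagenq.collagen_per_cell(
            stack, {"per_layer": np.array([500, 500])},
            {"per_layer_counts": np.array([5])})
        s2 = collagenq.collagen_per_cell(
            stack, {"per_layer": np.array([1000, 1000])},
            {"per_layer_counts": np.array([10])})
        assert s1.shg_per_cell == pytest.approx(s2.shg_per_cell)

    def test_mismatched_grids_rejected(self):
        stack = make_stack(np.zeros((2, 16, 16)))
        with pytest.raises(ValueError, match="grids"):
            collagenq.collagen_per_cell(
                stack, {"per_layer": np.array([1, 2])},
                {"per_layer_counts": np.array([1, 2, 3])})


class TestSiteTracing:
    def test_blank_layer_empty(self):
        assert collagenq.trace_fiber_sites(np.zeros((64, 64)), 1.0) == []

    def test_straight_fiber_tangents(self):
        theta = 30.0
        th = np.deg2rad(theta)
        d = np.array([0.0, -np.sin(th), np.cos(th)])
        ctr = np.array([0.0, 12.8, 12.8])
        spec = FiberSpec(np.stack([ctr - 30 * d, ctr + 30 * d]), 1.0, 50.0,
                         theta)
        vol = render_fibers([spec], (1, 128, 128), 0.2, 2.0)
        sites = collagenq.trace_fiber_sites(vol[0], 10.0, n_sites=6,
                                            min_separation_um=3.0,
                                            voxel_xy=0.2, seed=0)
        assert len(sites) >= 3
        for s in sites:
            diff = abs(s.tangent_deg - theta) % 180.0
            assert min(diff, 180.0 - diff) <= 5.0

    def test_no_site_near_crossing(self):
        specs = []
        for theta in (0.0, 90.0):
            th = np.deg2rad(theta)
            d = np.array([0.0, -np.sin(th), np.cos(th)])
            ctr = np.array([0.0, 12.8, 12.8])
            specs.append(FiberSpec(np.stack([ctr - 30 * d, ctr + 30 * d]),
                                   1.0, 50.0, theta))
        vol = render_fibers(specs, (1, 128, 128), 0.2, 2.0)
        sites = collagenq.trace_fiber_sites(vol[0], 10.0, n_sites=20,
                                            min_separation_um=2.0,
                                            voxel_xy=0.2,
                                            expected_fwhm_um=1.0, seed=0)
        crossing = np.array([12.8 / 0.2, 12.8 / 0.2])
        for s in sites:
            dist_um = np.hypot(s.y_px - crossing[0], s.x_px - crossing[1]) * 0.2
            assert dist_um > 1.0


class TestDiameterFit:
    def test_closed_form_gaussian_profile(self):
        # σ = 2 px = 0.4 µm → FWHM = 2.3548 × 0.4 = 0.9419 µm
        yy, xx = np.mgrid[0:64, 0:64].astype(float)
        img = 30.0 * np.exp(-((yy - 32) ** 2) / (2 * 2.0**2))
        site = FiberSite(0, 32.0, 32.0, 0.0)  # tangent along x
        m = collagenq.measure_fiber_diameter(img, site, voxel_xy=0.2)
        assert m.accepted
        assert m.fwhm_um == pytest.approx(FWHM_TO_SIGMA * 0.4, rel=0.01)
        assert m.fwhm_um == pytest.approx(FWHM_TO_SIGMA * m.sigma_um, rel=1e-9)
        assert 0 <= m.r_squared <= 1

    def test_rendered_fiber_recovered_noiseless(self):
        spec = FiberSpec(np.array([[0.0, 12.8, -5.0], [0.0, 12.8, 60.0]]),
                         1.0, 50.0, 0.0)
        vol = render_fibers([spec], (1, 128, 128), 0.2, 2.0)
        site = FiberSite(0, 64.0, 64.0, 0.0)
        m = collagenq.measure_fiber_diameter(vol[0], site, voxel_xy=0.2)
        assert m.accepted
        assert m.fwhm_um == pytest.approx(1.0, rel=0.05)

    def test_flat_profile_rejected(self):
        m = collagenq.measure_fiber_diameter(
            np.full((32, 32), 4.0), FiberSite(0, 16.0, 16.0, 0.0), 0.2)
        assert not m.accepted
        assert "flat" in m.reason


class TestDedup:
    def _meas(self, z, y, x, amp, fwhm=1.0):
        return collagenq.FiberDiameterMeasurement(
            (z, y, x), np.zeros(3), np.zeros(3), amp, 0.0,
            fwhm / FWHM_TO_SIGMA, 0.0, fwhm, 0.95, accepted=True)

    def test_adjacent_duplicate_keeps_stronger(self):
        kept = collagenq.adjacent_layer_dedup(
            [self._meas(0.0, 10.0, 10.0, 10.0),
             self._meas(2.0, 10.2, 10.1, 8.0)], voxel_z=2.0)
        assert len(kept) == 1
        assert kept[0].amplitude == 10.0

    def test_distant_sites_both_kept(self):
        kept = collagenq.adjacent_layer_dedup(
            [self._meas(0.0, 10.0, 10.0, 10.0),
             self._meas(2.0, 10.0, 20.0, 8.0)], voxel_z=2.0)
        assert len(kept) == 2

    def test_three_layer_chain_single_survivor(self):
        kept = collagenq.adjacent_layer_dedup(
            [self._meas(0.0, 10.0, 10.0, 9.0),
             self._meas(2.0, 10.3, 10.0, 11.0),
             self._meas(4.0, 10.6, 10.0, 10.0)], voxel_z=2.0)
        assert len(kept) == 1
        assert kept[0].amplitude == 11.0
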