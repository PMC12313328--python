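"""Ellipse fits, filters, region partition, slopes, moments, sequences."""

import math

import numpy as np
import pytest
from scipy import ndimage

from undulate.channel import ChannelGeometry, cavity_zero_crossing
from undulate.data import Detection
from undulate.features import (EXTENDED_FEATURE_NAMES, SEQUENCE_LENGTH,
                               ShapeSeries, apply_filters,
                               convex_hull_ratio, derive_feature_vector,
                               fit_ellipse, fit_slope, mask_perimeter,
                               partition_regions, prepare_mask_sequences,
                               prepare_sequences, relative_deformability,
                               shape_moments, shape_series)
from undulate.simulate import (AcquisitionConfig, crescent_patch,
                               generate_dataset)
from undulate.tracking import track_dataset
from .conftest import make_cell


def disc_mask(radius, size=None, center=None):
    size = size or int(2 * radius + 7)
    cy = cx = (size - 1) / 2 if center is None else None
    if center is not None:
        cy, cx = center
    yy, xx = np.mgrid[:size, :size]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2


def ellipse_mask(a, b, angle=0.0, size=None):
    size = size or int(2 * max(a, b) + 9)
    c = (size - 1) / 2
    yy, xx = np.mgrid[:size, :size]
    ct, st = math.cos(angle), math.sin(angle)
    u = (xx - c) * ct + (yy - c) * st
    v = -(xx - c) * st + (yy - c) * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


class TestFitEllipse:
    def test_disc_has_unit_aspect_ratio(self):
        fit = fit_ellipse(disc_mask(30))
        assert fit.ar == pytest.approx(1.0, abs=0.01)

    def test_axis_aligned_two_to_one_ellipse(self):
        fit = fit_ellipse(ellipse_mask(26, 13))
        assert fit.ar == pytest.approx(2.0, rel=0.02)
        # oracle: brute-force second moments of the raster
        mask = ellipse_mask(26, 13)
        yy, xx = np.nonzero(mask)
        expect = math.sqrt(((xx - xx.mean()) ** 2).mean()
                           / ((yy - yy.mean()) ** 2).mean())
        assert fit.ar == pytest.approx(expect, rel=1e-12)

    def test_rotation_by_90_degrees_inverts_ar(self):
        fit = fit_ellipse(ellipse_mask(26, 13, angle=math.pi / 2))
        assert fit.ar == pytest.approx(0.5, rel=0.02)

    def test_empty_and_multicomponent_masks_rejected(self):
        with pytest.raises(ValueError):
            fit_ellipse(np.zeros((5, 5), bool))
        two = np.zeros((9, 9), bool)
        two[1, 1] = two[7, 7] = True
        with pytest.raises(ValueError, match="components"):
            fit_ellipse(two)

    def test_render_fit_roundtrip_recovers_axes(self):
        acq = AcquisitionConfig(pixel_size=1.0, frame_shape=(120, 240),
                                x_origin=0.0)
        from undulate.simulate import TrueState, render_patch
        for a, b in [(26, 13), (12, 18), (8, 8)]:
            d = a / b
            st = TrueState(t=0, x=120.0, d_true=d, a=float(a), b=float(b))
            patch, _ = render_patch(st, acq)
            fit = fit_ellipse(patch, 1.0)
            assert fit.a == pytest.approx(a, rel=0.02)
            assert fit.b == pytest.approx(b, rel=0.02)


class TestConvexHullRatio:
    def test_disc_is_convex(self):
        assert convex_hull_ratio(disc_mask(20)) == pytest.approx(1.0,
                                                                 abs=0.01)

    def test_single_pixel(self):
        one = np.zeros((5, 5), bool)
        one[2, 2] = True
        assert convex_hull_ratio(one) == 1.0

    def test_crescent_matches_pixel_count_oracle(self):
        from skimage.morphology import convex_hull_image
        mask = crescent_patch(24.0, bite_scale=0.8)
        expect = convex_hull_image(
            mask, offset_coordinates=False).sum() / mask.sum()
        assert expect > 1.1   # a usable segmentation-failure fixture
        assert convex_hull_ratio(mask) == pytest.approx(expect, rel=1e-9)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            convex_hull_ratio(np.zeros((4, 4), bool))


def _series_from_masks(masks, xs, cell_id=0, pixel_size=1.0):
    dets = [Detection(frame_index=i, mask=m, offset=(0, 0),
                      centroid=(float(x), 0.0),
                      area=float(np.sum(m) * pixel_size ** 2))
            for i, (m, x) in enumerate(zip(masks, xs))]
    from undulate.tracking import Trajectory
    return shape_series(Trajectory(cell_id=cell_id, detections=dets),
                        pixel_size)


class TestApplyFilters:
    def _clean_series(self, cell_id, radius=10.0):
        xs = np.linspace(-35, 175, 12)
        masks = [disc_mask(radius) for _ in xs]
        return _series_from_masks(masks, xs, cell_id=cell_id)

    def test_constructed_fixture_counts(self):
        series = [self._clean_series(i) for i in range(9)]
        # two trajectories with one crescent frame each
        for i in (9, 10):
            xs = np.linspace(-35, 175, 12)
            masks = [disc_mask(10.0) for _ in xs]
            masks[5] = crescent_patch(10.0, bite_scale=0.9)
            series.append(_series_from_masks(masks, xs, cell_id=i))
        # one radius outlier (well past 3 SD of the remaining spread)
        series.append(self._clean_series(11, radius=17.0))
        report = apply_filters(series)
        assert len(report.kept) == 9
        reasons = sorted(r for _, r in report.discarded)
        assert reasons == ["hull ratio", "hull ratio", "radius outlier"]
        assert report.counts == {"kept": 9, "hull ratio": 2,
                                 "radius outlier": 1}

    def test_all_clean_kept(self):
        series = [self._clean_series(i) for i in range(5)]
        report = apply_filters(series)
        assert len(report.kept) == 5 and not report.discarded

    def test_hull_ratio_exactly_at_threshold_kept(self):
        series = [self._clean_series(0)]
        report = apply_filters(series, hull_threshold=1.0)
        # convex disc has ratio within rounding of 1.0; strict > applies
        assert len(report.kept) == 1

    def test_order_independent(self):
        series = [self._clean_series(i, radius=10 + 0.1 * i)
                  for i in range(8)]
        ids_fwd = {s.cell_id for s in apply_filters(series).kept}
        ids_rev = {s.cell_id for s in apply_filters(series[::-1]).kept}
        assert ids_fwd == ids_rev


@pytest.fixture(scope="module")
def default_series(geometry, acquisition):
    cell = make_cell(boundary_noise_sd=0.0)
    dataset = generate_dataset([cell], geometry, acquisition)
    kept, _ = track_dataset(dataset.detections, geometry)
    series = shape_series(kept[0], acquisition.pixel_size)
    partition_regions(series, geometry)
    return series


class TestPartitionAndDeformability:
    def test_cell_relaxed_at_stress_zero_crossing(self, geometry,
                                                  default_series):
        # noiseless default trace: measured AR is within 0.02 of 1 (a
        # sphere) right at the dv/dx zero crossing, and the cavity AR
        # minimum used as the rD baseline sits inside the cavity
        s = default_series
        zc = cavity_zero_crossing(geometry)
        near = np.abs(s.x - zc) <= 5.0
        assert np.abs(s.ar[near] - 1).min() <= 0.02
        assert 50 <= s.x[s.partition.baseline] < 100

    def test_first_peak_exceeds_second(self, default_series):
        s = default_series
        p = s.partition
        assert s.ar[p.peak1] > s.ar[p.peak2]

    def test_rd_baseline_is_zero(self, default_series):
        s = default_series
        rd, rd1, rd2 = relative_deformability(s)
        cav = (s.x >= 50) & (s.x < 100)
        assert rd[cav].min() == 0.0
        assert rd1 > 0 and rd2 > 0 and rd1 > rd2

    def test_rd1_matches_enumeration_oracle(self, default_series):
        s = default_series
        _, rd1, rd2 = relative_deformability(s)
        cav = (s.x >= 50) & (s.x < 100)
        base = s.ar[cav].min()
        pre = s.x < 50
        assert rd1 == pytest.approx(s.ar[pre].max() - base, abs=1e-12)

    def test_shift_invariance_of_rd(self, default_series):
        s = default_series
        rd, _, _ = relative_deformability(s)
        shifted = ShapeSeries(x=s.x, ar=s.ar + 0.37, area=s.area,
                              perimeter=s.perimeter,
                              detections=s.detections, cell_id=1)
        partition_regions(shifted, ChannelGeometry())
        rd_shift, _, _ = relative_deformability(shifted)
        np.testing.assert_allclose(rd_shift, rd, atol=1e-12)

    def test_monotone_series_flags_degenerate_relaxation(self, geometry):
        xs = np.linspace(-35, 175, 40)
        masks = [disc_mask(10) for _ in xs]
        s = _series_from_masks(masks, xs)
        s.ar = np.linspace(1.0, 2.0, 40)   # artificial monotone trace
        part = partition_regions(s, geometry)
        assert "R2" in part.degenerate

    def test_missing_cavity_coverage_rejected(self, geometry):
        xs = np.linspace(-35, 40, 20)
        masks = [disc_mask(8) for _ in xs]
        s = _series_from_masks(masks, xs)
        with pytest.raises(ValueError):
            partition_regions(s, geometry)


class TestFitSlope:
    def _line_series(self, slope, intercept=1.5, n=20, noise=None,
                     seed=0):
        xs = np.linspace(0, 60, n)
        ar = intercept + slope * xs
        if noise:
            ar = ar + np.random.default_rng(seed).normal(0, noise, n)
        masks = [disc_mask(8) for _ in xs]
        s = _series_from_masks(masks, xs)
        s.ar = ar
        return s

    def test_exact_line_recovered_to_machine_precision(self):
        s = self._line_series(-8.71e-3)
        assert fit_slope(s, 0, 19) == pytest.approx(-8.71e-3, abs=1e-12)

    def test_noisy_line_matches_normal_equations_oracle(self):
        s = self._line_series(9.75e-3, noise=0.05, seed=3)
        x, y = s.x, s.ar
        xc = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(xc.T @ xc, xc.T @ y)
        assert fit_slope(s, 0, 19) == pytest.approx(beta[1], abs=1e-10)

    def test_two_points_exact(self):
        s = self._line_series(0.0, n=2)
        s.ar = np.array([1.0, 1.2])
        assert fit_slope(s, 0, 1) == pytest.approx(
            0.2 / (s.x[1] - s.x[0]), abs=1e-15)

    def test_single_point_rejected(self):
        s = self._line_series(0.0)
        with pytest.raises(ValueError):
            fit_slope(s, 3, 3)


class TestShapeMoments:
    def test_translation_invariance(self):
        m1 = disc_mask(20, size=101, center=(50, 50))
        m2 = disc_mask(20, size=101, center=(33, 59))
        h1 = shape_moments(m1)
        h2 = shape_moments(m2)
        for k in (f"hu{i}" for i in range(1, 8)):
            assert h2[k] == pytest.approx(h1[k], rel=1e-6, abs=1e-12)

    def test_scale_invariance(self):
        h1 = shape_moments(ellipse_mask(60, 36))
        h2 = shape_moments(ellipse_mask(120, 72))
        for i in (1, 2, 3, 4):
            assert h2[f"hu{i}"] == pytest.approx(h1[f"hu{i}"], rel=1e-2,
                                                 abs=1e-10)

    def test_rotation_invariance_against_highres_oracle(self):
        angle = math.radians(37)
        h1 = shape_moments(ellipse_mask(60, 36))
        h2 = shape_moments(ellipse_mask(60, 36, angle=angle))
        for i in (1, 2, 3, 4):
            assert h2[f"hu{i}"] == pytest.approx(h1[f"hu{i}"], rel=1e-2,
                                                 abs=1e-10)


class TestDeriveFeatureVector:
    def test_zero_gain_cell_has_null_features(self, geometry, acquisition):
        cell = make_cell(gain=0.0, boundary_noise_sd=0.0)
        dataset = generate_dataset([cell], geometry, acquisition)
        kept, _ = track_dataset(dataset.detections, geometry)
        s = shape_series(kept[0], acquisition.pixel_size)
        fv = derive_feature_vector(s, geometry)
        # rasterization jitter bounds the residual feature magnitudes
        assert fv.values["rD1"] == pytest.approx(0.0, abs=0.02)
        assert fv.values["rD2"] == pytest.approx(0.0, abs=0.02)
        assert abs(fv.values["R2_slope"]) < 2e-3
        assert abs(fv.values["R3_slope"]) < 2e-3

    def test_larger_tau_gives_shallower_relaxation_slope(self, geometry,
                                                         acquisition):
        mags = []
        for tau in (0.03, 0.09):
            cell = make_cell(tau=tau, boundary_noise_sd=0.0)
            dataset = generate_dataset([cell], geometry, acquisition)
            kept, _ = track_dataset(dataset.detections, geometry)
            s = shape_series(kept[0], acquisition.pixel_size)
            fv = derive_feature_vector(s, geometry)
            mags.append(abs(fv.values["R2_slope"]))
        assert mags[0] > mags[1]

    def test_feature_counts(self, geometry, acquisition):
        cell = make_cell(boundary_noise_sd=0.0)
        dataset = generate_dataset([cell], geometry, acquisition)
        kept, _ = track_dataset(dataset.detections, geometry)
        s = shape_series(kept[0], acquisition.pixel_size)
        assert len(derive_feature_vector(s, geometry).values) == 5
        s2 = shape_series(kept[0], acquisition.pixel_size)
        fv = derive_feature_vector(s2, geometry, extended=True)
        assert len(fv.values) == 35
        assert set(fv.values) == set(EXTENDED_FEATURE_NAMES)


class TestSequencePreparation:
    def _series(self, n, geometry):
        xs = np.linspace(-29, 169, n)
        masks = [disc_mask(8) for _ in xs]
        s = _series_from_masks(masks, xs)
        partition_regions(s, geometry)
        return s

    def test_padding_and_validity_mask(self, geometry):
        seqs, valid, ids = prepare_sequences([self._series(30, geometry)],
                                             geometry)
        assert seqs.shape == (1, SEQUENCE_LENGTH, 4)
        assert valid.sum() == 30
        assert np.all(seqs[0, 30:] == 0.0)

    def test_full_length_sequence_unchanged(self, geometry):
        s = self._series(50, geometry)
        seqs, valid, _ = prepare_sequences([s], geometry)
        assert valid.all()
        np.testing.assert_allclose(seqs[0, :, 0], s.ar)

    def test_too_long_sequence_rejected_by_name(self, geometry):
        s = self._series(55, geometry)
        with pytest.raises(ValueError, match="trajectory 0"):
            prepare_sequences([s], geometry)

    def test_mask_sequence_tensor_contract(self, geometry, acquisition):
        cell = make_cell(boundary_noise_sd=0.0)
        dataset = generate_dataset([cell], geometry, acquisition)
        kept, _ = track_dataset(dataset.detections, geometry)
        s = shape_series(kept[0], acquisition.pixel_size)
        partition_regions(s, geometry)
        tensor, valid, _ = prepare_mask_sequences([s], geometry)
        assert tensor.shape == (1, 50, 96, 96, 2)
        n_valid = int(valid.sum())
        assert np.all(tensor[0, n_valid:] == 0)
        # channel 2 is the rasterized fitted ellipse: high overlap
        ch1 = tensor[0, 0, :, :, 0].astype(bool)
        ch2 = tensor[0, 0, :, :, 1].astype(bool)
        iou = (ch1 & ch2).sum() / (ch1 | ch2).sum()
        assert iou >= 0.95
        # masks are centered: centroid at the crop center
        rows, cols = np.nonzero(ch1)
        assert abs(rows.mean() - 48) < 1.5 and abs(cols.mean() - 48) < 1.5


def test_perimeter_of_disc_close_to_circumference():
    mask = disc_mask(30)
    assert mask_perimeter(mask, 1.0) == pytest.approx(2 * math.pi * 30,
                                                      rel=0.06)
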