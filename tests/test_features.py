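"""Mask construction, histogram features, morphology, normalization."""

import warnings

import numpy as np
import pandas as pd
import pytest
from skimage.draw import disk as draw_disk, polygon as draw_polygon

from stemstate import synth
from stemstate.features import (
    A2_HISTOGRAM_BIN_WIDTH,
    CellMask,
    FeatureFailureError,
    FeatureTable,
    MaskFailureError,
    a2_histogram_features,
    build_mask,
    denormalize_features,
    mean_gray,
    morphology_features,
    normalize_features,
)


def disk_mask(radius, pad=4):
    size = 2 * (radius + pad) + 1
    m = np.zeros((size, size), dtype=bool)
    rr, cc = draw_disk((radius + pad, radius + pad), radius)
    m[rr, cc] = True
    return CellMask(mask=m)


class TestBuildMask:
    def test_uniform_image_fails(self):
        with pytest.raises(MaskFailureError):
            build_mask(np.full((64, 64), 0.3, dtype=np.float32))

    def test_keeps_largest_of_two_blobs(self):
        img = np.zeros((100, 100), dtype=np.float32)
        img[10:60, 10:60] = 0.4  # 2500 px
        img[80:90, 80:90] = 0.4  # 100 px
        mask = build_mask(img)
        assert mask.mask[30, 30] and not mask.mask[85, 85]

    def test_synthetic_cell_iou(self, sparse_field, sparse_detections):
        """Masks built from accepted crops must overlap the rendered cell
        polygon with IoU >= 0.8 (median over detections)."""
        field, gt = sparse_field
        from shapely.geometry import Point, Polygon

        nuclei = [Polygon(r.nucleus_polygon[:, ::-1]) for r in gt.records]
        ious = []
        for det in sparse_detections.detections:
            c = Point(det.second_contour.centroid[1], det.second_contour.centroid[0])
            hits = [i for i, p in enumerate(nuclei) if p.contains(c)]
            if not hits:
                continue
            rec = gt.records[hits[0]]
            top, left, h, w = det.window
            mask = build_mask(field.pixels[top : top + h, left : left + w])
            truth = np.zeros((h, w), dtype=bool)
            rr, cc = draw_polygon(
                rec.cell_polygon[:, 0] - top, rec.cell_polygon[:, 1] - left, shape=(h, w)
            )
            truth[rr, cc] = True
            ious.append((mask.mask & truth).sum() / (mask.mask | truth).sum())
        assert len(ious) >= 40
        assert np.median(ious) >= 0.8


class TestA2Histogram:
    def test_delta_distribution(self):
        crop = np.full((40, 40), 0.30, dtype=np.float32)
        mask = CellMask(mask=np.ones((40, 40), dtype=bool))
        peak, fwhm = a2_histogram_features(crop, mask)
        # float32(0.30) sits an epsilon above the bin edge
        assert abs(peak - 0.30) <= A2_HISTOGRAM_BIN_WIDTH / 2 + 1e-6
        assert fwhm <= A2_HISTOGRAM_BIN_WIDTH + 1e-9

    def test_gaussian_fwhm(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0.2, 0.03, size=10_000).astype(np.float32)
        crop = vals.reshape(100, 100)
        mask = CellMask(mask=np.ones((100, 100), dtype=bool))
        _, fwhm = a2_histogram_features(crop, mask)
        expected = synth.GAUSSIAN_FWHM_FACTOR * 0.03
        assert abs(fwhm - expected) / expected < 0.15

    def test_bimodal_peak_at_taller_mode(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.15, 0.01, size=3000)
        b = rng.normal(0.35, 0.01, size=6000)
        crop = np.concatenate([a, b]).reshape(90, 100).astype(np.float32)
        mask = CellMask(mask=np.ones((90, 100), dtype=bool))
        peak, _ = a2_histogram_features(crop, mask)
        # histogram oracle by direct counting
        counts, edges = np.histogram(crop, bins=100, range=(0, 1))
        oracle = 0.5 * (edges[np.argmax(counts)] + edges[np.argmax(counts) + 1])
        assert peak == pytest.approx(oracle, abs=1e-9)
        assert abs(peak - 0.35) <= A2_HISTOGRAM_BIN_WIDTH / 2 + 1e-6

    def test_too_few_pixels(self):
        crop = np.full((5, 5), 0.3, dtype=np.float32)
        mask = CellMask(mask=np.ones((5, 5), dtype=bool))
        with pytest.raises(FeatureFailureError):
            a2_histogram_features(crop, mask)


class TestMorphology:
    def test_disk_circularity(self):
        area, perimeter, circ = morphology_features(disk_mask(50))
        assert circ >= 0.95
        assert area == pytest.approx(np.pi * 50**2, rel=0.02)

    def test_square_circularity(self):
        m = np.zeros((40, 40), dtype=bool)
        m[5:35, 5:35] = True
        _, _, circ = morphology_features(CellMask(mask=m))
        # the traced 0.5-level contour cuts the four corners slightly
        assert circ == pytest.approx(np.pi / 4, rel=0.05)

    def test_line_has_lowest_circularity(self):
        line = np.zeros((5, 60), dtype=bool)
        line[2, 2:58] = True
        shapes = [
            morphology_features(disk_mask(20))[2],
            morphology_features(CellMask(mask=np.pad(np.ones((20, 20), bool), 2)))[2],
            morphology_features(CellMask(mask=line))[2],
        ]
        assert shapes[2] == min(shapes)

    def test_matches_segment_contour_tracing(self, sparse_field, sparse_detections):
        """Cross-check of the two tracing implementations: pixel-count area
        and numpy polyline perimeter vs shapely geometry on the same traced
        boundary, within 2% (net of interior holes for the area)."""
        field, _ = sparse_field
        from shapely.geometry import Polygon

        checked = 0
        for det in sparse_detections.detections[:20]:
            top, left, h, w = det.window
            mask = build_mask(field.pixels[top : top + h, left : left + w])
            area, perimeter, _ = morphology_features(mask)
            polys = sorted(
                (Polygon(c[:, ::-1]) for c in _mask_contours(mask)),
                key=lambda p: p.area,
                reverse=True,
            )
            outer = polys[0]
            hole_area = sum(p.area for p in polys[1:] if outer.contains(p))
            assert area == pytest.approx(outer.area - hole_area, rel=0.02)
            assert perimeter == pytest.approx(outer.length, rel=0.02)
            checked += 1
        assert checked > 10


def _mask_contours(mask):
    from stemstate._imageops import trace_contours

    return trace_contours(mask.mask)


class TestMeanGray:
    def test_uniform(self):
        crop = np.full((20, 20), 7.0)
        assert mean_gray(crop, CellMask(mask=np.ones((20, 20), bool))) == 7.0

    def test_half_and_half(self):
        crop = np.zeros((10, 10))
        crop[:5] = 10.0
        assert mean_gray(crop, CellMask(mask=np.ones((10, 10), bool))) == 5.0

    def test_matches_rendered_ground_truth(self):
        """Oracle: re-summing the rendered SRS pixels over the true polygon
        must reproduce the generator's recorded per-cell mean."""
        mix = synth.TimepointMixture(1, {"diff": 1.0})
        field, gt = synth.generate_field(512, 512, 5, mix, modality="SRS", seed=8)
        rec = gt.records[0]
        from scipy import ndimage

        m = np.zeros(field.pixels.shape, bool)
        rr, cc = draw_polygon(rec.cell_polygon[:, 0], rec.cell_polygon[:, 1], m.shape)
        m[rr, cc] = True
        body = ndimage.binary_erosion(m, np.ones((3, 3), bool))
        assert field.pixels[body].mean() == pytest.approx(rec.mean_srs, rel=0.02)


class TestNormalization:
    def test_minmax_column(self):
        df = pd.DataFrame({"x": [2.0, 4.0, 6.0]})
        out = normalize_features(FeatureTable(df, ("x",)))
        assert out.normalized
        assert list(out.data["x"]) == [0.0, 0.5, 1.0]

    def test_constant_column_warns_and_zeroes(self):
        df = pd.DataFrame({"x": [3.0, 3.0, 3.0], "y": [1.0, 2.0, 3.0]})
        with pytest.warns(UserWarning, match="constant"):
            out = normalize_features(FeatureTable(df, ("x", "y")))
        assert (out.data["x"] == 0.0).all()

    def test_round_trip(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(30, 3)), columns=["a", "b", "c"])
        table = FeatureTable(df, ("a", "b", "c"))
        back = denormalize_features(normalize_features(table))
        assert np.allclose(back.data[["a", "b", "c"]], df[["a", "b", "c"]], atol=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            normalize_features(FeatureTable(pd.DataFrame({"x": [1.0]}), ("x",)))
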