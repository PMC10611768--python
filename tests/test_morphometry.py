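import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import ndimage as ndi

import woolscale as ws
from woolscale.morphometry import (
    FibreAxis,
    measure_windows,
    skeleton_length_px,
)
from conftest import chain_code_oracle


def _band_image(width_px=40, length_px=600, um_per_px=0.5, margin=15):
    px = np.full((width_px + 2 * margin, length_px), 30.0)
    px[margin : margin + width_px, :] = 128.0
    return ws.FibreImage(pixels=px, um_per_px=um_per_px, id="band")


class TestDetectFibre:
    def test_constant_width_band_exact(self):
        img = _band_image(width_px=40, um_per_px=0.5)
        _, mask, diameter, cv = ws.detect_fibre(img)
        assert diameter == pytest.approx(20.0)
        assert cv == pytest.approx(0.0)
        assert mask.sum() == 40 * 600

    def test_uniform_background_is_no_fibre(self):
        img = ws.FibreImage(pixels=np.full((50, 50), 30.0), um_per_px=0.5)
        with pytest.raises(ValueError, match="no fibre"):
            ws.detect_fibre(img)

    def test_synthetic_diameter_recovered(self, coronal_image):
        img, gt = coronal_image
        _, _, diameter, _ = ws.detect_fibre(img)
        assert diameter == pytest.approx(gt.true_diameter_um, abs=1.0)

    def test_fragment_warning(self):
        px = np.full((60, 60), 30.0)
        px[25:35, 10:50] = 128.0  # band not reaching any frame edge
        with pytest.warns(UserWarning, match="fragment"):
            ws.detect_fibre(ws.FibreImage(pixels=px, um_per_px=1.0))


class TestSegmentScaleEdges:
    def test_component_count_matches_drawn_arcs(self, coronal_image):
        img, _ = coronal_image
        _, mask, _, _ = ws.detect_fibre(img)
        skel = ws.segment_scale_edges(img, mask)
        _, n = ndi.label(skel, structure=np.ones((3, 3)))
        assert n == 31  # arcs drawn at 100/6 um spacing over 520 um

    def test_no_boundaries_gives_empty_skeleton(self):
        img = _band_image()
        _, mask, _, _ = ws.detect_fibre(img)
        skel = ws.segment_scale_edges(img, mask)
        assert not skel.any()

    def test_straight_chord_length(self):
        # one vertical drawn chord: skeleton length within 1 px sqrt(2) of truth
        img = _band_image(width_px=50, um_per_px=0.4)
        px = img.pixels.copy()
        px[15:65, 300] = 255.0
        img = ws.FibreImage(pixels=px, um_per_px=0.4)
        _, mask, _, _ = ws.detect_fibre(img)
        skel = ws.segment_scale_edges(img, mask)
        length_um = skeleton_length_px(skel) * img.um_per_px
        assert abs(length_um - 50 * 0.4) <= np.sqrt(2) * 0.4


class TestChainCodeLength:
    def test_empty(self):
        assert skeleton_length_px(np.zeros((5, 5), dtype=bool)) == 0.0

    def test_straight_and_diagonal(self):
        s = np.zeros((8, 8), dtype=bool)
        s[2, 1:6] = True  # 4 horizontal steps
        assert skeleton_length_px(s) == pytest.approx(4.0)
        s = np.eye(6, dtype=bool)
        assert skeleton_length_px(s) == pytest.approx(5 * np.sqrt(2))

    def test_corner_shortcut_not_double_counted(self):
        # L-corner: two unit steps, no extra diagonal
        s = np.zeros((3, 3), dtype=bool)
        s[0, 0] = s[1, 0] = s[1, 1] = True
        assert skeleton_length_px(s) == pytest.approx(2.0)
        assert chain_code_oracle(s) == pytest.approx(2.0)

    @settings(max_examples=80, deadline=None)
    @given(arrays(bool, (12, 12), elements=st.booleans()))
    def test_matches_bruteforce_oracle(self, raster):
        assert skeleton_length_px(raster) == pytest.approx(chain_code_oracle(raster))


class TestMeasureWindows:
    def _horizontal_axis(self, shape):
        return FibreAxis(
            centroid_rc=((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0),
            direction_rc=(0.0, 1.0),
            length_px=float(shape[1]),
        )

    def test_five_full_two_cut_regions_count_six(self):
        # scale boundaries at columns splitting window [100, 200) into 5
        # interior regions; the regions crossing 100 and 200 each add 0.5
        mask = np.zeros((10, 300), dtype=bool)
        mask[:, :] = True
        skel = np.zeros_like(mask)
        for col in (110, 125, 140, 155, 170, 185):
            skel[:, col] = True
        wins = measure_windows(skel, self._horizontal_axis(mask.shape), mask, 1.0)
        assert len(wins) == 3
        assert wins[1].full_scales == 5
        assert wins[1].partial_scales == 2
        assert wins[1].scale_count == 6.0

    def test_empty_skeleton_zero_perimeter_single_region(self):
        mask = np.ones((10, 250), dtype=bool)
        skel = np.zeros_like(mask)
        wins = measure_windows(skel, self._horizontal_axis(mask.shape), mask, 1.0)
        assert all(w.perimeter_um == 0.0 for w in wins)
        # the single region is cut by every window boundary: 0.5 each
        assert all(w.scale_count == 0.5 for w in wins)

    def test_too_short_errors(self):
        mask = np.ones((10, 50), dtype=bool)
        with pytest.raises(ValueError, match="too short"):
            measure_windows(
                np.zeros_like(mask), self._horizontal_axis(mask.shape), mask, 1.0
            )

    def test_window_geometry(self):
        mask = np.ones((10, 250), dtype=bool)
        wins = measure_windows(
            np.zeros_like(mask), self._horizontal_axis(mask.shape), mask, 1.0
        )
        for w in wins:
            assert w.end_um - w.start_um == pytest.approx(100.0)


class TestComputeSpi:
    def test_welsh_mountain_value(self):
        assert round(ws.compute_spi(542.0, 36.0), 1) == 15.1

    def test_zero_perimeter(self):
        assert ws.compute_spi(0.0, 55.0) == 0.0

    def test_dartmoor_band(self):
        spi = ws.compute_spi(754.0, 72.0)
        assert spi == pytest.approx(10.47, abs=0.01)
        assert 6 <= spi <= 11

    def test_nonpositive_diameter_errors(self):
        with pytest.raises(ValueError):
            ws.compute_spi(500.0, 0.0)

    @given(
        p=st.floats(0.0, 1e4),
        d=st.floats(1e-3, 1e3),
        c=st.floats(1e-3, 1e3),
    )
    def test_scale_invariance(self, p, d, c):
        assert ws.compute_spi(c * p, c * d) == pytest.approx(ws.compute_spi(p, d))


class TestClassifyPattern:
    @pytest.mark.parametrize(
        "diameter, expected",
        [
            (22.0, ws.ScalePattern.CORONAL),
            (36.0, ws.ScalePattern.CORONAL_RETICULATE),
            (72.0, ws.ScalePattern.RETICULATE),
            (25.0, ws.ScalePattern.CORONAL_RETICULATE),  # closed interval
            (50.0, ws.ScalePattern.CORONAL_RETICULATE),
            (24.999, ws.ScalePattern.CORONAL),
            (50.001, ws.ScalePattern.RETICULATE),
        ],
    )
    def test_thresholds(self, diameter, expected):
        assert ws.classify_pattern(diameter) is expected

    def test_nonpositive_errors(self):
        with pytest.raises(ValueError):
            ws.classify_pattern(0.0)


class TestGroundTruthRecovery:
    def test_batch_median_perimeter_error(self):
        # small noise-free batch across patterns; the full 20-image batch runs
        # in the acceptance suite
        rng_specs = [
            ws.ImageSpec(diameter_um=22, pattern=ws.ScalePattern.CORONAL,
                         scales_per_100um=6, seed=1),
            ws.ImageSpec(diameter_um=31, pattern=ws.ScalePattern.CORONAL_RETICULATE,
                         scales_per_100um=8, seed=2),
            ws.ImageSpec(diameter_um=45, pattern=ws.ScalePattern.CORONAL_RETICULATE,
                         scales_per_100um=10, seed=3),
            ws.ImageSpec(diameter_um=60, pattern=ws.ScalePattern.RETICULATE,
                         scales_per_100um=13, seed=4),
            ws.ImageSpec(diameter_um=72, pattern=ws.ScalePattern.RETICULATE,
                         scales_per_100um=16, seed=5),
        ]
        rel_errors, diam_errors = [], []
        for spec in rng_specs:
            img, gt = ws.generate_fibre_image(spec)
            m = ws.measure_fibre(img)
            truth = np.mean(gt.boundary_length_per_window)
            rel_errors.append(abs(m.total_perimeter_per_100um - truth) / truth)
            diam_errors.append(abs(m.diameter_um - gt.true_diameter_um))
        assert np.median(rel_errors) <= 0.05
        assert max(diam_errors) <= 1 * 0.2  # 1 px at 0.2 um/px

    def test_monotone_in_scale_density(self):
        perims = []
        for s in (4.0, 6.0, 8.0):
            spec = ws.ImageSpec(
                diameter_um=30, pattern=ws.ScalePattern.CORONAL,
                scales_per_100um=s, seed=0,
            )
            img, _ = ws.generate_fibre_image(spec)
            perims.append(ws.measure_fibre(img).total_perimeter_per_100um)
        assert perims[0] < perims[1] < perims[2]

    def test_measurement_consistency(self, reticulate_image):
        img, gt = reticulate_image
        m = ws.measure_fibre(img)
        assert m.spi == pytest.approx(
            m.total_perimeter_per_100um / m.diameter_um, rel=1e-9
        )
        assert np.mean([w.scale_count for w in m.windows]) == pytest.approx(
            np.mean(gt.scale_count_per_window), abs=1.0
        )
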