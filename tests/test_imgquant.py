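"""Segmentation, ring construction and N/C ratio against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mechanoquant import imgquant, synthgen
from mechanoquant.containers import ChannelImage, LabelMask


def disk_image(shape=(128, 128), center=(64, 64), r=20, inside=250.0, outside=10.0):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    img = np.full(shape, outside)
    img[(yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= r**2] = inside
    return ChannelImage(img, 0.1, "dapi")


class TestSegmentNuclei:
    def test_single_disk_area_within_5pct(self):
        seg = imgquant.segment_nuclei(disk_image())
        assert seg.n_labels == 1
        area = (seg.labels == 1).sum()
        assert abs(area - np.pi * 400) / (np.pi * 400) < 0.05

    def test_blank_image_yields_no_labels(self):
        blank = ChannelImage(np.full((64, 64), 7.0), 0.1)
        assert imgquant.segment_nuclei(blank).n_labels == 0

    def test_two_separated_disks_two_labels(self):
        yy, xx = np.mgrid[0:128, 0:128]
        img = np.full((128, 128), 10.0)
        img[(yy - 40) ** 2 + (xx - 40) ** 2 <= 15**2] = 250
        img[(yy - 90) ** 2 + (xx - 90) ** 2 <= 15**2] = 250
        seg = imgquant.segment_nuclei(ChannelImage(img, 0.1))
        assert seg.n_labels == 2

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            imgquant.SegmentationParams(low_quantile=0.9, high_quantile=0.5)

    def test_area_monotone_in_high_threshold(self):
        # absolute hysteresis thresholds: stricter edge acceptance never
        # grows the segmented nucleus
        img = disk_image()
        areas = []
        for hi in (0.3, 0.5, 0.7):
            p = imgquant.SegmentationParams(low_threshold=0.1, high_threshold=hi)
            seg = imgquant.segment_nuclei(img, p)
            areas.append((seg.labels > 0).sum())
        assert areas[0] >= areas[1] >= areas[2]


class TestRingMask:
    def brute_force_ring(self, nuclei: LabelMask, width: int) -> np.ndarray:
        """Pixel-enumeration oracle: nearest-nucleus ring assignment."""
        lab = nuclei.labels
        h, w = lab.shape
        out = np.zeros_like(lab)
        nuc_px = {k: np.argwhere(lab == k) for k in range(1, nuclei.n_labels + 1)}
        for y in range(h):
            for x in range(w):
                if lab[y, x] != 0:
                    continue
                best, bestd = 0, np.inf
                for k, pts in nuc_px.items():
                    d = np.sqrt(((pts - (y, x)) ** 2).sum(axis=1)).min()
                    if d < bestd:
                        best, bestd = k, d
                if bestd <= width:
                    out[y, x] = best
        return out

    def test_single_disk_ring_matches_enumeration(self):
        yy, xx = np.mgrid[0:64, 0:64]
        lab = (((yy - 32) ** 2 + (xx - 32) ** 2) <= 12**2).astype(np.int32)
        nuclei = LabelMask(lab, 0.1)
        rings = imgquant.ring_mask(nuclei, width_px=5)
        oracle = self.brute_force_ring(nuclei, 5)
        np.testing.assert_array_equal(rings.labels, oracle)

    def test_two_close_disks_no_double_counting(self):
        yy, xx = np.mgrid[0:80, 0:80]
        lab = np.zeros((80, 80), np.int32)
        lab[((yy - 40) ** 2 + (xx - 30) ** 2) <= 10**2] = 1
        lab[((yy - 40) ** 2 + (xx - 56) ** 2) <= 10**2] = 2
        rings = imgquant.ring_mask(LabelMask(lab, 0.1), width_px=5)
        oracle = self.brute_force_ring(LabelMask(lab, 0.1), 5)
        np.testing.assert_array_equal(rings.labels, oracle)
        assert ((rings.labels > 0) & (lab > 0)).sum() == 0

    def test_zero_width_rejected(self):
        nuclei = LabelMask(np.zeros((16, 16), np.int32), 0.1)
        with pytest.raises(ValueError):
            imgquant.ring_mask(nuclei, width_px=0)

    def test_corner_nucleus_ring_clipped(self):
        yy, xx = np.mgrid[0:64, 0:64]
        corner = LabelMask((((yy) ** 2 + (xx) ** 2) <= 12**2).astype(np.int32), 0.1)
        interior = LabelMask((((yy - 32) ** 2 + (xx - 32) ** 2) <= 12**2).astype(np.int32), 0.1)
        r_corner = (imgquant.ring_mask(corner, 5).labels > 0).sum()
        r_interior = (imgquant.ring_mask(interior, 5).labels > 0).sum()
        assert r_corner < r_interior

    def test_empty_input_empty_output(self):
        nuclei = LabelMask(np.zeros((16, 16), np.int32), 0.1)
        assert imgquant.ring_mask(nuclei, 5).n_labels == 0


class TestNcRatio:
    def test_uniform_stain_ratio_one(self, nc_scene_noisy):
        dapi, stain, actin, gt = nc_scene_noisy
        nuclei = gt.nuclei_mask()
        rings = imgquant.ring_mask(nuclei, 5)
        uniform = ChannelImage(np.full(nuclei.shape, 37.0), 0.1)
        for rec in imgquant.nc_ratio(uniform, nuclei, rings):
            if not rec.excluded:
                assert rec.nc_ratio == pytest.approx(1.0, abs=1e-12)

    def test_piecewise_constant_ratio_exact(self, nc_scene_clean):
        dapi, stain, actin, gt = nc_scene_clean
        nuclei = gt.nuclei_mask()
        rings = imgquant.ring_mask(nuclei, 5)
        recs = imgquant.nc_ratio(stain, nuclei, rings)
        assert recs[0].nc_ratio == 2.0

    def test_noisy_scene_matches_mask_enumeration_oracle(self, nc_scene_noisy):
        dapi, stain, actin, gt = nc_scene_noisy
        seg = imgquant.segment_nuclei(dapi)
        rings = imgquant.ring_mask(seg, 5)
        for rec in imgquant.nc_ratio(stain, seg, rings):
            if rec.excluded:
                continue
            oracle = (
                stain.pixels[seg.labels == rec.cell_id].mean()
                / stain.pixels[rings.labels == rec.cell_id].mean()
            )
            assert rec.nc_ratio == pytest.approx(oracle, abs=1e-9)

    def test_zero_ring_signal_excluded_not_crash(self):
        yy, xx = np.mgrid[0:64, 0:64]
        lab = (((yy - 32) ** 2 + (xx - 32) ** 2) <= 10**2).astype(np.int32)
        nuclei = LabelMask(lab, 0.1)
        rings = imgquant.ring_mask(nuclei, 5)
        stain = np.zeros((64, 64))
        stain[lab == 1] = 50.0
        recs = imgquant.nc_ratio(ChannelImage(stain, 0.1), nuclei, rings)
        assert recs[0].excluded and recs[0].reason == "zero cytoplasmic signal"

    def test_border_nucleus_flagged(self):
        yy, xx = np.mgrid[0:64, 0:64]
        lab = (((yy - 2) ** 2 + (xx - 32) ** 2) <= 10**2).astype(np.int32)
        nuclei = LabelMask(lab, 0.1)
        rings = imgquant.ring_mask(nuclei, 5)
        recs = imgquant.nc_ratio(ChannelImage(np.full((64, 64), 5.0), 0.1), nuclei, rings)
        assert recs[0].excluded and "border" in recs[0].reason

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(gain=st.floats(min_value=0.01, max_value=100.0))
    def test_gain_invariance(self, gain):
        yy, xx = np.mgrid[0:64, 0:64]
        lab = (((yy - 32) ** 2 + (xx - 32) ** 2) <= 10**2).astype(np.int32)
        nuclei = LabelMask(lab, 0.1)
        rings = imgquant.ring_mask(nuclei, 5)
        rng = np.random.default_rng(0)
        stain = rng.uniform(10, 100, size=(64, 64))
        r1 = imgquant.nc_ratio(ChannelImage(stain, 0.1), nuclei, rings)[0].nc_ratio
        r2 = imgquant.nc_ratio(ChannelImage(stain * gain, 0.1), nuclei, rings)[0].nc_ratio
        assert r2 == pytest.approx(r1, rel=1e-9)


class TestCellArea:
    def test_square_area_exact(self):
        img = np.zeros((200, 200))
        img[50:150, 50:150] = 100.0
        mask, areas = imgquant.cell_area(ChannelImage(img, 0.1), threshold=50.0)
        assert areas == [pytest.approx(100.0)]

    def test_blank_image_empty(self):
        mask, areas = imgquant.cell_area(ChannelImage(np.full((64, 64), 3.0), 0.1))
        assert areas == [] and mask.n_labels == 0

    def test_two_blobs_match_flood_fill_oracle(self):
        rng = np.random.default_rng(1)
        img = np.full((128, 128), 5.0) + rng.normal(0, 1, (128, 128)).clip(-4, 4)
        yy, xx = np.mgrid[0:128, 0:128]
        img[(yy - 40) ** 2 + (xx - 40) ** 2 <= 14**2] = 120
        img[(yy - 90) ** 2 + (xx - 95) ** 2 <= 20**2] = 150
        mask, areas = imgquant.cell_area(ChannelImage(img.clip(0), 0.1), threshold=60.0)

        # independent BFS flood fill on the same thresholded foreground
        fg = img > 60.0
        seen = np.zeros_like(fg)
        oracle_areas = []
        for sy, sx in np.argwhere(fg):
            if seen[sy, sx]:
                continue
            stack, count = [(sy, sx)], 0
            seen[sy, sx] = True
            while stack:
                y, x = stack.pop()
                count += 1
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < 128 and 0 <= nx < 128 and fg[ny, nx] and not seen[ny, nx]:
                            seen[ny, nx] = True
                            stack.append((ny, nx))
            if count >= 100:
                oracle_areas.append(count * 0.01)
        assert sorted(areas) == pytest.approx(sorted(oracle_areas))
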