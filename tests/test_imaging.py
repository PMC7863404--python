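"""Imaging: nucleus segmentation, cell classification, GFP scoring,
envelope profiles, TIFF round-trip."""

import numpy as np
import pytest

from cochleaquant.cochleomap import CochleaPolyline
from cochleaquant.imaging import (CellDetection, ControlStats, ImageStack,
                                  NucleusSegment, RowGeometry, classify_cells,
                                  control_stats, envelope_profile,
                                  gfp_quantify, load_stack, save_stack,
                                  segment_nuclei)


def ball_stack(centers, radius=2.2, amp=100.0, shape=(60, 60, 60),
               voxel=(0.25, 0.25, 0.25), noise_sd=0.0, seed=0,
               channel="DAPI"):
    """Soft-edged spheres at the given (x, y, z) µm centers."""
    img = np.zeros(shape, dtype=np.float32)
    dz, dy, dx = voxel[2], voxel[1], voxel[0]
    zz = np.arange(shape[0]) * dz
    yy = np.arange(shape[1]) * dy
    xx = np.arange(shape[2]) * dx
    for cx, cy, cz in centers:
        d = np.sqrt((zz[:, None, None] - cz) ** 2 + (yy[None, :, None] - cy) ** 2
                    + (xx[None, None, :] - cx) ** 2)
        img += amp * np.clip((radius - d) / 0.5 + 0.5, 0, 1)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = np.clip(img + rng.normal(0, noise_sd, shape).astype(np.float32),
                      0, None)
    return ImageStack(channels={channel: img}, voxel_size=voxel)


class TestSegmentNuclei:
    def test_five_disjoint_spheres_at_snr_20(self):
        centers = [(4, 4, 4), (11, 4, 4), (4, 11, 4), (11, 11, 4), (7.5, 7.5, 11)]
        stack = ball_stack(centers, noise_sd=5.0)  # SNR 20
        segs = segment_nuclei(stack)
        assert len(segs) == 5
        got = sorted(tuple(np.round(s.centroid_um, 1)) for s in segs)
        want = sorted(tuple(map(float, c)) for c in centers)
        for g, w in zip(got, want):
            assert np.linalg.norm(np.subtract(g, w)) < 0.25  # < 1 voxel

    def test_all_zero_channel_no_segments(self):
        stack = ImageStack(channels={"DAPI": np.zeros((20, 20, 20))},
                           voxel_size=(0.25, 0.25, 0.25))
        assert segment_nuclei(stack) == []

    def test_missing_channel_rejected(self):
        stack = ball_stack([(5, 5, 5)])
        with pytest.raises(KeyError):
            segment_nuclei(stack, channel="GFP")

    def test_overlapping_spheres_split_by_watershed(self):
        r = 2.2
        centers = [(6.0, 7.5, 7.5), (6.0 + 1.8 * r, 7.5, 7.5)]  # 20% overlap
        stack = ball_stack(centers)
        segs = segment_nuclei(stack, min_distance_um=1.5)
        assert len(segs) == 2
        got = sorted(s.centroid_um[0] for s in segs)
        assert got[0] == pytest.approx(centers[0][0], abs=0.3)
        assert got[1] == pytest.approx(centers[1][0], abs=0.3)

    def test_min_volume_filters_specks(self):
        stack = ball_stack([(7.5, 7.5, 7.5)])
        assert len(segment_nuclei(stack, min_volume_um3=1.0)) == 1
        assert segment_nuclei(stack, min_volume_um3=1e5) == []

    def test_masks_disjoint(self):
        centers = [(4, 4, 4), (11, 4, 4), (4, 11, 4)]
        segs = segment_nuclei(ball_stack(centers))
        seen = set()
        for s in segs:
            for c in map(tuple, s.coords):
                assert c not in seen
                seen.add(c)

    def test_noiseless_detection_count_equals_truth(self, wt_noiseless,
                                                    wt_noiseless_detections):
        _, _, truth, _ = wt_noiseless
        assert len(wt_noiseless_detections) == int(truth.alive.sum())


class TestClassifyCells:
    def test_full_agreement_on_noiseless_stack(self, wt_noiseless,
                                               wt_noiseless_detections):
        _, _, truth, _ = wt_noiseless
        alive = truth[truth.alive].reset_index(drop=True)
        pos = alive[["nx", "ny", "nz"]].to_numpy()
        for det in wt_noiseless_detections:
            i = int(np.argmin(np.linalg.norm(pos - det.centroid_um, axis=1)))
            assert det.type == alive.type[i]
            assert det.row == alive.row[i]

    def test_ihc_only_stack_all_typed_ihc(self):
        # nuclei on one row, on the IHC (negative-offset) side of the polyline
        centers = [(x, 5.0, 7.0) for x in (5.0, 13.0, 21.0, 29.0)]
        stack = ball_stack(centers, shape=(40, 60, 160))
        segs = segment_nuclei(stack)
        poly = CochleaPolyline(np.array([[0.0, 11.0], [40.0, 11.0]]))
        dets = classify_cells(segs, stack, RowGeometry(polyline=poly))
        assert len(dets) == 4
        assert all(d.type == "IHC" and d.row == 0 for d in dets)

    def test_equidistant_segment_goes_to_lower_row_with_flag(self):
        # middle nucleus exactly halfway between two known row centers
        centers = [(10.0, 14.0, 7.0), (20.0, 22.0, 7.0), (15.0, 18.0, 7.0)]
        stack = ball_stack(centers, shape=(40, 120, 120))
        segs = segment_nuclei(stack)
        poly = CochleaPolyline(np.array([[0.0, 8.0], [30.0, 8.0]]))
        dets = classify_cells(segs, stack,
                              RowGeometry(polyline=poly, row_spacing_um=8.0,
                                          row_offsets_um=(6.0, 14.0)))
        mid = [d for d in dets if abs(d.centroid_um[0] - 15.0) < 1.0][0]
        assert "ambiguous" in mid.flags
        assert mid.row == 1  # lower of the two OHC rows

    def test_empty_segments_rejected(self):
        stack = ball_stack([(5, 5, 5)])
        poly = CochleaPolyline(np.array([[0.0, 8.0], [30.0, 8.0]]))
        with pytest.raises(ValueError, match="segments"):
            classify_cells([], stack, RowGeometry(polyline=poly))

    def test_no_myosin_flagged_not_dropped(self):
        stack = ball_stack([(7.5, 5.0, 7.0)], shape=(40, 60, 60))
        segs = segment_nuclei(stack)
        stack.channels["MYO7A"] = np.zeros_like(stack.channel("DAPI"))
        poly = CochleaPolyline(np.array([[0.0, 11.0], [15.0, 11.0]]))
        dets = classify_cells(segs, stack, RowGeometry(polyline=poly))
        assert len(dets) == 1
        assert "no_myosin" in dets[0].flags


class TestGfpQuantify:
    def fake_detection(self, cid, ctype, intensity, stack_shape=(10, 10, 10)):
        img = np.full(stack_shape, float(intensity), dtype=np.float32)
        coords = np.argwhere(img > -1)[:8]
        seg = NucleusSegment(label=cid, coords=coords,
                             centroid_um=np.array([1.0, 1.0, 1.0]),
                             volume_um3=1.0)
        det = CellDetection(cell_id=cid, type=ctype, row=0 if ctype == "IHC" else 1,
                            segment=seg, apical_um=np.zeros(3),
                            basal_um=np.ones(3), position_um=0.0)
        return det, img

    def run_cells(self, intensities, mu=10.0, sigma=2.0):
        dets = []
        imgs = []
        for i, inten in enumerate(intensities):
            d, img = self.fake_detection(i, "OHC", inten)
            dets.append(d)
            imgs.append(img)
        # single shared image per cell is impossible; score one at a time
        ctrl = ControlStats(mean={"OHC": mu}, sd={"OHC": sigma})
        rows = []
        for d, img in zip(dets, imgs):
            stack = ImageStack(channels={"GFP": img}, voxel_size=(1, 1, 1))
            table, _ = gfp_quantify([d], stack, ctrl)
            rows.append(table.iloc[0])
        return rows

    def test_rule_application(self):
        # µ=10, σ=2, I=15 -> normalized 0.5, positive (15 > 14)
        row = self.run_cells([15.0])[0]
        assert row.normalized == pytest.approx(0.5)
        assert row.positive

    def test_intensity_at_control_mean_is_negative(self):
        row = self.run_cells([10.0])[0]
        assert row.normalized == pytest.approx(0.0)
        assert not row.positive

    def test_rate_counts_cells_above_cutoff(self):
        rows = self.run_cells([15.0, 13.0, 20.0, 10.0])
        assert sum(r.positive for r in rows) == 2  # rate 2/4 = 50%

    def test_zero_control_mean_rejected(self):
        with pytest.raises(ValueError):
            ControlStats(mean={"OHC": 0.0}, sd={"OHC": 1.0})

    def test_positivity_invariant_under_gain_rescale(self, treated_noisy):
        (params, stack, truth, polyline), (cp, cstack, cpoly) = treated_noisy
        segs = segment_nuclei(stack)
        dets = classify_cells(segs, stack, RowGeometry(
            polyline=polyline, row_spacing_um=params.row_spacing_um))
        cdets = classify_cells(segment_nuclei(cstack), cstack, RowGeometry(
            polyline=cpoly, row_spacing_um=cp.row_spacing_um))
        ctrl = control_stats(cdets, cstack)
        _, rates = gfp_quantify(dets, stack, ctrl)

        g = 3.7  # global acquisition gain applied to sample AND control
        stack2 = ImageStack(
            channels={k: v * g for k, v in stack.channels.items()},
            voxel_size=stack.voxel_size)
        cstack2 = ImageStack(
            channels={k: v * g for k, v in cstack.channels.items()},
            voxel_size=cstack.voxel_size)
        ctrl2 = control_stats(cdets, cstack2)
        _, rates2 = gfp_quantify(dets, stack2, ctrl2)
        assert rates2 == rates

    def test_recovers_programmed_transduction(self, treated_noisy):
        (params, stack, truth, polyline), (cp, cstack, cpoly) = treated_noisy
        segs = segment_nuclei(stack)
        dets = classify_cells(segs, stack, RowGeometry(
            polyline=polyline, row_spacing_um=params.row_spacing_um))
        cdets = classify_cells(segment_nuclei(cstack), cstack, RowGeometry(
            polyline=cpoly, row_spacing_um=cp.row_spacing_um))
        ctrl = control_stats(cdets, cstack)
        table, rates = gfp_quantify(dets, stack, ctrl)
        true_rate = truth[truth.alive].transduced.mean()
        got = table.positive.mean()
        assert got == pytest.approx(true_rate, abs=0.1)


class TestEnvelopeProfile:
    def test_flag_shell_peaks_at_profile_center(self, treated_noisy):
        (params, stack, truth, polyline), _ = treated_noisy
        segs = segment_nuclei(stack)
        dets = classify_cells(segs, stack, RowGeometry(
            polyline=polyline, row_spacing_um=params.row_spacing_um))
        trans = truth[truth.alive & truth.transduced]
        pos = trans[["nx", "ny", "nz"]].to_numpy()
        checked = 0
        for det in dets:
            d = np.linalg.norm(pos - det.centroid_um, axis=1)
            if d.min() > 1.0:
                continue
            prof = envelope_profile(det, stack)
            peak = prof.loc[prof.FLAG_norm.idxmax(), "position_um"]
            assert abs(peak) <= max(stack.voxel_size)
            checked += 1
            if checked >= 5:
                break
        assert checked >= 3

    def test_uniform_flag_flat_profile(self):
        shape = (40, 60, 60)
        stack = ball_stack([(7.5, 7.5, 5.0)], shape=shape)
        stack.channels["FLAG"] = np.full(shape, 50.0, dtype=np.float32)
        segs = segment_nuclei(stack)
        det = CellDetection(cell_id=0, type="IHC", row=0, segment=segs[0],
                            apical_um=np.zeros(3), basal_um=np.ones(3),
                            position_um=0.0)
        prof = envelope_profile(det, stack)
        np.testing.assert_allclose(prof.FLAG_norm, 1.0)

    def test_each_channel_normalized_to_own_max(self, treated_noisy):
        (params, stack, truth, polyline), _ = treated_noisy
        segs = segment_nuclei(stack)
        det = CellDetection(cell_id=0, type="IHC", row=0, segment=segs[0],
                            apical_um=np.zeros(3), basal_um=np.ones(3),
                            position_um=0.0)
        prof = envelope_profile(det, stack)
        assert prof.FLAG_norm.max() == pytest.approx(1.0)
        assert prof.DAPI_norm.max() == pytest.approx(1.0)

    def test_zero_channel_rejected(self):
        shape = (40, 60, 60)
        stack = ball_stack([(7.5, 7.5, 5.0)], shape=shape)
        stack.channels["FLAG"] = np.zeros(shape, dtype=np.float32)
        segs = segment_nuclei(stack)
        det = CellDetection(cell_id=0, type="IHC", row=0, segment=segs[0],
                            apical_um=np.zeros(3), basal_um=np.ones(3),
                            position_um=0.0)
        with pytest.raises(ValueError, match="zero"):
            envelope_profile(det, stack)


class TestTiffRoundTrip:
    def test_save_load_preserves_channels_and_voxels(self, tmp_path,
                                                     wt_noiseless):
        _, stack, _, _ = wt_noiseless
        path = tmp_path / "stack.ome.tif"
        save_stack(stack, path)
        back = load_stack(path)
        assert set(back.channels) == set(stack.channels)
        assert back.voxel_size == pytest.approx(stack.voxel_size)
        for ch in stack.channels:
            np.testing.assert_allclose(back.channels[ch],
                                       stack.channels[ch], atol=1e-6)
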