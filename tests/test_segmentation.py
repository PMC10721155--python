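"""Islet candidate detection and the inclusion/exclusion filter set."""

from __future__ import annotations

import random

import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage.draw import disk

from isletmorph.config import AnalysisConfig
from isletmorph.imaging_io import SectionImage
from isletmorph.segmentation import (
    ChannelMasks,
    detect_nuclei,
    extract_candidates,
    filter_candidates,
    focus_score,
    nucleus_table,
    segment_section,
    threshold_channel,
)
from isletmorph.synthetic_data import render_section


class TestThresholdChannel:
    def test_all_zero_channel_empty_mask(self):
        mask, _ = threshold_channel(np.zeros((32, 32), np.uint8), "otsu")
        assert not mask.any()

    def test_bimodal_otsu_selects_foreground_exactly(self):
        img = np.zeros((40, 40), np.uint8)
        img[10:30, 10:30] = 200
        mask, t = threshold_channel(img, "otsu", min_object_px=0, min_hole_px=0)
        assert t < 200
        np.testing.assert_array_equal(mask, img == 200)

    def test_fixed_threshold_is_strict(self):
        img = np.full((20, 20), 99, np.uint8)
        img[5:15, 5:15] = 101
        mask, _ = threshold_channel(img, "fixed", 100.0, min_object_px=0, min_hole_px=0)
        np.testing.assert_array_equal(mask, img > 100)
        mask, _ = threshold_channel(
            np.full((20, 20), 100, np.uint8), "fixed", 100.0, 0, 0
        )
        assert not mask.any()

    def test_small_specks_removed_and_holes_filled(self):
        img = np.zeros((60, 60), np.uint8)
        img[5:7, 5:7] = 200  # 4-px speck, below min_object_px
        img[20:50, 20:50] = 200
        img[33:36, 33:36] = 0  # 9-px hole, below min_hole_px
        mask, _ = threshold_channel(img, "fixed", 50.0, min_object_px=9, min_hole_px=64)
        assert not mask[5, 5]
        assert mask[34, 34]


class TestDetectNuclei:
    def _labels(self, centres, radius=3, shape=(40, 40)):
        m = np.zeros(shape, bool)
        for r, c in centres:
            rr, cc = disk((r, c), radius)
            m[rr, cc] = True
        return detect_nuclei(m, 1.0, min_sep_um=4.0)

    def test_separated_discs_two_labels(self):
        labels, cents = self._labels([(10, 10), (10, 30)])
        assert labels.max() == 2
        assert len(cents) == 2

    def test_touching_discs_split_by_watershed(self):
        # radius-3 um discs overlapping by 1 um: centres 5 um apart
        labels, _ = self._labels([(20, 15), (20, 20)])
        assert labels.max() == 2

    def test_empty_mask_no_labels(self):
        labels, cents = detect_nuclei(np.zeros((20, 20), bool), 1.0)
        assert labels.max() == 0
        assert len(cents) == 0


class TestFocusScore:
    def _sharp_region(self):
        img = np.zeros((60, 60), float)
        for r, c in [(15, 15), (15, 35), (35, 25)]:
            rr, cc = disk((r, c), 4)
            img[rr, cc] = 200.0
        mask = np.zeros((60, 60), bool)
        mask[5:55, 5:55] = True
        return img, mask

    def test_blurring_strictly_lowers_score(self):
        img, mask = self._sharp_region()
        blurred = ndi.gaussian_filter(img, 4.0)
        assert focus_score(img, mask) > focus_score(blurred, mask)

    def test_uniform_region_scores_zero(self):
        assert focus_score(np.full((20, 20), 80.0), np.ones((20, 20), bool)) == 0.0

    def test_invariant_to_global_intensity_scaling(self):
        img, mask = self._sharp_region()
        s1 = focus_score(img, mask)
        s2 = focus_score(img * 3.5, mask)
        assert s2 == pytest.approx(s1, rel=1e-9)

    def test_empty_region_raises(self):
        with pytest.raises(ValueError):
            focus_score(np.zeros((10, 10)), np.zeros((10, 10), bool))


def _section_from_channels(insulin, marker2, dapi, pixel_size=1.0):
    pixels = np.zeros(insulin.shape + (3,), np.uint8)
    pixels[:, :, 0] = marker2
    pixels[:, :, 1] = insulin
    pixels[:, :, 2] = dapi
    return SectionImage(pixels=pixels, pixel_size=pixel_size)


def _masks_and_nuclei(insulin, marker2, dapi, cfg):
    im, _ = threshold_channel(insulin, "fixed", 50.0, cfg.min_object_px, cfg.min_hole_px)
    mm, _ = threshold_channel(marker2, "fixed", 50.0, cfg.min_object_px, cfg.min_hole_px)
    dm, _ = threshold_channel(dapi, "fixed", 40.0, cfg.min_object_px, cfg.min_hole_px)
    masks = ChannelMasks(insulin=im, marker2=mm, dapi=dm)
    labels, _ = detect_nuclei(dm, 1.0, cfg.nucleus_min_sep_um)
    return masks, nucleus_table(labels, im, mm)


class TestExtractCandidates:
    def test_two_islets_far_apart_two_candidates(self, syn_config):
        insulin = np.zeros((200, 400), np.uint8)
        dapi = np.zeros_like(insulin)
        for c in (80, 300):  # 220 um apart
            rr, cc = disk((100, c), 20)
            insulin[rr, cc] = 200
            rr, cc = disk((100, c), 3)
            dapi[rr, cc] = 230
        masks, nuclei = _masks_and_nuclei(insulin, np.zeros_like(insulin), dapi, syn_config)
        cands, _ = extract_candidates(masks, 1.0, nuclei, syn_config)
        assert len(cands) == 2
        assert all(c.n_insulin_dapi_cells == 1 for c in cands)

    def test_small_gap_bridged_by_closing(self, syn_config):
        # beta patch and alpha patch 2 um apart merge into one candidate
        insulin = np.zeros((120, 120), np.uint8)
        marker2 = np.zeros_like(insulin)
        insulin[40:80, 30:58] = 200
        marker2[40:80, 60:90] = 200  # 2-px gap
        masks, nuclei = _masks_and_nuclei(insulin, marker2, np.zeros_like(insulin), syn_config)
        cands, _ = extract_candidates(masks, 1.0, nuclei, syn_config)
        assert len(cands) == 1


class TestFilterRules:
    def _run(self, insulin, marker2, dapi, cfg=None):
        cfg = cfg or AnalysisConfig(threshold_method="fixed")
        masks, nuclei = _masks_and_nuclei(insulin, marker2, dapi, cfg)
        cands, _ = extract_candidates(masks, 1.0, nuclei, cfg)
        return filter_candidates(cands, masks, nuclei, dapi.astype(float), 1.0, cfg)

    def test_subthreshold_area_excluded(self):
        # insulin+DAPI cell but candidate area <= 50 um^2
        insulin = np.zeros((40, 40), np.uint8)
        dapi = np.zeros_like(insulin)
        rr, cc = disk((20, 20), 3.6)  # ~40 px
        insulin[rr, cc] = 200
        rr, cc = disk((20, 20), 2)
        dapi[rr, cc] = 230
        islets, excluded = self._run(insulin, np.zeros_like(insulin), dapi)
        assert not islets
        assert excluded[0].exclusion_flags == {"subthreshold_area"}

    def test_insulin_without_nuclei_excluded(self):
        insulin = np.zeros((60, 60), np.uint8)
        rr, cc = disk((30, 30), 10)
        insulin[rr, cc] = 200
        islets, excluded = self._run(insulin, np.zeros_like(insulin), np.zeros_like(insulin))
        assert not islets
        assert excluded[0].exclusion_flags == {"no_insulin_dapi_cell"}

    def test_marker_only_region_excluded_as_nonbeta(self):
        marker2 = np.zeros((60, 60), np.uint8)
        dapi = np.zeros_like(marker2)
        rr, cc = disk((30, 30), 10)
        marker2[rr, cc] = 200
        rr, cc = disk((30, 30), 3)
        dapi[rr, cc] = 230
        islets, excluded = self._run(np.zeros_like(marker2), marker2, dapi)
        assert not islets
        assert excluded[0].exclusion_flags == {"nonbeta_only"}

    def test_valid_islet_retained(self):
        insulin = np.zeros((80, 80), np.uint8)
        dapi = np.zeros_like(insulin)
        rr, cc = disk((40, 40), 15)
        insulin[rr, cc] = 200
        rr, cc = disk((40, 40), 3)
        dapi[rr, cc] = 230
        islets, excluded = self._run(insulin, np.zeros_like(insulin), dapi)
        assert len(islets) == 1
        assert not excluded


class TestFixtureSection:
    """Planted-confounder specificity and valid-islet sensitivity."""

    def test_partition_covers_all_candidates(self, segmented_fixture):
        _, _, islets, excluded, _, _ = segmented_fixture
        labels = [c.label for c in islets] + [c.label for c in excluded]
        assert len(labels) == len(set(labels))
        assert all(not c.exclusion_flags for c in islets)
        assert all(c.exclusion_flags for c in excluded)

    def test_every_valid_islet_retained(self, segmented_fixture):
        _, truth, islets, _, _, _ = segmented_fixture
        assert len(islets) == len(truth.islets)
        # each truth islet centroid falls in exactly one retained candidate
        for t in truth.islets:
            c_px = int(round(t.centroid_um[0]))
            r_px = int(round(t.centroid_um[1]))
            hits = [
                c
                for c in islets
                if c.bbox[0].start <= r_px < c.bbox[0].stop
                and c.bbox[1].start <= c_px < c.bbox[1].stop
                and c.mask[r_px - c.bbox[0].start, c_px - c.bbox[1].start]
            ]
            assert len(hits) == 1

    def test_each_confounder_gets_exactly_its_flag(self, segmented_fixture):
        _, truth, _, excluded, _, _ = segmented_fixture
        expected_flag = {
            "hormone_no_dapi": "no_insulin_dapi_cell",
            "nonbeta_only": "nonbeta_only",
            "subthreshold_speck": "subthreshold_area",
            "blurred_islet": "out_of_focus",
            "near_contiguous_microclusters": "ambiguous_microclusters",
        }
        for conf in truth.confounders:
            c_px = int(round(conf.centroid_um[0]))
            r_px = int(round(conf.centroid_um[1]))
            hits = [
                c
                for c in excluded
                if c.bbox[0].start <= r_px < c.bbox[0].stop
                and c.bbox[1].start <= c_px < c.bbox[1].stop
            ]
            assert hits, f"confounder {conf.kind} not detected as a candidate"
            assert hits[0].exclusion_flags == {expected_flag[conf.kind]}, conf.kind

    def test_filtering_is_order_independent(self, segmented_fixture, syn_config):
        img, _, islets, excluded, masks, nuclei_labels = segmented_fixture
        cands = islets + excluded
        flags_by_label = {c.label: set(c.exclusion_flags) for c in cands}
        shuffled = cands[:]
        random.Random(0).shuffle(shuffled)
        nuclei = nucleus_table(nuclei_labels, masks.insulin, masks.marker2)
        islets2, excluded2 = filter_candidates(
            shuffled, masks, nuclei, img.channel("dapi"), img.pixel_size, syn_config
        )
        for c in islets2 + excluded2:
            assert set(c.exclusion_flags) == flags_by_label[c.label]
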