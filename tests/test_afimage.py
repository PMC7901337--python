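"""Ratiometric image construction, masking and multi-level thresholding."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aframan import afimage, phantom
from aframan.afimage import ScreenLabel, ThresholdBands


def pair_from(ch1, ch2):
    return phantom.AFImagePair(
        filter1=np.asarray(ch1, float),
        filter2=np.asarray(ch2, float),
        filter1_band_nm=phantom.FILTER1_NM,
        filter2_band_nm=phantom.FILTER2_NM,
    )


class TestMaskBackground:
    def test_uniform_above_threshold(self):
        assert afimage.mask_background(np.full((5, 5), 100.0), 50).all()

    def test_uniform_below_threshold_warns_empty(self):
        with pytest.warns(RuntimeWarning, match="exceeds the image maximum"):
            mask = afimage.mask_background(np.full((5, 5), 100.0), 101)
        assert not mask.any()

    @settings(deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 1000),
        t1=st.floats(0, 500),
        t2=st.floats(0, 500),
    )
    def test_monotone_in_threshold(self, seed, t1, t2):
        img = np.random.default_rng(seed).uniform(0, 1000, (20, 20))
        lo, hi = min(t1, t2), max(t1, t2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m_hi = afimage.mask_background(img, hi)
            m_lo = afimage.mask_background(img, lo)
        assert not np.any(m_hi & ~m_lo)  # mask(t2) subset of mask(t1)


class TestRatiometric:
    def test_identical_channels_give_unity(self):
        img = np.random.default_rng(0).uniform(10, 100, (10, 10))
        r = afimage.ratiometric(pair_from(img, img), np.ones((10, 10), bool))
        assert np.allclose(r.masked_values(), 1.0)

    def test_scalar_multiple(self):
        img = np.random.default_rng(1).uniform(10, 100, (10, 10))
        r = afimage.ratiometric(pair_from(2 * img, img), np.ones((10, 10), bool))
        assert np.allclose(r.masked_values(), 2.0)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="mask shape"):
            afimage.ratiometric(
                pair_from(np.ones((5, 5)), np.ones((5, 5))), np.ones((4, 4), bool)
            )

    def test_low_denominator_pixels_removed_and_counted(self):
        ch2 = np.full((4, 4), 50.0)
        ch2[0, :] = 0.5  # below the 1-count epsilon
        r = afimage.ratiometric(pair_from(np.ones((4, 4)), ch2), np.ones((4, 4), bool))
        assert r.provenance["n_low_denominator"] == 4
        assert not r.mask[0].any() and r.mask[1:].all()
        assert np.isnan(r.ratio[0]).all()

    def test_phantom_adipose_region_mean_below_threshold(self, demo_map):
        pair = phantom.render_af_pair(demo_map, noise_sd=0.0)
        mask = demo_map.specimen_mask
        r = afimage.ratiometric(pair, mask)
        adip = demo_map.labels == phantom.Tissue.ADIPOSE
        assert np.nanmean(r.ratio[adip]) <= 0.8

    def test_common_gain_field_leaves_ratio_unchanged(self, demo_map):
        pair = phantom.render_af_pair(demo_map, noise_sd=0.0)
        gain = np.random.default_rng(2).uniform(0.5, 1.5, demo_map.shape)
        scaled = pair_from(pair.filter1 * gain, pair.filter2 * gain)
        mask = demo_map.specimen_mask
        r0 = afimage.ratiometric(pair, mask)
        r1 = afimage.ratiometric(scaled, mask)
        common = r0.mask & r1.mask
        assert np.allclose(r0.ratio[common], r1.ratio[common], rtol=1e-9)


class TestScreenAdipose:
    def _rimg(self, values, mask=None):
        values = np.asarray(values, float)
        mask = np.isfinite(values) if mask is None else mask
        return afimage.RatiometricImage(
            ratio=np.where(mask, values, np.nan), mask=mask, mask_threshold=0.0
        )

    def test_interior_of_adipose_band(self):
        labels = afimage.screen_adipose(self._rimg(np.full((6, 6), 0.5)))
        assert (labels == ScreenLabel.ADIPOSE).all()

    def test_boundary_ratio_exactly_08_is_retained(self):
        labels = afimage.screen_adipose(self._rimg([[0.8]]))
        assert labels[0, 0] == ScreenLabel.RETAINED

    def test_fibrosis_mode_narrows_retained_band(self):
        rimg = self._rimg([[0.9, 1.1, 0.5, 2.5]])
        labels = afimage.screen_adipose(rimg, ThresholdBands(fibrosis_mode=True))
        assert labels[0, 0] == ScreenLabel.OUT_OF_RANGE  # fibrosis-like gap
        assert labels[0, 1] == ScreenLabel.RETAINED
        assert labels[0, 2] == ScreenLabel.ADIPOSE
        assert labels[0, 3] == ScreenLabel.OUT_OF_RANGE

    @settings(deadline=None, derandomize=True)
    @given(seed=st.integers(0, 500))
    def test_partition_is_exact(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.uniform(0, 3, (15, 15))
        mask = rng.uniform(size=(15, 15)) < 0.7
        labels = afimage.screen_adipose(self._rimg(values, mask))
        assert ((labels != ScreenLabel.UNMASKED) == mask).all()
        n = (
            (labels == ScreenLabel.ADIPOSE).sum()
            + (labels == ScreenLabel.RETAINED).sum()
            + (labels == ScreenLabel.OUT_OF_RANGE).sum()
            + (labels == ScreenLabel.UNMASKED).sum()
        )
        assert n == labels.size

    def test_phantom_screening_never_calls_tumour_adipose(self):
        # 20 seeded phantoms at default noise with common-mode fields
        tumour_as_adipose = 0
        adipose_recalls = []
        for seed in range(20):
            tmap = phantom.demo_tissue_map(shape=(100, 100), tumour_radius_px=18,
                                           stroma_halo_px=10, seed=seed)
            rng = np.random.default_rng(seed)
            blood = phantom.smooth_random_field(tmap.shape, rng, 0.6, 1.0)
            contact = phantom.smooth_random_field(tmap.shape, rng, 0.7, 1.0)
            pair = phantom.render_af_pair(
                tmap, blood_field=blood, contact_field=contact, seed=seed
            )
            rimg = afimage.ratiometric(pair, tmap.specimen_mask)
            labels = afimage.screen_adipose(rimg)
            truth = tmap.labels
            bad = (labels == ScreenLabel.ADIPOSE) & (
                (truth == phantom.Tissue.TUMOUR) | (truth == phantom.Tissue.STROMA)
            )
            tumour_as_adipose += int(bad.sum())
            adip = truth == phantom.Tissue.ADIPOSE
            adipose_recalls.append(
                float((labels[adip] == ScreenLabel.ADIPOSE).sum()) / adip.sum()
            )
        assert tumour_as_adipose == 0
        assert min(adipose_recalls) >= 0.8


class TestMultilevelReport:
    def test_band_areas_match_construction(self):
        values = np.full((10, 10), 0.5)
        values[:4] = 1.5  # 40 px in the upper band
        rimg = afimage.RatiometricImage(
            ratio=values, mask=np.ones((10, 10), bool), mask_threshold=0.0
        )
        rep = afimage.multilevel_threshold_report(rimg, [0.2, 0.8, 2.0])
        assert rep["area_fractions"] == [0.6, 0.4]
        assert rep["below_fraction"] == 0.0 and rep["above_fraction"] == 0.0
        assert rep["images"][1].sum() == 40
        assert sum(rep["area_fractions"]) + rep["below_fraction"] + rep["above_fraction"] == 1.0

    def test_single_interval_covers_everything(self):
        values = np.random.default_rng(3).uniform(0.1, 1.9, (8, 8))
        rimg = afimage.RatiometricImage(
            ratio=values, mask=np.ones((8, 8), bool), mask_threshold=0.0
        )
        rep = afimage.multilevel_threshold_report(rimg, [0.0, 2.0])
        assert rep["images"][0].all()
        assert rep["area_fractions"] == [1.0]

    def test_empty_mask_gives_empty_report(self):
        rimg = afimage.RatiometricImage(
            ratio=np.full((5, 5), np.nan), mask=np.zeros((5, 5), bool), mask_threshold=0.0
        )
        rep = afimage.multilevel_threshold_report(rimg, [0.0, 1.0, 2.0])
        assert rep["n_masked_px"] == 0
        assert all(f == 0.0 for f in rep["area_fractions"])

    def test_unsorted_edges_raise(self):
        rimg = afimage.RatiometricImage(
            ratio=np.ones((2, 2)), mask=np.ones((2, 2), bool), mask_threshold=0.0
        )
        with pytest.raises(ValueError, match="strictly increasing"):
            afimage.multilevel_threshold_report(rimg, [0.8, 0.2, 2.0])
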