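"""Spectral preprocessing chain and quality control."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from aframan import calibration, phantom, ramanproc
from aframan.profiles import RAMAN_GRID_CM1
from aframan.ramanproc import RamanSpectrum

from conftest import quiet_models


def flat_spectrum(value=0.0):
    wn = RAMAN_GRID_CM1.copy()
    return RamanSpectrum(wavenumber=wn, counts=np.full(wn.size, float(value)))


class TestCosmicRays:
    def test_clean_spectrum_unchanged(self, demo_map, class_points):
        s = phantom.render_raman(class_points["tumour"], demo_map,
                                 model_set=quiet_models(), seed=0)
        out = ramanproc.remove_cosmic_rays(s)
        assert np.allclose(out.counts, s.counts, atol=1e-12)
        assert out.meta["n_cosmic_channels"] == 0

    @pytest.mark.parametrize("spikes", [[(400, 1)], [(200, 2), (800, 1)]])
    def test_injected_spikes_removed_against_spike_free_oracle(
        self, demo_map, class_points, spikes
    ):
        # same-seed rendering without cosmic rays is the oracle
        models = quiet_models(noise_sd=8.0)
        clean = phantom.render_raman(class_points["adipose"], demo_map,
                                     model_set=models, seed=42)
        counts = clean.counts.copy()
        peak = counts.max()
        for idx, width in spikes:
            counts[idx : idx + width] += 20.0 * peak
        spiked = RamanSpectrum(wavenumber=clean.wavenumber, counts=counts)
        out = ramanproc.remove_cosmic_rays(spiked)
        for idx, width in spikes:
            sl = slice(idx, idx + width)
            assert np.all(np.abs(out.counts[sl] - clean.counts[sl]) <= 3 * 8.0)
        # band peaks untouched (within 1%)
        i1441 = clean.nearest_index(1441)
        assert out.counts[i1441] == pytest.approx(clean.counts[i1441], rel=0.01)

    def test_idempotent_on_output(self, demo_map, class_points):
        models = quiet_models(noise_sd=8.0)
        s = phantom.render_raman(class_points["stroma"], demo_map,
                                 model_set=models, seed=7)
        counts = s.counts.copy()
        counts[500] += 15 * counts.max()
        once = ramanproc.remove_cosmic_rays(
            RamanSpectrum(wavenumber=s.wavenumber, counts=counts)
        )
        twice = ramanproc.remove_cosmic_rays(once)
        assert np.allclose(once.counts, twice.counts, atol=1e-9)


class TestResponseCorrection:
    def test_already_calibrated_standard_is_identity(self, refs):
        std = calibration.render_intensity_standard(refs, count_scale=1.0)
        s = flat_spectrum(100.0)
        out = ramanproc.correct_response(s, refs, std)
        assert np.allclose(out.counts, s.counts, rtol=1e-6)

    def test_round_trip_recovers_truth(self, refs, demo_map, class_points):
        truth = phantom.render_raman(class_points["adipose"], demo_map,
                                     model_set=quiet_models(), seed=0)
        inst = phantom.InstrumentModel(response_curvature=0.3, axis_offset_cm1=0.0)
        g = inst.response(truth.wavenumber)
        distorted = truth.evolve(counts=truth.counts * g)
        # standard measured at certified scale through the same response
        certified = calibration.render_intensity_standard(refs, count_scale=1.0)
        measured_std = certified.evolve(counts=certified.counts * g)
        out = ramanproc.correct_response(distorted, refs, measured_std)
        big = truth.counts > 0.05 * truth.counts.max()
        assert np.allclose(out.counts[big], truth.counts[big], rtol=1e-6)

    def test_applying_twice_equals_squared_factor(self, refs):
        std = calibration.render_intensity_standard(refs, count_scale=2.0)
        s = flat_spectrum(50.0)
        once = ramanproc.correct_response(s, refs, std)
        twice = ramanproc.correct_response(once, refs, std)
        factor = refs.response_on(s.wavenumber) / np.maximum(
            ramanproc.savgol_filter(std.counts, 31, 3), 1e-300
        )
        expected = s.counts * factor**2
        assert np.allclose(twice.counts, expected, rtol=1e-9)

    def test_nonpositive_standard_raises(self, refs):
        bad = flat_spectrum(0.0)
        with pytest.raises(ValueError, match="non-positive"):
            ramanproc.correct_response(flat_spectrum(1.0), refs, bad)


class TestWavenumberCalibration:
    def test_identity_when_peaks_at_reference(self, refs):
        ps = calibration.render_polystyrene()
        s = calibration.render_polystyrene()
        out = ramanproc.calibrate_wavenumber(s, refs, ps, model="linear")
        fit = out.meta["wavenumber_fit"]
        assert fit["residual_rms_cm1"] < 0.05
        assert fit["coefficients"][0] == pytest.approx(0.0, abs=0.1)
        assert fit["coefficients"][1] == pytest.approx(1.0, abs=1e-3)

    def test_constructed_shift_recovered(self, refs):
        # peaks appear 4 cm^-1 high on the nominal axis -> fit offset -4
        true_ps = calibration.render_polystyrene()
        shifted = RamanSpectrum(
            wavenumber=true_ps.wavenumber,
            counts=np.interp(true_ps.wavenumber - 4.0, true_ps.wavenumber, true_ps.counts),
        )
        out = ramanproc.calibrate_wavenumber(true_ps, refs, shifted, model="linear")
        offset = out.meta["wavenumber_fit"]["coefficients"][0]
        assert offset == pytest.approx(-4.0, abs=0.1)

    def test_quadratic_residual_not_worse_than_linear(self, refs):
        inst = phantom.InstrumentModel(
            response_curvature=0.0, axis_offset_cm1=3.0, axis_stretch=1.01
        )
        measured = inst.distort(calibration.render_polystyrene())
        res = {}
        for model in ("linear", "quadratic"):
            out = ramanproc.calibrate_wavenumber(
                calibration.render_polystyrene(), refs, measured, model=model
            )
            res[model] = out.meta["wavenumber_fit"]["residual_rms_cm1"]
        assert res["quadratic"] <= res["linear"] + 1e-12

    def test_too_few_peaks_raises_listing_found(self, refs):
        with pytest.raises(ValueError, match="found 0"):
            ramanproc.calibrate_wavenumber(
                flat_spectrum(1.0), refs, flat_spectrum(1.0), model="linear"
            )


class TestBackgroundSubtraction:
    def test_pure_polynomial_removed(self):
        wn = RAMAN_GRID_CM1
        x = (wn - wn.mean()) / 600.0
        baseline = 500.0 + 300.0 * x + 200.0 * x**2
        s = RamanSpectrum(wavenumber=wn, counts=baseline)
        out = ramanproc.subtract_background(s, order=3)
        assert abs(np.median(out.counts)) < 1e-6 * baseline.max()

    def test_band_heights_within_5pct_of_baseline_free_oracle(
        self, demo_map, class_points
    ):
        models_base = quiet_models(baseline_fraction=0.3)
        models_free = quiet_models(baseline_fraction=0.0)
        for cls in ("adipose", "stroma", "tumour"):
            with_base = phantom.render_raman(class_points[cls], demo_map,
                                             model_set=models_base, seed=5)
            oracle = phantom.render_raman(class_points[cls], demo_map,
                                          model_set=models_free, seed=5)
            out = ramanproc.subtract_background(with_base)
            for center, _, amp in models_base[cls].bands:
                if amp < 0.3:
                    continue
                i = out.nearest_index(center)
                assert out.counts[i] == pytest.approx(oracle.counts[i], rel=0.05)

    def test_second_pass_nearly_idempotent(self, demo_map, class_points):
        s = phantom.render_raman(class_points["stroma"], demo_map,
                                 model_set=quiet_models(baseline_fraction=0.3), seed=2)
        once = ramanproc.subtract_background(s)
        twice = ramanproc.subtract_background(once)
        rms = np.sqrt(np.mean((twice.counts - once.counts) ** 2))
        assert rms < 0.01 * np.sqrt(np.mean(once.counts**2))


class TestSmoothing:
    def test_constant_unchanged(self):
        s = flat_spectrum(42.0)
        assert np.allclose(ramanproc.smooth(s).counts, 42.0)

    def test_peak_position_stable_within_one_channel(self):
        wn = RAMAN_GRID_CM1
        band = 100.0 * np.exp(-0.5 * ((wn - 1441.0) / 10.0) ** 2)
        s = RamanSpectrum(wavenumber=wn, counts=band)
        out = ramanproc.smooth(s, window=9, polyorder=3)
        assert abs(wn[np.argmax(out.counts)] - 1441.0) <= 1.0

    def test_smoothing_increases_snr(self, demo_map, class_points):
        s = phantom.render_raman(class_points["stroma"], demo_map,
                                 model_set=quiet_models(noise_sd=12.0), seed=8)
        before = ramanproc.qc(s).qc.snr
        after = ramanproc.qc(ramanproc.smooth(s)).qc.snr
        assert after > before

    def test_window_longer_than_spectrum_raises(self):
        s = RamanSpectrum(wavenumber=np.arange(600.0, 620.0), counts=np.zeros(20))
        with pytest.raises(ValueError, match="longer than"):
            ramanproc.smooth(s, window=21)


class TestQC:
    def _constructed(self, signal_at_1450, quiet_pattern):
        wn = RAMAN_GRID_CM1.copy()
        counts = np.zeros(wn.size)
        quiet = (wn >= 1370) & (wn <= 1410)
        counts[quiet] = quiet_pattern
        counts[np.argmin(np.abs(wn - 1450))] = signal_at_1450
        return RamanSpectrum(wavenumber=wn, counts=counts)

    @staticmethod
    def _unit_sd_pattern():
        # 41 channels: 20 at +1, 20 at -1, 1 at 0 -> mean 0, sd(ddof=1) = 1 exactly
        pat = np.zeros(41)
        pat[:20] = 1.0
        pat[20:40] = -1.0
        return pat

    def test_fluorescence_cutoff_is_strict_greater_than(self):
        s = self._constructed(100.0, self._unit_sd_pattern())
        s = RamanSpectrum(wavenumber=s.wavenumber,
                          counts=np.where(s.wavenumber == 780.0, 3001.0, s.counts))
        rep = ramanproc.qc(s).qc
        assert not rep.passed and "high_fluorescence" in rep.reasons
        at_limit = self._constructed(100.0, self._unit_sd_pattern())
        at_limit = RamanSpectrum(
            wavenumber=at_limit.wavenumber,
            counts=np.where(at_limit.wavenumber == 780.0, 3000.0, at_limit.counts),
        )
        assert ramanproc.qc(at_limit).qc.passed

    def test_snr_is_signal_over_quiet_sd(self):
        rep = ramanproc.qc(self._constructed(31.0, self._unit_sd_pattern())).qc
        assert rep.snr == pytest.approx(31.0)
        assert rep.passed

    def test_snr_exactly_at_threshold_passes(self):
        # sd exactly 2 (20 x +2, 20 x -2, 1 x 0), signal 31 -> snr == 15.5
        rep = ramanproc.qc(self._constructed(31.0, 2 * self._unit_sd_pattern())).qc
        assert rep.snr == 15.5
        assert rep.passed
        below = ramanproc.qc(self._constructed(30.9, 2 * self._unit_sd_pattern())).qc
        assert not below.passed and below.reasons == ("low_snr",)

    def test_axis_not_covering_windows_raises(self):
        s = RamanSpectrum(wavenumber=np.arange(800.0, 1200.0), counts=np.zeros(400))
        with pytest.raises(ValueError, match="does not cover"):
            ramanproc.qc(s)

    def test_snr_decreases_with_noise(self, demo_map, class_points):
        # Spearman correlation between injected noise and SNR over 50 seeds
        noise_levels = np.linspace(2.0, 40.0, 50)
        snrs = []
        for seed, sd in enumerate(noise_levels):
            s = phantom.render_raman(class_points["stroma"], demo_map,
                                     model_set=quiet_models(noise_sd=float(sd)),
                                     seed=seed)
            snrs.append(ramanproc.qc(s).qc.snr)
        rho, _ = spearmanr(noise_levels, snrs)
        assert rho < 0


class TestFullChain:
    def test_provenance_records_fixed_order(self, refs, measured_standards,
                                            demo_map, class_points):
        std, ps = measured_standards
        raw = phantom.render_raman(class_points["stroma"], demo_map, seed=1)
        out = ramanproc.process_all(raw, refs, std, ps)
        assert out.steps[-6:] == ramanproc.PIPELINE_ORDER

    def test_band_height_ratios_recovered_over_population(
        self, refs, measured_standards, demo_map, class_points, instrument
    ):
        # 100 spectra per class at default noise: processed band-height
        # ratios match the generating amplitude ratios to 10% (median)
        std, ps = measured_standards
        models = phantom.default_band_models()
        ratio_defs = {
            "adipose": (1441.0, 1655.0),
            "stroma": (860.0, 1450.0),
            "tumour": (1004.0, 1655.0),
        }
        for cls, (b1, b2) in ratio_defs.items():
            amps = {c: a for c, _, a in models[cls].bands}
            truth = amps[b1] / amps[b2]
            measured = []
            for seed in range(100):
                raw = phantom.render_raman(class_points[cls], demo_map,
                                           model_set=models, seed=seed)
                out = ramanproc.process_all(instrument.distort(raw), refs, std, ps)
                i1, i2 = out.nearest_index(b1), out.nearest_index(b2)
                measured.append(out.counts[i1] / out.counts[i2])
            mad = np.median(np.abs(np.array(measured) - truth)) / truth
            assert mad < 0.10, f"{cls}: relative MAD {mad:.3f}"
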