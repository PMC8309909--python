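"""R-peak detection, baseline removal, EA computation and coefficients."""

import numpy as np
import pytest

from torsoecg.records import ECGRecord, SegmentCoefficients, \
    COEFFICIENT_NAMES
from torsoecg.synthetic_ecg import (CohortConfig, synth_record,
                                    subject_record)
from torsoecg.ensemble_average import (
    EnsembleAverage, detect_r_peaks, remove_baseline,
    compute_ensemble_average, extract_coefficients)


@pytest.fixture(scope="module")
def cfg():
    return CohortConfig(seed=31)


def clean_record(cfg, hr=72.0, duration=60.0, seed=2, lead="D2",
                 side="front"):
    co = SegmentCoefficients.from_array(
        np.asarray(cfg.coeff_mean[f"{lead}{side}"], float))
    return synth_record(co, 0, hr, duration, cfg,
                        np.random.default_rng(seed), lead=lead, side=side)


class TestDetection:
    def test_beat_count_on_clean_record(self, cfg):
        rec = clean_record(cfg, hr=72.0, duration=60.0)
        peaks = detect_r_peaks(rec)
        assert abs(len(peaks) - 72) <= 1

    def test_peaks_within_20ms_of_ground_truth(self, cfg):
        rec = clean_record(cfg)
        det = detect_r_peaks(rec)
        truth = rec.meta["r_peaks"]
        tol = int(0.02 * rec.fs)
        for p in truth:
            assert np.min(np.abs(det - p)) <= tol

    def test_flat_record_finds_nothing(self):
        rec = ECGRecord(np.zeros(2000), fs=250.0)
        with pytest.warns(UserWarning):
            assert detect_r_peaks(rec).size == 0

    def test_strictly_increasing_with_refractory(self, cfg):
        peaks = detect_r_peaks(clean_record(cfg, hr=90.0))
        assert np.all(np.diff(peaks) >= int(0.2 * 250))

    def test_too_short_record_rejected(self):
        with pytest.raises(ValueError):
            detect_r_peaks(ECGRecord(np.zeros(250), fs=250.0))


class TestBaselineRemoval:
    def test_constant_offset_removed(self, cfg):
        rec = clean_record(cfg, duration=30.0)
        shifted = rec.with_samples(rec.samples + 0.4)
        out = remove_baseline(shifted)
        base = remove_baseline(rec)
        assert np.abs(out.samples - base.samples).max() < 1e-3  # < 1 uV

    def test_wander_attenuated_20db(self, cfg):
        rec = clean_record(cfg, duration=60.0)
        t = rec.t
        wander = 0.5 * np.sin(2 * np.pi * 0.3 * t + 0.7)
        noisy = rec.with_samples(rec.samples + wander)
        out = remove_baseline(noisy)
        residual = out.samples - remove_baseline(rec).samples
        atten_db = 10 * np.log10(np.sum(wander ** 2)
                                 / np.sum(residual ** 2))
        assert atten_db >= 20.0

    def test_qrs_band_preserved(self, cfg):
        """R amplitude relative to the isoelectric level attenuated by
        < 2 % (the filter legitimately removes the record's DC mean)."""
        rec = clean_record(cfg, duration=30.0)
        out = remove_baseline(rec)
        r = rec.meta["r_peaks"]
        before = rec.samples[r] - np.median(rec.samples)
        after = out.samples[r] - np.median(out.samples)
        assert np.abs(after - before).max() < 0.02 * before.mean()


class TestEnsembleAverage:
    def test_identical_beats_reproduce_beat_with_zero_sd(self):
        fs = 250.0
        beat = np.zeros(200)
        beat[70:90] = np.hanning(20)
        x = np.tile(beat, 8)
        rec = ECGRecord(x, fs=fs)
        peaks = np.arange(8) * 200 + 79
        ea = compute_ensemble_average(rec, peaks)
        assert np.allclose(ea.sd, 0.0)
        ref = x[peaks[3] - ea.fiducial:peaks[3] - ea.fiducial + ea.window]
        assert np.allclose(ea.mean, ref)

    def test_noise_attenuation_follows_sqrt_n(self, cfg):
        rec = clean_record(cfg, duration=120.0)
        rng = np.random.default_rng(0)
        sigma = 0.05
        noisy = rec.with_samples(rec.samples
                                 + rng.normal(0, sigma, len(rec.samples)))
        ea = compute_ensemble_average(noisy, rec.meta["r_peaks"])
        clean_ea = compute_ensemble_average(rec, rec.meta["r_peaks"])
        resid_sd = np.std(ea.mean - clean_ea.mean)
        expected = sigma / np.sqrt(ea.n_beats)
        assert resid_sd == pytest.approx(expected, rel=0.2)

    def test_linearity_in_amplitude(self, cfg):
        rec = clean_record(cfg, duration=40.0)
        peaks = rec.meta["r_peaks"]
        ea1 = compute_ensemble_average(rec, peaks)
        ea3 = compute_ensemble_average(
            rec.with_samples(3.0 * rec.samples), peaks)
        assert np.allclose(ea3.mean, 3.0 * ea1.mean)

    def test_fiducial_is_r_peak_of_mean(self, cfg):
        rec = clean_record(cfg, duration=60.0)
        ea = compute_ensemble_average(remove_baseline(rec),
                                      rec.meta["r_peaks"])
        assert int(np.argmax(np.abs(ea.mean))) == ea.fiducial

    def test_fewer_than_two_beats_rejected(self):
        rec = ECGRecord(np.zeros(2000), fs=250.0)
        with pytest.raises(ValueError):
            compute_ensemble_average(rec, np.array([500]))

    def test_wave_order_preserved(self, cfg):
        """P, R and T extrema of the EA appear in generation order."""
        rec = clean_record(cfg, duration=60.0)
        ea = compute_ensemble_average(remove_baseline(rec),
                                      rec.meta["r_peaks"])
        co = extract_coefficients(ea, norm=rec.meta["max_amplitude_mv"])
        assert co.tP >= 0 and co.tQRS >= 0
        assert np.isfinite(co.aP) and np.isfinite(co.aT)


class TestCoefficientExtraction:
    def test_noiseless_recovery_within_5_percent(self, cfg):
        rec = clean_record(cfg, duration=60.0)
        ea = compute_ensemble_average(remove_baseline(rec),
                                      rec.meta["r_peaks"])
        got = extract_coefficients(ea, norm=rec.meta["max_amplitude_mv"])
        want = rec.meta["coefficients"]
        for name in COEFFICIENT_NAMES:
            rel = abs(getattr(got, name) - getattr(want, name)) \
                / getattr(want, name)
            assert rel < 0.05, name

    def test_scale_invariance_of_normalized_amplitudes(self, cfg):
        rec = clean_record(cfg, duration=40.0)
        peaks = rec.meta["r_peaks"]
        ea1 = compute_ensemble_average(remove_baseline(rec), peaks)
        rec2 = rec.with_samples(2.0 * rec.samples)
        ea2 = compute_ensemble_average(remove_baseline(rec2), peaks)
        c1 = extract_coefficients(ea1, norm=1.5)
        c2 = extract_coefficients(ea2, norm=3.0)
        for name in COEFFICIENT_NAMES:
            assert getattr(c2, name) == pytest.approx(getattr(c1, name),
                                                      rel=1e-6)

    def test_duration_unit_arithmetic(self):
        """A wave occupying 0.21 s of a 1.0 s beat reports 210 ms/s."""
        fs = 500.0
        window = int(1.0 * fs)
        y = np.zeros(window)
        r0 = int(0.4 * fs)
        y[r0 - 25:r0 + 25] += np.hanning(50) * 1.0       # QRS stand-in
        t0 = int(0.70 * fs)
        width = int(0.21 * fs / 0.8565)                   # 5% support .21s
        y[t0:t0 + width] += np.hanning(width) * 0.25
        ea = EnsembleAverage(mean=y, sd=np.zeros_like(y), fiducial=r0,
                             window=window, n_beats=5, fs=fs)
        co = extract_coefficients(ea, norm=1.0, beat_period=1.0)
        assert co.dT == pytest.approx(210.0, rel=0.03)

    def test_missing_t_wave_flagged_nan_not_zero(self):
        fs = 250.0
        window = 250
        y = np.zeros(window)
        r0 = 100
        y[r0 - 12:r0 + 13] = np.hanning(25)
        ea = EnsembleAverage(mean=y, sd=np.zeros_like(y), fiducial=r0,
                             window=window, n_beats=4, fs=fs)
        co = extract_coefficients(ea, norm=1.0)
        assert np.isnan(co.aT) and np.isnan(co.dT) and np.isnan(co.tQRS)
        assert np.isnan(co.aP)

    def test_invalid_norm_rejected(self):
        ea = EnsembleAverage(mean=np.ones(100), sd=np.zeros(100),
                             fiducial=40, window=100, n_beats=3, fs=250.0)
        with pytest.raises(ValueError):
            extract_coefficients(ea, norm=0.0)


class TestCohortRecovery:
    def test_median_relative_error_below_5_percent(self, small_cohort):
        """End-to-end parameter recovery over a small clean cohort."""
        cfg, subjects = small_cohort
        errors = {name: [] for name in COEFFICIENT_NAMES}
        for spec in subjects:
            for lead, side in (("D1", "front"), ("D2", "front"),
                               ("D3", "back")):
                rec = subject_record(spec, cfg, lead, side, 0)
                peaks = detect_r_peaks(rec)
                ea = compute_ensemble_average(remove_baseline(rec), peaks)
                got = extract_coefficients(
                    ea, norm=rec.meta["max_amplitude_mv"])
                want = spec.coefficients[(lead, side)]
                for name in COEFFICIENT_NAMES:
                    errors[name].append(
                        abs(getattr(got, name) - getattr(want, name))
                        / getattr(want, name))
        for name, errs in errors.items():
            assert np.median(errs) < 0.05, name
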