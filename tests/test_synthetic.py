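"""Synthetic cohort generator: coefficients, templates, artifacts."""

import numpy as np
import pytest

from torsoecg.records import SegmentCoefficients, COEFFICIENT_NAMES
from torsoecg.synthetic_ecg import (
    CohortConfig, sample_subject_coefficients, beat_template,
    distort_coefficients, synth_record, add_motion_artifact,
    generate_cohort, subject_record,
)
from torsoecg.morphology import snr_db, dtw_distance
from torsoecg import cohort_tables


@pytest.fixture(scope="module")
def cfg():
    return CohortConfig(seed=11)


class TestCoefficientSampling:
    def test_zero_sd_returns_means_exactly(self):
        c = CohortConfig(coeff_sd=cohort_tables.VOLUNTEER_COEFFS_SD * 0.0)
        draws = sample_subject_coefficients(c, np.random.default_rng(0))
        assert draws[("D2", "front")].aQRS == 738.9
        assert draws[("D1", "back")].dT == 227.5

    def test_same_seed_identical_draws(self, cfg):
        a = sample_subject_coefficients(cfg, np.random.default_rng(42))
        b = sample_subject_coefficients(cfg, np.random.default_rng(42))
        for key in a:
            assert np.array_equal(a[key].as_array(), b[key].as_array())

    def test_monte_carlo_means_within_three_standard_errors(self, cfg):
        rng = np.random.default_rng(123)
        n = 1000
        draws = np.array([
            sample_subject_coefficients(cfg, rng)[("D2", "front")].as_array()
            for _ in range(n)])
        mean = np.asarray(cfg.coeff_mean["D2front"], float)
        sd = np.asarray(cfg.coeff_sd["D2front"], float)
        se = sd / np.sqrt(n)
        # truncation at zero is negligible at >20 sd from zero
        assert np.all(np.abs(draws.mean(axis=0) - mean) < 3.0 * se)

    def test_draws_never_negative(self, cfg):
        rng = np.random.default_rng(3)
        for _ in range(50):
            for co in sample_subject_coefficients(cfg, rng).values():
                assert np.all(co.as_array() >= 0.0)


class TestBeatTemplate:
    def test_wave_supports_match_configured_durations(self, cfg):
        co = SegmentCoefficients.from_array(
            np.asarray(cfg.coeff_mean["D2front"], float))
        hr, fs, amp = 60.0, 2000.0, 1.5   # fine fs to measure supports
        beat, r_idx = beat_template(co, hr, fs, amp)
        a = np.abs(beat)
        thr_r = 0.05 * a.max()
        # outer 5 % exceedance of the QRS complex: first/last above-
        # threshold sample between the P-QRS and QRS-T gaps (brief
        # polarity-crossing notches inside the complex do not end it)
        gap = int(0.02 * fs)
        above = a >= thr_r
        i = r_idx
        while i > gap and above[i - gap:i].any():
            i -= 1
        j = r_idx
        while j < len(a) - gap - 1 and above[j + 1:j + gap + 1].any():
            j += 1
        measured = (j - i) / fs
        assert measured == pytest.approx(co.dQRS / 1000.0, rel=0.03)

    def test_amplitudes_scale_with_coefficients(self, cfg):
        co = SegmentCoefficients.from_array(
            np.asarray(cfg.coeff_mean["D2front"], float))
        beat, r_idx = beat_template(co, 70.0, 250.0, 1.5)
        assert beat[r_idx] == pytest.approx(co.aQRS / 1000.0 * 1.5, rel=0.02)

    def test_overfull_beat_raises(self):
        co = SegmentCoefficients(aP=50, aQRS=700, aT=100, dP=300, dQRS=300,
                                 dT=390, tP=200, tQRS=200)
        with pytest.raises(ValueError, match="beat period"):
            beat_template(co, 70.0, 250.0, 1.5)

    def test_distortion_identity_at_zero(self, cfg):
        co = SegmentCoefficients.from_array(
            np.asarray(cfg.coeff_mean["D3back"], float))
        assert distort_coefficients(co, 0.0) is co


class TestSynthRecord:
    def test_sample_count_and_beat_count(self, cfg):
        co = SegmentCoefficients.from_array(
            np.asarray(cfg.coeff_mean["D2front"], float))
        rec = synth_record(co, 0, hr=60.0, duration=10.0, cfg=cfg,
                          rng=np.random.default_rng(0))
        assert len(rec.samples) == 2500
        assert abs(len(rec.meta["r_peaks"]) - 10) <= 1

    def test_position_zero_is_identity(self, cfg):
        co = SegmentCoefficients.from_array(
            np.asarray(cfg.coeff_mean["D2front"], float))
        a = synth_record(co, 0, 70.0, 20.0, cfg, np.random.default_rng(5))
        b = synth_record(co, 0, 70.0, 20.0, cfg, np.random.default_rng(5))
        assert np.array_equal(a.samples, b.samples)

    def test_amplitude_scale_property(self, cfg):
        """Scaling all amplitude coefficients by alpha scales the clean
        record by alpha exactly."""
        base = np.asarray(cfg.coeff_mean["D2front"], float)
        co1 = SegmentCoefficients.from_array(base)
        scaled = base.copy()
        scaled[:3] *= 2.5
        co2 = SegmentCoefficients.from_array(scaled)
        a = synth_record(co1, 0, 70.0, 15.0, cfg, np.random.default_rng(9))
        b = synth_record(co2, 0, 70.0, 15.0, cfg, np.random.default_rng(9))
        assert np.allclose(b.samples, 2.5 * a.samples, atol=1e-12)

    def test_dtw_distances_grow_with_position_for_d2_front(self, cfg):
        """Displaced templates reproduce the reference cohort's strictly
        increasing distance ordering for lead D2 on the front."""
        co = SegmentCoefficients.from_array(
            np.asarray(cfg.coeff_mean["D2front"], float))
        ref, _ = beat_template(co, cfg.hr_mean, cfg.fs, cfg.max_amp_mean)
        gains = cfg.position_gains("D2", "front")
        dists = []
        for k in range(1, 7):
            beat, _ = beat_template(distort_coefficients(co, gains[k]),
                                    cfg.hr_mean, cfg.fs, cfg.max_amp_mean)
            dists.append(dtw_distance(ref * 1e3, beat * 1e3))
        assert all(b > a for a, b in zip(dists, dists[1:]))
        targets = cohort_tables.dtw_targets("D2", "front")
        assert np.all(np.abs(dists - targets) <= 0.5 * targets)

    def test_invalid_position_rejected(self, cfg):
        co = SegmentCoefficients.from_array(
            np.asarray(cfg.coeff_mean["D2front"], float))
        with pytest.raises(ValueError):
            synth_record(co, 9, 70.0, 10.0, cfg, np.random.default_rng(0))


class TestMotionArtifact:
    def _record(self, cfg, seed=0):
        co = SegmentCoefficients.from_array(
            np.asarray(cfg.coeff_mean["D2front"], float))
        return synth_record(co, 0, 70.0, 30.0, cfg,
                            np.random.default_rng(seed))

    def test_zero_amplitude_mixture_identity(self, cfg):
        rec = self._record(cfg)
        import dataclasses

        quiet = dataclasses.replace(cfg, artifact_mix=(0.0, 0.0, 0.0))
        out = add_motion_artifact(rec, quiet, np.random.default_rng(1))
        assert np.array_equal(out.samples, rec.samples)

    def test_target_snr_realized_exactly(self, cfg):
        rec = self._record(cfg)
        out = add_motion_artifact(rec, cfg, np.random.default_rng(2),
                                  target_snr_db=0.0)
        assert snr_db(rec.samples, out.samples) == pytest.approx(0.0,
                                                                 abs=0.5)
        out10 = add_motion_artifact(rec, cfg, np.random.default_rng(2),
                                    target_snr_db=10.0)
        assert snr_db(rec.samples, out10.samples) == pytest.approx(10.0,
                                                                   abs=0.5)

    def test_same_seed_identical_realization(self, cfg):
        rec = self._record(cfg)
        a = add_motion_artifact(rec, cfg, np.random.default_rng(7),
                                target_snr_db=3.0)
        b = add_motion_artifact(rec, cfg, np.random.default_rng(7),
                                target_snr_db=3.0)
        assert np.array_equal(a.samples, b.samples)

    def test_condition_tagged_walking(self, cfg):
        out = add_motion_artifact(self._record(cfg), cfg,
                                  np.random.default_rng(3))
        assert out.condition == "walking"


class TestCohort:
    def test_cohort_is_bit_identical_across_runs(self):
        c1 = CohortConfig(n_subjects=3, rest_duration=20.0, seed=21)
        c2 = CohortConfig(n_subjects=3, rest_duration=20.0, seed=21)
        s1, s2 = generate_cohort(c1), generate_cohort(c2)
        for a, b in zip(s1, s2):
            assert a.hr == b.hr and a.max_amp == b.max_amp
            ra = subject_record(a, c1, "D3", "back", 2)
            rb = subject_record(b, c2, "D3", "back", 2)
            assert np.array_equal(ra.samples, rb.samples)

    def test_channels_share_rr_sequence(self, small_cohort):
        cfg, subjects = small_cohort
        spec = subjects[0]
        r1 = subject_record(spec, cfg, "D1", "front", 0)
        r2 = subject_record(spec, cfg, "D3", "back", 4)
        assert np.array_equal(r1.meta["r_peaks"], r2.meta["r_peaks"])

    def test_ground_truth_metadata_complete(self, small_cohort):
        cfg, subjects = small_cohort
        rec = subject_record(subjects[1], cfg, "D2", "front", 3)
        assert len(rec.meta["r_peaks"]) > 10
        assert isinstance(rec.meta["coefficients"], SegmentCoefficients)
        assert rec.meta["max_amplitude_mv"] > 0
        assert rec.meta["distortion_magnitude"] > 0
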