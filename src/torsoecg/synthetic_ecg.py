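"""Synthetic volunteer cohort: parametric ECG records with ground truth.

The volunteer recordings behind the reference tables are not public, so
this module generates a stand-in cohort.  Each subject is a draw of
segment coefficients (amplitudes, durations, timings of P/QRS/T) around
the cohort reference means, a heart rate, and a maximum amplitude; each
record is a train of template beats with log-normal RR jitter.  Three
aspects of the real study are emulated explicitly:

* **Coefficient semantics.**  A beat is built so that applying the
  package's own delineation (5 %-of-peak support, normalized units) to
  the clean template recovers the configured coefficients: P and T are
  raised-cosine lobes parameterized directly by their 5 % support, and
  the triphasic QRS is width-calibrated by a short fixed-point loop.
  The configured coefficients are therefore the record's ground truth,
  emitted in the record metadata together with the true R-peak times.

* **Position-dependent distortion.**  Displacing the electrodes changes
  wave amplitudes, durations and timings.  The distortion law applies a
  scalar magnitude per (lead, side, position), calibrated once per
  configuration so that the DTW distance between the displaced and the
  reference template matches the cohort's published mean distances.

* **Motion artifacts.**  Walking records receive an additive mixture of
  baseline wander (0.1-0.8 Hz), band-limited EMG-like noise and sparse
  electrode-motion transients, scaled to a per-subject target SNR
  (artifacts in the real study varied between subjects far more than
  between positions).

Within a subject and condition, all leads, sides and positions share the
same RR sequence, as they would in a simultaneous multi-channel
recording.  Every random draw descends from the master seed, so a
cohort is bit-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.stats import truncnorm

from torsoecg.records import ECGRecord, SegmentCoefficients, LEADS, SIDES
from torsoecg import cohort_tables

_HANN_SUPPORT = 1.0 - 2.0 * np.arcsin(np.sqrt(0.05)) / np.pi  # ~0.8565


@dataclass
class CohortConfig:
    """Study conditions of the synthetic cohort."""

    n_subjects: int = 20
    fs: float = 250.0
    rest_duration: float = 300.0      # s
    walking_duration: float = 300.0   # s
    hr_mean: float = 70.0             # bpm
    hr_sd: float = 8.0
    max_amp_mean: float = 1.5         # mV, subject maximum amplitude
    max_amp_sd: float = 0.2
    rr_cv: float = 0.03               # log-normal RR jitter
    coeff_mean: "object" = None       # DataFrame, defaults to cohort table
    coeff_sd: "object" = None
    artifact_snr_mean: float = 3.0    # dB, per-subject target
    artifact_snr_sd: float = 3.0
    artifact_mix: tuple = (0.5, 0.3, 0.2)  # wander, EMG, transients
    position_gain_jitter: float = 0.15     # per-subject log-normal CV
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("cohort needs at least one subject")
        if self.fs <= 0:
            raise ValueError("sampling frequency must be positive")
        if self.coeff_mean is None:
            self.coeff_mean = cohort_tables.VOLUNTEER_COEFFS_MEAN.copy()
        if self.coeff_sd is None:
            self.coeff_sd = cohort_tables.VOLUNTEER_COEFFS_SD.copy()
        if (np.asarray(self.coeff_sd) < 0).any():
            raise ValueError("coefficient SDs must be non-negative")
        self._gain_cache = {}

    def position_gains(self, lead: str, side: str) -> np.ndarray:
        """Distortion magnitudes for positions 0-6, calibrated lazily
        against the reference DTW-by-position table."""
        key = (lead, side)
        if key not in self._gain_cache:
            self._gain_cache[key] = _calibrate_gains(self, lead, side)
        return self._gain_cache[key]


def sample_subject_coefficients(cfg: CohortConfig, rng) -> dict:
    """Draw one subject's coefficients per (lead, side).

    Independent truncated-normal draws (truncated at zero) around the
    configured means; zero SD returns the mean exactly.
    """
    out = {}
    for lead in LEADS:
        for side in SIDES:
            col = f"{lead}{side}"
            mean = np.asarray(cfg.coeff_mean[col], float)
            sd = np.asarray(cfg.coeff_sd[col], float)
            vals = mean.copy()
            pos = sd > 0
            if pos.any():
                a = (0.0 - mean[pos]) / sd[pos]
                vals[pos] = truncnorm.rvs(
                    a, np.inf, loc=mean[pos], scale=sd[pos],
                    random_state=rng)
            out[(lead, side)] = SegmentCoefficients.from_array(vals)
    return out


# ---------------------------------------------------------------------------
# beat template

def _cos_lobe(t, center, support, amp):
    """Raised-cosine lobe whose 5 %-of-peak support equals ``support``."""
    width = support / _HANN_SUPPORT
    x = (t - center) / width + 0.5
    out = np.zeros_like(t)
    inside = (x > 0) & (x < 1)
    out[inside] = amp * np.sin(np.pi * x[inside]) ** 2
    return out


def _qrs_complex(t, onset, width, amp):
    """Triphasic QRS: small Q and S lobes flanking a tall R lobe.

    The lobes overlap so the complex magnitude only touches zero at the
    brief polarity crossings, never in sustained notches; downstream
    delineation can then find the outer 5 % edges by walking out from
    the R peak.
    """
    q = _cos_lobe(t, onset + 0.16 * width, 0.28 * width * _HANN_SUPPORT,
                  -0.11 * amp)
    r = _cos_lobe(t, onset + 0.50 * width, 0.55 * width * _HANN_SUPPORT,
                  amp)
    s = _cos_lobe(t, onset + 0.84 * width, 0.32 * width * _HANN_SUPPORT,
                  -0.17 * amp)
    return q + r + s


def _support_5pct(t, y):
    """Interval where |y| exceeds 5 % of its peak (sub-sample edges)."""
    a = np.abs(y)
    thr = 0.05 * a.max()
    above = a >= thr
    i0 = int(np.argmax(above))
    i1 = len(a) - 1 - int(np.argmax(above[::-1]))
    dt = t[1] - t[0]
    left = t[i0]
    if i0 > 0:
        left -= dt * (a[i0] - thr) / max(a[i0] - a[i0 - 1], 1e-30)
    right = t[i1]
    if i1 < len(a) - 1:
        right += dt * (a[i1] - thr) / max(a[i1] - a[i1 + 1], 1e-30)
    return left, right


def beat_template(coeffs: SegmentCoefficients, hr: float, fs: float,
                  max_amp: float, oversample: int = 8):
    """One beat sampled at ``fs`` with the R peak at 40 % of the window.

    Returns ``(samples_mV, r_index)``.  The wave supports measured at
    the 5 %-of-peak level equal the configured durations; gaps between
    the 5 % edges equal the configured timings.
    """
    T = 60.0 / hr
    n = int(round(T * fs))
    tt = np.arange(n * oversample) / (fs * oversample)
    r_time = 0.4 * T

    wP = coeffs.dP / 1000.0 * T
    wQ = coeffs.dQRS / 1000.0 * T
    wT = coeffs.dT / 1000.0 * T
    gP = coeffs.tP / 1000.0 * T
    gT = coeffs.tQRS / 1000.0 * T
    aP = coeffs.aP / 1000.0 * max_amp
    aR = coeffs.aQRS / 1000.0 * max_amp
    aT = coeffs.aT / 1000.0 * max_amp
    total = wP + gP + wQ + gT + wT
    if total > T:
        raise ValueError(
            f"segments occupy {total * 1000:.0f} ms > beat period "
            f"{T * 1000:.0f} ms")

    # width-calibrate the QRS so its measured 5 % support equals wQ and
    # its R peak lands on r_time
    width = wQ
    onset = r_time - 0.48 * width
    for _ in range(3):
        y = _qrs_complex(tt, onset, width, aR)
        left, right = _support_5pct(tt, y)
        width *= wQ / (right - left)
        onset += r_time - tt[int(np.argmax(y))]
    qrs = _qrs_complex(tt, onset, width, aR)
    left, right = _support_5pct(tt, qrs)

    p = _cos_lobe(tt, left - gP - wP / 2.0, wP, aP)
    twave = _cos_lobe(tt, right + gT + wT / 2.0, wT, aT)
    dense = qrs + p + twave
    beat = dense[::oversample].copy()
    r_index = int(np.argmax(beat))
    return beat + coeffs.c, r_index


def distort_coefficients(coeffs: SegmentCoefficients,
                         m: float) -> SegmentCoefficients:
    """Displaced-electrode distortion of magnitude ``m`` (0 = identity).

    A mixture of global and wave-specific amplitude changes, a QRS
    width change and timing shifts; the composition is fixed and the
    single magnitude is what the position calibration adjusts.
    """
    if m == 0.0:
        return coeffs
    g = 1.0 + 0.45 * m   # lead-projection gain, grows without bound
    mb = min(m, 2.0)     # bounded shape changes
    dP = coeffs.dP
    dQRS = coeffs.dQRS * (1.0 + 0.10 * mb)
    dT = coeffs.dT * max(1.0 - 0.06 * m, 0.5)
    tP = coeffs.tP * max(1.0 - 0.12 * m, 0.2)
    tQRS = coeffs.tQRS * (1.0 + 0.20 * mb)
    total = dP + dQRS + dT + tP + tQRS
    if total > 950.0:
        shrink = 950.0 / total
        dP, dQRS, dT, tP, tQRS = (x * shrink
                                  for x in (dP, dQRS, dT, tP, tQRS))
    return SegmentCoefficients(
        aP=coeffs.aP * g * (1.0 + 0.25 * mb),
        aQRS=coeffs.aQRS * g * max(1.0 - 0.20 * mb, 0.25),
        aT=coeffs.aT * g * (1.0 + 0.15 * mb),
        dP=dP, dQRS=dQRS, dT=dT, tP=tP, tQRS=tQRS,
        c=coeffs.c,
    )


def _calibrate_gains(cfg: CohortConfig, lead: str, side: str) -> np.ndarray:
    """Solve for the per-position distortion magnitudes that reproduce
    the reference cohort's mean DTW distances (bisection per position)."""
    from torsoecg.morphology import dtw_distance

    col = f"{lead}{side}"
    coeffs = SegmentCoefficients.from_array(
        np.asarray(cfg.coeff_mean[col], float))
    ref, _ = beat_template(coeffs, cfg.hr_mean, cfg.fs, cfg.max_amp_mean)
    ref_uv = ref * 1000.0
    targets = cohort_tables.dtw_targets(lead, side)

    def dist(m):
        beat, _ = beat_template(distort_coefficients(coeffs, m),
                                cfg.hr_mean, cfg.fs, cfg.max_amp_mean)
        return dtw_distance(ref_uv, beat * 1000.0)

    gains = [0.0]
    for target in targets:
        lo, hi = 0.0, 2.5
        while dist(hi) < target and hi < 60.0:
            hi *= 1.6
        for _ in range(35):
            mid = 0.5 * (lo + hi)
            if dist(mid) < target:
                lo = mid
            else:
                hi = mid
        gains.append(0.5 * (lo + hi))
    return np.array(gains)


# ---------------------------------------------------------------------------
# records

def synth_record(coeffs: SegmentCoefficients, position: int, hr: float,
                 duration: float, cfg: CohortConfig, rng,
                 lead: str = "D2", side: str = "front",
                 subject: str = "synthetic", max_amp: float | None = None,
                 gain_jitter: float = 1.0,
                 rr_factors: np.ndarray | None = None) -> ECGRecord:
    """Generate one clean record at the given electrode position.

    Position 0 is the identity; displaced positions distort the beat
    template by the calibrated magnitude times ``gain_jitter``.
    ``rr_factors`` (multiplicative jitter per beat) may be supplied so
    that simultaneously recorded channels share one RR sequence; if
    omitted they are drawn from ``rng``.
    """
    if position not in range(7):
        raise ValueError("position must be 0..6")
    max_amp = cfg.max_amp_mean if max_amp is None else max_amp
    m = cfg.position_gains(lead, side)[position] * gain_jitter
    beat, r_off = beat_template(distort_coefficients(coeffs, m),
                                hr, cfg.fs, max_amp)

    n = int(round(duration * cfg.fs))
    rr_nom = 60.0 / hr
    n_beats = int(np.ceil(duration / rr_nom)) + 2
    if rr_factors is None:
        sigma = np.sqrt(np.log(1.0 + cfg.rr_cv ** 2))
        rr_factors = np.exp(rng.normal(-sigma ** 2 / 2.0, sigma, n_beats))
    rr = rr_nom * rr_factors[:n_beats]
    r_times = np.cumsum(rr) - rr[0] + 0.4 * rr_nom

    samples = np.zeros(n)
    r_peaks = []
    for rt in r_times:
        start = int(round(rt * cfg.fs)) - r_off
        if start >= n:
            break
        lo = max(start, 0)
        hi = min(start + len(beat), n)
        if hi <= lo:
            continue
        samples[lo:hi] += beat[lo - start:hi - start]
        rp = start + r_off
        if 0 <= rp < n:
            r_peaks.append(rp)

    return ECGRecord(
        samples=samples, fs=cfg.fs, lead=lead, position=position,
        side=side, subject=str(subject), condition="rest",
        meta={
            "r_peaks": np.array(r_peaks, dtype=int),
            "coefficients": coeffs,
            "distortion_magnitude": float(m),
            "max_amplitude_mv": float(max_amp),
            "hr_bpm": float(hr),
        })


def add_motion_artifact(record: ECGRecord, cfg: CohortConfig, rng,
                        target_snr_db: float | None = None) -> ECGRecord:
    """Contaminate a record with walking-motion artifacts.

    Baseline wander, EMG-like noise and sparse transients are mixed in
    the configured power ratio and scaled so the SNR of the clean versus
    contaminated record equals ``target_snr_db`` exactly.  A zero-power
    mixture (or an infinite target) returns the samples unchanged.
    """
    if target_snr_db is None:
        target_snr_db = rng.normal(cfg.artifact_snr_mean,
                                   cfg.artifact_snr_sd)
    n = len(record.samples)
    fs = record.fs
    t = np.arange(n) / fs

    wander = np.zeros(n)
    for _ in range(4):
        f = rng.uniform(0.1, 0.8)
        wander += rng.uniform(0.3, 1.0) * np.sin(
            2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))

    emg = rng.standard_normal(n)
    sos = sps.butter(4, [20.0, min(60.0, 0.45 * fs)], btype="bandpass",
                     fs=fs, output="sos")
    emg = sps.sosfiltfilt(sos, emg)

    transients = np.zeros(n)
    n_events = rng.poisson(0.2 * record.duration)
    kernel_t = np.arange(int(0.6 * fs)) / fs
    for _ in range(n_events):
        start = int(rng.integers(0, max(n - len(kernel_t), 1)))
        amp = rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 2.0)
        kern = amp * np.exp(-kernel_t / 0.15)
        end = min(start + len(kern), n)
        transients[start:end] += kern[:end - start]

    parts = []
    for comp, weight in zip((wander, emg, transients), cfg.artifact_mix):
        power = np.sum(comp ** 2)
        if power > 0 and weight > 0:
            parts.append(np.sqrt(weight / power) * comp)
    if not parts or not np.isfinite(target_snr_db):
        return record.with_samples(record.samples.copy(),
                                   target_snr_db=float(target_snr_db))
    artifact = np.sum(parts, axis=0)

    p_sig = np.sum(record.samples ** 2)
    p_art = np.sum(artifact ** 2)
    if p_art == 0 or p_sig == 0:
        return record.with_samples(record.samples.copy(),
                                   target_snr_db=float(target_snr_db))
    scale = np.sqrt(p_sig / (p_art * 10.0 ** (target_snr_db / 10.0)))
    out = record.with_samples(record.samples + scale * artifact,
                              target_snr_db=float(target_snr_db))
    out.condition = "walking"
    return out


# ---------------------------------------------------------------------------
# cohort

@dataclass
class SubjectSpec:
    """Deterministic recipe for one synthetic subject."""

    subject_id: str
    hr: float
    max_amp: float
    coefficients: dict          # (lead, side) -> SegmentCoefficients
    gain_jitter: float
    artifact_snr_db: float
    rest_seed: int
    walking_seed: int


def generate_cohort(cfg: CohortConfig) -> list:
    """Draw the cohort's subject specifications from the master seed.

    Records are built on demand by :func:`subject_record`, keeping the
    cohort memory-light; the same spec always yields identical records.
    """
    rng = np.random.default_rng(cfg.seed)
    subjects = []
    for i in range(cfg.n_subjects):
        coeffs = sample_subject_coefficients(cfg, rng)
        hr = float(np.clip(rng.normal(cfg.hr_mean, cfg.hr_sd), 45.0, 120.0))
        max_amp = float(np.clip(rng.normal(cfg.max_amp_mean, cfg.max_amp_sd),
                                0.5, 3.0))
        sigma = np.sqrt(np.log(1.0 + cfg.position_gain_jitter ** 2))
        gain_jitter = float(np.exp(rng.normal(-sigma ** 2 / 2.0, sigma)))
        snr = float(rng.normal(cfg.artifact_snr_mean, cfg.artifact_snr_sd))
        subjects.append(SubjectSpec(
            subject_id=f"S{i + 1:02d}", hr=hr, max_amp=max_amp,
            coefficients=coeffs, gain_jitter=gain_jitter,
            artifact_snr_db=snr,
            rest_seed=int(rng.integers(2 ** 31)),
            walking_seed=int(rng.integers(2 ** 31))))
    return subjects


def _channel_index(lead: str, side: str, position: int) -> int:
    return (LEADS.index(lead) * 2 + SIDES.index(side)) * 7 + position


def subject_record(spec: SubjectSpec, cfg: CohortConfig, lead: str,
                   side: str, position: int,
                   condition: str = "rest") -> ECGRecord:
    """Build one record of a subject.

    Channels of the same condition share the RR sequence (simultaneous
    recording); walking channels each draw their own artifact
    realization at the subject's target SNR.
    """
    if condition == "rest":
        duration, seed = cfg.rest_duration, spec.rest_seed
    elif condition == "walking":
        duration, seed = cfg.walking_duration, spec.walking_seed
    else:
        raise ValueError(f"unknown condition {condition!r}")

    rr_rng = np.random.default_rng(seed)
    rr_nom = 60.0 / spec.hr
    n_beats = int(np.ceil(duration / rr_nom)) + 2
    sigma = np.sqrt(np.log(1.0 + cfg.rr_cv ** 2))
    rr_factors = np.exp(rr_rng.normal(-sigma ** 2 / 2.0, sigma, n_beats))

    chan_rng = np.random.default_rng(
        (seed, _channel_index(lead, side, position)))
    rec = synth_record(spec.coefficients[(lead, side)], position, spec.hr,
                       duration, cfg, chan_rng, lead=lead, side=side,
                       subject=spec.subject_id, max_amp=spec.max_amp,
                       gain_jitter=spec.gain_jitter, rr_factors=rr_factors)
    if condition == "walking":
        rec = add_motion_artifact(rec, cfg, chan_rng,
                                  target_snr_db=spec.artifact_snr_db)
    return rec
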