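"""Ensemble-average ECG: R-peak detection, beat averaging, coefficients.

The ensemble average (EA) of an ECG aligns successive beats at a
fiducial point — the R peak — and averages them pointwise, yielding the
subject's standard waveform plus a per-sample standard-deviation
envelope.  The beat window is the median RR interval, split 40 % before
and 60 % after the fiducial so both the P and the T wave stay inside
the frame at resting rates.

From the EA the P/QRS/T segment coefficients are extracted in the
normalized units used throughout the package: amplitudes in uV per mV
of the subject's maximum amplitude (the maximum absolute EA amplitude
across the three leads of a side), durations and inter-wave timings in
ms per s of beat period.  Waves are delineated at the 5 %-of-peak
level with sub-sample interpolation; an undetectable P or T yields NaN
coefficients (flagged missing), never zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from torsoecg.records import ECGRecord, SegmentCoefficients


@dataclass
class EnsembleAverage:
    """Mean beat waveform with its SD envelope."""

    mean: np.ndarray
    sd: np.ndarray
    fiducial: int           # R-peak index within the window
    window: int             # window length, samples
    n_beats: int
    fs: float

    @property
    def beat_period(self) -> float:
        """Beat period implied by the window, s."""
        return self.window / self.fs


def detect_r_peaks(record: ECGRecord) -> np.ndarray:
    """Detect R peaks with a Pan-Tompkins-style feature chain.

    Band-pass (5-25 Hz), differentiate, square, moving-window integrate
    (150 ms), threshold adaptively, then refine each detection to the
    extremum of the band-passed signal.  A refractory period of 200 ms
    is enforced.  Returns strictly increasing sample indices; a record
    with no discernible peaks returns an empty array with a warning.
    """
    x = np.asarray(record.samples, float)
    fs = record.fs
    if len(x) < 3 * fs:
        raise ValueError("record must be at least 3 s long")
    if np.ptp(x) == 0:
        warnings.warn("flat record: no R peaks found")
        return np.array([], dtype=int)

    sos = sps.butter(3, [5.0, min(25.0, 0.45 * fs)], btype="bandpass",
                     fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    feat = np.gradient(bp) ** 2
    win = max(int(0.150 * fs), 1)
    feat = np.convolve(feat, np.ones(win) / win, mode="same")

    refractory = int(0.2 * fs)
    cand, _ = sps.find_peaks(feat, distance=refractory)
    if cand.size == 0:
        warnings.warn("no R peaks found")
        return np.array([], dtype=int)
    level = np.percentile(feat[cand], 90)
    thr = 0.25 * level
    cand = cand[feat[cand] >= thr]
    if cand.size == 0:
        warnings.warn("no R peaks above threshold")
        return np.array([], dtype=int)

    # refine to the R extremum of the band-passed signal
    half = int(0.06 * fs)
    peaks = []
    for c in cand:
        lo = max(c - half, 0)
        hi = min(c + half + 1, len(x))
        peaks.append(lo + int(np.argmax(np.abs(bp[lo:hi]))))
    peaks = np.array(sorted(set(peaks)), dtype=int)
    keep = [int(peaks[0])]
    for p in peaks[1:]:
        if p - keep[-1] >= refractory:
            keep.append(int(p))
        elif np.abs(bp[p]) > np.abs(bp[keep[-1]]):
            keep[-1] = int(p)
    return np.array(keep, dtype=int)


def remove_baseline(record: ECGRecord) -> ECGRecord:
    """Zero-phase high-pass (0.67 Hz, 4th-order Butterworth).

    Removes the constant offset and baseline wander with negligible
    attenuation of the QRS band, so the offset coefficient of the beat
    model can be dropped downstream.
    """
    sos = sps.butter(4, 0.67, btype="highpass", fs=record.fs, output="sos")
    return record.with_samples(sps.sosfiltfilt(sos, record.samples),
                               baseline_removed=True)


def compute_ensemble_average(record: ECGRecord,
                             peaks: np.ndarray | None = None
                             ) -> EnsembleAverage:
    """Average beats aligned at their R peaks.

    Beats are windowed to the median RR interval (40 % pre / 60 %
    post fiducial); beats whose RR deviates more than 25 % from the
    median are dropped as rhythm outliers.  Requires at least two
    usable beats.
    """
    if peaks is None:
        peaks = detect_r_peaks(record)
    peaks = np.asarray(peaks, dtype=int)
    if peaks.size < 2:
        raise ValueError("ensemble average needs at least 2 detected beats")

    rr = np.diff(peaks)
    med_rr = float(np.median(rr))
    good = np.abs(rr - med_rr) <= 0.25 * med_rr
    window = int(round(med_rr))
    pre = int(round(0.4 * window))
    post = window - pre

    x = record.samples
    beats = []
    for i, p in enumerate(peaks):
        left_ok = i == 0 or good[i - 1]
        right_ok = i == len(peaks) - 1 or good[i]
        if not (left_ok and right_ok):
            continue
        if p - pre < 0 or p + post > len(x):
            continue
        beats.append(x[p - pre:p + post])
    if len(beats) < 2:
        raise ValueError("fewer than 2 usable beats for the ensemble")
    stack = np.vstack(beats)
    return EnsembleAverage(mean=stack.mean(axis=0), sd=stack.std(axis=0),
                           fiducial=pre, window=window,
                           n_beats=len(beats), fs=record.fs)


# ---------------------------------------------------------------------------
# coefficient extraction

def _crossing(a: np.ndarray, i: int, thr: float, step: int) -> float:
    """Sub-sample index where |a| falls below ``thr`` walking from ``i``
    in direction ``step``; the level must stay low for ~3 samples so the
    zero crossings inside a multiphasic complex are not mistaken for
    its edge."""
    n = len(a)
    j = i
    while 0 <= j + step < n:
        j += step
        if abs(a[j]) < thr:
            if step > 0:
                ahead = np.abs(a[j:min(j + 3, n)])
            else:
                ahead = np.abs(a[max(j - 2, 0):j + 1])
            if np.all(ahead < thr) or j in (0, n - 1):
                prev = j - step
                denom = abs(a[prev]) - abs(a[j])
                frac = (abs(a[prev]) - thr) / denom if denom > 0 else 0.0
                return prev + step * frac
    return float(j)


def _wave_bounds(a: np.ndarray, peak: int, thr: float):
    left = _crossing(a, peak, thr, -1)
    right = _crossing(a, peak, thr, +1)
    return left, right


def extract_coefficients(ea: EnsembleAverage, norm: float,
                         beat_period: float | None = None
                         ) -> SegmentCoefficients:
    """Normalized P/QRS/T coefficients of an ensemble-average beat.

    ``norm`` is the subject's maximum amplitude in mV (cross-lead
    maximum of the EA on that side); ``beat_period`` defaults to the EA
    window.  Amplitudes are reported in uV/mV, durations and timings in
    ms/s.  An undetectable P or T wave leaves its coefficients NaN.
    """
    if norm <= 0:
        raise ValueError("normalization amplitude must be positive")
    T = beat_period if beat_period is not None else ea.beat_period
    fs = ea.fs
    y = ea.mean - np.median(ea.mean)

    r_idx = ea.fiducial
    zone = slice(max(r_idx - int(0.06 * fs), 0), r_idx + int(0.06 * fs))
    r_idx = zone.start + int(np.argmax(np.abs(y[zone])))
    r_amp = abs(y[r_idx])
    if r_amp == 0:
        raise ValueError("flat ensemble average")

    thr_qrs = 0.05 * r_amp
    q_on, q_off = _wave_bounds(y, r_idx, thr_qrs)

    def norm_amp(v):
        return abs(v) / norm * 1000.0

    def norm_dur(samples):
        return samples / fs / T * 1000.0

    # P wave: search window before QRS onset
    p_vals = {"amp": np.nan, "on": np.nan, "off": np.nan}
    lo = max(int(q_on - 0.45 * T * fs), 0)
    hi = int(q_on) - max(int(0.01 * fs), 2)
    if hi > lo + 3:
        seg = y[lo:hi]
        p_idx = lo + int(np.argmax(np.abs(seg)))
        p_amp = abs(y[p_idx])
        if p_amp > 0.02 * r_amp:
            p_on, p_off = _wave_bounds(y, p_idx, 0.05 * p_amp)
            p_vals = {"amp": p_amp, "on": p_on, "off": min(p_off, q_on)}

    # T wave: search window after QRS offset
    t_vals = {"amp": np.nan, "on": np.nan, "off": np.nan}
    lo = int(q_off) + max(int(0.02 * fs), 2)
    hi = min(int(q_off + 0.60 * T * fs), len(y))
    if hi > lo + 3:
        seg = y[lo:hi]
        t_idx = lo + int(np.argmax(np.abs(seg)))
        t_amp = abs(y[t_idx])
        if t_amp > 0.02 * r_amp:
            t_on, t_off = _wave_bounds(y, t_idx, 0.05 * t_amp)
            t_vals = {"amp": t_amp, "on": max(t_on, q_off), "off": t_off}

    return SegmentCoefficients(
        aP=norm_amp(p_vals["amp"]) if np.isfinite(p_vals["amp"]) else np.nan,
        aQRS=norm_amp(r_amp),
        aT=norm_amp(t_vals["amp"]) if np.isfinite(t_vals["amp"]) else np.nan,
        dP=norm_dur(p_vals["off"] - p_vals["on"]),
        dQRS=norm_dur(q_off - q_on),
        dT=norm_dur(t_vals["off"] - t_vals["on"]),
        tP=max(norm_dur(q_on - p_vals["off"]), 0.0)
        if np.isfinite(p_vals["off"]) else np.nan,
        tQRS=max(norm_dur(t_vals["on"] - q_off), 0.0)
        if np.isfinite(t_vals["on"]) else np.nan,
    )
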