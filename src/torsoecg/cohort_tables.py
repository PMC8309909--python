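"""Reference statistics of the 20-volunteer resting/walking ECG study.

These tables summarize the volunteer cohort (20 healthy young males,
250 Hz, Mason-Likar reference placement, seven electrode positions on
front and back) that the synthetic generator emulates, together with
the matching outputs of the finite-element heart model study.  They
serve three roles in the package: defaults for the cohort generator,
calibration targets for the position-distortion law, and the inputs of
the headline front/back and model-versus-volunteer comparisons.

All values are mean (and SD where given).  Units follow the coefficient
conventions: amplitudes in uV per mV of subject maximum, durations and
timings in ms per s of beat period, DTW distances in uV, SNR in dB.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from torsoecg.records import COEFFICIENT_NAMES

LEAD_SIDE_COLUMNS = ["D1front", "D1back", "D2front", "D2back",
                     "D3front", "D3back"]

#: Cohort anthropometry (cm): inter-clavipectoral-triangle distance Wh
#: and sternal-angle-to-umbilical distance Wv, with the resulting
#: per-step electrode displacements at f = 0.125.
ANTHROPOMETRY = {
    "Wh_mean": 28.8, "Wh_sd": 1.4,
    "Wv_mean": 43.2, "Wv_sd": 3.3,
    "step_horizontal_mean": 3.6, "step_horizontal_sd": 0.1,
    "step_vertical_mean": 5.4, "step_vertical_sd": 0.4,
    "fs_hz": 250.0,
    "n_subjects": 20,
    "age_mean": 26.3, "age_sd": 5.7,
    "bmi_mean": 24.4, "bmi_sd": 4.8,
}


def _table(data: dict, index) -> pd.DataFrame:
    return pd.DataFrame(data, index=list(index))


#: Segment-coefficient means of the volunteer cohort at the reference
#: position (rows: coefficients; columns: lead x side).
VOLUNTEER_COEFFS_MEAN = _table({
    "D1front": [92.7, 544.0, 207.3, 95.3, 105.9, 214.6, 93.1, 89.6],
    "D1back":  [92.3, 558.5, 170.2, 107.7, 105.0, 227.5, 99.3, 97.0],
    "D2front": [68.5, 738.9, 93.1, 105.5, 101.2, 248.2, 98.3, 79.1],
    "D2back":  [67.0, 750.6, 93.7, 105.1, 103.1, 243.1, 97.5, 80.3],
    "D3front": [71.2, 735.0, 108.3, 103.9, 101.2, 238.7, 96.9, 73.5],
    "D3back":  [67.4, 743.7, 99.0, 101.8, 108.9, 242.1, 103.7, 88.4],
}, COEFFICIENT_NAMES)

#: Matching standard deviations of the cohort coefficients.
VOLUNTEER_COEFFS_SD = _table({
    "D1front": [4.5, 8.1, 12.0, 1.6, 2.6, 2.5, 1.2, 2.6],
    "D1back":  [3.8, 10.1, 9.6, 1.5, 1.7, 5.1, 1.9, 3.0],
    "D2front": [3.2, 14.2, 4.4, 1.7, 1.8, 3.9, 1.9, 2.4],
    "D2back":  [2.6, 14.6, 5.6, 1.8, 1.9, 3.7, 2.6, 1.9],
    "D3front": [3.1, 14.8, 6.9, 1.5, 1.6, 3.9, 1.9, 1.6],
    "D3back":  [2.8, 14.7, 5.7, 2.0, 1.8, 7.4, 2.8, 2.3],
}, COEFFICIENT_NAMES)

#: Segment coefficients of the finite-element model study at the
#: reference position (point values, same layout).
MODEL_COEFFS = _table({
    "D1front": [70.3, 214.6, 233.6, 86.2, 71.8, 192.5, 51.7, 77.6],
    "D1back":  [82.9, 156.1, 165.1, 89.1, 77.6, 204.0, 51.7, 63.2],
    "D2front": [97.0, 873.2, 188.7, 83.3, 83.3, 212.6, 54.6, 34.5],
    "D2back":  [97.2, 852.4, 186.9, 92.0, 83.3, 209.8, 51.7, 43.1],
    "D3front": [112.6, 746.7, 178.6, 89.1, 80.5, 206.9, 40.2, 43.1],
    "D3back":  [109.6, 784.0, 170.6, 103.4, 92.0, 198.3, 31.6, 46.0],
}, COEFFICIENT_NAMES)

#: Per-lead similarity (%) between the model and the volunteer cohort
#: at the reference position, with SDs across volunteers.
MODEL_VOLUNTEER_SIMILARITY = pd.DataFrame({
    "similarity": [89.3, 87.9, 87.0, 88.1, 88.2, 86.9],
    "sd": [9.2, 12.1, 8.3, 7.8, 8.8, 11.8],
}, index=LEAD_SIDE_COLUMNS)

#: DTW distance (uV, mean) between each displaced position and the
#: reference, volunteer cohort at rest.
VOLUNTEER_DTW_MEAN = _table({
    "position_1": [8.1, 9.8, 1.0, 0.9, 1.8, 0.8],
    "position_2": [88.7, 59.0, 48.6, 67.8, 94.1, 64.3],
    "position_3": [223.7, 152.5, 145.8, 140.0, 223.2, 189.2],
    "position_4": [271.7, 184.8, 162.6, 186.1, 389.9, 243.6],
    "position_5": [301.7, 239.3, 233.1, 270.7, 446.2, 381.6],
    "position_6": [263.5, 196.1, 292.0, 313.8, 488.9, 453.0],
}, LEAD_SIDE_COLUMNS)

#: Matching standard deviations.
VOLUNTEER_DTW_SD = _table({
    "position_1": [0.9, 1.8, 0.6, 0.3, 0.3, 0.5],
    "position_2": [27.1, 26.6, 5.2, 4.8, 50.3, 54.1],
    "position_3": [38.5, 14.9, 20.8, 10.1, 71.9, 74.4],
    "position_4": [20.2, 17.9, 34.1, 39.2, 65.6, 63.2],
    "position_5": [24.4, 20.4, 38.7, 23.7, 90.0, 95.4],
    "position_6": [21.1, 23.6, 36.1, 39.6, 92.6, 99.7],
}, LEAD_SIDE_COLUMNS)

#: DTW distance (uV) of the finite-element model study, same layout.
MODEL_DTW = _table({
    "position_1": [40.30, 79.07, 55.97, 32.15, 189.31, 72.94],
    "position_2": [116.41, 135.30, 123.44, 61.68, 259.32, 150.58],
    "position_3": [111.05, 114.52, 275.74, 101.80, 368.67, 307.16],
    "position_4": [141.46, 130.26, 338.18, 333.50, 424.79, 421.65],
    "position_5": [202.18, 197.82, 326.10, 361.46, 427.49, 463.91],
    "position_6": [141.45, 170.27, 372.51, 417.04, 583.20, 544.57],
}, LEAD_SIDE_COLUMNS)

#: SNR (dB, mean/SD) of walking recordings at each displaced position
#: versus the reference, per lead.
WALKING_SNR_MEAN = _table({
    "position_1": [-1.62, -2.14, 1.03],
    "position_2": [0.84, 2.72, 1.08],
    "position_3": [3.96, 3.58, 2.68],
    "position_4": [4.80, 7.25, 6.03],
    "position_5": [-0.33, 3.72, 3.89],
    "position_6": [2.19, -1.08, 0.59],
}, ["D1", "D2", "D3"])

WALKING_SNR_SD = _table({
    "position_1": [3.12, 3.22, 3.71],
    "position_2": [4.71, 2.54, 1.87],
    "position_3": [3.95, 4.83, 2.03],
    "position_4": [5.18, 7.58, 5.04],
    "position_5": [5.82, 3.62, 3.17],
    "position_6": [4.31, 3.89, 6.80],
}, ["D1", "D2", "D3"])

#: DTW variation (%) of walking recordings, same layout.
WALKING_VARIATION_MEAN = _table({
    "position_1": [14.3, 12.9, 23.8],
    "position_2": [18.2, 13.2, 37.9],
    "position_3": [18.4, 13.8, 26.1],
    "position_4": [21.1, 14.3, 25.3],
    "position_5": [19.1, 15.3, 16.9],
    "position_6": [19.6, 19.8, 21.7],
}, ["D1", "D2", "D3"])

WALKING_VARIATION_SD = _table({
    "position_1": [4.1, 11.9, 14.3],
    "position_2": [10.8, 7.5, 25.3],
    "position_3": [10.7, 6.5, 7.1],
    "position_4": [7.3, 7.1, 11.1],
    "position_5": [8.6, 10.8, 12.1],
    "position_6": [10.5, 13.2, 6.6],
}, ["D1", "D2", "D3"])


def dtw_targets(lead: str, side: str) -> np.ndarray:
    """Calibration targets: mean DTW distance (uV) at positions 1-6."""
    return VOLUNTEER_DTW_MEAN.loc[f"{lead}{side}"].to_numpy(float)
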