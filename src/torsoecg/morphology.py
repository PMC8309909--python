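"""Waveform comparison statistics: DTW, SNR, percentage difference/similarity.

Dynamic time warping is computed from the squared single-dimension
Euclidean distance matrix ``D(x, y) = (s_ref[x] - s_cmp[y])**2`` with the
cumulative cost recurrence

    C(x, y) = D(x, y) + min(C(x, y-1), C(x-1, y-1), C(x-1, y))

and the warp path recovered by backtracking from ``(m, n)`` toward the
adjacent predecessor of lowest accumulated cost.  Ties prefer the
diagonal step, then the vertical one; the convention is fixed so results
are reproducible.  No global path constraint (band) is applied.

The scalar distance reported alongside the aligned signals is the mean
absolute difference ``mean(|S1w - S2w|)`` along the warp path, which has
the units of the input amplitudes (callers pass uV to obtain uV).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class DTWResult:
    """Alignment of a comparison waveform against a reference."""

    distance_matrix: np.ndarray  # (m, n) squared sample differences
    cost_matrix: np.ndarray      # (m, n) accumulated cost
    path: np.ndarray             # (L, 2) monotone (x, y) index pairs
    s1_warped: np.ndarray        # reference replayed along the path
    s2_warped: np.ndarray        # comparison replayed along the path
    distance: float              # mean |S1w - S2w| along the path

    @property
    def cumulative_cost(self) -> float:
        return float(self.cost_matrix[-1, -1])


def dtw_align(s_ref, s_cmp) -> DTWResult:
    """Align ``s_cmp`` against ``s_ref`` by dynamic time warping."""
    s1 = np.asarray(s_ref, dtype=float)
    s2 = np.asarray(s_cmp, dtype=float)
    if s1.size == 0 or s2.size == 0:
        raise ValueError("DTW inputs must be non-empty")
    if not (np.all(np.isfinite(s1)) and np.all(np.isfinite(s2))):
        raise ValueError("DTW inputs must be finite")

    m, n = s1.size, s2.size
    D = (s1[:, None] - s2[None, :]) ** 2
    C = np.empty_like(D)
    np.cumsum(D[0, :], out=C[0, :])
    np.cumsum(D[:, 0], out=C[:, 0])
    for x in range(1, m):
        prev = C[x - 1]
        row = C[x]
        # row[y] depends on row[y-1]: sequential in y, vectorized min of the
        # two predecessors that are already known.
        upper = np.minimum(prev[1:], prev[:-1])
        acc = row[0]
        Dx = D[x]
        for y in range(1, n):
            acc = Dx[y] + min(upper[y - 1], acc)
            row[y] = acc

    path = _backtrack(C)
    s1w = s1[path[:, 0]]
    s2w = s2[path[:, 1]]
    distance = float(np.mean(np.abs(s1w - s2w)))
    return DTWResult(D, C, path, s1w, s2w, distance)


def _backtrack(C: np.ndarray) -> np.ndarray:
    """Recover the warp path from (m, n) back to (1, 1).

    Ties between candidate predecessors prefer the diagonal, then the
    vertical (previous row) step.
    """
    m, n = C.shape
    x, y = m - 1, n - 1
    rev = [(x, y)]
    while x > 0 or y > 0:
        if x == 0:
            y -= 1
        elif y == 0:
            x -= 1
        else:
            diag, vert, horz = C[x - 1, y - 1], C[x - 1, y], C[x, y - 1]
            best = min(diag, vert, horz)
            if diag == best:
                x, y = x - 1, y - 1
            elif vert == best:
                x -= 1
            else:
                y -= 1
        rev.append((x, y))
    return np.array(rev[::-1], dtype=int)


def dtw_distance(s_ref, s_cmp) -> float:
    """Scalar DTW distance: mean |S1w - S2w| along the optimal warp path."""
    return dtw_align(s_ref, s_cmp).distance


def snr_db(xr, xp) -> float:
    """Signal-to-noise ratio 10*log10(sum(xr^2) / sum((xp - xr)^2)) in dB."""
    xr = np.asarray(xr, dtype=float)
    xp = np.asarray(xp, dtype=float)
    if xr.shape != xp.shape:
        raise ValueError("signals must have equal length")
    err = np.sum((xp - xr) ** 2)
    if err == 0.0:
        raise ValueError("signals are identical: SNR is infinite")
    return float(10.0 * np.log10(np.sum(xr ** 2) / err))


def percent_difference(e1: float, e2: float) -> float:
    """|E1 - E2| over the pair mean, as a percentage."""
    denom = 0.5 * (e1 + e2)
    if denom == 0.0:
        raise ValueError("percent difference undefined for E1 + E2 = 0")
    return float(abs(e1 - e2) / denom * 100.0)


def percent_similarity(e1: float, e2: float) -> float:
    """100% minus the percentage difference."""
    return 100.0 - percent_difference(e1, e2)


def variation_percent(s_ref, s_cmp) -> float:
    """DTW distance as a percentage of the reference peak-to-peak amplitude."""
    s_ref = np.asarray(s_ref, dtype=float)
    ptp = float(np.max(s_ref) - np.min(s_ref))
    if ptp == 0.0:
        raise ValueError("flat reference: variation undefined")
    return dtw_distance(s_ref, s_cmp) / ptp * 100.0
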