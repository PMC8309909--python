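"""Containers for sampled ECG lead signals and segment coefficients."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

LEADS = ("D1", "D2", "D3")
SIDES = ("front", "back")
POSITIONS = tuple(range(7))


@dataclass
class ECGRecord:
    """A sampled single-lead ECG with acquisition metadata.

    ``samples`` are in mV.  ``meta`` is a free-form side channel; the
    synthetic generator stores ground truth there (true R-peak sample
    indices under ``"r_peaks"``, the true segment coefficients under
    ``"coefficients"``, the subject's normalization amplitude under
    ``"max_amplitude_mv"``).
    """

    samples: np.ndarray
    fs: float
    lead: str = "D2"
    position: int = 0
    side: str = "front"
    subject: str = "model"
    condition: str = "rest"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling frequency must be positive")
        if self.lead not in LEADS:
            raise ValueError(f"unknown lead {self.lead!r}")
        if self.side not in SIDES:
            raise ValueError(f"unknown side {self.side!r}")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs

    def with_samples(self, samples: np.ndarray, **meta) -> "ECGRecord":
        rec = replace(self, samples=np.asarray(samples, float))
        rec.meta = {**self.meta, **meta}
        return rec

    def to_csv(self, path: str | Path) -> None:
        """Write the record as a two-column CSV plus a JSON sidecar."""
        path = Path(path)
        pd.DataFrame({"t_s": self.t, f"{self.lead}_mv": self.samples}).to_csv(
            path, index=False
        )
        sidecar = {
            "fs": self.fs,
            "lead": self.lead,
            "position": self.position,
            "side": self.side,
            "subject": self.subject,
            "condition": self.condition,
            "meta": _jsonable(self.meta),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "ECGRecord":
        path = Path(path)
        df = pd.read_csv(path)
        side = json.loads(path.with_suffix(".json").read_text())
        meta = side.pop("meta", {})
        return cls(samples=df.iloc[:, 1].to_numpy(), meta=meta, **side)


COEFFICIENT_NAMES = ("aP", "aQRS", "aT", "dP", "dQRS", "dT", "tP", "tQRS")


@dataclass
class SegmentCoefficients:
    """Normalized descriptors of the P/QRS/T segments of one beat.

    Amplitudes ``aP, aQRS, aT`` are in uV per mV of the subject's maximum
    amplitude; durations ``dP, dQRS, dT`` and timings ``tP`` (P offset to
    QRS onset) and ``tQRS`` (QRS offset to T onset) are in ms per s of
    beat period.  ``c`` is the optional baseline offset in mV, zero once
    the baseline has been removed.
    """

    aP: float
    aQRS: float
    aT: float
    dP: float
    dQRS: float
    dT: float
    tP: float
    tQRS: float
    c: float = 0.0

    def __post_init__(self):
        for name in ("aP", "aQRS", "aT", "tP", "tQRS"):
            v = getattr(self, name)
            if np.isfinite(v) and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        total = self.dP + self.dQRS + self.dT
        if np.isfinite(total) and total > 1000.0:
            raise ValueError(
                f"segment durations occupy {total:.1f} ms/s > the full beat"
            )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in COEFFICIENT_NAMES])

    @classmethod
    def from_array(cls, values, c: float = 0.0) -> "SegmentCoefficients":
        return cls(**dict(zip(COEFFICIENT_NAMES, map(float, values))), c=c)

    def as_dict(self) -> dict:
        return asdict(self)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, SegmentCoefficients):
        return obj.as_dict()
    return obj
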