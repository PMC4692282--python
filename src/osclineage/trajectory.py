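"""Uniform-grid time series container shared across modules."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

FRAME_INTERVAL_MIN = 3.0  # microscopy frame rate emulated everywhere


@dataclass(frozen=True)
class Trajectory:
    """A single series sampled on a strictly increasing uniform time grid."""

    times: np.ndarray  # min
    values: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or times.shape != values.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if times.size >= 2:
            dt = np.diff(times)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("times must lie on a uniform grid (no gaps)")

    @property
    def dt(self) -> float:
        if self.times.size < 2:
            raise ValueError("dt undefined for fewer than two samples")
        return float(self.times[1] - self.times[0])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_min": self.times, "value": self.values}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "Trajectory":
        df = pd.read_csv(path)
        return cls(df["time_min"].to_numpy(), df["value"].to_numpy())
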