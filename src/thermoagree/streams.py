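"""Time-stamped temperature stream containers.

Two stream kinds exist: the high-rate double-sensor stream (t, th1, th2,
optional ambient) and the sparse esophageal reference stream (t, temp).
Timestamps are seconds since stream start and must be strictly increasing.
Temperatures outside a plausibility corridor (detached sensor, logger
glitch) are *flagged*, never dropped: the 2-SD artifact filter downstream is
the only exclusion step in the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PLAUSIBILITY_CORRIDOR",
    "DualSensorStream",
    "ReferenceStream",
]

#: Default plausible skin/probe temperature range in °C.
PLAUSIBILITY_CORRIDOR = (15.0, 45.0)


def _check_time(t: np.ndarray) -> None:
    if t.size and t[0] < 0:
        raise ValueError("timestamps must be non-negative")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
        raise ValueError(f"timestamps must be strictly increasing (row {bad})")


@dataclass
class DualSensorStream:
    """1-Hz-class double-sensor stream: skin (th1) and outer (th2) readings."""

    t: np.ndarray
    th1: np.ndarray
    th2: np.ndarray
    ambient: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.th1 = np.asarray(self.th1, dtype=float)
        self.th2 = np.asarray(self.th2, dtype=float)
        if self.ambient is not None:
            self.ambient = np.asarray(self.ambient, dtype=float)
        n = self.t.size
        for name in ("th1", "th2", "ambient"):
            v = getattr(self, name)
            if v is not None and v.size != n:
                raise ValueError(f"{name} length {v.size} != t length {n}")
        _check_time(self.t)

    def __len__(self) -> int:
        return int(self.t.size)

    def plausibility_flags(
        self, corridor: tuple[float, float] = PLAUSIBILITY_CORRIDOR
    ) -> np.ndarray:
        """Boolean mask of samples with either sensor outside ``corridor``."""
        lo, hi = corridor
        return (
            (self.th1 < lo) | (self.th1 > hi) | (self.th2 < lo) | (self.th2 > hi)
        )

    def to_frame(self) -> pd.DataFrame:
        data = {"t_s": self.t, "th1_c": self.th1, "th2_c": self.th2}
        if self.ambient is not None:
            data["ambient_c"] = self.ambient
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DualSensorStream":
        ambient = (
            frame["ambient_c"].to_numpy() if "ambient_c" in frame.columns else None
        )
        return cls(
            t=frame["t_s"].to_numpy(),
            th1=frame["th1_c"].to_numpy(),
            th2=frame["th2_c"].to_numpy(),
            ambient=ambient,
        )


@dataclass
class ReferenceStream:
    """Sparse esophageal reference stream (one reading every ~30 min)."""

    t: np.ndarray
    temp: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.temp = np.asarray(self.temp, dtype=float)
        if self.temp.size != self.t.size:
            raise ValueError(f"temp length {self.temp.size} != t length {self.t.size}")
        _check_time(self.t)

    def __len__(self) -> int:
        return int(self.t.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.t, "temp_c": self.temp})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ReferenceStream":
        return cls(t=frame["t_s"].to_numpy(), temp=frame["temp_c"].to_numpy())
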