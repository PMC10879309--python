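"""The ratiometric calcium trace container and its CSV round-trip."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError

__all__ = ["TraceMeta", "CalciumTrace", "write_trace_csv", "read_trace_csv"]


@dataclass
class TraceMeta:
    """Provenance of a trace: crossing scheme, synergid side, replicate."""

    female: str = "wildtype"
    pollen: str = "wildtype"
    side: str = "combined"          # left | right | combined
    replicate: int = 0
    contact_aligned: bool = True

    @property
    def scheme(self) -> str:
        return f"{self.female}x{self.pollen}"


@dataclass
class CalciumTrace:
    """A time-ordered YFP/CFP ratio trace for one region of interest.

    ``time_s`` is uniformly spaced and shifted so that t = 0 is the annotated
    moment of pollen tube-synergid contact (negative times are pre-contact
    frames).  ``low_signal`` flags frames in which most ROI pixels sat at the
    CFP denominator floor during extraction.
    """

    time_s: np.ndarray
    ratio: np.ndarray
    meta: TraceMeta = field(default_factory=TraceMeta)
    low_signal: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)
        if self.time_s.shape != self.ratio.shape:
            raise ValueError("time_s and ratio must have the same length")
        if self.time_s.size >= 2:
            steps = np.diff(self.time_s)
            if np.any(steps <= 0):
                raise ValueError("time_s must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=1e-6):
                raise ValueError("time_s must be uniformly spaced")
        if not np.all(np.isfinite(self.ratio)):
            raise ValueError("ratio values must be finite")

    def __len__(self) -> int:
        return self.time_s.size

    @property
    def frame_interval_s(self) -> float:
        if len(self) < 2:
            raise ValueError("frame interval undefined for traces of length < 2")
        return float(self.time_s[1] - self.time_s[0])

    @property
    def duration_s(self) -> float:
        """Post-contact observation span in seconds."""
        return float(self.time_s[-1] - max(self.time_s[0], 0.0))


def write_trace_csv(trace: CalciumTrace, path: str | Path) -> None:
    """Write a trace as CSV with columns frame, time_s, ratio, low_signal_flag."""
    flags = (trace.low_signal if trace.low_signal is not None
             else np.zeros(len(trace), dtype=bool))
    pd.DataFrame({
        "frame": np.arange(len(trace)),
        "time_s": trace.time_s,
        "ratio": trace.ratio,
        "low_signal_flag": flags.astype(int),
    }).to_csv(path, index=False)


def read_trace_csv(path: str | Path, meta: TraceMeta | None = None) -> CalciumTrace:
    df = pd.read_csv(path)
    required = {"time_s", "ratio"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: trace CSV must contain columns {sorted(required)}"
        )
    low = (df["low_signal_flag"].to_numpy().astype(bool)
           if "low_signal_flag" in df.columns else None)
    return CalciumTrace(
        time_s=df["time_s"].to_numpy(dtype=float),
        ratio=df["ratio"].to_numpy(dtype=float),
        meta=meta or TraceMeta(),
        low_signal=low,
    )
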