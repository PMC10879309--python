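"""Transient detection by peak prominence with trace-relative thresholds.

Prominence of a local maximum is its height above the larger of the two
reference troughs that separate it from higher terrain: scanning outward
from the peak until a strictly higher sample (or the trace end) is met, the
reference trough on each side is the lowest sample in the scanned span, and

    prominence = trace[peak] - max(left trough, right trough).

Detection is trace-relative: with ``m`` the minimum prominence registered
among all local maxima of a trace, only peaks with prominence strictly
greater than ``multiplier * m`` are retained — 1.1x for amplitude analyses
(lenient, so weakly oscillating traces still contribute) and 5x for
frequency analyses (strict, so noise blips do not masquerade as transients).
A direct consequence is that the minimum-prominence peak of a trace is
always excluded for any multiplier > 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, ContractError
from .trace import CalciumTrace

__all__ = ["Peak", "PeakSet", "AnalysisConfig", "find_local_maxima",
           "compute_prominence", "detect_transients", "intervals",
           "amplitudes", "trace_summary"]

#: Multiplier used when pooling transient amplitudes/intensities.
AMPLITUDE_MULTIPLIER = 1.1
#: Multiplier used when measuring oscillation frequency.
FREQUENCY_MULTIPLIER = 5.0


@dataclass(frozen=True)
class Peak:
    """One detected calcium transient."""

    index: int
    time_s: float
    height: float
    prominence: float
    left_base: int
    right_base: int


@dataclass
class PeakSet:
    """Detected transients of one trace, in time order."""

    trace: CalciumTrace
    peaks: list[Peak] = field(default_factory=list)
    multiplier: float | None = None
    min_prominence_registered: float | None = None

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def times(self) -> np.ndarray:
        return np.array([p.time_s for p in self.peaks])

    @property
    def heights(self) -> np.ndarray:
        return np.array([p.height for p in self.peaks])

    @property
    def prominences(self) -> np.ndarray:
        return np.array([p.prominence for p in self.peaks])


@dataclass(frozen=True)
class AnalysisConfig:
    """Detection mode and its trace-relative threshold multiplier."""

    mode: str = "amplitude"            # amplitude | frequency
    multiplier: float | None = None    # default follows the mode
    min_separation_s: float = 0.0
    tie: str = "exclusive"             # exclusive | inclusive base-scan stop
    keep_singleton: bool = False       # retain a lone local maximum

    def __post_init__(self) -> None:
        if self.mode not in ("amplitude", "frequency"):
            raise ConfigError("mode must be amplitude or frequency")
        if self.multiplier is None:
            object.__setattr__(
                self, "multiplier",
                AMPLITUDE_MULTIPLIER if self.mode == "amplitude"
                else FREQUENCY_MULTIPLIER)
        if self.multiplier <= 1.0:
            raise ConfigError("multiplier must exceed 1")
        if self.min_separation_s < 0:
            raise ConfigError("min_separation_s must be non-negative")
        if self.tie not in ("exclusive", "inclusive"):
            raise ConfigError("tie must be exclusive or inclusive")


def _values(trace: CalciumTrace | np.ndarray) -> np.ndarray:
    if isinstance(trace, CalciumTrace):
        return trace.ratio
    return np.asarray(trace, dtype=float)


def find_local_maxima(trace: CalciumTrace | np.ndarray) -> np.ndarray:
    """Indices of interior local maxima; plateaus yield their centre sample.

    A strict local maximum satisfies y[i-1] < y[i] > y[i+1].  A flat run of
    equal values bounded by strictly lower neighbours on both sides counts
    as one peak at its centre sample (the left of the two centre samples on
    even-length plateaus).  Trace endpoints are never peaks.
    """
    y = _values(trace)
    n = y.size
    out: list[int] = []
    i = 1
    while i < n - 1:
        if y[i] > y[i - 1]:
            j = i
            while j + 1 < n and y[j + 1] == y[i]:
                j += 1
            if j + 1 < n and y[j + 1] < y[i]:
                out.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    return np.asarray(out, dtype=int)


def compute_prominence(
    trace: CalciumTrace | np.ndarray,
    index: int,
    tie: str = "exclusive",
) -> tuple[float, int, int]:
    """Prominence and flanking base positions of the local maximum at ``index``.

    The scan on each side stops at the first sample strictly greater than
    the peak value (``tie='inclusive'`` stops at greater-or-equal samples
    outside the peak's own plateau) or at the trace end; the base is the
    nearest minimum within the scanned span.  Raises :class:`ContractError`
    if ``index`` is not a local maximum as defined by
    :func:`find_local_maxima`.
    """
    y = _values(trace)
    maxima = find_local_maxima(y)
    if index not in maxima:
        raise ContractError(f"index {index} is not a local maximum")
    peak_val = y[index]

    # plateau extent of this peak (equal-value run through `index`)
    lo = index
    while lo - 1 >= 0 and y[lo - 1] == peak_val:
        lo -= 1
    hi = index
    while hi + 1 < y.size and y[hi + 1] == peak_val:
        hi += 1

    def stops(v: float) -> bool:
        return v > peak_val if tie == "exclusive" else v >= peak_val

    left_base = lo
    left_min = peak_val
    j = lo - 1
    while j >= 0 and not stops(y[j]):
        if y[j] < left_min:
            left_min, left_base = y[j], j
        j -= 1
    right_base = hi
    right_min = peak_val
    j = hi + 1
    while j < y.size and not stops(y[j]):
        if y[j] < right_min:
            right_min, right_base = y[j], j
        j += 1

    prominence = peak_val - max(left_min, right_min)
    return float(prominence), int(left_base), int(right_base)


def detect_transients(
    trace: CalciumTrace,
    cfg: AnalysisConfig | None = None,
) -> PeakSet:
    """Detect transients passing the trace-relative prominence threshold."""
    cfg = cfg or AnalysisConfig()
    if len(trace) < 3:
        warnings.warn("trace has fewer than 3 samples; no peaks detectable")
        return PeakSet(trace=trace, multiplier=cfg.multiplier)

    maxima = find_local_maxima(trace)
    if maxima.size == 0:
        return PeakSet(trace=trace, multiplier=cfg.multiplier)

    candidates = []
    for idx in maxima:
        prom, lb, rb = compute_prominence(trace, int(idx), tie=cfg.tie)
        candidates.append(Peak(index=int(idx), time_s=float(trace.time_s[idx]),
                               height=float(trace.ratio[idx]),
                               prominence=prom, left_base=lb, right_base=rb))
    m = min(p.prominence for p in candidates)

    if len(candidates) == 1 and cfg.keep_singleton:
        kept = candidates
    else:
        kept = [p for p in candidates if p.prominence > cfg.multiplier * m]

    if cfg.min_separation_s > 0 and len(kept) > 1:
        # greedily keep the more prominent peak of any too-close pair
        selected: list[Peak] = []
        for p in sorted(kept, key=lambda p: -p.prominence):
            if all(abs(p.time_s - q.time_s) >= cfg.min_separation_s
                   for q in selected):
                selected.append(p)
        kept = sorted(selected, key=lambda p: p.index)

    return PeakSet(trace=trace, peaks=kept, multiplier=cfg.multiplier,
                   min_prominence_registered=m)


def intervals(peaks: PeakSet) -> np.ndarray:
    """Inter-transient intervals in seconds (empty for < 2 peaks)."""
    if len(peaks) < 2:
        return np.array([])
    return np.diff(peaks.times)


def amplitudes(peaks: PeakSet, convention: str = "height") -> np.ndarray:
    """Per-peak intensity: absolute ratio at the peak, or its prominence."""
    if convention not in ("height", "prominence"):
        raise ConfigError("convention must be height or prominence")
    if len(peaks) == 0:
        return np.array([])
    return peaks.heights if convention == "height" else peaks.prominences


def trace_summary(peaks: PeakSet) -> dict[str, float]:
    """Per-trace summary: counts, mean prominence/interval, peaks per minute."""
    ivals = intervals(peaks)
    mean_interval = float(ivals.mean()) if ivals.size else float("nan")
    return {
        "n_peaks": float(len(peaks)),
        "mean_prominence": (float(peaks.prominences.mean())
                            if len(peaks) else 0.0),
        "mean_height": float(peaks.heights.mean()) if len(peaks) else 0.0,
        "mean_interval_s": mean_interval,
        "peaks_per_min": (60.0 / mean_interval
                          if np.isfinite(mean_interval) and mean_interval > 0
                          else float("nan")),
        "duration_s": peaks.trace.duration_s,
    }
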