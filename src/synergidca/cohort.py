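"""Cohort-level pooling, representative-trace selection and statistics.

A crossing scheme pools every retained peak of its replicate traces into
one sample (the observational unit is the peak, matching the published
peak-count design; a per-trace-mean alternative is available for
replicate-level inference).  Summaries follow notched-boxplot conventions:
quartiles by linear interpolation, whiskers at the most extreme data point
within 1.5 IQR of the box, and notches at median +/- 1.57 IQR / sqrt(n) as
an approximate 95% confidence interval for the median.  Cohorts are
compared by one-way ANOVA (alpha = 0.05) with Tukey HSD post-hoc pairwise
comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import ConfigError, ContractError
from .peaks import (AnalysisConfig, PeakSet, amplitudes, detect_transients,
                    intervals)
from .trace import CalciumTrace

__all__ = ["CrossScheme", "BoxStats", "AnovaResult", "PosthocResult",
           "pool", "rank_traces", "select_median_trace", "box_stats",
           "one_way_anova", "tukey_hsd"]


@dataclass
class CrossScheme:
    """A labelled cohort of replicate traces with their detected peaks."""

    label: str
    traces: list[CalciumTrace]
    amplitude_peaks: list[PeakSet] = field(default_factory=list)
    frequency_peaks: list[PeakSet] = field(default_factory=list)

    @classmethod
    def from_traces(
        cls,
        label: str,
        traces: list[CalciumTrace],
        amplitude_cfg: AnalysisConfig | None = None,
        frequency_cfg: AnalysisConfig | None = None,
    ) -> "CrossScheme":
        """Run both detection modes on every replicate trace."""
        amp_cfg = amplitude_cfg or AnalysisConfig(mode="amplitude")
        freq_cfg = frequency_cfg or AnalysisConfig(mode="frequency")
        return cls(
            label=label,
            traces=list(traces),
            amplitude_peaks=[detect_transients(t, amp_cfg) for t in traces],
            frequency_peaks=[detect_transients(t, freq_cfg) for t in traces],
        )

    @property
    def n_traces(self) -> int:
        return len(self.traces)


def pool(
    scheme: CrossScheme,
    what: str = "amplitudes",
    convention: str = "height",
    per_trace_mean: bool = False,
) -> pd.DataFrame:
    """Concatenate per-trace peak statistics with provenance tags.

    ``what='amplitudes'`` pools peak intensities from the lenient (1.1x)
    detection; ``what='intervals'`` pools inter-transient intervals from the
    strict (5x) detection.  Returns a DataFrame with columns ``value`` and
    ``trace`` (replicate position within the scheme).  With
    ``per_trace_mean`` each trace contributes its mean instead of its peaks.
    """
    if what not in ("amplitudes", "intervals"):
        raise ConfigError("what must be amplitudes or intervals")
    peaksets = (scheme.amplitude_peaks if what == "amplitudes"
                else scheme.frequency_peaks)
    if not peaksets:
        warnings.warn(f"scheme {scheme.label!r} has no traces; empty pool")
        return pd.DataFrame({"value": [], "trace": []})

    values, tags = [], []
    for i, ps in enumerate(peaksets):
        v = (amplitudes(ps, convention) if what == "amplitudes"
             else intervals(ps))
        if per_trace_mean:
            if v.size:
                values.append(np.array([v.mean()]))
                tags.append(np.array([i]))
        else:
            values.append(v)
            tags.append(np.full(v.size, i))
    if not values:
        return pd.DataFrame({"value": [], "trace": []})
    return pd.DataFrame({"value": np.concatenate(values),
                         "trace": np.concatenate(tags).astype(int)})


def _mean_prominences(scheme: CrossScheme) -> np.ndarray:
    """Per-trace mean peak prominence (0 for traces without retained peaks)."""
    out = []
    for ps in scheme.amplitude_peaks:
        out.append(float(ps.prominences.mean()) if len(ps) else 0.0)
    return np.asarray(out)


def rank_traces(scheme: CrossScheme) -> np.ndarray:
    """Trace indices in ascending order of mean peak prominence (stable)."""
    means = _mean_prominences(scheme)
    return np.argsort(means, kind="stable")


def select_median_trace(scheme: CrossScheme) -> int:
    """Index of the replicate with median mean peak prominence.

    With n replicates this is position ceil(n/2) of the ascending order —
    the lower median when n is even — matching how representative traces
    are chosen for display.
    """
    order = rank_traces(scheme)
    if order.size == 0:
        raise ContractError("scheme has no traces")
    return int(order[int(np.ceil(order.size / 2)) - 1])


@dataclass(frozen=True)
class BoxStats:
    """Notched-boxplot summary of one pooled sample."""

    n: int
    median: float
    q1: float
    q3: float
    iqr: float
    whisker_lo: float
    whisker_hi: float
    notch_lo: float
    notch_hi: float


def box_stats(values: np.ndarray | list[float]) -> BoxStats:
    """Quartiles, 1.5 IQR whiskers and McGill median notches."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ContractError("box_stats requires at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    notch = 1.57 * iqr / np.sqrt(v.size)
    return BoxStats(
        n=int(v.size), median=float(med), q1=float(q1), q3=float(q3),
        iqr=float(iqr),
        whisker_lo=float(inside.min()), whisker_hi=float(inside.max()),
        notch_lo=float(med - notch), notch_hi=float(med + notch),
    )


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    alpha: float
    group_means: tuple[float, ...]

    @property
    def significant(self) -> bool:
        return self.p < self.alpha


@dataclass(frozen=True)
class PosthocResult:
    """Tukey HSD pairwise comparisons (family-wise adjusted p-values)."""

    pairs: tuple[tuple[str, str], ...]
    mean_diffs: tuple[float, ...]
    p_adjusted: tuple[float, ...]
    reject: tuple[bool, ...]
    alpha: float


def _check_groups(groups: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    if len(groups) < 2:
        raise ContractError("need at least two groups")
    cleaned = {}
    for name, values in groups.items():
        v = np.asarray(values, dtype=float)
        if v.size < 2:
            raise ContractError(f"group {name!r} has n={v.size} < 2")
        cleaned[name] = v
    return cleaned


def one_way_anova(groups: dict[str, np.ndarray],
                  alpha: float = 0.05) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA across pooled value sets."""
    groups = _check_groups(groups)
    arrays = list(groups.values())
    f_stat, p = stats.f_oneway(*arrays)
    n_total = sum(a.size for a in arrays)
    return AnovaResult(
        F=float(f_stat),
        df_between=len(arrays) - 1,
        df_within=n_total - len(arrays),
        p=float(p),
        alpha=alpha,
        group_means=tuple(float(a.mean()) for a in arrays),
    )


def tukey_hsd(groups: dict[str, np.ndarray],
              alpha: float = 0.05) -> PosthocResult:
    """Tukey HSD multiple comparison of group means."""
    groups = _check_groups(groups)
    values = np.concatenate(list(groups.values()))
    labels = np.concatenate([np.full(v.size, name, dtype=object)
                             for name, v in groups.items()])
    res = pairwise_tukeyhsd(values, labels, alpha=alpha)
    pairs = tuple((str(a), str(b)) for a, b
                  in zip(res.groupsunique[res._multicomp.pairindices[0]],
                         res.groupsunique[res._multicomp.pairindices[1]]))
    return PosthocResult(
        pairs=pairs,
        mean_diffs=tuple(float(d) for d in res.meandiffs),
        p_adjusted=tuple(float(p) for p in res.pvalues),
        reject=tuple(bool(r) for r in res.reject),
        alpha=alpha,
    )
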