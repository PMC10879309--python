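"""Ground-truthed simulation of synergid calcium ratio traces.

The generator draws transient onset times from a gamma renewal process,
transient amplitudes from a lognormal law, and superposes
difference-of-exponentials transients on a constant baseline with white
baseline noise:

    ratio(t) = baseline + sum_k A_k * g(t - t_k) + eps(t)

where ``g`` is normalised to unit peak so each ``A_k`` is the true transient
amplitude in ratio units.  Interval draws, amplitude draws, duration, noise
and the burst decision use independent child streams of one master seed, so
trace-level ground truth is reproducible independently of downstream image
noise settings.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .errors import ConfigError
from .presets import GenotypePreset
from .trace import CalciumTrace, TraceMeta

__all__ = ["TraceSimConfig", "GroundTruth", "simulate_trace",
           "simulate_synergid_pair", "transient_kernel"]

#: Baseline ratio noise standard deviation (ratio units).
BASELINE_NOISE_SD = 0.02

#: Temporal correlation of the baseline noise, as the sigma of a Gaussian
#: smoothing kernel in frames.  ROI-averaged ratio baselines fluctuate
#: slowly (focus drift, cytoplasmic movement) rather than frame-to-frame,
#: so the white innovation is smoothed over ~15 s at the 10 s frame
#: interval and renormalised to the stated standard deviation.
BASELINE_NOISE_SMOOTH_FRAMES = 1.5

#: The terminal burst, when present, is injected this long before trace end
#: so that its rising phase is fully sampled (seconds).
_BURST_MARGIN_S = 30.0


@dataclass(frozen=True)
class TraceSimConfig:
    """Acquisition settings for one simulated trace.

    Defaults mirror the study conditions: a 10 s frame interval and an
    interaction duration drawn uniformly between 16 and 58 minutes.
    """

    frame_interval_s: float = 10.0
    duration_min_s: float = 16 * 60.0
    duration_max_s: float = 58 * 60.0
    pre_contact_frames: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval_s <= 0:
            raise ConfigError("frame_interval_s must be positive")
        if self.duration_min_s <= 0 or self.duration_max_s <= 0:
            raise ConfigError("duration bounds must be positive")
        if self.duration_min_s > self.duration_max_s:
            raise ConfigError("duration_min_s must not exceed duration_max_s")
        if self.pre_contact_frames < 0:
            raise ConfigError("pre_contact_frames must be non-negative")


@dataclass
class GroundTruth:
    """Everything the generator knows that a detector must recover."""

    true_transient_times: np.ndarray     # seconds, strictly increasing
    true_amplitudes: np.ndarray          # ratio units
    true_ratio_trace: np.ndarray         # noise-free ratio per frame
    burst_frame: int | None = None
    drift_track: np.ndarray | None = None  # (T, 2) cumulative (dx, dy), px


def transient_kernel(t: np.ndarray, rise_s: float, decay_s: float) -> np.ndarray:
    """Difference-of-exponentials transient, normalised to unit peak."""
    t = np.asarray(t, dtype=float)
    g = np.where(t >= 0.0, np.exp(-t / decay_s) - np.exp(-t / rise_s), 0.0)
    t_peak = rise_s * decay_s / (decay_s - rise_s) * np.log(decay_s / rise_s)
    peak = np.exp(-t_peak / decay_s) - np.exp(-t_peak / rise_s)
    return g / peak


def _baseline_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Temporally correlated baseline noise with stationary SD BASELINE_NOISE_SD."""
    white = rng.normal(0.0, 1.0, n)
    smooth = gaussian_filter1d(white, BASELINE_NOISE_SMOOTH_FRAMES)
    # renormalise by the kernel's theoretical variance-reduction factor so
    # the stationary SD is exact rather than matched per trace
    impulse = np.zeros(101)
    impulse[impulse.size // 2] = 1.0
    kernel = gaussian_filter1d(impulse, BASELINE_NOISE_SMOOTH_FRAMES)
    return BASELINE_NOISE_SD * smooth / np.sqrt(np.sum(kernel ** 2))


def _draw_renewal_times(rng: np.random.Generator, preset: GenotypePreset,
                        duration_s: float) -> np.ndarray:
    scale = preset.mean_interval_s / preset.interval_shape
    times = []
    t = rng.gamma(preset.interval_shape, scale)
    while t < duration_s:
        times.append(t)
        t += rng.gamma(preset.interval_shape, scale)
    return np.asarray(times, dtype=float)


def _draw_amplitudes(rng: np.random.Generator, preset: GenotypePreset,
                     n: int) -> np.ndarray:
    if preset.amplitude_mean == 0.0 or n == 0:
        return np.zeros(n)
    cv = preset.amplitude_cv
    sigma2 = np.log1p(cv ** 2)
    mu = np.log(preset.amplitude_mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), n)


def simulate_trace(
    preset: GenotypePreset,
    cfg: TraceSimConfig,
    meta: TraceMeta | None = None,
) -> tuple[CalciumTrace, GroundTruth]:
    """Simulate one contact-aligned ratio trace with full ground truth.

    The time axis places t = 0 on the first frame after the pre-contact
    block; transients occur only at t > 0.  With ``preset.burst_probability``
    the trace ends in a single large terminal transient (the rupture burst),
    recorded as the last ground-truth transient.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_dur, rng_int, rng_amp, rng_noise, rng_burst = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    duration_s = float(rng_dur.uniform(cfg.duration_min_s, cfg.duration_max_s))
    times = _draw_renewal_times(rng_int, preset, duration_s)
    amps = _draw_amplitudes(rng_amp, preset, len(times))

    burst_time: float | None = None
    if preset.burst_probability > 0 and rng_burst.random() < preset.burst_probability:
        burst_time = max(duration_s - _BURST_MARGIN_S, 0.0)
        keep = times < burst_time
        times, amps = times[keep], amps[keep]
        times = np.append(times, burst_time)
        amps = np.append(amps, preset.burst_amplitude_multiplier
                         * preset.amplitude_mean)

    dt = cfg.frame_interval_s
    n_post = int(np.ceil(duration_s / dt))
    time_s = (np.arange(cfg.pre_contact_frames + n_post)
              - cfg.pre_contact_frames) * dt

    clean = np.full(time_s.shape, preset.baseline_ratio)
    for t_k, a_k in zip(times, amps):
        clean = clean + a_k * transient_kernel(
            time_s - t_k, preset.transient_rise_s, preset.transient_decay_s)

    ratio = clean + _baseline_noise(rng_noise, time_s.size)

    burst_frame = None
    if burst_time is not None:
        burst_frame = int(cfg.pre_contact_frames + np.floor(burst_time / dt))

    trace = CalciumTrace(time_s=time_s, ratio=ratio, meta=meta or TraceMeta())
    truth = GroundTruth(
        true_transient_times=times,
        true_amplitudes=amps,
        true_ratio_trace=clean,
        burst_frame=burst_frame,
    )
    return trace, truth


def _inject_transient(trace: CalciumTrace, truth: GroundTruth,
                      preset: GenotypePreset, t_s: float, amp: float,
                      *, as_burst: bool) -> None:
    bump = amp * transient_kernel(trace.time_s - t_s,
                                  preset.transient_rise_s,
                                  preset.transient_decay_s)
    trace.ratio = trace.ratio + bump
    truth.true_ratio_trace = truth.true_ratio_trace + bump
    keep = truth.true_transient_times < t_s
    truth.true_transient_times = np.append(truth.true_transient_times[keep], t_s)
    truth.true_amplitudes = np.append(truth.true_amplitudes[keep], amp)
    if as_burst:
        dt = trace.frame_interval_s
        pre = int(np.round(-trace.time_s[0] / dt))
        truth.burst_frame = int(pre + np.floor(t_s / dt))


def simulate_synergid_pair(
    preset: GenotypePreset,
    cfg: TraceSimConfig,
    female: str | None = None,
    pollen: str | None = None,
    replicate: int = 0,
) -> tuple[tuple[CalciumTrace, GroundTruth], tuple[CalciumTrace, GroundTruth]]:
    """Simulate the left and right synergid of one reception event.

    Both cells oscillate independently, but the terminal rupture burst, when
    it occurs, appears in the receptive (right) synergid and as a concurrent
    transient of equal amplitude in its sister cell — calcium floods the
    remaining synergid when the receptive one bursts.  Both traces share the
    receptive cell's duration so they can be rendered into one stack.
    """
    ss = np.random.SeedSequence(cfg.seed)
    seed_r, seed_l, seed_burst = (int(s.generate_state(1)[0] % (2 ** 31))
                                  for s in ss.spawn(3))

    quiet = preset.without_burst()
    female = female or preset.name
    pollen = pollen or "wildtype"

    cfg_r = replace(cfg, seed=seed_r)
    right, truth_r = simulate_trace(
        quiet, cfg_r, TraceMeta(female=female, pollen=pollen, side="right",
                                replicate=replicate))
    # Same frame count for the sister: pin the bounds to the realised span.
    dt = cfg.frame_interval_s
    dur = (len(right) - cfg.pre_contact_frames) * dt
    cfg_l = replace(cfg, seed=seed_l, duration_min_s=dur, duration_max_s=dur)
    left, truth_l = simulate_trace(
        quiet, cfg_l, TraceMeta(female=female, pollen=pollen, side="left",
                                replicate=replicate))

    rng_burst = np.random.default_rng(seed_burst)
    if preset.burst_probability > 0 and rng_burst.random() < preset.burst_probability:
        t_burst = max(dur - _BURST_MARGIN_S, 0.0)
        amp = preset.burst_amplitude_multiplier * preset.amplitude_mean
        _inject_transient(right, truth_r, preset, t_burst, amp, as_burst=True)
        _inject_transient(left, truth_l, preset, t_burst, amp, as_burst=True)

    return (left, truth_l), (right, truth_r)
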