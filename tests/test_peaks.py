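import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal

from synergidca import (AnalysisConfig, CalciumTrace, amplitudes,
                        compute_prominence, detect_transients,
                        find_local_maxima, intervals, trace_summary)
from synergidca.errors import ConfigError, ContractError

WORKED = np.array([0.0, 1.0, 0.0, 3.0, 0.0, 2.0, 0.0])


def as_trace(values, dt=10.0):
    values = np.asarray(values, dtype=float)
    return CalciumTrace(time_s=np.arange(values.size) * dt, ratio=values)


def brute_prominence(y, i):
    """Independent oracle: window bounded by strictly higher samples/ends."""
    y = np.asarray(y, dtype=float)
    higher = np.flatnonzero(y > y[i])
    left_bound = higher[higher < i].max() + 1 if (higher < i).any() else 0
    right_bound = higher[higher > i].min() - 1 if (higher > i).any() else y.size - 1
    return y[i] - max(y[left_bound:i + 1].min(), y[i:right_bound + 1].min())


class TestLocalMaxima:
    def test_worked_example(self):
        assert list(find_local_maxima(WORKED)) == [1, 3, 5]

    def test_monotone_trace_has_no_maxima(self):
        assert find_local_maxima(np.arange(10.0)).size == 0

    def test_plateau_yields_left_centre_sample(self):
        assert list(find_local_maxima([0.0, 2.0, 2.0, 0.0])) == [1]
        assert list(find_local_maxima([0.0, 2.0, 2.0, 2.0, 0.0])) == [2]

    def test_endpoints_never_peaks(self):
        assert find_local_maxima([5.0, 1.0, 5.0]).size == 0

    def test_agrees_with_scipy_on_random_traces(self, rng):
        for _ in range(50):
            y = rng.uniform(0, 10, rng.integers(3, 200))
            assert np.array_equal(find_local_maxima(y),
                                  signal.find_peaks(y)[0])


class TestProminence:
    @pytest.mark.parametrize("index,expected", [(1, 1.0), (3, 3.0), (5, 2.0)])
    def test_worked_example(self, index, expected):
        prom, lb, rb = compute_prominence(WORKED, index)
        assert prom == expected
        assert lb < index < rb

    def test_non_maximum_index_rejected(self):
        with pytest.raises(ContractError):
            compute_prominence(WORKED, 2)

    def test_matches_brute_force_and_scipy_on_random_traces(self, rng):
        for _ in range(200):
            y = rng.uniform(0, 10, rng.integers(3, 200))
            idx = find_local_maxima(y)
            if idx.size == 0:
                continue
            scipy_proms = signal.peak_prominences(y, idx)[0]
            for k, i in enumerate(idx):
                prom, _, _ = compute_prominence(y, int(i))
                assert prom == brute_prominence(y, int(i))
                assert prom == scipy_proms[k]

    def test_bases_are_nearest_minima_on_ties(self):
        # both zeros tie as left trough; the nearest one is the base
        prom, lb, rb = compute_prominence(np.array([0.0, 1.0, 0.0, 3.0, 1.0]),
                                          3)
        assert prom == 2.0 and lb == 2 and rb == 4

    def test_inclusive_tie_stops_at_equal_height_peaks(self):
        y = np.array([0.0, 2.0, 1.0, 2.0, 0.0])
        prom_excl, _, _ = compute_prominence(y, 1, tie="exclusive")
        prom_incl, _, _ = compute_prominence(y, 1, tie="inclusive")
        assert prom_excl == 2.0       # scan passes the equal peak to the end
        assert prom_incl == 1.0       # equal peak terminates the scan

    @given(st.lists(st.integers(0, 100), min_size=3, max_size=60),
           st.integers(-50, 50))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_shift_invariance_and_scale_equivariance(self, values, shift):
        y = np.array(values, dtype=float)
        for i in find_local_maxima(y):
            base, _, _ = compute_prominence(y, int(i))
            shifted, _, _ = compute_prominence(y + shift, int(i))
            scaled, _, _ = compute_prominence(3.0 * y, int(i))
            assert shifted == base
            assert scaled == 3.0 * base

    @given(st.lists(st.floats(0, 10, allow_nan=False), min_size=3,
                    max_size=100))
    @settings(max_examples=300, derandomize=True, deadline=None)
    def test_brute_force_oracle_property(self, values):
        y = np.array(values)
        for i in find_local_maxima(y):
            prom, _, _ = compute_prominence(y, int(i))
            assert prom == brute_prominence(y, int(i))


class TestDetection:
    def test_amplitude_mode_excludes_the_minimum_prominence_peak(self):
        ps = detect_transients(as_trace(WORKED), AnalysisConfig(mode="amplitude"))
        assert len(ps) == 2
        assert sorted(ps.prominences) == [2.0, 3.0]

    def test_frequency_mode_excludes_everything_on_the_worked_example(self):
        ps = detect_transients(as_trace(WORKED), AnalysisConfig(mode="frequency"))
        assert len(ps) == 0

    def test_flat_trace_has_no_transients(self):
        assert len(detect_transients(as_trace(np.ones(20)))) == 0

    def test_short_trace_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            assert len(detect_transients(as_trace([1.0, 2.0]))) == 0

    def test_minimum_prominence_peak_always_excluded(self, rng):
        for _ in range(50):
            y = rng.uniform(0, 10, 100)
            ps = detect_transients(as_trace(y), AnalysisConfig(mode="amplitude"))
            if ps.min_prominence_registered is not None and len(ps):
                assert ps.prominences.min() > ps.min_prominence_registered

    def test_raising_multiplier_never_retains_more_peaks(self, rng):
        y = rng.uniform(0, 10, 150)
        counts = [len(detect_transients(
            as_trace(y), AnalysisConfig(multiplier=m)))
            for m in (1.1, 2.0, 5.0, 20.0)]
        assert counts == sorted(counts, reverse=True)

    def test_single_local_maximum_retained_only_with_keep_singleton(self):
        y = np.array([0.0, 1.0, 0.5, 2.0, 0.0])  # two peaks -> drop min; but
        lone = np.array([0.0, 2.0, 0.0])          # a lone peak is its own min
        assert len(detect_transients(as_trace(lone))) == 0
        kept = detect_transients(as_trace(lone),
                                 AnalysisConfig(keep_singleton=True))
        assert len(kept) == 1
        assert len(detect_transients(as_trace(y))) == 1

    def test_min_separation_keeps_the_more_prominent_peak(self):
        y = np.array([0.0, 5.0, 0.0, 4.0, 0.0, 0.0, 0.0, 3.0, 0.0, 0.1, 0.0])
        close = detect_transients(as_trace(y, dt=1.0),
                                  AnalysisConfig(min_separation_s=3.0))
        far = detect_transients(as_trace(y, dt=1.0), AnalysisConfig())
        assert len(far) == 3
        assert len(close) == 2          # the 4.0 peak sits 2 s from the 5.0 peak
        assert close.peaks[0].height == 5.0

    def test_invalid_multiplier_rejected(self):
        with pytest.raises(ConfigError):
            AnalysisConfig(multiplier=0.9)


class TestIntervalsAndAmplitudes:
    def test_interval_arithmetic_and_frequency(self):
        y = np.zeros(25)
        y[[6, 12, 19]] = 5.0
        y[3] = 0.5                       # small blip sets the minimum prominence
        ps = detect_transients(as_trace(y), AnalysisConfig())
        assert np.array_equal(intervals(ps), [60.0, 70.0])
        assert trace_summary(ps)["peaks_per_min"] == pytest.approx(60 / 65)

    def test_single_peak_has_no_intervals(self):
        y = np.zeros(9)
        y[[2, 6]] = [5.0, 1.0]
        ps = detect_transients(as_trace(y))
        assert len(ps) == 1 and intervals(ps).size == 0

    def test_height_convention_on_worked_example(self):
        ps = detect_transients(as_trace(WORKED))
        assert sorted(amplitudes(ps, "height")) == [2.0, 3.0]

    def test_height_never_below_prominence(self, rng):
        for _ in range(20):
            y = rng.uniform(0, 10, 120)
            ps = detect_transients(as_trace(y))
            if len(ps):
                assert np.all(amplitudes(ps, "height")
                              >= amplitudes(ps, "prominence"))

    def test_unknown_convention_rejected(self):
        ps = detect_transients(as_trace(WORKED))
        with pytest.raises(ConfigError):
            amplitudes(ps, "area")
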