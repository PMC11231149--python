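"""OMPG onset detection, speciation interval and simultaneity classifier."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from islandrad import (
    MigrantSeries,
    OnsetDetector,
    classify_simultaneous,
    detect_onsets,
    moving_average,
    speciation_interval,
)


def brute_force_onsets(means: np.ndarray, window: int, threshold: float):
    """Independent re-scan oracle: recompute each trailing average by
    direct summation and scan generation by generation."""
    T = len(means)
    first = second = None
    for t in range(window - 1, T):
        n_below = 0
        for k in range(3):
            avg = sum(means[t - window + 1 : t + 1, k]) / window
            if avg < threshold:
                n_below += 1
        if first is None and n_below >= 2:
            first = t
        if second is None and n_below == 3:
            second = t
        if second is not None:
            break
    return first, second


def step_series(cross_gens, window=50, T=None):
    """Three-pair series where pair k's moving average first drops below 1
    exactly at generation cross_gens[k]: the raw series steps from
    ``window`` (large enough that a single remaining high value keeps the
    trailing mean at threshold) to 0 ``window`` generations earlier."""
    T = T or max(cross_gens) + window
    means = np.full((T, 3), float(window))
    for k, g in enumerate(cross_gens):
        means[g - window + 1 :, k] = 0.0
    return MigrantSeries(means, window=window)


class TestMovingAverage:
    def test_constant_series(self):
        out = moving_average(np.full(120, 3.0), 50)
        assert np.isnan(out[:49]).all()
        assert np.allclose(out[49:], 3.0)

    def test_zero_series(self):
        assert np.allclose(moving_average(np.zeros(60), 50)[49:], 0.0)

    def test_ramp_against_direct_summation(self):
        # mean of 1..50 = 25.5 at the first defined index
        out = moving_average(np.arange(1, 101), 50)
        assert out[49] == pytest.approx(25.5)
        for t in (49, 60, 99):
            assert out[t] == pytest.approx(np.arange(1, 101)[t - 49 : t + 1].mean())

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            moving_average(np.array([]), 50)


class TestDetectOnsets:
    def test_never_isolated(self):
        series = MigrantSeries(np.full((200, 3), 2.0), window=50)
        assert detect_onsets(series, 1.0) == (None, None)

    def test_staggered_crossings(self):
        # pairs cross below 1 at generations 100, 120, 125
        series = step_series([100, 120, 125])
        assert detect_onsets(series, 1.0) == (120, 125)

    def test_all_pairs_cross_together(self):
        series = step_series([80, 80, 80])
        first, second = detect_onsets(series, 1.0)
        assert first == second == 80
        assert speciation_interval((first, second)) == 0

    def test_strictly_below_not_at_threshold(self):
        means = np.full((100, 3), 1.0)  # average exactly at threshold
        assert detect_onsets(MigrantSeries(means, window=50), 1.0) == (None, None)


class TestSpeciationInterval:
    @pytest.mark.parametrize(
        "onsets,expected", [((460, 465), 5), ((100, 100), 0), ((100, 7826), 7726)]
    )
    def test_interval_is_onset_difference(self, onsets, expected):
        assert speciation_interval(onsets) == expected

    def test_censored_rejected(self):
        with pytest.raises(ValueError):
            speciation_interval((100, None))


class TestClassifySimultaneous:
    @pytest.mark.parametrize(
        "interval,expected", [(10, True), (11, False), (0, True)]
    )
    def test_inclusive_cutoff(self, interval, expected):
        assert classify_simultaneous(interval, cutoff=10) is expected


series_strategy = st.integers(0, 2**32 - 1)


class TestDetectorProperties:
    @given(seed=series_strategy)
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        T = int(rng.integers(30, 300))
        window = int(rng.integers(1, 40))
        # declining-with-noise series resembling migrant collapse
        base = np.linspace(rng.uniform(1, 4), 0, T)[:, None]
        means = np.clip(base + rng.normal(0, 0.5, (T, 3)), 0, None)
        series = MigrantSeries(means, window=window)
        assert detect_onsets(series, 1.0) == brute_force_onsets(means, window, 1.0)

    @given(seed=series_strategy)
    @settings(max_examples=40, deadline=None)
    def test_online_detector_equals_posthoc(self, seed):
        rng = np.random.default_rng(seed)
        T, window = 200, int(rng.integers(1, 60))
        means = np.clip(
            np.linspace(3, -1, T)[:, None] + rng.normal(0, 0.4, (T, 3)), 0, None
        )
        det = OnsetDetector(window=window, threshold=1.0)
        for row in means:
            det.update(row)
        assert (det.onset_first, det.onset_second) == detect_onsets(
            MigrantSeries(means, window=window), 1.0
        )

    @given(seed=series_strategy, bump=st.floats(0.1, 3.0))
    @settings(max_examples=40, deadline=None)
    def test_raising_threshold_never_delays_onsets(self, seed, bump):
        rng = np.random.default_rng(seed)
        means = np.clip(
            np.linspace(3, -0.5, 150)[:, None] + rng.normal(0, 0.4, (150, 3)), 0, None
        )
        series = MigrantSeries(means, window=20)
        lo = detect_onsets(series, 1.0)
        hi = detect_onsets(series, 1.0 + bump)
        for a, b in zip(hi, lo):
            if b is not None:
                assert a is not None and a <= b

    @given(shift=st.integers(0, 10_000), first=st.integers(0, 500), gap=st.integers(0, 500))
    @settings(max_examples=50, deadline=None)
    def test_interval_invariant_under_time_shift(self, shift, first, gap):
        assert speciation_interval((first, first + gap)) == speciation_interval(
            (first + shift, first + gap + shift)
        )
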