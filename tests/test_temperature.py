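"""Temperature features: percentile filter, diurnal metrics, complexity.

Brute-force oracles here are written independently of the library code
(explicit loops, no shared helpers) so they can certify the vectorised
implementations.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wearadetect.temperature import (
    coarse_grain,
    complexity_index,
    complexity_profile,
    diurnal_amplitude,
    percentile_filter,
    sleep_wake_means,
    temperature_features_for_night,
)
from wearadetect.synthetic import simulate_temperature_day

from conftest import make_night


# ---------------------------------------------------------------------------
# independent brute-force oracles


def ci_oracle(values):
    """Complexity index by explicit loops: z-score (population SD), then
    root-sum-square of successive differences over the series length."""
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / n
    if var == 0.0:
        return 0.0
    sd = math.sqrt(var)
    z = [(v - mean) / sd for v in values]
    acc = 0.0
    for i in range(n - 1):
        acc += (z[i + 1] - z[i]) ** 2
    return math.sqrt(acc) / n


def coarse_grain_oracle(values, scale):
    w = 2**scale
    out = []
    i = 0
    while i + w <= len(values):
        out.append(sum(values[i : i + w]) / w)
        i += w
    return out


# ---------------------------------------------------------------------------
# percentile filter


def test_filter_one_to_hundred_keeps_six_to_ninetyfive():
    # linear-interpolation percentiles of 1..100 are 5.95 and 95.05
    x = np.arange(1.0, 101.0)
    out = percentile_filter(x)
    survivors = out[~np.isnan(out)]
    assert survivors.min() == 6 and survivors.max() == 95
    assert survivors.size == 90


def test_filter_constant_series_unchanged():
    x = np.full(100, 33.0)
    out = percentile_filter(x)
    assert np.array_equal(out, x)


def test_filter_removes_single_spike():
    rng = np.random.default_rng(0)
    x = 33.0 + 0.1 * rng.standard_normal(1440)
    x[700] += 10.0
    out = percentile_filter(x)
    assert np.isnan(out[700])


def test_filter_short_series_fully_masked():
    x = np.full(19, 33.0)
    assert np.isnan(percentile_filter(x)).all()


def test_filter_preserves_indices_and_never_widens_range():
    rng = np.random.default_rng(1)
    for _ in range(20):
        x = 33 + rng.standard_normal(200)
        out = percentile_filter(x)
        keep = ~np.isnan(out)
        assert np.array_equal(out[keep], x[keep])
        assert out[keep].max() - out[keep].min() <= x.max() - x.min()


# ---------------------------------------------------------------------------
# diurnal metrics


def test_amplitude_constant_zero():
    assert diurnal_amplitude(np.full(100, 33.0)) == 0.0


def test_amplitude_noiseless_sinusoid_after_filter():
    rng = np.random.default_rng(0)
    series = simulate_temperature_day(3.0, 0.0, 0.0, rng)
    assert series.max() - series.min() == pytest.approx(3.0, abs=1e-6)
    amp = diurnal_amplitude(percentile_filter(series))
    # the filter trims the sinusoid's extremes: cos(0.05*pi) shrinkage
    assert 2.7 < amp <= 3.0


def test_amplitude_matches_bruteforce_on_discrete_values():
    x = np.array([33.0, 34.0, 36.0] * 20)
    filtered = percentile_filter(x)
    survivors = [v for v in filtered if not math.isnan(v)]
    assert diurnal_amplitude(filtered) == pytest.approx(max(survivors) - min(survivors))


def test_sleep_wake_means_block_values():
    rng = np.random.default_rng(0)
    # sleep 23:00 -> 07:00; on the noon-anchored day minutes 660..1140
    series = np.full(1440, 33.0)
    onset, wake = 23.0, 7.0
    sl = slice(11 * 60, 19 * 60)
    series[sl] = 35.0
    s, w, d = sleep_wake_means(series, onset, wake)
    assert (s, w, d) == (35.0, 33.0, 2.0)


def test_sleep_wake_means_all_asleep():
    series = np.full(1440, 34.0)
    s, w, d = sleep_wake_means(series, 12.0, 12.0 + 23.9999)
    assert w is None and d is None and s == pytest.approx(34.0)


def test_sleep_wake_means_random_vs_masked_oracle():
    rng = np.random.default_rng(5)
    for _ in range(10):
        series = 33 + rng.standard_normal(1440)
        onset = float(rng.uniform(0, 24))
        wake = float((onset + rng.uniform(1, 12)) % 24)
        s, w, _ = sleep_wake_means(series, onset, wake)
        sleep_vals, wake_vals = [], []
        for m in range(1440):
            clock = (12.0 + m / 60.0) % 24.0
            rel = (clock - onset) % 24.0
            span = (wake - onset) % 24.0
            (sleep_vals if rel < span else wake_vals).append(series[m])
        assert s == pytest.approx(np.mean(sleep_vals))
        assert w == pytest.approx(np.mean(wake_vals))


# ---------------------------------------------------------------------------
# coarse graining


@pytest.mark.parametrize(
    "values,scale,expected",
    [
        ([1, 2, 3, 4, 5, 6, 7, 8], 1, [1.5, 3.5, 5.5, 7.5]),
        ([1, 2, 3, 4, 5], 1, [1.5, 3.5]),  # trailing remainder dropped
        ([1, 2, 3, 4, 5], 2, [2.5]),  # width 2**2, floor(5/4) = 1 block
        ([1, 2, 3], 0, [1, 2, 3]),  # scale 0 is the identity
    ],
)
def test_coarse_grain_examples(values, scale, expected):
    assert coarse_grain(np.array(values, float), scale).tolist() == expected


def test_coarse_grain_mean_conservation():
    rng = np.random.default_rng(2)
    for _ in range(50):
        x = rng.standard_normal(int(rng.integers(8, 300)))
        for s in range(4):
            if x.size < 2**s:
                continue
            g = coarse_grain(x, s)
            consumed = x[: g.size * 2**s]
            assert g.mean() == pytest.approx(consumed.mean(), abs=1e-12)


def test_coarse_grain_matches_oracle():
    rng = np.random.default_rng(3)
    for _ in range(200):
        x = rng.standard_normal(int(rng.integers(8, 128)))
        s = int(rng.integers(0, 4))
        if x.size < 2**s:
            continue
        np.testing.assert_allclose(
            coarse_grain(x, s), coarse_grain_oracle(list(x), s), atol=1e-12
        )


# ---------------------------------------------------------------------------
# complexity index


def test_ci_constant_is_zero():
    assert complexity_index(np.full(256, 5.0)) == 0.0


def test_ci_alternating_closed_form():
    x = np.tile([1.0, -1.0], 128)
    # z-scored series is itself; 255 successive differences of magnitude 2
    assert complexity_index(x) == pytest.approx(2 * math.sqrt(255) / 256, abs=1e-12)


def test_ci_linear_ramp_closed_form():
    x = np.arange(256.0)
    # population SD of 0..N-1 is sqrt((N^2-1)/12); diffs all 1/sd
    sd = math.sqrt((256**2 - 1) / 12)
    expected = math.sqrt(255) / sd / 256
    assert complexity_index(x) == pytest.approx(expected, abs=1e-12)
    assert expected == pytest.approx(8.44e-4, rel=1e-2)


def test_ci_too_short_is_null():
    assert complexity_index(np.array([1.0])) is None


def test_ci_matches_bruteforce_on_random_series():
    rng = np.random.default_rng(4)
    for _ in range(1000):
        x = rng.standard_normal(int(rng.integers(2, 80)))
        assert complexity_index(x) == pytest.approx(ci_oracle(list(x)), abs=1e-12)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(-50, 50), min_size=4, max_size=64),
    st.floats(0.1, 10),
    st.floats(-20, 20),
)
def test_ci_affine_invariance(values, a, b):
    """CI(a*x + b) == CI(x) for a != 0 — z-scoring guarantees it."""
    x = np.asarray(values)
    base = complexity_index(x)
    scaled = complexity_index(a * x + b)
    assert scaled == pytest.approx(base, abs=1e-9)


# ---------------------------------------------------------------------------
# complexity profile


def test_profile_alternating_block():
    temp = np.full(1440, 33.0)
    onset, wake = 23.0, 7.0  # midpoint 03:00 -> minute 900
    block = slice(900 - 128, 900 + 128)
    temp[block] = 33.0 + np.tile([0.5, -0.5], 128)
    prof = complexity_profile(temp, onset, wake)
    assert prof["complexity_0"] == pytest.approx(2 * math.sqrt(255) / 256, abs=1e-9)
    # every pairwise mean is 0 -> grained series constant -> CI 0 by convention
    assert prof["complexity_1"] == 0.0


def test_profile_null_when_sleep_too_short():
    temp = np.full(1440, 33.0)
    prof = complexity_profile(temp, 2.0, 2.0 + 200 / 60.0)  # 200-minute night
    assert all(v is None for v in prof.values())


def test_profile_noise_raises_complexity():
    rng = np.random.default_rng(6)
    clean = simulate_temperature_day(3.0, 0.0, 0.0, rng, peak_minute=900)
    noisy = clean + 0.2 * rng.standard_normal(1440)
    c_clean = complexity_profile(clean, 23.0, 7.0)["complexity_0"]
    c_noisy = complexity_profile(noisy, 23.0, 7.0)["complexity_0"]
    assert c_noisy > c_clean


def test_night_features_null_without_temperature():
    night = make_night(None, present=False)
    feats = temperature_features_for_night(night)
    assert all(v is None for v in feats.values())
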