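"""Diurnal and multiscale-complexity features of distal skin temperature.

Per 24-h period (noon-anchored, 1440 minute slots) the module computes:

* a 5th/95th-percentile filter discarding non-representative extremes
  (non-wear, fever) before the diurnal metrics,
* the diurnal amplitude (daily maximum minus daily minimum of the
  surviving values),
* sleep/wake means and their difference (circadian rhythm stability),
* multiscale complexity indices ``complexity_0..3``: the complexity
  index (CI) of a 256-minute block centred on the midpoint of the sleep
  episode, computed on the raw series at coarse-graining scales
  2^0..2^3.  The CI of a series is the root-sum-square of successive
  differences after z-scoring, normalised by the series length — a
  point-to-point jaggedness / information proxy.

The complexity block is taken from the *unfiltered* series: percentile
filtering punches holes in the sleep period and would void the required
256 contiguous samples on almost every night.
"""

from __future__ import annotations

import numpy as np

from .synthetic import MINUTES_PER_DAY, NightRecord
from .sleep import circular_difference, circular_midpoint

MIN_VALID_MINUTES = 20
COMPLEXITY_SAMPLES = 256
COMPLEXITY_SCALES = (0, 1, 2, 3)

TEMPERATURE_FEATURE_NAMES = (
    "temperature_max",
    "sleep_mean",
    "wake_mean",
    "sleep_wake_difference",
    "diurnal_distal_body_temp_amp",
    "complexity_0",
    "complexity_1",
    "complexity_2",
    "complexity_3",
)


def percentile_filter(series: np.ndarray) -> np.ndarray:
    """Mask values strictly outside the [5th, 95th] percentile band.

    Percentiles use linear interpolation between order statistics over
    the non-missing values of the 24-h period.  Survivors keep their
    original minute indices; removed/missing values become NaN.  Series
    with fewer than 20 valid minutes are fully masked (downstream
    features go null).
    """
    x = np.asarray(series, dtype=float)
    out = np.full_like(x, np.nan)
    valid = ~np.isnan(x)
    if valid.sum() < MIN_VALID_MINUTES:
        return out
    lo, hi = np.percentile(x[valid], [5.0, 95.0])
    keep = valid & (x >= lo) & (x <= hi)
    out[keep] = x[keep]
    return out


def diurnal_amplitude(filtered: np.ndarray) -> float | None:
    """Daily maximum minus daily minimum of the surviving values."""
    valid = filtered[~np.isnan(filtered)]
    if valid.size == 0:
        return None
    return float(valid.max() - valid.min())


def _sleep_mask(sleep_onset: float, wake_onset: float) -> np.ndarray:
    """Boolean minute mask of the sleep interval on the noon-anchored day."""
    clock = (12.0 + np.arange(MINUTES_PER_DAY) / 60.0) % 24.0
    span = circular_difference(sleep_onset, wake_onset)
    rel = (clock - sleep_onset) % 24.0
    return rel < span


def sleep_wake_means(
    filtered: np.ndarray, sleep_onset: float, wake_onset: float
) -> tuple[float | None, float | None, float | None]:
    """Mean filtered temperature over sleeping/waking minutes and their difference.

    Minute membership is decided by the (circular) sleep interval; means
    are over surviving minutes only.  An empty side yields None, and the
    difference is None unless both sides are present.
    """
    mask = _sleep_mask(sleep_onset, wake_onset)
    valid = ~np.isnan(filtered)

    def _mean(m: np.ndarray) -> float | None:
        sel = filtered[m & valid]
        return float(sel.mean()) if sel.size else None

    sleep_mean = _mean(mask)
    wake_mean = _mean(~mask)
    diff = None if (sleep_mean is None or wake_mean is None) else sleep_mean - wake_mean
    return sleep_mean, wake_mean, diff


def coarse_grain(series: np.ndarray, scale: int) -> np.ndarray:
    """Block means of width 2**scale; the trailing remainder is dropped."""
    if scale < 0:
        raise ValueError("scale must be >= 0")
    x = np.asarray(series, dtype=float)
    w = 2**scale
    n = x.size // w
    if n == 0:
        raise ValueError(f"series of length {x.size} too short for scale {scale}")
    return x[: n * w].reshape(n, w).mean(axis=1)


def complexity_index(series: np.ndarray) -> float | None:
    """Normalised complexity index of a series.

    The series is z-scored (population SD); the CI is the root-sum-square
    of successive differences divided by the series length.  A
    zero-variance series has CI 0 by convention; length < 2 yields None.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        return None
    sd = x.std()  # population SD
    if sd == 0:
        return 0.0
    z = (x - x.mean()) / sd
    return float(np.sqrt(np.sum(np.diff(z) ** 2)) / z.size)


def complexity_profile(
    temperature: np.ndarray, sleep_onset: float, wake_onset: float
) -> dict[str, float | None]:
    """CI at scales 0-3 of the 256-minute block centred on the night midpoint.

    The block runs 128 minutes either side of the sleep-episode midpoint
    and must lie wholly inside the sleep period with every minute
    non-missing; otherwise all four values are null (no shifting toward
    onset/offset, whose variance the features deliberately avoid).
    """
    out: dict[str, float | None] = {f"complexity_{s}": None for s in COMPLEXITY_SCALES}
    if temperature is None or sleep_onset is None or wake_onset is None:
        return out
    span = circular_difference(sleep_onset, wake_onset)
    if span * 60.0 < COMPLEXITY_SAMPLES:
        return out
    mid_clock = circular_midpoint(sleep_onset, wake_onset)
    mid_idx = int(round(((mid_clock - 12.0) % 24.0) * 60.0))
    half = COMPLEXITY_SAMPLES // 2
    lo, hi = mid_idx - half, mid_idx + half
    if lo < 0 or hi > MINUTES_PER_DAY:
        return out
    # the block must also sit inside the sleep interval
    sleep = _sleep_mask(sleep_onset, wake_onset)
    block = np.asarray(temperature, dtype=float)[lo:hi]
    if not sleep[lo:hi].all() or np.isnan(block).any():
        return out
    for s in COMPLEXITY_SCALES:
        out[f"complexity_{s}"] = complexity_index(coarse_grain(block, s))
    return out


def temperature_features_for_night(night: NightRecord) -> dict:
    """Per-night temperature feature row (nulls when the series is absent).

    ``temperature_deviation`` and ``temperature_trend_deviation`` are
    baseline-relative features that need cross-night state; they are
    filled in by :func:`add_baseline_deviation_features` at table level.
    This function additionally returns the helper column ``_night_mean``.
    """
    out: dict[str, float | None] = {name: None for name in TEMPERATURE_FEATURE_NAMES}
    out["_night_mean"] = None
    if not night.present or night.temperature is None:
        return out
    filtered = percentile_filter(night.temperature)
    valid = filtered[~np.isnan(filtered)]
    if valid.size:
        out["temperature_max"] = float(valid.max())
        out["_night_mean"] = float(valid.mean())
        out["diurnal_distal_body_temp_amp"] = diurnal_amplitude(filtered)
    if night.sleep_onset is not None and night.wake_onset is not None:
        s, w, d = sleep_wake_means(filtered, night.sleep_onset, night.wake_onset)
        out["sleep_mean"], out["wake_mean"], out["sleep_wake_difference"] = s, w, d
        out.update(complexity_profile(night.temperature, night.sleep_onset, night.wake_onset))
    return out


def add_baseline_deviation_features(frame, window: int = 30, trend_window: int = 3):
    """Fill the baseline-relative temperature surrogates on a nightly frame.

    ``temperature_deviation`` is the night's mean filtered temperature
    minus the subject's trailing ``window``-night baseline mean
    (preceding present nights only; null before any baseline exists);
    ``temperature_trend_deviation`` is the deviation minus its trailing
    ``trend_window``-night moving average.  Both stand in for proprietary
    device summaries of the same names.
    """
    frame = frame.sort_values(["subject_id", "night_date"]).copy()

    def _per_subject(g):
        m = g["_night_mean"]
        baseline = m.shift(1).rolling(window, min_periods=1).mean()
        dev = m - baseline
        trend = dev - dev.rolling(trend_window, min_periods=1).mean()
        g["temperature_deviation"] = dev
        g["temperature_trend_deviation"] = trend
        return g

    frame = (
        frame.groupby("subject_id", group_keys=False, sort=False)[frame.columns]
        .apply(_per_subject)
    )
    return frame.drop(columns=["_night_mean"])
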