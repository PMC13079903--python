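"""Canonical nightly feature table: names, ordering and set grouping.

The 36 per-night features are grouped into five sets by the data stream
they derive from and their level of derivation:

* Set 1 — HR and HRV summaries,
* Set 2 — primary sleep summaries (onsets, total sleep time, ...),
* Set 3 — secondary sleep features (long/short contiguous-sleep windows),
* Set 4 — primary temperature summaries,
* Set 5 — secondary temperature features (diurnal metrics and the
  multiscale complexity indices).

Feature order is fixed; downstream window flattening and importance
aggregation rely on it.
"""

from __future__ import annotations

# fmt: off
FEATURES: tuple[str, ...] = (
    # Set 1 — HR and HRV
    "hr_low_duration", "hr_lowest", "breath_average", "breath_v_average",
    "hr_average", "rmssd", "rem_rmssd", "nrem_rmssd",
    # Set 2 — primary sleep
    "sleep_onset", "wake_onset", "total_sleep_time", "wake_up_count",
    "onset_latency", "midpoint_time", "restless", "got_up_count",
    # Set 3 — secondary sleep
    "sleep_percentage", "ST_long", "WT_long", "ST_short", "WT_short",
    "LW_count", "SW_count", "LW_len", "SW_len",
    # Set 4 — primary temperature
    "temperature_max", "temperature_deviation", "temperature_trend_deviation",
    # Set 5 — secondary temperature
    "sleep_mean", "wake_mean", "sleep_wake_difference",
    "diurnal_distal_body_temp_amp",
    "complexity_0", "complexity_1", "complexity_2", "complexity_3",
)
# fmt: on

FEATURE_SETS: dict[int, tuple[str, ...]] = {
    1: FEATURES[0:8],
    2: FEATURES[8:16],
    3: FEATURES[16:25],
    4: FEATURES[25:28],
    5: FEATURES[28:36],
}

#: The four "commonly used" nightly indicators, one per data stream.
COMMON_FEATURES: tuple[str, ...] = (
    "hr_average",
    "rmssd",
    "total_sleep_time",
    "diurnal_distal_body_temp_amp",
)

KEY_COLUMNS: tuple[str, ...] = ("subject_id", "night_date")

assert len(FEATURES) == 36
assert sum(len(v) for v in FEATURE_SETS.values()) == 36
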