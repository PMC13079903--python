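"""Sleep-window phenotyping and per-night sleep features from hypnograms.

Secondary sleep features follow the contiguous-sleep-window phenotyping
approach: within each night we identify *long* (> 6 h) and *short*
(< 3 h) windows of contiguous sleep containing no internal wake run
longer than 10 min, with distinct windows separated by at least 60 min
of wake.  Wake runs between 10 and 60 min are contradictory under a
literal reading of those two rules; the default resolves in favour of
the 60-min separation rule (such gaps are absorbed into one window and
counted as wake time), and ``strict=True`` instead splits windows at any
wake run longer than 10 min.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import EPOCHS_PER_HOUR, NightRecord

HOURS_PER_EPOCH = 1.0 / EPOCHS_PER_HOUR
MAX_INTERNAL_WAKE_EPOCHS = 20  # 10 min
SEPARATION_EPOCHS = 120  # 60 min
LONG_HOURS = 6.0
SHORT_HOURS = 3.0

_VALID_STAGES = frozenset("WLDR")

SLEEP_FEATURE_NAMES = (
    "sleep_percentage",
    "ST_long",
    "WT_long",
    "ST_short",
    "WT_short",
    "LW_count",
    "SW_count",
    "LW_len",
    "SW_len",
    "sleep_onset",
    "wake_onset",
    "total_sleep_time",
    "wake_up_count",
    "got_up_count",
    "restless",
    "onset_latency",
    "midpoint_time",
)


@dataclass
class SleepWindow:
    """Half-open epoch span [start, end) of one contiguous-sleep window."""

    start: int
    end: int
    sleep_time: float  # hours of sleep epochs within the span
    wake_time: float  # hours of wake epochs within the span

    @property
    def span_hours(self) -> float:
        return (self.end - self.start) * HOURS_PER_EPOCH

    @property
    def kind(self) -> str:
        if self.span_hours > LONG_HOURS:
            return "long"
        if self.span_hours < SHORT_HOURS:
            return "short"
        return "other"


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) runs where ``mask`` is True."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.nonzero(diff == 1)[0]
    ends = np.nonzero(diff == -1)[0]
    return list(zip(starts.tolist(), ends.tolist()))


def extract_sleep_windows(hypnogram, strict: bool = False) -> list[SleepWindow]:
    """Identify contiguous-sleep windows in a 30-s-epoch hypnogram.

    Maximal spans of sleep are merged across internal wake runs shorter
    than the separation threshold (60 min; 10 min in strict mode);
    leading/trailing wake is excluded from every window.
    """
    stages = np.asarray(hypnogram, dtype="<U1")
    unknown = set(np.unique(stages)) - _VALID_STAGES
    if unknown:
        raise ValueError(f"unknown hypnogram stage codes: {sorted(unknown)}")
    sleep = stages != "W"
    sleep_runs = _runs(sleep)
    if not sleep_runs:
        return []
    groups: list[list[tuple[int, int]]] = [[sleep_runs[0]]]
    for run in sleep_runs[1:]:
        gap = run[0] - groups[-1][-1][1]
        merge = (gap <= MAX_INTERNAL_WAKE_EPOCHS) if strict else (gap < SEPARATION_EPOCHS)
        if merge:
            groups[-1].append(run)
        else:
            groups.append([run])
    windows = []
    for group in groups:
        start, end = group[0][0], group[-1][1]
        sleep_epochs = int(sleep[start:end].sum())
        wake_epochs = (end - start) - sleep_epochs
        windows.append(
            SleepWindow(
                start=start,
                end=end,
                sleep_time=sleep_epochs * HOURS_PER_EPOCH,
                wake_time=wake_epochs * HOURS_PER_EPOCH,
            )
        )
    return windows


def circular_difference(start_hour: float, end_hour: float) -> float:
    """Hours from ``start_hour`` forward to ``end_hour`` on the 24-h clock."""
    return (end_hour - start_hour) % 24.0


def circular_midpoint(start_hour: float, end_hour: float) -> float:
    """Clock-hour midpoint of the interval running start -> end."""
    return (start_hour + circular_difference(start_hour, end_hour) / 2.0) % 24.0


def sleep_features_for_night(night: NightRecord, strict: bool = False,
                             literal_sleep_percentage: bool = False) -> dict:
    """Per-night sleep feature row (secondary set + surrogate primary set).

    Returns all-null values (no exception) when the hypnogram is absent.
    ``wake_up_count``/``got_up_count``/``restless``/``onset_latency`` are
    surrogates for proprietary device summaries: wake runs inside the
    sleep period, wake runs of at least 5 min, transitions into wake, and
    a constant zero latency respectively.
    """
    out: dict[str, float | None] = {name: None for name in SLEEP_FEATURE_NAMES}
    if not night.present or night.hypnogram is None:
        return out
    stages = np.asarray(night.hypnogram, dtype="<U1")
    windows = extract_sleep_windows(stages, strict=strict)

    longs = [w for w in windows if w.kind == "long"]
    shorts = [w for w in windows if w.kind == "short"]
    out["LW_count"] = float(len(longs))
    out["SW_count"] = float(len(shorts))
    out["ST_long"] = sum(w.sleep_time for w in longs) if longs else None
    out["WT_long"] = sum(w.wake_time for w in longs) if longs else None
    out["ST_short"] = sum(w.sleep_time for w in shorts) if shorts else None
    out["WT_short"] = sum(w.wake_time for w in shorts) if shorts else None
    out["LW_len"] = float(np.mean([w.span_hours for w in longs])) if longs else None
    out["SW_len"] = float(np.mean([w.span_hours for w in shorts])) if shorts else None

    sleep = stages != "W"
    n_sleep = int(sleep.sum())
    n_wake = int((~sleep).sum())
    if literal_sleep_percentage:
        out["sleep_percentage"] = n_sleep / n_wake if n_wake else None
    else:
        out["sleep_percentage"] = n_sleep / (n_sleep + n_wake)

    wake_runs = _runs(~sleep)
    # the hypnogram spans onset..final wake onset, so every wake run is internal
    out["wake_up_count"] = float(len(wake_runs))
    out["got_up_count"] = float(sum(1 for s, e in wake_runs if e - s >= 10))
    transitions_into_wake = int(np.sum((stages[1:] == "W") & (stages[:-1] != "W")))
    out["restless"] = float(transitions_into_wake)
    out["onset_latency"] = 0.0

    if night.sleep_onset is not None and night.wake_onset is not None:
        out["sleep_onset"] = night.sleep_onset
        out["wake_onset"] = night.wake_onset
        out["total_sleep_time"] = circular_difference(night.sleep_onset, night.wake_onset)
        out["midpoint_time"] = circular_midpoint(night.sleep_onset, night.wake_onset)
    return out
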