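"""Shared fixtures: small simulated cohorts and derived tables.

Heavy objects are session-scoped so the full suite simulates each cohort
once.  All randomness is seeded.
"""

from __future__ import annotations

from datetime import date

import numpy as np
import pytest

from wearadetect.synthetic import GeneratorConfig, NightRecord, simulate_cohort
from wearadetect.windowing import (
    anchor_start_dates,
    attach_labels,
    extract_nightly_features,
    extract_windows,
    stratified_split,
)


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """12 subjects/class over 50 nights — fast, still structured."""
    return GeneratorConfig(
        n_subjects_per_class=12,
        start_date=date(2020, 4, 22),
        end_date=date(2020, 6, 11),
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_nightly(small_cohort):
    return extract_nightly_features(small_cohort)


@pytest.fixture(scope="session")
def default_cohort():
    """The default study-condition cohort: 120 subjects/class, 129 nights."""
    return simulate_cohort(GeneratorConfig(n_subjects_per_class=120, rng_seed=7))


@pytest.fixture(scope="session")
def default_nightly(default_cohort):
    return extract_nightly_features(default_cohort)


@pytest.fixture(scope="session")
def default_windows(default_cohort, default_nightly):
    dates = default_cohort.config.night_dates
    anchors = anchor_start_dates(default_nightly, dates)
    return {
        L: attach_labels(
            extract_windows(default_nightly, L, dates, anchors), default_cohort.subjects
        )
        for L in (1, 3, 7, 14, 21)
    }


@pytest.fixture(scope="session")
def default_split(default_cohort):
    return stratified_split(default_cohort.subjects, 0.8, rng_seed=0)


def make_night(hypnogram=None, sleep_onset=23.0, wake_onset=7.0, temperature=None,
               present=True, subject_id="T0", night_date=date(2020, 5, 1)) -> NightRecord:
    """Hand-built night record for rule-tracing tests."""
    if hypnogram is not None:
        hypnogram = np.asarray(hypnogram, dtype="<U1")
    return NightRecord(
        subject_id=subject_id,
        night_date=night_date,
        present=present,
        temperature=temperature,
        hypnogram=hypnogram,
        sleep_onset=sleep_onset,
        wake_onset=wake_onset,
    )


def hyp(*segments) -> np.ndarray:
    """Build a hypnogram from (stage, n_epochs) segments."""
    parts = [np.full(n, s, dtype="<U1") for s, n in segments]
    return np.concatenate(parts)
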