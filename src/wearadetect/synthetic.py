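"""Synthetic wearable cohort generator.

Generates subject cohorts and per-night raw streams (minute-level distal
skin temperature, 30-s hypnograms, scalar HR/HRV/respiration summaries)
with the class-conditional statistical structure the downstream analysis
assumes, so the whole pipeline runs without access to any private
wearable dataset.

Two classes are simulated: subjects self-reporting a diabetes diagnosis
(DM, label 1) and subjects self-reporting no such diagnosis (no-DM-DX,
label 0).  The nightly marginal distributions of heart rate, RMSSD,
total sleep time and diurnal temperature amplitude follow configurable
location/scale parameters whose defaults are the published
class-conditional means/SDs; nightly values decompose into a persistent
subject-level random effect plus night-to-night noise so that multi-night
windows from one subject are correlated, as they are in real data.

DM-class nights additionally carry higher hypnogram wake-fragmentation
hazard (insomnia-like sleep) and a smoother (more autocorrelated, hence
less complex) temperature noise process.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal, stats

AGE_BINS = ("30-39", "40-49", "50-59", "60-69", "70-79")
SEXES = ("M", "F", "O")
STAGES = ("W", "L", "D", "R")
EPOCH_SECONDS = 30.0
EPOCHS_PER_HOUR = 3600.0 / EPOCH_SECONDS
MINUTES_PER_DAY = 1440

# Cohort composition weights over the five retained age bins and sexes,
# close to the published demographic proportions of each class.
_AGE_WEIGHTS = {
    0: np.array([0.262, 0.330, 0.249, 0.118, 0.041]),
    1: np.array([0.130, 0.263, 0.308, 0.218, 0.081]),
}
_SEX_WEIGHTS = {
    0: np.array([0.600, 0.399, 0.001]),
    1: np.array([0.727, 0.273, 0.000]),
}

_OTHER_CONDITIONS = (
    "hypertension",
    "sleep_apnea",
    "asthma",
    "cancer",
    "anemia",
)


class ConfigurationError(ValueError):
    """Raised when generator configuration is invalid."""


@dataclass
class ClassParams:
    """Nightly distribution parameters for one class.

    Location/scale pairs parameterise truncated-normal nightly marginals
    (truncated at zero).  Defaults are the published class-conditional
    moments: heart rate (BPM), RMSSD (ms), total sleep time (h) and
    diurnal distal temperature amplitude (°C).
    """

    hr_mean: tuple[float, float] = (62.713, 8.852)
    rmssd: tuple[float, float] = (42.944, 24.973)
    tst: tuple[float, float] = (7.946, 1.726)
    ddbta: tuple[float, float] = (7.261, 2.848)
    #: per-30s-epoch hazard of a wake intrusion terminating a sleep bout
    fragmentation_hazard: float = 0.005
    #: probability that a wake bout is a long (>= 60 min) detached gap
    long_gap_prob: float = 0.01
    #: lag-1 autocorrelation of the AR(1) temperature noise
    temp_autocorr: float = 0.86
    #: stationary SD of the temperature noise (°C)
    temp_noise_scale: float = 0.15
    #: log-SD of the subject-level multiplier on the fragmentation hazard
    hazard_subject_sd: float = 0.5
    #: SD of the subject-level shift on the temperature autocorrelation
    autocorr_subject_sd: float = 0.04

    def validate(self) -> None:
        for name in ("hr_mean", "rmssd", "tst", "ddbta"):
            loc, scale = getattr(self, name)
            if scale <= 0:
                raise ConfigurationError(f"{name} scale must be > 0, got {scale}")
        if not 0.0 <= self.fragmentation_hazard < 1.0:
            raise ConfigurationError("fragmentation_hazard must be in [0, 1)")
        if not 0.0 <= self.temp_autocorr < 1.0:
            raise ConfigurationError("temp_autocorr must be in [0, 1)")
        if self.temp_noise_scale < 0:
            raise ConfigurationError("temp_noise_scale must be >= 0")


def _dm_defaults() -> ClassParams:
    return ClassParams(
        hr_mean=(67.819, 9.569),
        rmssd=(30.141, 17.180),
        tst=(7.649, 1.990),
        ddbta=(6.008, 2.438),
        fragmentation_hazard=0.009,
        long_gap_prob=0.030,
        temp_autocorr=0.93,
        temp_noise_scale=0.15,
    )


@dataclass
class GeneratorConfig:
    """Full configuration for :func:`simulate_cohort`.

    The default date range (2020-04-22 up to, exclusively, 2020-08-29)
    spans exactly 129 nights.  ``missingness`` is the per-night
    independent probability that a subject's night carries no payload.
    ``subject_effect_fraction`` is the fraction of each scalar summary's
    variance attributed to a persistent subject-level random effect.
    """

    n_subjects_per_class: int = 60
    prevalence: float | None = None  # overrides per-class counts when set
    start_date: date = date(2020, 4, 22)
    end_date: date = date(2020, 8, 29)  # exclusive
    control: ClassParams = field(default_factory=ClassParams)
    dm: ClassParams = field(default_factory=_dm_defaults)
    missingness: float = 0.35
    subject_effect_fraction: float = 0.35
    #: fraction of no-DM-DX subjects carrying another chronic condition
    chronic_condition_fraction: float = 0.2
    #: how far (0..1) a chronic-condition subject's HR/HRV/sleep parameters
    #: shift toward the DM values; temperature parameters never shift
    chronic_shift: float = 0.5
    #: fraction of DM-labelled subjects generated from control physiology
    #: (emulates self-report label noise; these drive false negatives)
    dm_control_like_fraction: float = 0.1
    temperature_baseline: float = 33.0
    temperature_band: tuple[float, float] = (20.0, 42.0)
    sleep_onset_loc: float = 23.5  # clock hours
    sleep_onset_scale: float = 0.7
    rng_seed: int = 0

    @property
    def n_nights(self) -> int:
        return (self.end_date - self.start_date).days

    @property
    def night_dates(self) -> list[date]:
        return [self.start_date + timedelta(days=i) for i in range(self.n_nights)]

    def validate(self) -> None:
        if self.n_nights <= 0:
            raise ConfigurationError("date_range must span at least one night")
        if not 0.0 <= self.missingness < 1.0:
            raise ConfigurationError("missingness must be in [0, 1)")
        if self.prevalence is not None and not 0.0 < self.prevalence < 1.0:
            raise ConfigurationError("prevalence must be in (0, 1)")
        if self.n_subjects_per_class <= 0:
            raise ConfigurationError("n_subjects_per_class must be positive")
        if not 0.0 <= self.subject_effect_fraction < 1.0:
            raise ConfigurationError("subject_effect_fraction must be in [0, 1)")
        self.control.validate()
        self.dm.validate()

    def class_params(self, label: int) -> ClassParams:
        return self.dm if label == 1 else self.control

    def nightly_marginal(self, label: int, feature: str) -> stats.rv_continuous:
        """Frozen truncated-normal nightly marginal for a scalar summary.

        ``feature`` is one of ``hr_mean``, ``rmssd``, ``tst``, ``ddbta``.
        """
        loc, scale = getattr(self.class_params(label), feature)
        a = (0.0 - loc) / scale
        return stats.truncnorm(a, np.inf, loc=loc, scale=scale)

    def nominal_cohens_d(self, feature: str = "hr_mean") -> float:
        """Cohen's d implied by the configured locations/scales (pooled SD)."""
        loc1, s1 = getattr(self.dm, feature)
        loc0, s0 = getattr(self.control, feature)
        pooled = np.sqrt((s1**2 + s0**2) / 2.0)
        return (loc1 - loc0) / pooled


@dataclass
class SubjectProfile:
    subject_id: str
    label: int
    age_bin: str
    sex: str
    other_conditions: frozenset[str] = frozenset()


@dataclass
class NightRecord:
    """One subject-night.  A missing night keeps the date but no payload."""

    subject_id: str
    night_date: date
    present: bool
    temperature: np.ndarray | None = None  # 1440 minute values, noon-anchored
    hypnogram: np.ndarray | None = None  # 30-s epochs in {W,L,D,R}
    sleep_onset: float | None = None  # clock hours
    wake_onset: float | None = None
    summaries: dict[str, float] = field(default_factory=dict)


@dataclass
class Cohort:
    config: GeneratorConfig
    subjects: pd.DataFrame  # subject_id, label, age_bin, sex, other_conditions
    nights: dict[str, list[NightRecord]]

    def summaries_frame(self) -> pd.DataFrame:
        """Long frame of per-night scalar summaries (one row per present night)."""
        rows = []
        for sid, recs in self.nights.items():
            for r in recs:
                if not r.present:
                    continue
                row = {"subject_id": sid, "night_date": r.night_date}
                row.update(r.summaries)
                row["sleep_onset"] = r.sleep_onset
                row["wake_onset"] = r.wake_onset
                rows.append(row)
        return pd.DataFrame(rows)

    def iter_present_nights(self):
        for sid in self.subjects["subject_id"]:
            for r in self.nights[sid]:
                if r.present:
                    yield r


# ---------------------------------------------------------------------------
# low-level simulators


def simulate_hypnogram(
    params: ClassParams, night_length: float, rng: np.random.Generator
) -> np.ndarray:
    """Simulate a 30-s-epoch hypnogram spanning ``night_length`` hours.

    Alternating sleep/wake bouts: sleep bouts end with the per-epoch
    fragmentation hazard; wake bouts are short (minutes) except that with
    probability ``long_gap_prob`` a wake bout is a long (>= 60 min) gap,
    which splits the night into detached sleep spans.  The hypnogram
    begins and ends with sleep (onset and final wake onset bound it).
    """
    if not 0.0 < night_length <= 16.0:
        raise ConfigurationError("night_length must be in (0, 16] hours")
    n_epochs = max(int(round(night_length * EPOCHS_PER_HOUR)), 1)
    h = params.fragmentation_hazard
    out = np.empty(n_epochs, dtype="<U1")
    pos = 0
    asleep = True
    while pos < n_epochs:
        if asleep:
            bout = n_epochs - pos if h == 0 else min(rng.geometric(h), n_epochs - pos)
            out[pos : pos + bout] = _sleep_stages(bout, rng)
        else:
            if rng.random() < params.long_gap_prob:
                bout = 120 + rng.geometric(0.05)  # >= 60 min gap
            else:
                bout = rng.geometric(0.5)  # ~1 min typical intrusion
            bout = min(bout, n_epochs - pos)
            out[pos : pos + bout] = "W"
        pos += bout
        asleep = not asleep
    # the night is bounded by sleep onset and final wake onset
    if out[-1] == "W":
        last = np.max(np.nonzero(out != "W")[0]) if (out != "W").any() else 0
        out[last + 1 :] = _sleep_stages(n_epochs - last - 1, rng)
    if out[0] == "W":
        first = np.min(np.nonzero(out != "W")[0])
        out[:first] = out[first]
    return out


def _sleep_stages(n: int, rng: np.random.Generator) -> np.ndarray:
    """Fill a sleep bout with light/deep/REM runs (sticky Markov chain)."""
    if n <= 0:
        return np.empty(0, dtype="<U1")
    stages = np.empty(n, dtype="<U1")
    current = rng.choice(["L", "D", "R"], p=[0.55, 0.20, 0.25])
    pos = 0
    while pos < n:
        run = min(rng.geometric(1 / 20.0), n - pos)  # ~10-min stage runs
        stages[pos : pos + run] = current
        pos += run
        current = rng.choice(["L", "D", "R"], p=[0.55, 0.20, 0.25])
    return stages


def simulate_temperature_day(
    amplitude: float,
    autocorrelation: float,
    noise_scale: float,
    rng: np.random.Generator,
    baseline: float = 33.0,
    peak_minute: int = 900,
    band: tuple[float, float] | None = None,
) -> np.ndarray:
    """One 24-h (1440-minute) distal-temperature day, anchored at noon.

    The deterministic part is a sinusoid of peak-to-trough range
    ``amplitude`` peaking at ``peak_minute`` (during sleep — distal skin
    temperature rises at night as heat is dissipated through the
    extremities), plus stationary AR(1) noise with lag-1 autocorrelation
    ``autocorrelation`` and stationary SD ``noise_scale``.
    """
    if amplitude < 0:
        raise ConfigurationError("amplitude must be >= 0")
    t = np.arange(MINUTES_PER_DAY)
    series = baseline + (amplitude / 2.0) * np.cos(
        2.0 * np.pi * (t - peak_minute) / MINUTES_PER_DAY
    )
    if noise_scale > 0:
        phi = autocorrelation
        innov = rng.standard_normal(MINUTES_PER_DAY) * noise_scale * np.sqrt(1 - phi**2)
        innov[0] = rng.standard_normal() * noise_scale
        noise = signal.lfilter([1.0], [1.0, -phi], innov)
        series = series + noise
    if band is not None:
        series = np.clip(series, band[0], band[1])
    return series


# ---------------------------------------------------------------------------
# cohort-level simulation


def _truncate_pos(x: np.ndarray | float) -> np.ndarray | float:
    return np.maximum(x, 1e-6)


def simulate_cohort(config: GeneratorConfig) -> Cohort:
    """Simulate the full cohort: subjects, nightly records and summaries.

    Deterministic given ``config.rng_seed``; each subject draws from an
    independent child RNG stream so cohort composition is invariant to
    subject ordering.
    """
    config.validate()
    root = np.random.SeedSequence(config.rng_seed)

    if config.prevalence is not None:
        total = 2 * config.n_subjects_per_class
        n_dm = max(int(round(total * config.prevalence)), 1)
        n_ctrl = total - n_dm
    else:
        n_dm = n_ctrl = config.n_subjects_per_class
    labels = [0] * n_ctrl + [1] * n_dm

    comp_rng = np.random.default_rng(root.spawn(1)[0])
    profiles: list[SubjectProfile] = []
    for i, label in enumerate(labels):
        age_bin = comp_rng.choice(AGE_BINS, p=_AGE_WEIGHTS[label] / _AGE_WEIGHTS[label].sum())
        sex = comp_rng.choice(SEXES, p=_SEX_WEIGHTS[label] / _SEX_WEIGHTS[label].sum())
        conditions: frozenset[str] = frozenset()
        if (
            label == 0
            and config.chronic_condition_fraction > 0
            and comp_rng.random() < config.chronic_condition_fraction
        ):
            k = comp_rng.integers(1, 3)
            conditions = frozenset(comp_rng.choice(_OTHER_CONDITIONS, size=k, replace=False))
        profiles.append(
            SubjectProfile(f"S{i:05d}", int(label), str(age_bin), str(sex), conditions)
        )

    subject_seeds = root.spawn(len(profiles) + 1)[1:]
    nights: dict[str, list[NightRecord]] = {}
    for profile, seed in zip(profiles, subject_seeds):
        rng = np.random.default_rng(seed)
        nights[profile.subject_id] = _simulate_subject_nights(config, profile, rng)

    subjects = pd.DataFrame(
        {
            "subject_id": [p.subject_id for p in profiles],
            "label": [p.label for p in profiles],
            "age_bin": [p.age_bin for p in profiles],
            "sex": [p.sex for p in profiles],
            "other_conditions": [";".join(sorted(p.other_conditions)) for p in profiles],
        }
    )
    return Cohort(config=config, subjects=subjects, nights=nights)


def _effective_params(
    config: GeneratorConfig, profile: SubjectProfile, rng: np.random.Generator
) -> ClassParams:
    """Per-subject physiology parameters, honouring the confound knobs."""
    if profile.label == 1:
        if rng.random() < config.dm_control_like_fraction:
            return config.control  # control-like physiology, DM label
        return config.dm
    params = config.control
    if profile.other_conditions:
        # partial shift of HR/HRV/sleep parameters toward DM values;
        # temperature parameters stay at control values, encoding that
        # temperature features remain specific to DM
        w = config.chronic_shift
        mix = lambda a, b: (a[0] + w * (b[0] - a[0]), a[1] + w * (b[1] - a[1]))
        params = dataclasses.replace(
            params,
            hr_mean=mix(params.hr_mean, config.dm.hr_mean),
            rmssd=mix(params.rmssd, config.dm.rmssd),
            tst=mix(params.tst, config.dm.tst),
            fragmentation_hazard=params.fragmentation_hazard
            + w * (config.dm.fragmentation_hazard - params.fragmentation_hazard),
        )
    return params


def _simulate_subject_nights(
    config: GeneratorConfig, profile: SubjectProfile, rng: np.random.Generator
) -> list[NightRecord]:
    params = _effective_params(config, profile, rng)
    rho = config.subject_effect_fraction
    sub_sd = np.sqrt(rho)
    night_sd = np.sqrt(1.0 - rho)

    # persistent subject-level random effects (location shifts)
    eff = {
        name: rng.standard_normal() * getattr(params, name)[1] * sub_sd
        for name in ("hr_mean", "rmssd", "tst", "ddbta")
    }
    onset_loc = config.sleep_onset_loc + rng.standard_normal() * 0.4
    # subject-level heterogeneity in sleep fragmentation and temperature
    # smoothness, so these traits behave like the scalar summaries:
    # persistent between-subject differences plus night-to-night noise
    hazard_subj = params.fragmentation_hazard * float(
        np.exp(rng.standard_normal() * params.hazard_subject_sd)
    )
    phi_subj = params.temp_autocorr + rng.standard_normal() * params.autocorr_subject_sd

    records: list[NightRecord] = []
    for night_date in config.night_dates:
        if rng.random() < config.missingness:
            records.append(NightRecord(profile.subject_id, night_date, present=False))
            continue

        def draw(name: str) -> float:
            loc, scale = getattr(params, name)
            v = loc + eff[name] + rng.standard_normal() * scale * night_sd
            return float(_truncate_pos(v))

        hr = draw("hr_mean")
        rmssd = draw("rmssd")
        tst = min(draw("tst"), 15.9)
        ddbta = draw("ddbta")

        sleep_onset = (onset_loc + rng.standard_normal() * config.sleep_onset_scale) % 24.0
        hazard_night = min(hazard_subj * float(np.exp(rng.standard_normal() * 0.25)), 0.2)
        night_params = dataclasses.replace(params, fragmentation_hazard=hazard_night)
        hypnogram = simulate_hypnogram(night_params, tst, rng)
        span_hours = len(hypnogram) / EPOCHS_PER_HOUR
        wake_onset = (sleep_onset + span_hours) % 24.0

        phi_night = float(np.clip(phi_subj + rng.standard_normal() * 0.02, 0.5, 0.99))
        # temperature peaks near the middle of the sleep episode
        mid_clock = (sleep_onset + span_hours / 2.0) % 24.0
        peak_minute = int(((mid_clock - 12.0) % 24.0) * 60.0)
        temperature = simulate_temperature_day(
            ddbta,
            phi_night,
            params.temp_noise_scale,
            rng,
            baseline=config.temperature_baseline,
            peak_minute=peak_minute,
            band=config.temperature_band,
        )

        summaries = {
            "hr_average": hr,
            "hr_lowest": max(hr - abs(rng.normal(8.0, 2.0)), 30.0),
            "rmssd": rmssd,
            "rem_rmssd": float(_truncate_pos(rmssd * rng.normal(1.10, 0.05))),
            "nrem_rmssd": float(_truncate_pos(rmssd * rng.normal(0.95, 0.05))),
            "breath_average": float(rng.normal(15.5, 1.5)),
            "breath_v_average": float(abs(rng.normal(1.5, 0.5))),
            "hr_low_duration": float(abs(rng.normal(300.0, 60.0))),
            "total_sleep_time": span_hours,
        }
        records.append(
            NightRecord(
                profile.subject_id,
                night_date,
                present=True,
                temperature=temperature,
                hypnogram=hypnogram,
                sleep_onset=float(sleep_onset),
                wake_onset=float(wake_onset),
                summaries=summaries,
            )
        )
    return records


# ---------------------------------------------------------------------------
# on-disk interchange formats (plain-text CSV + parquet for minute data)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write subjects.csv, summaries.csv, hypnograms.csv and nights.parquet."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.subjects.to_csv(out / "subjects.csv", index=False)
    cohort.summaries_frame().to_csv(out / "summaries.csv", index=False)

    hyp_rows, temp_frames = [], []
    for rec in cohort.iter_present_nights():
        n = len(rec.hypnogram)
        hyp_rows.append(
            pd.DataFrame(
                {
                    "subject_id": rec.subject_id,
                    "night_date": rec.night_date,
                    "epoch_index": np.arange(n),
                    "stage": rec.hypnogram,
                }
            )
        )
        temp_frames.append(
            pd.DataFrame(
                {
                    "subject_id": rec.subject_id,
                    "night_date": rec.night_date,
                    "minute_index": np.arange(MINUTES_PER_DAY, dtype=np.int32),
                    "temperature_c": rec.temperature,
                }
            )
        )
    hyp = pd.concat(hyp_rows, ignore_index=True) if hyp_rows else pd.DataFrame(
        columns=["subject_id", "night_date", "epoch_index", "stage"]
    )
    hyp.to_csv(out / "hypnograms.csv", index=False)
    temps = pd.concat(temp_frames, ignore_index=True) if temp_frames else pd.DataFrame(
        columns=["subject_id", "night_date", "minute_index", "temperature_c"]
    )
    temps.to_parquet(out / "nights.parquet", index=False)


def read_cohort(in_dir: str | Path, config: GeneratorConfig | None = None) -> Cohort:
    """Rebuild a :class:`Cohort` from the on-disk interchange files."""
    d = Path(in_dir)
    subjects = pd.read_csv(d / "subjects.csv", keep_default_na=False)
    summaries = pd.read_csv(d / "summaries.csv", parse_dates=["night_date"])
    hyps = pd.read_csv(d / "hypnograms.csv", parse_dates=["night_date"])
    temps = pd.read_parquet(d / "nights.parquet")
    temps["night_date"] = pd.to_datetime(temps["night_date"])
    config = config or GeneratorConfig()

    hyp_groups = {k: g for k, g in hyps.groupby(["subject_id", "night_date"], sort=False)}
    temp_groups = {k: g for k, g in temps.groupby(["subject_id", "night_date"], sort=False)}
    nights: dict[str, list[NightRecord]] = {}
    summary_cols = [
        c for c in summaries.columns if c not in ("subject_id", "night_date", "sleep_onset", "wake_onset")
    ]
    sum_idx = summaries.set_index(["subject_id", "night_date"])
    all_dates = config.night_dates
    for sid in subjects["subject_id"]:
        recs = []
        for nd in all_dates:
            key = (sid, pd.Timestamp(nd))
            if key not in sum_idx.index:
                recs.append(NightRecord(sid, nd, present=False))
                continue
            row = sum_idx.loc[key]
            hyp = hyp_groups.get(key)
            tmp = temp_groups.get(key)
            recs.append(
                NightRecord(
                    sid,
                    nd,
                    present=True,
                    temperature=None if tmp is None else tmp["temperature_c"].to_numpy(),
                    hypnogram=None if hyp is None else hyp["stage"].to_numpy(dtype="<U1"),
                    sleep_onset=float(row["sleep_onset"]),
                    wake_onset=float(row["wake_onset"]),
                    summaries={c: float(row[c]) for c in summary_cols},
                )
            )
        nights[sid] = recs
    return Cohort(config=config, subjects=subjects, nights=nights)
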