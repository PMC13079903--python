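"""Nightly feature table assembly, multi-night windowing and cohort splits.

Windows are rolling, overlapping spans of L consecutive calendar nights
(L in {1, 3, 7, 14, 21}) with a 1-night stride.  Data-quality caps on
missing nights are applied per length — 0 for L=1, 2 for L=3 and L=7,
4 for L=14, 6 for L=21 — and additionally no aligned 7-night block may
miss more than 2 nights.  The start dates of valid 21-night windows
anchor the window sets of every other length, so all window-length
datasets share an identical (subject, start_date) key set and models of
different lengths are evaluated on the same material.
"""

from __future__ import annotations

import warnings
from datetime import timedelta

import numpy as np
import pandas as pd

from .features_table import FEATURES
from .sleep import sleep_features_for_night
from .synthetic import Cohort
from .temperature import add_baseline_deviation_features, temperature_features_for_night

WINDOW_LENGTHS = (1, 3, 7, 14, 21)
MISSING_CAPS = {1: 0, 3: 2, 7: 2, 14: 4, 21: 6}
WEEK = 7
WEEKLY_CAP = 2
ANCHOR_LENGTH = 21


def flat_columns(length: int) -> list[str]:
    """Night-major flattened column names: night 0's 36 features, then night 1's, ..."""
    return [f"{feat}__n{i:02d}" for i in range(length) for feat in FEATURES]


def flat_layout(length: int) -> dict[str, tuple[str, int]]:
    """Map flattened column -> (base feature, night position)."""
    return {
        f"{feat}__n{i:02d}": (feat, i) for i in range(length) for feat in FEATURES
    }


# ---------------------------------------------------------------------------
# nightly table


def extract_nightly_features(cohort: Cohort, strict_sleep: bool = False) -> pd.DataFrame:
    """Run sleep + temperature extraction over a cohort into the nightly table."""
    sleep_rows, temp_rows, keys = [], [], []
    for sid in cohort.subjects["subject_id"]:
        for rec in cohort.nights[sid]:
            keys.append((sid, rec.night_date, rec.present))
            sleep_rows.append(sleep_features_for_night(rec, strict=strict_sleep))
            temp_rows.append(temperature_features_for_night(rec))
    key_df = pd.DataFrame(keys, columns=["subject_id", "night_date", "night_present"])
    sleep_df = pd.concat([key_df[["subject_id", "night_date"]], pd.DataFrame(sleep_rows)], axis=1)
    temp_df = pd.concat([key_df[["subject_id", "night_date"]], pd.DataFrame(temp_rows)], axis=1)
    temp_df = add_baseline_deviation_features(temp_df)
    summaries = cohort.summaries_frame()
    table = build_nightly_table(sleep_df, temp_df, summaries)
    table = table.merge(cohort.subjects[["subject_id", "label"]], on="subject_id", how="left")
    return table


def build_nightly_table(
    sleep_features: pd.DataFrame,
    temperature_features: pd.DataFrame,
    summaries: pd.DataFrame,
) -> pd.DataFrame:
    """Outer-join the three per-night frames into the 36-column nightly table.

    A night with no extractable feature at all is marked absent
    (``night_present = False``).  Duplicate (subject, date) keys raise.
    """
    keys = ["subject_id", "night_date"]
    frames = {
        "sleep_features": sleep_features,
        "temperature_features": temperature_features,
        "summaries": summaries,
    }
    for name, f in frames.items():
        if len(f) and f.duplicated(subset=keys).any():
            raise ValueError(f"duplicate (subject_id, night_date) rows in {name}")

    table = None
    for f in frames.values():
        if table is None:
            table = f.copy()
        else:
            overlap = [c for c in f.columns if c in table.columns and c not in keys]
            table = table.merge(f.drop(columns=overlap), on=keys, how="outer")
    if table is None or table.empty:
        return pd.DataFrame(columns=keys + list(FEATURES) + ["night_present"])

    for feat in FEATURES:
        if feat not in table.columns:
            table[feat] = np.nan
    table = table[keys + list(FEATURES)].sort_values(keys).reset_index(drop=True)
    table["night_present"] = table[list(FEATURES)].notna().any(axis=1)
    return table


# ---------------------------------------------------------------------------
# window validity and extraction


def valid_window(present_mask: np.ndarray, length: int) -> bool:
    """Data-quality rule for one candidate window.

    True iff total missing nights <= the per-length cap and, for
    L >= 7, every aligned non-overlapping 7-night block from the window
    start misses at most 2 nights.
    """
    mask = np.asarray(present_mask, dtype=bool)
    if mask.size != length:
        raise ValueError(f"mask length {mask.size} != window length {length}")
    if length not in MISSING_CAPS:
        raise ValueError(f"unsupported window length {length}")
    missing = int((~mask).sum())
    if missing > MISSING_CAPS[length]:
        return False
    if length >= WEEK:
        for start in range(0, length - WEEK + 1, WEEK):
            if int((~mask[start : start + WEEK]).sum()) > WEEKLY_CAP:
                return False
    return True


def _presence_by_subject(nightly: pd.DataFrame, dates: list) -> dict[str, np.ndarray]:
    date_index = {pd.Timestamp(d): i for i, d in enumerate(dates)}
    out = {}
    for sid, g in nightly.groupby("subject_id", sort=False):
        mask = np.zeros(len(dates), dtype=bool)
        for nd, present in zip(g["night_date"], g["night_present"]):
            idx = date_index.get(pd.Timestamp(nd))
            if idx is not None:
                mask[idx] = bool(present)
        out[sid] = mask
    return out


def anchor_start_dates(nightly: pd.DataFrame, dates: list) -> dict[str, list]:
    """Per subject, start dates of valid 21-night windows inside the range."""
    presence = _presence_by_subject(nightly, dates)
    anchors: dict[str, list] = {}
    for sid, mask in presence.items():
        starts = []
        for i in range(0, len(dates) - ANCHOR_LENGTH + 1):
            if valid_window(mask[i : i + ANCHOR_LENGTH], ANCHOR_LENGTH):
                starts.append(dates[i])
        anchors[sid] = starts
    return anchors


def extract_windows(
    nightly: pd.DataFrame,
    length: int,
    dates: list,
    anchors: dict[str, list] | None = None,
) -> pd.DataFrame:
    """Build the flattened window dataset for one window length.

    One row per (subject, anchor start date) whose L-night mask passes
    :func:`valid_window`; feature cells of missing nights stay NaN until
    the model-stage zero-fill.  ``anchors`` defaults to the valid
    21-night start dates computed from the same table.
    """
    if anchors is None:
        anchors = anchor_start_dates(nightly, dates)
    presence = _presence_by_subject(nightly, dates)
    date_index = {pd.Timestamp(d): i for i, d in enumerate(dates)}
    cols = flat_columns(length)

    # per-subject matrix of nightly features aligned to the date range
    feat_arrays: dict[str, np.ndarray] = {}
    for sid, g in nightly.groupby("subject_id", sort=False):
        arr = np.full((len(dates), len(FEATURES)), np.nan)
        idx = [date_index[pd.Timestamp(d)] for d in g["night_date"] if pd.Timestamp(d) in date_index]
        sub = g[g["night_date"].map(lambda d: pd.Timestamp(d) in date_index)]
        arr[idx, :] = sub[list(FEATURES)].to_numpy(dtype=float)
        feat_arrays[sid] = arr

    rows, meta = [], []
    for sid, starts in anchors.items():
        mask = presence.get(sid)
        if mask is None:
            continue
        for start in starts:
            i = date_index[pd.Timestamp(start)]
            if i + length > len(dates):
                continue
            if not valid_window(mask[i : i + length], length):
                continue
            block = feat_arrays[sid][i : i + length]
            # absent nights contribute all-NaN feature rows
            block = np.where(mask[i : i + length, None], block, np.nan)
            rows.append(block.reshape(-1))
            meta.append((sid, pd.Timestamp(start)))
    if not rows:
        return pd.DataFrame(columns=["subject_id", "start_date"] + cols)
    out = pd.DataFrame(rows, columns=cols)
    out.insert(0, "start_date", [m[1] for m in meta])
    out.insert(0, "subject_id", [m[0] for m in meta])
    return out


def attach_labels(windows: pd.DataFrame, subjects: pd.DataFrame) -> pd.DataFrame:
    lab = subjects.set_index("subject_id")["label"]
    out = windows.copy()
    out.insert(2, "label", out["subject_id"].map(lab).astype(int))
    return out


# ---------------------------------------------------------------------------
# cohort splitting / sampling


def stratified_split(
    subjects: pd.DataFrame, train_fraction: float = 0.8, rng_seed: int = 0
) -> tuple[list[str], list[str]]:
    """Subject-disjoint train/test split, stratified by (label, age_bin).

    Per-stratum train counts are the rounded global fraction; a stratum
    with a single subject goes to train with a warning.  Deterministic
    given the seed.
    """
    rng = np.random.default_rng(rng_seed)
    train_ids: list[str] = []
    test_ids: list[str] = []
    for (_, _), g in subjects.groupby(["label", "age_bin"], sort=True):
        ids = g["subject_id"].tolist()
        if len(ids) == 1:
            warnings.warn(f"stratum with a single subject ({ids[0]}); assigned to train")
            train_ids.extend(ids)
            continue
        perm = rng.permutation(len(ids))
        n_train = int(round(train_fraction * len(ids)))
        n_train = min(max(n_train, 1), len(ids) - 1)
        for j, p in enumerate(perm):
            (train_ids if j < n_train else test_ids).append(ids[p])
    return sorted(train_ids), sorted(test_ids)


def stratified_class_sample(
    subjects: pd.DataFrame, n_per_class: int, rng_seed: int = 0
) -> pd.DataFrame:
    """Sample a class-balanced cohort matched on (age_bin, sex).

    Within every (age_bin, sex) cell the two classes contribute equal
    counts (the cell minimum, scaled down if the per-class target is
    exceeded).  Cells that cannot meet their share shrink with a warning.
    """
    rng = np.random.default_rng(rng_seed)
    cells = []
    for (age, sex), g in subjects.groupby(["age_bin", "sex"], sort=True):
        n0 = (g["label"] == 0).sum()
        n1 = (g["label"] == 1).sum()
        cells.append(((age, sex), g, min(n0, n1)))
    total_balanced = sum(c[2] for c in cells)
    if total_balanced < n_per_class:
        warnings.warn(
            f"only {total_balanced} balanced subjects per class available "
            f"(requested {n_per_class})"
        )
    scale = min(1.0, n_per_class / total_balanced) if total_balanced else 0.0
    chosen = []
    for (age, sex), g, cap in cells:
        take = int(round(cap * scale))
        if take == 0:
            continue
        for label in (0, 1):
            ids = g.loc[g["label"] == label, "subject_id"].tolist()
            pick = rng.choice(len(ids), size=take, replace=False)
            chosen.extend(ids[p] for p in pick)
    return subjects[subjects["subject_id"].isin(chosen)].reset_index(drop=True)
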