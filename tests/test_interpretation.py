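"""Importance aggregation, ablation, Dunn/BH chain and population tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wearadetect.features_table import FEATURE_SETS, FEATURES
from wearadetect.interpretation import (
    ablation_sweep,
    chronic_condition_analysis,
    cohens_d,
    dunn_test,
    false_negative_profile,
    nightly_population_tests,
    subject_mean_probabilities,
)
from wearadetect.model import DMScreeningModel, ModelSpec
from wearadetect.windowing import flat_columns

from test_model import toy_windows


# ---------------------------------------------------------------------------
# Dunn's test vs an independent oracle


def dunn_oracle(groups):
    """Independent Dunn implementation: manual ranking with midranks,
    explicit tie correction, normal CDF via erfc."""
    labels, pooled = [], []
    for name, vals in groups.items():
        for v in vals:
            labels.append(name)
            pooled.append(float(v))
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        midrank = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = midrank
        i = j + 1
    n = len(pooled)
    tie_counts = {}
    for v in pooled:
        tie_counts[v] = tie_counts.get(v, 0) + 1
    tie_term = sum(t**3 - t for t in tie_counts.values()) / (12.0 * (n - 1))
    out = {}
    names = list(groups)
    for a, b in itertools.combinations(names, 2):
        ra = [r for r, l in zip(ranks, labels) if l == a]
        rb = [r for r, l in zip(ranks, labels) if l == b]
        se = math.sqrt((n * (n + 1) / 12.0 - tie_term) * (1 / len(ra) + 1 / len(rb)))
        z = (sum(ra) / len(ra) - sum(rb) / len(rb)) / se
        out[(a, b)] = (z, math.erfc(abs(z) / math.sqrt(2.0)))
    return out


def bh_oracle(pvals):
    """Benjamini-Hochberg step-up, by hand."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        k = m - rank_from_end
        val = min(pvals[i] * m / k, prev)
        adj[i] = val
        prev = val
    return adj


def test_dunn_matches_oracle_on_fixture():
    rng = np.random.default_rng(0)
    groups = {
        "a": rng.normal(0, 1, 10).round(1),  # rounding forces ties
        "b": rng.normal(0.8, 1, 10).round(1),
        "c": rng.normal(-0.5, 1, 10).round(1),
    }
    result = dunn_test(groups)
    oracle = dunn_oracle(groups)
    for _, row in result.iterrows():
        z, p = oracle[(row["group_a"], row["group_b"])]
        assert row["z"] == pytest.approx(z, abs=1e-8)
        assert row["p_raw"] == pytest.approx(p, abs=1e-8)
    adj = bh_oracle(result["p_raw"].tolist())
    np.testing.assert_allclose(result["p_adj"].to_numpy(), adj, atol=1e-8)


def test_bh_preserves_raw_ordering():
    rng = np.random.default_rng(1)
    groups = {k: rng.normal(i * 0.3, 1, 15) for i, k in enumerate("abcd")}
    result = dunn_test(groups)
    raw_order = result["p_raw"].rank(method="first")
    adj_order = result["p_adj"].rank(method="first")
    sorted_raw = result.sort_values("p_raw")
    assert sorted_raw["p_adj"].is_monotonic_increasing


# ---------------------------------------------------------------------------
# importance aggregation


def test_planted_signal_ranks_first():
    rng = np.random.default_rng(2)
    w = toy_windows(n_per_class=80, margin=0.0, seed=3)
    cols = flat_columns(1)
    w[cols] = rng.standard_normal(w[cols].shape)
    w["complexity_0__n00"] += 2.0 * w["label"]  # the planted informative feature
    res = DMScreeningModel(w, spec=ModelSpec(family="trees", window_length=1)).fit()
    imp = res.feature_importances()
    assert imp.idxmax() == "complexity_0"
    assert imp.sum() == pytest.approx(1.0, abs=1e-9)


def test_linear_importance_same_contract():
    w = toy_windows(margin=2.0)
    res = DMScreeningModel(w, spec=ModelSpec(family="linear", window_length=1)).fit()
    imp = res.feature_importances()
    assert set(imp.index) == set(FEATURES)
    assert imp.sum() == pytest.approx(1.0)
    assert imp.idxmax() == "hr_low_duration"  # toy margin sits on the first column


def test_importance_aggregates_over_nights(default_windows, default_split):
    train_ids, _ = default_split
    w = default_windows[3]
    res = DMScreeningModel(
        w[w["subject_id"].isin(train_ids)],
        spec=ModelSpec(family="linear", window_length=3),
    ).fit()
    imp = res.feature_importances()
    assert len(imp) == 36 and imp.sum() == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# ablation


def make_planted_windows(n_per_class=60, n_subjects=12, seed=0, signal_features=("complexity_0",)):
    """Window frame where only the named features carry class signal."""
    rng = np.random.default_rng(seed)
    cols = flat_columns(1)
    rows = []
    for label in (0, 1):
        for i in range(n_per_class):
            x = dict(zip(cols, rng.standard_normal(len(cols))))
            for f in signal_features:
                x[f + "__n00"] += 1.5 * label
            x["subject_id"] = f"p{label}_{i % n_subjects}"
            x["start_date"] = pd.Timestamp("2020-05-01")
            x["label"] = label
            rows.append(x)
    return pd.DataFrame(rows)


def test_ablation_trains_31_combinations():
    w = make_planted_windows(n_per_class=30, seed=1)
    abl = ablation_sweep(w, w, spec=ModelSpec(family="linear", window_length=1))
    assert len(abl.combinations) == 31
    assert (abl.set_deltas["n_additions"] == 16).all()


def test_ablation_temperature_signal_ranks_set_five():
    w = make_planted_windows(
        n_per_class=90, seed=2,
        signal_features=("complexity_0", "complexity_1", "diurnal_distal_body_temp_amp"),
    )
    test_w = make_planted_windows(
        n_per_class=60, seed=5,
        signal_features=("complexity_0", "complexity_1", "diurnal_distal_body_temp_amp"),
    )
    abl = ablation_sweep(w, test_w, spec=ModelSpec(family="linear", window_length=1))
    assert abl.best_set() == 5
    deltas = abl.set_deltas.set_index("feature_set")["delta_auroc_mean"]
    assert all(deltas[5] > deltas[s] for s in (1, 2, 3, 4))


def test_ablation_all_noise_deltas_near_zero():
    deltas_by_seed = []
    for seed in range(5):
        w = make_planted_windows(n_per_class=50, seed=seed, signal_features=())
        test_w = make_planted_windows(n_per_class=40, seed=seed + 50, signal_features=())
        abl = ablation_sweep(w, test_w, spec=ModelSpec(family="linear", window_length=1))
        deltas_by_seed.append(abl.set_deltas["delta_auroc_mean"].to_numpy())
    mean_deltas = np.mean(deltas_by_seed, axis=0)
    assert np.abs(mean_deltas).max() < 0.05


def test_ablation_full_combination_matches_main_pipeline():
    w = make_planted_windows(n_per_class=40, seed=3)
    test_w = make_planted_windows(n_per_class=30, seed=4)
    spec = ModelSpec(family="linear", window_length=1)
    abl = ablation_sweep(w, test_w, spec=spec, seed=0)
    full = abl.combinations.loc[abl.combinations["combination"] == "12345", "auroc"].iloc[0]
    direct = DMScreeningModel(w, spec=spec, seed=0).fit().evaluate(test_w).auroc
    assert full == direct


# ---------------------------------------------------------------------------
# chronic-condition analysis


def _subjects_frame(groups):
    rows = []
    for sid, (label, cond) in groups.items():
        rows.append({"subject_id": sid, "label": label, "other_conditions": cond,
                     "age_bin": "40-49", "sex": "M"})
    return pd.DataFrame(rows)


def test_identical_groups_not_significant():
    rng = np.random.default_rng(4)
    sids = [f"s{i}" for i in range(60)]
    groups = {}
    for i, sid in enumerate(sids):
        label = 1 if i < 20 else 0
        cond = "hypertension" if 20 <= i < 40 else ""
        groups[sid] = (label, cond)
    scores = rng.random(600)
    window_subjects = pd.Series(np.repeat(sids, 10))
    out = chronic_condition_analysis(scores, window_subjects, _subjects_frame(groups))
    assert out["kruskal"]["p"] > 0.05
    assert (out["dunn"]["p_adj"] > 0.05).all()


def test_planted_shift_detected():
    rng = np.random.default_rng(5)
    sids = [f"s{i}" for i in range(120)]
    groups, scores = {}, []
    for i, sid in enumerate(sids):
        label = 1 if i < 40 else 0
        cond = "sleep_apnea" if 40 <= i < 80 else ""
        groups[sid] = (label, cond)
        base = 0.8 if label else (0.5 if cond else 0.2)
        scores.extend(rng.normal(base, 0.1, 5))
    window_subjects = pd.Series(np.repeat(sids, 5))
    out = chronic_condition_analysis(np.array(scores), window_subjects,
                                     _subjects_frame(groups))
    assert out["kruskal"]["p"] < 0.001
    assert out["group_sizes"] == {"DM": 40, "other": 40, "none": 40}


def test_subject_probability_groups_partition():
    rng = np.random.default_rng(6)
    sids = ["a", "b", "c"]
    subjects = _subjects_frame({"a": (1, ""), "b": (0, "asthma"), "c": (0, "")})
    probs = subject_mean_probabilities(
        rng.random(9), pd.Series(np.repeat(sids, 3)), subjects
    )
    assert dict(zip(probs["subject_id"], probs["group"])) == {
        "a": "DM", "b": "other", "c": "none"
    }


# ---------------------------------------------------------------------------
# population tests


def test_null_effect_size_near_zero():
    rng = np.random.default_rng(7)
    frame = pd.DataFrame({
        "subject_id": "x",
        "label": np.repeat([0, 1], 2000),
        "hr_average": rng.normal(60, 8, 4000),
    })
    out = nightly_population_tests(frame, features=("hr_average",))
    assert abs(out["cohens_d"].iloc[0]) < 0.1
    assert out["p"].iloc[0] > 0.001


def test_unit_shift_recovers_d_of_one():
    rng = np.random.default_rng(8)
    frame = pd.DataFrame({
        "subject_id": "x",
        "label": np.repeat([0, 1], 10_000),
        "diurnal_distal_body_temp_amp": np.concatenate([
            rng.normal(0, 1, 10_000), rng.normal(1, 1, 10_000)
        ]),
    })
    out = nightly_population_tests(frame, features=("diurnal_distal_body_temp_amp",))
    assert out["cohens_d"].iloc[0] == pytest.approx(1.0, abs=0.05)


def test_u_statistic_matches_pairwise_count():
    rng = np.random.default_rng(9)
    x1 = rng.normal(1, 1, 20)
    x0 = rng.normal(0, 1, 20)
    frame = pd.DataFrame({
        "subject_id": "x",
        "label": np.repeat([1, 0], 20),
        "sleep_mean": np.concatenate([x1, x0]),
    })
    out = nightly_population_tests(frame, features=("sleep_mean",))
    brute = sum(
        1.0 if a > b else (0.5 if a == b else 0.0) for a in x1 for b in x0
    )
    assert out["U"].iloc[0] == pytest.approx(brute)


def test_common_feature_filters_trim_tails():
    rng = np.random.default_rng(10)
    frame = pd.DataFrame({
        "subject_id": "x",
        "label": np.repeat([0, 1], 1000),
        "hr_average": rng.normal(60, 8, 2000),
    })
    out = nightly_population_tests(frame, features=("hr_average",))
    # 5%/95% filter keeps ~90% of each class
    assert out["n_dm"].iloc[0] <= 920 and out["n_ctrl"].iloc[0] <= 920


# ---------------------------------------------------------------------------
# false-negative profiling


def test_false_negatives_resemble_true_negatives():
    """DM windows generated from control physiology should, when missed,
    sit closer to TN than TP in the common features."""
    rng = np.random.default_rng(11)
    n = 300
    labels = np.repeat([0, 1], n)
    # control-like DM fraction: physiology drawn from the control distribution
    control_like = np.zeros(2 * n, bool)
    control_like[n : n + 60] = True
    hr = np.where((labels == 1) & ~control_like, rng.normal(68, 3, 2 * n),
                  rng.normal(60, 3, 2 * n))
    scores = (hr - 60) / 10 + rng.normal(0, 0.05, 2 * n)
    feats = pd.DataFrame({"hr_average": hr})
    out = false_negative_profile(scores, labels, feats, threshold=0.4,
                                 features=("hr_average",))
    assert min(out["group_sizes"].values()) > 0
    t = out["tests"][0]
    assert abs(t["median_FN"] - t["median_TN"]) < abs(t["median_FN"] - t["median_TP"])
    assert t["kruskal_p"] < 0.001


def test_no_false_negatives_skips_with_warning():
    scores = np.array([0.9, 0.9, 0.1, 0.1])
    labels = np.array([1, 1, 0, 0])
    feats = pd.DataFrame({"hr_average": [1.0, 2.0, 3.0, 4.0]})
    with pytest.warns(UserWarning, match="skipped"):
        out = false_negative_profile(scores, labels, feats, threshold=0.5)
    assert out["tests"] is None
    assert out["group_sizes"]["FN"] == 0


def test_group_sizes_reported():
    rng = np.random.default_rng(12)
    scores = rng.random(100)
    labels = (rng.random(100) < 0.4).astype(int)
    feats = pd.DataFrame({"hr_average": rng.normal(60, 5, 100)})
    out = false_negative_profile(scores, labels, feats, threshold=0.5,
                                 features=("hr_average",))
    assert set(out["group_sizes"]) == {"TN", "FN", "TP"}
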