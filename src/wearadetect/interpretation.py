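"""Feature importance, feature-set ablation and condition-specificity tests.

Three analyses sit on top of a fitted screening model:

* importance aggregation — model-native importances summed over night
  positions per base feature (see
  :meth:`wearadetect.model.DMScreeningResults.feature_importances`),
* a feature-set ablation sweep — retraining on every nonempty
  combination of the five feature sets and scoring each set by its mean
  marginal AUROC gain over the 16 subsets of the other four sets (the
  empty-prefix baseline is chance, AUROC 0.5),
* nonparametric statistical chains — Mann-Whitney U population tests
  with Cohen's d per nightly feature, and Kruskal-Wallis followed by
  Dunn's posthoc test (Benjamini-Hochberg adjusted) for group
  comparisons of per-subject mean predicted probabilities and for the
  TN/FN/TP window-profile analysis.

Dunn's test is implemented here (pooled-rank z statistics with tie
correction) and verified against an independent brute-force oracle in
the test suite.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .features_table import COMMON_FEATURES, FEATURE_SETS
from .model import DMScreeningModel, ModelSpec

CHANCE_AUROC = 0.5


# ---------------------------------------------------------------------------
# Dunn's posthoc test


def dunn_test(groups: dict[str, np.ndarray], adjust: str = "fdr_bh") -> pd.DataFrame:
    """Two-sided Dunn's posthoc test over all group pairs.

    Pooled ranks with tie correction; z_ij = (Rbar_i - Rbar_j) /
    sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j)) with
    T = sum(t^3 - t) over tie groups.  P-values are adjusted with
    Benjamini-Hochberg by default.
    """
    names = list(groups)
    values = [np.asarray(groups[n], dtype=float) for n in names]
    pooled = np.concatenate(values)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes, pos = {}, {}, 0
    for name, v in zip(names, values):
        mean_ranks[name] = ranks[pos : pos + v.size].mean()
        sizes[name] = v.size
        pos += v.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z, "p_raw": p})
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p_raw"], method=adjust)[1]
    return out


# ---------------------------------------------------------------------------
# ablation


@dataclass
class AblationResult:
    """Test performance per feature-set combination, plus per-set marginal gains."""

    combinations: pd.DataFrame  # combination, auroc, auprc
    set_deltas: pd.DataFrame  # feature_set, mean/quantile delta-AUROC

    def best_set(self) -> int:
        idx = self.set_deltas["delta_auroc_mean"].idxmax()
        return int(self.set_deltas.loc[idx, "feature_set"])


def ablation_sweep(
    train_windows: pd.DataFrame,
    test_windows: pd.DataFrame,
    spec: ModelSpec | None = None,
    seed: int = 0,
) -> AblationResult:
    """Retrain on all 31 nonempty feature-set combinations, score on test.

    The marginal gain of set S is the mean, over the 16 subsets T of the
    other four sets, of AUROC(T ∪ S) − AUROC(T); AUROC(∅) is chance
    (0.5).  Orderings collapse to combinations since model output
    depends only on the feature set.
    """
    spec = spec or ModelSpec()
    sets = sorted(FEATURE_SETS)
    perf: dict[frozenset, dict] = {frozenset(): {"auroc": CHANCE_AUROC, "auprc": np.nan}}
    rows = []
    for r in range(1, len(sets) + 1):
        for combo in itertools.combinations(sets, r):
            res = DMScreeningModel(
                train_windows, spec=spec, feature_sets=combo, seed=seed
            ).fit()
            report = res.evaluate(test_windows)
            perf[frozenset(combo)] = {"auroc": report.auroc, "auprc": report.auprc}
            rows.append(
                {
                    "combination": "".join(map(str, combo)),
                    "n_sets": r,
                    "auroc": report.auroc,
                    "auprc": report.auprc,
                }
            )
    delta_rows = []
    for s in sets:
        others = [o for o in sets if o != s]
        deltas = []
        for r in range(len(others) + 1):
            for t in itertools.combinations(others, r):
                base = perf[frozenset(t)]["auroc"]
                extended = perf[frozenset(t) | {s}]["auroc"]
                deltas.append(extended - base)
        deltas = np.asarray(deltas)
        delta_rows.append(
            {
                "feature_set": s,
                "delta_auroc_mean": float(deltas.mean()),
                "delta_auroc_q25": float(np.quantile(deltas, 0.25)),
                "delta_auroc_q75": float(np.quantile(deltas, 0.75)),
                "n_additions": len(deltas),
            }
        )
    return AblationResult(
        combinations=pd.DataFrame(rows), set_deltas=pd.DataFrame(delta_rows)
    )


# ---------------------------------------------------------------------------
# chronic-condition specificity


def subject_mean_probabilities(
    scores: np.ndarray, window_subjects: pd.Series, subjects: pd.DataFrame
) -> pd.DataFrame:
    """Per-subject mean predicted probability with condition-group labels.

    Groups partition the scored subjects: ``DM`` (label 1), ``other``
    (label 0 with another chronic condition), ``none`` (label 0, no
    chronic conditions).
    """
    df = pd.DataFrame({"subject_id": np.asarray(window_subjects), "score": scores})
    per_subject = df.groupby("subject_id")["score"].mean().rename("mean_probability")
    info = subjects.set_index("subject_id")
    out = per_subject.reset_index()
    out["label"] = out["subject_id"].map(info["label"]).astype(int)
    conditions = out["subject_id"].map(info["other_conditions"]).fillna("")
    out["group"] = np.where(
        out["label"] == 1, "DM", np.where(conditions.astype(str) != "", "other", "none")
    )
    return out


def chronic_condition_analysis(
    scores: np.ndarray, window_subjects: pd.Series, subjects: pd.DataFrame
) -> dict:
    """Kruskal-Wallis omnibus + Dunn's posthoc over the three condition groups."""
    probs = subject_mean_probabilities(scores, window_subjects, subjects)
    groups = {
        g: probs.loc[probs["group"] == g, "mean_probability"].to_numpy()
        for g in ("DM", "other", "none")
        if (probs["group"] == g).any()
    }
    if len(groups) < 2:
        warnings.warn("fewer than two condition groups present; tests skipped")
        return {"subject_probabilities": probs, "kruskal": None, "dunn": None}
    kw_stat, kw_p = stats.kruskal(*groups.values())
    dunn = dunn_test(groups) if len(groups) >= 2 else None
    return {
        "subject_probabilities": probs,
        "group_sizes": {g: len(v) for g, v in groups.items()},
        "kruskal": {"statistic": float(kw_stat), "p": float(kw_p)},
        "dunn": dunn,
    }


def compare_feature_set_models(
    probs_reduced: pd.DataFrame, probs_full: pd.DataFrame, alternative: str = "two-sided"
) -> pd.DataFrame:
    """Mann-Whitney U per condition group between two models' probabilities.

    Compares each group's per-subject mean probabilities under a reduced
    feature-set model against its counterpart under the full model
    (one-sided alternatives supported via ``alternative``).
    """
    rows = []
    for g in sorted(set(probs_reduced["group"]) & set(probs_full["group"])):
        a = probs_reduced.loc[probs_reduced["group"] == g, "mean_probability"]
        b = probs_full.loc[probs_full["group"] == g, "mean_probability"]
        u, p = stats.mannwhitneyu(a, b, alternative=alternative)
        rows.append({"group": g, "U": float(u), "p": float(p), "n_a": len(a), "n_b": len(b)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# population-level nightly feature tests


def cohens_d(x1: np.ndarray, x0: np.ndarray) -> float:
    """Pooled-SD Cohen's d (group 1 minus group 0)."""
    x1 = np.asarray(x1, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    n1, n0 = x1.size, x0.size
    pooled = np.sqrt(
        ((n1 - 1) * x1.var(ddof=1) + (n0 - 1) * x0.var(ddof=1)) / (n1 + n0 - 2)
    )
    return float((x1.mean() - x0.mean()) / pooled)


#: quantile-filter bounds applied to the commonly used features before testing
COMMON_FEATURE_FILTERS = {
    "hr_average": (0.05, 0.95),
    "rmssd": (None, 0.98),
    "total_sleep_time": (0.01, 0.99),
    "diurnal_distal_body_temp_amp": (None, None),
}


def filter_common_feature(values: pd.Series, feature: str) -> pd.Series:
    """Drop values outside the published quantile bounds for a common feature."""
    lo_q, hi_q = COMMON_FEATURE_FILTERS.get(feature, (None, None))
    out = values.dropna()
    if lo_q is not None:
        out = out[out >= out.quantile(lo_q)]
    if hi_q is not None:
        out = out[out <= out.quantile(hi_q)]
    return out


def nightly_population_tests(
    nightly: pd.DataFrame,
    features: tuple[str, ...] = COMMON_FEATURES,
    by_age_bin: bool = False,
    subjects: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Two-sided Mann-Whitney U and Cohen's d per feature, DM vs no-DM-DX.

    Commonly used features are quantile-filtered first (HR outside
    5/95%, RMSSD above 98%, TST outside 1/99%; amplitude unfiltered).
    Optionally stratified by age bin (requires ``subjects``).
    """
    frame = nightly
    if by_age_bin:
        if subjects is None:
            raise ValueError("subjects frame required for per-age-bin tests")
        frame = frame.merge(subjects[["subject_id", "age_bin"]], on="subject_id")
        strata = [(b, g) for b, g in frame.groupby("age_bin")]
    else:
        strata = [("all", frame)]
    rows = []
    for stratum, g in strata:
        for feat in features:
            x1 = filter_common_feature(g.loc[g["label"] == 1, feat], feat)
            x0 = filter_common_feature(g.loc[g["label"] == 0, feat], feat)
            if x1.empty or x0.empty:
                continue
            u, p = stats.mannwhitneyu(x1, x0, alternative="two-sided")
            rows.append(
                {
                    "stratum": stratum,
                    "feature": feat,
                    "U": float(u),
                    "p": float(p),
                    "cohens_d": cohens_d(x1.to_numpy(), x0.to_numpy()),
                    "n_dm": len(x1),
                    "n_ctrl": len(x0),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# false-negative profiling


def false_negative_profile(
    scores: np.ndarray,
    labels: np.ndarray,
    window_features: pd.DataFrame,
    threshold: float,
    features: tuple[str, ...] = COMMON_FEATURES,
) -> dict:
    """Compare commonly used features across TN / FN / TP windows.

    Windows are partitioned at the operating threshold; per feature a
    Kruskal-Wallis omnibus and a two-sided Dunn's posthoc (BH-adjusted)
    are run across the three groups.  Skipped with a warning when any
    group is empty.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = scores >= threshold
    group = np.where(
        (labels == 1) & pred, "TP", np.where((labels == 1) & ~pred, "FN", np.where(~pred, "TN", "FP"))
    )
    sizes = {g: int(np.sum(group == g)) for g in ("TN", "FN", "TP")}
    if min(sizes.values()) == 0:
        warnings.warn(f"empty outcome group ({sizes}); profile analysis skipped")
        return {"group_sizes": sizes, "tests": None}
    tests = []
    for feat in features:
        vals = window_features[feat].to_numpy(dtype=float)
        groups = {
            g: vals[(group == g) & ~np.isnan(vals)] for g in ("TN", "FN", "TP")
        }
        if min(len(v) for v in groups.values()) == 0:
            continue
        kw_stat, kw_p = stats.kruskal(*groups.values())
        dunn = dunn_test(groups)
        medians = {f"median_{g}": float(np.median(v)) for g, v in groups.items()}
        tests.append(
            {
                "feature": feat,
                "kruskal_statistic": float(kw_stat),
                "kruskal_p": float(kw_p),
                "dunn": dunn,
                **medians,
            }
        )
    return {"group_sizes": sizes, "tests": tests}
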