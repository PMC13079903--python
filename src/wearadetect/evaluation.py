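"""ROC/PRC evaluation, Youden-threshold confusion metrics, and the
repeated-resampling imbalanced-cohort protocol.

The balanced protocol scores held-out windows directly.  The imbalanced
protocol emulates screening in a general population: the DM pool is kept
whole while no-DM-DX subjects are repeatedly resampled (age/sex-balanced
to the DM pool's strata) so the subject-level class balance matches a
target prevalence; a fixed number of windows per subject preserves that
balance at window level.  Curves are summarised pointwise (median and
interquartile band) on fixed FPR/recall grids across repetitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_auc_score, roc_curve

GRID_POINTS = 101


@dataclass
class EvalReport:
    """Curves and scalar metrics for one score set (or one protocol run)."""

    auroc: float
    auprc: float
    fpr: np.ndarray
    tpr: np.ndarray
    roc_thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    threshold: float  # optimal operating threshold (Youden's J)
    confusion: dict  # counts + derived metrics at that threshold
    n_pos: int
    n_neg: int
    # populated by resampled protocols only
    repetition_metrics: pd.DataFrame | None = None
    median_curves: dict | None = None

    def plot(self, axes=None):
        """ROC and PRC curves (with IQR bands for resampled protocols)."""
        import matplotlib.pyplot as plt

        if axes is None:
            _, axes = plt.subplots(1, 2, figsize=(9, 4))
        ax_roc, ax_prc = axes
        ax_roc.plot(self.fpr, self.tpr, label=f"AUROC = {self.auroc:.2f}")
        ax_roc.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
        ax_prc.plot(self.recall, self.precision, label=f"AUPRC = {self.auprc:.2f}")
        if self.median_curves is not None:
            m = self.median_curves
            ax_roc.fill_between(m["grid"], m["tpr_q25"], m["tpr_q75"], alpha=0.3)
            ax_prc.fill_between(m["grid"], m["precision_q25"], m["precision_q75"], alpha=0.3)
        prevalence = self.n_pos / (self.n_pos + self.n_neg)
        ax_prc.axhline(prevalence, ls="--", c="grey", lw=0.8)
        ax_roc.set(xlabel="FPR", ylabel="TPR", title="ROC")
        ax_prc.set(xlabel="Recall", ylabel="Precision", title="PRC")
        for ax in axes:
            ax.legend(loc="lower right")
        return axes

    def to_dict(self) -> dict:
        out = {
            "auroc": self.auroc,
            "auprc": self.auprc,
            "threshold": self.threshold,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
        }
        out.update({k: v for k, v in self.confusion.items()})
        return out


def confusion_at_threshold(scores, labels, threshold: float) -> dict:
    """Confusion counts and derived metrics; positive iff score >= threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    n_pos, n_neg = tp + fn, fp + tn
    sens = tp / n_pos if n_pos else np.nan
    spec = tn / n_neg if n_neg else np.nan
    prec = tp / (tp + fp) if (tp + fp) else np.nan
    f1 = 2 * prec * sens / (prec + sens) if (prec + sens) else np.nan
    return {
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
        "tpr": sens,
        "fpr": fp / n_neg if n_neg else np.nan,
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "recall": sens,
        "f1": f1,
    }


def youden_threshold(fpr: np.ndarray, tpr: np.ndarray, thresholds: np.ndarray) -> float:
    """Threshold maximising J = sensitivity + specificity - 1 = TPR - FPR."""
    j = tpr - fpr
    best = int(np.argmax(j))
    thr = thresholds[best]
    if not np.isfinite(thr):
        finite = thresholds[np.isfinite(thresholds)]
        thr = (finite.max() + 1.0) if finite.size else 1.0
    return float(thr)


def roc_prc(scores, labels) -> EvalReport:
    """Full evaluation of one score set.

    AUROC is the trapezoid area over unique-score thresholds (score ties
    grouped); AUPRC is the step-wise average-precision rule.  The
    operating threshold maximises Youden's J; predictions are positive
    at score >= threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, roc_thr = roc_curve(labels, scores)
    auroc = float(roc_auc_score(labels, scores))
    precision, recall, _ = precision_recall_curve(labels, scores)
    auprc = float(average_precision_score(labels, scores))
    thr = youden_threshold(fpr, tpr, roc_thr)
    confusion = confusion_at_threshold(scores, labels, thr)
    return EvalReport(
        auroc=auroc,
        auprc=auprc,
        fpr=fpr,
        tpr=tpr,
        roc_thresholds=roc_thr,
        precision=precision,
        recall=recall,
        threshold=thr,
        confusion=confusion,
        n_pos=int((labels == 1).sum()),
        n_neg=int((labels == 0).sum()),
    )


# ---------------------------------------------------------------------------
# imbalanced-cohort protocol


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights``."""
    if weights.sum() == 0:
        return np.zeros_like(weights, dtype=int)
    quota = weights / weights.sum() * total
    base = np.floor(quota).astype(int)
    short = total - base.sum()
    order = np.argsort(-(quota - base))
    base[order[:short]] += 1
    return base


def _grid_curves(fpr, tpr, recall, precision):
    """Interpolate one repetition's curves onto the fixed grids."""
    grid = np.linspace(0.0, 1.0, GRID_POINTS)
    tpr_i = np.interp(grid, fpr, tpr)
    order = np.argsort(recall)
    prec_i = np.interp(grid, np.asarray(recall)[order], np.asarray(precision)[order])
    return tpr_i, prec_i


def imbalanced_protocol(
    results,
    dm_windows: pd.DataFrame,
    control_windows: pd.DataFrame,
    subjects: pd.DataFrame,
    prevalence: float = 0.179,
    reps: int = 100,
    windows_per_subject: int = 10,
    rng_seed: int = 0,
) -> EvalReport:
    """Repeated-resampling evaluation at a population prevalence.

    Per repetition: control subjects are sampled (age/sex strata
    allocated proportionally to the DM pool, largest-remainder rounding)
    so the subject-level DM fraction equals ``prevalence``;
    ``windows_per_subject`` windows are sampled per subject (with
    replacement when a subject has fewer); the fitted ``results`` scores
    the pooled windows and curves/metrics are recorded.  The returned
    report carries the pointwise median curves with 25-75% bands and the
    per-repetition metric table; its scalar fields are medians.
    """
    rng = np.random.default_rng(rng_seed)
    dm_ids = sorted(dm_windows["subject_id"].unique())
    n_dm = len(dm_ids)
    n_controls = int(round(n_dm * (1.0 - prevalence) / prevalence))

    info = subjects.set_index("subject_id")
    dm_strata = pd.Series(
        [f"{info.loc[s, 'age_bin']}|{info.loc[s, 'sex']}" for s in dm_ids]
    ).value_counts()
    ctrl_ids = pd.Series(sorted(control_windows["subject_id"].unique()))
    ctrl_strata = ctrl_ids.map(lambda s: f"{info.loc[s, 'age_bin']}|{info.loc[s, 'sex']}")

    # score every pool window once; repetitions only resample rows
    dm_scores = np.asarray(results.predict_proba(dm_windows), dtype=float)
    ctrl_scores = np.asarray(results.predict_proba(control_windows), dtype=float)
    dm_by_subject = {s: np.nonzero((dm_windows["subject_id"] == s).to_numpy())[0] for s in dm_ids}
    ctrl_by_subject = {
        s: np.nonzero((control_windows["subject_id"] == s).to_numpy())[0] for s in ctrl_ids
    }

    strata = dm_strata.index.to_numpy()
    alloc = _largest_remainder(dm_strata.to_numpy(dtype=float), n_controls)

    def _sample_windows(idx: np.ndarray) -> np.ndarray:
        if len(idx) >= windows_per_subject:
            return rng.choice(idx, size=windows_per_subject, replace=False)
        return rng.choice(idx, size=windows_per_subject, replace=True)

    rep_rows, tpr_grids, prec_grids = [], [], []
    for rep in range(reps):
        picked: list[str] = []
        deficit = 0
        for stratum, want in zip(strata, alloc):
            avail = ctrl_ids[ctrl_strata == stratum].tolist()
            if len(avail) < want:
                deficit += want - len(avail)
                picked.extend(avail)
            else:
                picked.extend(rng.choice(avail, size=want, replace=False))
        if deficit:
            rest = sorted(set(ctrl_ids) - set(picked))
            take = min(deficit, len(rest))
            if take < deficit:
                warnings.warn("control pool smaller than requested sample")
            if take:
                picked.extend(rng.choice(rest, size=take, replace=False))

        pos_idx = np.concatenate([_sample_windows(dm_by_subject[s]) for s in dm_ids])
        neg_idx = np.concatenate([_sample_windows(ctrl_by_subject[s]) for s in picked])
        scores = np.concatenate([dm_scores[pos_idx], ctrl_scores[neg_idx]])
        labels = np.concatenate([np.ones(len(pos_idx), int), np.zeros(len(neg_idx), int)])
        rep_report = roc_prc(scores, labels)
        rep_rows.append(
            {
                "repetition": rep,
                "auroc": rep_report.auroc,
                "auprc": rep_report.auprc,
                "threshold": rep_report.threshold,
                "sensitivity": rep_report.confusion["sensitivity"],
                "specificity": rep_report.confusion["specificity"],
                "n_pos_windows": int(labels.sum()),
                "n_neg_windows": int((labels == 0).sum()),
                "n_control_subjects": len(picked),
            }
        )
        tpr_i, prec_i = _grid_curves(
            rep_report.fpr, rep_report.tpr, rep_report.recall, rep_report.precision
        )
        tpr_grids.append(tpr_i)
        prec_grids.append(prec_i)

    rep_df = pd.DataFrame(rep_rows)
    tpr_grids = np.vstack(tpr_grids)
    prec_grids = np.vstack(prec_grids)
    grid = np.linspace(0.0, 1.0, GRID_POINTS)
    median_curves = {
        "grid": grid,
        "tpr_median": np.median(tpr_grids, axis=0),
        "tpr_q25": np.quantile(tpr_grids, 0.25, axis=0),
        "tpr_q75": np.quantile(tpr_grids, 0.75, axis=0),
        "precision_median": np.median(prec_grids, axis=0),
        "precision_q25": np.quantile(prec_grids, 0.25, axis=0),
        "precision_q75": np.quantile(prec_grids, 0.75, axis=0),
    }
    med = rep_df.median(numeric_only=True)
    confusion = {
        "sensitivity": float(med["sensitivity"]),
        "specificity": float(med["specificity"]),
    }
    return EvalReport(
        auroc=float(med["auroc"]),
        auprc=float(med["auprc"]),
        fpr=grid,
        tpr=median_curves["tpr_median"],
        roc_thresholds=np.array([]),
        precision=median_curves["precision_median"],
        recall=grid,
        threshold=float(med["threshold"]),
        confusion=confusion,
        n_pos=int(rep_df["n_pos_windows"].iloc[0]),
        n_neg=int(rep_df["n_neg_windows"].iloc[0]),
        repetition_metrics=rep_df,
        median_curves=median_curves,
    )
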