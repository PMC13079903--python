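"""Window classifiers, statsmodels-style: a Model built from window data
whose ``fit()`` returns a Results object.

Two families are supported with the published, pre-optimised defaults:

* ``"trees"`` — gradient-boosted trees (XGBClassifier; 200 estimators,
  learning rate 0.01, max depth 3),
* ``"linear"`` — L2-regularised logistic regression (C = 0.01).

Preprocessing follows the published protocol: a standardising scaler is
fit on the training windows with missing cells excluded, applied to any
data scored later, and missing cells are then zero-filled — zero being
the post-scaling training mean, so an absent night contributes the
train-average physiology rather than an arbitrary value.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GroupKFold
from xgboost import XGBClassifier

from .features_table import FEATURES, FEATURE_SETS
from .evaluation import EvalReport, roc_prc
from .windowing import flat_columns, flat_layout

DEFAULT_TREES = {"n_estimators": 200, "learning_rate": 0.01, "max_depth": 3}
DEFAULT_LINEAR = {"C": 0.01, "penalty": "l2"}


@dataclass
class ModelSpec:
    """Classifier family + hyperparameters for one window length."""

    family: str = "trees"  # {"trees", "linear"}
    window_length: int = 21
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in ("trees", "linear"):
            raise ValueError(f"unknown family {self.family!r}")
        defaults = DEFAULT_TREES if self.family == "trees" else DEFAULT_LINEAR
        self.hyperparameters = {**defaults, **self.hyperparameters}

    @property
    def capacity(self) -> float:
        """Rough model-capacity ordering used for tie-breaking in tuning."""
        h = self.hyperparameters
        if self.family == "trees":
            return h["n_estimators"] * h["max_depth"] * h["learning_rate"]
        return h["C"]


class WindowScaler:
    """Per-column standardiser fit on observed (non-missing) cells only.

    ``transform`` standardises then zero-fills missing cells.  An
    all-missing column gets location 0 / scale 1 with a warning.
    """

    def __init__(self):
        self.location_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "WindowScaler":
        X = np.asarray(X, dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            loc = np.nanmean(X, axis=0)
            scale = np.nanstd(X, axis=0)
        dead = np.isnan(loc)
        if dead.any():
            warnings.warn(f"{int(dead.sum())} all-missing column(s); using location 0, scale 1")
        loc[dead] = 0.0
        scale[dead | (scale == 0)] = 1.0
        self.location_, self.scale_ = loc, scale
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=float) - self.location_) / self.scale_
        return np.nan_to_num(Z, nan=0.0)

    def to_dict(self) -> dict:
        return {"location": self.location_.tolist(), "scale": self.scale_.tolist()}


class DMScreeningModel:
    """Diabetes-screening window classifier (the Model object).

    Built from a flattened window DataFrame (columns ``subject_id``,
    ``start_date``, ``label`` plus night-major flattened features);
    ``fit()`` returns a :class:`DMScreeningResults`.

    ``feature_sets`` restricts the model to a subset of the five feature
    sets (columns of excluded sets are removed, not zeroed) — the
    mechanism behind the ablation sweep.
    """

    def __init__(
        self,
        windows: pd.DataFrame,
        spec: ModelSpec | None = None,
        feature_sets: tuple[int, ...] | None = None,
        seed: int = 0,
    ):
        self.spec = spec or ModelSpec()
        self.seed = seed
        self.feature_sets = tuple(sorted(feature_sets)) if feature_sets else (1, 2, 3, 4, 5)
        base = [f for s in self.feature_sets for f in FEATURE_SETS[s]]
        keep = set(base)
        L = self.spec.window_length
        self.columns = [c for c, (f, _) in flat_layout(L).items() if f in keep]
        missing_cols = [c for c in self.columns if c not in windows.columns]
        if missing_cols:
            raise ValueError(f"window frame lacks columns, e.g. {missing_cols[:3]}")
        self.windows = windows
        if windows["label"].nunique() < 2:
            raise ValueError("training windows contain a single class")

    @classmethod
    def from_windows(cls, windows: pd.DataFrame, family: str = "trees",
                     window_length: int = 21, **kwargs) -> "DMScreeningModel":
        return cls(windows, spec=ModelSpec(family=family, window_length=window_length), **kwargs)

    def _make_estimator(self):
        h = self.spec.hyperparameters
        if self.spec.family == "trees":
            return XGBClassifier(
                n_estimators=h["n_estimators"],
                learning_rate=h["learning_rate"],
                max_depth=h["max_depth"],
                tree_method="hist",
                n_jobs=1,
                random_state=self.seed,
                eval_metric="logloss",
            )
        if h["penalty"] != "l2":
            raise ValueError("only the L2 penalty is supported for the linear family")
        return LogisticRegression(C=h["C"], max_iter=2000, random_state=self.seed)

    def fit(self) -> "DMScreeningResults":
        X = self.windows[self.columns].to_numpy(dtype=float)
        y = self.windows["label"].to_numpy(dtype=int)
        scaler = WindowScaler().fit(X)
        est = self._make_estimator()
        est.fit(scaler.transform(X), y)
        return DMScreeningResults(model=self, estimator=est, scaler=scaler)


class DMScreeningResults:
    """Fitted classifier + scaler; scoring, evaluation and interpretation."""

    def __init__(self, model: DMScreeningModel, estimator, scaler: WindowScaler):
        self.model = model
        self.estimator = estimator
        self.scaler = scaler

    @property
    def spec(self) -> ModelSpec:
        return self.model.spec

    def predict_proba(self, windows: pd.DataFrame) -> np.ndarray:
        """P(DM) for each window row."""
        X = windows[self.model.columns].to_numpy(dtype=float)
        return self.estimator.predict_proba(self.scaler.transform(X))[:, 1]

    def evaluate(self, windows: pd.DataFrame) -> EvalReport:
        scores = self.predict_proba(windows)
        labels = windows["label"].to_numpy(dtype=int)
        return roc_prc(scores, labels)

    def feature_importances(self) -> pd.Series:
        """Per-base-feature importance, aggregated over night positions.

        Tree models use the native gain-based importances; the linear
        model uses mean |coefficient|.  Importances are summed across the
        L night positions of each base feature and normalised to sum 1.
        """
        layout = flat_layout(self.spec.window_length)
        if self.spec.family == "trees":
            per_col = np.asarray(self.estimator.feature_importances_, dtype=float)
        else:
            per_col = np.abs(np.asarray(self.estimator.coef_).ravel())
        agg: dict[str, float] = {f: 0.0 for f in FEATURES if any(
            f in FEATURE_SETS[s] for s in self.model.feature_sets)}
        for col, value in zip(self.model.columns, per_col):
            feat, _ = layout[col]
            agg[feat] += float(value)
        out = pd.Series(agg)
        total = out.sum()
        return out / total if total > 0 else out

    def summary(self) -> str:
        """Human-readable fit summary."""
        w = self.model.windows
        train_auroc = self.evaluate(w).auroc
        lines = [
            "DM screening window classifier",
            "=" * 46,
            f"family:            {self.spec.family}",
            f"window length:     {self.spec.window_length} nights",
            f"feature sets:      {self.model.feature_sets}",
            f"hyperparameters:   {self.spec.hyperparameters}",
            f"train windows:     {len(w)} ({w['label'].sum()} DM)",
            f"train subjects:    {w['subject_id'].nunique()}",
            f"train AUROC:       {train_auroc:.3f}",
        ]
        top = self.feature_importances().sort_values(ascending=False).head(5)
        lines.append("top features:")
        for name, v in top.items():
            lines.append(f"  {name:<32s} {v:.3f}")
        return "\n".join(lines)

    def to_sidecar(self) -> dict:
        """JSON-serialisable provenance sidecar for a saved model artifact."""
        return {
            "family": self.spec.family,
            "window_length": self.spec.window_length,
            "hyperparameters": self.spec.hyperparameters,
            "feature_sets": list(self.model.feature_sets),
            "seed": self.model.seed,
            "scaler": self.scaler.to_dict(),
        }


def tune_hyperparameters(
    grid: list[ModelSpec],
    windows: pd.DataFrame,
    k: int = 3,
    seed: int = 0,
) -> ModelSpec:
    """Select the grid spec with best mean validation AUROC under
    subject-grouped k-fold cross-validation (ties break toward smaller
    capacity).  Grouping by subject prevents overlapping windows from one
    person straddling a fold boundary."""
    if not grid:
        raise ValueError("empty hyperparameter grid")
    if len(grid) == 1:
        return grid[0]
    groups = windows["subject_id"].to_numpy()
    splitter = GroupKFold(n_splits=k)
    best_spec, best_score = None, -np.inf
    for spec in sorted(grid, key=lambda s: s.capacity):
        scores = []
        for tr_idx, va_idx in splitter.split(windows, groups=groups):
            tr, va = windows.iloc[tr_idx], windows.iloc[va_idx]
            if tr["label"].nunique() < 2 or va["label"].nunique() < 2:
                continue
            res = DMScreeningModel(tr, spec=spec, seed=seed).fit()
            scores.append(res.evaluate(va).auroc)
        mean_score = float(np.mean(scores)) if scores else -np.inf
        if mean_score > best_score:  # strict: first (smallest-capacity) wins ties
            best_spec, best_score = spec, mean_score
    return best_spec
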