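"""End-to-end orchestration: simulate -> extract -> window -> train ->
evaluate -> interpret, with YAML configuration and provenance hashing.

Every artifact directory carries ``config.json`` with the configuration
hash; ``metrics.json`` collects all scalar results.  All randomness
flows from one root seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .evaluation import imbalanced_protocol
from .interpretation import (
    ablation_sweep,
    chronic_condition_analysis,
    nightly_population_tests,
    false_negative_profile,
)
from .model import DMScreeningModel, ModelSpec
from .synthetic import ClassParams, GeneratorConfig, simulate_cohort, write_cohort
from .windowing import (
    WINDOW_LENGTHS,
    anchor_start_dates,
    attach_labels,
    extract_nightly_features,
    extract_windows,
    stratified_split,
)

_GEN_SIMPLE_FIELDS = {
    "n_subjects_per_class", "prevalence", "missingness", "subject_effect_fraction",
    "chronic_condition_fraction", "chronic_shift", "dm_control_like_fraction",
    "temperature_baseline", "sleep_onset_loc", "sleep_onset_scale", "rng_seed",
}


@dataclass
class RunConfig:
    """Serializable configuration for a full pipeline run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    window_lengths: tuple[int, ...] = WINDOW_LENGTHS
    families: tuple[str, ...] = ("linear", "trees")
    train_fraction: float = 0.8
    seed: int = 0
    imbalanced_prevalence: float = 0.179
    imbalanced_reps: int = 100
    windows_per_subject: int = 10
    run_imbalanced: bool = True
    run_ablation: bool = False
    ablation_family: str = "linear"
    write_raw_streams: bool = False

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        gen_raw = raw.pop("generator", {})
        known = {f.name for f in dataclasses.fields(cls)} - {"generator"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown RunConfig keys: {sorted(unknown)}")
        gen = _generator_from_dict(gen_raw)
        cfg = cls(generator=gen, **raw)
        cfg.generator.rng_seed = cfg.generator.rng_seed or cfg.seed
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        gen = dataclasses.asdict(self.generator)
        gen["start_date"] = self.generator.start_date.isoformat()
        gen["end_date"] = self.generator.end_date.isoformat()
        out = dataclasses.asdict(self)
        out["generator"] = gen
        out["window_lengths"] = list(self.window_lengths)
        out["families"] = list(self.families)
        return out

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _generator_from_dict(raw: dict) -> GeneratorConfig:
    raw = dict(raw)
    kwargs = {}
    for key in list(raw):
        if key in _GEN_SIMPLE_FIELDS:
            kwargs[key] = raw.pop(key)
    for key in ("start_date", "end_date"):
        if key in raw:
            kwargs[key] = date.fromisoformat(str(raw.pop(key)))
    for cls_key in ("control", "dm"):
        if cls_key in raw:
            params = raw.pop(cls_key)
            cp = ClassParams() if cls_key == "control" else GeneratorConfig().dm
            known = {f.name for f in dataclasses.fields(ClassParams)}
            unknown = set(params) - known
            if unknown:
                raise ValueError(f"unknown {cls_key} keys: {sorted(unknown)}")
            for k, v in params.items():
                setattr(cp, k, tuple(v) if isinstance(v, list) else v)
            kwargs[cls_key] = cp
    if raw:
        raise ValueError(f"unknown generator keys: {sorted(raw)}")
    return GeneratorConfig(**kwargs)


SMALL_PRESET = {
    "generator": {"n_subjects_per_class": 60, "start_date": "2020-04-22",
                  "end_date": "2020-06-01"},
    "window_lengths": [1, 7, 21],
    "families": ["linear"],
    "imbalanced_reps": 20,
}


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run every stage and write artifacts; returns the metrics dict.

    Stages are resumable in the sense that each writes its own artifact
    files; the returned ``metrics.json`` is deterministic given the
    configuration (including seeds).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    log: list[dict] = []
    timings: list[dict] = []
    chash = config.config_hash()

    def stage(name, **counts):
        log.append({"stage": name, **counts})
        timings.append({"stage": name, "elapsed_s": round(time.time() - t0, 2)})

    (out / "config.json").write_text(
        json.dumps({"config_hash": chash, **config.to_dict()}, indent=2, default=str)
    )

    cohort = simulate_cohort(config.generator)
    if config.write_raw_streams:
        write_cohort(cohort, out / "raw")
    stage("simulate", subjects=len(cohort.subjects))

    nightly = extract_nightly_features(cohort)
    nightly.to_csv(out / "nightly_features.csv", index=False)
    n_present = int(nightly["night_present"].sum())
    stage("extract", nights_total=len(nightly), nights_present=n_present,
          nights_dropped=len(nightly) - n_present)

    dates = config.generator.night_dates
    anchors = anchor_start_dates(nightly, dates)
    windows = {}
    for L in config.window_lengths:
        w = attach_labels(extract_windows(nightly, L, dates, anchors), cohort.subjects)
        windows[L] = w
        w.to_parquet(out / f"windows_L{L}.parquet", index=False)
    stage("windows", **{f"L{L}": len(w) for L, w in windows.items()})

    train_ids, test_ids = stratified_split(
        cohort.subjects, config.train_fraction, rng_seed=config.seed
    )
    (out / "split.json").write_text(
        json.dumps({"config_hash": chash, "seed": config.seed,
                    "train": train_ids, "test": test_ids}, indent=2)
    )
    stage("split", train=len(train_ids), test=len(test_ids))

    metrics: dict = {"config_hash": chash, "stages": log}
    results_by_key = {}
    for family in config.families:
        for L in config.window_lengths:
            w = windows[L]
            tr = w[w["subject_id"].isin(train_ids)]
            te = w[w["subject_id"].isin(test_ids)]
            if tr.empty or te.empty or tr["label"].nunique() < 2 or te["label"].nunique() < 2:
                warnings.warn(f"skipping {family} L={L}: insufficient data")
                continue
            spec = ModelSpec(family=family, window_length=L)
            res = DMScreeningModel(tr, spec=spec, seed=config.seed).fit()
            report = res.evaluate(te)
            key = f"{family}_L{L}"
            results_by_key[key] = (res, te)
            metrics[key] = report.to_dict()
    stage("train_evaluate")

    best_key = max(
        (k for k in results_by_key), default=None, key=lambda k: metrics[k]["auroc"]
    )
    metrics["best_model"] = best_key

    if best_key is not None:
        res, te = results_by_key[best_key]
        res_scores = res.predict_proba(te)
        cc = chronic_condition_analysis(res_scores, te["subject_id"], cohort.subjects)
        if cc["kruskal"] is not None:
            metrics["chronic_conditions"] = {
                "kruskal": cc["kruskal"],
                "group_sizes": cc["group_sizes"],
                "dunn": cc["dunn"].to_dict(orient="records"),
            }
        res.feature_importances().rename("importance").to_csv(out / "importance.csv")

        pop = nightly_population_tests(nightly[nightly["night_present"]])
        pop.to_csv(out / "population_tests.csv", index=False)
        metrics["population_tests"] = pop.to_dict(orient="records")

        # TN/FN/TP window profiling of the common features at the Youden threshold
        report = metrics[best_key]
        common_cols = {
            feat: [c for c in te.columns if c.startswith(feat + "__n")]
            for feat in ("hr_average", "rmssd", "total_sleep_time",
                         "diurnal_distal_body_temp_amp")
        }
        window_feats = pd.DataFrame(
            {feat: te[cols].mean(axis=1) for feat, cols in common_cols.items()}
        )
        fn = false_negative_profile(
            res_scores, te["label"].to_numpy(), window_feats, report["threshold"]
        )
        if fn["tests"] is not None:
            metrics["false_negative_profile"] = {
                "group_sizes": fn["group_sizes"],
                "tests": [
                    {k: v for k, v in t.items() if k != "dunn"} for t in fn["tests"]
                ],
            }

    if config.run_imbalanced and best_key is not None:
        res, te = results_by_key[best_key]
        L = res.spec.window_length
        w = windows[L]
        pool = w[w["subject_id"].isin(test_ids)]
        dm_pool = pool[pool["label"] == 1]
        ctrl_pool = pool[pool["label"] == 0]
        if dm_pool.empty or ctrl_pool.empty:
            warnings.warn("imbalanced protocol skipped: empty pool")
        else:
            imb = imbalanced_protocol(
                res, dm_pool, ctrl_pool, cohort.subjects,
                prevalence=config.imbalanced_prevalence,
                reps=config.imbalanced_reps,
                windows_per_subject=config.windows_per_subject,
                rng_seed=config.seed,
            )
            metrics["imbalanced"] = imb.to_dict()
            imb.repetition_metrics.to_csv(out / "imbalanced_repetitions.csv", index=False)
    stage("protocols")

    if config.run_ablation and best_key is not None:
        res, te = results_by_key[best_key]
        L = res.spec.window_length
        w = windows[L]
        tr = w[w["subject_id"].isin(train_ids)]
        abl = ablation_sweep(
            tr, te, spec=ModelSpec(family=config.ablation_family, window_length=L),
            seed=config.seed,
        )
        abl.combinations.to_csv(out / "ablation.csv", index=False)
        metrics["ablation"] = abl.set_deltas.to_dict(orient="records")
    stage("done")

    metrics["stages"] = log
    (out / "stage_log.json").write_text(json.dumps(timings, indent=2))
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2, default=float))
    return metrics
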