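"""End-to-end experiment orchestration.

Runs simulate -> threshold method -> ML harness -> comparison report from a
single validated configuration, writing every intermediate artifact as CSV
so each stage can be re-run in isolation from files.  Identical
configuration and seed give byte-identical CSV outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
import time
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import sklearn
import xgboost
import yaml

from . import __version__
from .loadmap import AREAS, TrialRecord, write_trials
from .metrics import MetricsReport, comparison_table, format_comparison_text, confusion, report_from
from .ml import (
    ALGORITHMS,
    ALGORITHM_LABELS,
    FeatureConfig,
    SplitSpec,
    TrainSpec,
    evaluate_model,
    split_data,
    train_model,
)
from .synthetic import DEFAULT_REDISTRIBUTION, EffortModel, StudyDesign, simulate_study
from .threshold import DEFAULT_THRESHOLD, build_pairs, cutoff_roc, classify_pair, diff_profile

log = logging.getLogger("manugrip")

__all__ = ["RunConfig", "run_experiment", "threshold_report", "THRESHOLD_LABEL"]

THRESHOLD_LABEL = "Thresholds"

#: Every key RunConfig accepts, with its default.  Unknown keys are rejected.
_CONFIG_DEFAULTS: dict = {
    # study design
    "n_subjects": 54,
    "n_males": 25,
    "n_right_handed": 52,
    "sessions": 2,
    "trials_per_hand_per_session": 3,
    "age_low": 19,
    "age_high": 53,
    # effort model
    "force_fraction_low": 0.5,
    "force_fraction_high": 0.75,
    "redistribution_delta": {a.value: v for a, v in DEFAULT_REDISTRIBUTION.items()},
    "delta_jitter_sd": 0.5,
    "force_noise_sd": 0.04,
    # threshold method
    "diff_threshold": DEFAULT_THRESHOLD,
    # ML harness
    "train_fraction": 0.8,
    "group_by_subject": False,
    "cv_folds": 5,
    "algorithms": list(ALGORITHMS),
    "include_thumb": False,
    # run
    "outdir": "manugrip_run",
    "seed": 0,
    "verbosity": "info",
}


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Validated flat configuration of one end-to-end experiment run."""

    values: Mapping

    def __post_init__(self) -> None:
        unknown = set(self.values) - set(_CONFIG_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        merged = dict(_CONFIG_DEFAULTS)
        merged.update(self.values)
        object.__setattr__(self, "values", merged)
        # construct the specs eagerly so bad values fail before any computation
        self.design()
        self.effort_model()
        self.split_spec()
        for alg in merged["algorithms"]:
            if alg not in ALGORITHMS:
                raise ValueError(f"unknown algorithm {alg!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a flat key/value mapping")
        return cls(values=data)

    def __getitem__(self, key: str):
        return self.values[key]

    def design(self) -> StudyDesign:
        v = self.values
        return StudyDesign(
            n_subjects=int(v["n_subjects"]),
            n_males=int(v["n_males"]),
            n_right_handed=int(v["n_right_handed"]),
            sessions=int(v["sessions"]),
            trials_per_hand_per_session=int(v["trials_per_hand_per_session"]),
            age_range=(int(v["age_low"]), int(v["age_high"])),
            seed=int(v["seed"]),
        )

    def effort_model(self) -> EffortModel:
        v = self.values
        delta_raw = v["redistribution_delta"]
        delta = {a: float(delta_raw.get(a.value, 0.0)) for a in AREAS}
        return EffortModel(
            force_fraction_low=float(v["force_fraction_low"]),
            force_fraction_high=float(v["force_fraction_high"]),
            redistribution_delta=delta,
            delta_jitter_sd=float(v["delta_jitter_sd"]),
            force_noise_sd=float(v["force_noise_sd"]),
        )

    def split_spec(self) -> SplitSpec:
        v = self.values
        return SplitSpec(
            train_fraction=float(v["train_fraction"]),
            group_by_subject=bool(v["group_by_subject"]),
            seed=int(v["seed"]),
        )

    def train_spec(self, algorithm: str) -> TrainSpec:
        return TrainSpec(algorithm=algorithm, cv_folds=int(self.values["cv_folds"]), seed=int(self.values["seed"]))

    def feature_config(self) -> FeatureConfig:
        return FeatureConfig(include_thumb=bool(self.values["include_thumb"]))


def threshold_report(records: Sequence[TrialRecord], diff_threshold: float = DEFAULT_THRESHOLD):
    """Run the conventional method end to end on trial records.

    Returns ``(pairs, roc, report)`` where ``report`` evaluates the chosen
    cutoff on the same labelled pairs the ROC was built from (the
    conventional method has no held-out split), using the exceedance count
    as the continuous score for AUC and its DeLong CI.
    """
    pairs = build_pairs(records)
    roc = cutoff_roc(pairs, threshold=diff_threshold)
    profiles = [diff_profile(p, diff_threshold) for p in pairs]
    truth = np.array([1 if p.truth == "insincere" else 0 for p in pairs])
    predicted = np.array(
        [1 if classify_pair(pr, roc.chosen_cutoff) == "insincere" else 0 for pr in profiles]
    )
    counts = np.array([pr.count_exceeding for pr in profiles], dtype=float)
    cm = confusion(truth, predicted, positive_label=1)
    report = report_from(cm, counts, truth, method_label=THRESHOLD_LABEL)
    return pairs, roc, report


def _pairs_frame(pairs, diff_threshold: float) -> pd.DataFrame:
    rows = []
    for p in pairs:
        pr = diff_profile(p, diff_threshold)
        row = {"pair_id": p.pair_id, "truth": p.truth}
        for a in AREAS:
            row[f"diff_{a.value}"] = pr.diff[a]
        row["count_exceeding"] = pr.count_exceeding
        rows.append(row)
    return pd.DataFrame(rows)


def run_experiment(config: RunConfig) -> dict:
    """Run the full pipeline and write all report files to the output directory.

    Outputs: ``trials.csv``, ``pairs.csv``, ``cutoff_roc.csv``,
    ``metrics.csv`` (one row per method), ``comparison.csv`` /
    ``comparison.txt`` (methods as columns), and ``manifest.json``.
    Returns a summary dict with the per-method reports.
    """
    t0 = time.time()
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        design = config.design()
        model = config.effort_model()
        records = simulate_study(design, model)
        write_trials(records, outdir / "trials.csv")
        log.info("stage=simulate seed=%s records=%d", design.seed, len(records))

        stage = "threshold"
        pairs, roc, thr_report = threshold_report(records, float(config["diff_threshold"]))
        _pairs_frame(pairs, float(config["diff_threshold"])).to_csv(outdir / "pairs.csv", index=False)
        roc.as_frame().to_csv(outdir / "cutoff_roc.csv", index=False)
        log.info(
            "stage=threshold seed=%s cutoff=%d sens=%.4f spec=%.4f auc=%.4f",
            design.seed, roc.chosen_cutoff, roc.chosen_sensitivity, roc.chosen_specificity, roc.auc,
        )

        stage = "ml"
        train, val = split_data(records, config.split_spec())
        reports: list[MetricsReport] = []
        for alg in config["algorithms"]:
            fitted = train_model(train, config.train_spec(alg), config.feature_config())
            reports.append(evaluate_model(fitted, val))
            log.info("stage=ml algorithm=%s seed=%s cv_auc=%.4f", alg, config["seed"], fitted.cv_auc)

        stage = "report"
        ordered = sorted(reports, key=lambda r: -r.auc) + [thr_report]
        rows = []
        for r in ordered:
            rows.append(
                {
                    "method": r.method_label,
                    "sensitivity": r.sensitivity,
                    "specificity": r.specificity,
                    "accuracy": r.accuracy,
                    "accuracy_ci_lo": r.accuracy_ci[0],
                    "accuracy_ci_hi": r.accuracy_ci[1],
                    "auc": r.auc,
                    "auc_ci_lo": r.auc_ci[0],
                    "auc_ci_hi": r.auc_ci[1],
                    "n_pos": r.n_pos,
                    "n_neg": r.n_neg,
                }
            )
        pd.DataFrame(rows).to_csv(outdir / "metrics.csv", index=False)
        table = comparison_table(ordered)
        table.to_csv(outdir / "comparison.csv", index_label="Method")
        header = (
            "# Split mode: {} | positive class: submaximal | sex codes female=0 male=1 | "
            "handedness codes right=0 left=1\n"
        ).format("grouped-by-subject" if config["group_by_subject"] else "record-level stratified")
        (outdir / "comparison.txt").write_text(header + format_comparison_text(table), encoding="utf-8")

        manifest = {
            "config": {k: v for k, v in config.values.items()},
            "seed": config["seed"],
            "versions": {
                "manugrip": __version__,
                "python": platform.python_version(),
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "scikit-learn": sklearn.__version__,
                "xgboost": xgboost.__version__,
            },
            "wall_clock_seconds": round(time.time() - t0, 3),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8")
    except Exception as exc:
        raise RuntimeError(f"experiment failed in stage '{stage}': {exc}") from exc
    return {"threshold": thr_report, "roc": roc, "ml_reports": reports, "outdir": outdir}
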