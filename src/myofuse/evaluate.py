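"""Metrics, 10-fold cross-validation, baselines and experiment orchestration.

Per-class one-vs-rest confusion counts feed the standard metric set:
accuracy (TP+TN)/(TP+TN+FP+FN), precision TP/(TP+FP), recall TP/(TP+FN)
and F-score 2PR/(P+R) = 2TP/(2TP+FP+FN).  A historically common misprint
writes precision with TN in the denominator; that literal form is exposed
as :func:`precision_as_printed` for auditability but never used.

The experiment driver reproduces the full comparison roster on synthetic
data: feature-based KNN/SVM baselines per modality under 10-fold CV, the
temporal convolutional classifier per modality on a stratified train/test
split, and Dempster-Shafer fusion of each classifier family — emitting a
9-model x 3-state x 3-metric report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.impute import SimpleImputer
from sklearn.model_selection import StratifiedKFold, cross_val_predict, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import features as feat
from . import fusion, preprocess, synthgen, tcn
from .states import STATES

__all__ = [
    "ClassCounts",
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "accuracy",
    "precision",
    "precision_as_printed",
    "recall",
    "f_score",
    "f_score_from_counts",
    "metrics_report",
    "ten_fold_cv",
    "run_baseline",
    "ExperimentConfig",
    "run_experiment",
]

SEMG_FEATURES = ["semg_rms", "semg_iemg", "semg_zc", "semg_arv"]
ECG_FEATURES = ["ecg_mean", "ecg_lf", "ecg_lf_hf"]


@dataclass(frozen=True)
class ClassCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class ConfusionCounts:
    """One-vs-rest counts per class over a prediction batch."""

    per_class: dict[int, ClassCounts]

    @property
    def n(self) -> int:
        return next(iter(self.per_class.values())).total


def confusion(labels, predictions, class_order=STATES) -> ConfusionCounts:
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape or labels.size == 0:
        raise ValueError("labels and predictions must be equal-length, non-empty")
    per_class = {}
    for c in class_order:
        tp = int(np.sum((labels == c) & (predictions == c)))
        tn = int(np.sum((labels != c) & (predictions != c)))
        fp = int(np.sum((labels != c) & (predictions == c)))
        fn = int(np.sum((labels == c) & (predictions != c)))
        per_class[c] = ClassCounts(tp=tp, tn=tn, fp=fp, fn=fn)
    return ConfusionCounts(per_class=per_class)


def accuracy(c: ClassCounts) -> float:
    if c.total == 0:
        raise ValueError("empty counts")
    return (c.tp + c.tn) / c.total


def precision(c: ClassCounts) -> float:
    denom = c.tp + c.fp
    return c.tp / denom if denom else 0.0


def precision_as_printed(c: ClassCounts) -> float:
    """The TP/(TP+TN) variant as sometimes misprinted; audit-only."""
    denom = c.tp + c.tn
    return c.tp / denom if denom else 0.0


def recall(c: ClassCounts) -> float:
    denom = c.tp + c.fn
    return c.tp / denom if denom else 0.0


def f_score(p: float, r: float) -> float:
    """Harmonic mean 2pr/(p+r); 0 by convention when p + r == 0."""
    if not (0 <= p <= 1 and 0 <= r <= 1):
        raise ValueError("precision and recall must lie in [0, 1]")
    return 0.0 if p + r == 0 else 2 * p * r / (p + r)


def f_score_from_counts(c: ClassCounts) -> float:
    denom = 2 * c.tp + c.fp + c.fn
    return 2 * c.tp / denom if denom else 0.0


@dataclass
class MetricsReport:
    """Per-class and macro-averaged accuracy/precision/recall/F-score."""

    per_class: dict[int, dict[str, float]]
    macro: dict[str, float]

    def as_rows(self, model: str) -> list[dict]:
        rows = []
        for state in STATES:
            m = self.per_class[state]
            rows.append(
                {
                    "model": model,
                    "state": state,
                    "precision": m["precision"],
                    "recall": m["recall"],
                    "f_score": m["f_score"],
                }
            )
        return rows


def metrics_report(labels, predictions) -> MetricsReport:
    counts = confusion(labels, predictions)
    per_class = {}
    for state, c in counts.per_class.items():
        p, r = precision(c), recall(c)
        per_class[state] = {
            "accuracy": accuracy(c),
            "precision": p,
            "recall": r,
            "f_score": f_score_from_counts(c),
        }
    macro = {
        key: float(np.mean([per_class[s][key] for s in STATES]))
        for key in ("accuracy", "precision", "recall", "f_score")
    }
    return MetricsReport(per_class=per_class, macro=macro)


def ten_fold_cv(X, y, model_factory, seed: int = 0, n_splits: int = 10) -> dict:
    """Stratified k-fold CV; every record lands in exactly one test fold.

    ``model_factory()`` must return an estimator with fit/predict.  The
    summary accuracy is the mean of the per-fold accuracies, and pooled
    out-of-fold predictions are kept for per-class metrics.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    if len(X) < n_splits:
        raise ValueError(f"dataset of {len(X)} too small for {n_splits}-fold CV")
    smallest = np.bincount(np.unique(y, return_inverse=True)[1]).min()
    if smallest < n_splits:
        raise ValueError(
            f"stratified {n_splits}-fold CV needs >= {n_splits} records per "
            f"class (smallest class has {smallest})"
        )
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    fold_acc, fold_reports = [], []
    pooled_pred = np.empty_like(y)
    fold_of = np.empty(len(y), dtype=int)
    for i, (tr, te) in enumerate(skf.split(X, y)):
        model = model_factory()
        model.fit(X[tr], y[tr])
        pred = model.predict(X[te])
        pooled_pred[te] = pred
        fold_of[te] = i
        fold_acc.append(float(np.mean(pred == y[te])))
        fold_reports.append(metrics_report(y[te], pred))
    return {
        "mean_accuracy": float(np.mean(fold_acc)),
        "fold_accuracies": fold_acc,
        "fold_reports": fold_reports,
        "pooled_report": metrics_report(y, pooled_pred),
        "pooled_predictions": pooled_pred,
        "fold_of": fold_of,
    }


def _baseline_pipeline(algorithm: str, hyper: dict | None, seed: int) -> Pipeline:
    hyper = hyper or {}
    if algorithm.upper() == "KNN":
        clf = KNeighborsClassifier(n_neighbors=hyper.get("k", 5))
    elif algorithm.upper() == "SVM":
        clf = SVC(
            kernel=hyper.get("kernel", "rbf"),
            C=hyper.get("C", 1.0),
            random_state=seed,
        )
    else:
        raise ValueError(f"unknown baseline algorithm {algorithm!r}")
    return Pipeline(
        [
            ("impute", SimpleImputer(strategy="mean")),
            ("scale", StandardScaler()),
            ("clf", clf),
        ]
    )


def _feature_matrix(table: pd.DataFrame, columns: list[str]) -> np.ndarray:
    cols = [c for c in columns if c in table.columns and table[c].notna().any()]
    if not cols:
        raise ValueError("no usable feature columns")
    return table[cols].to_numpy(dtype=float)


def run_baseline(
    features_table: pd.DataFrame,
    algorithm: str = "KNN",
    hyper: dict | None = None,
    seed: int = 0,
    feature_columns: list[str] | None = None,
) -> dict:
    """10-fold CV of a feature-based KNN or SVM classifier."""
    y = features_table["state"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("feature table contains a single class")
    cols = feature_columns or feat.FEATURE_COLUMNS
    X = _feature_matrix(features_table, cols)
    return ten_fold_cv(
        X, y, lambda: _baseline_pipeline(algorithm, hyper, seed), seed=seed
    )


@dataclass
class ExperimentConfig:
    """End-to-end experiment settings (synthetic scale by default)."""

    n_per_state: int = 30
    input_len: int = 800
    epochs: int = 3
    batch_size: int = 16
    test_fraction: float = 0.3
    knn_k: int = 5
    svm_c: float = 1.0
    seed: int = 0
    synth: synthgen.SynthConfig = field(default_factory=synthgen.SynthConfig)
    out_dir: str | None = None


def _proba_to_state_probs(proba_row, classes) -> tcn.StateProbabilities:
    p = {int(c): float(v) for c, v in zip(classes, proba_row)}
    for s in STATES:
        p.setdefault(s, 0.0)
    total = sum(p.values())
    return tcn.StateProbabilities(p={s: p[s] / total for s in STATES})


def _fuse_pairs(proba_semg, proba_ecg, classes_semg, classes_ecg, weights):
    fused = []
    for ps, pe in zip(proba_semg, proba_ecg):
        state, _conf, _m = fusion.fuse_probabilities(
            _proba_to_state_probs(ps, classes_semg),
            _proba_to_state_probs(pe, classes_ecg),
            weights,
        )
        fused.append(state)
    return np.asarray(fused)


def run_experiment(config: ExperimentConfig | None = None) -> dict:
    """Synthetic-data replication of the full model comparison.

    Pipeline: generate paired records -> preprocess to length-normalised
    periods and to feature vectors -> per-modality KNN/SVM (10-fold CV)
    and TCN (train/test split) -> Dempster-Shafer fusion per classifier
    family -> one consolidated table (model x state x metric).
    """
    config = config or ExperimentConfig()
    seed = config.seed
    pairs = synthgen.generate_dataset(config.n_per_state, config.synth, seed=seed)
    y_all = np.array([p.state for p in pairs])

    # ---- feature arm: KNN / SVM baselines under 10-fold CV --------------
    table = feat.feature_table(pairs)
    reports: dict[str, MetricsReport] = {}
    detail: dict[str, dict] = {}
    proba_oof: dict[str, np.ndarray] = {}
    classes_of: dict[str, np.ndarray] = {}
    acc_of: dict[str, float] = {}

    baseline_specs = {
        "ECG-KNN": ("KNN", ECG_FEATURES, {"k": config.knn_k}),
        "sEMG-KNN": ("KNN", SEMG_FEATURES, {"k": config.knn_k}),
        "ECG-SVM": ("SVM", ECG_FEATURES, {"C": config.svm_c}),
        "sEMG-SVM": ("SVM", SEMG_FEATURES, {"C": config.svm_c}),
    }
    skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=seed)
    for name, (algo, cols, hyper) in baseline_specs.items():
        res = run_baseline(table, algo, hyper, seed=seed, feature_columns=cols)
        reports[name] = res["pooled_report"]
        detail[name] = {
            "mean_accuracy": res["mean_accuracy"],
            "fold_accuracies": res["fold_accuracies"],
        }
        acc_of[name] = res["mean_accuracy"]
        X = _feature_matrix(table, cols)
        pipe = _baseline_pipeline(algo, hyper, seed)
        if algo == "KNN":
            proba = cross_val_predict(pipe, X, y_all, cv=skf, method="predict_proba")
        else:
            # SVM margins -> softmax surrogate probabilities for the BPA
            scores = cross_val_predict(
                pipe, X, y_all, cv=skf, method="decision_function"
            )
            e = np.exp(scores - scores.max(axis=1, keepdims=True))
            proba = e / e.sum(axis=1, keepdims=True)
        proba_oof[name] = proba
        classes_of[name] = np.unique(y_all)

    # fused feature baselines: D-S combination of the two modality models
    for algo in ("KNN", "SVM"):
        w = fusion.estimate_credibility(acc_of[f"sEMG-{algo}"], acc_of[f"ECG-{algo}"])
        fused_pred = _fuse_pairs(
            proba_oof[f"sEMG-{algo}"],
            proba_oof[f"ECG-{algo}"],
            classes_of[f"sEMG-{algo}"],
            classes_of[f"ECG-{algo}"],
            w,
        )
        name = f"ECG-sEMG-{algo}"
        reports[name] = metrics_report(y_all, fused_pred)
        detail[name] = {
            "mean_accuracy": float(np.mean(fused_pred == y_all)),
            "credibility": asdict(w),
        }

    # ---- sequence arm: per-modality TCN on a stratified split ------------
    idx = np.arange(len(pairs))
    tr_idx, te_idx = train_test_split(
        idx,
        test_size=config.test_fraction,
        stratify=y_all,
        random_state=seed,
    )
    series = {
        "sEMG": [
            preprocess.record_to_period_series(p.semg, L=config.input_len)
            for p in pairs
        ],
        "ECG": [
            preprocess.record_to_period_series(p.ecg, L=config.input_len)
            for p in pairs
        ],
    }
    tcn_pred_test: dict[str, np.ndarray] = {}
    tcn_proba_test: dict[str, np.ndarray] = {}
    tcn_train_acc: dict[str, float] = {}
    for mod_i, modality in enumerate(("sEMG", "ECG")):
        net_cfg = tcn.NetConfig(
            input_len=config.input_len,
            epochs=config.epochs,
            batch_size=config.batch_size,
            seed=synthgen.derive_seed(seed, 100 + mod_i),
        )
        model = tcn.build_model(net_cfg)
        X = np.stack([series[modality][i].values for i in idx]).astype(np.float32)
        tcn.train(model, X[tr_idx], y_all[tr_idx], net_cfg)
        name = f"{modality}-TCN"
        pred_te = model.predict_states(X[te_idx])
        tcn_pred_test[name] = pred_te
        tcn_proba_test[name] = model.predict_proba_batch(X[te_idx])
        tcn_train_acc[name] = float(
            np.mean(model.predict_states(X[tr_idx]) == y_all[tr_idx])
        )
        reports[name] = metrics_report(y_all[te_idx], pred_te)
        detail[name] = {
            "mean_accuracy": float(np.mean(pred_te == y_all[te_idx])),
            "train_accuracy": tcn_train_acc[name],
        }

    w_tcn = fusion.estimate_credibility(
        tcn_train_acc["sEMG-TCN"], tcn_train_acc["ECG-TCN"]
    )
    fused_tcn = _fuse_pairs(
        tcn_proba_test["sEMG-TCN"],
        tcn_proba_test["ECG-TCN"],
        STATES,
        STATES,
        w_tcn,
    )
    reports["ECG-sEMG-TCN"] = metrics_report(y_all[te_idx], fused_tcn)
    detail["ECG-sEMG-TCN"] = {
        "mean_accuracy": float(np.mean(fused_tcn == y_all[te_idx])),
        "credibility": asdict(w_tcn),
    }

    rows = []
    for name, report in reports.items():
        rows.extend(report.as_rows(name))
    table_report = pd.DataFrame(rows)

    result = {
        "table": table_report,
        "reports": reports,
        "detail": detail,
        "config": config,
    }
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table_report.to_csv(out / "comparison.csv", index=False)
        payload = {
            "detail": detail,
            "macro": {k: v.macro for k, v in reports.items()},
            "per_class": {
                k: {str(s): v.per_class[s] for s in STATES} for k, v in reports.items()
            },
        }
        (out / "report.json").write_text(json.dumps(payload, indent=1))
    return result
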