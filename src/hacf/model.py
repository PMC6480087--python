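"""Classifier training, cross-validation and the evaluation-metric suite.

The classifier is a support-vector machine over standardized features
(zero mean, unit variance on the training data), with Platt-scaled
probability outputs so every score lies in [0, 1].  Hyperparameters are
exposed in :class:`SVMConfig`; the defaults (RBF kernel, C = 1,
gamma = 1/(d * var)) are the standard choice and everything is seeded for
reproducibility.  Class weighting is off by default — the training design
is deliberately imbalanced (1 positive : 10 negatives, mirroring the
genomic prior that enhancers cover a minority of the genome) — but can be
switched on via config.

Count-based metrics follow the usual confusion-table definitions:
Sens = TP/(TP+FN), Spec = TN/(TN+FP), precision = TP/(TP+FP),
ACC = (TP+TN)/total, GM = sqrt(precision * recall), and Matthews'
correlation coefficient.  Hard labels use a fixed score threshold of 0.5,
matching the genome-scanning rule; AUC is the rank-based (Mann-Whitney)
area under the ROC curve on the pooled scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import joblib
import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.inspection import permutation_importance
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import LeaveOneOut as _SkLOO
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureRecipe, SchemaError

SCORE_THRESHOLD = 0.5  # hard-label cutoff, shared with the genome scanner


@dataclass(frozen=True)
class SVMConfig:
    kernel: str = "rbf"
    C: float = 1.0
    gamma: Union[str, float] = "scale"
    class_weight: Optional[str] = None  # None or "balanced"
    seed: int = 0


@dataclass
class EvaluationReport:
    """Confusion counts plus the derived metric suite.

    Metrics with a zero denominator are reported as NaN (the undefined
    marker), never raised.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    sens: float
    spec: float
    precision: float
    acc: float
    gm: float
    mcc: float
    auc: float = float("nan")

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def compute_metrics(tp: int, tn: int, fp: int, fn: int) -> EvaluationReport:
    """Metric suite from a confusion table (both classes must be present)."""
    for name, v in (("tp", tp), ("tn", tn), ("fp", fp), ("fn", fn)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    if tp + fn < 1 or tn + fp < 1:
        raise ValueError("both classes must be present (tp+fn >= 1 and tn+fp >= 1)")
    sens = _safe_div(tp, tp + fn)
    spec = _safe_div(tn, tn + fp)
    precision = _safe_div(tp, tp + fp)
    acc = _safe_div(tp + tn, tp + tn + fp + fn)
    gm = math.sqrt(precision * sens) if not math.isnan(precision) else float("nan")
    denom = (tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else float("nan")
    return EvaluationReport(
        tp=tp, tn=tn, fp=fp, fn=fn,
        sens=sens, spec=spec, precision=precision, acc=acc, gm=gm, mcc=mcc,
    )


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based AUC (ties count 1/2); requires both label classes."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


@dataclass
class TrainedModel:
    """A fitted scorer: feature recipe + standardizer + SVM + seed.

    ``feature_names`` are the training columns; scoring validates the
    incoming matrix against them.  ``recipe`` records how to featurize raw
    sequences (used by the genome scanner).
    """

    recipe: FeatureRecipe
    pipeline: Pipeline
    config: SVMConfig
    seed: int
    feature_names: tuple[str, ...] = ()

    def score(self, X: pd.DataFrame) -> np.ndarray:
        """Probability-like score in [0, 1] per row (positive-class)."""
        if self.feature_names and list(X.columns) != list(self.feature_names):
            raise SchemaError(
                f"feature matrix has {len(X.columns)} columns, model expects "
                f"{len(self.feature_names)} (first mismatch: "
                f"{next((a for a, b in zip(X.columns, self.feature_names) if a != b), 'length')})"
            )
        return self.pipeline.predict_proba(X.to_numpy())[:, 1]

    def save(self, path: str | Path) -> None:
        joblib.dump(
            {"recipe": self.recipe, "pipeline": self.pipeline,
             "config": self.config, "seed": self.seed,
             "feature_names": self.feature_names},
            path,
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        d = joblib.load(path)
        return cls(recipe=d["recipe"], pipeline=d["pipeline"],
                   config=d["config"], seed=d["seed"],
                   feature_names=tuple(d.get("feature_names", ())))


def train_classifier(
    X: pd.DataFrame,
    y: Sequence[int],
    config: SVMConfig = SVMConfig(),
    recipe: Optional[FeatureRecipe] = None,
) -> TrainedModel:
    """Fit the standardize-then-SVM pipeline; deterministic given the seed."""
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels must contain both classes")
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")
    if not np.all(np.isfinite(X.to_numpy())):
        raise ValueError("feature matrix contains non-finite values")
    if recipe is None:
        recipe = FeatureRecipe(kind="hacf", kept_acf_names=tuple(
            c for c in X.columns if c.startswith("acf_")
        ) or None)
    svm = SVC(
        kernel=config.kernel,
        C=config.C,
        gamma=config.gamma,
        class_weight=config.class_weight,
        random_state=config.seed,
    )
    # Platt-scaled probabilities in [0, 1] (sigmoid calibration on internal CV)
    pipe = Pipeline(
        [
            ("scale", StandardScaler()),
            ("svm", CalibratedClassifierCV(svm, method="sigmoid", ensemble=False)),
        ]
    )
    pipe.fit(X.to_numpy(), y)
    return TrainedModel(recipe=recipe, pipeline=pipe, config=config,
                        seed=config.seed, feature_names=tuple(X.columns))


@dataclass(frozen=True)
class KFoldScheme:
    k: int = 5


@dataclass(frozen=True)
class LeaveOneOutScheme:
    pass


@dataclass(frozen=True)
class SplitScheme:
    train_frac: float = 0.4


Scheme = Union[KFoldScheme, LeaveOneOutScheme, SplitScheme]


def _iter_folds(scheme: Scheme, y: np.ndarray, seed: int):
    n = len(y)
    idx = np.arange(n)
    if isinstance(scheme, KFoldScheme):
        if scheme.k < 2 or scheme.k > np.bincount(y).min():
            raise ValueError(f"k={scheme.k} invalid for class counts {np.bincount(y)}")
        kf = StratifiedKFold(n_splits=scheme.k, shuffle=True, random_state=seed)
        yield from kf.split(idx, y)
    elif isinstance(scheme, LeaveOneOutScheme):
        yield from _SkLOO().split(idx)
    elif isinstance(scheme, SplitScheme):
        if not 0 < scheme.train_frac < 1:
            raise ValueError(f"train_frac must be in (0,1), got {scheme.train_frac}")
        tr, te = train_test_split(
            idx, train_size=scheme.train_frac, stratify=y, random_state=seed
        )
        yield tr, te
    else:  # pragma: no cover
        raise TypeError(f"unknown scheme {scheme!r}")


def cross_validate(
    X: pd.DataFrame,
    y: Sequence[int],
    scheme: Scheme = KFoldScheme(5),
    seed: int = 0,
    config: Optional[SVMConfig] = None,
) -> tuple[EvaluationReport, list[EvaluationReport]]:
    """Stratified cross-validation with pooled scoring.

    Held-out scores from all folds are pooled: AUC is computed on the
    pooled scores, and the count metrics on pooled hard labels at the 0.5
    threshold.  Per-fold count reports are returned alongside (per-fold
    AUC is left NaN when a fold's test part is single-class, as in
    leave-one-out).
    """
    y = np.asarray(y, dtype=int)
    if config is None:
        config = SVMConfig(seed=seed)
    pooled_scores = np.full(len(y), np.nan)
    fold_reports: list[EvaluationReport] = []
    for tr, te in _iter_folds(scheme, y, seed):
        model = train_classifier(X.iloc[tr], y[tr], config=config)
        s = model.pipeline.predict_proba(X.iloc[te].to_numpy())[:, 1]
        pooled_scores[te] = s
        pred = (s > SCORE_THRESHOLD).astype(int)
        tp = int(np.sum((pred == 1) & (y[te] == 1)))
        tn = int(np.sum((pred == 0) & (y[te] == 0)))
        fp = int(np.sum((pred == 1) & (y[te] == 0)))
        fn = int(np.sum((pred == 0) & (y[te] == 1)))
        if tp + fn >= 1 and tn + fp >= 1:
            rep = compute_metrics(tp, tn, fp, fn)
            if len(np.unique(y[te])) == 2:
                rep.auc = roc_auc(s, y[te])
            fold_reports.append(rep)
    scored = ~np.isnan(pooled_scores)
    ys, ss = y[scored], pooled_scores[scored]
    pred = (ss > SCORE_THRESHOLD).astype(int)
    overall = compute_metrics(
        tp=int(np.sum((pred == 1) & (ys == 1))),
        tn=int(np.sum((pred == 0) & (ys == 0))),
        fp=int(np.sum((pred == 1) & (ys == 0))),
        fn=int(np.sum((pred == 0) & (ys == 1))),
    )
    overall.auc = roc_auc(ss, ys)
    return overall, fold_reports


def feature_importance(
    model: TrainedModel,
    X: pd.DataFrame,
    y: Sequence[int],
    n_repeats: int = 5,
    seed: int = 0,
) -> list[tuple[str, float]]:
    """Permutation importance: mean AUC drop per shuffled feature, descending."""
    y = np.asarray(y, dtype=int)
    if model.feature_names and list(X.columns) != list(model.feature_names):
        raise SchemaError("feature matrix does not match the model's training columns")
    res = permutation_importance(
        model.pipeline,
        X.to_numpy(),
        y,
        scoring="roc_auc",
        n_repeats=n_repeats,
        random_state=seed,
    )
    order = np.argsort(-res.importances_mean, kind="stable")
    return [(X.columns[i], float(res.importances_mean[i])) for i in order]


def write_report(report: EvaluationReport, path: str | Path) -> None:
    """Evaluation report as two-line TSV (header + values)."""
    d = report.to_dict()
    with open(path, "w") as fh:
        fh.write("\t".join(d) + "\n")
        fh.write("\t".join(f"{v:.6g}" if isinstance(v, float) else str(v) for v in d.values()) + "\n")
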