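"""Sparse random-forest evaluation over repeated train/test splits.

The screening stage nominates a handful of strong features; here small
random forests (100 trees, at most a few features) are evaluated over
repeated stratified 50:50 train/test splits of the *subjects*, so no
subject ever appears in both halves of a split.  For each repeat the
forest is refitted and scored on the held-out half; AUC comes from the
predicted patient probability (tree-vote fraction) while accuracy,
precision, recall and F1 come from majority-vote labels with the
patient class positive.  The report carries per-repeat values, their
means, and the raw confusion counts.

Splits are stratified by class: with a heavy class imbalance an
unstratified half can lose every control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import train_test_split

logger = logging.getLogger(__name__)

_METRICS = ("auc", "accuracy", "precision", "recall", "f_score")


@dataclass(frozen=True)
class EvaluationProtocol:
    """Settings of one repeated-split evaluation."""

    feature_subset: tuple[str, ...]
    n_repeats: int = 50
    test_fraction: float = 0.5
    n_trees: int = 100
    base_seed: int = 0
    positive_class: str = "patient"

    def __post_init__(self) -> None:
        if not self.feature_subset:
            raise ValueError("feature_subset must be nonempty")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")


@dataclass
class ClassificationReport:
    """Per-repeat and mean metrics for one feature subset.

    ``per_repeat`` has one row per split with the five metrics plus the
    confusion counts (tn, fp, fn, tp) on the test half.
    """

    protocol: EvaluationProtocol
    per_repeat: pd.DataFrame

    @property
    def means(self) -> dict[str, float]:
        return {m: float(self.per_repeat[m].mean()) for m in _METRICS}

    @property
    def mean_auc(self) -> float:
        return self.means["auc"]

    def summary(self) -> str:
        m = self.means
        lines = [
            f"Random forest ({self.protocol.n_trees} trees), "
            f"{self.protocol.n_repeats} stratified "
            f"{1 - self.protocol.test_fraction:.0%}:{self.protocol.test_fraction:.0%} splits",
            "features: " + ", ".join(self.protocol.feature_subset),
            "-" * 60,
        ]
        lines += [f"mean {name:<10} {m[name]:.3f}" for name in _METRICS]
        return "\n".join(lines)


def repeated_evaluation(
    table: pd.DataFrame, protocol: EvaluationProtocol
) -> ClassificationReport:
    """Evaluate one feature subset over repeated stratified splits.

    The table must hold a single test type with both classes present;
    rows with NaN in the selected features are dropped (logged).  Split
    ``i`` uses random state ``base_seed + i`` for both the split and the
    forest, making the whole report reproducible.
    """
    if table["test_type"].nunique() > 1:
        raise ValueError("evaluation table must contain a single test type")
    missing = [f for f in protocol.feature_subset if f not in table.columns]
    if missing:
        raise ValueError(f"features not in table: {missing}")

    X = table[list(protocol.feature_subset)].to_numpy(dtype=float)
    y = (table["label"] == protocol.positive_class).to_numpy()
    ok = np.all(np.isfinite(X), axis=1)
    if not ok.all():
        logger.info("dropping %d rows with NaN features", int((~ok).sum()))
        X, y = X[ok], y[ok]
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both classes must be present")
    n_minority = int(min(y.sum(), len(y) - y.sum()))
    if n_minority < 2:
        raise ValueError("stratified splitting needs >= 2 subjects per class")

    rows = []
    for i in range(protocol.n_repeats):
        seed = protocol.base_seed + i
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y,
            test_size=protocol.test_fraction,
            stratify=y,
            random_state=seed,
        )
        clf = RandomForestClassifier(
            n_estimators=protocol.n_trees, random_state=seed
        )
        clf.fit(X_tr, y_tr)
        scores = clf.predict_proba(X_te)[:, list(clf.classes_).index(True)]
        y_hat = clf.predict(X_te)
        tn, fp, fn, tp = confusion_matrix(y_te, y_hat, labels=[False, True]).ravel()
        rows.append(
            {
                "repeat": i,
                "auc": roc_auc_score(y_te, scores),
                "accuracy": accuracy_score(y_te, y_hat),
                "precision": precision_score(y_te, y_hat, zero_division=0),
                "recall": recall_score(y_te, y_hat, zero_division=0),
                "f_score": f1_score(y_te, y_hat, zero_division=0),
                "tn": int(tn), "fp": int(fp), "fn": int(fn), "tp": int(tp),
            }
        )
    return ClassificationReport(protocol=protocol, per_repeat=pd.DataFrame(rows))


def evaluate_candidate_sets(
    table: pd.DataFrame,
    candidate_sets: list[tuple[str, ...] | list[str]],
    protocol: EvaluationProtocol | None = None,
    **protocol_kwargs,
) -> tuple[pd.DataFrame, list[ClassificationReport]]:
    """Evaluate several feature subsets and rank them.

    Returns a ranking DataFrame (mean metrics per subset, sorted by mean
    AUC descending, ties broken by accuracy then subset name) and the
    matching reports in the same order.
    """
    reports = []
    for subset in candidate_sets:
        if protocol is None:
            proto = EvaluationProtocol(feature_subset=tuple(subset), **protocol_kwargs)
        else:
            proto = replace(protocol, feature_subset=tuple(subset))
        reports.append(repeated_evaluation(table, proto))

    rows = []
    for rep in reports:
        row = {"features": ", ".join(rep.protocol.feature_subset)}
        row.update(rep.means)
        rows.append(row)
    ranking = pd.DataFrame(rows)
    order = ranking.sort_values(
        by=["auc", "accuracy", "features"], ascending=[False, False, True]
    ).index
    ranking = ranking.loc[order].reset_index(drop=True)
    reports = [reports[i] for i in order]
    return ranking, reports
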