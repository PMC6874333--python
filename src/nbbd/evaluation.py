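"""Classifier harness: random-forest training, the five performance metrics,
the FSDS-size x method x k experiment grid, and a Kruskal-Wallis
differential-abundance check.

The experiment protocol mirrors a nested feature-selection design: features
are ranked on a (possibly small) feature-selection subset of the training
samples, the classifier is always trained on the *full* training table
restricted to those features, and evaluated once on a held-out test table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .otu import OTUTable, nested_subsets, to_relative_abundance

logger = logging.getLogger(__name__)

__all__ = ["EvalReport", "train_rf", "evaluate", "report_from_confusion",
           "experiment_grid", "summarize_top", "kruskal_wallis"]

DEFAULT_K_GRID = (10, 20, 30, 40, 50, 60)


@dataclass
class EvalReport:
    """Binary-classification metrics with their confusion counts."""

    acc: float
    sn: float
    sp: float
    mcc: float
    auc: float | None
    confusion: tuple[int, int, int, int]  # TP, FP, TN, FN
    n_features: int = 0
    method: str = ""
    fsds: str = ""

    def as_dict(self) -> dict:
        tp, fp, tn, fn = self.confusion
        return {"fsds": self.fsds, "method": self.method,
                "n_features": self.n_features, "acc": self.acc, "sn": self.sn,
                "sp": self.sp, "mcc": self.mcc, "auc": self.auc,
                "tp": tp, "fp": fp, "tn": tn, "fn": fn}


def _positive_label(labels: np.ndarray, pos_label=None):
    classes = sorted(np.unique(labels))
    if len(classes) != 2:
        raise ValueError(f"labels must be binary, got {classes}")
    if pos_label is None:
        return classes[1]
    if pos_label not in classes:
        raise ValueError(f"pos_label {pos_label!r} not among {classes}")
    return pos_label


def train_rf(train: OTUTable, features: Sequence[str], n_trees: int = 500,
             seed: int = 0) -> RandomForestClassifier:
    """Fit a 500-tree random forest on the feature-restricted
    relative-abundance matrix."""
    if not list(features):
        raise ValueError("empty feature list (attack-set selection found no features?)")
    sub = to_relative_abundance(train).restrict_taxa(list(features))
    y = train.labels
    if y is None:
        raise ValueError("training table carries no labels")
    _positive_label(y.to_numpy())
    model = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    model.fit(sub.values, y.to_numpy())
    model.nbbd_features_ = list(features)
    return model


def _rank_auc(y_true: np.ndarray, scores: np.ndarray, pos) -> float:
    """AUC as the Mann-Whitney rank statistic with midranks for ties."""
    pos_mask = y_true == pos
    n1, n0 = int(pos_mask.sum()), int((~pos_mask).sum())
    ranks = stats.rankdata(scores)
    u = ranks[pos_mask].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def report_from_confusion(tp: int, fp: int, tn: int, fn: int,
                          auc: float | None = None) -> EvalReport:
    """Metrics from raw confusion counts (AUC supplied separately)."""
    total = tp + fp + tn + fn
    acc = (tp + tn) / total if total else 0.0
    sn = tp / (tp + fn) if (tp + fn) else 0.0
    sp = tn / (tn + fp) if (tn + fp) else 0.0
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0
    return EvalReport(acc=acc, sn=sn, sp=sp, mcc=mcc, auc=auc,
                      confusion=(tp, fp, tn, fn))


def evaluate(model: RandomForestClassifier, test: OTUTable,
             features: Sequence[str] | None = None,
             pos_label=None) -> EvalReport:
    """Evaluate a fitted model on a labeled test table.

    Confusion counts use a 0.5 threshold on the positive-class probability;
    AUC is the rank statistic over predicted probabilities (midranks for
    ties). A single-class test set yields AUC ``None``.
    """
    if features is None:
        features = getattr(model, "nbbd_features_", None)
        if features is None:
            raise ValueError("features must be given or recorded on the model")
    if test.labels is None:
        raise ValueError("test table carries no labels")
    y = test.labels.to_numpy()
    sub = to_relative_abundance(test).restrict_taxa(list(features))
    classes = list(model.classes_)
    pos = _positive_label(np.asarray(classes), pos_label)
    proba = model.predict_proba(sub.values)[:, classes.index(pos)]
    pred_pos = proba >= 0.5
    actual_pos = y == pos
    tp = int(np.sum(pred_pos & actual_pos))
    fp = int(np.sum(pred_pos & ~actual_pos))
    tn = int(np.sum(~pred_pos & ~actual_pos))
    fn = int(np.sum(~pred_pos & actual_pos))
    if len(np.unique(y)) < 2:
        logger.warning("single-class test set: AUC undefined")
        auc = None
    else:
        auc = _rank_auc(y, proba, pos)
    rep = report_from_confusion(tp, fp, tn, fn, auc=auc)
    rep.n_features = len(list(features))
    return rep


# ---------------------------------------------------------------------------
# Experiment grid
# ---------------------------------------------------------------------------

#: a feature-selection method for the grid: callable(fsds_table, k, seed) ->
#: list of selected taxa. Raise to mark the cell failed; return [] for the
#: adaptive (attack set) methods that found nothing.
SelectorFn = Callable[[OTUTable, int, int], list]


def experiment_grid(
    train: OTUTable,
    test: OTUTable,
    fsds_sizes: Sequence[int],
    methods: Mapping[str, SelectorFn],
    k_grid: Sequence[int] = DEFAULT_K_GRID,
    n_trees: int = 500,
    seed: int = 0,
    include_baseline: bool = True,
) -> pd.DataFrame:
    """Run the full FSDS-size x method x k sweep.

    For every cell, features are chosen on the nested feature-selection
    subset only, the forest is trained on the full training table, and
    metrics come from the held-out test table. Failures (for instance an
    empty attack-set intersection) become status rows so the sweep always
    completes.
    """
    subsets = nested_subsets(train, list(fsds_sizes), seed=seed)
    rows: list[dict] = []
    for n_per_group, fsds in zip(fsds_sizes, subsets):
        tag = f"DS{2 * n_per_group}"
        if include_baseline:
            rep = evaluate(train_rf(train, train.taxon_ids, n_trees, seed), test)
            rep.method, rep.fsds, rep.n_features = "none", tag, train.n_taxa
            rows.append({**rep.as_dict(), "k": None, "status": "ok"})
        for name, select in methods.items():
            for k in k_grid:
                row = {"fsds": tag, "method": name, "k": k}
                try:
                    features = list(select(fsds, k, seed))
                    if not features:
                        rows.append({**row, "status": "no_features"})
                        continue
                    model = train_rf(train, features, n_trees, seed)
                    rep = evaluate(model, test)
                    rep.method, rep.fsds = name, tag
                    rows.append({**rep.as_dict(), "k": k, "status": "ok"})
                except Exception as exc:  # cell failure must not stop the sweep
                    logger.warning("grid cell %s/%s/k=%d failed: %s",
                                   tag, name, k, exc)
                    rows.append({**row, "status": f"error: {exc}"})
    return pd.DataFrame(rows)


def summarize_top(grid: pd.DataFrame) -> pd.DataFrame:
    """Best row per (fsds, method): highest AUC, then fewest features."""
    ok = grid[grid["status"] == "ok"].copy()
    ok = ok.sort_values(["auc", "n_features"], ascending=[False, True])
    return (ok.groupby(["fsds", "method"], as_index=False).first()
              .sort_values(["fsds", "method"]).reset_index(drop=True))


def kruskal_wallis(table: OTUTable, taxon: str) -> tuple[float, float]:
    """Kruskal-Wallis H and p-value for one taxon between the two groups.

    Rank-based with tie correction; with two groups it is monotonically
    related to the Mann-Whitney U test. All-tied values give H=0, p=1.
    """
    if table.labels is None:
        raise ValueError("table carries no labels")
    groups = sorted(table.labels.unique())
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    col = table.data[taxon]
    a = col[table.labels == groups[0]].to_numpy()
    b = col[table.labels == groups[1]].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 samples")
    if np.all(np.r_[a, b] == np.r_[a, b][0]):
        return 0.0, 1.0
    h, p = stats.kruskal(a, b)
    return float(h), float(p)
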