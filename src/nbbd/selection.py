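"""Feature ranking and top-k selection.

Baselines: information gain (IG), one-way ANOVA F statistic (FStat),
recursive feature elimination with an L1-penalised logistic model (RFE-LASSO)
and random-forest feature importance (RFFI). The hybrid score multiplies
RFFI by an NTPS score so a taxon must look important to the forest *and*
rewire between the phenotype networks to rank highly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from .otu import OTUTable

logger = logging.getLogger(__name__)

__all__ = ["SelectionResult", "rank_information_gain", "rank_f_statistic",
           "rfe_lasso", "rffi", "hybrid_score", "select_top_k"]


@dataclass
class SelectionResult:
    """Ranked taxa from one feature-selection method."""

    method: str
    ranked_taxa: list[str]
    scores: dict[str, float]
    k: int | str  # integer, or "adaptive" for attack-set selection

    def top(self, k: int) -> list[str]:
        return self.ranked_taxa[:k]


def _require_binary_labels(table: OTUTable) -> np.ndarray:
    if table.labels is None:
        raise ValueError("table carries no labels")
    y = table.labels.to_numpy()
    if len(np.unique(y)) != 2:
        raise ValueError("labels must be binary")
    return y


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def rank_information_gain(table: OTUTable, n_bins: int = 10) -> dict[str, float]:
    """IG per taxon after equal-width discretisation of its abundance.

    IG = H(label) - H(label | bin), base-2. A constant feature occupies a
    single bin and scores 0.
    """
    y = _require_binary_labels(table)
    classes, y_idx = np.unique(y, return_inverse=True)
    h_y = _entropy(np.bincount(y_idx).astype(float))
    x = table.values
    scores: dict[str, float] = {}
    n = len(y)
    for j, taxon in enumerate(table.taxon_ids):
        col = x[:, j]
        lo, hi = col.min(), col.max()
        if hi <= lo:
            scores[taxon] = 0.0
            continue
        bins = np.clip(((col - lo) / (hi - lo) * n_bins).astype(int), 0, n_bins - 1)
        h_cond = 0.0
        for b in np.unique(bins):
            in_bin = bins == b
            h_cond += in_bin.sum() / n * _entropy(
                np.bincount(y_idx[in_bin], minlength=len(classes)).astype(float)
            )
        scores[taxon] = max(0.0, h_y - h_cond)
    return scores


def rank_f_statistic(table: OTUTable) -> dict[str, float]:
    """One-way ANOVA F per taxon between the two phenotype groups.

    Zero within-group variance with unequal means (infinite F) is replaced by
    the largest finite float so the taxon still tops the ranking.
    """
    y = _require_binary_labels(table)
    groups = np.unique(y)
    for g in groups:
        if (y == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    x = table.values
    a, b = x[y == groups[0]], x[y == groups[1]]
    with np.errstate(invalid="ignore", divide="ignore"):
        f, _ = stats.f_oneway(a, b)
    f = np.asarray(f, dtype=float)
    f[np.isnan(f)] = 0.0  # identical constant groups
    big = np.isinf(f)
    if big.any():
        logger.info("taxa with zero within-group variance capped at max float: %s",
                    [t for t, m in zip(table.taxon_ids, big) if m])
        f[big] = np.finfo(float).max
    return dict(zip(table.taxon_ids, f))


def rfe_lasso(table: OTUTable, k: int, step: int = 10, c: float = 1.0,
              seed: int = 0) -> SelectionResult:
    """Recursive feature elimination with an L1-penalised logistic model.

    Each iteration fits the model on the surviving taxa, ranks by |coef| and
    drops the ``step`` lowest (fewer on the last iteration to land exactly on
    ``k`` survivors).
    """
    y = _require_binary_labels(table)
    if not (1 <= k <= table.n_taxa):
        raise ValueError("k must satisfy 1 <= k <= n_taxa")
    surviving = list(table.taxon_ids)
    x_all = table.data
    coefs: dict[str, float] = {}
    while len(surviving) > k:
        model = LogisticRegression(l1_ratio=1.0, C=c, solver="liblinear",
                                   random_state=seed, max_iter=2000)
        model.fit(x_all.loc[:, surviving].to_numpy(), y)
        w = np.abs(model.coef_[0])
        coefs = dict(zip(surviving, w))
        n_drop = min(step, len(surviving) - k)
        order = sorted(surviving, key=lambda t: (coefs[t], t))
        for t in order[:n_drop]:
            surviving.remove(t)
    model = LogisticRegression(l1_ratio=1.0, C=c, solver="liblinear",
                               random_state=seed, max_iter=2000)
    model.fit(x_all.loc[:, surviving].to_numpy(), y)
    final = dict(zip(surviving, np.abs(model.coef_[0])))
    ranked = sorted(surviving, key=lambda t: (-final[t], t))
    return SelectionResult(method="rfe_lasso", ranked_taxa=ranked,
                           scores=final, k=k)


def rffi(table: OTUTable, n_trees: int = 500, seed: int = 0) -> dict[str, float]:
    """Impurity-decrease feature importances from a random forest.

    Scores are nonnegative and sum to 1; deterministic given the seed.
    """
    y = _require_binary_labels(table)
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    forest.fit(table.values, y)
    imp = forest.feature_importances_.astype(float)
    total = imp.sum()
    if total <= 0:
        logger.warning("forest produced all-zero importances; using uniform scores")
        imp = np.full_like(imp, 1.0 / len(imp))
    else:
        imp = imp / total
    return dict(zip(table.taxon_ids, imp))


def hybrid_score(rffi_scores: dict[str, float],
                 ntps_scores: dict[str, float]) -> dict[str, float]:
    """Elementwise product of RFFI and NTPS scores on the shared taxa.

    Taxa absent from either input are excluded (their hybrid score is
    undefined, not zero).
    """
    shared = sorted(set(rffi_scores) & set(ntps_scores))
    if not shared:
        raise ValueError("the two score tables share no taxa")
    return {t: rffi_scores[t] * ntps_scores[t] for t in shared}


def select_top_k(scores: dict[str, float], k: int,
                 method: str = "scores") -> SelectionResult:
    """Top-k taxa by score descending; ties break lexicographically."""
    if k < 1:
        raise ValueError("k must be at least 1")
    if k > len(scores):
        raise ValueError(f"k={k} exceeds the {len(scores)} scored taxa")
    for t, v in scores.items():
        if not np.isfinite(v) or v < 0:
            raise ValueError(f"score for {t!r} is not a finite nonnegative number")
    ranked = sorted(scores, key=lambda t: (-scores[t], t))
    return SelectionResult(method=method, ranked_taxa=ranked[:k],
                           scores={t: scores[t] for t in ranked[:k]}, k=k)
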