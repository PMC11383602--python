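"""Univariate filter importance of delta features for a two-class split.

Each feature is scored by its two-class ROC area (Mann-Whitney U statistic
normalized by n1*n2, ties counted one half), symmetrized as
``max(AUC, 1 - AUC)`` so the score lies in [0.5, 1] regardless of the
direction of separation.  Features with score >= 0.9 are retained as
"response-defining".
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

SCORE_THRESHOLD = 0.9


def roc_auc(values: np.ndarray, positive: np.ndarray) -> float:
    """Rank-based AUC of a numeric predictor for a boolean class vector."""
    ranks = stats.rankdata(values)
    n1 = int(positive.sum())
    n2 = int((~positive).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both classes must be non-empty")
    u = ranks[positive].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n2))


def auc_importance(
    table: pd.DataFrame,
    labels: pd.Series | np.ndarray | dict,
    threshold: float = SCORE_THRESHOLD,
) -> pd.DataFrame:
    """Per-feature classification score with a retention flag.

    ``labels`` must contain exactly two classes with at least two members
    each.  Returns columns ``auc``, ``score`` (= max(AUC, 1-AUC)) and
    ``retained`` (score >= threshold).
    """
    if isinstance(labels, dict):
        labels = pd.Series(labels)
    if isinstance(labels, pd.Series):
        labels = labels.reindex(table.index).to_numpy()
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"expected exactly 2 classes, got {list(classes)}")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 members")
    positive = labels == classes[1]
    mat = table.to_numpy()
    ranks = np.apply_along_axis(stats.rankdata, 0, mat)
    n1, n2 = int(positive.sum()), int((~positive).sum())
    u = ranks[positive].sum(axis=0) - n1 * (n1 + 1) / 2
    auc = u / (n1 * n2)
    score = np.maximum(auc, 1.0 - auc)
    return pd.DataFrame(
        {"auc": auc, "score": score, "retained": score >= threshold},
        index=table.columns,
    )
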