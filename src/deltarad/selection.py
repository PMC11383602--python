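"""Delta features and the two-stage feature filter.

Stage 1 keeps features stable against segmentation variability
(intraclass correlation ICC >= 0.75 between two segmentations of the same
scans); stage 2 prunes redundancy (iterative removal until all pairwise
Spearman |rho| < 0.85).  Retention reasons are recorded per feature.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

ICC_THRESHOLD = 0.75
RHO_MAX = 0.85


def delta(pre: pd.Series, post: pd.Series) -> pd.Series:
    """Elementwise post - pre over an identical feature catalog."""
    if list(pre.index) != list(post.index):
        raise ValueError("feature catalogs of the two time points differ")
    return post - pre


def delta_table(pre_table: pd.DataFrame, post_table: pd.DataFrame) -> pd.DataFrame:
    """Subject x feature delta matrix for subjects present at both time points."""
    shared = pre_table.index.intersection(post_table.index)
    missing = pre_table.index.symmetric_difference(post_table.index)
    if len(missing):
        log.warning("subjects without both time points excluded: %s", list(missing))
    if list(pre_table.columns) != list(post_table.columns):
        raise ValueError("feature catalogs of the two tables differ")
    return post_table.loc[shared] - pre_table.loc[shared]


def icc_consistency(a: np.ndarray, b: np.ndarray, model: str = "icc3") -> float:
    """Two-segmentation ICC from the two-way ANOVA closed form.

    ``icc3`` is ICC(3,1) (two-way mixed, single rater, consistency),
    (BMS - EMS) / (BMS + EMS) for k = 2 raters; ``icc2`` is the ICC(2,1)
    absolute-agreement alternative.  Returns NaN for constant inputs.
    """
    x = np.column_stack([a, b]).astype(float)
    n, k = x.shape
    if n < 3:
        raise ValueError("ICC requires at least 3 subjects")
    grand = x.mean()
    subj_means = x.mean(axis=1)
    rater_means = x.mean(axis=0)
    bms = k * ((subj_means - grand) ** 2).sum() / (n - 1)
    jms = n * ((rater_means - grand) ** 2).sum() / (k - 1)
    resid = x - subj_means[:, None] - rater_means[None, :] + grand
    ems = (resid**2).sum() / ((n - 1) * (k - 1))
    denom_base = bms + (k - 1) * ems
    if model == "icc3":
        denom = denom_base
    elif model == "icc2":
        denom = denom_base + k * (jms - ems) / n
    else:
        raise ValueError(f"unknown ICC model {model!r}")
    if denom == 0:
        return float("nan")
    return float((bms - ems) / denom)


def icc_filter(
    features_a: pd.DataFrame,
    features_b: pd.DataFrame,
    threshold: float = ICC_THRESHOLD,
    model: str = "icc3",
) -> pd.DataFrame:
    """Per-feature segmentation-stability filter.

    ``features_a``/``features_b`` hold the same scans x features under the
    two segmentations.  Returns a frame with columns ``icc``, ``retained``,
    ``reason``; constant features have undefined ICC and are dropped.
    """
    if list(features_a.columns) != list(features_b.columns):
        raise ValueError("feature sets differ between segmentations")
    if not features_a.index.equals(features_b.index):
        raise ValueError("scan sets differ between segmentations")
    if len(features_a) < 3:
        raise ValueError("ICC filter requires at least 3 scans")
    rows = []
    for col in features_a.columns:
        icc = icc_consistency(
            features_a[col].to_numpy(), features_b[col].to_numpy(), model=model
        )
        if np.isnan(icc):
            rows.append((col, icc, False, "icc_fail"))
            log.info("feature %s constant across scans; ICC undefined, dropped", col)
        else:
            ok = icc >= threshold
            rows.append((col, icc, ok, "kept" if ok else "icc_fail"))
    return pd.DataFrame(rows, columns=["feature", "icc", "retained", "reason"]).set_index(
        "feature"
    )


def correlation_prune(table: pd.DataFrame, rho_max: float = RHO_MAX) -> list[str]:
    """Greedy redundancy pruning until max pairwise Spearman |rho| < rho_max.

    Repeatedly takes the most correlated remaining pair at or above the
    threshold and drops the member with the larger mean absolute correlation
    to all other remaining features; ties break deterministically toward
    dropping the later catalog column.
    """
    if len(table) < 3:
        raise ValueError("correlation pruning requires at least 3 subjects")
    cols = list(table.columns)
    ranks = table.rank()
    corr = np.abs(np.corrcoef(ranks.to_numpy(), rowvar=False))
    corr = np.atleast_2d(corr)
    np.fill_diagonal(corr, 0.0)
    corr = np.nan_to_num(corr)  # constant columns correlate with nothing
    alive = np.ones(len(cols), dtype=bool)
    while True:
        sub = np.where(alive[:, None] & alive[None, :], corr, 0.0)
        hi = sub.max()
        if hi < rho_max:
            break
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        i, j = min(i, j), max(i, j)
        mean_i = sub[i, alive].sum() / max(alive.sum() - 1, 1)
        mean_j = sub[j, alive].sum() / max(alive.sum() - 1, 1)
        drop = j if mean_j >= mean_i else i  # tie -> later catalog column
        alive[drop] = False
    return [c for c, a in zip(cols, alive) if a]


def select_features(
    delta: pd.DataFrame,
    features_seg_a: pd.DataFrame | None = None,
    features_seg_b: pd.DataFrame | None = None,
    icc_threshold: float = ICC_THRESHOLD,
    rho_max: float = RHO_MAX,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-stage filter: segmentation-stability ICC, then redundancy pruning.

    Returns the filtered delta table and a retention report with mutually
    exclusive reasons {kept, icc_fail, corr_pruned}.
    """
    report = pd.DataFrame(
        {"icc": np.nan, "retained": True, "reason": "kept"}, index=delta.columns
    )
    table = delta
    if features_seg_a is not None and features_seg_b is not None:
        icc_rep = icc_filter(features_seg_a, features_seg_b, threshold=icc_threshold)
        report.loc[icc_rep.index, "icc"] = icc_rep["icc"]
        failed = icc_rep.index[~icc_rep["retained"]]
        report.loc[failed, ["retained", "reason"]] = [False, "icc_fail"]
        table = table.drop(columns=failed, errors="ignore")
    kept = correlation_prune(table, rho_max=rho_max)
    pruned = [c for c in table.columns if c not in set(kept)]
    report.loc[pruned, ["retained", "reason"]] = [False, "corr_pruned"]
    return delta[kept], report


def spearman_abs_max(table: pd.DataFrame) -> float:
    """Largest pairwise |Spearman rho| in a table (post-pruning check)."""
    if table.shape[1] < 2:
        return 0.0
    rho = np.abs(stats.spearmanr(table.to_numpy()).statistic)
    rho = np.atleast_2d(rho)
    np.fill_diagonal(rho, 0.0)
    return float(np.nanmax(rho))
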