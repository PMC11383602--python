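"""Patient-cohort stratification on preclinically defined feature subsets.

Patients are clustered (k-means on Z-scored delta features, silhouette-
selected k, Jaccard bootstrap) using only feature names defined in the
preclinical analysis — no patient outcome enters the clustering inputs.
Lung-function decline (FVC, percent predicted and mL) and clinical
covariates are then compared across the resulting clusters with
Mann-Whitney U and Fisher's exact tests.
"""

from __future__ import annotations

import logging
from math import lgamma

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import ClusterResult, cluster_with_diagnostics

log = logging.getLogger(__name__)

OUTCOME_COLUMNS = frozenset(
    {
        "fvc_pct_pre",
        "fvc_pct_post",
        "fvc_ml_pre",
        "fvc_ml_post",
        "delta_fvc_pct",
        "delta_fvc_ml",
        "annualized_fvc_pct",
        "annualized_fvc_ml",
    }
)


def fvc_delta(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-patient FVC change (post - pre) and annualized rate.

    Patients missing either time point are excluded with a log entry; a
    post date on or before the pre date is a validation error.
    """
    required = ["fvc_pct_pre", "fvc_pct_post", "fvc_ml_pre", "fvc_ml_post", "date_pre", "date_post"]
    missing_cols = [c for c in required if c not in cohort.columns]
    if missing_cols:
        raise ValueError(f"cohort table missing columns: {missing_cols}")
    usable = cohort.dropna(subset=required)
    dropped = cohort.index.difference(usable.index)
    if len(dropped):
        log.warning("patients excluded for missing time points: %s", list(dropped))
    pre = pd.to_datetime(usable["date_pre"])
    post = pd.to_datetime(usable["date_post"])
    days = (post - pre).dt.days.astype(float)
    if (days <= 0).any():
        bad = usable.index[days <= 0].tolist()
        raise ValueError(f"post date not after pre date for {bad}")
    d_pct = usable["fvc_pct_post"] - usable["fvc_pct_pre"]
    d_ml = usable["fvc_ml_post"] - usable["fvc_ml_pre"]
    return pd.DataFrame(
        {
            "delta_fvc_pct": d_pct,
            "delta_fvc_ml": d_ml,
            "interval_days": days,
            "annualized_fvc_pct": d_pct * 365.25 / days,
            "annualized_fvc_ml": d_ml * 365.25 / days,
        }
    )


def stratify(
    delta_table: pd.DataFrame,
    feature_subset: list[str],
    k: int | None = None,
    k_range: tuple[int, int] = (2, 8),
    B: int = 1000,
    seed: int = 0,
) -> ClusterResult:
    """K-means stratification of patients on a preclinical feature subset.

    The subset is intersected with the patient table's columns (an empty
    intersection is an error) and must not contain outcome variables; k is
    silhouette-selected within ``k_range`` capped at n - 1 unless given.
    """
    banned = OUTCOME_COLUMNS & set(feature_subset)
    if banned:
        raise ValueError(f"outcome variables may not enter clustering: {sorted(banned)}")
    present = [f for f in feature_subset if f in delta_table.columns]
    if not present:
        raise ValueError("feature subset empty after intersection with patient table")
    if len(present) < len(feature_subset):
        log.warning(
            "%d of %d subset features absent from the patient table",
            len(feature_subset) - len(present),
            len(feature_subset),
        )
    sub = delta_table[present]
    n = len(sub)
    k_range = (k_range[0], min(k_range[1], n - 1))
    return cluster_with_diagnostics(
        sub, method="kmeans", k=k, k_range=k_range, B=B, seed=seed
    )


# ---------------------------------------------------------------------------
# group comparison tests


def mann_whitney(a, b) -> float:
    """Two-sided Mann-Whitney U P value; exact for n <= 8 per group
    (without ties), otherwise the tie-corrected normal approximation."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (max(a.size, b.size) <= 8 and not ties) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def _log_fact(n: int) -> float:
    return lgamma(n + 1)


def fisher_exact_rxc(table: np.ndarray) -> float:
    """Two-sided Fisher's exact P for a small r x c contingency table.

    Enumerates all tables with the observed margins and sums the
    probabilities of those no more probable than the observed table
    (the standard conditional-probability two-sided rule).  For 2x2 this
    reproduces ``scipy.stats.fisher_exact``.
    """
    obs = np.asarray(table, dtype=int)
    if obs.ndim != 2 or (obs < 0).any():
        raise ValueError("contingency table must be a non-negative 2D array")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    n = int(obs.sum())
    if n == 0:
        raise ValueError("empty contingency table")
    const = sum(_log_fact(r) for r in rows) + sum(_log_fact(c) for c in cols) - _log_fact(n)

    def logp(t: np.ndarray) -> float:
        return const - sum(_log_fact(int(v)) for v in t.ravel())

    p_obs = logp(obs)
    r, c = obs.shape

    total = 0.0

    def recurse(i: int, remaining_cols: np.ndarray, acc: list):
        nonlocal total
        if i == r - 1:
            t = np.array(acc + [remaining_cols])
            if (t >= 0).all():
                lp = logp(t)
                if lp <= p_obs + 1e-10:
                    total += np.exp(lp)
            return
        ri = rows[i]
        # enumerate row i cell values summing to ri within column budgets
        def cells(j: int, left: int, row: list):
            if j == c - 1:
                if left <= remaining_cols[c - 1]:
                    yield row + [left]
                return
            for v in range(min(left, remaining_cols[j]) + 1):
                yield from cells(j + 1, left - v, row + [v])

        for row in cells(0, int(ri), []):
            recurse(i + 1, remaining_cols - np.array(row), acc + [row])

    recurse(0, cols.copy(), [])
    return float(min(total, 1.0))


def group_tests(cohort: pd.DataFrame, labels: pd.Series | dict, variables: list[str]) -> pd.DataFrame:
    """Compare variables across cluster labels.

    Numeric variables use the two-sided Mann-Whitney U test (two groups);
    categorical/boolean variables use Fisher's exact test on the
    cross-tabulation.  Empty groups are an error.
    """
    if isinstance(labels, dict):
        labels = pd.Series(labels)
    labels = labels.reindex(cohort.index)
    groups = sorted(labels.dropna().unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    rows = []
    for var in variables:
        col = cohort[var]
        if pd.api.types.is_numeric_dtype(col) and not pd.api.types.is_bool_dtype(col):
            if len(groups) != 2:
                raise ValueError(f"Mann-Whitney comparison of {var} needs exactly 2 groups")
            a = col[labels == groups[0]].dropna()
            b = col[labels == groups[1]].dropna()
            p = mann_whitney(a, b)
            kind = "mann_whitney"
        else:
            tab = pd.crosstab(col, labels).to_numpy()
            p = fisher_exact_rxc(tab)
            kind = "fisher_exact"
        rows.append((var, kind, p))
    return pd.DataFrame(rows, columns=["variable", "test", "p"]).set_index("variable")
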