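"""Proteome statistics: differential expression, radioproteomic association
modules, pathway over-representation, and cell-type signature deconvolution.

The association module of one response-defining delta radiomic feature is
the set of proteins whose log2 expression intensity correlates with it
(Spearman |rho| >= 0.6, P < 0.05), split into positively and negatively
correlated halves.  Module members are ranked by log10 P and weighted by
the correlation coefficient before entering signature deconvolution, which
tests by two-sample Kolmogorov-Smirnov whether the markers of a cell type
concentrate at one end of the signed-weight ranking.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

RHO_MIN = 0.6
P_MAX = 0.05
GENE_RATIO_MIN = 0.10
PADJ_MAX = 0.05
KS_ALPHA = 0.01
FC_THRESHOLD = 0.3

#: pseudo-sample weight of the median-variance prior in moderated tests
NU0 = 3.0


# ---------------------------------------------------------------------------
# differential expression


def differential_expression(
    proteome: pd.DataFrame,
    group_labels: pd.Series | dict,
    reference: str | None = None,
    fc_threshold: float = FC_THRESHOLD,
    p_threshold: float = P_MAX,
    nu0: float = NU0,
) -> pd.DataFrame:
    """Per-protein moderated Welch t test on log2 intensities.

    Group variances are shrunk toward the across-protein median pooled
    variance with a prior weight of ``nu0`` pseudo-samples, which stabilizes
    small-sample variance estimates in the spirit of empirical-Bayes
    moderation.  ``log2FC`` is the non-reference minus reference group mean.
    A protein is flagged significant when |log2FC| > 0.3 and P < 0.05; a
    Benjamini-Hochberg adjusted column is provided alongside.
    """
    if isinstance(group_labels, dict):
        group_labels = pd.Series(group_labels)
    group_labels = group_labels.reindex(proteome.columns)
    groups = sorted(group_labels.dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"expected 2 groups, got {groups}")
    if reference is None:
        reference = groups[0]
    other = [g for g in groups if g != reference][0]
    a = proteome.loc[:, group_labels == reference].to_numpy(dtype=float)
    b = proteome.loc[:, group_labels == other].to_numpy(dtype=float)
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")

    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1, v2 = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    s0 = float(np.median(pooled))
    v1s = (nu0 * s0 + (n1 - 1) * v1) / (nu0 + n1 - 1)
    v2s = (nu0 * s0 + (n2 - 1) * v2) / (nu0 + n2 - 1)

    fc = m2 - m1
    se2 = v1s / n1 + v2s / n2
    t = fc / np.sqrt(se2)
    df = se2**2 / (
        (v1s / n1) ** 2 / (n1 - 1 + nu0) + (v2s / n2) ** 2 / (n2 - 1 + nu0)
    )
    p = 2 * stats.t.sf(np.abs(t), df)
    padj = multipletests(p, method="fdr_bh")[1]
    flag = (np.abs(fc) > fc_threshold) & (p < p_threshold)
    return pd.DataFrame(
        {"log2FC": fc, "t": t, "df": df, "p": p, "padj": padj, "significant": flag},
        index=proteome.index,
    )


# ---------------------------------------------------------------------------
# Spearman correlation with exact small-sample P


@lru_cache(maxsize=8)
def _exact_rho_null(n: int) -> np.ndarray:
    """Sorted |rho| values over all n! rank permutations (untied data)."""
    base = np.arange(1, n + 1)
    denom = n * (n * n - 1)
    rhos = []
    for perm in permutations(range(1, n + 1)):
        d2 = ((base - np.array(perm)) ** 2).sum()
        rhos.append(1 - 6 * d2 / denom)
    return np.sort(np.abs(np.array(rhos)))


def spearman_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho (average ranks for ties) with a two-sided P value.

    P comes from the t approximation ``t = rho * sqrt((n-2)/(1-rho^2))``;
    for n <= 9 with untied data the exact permutation null is used instead.
    |rho| = 1 is reported at the smallest representable P.
    """
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0 - 1e-12:
        log.debug("|rho| = 1: P reported as smallest representable")
        return math.copysign(1.0, rho), float(np.finfo(float).tiny)
    untied = len(np.unique(rx)) == n and len(np.unique(ry)) == n
    if n <= 9 and untied:
        null = _exact_rho_null(n)
        p = float((null >= abs(rho) - 1e-12).mean())
        return rho, p
    t = rho * math.sqrt((n - 2) / (1 - rho * rho))
    return rho, float(2 * stats.t.sf(abs(t), n - 2))


# ---------------------------------------------------------------------------
# association modules


@dataclass
class AssociationModule:
    """Signed correlated-protein sets of one delta radiomic feature."""

    feature: str
    members: pd.DataFrame = field(repr=False)  # protein-indexed: rho, p, weight

    @property
    def positive(self) -> pd.DataFrame:
        return self.members[self.members["rho"] > 0]

    @property
    def negative(self) -> pd.DataFrame:
        return self.members[self.members["rho"] < 0]

    @property
    def proteins(self) -> set[str]:
        return set(self.members.index)


def build_association_module(
    feature_values: pd.Series,
    proteome: pd.DataFrame,
    rho_min: float = RHO_MIN,
    p_max: float = P_MAX,
) -> AssociationModule:
    """Correlate one delta feature against every protein and threshold.

    Members satisfy |rho| >= 0.6 and P < 0.05 (two-sided application of the
    threshold); the deconvolution weight is ``sign(rho) * (-log10 P) * |rho|``
    (proteins ranked by log10 P and weighted by the correlation coefficient).
    Requires at least 5 samples shared between feature and proteome.
    """
    shared = [s for s in feature_values.index if s in proteome.columns]
    if len(shared) < 5:
        raise ValueError(f"only {len(shared)} shared samples; need >= 5")
    x = feature_values.loc[shared].to_numpy(dtype=float)
    rows = []
    for prot, series in proteome[shared].iterrows():
        rho, p = spearman_with_p(x, series.to_numpy(dtype=float))
        if abs(rho) >= rho_min and p < p_max:
            weight = math.copysign(1.0, rho) * (-math.log10(p)) * abs(rho)
            rows.append((prot, rho, p, weight))
    members = pd.DataFrame(rows, columns=["protein", "rho", "p", "weight"]).set_index(
        "protein"
    )
    return AssociationModule(feature=str(feature_values.name), members=members)


def build_modules(
    delta_table: pd.DataFrame, proteome: pd.DataFrame, features: list[str] | None = None, **kw
) -> dict[str, AssociationModule]:
    feats = features if features is not None else list(delta_table.columns)
    return {
        f: build_association_module(delta_table[f], proteome, **kw) for f in feats
    }


def association_weights(
    feature_values: pd.Series, proteome: pd.DataFrame
) -> pd.Series:
    """Unthresholded signed deconvolution weights for every protein."""
    shared = [s for s in feature_values.index if s in proteome.columns]
    if len(shared) < 5:
        raise ValueError(f"only {len(shared)} shared samples; need >= 5")
    x = feature_values.loc[shared].to_numpy(dtype=float)
    out = {}
    for prot, series in proteome[shared].iterrows():
        rho, p = spearman_with_p(x, series.to_numpy(dtype=float))
        out[prot] = math.copysign(1.0, rho) * (-math.log10(p)) * abs(rho) if rho else 0.0
    return pd.Series(out, name=feature_values.name)


# ---------------------------------------------------------------------------
# over-representation analysis


def ora_enrichment(
    member_set: set[str],
    background_set: set[str],
    collection: dict[str, set[str]],
    gene_ratio_min: float = GENE_RATIO_MIN,
    padj_max: float = PADJ_MAX,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query set in each gene set.

    GeneRatio is overlap / |member_set|; P values are BH-adjusted across the
    collection and terms are retained when GeneRatio >= 0.10 and
    adjusted P < 0.05.  An empty query yields an empty result.
    """
    member_set = set(member_set)
    background_set = set(background_set)
    if not member_set <= background_set:
        raise ValueError("member_set must be a subset of background_set")
    cols = ["term", "overlap", "term_size", "gene_ratio", "p", "padj", "retained"]
    if not member_set:
        return pd.DataFrame(columns=cols).set_index("term")
    n_bg = len(background_set)
    n_mem = len(member_set)
    rows = []
    for term, genes in collection.items():
        term_bg = genes & background_set
        k = len(genes & member_set)
        p = float(stats.hypergeom.sf(k - 1, n_bg, len(term_bg), n_mem))
        rows.append((term, k, len(term_bg), k / n_mem, p))
    df = pd.DataFrame(rows, columns=cols[:5]).set_index("term")
    df["padj"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    df["retained"] = (df["gene_ratio"] >= gene_ratio_min) & (df["padj"] < padj_max)
    return df


def terms_in_multiple_modules(
    results_by_module: dict[str, pd.DataFrame], min_modules: int = 2
) -> list[str]:
    """Display rule: terms retained in at least ``min_modules`` modules."""
    counts: dict[str, int] = {}
    for df in results_by_module.values():
        for term in df.index[df["retained"]]:
            counts[term] = counts.get(term, 0) + 1
    return sorted(t for t, c in counts.items() if c >= min_modules)


# ---------------------------------------------------------------------------
# cell-type signature deconvolution


def signature_deconvolution(
    weights: pd.Series,
    signatures: dict[str, set[str]] | pd.DataFrame,
    min_markers: int = 5,
    min_list: int = 50,
    alpha: float = KS_ALPHA,
) -> pd.DataFrame:
    """Weighted cell-type signature enrichment on a ranked protein list.

    Proteins are ordered by their signed association weight; for each
    signature the rank positions of its markers are compared with those of
    all other proteins by a two-sample Kolmogorov-Smirnov test.  The sign of
    the reported score is the direction of the members' median weight; the
    score itself is the signed -log10 P.  Signatures with fewer than
    ``min_markers`` markers present are skipped with a warning.
    """
    if isinstance(signatures, pd.DataFrame):
        signatures = {
            ct: set(sub["gene"]) for ct, sub in signatures.groupby("cell_type")
        }
    if len(weights) < min_list:
        raise ValueError(f"ranked list covers {len(weights)} proteins; need >= {min_list}")
    ordered = weights.sort_values(ascending=False)
    positions = pd.Series(np.arange(1, len(ordered) + 1), index=ordered.index)
    rows = []
    for name, markers in sorted(signatures.items()):
        present = [m for m in markers if m in positions.index]
        if len(present) < min_markers:
            log.warning("signature %s: only %d markers present, skipped", name, len(present))
            continue
        member_pos = positions.loc[present].to_numpy(dtype=float)
        other_pos = positions.drop(index=present).to_numpy(dtype=float)
        ks = stats.ks_2samp(member_pos, other_pos)
        sign = 1.0 if float(np.median(ordered.loc[present])) >= 0 else -1.0
        p = max(float(ks.pvalue), np.finfo(float).tiny)
        rows.append(
            (name, len(present), float(ks.statistic), p, sign, sign * (-math.log10(p)), p < alpha)
        )
    return pd.DataFrame(
        rows,
        columns=["cell_type", "n_markers", "ks_D", "p", "sign", "signed_log10p", "significant"],
    ).set_index("cell_type")
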