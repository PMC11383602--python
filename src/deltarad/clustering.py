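"""Unsupervised clustering with clusterability, model-selection and
stability diagnostics.

Feature tables are Z-scored per feature, clustered by agglomerative
hierarchical (Euclidean, Ward) or k-means (25 restarts), with the cluster
count chosen by the average silhouette over a scanned range.  Clusterability
is assessed by the Hopkins statistic and stability by bootstrap Jaccard
matching in the style of ``fpc::clusterboot``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

log = logging.getLogger(__name__)

DEFAULT_K_RANGE = (2, 8)
DEFAULT_B = 1000


@dataclass
class ClusterResult:
    method: str
    k: int
    labels: np.ndarray  # values in 1..k, one per subject
    subjects: list[str]
    hopkins: float | None = None
    silhouette_by_k: dict[int, float] = field(default_factory=dict)
    silhouette: float | None = None
    jaccard: dict[int, float] = field(default_factory=dict)  # per-cluster mean
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "k": self.k,
            "labels": dict(zip(self.subjects, (int(v) for v in self.labels))),
            "hopkins": self.hopkins,
            "silhouette_by_k": {int(k): v for k, v in self.silhouette_by_k.items()},
            "silhouette": self.silhouette,
            "jaccard": {int(c): v for c, v in self.jaccard.items()},
            "seed": self.seed,
        }


def zscore(table: pd.DataFrame) -> pd.DataFrame:
    """Column-wise standardization (mean 0, sd 1 with n-1 denominator);
    constant columns become zeros with a warning."""
    if len(table) < 2:
        raise ValueError("Z-scoring requires at least 2 subjects")
    sd = table.std(ddof=1)
    constant = sd == 0
    if constant.any():
        log.warning("%d constant features set to 0 by Z-scoring", int(constant.sum()))
    sd = sd.replace(0.0, 1.0)
    return (table - table.mean()) / sd


def hopkins(table: pd.DataFrame | np.ndarray, m_probe: int | None = None, seed: int = 0) -> float:
    """Hopkins clusterability statistic H = sum(u) / (sum(u) + sum(w)).

    ``u`` are nearest-neighbor distances from ``m_probe`` uniform pseudo-
    points in the data bounding box to the data; ``w`` are nearest-neighbor
    distances (self excluded) from ``m_probe`` sampled real points.
    H near 0.5 indicates unstructured data, near 1 strong clustering.
    """
    x = np.asarray(table, dtype=float)
    n = len(x)
    if m_probe is None:
        m_probe = max(1, n // 10)
    if not 1 <= m_probe < n:
        raise ValueError(f"m_probe must satisfy 1 <= m_probe < n, got {m_probe} vs n={n}")
    lo, hi = x.min(axis=0), x.max(axis=0)
    if np.allclose(lo, hi):
        raise ValueError("degenerate data: all points identical")
    rng = np.random.default_rng(seed)
    from scipy.spatial import cKDTree

    tree = cKDTree(x)
    uniform = rng.uniform(lo, hi, size=(m_probe, x.shape[1]))
    u = tree.query(uniform, k=1)[0]
    idx = rng.choice(n, size=m_probe, replace=False)
    w = tree.query(x[idx], k=2)[0][:, 1]  # first hit is the point itself
    return float(u.sum() / (u.sum() + w.sum()))


def cluster(
    table: pd.DataFrame | np.ndarray,
    method: str = "kmeans",
    k: int = 2,
    linkage_method: str = "ward",
    seed: int = 0,
) -> np.ndarray:
    """Cluster rows into k groups; labels are 1..k.

    Hierarchical uses Euclidean distance with the given linkage cut at k;
    k-means uses 25 random restarts with the best within-cluster sum of
    squares, deterministic per seed.
    """
    x = np.asarray(table, dtype=float)
    n = len(x)
    if n <= k:
        raise ValueError(f"need more subjects ({n}) than clusters ({k})")
    if method == "hierarchical":
        z = linkage(x, method=linkage_method, metric="euclidean")
        return fcluster(z, t=k, criterion="maxclust")
    if method == "kmeans":
        km = KMeans(n_clusters=k, n_init=25, random_state=seed)
        return km.fit_predict(x) + 1
    raise ValueError(f"unknown method {method!r}")


def silhouette_direct(x: np.ndarray, labels: np.ndarray) -> float:
    """Average silhouette width by the direct O(n^2) a(i)/b(i) formula."""
    x = np.asarray(x, dtype=float)
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))
    n = len(x)
    vals = []
    for i in range(n):
        same = (labels == labels[i]) & (np.arange(n) != i)
        if not same.any():
            vals.append(0.0)
            continue
        a = d[i, same].mean()
        b = min(
            d[i, labels == other].mean() for other in np.unique(labels) if other != labels[i]
        )
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))


def select_k_silhouette(
    table: pd.DataFrame | np.ndarray,
    method: str = "kmeans",
    k_range: tuple[int, int] = DEFAULT_K_RANGE,
    seed: int = 0,
) -> tuple[int, dict[int, float]]:
    """Choose k maximizing the average silhouette width (ties -> smallest k)."""
    x = np.asarray(table, dtype=float)
    n = len(x)
    k_lo, k_hi = k_range
    k_hi = min(k_hi, n - 1)
    if k_lo > k_hi:
        raise ValueError(f"empty k range for n={n}")
    scores: dict[int, float] = {}
    for k in range(k_lo, k_hi + 1):
        labels = cluster(x, method=method, k=k, seed=seed)
        if len(np.unique(labels)) < 2:
            scores[k] = -1.0
            continue
        scores[k] = float(silhouette_score(x, labels, metric="euclidean"))
    best = max(scores, key=lambda k: (scores[k], -k))
    return best, scores


def jaccard_bootstrap(
    table: pd.DataFrame | np.ndarray,
    method: str = "kmeans",
    k: int = 2,
    B: int = DEFAULT_B,
    seed: int = 0,
    index_sampler=None,
) -> dict[int, float]:
    """Per-cluster mean bootstrap Jaccard stability.

    Each resample (with replacement) is re-clustered with the same method
    and k; every original cluster — restricted to the subjects present in
    the resample — is matched to its maximum-Jaccard counterpart among the
    new clusters.  Resamples in which an original cluster has fewer than
    two members present (the cluster "dissolves") still contribute their
    achieved Jaccard.  ``index_sampler`` is a test hook yielding resample
    index arrays.
    """
    x = np.asarray(table, dtype=float)
    n = len(x)
    if n < 2 * k:
        raise ValueError(f"Jaccard bootstrap requires n >= 2k (n={n}, k={k})")
    rng = np.random.default_rng(seed)
    original = cluster(x, method=method, k=k, seed=seed)
    orig_sets = {c: set(np.flatnonzero(original == c)) for c in range(1, k + 1)}
    sums = {c: 0.0 for c in orig_sets}
    counts = {c: 0 for c in orig_sets}
    for b in range(B):
        idx = (
            next(index_sampler)
            if index_sampler is not None
            else rng.integers(0, n, size=n)
        )
        new_labels = cluster(x[idx], method=method, k=k, seed=seed + b + 1)
        new_sets: dict[int, set[int]] = {}
        for pos, lab in enumerate(new_labels):
            new_sets.setdefault(int(lab), set()).add(int(idx[pos]))
        sampled = set(int(i) for i in idx)
        for c, orig in orig_sets.items():
            present = orig & sampled
            if not present:
                continue  # cluster absent from this resample: no information
            best = max(
                (len(present & g) / len(present | g)) for g in new_sets.values()
            )
            sums[c] += best
            counts[c] += 1
    return {c: sums[c] / max(counts[c], 1) for c in sums}


def cluster_with_diagnostics(
    table: pd.DataFrame,
    method: str = "kmeans",
    k: int | None = None,
    k_range: tuple[int, int] = DEFAULT_K_RANGE,
    B: int = DEFAULT_B,
    seed: int = 0,
) -> ClusterResult:
    """Z-scored clustering with Hopkins, silhouette scan and Jaccard bootstrap."""
    z = zscore(table)
    x = z.to_numpy()
    h = hopkins(x, seed=seed)
    sil_by_k: dict[int, float] = {}
    if k is None:
        k, sil_by_k = select_k_silhouette(x, method=method, k_range=k_range, seed=seed)
    labels = cluster(x, method=method, k=k, seed=seed)
    sil = (
        float(silhouette_score(x, labels)) if len(np.unique(labels)) > 1 else float("nan")
    )
    if len(x) >= 2 * k:
        jac = jaccard_bootstrap(x, method=method, k=k, B=B, seed=seed)
    else:
        log.warning("n=%d too small for Jaccard bootstrap at k=%d; skipped", len(x), k)
        jac = {}
    return ClusterResult(
        method=method,
        k=k,
        labels=labels,
        subjects=[str(s) for s in table.index],
        hopkins=h,
        silhouette_by_k=sil_by_k,
        silhouette=sil,
        jaccard=jac,
        seed=seed,
    )
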