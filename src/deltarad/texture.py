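"""3D texture-matrix features on discretized volumes.

All families operate on a :class:`~deltarad.volumes.DiscretizedVolume`
(integer gray levels, 0 outside the mask):

* GLCM / mGLCM — symmetric co-occurrence over the 13 unique distance-1
  direction offsets; "m" (merged) sums the 13 direction matrices before
  normalization, the plain variant averages per-direction feature values.
* GLRLM / mGLRLM — run lengths along the same 13 directions, averaged or
  merged analogously.
* GLSZM — 26-connected same-level zones by size.
* GLDZM — the same zones by city-block distance to the ROI border.
* NGTDM — neighborhood (26-neighbor) gray-tone difference.
* NGLDM — neighborhood gray-level dependence (alpha = 0, i.e. neighbors
  counted as dependent when their level is identical).

Degenerate-input conventions (continuity limits, applied throughout):
entropy of a single-bin distribution is 0; correlation-type features with
zero gray-level variance are 0; the maximal correlation coefficient (MCC)
with fewer than two gray levels is 1.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from scipy import ndimage

from .volumes import DiscretizedVolume

#: 13 unique distance-1 offsets (first non-zero component positive)
DIRECTIONS: tuple[tuple[int, int, int], ...] = tuple(
    d for d in product((-1, 0, 1), repeat=3) if d > (0, 0, 0)
)
assert len(DIRECTIONS) == 13

#: all 26 neighbor offsets
NEIGHBOR_OFFSETS: tuple[tuple[int, int, int], ...] = tuple(
    d for d in product((-1, 0, 1), repeat=3) if d != (0, 0, 0)
)

_CONN26 = np.ones((3, 3, 3), dtype=np.int8)


def _pair_slices(d):
    """Slices (sa, sb) such that arr[sa] and arr[sb] are voxel pairs offset by d."""
    sa, sb = [], []
    for di in d:
        if di == 0:
            sa.append(slice(None))
            sb.append(slice(None))
        elif di > 0:
            sa.append(slice(None, -di))
            sb.append(slice(di, None))
        else:
            sa.append(slice(-di, None))
            sb.append(slice(None, di))
    return tuple(sa), tuple(sb)


# ---------------------------------------------------------------------------
# GLCM


def _memo(disc: DiscretizedVolume, key: str, fn):
    if key not in disc._cache:
        disc._cache[key] = fn()
    return disc._cache[key]


def glcm_matrices(disc: DiscretizedVolume) -> np.ndarray:
    """Per-direction symmetric co-occurrence count matrices, shape (13, Ng, Ng)."""
    return _memo(disc, "glcm", lambda: _glcm_matrices(disc))


def _glcm_matrices(disc: DiscretizedVolume) -> np.ndarray:
    ng = disc.n_bins
    lev = disc.levels
    out = np.zeros((len(DIRECTIONS), ng, ng), dtype=np.int64)
    for k, d in enumerate(DIRECTIONS):
        sa, sb = _pair_slices(d)
        a = lev[sa].ravel()
        b = lev[sb].ravel()
        valid = (a > 0) & (b > 0)
        idx = (a[valid] - 1) * ng + (b[valid] - 1)
        cnt = np.bincount(idx, minlength=ng * ng).reshape(ng, ng)
        out[k] = cnt + cnt.T  # symmetric: count each ordered pair both ways
    return out


def _glcm_features_from_counts(counts: np.ndarray) -> dict[str, float]:
    total = counts.sum()
    present = counts.sum(axis=1) > 0
    lv = np.flatnonzero(present) + 1.0
    if total == 0 or lv.size == 0:
        # no valid pairs: single-voxel/degenerate region conventions
        lv = np.array([1.0])
        p = np.array([[1.0]])
    else:
        p = counts[np.ix_(present, present)] / total

    i = lv[:, None]
    j = lv[None, :]
    px = p.sum(axis=1)
    mu = float((i * p).sum())
    var = float(((i - mu) ** 2 * p).sum())

    dmat = np.abs(i - j)
    smat = i + j

    nd = int(lv.max() - lv.min()) + 1
    pd = np.bincount((dmat.astype(int)).ravel() - 0, weights=p.ravel(), minlength=nd)
    dvals = np.arange(pd.size, dtype=float)
    smin = int(2 * lv.min())
    ps = np.bincount(
        (smat.astype(int) - smin).ravel(), weights=p.ravel()
    )
    svals = np.arange(ps.size, dtype=float) + smin

    def _ent(q):
        q = q[q > 0]
        return float(-(q * np.log2(q)).sum()) if q.size else 0.0

    diff_avg = float((dvals * pd).sum())
    sum_avg = float((svals * ps).sum())

    feats = {
        "joint_max": float(p.max()),
        "joint_avg": mu,
        "joint_var": var,
        "joint_entropy": _ent(p.ravel()),
        "diff_avg": diff_avg,
        "diff_var": float(((dvals - diff_avg) ** 2 * pd).sum()),
        "diff_entropy": _ent(pd),
        "sum_avg": sum_avg,
        "sum_var": float(((svals - sum_avg) ** 2 * ps).sum()),
        "sum_entropy": _ent(ps),
        "energy": float((p**2).sum()),
        "contrast": float(((i - j) ** 2 * p).sum()),
        "dissimilarity": float((dmat * p).sum()),
        "inv_diff": float((p / (1.0 + dmat)).sum()),
        "inv_diff_norm": float((p / (1.0 + dmat / lv.size)).sum()),
        "inv_diff_mom": float((p / (1.0 + dmat**2)).sum()),
        "inv_diff_mom_norm": float((p / (1.0 + (dmat / lv.size) ** 2)).sum()),
        "autocorrelation": float((i * j * p).sum()),
        "cluster_tendency": float(((i + j - 2 * mu) ** 2 * p).sum()),
        "cluster_shade": float(((i + j - 2 * mu) ** 3 * p).sum()),
        "cluster_prominence": float(((i + j - 2 * mu) ** 4 * p).sum()),
    }

    off = dmat > 0
    feats["inv_var"] = float((p[off] / dmat[off] ** 2).sum()) if off.any() else 0.0
    feats["correlation"] = (
        float(((i * j * p).sum() - mu * mu) / var) if var > 0 else 0.0
    )

    hxy = feats["joint_entropy"]
    hx = _ent(px)
    pxpy = px[:, None] * px[None, :]
    nz = (p > 0) & (pxpy > 0)
    hxy1 = float(-(p[nz] * np.log2(pxpy[nz])).sum())
    nz2 = pxpy > 0
    hxy2 = float(-(pxpy[nz2] * np.log2(pxpy[nz2])).sum())
    feats["info_corr1"] = (hxy - hxy1) / hx if hx > 0 else 0.0
    arg = 1.0 - np.exp(-2.0 * max(hxy2 - hxy, 0.0))
    feats["info_corr2"] = float(np.sqrt(max(arg, 0.0)))

    if lv.size < 2:
        feats["MCC"] = 1.0
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            a = p / px[:, None]
            b = p / px[None, :]
        a[~np.isfinite(a)] = 0.0
        b[~np.isfinite(b)] = 0.0
        q = a @ b.T  # Q_ij = sum_k p_ik p_jk / (px_i px_k)
        ev = np.sort(np.abs(np.linalg.eigvals(q)))
        feats["MCC"] = float(np.sqrt(np.clip(ev[-2], 0.0, 1.0)))
    return feats


def glcm_features(disc: DiscretizedVolume, mode: str = "averaged") -> dict[str, float]:
    """Co-occurrence features; ``mode`` 'averaged' (per-direction feature
    means) or 'merged' (direction matrices summed before normalization)."""
    if disc.n_voxels < 2:
        raise ValueError("GLCM requires at least 2 in-mask voxels")
    mats = glcm_matrices(disc)
    if mode == "merged":
        return _glcm_features_from_counts(mats.sum(axis=0))
    if mode != "averaged":
        raise ValueError(f"unknown GLCM mode {mode!r}")
    per_dir = [
        _glcm_features_from_counts(m) for m in mats if m.sum() > 0
    ]  # directions without valid pairs are skipped
    if not per_dir:
        return _glcm_features_from_counts(mats.sum(axis=0))
    return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}


# ---------------------------------------------------------------------------
# run / zone / dependence shared machinery

_CANONICAL = (
    "small",
    "large",
    "low_gray",
    "high_gray",
    "small_low",
    "small_high",
    "large_low",
    "large_high",
    "gnu",
    "gnu_norm",
    "jnu",
    "jnu_norm",
    "percentage",
    "g_var",
    "j_var",
    "entropy",
    "energy",
)


def _jmatrix_features(counts: np.ndarray, n_possible: float) -> dict[str, float]:
    """Canonical features of a (gray level x integer attribute) count matrix.

    Rows are gray levels 1..Ng, columns the attribute j = 1..Nj (run length,
    zone size, zone distance, or dependence count).  ``n_possible`` is the
    denominator of the percentage feature (voxels that could form entries).
    """
    n = counts.sum()
    if n == 0:
        return {k: 0.0 for k in _CANONICAL}
    ng, nj = counts.shape
    i = np.arange(1, ng + 1, dtype=float)
    j = np.arange(1, nj + 1, dtype=float)
    si = counts.sum(axis=1).astype(float)
    sj = counts.sum(axis=0).astype(float)
    p = counts / n
    pi = si / n
    pj = sj / n
    mu_i = float((i * pi).sum())
    mu_j = float((j * pj).sum())
    pz = p[p > 0]
    cross = counts / n
    ii = i[:, None]
    jj = j[None, :]
    return {
        "small": float((pj / j**2).sum()),
        "large": float((pj * j**2).sum()),
        "low_gray": float((pi / i**2).sum()),
        "high_gray": float((pi * i**2).sum()),
        "small_low": float((cross / (ii**2 * jj**2)).sum()),
        "small_high": float((cross * ii**2 / jj**2).sum()),
        "large_low": float((cross * jj**2 / ii**2).sum()),
        "large_high": float((cross * ii**2 * jj**2).sum()),
        "gnu": float((si**2).sum() / n),
        "gnu_norm": float((si**2).sum() / n**2),
        "jnu": float((sj**2).sum() / n),
        "jnu_norm": float((sj**2).sum() / n**2),
        "percentage": float(n / n_possible) if n_possible > 0 else 0.0,
        "g_var": float((p * (ii - mu_i) ** 2).sum()),
        "j_var": float((p * (jj - mu_j) ** 2).sum()),
        "entropy": float(-(pz * np.log2(pz)).sum()),
        "energy": float((p**2).sum()),
    }


_GLRLM_KEYS = (
    "small", "large", "low_gray", "high_gray", "small_low", "small_high",
    "large_low", "large_high", "gnu", "gnu_norm", "jnu", "jnu_norm",
    "percentage", "g_var", "j_var", "entropy",
)

_NGLDM_KEYS = (
    "small", "large", "low_gray", "high_gray", "small_low", "small_high",
    "large_low", "large_high", "gnu", "gnu_norm", "jnu", "jnu_norm",
    "g_var", "j_var", "entropy", "energy",
)


def _map_names(canon: dict[str, float], names, keys) -> dict[str, float]:
    return {name: canon[key] for name, key in zip(names, keys)}


# ---------------------------------------------------------------------------
# GLRLM

_LINE_ORDER_CACHE: dict = {}


def _line_order(shape, d):
    """Sorted traversal order grouping voxels into lines along direction d."""
    key = (shape, d)
    cached = _LINE_ORDER_CACHE.get(key)
    if cached is not None:
        return cached
    idx = np.indices(shape).reshape(3, -1)
    a0 = next(a for a in range(3) if d[a] != 0)
    t = d[a0] * idx[a0]  # line parameter: advances by 1 per step along d
    line = [idx[a] - t * d[a] for a in range(3)]
    order = np.lexsort((t, line[2], line[1], line[0]))
    k = np.stack(line)[:, order]
    newline = np.any(k[:, 1:] != k[:, :-1], axis=0)
    _LINE_ORDER_CACHE[key] = (order, newline)
    return order, newline


def glrlm_matrices(disc: DiscretizedVolume) -> list[np.ndarray]:
    """Run-length count matrices (Ng x Lmax) for each of the 13 directions."""
    return _memo(disc, "glrlm", lambda: _glrlm_matrices(disc))


def _glrlm_matrices(disc: DiscretizedVolume) -> list[np.ndarray]:
    ng = disc.n_bins
    lmax = max(disc.levels.shape)
    flat = disc.levels.ravel()
    out = []
    for d in DIRECTIONS:
        order, newline = _line_order(disc.levels.shape, d)
        lv = flat[order]
        change = np.empty(lv.size, dtype=bool)
        change[0] = True
        change[1:] = newline | (lv[1:] != lv[:-1])
        starts = np.flatnonzero(change)
        lengths = np.diff(np.append(starts, lv.size))
        vals = lv[starts]
        keep = vals > 0
        m = np.bincount(
            (vals[keep] - 1) * lmax + (lengths[keep] - 1), minlength=ng * lmax
        ).reshape(ng, lmax)
        out.append(m)
    return out


def glrlm_features(disc: DiscretizedVolume, mode: str = "averaged") -> dict[str, float]:
    from .catalog import GLRLM_FEATURES

    mats = glrlm_matrices(disc)
    nvox = disc.n_voxels
    if mode == "merged":
        canon = _jmatrix_features(np.sum(mats, axis=0), nvox * len(mats))
        return _map_names(canon, GLRLM_FEATURES, _GLRLM_KEYS)
    if mode != "averaged":
        raise ValueError(f"unknown GLRLM mode {mode!r}")
    per_dir = [_jmatrix_features(m, nvox) for m in mats]
    return {
        name: float(np.mean([_map_names(f, GLRLM_FEATURES, _GLRLM_KEYS)[name] for f in per_dir]))
        for name in GLRLM_FEATURES
    }


# ---------------------------------------------------------------------------
# zones (GLSZM / GLDZM)


def zone_table(disc: DiscretizedVolume) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """26-connected same-level zones: (level, size, border distance) per zone.

    Border distance is the minimum city-block distance of any zone voxel to
    the ROI edge (voxels on the edge have distance 1); the lattice boundary
    counts as edge.
    """
    return _memo(disc, "zones", lambda: _zone_table(disc))


def _zone_table(disc: DiscretizedVolume) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    lev = disc.levels
    padded = np.pad(disc.mask, 1)
    dist = ndimage.distance_transform_cdt(padded, metric="taxicab")[1:-1, 1:-1, 1:-1]
    levels_out, sizes_out, dists_out = [], [], []
    for g in np.unique(lev[disc.mask]):
        where = lev == g
        idx = np.argwhere(where)
        lo = np.maximum(idx.min(axis=0) - 1, 0)
        hi = np.minimum(idx.max(axis=0) + 2, lev.shape)
        sl = tuple(slice(a, b) for a, b in zip(lo, hi))
        lab, nlab = ndimage.label(where[sl], structure=_CONN26)
        if nlab == 0:
            continue
        zone_ids = lab[where[sl]]  # 1..nlab, one entry per voxel of level g
        sizes = np.bincount(zone_ids, minlength=nlab + 1)[1:]
        dmin = np.full(nlab + 1, np.iinfo(np.int64).max)
        np.minimum.at(dmin, zone_ids, dist[sl][where[sl]])
        levels_out.append(np.full(nlab, g))
        sizes_out.append(sizes)
        dists_out.append(dmin[1:])
    return (
        np.concatenate(levels_out),
        np.concatenate(sizes_out),
        np.concatenate(dists_out).astype(int),
    )


def glszm_matrix(disc: DiscretizedVolume) -> np.ndarray:
    levels, sizes, _ = zone_table(disc)
    ng = disc.n_bins
    smax = int(sizes.max())
    return np.bincount(
        (levels - 1) * smax + (sizes - 1), minlength=ng * smax
    ).reshape(ng, smax)


def gldzm_matrix(disc: DiscretizedVolume) -> np.ndarray:
    levels, _, dists = zone_table(disc)
    ng = disc.n_bins
    dmax = int(dists.max())
    return np.bincount(
        (levels - 1) * dmax + (dists - 1), minlength=ng * dmax
    ).reshape(ng, dmax)


def glszm_features(disc: DiscretizedVolume) -> dict[str, float]:
    from .catalog import GLSZM_FEATURES

    canon = _jmatrix_features(glszm_matrix(disc), disc.n_voxels)
    return _map_names(canon, GLSZM_FEATURES, _GLRLM_KEYS)


def gldzm_features(disc: DiscretizedVolume) -> dict[str, float]:
    from .catalog import GLDZM_FEATURES

    canon = _jmatrix_features(gldzm_matrix(disc), disc.n_voxels)
    return _map_names(canon, GLDZM_FEATURES, _GLRLM_KEYS)


# ---------------------------------------------------------------------------
# neighborhood families (NGTDM / NGLDM)


def _neighbor_stats(disc: DiscretizedVolume):
    """Per-voxel neighbor sum, neighbor count, and same-level neighbor count
    over the in-mask 26-neighborhood."""
    return _memo(disc, "neighbors", lambda: _neighbor_stats_impl(disc))


def _neighbor_stats_impl(disc: DiscretizedVolume):
    lev = disc.levels
    inm = disc.mask
    levf = lev.astype(np.float64) * inm
    nb_sum = np.zeros_like(levf)
    nb_cnt = np.zeros(lev.shape, dtype=np.int32)
    eq_cnt = np.zeros(lev.shape, dtype=np.int32)
    for d in NEIGHBOR_OFFSETS:
        sa, sb = _pair_slices(d)
        nb_sum[sa] += levf[sb]
        nb_cnt[sa] += inm[sb]
        eq_cnt[sa] += (lev[sa] == lev[sb]) & inm[sb]
    eq_cnt *= inm  # only defined for in-mask voxels
    return nb_sum, nb_cnt, eq_cnt


def ngtdm_table(disc: DiscretizedVolume) -> tuple[np.ndarray, np.ndarray, int]:
    """NGTDM (n_i, s_i) per gray level and the count of contributing voxels."""
    nb_sum, nb_cnt, _ = _neighbor_stats(disc)
    valid = disc.mask & (nb_cnt > 0)
    lev = disc.levels[valid]
    avg = nb_sum[valid] / nb_cnt[valid]
    diff = np.abs(lev - avg)
    ng = disc.n_bins
    n_i = np.bincount(lev - 1, minlength=ng).astype(float)
    s_i = np.bincount(lev - 1, weights=diff, minlength=ng)
    return n_i, s_i, int(valid.sum())


def ngtdm_features(disc: DiscretizedVolume) -> dict[str, float]:
    n_i, s_i, n = ngtdm_table(disc)
    if n == 0:
        return {k: 0.0 for k in ("coarseness", "contrast", "busyness", "complexity", "strength")}
    p = n_i / n
    i = np.arange(1, p.size + 1, dtype=float)
    present = p > 0
    ngp = int(present.sum())
    ps, iv, sv = p[present], i[present], s_i[present]

    dens = float((p * s_i).sum())
    coarseness = 1.0 / dens if dens > 0 else 1e6

    if ngp < 2:
        contrast = 0.0
    else:
        contrast = (
            float((ps[:, None] * ps[None, :] * (iv[:, None] - iv[None, :]) ** 2).sum())
            / (ngp * (ngp - 1))
        ) * (float(s_i.sum()) / n)

    ipi = iv * ps
    denom = float(np.abs(ipi[:, None] - ipi[None, :]).sum())
    busyness = dens / denom if denom > 0 else 0.0

    pssum = ps[:, None] + ps[None, :]
    num = np.abs(iv[:, None] - iv[None, :]) * (
        (ps * sv)[:, None] + (ps * sv)[None, :]
    )
    complexity = float((num / pssum).sum()) / n

    stot = float(s_i.sum())
    strength = (
        float((pssum * (iv[:, None] - iv[None, :]) ** 2).sum()) / stot
        if stot > 0
        else 0.0
    )
    return {
        "coarseness": coarseness,
        "contrast": contrast,
        "busyness": busyness,
        "complexity": complexity,
        "strength": strength,
    }


def ngldm_matrix(disc: DiscretizedVolume) -> np.ndarray:
    """Dependence-count matrix s(i, k+1), k = same-level in-mask neighbors."""
    _, _, eq_cnt = _neighbor_stats(disc)
    lev = disc.levels[disc.mask]
    k = eq_cnt[disc.mask]
    ng = disc.n_bins
    nj = 27  # 26 neighbors max -> dependence count column k+1 in 1..27
    return np.bincount((lev - 1) * nj + k, minlength=ng * nj).reshape(ng, nj)


def ngldm_features(disc: DiscretizedVolume) -> dict[str, float]:
    from .catalog import NGLDM_FEATURES

    canon = _jmatrix_features(ngldm_matrix(disc), disc.n_voxels)
    return _map_names(canon, NGLDM_FEATURES, _NGLDM_KEYS)
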