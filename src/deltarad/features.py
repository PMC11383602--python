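"""Per-scan radiomic feature extraction.

``extract_all`` turns a resampled, calibrated volume/mask pair into the
1,388-value feature vector defined by :mod:`deltarad.catalog`: first-order
(histogram) statistics and eight texture families on the original volume,
two shape features, and histogram+texture on each of the 8 undecimated
single-level wavelet subbands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import texture
from .catalog import FEATURE_NAMES, TEXTURE_FAMILIES
from .volumes import (
    DiscretizedVolume,
    SegmentationMask,
    VolumeGrid,
    discretize,
    discretize_adaptive,
)

log = logging.getLogger(__name__)

#: Haar analysis pair (undecimated): L averages, H differences; an H response
#: is exactly zero on constants.
HAAR_LOW = (0.5, 0.5)
HAAR_HIGH = (0.5, -0.5)


# ---------------------------------------------------------------------------
# first-order (histogram) features


def histogram_features(
    intensities: np.ndarray, bin_levels: np.ndarray | None = None
) -> dict[str, float]:
    """The 17 first-order statistics of the in-mask intensities.

    ``bin_levels`` are the discretized gray levels of the same voxels; the
    two histogram-probability features (entropy, uniformity) are computed on
    that discrete distribution.  A constant region has variance 0, entropy 0
    and uniformity 1.
    """
    x = np.asarray(intensities, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("histogram features require at least one value")
    mu = float(x.mean())
    var = float(x.var())  # population variance
    sd = np.sqrt(var)
    cent = x - mu
    skew = float((cent**3).mean() / sd**3) if sd > 0 else 0.0
    kurt = float((cent**4).mean() / sd**4) if sd > 0 else 0.0
    p10, q1, med, q3, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    mid = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(mid - mid.mean()).mean()) if mid.size else 0.0
    if bin_levels is None:
        bin_levels = np.ones_like(x, dtype=np.int64)
    counts = np.bincount(np.asarray(bin_levels, dtype=np.int64))
    prob = counts[counts > 0] / counts.sum()
    return {
        "mean": mu,
        "variance": var,
        "skewness": skew,
        "kurtosis": kurt,
        "median": float(med),
        "minimum": float(x.min()),
        "p10": float(p10),
        "p90": float(p90),
        "maximum": float(x.max()),
        "iqr": float(q3 - q1),
        "range": float(x.max() - x.min()),
        "mad": float(np.abs(cent).mean()),
        "rmad": rmad,
        "energy": float((x**2).sum()),
        "rms": float(np.sqrt((x**2).mean())),
        "entropy": float(-(prob * np.log2(prob)).sum()),
        "uniformity": float((prob**2).sum()),
    }


# ---------------------------------------------------------------------------
# shape


def shape_features(mask: SegmentationMask) -> dict[str, float]:
    """Mesh-free shape descriptors: voxel volume (mm^3) and the exposed
    voxel-face surface area (mm^2)."""
    m = mask.values
    if not m.any():
        raise ValueError("shape features require a non-empty mask")
    sx, sy, sz = mask.spacing
    voxvol = sx * sy * sz
    face_areas = (sy * sz, sx * sz, sx * sy)
    surface = 0.0
    for axis, area in enumerate(face_areas):
        padded = np.pad(m, [(1, 1) if a == axis else (0, 0) for a in range(3)])
        diff = np.diff(padded.astype(np.int8), axis=axis)
        surface += np.abs(diff).sum() * area
    return {
        "volume_mm3": float(m.sum() * voxvol),
        "surface_mm2": float(surface),
    }


# ---------------------------------------------------------------------------
# wavelet subbands


def wavelet_subbands(
    vol: VolumeGrid,
    low: tuple[float, ...] = HAAR_LOW,
    high: tuple[float, ...] = HAAR_HIGH,
) -> dict[str, np.ndarray]:
    """Single-level undecimated separable 3D wavelet decomposition.

    Returns the 8 subbands keyed LLL..HHH; letter *i* of the label selects
    the low- or high-pass kernel applied along array axis *i*.  Boundaries
    are handled symmetrically; each subband has the lattice of the input.
    """
    if any(s < len(low) for s in vol.shape):
        raise ValueError(f"volume {vol.shape} smaller than filter support {len(low)}")
    kernels = {"L": np.asarray(low, dtype=np.float64), "H": np.asarray(high, dtype=np.float64)}
    out = {}
    # factor per-axis passes: compute L/H along axis 0 once, reuse for all labels
    stage0 = {c: ndimage.correlate1d(vol.values, kernels[c], axis=0, mode="reflect") for c in "LH"}
    for c0 in "LH":
        stage1 = {
            c: ndimage.correlate1d(stage0[c0], kernels[c], axis=1, mode="reflect")
            for c in "LH"
        }
        for c1 in "LH":
            for c2 in "LH":
                out[c0 + c1 + c2] = ndimage.correlate1d(
                    stage1[c1], kernels[c2], axis=2, mode="reflect"
                )
    return out


# ---------------------------------------------------------------------------
# full extraction


@dataclass
class FeatureVector:
    """One scan's 1,388 named feature values."""

    subject_id: str
    timepoint: str
    values: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if tuple(self.values.index) != FEATURE_NAMES:
            raise ValueError("feature vector does not match the catalog")


_FAMILY_FUNCS = {
    "GLCM": lambda d: texture.glcm_features(d, "averaged"),
    "mGLCM": lambda d: texture.glcm_features(d, "merged"),
    "GLRLM": lambda d: texture.glrlm_features(d, "averaged"),
    "mGLRLM": lambda d: texture.glrlm_features(d, "merged"),
    "GLSZM": texture.glszm_features,
    "GLDZM": texture.gldzm_features,
    "NGTDM": texture.ngtdm_features,
    "NGLDM": texture.ngldm_features,
}


def _scan_block_values(disc: DiscretizedVolume, raw_in_mask: np.ndarray, prefix: str) -> dict[str, float]:
    out = {}
    hist = histogram_features(raw_in_mask, disc.in_mask_levels)
    out.update({f"{prefix}hist_{k}": v for k, v in hist.items()})
    for fam, feats in TEXTURE_FAMILIES.items():
        vals = _FAMILY_FUNCS[fam](disc)
        out.update({f"{prefix}{fam}_{k}": vals[k] for k in feats})
    return out


def _crop_to_mask(vol: VolumeGrid, mask: SegmentationMask, margin: int = 1):
    """Bounding-box crop around the mask (texture features are unaffected)."""
    idx = np.argwhere(mask.values)
    lo = np.maximum(idx.min(axis=0) - margin, 0)
    hi = np.minimum(idx.max(axis=0) + margin + 1, mask.values.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    v = VolumeGrid(vol.values[sl], vol.spacing, vol.origin)
    m = SegmentationMask(mask.values[sl], mask.spacing, mask.origin)
    return v, m


def extract_all(
    vol: VolumeGrid,
    mask: SegmentationMask,
    subject_id: str = "",
    timepoint: str = "",
    bin_size: float = 50.0,
    hu_range: tuple[float, float] = (-1000.0, 200.0),
    wavelet_low: tuple[float, ...] = HAAR_LOW,
    wavelet_high: tuple[float, ...] = HAAR_HIGH,
) -> FeatureVector:
    """Compute the full 1,388-feature vector for one resampled, calibrated scan.

    The original volume is discretized with the fixed HU bin configuration;
    each wavelet subband is re-discretized with the same bin count over its
    own in-mask range (the HU window is meaningless after high-pass
    filtering).  Non-finite values are replaced by 0 and logged.
    """
    vol, mask = _crop_to_mask(vol, mask)
    disc = discretize(vol, mask, bin_size=bin_size, hu_range=hu_range)
    raw = vol.values[mask.values]

    values = _scan_block_values(disc, raw, "")
    values.update({f"shape_{k}": v for k, v in shape_features(mask).items()})

    n_bins = disc.n_bins
    for label, band in wavelet_subbands(vol, wavelet_low, wavelet_high).items():
        band_disc = discretize_adaptive(band, mask.values, n_bins=n_bins, spacing=vol.spacing)
        values.update(_scan_block_values(band_disc, band[mask.values], f"{label}_"))

    series = pd.Series(values, dtype=np.float64).reindex(list(FEATURE_NAMES))
    bad = ~np.isfinite(series.to_numpy())
    if bad.any():
        log.warning(
            "%s/%s: %d non-finite feature values replaced by 0 (%s...)",
            subject_id,
            timepoint,
            int(bad.sum()),
            series.index[bad][:3].tolist(),
        )
        series[bad] = 0.0
    return FeatureVector(subject_id=subject_id, timepoint=timepoint, values=series)
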