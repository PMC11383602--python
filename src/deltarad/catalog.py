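"""The versioned radiomic feature catalog.

The per-scan feature vector holds 1,388 features: 17 first-order (histogram)
statistics, 137 texture features across eight 3D matrix families, 2 shape
features on the original volume, and the 154 histogram+texture features
replicated on each of the 8 single-level wavelet subbands (LLL..HHH), i.e.
17 + 137 + 2 + 8*154 = 1,388.

The texture-family composition is fixed here as the normative manifest:

====== ==== =========================================================
family   n  definition
====== ==== =========================================================
GLCM    26  gray-level co-occurrence, per-direction features averaged
mGLCM   26  co-occurrence matrices merged over directions, then features
GLRLM   16  gray-level run length, per-direction features averaged
mGLRLM  16  run-length matrices merged over directions
GLSZM   16  gray-level size zone (26-connected zones)
GLDZM   16  gray-level distance zone (zone distance to ROI border)
NGTDM    5  neighborhood gray tone difference
NGLDM   16  neighborhood gray level dependence (26-neighborhood, alpha=0)
====== ==== =========================================================

Feature names are ``<family>_<feature>`` for original-volume texture
features, ``hist_<feature>`` for first-order statistics, ``shape_<feature>``
for shape, and ``<subband>_<family>_<feature>`` for wavelet features
(e.g. ``LLH_GLSZM_GLnonuniformity_norm``, ``LHL_mGLCM_MCC``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import product

CATALOG_VERSION = "1.0"

HIST_FEATURES = (
    "mean",
    "variance",
    "skewness",
    "kurtosis",
    "median",
    "minimum",
    "p10",
    "p90",
    "maximum",
    "iqr",
    "range",
    "mad",
    "rmad",
    "energy",
    "rms",
    "entropy",
    "uniformity",
)

GLCM_FEATURES = (
    "joint_max",
    "joint_avg",
    "joint_var",
    "joint_entropy",
    "diff_avg",
    "diff_var",
    "diff_entropy",
    "sum_avg",
    "sum_var",
    "sum_entropy",
    "energy",
    "contrast",
    "dissimilarity",
    "inv_diff",
    "inv_diff_norm",
    "inv_diff_mom",
    "inv_diff_mom_norm",
    "inv_var",
    "correlation",
    "autocorrelation",
    "cluster_tendency",
    "cluster_shade",
    "cluster_prominence",
    "info_corr1",
    "info_corr2",
    "MCC",
)

GLRLM_FEATURES = (
    "SRE",
    "LRE",
    "LGLRE",
    "HGLRE",
    "SRLGLE",
    "SRHGLE",
    "LRLGLE",
    "LRHGLE",
    "GLnonuniformity",
    "GLnonuniformity_norm",
    "RLnonuniformity",
    "RLnonuniformity_norm",
    "run_percentage",
    "GL_var",
    "RL_var",
    "run_entropy",
)

GLSZM_FEATURES = (
    "SZE",
    "LZE",
    "LGLZE",
    "HGLZE",
    "SZLGLE",
    "SZHGLE",
    "LZLGLE",
    "LZHGLE",
    "GLnonuniformity",
    "GLnonuniformity_norm",
    "ZSnonuniformity",
    "ZSnonuniformity_norm",
    "zone_percentage",
    "GL_var",
    "ZS_var",
    "zone_entropy",
)

GLDZM_FEATURES = (
    "SDE",
    "LDE",
    "LGLE",
    "HGLE",
    "SDLGLE",
    "SDHGLE",
    "LDLGLE",
    "LDHGLE",
    "GLnonuniformity",
    "GLnonuniformity_norm",
    "ZDnonuniformity",
    "ZDnonuniformity_norm",
    "zone_percentage",
    "GL_var",
    "ZD_var",
    "ZD_entropy",
)

NGTDM_FEATURES = ("coarseness", "contrast", "busyness", "complexity", "strength")

NGLDM_FEATURES = (
    "LDE",
    "HDE",
    "LGLCE",
    "HGLCE",
    "LDLGLE",
    "LDHGLE",
    "HDLGLE",
    "HDHGLE",
    "GLnonuniformity",
    "GLnonuniformity_norm",
    "DCnonuniformity",
    "DCnonuniformity_norm",
    "GL_var",
    "DC_var",
    "DC_entropy",
    "DC_energy",
)

SHAPE_FEATURES = ("volume_mm3", "surface_mm2")

#: texture families in catalog order with their feature tuples
TEXTURE_FAMILIES: dict[str, tuple[str, ...]] = {
    "GLCM": GLCM_FEATURES,
    "mGLCM": GLCM_FEATURES,
    "GLRLM": GLRLM_FEATURES,
    "mGLRLM": GLRLM_FEATURES,
    "GLSZM": GLSZM_FEATURES,
    "GLDZM": GLDZM_FEATURES,
    "NGTDM": NGTDM_FEATURES,
    "NGLDM": NGLDM_FEATURES,
}

#: wavelet subband labels; letter i gives the filter (L low / H high) on axis i
SUBBANDS = tuple("".join(c) for c in product("LH", repeat=3))  # LLL..HHH


@dataclass(frozen=True)
class FeatureDescriptor:
    name: str
    feature_class: str  # histogram | texture | shape
    family: str  # HIST | GLCM | mGLCM | ... | SHAPE
    subband: str  # "none" or LLL..HHH
    base: str  # feature name within its family


def _scan_block(subband: str) -> list[FeatureDescriptor]:
    prefix = "" if subband == "none" else f"{subband}_"
    out = [
        FeatureDescriptor(f"{prefix}hist_{f}", "histogram", "HIST", subband, f)
        for f in HIST_FEATURES
    ]
    for fam, feats in TEXTURE_FAMILIES.items():
        out.extend(
            FeatureDescriptor(f"{prefix}{fam}_{f}", "texture", fam, subband, f)
            for f in feats
        )
    return out


def build_catalog() -> tuple[FeatureDescriptor, ...]:
    """Build the ordered 1,388-feature catalog and assert its arithmetic."""
    descriptors = _scan_block("none")
    descriptors += [
        FeatureDescriptor(f"shape_{f}", "shape", "SHAPE", "none", f)
        for f in SHAPE_FEATURES
    ]
    for sb in SUBBANDS:
        descriptors += _scan_block(sb)

    n_hist = sum(1 for d in descriptors if d.feature_class == "histogram" and d.subband == "none")
    n_tex = sum(1 for d in descriptors if d.feature_class == "texture" and d.subband == "none")
    n_shape = sum(1 for d in descriptors if d.feature_class == "shape")
    n_wav = sum(1 for d in descriptors if d.subband != "none")
    assert n_hist == 17, n_hist
    assert n_tex == 137, n_tex
    assert n_shape == 2, n_shape
    assert n_wav == 8 * 154 == 1232, n_wav
    assert len(descriptors) == 17 + 137 + 2 + 8 * 154 == 1388
    names = [d.name for d in descriptors]
    assert len(set(names)) == len(names), "duplicate feature names"
    return tuple(descriptors)


CATALOG: tuple[FeatureDescriptor, ...] = build_catalog()
FEATURE_NAMES: tuple[str, ...] = tuple(d.name for d in CATALOG)


def class_counts() -> dict[str, int]:
    """Feature counts by class: histogram/texture/shape on the original
    volume plus the wavelet-tagged replicates."""
    return {
        "histogram": sum(
            1 for d in CATALOG if d.feature_class == "histogram" and d.subband == "none"
        ),
        "texture": sum(
            1 for d in CATALOG if d.feature_class == "texture" and d.subband == "none"
        ),
        "shape": sum(1 for d in CATALOG if d.feature_class == "shape"),
        "wavelet": sum(1 for d in CATALOG if d.subband != "none"),
        "total": len(CATALOG),
    }


def manifest() -> dict:
    """JSON-serializable catalog manifest (the normative feature list)."""
    return {
        "version": CATALOG_VERSION,
        "counts": class_counts(),
        "features": [
            {
                "name": d.name,
                "class": d.feature_class,
                "family": d.family,
                "subband": d.subband,
                "feature": d.base,
            }
            for d in CATALOG
        ],
    }


def write_manifest(path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest(), fh, indent=1)
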