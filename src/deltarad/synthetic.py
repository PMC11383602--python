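"""Synthetic study inputs with the statistical structure the pipeline assumes.

The generator emulates a paired pre/post-treatment micro-CT experiment in a
fibrosis model: each subject carries a "lung" (ellipsoidal ROI) of noisy
parenchyma plus dense textured lesions.  Between time points, responders
lose most of the lesion density and texture contrast while non-responders
progress slightly, so delta radiomic profiles form two planted response
clusters.  Proteomes are coupled to realized delta-feature values through a
Gaussian copula (exact rank-correlation control), marker tables satisfy the
log2FC > 0.3 / adjusted P < 0.05 signature definition, and cohort lung
function (FVC) trajectories are drawn per planted cluster.

Everything is deterministic per seed: identical spec + seed reproduces
bit-identical arrays and tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .volumes import HU_MAX, HU_MIN, SegmentationMask, VolumeGrid

log = logging.getLogger(__name__)

RESPONDER = "responder"
NONRESPONDER = "nonresponder"

#: post/pre multiplier of lesion density and texture amplitude per class
RESPONSE_EFFECTS = {RESPONDER: 0.25, NONRESPONDER: 1.1}


@dataclass
class PhantomSpec:
    """Parameters of one subject's paired pre/post phantom.

    Defaults describe the study conditions used throughout: a 64^3 lattice
    at 0.15 mm isotropic spacing (desk-scale while giving the texture
    matrices ample support), air background, emphysematous-to-normal
    parenchyma around -650 HU, and a handful of dense lesions whose
    intra-lesion texture is spatially correlated noise.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_spacing: float = 0.15  # mm, isotropic
    background_HU: float = -1000.0
    parenchyma_HU_mean: float = -650.0
    parenchyma_HU_sd: float = 60.0
    lesion_count: int = 5
    lesion_radius_range: tuple[float, float] = (0.9, 1.8)  # mm
    lesion_HU_shift: float = 420.0
    lesion_texture_sd: float = 120.0
    lesion_texture_scale: float = 0.45  # mm correlation length of lesion noise
    acquisition_noise_sd: float = 12.0
    response_class: str = RESPONDER
    seed: int = 0

    def validate(self) -> None:
        if self.response_class not in (RESPONDER, NONRESPONDER):
            raise ValueError(f"unknown response_class {self.response_class!r}")
        if self.lesion_count < 0:
            raise ValueError("lesion_count must be >= 0")
        if self.lesion_radius_range[0] > self.lesion_radius_range[1]:
            raise ValueError("lesion_radius_range must be (low, high)")
        for v in (self.background_HU, self.parenchyma_HU_mean):
            if not HU_MIN <= v <= HU_MAX:
                raise ValueError(f"HU value {v} outside [{HU_MIN}, {HU_MAX}]")


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generator, for test assertions."""

    response_class: dict[str, str] = field(default_factory=dict)
    planted_correlations: list[dict] = field(default_factory=list)  # feature/protein/rho
    marker_membership: dict[str, list[str]] = field(default_factory=dict)
    fvc_slopes: dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def _ellipsoid_mask(shape, axes_frac=(0.42, 0.40, 0.44)) -> np.ndarray:
    grids = np.indices(shape).astype(np.float64)
    c = [(s - 1) / 2 for s in shape]
    r = [f * s for f, s in zip(axes_frac, shape)]
    d2 = sum(((g - ci) / ri) ** 2 for g, ci, ri in zip(grids, c, r))
    return d2 <= 1.0


def _correlated_noise(rng, shape, sigma_vox, sd):
    """Gaussian-filtered white noise rescaled to unit-free sd."""
    white = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="nearest")
    s = smooth.std()
    return smooth * (sd / s) if s > 0 else smooth


def make_phantom_pair(
    spec: PhantomSpec,
) -> tuple[VolumeGrid, VolumeGrid, SegmentationMask]:
    """Generate the pre/post volume pair and their shared lung mask.

    Responders reduce lesion HU shift and texture amplitude at the second
    time point; non-responders keep or slightly increase them.  The lesion
    geometry and the parenchyma field are shared between time points so the
    delta signal is lesion-driven; per-time-point acquisition noise is
    independent.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.grid_shape)
    sp = float(spec.voxel_spacing)
    mask_arr = _ellipsoid_mask(shape)

    parenchyma = spec.parenchyma_HU_mean + _correlated_noise(
        rng, shape, sigma_vox=1.0, sd=spec.parenchyma_HU_sd
    )
    base = np.where(mask_arr, parenchyma, spec.background_HU)

    # lesion placement: centers strictly inside an eroded mask
    interior = ndimage.binary_erosion(mask_arr, iterations=3)
    coords = np.argwhere(interior)
    if spec.lesion_count > 0 and coords.size == 0:
        raise ValueError("mask interior too small to place lesions (grid_shape)")

    lesion_weight = np.zeros(shape)
    grids = np.indices(shape).astype(np.float64)
    for _ in range(spec.lesion_count):
        for attempt in range(100):
            center = coords[rng.integers(len(coords))]
            radius_mm = rng.uniform(*spec.lesion_radius_range)
            r_vox = radius_mm / sp
            d2 = sum((g - c) ** 2 for g, c in zip(grids, center)) / r_vox**2
            blob = np.clip(1.0 - d2, 0.0, None)  # soft-edged sphere
            if (blob > 0)[mask_arr].any():
                lesion_weight = np.maximum(lesion_weight, blob)
                break
        else:
            raise ValueError("could not place lesion inside mask (lesion_radius_range)")

    tex_sigma = spec.lesion_texture_scale / sp
    texture_field = _correlated_noise(rng, shape, tex_sigma, 1.0) if spec.lesion_count else 0.0

    effect = RESPONSE_EFFECTS[spec.response_class]
    vols = []
    for factor in (1.0, effect):  # pre, post
        hu = base + lesion_weight * (
            factor * spec.lesion_HU_shift
            + factor * spec.lesion_texture_sd * texture_field
        )
        if spec.acquisition_noise_sd > 0:
            hu = hu + rng.normal(0.0, spec.acquisition_noise_sd, shape)
        np.clip(hu, HU_MIN, HU_MAX, out=hu)
        vols.append(VolumeGrid(hu, (sp, sp, sp)))

    mask = SegmentationMask(mask_arr, (sp, sp, sp))
    return vols[0], vols[1], mask


def perturb_mask(
    mask: SegmentationMask, magnitude: float = 1.0, seed: int = 0
) -> SegmentationMask:
    """Simulate an alternative semiautomatic segmentation.

    The mask boundary is moved by up to ``magnitude`` voxels along a smooth
    random field: outward (dilation) where the field is positive, inward
    (erosion) where negative.  At the default magnitude the perturbed mask
    keeps Dice >= 0.9 with the original; a larger magnitude that breaks that
    regime triggers a warning.
    """
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    if magnitude == 0:
        return SegmentationMask(mask.values.copy(), mask.spacing, mask.origin)
    rng = np.random.default_rng(seed)
    d_in = ndimage.distance_transform_edt(mask.values)
    d_out = ndimage.distance_transform_edt(~mask.values)
    signed = d_out - d_in  # negative inside, positive outside
    f = _correlated_noise(rng, mask.values.shape, sigma_vox=3.0, sd=1.0)
    new = signed < magnitude * f
    if not new.any():
        raise ValueError("perturbation erased the mask")
    inter = (new & mask.values).sum()
    dice = 2 * inter / (new.sum() + mask.values.sum())
    if dice < 0.9:
        log.warning("perturb_mask: Dice %.3f below 0.9 at magnitude %s", dice, magnitude)
    return SegmentationMask(new, mask.spacing, mask.origin)


# ---------------------------------------------------------------------------
# imaging cohort


def simulate_imaging_cohort(
    n_subjects: int = 20,
    responder_fraction: float = 0.5,
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
) -> tuple[list[dict], SyntheticTruth]:
    """Generate paired phantoms for a cohort, half responders by default.

    Returns a list of per-subject records ``{subject_id, spec, pre, post,
    mask}`` plus the planted truth.  Subject-to-subject variation comes from
    independent lesion geometry and noise draws.
    """
    base = base_spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    n_resp = int(round(n_subjects * responder_fraction))
    classes = [RESPONDER] * n_resp + [NONRESPONDER] * (n_subjects - n_resp)
    truth = SyntheticTruth()
    subjects = []
    for i, cls in enumerate(classes):
        sid = f"S{i + 1:03d}"
        spec = PhantomSpec(
            **{
                **asdict(base),
                "response_class": cls,
                "seed": int(rng.integers(0, 2**31 - 1)),
            }
        )
        pre, post, mask = make_phantom_pair(spec)
        subjects.append(
            {"subject_id": sid, "spec": spec, "pre": pre, "post": post, "mask": mask}
        )
        truth.response_class[sid] = cls
    return subjects, truth


# ---------------------------------------------------------------------------
# proteome


def spearman_to_pearson_copula(rho_s: float) -> float:
    """Gaussian-copula latent Pearson correlation giving Spearman ``rho_s``."""
    return float(2.0 * np.sin(np.pi * rho_s / 6.0))


def make_proteome(
    delta_table: pd.DataFrame,
    planted: list[dict] | None = None,
    n_proteins: int = 400,
    noise_sd: float = 0.0,
    mean_log2: float = 25.0,
    scale_log2: float = 1.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Protein x sample log2-intensity matrix with planted rank correlations.

    Each planted entry ``{"feature": ..., "protein": ..., "rho": ...}``
    couples a protein to the realized delta-feature values of the cohort via
    a Gaussian copula, so the expected Spearman correlation equals the
    target; ``noise_sd = 0`` with target rho = +/-1 yields an exact monotone
    copy.  All other proteins are exchangeable Gaussian noise.
    """
    planted = planted or []
    samples = list(delta_table.index)
    n = len(samples)
    rng = np.random.default_rng(seed)
    planted_proteins = {p["protein"] for p in planted}
    if n_proteins < len(planted_proteins):
        raise ValueError(
            f"n_proteins={n_proteins} smaller than {len(planted_proteins)} planted proteins"
        )
    names = [f"PROT{i + 1:05d}" for i in range(n_proteins)]
    free = [p for p in names if p not in planted_proteins]
    if len(free) + len(planted_proteins) > n_proteins:
        raise ValueError("planted protein ids collide with generated names")

    mat = pd.DataFrame(
        rng.normal(mean_log2, scale_log2, size=(n_proteins, n)),
        index=names,
        columns=samples,
    )
    truth = SyntheticTruth()
    for entry in planted:
        feat, prot, rho = entry["feature"], entry["protein"], float(entry["rho"])
        if not 0.6 <= abs(rho) <= 1.0:
            raise ValueError(f"planted |rho| must be in [0.6, 1], got {rho}")
        x = delta_table[feat].to_numpy()
        ranks = stats.rankdata(x)
        z = stats.norm.ppf((ranks - 0.5) / n)
        z = z / z.std() if z.std() > 0 else z
        r = spearman_to_pearson_copula(rho)
        latent = r * z + np.sqrt(max(1.0 - r**2, 0.0)) * rng.standard_normal(n)
        if noise_sd > 0:
            latent = latent + rng.normal(0.0, noise_sd, n)
        if prot not in mat.index:
            raise ValueError(f"planted protein {prot} outside generated id range")
        mat.loc[prot] = mean_log2 + scale_log2 * latent
        truth.planted_correlations.append({"feature": feat, "protein": prot, "rho": rho})
    return mat, truth


# ---------------------------------------------------------------------------
# signatures & cohort


def make_signatures(
    n_celltypes: int = 4,
    markers_per_type: int = 20,
    overlap_fraction: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Cell-type marker table (gene, cell_type, log2FC, padj).

    Markers satisfy the signature definition log2FC > 0.3 and adjusted
    P < 0.05; sets are disjoint unless ``overlap_fraction`` > 0.
    """
    if markers_per_type < 5:
        raise ValueError("markers_per_type must be >= 5")
    if n_celltypes < 1:
        raise ValueError("n_celltypes must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    gene_counter = 0
    previous: list[str] = []
    for ct in range(n_celltypes):
        name = f"celltype_{ct + 1}"
        n_shared = int(round(overlap_fraction * markers_per_type)) if previous else 0
        shared = list(rng.choice(previous, size=n_shared, replace=False)) if n_shared else []
        genes = []
        for _ in range(markers_per_type - len(shared)):
            gene_counter += 1
            genes.append(f"GENE{gene_counter:05d}")
        for g in genes + shared:
            rows.append(
                {
                    "gene": g,
                    "cell_type": name,
                    "log2FC": float(rng.uniform(0.5, 2.5)),
                    "padj": float(rng.uniform(1e-6, 0.04)),
                }
            )
        previous.extend(genes)
    df = pd.DataFrame(rows)
    assert (df["log2FC"] > 0.3).all() and (df["padj"] < 0.05).all()
    return df


def make_cohort(
    n_patients: int = 16,
    cluster_effects: dict[str, float] | None = None,
    fvc_delta_sd: float = 2.0,
    baseline_mean: float = 75.0,
    baseline_sd: float = 10.0,
    interval_days: float = 182.625,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Clinical cohort table with FVC trajectories coupled to planted clusters.

    ``cluster_effects`` maps cluster label to the mean FVC %-predicted change
    over the follow-up interval (default half a year); per-patient deltas are
    Gaussian around that mean.  Baselines are drawn independently of cluster
    (outcome-independent baselines).  FVC volumes assume 4,000 mL predicted.
    """
    effects = cluster_effects or {"A": -1.0, "B": -10.0}
    rng = np.random.default_rng(seed)
    labels = sorted(effects)
    pred_ml = 4000.0
    rows = []
    truth = SyntheticTruth()
    t0 = pd.Timestamp("2020-01-01")
    for i in range(n_patients):
        pid = f"P{i + 1:03d}"
        cl = labels[i % len(labels)]
        base_pct = rng.normal(baseline_mean, baseline_sd)
        delta_pct = rng.normal(effects[cl], fvc_delta_sd)
        pre_date = t0 + pd.Timedelta(days=int(rng.integers(0, 90)))
        rows.append(
            {
                "patient_id": pid,
                "etiology": rng.choice(["IPF", "CTD-ILD", "other"]),
                "sex": rng.choice(["F", "M"]),
                "smoking": rng.choice(["never", "former"]),
                "disease_duration_yr": float(rng.uniform(0.5, 8.0)),
                "concomitant_therapy": bool(rng.integers(0, 2)),
                "ph_flag": bool(rng.random() < 0.25),
                "fvc_pct_pre": float(base_pct),
                "fvc_pct_post": float(base_pct + delta_pct),
                "fvc_ml_pre": float(base_pct / 100.0 * pred_ml),
                "fvc_ml_post": float((base_pct + delta_pct) / 100.0 * pred_ml),
                "date_pre": pre_date.date().isoformat(),
                "date_post": (pre_date + pd.Timedelta(days=interval_days)).date().isoformat(),
            }
        )
        truth.response_class[pid] = cl
        truth.fvc_slopes[pid] = float(delta_pct)
    return pd.DataFrame(rows).set_index("patient_id"), truth


def make_patient_delta_table(
    truth_labels: dict[str, str],
    feature_names: list[str],
    effect_size: float = 2.5,
    n_informative: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Patient x feature delta table whose informative features shift by
    cluster, for stratification tests without patient-level imaging."""
    rng = np.random.default_rng(seed)
    patients = list(truth_labels)
    labels = sorted(set(truth_labels.values()))
    k = len(feature_names) if n_informative is None else n_informative
    mat = rng.standard_normal((len(patients), len(feature_names)))
    centers = {lab: i * effect_size for i, lab in enumerate(labels)}
    for r, pid in enumerate(patients):
        mat[r, :k] += centers[truth_labels[pid]]
    return pd.DataFrame(mat, index=patients, columns=feature_names)


# ---------------------------------------------------------------------------
# writers


def write_gmt(collection: dict[str, set[str] | list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            fh.write("\t".join([name, "synthetic"] + sorted(genes)) + "\n")


def read_gmt(path) -> dict[str, set[str]]:
    out = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                out[parts[0]] = set(parts[2:])
    return out
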