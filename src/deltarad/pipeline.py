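"""End-to-end orchestration with a validated configuration, per-stage seeds
and reproducibility manifests.

``RunConfig`` gathers every stage parameter with the analysis defaults
(0.15 mm preclinical / 2.75 mm clinical voxels, 50 HU bins over
[-1000, 200] HU, ICC >= 0.75, Spearman prune at 0.85, importance score
>= 0.9, module membership |rho| >= 0.6 & P < 0.05, GeneRatio >= 0.10 &
adjusted P < 0.05, deconvolution significance P < 0.01).  A single base
seed fans out to stage seeds through a fixed counter scheme so stages are
individually reproducible without seed collisions.  Each run writes a
manifest with the config hash, stage seeds, catalog version and output
checksums; outputs are write-once.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, importance, omics, selection, synthetic
from .catalog import CATALOG_VERSION
from .features import extract_all
from .synthetic import PhantomSpec

log = logging.getLogger(__name__)

#: fixed stage order; a stage's seed is derived from (base_seed, its index)
STAGES = (
    "simulate",
    "extract",
    "delta",
    "cluster",
    "importance",
    "modules",
    "enrich",
    "deconvolve",
    "stratify",
)


def stage_seed(base_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 via a counter scheme."""
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence([int(base_seed), idx]).generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    voxel_mm: float = 0.15
    voxel_mm_clinical: float = 2.75
    bin_size_hu: float = 50.0
    hu_range: tuple[float, float] = (-1000.0, 200.0)
    icc_threshold: float = 0.75
    rho_prune: float = 0.85
    importance_threshold: float = 0.9
    module_rho_min: float = 0.6
    module_p_max: float = 0.05
    gene_ratio_min: float = 0.10
    padj_max: float = 0.05
    ks_alpha: float = 0.01
    n_subjects: int = 20
    responder_fraction: float = 0.5
    n_proteins: int = 400
    bootstrap_B: int = 1000
    k_range: tuple[int, int] = (2, 8)
    seed: int = 0
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    mask_perturb_magnitude: float = 1.0
    run_icc_filter: bool = True

    def validate(self) -> None:
        for name in ("rho_prune", "module_rho_min", "icc_threshold", "importance_threshold"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("module_p_max", "padj_max", "ks_alpha", "gene_ratio_min"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.voxel_mm <= 0 or self.voxel_mm_clinical <= 0:
            raise ValueError("voxel sizes must be positive")
        if self.hu_range[0] >= self.hu_range[1]:
            raise ValueError(f"invalid hu_range {self.hu_range}")
        if self.bootstrap_B < 1:
            raise ValueError("bootstrap_B must be >= 1")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _checksum_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


@dataclass
class RunArtifacts:
    """In-memory artifacts handed from stage to stage."""

    config: RunConfig
    subjects: list | None = None
    truth: synthetic.SyntheticTruth | None = None
    pre_features: pd.DataFrame | None = None
    post_features: pd.DataFrame | None = None
    pre_features_alt: pd.DataFrame | None = None
    post_features_alt: pd.DataFrame | None = None
    delta: pd.DataFrame | None = None
    retention: pd.DataFrame | None = None
    cluster_result: clustering.ClusterResult | None = None
    importance: pd.DataFrame | None = None
    proteome: pd.DataFrame | None = None
    proteome_truth: synthetic.SyntheticTruth | None = None
    modules: dict | None = None
    enrichment: dict | None = None
    signatures: pd.DataFrame | None = None
    deconvolution: dict | None = None
    manifest: dict = field(default_factory=dict)


def _require(art: RunArtifacts, attr: str, produced_by: str):
    value = getattr(art, attr)
    if value is None:
        raise RuntimeError(f"missing upstream artifact {attr!r}: run stage {produced_by!r} first")
    return value


def run_simulate(art: RunArtifacts) -> RunArtifacts:
    cfg = art.config
    base = PhantomSpec(grid_shape=tuple(cfg.grid_shape), voxel_spacing=cfg.voxel_mm)
    art.subjects, art.truth = synthetic.simulate_imaging_cohort(
        n_subjects=cfg.n_subjects,
        responder_fraction=cfg.responder_fraction,
        base_spec=base,
        seed=stage_seed(cfg.seed, "simulate"),
    )
    return art

def _extract_table(records, which: str, cfg: RunConfig, masks=None) -> pd.DataFrame:
    rows = {}
    for i, rec in enumerate(records):
        mask = masks[i] if masks is not None else rec["mask"]
        fv = extract_all(
            rec[which],
            mask,
            subject_id=rec["subject_id"],
            timepoint=which,
            bin_size=cfg.bin_size_hu,
            hu_range=cfg.hu_range,
        )
        rows[rec["subject_id"]] = fv.values
    return pd.DataFrame(rows).T


def run_extract(art: RunArtifacts) -> RunArtifacts:
    cfg = art.config
    subjects = _require(art, "subjects", "simulate")
    art.pre_features = _extract_table(subjects, "pre", cfg)
    art.post_features = _extract_table(subjects, "post", cfg)
    if cfg.run_icc_filter:
        seed0 = stage_seed(cfg.seed, "extract")
        alt_masks = [
            synthetic.perturb_mask(rec["mask"], cfg.mask_perturb_magnitude, seed=seed0 + i)
            for i, rec in enumerate(subjects)
        ]
        art.pre_features_alt = _extract_table(subjects, "pre", cfg, masks=alt_masks)
        art.post_features_alt = _extract_table(subjects, "post", cfg, masks=alt_masks)
    return art


def run_delta(art: RunArtifacts) -> RunArtifacts:
    cfg = art.config
    pre = _require(art, "pre_features", "extract")
    post = _require(art, "post_features", "extract")
    raw_delta = selection.delta_table(pre, post)
    if cfg.run_icc_filter and art.pre_features_alt is not None:
        # stability assessed on per-time-point features across both scans
        seg_a = pd.concat([pre, post], keys=["pre", "post"])
        seg_b = pd.concat([art.pre_features_alt, art.post_features_alt], keys=["pre", "post"])
        art.delta, art.retention = selection.select_features(
            raw_delta, seg_a, seg_b, icc_threshold=cfg.icc_threshold, rho_max=cfg.rho_prune
        )
    else:
        art.delta, art.retention = selection.select_features(
            raw_delta, icc_threshold=cfg.icc_threshold, rho_max=cfg.rho_prune
        )
    return art


def run_cluster(art: RunArtifacts) -> RunArtifacts:
    cfg = art.config
    delta = _require(art, "delta", "delta")
    art.cluster_result = clustering.cluster_with_diagnostics(
        delta,
        method="kmeans",
        k=2,
        B=cfg.bootstrap_B,
        seed=stage_seed(cfg.seed, "cluster"),
    )
    return art


def run_importance(art: RunArtifacts) -> RunArtifacts:
    cfg = art.config
    delta = _require(art, "delta", "delta")
    res = _require(art, "cluster_result", "cluster")
    labels = pd.Series(res.labels, index=delta.index)
    art.importance = importance.auc_importance(
        delta, labels, threshold=cfg.importance_threshold
    )
    return art


def run_modules(art: RunArtifacts, planted: list[dict] | None = None) -> RunArtifacts:
    cfg = art.config
    delta = _require(art, "delta", "delta")
    imp = _require(art, "importance", "importance")
    if art.proteome is None:
        art.proteome, art.proteome_truth = synthetic.make_proteome(
            delta,
            planted=planted,
            n_proteins=cfg.n_proteins,
            seed=stage_seed(cfg.seed, "modules"),
        )
    selected = list(imp.index[imp["retained"]])
    if not selected:  # fall back to top-scoring features so modules exist
        selected = list(imp["score"].nlargest(5).index)
        log.warning("no features passed the importance threshold; using top 5 by score")
    art.modules = omics.build_modules(
        delta, art.proteome, features=selected,
        rho_min=cfg.module_rho_min, p_max=cfg.module_p_max,
    )
    return art


def run_enrich(art: RunArtifacts, collection: dict[str, set[str]] | None = None) -> RunArtifacts:
    cfg = art.config
    modules = _require(art, "modules", "modules")
    proteome = _require(art, "proteome", "modules")
    background = set(proteome.index)
    if collection is None:
        rng = np.random.default_rng(stage_seed(cfg.seed, "enrich"))
        names = list(proteome.index)
        collection = {
            f"pathway_{i + 1}": set(rng.choice(names, size=25, replace=False))
            for i in range(12)
        }
    art.enrichment = {
        feat: omics.ora_enrichment(
            mod.proteins, background, collection,
            gene_ratio_min=cfg.gene_ratio_min, padj_max=cfg.padj_max,
        )
        for feat, mod in modules.items()
    }
    return art


def run_deconvolve(art: RunArtifacts, signatures: pd.DataFrame | None = None) -> RunArtifacts:
    cfg = art.config
    modules = _require(art, "modules", "modules")
    delta = _require(art, "delta", "delta")
    proteome = _require(art, "proteome", "modules")
    if signatures is None:
        signatures = synthetic.make_signatures(seed=stage_seed(cfg.seed, "deconvolve"))
        # synthetic marker genes are placeholders; map them onto protein ids
        gene_map = dict(zip(sorted(signatures["gene"].unique()), sorted(proteome.index)))
        signatures = signatures.assign(gene=signatures["gene"].map(gene_map))
    art.signatures = signatures
    art.deconvolution = {}
    for feat in modules:
        weights = omics.association_weights(delta[feat], proteome)
        art.deconvolution[feat] = omics.signature_deconvolution(
            weights, signatures, alpha=cfg.ks_alpha
        )
    return art


_STAGE_FUNCS = {
    "simulate": run_simulate,
    "extract": run_extract,
    "delta": run_delta,
    "cluster": run_cluster,
    "importance": run_importance,
    "modules": run_modules,
    "enrich": run_enrich,
    "deconvolve": run_deconvolve,
}


def run_stage(name: str, art: RunArtifacts) -> RunArtifacts:
    if name not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {name!r}; expected one of {list(_STAGE_FUNCS)}")
    return _STAGE_FUNCS[name](art)


def run_all(config: RunConfig, outdir: str | Path | None = None) -> RunArtifacts:
    """Run simulate → extract → delta → cluster → importance → modules →
    enrich → deconvolve and optionally write artifacts plus a manifest."""
    config.validate()
    art = RunArtifacts(config=config)
    for name in ("simulate", "extract", "delta", "cluster", "importance",
                 "modules", "enrich", "deconvolve"):
        log.info("stage %s", name)
        art = run_stage(name, art)
    if outdir is not None:
        write_artifacts(art, Path(outdir))
    return art


def write_artifacts(art: RunArtifacts, outdir: Path) -> dict:
    """Write stage outputs as TSV/JSON plus a reproducibility manifest.

    Outputs are write-once: refusing to overwrite an existing manifest
    guards against mutating a previous run's artifacts.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists():
        raise FileExistsError(f"{manifest_path} exists; artifacts are write-once")
    files = {}

    def _write_tsv(df: pd.DataFrame, name: str):
        path = outdir / name
        df.to_csv(path, sep="\t", float_format="%.10g")
        files[name] = _checksum_file(path)

    if art.delta is not None:
        _write_tsv(art.delta, "delta_features.tsv")
    if art.retention is not None:
        _write_tsv(art.retention, "retention_report.tsv")
    if art.importance is not None:
        _write_tsv(art.importance, "importance.tsv")
    if art.proteome is not None:
        _write_tsv(art.proteome, "proteome_log2.tsv")
    if art.cluster_result is not None:
        path = outdir / "cluster_report.json"
        path.write_text(json.dumps(art.cluster_result.to_dict(), indent=1))
        files["cluster_report.json"] = _checksum_file(path)
    if art.modules is not None:
        payload = {
            feat: mod.members.reset_index().to_dict(orient="records")
            for feat, mod in art.modules.items()
        }
        path = outdir / "modules.json"
        path.write_text(json.dumps(payload, indent=1))
        files["modules.json"] = _checksum_file(path)
    if art.deconvolution is not None:
        for feat, df in art.deconvolution.items():
            _write_tsv(df, f"deconvolution_{feat}.tsv")

    manifest = {
        "config": asdict(art.config),
        "config_hash": art.config.config_hash(),
        "catalog_version": CATALOG_VERSION,
        "stage_seeds": {s: stage_seed(art.config.seed, s) for s in STAGES},
        "files": files,
    }
    manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
    art.manifest = manifest
    return manifest
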