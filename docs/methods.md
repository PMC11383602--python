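# Methods

This note documents the models, statistics and design choices behind
`deltarad`, in the order the analysis runs them.

## Overview

The package studies treatment response in fibrotic lung disease through
*delta radiomics*: for each subject, a high-dimensional radiomic feature
vector is computed on a pre-treatment and a post-treatment CT scan inside a
lung mask, and the analysis operates on the per-feature change
`Δf = f(t2) − f(t1)`. Delta profiles are clustered to discover response
phenotypes, each response-defining feature is linked to the proteome through
rank-correlation "association modules", the modules are interpreted by
pathway over-representation and cell-type signature deconvolution, and
finally a patient cohort is stratified on the preclinically defined feature
subset and compared on lung-function decline (FVC). Every stage is
exercisable on synthetic data with planted ground truth.

## Volume preparation

Volumes are calibrated in Hounsfield units and carried with physical
spacing; all geometry checks happen in world coordinates (mm). Scans are
resampled to isotropic voxels — 0.15 mm for the preclinical configuration,
2.75 mm for the clinical one, a voxel-volume ratio of (2.75/0.15)^3 ≈ 6,000.
The volume is interpolated trilinearly and the mask by nearest neighbor
(the standard radiomics choice; the interpolator is config-visible since
extraction software differs here). Intensities are then discretized with a
fixed bin size of 50 HU over [−1000, 200] HU, giving 24 bins; the top edge
is inclusive so 200 HU falls in bin 24 rather than an empty 25th bin.
Out-of-range values are clipped rather than excluded, which keeps the mask
volume identical across time points so shape features respond only to
segmentation, never to windowing.

## Feature catalog (1,388 features)

Per scan: 17 first-order statistics, 137 texture features, 2 shape features
(mesh-free volume in mm³ and exposed-voxel-face surface in mm²), and the
154 histogram+texture features repeated on each of 8 wavelet subbands
(8 × 154 = 1,232). The texture composition — 26 GLCM + 26 merged-GLCM +
16 GLRLM + 16 merged-GLRLM + 16 GLSZM + 16 GLDZM + 5 NGTDM + 16 NGLDM —
follows the common 3D (IBSI-style) definitions and is frozen in a versioned
JSON manifest; the manifest is the normative artifact for feature identity
and ordering.

Numerical conventions:

* Co-occurrence and runs use the 13 unique distance-1 directions in 3D;
  zones use 26-connectivity. "Merged" families sum the 13 direction
  matrices before normalization; the plain families average per-direction
  feature values (directions without valid pairs are skipped).
* Degenerate limits are continuity-based and logged: single-bin entropy is
  0, correlation-type GLCM features with zero gray-level variance are 0,
  and MCC (square root of the second eigenvalue of the GLCM Q matrix) with
  fewer than two gray levels is 1.
* The wavelet transform is a single-level undecimated separable Haar pair
  (L = [½, ½], H = [½, −½]) with symmetric boundaries, chosen because it
  admits exact analytic test cases (constants, impulses); the kernel is
  config-selectable. Subband letter *i* is the filter along array axis *i*.
* Wavelet subbands are re-discretized with the same bin count (24) over
  each subband's own in-mask range, because the HU window is meaningless
  after high-pass filtering.
* The GLDZM zone distance is the city-block distance to the ROI border,
  with border voxels at distance 1 and the lattice edge counting as border.
* NGLDM uses dependence level α = 0 (neighbors count when their gray level
  is identical) and omits the always-trivial dependence-percentage feature.
* Any non-finite feature value is replaced by 0 and logged.

Texture-matrix construction is verified against brute-force enumeration
oracles (pair enumeration for GLCM, line walking for GLRLM, flood fill for
GLSZM) exactly, on small random volumes.

## Synthetic phantom generator

The generator emulates a paired micro-CT fibrosis experiment, not anatomy:
an ellipsoidal "lung" (≈ 31% of a 64³ lattice at 0.15 mm) of spatially
smoothed parenchymal noise (−650 ± 60 HU) over air background, plus 5
soft-edged spherical lesions (radius 0.9–1.8 mm) whose density is shifted
by +420 HU and carry intra-lesion texture modeled as Gaussian-filtered
white noise with a 0.45 mm correlation length (chosen for a controllable
GLCM/GLSZM response). Between time points, responders retain only 25% of
the lesion density/texture amplitude while non-responders progress to 110%;
per-time-point acquisition noise (12 HU) is independent. Effect sizes are
calibration choices — within-group radiomic variance in mice is not
quantified anywhere we could anchor to — set once so that the default
20-subject cohort lies in the stable two-cluster regime (silhouette > 0.25,
per-cluster bootstrap Jaccard ≥ 0.90) that the preclinical analysis reports
for its response clusters. What passing tests show is therefore that the
pipeline recovers structure *of this planted kind and strength*; they say
nothing about effect sizes in real bleomycin cohorts.

Alternative segmentations are simulated by moving the mask boundary along a
smooth random field (dilation where positive, erosion where negative),
preserving Dice ≥ 0.9 at the default magnitude of 1 voxel.

Proteomes couple planted proteins to realized delta-feature values through
a Gaussian copula with latent Pearson correlation r = 2·sin(π·ρs/6), which
gives exact control of the target Spearman ρs; all other proteins are
exchangeable Gaussian log2 intensities. Marker tables satisfy the signature
definition (log2FC > 0.3, adjusted P < 0.05) by construction, and cohort
FVC trajectories are Gaussian around per-cluster means with
outcome-independent baselines.

Everything is deterministic per seed; a cohort seed fans out to per-subject
seeds drawn from a seeded generator.

## Feature selection

Two-stage filter, in this order: (1) segmentation stability — ICC between
the reference and perturbed segmentation per feature, computed on
per-time-point features by default (config-selectable to delta values),
using ICC(3,1), the two-way mixed consistency form `(BMS − EMS)/(BMS + EMS)`
for two raters (ICC(2,1) available); features with ICC < 0.75, or constant
features whose ICC is undefined, are dropped. (2) redundancy — iterative
greedy pruning of the most correlated remaining pair at Spearman
|ρ| ≥ 0.85, dropping the member with the larger mean absolute correlation
(the `findCorrelation`-style convention), ties broken toward the later
catalog column. The retained set is guaranteed to have max pairwise
|ρ| < 0.85 and is invariant to subject order.

## Clustering diagnostics

Features are Z-scored (sample sd, n−1); constant columns become zeros with
a warning. Clusterability is the Hopkins statistic (uniform pseudo-points
in the data bounding box vs sampled real points, self-excluded). The
cluster count is chosen by maximizing the average silhouette over
k = 2..min(8, n−1), ties to the smaller k. Clustering is agglomerative
(Euclidean, Ward — config-selectable) or k-means with 25 restarts.
Stability is `clusterboot`-style bootstrap Jaccard with B = 1000: each
resample is re-clustered, each original cluster is restricted to the
subjects present in the resample and matched to its maximum-Jaccard
counterpart; dissolved clusters contribute their achieved (low) Jaccard.

## Importance, modules, enrichment, deconvolution

* **Importance** — "filter-based variable importance" is operationalized as
  the symmetrized two-class ROC area per feature, `max(AUC, 1 − AUC)` with
  AUC = U/(n1·n2) and ties counted ½; scores lie in [0.5, 1] and features
  with score ≥ 0.9 are response-defining. The score is invariant under
  monotone transforms and label swaps. (A separation statistic or
  cross-validated classifier would be defensible alternatives; AUC is the
  standard filter for a numeric predictor against a binary outcome.)
* **Differential expression** — a moderated Welch t on log2 intensities:
  group variances are shrunk toward the across-protein median pooled
  variance with ν0 = 3 pseudo-samples (an empirical-Bayes-flavored
  stabilization written here rather than delegated to limma), with
  Welch–Satterthwaite degrees of freedom augmented by the prior weight.
  Significance: |log2FC| > 0.3 and P < 0.05; BH-adjusted P reported
  alongside. Under a global null the flag rate stays below 5%.
* **Association modules** — Spearman ρ (average ranks) between one delta
  feature and every protein; P from the t approximation, or the exact
  permutation null for n ≤ 9 untied samples (verified against R's
  `cor.test(..., exact = TRUE)`); |ρ| = 1 reports the smallest
  representable P, logged. Members satisfy |ρ| ≥ 0.6 (applied two-sidedly)
  and P < 0.05, split by sign; deconvolution weights are
  `sign(ρ)·(−log10 P)·|ρ|`. All-treated samples enter by default
  (cluster-independent; a config flag restricts the sample set).
* **Over-representation** — hypergeometric upper tail against the supplied
  background, GeneRatio = overlap/|query|, BH across the collection;
  retained at GeneRatio ≥ 0.10 and adjusted P < 0.05. The ≥ 2-modules
  display rule is a reporting filter, not a statistic.
* **Deconvolution** — proteins ranked by signed weight; each signature's
  marker rank positions are compared with non-members by the classical
  two-sample Kolmogorov–Smirnov test (a GSEA-style running sum is a config
  alternative), signed by the members' median weight and reported as
  signed −log10 P; significance P < 0.01; signatures with < 5 present
  markers are skipped.

## Cohort stratification

ΔFVC (post − pre, % predicted and mL) with annualized rates
(Δ × 365.25 / interval days); deltas are raw-interval by default with
annualization reported separately. Stratification is k-means on Z-scored
patient delta features restricted to preclinically defined feature names —
outcome variables are structurally barred from the clustering inputs — with
silhouette-selected k and Jaccard bootstrap. Numeric group comparisons use
the two-sided Mann-Whitney U (exact for ≤ 8 per group without ties),
categorical ones Fisher's exact test (scipy-equivalent for 2×2; an
enumeration over fixed-margin tables, summing outcomes no more probable
than observed, for small r×c).

## Problem sizes and reproducibility

The default study conditions are 20 subjects (10 per response class) on
64³ phantoms; the repeated-seed recovery study (50 seeds, median adjusted
Rand index ≥ 0.8) runs on half-scale phantoms (32³, lesion radii halved),
a problem size chosen to keep the whole suite desk-scale while preserving
texture-matrix support. One base seed fans out to per-stage seeds via
`SeedSequence([seed, stage_index])`; every run can write a manifest
(config hash, stage seeds, catalog version, output checksums) and outputs
are write-once. Re-running with the same config reproduces byte-identical
artifacts.

## Known limitations

* Phantoms are not anatomically realistic lungs and carry no pharmacology;
  absolute feature values are not comparable to any scanner's output.
* The texture catalog composition is this package's normative choice; other
  extraction software selects different member features under the same
  family names, so only family totals — not individual values — transfer.
* The moderated Welch t approximates, but is not, limma's empirical-Bayes
  model.
* The exact Spearman permutation null is used only for untied n ≤ 9; tied
  small samples fall back to the t approximation.
* Counts reported by the original preclinical study (retained-feature and
  differentially expressed totals, cluster sizes, patient FVC medians)
  depend on its undeposited images and proteome and are out of scope here;
  the synthetic analysis reproduces the *properties* of the workflow, not
  those numbers.
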