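# deltarad

Delta radiomics of paired CT volumes with radioproteomic integration:
a tested re-implementation of a treatment-response stratification workflow
for fibrotic lung disease, runnable end to end on synthetic data.

## The problem

Antifibrotic treatment response is heterogeneous, and conventional lung
densitometry often misses it. This analysis asks whether the *change* in
high-dimensional radiomic texture between a pre- and a post-treatment CT
scan — delta radiomics, `Δf = f(t2) − f(t1)` per feature — carries
molecular response information, and whether feature subsets defined that
way stratify patients by lung-function decline.

The pipeline:

1. **Extraction** — lungs resampled to isotropic voxels (0.15 mm
   preclinical / 2.75 mm clinical) and discretized at a fixed 50 HU bin
   size over [−1000, 200] HU; 1,388 features per scan (17 histogram, 137
   texture across GLCM/GLRLM/GLSZM/GLDZM/NGTDM/NGLDM families incl. merged
   variants, 2 shape, and 154 features on each of 8 undecimated wavelet
   subbands).
2. **Selection** — delta features stable against segmentation variation
   (ICC ≥ 0.75) and non-redundant (pairwise Spearman |ρ| < 0.85).
3. **Response clustering** — Z-scored k-means/hierarchical clustering with
   Hopkins clusterability, silhouette-selected k, and bootstrap Jaccard
   stability (B = 1000).
4. **Importance** — response-defining features by symmetrized ROC-AUC
   filter score ≥ 0.9.
5. **Radioproteomic association modules** — per feature, the proteins with
   Spearman |ρ| ≥ 0.6 and P < 0.05, split by sign; hypergeometric pathway
   over-representation (GeneRatio ≥ 0.10, BH-adjusted P < 0.05); weighted
   cell-type signature deconvolution by two-sample Kolmogorov–Smirnov test
   on ranked, `sign(ρ)·(−log10 P)·|ρ|`-weighted protein lists (P < 0.01).
6. **Cohort stratification** — patients clustered on the preclinically
   defined feature subset only; ΔFVC (% predicted and mL, annualized)
   compared by Mann-Whitney U, covariates by Fisher's exact test.

A synthetic-data module generates every input with planted ground truth:
paired phantoms whose delta profiles form two response clusters, proteomes
coupled to realized feature values through a Gaussian copula (exact
Spearman targets), marker signatures satisfying log2FC > 0.3 / adjusted
P < 0.05, and FVC trajectories coupled to cluster identity.
See `docs/methods.md` for models, conventions and limitations.

## Worked example

The analysis is organized as numbered drivers over the library:

```sh
python analysis/01_simulate_and_extract.py --seed 1 --results results
python analysis/02_select_delta_features.py --results results
python analysis/03_cluster_response.py --seed 1 --results results
python analysis/04_feature_importance.py --results results
# ... 05 modules/enrichment, 06 deconvolution, 07 cohort stratification
```

With `--seed 1`, step 02 prints

```
delta features: 1388 total -> 111 retained
  dropped for segmentation instability (ICC < 0.75): 691
  pruned as redundant (|rho| >= 0.85):               586
```

and step 03

```
Hopkins H = 0.558  (0.5 = unstructured)
silhouette-selected k = 2; silhouette by k: 2:0.191, 3:0.183, 4:0.098, ...
per-cluster mean bootstrap Jaccard: 1:0.983, 2:0.984
adjusted Rand index vs planted response classes: 1.000
```

Hopkins above 0.5 says the delta table is clusterable; the silhouette scan
picks k = 2; both clusters sit in the stable bootstrap regime; and the
recovered labels match the planted responder / non-responder classes
exactly. Step 04 retains 25 response-defining features (score ≥ 0.9);
step 05 recovers all 24 planted feature–protein couplings per planted
feature into the association modules and finds only the planted pathways
enriched in ≥ 2 modules; step 06 assigns the planted profibrotic-up /
regenerative-down signature pair strongly opposite signed enrichment
(signed −log10 P of +20.8 and −21.8, both P < 0.01, random-marker controls
non-significant); step 07 recovers two patient clusters differing in ΔFVC
(median +0.1 vs −12.0 %predicted, Mann-Whitney P = 0.0002) but not in
baseline FVC or covariates.

Library use mirrors the scripts:

```python
from deltarad.synthetic import PhantomSpec, simulate_imaging_cohort
from deltarad.features import extract_all

subjects, truth = simulate_imaging_cohort(n_subjects=20, seed=1)
fv = extract_all(subjects[0]["pre"], subjects[0]["mask"])   # 1,388 values
```

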