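"""Generator contracts: determinism, planted structure, perturbations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from deltarad.features import extract_all
from deltarad.synthetic import (
    PhantomSpec,
    make_cohort,
    make_phantom_pair,
    make_proteome,
    make_signatures,
    perturb_mask,
    simulate_imaging_cohort,
    spearman_to_pearson_copula,
)
from deltarad.volumes import HU_MAX, HU_MIN


class TestPhantom:
    def test_seed_determinism_bit_identical(self):
        spec = PhantomSpec(seed=123)
        a_pre, a_post, a_mask = make_phantom_pair(spec)
        b_pre, b_post, b_mask = make_phantom_pair(PhantomSpec(seed=123))
        assert (a_pre.values == b_pre.values).all()
        assert (a_post.values == b_post.values).all()
        assert (a_mask.values == b_mask.values).all()

    def test_different_seeds_same_mask_topology(self):
        a = make_phantom_pair(PhantomSpec(seed=1))
        b = make_phantom_pair(PhantomSpec(seed=2))
        assert not (a[0].values == b[0].values).all()
        assert (a[2].values == b[2].values).all()  # mask geometry is seed-free

    def test_no_lesions_no_noise_identity_case(self):
        spec = PhantomSpec(
            lesion_count=0, acquisition_noise_sd=0.0, parenchyma_HU_sd=0.0, seed=5
        )
        pre, post, mask = make_phantom_pair(spec)
        assert (pre.values == post.values).all()
        fv_pre = extract_all(pre, mask)
        fv_post = extract_all(post, mask)
        assert (fv_pre.values == fv_post.values).all()

    def test_hu_within_calibrated_bounds(self):
        pre, post, _ = make_phantom_pair(PhantomSpec(seed=3))
        for v in (pre, post):
            assert v.values.min() >= HU_MIN and v.values.max() <= HU_MAX

    def test_responder_loses_lesion_density(self):
        spec = PhantomSpec(response_class="responder", seed=9)
        pre, post, mask = make_phantom_pair(spec)
        assert post.values[mask.values].mean() < pre.values[mask.values].mean()

    def test_invalid_class_rejected(self):
        with pytest.raises(ValueError, match="response_class"):
            make_phantom_pair(PhantomSpec(response_class="bogus"))


class TestPerturbMask:
    @pytest.fixture()
    def sphere(self):
        g = np.indices((30, 30, 30)).astype(float)
        d2 = sum((gi - 14.5) ** 2 for gi in g)
        from deltarad.volumes import SegmentationMask

        return SegmentationMask(d2 <= 12**2, (1, 1, 1))

    def test_zero_magnitude_is_identity(self, sphere):
        out = perturb_mask(sphere, magnitude=0, seed=1)
        assert (out.values == sphere.values).all()

    def test_default_magnitude_keeps_dice_high(self, sphere):
        out = perturb_mask(sphere, magnitude=1, seed=1)
        inter = (out.values & sphere.values).sum()
        dice = 2 * inter / (out.values.sum() + sphere.values.sum())
        assert dice >= 0.9
        assert not (out.values == sphere.values).all()

    def test_huge_magnitude_warns(self, sphere, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="deltarad.synthetic"):
            perturb_mask(sphere, magnitude=12, seed=1)
        assert any("Dice" in r.message for r in caplog.records)


class TestProteome:
    @pytest.fixture()
    def delta(self, rng):
        return pd.DataFrame(
            rng.normal(size=(12, 3)), columns=["f1", "f2", "f3"],
            index=[f"S{i}" for i in range(12)],
        )

    @pytest.mark.parametrize("target", [1.0, -1.0])
    def test_exact_monotone_copy_at_unit_target(self, delta, target):
        planted = [{"feature": "f1", "protein": "PROT00001", "rho": target}]
        mat, _ = make_proteome(delta, planted, n_proteins=10, noise_sd=0.0, seed=1)
        rho = stats.spearmanr(delta["f1"], mat.loc["PROT00001"]).statistic
        assert rho == pytest.approx(target)

    def test_copula_hits_target_on_average(self, delta):
        # mean realized Spearman rho over 100 seeds within [0.65, 0.95]
        rhos = []
        for seed in range(100):
            mat, _ = make_proteome(
                delta.iloc[:10],
                [{"feature": "f2", "protein": "PROT00002", "rho": 0.8}],
                n_proteins=5,
                seed=seed,
            )
            rhos.append(
                stats.spearmanr(delta["f2"].iloc[:10], mat.loc["PROT00002"]).statistic
            )
        assert 0.65 <= np.mean(rhos) <= 0.95

    def test_copula_transform_endpoints(self):
        assert spearman_to_pearson_copula(1.0) == pytest.approx(1.0)
        assert spearman_to_pearson_copula(0.0) == pytest.approx(0.0)

    def test_too_few_proteins_rejected(self, delta):
        planted = [
            {"feature": "f1", "protein": f"PROT0000{i}", "rho": 0.8} for i in range(1, 4)
        ]
        with pytest.raises(ValueError, match="n_proteins"):
            make_proteome(delta, planted, n_proteins=2)

    def test_intensities_finite_and_deterministic(self, delta):
        a, _ = make_proteome(delta, n_proteins=50, seed=9)
        b, _ = make_proteome(delta, n_proteins=50, seed=9)
        assert np.isfinite(a.to_numpy()).all()
        assert (a.to_numpy() == b.to_numpy()).all()


class TestSignaturesAndCohort:
    def test_markers_satisfy_signature_definition(self):
        df = make_signatures(n_celltypes=3, markers_per_type=10, seed=0)
        assert (df["log2FC"] > 0.3).all()
        assert (df["padj"] < 0.05).all()
        assert df.groupby("cell_type").size().eq(10).all()
        # disjoint by default
        assert df["gene"].is_unique

    def test_too_few_markers_rejected(self):
        with pytest.raises(ValueError, match="markers_per_type"):
            make_signatures(markers_per_type=0)

    def test_cohort_cluster_effects_detectable(self):
        # planted -1% vs -10% FVC delta, sd 2%: Mann-Whitney P < 0.05 at
        # n=8 per group in >= 80% of seeds
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            cohort, truth = make_cohort(
                n_patients=16, cluster_effects={"A": -1.0, "B": -10.0}, seed=seed
            )
            delta = cohort["fvc_pct_post"] - cohort["fvc_pct_pre"]
            labels = pd.Series(truth.response_class)
            p = stats.mannwhitneyu(
                delta[labels == "A"], delta[labels == "B"], alternative="two-sided"
            ).pvalue
            hits += p < 0.05
        assert hits / n_seeds >= 0.8

    def test_cohort_dates_ordered(self):
        cohort, _ = make_cohort(n_patients=6, seed=1)
        assert (
            pd.to_datetime(cohort["date_post"]) > pd.to_datetime(cohort["date_pre"])
        ).all()


class TestEndToEndSeparation:
    def test_planted_clusters_separate_downstream(self, cohort_delta):
        # 10 + 10 planted response classes must yield silhouette > 0.25 at k=2
        from sklearn.metrics import silhouette_score

        from deltarad.clustering import cluster, zscore

        delta, truth = cohort_delta
        z = zscore(delta)
        labels = cluster(z, "kmeans", k=2, seed=0)
        assert silhouette_score(z.to_numpy(), labels) > 0.25
        planted = [truth.response_class[s] for s in delta.index]
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(planted, labels) >= 0.8
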