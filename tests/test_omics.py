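"""Differential expression, association modules, ORA, and deconvolution."""

import math
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from deltarad.omics import (
    build_association_module,
    differential_expression,
    ora_enrichment,
    signature_deconvolution,
    spearman_with_p,
    terms_in_multiple_modules,
)


def spearman_rank_formula(x, y):
    """Independent oracle: rho = 1 - 6*sum(d^2)/(n(n^2-1)) for untied data."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(x)
    return 1 - 6 * ((rx - ry) ** 2).sum() / (n * (n**2 - 1))


def hypergeom_tail_oracle(k, N, K, n):
    """Upper-tail P(X >= k) by direct enumeration of the hypergeometric pmf."""
    return sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1)) / comb(
        N, n
    )


class TestDifferentialExpression:
    def _proteome(self, rng, n_prot=50, n_per=5, shift=0.0):
        a = rng.normal(25, 0.3, (n_prot, n_per))
        b = rng.normal(25 + shift, 0.3, (n_prot, n_per))
        mat = pd.DataFrame(
            np.hstack([a, b]),
            index=[f"P{i}" for i in range(n_prot)],
            columns=[f"v{i}" for i in range(n_per)] + [f"t{i}" for i in range(n_per)],
        )
        labels = pd.Series(
            ["vehicle"] * n_per + ["treated"] * n_per, index=mat.columns
        )
        return mat, labels

    def test_identical_groups_unflagged(self, rng):
        mat, labels = self._proteome(rng)
        mat.iloc[:, 5:] = mat.iloc[:, :5].to_numpy()
        res = differential_expression(mat, labels, reference="vehicle")
        assert (res["log2FC"] == 0).all()
        assert not res["significant"].any()

    def test_planted_shift_power(self):
        # 1.0 log2-unit shift, sd 0.3, n=5+5: flagged in >= 95% of proteins
        rng = np.random.default_rng(1)
        mat, labels = self._proteome(rng, n_prot=200, shift=1.0)
        res = differential_expression(mat, labels, reference="vehicle")
        assert res["significant"].mean() >= 0.95
        assert res["log2FC"].mean() == pytest.approx(1.0, abs=0.1)

    def test_global_null_flag_rate(self):
        # aggregate over seeds: expected joint rate P(|FC|>0.3 and p<0.05) < 5%
        rates = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            mat, labels = self._proteome(rng, n_prot=500, shift=0.0)
            res = differential_expression(mat, labels, reference="vehicle")
            rates.append(res["significant"].mean())
        assert np.mean(rates) < 0.05

    def test_bh_adjustment_monotone_in_raw_p(self, rng):
        mat, labels = self._proteome(rng, n_prot=100, shift=0.2)
        res = differential_expression(mat, labels).sort_values("p")
        assert (np.diff(res["padj"]) >= -1e-12).all()

    def test_small_group_rejected(self, rng):
        mat, labels = self._proteome(rng)
        labels.iloc[:] = ["vehicle"] + ["treated"] * 9
        with pytest.raises(ValueError, match="at least 2"):
            differential_expression(mat, labels)


class TestSpearman:
    def test_matches_rank_formula_oracle(self, rng):
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        rho, _ = spearman_with_p(x, y)
        assert rho == pytest.approx(spearman_rank_formula(x, y), abs=1e-12)

    def test_exact_small_sample_p_matches_r_cor_test(self):
        # frozen oracle: R cor.test(x, y, method="spearman", exact=TRUE)
        x = np.array([0.3, -1.2, 0.8, 2.1, -0.5, 0.05, 1.4, -0.9])
        y = np.array([1.0, 0.2, -0.3, 1.8, 0.7, -1.1, 0.4, 0.9])
        rho, p = spearman_with_p(x, y)
        assert rho == pytest.approx(0.261904761904762, abs=1e-12)
        assert p == pytest.approx(0.536408730158730, abs=1e-12)

    def test_perfect_monotone_relations(self):
        x = np.arange(10.0)
        assert spearman_with_p(x, np.exp(x))[0] == 1.0
        assert spearman_with_p(x, -(x**3))[0] == -1.0


class TestAssociationModule:
    @pytest.fixture()
    def feature(self, rng):
        return pd.Series(rng.normal(size=10), index=[f"S{i}" for i in range(10)], name="f")

    def test_monotone_copy_enters_positive_set(self, feature):
        prot = pd.DataFrame([np.exp(feature.to_numpy())], index=["P1"], columns=feature.index)
        mod = build_association_module(feature, prot)
        assert "P1" in set(mod.positive.index)
        assert mod.members.loc["P1", "rho"] == 1.0

    def test_monotone_reversal_enters_negative_set(self, feature):
        prot = pd.DataFrame([-feature.to_numpy()], index=["P1"], columns=feature.index)
        mod = build_association_module(feature, prot)
        assert "P1" in set(mod.negative.index)

    def test_membership_invariant_under_monotone_transforms(self, feature, rng):
        prot = pd.DataFrame(
            rng.normal(size=(20, 10)), index=[f"P{i}" for i in range(20)],
            columns=feature.index,
        )
        mod1 = build_association_module(feature, prot)
        mod2 = build_association_module(feature.rank(), np.exp(prot * 0.3))
        assert mod1.proteins == mod2.proteins

    def test_weights_follow_rank_and_correlation_rule(self, feature, rng):
        prot = pd.DataFrame(
            [feature.to_numpy() + rng.normal(0, 0.3, 10)], index=["P1"],
            columns=feature.index,
        )
        mod = build_association_module(feature, prot)
        if len(mod.members):
            row = mod.members.loc["P1"]
            assert row["weight"] == pytest.approx(
                math.copysign(1, row["rho"]) * (-math.log10(row["p"])) * abs(row["rho"])
            )

    def test_planted_correlations_recovered(self):
        # sensitivity >= 0.8 for target rho = 0.8 at n = 10
        from deltarad.synthetic import make_proteome

        rng = np.random.default_rng(3)
        delta = pd.DataFrame(
            rng.normal(size=(10, 4)), columns=list("abcd"),
            index=[f"S{i}" for i in range(10)],
        )
        planted = [
            {"feature": "a", "protein": f"PROT{i:05d}", "rho": 0.8} for i in range(1, 31)
        ]
        mat, _ = make_proteome(delta, planted, n_proteins=100, seed=7)
        mod = build_association_module(delta["a"], mat)
        hits = len({p["protein"] for p in planted} & mod.proteins)
        assert hits / len(planted) >= 0.8

    def test_too_few_samples_rejected(self, rng):
        f = pd.Series(rng.normal(size=4), index=list("wxyz"), name="f")
        prot = pd.DataFrame(rng.normal(size=(3, 4)), columns=list("wxyz"))
        with pytest.raises(ValueError, match="shared samples"):
            build_association_module(f, prot)


class TestORA:
    def test_exact_copy_term_retained(self):
        members = {"g1", "g2", "g3", "g4", "g5"}
        bg = {f"g{i}" for i in range(1, 51)}
        res = ora_enrichment(members, bg, {"term": set(members)})
        assert res.loc["term", "gene_ratio"] == 1.0
        assert res.loc["term", "retained"]
        assert res.loc["term", "p"] == pytest.approx(
            hypergeom_tail_oracle(5, 50, 5, 5), rel=1e-12
        )

    def test_tail_matches_enumeration_oracle(self):
        # 4 of 10 members from a 20-gene term in a 100-gene background
        bg = {f"g{i}" for i in range(100)}
        term = {f"g{i}" for i in range(20)}
        members = {f"g{i}" for i in range(4)} | {f"g{i}" for i in range(50, 56)}
        res = ora_enrichment(members, bg, {"t": term})
        assert res.loc["t", "overlap"] == 4
        assert res.loc["t", "p"] == pytest.approx(
            hypergeom_tail_oracle(4, 100, 20, 10), rel=1e-12
        )

    def test_random_instances_match_oracle(self, rng):
        for _ in range(10):
            n_bg = int(rng.integers(20, 200))
            bg = {f"g{i}" for i in range(n_bg)}
            term = set(rng.choice(sorted(bg), size=rng.integers(3, n_bg // 2), replace=False))
            members = set(rng.choice(sorted(bg), size=rng.integers(3, n_bg // 2), replace=False))
            res = ora_enrichment(members, bg, {"t": term})
            k = len(term & members)
            assert res.loc["t", "p"] == pytest.approx(
                hypergeom_tail_oracle(k, n_bg, len(term), len(members)), rel=1e-10
            )

    def test_disjoint_term_not_retained(self):
        bg = {f"g{i}" for i in range(40)}
        res = ora_enrichment({"g1", "g2"}, bg, {"t": {"g30", "g31"}})
        assert res.loc["t", "gene_ratio"] == 0.0
        assert not res.loc["t", "retained"]

    def test_empty_member_set_empty_result(self):
        res = ora_enrichment(set(), {"g1"}, {"t": {"g1"}})
        assert res.empty

    def test_member_not_in_background_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            ora_enrichment({"x"}, {"g1"}, {})

    def test_cross_module_display_rule(self):
        df_yes = pd.DataFrame({"retained": [True]}, index=["shared"])
        df_no = pd.DataFrame({"retained": [False]}, index=["shared"])
        shown = terms_in_multiple_modules({"m1": df_yes, "m2": df_yes, "m3": df_no})
        assert shown == ["shared"]
        assert terms_in_multiple_modules({"m1": df_yes, "m2": df_no}) == []


class TestDeconvolution:
    def _weights(self, n=100, seed=0):
        rng = np.random.default_rng(seed)
        w = pd.Series(rng.normal(size=n), index=[f"P{i}" for i in range(n)])
        return w

    def test_top_ranked_signature_significant(self):
        w = self._weights()
        top = set(w.sort_values(ascending=False).index[:15])
        res = signature_deconvolution(w, {"sig": top})
        assert res.loc["sig", "p"] < 0.01
        assert res.loc["sig", "signed_log10p"] > 0

    def test_interleaved_markers_not_significant(self):
        w = pd.Series(np.linspace(1, -1, 100), index=[f"P{i}" for i in range(100)])
        spread = {f"P{i}" for i in range(0, 100, 10)}
        res = signature_deconvolution(w, {"sig": spread})
        assert res.loc["sig", "p"] > 0.1

    def test_sign_flips_when_weights_negated(self):
        w = self._weights(seed=5)
        top = set(w.sort_values(ascending=False).index[:12])
        res_pos = signature_deconvolution(w, {"sig": top})
        res_neg = signature_deconvolution(-w, {"sig": top})
        assert res_pos.loc["sig", "sign"] == -res_neg.loc["sig", "sign"]
        assert res_pos.loc["sig", "p"] == pytest.approx(res_neg.loc["sig", "p"], rel=1e-9)

    def test_sparse_signature_skipped(self):
        w = self._weights()
        res = signature_deconvolution(w, {"tiny": {"P1", "P2"}})
        assert res.empty

    def test_short_list_rejected(self):
        w = self._weights(n=20)
        with pytest.raises(ValueError, match="50"):
            signature_deconvolution(w, {"s": set(w.index[:6])})

    def test_opposing_cell_types_get_opposite_signs(self):
        # planted profibrotic-up / regenerative-down structure
        from deltarad.synthetic import make_proteome

        rng = np.random.default_rng(11)
        delta = pd.DataFrame(
            rng.normal(size=(12, 2)), columns=["f", "g"],
            index=[f"S{i}" for i in range(12)],
        )
        up = [f"PROT{i:05d}" for i in range(1, 11)]
        down = [f"PROT{i:05d}" for i in range(11, 21)]
        planted = [{"feature": "f", "protein": p, "rho": 0.9} for p in up] + [
            {"feature": "f", "protein": p, "rho": -0.9} for p in down
        ]
        mat, _ = make_proteome(delta, planted, n_proteins=120, seed=13)
        from deltarad.omics import association_weights

        w = association_weights(delta["f"], mat)
        res = signature_deconvolution(
            w, {"myofibroblast": set(up), "AT2": set(down)}
        )
        assert res.loc["myofibroblast", "signed_log10p"] > 0
        assert res.loc["AT2", "signed_log10p"] < 0
        assert (res["p"] < 0.01).all()
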