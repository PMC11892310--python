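"""Two-locus stratification, additive-epistasis ANOVA, contrasts."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
import statsmodels.formula.api as smf

from cottonmine import epistasis as ep
from cottonmine.errors import InsufficientDataError


def balanced_design(beta_a=2.0, beta_d=1.0, beta_i=0.0, sigma=0.0, n_per=10, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for a in (0, 2):
        for d in (0, 2):
            for k in range(n_per):
                y = 30 + beta_a * (a == 2) + beta_d * (d == 2) + beta_i * (a == 2 and d == 2)
                rows.append((f"r{a}{d}{k}", a, d, y + rng.normal(0, sigma)))
    df = pd.DataFrame(rows, columns=["ril", "a", "d", "y"]).set_index("ril")
    return ep.stratify(df["a"], df["d"], df["y"])


class TestStratify:
    def test_het_and_missing_excluded_and_tallied(self):
        idx = ["r1", "r2", "r3", "r4", "r5"]
        a = pd.Series([0, 1, 2, 0, -1], index=idx)
        d = pd.Series([0, 0, 2, 2, 0], index=idx)
        y = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0], index=idx)
        design = ep.stratify(a, d, y)
        assert len(design.data) == 3
        assert design.n_excluded["heterozygous"] == 1
        assert design.n_excluded["missing"] == 1
        assert design.class_sizes().sum() == 3

    def test_no_retained_ril_raises(self):
        a = pd.Series([1, 1], index=["r1", "r2"])
        d = pd.Series([0, 0], index=["r1", "r2"])
        y = pd.Series([1.0, 2.0], index=["r1", "r2"])
        with pytest.raises(InsufficientDataError):
            ep.stratify(a, d, y)

    def test_class_sizes_match_generator_manifest(self, small_dataset):
        ds = small_dataset
        a = pd.Series(ds.genotypes[:, ds.drivers["A"]], index=ds.ril_ids)
        d = pd.Series(ds.genotypes[:, ds.drivers["D"]], index=ds.ril_ids)
        y = ds.phenotype.set_index("ril_id")["value"]
        design = ep.stratify(a, d, y)
        assert design.class_sizes().to_dict() == ds.manifest["class_sizes"]


class TestAdditiveAnova:
    def test_noiseless_additive_interaction_ss_zero(self):
        res = ep.additive_anova(balanced_design(sigma=0.0))
        assert res.terms.loc["A:D", "sum_sq"] == pytest.approx(0.0, abs=1e-18)
        assert res.terms.loc["A", "sum_sq"] > 0

    def test_balanced_type1_equals_type2(self):
        design = balanced_design(sigma=1.0, beta_i=0.5, seed=4)
        ours = ep.additive_anova(design).terms
        model = smf.ols("value ~ C(A) * C(D)", data=design.data).fit()
        type1 = sm.stats.anova_lm(model, typ=1)
        for term, t1_term in [("A", "C(A)"), ("D", "C(D)"), ("A:D", "C(A):C(D)")]:
            assert ours.loc[term, "sum_sq"] == pytest.approx(type1.loc[t1_term, "sum_sq"])

    def test_ss_decomposition_on_balanced_design(self):
        design = balanced_design(sigma=1.0, seed=8)
        res = ep.additive_anova(design)
        total = ((design.data["value"] - design.data["value"].mean()) ** 2).sum()
        assert res.terms["sum_sq"].sum() == pytest.approx(total)

    def test_residual_df_counts_estimated_cells(self):
        design = balanced_design(sigma=1.0, n_per=7, seed=2)
        res = ep.additive_anova(design)
        assert res.terms.loc["Residual", "df"] == 4 * 7 - 4

    def test_shift_invariance(self):
        design = balanced_design(sigma=1.0, seed=3)
        res1 = ep.additive_anova(design)
        shifted = ep.TwoLocusDesign(data=design.data.assign(value=design.data["value"] + 100))
        res2 = ep.additive_anova(shifted)
        pd.testing.assert_frame_equal(res1.terms[["F", "p"]], res2.terms[["F", "p"]])

    def test_parameter_recovery_full_population(self, default_dataset):
        """beta_a=2, beta_d=1, interaction 0 at n=550: recovered within 3 SE."""
        ds = default_dataset
        a = pd.Series(ds.genotypes[:, ds.drivers["A"]], index=ds.ril_ids)
        d = pd.Series(ds.genotypes[:, ds.drivers["D"]], index=ds.ril_ids)
        y = ds.phenotype.set_index("ril_id")["value"]
        design = ep.stratify(a, d, y)
        model = smf.ols("value ~ I(A == 'ALT') * I(D == 'ALT')", data=design.data).fit()
        for name, truth in [
            ("I(A == 'ALT')[T.True]", ds.config.beta_a),
            ("I(D == 'ALT')[T.True]", ds.config.beta_d),
        ]:
            est, se = model.params[name], model.bse[name]
            assert abs(est - truth) < 3 * se
        res = ep.additive_anova(design)
        assert res.terms.loc["A:D", "p"] > 0.05

    def test_empty_classes_rejected(self):
        df = pd.DataFrame(
            {"a": [0, 0, 2, 2], "d": [0, 0, 0, 0], "y": [1.0, 2.0, 3.0, 4.0]},
            index=["r1", "r2", "r3", "r4"],
        )
        design = ep.stratify(df["a"], df["d"], df["y"])
        with pytest.raises(InsufficientDataError):
            ep.additive_anova(design)


class TestContrasts:
    def test_best_class_not_compared_to_itself(self):
        res = ep.contrasts_vs_best(balanced_design(sigma=0.5, seed=6))
        assert "ALT/ALT" not in res.index
        assert set(res["best_class"]) == {"ALT/ALT"}

    def test_three_sigma_gap_flagged_at_finest_level(self):
        for seed in range(20):
            design = balanced_design(beta_a=3.0, beta_d=0.0, sigma=1.0, n_per=50, seed=seed)
            res = ep.contrasts_vs_best(design)
            assert res.loc["REF/REF", "p"] < 0.001
            assert res.loc["REF/REF", "alpha_passed"] == 0.001

    def test_null_gap_rarely_significant(self):
        pvals = [
            ep.contrasts_vs_best(
                balanced_design(beta_a=0.0, beta_d=0.0, sigma=1.0, n_per=40, seed=s)
            )["p"].min()
            for s in range(40)
        ]
        assert np.mean(np.array(pvals) < 0.001) < 0.2


class TestExpressionSummary:
    def test_driver_gene_responds_to_own_locus_only(self, default_dataset):
        ds = default_dataset
        gene_a = ds.manifest["driver_a"]["gene_id"]
        gene_d = ds.manifest["driver_d"]["gene_id"]
        a = pd.Series(ds.genotypes[:, ds.drivers["A"]], index=ds.ril_ids)
        d = pd.Series(ds.genotypes[:, ds.drivers["D"]], index=ds.ril_ids)
        y = ds.phenotype.set_index("ril_id")["value"]
        expr = ds.expression["16DPA"].values.loc[[gene_a, gene_d]].T
        design = ep.stratify(a, d, y, expression=expr)
        summaries = ep.genotype_expression_summary(design)
        res_a = summaries[gene_a]
        assert res_a.terms.loc["A", "p"] < 1e-6
        assert res_a.terms.loc["A:D", "p"] > 0.01
        res_d = summaries[gene_d]
        assert res_d.terms.loc["D", "p"] < 1e-6
        assert res_d.terms.loc["A:D", "p"] > 0.01
        # ALT classes express higher than REF classes for the driven gene
        groups = res_a.groups
        assert groups.loc["ALT/REF", "mean"] > groups.loc["REF/REF", "mean"]

    def test_class_means_match_generator_expectations(self, default_dataset):
        ds = default_dataset
        gene_a = ds.manifest["driver_a"]["gene_id"]
        a = pd.Series(ds.genotypes[:, ds.drivers["A"]], index=ds.ril_ids)
        d = pd.Series(ds.genotypes[:, ds.drivers["D"]], index=ds.ril_ids)
        y = ds.phenotype.set_index("ril_id")["value"]
        expr = ds.expression["16DPA"].values.loc[[gene_a]].T
        design = ep.stratify(a, d, y, expression=expr)
        summary = ep.genotype_expression_summary(design)[gene_a]
        g = summary.groups
        fold = (
            g.loc[["ALT/REF", "ALT/ALT"], "mean"].mean()
            / g.loc[["REF/REF", "REF/ALT"], "mean"].mean()
        )
        assert fold == pytest.approx(ds.config.eqtl_fold, rel=0.25)

    def test_missing_expression_rejected(self):
        with pytest.raises(ValueError):
            ep.genotype_expression_summary(balanced_design())
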