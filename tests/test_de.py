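import subprocess

import numpy as np
import pandas as pd
import pytest

from mirnarray.de import (
    ContrastMatrix,
    ModeratedLinearModel,
    bh_adjust,
    build_design,
    contrast_fit,
    decide_tests,
    estimate_prior,
    lm_fit,
    make_contrasts,
    moderate,
    significant_table,
    trigamma_inverse,
    write_reports,
)

from conftest import make_exprs, make_targets


@pytest.fixture()
def paired_targets():
    return make_targets(["A", "A", "B", "B", "C", "C"], subjects=[1, 2, 1, 2, 1, 2])


class TestDesign:
    def test_three_treatments_plus_subject(self, paired_targets):
        design = build_design(paired_targets, ["Treatment", "Subject"])
        assert design.values.shape == (6, 4)
        assert design.coef_names[:3] == ["A", "B", "C"]
        assert np.linalg.matrix_rank(design.values) == 4

    def test_single_level_factor_is_intercept_only(self):
        targets = make_targets(["A", "A", "A"])
        design = build_design(targets, ["Treatment"])
        np.testing.assert_array_equal(design.values, np.ones((3, 1)))

    def test_duplicate_factor_columns_rank_error(self, paired_targets):
        with pytest.raises(ValueError, match="confounded"):
            build_design(paired_targets, ["Treatment", "Treatment"])

    def test_unknown_factor_rejected(self, paired_targets):
        with pytest.raises(KeyError):
            build_design(paired_targets, ["Treatment", "Batch"])


class TestContrastMatrix:
    def test_parser_builds_difference(self, paired_targets):
        design = build_design(paired_targets, ["Treatment"])
        contrasts = make_contrasts(["B-A", "C-A"], design)
        np.testing.assert_array_equal(
            contrasts.values, [[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]]
        )

    def test_all_zero_contrast_rejected(self):
        with pytest.raises(ValueError):
            ContrastMatrix(np.zeros((2, 1)), ["null"], ["A", "B"])


class TestLmFit:
    def test_intercept_only_closed_form(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 5))
        exprs = make_exprs(X, ["A"] * 5)
        design = build_design(make_targets(["A"] * 5), ["Treatment"])
        fit = lm_fit(exprs, design)
        np.testing.assert_allclose(fit.coefficients[:, 0], X.mean(axis=1))
        np.testing.assert_allclose(fit.sigma, X.std(axis=1, ddof=1))
        assert fit.df_residual == 4

    def test_exact_fit_zero_sigma(self):
        values = np.array([[1.0, 1.0, 4.0, 4.0]])
        exprs = make_exprs(values, ["A", "A", "B", "B"])
        design = build_design(make_targets(["A", "A", "B", "B"]))
        fit = lm_fit(exprs, design)
        assert fit.sigma[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_lstsq_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 6))
        treatments = ["A", "A", "B", "B", "C", "C"]
        exprs = make_exprs(X, treatments)
        design = build_design(make_targets(treatments))
        fit = lm_fit(exprs, design)
        for g in range(20):
            beta, rss, *_ = np.linalg.lstsq(design.values, X[g], rcond=None)
            np.testing.assert_allclose(fit.coefficients[g], beta, atol=1e-10)
            np.testing.assert_allclose(
                fit.sigma[g], np.sqrt(rss[0] / fit.df_residual), atol=1e-10
            )

    def test_no_residual_df_rejected(self):
        exprs = make_exprs(np.zeros((3, 2)), ["A", "B"])
        design = build_design(make_targets(["A", "B"]))
        with pytest.raises(ValueError, match="residual"):
            lm_fit(exprs, design)


class TestContrastFit:
    @pytest.fixture()
    def fit(self):
        rng = np.random.default_rng(2)
        treatments = ["A"] * 3 + ["B"] * 3
        exprs = make_exprs(rng.normal(size=(10, 6)), treatments)
        return lm_fit(exprs, build_design(make_targets(treatments)))

    def test_identity_contrast_is_noop(self, fit):
        identity = ContrastMatrix(np.eye(2), ["A", "B"], ["A", "B"])
        rotated = contrast_fit(fit, identity)
        np.testing.assert_allclose(rotated.coefficients, fit.coefficients)
        np.testing.assert_allclose(rotated.stdev_unscaled, fit.stdev_unscaled)

    def test_two_sample_unscaled_sd(self, fit):
        contrast = ContrastMatrix(np.array([[-1.0], [1.0]]), ["B-A"], ["A", "B"])
        rotated = contrast_fit(fit, contrast)
        np.testing.assert_allclose(rotated.stdev_unscaled, np.sqrt(2.0 / 3.0))

    def test_zero_sum_contrast_on_equal_coefficients(self):
        values = np.tile([[2.0]], (1, 6)).astype(float)
        exprs = make_exprs(values + np.array([[0, 0, 0, 0, 0.5, -0.5]]), ["A", "A", "B", "B", "C", "C"])
        design = build_design(make_targets(["A", "A", "B", "B", "C", "C"]))
        fit = lm_fit(exprs, design)
        contrast = ContrastMatrix(np.array([[1.0], [-1.0], [0.0]]), ["A-B"], ["A", "B", "C"])
        rotated = contrast_fit(fit, contrast)
        assert rotated.coefficients[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_dimension_mismatch_rejected(self, fit):
        bad = ContrastMatrix(np.ones((3, 1)), ["x"], ["a", "b", "c"])
        with pytest.raises(ValueError):
            contrast_fit(fit, bad)


class TestModeration:
    def test_identical_variances_infinite_prior(self):
        rng = np.random.default_rng(3)
        treatments = ["A"] * 3 + ["B"] * 3
        base = rng.normal(size=6)
        X = np.tile(base, (20, 1)) + rng.normal(size=(20, 1))  # same within-gene pattern
        exprs = make_exprs(X, treatments)
        fit = lm_fit(exprs, build_design(make_targets(treatments)))
        stats_ = moderate(fit)
        assert np.isinf(stats_.df_prior)
        np.testing.assert_allclose(stats_.s2_post, stats_.s2_post[0])

    def test_hyperparameter_recovery(self):
        rng = np.random.default_rng(7)
        d0, s02, dg, G = 4.0, 4.0, 4, 10_000
        sigma2 = s02 * d0 / rng.chisquare(d0, G)
        s2 = sigma2 * rng.chisquare(dg, G) / dg
        d0_hat, s02_hat = estimate_prior(s2, dg)
        assert 3.5 <= d0_hat <= 4.5
        assert 3.6 <= s02_hat <= 4.4

    def test_moderated_t_between_ordinary_and_pooled(self):
        rng = np.random.default_rng(4)
        treatments = ["A"] * 3 + ["B"] * 3
        X = rng.normal(size=(200, 6)) * rng.uniform(0.5, 2.0, size=(200, 1))
        exprs = make_exprs(X, treatments)
        design = build_design(make_targets(treatments))
        contrasts = make_contrasts(["B-A"], design)
        fit = contrast_fit(lm_fit(exprs, design), contrasts)
        stats_ = moderate(fit)
        with np.errstate(divide="ignore"):
            t_ord = fit.coefficients[:, 0] / (fit.stdev_unscaled[:, 0] * fit.sigma)
        t_pool = fit.coefficients[:, 0] / (
            fit.stdev_unscaled[:, 0] * np.sqrt(stats_.s2_prior)
        )
        t_mod = stats_.t[:, 0]
        lo = np.minimum(np.abs(t_ord), np.abs(t_pool))
        hi = np.maximum(np.abs(t_ord), np.abs(t_pool))
        ok = (np.abs(t_mod) >= lo - 1e-9) & (np.abs(t_mod) <= hi + 1e-9)
        assert ok.all()
        assert (np.sign(t_mod) == np.sign(t_ord)).all()

    def test_zero_prior_df_recovers_ordinary_t(self):
        rng = np.random.default_rng(5)
        treatments = ["A"] * 3 + ["B"] * 3
        exprs = make_exprs(rng.normal(size=(50, 6)), treatments)
        design = build_design(make_targets(treatments))
        fit = contrast_fit(lm_fit(exprs, design), make_contrasts(["B-A"], design))
        stats_ = moderate(fit, df_prior=0.0, s2_prior=1.0)
        t_ord = fit.coefficients[:, 0] / (fit.stdev_unscaled[:, 0] * fit.sigma)
        np.testing.assert_allclose(stats_.t[:, 0], t_ord)
        assert stats_.df_total == fit.df_residual

    def test_all_zero_variances_rejected(self):
        treatments = ["A", "A", "B", "B"]
        exprs = make_exprs(np.tile([[1.0, 1.0, 2.0, 2.0]], (3, 1)), treatments)
        fit = lm_fit(exprs, build_design(make_targets(treatments)))
        with pytest.raises(ValueError):
            moderate(fit)

    def test_trigamma_inverse_round_trip(self):
        from scipy.special import polygamma

        for y in [1e-5, 0.01, 0.5, 5.0, 1e6]:
            x = trigamma_inverse(y)
            assert float(polygamma(1, x)) == pytest.approx(y, rel=1e-6)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust(np.array([0.2])), [0.2])

    def test_hand_example(self):
        np.testing.assert_allclose(
            bh_adjust(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03]
        )

    def test_matches_step_up_oracle(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=40)
        n = len(p)
        order = np.argsort(p)
        adj = np.empty(n)
        running = 1.0
        for rank in range(n, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * n / rank)
            adj[i] = running
        np.testing.assert_allclose(bh_adjust(p), adj)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=100)
        assert (bh_adjust(p) >= p - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.5]))


class TestDecideTests:
    @staticmethod
    def stats_from(X, treatments, contrasts_spec):
        exprs = make_exprs(X, treatments)
        design = build_design(make_targets(treatments))
        contrasts = make_contrasts(contrasts_spec, design)
        return moderate(contrast_fit(lm_fit(exprs, design), contrasts))

    def test_null_p_values_give_empty_decision(self):
        stats_ = self.stats_from(
            np.tile([[0.0, 0.0, 0.0, 0.0]], (5, 1))
            + np.random.default_rng(8).normal(0, 1e-6, size=(5, 4)),
            ["A", "A", "B", "B"],
            ["B-A"],
        )
        stats_.p_value[:] = 1.0
        decision = decide_tests(stats_)
        assert (decision.to_numpy() == 0).all()

    def test_single_contrast_separated_equals_nested(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(100, 6))
        X[:10, 3:] += 3.0
        stats_ = self.stats_from(X, ["A"] * 3 + ["B"] * 3, ["B-A"])
        a = decide_tests(stats_, "separated", "BH", 0.05)
        b = decide_tests(stats_, "nestedF", "BH", 0.05)
        assert set(a.index[a["B-A"] != 0]) == set(b.index[b["B-A"] != 0])

    def test_cutoff_one_unadjusted_marks_all_nonzero(self):
        rng = np.random.default_rng(10)
        stats_ = self.stats_from(rng.normal(size=(30, 4)), ["A", "A", "B", "B"], ["B-A"])
        decision = decide_tests(stats_, "separated", "none", 1.0)
        signs = np.sign(stats_.coefficients[:, 0])
        np.testing.assert_array_equal(decision["B-A"].to_numpy(), signs)

    def test_unknown_method_rejected(self):
        rng = np.random.default_rng(11)
        stats_ = self.stats_from(rng.normal(size=(10, 4)), ["A", "A", "B", "B"], ["B-A"])
        with pytest.raises(ValueError):
            decide_tests(stats_, method="bogus")


class TestSignificantTable:
    @pytest.fixture()
    def stats_(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(20, 6))
        X[:3, 3:] += 4.0
        return TestDecideTests.stats_from(X, ["A"] * 3 + ["B"] * 3, ["B-A"])

    def test_exact_column_set(self, stats_):
        table = significant_table(stats_, "B-A")
        assert list(table.columns) == ["Probe", "Gene", "M", "A", "t", "pval", "adj.pval", "fdr.pval"]
        assert len(table) == 20  # all analyzed genes, not only significant

    def test_adjust_none_duplicates_pval(self, stats_):
        table = significant_table(stats_, "B-A", adjust="none")
        np.testing.assert_array_equal(table["adj.pval"], table["pval"])

    def test_adjust_bh_duplicates_fdr(self, stats_):
        table = significant_table(stats_, "B-A", adjust="BH")
        np.testing.assert_array_equal(table["adj.pval"], table["fdr.pval"])

    def test_representative_probe_is_smallest(self, stats_):
        table = significant_table(
            stats_, "B-A", gene_probes={g: ["zz", "aa"] for g in stats_.gene_names}
        )
        assert set(table["Probe"]) == {"aa"}


class TestWriteReports:
    def test_html_links_match_significant_count(self, tmp_path):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(50, 6))
        X[:3, 3:] += 6.0
        stats_ = TestDecideTests.stats_from(X, ["A"] * 3 + ["B"] * 3, ["B-A"])
        decisions = decide_tests(stats_)
        table = significant_table(stats_, "B-A")
        files = write_reports({"B-A": table}, decisions, tmp_path)
        html = (tmp_path / "de_B-A.html").read_text()
        n_sig = int((decisions["B-A"] != 0).sum())
        assert html.count('<a href="http://microrna.sanger.ac.uk/') == n_sig
        assert n_sig == 3
        tsv = pd.read_csv(tmp_path / "de_B-A.tsv", sep="\t")
        assert len(tsv) == 50

    def test_zero_significant_still_valid_html(self, tmp_path):
        rng = np.random.default_rng(14)
        stats_ = TestDecideTests.stats_from(
            rng.normal(size=(30, 6)), ["A"] * 3 + ["B"] * 3, ["B-A"]
        )
        decisions = decide_tests(stats_)
        decisions[:] = 0
        table = significant_table(stats_, "B-A")
        write_reports({"B-A": table}, decisions, tmp_path)
        html = (tmp_path / "de_B-A.html").read_text()
        assert "<ul>" in html and html.count("<a href=") == 0


class TestEstimatorInterface:
    def test_sklearn_params_round_trip(self):
        model = ModeratedLinearModel(design=np.ones((4, 1)))
        params = model.get_params()
        assert "design" in params and "contrasts" in params
        clone = ModeratedLinearModel(**params)
        rng = np.random.default_rng(15)
        X = rng.normal(size=(4, 30))
        clone.fit(X)
        assert clone.t_.shape == (30, 1)
        assert clone.df_residual_ == 3

    def test_estimator_matches_functions(self):
        rng = np.random.default_rng(16)
        treatments = ["A"] * 3 + ["B"] * 3
        X = rng.normal(size=(40, 6))
        design = build_design(make_targets(treatments))
        contrasts = make_contrasts(["B-A"], design)
        model = ModeratedLinearModel(design=design, contrasts=contrasts).fit(X.T)
        stats_ = moderate(
            contrast_fit(lm_fit(make_exprs(X, treatments), design), contrasts)
        )
        np.testing.assert_allclose(model.t_, stats_.t)
        np.testing.assert_allclose(model.p_value_, stats_.p_value)


def test_null_type_one_error_rate():
    """Under a pure-noise model the moderated-t p<0.05 rate is ~5%."""
    rng = np.random.default_rng(17)
    G = 2000
    sd = rng.uniform(0.5, 2.0, size=(G, 1))
    X = rng.normal(size=(G, 6)) * sd
    treatments = ["A"] * 3 + ["B"] * 3
    design = build_design(make_targets(treatments))
    fit = contrast_fit(
        lm_fit(make_exprs(X, treatments), design), make_contrasts(["B-A"], design)
    )
    stats_ = moderate(fit)
    rate = float((stats_.p_value[:, 0] < 0.05).mean())
    assert abs(rate - 0.05) <= 0.02


def test_moderated_stats_match_limma_oracle(tmp_path):
    """Independent cross-check of lmFit/contrasts.fit/eBayes via Rscript."""
    rng = np.random.default_rng(18)
    X = rng.normal(size=(60, 6)) * rng.uniform(0.5, 2.0, size=(60, 1))
    X[:5, 3:] += 2.0
    np.savetxt(tmp_path / "x.tsv", X, delimiter="\t")
    script = f"""
suppressMessages(library(limma))
X <- as.matrix(read.delim("{tmp_path / 'x.tsv'}", header=FALSE))
design <- cbind(A=c(1,1,1,0,0,0), B=c(0,0,0,1,1,1))
fit <- lmFit(X, design)
fit2 <- eBayes(contrasts.fit(fit, makeContrasts(B-A, levels=design)))
out <- cbind(fit2$t[,1], fit2$p.value[,1], rep(fit2$df.prior, nrow(X)), rep(fit2$s2.prior, nrow(X)))
write.table(out, "{tmp_path / 'out.tsv'}", row.names=FALSE, col.names=FALSE)
"""
    subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
    expected = np.loadtxt(tmp_path / "out.tsv")
    treatments = ["A"] * 3 + ["B"] * 3
    design = build_design(make_targets(treatments))
    fit = contrast_fit(
        lm_fit(make_exprs(X, treatments), design), make_contrasts(["B-A"], design)
    )
    stats_ = moderate(fit)
    assert stats_.df_prior == pytest.approx(expected[0, 2], rel=1e-6)
    assert stats_.s2_prior == pytest.approx(expected[0, 3], rel=1e-6)
    np.testing.assert_allclose(stats_.t[:, 0], expected[:, 0], rtol=1e-8)
    np.testing.assert_allclose(stats_.p_value[:, 0], expected[:, 1], rtol=1e-6)
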