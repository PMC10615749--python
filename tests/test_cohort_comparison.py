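"""Long-format construction, 2x2 odds ratios, and the clustered models."""

import math
import shutil
import subprocess

import numpy as np
import pytest
import statsmodels.api as sm

from termref import (
    EstimationError,
    LongOutcome,
    ValidationError,
    build_long,
    fit_binomial_mlm,
    fit_ordinal_mlm,
    icc_latent,
    marginal_odds_ratio,
    simulate_band_source_cohort,
)


class TestBuildLong:
    def test_two_rows_per_dually_classified_child(self, small_classifications):
        rows = build_long(
            small_classifications["manual"], small_classifications["reference"]
        )
        n_children = len(small_classifications["manual"].frame)
        per_child = {}
        for r in rows:
            per_child[r.child_id] = per_child.get(r.child_id, 0) + 1
        assert all(v <= 2 for v in per_child.values())
        assert len(rows) <= 2 * n_children

    def test_binary_and_ordinal_encodings(self, small_classifications):
        bin_rows = build_long(
            small_classifications["manual"],
            small_classifications["reference"],
            outcome="binary",
        )
        ord_rows = build_long(
            small_classifications["manual"],
            small_classifications["reference"],
            outcome="ordinal",
        )
        assert set(r.outcome for r in bin_rows) <= {0, 1}
        assert set(r.outcome for r in ord_rows) <= {0, 1, 2}
        # binary == (ordinal >= moderate) row by row
        for rb, ro in zip(bin_rows, ord_rows):
            assert rb.outcome == int(ro.outcome >= 1)

    def test_mismatched_children_rejected(self, small_classifications):
        import dataclasses

        truncated = dataclasses.replace(
            small_classifications["reference"],
            frame=small_classifications["reference"].frame.iloc[:-1],
        )
        with pytest.raises(ValidationError):
            build_long(small_classifications["manual"], truncated)

    def test_invalid_outcome_kind(self, small_classifications):
        with pytest.raises(ValidationError):
            build_long(
                small_classifications["manual"],
                small_classifications["reference"],
                outcome="continuous",
            )


class TestMarginalOddsRatio:
    def test_reported_table_counts(self):
        # cognitive moderate/severe: reference 804/642 vs manual 621/825
        res = marginal_odds_ratio(804, 642, 621, 825)
        assert res.odds_ratio == pytest.approx(1.664, abs=1e-3)
        assert res.ci_low < res.odds_ratio < res.ci_high

    @pytest.mark.parametrize(
        "cells, expected",
        [((10, 10, 10, 10), 1.0), ((20, 10, 10, 20), 4.0)],
    )
    def test_simple_tables(self, cells, expected):
        assert marginal_odds_ratio(*cells).odds_ratio == pytest.approx(expected)

    def test_zero_cell_continuity_correction(self):
        res = marginal_odds_ratio(0, 10, 5, 5)
        assert res.continuity_corrected
        assert res.odds_ratio == pytest.approx((0.5 * 5.5) / (10.5 * 5.5))

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError):
            marginal_odds_ratio(0, 0, 5, 5)


class TestIccLatent:
    @pytest.mark.parametrize(
        "sigma2, expected",
        [(0.0, 0.0), (math.pi**2 / 3.0, 0.5), (0.1732, 0.050)],
    )
    def test_values(self, sigma2, expected):
        assert icc_latent(sigma2) == pytest.approx(expected, abs=5e-4)

    def test_negative_variance_rejected(self):
        with pytest.raises(ValidationError):
            icc_latent(-0.1)


@pytest.fixture(scope="module")
def clustered_data():
    return simulate_band_source_cohort(
        n_centers=12, n_children=80, log_or=0.62, sigma2_c=0.3, seed=42
    )


@pytest.fixture(scope="module")
def clustered_fit(clustered_data):
    return fit_binomial_mlm(clustered_data)


class TestBinomialMlm:
    def test_zero_variance_reduces_to_plain_logistic(self):
        """Data with no center effect: the mixed fit matches ordinary
        logistic regression coefficients to 1e-4."""
        data = simulate_band_source_cohort(
            n_centers=8, n_children=60, log_or=0.6, sigma2_c=0.0, seed=3
        )
        fit = fit_binomial_mlm(data)
        X = np.column_stack(
            [np.ones(len(data)), [r.band_source for r in data]]
        )
        y = np.array([r.outcome for r in data])
        plain = sm.Logit(y, X).fit(disp=0)
        assert fit.sigma2_c < 1e-4
        assert fit.coef["intercept"] == pytest.approx(plain.params[0], abs=1e-4)
        assert fit.coef["band_source"] == pytest.approx(plain.params[1], abs=1e-4)

    def test_agrees_with_lme4_glmer(self, clustered_data, clustered_fit, tmp_path):
        """Independent oracle: lme4::glmer with the same quadrature rule
        reproduces coefficients, SEs and the variance component."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable: oracle cannot run")
        csv = tmp_path / "glmm.csv"
        with open(csv, "w") as fh:
            fh.write("y,src,center\n")
            for r in clustered_data:
                fh.write(f"{r.outcome},{r.band_source},{r.center_id}\n")
        script = (
            "suppressMessages(library(lme4));"
            f"d <- read.csv('{csv}');"
            "m <- glmer(y ~ src + (1|center), data=d, family=binomial, nAGQ=21);"
            "co <- summary(m)$coefficients;"
            "cat(co[1,1], co[2,1], co[2,2], as.numeric(VarCorr(m)$center),"
            "    as.numeric(logLik(m)))"
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        b0, b1, se1, s2, ll = map(float, out.stdout.split())
        fit = clustered_fit
        assert fit.coef["intercept"] == pytest.approx(b0, abs=1e-4)
        assert fit.coef["band_source"] == pytest.approx(b1, abs=1e-4)
        assert fit.se["band_source"] == pytest.approx(se1, abs=1e-3)
        assert fit.sigma2_c == pytest.approx(s2, abs=1e-4)
        assert fit.loglik == pytest.approx(ll, abs=1e-3)

    def test_quadrature_converged(self, clustered_data):
        """Going from 11 to 41 quadrature nodes leaves the maximized
        log-likelihood unchanged to < 1e-6."""
        f11 = fit_binomial_mlm(clustered_data, n_nodes=11)
        f41 = fit_binomial_mlm(clustered_data, n_nodes=41)
        assert abs(f11.loglik - f41.loglik) < 1e-6

    def test_conditional_exceeds_marginal(self):
        """With a large center variance the conditional (center-specific)
        OR exceeds the population-averaged 2x2 OR."""
        data = simulate_band_source_cohort(
            n_centers=15, n_children=300, log_or=0.62, sigma2_c=2.0, seed=8
        )
        fit = fit_binomial_mlm(data)
        a = sum(r.outcome for r in data if r.band_source == 1)
        b = sum(1 - r.outcome for r in data if r.band_source == 1)
        c = sum(r.outcome for r in data if r.band_source == 0)
        d = sum(1 - r.outcome for r in data if r.band_source == 0)
        marginal = marginal_odds_ratio(a, b, c, d).odds_ratio
        assert fit.odds_ratio > marginal

    def test_wald_ci_consistent_with_p_value(self, clustered_fit):
        """The 95% CI excludes 1 exactly when |z| > 1.96 (p < 0.05)."""
        fit = clustered_fit
        excludes_one = fit.or_ci_low > 1.0 or fit.or_ci_high < 1.0
        assert excludes_one == (fit.p_value < 0.05)
        assert fit.or_ci_low < fit.odds_ratio < fit.or_ci_high

    def test_no_variation_rejected(self):
        rows = [
            LongOutcome(f"k{i}", f"C{i % 3}", i % 2, 1) for i in range(30)
        ]
        with pytest.raises(EstimationError):
            fit_binomial_mlm(rows)

    def test_separation_rejected(self):
        rows = [
            LongOutcome(f"k{i}", f"C{i % 4}", i % 2, i % 2) for i in range(200)
        ]
        with pytest.raises(EstimationError):
            fit_binomial_mlm(rows)

    def test_single_center_rejected(self):
        rows = [LongOutcome(f"k{i}", "C1", i % 2, (i // 2) % 2) for i in range(40)]
        with pytest.raises(ValidationError):
            fit_binomial_mlm(rows)

    def test_child_intercept_flag(self):
        """With no child-level variance in the data, the nested model
        reproduces the center-only fit."""
        data = simulate_band_source_cohort(
            n_centers=6, n_children=40, sigma2_c=0.2, seed=9
        )
        nested = fit_binomial_mlm(data, child_intercept=True, n_nodes=11)
        default = fit_binomial_mlm(data, n_nodes=11)
        assert nested.sigma2_child == pytest.approx(0.0, abs=1e-2)
        assert nested.coef["band_source"] == pytest.approx(
            default.coef["band_source"], abs=1e-3
        )
        assert nested.sigma2_c == pytest.approx(default.sigma2_c, abs=1e-3)


class TestOrdinalMlm:
    def test_two_category_reduction_matches_binomial(self, clustered_data):
        """A 2-level ordinal outcome is the same likelihood as the
        binomial model (threshold = -intercept); fits agree to 1e-6."""
        fb = fit_binomial_mlm(clustered_data)
        fo = fit_ordinal_mlm(clustered_data)
        assert fo.coef["band_source"] == pytest.approx(
            fb.coef["band_source"], abs=1e-6
        )
        assert fo.coef["threshold_1"] == pytest.approx(
            -fb.coef["intercept"], abs=1e-6
        )
        assert fo.sigma2_c == pytest.approx(fb.sigma2_c, abs=1e-6)
        assert fo.loglik == pytest.approx(fb.loglik, abs=1e-6)

    def test_proportional_odds_recovery(self):
        """Simulated proportional-odds data: common OR recovered within
        its Wald interval and thresholds near truth."""
        rng = np.random.default_rng(5)
        from scipy.special import expit

        c1, c2, log_or, s2 = -0.3, 1.2, 0.62, 0.17
        rows = []
        for c in range(15):
            b = rng.normal(0, math.sqrt(s2))
            for i in range(100):
                for src in (0, 1):
                    eta = log_or * src + b
                    u = rng.random()
                    y = 0 if u < expit(c1 - eta) else (1 if u < expit(c2 - eta) else 2)
                    rows.append(LongOutcome(f"C{c}-{i}", f"C{c}", src, y))
        fit = fit_ordinal_mlm(rows)
        assert fit.converged
        assert fit.or_ci_low < math.exp(log_or) < fit.or_ci_high
        assert fit.coef["threshold_1"] == pytest.approx(c1, abs=0.2)
        assert fit.coef["threshold_2"] == pytest.approx(c2, abs=0.2)
        assert fit.coef["threshold_1"] < fit.coef["threshold_2"]

    def test_sigma_zero_matches_ordered_model(self):
        """At zero center variance the cumulative-logit fit matches the
        independent proportional-odds implementation in statsmodels."""
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        rng = np.random.default_rng(17)
        from scipy.special import expit

        rows = []
        for c in range(5):
            for i in range(120):
                for src in (0, 1):
                    eta = 0.5 * src
                    u = rng.random()
                    y = 0 if u < expit(-0.5 - eta) else (1 if u < expit(1.0 - eta) else 2)
                    rows.append(LongOutcome(f"C{c}-{i}", f"C{c}", src, y))
        fit = fit_ordinal_mlm(rows)
        x = np.array([[r.band_source] for r in rows], dtype=float)
        y = np.array([r.outcome for r in rows])
        om = OrderedModel(y, x, distr="logit").fit(method="bfgs", disp=0)
        # OrderedModel: params = [beta, cut1, log-gap]; note its beta sign
        # convention matches ours (higher eta -> higher category)
        assert fit.sigma2_c < 5e-3
        assert fit.coef["band_source"] == pytest.approx(om.params[0], abs=5e-3)

    def test_no_variation_rejected(self):
        rows = [LongOutcome(f"k{i}", f"C{i % 3}", i % 2, 2) for i in range(30)]
        with pytest.raises(EstimationError):
            fit_ordinal_mlm(rows)
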