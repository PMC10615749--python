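"""Eligibility screening and the clustered synthetic cohort generator."""

import numpy as np
import pytest

from termref import (
    AssessmentRecord,
    CandidateBirth,
    SynthConfig,
    ValidationError,
    generate_candidates,
    generate_cohorts,
    records_to_frame,
    screen_eligibility,
)
from termref.reference_norms import COMPOSITES


def healthy_candidate(**overrides) -> CandidateBirth:
    base = dict(
        gestational_age_weeks=39.5,
        singleton=True,
        birth_weight_appropriate=True,
        resuscitated=False,
        congenital_anomaly=False,
        nicu_admission=False,
        cns_disorder=False,
        cps_custody=False,
        parent_incarcerated_or_psychosis=False,
    )
    base.update(overrides)
    return CandidateBirth(**base)


class TestScreening:
    def test_all_criteria_pass(self):
        eligible, failed = screen_eligibility(healthy_candidate())
        assert eligible and failed == []

    @pytest.mark.parametrize(
        "overrides, expected_failures",
        [
            ({"gestational_age_weeks": 38.9}, ["gestational_age"]),
            ({"gestational_age_weeks": 41.0}, ["gestational_age"]),
            ({"cns_disorder": True, "gestational_age_weeks": 40.0}, ["cns_disorder"]),
            ({"singleton": False}, ["singleton"]),
            ({"nicu_admission": True}, ["nicu_admission"]),
            (
                {"resuscitated": True, "congenital_anomaly": True},
                ["resuscitated", "congenital_anomaly"],
            ),
        ],
    )
    def test_failures_exhaustive_and_ordered(self, overrides, expected_failures):
        eligible, failed = screen_eligibility(healthy_candidate(**overrides))
        assert not eligible
        assert failed == expected_failures

    def test_window_boundaries_inclusive(self):
        assert screen_eligibility(healthy_candidate(gestational_age_weeks=39.0))[0]
        # 40 6/7 weeks is the last eligible day
        assert screen_eligibility(
            healthy_candidate(gestational_age_weeks=40.0 + 6.0 / 7.0)
        )[0]

    def test_missing_field_names_the_field(self):
        with pytest.raises(ValidationError, match="singleton"):
            healthy_candidate(singleton=None)

    def test_gestational_age_bounds(self):
        with pytest.raises(ValidationError):
            healthy_candidate(gestational_age_weeks=18.0)

    def test_candidate_stream_contains_both_outcomes(self):
        decisions = [screen_eligibility(c)[0] for c in generate_candidates(200, seed=4)]
        assert any(decisions) and not all(decisions)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_centers": 0},
            {"index_per_center": 0},
            {"accrual_ratio": 0},
            {"composite_sds_ref": (11.2, -1.0, 10.9)},
            {"inter_composite_corr": 1.0},
            {"center_icc": 1.0},
            {"missing_rates": (0.5, 1.0, 0.5)},
            {"index_sizes": (10, 10)},  # wrong length for 15 centers
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            SynthConfig(**kwargs)

    def test_correlation_matrix_positive_definite(self):
        cfg = SynthConfig(inter_composite_corr=0.9)
        assert np.all(np.linalg.eigvalsh(cfg.correlation_matrix()) > 0)


class TestGeneration:
    def test_count_arithmetic(self):
        cfg = SynthConfig(n_centers=15, index_per_center=10, accrual_ratio=5, seed=1)
        records = generate_cohorts(cfg)
        assert sum(r.cohort == "index" for r in records) == 150
        assert sum(r.cohort == "reference" for r in records) == 30

    def test_unequal_center_sizes(self):
        cfg = SynthConfig(
            n_centers=3,
            index_per_center=10,
            index_sizes=(5, 12, 20),
            accrual_ratio=5,
            seed=1,
        )
        frame = records_to_frame(generate_cohorts(cfg))
        idx = frame[frame.cohort == "index"].groupby("center_id").size()
        assert list(idx) == [5, 12, 20]
        ref = frame[frame.cohort == "reference"].groupby("center_id").size()
        assert list(ref) == [1, 3, 4]  # ceil(size / 5)

    def test_determinism(self):
        cfg = SynthConfig(n_centers=4, index_per_center=20, seed=77)
        assert generate_cohorts(cfg) == generate_cohorts(cfg)
        assert (
            records_to_frame(generate_cohorts(cfg)).to_csv()
            == records_to_frame(generate_cohorts(cfg)).to_csv()
        )

    def test_scores_integer_in_range(self, small_records):
        for r in small_records[:200]:
            for c in COMPOSITES:
                v = getattr(r, c)
                assert v is None or (isinstance(v, int) and 40 <= v <= 160)

    def test_moment_recovery_without_clustering(self):
        """With icc 0 the reference sample moments match the configured
        means/SDs within 3 standard errors (~1800 reference children)."""
        cfg = SynthConfig(
            n_centers=15,
            index_per_center=600,
            accrual_ratio=5,
            center_icc=0.0,
            missing_rates=(0.0, 0.0, 0.0),
            seed=42,
        )
        frame = records_to_frame(generate_cohorts(cfg))
        ref = frame[frame.cohort == "reference"]
        n = len(ref)
        assert n == 15 * 120
        for j, comp in enumerate(COMPOSITES):
            mu, sd = cfg.composite_means_ref[j], cfg.composite_sds_ref[j]
            x = ref[comp].astype(float)
            se_mean = sd / np.sqrt(n)
            se_sd = sd / np.sqrt(2 * (n - 1))
            assert abs(x.mean() - mu) < 3 * se_mean + 0.5  # +rounding slack
            assert abs(x.std(ddof=1) - sd) < 3 * se_sd + 0.3

    def test_missingness_rates_converge(self):
        cfg = SynthConfig(
            n_centers=10,
            index_per_center=400,
            missing_rates=(0.05, 0.10, 0.20),
            seed=5,
        )
        frame = records_to_frame(generate_cohorts(cfg))
        n = len(frame)
        for j, comp in enumerate(COMPOSITES):
            rate = frame[comp].isna().mean()
            p = cfg.missing_rates[j]
            assert abs(rate - p) < 3 * np.sqrt(p * (1 - p) / n)

    @pytest.mark.parametrize("icc", [0.0, 0.05])
    def test_anova_icc_recovery(self, icc):
        """One-way ANOVA variance components on the generated index scores
        recover the configured center ICC within Monte-Carlo error."""
        cfg = SynthConfig(
            n_centers=100,
            index_per_center=100,
            center_icc=icc,
            missing_rates=(0.0, 0.0, 0.0),
            seed=11,
        )
        frame = records_to_frame(generate_cohorts(cfg))
        idx = frame[frame.cohort == "index"]
        x = idx["cognitive"].astype(float).to_numpy()
        groups = idx["center_id"].to_numpy()
        k = cfg.n_centers
        m = cfg.index_per_center
        grand = x.mean()
        group_means = np.array([x[groups == g].mean() for g in np.unique(groups)])
        msb = m * np.sum((group_means - grand) ** 2) / (k - 1)
        msw = (
            sum(np.sum((x[groups == g] - x[groups == g].mean()) ** 2) for g in np.unique(groups))
            / (k * (m - 1))
        )
        icc_hat = (msb - msw) / (msb + (m - 1) * msw)
        # Fisher large-sample SE of the one-way ICC estimator
        se = np.sqrt(
            2 * (1 - icc) ** 2 * (1 + (m - 1) * icc) ** 2 / (m * (m - 1) * (k - 1))
        )
        assert abs(icc_hat - icc) < 3 * se + 0.005

    def test_record_validation(self):
        with pytest.raises(ValidationError):
            AssessmentRecord("k1", "c1", "index", cognitive=30)
        with pytest.raises(ValidationError):
            AssessmentRecord("k1", "c1", "preterm")
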