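"""Synthetic clustered cohorts with the score structure the analysis assumes.

The generator emulates a multicenter follow-up study: ~15 centers each
contribute an extremely-preterm (index) cohort and a smaller healthy
term-born (reference) cohort recruited at a configurable accrual ratio.
Latent composite scores (cognitive, language, motor) are multivariate
normal with cohort-specific means/SDs, a shared center shift contributing
a configurable fraction (ICC) of total variance, and cross-composite
correlation; observed scores are rounded to integers, clipped to the valid
range, and made missing completely at random per composite.

Candidate term births carry the chart-review attributes used to screen the
reference sample (gestational age 39 0/7 - 40 6/7 weeks, singleton,
appropriate weight, benign course, no exclusion conditions).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .reference_norms import COMPOSITES
from .severity_classification import SCORE_MAX, SCORE_MIN

# ---------------------------------------------------------------------------
# configuration

#: reference-cohort moments typical of a healthy term sample
#: (means ~97.5/97.9/98.2, SDs ~11.2/16.0/10.9 for cog/lang/motor)
_REF_MEANS = (97.5, 97.9, 98.2)
_REF_SDS = (11.2, 16.0, 10.9)
#: index-cohort (extremely preterm) moments: lower means, wider spread
_INDEX_MEANS = (83.9, 80.2, 83.3)
_INDEX_SDS = (15.1, 17.4, 16.2)
#: per-composite missingness (cognitive scored almost always; motor least)
_MISSING_RATES = (0.005, 0.03, 0.035)


@dataclass(frozen=True)
class SynthConfig:
    """Design parameters of a synthetic two-cohort clustered study.

    ``accrual_ratio`` is the number of index children assessed per
    reference child (planned design 1:5). ``center_icc`` is the fraction
    of total score variance attributable to center membership (design
    assumption 0.05). Moments are per composite in the order
    (cognitive, language, motor).
    """

    n_centers: int = 15
    index_per_center: int = 97
    accrual_ratio: int = 5
    composite_means_ref: tuple[float, float, float] = _REF_MEANS
    composite_sds_ref: tuple[float, float, float] = _REF_SDS
    composite_means_index: tuple[float, float, float] = _INDEX_MEANS
    composite_sds_index: tuple[float, float, float] = _INDEX_SDS
    inter_composite_corr: float = 0.6
    center_icc: float = 0.05
    missing_rates: tuple[float, float, float] = _MISSING_RATES
    seed: int = 0
    #: optional per-center index sizes for unequal designs (overrides
    #: index_per_center when given)
    index_sizes: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        if self.n_centers < 1:
            raise ValidationError("n_centers must be positive")
        if self.index_per_center < 1:
            raise ValidationError("index_per_center must be positive")
        if self.accrual_ratio < 1:
            raise ValidationError("accrual_ratio must be a positive count")
        for name in ("composite_sds_ref", "composite_sds_index"):
            if any(s <= 0 for s in getattr(self, name)):
                raise ValidationError(f"{name}: all SDs must be positive")
        if not 0.0 <= self.inter_composite_corr < 1.0:
            raise ValidationError("inter_composite_corr must lie in [0, 1)")
        if not 0.0 <= self.center_icc < 1.0:
            raise ValidationError("center_icc must lie in [0, 1)")
        if any(not 0.0 <= r < 1.0 for r in self.missing_rates):
            raise ValidationError("missing_rates must each lie in [0, 1)")
        if self.index_sizes is not None:
            if len(self.index_sizes) != self.n_centers:
                raise ValidationError("index_sizes length must equal n_centers")
            if any(m < 1 for m in self.index_sizes):
                raise ValidationError("index_sizes must be positive")

    def correlation_matrix(self) -> np.ndarray:
        """Exchangeable 3x3 correlation matrix; positive definite for
        inter_composite_corr in [0, 1)."""
        r = self.inter_composite_corr
        return np.full((3, 3), r) + np.eye(3) * (1.0 - r)

    def per_center_sizes(self) -> tuple[list[int], list[int]]:
        """(index sizes, reference sizes) per center; reference accrual is
        ceil(index / ratio)."""
        idx = (
            list(self.index_sizes)
            if self.index_sizes is not None
            else [self.index_per_center] * self.n_centers
        )
        ref = [int(np.ceil(m / self.accrual_ratio)) for m in idx]
        return idx, ref


# ---------------------------------------------------------------------------
# reference-sample eligibility screening

#: chart-review criteria in screening order; (field, favourable value)
_SCREEN_CRITERIA: tuple[tuple[str, bool], ...] = (
    ("gestational_age", True),  # handled specially: 39 0/7 - 40 6/7 weeks
    ("singleton", True),
    ("birth_weight_appropriate", True),
    ("resuscitated", False),
    ("congenital_anomaly", False),
    ("nicu_admission", False),
    ("cns_disorder", False),
    ("cps_custody", False),
    ("parent_incarcerated_or_psychosis", False),
)

GA_MIN_WEEKS = 39.0
GA_MAX_WEEKS = 40.0 + 6.0 / 7.0


@dataclass(frozen=True)
class CandidateBirth:
    """A term birth considered for the healthy reference sample."""

    gestational_age_weeks: float
    singleton: bool
    birth_weight_appropriate: bool
    resuscitated: bool
    congenital_anomaly: bool
    nicu_admission: bool
    cns_disorder: bool
    cps_custody: bool
    parent_incarcerated_or_psychosis: bool

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) is None:
                raise ValidationError(f"candidate field '{f.name}' is missing")
        if not 20.0 <= self.gestational_age_weeks <= 44.0:
            raise ValidationError(
                "gestational_age_weeks must lie in [20, 44], got "
                f"{self.gestational_age_weeks}"
            )


def screen_eligibility(candidate: CandidateBirth) -> tuple[bool, list[str]]:
    """Apply the reference-sample inclusion/exclusion rules to one birth.

    Eligibility requires: singleton birth at 39 0/7 - 40 6/7 weeks,
    appropriate birth weight, no resuscitation, no congenital anomaly, a
    benign course with no NICU admission, and none of the exclusion
    conditions (major CNS disorder, protective-services custody, parental
    incarceration or psychosis).

    Returns (eligible, failed criteria). The failure list is exhaustive
    and follows the screening order, not just the first failure.
    """
    failed: list[str] = []
    for name, favourable in _SCREEN_CRITERIA:
        if name == "gestational_age":
            ok = GA_MIN_WEEKS <= candidate.gestational_age_weeks <= GA_MAX_WEEKS
        else:
            ok = getattr(candidate, name) is favourable
        if not ok:
            failed.append(name)
    return (not failed, failed)


def generate_candidates(n: int, seed: int = 0) -> list[CandidateBirth]:
    """Draw candidate term births with realistic attribute rates.

    Gestational age is uniform over term (38-42 weeks) so roughly half the
    candidates fall in the 39 0/7 - 40 6/7 window; adverse flags use small
    population-plausible rates. Intended for screening demonstrations, not
    for fitting.
    """
    if n < 1:
        raise ValidationError("n must be positive")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        out.append(
            CandidateBirth(
                gestational_age_weeks=float(rng.uniform(38.0, 42.0)),
                singleton=bool(rng.random() > 0.03),
                birth_weight_appropriate=bool(rng.random() > 0.10),
                resuscitated=bool(rng.random() < 0.05),
                congenital_anomaly=bool(rng.random() < 0.03),
                nicu_admission=bool(rng.random() < 0.08),
                cns_disorder=bool(rng.random() < 0.01),
                cps_custody=bool(rng.random() < 0.01),
                parent_incarcerated_or_psychosis=bool(rng.random() < 0.02),
            )
        )
    return out


# ---------------------------------------------------------------------------
# assessment records and cohort generation


@dataclass(frozen=True)
class AssessmentRecord:
    """One child's assessment: cohort label, center, composite scores.

    Scores are integers in [40, 160] or None when the composite was not
    obtained; a child enters the analysis with at least one composite.
    """

    child_id: str
    center_id: str
    cohort: str  # "reference" | "index"
    cognitive: Optional[int] = None
    language: Optional[int] = None
    motor: Optional[int] = None
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cohort not in ("reference", "index"):
            raise ValidationError(
                f"cohort must be 'reference' or 'index', got {self.cohort!r}"
            )
        for comp in COMPOSITES:
            v = getattr(self, comp)
            if v is None:
                continue
            if not float(v).is_integer():
                raise ValidationError(f"{comp} score must be an integer, got {v}")
            if not SCORE_MIN <= v <= SCORE_MAX:
                raise ValidationError(
                    f"{comp} score {v} outside [{SCORE_MIN}, {SCORE_MAX}]"
                )

    def scores(self) -> dict[str, Optional[int]]:
        return {c: getattr(self, c) for c in COMPOSITES}

    def has_any_score(self) -> bool:
        return any(getattr(self, c) is not None for c in COMPOSITES)


def generate_cohorts(config: SynthConfig, seed: Optional[int] = None) -> list[AssessmentRecord]:
    """Generate reference and index cohorts across centers.

    Per center the index cohort has its configured size and the reference
    cohort ceil(size / accrual_ratio) children. Each child's latent
    3-vector is

        score = mean_cohort + sd_cohort * (u_center + e_child)

    with u_center ~ MVN(0, icc * R) shared by both cohorts of the center
    and e_child ~ MVN(0, (1 - icc) * R), R the exchangeable correlation
    matrix — so each composite has total variance sd^2 of which the center
    shift contributes fraction ``center_icc``. Scores are rounded half-up,
    clipped to [40, 160], then each composite is independently set missing
    with its configured rate. Fully reproducible given (config, seed).
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    corr = config.correlation_matrix()
    chol = np.linalg.cholesky(corr)
    icc = config.center_icc

    means = {
        "index": np.asarray(config.composite_means_index),
        "reference": np.asarray(config.composite_means_ref),
    }
    sds = {
        "index": np.asarray(config.composite_sds_index),
        "reference": np.asarray(config.composite_sds_ref),
    }
    miss = np.asarray(config.missing_rates)

    idx_sizes, ref_sizes = config.per_center_sizes()
    records: list[AssessmentRecord] = []
    width = len(str(config.n_centers))
    for c in range(config.n_centers):
        center_id = f"C{c + 1:0{width}d}"
        u_center = np.sqrt(icc) * (chol @ rng.standard_normal(3))
        for cohort, size in (("index", idx_sizes[c]), ("reference", ref_sizes[c])):
            z = rng.standard_normal((size, 3)) @ chol.T * np.sqrt(1.0 - icc)
            latent = means[cohort] + sds[cohort] * (u_center + z)
            # half-up rounding (latent scores are positive), then clip
            observed = np.clip(np.floor(latent + 0.5), SCORE_MIN, SCORE_MAX).astype(int)
            dropped = rng.random((size, 3)) < miss
            for i in range(size):
                vals = {
                    comp: (None if dropped[i, j] else int(observed[i, j]))
                    for j, comp in enumerate(COMPOSITES)
                }
                records.append(
                    AssessmentRecord(
                        child_id=f"{center_id}-{cohort[:3].upper()}-{i + 1:04d}",
                        center_id=center_id,
                        cohort=cohort,
                        **vals,
                    )
                )
    return records


def records_to_frame(records: Sequence[AssessmentRecord]) -> pd.DataFrame:
    """Tabular view: one row per child, scores as nullable integers,
    covariates expanded into columns."""
    covariate_keys: list[str] = []
    for r in records:
        for k in r.covariates:
            if k not in covariate_keys:
                covariate_keys.append(k)
    rows = []
    for r in records:
        row = {
            "child_id": r.child_id,
            "center_id": r.center_id,
            "cohort": r.cohort,
            **{c: getattr(r, c) for c in COMPOSITES},
        }
        for k in covariate_keys:
            row[k] = r.covariates.get(k)
        rows.append(row)
    frame = pd.DataFrame(rows)
    for c in COMPOSITES:
        frame[c] = frame[c].astype("Int64")
    return frame
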