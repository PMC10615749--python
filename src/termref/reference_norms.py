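"""Reference-sample norms and severity cut-points.

A concurrently recruited healthy term-reference (TR) sample provides local
norms for the Bayley-III composite scores (cognitive, language, motor).
Impairment thresholds are then placed at one and two sample standard
deviations below the TR mean, replacing the test publisher's fixed cuts of
85 and 70 (which are the 1- and 2-SD cuts of the normative N(100, 15)).

The sampling uncertainty of the reference SD is summarised with the exact
chi-square interval: if s is the sample SD of n normal observations,
(n-1) s^2 / sigma^2 ~ chi-square(n-1), giving

    [ s * sqrt((n-1) / q_{1-a/2}),  s * sqrt((n-1) / q_{a/2}) ]

with q the chi-square quantiles on n-1 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from ._utils import round_half_up
from .exceptions import DegenerateVarianceError, InsufficientDataError, ValidationError

Composite = Literal["cognitive", "language", "motor"]

#: the three Bayley-III composite domains, in reporting order
COMPOSITES: tuple[str, str, str] = ("cognitive", "language", "motor")

#: publisher's normative thresholds: 1 and 2 SD below the N(100, 15) mean
MANUAL_MODERATE_CUT = 85.0
MANUAL_SEVERE_CUT = 70.0


@dataclass(frozen=True)
class CompositeNorms:
    """Sample moments of one composite in the reference cohort.

    ``sd`` uses the n-1 denominator; the CI is the exact chi-square
    interval for a normal SD at ``ci_level``.
    """

    composite: str
    n: int
    mean: float
    sd: float
    sd_ci_low: float
    sd_ci_high: float
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError("norms require n >= 2")
        if self.sd <= 0:
            raise ValidationError("norms require sd > 0")
        if not (self.sd_ci_low <= self.sd <= self.sd_ci_high):
            raise ValidationError("SD confidence interval must bracket the SD")


@dataclass(frozen=True)
class SeverityBands:
    """Two cut-points defining the three severity levels for one composite.

    normal/mild : score >= moderate_cut
    moderate    : severe_cut <= score < moderate_cut
    severe      : score < severe_cut
    """

    composite: str
    source: Literal["manual", "reference"]
    moderate_cut: float
    severe_cut: float

    def __post_init__(self) -> None:
        if not self.severe_cut < self.moderate_cut:
            raise ValidationError(
                f"severe_cut ({self.severe_cut}) must lie below "
                f"moderate_cut ({self.moderate_cut})"
            )

    def rounded(self, ndigits: int = 2) -> tuple[float, float]:
        """Display form of the cuts (half-up, 2 decimals by default)."""
        return (
            round_half_up(self.moderate_cut, ndigits),
            round_half_up(self.severe_cut, ndigits),
        )


def sd_confidence_interval(
    sd: float, n: int, level: float = 0.95
) -> tuple[float, float]:
    """Exact chi-square confidence interval for a normal standard deviation.

    Parameters
    ----------
    sd
        Sample standard deviation (n-1 denominator), must be positive.
    n
        Sample size, at least 2.
    level
        Confidence level in (0, 1).
    """
    if not 0.0 < level < 1.0:
        raise ValidationError(f"confidence level must be in (0, 1), got {level}")
    if n < 2:
        raise ValidationError(f"need n >= 2 for an SD interval, got {n}")
    if sd <= 0:
        raise ValidationError(f"sd must be positive, got {sd}")
    df = n - 1
    alpha = 1.0 - level
    q_hi = stats.chi2.ppf(1.0 - alpha / 2.0, df)
    q_lo = stats.chi2.ppf(alpha / 2.0, df)
    return float(sd * np.sqrt(df / q_hi)), float(sd * np.sqrt(df / q_lo))


def estimate_norms(
    scores: Iterable[float | None],
    composite: str,
    ci_level: float = 0.95,
) -> CompositeNorms:
    """Estimate reference-sample moments for one composite.

    Missing entries (None / NaN) are dropped before computation. Raises
    :class:`InsufficientDataError` for fewer than two observed scores and
    :class:`DegenerateVarianceError` for zero spread (bands undefined).
    """
    import pandas as pd

    # accepts plain sequences and nullable pandas columns alike
    arr = np.asarray([float(s) for s in scores if not pd.isna(s)], dtype=float)
    if arr.size < 2:
        raise InsufficientDataError(
            f"{composite}: need >= 2 non-missing scores, got {arr.size}"
        )
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    if sd == 0.0:
        raise DegenerateVarianceError(
            f"{composite}: zero variance in reference scores; bands undefined"
        )
    lo, hi = sd_confidence_interval(sd, int(arr.size), ci_level)
    return CompositeNorms(
        composite=composite,
        n=int(arr.size),
        mean=mean,
        sd=sd,
        sd_ci_low=lo,
        sd_ci_high=hi,
        ci_level=ci_level,
    )


def derive_bands(norms: CompositeNorms) -> SeverityBands:
    """Reference-derived cuts at mean - 1*SD and mean - 2*SD.

    Cuts are carried at full precision; display rounding (2 decimals,
    half-up) is applied only when reporting.
    """
    return SeverityBands(
        composite=norms.composite,
        source="reference",
        moderate_cut=norms.mean - norms.sd,
        severe_cut=norms.mean - 2.0 * norms.sd,
    )


def manual_bands(composite: str) -> SeverityBands:
    """Publisher norm-based cuts, identical (85, 70) for every composite."""
    return SeverityBands(
        composite=composite,
        source="manual",
        moderate_cut=MANUAL_MODERATE_CUT,
        severe_cut=MANUAL_SEVERE_CUT,
    )


def norms_table(norms: Sequence[CompositeNorms]) -> "pd.DataFrame":
    """Tidy table of moments and SD CIs (1-decimal display columns)."""
    import pandas as pd

    rows = []
    for nm in norms:
        rows.append(
            {
                "composite": nm.composite,
                "n": nm.n,
                "mean": round_half_up(nm.mean, 1),
                "sd": round_half_up(nm.sd, 1),
                "sd_ci_low": round_half_up(nm.sd_ci_low, 1),
                "sd_ci_high": round_half_up(nm.sd_ci_high, 1),
                "ci_level": nm.ci_level,
            }
        )
    return pd.DataFrame(rows)


def bands_table(bands: Sequence[SeverityBands]) -> "pd.DataFrame":
    """Tidy table of cut-points (2-decimal display columns)."""
    import pandas as pd

    rows = []
    for b in bands:
        mod, sev = b.rounded()
        rows.append(
            {
                "composite": b.composite,
                "source": b.source,
                "moderate_cut": mod,
                "severe_cut": sev,
            }
        )
    return pd.DataFrame(rows)
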