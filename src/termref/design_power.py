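"""Design and power arithmetic for the reference-sample plan.

The study was sized for a two-group comparison of impairment proportions:
an expected 5% rate of severe impairment under publisher norms versus 15%
under reference-derived thresholds, 180 children per group, alpha 0.05,
with children clustered in ~15 centers at an intraclass correlation of
0.05. This module provides the closed-form normal-approximation power,
a clustered Monte-Carlo power simulation, the standard design effect
1 + (m - 1) * ICC, and accrual-ratio bookkeeping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, special, stats

from .exceptions import ValidationError

_LOGIT_SCALE_VAR = math.pi**2 / 3.0


@dataclass(frozen=True)
class PowerDesign:
    """A clustered two-proportion design to be evaluated by simulation."""

    p_manual: float = 0.05
    p_reference: float = 0.15
    n_per_group: int = 180
    n_clusters: int = 15
    icc: float = 0.0
    alpha: float = 0.05
    n_sims: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_manual", "p_reference"):
            p = getattr(self, name)
            if not 0.0 < p < 1.0:
                raise ValidationError(f"{name} must lie in (0, 1), got {p}")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.n_per_group < 2:
            raise ValidationError("n_per_group must be >= 2")
        if self.n_clusters < 1:
            raise ValidationError("n_clusters must be >= 1")
        if not 0.0 <= self.icc < 1.0:
            raise ValidationError("icc must lie in [0, 1)")
        if self.n_sims < 1:
            raise ValidationError("n_sims must be positive")


@dataclass(frozen=True)
class PowerEstimate:
    """A power value with its Monte-Carlo uncertainty (when simulated)."""

    power: float
    method: str  # "analytic" | "simulation"
    mc_ci_low: Optional[float] = None
    mc_ci_high: Optional[float] = None
    n_sims: Optional[int] = None
    seed: Optional[int] = None
    low_sim_warning: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.power <= 1.0:
            raise ValidationError("power must lie in [0, 1]")
        if self.mc_ci_low is not None and not (
            self.mc_ci_low <= self.power <= self.mc_ci_high
        ):
            raise ValidationError("Monte-Carlo CI must bracket the power estimate")


def analytic_power_two_proportions(
    p1: float, p2: float, n1: int, n2: int, alpha: float = 0.05
) -> float:
    """Two-sided normal-approximation power for a two-proportion z-test.

    The rejection threshold uses the pooled-null standard error and the
    power is evaluated under the alternative-variance standard error:

        power = Phi((d - z * se0) / se1) + Phi((-d - z * se0) / se1)

    with d = p2 - p1. Returns approximately ``alpha`` when p1 == p2.
    """
    for name, p in (("p1", p1), ("p2", p2)):
        if not 0.0 < p < 1.0:
            raise ValidationError(f"{name} must lie in (0, 1), got {p}")
    if n1 < 2 or n2 < 2:
        raise ValidationError("group sizes must be >= 2")
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"alpha must lie in (0, 1), got {alpha}")
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    se0 = math.sqrt(pbar * (1.0 - pbar) * (1.0 / n1 + 1.0 / n2))
    se1 = math.sqrt(p1 * (1.0 - p1) / n1 + p2 * (1.0 - p2) / n2)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    d = p2 - p1
    return float(
        stats.norm.cdf((d - z * se0) / se1) + stats.norm.cdf((-d - z * se0) / se1)
    )


def _calibrate_intercept(p: float, sigma: float, n_quad: int = 64) -> float:
    """Intercept a such that E[expit(a + sigma*U)] = p for U ~ N(0,1)."""
    if sigma == 0.0:
        return float(special.logit(p))
    nodes, weights = hermgauss(n_quad)
    w = weights / math.sqrt(math.pi)
    z = math.sqrt(2.0) * sigma * nodes

    def marginal(a: float) -> float:
        return float(w @ special.expit(a + z)) - p

    return float(optimize.brentq(marginal, -30.0, 30.0))


def simulate_power(design: PowerDesign) -> PowerEstimate:
    """Monte-Carlo power of the pooled-SE two-proportion z-test.

    Each replicate draws two groups of ``n_per_group`` Bernoulli outcomes.
    With ``icc`` > 0 each group's children are spread over ``n_clusters``
    centers whose normal random intercepts act on the logit scale, with
    the intercept variance set to icc * pi^2/3 / (1 - icc) so the latent
    intraclass correlation equals the input; group-level intercepts are
    calibrated so marginal rates match p_manual / p_reference. icc = 0
    reduces to independent draws. Power is the rejection fraction with an
    exact (Clopper-Pearson) binomial CI.
    """
    rng = np.random.default_rng(design.seed)
    n, sims = design.n_per_group, design.n_sims
    z_crit = stats.norm.ppf(1.0 - design.alpha / 2.0)

    if design.icc == 0.0:
        k1 = rng.binomial(n, design.p_manual, size=sims)
        k2 = rng.binomial(n, design.p_reference, size=sims)
    else:
        sigma = math.sqrt(design.icc * _LOGIT_SCALE_VAR / (1.0 - design.icc))
        a1 = _calibrate_intercept(design.p_manual, sigma)
        a2 = _calibrate_intercept(design.p_reference, sigma)
        # children allocated to clusters as evenly as possible; independent
        # cluster effects per group (a cluster-randomized style contrast)
        sizes = np.full(design.n_clusters, n // design.n_clusters)
        sizes[: n % design.n_clusters] += 1
        k1 = np.zeros(sims, dtype=int)
        k2 = np.zeros(sims, dtype=int)
        for m in sizes[sizes > 0]:
            b1 = rng.normal(0.0, sigma, size=sims)
            b2 = rng.normal(0.0, sigma, size=sims)
            k1 += rng.binomial(m, special.expit(a1 + b1))
            k2 += rng.binomial(m, special.expit(a2 + b2))

    p1_hat = k1 / n
    p2_hat = k2 / n
    pooled = (k1 + k2) / (2.0 * n)
    se0 = np.sqrt(pooled * (1.0 - pooled) * (2.0 / n))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se0 > 0, (p2_hat - p1_hat) / se0, 0.0)
    rejections = int(np.sum(np.abs(z) > z_crit))

    ci = stats.binomtest(rejections, sims).proportion_ci(
        confidence_level=0.95, method="exact"
    )
    return PowerEstimate(
        power=rejections / sims,
        method="simulation",
        mc_ci_low=float(ci.low),
        mc_ci_high=float(ci.high),
        n_sims=sims,
        seed=design.seed,
        low_sim_warning=sims < 100,
    )


def design_effect(m: float, icc: float) -> float:
    """Variance inflation 1 + (m - 1) * ICC for mean cluster size m."""
    if m < 1:
        raise ValidationError(f"mean cluster size must be >= 1, got {m}")
    if not 0.0 <= icc < 1.0:
        raise ValidationError(f"icc must lie in [0, 1), got {icc}")
    return 1.0 + (m - 1.0) * icc


def accrual_ratio(n_index_assessed: int, n_reference_assessed: int) -> str:
    """Achieved accrual expressed as '1:k', k = round(index / reference)."""
    if n_reference_assessed <= 0:
        raise ValidationError("reference count must be positive")
    if n_index_assessed <= 0:
        raise ValidationError("index count must be positive")
    k = int(round(n_index_assessed / n_reference_assessed))
    return f"1:{k}"


def required_n_for_power(
    p1: float,
    p2: float,
    target_power: float = 0.9,
    alpha: float = 0.05,
    n_max: int = 1_000_000,
) -> int:
    """Smallest equal group size reaching the target analytic power
    (bisection over the monotone analytic power curve)."""
    if not 0.0 < target_power < 1.0:
        raise ValidationError("target_power must lie in (0, 1)")
    if p1 == p2:
        raise ValidationError("cannot size a null effect")
    lo, hi = 2, n_max
    if analytic_power_two_proportions(p1, p2, hi, hi, alpha) < target_power:
        raise ValidationError("target power unreachable within n_max")
    while lo < hi:
        mid = (lo + hi) // 2
        if analytic_power_two_proportions(p1, p2, mid, mid, alpha) >= target_power:
            hi = mid
        else:
            lo = mid + 1
    return lo
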