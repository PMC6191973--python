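"""Required sample sizes with maximin substitution and small-sample corrections.

Planning starts from the normal-approximation identity linking estimator
variance and power for a two-tailed test,

    Var(beta_hat) = ( beta / (z_{1-alpha/2} + z_{1-gamma}) )^2,

with ``beta = ES * sqrt(sigma_y_sq / 2)``.  Solving this for the budget with
the optimal-allocation variance and converting budget to subjects yields the
unrounded total ``n_raw``; for a subject-count budget this reduces to
``n_raw = 2 ((z_{1-alpha/2} + z_{1-gamma}) / ES)^2 * V`` with ``V`` the
scale-free variance coefficient of the design.

Because the planning quantiles come from the standard normal while the
analyses are exact t-tests with estimated variances, small additive
corrections are applied per arm after rounding: for a pooled-variance t-test
(the crossover analyses) +1 subject per sequence at alpha = 0.05 and +2 at
alpha = 0.01; for an unpooled (Welch) t-test (the parallel and extended
parallel analyses) +2 / +4 when both arms have at least 8 subjects and
+3 / +4 otherwise.  These corrections are sufficient for planned powers of
80-90%.

Rounding of the unrounded total (a choice the closed theory does not make):
the crossover allocation is exactly 1:1, so each sequence gets the ceiling
of half the unrounded total (arms stay equal).  For the parallel and
extended parallel designs the total is first rounded up, then split by the
optimal proportion with the first arm rounded to the nearest integer.  This
reconstruction reproduces the reference sample sizes checked in the test
suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

from .maximin import MaximinResult, maximin_params
from .model import (
    CostStructure,
    DesignKind,
    EffectOfInterest,
    ICCRectangle,
    validate_combination,
)
from .variance import optimal_allocation, variance_coefficient

__all__ = [
    "PowerSpec",
    "SampleSizePlan",
    "raw_sample_size",
    "maximin_sample_size",
    "power_from_variance",
    "predictive_interval",
]

# ceiling with protection against upward float dust (e.g. 30.000000000001)
_CEIL_TOL = 1e-9


def _ceil(x: float) -> int:
    return math.ceil(x - _CEIL_TOL)


@dataclass(frozen=True)
class PowerSpec:
    """Two-tailed type-I error rate, target power and standardized effect size."""

    alpha: float
    power: float
    es: float

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if not (0.0 < self.power < 1.0):
            raise ValueError("power must lie in (0, 1)")
        if self.es == 0:
            raise ValueError("effect size must be nonzero")

    @property
    def z_sum(self) -> float:
        return float(norm.ppf(1.0 - self.alpha / 2.0) + norm.ppf(self.power))


def raw_sample_size(
    design: DesignKind,
    effect: EffectOfInterest,
    spec: PowerSpec,
    costs: CostStructure,
    rhoA: float,
    rhoB: float,
) -> float:
    """Unrounded total number of subjects at a given ICC pair.

    Solves the normal-approximation power identity with the
    optimal-allocation variance under the budget function: the budget needed
    is ``C = 2 (z/ES)^2 * V(rhoA, rhoB)`` and the subject total follows from
    the per-subject arm costs at the optimal allocation.  The two-tailed
    planning ignores the sign of ES.
    """
    design = DesignKind(design)
    effect = EffectOfInterest(effect)
    validate_combination(design, effect)
    es = abs(spec.es)
    V = float(variance_coefficient(design, effect, costs, rhoA, rhoB))
    C_needed = 2.0 * (spec.z_sum / es) ** 2 * V
    try:
        ratio = optimal_allocation(design, effect, costs, rhoA, rhoB)
    except ValueError:
        ratio = 1.0  # interaction at rho = 1: no interior optimum, split equally
    p1 = ratio / (1.0 + ratio)
    k1, k2 = costs.per_subject_costs(design)
    return C_needed / (p1 * k1 + (1.0 - p1) * k2)


@dataclass(frozen=True)
class SampleSizePlan:
    """Integer per-arm sample sizes after rounding and correction.

    ``n1``/``n2`` include ``correction_per_arm`` extra subjects each;
    ``N = n1 + n2 >= ceil(n_raw)``.  Arm 1 is the A, AA or AB sequence.
    """

    design: DesignKind
    effect: EffectOfInterest
    rho_star: tuple[float, float]
    allocation_ratio: float
    p1: float
    n_raw: float
    n1_pre: int
    n2_pre: int
    correction_per_arm: int
    test: str  # "pooled" or "unpooled"
    maximin: MaximinResult | None = None

    @property
    def n1(self) -> int:
        return self.n1_pre + self.correction_per_arm

    @property
    def n2(self) -> int:
        return self.n2_pre + self.correction_per_arm

    @property
    def N(self) -> int:
        return self.n1 + self.n2


def _round_arms(design: DesignKind, n_raw: float, p1: float) -> tuple[int, int]:
    if design is DesignKind.CROSSOVER:
        half = _ceil(n_raw / 2.0)  # optimal allocation is exactly 1:1
        return max(half, 1), max(half, 1)
    total = _ceil(n_raw)
    n1 = int(math.floor(total * p1 + 0.5))
    n1 = min(max(n1, 1), total - 1)
    return n1, total - n1


def _correction(test: str, alpha: float, min_arm: int) -> int:
    strict = alpha <= 0.025  # the published rules cover alpha = 0.05 and 0.01
    if test == "pooled":
        return 2 if strict else 1
    if strict:
        return 4
    return 2 if min_arm >= 8 else 3


def maximin_sample_size(
    design: DesignKind,
    effect: EffectOfInterest,
    spec: PowerSpec,
    costs: CostStructure,
    rect: ICCRectangle,
) -> SampleSizePlan:
    """Sample-size plan guaranteeing the target power over the rectangle.

    The worst-case ICC pair comes from :func:`maximin_params`; the unrounded
    total from :func:`raw_sample_size` at that pair; arms are rounded per
    the module rules and the t-test correction for the design's analysis
    (pooled for crossover, unpooled for the parallel designs) is added per
    arm.  The "fewer than 8 per arm" trigger for the larger unpooled
    correction is evaluated on the post-rounding, pre-correction counts.
    """
    design = DesignKind(design)
    effect = EffectOfInterest(effect)
    mm = maximin_params(design, effect, costs, rect)
    rhoA, rhoB = mm.rho_at
    n_raw = raw_sample_size(design, effect, spec, costs, rhoA, rhoB)
    p1 = mm.p1
    n1_pre, n2_pre = _round_arms(design, n_raw, p1)
    test = "pooled" if design is DesignKind.CROSSOVER else "unpooled"
    corr = _correction(test, spec.alpha, min(n1_pre, n2_pre))
    return SampleSizePlan(
        design=design,
        effect=effect,
        rho_star=mm.rho_at,
        allocation_ratio=mm.allocation_ratio,
        p1=p1,
        n_raw=n_raw,
        n1_pre=n1_pre,
        n2_pre=n2_pre,
        correction_per_arm=corr,
        test=test,
        maximin=mm,
    )


def power_from_variance(variance: float, beta: float, alpha: float) -> float:
    """Achieved power of a two-tailed z-test given the estimator variance.

    Inverts the planning identity: ``1 - gamma =
    Phi(|beta| / sqrt(Var) - z_{1-alpha/2})``.  At ``beta = 0`` this returns
    ``alpha/2`` (one tail of the two-sided test under the normal
    approximation).
    """
    if variance <= 0:
        raise ValueError("variance must be > 0")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    z_a = norm.ppf(1.0 - alpha / 2.0)
    return float(norm.cdf(abs(beta) / math.sqrt(variance) - z_a))


def predictive_interval(
    pi: float, n_sim: int, level: float = 0.95
) -> tuple[float, float]:
    """Monte Carlo predictive interval around a nominal power ``pi``.

    ``pi +/- z * sqrt(pi (1 - pi) / n_sim)`` with ``z`` the two-sided
    normal quantile for ``level``.  A simulated power below the lower bound
    signals a systematic (not chance) shortfall.
    """
    if not (0.0 < pi < 1.0):
        raise ValueError("pi must lie in (0, 1)")
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    z = float(norm.ppf(0.5 + level / 2.0))
    half = z * math.sqrt(pi * (1.0 - pi) / n_sim)
    return (pi - half, pi + half)
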