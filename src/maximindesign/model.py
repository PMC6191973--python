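"""Core domain types for two-treatment trial designs.

The package compares three two-treatment, two-sequence designs:

* ``parallel`` (A/B): each subject receives one treatment and is measured once.
* ``extended_parallel`` (AA/BB): each subject receives the same treatment in
  two periods; the only design here that identifies a treatment-by-period
  interaction next to the crossover.
* ``crossover`` (AB/BA): each subject receives both treatments in one of two
  randomized orders.

Outcomes are modelled by a heteroscedastic linear mixed model: a shared
between-subject random intercept with variance ``sigma0_sq`` and
treatment-dependent within-subject error variances ``sigmaEpsA_sq`` and
``sigmaEpsB_sq``.  The resulting total variances are
``sigma_A^2 = sigma0_sq + sigmaEpsA_sq`` and analogously for B, and the
intraclass correlations (ICCs) are ``rho_A = sigma0_sq / sigma_A^2`` and
``rho_B = sigma0_sq / sigma_B^2``.  All design efficiencies in this package
are functions of ``(rho_A, rho_B)`` and of the cost structure only, which is
why the ICCs (rather than raw variance components) are the primary inputs.

Conventions fixed throughout:

* treatment coded 0 for A and 1 for B, period coded 0/1 (results are
  invariant to recoding, so no alternative codings are supported);
* the first-listed sequence (A, AA or AB) is "arm 1";
* ``sigma_y_sq = sigma_A^2 + sigma_B^2`` is the total-variance scale and
  defaults to 2 so that the standardized effect size
  ``ES = beta / sqrt(0.5 * sigma_y_sq)`` coincides numerically with ``beta``;
* ICCs of exactly 0 are rejected (they appear in denominators everywhere),
  ICCs of exactly 1 (no within-subject error) are allowed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import NamedTuple


class DesignKind(str, Enum):
    """The three supported two-treatment designs."""

    PARALLEL = "parallel"
    EXTENDED_PARALLEL = "extended_parallel"
    CROSSOVER = "crossover"


class EffectOfInterest(str, Enum):
    """Which fixed effect the design is optimized for.

    ``TREATMENT`` is the main treatment effect (``beta_treat``);
    ``TREATMENT_BY_PERIOD`` is the treatment-by-period interaction
    (``beta_interaction``), which a single-period parallel design cannot
    estimate.
    """

    TREATMENT = "treatment"
    TREATMENT_BY_PERIOD = "treatment_by_period"


def validate_combination(design: DesignKind, effect: EffectOfInterest) -> None:
    """Reject the one unsupported design/effect pairing.

    The treatment-by-period interaction requires two periods, so it is not
    estimable in a single-period parallel trial.
    """
    design = DesignKind(design)
    effect = EffectOfInterest(effect)
    if design is DesignKind.PARALLEL and effect is EffectOfInterest.TREATMENT_BY_PERIOD:
        raise ValueError(
            "a single-period parallel design cannot estimate a "
            "treatment-by-period interaction"
        )


@dataclass(frozen=True)
class CostStructure:
    """Monetary costs defining the budget constraint.

    Parameters
    ----------
    c_A, c_B
        Per-subject cost of administering treatment A resp. B (per period in
        which the treatment is given).
    c_t
        Cost of one measurement.
    c_sp
        Subject-specific cost (recruitment, reward, ...) in the one-period
        parallel design.
    c_s2p
        Subject-specific cost in the two-period designs (AA/BB and AB/BA);
        typically between ``c_sp`` and ``2 * c_sp`` because two periods and a
        possible washout are involved.
    c_ts
        Administration cost per treatment sequence.  Every design has two
        sequences, so the net budget available for subjects is
        ``C = C_star - 2 * c_ts`` regardless of the design.
    """

    c_A: float = 0.0
    c_B: float = 0.0
    c_t: float = 0.0
    c_sp: float = 0.0
    c_s2p: float = 0.0
    c_ts: float = 0.0

    def __post_init__(self) -> None:
        for name in ("c_A", "c_B", "c_t", "c_sp", "c_s2p", "c_ts"):
            if getattr(self, name) < 0:
                raise ValueError(f"cost component {name} must be >= 0")
        # every design arm must have a strictly positive per-subject cost,
        # otherwise the budget constraint does not bound the sample size
        if min(self.parallel_arm_costs + self.extended_parallel_arm_costs) <= 0 or (
            self.crossover_subject_cost <= 0
        ):
            raise ValueError(
                "per-subject cost of every design arm must be > 0; "
                "set at least one of c_A/c_B, c_t, c_sp, c_s2p"
            )
        if not (self.c_sp <= self.c_s2p <= 2 * self.c_sp):
            warnings.warn(
                "expected c_sp <= c_s2p <= 2*c_sp (two-period subject costs "
                "between one and two times the one-period costs); "
                "continuing with the values as given",
                stacklevel=2,
            )

    # -- per-subject effective costs, one value per arm -------------------
    @property
    def parallel_arm_costs(self) -> tuple[float, float]:
        """(A-arm, B-arm) per-subject cost in the parallel design."""
        return (self.c_A + self.c_t + self.c_sp, self.c_B + self.c_t + self.c_sp)

    @property
    def extended_parallel_arm_costs(self) -> tuple[float, float]:
        """(AA-arm, BB-arm) per-subject cost: two treatments, two measurements."""
        return (
            2 * self.c_A + 2 * self.c_t + self.c_s2p,
            2 * self.c_B + 2 * self.c_t + self.c_s2p,
        )

    @property
    def crossover_subject_cost(self) -> float:
        """Per-subject cost in the crossover design (same in both sequences)."""
        return self.c_A + self.c_B + 2 * self.c_t + self.c_s2p

    def per_subject_costs(self, design: DesignKind) -> tuple[float, float]:
        """Per-subject cost of (arm 1, arm 2) for ``design``."""
        design = DesignKind(design)
        if design is DesignKind.PARALLEL:
            return self.parallel_arm_costs
        if design is DesignKind.EXTENDED_PARALLEL:
            return self.extended_parallel_arm_costs
        w = self.crossover_subject_cost
        return (w, w)

    # -- canonical special cases ------------------------------------------
    @classmethod
    def subject_count(cls) -> "CostStructure":
        """Budget = total number of subjects (c_sp = c_s2p = 1, rest 0)."""
        return cls(c_sp=1.0, c_s2p=1.0)

    @classmethod
    def measurement_count(cls) -> "CostStructure":
        """Budget = total number of measurements (c_t = 1, rest 0)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return cls(c_t=1.0)


@dataclass(frozen=True)
class ICCRectangle:
    """Plausible ranges for the two intraclass correlations.

    The rectangle ``[rhoA_low, rhoA_high] x [rhoB_low, rhoB_high]`` is the
    domain of the maximin search.  Degenerate point ranges (low == high) are
    allowed; the maximin design then reduces to the locally optimal design at
    that point.
    """

    rhoA_low: float
    rhoA_high: float
    rhoB_low: float
    rhoB_high: float

    def __post_init__(self) -> None:
        for lo, hi, lab in (
            (self.rhoA_low, self.rhoA_high, "rhoA"),
            (self.rhoB_low, self.rhoB_high, "rhoB"),
        ):
            if not (0.0 < lo <= hi <= 1.0):
                raise ValueError(
                    f"need 0 < {lab}_low <= {lab}_high <= 1, got [{lo}, {hi}]"
                )

    @property
    def corners(self) -> list[tuple[float, float]]:
        return [
            (self.rhoA_low, self.rhoB_low),
            (self.rhoA_low, self.rhoB_high),
            (self.rhoA_high, self.rhoB_low),
            (self.rhoA_high, self.rhoB_high),
        ]

    @property
    def is_point(self) -> bool:
        return self.rhoA_low == self.rhoA_high and self.rhoB_low == self.rhoB_high

    def contains(self, rhoA: float, rhoB: float, tol: float = 1e-12) -> bool:
        return (
            self.rhoA_low - tol <= rhoA <= self.rhoA_high + tol
            and self.rhoB_low - tol <= rhoB <= self.rhoB_high + tol
        )

    @property
    def phi_range(self) -> tuple[float, float]:
        """Induced range of the variance ratio ``phi = rho_B / rho_A``."""
        return (self.rhoB_low / self.rhoA_high, self.rhoB_high / self.rhoA_low)


class VarianceComponents(NamedTuple):
    sigma0_sq: float
    sigmaEpsA_sq: float
    sigmaEpsB_sq: float
    sigmaA_sq: float
    sigmaB_sq: float


def icc_to_variance_components(
    rhoA: float, rhoB: float, sigma_y_sq: float = 2.0
) -> VarianceComponents:
    """Variance components implied by the two ICCs at a fixed total scale.

    Given ``rho_A``, ``rho_B`` and the total variance
    ``sigma_y_sq = sigma_A^2 + sigma_B^2``, the components are uniquely
    determined (the model assumes a common between-subject variance):

    ``sigma_A^2 = sigma_y_sq * rho_B / (rho_A + rho_B)``,
    ``sigma_B^2 = sigma_y_sq * rho_A / (rho_A + rho_B)``,
    ``sigma0^2 = sigma_y_sq * rho_A * rho_B / (rho_A + rho_B)``.

    The mapping round-trips: recomputing the ICCs from the returned
    components gives back the inputs.
    """
    if not (0.0 < rhoA <= 1.0 and 0.0 < rhoB <= 1.0):
        raise ValueError("intraclass correlations must lie in (0, 1]")
    if sigma_y_sq <= 0:
        raise ValueError("sigma_y_sq must be > 0")
    s = rhoA + rhoB
    sigmaA_sq = sigma_y_sq * rhoB / s
    sigmaB_sq = sigma_y_sq * rhoA / s
    sigma0_sq = sigma_y_sq * rhoA * rhoB / s
    return VarianceComponents(
        sigma0_sq=sigma0_sq,
        sigmaEpsA_sq=sigmaA_sq - sigma0_sq,
        sigmaEpsB_sq=sigmaB_sq - sigma0_sq,
        sigmaA_sq=sigmaA_sq,
        sigmaB_sq=sigmaB_sq,
    )


def variance_ratio(rhoA: float, rhoB: float) -> float:
    """Variance ratio ``phi = sigma_A^2 / sigma_B^2 = rho_B / rho_A``."""
    if rhoA <= 0:
        raise ValueError("rhoA must be > 0")
    return rhoB / rhoA


def beta_from_effect_size(es: float, sigma_y_sq: float = 2.0) -> float:
    """Regression coefficient implied by a standardized effect size.

    ``ES = beta / sqrt(0.5 * (sigma_A^2 + sigma_B^2))``, so
    ``beta = ES * sqrt(sigma_y_sq / 2)``.
    """
    if sigma_y_sq <= 0:
        raise ValueError("sigma_y_sq must be > 0")
    return es * math.sqrt(sigma_y_sq / 2.0)


@dataclass(frozen=True)
class ModelParams:
    """Fixed effects and variance components of the generating mixed model."""

    sigma0_sq: float
    sigmaEpsA_sq: float
    sigmaEpsB_sq: float
    beta0: float = 0.0
    beta_treat: float = 0.0
    beta_time: float = 0.0
    beta_interaction: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma0_sq < 0 or self.sigmaEpsA_sq < 0 or self.sigmaEpsB_sq < 0:
            raise ValueError("variance components must be >= 0")
        if self.sigmaA_sq <= 0 or self.sigmaB_sq <= 0:
            raise ValueError("total variances sigma_A^2 and sigma_B^2 must be > 0")

    @property
    def sigmaA_sq(self) -> float:
        return self.sigma0_sq + self.sigmaEpsA_sq

    @property
    def sigmaB_sq(self) -> float:
        return self.sigma0_sq + self.sigmaEpsB_sq

    @property
    def rhoA(self) -> float:
        return self.sigma0_sq / self.sigmaA_sq

    @property
    def rhoB(self) -> float:
        return self.sigma0_sq / self.sigmaB_sq

    @property
    def phi(self) -> float:
        return self.sigmaA_sq / self.sigmaB_sq

    @classmethod
    def from_icc(
        cls,
        rhoA: float,
        rhoB: float,
        sigma_y_sq: float = 2.0,
        **betas: float,
    ) -> "ModelParams":
        """Build generating parameters from ICCs plus fixed effects."""
        comps = icc_to_variance_components(rhoA, rhoB, sigma_y_sq)
        return cls(
            sigma0_sq=comps.sigma0_sq,
            sigmaEpsA_sq=comps.sigmaEpsA_sq,
            sigmaEpsB_sq=comps.sigmaEpsB_sq,
            **betas,
        )


@dataclass(frozen=True)
class DesignSolution:
    """A design evaluated at a specific pair of ICCs.

    ``allocation_ratio`` is ``n1/n2`` with arm 1 the A, AA or AB sequence;
    ``variance`` is the estimator variance per unit ``sigma_y_sq / C``;
    ``branch`` identifies which closed-form case produced the solution
    ("optimal", "degenerate", "grid", or a named maximin case).
    """

    design: DesignKind
    effect: EffectOfInterest
    allocation_ratio: float
    p1: float
    variance: float
    rho_at: tuple[float, float]
    branch: str = "optimal"

    def __post_init__(self) -> None:
        if self.allocation_ratio <= 0:
            raise ValueError("allocation_ratio must be > 0")
        if not (0.0 < self.p1 < 1.0):
            raise ValueError("p1 must lie in (0, 1)")
        if self.variance <= 0:
            raise ValueError("variance must be > 0")

    @property
    def rho_star(self) -> tuple[float, float]:
        """Alias used when the solution is a maximin result."""
        return self.rho_at
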