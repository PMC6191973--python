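"""Asymptotic variances, optimal allocations and budget accounting.

All variances here are asymptotic variances of the maximum-likelihood
estimators under the heteroscedastic mixed model, expressed per unit of
``sigma_y_sq / C`` (total outcome variance over net budget) or, for
:func:`variance_at_allocation`, per unit of ``sigma_y_sq / N``.  The closed
forms are exact functions of the two intraclass correlations and of the cost
structure; no model fitting happens in this module.

The budget functions are

* parallel:          ``C* = 2 c_ts + n (c_sp + c_t) + p n c_A + (1-p) n c_B``
* crossover:         ``C* = 2 c_ts + n (c_s2p + c_A + c_B + 2 c_t)``
* extended parallel: ``C* = 2 c_ts + n c_s2p + 2 n p c_A + 2 n (1-p) c_B + 2 n c_t``

which are all of the form ``2 c_ts + n (p k1 + (1-p) k2)`` with ``(k1, k2)``
the per-subject arm costs from :meth:`CostStructure.per_subject_costs`.  In
the extended parallel design each subject is treated and measured twice, so
its arm costs carry ``2 c_A + 2 c_t + c_s2p`` (and analogously for B); the
same coefficients are used consistently in the allocation ratios and
variances below.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    CostStructure,
    DesignKind,
    EffectOfInterest,
    validate_combination,
)

__all__ = [
    "BudgetSpec",
    "budget_required",
    "subjects_for_budget",
    "variance_at_allocation",
    "optimal_allocation",
    "variance_coefficient",
    "optimal_variance",
]


@dataclass(frozen=True)
class BudgetSpec:
    """Total budget ``C_star`` and the net budget ``C = C_star - 2 c_ts``."""

    C_star: float
    c_ts: float = 0.0

    @property
    def C(self) -> float:
        return self.C_star - 2 * self.c_ts

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("net budget C = C_star - 2*c_ts must be > 0")


def budget_required(
    design: DesignKind, n: float, p1: float, costs: CostStructure
) -> float:
    """Total budget ``C*`` required by ``n`` subjects allocated ``p1`` to arm 1."""
    if n <= 0:
        raise ValueError("n must be > 0")
    if not (0.0 < p1 < 1.0):
        raise ValueError("p1 must lie in (0, 1)")
    k1, k2 = costs.per_subject_costs(design)
    return 2 * costs.c_ts + n * (p1 * k1 + (1.0 - p1) * k2)


def subjects_for_budget(
    design: DesignKind, C: float, p1: float, costs: CostStructure
) -> float:
    """(Fractional) number of subjects affordable with net budget ``C``."""
    if C <= 0:
        raise ValueError("net budget C must be > 0")
    if not (0.0 < p1 < 1.0):
        raise ValueError("p1 must lie in (0, 1)")
    k1, k2 = costs.per_subject_costs(design)
    return C / (p1 * k1 + (1.0 - p1) * k2)


def _check_rho(rhoA, rhoB) -> None:
    rhoA = np.asarray(rhoA, dtype=float)
    rhoB = np.asarray(rhoB, dtype=float)
    if np.any(rhoA <= 0) or np.any(rhoB <= 0) or np.any(rhoA > 1) or np.any(rhoB > 1):
        raise ValueError("intraclass correlations must lie in (0, 1]")


def variance_at_allocation(
    design: DesignKind,
    effect: EffectOfInterest,
    p: float,
    rhoA,
    rhoB,
    sigma_y_sq: float = 2.0,
    N: float = 1.0,
):
    """Estimator variance for ``N`` subjects with proportion ``p`` in arm 1.

    Implements the five asymptotic-variance cells (three designs for the
    treatment effect; crossover and extended parallel for the interaction).
    ``rhoA``/``rhoB`` may be numpy arrays; the result broadcasts.
    """
    design = DesignKind(design)
    effect = EffectOfInterest(effect)
    validate_combination(design, effect)
    _check_rho(rhoA, rhoB)
    if not (0.0 < p < 1.0):
        raise ValueError("p must lie in the open interval (0, 1)")
    if N <= 0:
        raise ValueError("N must be > 0")
    rhoA = np.asarray(rhoA, dtype=float)
    rhoB = np.asarray(rhoB, dtype=float)
    s = rhoA + rhoB
    q = p * (1.0 - p)

    if design is DesignKind.CROSSOVER:
        if effect is EffectOfInterest.TREATMENT:
            num = (rhoA - rhoB) ** 2 * q + rhoA * rhoB * (1.0 - rhoA * rhoB)
            den = s * (s + 2.0 * rhoA * rhoB)
            out = num / den * sigma_y_sq / (q * N)
        else:
            out = (1.0 + 2.0 * rhoA * rhoB / s) * sigma_y_sq / (q * N)
    elif design is DesignKind.PARALLEL:
        out = (rhoB / p + rhoA / (1.0 - p)) / s * sigma_y_sq / N
    else:  # extended parallel
        if effect is EffectOfInterest.TREATMENT:
            out = (
                (rhoB / p + rhoA / (1.0 - p) + rhoA * rhoB / q)
                / s
                * sigma_y_sq
                / (2.0 * N)
            )
        else:
            out = (
                (rhoB * (1.0 - rhoA) / p + rhoA * (1.0 - rhoB) / (1.0 - p))
                / s
                * 2.0
                * sigma_y_sq
                / N
            )
    return out if out.ndim else float(out)


def optimal_allocation(
    design: DesignKind,
    effect: EffectOfInterest,
    costs: CostStructure,
    rhoA: float,
    rhoB: float,
) -> float:
    """Variance-minimizing allocation ratio ``n1/n2`` under the budget.

    The crossover ratio is exactly 1 for both effects.  For the other
    designs the ratio trades off the arm ICCs against the per-subject arm
    costs: expensive or high-ICC arms receive fewer subjects.

    Raises
    ------
    ValueError
        For the parallel/interaction combination, and for the extended
        parallel interaction ratio when ``rhoA`` or ``rhoB`` equals 1 (the
        ratio then degenerates to 0 or infinity and no interior optimum
        exists; the optimal *variance* remains finite and is available from
        :func:`optimal_variance`).
    """
    design = DesignKind(design)
    effect = EffectOfInterest(effect)
    validate_combination(design, effect)
    _check_rho(rhoA, rhoB)
    if design is DesignKind.CROSSOVER:
        return 1.0
    k1, k2 = costs.per_subject_costs(design)
    cost_part = np.sqrt(k2 / k1)
    if design is DesignKind.PARALLEL:
        return float(np.sqrt(rhoB / rhoA) * cost_part)
    if effect is EffectOfInterest.TREATMENT:
        return float(np.sqrt(rhoB * (1.0 + rhoA) / (rhoA * (1.0 + rhoB))) * cost_part)
    if rhoA >= 1.0 or rhoB >= 1.0:
        raise ValueError(
            "extended-parallel interaction allocation is undefined at rho = 1 "
            "(no within-subject error in one arm); evaluate the variance "
            "directly instead"
        )
    return float(
        np.sqrt(rhoB * (1.0 - rhoA) / (rhoA * (1.0 - rhoB))) * cost_part
    )


def variance_coefficient(
    design: DesignKind,
    effect: EffectOfInterest,
    costs: CostStructure,
    rhoA,
    rhoB,
):
    """Optimal-allocation estimator variance per unit ``sigma_y_sq / C``.

    This is the scale-free core quantity of the package: multiply by
    ``sigma_y_sq`` and divide by the net budget ``C`` to obtain the variance
    of the effect estimator under optimal allocation.  Vectorized over
    ``rhoA``/``rhoB``.
    """
    design = DesignKind(design)
    effect = EffectOfInterest(effect)
    validate_combination(design, effect)
    _check_rho(rhoA, rhoB)
    rhoA = np.asarray(rhoA, dtype=float)
    rhoB = np.asarray(rhoB, dtype=float)
    s = rhoA + rhoB
    if design is DesignKind.CROSSOVER:
        w = costs.crossover_subject_cost
        if effect is EffectOfInterest.TREATMENT:
            out = w * (1.0 - 2.0 * rhoA * rhoB / s)
        else:
            out = 4.0 * w * (1.0 + 2.0 * rhoA * rhoB / s)
    elif design is DesignKind.PARALLEL:
        vA, vB = costs.parallel_arm_costs
        out = (np.sqrt(vA * rhoB) + np.sqrt(vB * rhoA)) ** 2 / s
    else:
        wA, wB = costs.extended_parallel_arm_costs
        if effect is EffectOfInterest.TREATMENT:
            out = (
                np.sqrt(wA * rhoB * (1.0 + rhoA)) + np.sqrt(wB * rhoA * (1.0 + rhoB))
            ) ** 2 / (2.0 * s)
        else:
            out = (
                2.0
                * (
                    np.sqrt(wA * rhoB * (1.0 - rhoA))
                    + np.sqrt(wB * rhoA * (1.0 - rhoB))
                )
                ** 2
                / s
            )
    return out if out.ndim else float(out)


def optimal_variance(
    design: DesignKind,
    effect: EffectOfInterest,
    costs: CostStructure,
    rhoA,
    rhoB,
    sigma_y_sq: float = 2.0,
    C: float = 1.0,
):
    """Estimator variance at the optimal allocation for net budget ``C``.

    Equals :func:`variance_at_allocation` evaluated at the allocation from
    :func:`optimal_allocation` with the number of subjects implied by the
    budget identity ``budget_required(design, n, p1, costs) = C + 2 c_ts``.
    """
    if C <= 0:
        raise ValueError("net budget C must be > 0")
    coeff = variance_coefficient(design, effect, costs, rhoA, rhoB)
    return coeff * sigma_y_sq / C
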