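"""Trial simulation under the heteroscedastic mixed model and exact t-tests.

The generator draws outcomes from

    y_ij = beta0 + beta_treat * treat + beta_time * time
           + beta_interaction * treat * time + u0_j + eps_ij,

with a shared subject intercept ``u0_j ~ N(0, sigma0_sq)`` and independent
errors whose variance is ``sigmaEpsA_sq`` under treatment A and
``sigmaEpsB_sq`` under B.  The single-period parallel design uses the
one-measurement reduction (intercept and error are not separable there).

Analyses mirror how such trials are actually tested, and are exact under
the generating model (no asymptotics):

===================  ====================  =========================
design / effect      per-subject score     two-sample t-test
===================  ====================  =========================
crossover/treatment  period difference     pooled variance
crossover/interact.  period mean           pooled variance
parallel/treatment   raw score             unpooled (Welch)
ext.par./treatment   period mean           unpooled (Welch)
ext.par./interact.   period difference     unpooled (Welch)
===================  ====================  =========================

The pooled tests are justified because the model implies equal score
variances between the two crossover sequences; the parallel-design scores
inherit the treatment-dependent variances, hence Welch with
Welch-Satterthwaite degrees of freedom.  If both score groups are constant
(possible when all variance components are zero, or for difference scores
when the error variances are zero) the test declares exact separation:
p = 0 when the group means differ, p = 1 when they coincide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .model import (
    CostStructure,
    DesignKind,
    EffectOfInterest,
    ICCRectangle,
    ModelParams,
    beta_from_effect_size,
    validate_combination,
)
from .samplesize import PowerSpec, SampleSizePlan, maximin_sample_size, predictive_interval

__all__ = [
    "TrialData",
    "TestResult",
    "MonteCarloPowerResult",
    "simulate_trial",
    "analyze",
    "monte_carlo_power",
]


@dataclass(frozen=True)
class TrialData:
    """Long-format simulated outcomes.

    Rows are ordered arm 1 then arm 2 and, within the two-period designs,
    subject-major with period 0 before period 1.  ``treatment`` is coded
    0 = A, 1 = B; arm 1 is the A, AA or AB sequence.
    """

    design: DesignKind
    n1: int
    n2: int
    subject_id: np.ndarray
    period: np.ndarray
    treatment: np.ndarray
    y: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "period": self.period,
                "treatment": self.treatment,
                "y": self.y,
            }
        )

    def arm_scores(self, kind: str) -> tuple[np.ndarray, np.ndarray]:
        """Per-subject scores ("raw", "difference" or "mean") per arm."""
        if self.design is DesignKind.PARALLEL:
            if kind != "raw":
                raise ValueError("parallel data only provide raw scores")
            return self.y[: self.n1], self.y[self.n1 :]
        wide = self.y.reshape(-1, 2)  # subject-major, periods 0/1
        if kind == "difference":
            scores = wide[:, 1] - wide[:, 0]
        elif kind == "mean":
            scores = wide.mean(axis=1)
        else:
            raise ValueError("two-period data provide 'difference' or 'mean' scores")
        return scores[: self.n1], scores[self.n1 :]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float
    reject: bool
    estimate: float  # difference in group score means (arm 1 minus arm 2)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_trial(
    design: DesignKind,
    n1: int,
    n2: int,
    params: ModelParams,
    seed=None,
) -> TrialData:
    """Draw one trial of ``n1 + n2`` subjects; deterministic given ``seed``."""
    design = DesignKind(design)
    if n1 < 2 or n2 < 2:
        raise ValueError("each arm needs at least 2 subjects")
    rng = _as_rng(seed)
    N = n1 + n2
    sdA = math.sqrt(params.sigmaEpsA_sq)
    sdB = math.sqrt(params.sigmaEpsB_sq)

    if design is DesignKind.PARALLEL:
        treat = np.repeat([0, 1], [n1, n2])
        sd_tot = np.where(
            treat == 0, math.sqrt(params.sigmaA_sq), math.sqrt(params.sigmaB_sq)
        )
        y = params.beta0 + params.beta_treat * treat + rng.normal(0.0, sd_tot)
        return TrialData(
            design=design,
            n1=n1,
            n2=n2,
            subject_id=np.arange(N),
            period=np.zeros(N, dtype=int),
            treatment=treat,
            y=y,
        )

    # two-period designs: treatment pattern per (arm, period)
    if design is DesignKind.CROSSOVER:
        arm_treat = {0: (0, 1), 1: (1, 0)}  # AB / BA
    else:
        arm_treat = {0: (0, 0), 1: (1, 1)}  # AA / BB
    arm = np.repeat([0, 1], [n1, n2])
    treat = np.array([arm_treat[a] for a in arm]).ravel()
    period = np.tile([0, 1], N)
    subject = np.repeat(np.arange(N), 2)
    u0 = rng.normal(0.0, math.sqrt(params.sigma0_sq), size=N)
    eps_sd = np.where(treat == 0, sdA, sdB)
    eps = rng.normal(0.0, eps_sd)
    y = (
        params.beta0
        + params.beta_treat * treat
        + params.beta_time * period
        + params.beta_interaction * treat * period
        + u0[subject]
        + eps
    )
    return TrialData(
        design=design,
        n1=n1,
        n2=n2,
        subject_id=subject,
        period=period,
        treatment=treat,
        y=y,
    )


def _two_sample_t(
    x: np.ndarray, y: np.ndarray, pooled: bool, alpha: float
) -> TestResult:
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("each group needs at least 2 scores")
    mx, my = float(x.mean()), float(y.mean())
    vx = float(x.var(ddof=1))
    vy = float(y.var(ddof=1))
    if pooled:
        df = float(nx + ny - 2)
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / df
        se2 = sp2 * (1.0 / nx + 1.0 / ny)
    else:
        se2 = vx / nx + vy / ny
        if se2 > 0:
            df = se2**2 / (
                (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
            )
        else:
            df = float(nx + ny - 2)
    diff = mx - my
    if se2 == 0.0:
        # exact separation convention for zero-variance scores
        if diff == 0.0:
            return TestResult(0.0, df, 1.0, False, diff)
        stat = math.inf if diff > 0 else -math.inf
        return TestResult(stat, df, 0.0, 0.0 < alpha, diff)
    stat = diff / math.sqrt(se2)
    p = 2.0 * float(t_dist.sf(abs(stat), df))
    return TestResult(stat, df, p, p < alpha, diff)


_SCORE_KIND = {
    (DesignKind.CROSSOVER, EffectOfInterest.TREATMENT): ("difference", True),
    (DesignKind.CROSSOVER, EffectOfInterest.TREATMENT_BY_PERIOD): ("mean", True),
    (DesignKind.PARALLEL, EffectOfInterest.TREATMENT): ("raw", False),
    (DesignKind.EXTENDED_PARALLEL, EffectOfInterest.TREATMENT): ("mean", False),
    (DesignKind.EXTENDED_PARALLEL, EffectOfInterest.TREATMENT_BY_PERIOD): (
        "difference",
        False,
    ),
}


def analyze(data: TrialData, effect: EffectOfInterest, alpha: float) -> TestResult:
    """Two-sample t-test of ``effect`` on the design's per-subject scores."""
    effect = EffectOfInterest(effect)
    validate_combination(data.design, effect)
    kind, pooled = _SCORE_KIND[(data.design, effect)]
    s1, s2 = data.arm_scores(kind)
    return _two_sample_t(s1, s2, pooled, alpha)


@dataclass(frozen=True)
class MonteCarloPowerResult:
    """Rejection proportion of a planned design over seeded replications."""

    power: float
    n_sim: int
    plan: SampleSizePlan
    rho_generating: tuple[float, float]
    predictive_interval: tuple[float, float]
    within_or_above: bool  # power >= lower predictive bound at the nominal target


def monte_carlo_power(
    design: DesignKind,
    effect: EffectOfInterest,
    spec: PowerSpec,
    costs: CostStructure,
    rect: ICCRectangle,
    rho_eval="maximin",
    sigma_y_sq: float = 2.0,
    n_sim: int = 25_000,
    seed: int = 0,
    under_null: bool = False,
) -> MonteCarloPowerResult:
    """Simulated power (or type-I error) of the maximin sample-size plan.

    Plans ``N`` via :func:`maximin_sample_size`, generates ``n_sim``
    replications at ``rho_eval`` (default: the worst-case ICC pair, where
    the plan must still deliver the target power) with the effect implied by
    ``spec.es`` on the coefficient of interest, analyzes each with the
    design's exact t-test and returns the rejection proportion.  With
    ``under_null=True`` the target coefficient is set to 0, so the
    rejection proportion estimates the type-I error rate.

    Each replication draws from its own stream spawned from ``seed``, so
    the estimate is reproducible and independent of replication order.
    """
    design = DesignKind(design)
    effect = EffectOfInterest(effect)
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    plan = maximin_sample_size(design, effect, spec, costs, rect)
    rho = plan.rho_star if isinstance(rho_eval, str) and rho_eval == "maximin" else tuple(rho_eval)
    beta = 0.0 if under_null else beta_from_effect_size(spec.es, sigma_y_sq)
    betas = {"beta0": 0.0, "beta_time": 0.25, "beta_treat": 0.0, "beta_interaction": 0.0}
    if effect is EffectOfInterest.TREATMENT:
        betas["beta_treat"] = beta
    else:
        betas["beta_interaction"] = beta
    params = ModelParams.from_icc(rho[0], rho[1], sigma_y_sq, **betas)

    streams = np.random.SeedSequence(seed).spawn(n_sim)
    rejections = 0
    for child in streams:
        data = simulate_trial(
            design, plan.n1, plan.n2, params, np.random.default_rng(child)
        )
        if analyze(data, effect, spec.alpha).reject:
            rejections += 1
    power = rejections / n_sim
    pi = predictive_interval(spec.power, n_sim)
    return MonteCarloPowerResult(
        power=power,
        n_sim=n_sim,
        plan=plan,
        rho_generating=(float(rho[0]), float(rho[1])),
        predictive_interval=pi,
        within_or_above=power >= pi[0],
    )
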