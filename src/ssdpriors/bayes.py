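"""Bayesian ideal observer for the jump / no-jump decision.

The observer sees a noisy percept of the true displacement x,
x_hat ~ N(x, sigma_t^2), and knows the generative displacement
distributions x|J ~ N(0, sigma_J^2) (jump) and x|noJ ~ N(0, sigma_noJ^2)
(no jump) together with the prior P(J).  Because both hypotheses are
zero-mean Gaussians, the posterior log-odds are monotone in x_hat^2 and the
optimal rule reduces to a quadratic criterion:

    report "jumped"  iff  x_hat^2 > xc^2,

    xc^2 = [log((sJ^2+st^2)/(sn^2+st^2)) + 2 log((1-P(J))/P(J))]
           / [1/(sn^2+st^2) - 1/(sJ^2+st^2)].

Since x_hat^2 / sigma_t^2 is a noncentral chi-square variable with one
degree of freedom and noncentrality x^2/sigma_t^2, the probability of
reporting a jump at true displacement x is the upper tail of that
distribution above xc^2/sigma_t^2.  A sufficiently strong jump prior makes
xc^2 negative, in which case the observer always reports a jump.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

__all__ = [
    "BayesParams",
    "DecisionCriterion",
    "decision_criterion",
    "jump_probability",
    "psychometric_curve",
    "bayes_prior_use",
    "PRIOR_USE_WINDOW",
]

#: Displacement window (degrees) over which prior use is averaged: the
#: range of small displacements well represented under both priors.
PRIOR_USE_WINDOW = (0.0, 2.0)


@dataclass(frozen=True)
class BayesParams:
    """Observer parameters, all sigmas in degrees of visual angle.

    sigma_t is the perceptual (image) uncertainty about the displacement;
    sigma_jump and sigma_nojump the widths of the jump and non-jump
    displacement distributions; prior_jump the cued P(J).
    """

    sigma_t: float
    sigma_jump: float
    sigma_nojump: float
    prior_jump: float

    def __post_init__(self) -> None:
        for name in ("sigma_t", "sigma_jump", "sigma_nojump"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.prior_jump < 1.0:
            raise ValueError("prior_jump must lie in (0,1)")

    def to_json(self) -> str:
        return json.dumps(
            {
                "sigma_t": self.sigma_t,
                "sigma_jump": self.sigma_jump,
                "sigma_nojump": self.sigma_nojump,
                "prior_jump": self.prior_jump,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "BayesParams":
        return cls(**json.loads(s))

    def with_prior(self, prior_jump: float) -> "BayesParams":
        return replace(self, prior_jump=prior_jump)


@dataclass(frozen=True)
class DecisionCriterion:
    """Squared criterion xc^2 (deg^2); negative values are legitimate and
    mean the observer reports a jump at every percept."""

    xhat_c_sq: float


def decision_criterion(params: BayesParams) -> DecisionCriterion:
    """Optimal squared-percept criterion for the jump report.

    Raises if sigma_jump == sigma_nojump (the quadratic term vanishes and
    no criterion on x_hat^2 exists).
    """
    vj = params.sigma_jump**2 + params.sigma_t**2
    vn = params.sigma_nojump**2 + params.sigma_t**2
    if vj == vn:
        raise ValueError(
            "criterion undefined: sigma_jump == sigma_nojump gives a "
            "degenerate (zero) denominator"
        )
    num = math.log(vj / vn) + 2.0 * math.log((1.0 - params.prior_jump) / params.prior_jump)
    den = 1.0 / vn - 1.0 / vj
    return DecisionCriterion(num / den)


def jump_probability(x, params: BayesParams):
    """Probability of reporting "jumped" at true displacement x (degrees).

    Upper tail of the noncentral chi-square(df=1, lambda=x^2/sigma_t^2)
    above xc^2/sigma_t^2.  Symmetric in +/-x; exactly 1 when the criterion
    is non-positive.  Scalar in, scalar out; array in, array out.
    """
    xc2 = decision_criterion(params).xhat_c_sq
    x = np.asarray(x, dtype=float)
    if xc2 <= 0.0:
        out = np.ones_like(x)
        return float(out) if out.ndim == 0 else out
    st2 = params.sigma_t**2
    nc = x**2 / st2
    out = stats.ncx2.sf(xc2 / st2, df=1, nc=nc)
    return float(out) if np.ndim(out) == 0 else out


def psychometric_curve(params: BayesParams, displacements) -> np.ndarray:
    """Jump-report probability over a displacement grid (nondecreasing in
    |x|)."""
    displacements = np.atleast_1d(np.asarray(displacements, dtype=float))
    if displacements.size == 0:
        raise ValueError("displacement grid must be nonempty")
    return np.asarray(jump_probability(displacements, params))


def bayes_prior_use(
    params_low: BayesParams,
    params_high: BayesParams,
    window: tuple[float, float] = PRIOR_USE_WINDOW,
    n_grid: int = 201,
) -> float:
    """Mean difference of the high- minus low-prior psychometric curves over
    the displacement window.  The two parameter sets must differ only in
    prior_jump."""
    same = (
        params_low.sigma_t == params_high.sigma_t
        and params_low.sigma_jump == params_high.sigma_jump
        and params_low.sigma_nojump == params_high.sigma_nojump
    )
    if not same:
        raise ValueError("parameter sets must differ only in prior_jump")
    lo, hi = window
    grid = np.linspace(lo, hi, n_grid) if hi > lo else np.array([lo])
    high = psychometric_curve(params_high, grid)
    low = psychometric_curve(params_low, grid)
    return float(np.mean(high - low))
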