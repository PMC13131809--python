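"""Maximum-likelihood fitting of the combined model to binary reports.

Twelve free parameters per session: the image noise sigma_t and the
saccade-driven (non-jump width) noise sigma_nojump for each of the four
noise conditions, the jump-distribution width sigma_jump, and the three
cued priors (0.2, 0.5, 0.8) as fitted probabilities.  Mirroring the
division of labor in the combined model, image noise enters the perceptron
component (as the input-encoding width for that condition) while
saccade-driven noise enters the Bayesian component, whose own perceptual
uncertainty stays pinned at 0.1 deg in every condition.  The perceptron
component is instantiated from a per-prior psychometric curve fit
(cumulative Gaussian in |x| with guess and lapse rates): the curve value
at each input-bin center sets that bin's learned jump association, and the
perceptron output is the activation-weighted average of the fitted curve.

Optimization is bounded quasi-Newton (L-BFGS-B) from multiple seeded
restarts; the likelihood is the Bernoulli log-likelihood of the binary
responses with model probabilities clamped away from 0 and 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .bayes import BayesParams, decision_criterion
from .perceptron import InputGrid
from .task import CONDITION_ORDER

__all__ = [
    "FreeParameterVector",
    "FitResult",
    "PsychometricCurve",
    "psychometric_fit",
    "negative_log_likelihood",
    "fit_combined",
    "generate_from_params",
]

CUE_PRIORS = (0.2, 0.5, 0.8)
#: Perceptual uncertainty of the Bayesian component, pinned in all
#: conditions (image noise is carried by the perceptron component).
BAYES_SIGMA_T = 0.1
P_CLAMP = 1e-9
SIGMA_BOUNDS = (0.01, 10.0)
PRIOR_BOUNDS = (0.01, 0.99)


@dataclass(frozen=True)
class FreeParameterVector:
    """The 12 free parameters, condition order = CONDITION_ORDER and prior
    order = CUE_PRIORS.  ``sigma_t`` is the per-condition image noise
    (perceptron encoding width); ``sigma_nojump`` the per-condition
    saccade-driven noise (Bayesian non-jump width)."""

    sigma_t: tuple[float, float, float, float]
    sigma_nojump: tuple[float, float, float, float]
    sigma_jump: float
    priors: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.sigma_t) != 4 or len(self.sigma_nojump) != 4 or len(self.priors) != 3:
            raise ValueError("expected 4 sigma_t, 4 sigma_nojump, 3 priors")
        if min(self.sigma_t) <= 0 or min(self.sigma_nojump) <= 0 or self.sigma_jump <= 0:
            raise ValueError("sigmas must be positive")
        if not all(0.0 < p < 1.0 for p in self.priors):
            raise ValueError("priors must lie in (0,1)")

    def to_array(self) -> np.ndarray:
        return np.array([*self.sigma_t, *self.sigma_nojump, self.sigma_jump, *self.priors])

    @classmethod
    def from_array(cls, v) -> "FreeParameterVector":
        v = np.asarray(v, dtype=float)
        if v.size != 12:
            raise ValueError("parameter vector must have length 12")
        return cls(tuple(v[:4]), tuple(v[4:8]), float(v[8]), tuple(v[9:12]))


@dataclass
class FitResult:
    estimates: FreeParameterVector | None
    negative_log_likelihood: float
    converged: bool
    restarts: pd.DataFrame = field(repr=False, default=None)
    seed: int | None = None


@dataclass
class PsychometricCurve:
    """Cumulative Gaussian in |x| with guess (lower) and lapse (upper)
    rates: psi(x) = guess + (1-guess-lapse) * Phi((|x|-mu)/sigma)."""

    mu: float
    sigma: float
    guess: float
    lapse: float
    degenerate: bool = False

    def __call__(self, x):
        z = (np.abs(np.asarray(x, dtype=float)) - self.mu) / self.sigma
        out = self.guess + (1.0 - self.guess - self.lapse) * stats.norm.cdf(z)
        return float(out) if np.ndim(out) == 0 else out


def psychometric_fit(trials: pd.DataFrame, prior: float | None = None) -> PsychometricCurve:
    """MLE cumulative-Gaussian fit of jump reports against |displacement|.

    ``trials`` needs displacement_deg and response columns; if ``prior`` is
    given, rows are restricted to that cued prior first.  Degenerate data
    (a single response value) yield a flagged constant curve at the
    corresponding bound.
    """
    df = trials if prior is None else trials[trials["prior"] == prior]
    x = df["displacement_deg"].abs().to_numpy(dtype=float)
    r = df["response"].to_numpy(dtype=float)
    if len(np.unique(np.round(x, 9))) < 2:
        raise ValueError("need >= 2 distinct |displacement| values")
    if r.min() == r.max():  # all-same response: boundary fit
        level = 1.0 - P_CLAMP if r.min() == 1.0 else P_CLAMP
        return PsychometricCurve(0.0, 1.0, level, 1.0 - level, degenerate=True)

    def nll(theta):
        mu, log_sigma, guess, lapse = theta
        psi = PsychometricCurve(mu, np.exp(log_sigma), guess, lapse)(x)
        psi = np.clip(psi, P_CLAMP, 1.0 - P_CLAMP)
        return -np.sum(r * np.log(psi) + (1.0 - r) * np.log1p(-psi))

    bounds = [(0.0, 7.5), (np.log(0.01), np.log(10.0)), (0.0, 0.5), (0.0, 0.5)]
    best = None
    for mu0 in (0.5, 1.5, 3.0):
        res = optimize.minimize(
            nll, x0=[mu0, np.log(0.7), 0.05, 0.05], method="L-BFGS-B", bounds=bounds
        )
        if best is None or res.fun < best.fun:
            best = res
    mu, log_sigma, guess, lapse = best.x
    return PsychometricCurve(float(mu), float(np.exp(log_sigma)), float(guess), float(lapse))


def _fast_jump_prob(absx: np.ndarray, params: BayesParams) -> np.ndarray:
    """Gaussian-tail form of the decision probability: with percept
    x_hat ~ N(x, sigma_t^2), P(x_hat^2 > xc^2) = Phi((x-xc)/st) +
    Phi((-x-xc)/st) for xc = sqrt(xc^2).  Identical to the noncentral
    chi-square form, but much cheaper inside the optimizer."""
    xc2 = decision_criterion(params).xhat_c_sq
    if xc2 <= 0.0:
        return np.ones_like(absx)
    xc = np.sqrt(xc2)
    st = params.sigma_t
    return special.ndtr((absx - xc) / st) + special.ndtr((-xc - absx) / st)


def _condition_labels(df: pd.DataFrame) -> np.ndarray:
    if "condition" in df.columns:
        return df["condition"].to_numpy()
    return np.where(df["saccade"].astype(bool), df["image_noise"], "no_saccade")


def _encode_rows(absx: np.ndarray, sigma: float, grid: InputGrid) -> np.ndarray:
    """Vectorized truncated-Gaussian population encoding, one row per trial."""
    mu = np.clip(absx, grid.lo, grid.hi)
    z = (grid.centers[None, :] - mu[:, None]) / sigma
    a = np.exp(-0.5 * z * z)
    s = a.sum(axis=1, keepdims=True)
    bad = s[:, 0] <= 0.0
    if bad.any():  # ultra-narrow encoding: fall back to one-hot
        idx = np.clip(((mu[bad] - grid.lo) / grid.bin_width).astype(int), 0, grid.n_units - 1)
        a[bad] = 0.0
        a[bad, idx] = 1.0
        s = a.sum(axis=1, keepdims=True)
    return a / s


def model_probabilities(
    params: FreeParameterVector,
    trials: pd.DataFrame,
    psych_curves: dict,
    w_bayes: float = 0.1,
    grid: InputGrid | None = None,
) -> np.ndarray:
    """Combined-model jump-report probability per trial."""
    grid = grid or InputGrid()
    cond = _condition_labels(trials)
    cue = trials["prior"].to_numpy(dtype=float)
    absx = trials["displacement_deg"].abs().to_numpy(dtype=float)
    psi = {p: np.asarray(psych_curves[p](grid.centers)) for p in np.unique(cue)}
    p = np.empty(len(trials))
    for ci, cname in enumerate(CONDITION_ORDER):
        m_c = cond == cname
        if not m_c.any():
            continue
        enc = _encode_rows(absx[m_c], params.sigma_t[ci], grid)
        o_p_all = {q: enc @ psi[q] for q in psi}
        p_c = np.empty(m_c.sum())
        cue_c = cue[m_c]
        for qi, q in enumerate(CUE_PRIORS):
            m_q = cue_c == q
            if not m_q.any():
                continue
            bp = BayesParams(
                sigma_t=BAYES_SIGMA_T,
                sigma_jump=params.sigma_jump,
                sigma_nojump=params.sigma_nojump[ci],
                prior_jump=params.priors[qi],
            )
            o_b = _fast_jump_prob(absx[m_c][m_q], bp)
            p_c[m_q] = w_bayes * o_b + (1.0 - w_bayes) * o_p_all[q][m_q]
        p[m_c] = p_c
    return np.clip(p, P_CLAMP, 1.0 - P_CLAMP)


def negative_log_likelihood(
    params: FreeParameterVector,
    trials: pd.DataFrame,
    psych_curves: dict | None = None,
    w_bayes: float = 0.1,
) -> float:
    """Bernoulli negative log-likelihood of the observed binary responses
    under the combined model (order-invariant; probabilities clamped)."""
    if psych_curves is None:
        psych_curves = {
            q: psychometric_fit(trials, q) for q in np.unique(trials["prior"])
        }
    # a jump distribution no wider than the non-jump distribution makes the
    # criterion ill-posed; steer the optimizer away with a smooth penalty
    gap = params.sigma_jump - max(params.sigma_nojump)
    if gap <= 1e-6:
        return 1e8 * (1.0 + abs(gap))
    p = model_probabilities(params, trials, psych_curves, w_bayes)
    r = trials["response"].to_numpy(dtype=float)
    return float(-np.sum(r * np.log(p) + (1.0 - r) * np.log1p(-p)))


def _default_start() -> np.ndarray:
    return np.array([0.3, 0.3, 1.0, 2.0, 0.5, 1.0, 1.0, 1.0, 2.5, 0.2, 0.5, 0.8])


def fit_combined(
    trials: pd.DataFrame,
    bounds: list | None = None,
    n_restarts: int = 8,
    seed: int | None = None,
    w_bayes: float = 0.1,
    maxiter: int = 120,
) -> FitResult:
    """Best-of-restarts bounded minimization of the combined-model NLL.

    Per-prior psychometric curves are fit once from the data and reused for
    every likelihood evaluation.  Deterministic given ``seed``; all restart
    endpoints are returned for diagnostics.
    """
    rng = np.random.default_rng(seed)
    psych_curves = {q: psychometric_fit(trials, q) for q in np.unique(trials["prior"])}
    if bounds is None:
        bounds = [SIGMA_BOUNDS] * 9 + [PRIOR_BOUNDS] * 3

    def objective(v):
        return negative_log_likelihood(
            FreeParameterVector.from_array(v), trials, psych_curves, w_bayes
        )

    starts = [_default_start()]
    for _ in range(max(0, n_restarts - 1)):
        sig = np.exp(rng.uniform(np.log(0.05), np.log(3.0), size=9))
        pri = rng.uniform(0.1, 0.9, size=3)
        starts.append(np.concatenate([sig, pri]))

    rows, best = [], None
    for i, x0 in enumerate(starts):
        res = optimize.minimize(
            objective, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter},
        )
        rows.append({"restart": i, "nll": float(res.fun), "success": bool(res.success)})
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    restarts = pd.DataFrame(rows)
    if best is None:
        return FitResult(None, float("inf"), False, restarts, seed)
    return FitResult(
        FreeParameterVector.from_array(best.x),
        float(best.fun),
        bool(restarts["success"].any()),
        restarts,
        seed,
    )


def self_consistent_curves(
    params: FreeParameterVector,
    w_bayes: float = 0.1,
    n_iter: int = 4,
    grid_max: float = 6.0,
    n_grid: int = 241,
) -> dict:
    """Per-cue psychometric curves that are fixed points of the fitting
    procedure's curve-refit step.

    The session fit instantiates the perceptron from a psychometric curve
    refit to the very responses being modeled, so a recovery ground truth
    whose curves differ from what refitting returns is mis-specified by
    construction.  Starting from plain cumulative Gaussians, each iteration
    replaces every cue's curve with the best cumulative-Gaussian fit to the
    combined model's mean output over the four conditions, weighted by the
    task displacement density for that cue.  Returns {cue_prior: curve}.
    """
    xs = np.linspace(0.0, grid_max, n_grid)
    from .combined import JUMP_SIGMA_TASK, NOJUMP_SIGMA_TASK

    curves = {
        q: PsychometricCurve(1.5 - q, 0.5, 0.02, 0.02) for q in CUE_PRIORS
    }
    rows = []
    for cname in CONDITION_ORDER:
        for q in CUE_PRIORS:
            for x in xs:
                rows.append(
                    {
                        "condition": cname,
                        "prior": q,
                        "displacement_deg": x,
                        "response": 0,
                    }
                )
    df = pd.DataFrame(rows)
    for qi, q in enumerate(CUE_PRIORS):
        pj = params.priors[qi]
        dens = pj * stats.norm.pdf(xs, 0, JUMP_SIGMA_TASK) + (1 - pj) * stats.norm.pdf(
            xs, 0, NOJUMP_SIGMA_TASK
        )
        df.loc[df["prior"] == q, "weight"] = np.tile(dens, len(CONDITION_ORDER))
    for _ in range(n_iter):
        p = model_probabilities(params, df, curves, w_bayes)
        new = {}
        for q in CUE_PRIORS:
            m = (df["prior"] == q).to_numpy()
            # mean model output across the four conditions at each x
            pm = p[m].reshape(len(CONDITION_ORDER), -1).mean(axis=0)
            w = df.loc[m, "weight"].to_numpy()[: len(xs)]

            def sse(theta, pm=pm, w=w):
                mu, log_sigma, guess, lapse = theta
                psi = PsychometricCurve(mu, np.exp(log_sigma), guess, lapse)(xs)
                return float(np.sum(w * (psi - pm) ** 2))

            best = None
            for mu0 in (0.5, 1.5):
                r = optimize.minimize(
                    sse,
                    x0=[mu0, np.log(0.7), 0.05, 0.05],
                    method="L-BFGS-B",
                    bounds=[(0.0, grid_max), (np.log(0.01), np.log(10.0)), (0, 0.5), (0, 0.5)],
                )
                if best is None or r.fun < best.fun:
                    best = r
            mu, ls, g, l = best.x
            new[q] = PsychometricCurve(float(mu), float(np.exp(ls)), float(g), float(l))
        curves = new
    return curves


def generate_from_params(
    params: FreeParameterVector,
    psych_curves: dict | None = None,
    n_trials: int = 2000,
    w_bayes: float = 0.1,
    seed: int | None = None,
    session_id: str = "sim",
) -> pd.DataFrame:
    """Synthesize a session from a known parameter vector (the parameter-
    recovery ground truth): trials interleave the four conditions and three
    cue priors uniformly; displacements follow the task mixture given the
    fitted prior; responses are Bernoulli draws from the model probability.
    Returns a trial table in the task CSV schema.
    """
    from .combined import JUMP_SIGMA_TASK, NOJUMP_SIGMA_TASK
    from .task import PROBE_SIGMAS

    if psych_curves is None:
        psych_curves = self_consistent_curves(params, w_bayes)
    rng = np.random.default_rng(seed)
    cells = [(c, q) for c in CONDITION_ORDER for q in CUE_PRIORS]
    idx = rng.integers(len(cells), size=n_trials)
    rows = []
    for k in idx:
        cname, q = cells[k]
        true_p = params.priors[CUE_PRIORS.index(q)]
        jumped = rng.random() < true_p
        x = rng.normal(0.0, JUMP_SIGMA_TASK if jumped else NOJUMP_SIGMA_TASK)
        rows.append(
            {
                "session_id": session_id,
                "prior": q,
                "saccade": int(cname != "no_saccade"),
                "image_noise": "low" if cname == "no_saccade" else cname,
                "probe_sigma": PROBE_SIGMAS["low" if cname == "no_saccade" else cname],
                "displacement_deg": x,
                "response": 0,
                "valid": 1,
            }
        )
    df = pd.DataFrame(rows)
    p = model_probabilities(params, df, psych_curves, w_bayes)
    df["response"] = (rng.random(n_trials) < p).astype(int)
    return df
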