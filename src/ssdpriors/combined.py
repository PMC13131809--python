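"""Weighted combination of the Bayesian observer and the category net.

The combined report probability is O_C = w_B * O_B + w_P * O_P with
w_B + w_P = 1.  Saccade-driven noise lives in the Bayesian component (the
non-jump distribution widens when a saccade intervenes, image uncertainty
pinned at 0.1 deg); image noise lives in the perceptron component (input
encoding noise 0.1 / 1 / 2 deg for low / medium / high).

``simulate_experiment`` runs the standard protocol: 1000 training trials in
the with-saccade low-image-noise condition (learning rate 0.5), then 1000
test trials with frozen weights spread over the four noise conditions at
priors 0.2 and 0.8, recording the model output and a Bernoulli response per
trial.  Prior use — the high-minus-low-prior difference in jump-report
rates over 0-2 deg displacements — rises from the no-saccade to the
with-saccade condition but falls as image noise grows (the inverted-V,
"anti-Bayesian" pattern).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bayes import BayesParams, jump_probability, PRIOR_USE_WINDOW
from .perceptron import InputGrid, PerceptronNet, encode_input, forward, train_step
from .task import CONDITION_ORDER, PROBE_SIGMAS

__all__ = [
    "CombinedParams",
    "SimulationResult",
    "combined_output",
    "simulate_experiment",
    "behavioral_prior_use",
    "compare_prior_use",
]

#: Generative displacement widths of the task (degrees): jump draws are
#: broad, non-jump draws narrow.
JUMP_SIGMA_TASK = 2.5
NOJUMP_SIGMA_TASK = 0.2


@dataclass(frozen=True)
class CombinedParams:
    """Simulation protocol parameters (degrees / trials)."""

    w_bayes: float = 0.1
    sigma_jump: float = 2.5
    sigma_nojump_nosacc: float = 0.5
    sigma_nojump_sacc: float = 1.0
    bayes_sigma_t: float = 0.1
    perceptron_noise: tuple[float, float, float] = (0.1, 1.0, 2.0)  # low/med/high
    learning_rate: float = 0.5
    n_train: int = 1000
    n_test: int = 1000
    priors: tuple[float, ...] = (0.2, 0.8)

    def __post_init__(self) -> None:
        if not 0.0 <= self.w_bayes <= 1.0:
            raise ValueError("w_bayes must lie in [0,1]")

    @property
    def w_perceptron(self) -> float:
        return 1.0 - self.w_bayes

    def sigma_nojump(self, saccade: bool) -> float:
        return self.sigma_nojump_sacc if saccade else self.sigma_nojump_nosacc

    def encode_noise(self, condition: str) -> float:
        lo, med, hi = self.perceptron_noise
        return {"no_saccade": lo, "low": lo, "medium": med, "high": hi}[condition]

    def bayes_params(self, condition: str, prior: float) -> BayesParams:
        return BayesParams(
            sigma_t=self.bayes_sigma_t,
            sigma_jump=self.sigma_jump,
            sigma_nojump=self.sigma_nojump(condition != "no_saccade"),
            prior_jump=prior,
        )


@dataclass
class SimulationResult:
    """Test-phase records plus prior-use summaries.

    ``trials`` columns: condition, prior, jumped, displacement_deg, o_bayes,
    o_perceptron, o_combined, response.  ``prior_use`` is computed from the
    sampled binary responses, ``output_prior_use`` from the deterministic
    model outputs (useful for low-variance checks).
    """

    trials: pd.DataFrame
    prior_use: dict
    output_prior_use: dict
    net: PerceptronNet = field(repr=False, default=None)


def combined_output(o_b, o_p, w_b: float):
    """Convex combination w_b*o_b + (1-w_b)*o_p of the model outputs."""
    o_b = np.asarray(o_b, dtype=float)
    o_p = np.asarray(o_p, dtype=float)
    if np.any((o_b < 0) | (o_b > 1)) or np.any((o_p < 0) | (o_p > 1)):
        raise ValueError("component outputs must lie in [0,1]")
    if not 0.0 <= w_b <= 1.0:
        raise ValueError("w_b must lie in [0,1]")
    out = w_b * o_b + (1.0 - w_b) * o_p
    return float(out) if out.ndim == 0 else out


def _draw_displacement(rng: np.random.Generator, jumped: bool) -> float:
    sigma = JUMP_SIGMA_TASK if jumped else NOJUMP_SIGMA_TASK
    return float(rng.normal(0.0, sigma))


def simulate_experiment(
    params: CombinedParams = CombinedParams(), seed: int | None = None
) -> SimulationResult:
    """Run the training + test protocol, deterministic per seed."""
    rng = np.random.default_rng(seed)
    grid = InputGrid()
    net = PerceptronNet(priors=params.priors, learning_rate=params.learning_rate, grid=grid)
    train_noise = params.encode_noise("low")

    # Training phase: with-saccade, low image noise; priors interleaved.
    for _ in range(params.n_train):
        prior = float(rng.choice(params.priors))
        jumped = rng.random() < prior
        x = _draw_displacement(rng, jumped)
        act = encode_input(x, train_noise, grid)
        train_step(net, act, jumped, prior)

    # Test phase: frozen weights, four noise conditions x two priors.
    cells = [(c, p) for c in CONDITION_ORDER for p in params.priors]
    rows = []
    for _ in range(params.n_test):
        cond, prior = cells[rng.integers(len(cells))]
        jumped = rng.random() < prior
        x = _draw_displacement(rng, jumped)
        o_b = jump_probability(abs(x), params.bayes_params(cond, prior))
        act = encode_input(x, params.encode_noise(cond), grid)
        # weights are updated unclamped, so the normalized output can leave
        # [0,1] slightly once weights cross zero; clip before combining
        o_p = float(np.clip(forward(net, act, prior)[0], 0.0, 1.0))
        o_c = combined_output(o_b, o_p, params.w_bayes)
        rows.append(
            {
                "condition": cond,
                "prior": prior,
                "jumped": int(jumped),
                "displacement_deg": x,
                "o_bayes": o_b,
                "o_perceptron": o_p,
                "o_combined": o_c,
                "response": int(rng.random() < o_c),
            }
        )
    trials = pd.DataFrame(rows)
    prior_use = _prior_use_table(trials, "response", params.priors)
    output_prior_use = _prior_use_table(trials, "o_combined", params.priors)
    return SimulationResult(trials, prior_use, output_prior_use, net)


def _prior_use_table(trials: pd.DataFrame, column: str, priors) -> dict:
    lo_p, hi_p = min(priors), max(priors)
    lo_w, hi_w = PRIOR_USE_WINDOW
    out = {}
    absx = trials["displacement_deg"].abs()
    sel = trials[(absx >= lo_w) & (absx <= hi_w)]
    for cond in CONDITION_ORDER:
        sub = sel[sel["condition"] == cond]
        hi = sub[sub["prior"] == hi_p][column]
        lo = sub[sub["prior"] == lo_p][column]
        if len(hi) == 0 or len(lo) == 0:
            warnings.warn(f"prior use undefined in condition {cond!r}: empty prior cell")
            out[cond] = float("nan")
        else:
            out[cond] = float(hi.mean() - lo.mean())
    return out


def behavioral_prior_use(
    trials: pd.DataFrame,
    window: tuple[float, float] = PRIOR_USE_WINDOW,
    prior_low: float = 0.2,
    prior_high: float = 0.8,
) -> dict:
    """Per-noise-condition difference in jump-report rates between priors,
    over trials with |displacement| inside the window.

    Accepts either simulation records (a ``condition`` column) or the task
    trial-table schema (``saccade`` + ``image_noise`` columns).  A prior
    cell empty within the window yields NaN with a warning, never a silent
    zero.
    """
    df = trials.copy()
    if "condition" not in df.columns:
        df["condition"] = np.where(
            df["saccade"].astype(bool), df["image_noise"], "no_saccade"
        )
        df = df.rename(columns={"response": "response"})
    lo_w, hi_w = window
    absx = df["displacement_deg"].abs()
    sel = df[(absx >= lo_w) & (absx <= hi_w)]
    out = {}
    for cond in CONDITION_ORDER:
        sub = sel[sel["condition"] == cond]
        hi = sub[sub["prior"] == prior_high]["response"]
        lo = sub[sub["prior"] == prior_low]["response"]
        if len(hi) == 0 or len(lo) == 0:
            warnings.warn(
                f"prior use undefined in condition {cond!r}: a prior cell is empty"
            )
            out[cond] = float("nan")
        else:
            out[cond] = float(hi.mean() - lo.mean())
    return out


def compare_prior_use(values: pd.DataFrame) -> dict:
    """Session-level tests of the prior-use pattern across noise conditions.

    ``values``: one row per session, columns = the four noise conditions.
    Returns the paired t-test for no-saccade vs the common (with-saccade,
    low-image-noise) condition, a repeated-measures ANOVA over the three
    image-noise levels, and pairwise paired-t follow-ups.
    """
    needed = set(CONDITION_ORDER)
    if not needed.issubset(values.columns):
        raise ValueError(f"values must have columns {sorted(needed)}")
    if len(values) < 2:
        raise ValueError("need at least 2 sessions")

    def _paired(a, b):
        diff = np.asarray(a) - np.asarray(b)
        if np.allclose(diff, diff[0]) and np.allclose(diff[0], 0.0):
            return 0.0, 1.0
        t, p = stats.ttest_rel(a, b)
        return float(t), float(p)

    t_sacc, p_sacc = _paired(values["low"], values["no_saccade"])

    # repeated-measures ANOVA across image-noise levels (with saccade)
    from statsmodels.stats.anova import AnovaRM

    long = values[["low", "medium", "high"]].reset_index(drop=True)
    long["session"] = np.arange(len(long))
    long = long.melt(id_vars="session", var_name="noise", value_name="prior_use")
    wide = values[["low", "medium", "high"]]
    within_dev = wide.sub(wide.mean(axis=1), axis=0).abs().values.max()
    if within_dev < 1e-12:  # no within-session variation across levels
        f_stat, p_anova = 0.0, 1.0
    else:
        res = AnovaRM(long, "prior_use", "session", within=["noise"]).fit()
        f_stat = float(res.anova_table["F Value"].iloc[0])
        p_anova = float(res.anova_table["Pr > F"].iloc[0])

    pairwise = {}
    for a, b in (("low", "medium"), ("low", "high"), ("medium", "high")):
        pairwise[f"{a}_vs_{b}"] = _paired(values[a], values[b])

    return {
        "saccade_paired_t": (t_sacc, p_sacc),
        "image_noise_rm_anova": (f_stat, p_anova),
        "image_noise_pairwise": pairwise,
    }
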