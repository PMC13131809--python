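"""Firing-rate analyses for prior modulation in frontal-eye-field neurons.

The analyses quantify how the difference in firing between high- and
low-prior trials (the "neuronal prior use") behaves across the four noise
conditions of the task, aligned to four task events (fixation acquisition,
probe onset, intervening-saccade offset = the reafferent event, and the
response).  The central statistic is the signed Wilcoxon rank-sum effect
size z/sqrt(n), positive when high-prior rates exceed low-prior rates.

Epoch rates (spike count / window duration) feed all statistics;
z-scored, Gaussian-smoothed series are produced only for visualization.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .task import CONDITION_ORDER

__all__ = [
    "NeuronRecording",
    "EpochDefinition",
    "EffectSizeResult",
    "RegressionDesign",
    "SilentNeuronError",
    "FIXATION_EPOCH",
    "REAFFERENT_EPOCH",
    "PATTERN_TEMPLATES",
    "zscore_rates",
    "smooth",
    "epoch_rate",
    "wilcoxon_effect",
    "exact_rank_sum_p",
    "epoch_prior_screen",
    "sliding_bins",
    "normalize_to_common",
    "neuron_behavior_correlation",
    "build_mixed_designs",
    "fit_mixed_models",
    "classify_pattern",
]

log = logging.getLogger(__name__)

#: Default per-alignment analysis windows (ms relative to the event).
DEFAULT_WINDOWS = {
    "fixation": (-100.0, 400.0),
    "probe": (-100.0, 500.0),
    "reafferent": (-200.0, 1000.0),
    "response": (-300.0, 300.0),
}

PRIOR_LOW, PRIOR_HIGH = 0.2, 0.8


class SilentNeuronError(ValueError):
    """Raised when a neuron has zero spike-count variance (SD = 0)."""


@dataclass(frozen=True)
class EpochDefinition:
    alignment: str
    start: float  # ms
    end: float  # ms

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("epoch start must precede end")

    @property
    def duration_s(self) -> float:
        return (self.end - self.start) / 1000.0


FIXATION_EPOCH = EpochDefinition("fixation", 0.0, 250.0)
REAFFERENT_EPOCH = EpochDefinition("reafferent", 0.0, 800.0)


@dataclass
class NeuronRecording:
    """Event-aligned spike series with per-trial condition labels.

    ``trials``: one row per trial with at least ``condition`` (noise label),
    ``prior``, ``displacement_deg``, ``response``.  ``spikes`` maps each
    alignment event to a list (one entry per trial) of spike-time arrays in
    ms relative to the event, or None when the trial lacks that alignment.
    """

    neuron_id: str
    trials: pd.DataFrame
    spikes: dict
    windows: dict = field(default_factory=lambda: dict(DEFAULT_WINDOWS))
    session_id: str = ""

    def __post_init__(self) -> None:
        for ev, series in self.spikes.items():
            if len(series) != len(self.trials):
                raise ValueError(
                    f"alignment {ev!r}: {len(series)} spike series for "
                    f"{len(self.trials)} trials"
                )


def zscore_rates(
    rec: NeuronRecording, bin_ms: float = 20.0, alignment: str = "reafferent"
) -> tuple[np.ndarray, np.ndarray]:
    """Z-score normalized binned rates, pooled across all task conditions.

    Spikes are binned into non-overlapping ``bin_ms`` bins over the
    alignment window; the pooled mean and SD over every trial x bin entry
    define the normalization, so the returned array has pooled mean 0 and
    SD 1.  Returns (n_trials x n_bins array, bin centers in ms).
    """
    t0, t1 = rec.windows[alignment]
    edges = np.arange(t0, t1 + 0.5 * bin_ms, bin_ms)
    counts = np.vstack(
        [
            np.histogram(np.asarray(s, dtype=float), bins=edges)[0]
            for s in rec.spikes[alignment]
        ]
    ).astype(float)
    sd = counts.std()
    if sd == 0:
        raise SilentNeuronError(
            f"neuron {rec.neuron_id}: zero pooled SD, cannot z-score"
        )
    z = (counts - counts.mean()) / sd
    centers = edges[:-1] + 0.5 * bin_ms
    return z, centers


def smooth(
    series: np.ndarray, kernel_sigma_ms: float = 20.0, bin_ms: float = 20.0
) -> np.ndarray:
    """Linear convolution with a unit-area Gaussian kernel (sigma in ms,
    truncated at +/-3 sigma).  Works on 1-D series or (trials x bins)."""
    sigma_bins = kernel_sigma_ms / bin_ms
    radius = max(1, int(np.ceil(3.0 * sigma_bins)))
    t = np.arange(-radius, radius + 1)
    kernel = np.exp(-0.5 * (t / sigma_bins) ** 2)
    kernel /= kernel.sum()
    arr = np.asarray(series, dtype=float)
    if arr.ndim == 1:
        return np.convolve(arr, kernel, mode="same")
    return np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="same"), -1, arr)


def epoch_rate(rec: NeuronRecording, epoch: EpochDefinition) -> pd.Series:
    """Per-trial firing rate (spikes/s) in the epoch window; trials missing
    the alignment are skipped with a log entry."""
    series = rec.spikes.get(epoch.alignment)
    if series is None:
        raise KeyError(f"no spikes aligned to {epoch.alignment!r}")
    rates = {}
    for i, s in enumerate(series):
        if s is None:
            log.info("neuron %s trial %d: missing %s alignment, skipped",
                     rec.neuron_id, i, epoch.alignment)
            continue
        s = np.asarray(s, dtype=float)
        n = int(np.count_nonzero((s >= epoch.start) & (s < epoch.end)))
        rates[i] = n / epoch.duration_s
    return pd.Series(rates, dtype=float)


@dataclass(frozen=True)
class EffectSizeResult:
    """Signed rank-sum effect z/sqrt(n): positive when the high-prior
    sample ranks above the low-prior sample."""

    effect: float
    p_value: float
    n_high: int
    n_low: int


def wilcoxon_effect(high, low) -> EffectSizeResult:
    """Wilcoxon rank-sum effect size with tie-corrected normal z.

    Two-sided p from the normal approximation; all-identical samples give
    effect 0, p 1.
    """
    high = np.asarray(high, dtype=float)
    low = np.asarray(low, dtype=float)
    n1, n2 = len(high), len(low)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be nonempty")
    n = n1 + n2
    pooled = np.concatenate([high, low])
    ranks = stats.rankdata(pooled)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1.0))
    var = n1 * n2 / 12.0 * ((n + 1.0) - tie_term)
    if var <= 0:  # every value identical
        return EffectSizeResult(0.0, 1.0, n1, n2)
    z = (u - mu) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return EffectSizeResult(float(z / np.sqrt(n)), float(min(p, 1.0)), n1, n2)


def exact_rank_sum_p(high, low) -> float:
    """Exact two-sided rank-sum p by enumeration of all group assignments
    (test oracle for small samples; O(C(n1+n2, n1)))."""
    high = np.asarray(high, dtype=float)
    low = np.asarray(low, dtype=float)
    n1 = len(high)
    pooled = np.concatenate([high, low])
    ranks = stats.rankdata(pooled)
    mu = n1 * (len(pooled) - n1) / 2.0
    offset = n1 * (n1 + 1) / 2.0
    obs = abs(ranks[:n1].sum() - offset - mu)
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(ranks[list(comb)].sum() - offset - mu) >= obs - 1e-9:
            count += 1
    return count / total


def _prior_rates(
    rec: NeuronRecording, epoch: EpochDefinition, condition: str
) -> tuple[np.ndarray, np.ndarray]:
    rates = epoch_rate(rec, epoch)
    tr = rec.trials.iloc[rates.index]
    mask = tr["condition"].to_numpy() == condition
    high = rates.to_numpy()[mask & (tr["prior"].to_numpy() == PRIOR_HIGH)]
    low = rates.to_numpy()[mask & (tr["prior"].to_numpy() == PRIOR_LOW)]
    return high, low


def condition_effects(
    rec: NeuronRecording, epoch: EpochDefinition = REAFFERENT_EPOCH
) -> dict:
    """Prior-contrast effect size per noise condition (rates computed once
    and sliced, so this is the efficient path for whole-population runs)."""
    rates = epoch_rate(rec, epoch)
    tr = rec.trials.iloc[rates.index]
    vals = rates.to_numpy()
    cond = tr["condition"].to_numpy()
    prior = tr["prior"].to_numpy()
    out = {}
    for c in CONDITION_ORDER:
        m = cond == c
        out[c] = wilcoxon_effect(
            vals[m & (prior == PRIOR_HIGH)], vals[m & (prior == PRIOR_LOW)]
        )
    return out


def epoch_prior_screen(
    neurons: Iterable[NeuronRecording],
    epochs: Mapping[str, EpochDefinition] | None = None,
    alpha: float = 0.025,
    condition: str = "low",
) -> pd.DataFrame:
    """High- vs low-prior rank-sum screen per neuron and epoch in the given
    (by default common) condition.  alpha = 0.025 corrects for the two
    canonical epochs."""
    epochs = epochs or {"fixation": FIXATION_EPOCH, "reafferent": REAFFERENT_EPOCH}
    rows = []
    for rec in neurons:
        for name, epoch in epochs.items():
            high, low = _prior_rates(rec, epoch, condition)
            res = wilcoxon_effect(high, low)
            rows.append(
                {
                    "neuron_id": rec.neuron_id,
                    "session_id": rec.session_id,
                    "epoch": name,
                    "effect": res.effect,
                    "p_value": res.p_value,
                    "significant": res.p_value < alpha,
                    "n_high": res.n_high,
                    "n_low": res.n_low,
                }
            )
    return pd.DataFrame(rows)


def sliding_bins(
    rec: NeuronRecording,
    window_ms: float = 100.0,
    step_ms: float = 50.0,
    span: tuple[float, float] = (0.0, 800.0),
    alignment: str = "reafferent",
    alpha: float = 0.025 / 15,
    condition: str = "low",
) -> tuple[pd.DataFrame, int | None]:
    """Prior contrast in successive overlapping bins of the reafferent
    window (15 bins for the default 0-800 ms span; alpha corrected
    accordingly).  Returns the per-bin table and the earliest significant
    bin index (None if never significant)."""
    starts = np.arange(span[0], span[1] - window_ms + 0.5 * step_ms, step_ms)
    rows = []
    earliest = None
    for i, s in enumerate(starts):
        epoch = EpochDefinition(alignment, float(s), float(s + window_ms))
        high, low = _prior_rates(rec, epoch, condition)
        res = wilcoxon_effect(high, low)
        sig = res.p_value < alpha
        if sig and earliest is None:
            earliest = i
        rows.append(
            {
                "bin": i,
                "start_ms": float(s),
                "end_ms": float(s + window_ms),
                "effect": res.effect,
                "p_value": res.p_value,
                "significant": sig,
            }
        )
    return pd.DataFrame(rows), earliest


def normalize_to_common(
    values: Mapping[str, float], common: float, eps: float = 0.01
) -> dict:
    """Divide per-condition values by the common-condition value; the
    common condition itself maps to exactly 1.  |common| below ``eps``
    raises, so the caller can exclude the session."""
    if abs(common) < eps:
        raise ValueError(
            f"common-condition value {common:.4g} below floor {eps}; "
            "session excluded from normalization"
        )
    return {k: float(v) / common for k, v in values.items()}


def neuron_behavior_correlation(neuronal, behavioral) -> tuple[float, float]:
    """Pearson correlation across sessions between normalized neuronal and
    behavioral prior use (two-sided p)."""
    x = np.asarray(neuronal, dtype=float)
    y = np.asarray(behavioral, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired sessions")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Mixed-effects regression designs

FIXED_TERMS = (
    "prior",
    "saccade",
    "image",
    "displacement",
    "image_x_saccade",
    "image_x_prior",
    "saccade_x_prior",
)

IMAGE_CODES = {"low": 0.0, "medium": 1.0, "high": 2.0}


@dataclass
class RegressionDesign:
    outcome: str
    group: str
    data: pd.DataFrame = field(repr=False)
    fixed_terms: tuple
    aliased_terms: tuple = ()

    @property
    def is_rank_deficient(self) -> bool:
        return len(self.aliased_terms) > 0


def _coded_table(df: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame(index=df.index)
    if "condition" in df.columns:
        cond = df["condition"].astype(str)
        out["saccade"] = (cond != "no_saccade").astype(float)
        out["image"] = cond.map(lambda c: IMAGE_CODES.get(c, 0.0)).astype(float)
    else:
        out["saccade"] = df["saccade"].astype(float)
        out["image"] = df["image_noise"].map(IMAGE_CODES).astype(float)
    out["prior"] = (df["prior"] == PRIOR_HIGH).astype(float)
    out["displacement"] = df["displacement_deg"].abs().astype(float)
    out["image_x_saccade"] = out["image"] * out["saccade"]
    out["image_x_prior"] = out["image"] * out["prior"]
    out["saccade_x_prior"] = out["saccade"] * out["prior"]
    return out


def _detect_aliased(X: pd.DataFrame, tol: float = 1e-8) -> list[str]:
    """Greedy left-to-right detection of columns linearly dependent on an
    intercept plus the columns before them."""
    cols = list(X.columns)
    kept = [np.ones(len(X))]
    aliased = []
    for c in cols:
        trial = np.column_stack(kept + [X[c].to_numpy()])
        if np.linalg.matrix_rank(trial, tol=tol * max(1.0, np.abs(trial).max())) == len(kept):
            aliased.append(c)
        else:
            kept.append(X[c].to_numpy())
    return aliased


def build_mixed_designs(
    trials: pd.DataFrame, rates: pd.Series | np.ndarray | str = "rate"
) -> tuple[RegressionDesign, RegressionDesign]:
    """Construct the behavioral (binomial, grouped by session) and neural
    (linear, grouped by neuron) regression designs with the seven fixed
    effects: prior, saccade noise, image noise, displacement, and the
    image x saccade, image x prior, saccade x prior interactions.

    Because image noise varies only on with-saccade trials, the
    image x saccade column is linearly dependent on the main effects in the
    standard grid; aliased columns are detected and reported on the design
    (and dropped at fit time).  Missing columns raise with their names.
    """
    required = {"session_id", "prior", "displacement_deg", "response"}
    if "condition" not in trials.columns:
        required |= {"saccade", "image_noise"}
    missing = sorted(required - set(trials.columns))
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    trials = trials[trials["prior"].isin([PRIOR_LOW, PRIOR_HIGH])].reset_index(drop=True)
    coded = _coded_table(trials)
    if isinstance(rates, str):
        if rates not in trials.columns:
            raise ValueError(f"trial table missing columns: ['{rates}']")
        rate_vals = trials[rates].to_numpy(dtype=float)
    else:
        rate_vals = np.asarray(rates, dtype=float)
    if "neuron_id" not in trials.columns:
        raise ValueError("trial table missing columns: ['neuron_id']")

    aliased = tuple(_detect_aliased(coded[list(FIXED_TERMS)]))
    data = coded.copy()
    data["session_id"] = trials["session_id"].to_numpy()
    data["neuron_id"] = trials["neuron_id"].to_numpy()
    data["response"] = trials["response"].to_numpy(dtype=float)
    data["rate"] = rate_vals

    behavioral = RegressionDesign(
        outcome="response", group="session_id", data=data,
        fixed_terms=FIXED_TERMS, aliased_terms=aliased,
    )
    neural = RegressionDesign(
        outcome="rate", group="neuron_id", data=data,
        fixed_terms=FIXED_TERMS, aliased_terms=aliased,
    )
    return behavioral, neural


def _fit_linear_mixed(design: RegressionDesign, random_slopes: Sequence[str]) -> pd.DataFrame:
    import statsmodels.api as sm

    terms = [t for t in design.fixed_terms if t not in design.aliased_terms]
    X = sm.add_constant(design.data[terms])
    re_cols = ["const_re"] + [t for t in random_slopes if t in terms]
    exog_re = pd.DataFrame({"const_re": np.ones(len(design.data))})
    for t in re_cols[1:]:
        exog_re[t] = design.data[t].to_numpy()
    model = sm.MixedLM(
        design.data[design.outcome].to_numpy(dtype=float),
        X,
        groups=design.data[design.group],
        exog_re=exog_re,
    )
    res = model.fit(reml=True, method="lbfgs", maxiter=200)
    rows = []
    for term in ["const"] + terms:
        rows.append(
            {
                "term": term,
                "coef": float(res.params[term]),
                "se": float(res.bse[term]),
                "stat": float(res.tvalues[term]),
                "p_value": float(res.pvalues[term]),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["converged"] = bool(res.converged)
    return out


def _fit_binomial_mixed(design: RegressionDesign, random_slopes: Sequence[str]) -> pd.DataFrame:
    from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

    terms = [t for t in design.fixed_terms if t not in design.aliased_terms]
    data = design.data.copy()
    data["grp"] = data[design.group].astype(str)
    formula = f"{design.outcome} ~ " + " + ".join(terms)
    vc_formulas = {"grp": "0 + C(grp)"}
    for t in random_slopes:
        if t in terms:
            vc_formulas[f"grp_{t}"] = f"0 + C(grp):{t}"
    model = BinomialBayesMixedGLM.from_formula(formula, vc_formulas, data)
    res = model.fit_vb()
    names = list(model.exog_names)
    rows = []
    for i, name in enumerate(names):
        coef = float(res.fe_mean[i])
        se = float(res.fe_sd[i])
        z = coef / se if se > 0 else 0.0
        rows.append(
            {
                "term": "const" if name == "Intercept" else name,
                "coef": coef,
                "se": se,
                "stat": z,
                "p_value": float(2.0 * stats.norm.sf(abs(z))),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["converged"] = True
    return out


def fit_mixed_models(
    designs: tuple[RegressionDesign, RegressionDesign],
    random_slopes: Sequence[str] = ("prior",),
) -> dict:
    """Fit the behavioral (binomial GLMM, variational approximation) and
    neural (linear mixed model, REML) designs; returns coefficient tables
    keyed 'behavioral' and 'neural'.  Random effects: per-group intercepts
    plus independent slopes for ``random_slopes``."""
    behavioral, neural = designs
    out = {}
    try:
        out["behavioral"] = _fit_binomial_mixed(behavioral, random_slopes)
    except Exception as exc:  # noqa: BLE001 - surfaced, not swallowed
        out["behavioral"] = pd.DataFrame()
        out["behavioral"].attrs["converged"] = False
        out["behavioral"].attrs["error"] = str(exc)
        log.warning("behavioral mixed model failed: %s", exc)
    try:
        out["neural"] = _fit_linear_mixed(neural, random_slopes)
    except Exception as exc:  # noqa: BLE001
        out["neural"] = pd.DataFrame()
        out["neural"].attrs["converged"] = False
        out["neural"].attrs["error"] = str(exc)
        log.warning("neural mixed model failed: %s", exc)
    return out


# ---------------------------------------------------------------------------
# Qualitative pattern classification

#: Canonical high-minus-low-prior gain profiles over CONDITION_ORDER
#: (no-saccade, common, medium, high), scaled so the common condition is 1.
PATTERN_TEMPLATES = {
    "bayesian": (0.25, 1.0, 1.0, 1.0),
    "anti_bayesian": (1.0, 1.0, 0.55, 0.25),
    "prior_only": (1.0, 1.0, 1.0, 1.0),
    "output_mirroring": (0.25, 1.0, 0.55, 0.25),
}


def classify_pattern(
    effects: Mapping[str, float],
    templates: Mapping[str, Sequence[float]] | None = None,
    floor: float = 0.05,
    mirroring_profile: Mapping[str, float] | None = None,
) -> str:
    """Assign the qualitative prior-use signature best matching a neuron's
    per-condition effect sizes.

    The observed effect vector (over CONDITION_ORDER) is first linearized
    — the rank-sum effect compresses large rate differences, so each
    effect is converted to its equivalent normal shift via the
    common-language effect size, d = sqrt(2) * Phi^-1(e/sqrt(3) + 1/2) —
    and then compared to each canonical gain template under a free
    positive scale (least squares); the smallest residual wins.  A
    common-condition effect below ``floor`` in magnitude, or a tie, is
    'unclassified'.

    The output-mirroring outcome is defined as tracking the *session's*
    behavioral prior use, so when ``mirroring_profile`` (per-condition
    behavioral prior use) is supplied it replaces the canonical
    output-mirroring template, normalized to its common-condition value.
    """
    templates = dict(templates or PATTERN_TEMPLATES)
    if mirroring_profile is not None:
        prof = np.array([float(mirroring_profile[c]) for c in CONDITION_ORDER])
        ref = prof[CONDITION_ORDER.index("low")]
        if np.all(np.isfinite(prof)) and abs(ref) > 1e-9:
            templates["output_mirroring"] = prof / ref
    try:
        e = np.array([float(effects[c]) for c in CONDITION_ORDER])
    except KeyError as exc:
        raise ValueError(f"effect size missing for condition {exc}") from exc
    common = e[CONDITION_ORDER.index("low")]
    if abs(common) < floor:
        return "unclassified"
    e = e * np.sign(common)
    # effect -> AUC -> equivalent normal shift (undoes rank-sum saturation)
    auc = np.clip(e / np.sqrt(3.0) + 0.5, 1e-6, 1.0 - 1e-6)
    e = np.sqrt(2.0) * stats.norm.ppf(auc)
    resid = {}
    for name, t in templates.items():
        t = np.asarray(t, dtype=float)
        s = max(0.0, float(e @ t) / float(t @ t))
        resid[name] = float(np.sum((e - s * t) ** 2))
    ordered = sorted(resid.items(), key=lambda kv: kv[1])
    if len(ordered) > 1 and abs(ordered[0][1] - ordered[1][1]) < 1e-12:
        return "unclassified"
    return ordered[0][0]


# ---------------------------------------------------------------------------
# Spike-table serialization (long CSV: neuron_id, trial_id, alignment_event,
# spike_time_ms)

def write_spikes(recordings: Iterable[NeuronRecording], path) -> None:
    rows = []
    for rec in recordings:
        for ev, series in rec.spikes.items():
            for trial, s in enumerate(series):
                if s is None:
                    continue
                for t in np.asarray(s, dtype=float):
                    rows.append((rec.neuron_id, trial, ev, t))
    pd.DataFrame(
        rows, columns=["neuron_id", "trial_id", "alignment_event", "spike_time_ms"]
    ).to_csv(path, index=False)


def read_spikes(path, n_trials_by_neuron: Mapping[str, int]) -> dict:
    """Read a long spike table back into {neuron_id: {alignment: [arrays]}}."""
    df = pd.read_csv(path)
    out = {}
    for (nid, ev), grp in df.groupby(["neuron_id", "alignment_event"]):
        n = n_trials_by_neuron[str(nid)]
        series = [np.array([]) for _ in range(n)]
        for trial, g in grp.groupby("trial_id"):
            series[int(trial)] = np.sort(g["spike_time_ms"].to_numpy(dtype=float))
        out.setdefault(str(nid), {})[ev] = series
    return out
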