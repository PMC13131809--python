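"""Ground-truth generators for behavioral sessions and model neurons.

Behavior is generated by the combined Bayesian + category-learning model
under the standard task grid (conditions equally likely and randomly
interleaved; displacements drawn from the N(0, 2.5^2) jump and N(0, 0.2^2)
non-jump mixtures given the cued prior; binary reports are Bernoulli draws
from the model output).  Model neurons are inhomogeneous-Poisson spikers
whose high-minus-low-prior rate difference in the reafferent window follows
one of four canonical patterns:

* ``bayesian`` — the prior effect grows with saccade-driven noise and is
  untouched by image noise;
* ``anti_bayesian`` — the effect shrinks with image noise and is untouched
  by the saccade;
* ``prior_only`` — constant across all conditions;
* ``output_mirroring`` — tracks the behavioral prior use per condition.

The modulation begins at the reafferent event and ends by +800 ms.  Every
generator is deterministic given its seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .combined import (
    CombinedParams,
    JUMP_SIGMA_TASK,
    NOJUMP_SIGMA_TASK,
    behavioral_prior_use,
    combined_output,
)
from .bayes import jump_probability
from .neural import DEFAULT_WINDOWS, PATTERN_TEMPLATES, NeuronRecording
from .perceptron import InputGrid, PerceptronNet, encode_input, forward, train_step
from .task import (
    CONDITION_ORDER,
    PROBE_SIGMAS,
    SessionTable,
    standard_condition_grid,
)

__all__ = ["GroundTruth", "SyntheticNeuron", "gen_behavior", "gen_neuron", "gen_cohort", "Cohort"]

#: Median saccadic response latency (ms) used to place the response event.
RESPONSE_MEDIAN_MS = 611.0


@dataclass(frozen=True)
class GroundTruth:
    """Everything needed to regenerate a session and its neuron."""

    combined: CombinedParams = field(default_factory=CombinedParams)
    pattern: str = "anti_bayesian"
    base_rate: float = 20.0  # spikes/s
    modulation_depth: float = 5.0  # spikes/s added on high-prior trials
    displacement_gain: float = 1.5  # spikes/s per degree of |displacement|
    pattern_gains: tuple[float, float, float, float] | None = None
    behav_interactions: tuple[float, float] | None = None  # logit offsets (sacc, image)
    high_noise_sigma: float = 2.0  # probe width of the high image-noise level
    seed: int = 0

    def gains(self) -> np.ndarray:
        """Per-condition prior gain over CONDITION_ORDER (output_mirroring
        is resolved at generation time from the behavioral prior use)."""
        if self.pattern_gains is not None:
            return np.asarray(self.pattern_gains, dtype=float)
        return np.asarray(PATTERN_TEMPLATES[self.pattern], dtype=float)


def _train_net(params: CombinedParams, priors, rng: np.random.Generator) -> PerceptronNet:
    grid = InputGrid()
    net = PerceptronNet(priors=priors, learning_rate=params.learning_rate, grid=grid)
    noise = params.encode_noise("low")
    priors = list(priors)
    for _ in range(params.n_train):
        prior = float(priors[rng.integers(len(priors))])
        jumped = rng.random() < prior
        sigma = JUMP_SIGMA_TASK if jumped else NOJUMP_SIGMA_TASK
        x = float(rng.normal(0.0, sigma))
        train_step(net, encode_input(x, noise, grid), jumped, prior)
    return net


def gen_behavior(
    truth: GroundTruth,
    n_trials: int = 2000,
    seed: int | None = None,
    session_id: str = "s000",
    include_half_prior: bool = True,
) -> SessionTable:
    """One synthetic behavioral session from the ground-truth model.

    Trial types (the standard grid, including the 0.5-prior low-image cells
    unless ``include_half_prior`` is False) are equally likely and randomly
    interleaved.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    grid_specs = standard_condition_grid(truth.high_noise_sigma)
    if not include_half_prior:
        grid_specs = [s for s in grid_specs if s.prior_jump != 0.5]
    priors = sorted({s.prior_jump for s in grid_specs})
    params = truth.combined
    net = _train_net(params, priors, rng)
    igrid = net.grid

    idx = rng.integers(len(grid_specs), size=n_trials)
    rows = []
    for k in idx:
        spec = grid_specs[k]
        cond = spec.noise_condition
        prior = spec.prior_jump
        jumped = rng.random() < prior
        sigma = JUMP_SIGMA_TASK if jumped else NOJUMP_SIGMA_TASK
        x = float(rng.normal(0.0, sigma))
        o_b = jump_probability(abs(x), params.bayes_params(cond, prior))
        o_p = float(
            np.clip(forward(net, encode_input(x, params.encode_noise(cond), igrid), prior)[0], 0.0, 1.0)
        )
        o_c = combined_output(o_b, o_p, params.w_bayes)
        if truth.behav_interactions is not None:
            # extra prior x noise interactions on the logit scale, coded
            # relative to the common cell (saccade=1, image=0) so positive
            # b_sp deepens the saccade effect and negative b_ip the image
            # effect without touching the common condition
            b_sp, b_ip = truth.behav_interactions
            hi = 1.0 if prior == 0.8 else 0.0
            sacc = 1.0 if spec.saccade_present else 0.0
            img = {"low": 0.0, "medium": 1.0, "high": 2.0}[spec.image_noise_level]
            pc = np.clip(o_c, 1e-6, 1 - 1e-6)
            logit = np.log(pc / (1 - pc)) + b_sp * (sacc - 1.0) * hi + b_ip * img * hi
            o_c = 1.0 / (1.0 + np.exp(-logit))
        rows.append(
            {
                "session_id": session_id,
                "prior": prior,
                "saccade": int(spec.saccade_present),
                "image_noise": spec.image_noise_level,
                "probe_sigma": spec.probe_sigma,
                "displacement_deg": x,
                "response": int(rng.random() < o_c),
                "valid": 1,
            }
        )
    return SessionTable(pd.DataFrame(rows), session_id=session_id)


@dataclass
class SyntheticNeuron:
    recording: NeuronRecording
    truth: GroundTruth


def _poisson_spikes(rng, rate_hz: float, t0: float, t1: float) -> np.ndarray:
    dur_s = (t1 - t0) / 1000.0
    n = rng.poisson(max(rate_hz, 0.0) * dur_s)
    return np.sort(rng.uniform(t0, t1, size=n))


def gen_neuron(
    truth: GroundTruth,
    session: SessionTable,
    seed: int | None = None,
    neuron_id: str = "n000",
    alignments: tuple | None = None,
) -> SyntheticNeuron:
    """Poisson model neuron for a behavioral session.

    Base rate everywhere; in the reafferent window [0, 800] ms the rate on
    high-prior trials gains ``modulation_depth`` x the pattern's condition
    gain, and |displacement| adds a monotone rate term (displacement tuning
    of the reafferent response).  Negative programmed rates are clamped at
    zero with a warning.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    df = session.trials[session.trials["prior"].isin([0.2, 0.8])].reset_index(drop=True)
    cond = np.where(df["saccade"].astype(bool), df["image_noise"], "no_saccade")
    gains = truth.gains()
    if truth.pattern == "output_mirroring":
        pu = behavioral_prior_use(session.trials)
        ref = pu.get("low", np.nan)
        if not np.isfinite(ref) or abs(ref) < 1e-6:
            warnings.warn("behavioral prior use degenerate; using template gains")
        else:
            gains = np.array(
                [pu[c] / ref if np.isfinite(pu[c]) else 1.0 for c in CONDITION_ORDER]
            )
    gain_by_cond = dict(zip(CONDITION_ORDER, gains))

    n = len(df)
    high = (df["prior"].to_numpy() == 0.8).astype(float)
    gain_vec = np.array([gain_by_cond[c] for c in cond])
    depth = truth.modulation_depth * gain_vec * high
    depth += truth.displacement_gain * df["displacement_deg"].abs().to_numpy()
    rate_mod = truth.base_rate + depth
    if (rate_mod < 0).any():
        warnings.warn("negative programmed rate clamped at 0")
        rate_mod = np.maximum(rate_mod, 0.0)

    def _segment(rates_hz: np.ndarray, t0: float, t1: float) -> list:
        dur_s = (t1 - t0) / 1000.0
        counts = rng.poisson(rates_hz * dur_s) if dur_s > 0 else np.zeros(n, int)
        times = rng.uniform(t0, t1, size=int(counts.sum()))
        return [np.sort(a) for a in np.split(times, np.cumsum(counts)[:-1])]

    base = np.full(n, truth.base_rate)
    spikes = {}
    windows = {
        ev: w for ev, w in DEFAULT_WINDOWS.items()
        if alignments is None or ev in alignments
    }
    for ev, (t0, t1) in windows.items():
        if ev == "reafferent":
            segs = [_segment(base, t0, 0.0), _segment(rate_mod, 0.0, 800.0),
                    _segment(base, 800.0, t1)]
            spikes[ev] = [np.concatenate([s[i] for s in segs]) for i in range(n)]
        else:
            spikes[ev] = _segment(base, t0, t1)
    rt = RESPONSE_MEDIAN_MS * np.exp(rng.normal(0.0, 0.25, size=n))  # lognormal

    trials = df.copy()
    trials["condition"] = cond
    trials["response_time_ms"] = rt
    rec = NeuronRecording(
        neuron_id=neuron_id,
        trials=trials,
        spikes=spikes,
        session_id=session.session_id,
    )
    return SyntheticNeuron(rec, truth)


@dataclass
class Cohort:
    sessions: list
    neurons: list
    manifest: dict


def gen_cohort(
    truths: list[GroundTruth],
    n_sessions: int,
    seed: int | None = None,
    n_trials: int = 2000,
) -> Cohort:
    """Paired behavioral + neural dataset: one neuron per session, truths
    assigned round-robin.  Child seeds are spawned deterministically from
    ``seed``."""
    if not truths:
        raise ValueError("truth list must be nonempty")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * n_sessions)
    sessions, neurons = [], []
    manifest = {"seed": seed, "n_sessions": n_sessions, "sessions": []}
    for i in range(n_sessions):
        truth = truths[i % len(truths)]
        sid, nid = f"s{i:03d}", f"n{i:03d}"
        beh_seed = int(children[2 * i].generate_state(1)[0] % (2**31))
        neu_seed = int(children[2 * i + 1].generate_state(1)[0] % (2**31))
        table = gen_behavior(truth, n_trials=n_trials, seed=beh_seed, session_id=sid)
        neuron = gen_neuron(truth, table, seed=neu_seed, neuron_id=nid)
        sessions.append(table)
        neurons.append(neuron)
        entry = asdict(truth)
        entry.update(
            {"session_id": sid, "neuron_id": nid,
             "behavior_seed": beh_seed, "neuron_seed": neu_seed}
        )
        manifest["sessions"].append(entry)
    return Cohort(sessions, neurons, manifest)


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
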