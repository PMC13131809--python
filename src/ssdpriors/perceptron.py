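"""Two-layer perceptron-like category-learning network.

Displacement magnitudes are encoded by a bank of 75 input units tiling
0-7.5 deg in 0.1-deg bins.  Sensory noise spreads the input activation as a
Gaussian over bin centers, truncated to the grid and renormalized so total
input activation is always 1.  Each cued prior has its own input bank and
weight matrix to two output units ("jump", "no jump"); outputs are the
weighted input sums normalized to sum to 1, and learning is the error-based
rule  delta_w_ij = beta * a_i * (d - o_j)  with desired outputs d = (1,0)
on jump trials and (0,1) otherwise.

Under identical low-noise training per prior, the two banks learn different
displacement-to-category associations (the high-prior bank reports "jump"
more readily at small displacements).  Test-time input noise blurs activation
across bins, collapsing that learned difference — the mechanism behind the
anti-Bayesian decrease of prior use with image noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "InputGrid",
    "PerceptronNet",
    "encode_input",
    "forward",
    "train_step",
    "train",
]


@dataclass(frozen=True)
class InputGrid:
    """Input-unit grid: bins of ``bin_width`` deg tiling [lo, hi]."""

    bin_width: float = 0.1
    lo: float = 0.0
    hi: float = 7.5

    def __post_init__(self) -> None:
        n = (self.hi - self.lo) / self.bin_width
        if abs(n - round(n)) > 1e-9:
            raise ValueError("grid range must be an integer number of bins")

    @property
    def n_units(self) -> int:
        return int(round((self.hi - self.lo) / self.bin_width))

    @property
    def centers(self) -> np.ndarray:
        return self.lo + (np.arange(self.n_units) + 0.5) * self.bin_width

    def bin_index(self, x: float) -> int:
        """Index of the bin containing |x| (clamped to the grid)."""
        x = min(max(abs(x), self.lo), self.hi)
        return min(int((x - self.lo) / self.bin_width), self.n_units - 1)


def encode_input(x: float, noise_sigma: float, grid: InputGrid | None = None) -> np.ndarray:
    """Population activation for displacement x at the given sensory noise.

    A Gaussian density centered on |x| (clamped to the grid range) is
    evaluated at bin centers, truncated to the grid and renormalized to sum
    to 1.  Zero noise yields a one-hot at the bin containing |x|.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be nonnegative")
    grid = grid or InputGrid()
    mu = min(max(abs(float(x)), grid.lo), grid.hi)
    a = np.zeros(grid.n_units)
    if noise_sigma == 0.0:
        a[grid.bin_index(mu)] = 1.0
        return a
    z = (grid.centers - mu) / noise_sigma
    a = np.exp(-0.5 * z * z)
    s = a.sum()
    if s == 0.0:  # width far below the bin scale: underflow, one-hot limit
        a[grid.bin_index(mu)] = 1.0
        return a
    return a / s


@dataclass
class PerceptronNet:
    """Prior-indexed weight banks (n_units x 2; columns = jump, no-jump)."""

    priors: Sequence[float]
    learning_rate: float = 0.5
    grid: InputGrid = field(default_factory=InputGrid)
    init_weight: float = 0.5
    weights: dict = field(init=False)

    def __post_init__(self) -> None:
        self.weights = {
            float(p): np.full((self.grid.n_units, 2), self.init_weight)
            for p in self.priors
        }

    def to_json(self) -> str:
        return json.dumps(
            {str(p): w.tolist() for p, w in self.weights.items()}
        )

    def load_json(self, s: str) -> None:
        for p, rows in json.loads(s).items():
            self.weights[float(p)] = np.asarray(rows, dtype=float)


def forward(net: PerceptronNet, act: np.ndarray, prior: float) -> tuple[float, float]:
    """Normalized (o_jump, o_nojump) for one input activation pattern."""
    w = net.weights.get(float(prior))
    if w is None:
        raise KeyError(f"no weight bank for prior {prior}")
    a = act @ w
    s = a[0] + a[1]
    if s == 0:
        raise ZeroDivisionError(
            "degenerate weights: output activations sum to zero"
        )
    return a[0] / s, a[1] / s


def train_step(net: PerceptronNet, act: np.ndarray, jumped: bool, prior: float) -> PerceptronNet:
    """One error-based update of the given prior's weight bank (in place)."""
    o = np.array(forward(net, act, prior))
    d = np.array([1.0, 0.0]) if jumped else np.array([0.0, 1.0])
    net.weights[float(prior)] += net.learning_rate * np.outer(act, d - o)
    return net


def train(
    net: PerceptronNet,
    trials: Iterable[tuple[float, bool, float]],
    noise_sigma: float | Mapping[float, float],
    seed: int | None = None,
) -> PerceptronNet:
    """Sequentially encode and learn a stream of (x, jumped, prior) trials.

    ``noise_sigma`` may be a scalar or a mapping prior -> sigma.  The input
    encoding is deterministic, so the result depends only on the trial
    stream; ``seed`` is accepted for interface uniformity and unused.
    """
    trials = list(trials)
    if not trials:
        raise ValueError("training stream must be nonempty")
    for x, jumped, prior in trials:
        sigma = noise_sigma[prior] if isinstance(noise_sigma, Mapping) else noise_sigma
        act = encode_input(x, sigma, net.grid)
        train_step(net, act, bool(jumped), prior)
    return net
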