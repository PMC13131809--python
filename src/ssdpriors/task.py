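"""Task structure for the saccadic suppression of displacement (SSD) paradigm.

A subject fixates, a Gaussian probe appears, an instructed saccade is made
(on most trials), and the probe may be displaced mid-saccade.  The subject
reports "jumped" or "did not jump".  Uncertainty is manipulated two ways:

* saccade-driven noise — the intervening saccade is either required
  ("with saccade") or replaced by steady fixation ("no saccade");
* image noise — the width of the Gaussian probe (low / medium / high).

Image noise varies only on with-saccade trials, so the full grid has four
noise conditions.  The with-saccade, low-image-noise condition is shared by
both manipulations and serves as the *common* reference condition.  Each
trial also carries a cued prior probability of displacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "ConditionSpec",
    "SessionTable",
    "CONDITION_ORDER",
    "PROBE_SIGMAS",
    "standard_condition_grid",
    "filter_sessions",
    "read_trials",
    "write_trials",
]

#: Canonical ordering of the four noise conditions, from lowest combined
#: noise to highest: no-saccade/low-image, then with-saccade at low, medium
#: and high image noise.  "low" is the common condition.
CONDITION_ORDER = ("no_saccade", "low", "medium", "high")

#: Probe standard deviations (degrees of visual angle) per image-noise level.
#: The alternative high-noise width of 1.75 deg was used for one subject.
PROBE_SIGMAS = {"low": 0.5, "medium": 1.25, "high": 2.0}
HIGH_NOISE_SIGMAS = (2.0, 1.75)

STANDARD_PRIORS = (0.2, 0.8)

#: Column schema for behavioral trial tables (CSV with header row).
TRIAL_COLUMNS = [
    "session_id",
    "prior",
    "saccade",
    "image_noise",
    "probe_sigma",
    "displacement_deg",
    "response",
    "valid",
]


@dataclass(frozen=True)
class ConditionSpec:
    """One cell of the prior x noise grid.

    ``prior_jump`` is the cued probability that the probe is displaced,
    ``probe_sigma`` the width of the Gaussian probe in degrees.
    """

    prior_jump: float
    saccade_present: bool
    image_noise_level: str  # "low" | "medium" | "high"
    probe_sigma: float

    def __post_init__(self) -> None:
        if not 0.0 < self.prior_jump < 1.0:
            raise ValueError(f"prior_jump must be in (0,1), got {self.prior_jump}")
        if self.image_noise_level not in PROBE_SIGMAS:
            raise ValueError(f"unknown image noise level {self.image_noise_level!r}")
        if not self.saccade_present and self.image_noise_level != "low":
            raise ValueError("the no-saccade condition exists only at low image noise")
        if self.probe_sigma <= 0:
            raise ValueError("probe_sigma must be positive")

    @property
    def noise_condition(self) -> str:
        """Label among the four noise conditions (see CONDITION_ORDER)."""
        if not self.saccade_present:
            return "no_saccade"
        return self.image_noise_level

    @property
    def is_common(self) -> bool:
        """True for the with-saccade, low-image-noise reference condition."""
        return self.saccade_present and self.image_noise_level == "low"


def standard_condition_grid(high_noise_sigma: float = 2.0) -> list[ConditionSpec]:
    """The standard trial-type grid: four noise conditions at priors 0.2 and
    0.8, plus a 0.5-prior variant of the two low-image-noise conditions
    (used for model fitting).

    Parameters
    ----------
    high_noise_sigma : float
        Probe sigma of the high image-noise condition; 2.0 deg standard,
        1.75 deg alternative.
    """
    if high_noise_sigma not in HIGH_NOISE_SIGMAS:
        raise ValueError(
            f"high_noise_sigma must be one of {HIGH_NOISE_SIGMAS}, got {high_noise_sigma}"
        )
    sigmas = dict(PROBE_SIGMAS, high=high_noise_sigma)
    specs: list[ConditionSpec] = []
    for prior in STANDARD_PRIORS:
        specs.append(ConditionSpec(prior, False, "low", sigmas["low"]))
        for level in ("low", "medium", "high"):
            specs.append(ConditionSpec(prior, True, level, sigmas[level]))
    # 0.5-prior variants of the two low-image-noise conditions
    specs.append(ConditionSpec(0.5, False, "low", sigmas["low"]))
    specs.append(ConditionSpec(0.5, True, "low", sigmas["low"]))
    return specs


def common_condition(grid: Iterable[ConditionSpec]) -> str:
    """Return the unique noise-condition label designated common."""
    labels = {s.noise_condition for s in grid if s.is_common}
    if len(labels) != 1:
        raise ValueError(f"expected exactly one common noise condition, found {labels}")
    return labels.pop()


@dataclass
class SessionTable:
    """Behavioral trials of one recording session.

    ``trials`` follows the TRIAL_COLUMNS schema; ``response`` is 1 when the
    subject reported "jumped".  The ``valid`` flag abstracts the probe-timing
    filter (probe landed before the end of the intervening saccade).
    """

    trials: pd.DataFrame
    session_id: str = field(default="")

    def __post_init__(self) -> None:
        missing = [c for c in TRIAL_COLUMNS if c not in self.trials.columns]
        if missing:
            raise ValueError(f"trial table missing columns: {missing}")
        if not self.session_id:
            ids = self.trials["session_id"].unique()
            self.session_id = str(ids[0]) if len(ids) else ""
        bad = set(self.trials["response"].unique()) - {0, 1}
        if bad:
            raise ValueError(f"response must be binary, found values {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.trials)

    def condition_counts(self, zero_only: bool = False) -> pd.Series:
        """Valid-trial counts per (noise condition, prior) cell."""
        df = self.trials[self.trials["valid"].astype(bool)]
        if zero_only:
            df = df[df["displacement_deg"] == 0.0]
        cond = df.apply(
            lambda r: r["image_noise"] if r["saccade"] else "no_saccade", axis=1
        )
        if df.empty:
            return pd.Series(dtype=int)
        return df.groupby([cond, df["prior"]]).size()

    def is_eligible(
        self, min_per_condition: int = 10, zero_only: bool = False
    ) -> bool:
        """Analysis eligibility: every (condition, prior) cell of the
        standard 0.2/0.8 grid holds at least ``min_per_condition`` valid
        trials (of zero displacement when ``zero_only``)."""
        counts = self.condition_counts(zero_only=zero_only)
        for noise in CONDITION_ORDER:
            for prior in STANDARD_PRIORS:
                if counts.get((noise, prior), 0) < min_per_condition:
                    return False
        return True


def filter_sessions(
    tables: Sequence[SessionTable],
    min_per_condition: int = 10,
    zero_only: bool = False,
) -> list[SessionTable]:
    """Keep sessions with at least ``min_per_condition`` valid trials in
    every standard condition (zero-displacement trials only when
    ``zero_only``).  Empty input yields empty output."""
    if min_per_condition < 1:
        raise ValueError("min_per_condition must be >= 1")
    return [t for t in tables if t.is_eligible(min_per_condition, zero_only)]


def read_trials(path) -> SessionTable:
    df = pd.read_csv(path)
    return SessionTable(df)


def write_trials(table: SessionTable, path) -> None:
    table.trials.to_csv(path, index=False, columns=TRIAL_COLUMNS)
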