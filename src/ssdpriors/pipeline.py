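"""End-to-end orchestration: simulate -> fit -> analyze -> report.

``run_pipeline`` drives a full synthetic study (or pre-existing trial
tables) through the behavioral prior-use summary, the model fit, the
neural effect-size analyses and the mixed-effects regressions, writing
plain tabular text and JSON into the output directory.  All stage seeds
derive deterministically from the global seed and every output carries a
hash of the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import combined, fitting, neural, synth, task

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    """Raised when a stage fails; names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "ssdpriors_run"
    n_sessions: int = 8
    n_trials: int = 1200
    pattern: str = "anti_bayesian"
    base_rate: float = 20.0
    modulation_depth: float = 5.0
    w_bayes: float = 0.1
    high_noise_sigma: float = 2.0
    run_fit: bool = False
    fit_sessions: int = 1
    fit_restarts: int = 4
    stages: tuple = ("simulate", "analyze", "report")

    def validate(self) -> None:
        if self.n_sessions < 2:
            raise ValueError("n_sessions must be >= 2")
        if self.n_trials < 80:
            raise ValueError("n_trials must be >= 80")
        if not 0.0 <= self.w_bayes <= 1.0:
            raise ValueError("w_bayes must lie in [0,1]")
        if self.high_noise_sigma not in task.HIGH_NOISE_SIGMAS:
            raise ValueError(
                f"high_noise_sigma must be one of {task.HIGH_NOISE_SIGMAS}"
            )
        if self.pattern not in neural.PATTERN_TEMPLATES:
            raise ValueError(f"unknown neural pattern {self.pattern!r}")

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    cfg = RunConfig(**raw)
    if isinstance(cfg.stages, list):
        cfg.stages = tuple(cfg.stages)
    return cfg


def _write_json(obj, path: Path, meta: dict) -> None:
    with open(path, "w") as fh:
        json.dump({"meta": meta, "results": obj}, fh, indent=2, sort_keys=True)


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages; returns the report bundle as a dict and
    writes tables/JSON under ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config.config_hash(), "seed": config.seed}
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh)

    bundle: dict = {"meta": meta}
    truth = synth.GroundTruth(
        combined=combined.CombinedParams(w_bayes=config.w_bayes),
        pattern=config.pattern,
        base_rate=config.base_rate,
        modulation_depth=config.modulation_depth,
        high_noise_sigma=config.high_noise_sigma,
        seed=config.seed,
    )

    cohort = None
    if "simulate" in config.stages:
        try:
            cohort = synth.gen_cohort(
                [truth], config.n_sessions, seed=config.seed, n_trials=config.n_trials
            )
            for table in cohort.sessions:
                task.write_trials(table, out / f"trials_{table.session_id}.csv")
            neural.write_spikes(
                [n.recording for n in cohort.neurons], out / "spikes.csv"
            )
            synth.write_manifest(cohort.manifest, out / "manifest.json")
            log.info("simulated %d sessions x %d trials", config.n_sessions, config.n_trials)
        except Exception as exc:
            raise PipelineError("simulate", str(exc)) from exc
    if cohort is None:
        raise PipelineError("analyze", "no data: the simulate stage is required")

    if "analyze" in config.stages:
        try:
            bundle.update(_analyze(cohort, config))
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("analyze", str(exc)) from exc

    if config.run_fit and "analyze" in config.stages:
        try:
            fits = []
            for table in cohort.sessions[: config.fit_sessions]:
                res = fitting.fit_combined(
                    table.trials,
                    n_restarts=config.fit_restarts,
                    seed=config.seed,
                    w_bayes=config.w_bayes,
                )
                fits.append(
                    {
                        "session_id": table.session_id,
                        "nll": res.negative_log_likelihood,
                        "converged": res.converged,
                        "estimates": None
                        if res.estimates is None
                        else res.estimates.to_array().tolist(),
                    }
                )
            bundle["fits"] = fits
        except Exception as exc:
            raise PipelineError("fit", str(exc)) from exc

    if "report" in config.stages:
        try:
            _write_json(
                {k: v for k, v in bundle.items() if k != "meta"},
                out / "report.json",
                meta,
            )
        except Exception as exc:
            raise PipelineError("report", str(exc)) from exc
    return bundle


def _analyze(cohort: synth.Cohort, config: RunConfig) -> dict:
    out: dict = {}
    # behavioral prior use per session and condition (Fig.-2g style table)
    pu_rows = []
    for table in cohort.sessions:
        pu = combined.behavioral_prior_use(table.trials)
        pu_rows.append({"session_id": table.session_id, **pu})
    pu_df = pd.DataFrame(pu_rows).set_index("session_id")
    out["prior_use"] = pu_df.to_dict(orient="index")
    out["prior_use_tests"] = _jsonable(combined.compare_prior_use(pu_df))

    # epoch screen + sliding bins in the common condition
    recs = [n.recording for n in cohort.neurons]
    screen = neural.epoch_prior_screen(recs)
    out["epoch_screen"] = {
        epoch: {
            "n_significant": int(g["significant"].sum()),
            "n_total": int(len(g)),
            "mean_effect": float(g["effect"].mean()),
        }
        for epoch, g in screen.groupby("epoch")
    }
    earliest = {}
    for rec in recs:
        _, e = neural.sliding_bins(rec)
        earliest[rec.neuron_id] = e
    out["earliest_significant_bin"] = earliest

    # per-condition effects, classification, neuron-behavior correlation
    effects_rows = []
    for rec in recs:
        eff = {
            c: neural.wilcoxon_effect(
                *neural._prior_rates(rec, neural.REAFFERENT_EPOCH, c)
            ).effect
            for c in task.CONDITION_ORDER
        }
        profile = (
            pu_df.loc[rec.session_id].to_dict()
            if rec.session_id in pu_df.index
            else None
        )
        effects_rows.append(
            {
                "neuron_id": rec.neuron_id,
                "session_id": rec.session_id,
                **eff,
                "pattern": neural.classify_pattern(eff, mirroring_profile=profile),
            }
        )
    eff_df = pd.DataFrame(effects_rows)
    out["pattern_counts"] = eff_df["pattern"].value_counts().to_dict()

    corr = {}
    for cond in ("no_saccade", "medium", "high"):
        pairs = []
        for _, row in eff_df.iterrows():
            try:
                ne = neural.normalize_to_common(
                    {c: row[c] for c in task.CONDITION_ORDER}, row["low"]
                )
                bu = pu_df.loc[row["session_id"]].to_dict()
                be = neural.normalize_to_common(bu, bu["low"])
            except ValueError:
                continue
            pairs.append((ne[cond], be[cond]))
        if len(pairs) >= 3:
            x, y = zip(*pairs)
            try:
                r, p = neural.neuron_behavior_correlation(x, y)
                corr[cond] = {"r": r, "p": p, "n": len(pairs)}
            except ValueError as exc:
                corr[cond] = {"error": str(exc)}
        else:
            corr[cond] = {"error": f"only {len(pairs)} usable sessions"}
    out["neuron_behavior_correlation"] = corr

    # mixed-effects regressions on the joined trial/rate table
    joined = _join_rates(cohort)
    designs = neural.build_mixed_designs(joined)
    tables = neural.fit_mixed_models(designs)
    out["mixed_models"] = {
        name: tbl.to_dict(orient="records") for name, tbl in tables.items()
    }
    out["aliased_terms"] = list(designs[0].aliased_terms)
    out["counts"] = {
        "sessions": len(cohort.sessions),
        "neurons": len(recs),
        "trials": int(sum(len(t) for t in cohort.sessions)),
    }
    return out


def _join_rates(cohort: synth.Cohort) -> pd.DataFrame:
    frames = []
    for n in cohort.neurons:
        rates = neural.epoch_rate(n.recording, neural.REAFFERENT_EPOCH)
        df = n.recording.trials.iloc[rates.index].copy()
        df["rate"] = rates.to_numpy()
        df["neuron_id"] = n.recording.neuron_id
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return float(obj)
    return obj
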