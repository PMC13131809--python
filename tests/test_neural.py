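import numpy as np
import pandas as pd
import pytest

from ssdpriors.neural import (
    EpochDefinition,
    FIXATION_EPOCH,
    REAFFERENT_EPOCH,
    NeuronRecording,
    PATTERN_TEMPLATES,
    SilentNeuronError,
    build_mixed_designs,
    classify_pattern,
    condition_effects,
    epoch_prior_screen,
    epoch_rate,
    exact_rank_sum_p,
    neuron_behavior_correlation,
    normalize_to_common,
    read_spikes,
    sliding_bins,
    smooth,
    wilcoxon_effect,
    write_spikes,
    zscore_rates,
)
from ssdpriors.task import CONDITION_ORDER


def _simple_recording(spike_lists, alignment="reafferent", conds=None, priors=None):
    n = len(spike_lists)
    trials = pd.DataFrame(
        {
            "condition": conds if conds is not None else ["low"] * n,
            "prior": priors if priors is not None else [0.8] * n,
            "displacement_deg": np.zeros(n),
            "response": np.zeros(n, dtype=int),
        }
    )
    return NeuronRecording(
        neuron_id="n0",
        trials=trials,
        spikes={alignment: [np.asarray(s, dtype=float) for s in spike_lists]},
    )


class TestZScore:
    def test_pooled_mean_zero_sd_one(self, rng):
        spikes = [np.sort(rng.uniform(-200, 1000, rng.integers(0, 40))) for _ in range(60)]
        rec = _simple_recording(spikes)
        z, centers = zscore_rates(rec)
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.std() == pytest.approx(1.0, abs=1e-9)
        assert len(centers) == 60  # 1200 ms window / 20 ms bins

    def test_silent_neuron_flagged(self):
        rec = _simple_recording([[] for _ in range(10)])
        with pytest.raises(SilentNeuronError):
            zscore_rates(rec)

    def test_matches_two_pass_oracle(self, rng):
        spikes = [np.sort(rng.uniform(-200, 1000, rng.poisson(15))) for _ in range(30)]
        rec = _simple_recording(spikes)
        z, _ = zscore_rates(rec, bin_ms=20)
        edges = np.arange(-200, 1001, 20)
        counts = np.array([np.histogram(s, bins=edges)[0] for s in spikes], float)
        manual = (counts - counts.mean()) / counts.std()
        assert np.allclose(z, manual)


class TestSmooth:
    def test_delta_becomes_unit_area_bump(self):
        series = np.zeros(41)
        series[20] = 1.0
        out = smooth(series)
        assert out.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.argmax(out) == 20

    def test_constant_series_unchanged_interior(self):
        out = smooth(np.ones(50))
        assert np.allclose(out[5:-5], 1.0)

    def test_matches_direct_convolution(self, rng):
        series = rng.normal(size=64)
        sigma_bins = 1.0
        radius = 3
        t = np.arange(-radius, radius + 1)
        k = np.exp(-0.5 * (t / sigma_bins) ** 2)
        k /= k.sum()
        direct = np.convolve(series, k, mode="same")
        assert np.allclose(smooth(series), direct)


class TestEpochRate:
    def test_no_spikes_zero_rate(self):
        rec = _simple_recording([[]])
        assert epoch_rate(rec, REAFFERENT_EPOCH).iloc[0] == 0.0

    def test_rate_arithmetic(self):
        # 8 spikes in the 800 ms window -> 10 spikes/s
        rec = _simple_recording([np.linspace(50, 750, 8)])
        assert epoch_rate(rec, REAFFERENT_EPOCH).iloc[0] == pytest.approx(10.0)

    def test_missing_alignment_trial_skipped(self):
        rec = _simple_recording([[10.0], [20.0]])
        rec.spikes["reafferent"][1] = None
        rates = epoch_rate(rec, REAFFERENT_EPOCH)
        assert list(rates.index) == [0]

    def test_epoch_bounds_validated(self):
        with pytest.raises(ValueError):
            EpochDefinition("reafferent", 100.0, 100.0)

    def test_rate_step_recovered(self, rng):
        # Poisson neuron stepping from 10 to 30 spikes/s at the event
        pre = [np.sort(rng.uniform(-200, 0, rng.poisson(2))) for _ in range(200)]
        post = [np.sort(rng.uniform(0, 800, rng.poisson(24))) for _ in range(200)]
        rec = _simple_recording([np.concatenate([a, b]) for a, b in zip(pre, post)])
        rates = epoch_rate(rec, REAFFERENT_EPOCH)
        assert rates.mean() == pytest.approx(30.0, rel=0.1)


class TestWilcoxonEffect:
    def test_identical_samples_zero(self):
        res = wilcoxon_effect([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert res.effect == 0.0 and res.p_value == 1.0

    def test_sign_convention(self):
        up = wilcoxon_effect([5, 6, 7, 8], [1, 2, 3, 4])
        down = wilcoxon_effect([1, 2, 3, 4], [5, 6, 7, 8])
        assert up.effect > 0 > down.effect
        assert up.effect == pytest.approx(-down.effect)

    def test_effect_bounded_by_extreme_ranks(self, rng):
        n1 = n2 = 6
        extreme = wilcoxon_effect(np.arange(n2, n2 + n1), np.arange(n2))
        for _ in range(20):
            a, b = rng.normal(size=n1), rng.normal(size=n2)
            assert abs(wilcoxon_effect(a, b).effect) <= extreme.effect + 1e-12

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_effect([], [1.0])

    @pytest.mark.parametrize("seed", range(6))
    def test_p_close_to_exact_enumeration(self, seed):
        r = np.random.default_rng(seed)
        high = r.normal(0.8, 1, size=7)
        low = r.normal(0, 1, size=6)
        res = wilcoxon_effect(high, low)
        exact = exact_rank_sum_p(high, low)
        # normal approximation vs exhaustive enumeration at n = 13
        assert res.p_value == pytest.approx(exact, abs=0.08)


class TestScreenAndSlidingBins:
    def test_fifteen_bins(self, anti_bayesian_neuron):
        table, earliest = sliding_bins(anti_bayesian_neuron.recording)
        assert len(table) == 15
        assert table["start_ms"].iloc[0] == 0.0
        assert table["end_ms"].iloc[-1] == 800.0

    def test_modulated_neuron_flagged_in_reafferent_epoch(self, anti_bayesian_neuron):
        screen = epoch_prior_screen([anti_bayesian_neuron.recording])
        by_epoch = screen.set_index("epoch")
        assert bool(by_epoch.loc["reafferent", "significant"])
        assert by_epoch.loc["reafferent", "effect"] > 0
        assert not bool(by_epoch.loc["fixation", "significant"])

    def test_injected_late_modulation_located(self, rng):
        # prior difference only in 200-450 ms: earliest significant bin ~ 4
        n = 160
        priors = [0.8] * (n // 2) + [0.2] * (n // 2)
        spikes = []
        for p in priors:
            base = rng.uniform(-200, 1000, rng.poisson(24))
            extra = rng.uniform(200, 450, rng.poisson(10 if p == 0.8 else 0))
            spikes.append(np.sort(np.concatenate([base, extra])))
        rec = _simple_recording(spikes, priors=priors)
        table, earliest = sliding_bins(rec)
        assert earliest is not None
        assert 2 <= earliest <= 5
        assert not table["significant"][10:].any()


class TestNormalizeAndCorrelate:
    def test_ratio_normalization(self):
        out = normalize_to_common({"a": 0.2, "low": 0.4, "b": 0.8}, 0.4)
        assert out == {"a": 0.5, "low": 1.0, "b": 2.0}

    def test_small_common_excluded(self):
        with pytest.raises(ValueError, match="floor"):
            normalize_to_common({"a": 1.0}, 0.001)

    def test_perfect_correlation(self):
        r, p = neuron_behavior_correlation([1, 2, 3, 4], [1, 2, 3, 4])
        assert r == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            neuron_behavior_correlation([1, 1, 1], [1, 2, 3])

    def test_null_calibration(self, rng):
        hits = 0
        reps = 300
        for _ in range(reps):
            _, p = neuron_behavior_correlation(rng.normal(size=12), rng.normal(size=12))
            hits += p < 0.05
        assert hits / reps == pytest.approx(0.05, abs=0.04)


class TestMixedDesigns:
    def _table(self, rng, n=400):
        conds = rng.choice(CONDITION_ORDER, size=n)
        return pd.DataFrame(
            {
                "session_id": rng.choice(["s1", "s2", "s3"], size=n),
                "neuron_id": "n1",
                "condition": conds,
                "prior": rng.choice([0.2, 0.8], size=n),
                "displacement_deg": rng.normal(0, 2, size=n),
                "response": rng.integers(0, 2, size=n),
                "rate": rng.normal(20, 4, size=n),
            }
        )

    def test_fixed_term_list(self, rng):
        behavioral, neural = build_mixed_designs(self._table(rng))
        assert behavioral.fixed_terms == (
            "prior",
            "saccade",
            "image",
            "displacement",
            "image_x_saccade",
            "image_x_prior",
            "saccade_x_prior",
        )
        assert behavioral.group == "session_id"
        assert neural.group == "neuron_id"

    def test_image_by_saccade_aliased_in_standard_grid(self, rng):
        behavioral, _ = build_mixed_designs(self._table(rng))
        # image noise varies only with a saccade, so this interaction is
        # linearly dependent on the main effects
        assert "image_x_saccade" in behavioral.aliased_terms
        assert behavioral.is_rank_deficient

    def test_single_condition_rank_deficiency_reported(self, rng):
        df = self._table(rng)
        df["condition"] = "low"
        behavioral, _ = build_mixed_designs(df)
        assert len(behavioral.aliased_terms) >= 3

    def test_missing_columns_named(self, rng):
        df = self._table(rng).drop(columns=["response"])
        with pytest.raises(ValueError, match="response"):
            build_mixed_designs(df)


class TestClassifyPattern:
    def test_flat_profile_is_prior_only(self):
        eff = {c: 0.4 for c in CONDITION_ORDER}
        assert classify_pattern(eff) == "prior_only"

    def test_image_noise_reduction_is_anti_bayesian(self):
        eff = dict(zip(CONDITION_ORDER, [0.4, 0.4, 0.22, 0.1]))
        assert classify_pattern(eff) == "anti_bayesian"

    def test_saccade_increase_is_bayesian(self):
        eff = dict(zip(CONDITION_ORDER, [0.1, 0.4, 0.4, 0.4]))
        assert classify_pattern(eff) == "bayesian"

    def test_both_effects_is_output_mirroring(self):
        eff = dict(zip(CONDITION_ORDER, [0.1, 0.4, 0.22, 0.1]))
        assert classify_pattern(eff) == "output_mirroring"

    def test_negative_common_effect_uses_magnitude(self):
        eff = dict(zip(CONDITION_ORDER, [-0.4, -0.4, -0.22, -0.1]))
        assert classify_pattern(eff) == "anti_bayesian"

    def test_tiny_common_effect_unclassified(self):
        eff = dict(zip(CONDITION_ORDER, [0.0, 0.01, 0.0, 0.0]))
        assert classify_pattern(eff) == "unclassified"

    def test_missing_condition_rejected(self):
        with pytest.raises(ValueError):
            classify_pattern({"low": 0.4})

    def test_templates_classify_themselves(self):
        for name, gains in PATTERN_TEMPLATES.items():
            eff = dict(zip(CONDITION_ORDER, 0.4 * np.asarray(gains)))
            assert classify_pattern(eff) == name


def test_spike_table_round_trip(tmp_path, anti_bayesian_neuron):
    rec = anti_bayesian_neuron.recording
    path = tmp_path / "spikes.csv"
    write_spikes([rec], path)
    back = read_spikes(path, {rec.neuron_id: len(rec.trials)})
    for ev, series in rec.spikes.items():
        for a, b in zip(series, back[rec.neuron_id][ev]):
            assert np.allclose(np.sort(a), b)


def test_condition_effects_matches_per_condition_tests(anti_bayesian_neuron):
    rec = anti_bayesian_neuron.recording
    eff = condition_effects(rec)
    assert set(eff) == set(CONDITION_ORDER)
    # anti-Bayesian generator: effect shrinks with image noise
    assert eff["low"].effect > eff["high"].effect
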