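import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ssdpriors.perceptron import (
    InputGrid,
    PerceptronNet,
    encode_input,
    forward,
    train,
    train_step,
)


class TestInputGrid:
    def test_default_grid_has_75_units(self):
        grid = InputGrid()
        assert grid.n_units == 75
        assert grid.centers[0] == pytest.approx(0.05)
        assert grid.centers[-1] == pytest.approx(7.45)

    def test_non_tiling_range_rejected(self):
        with pytest.raises(ValueError):
            InputGrid(bin_width=0.1, lo=0.0, hi=7.44)


class TestEncodeInput:
    def test_zero_noise_is_one_hot(self):
        a = encode_input(1.0, 0.0)
        assert a.sum() == 1.0
        assert np.count_nonzero(a) == 1
        assert a[InputGrid().bin_index(1.0)] == 1.0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.floats(-10.0, 10.0), st.floats(0.0, 3.0))
    def test_activation_always_sums_to_one(self, x, sigma):
        a = encode_input(x, sigma)
        assert a.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(a >= 0)

    def test_activation_at_zero_decreases_with_distance(self):
        # truncated Gaussian centered at the range edge: brute-force oracle
        grid = InputGrid()
        a = encode_input(0.0, 1.0, grid)
        assert np.all(np.diff(a) <= 0)
        dens = np.exp(-0.5 * (grid.centers - 0.0) ** 2)
        assert np.allclose(a, dens / dens.sum())

    def test_out_of_range_displacement_clamped(self):
        a = encode_input(12.0, 0.5)
        assert np.argmax(a) == 74  # mass piles at the upper edge

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            encode_input(1.0, -0.1)

    def test_sign_ignored(self):
        assert np.allclose(encode_input(-1.3, 0.7), encode_input(1.3, 0.7))


class TestForward:
    def test_equal_weights_give_half(self):
        net = PerceptronNet(priors=(0.2, 0.8), init_weight=0.37)
        a = encode_input(1.0, 0.5)
        assert forward(net, a, 0.2) == pytest.approx((0.5, 0.5))

    def test_one_hot_reduces_to_weight_ratio(self, rng):
        net = PerceptronNet(priors=(0.2,))
        net.weights[0.2] = rng.uniform(0.1, 1.0, size=(75, 2))
        a = encode_input(3.0, 0.0)
        i = int(np.argmax(a))
        w = net.weights[0.2][i]
        assert forward(net, a, 0.2) == pytest.approx(tuple(w / w.sum()))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_outputs_sum_to_one(self, seed):
        r = np.random.default_rng(seed)
        net = PerceptronNet(priors=(0.5,))
        net.weights[0.5] = r.uniform(0.0, 2.0, size=(75, 2)) + 1e-6
        a = encode_input(r.uniform(0, 7.5), r.uniform(0.05, 2.0))
        o = forward(net, a, 0.5)
        assert o[0] + o[1] == pytest.approx(1.0, abs=1e-12)
        assert 0.0 <= o[0] <= 1.0

    def test_unknown_prior_rejected(self):
        net = PerceptronNet(priors=(0.2,))
        with pytest.raises(KeyError):
            forward(net, encode_input(1.0, 0.5), 0.8)

    def test_zero_weights_degenerate(self):
        net = PerceptronNet(priors=(0.2,), init_weight=0.0)
        with pytest.raises(ZeroDivisionError):
            forward(net, encode_input(1.0, 0.5), 0.2)


class TestTrainStep:
    def test_hand_computed_update(self):
        # one-hot input, output (0.5, 0.5), jump label, beta=0.5:
        # delta w = 0.5 * 1 * (d - o) = (+0.25, -0.25)
        net = PerceptronNet(priors=(0.2,), learning_rate=0.5)
        a = encode_input(1.0, 0.0)
        i = int(np.argmax(a))
        before = net.weights[0.2].copy()
        train_step(net, a, jumped=True, prior=0.2)
        delta = net.weights[0.2] - before
        assert delta[i] == pytest.approx((0.25, -0.25))
        delta[i] = 0
        assert np.all(delta == 0)

    def test_correct_output_no_change(self):
        net = PerceptronNet(priors=(0.2,))
        net.weights[0.2][:, 0] = 1.0
        net.weights[0.2][:, 1] = 0.0
        before = net.weights[0.2].copy()
        train_step(net, encode_input(2.0, 0.3), jumped=True, prior=0.2)
        assert np.allclose(net.weights[0.2], before)

    def test_zero_learning_rate_no_change(self):
        net = PerceptronNet(priors=(0.2,), learning_rate=0.0)
        before = net.weights[0.2].copy()
        train_step(net, encode_input(2.0, 0.3), jumped=False, prior=0.2)
        assert np.allclose(net.weights[0.2], before)

    def test_other_priors_untouched(self, rng):
        net = PerceptronNet(priors=(0.2, 0.8))
        before = net.weights[0.8].copy()
        for _ in range(20):
            train_step(net, encode_input(rng.uniform(0, 5), 0.3), True, 0.2)
        assert np.array_equal(net.weights[0.8], before)


class TestTrain:
    def _trials(self, rng, n, priors=(0.2, 0.8)):
        out = []
        for _ in range(n):
            prior = float(rng.choice(priors))
            jumped = rng.random() < prior
            x = rng.normal(0, 2.5 if jumped else 0.2)
            out.append((x, jumped, prior))
        return out

    def test_output_increases_with_displacement(self):
        # averaged over training realizations the jump output rises through
        # the densely-trained small-displacement range and stays high for
        # clear jumps (sparsely visited bins keep rough per-seed profiles)
        xs = (0.1, 0.4, 0.8, 1.5, 3.0)
        acc = {0.2: np.zeros(len(xs)), 0.8: np.zeros(len(xs))}
        n_seeds = 8
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            net = PerceptronNet(priors=(0.2, 0.8), learning_rate=0.5)
            train(net, self._trials(r, 1000), noise_sigma=0.1)
            for prior in acc:
                acc[prior] += [forward(net, encode_input(x, 0.1), prior)[0] for x in xs]
        for prior, tot in acc.items():
            mean = tot / n_seeds
            assert mean[0] < mean[1] < mean[2]
            assert np.all(mean[2:] > 0.5)
            assert mean[-1] > mean[0]

    def test_all_jump_training_saturates(self):
        net = PerceptronNet(priors=(0.5,), learning_rate=0.5)
        train(net, [(1.5, True, 0.5)] * 300, noise_sigma=0.0)
        assert forward(net, encode_input(1.5, 0.0), 0.5)[0] > 0.99

    def test_training_reduces_classification_error(self, rng):
        net = PerceptronNet(priors=(0.5,), learning_rate=0.5)
        trials = self._trials(rng, 800, priors=(0.5,))

        def error(n):
            wrong = 0
            for x, jumped, prior in trials:
                o = forward(n, encode_input(x, 0.0), prior)[0]
                wrong += (o > 0.5) != jumped
            return wrong / len(trials)

        before = error(net)
        train(net, trials, noise_sigma=0.0)
        assert error(net) < before

    def test_empty_stream_rejected(self):
        net = PerceptronNet(priors=(0.5,))
        with pytest.raises(ValueError):
            train(net, [], noise_sigma=0.1)

    def test_image_noise_collapses_prior_difference(self):
        # identical low-noise training; rising test-time encoding noise
        # shrinks the learned output gap between priors at matched small
        # displacements (weighted by the task displacement density, where
        # the learned category boundary lives), averaged over realizations
        from scipy import stats as sps

        xs = np.linspace(0, 2, 41)
        w = 0.5 * sps.norm.pdf(xs, 0, 2.5) + 0.5 * sps.norm.pdf(xs, 0, 0.2)
        gaps = {0.1: [], 1.0: [], 2.0: []}
        for seed in range(8):
            r = np.random.default_rng(seed)
            net = PerceptronNet(priors=(0.2, 0.8), learning_rate=0.5)
            train(net, self._trials(r, 1000), noise_sigma=0.1)
            for sigma in gaps:
                diff = np.array(
                    [
                        forward(net, encode_input(x, sigma), 0.8)[0]
                        - forward(net, encode_input(x, sigma), 0.2)[0]
                        for x in xs
                    ]
                )
                gaps[sigma].append(float(np.sum(w * diff) / w.sum()))
        means = [np.mean(gaps[s]) for s in (0.1, 1.0, 2.0)]
        assert means[0] > means[1] > means[2]


def test_weight_json_round_trip():
    net = PerceptronNet(priors=(0.2, 0.8))
    net.weights[0.2][10, 0] = 1.25
    blob = net.to_json()
    other = PerceptronNet(priors=(0.2, 0.8))
    other.load_json(blob)
    for p in (0.2, 0.8):
        assert np.array_equal(other.weights[p], net.weights[p])
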