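"""Relevance propagation: rules, conditions, rankings, aggregation."""

from __future__ import annotations

import numpy as np
import pytest

from caprivox import nn
from caprivox.explain import (ClassHeatmapSpec, class_average_heatmap, rank_channels,
                              relevance, sample_report, select_central)
from caprivox.network import ArchitectureSpec, Network, build


def _toy_dense(shapes: list[tuple[int, int, bool]], seed: int = 0) -> Network:
    """Zero-bias dense stack; shapes = [(n_in, n_out, relu), ...]."""
    rng = np.random.default_rng(seed)
    layers = []
    for i, (n_in, n_out, relu) in enumerate(shapes):
        d = nn.Dense(n_in, n_out, relu=relu, rng=rng)
        d.b[...] = 0.0
        name = "output" if i == len(shapes) - 1 else f"fc_{i + 1}"
        layers.append((name, d))
    return Network(layers=layers, spec=None)


@pytest.fixture(scope="module")
def conv_net() -> Network:
    net = build(ArchitectureSpec(width_multiplier=0.0625, input_shape=(32, 16, 1)), seed=9)
    net.norm = (0.0, 1.0)
    return net


@pytest.fixture(scope="module")
def conv_input() -> np.ndarray:
    return np.random.default_rng(17).standard_normal((32, 16)).astype(np.float32)


class TestRelevanceRules:
    def test_single_linear_layer_epsilon_oracle(self):
        """R_i = x_i * w_i * y / (y + eps) for y = w.x without bias."""
        net = _toy_dense([(3, 1, False)])
        w = net.layer("output").W[:, 0]
        x = np.array([[1.0, 2.0, -0.5]], dtype=np.float32)
        y = float(x[0] @ w)
        bundle = relevance(net, x, 0)
        expected = x[0] * w * y / (y + 1e-6)
        assert np.allclose(bundle.heatmap, expected, atol=1e-5)

    def test_zero_input_zero_bias_gives_zero_heatmap(self):
        net = _toy_dense([(4, 4, True), (4, 2, False)])
        bundle = relevance(net, np.zeros((1, 4), dtype=np.float32), 0)
        assert np.allclose(bundle.heatmap, 0.0)

    @pytest.mark.parametrize("shapes", [
        [(6, 1, False)],
        [(8, 5, True), (5, 3, False)],
        [(10, 16, True), (16, 8, True), (8, 4, False)],
    ])
    def test_epsilon_conservation_on_zero_bias_nets(self, shapes):
        """Total input relevance equals the target pre-softmax score."""
        net = _toy_dense(shapes, seed=3)
        rng = np.random.default_rng(8)
        x = rng.standard_normal((1, shapes[0][0])).astype(np.float32)
        for target in range(shapes[-1][1]):
            bundle = relevance(net, x, target)
            if abs(bundle.score) < 1e-3:
                continue
            rel_err = abs(bundle.heatmap.sum() - bundle.score) / abs(bundle.score)
            assert rel_err < 1e-4

    def test_relevance_tensors_match_activation_shapes(self, conv_net, conv_input):
        bundle = relevance(conv_net, conv_input, 2)
        for name, layer in conv_net.layers:
            assert bundle.layer_relevance[name].shape == layer.last_output.shape[1:]

    def test_heatmap_matches_input_shape(self, conv_net, conv_input):
        assert relevance(conv_net, conv_input, 0).heatmap.shape == (32, 16)


class TestConditions:
    def test_vacuous_condition_equals_unconditional(self, conv_net, conv_input):
        unc = relevance(conv_net, conv_input, 1).heatmap
        width = conv_net.layer("block_2/conv_1").n_channels
        cond = relevance(conv_net, conv_input, 1,
                         {"block_2/conv_1": tuple(range(width))}).heatmap
        assert np.allclose(cond, unc, atol=1e-9)

    @pytest.mark.parametrize("layer", ["block_1/conv_2", "fc_2", "output"])
    def test_singleton_decomposition(self, conv_net, conv_input, layer):
        """Singleton-channel conditional heatmaps sum to the unconditional one."""
        unc = relevance(conv_net, conv_input, 4).heatmap
        width = conv_net.layer(layer).n_channels
        acc = np.zeros_like(unc)
        for c in range(width):
            acc += relevance(conv_net, conv_input, 4, {layer: (c,)}).heatmap
        scale = np.abs(unc).max() + 1e-12
        assert np.abs(acc - unc).max() / scale < 1e-6

    def test_unknown_layer_rejected(self, conv_net, conv_input):
        with pytest.raises(ValueError, match="unknown layer"):
            relevance(conv_net, conv_input, 0, {"block_9/conv_1": (0,)})

    def test_out_of_range_channel_rejected(self, conv_net, conv_input):
        with pytest.raises(ValueError, match="out of range"):
            relevance(conv_net, conv_input, 0, {"output": (99,)})

    def test_channelless_layer_rejected(self, conv_net, conv_input):
        with pytest.raises(ValueError, match="channel axis"):
            relevance(conv_net, conv_input, 0, {"pool_1": (0,)})


class TestRankChannels:
    def test_concentrated_relevance_ranks_first(self):
        # second hidden unit is the only path to the target output
        net = _toy_dense([(4, 3, True), (3, 2, False)], seed=1)
        d2 = net.layer("output")
        d2.W[...] = 0.0
        d2.W[1, 0] = 1.0
        x = np.abs(np.random.default_rng(2).standard_normal((1, 4))).astype(np.float32)
        ranking = rank_channels(net, x, 0, "fc_1")
        assert ranking.channels[0] == 1

    def test_scores_sum_to_layer_total(self, conv_net, conv_input):
        ranking = rank_channels(conv_net, conv_input, 3, "block_3/conv_2")
        total = relevance(conv_net, conv_input, 3).layer_relevance["block_3/conv_2"].sum()
        assert sum(ranking.scores) == pytest.approx(float(total), abs=1e-6 * max(1, abs(total)))

    def test_scores_sorted_descending_ties_by_index(self, conv_net, conv_input):
        ranking = rank_channels(conv_net, conv_input, 3, "block_2/conv_2")
        scores = ranking.scores
        assert all(a >= b for a, b in zip(scores, scores[1:]))
        for (c1, s1), (c2, s2) in zip(ranking.ranking, ranking.ranking[1:]):
            if s1 == s2:
                assert c1 < c2

    def test_channel_permutation_equivariance(self):
        """Consistently permuting a layer's channels permutes its ranking."""
        net = _toy_dense([(5, 4, True), (4, 3, False)], seed=5)
        x = np.random.default_rng(6).standard_normal((1, 5)).astype(np.float32)
        base = rank_channels(net, x, 1, "fc_1")
        perm = np.array([2, 0, 3, 1])
        net2 = _toy_dense([(5, 4, True), (4, 3, False)], seed=5)
        net2.layer("fc_1").W[...] = net.layer("fc_1").W[:, perm]
        net2.layer("output").W[...] = net.layer("output").W[perm, :]
        permuted = rank_channels(net2, x, 1, "fc_1")
        inv = np.argsort(perm)
        base_scores = dict(base.ranking)
        perm_scores = dict(permuted.ranking)
        for c, s in base_scores.items():
            assert perm_scores[int(inv[c])] == pytest.approx(s, abs=1e-6)
        # ordering agrees wherever scores are strictly distinct (ties break by index)
        distinct = [c for c, s in base.ranking if sum(
            abs(s - s2) < 1e-9 for s2 in base.scores) == 1]
        base_pos = {c: i for i, (c, _) in enumerate(base.ranking)}
        perm_pos = {c: i for i, (c, _) in enumerate(permuted.ranking)}
        for c in distinct:
            assert perm_pos[int(inv[c])] == base_pos[c]


class TestSampleReport:
    def test_top_k_count_and_order(self, conv_net, conv_input):
        rep = sample_report(conv_net, conv_input, 2, ["block_4/conv_1"], k=6)
        entries = rep["block_4/conv_1"]
        assert len(entries) == 6
        scores = [s for _, s, _ in entries]
        assert all(a >= b for a, b in zip(scores, scores[1:]))

    def test_full_width_report_decomposes(self, conv_net, conv_input):
        layer = "block_4/conv_2"
        width = conv_net.layer(layer).n_channels
        rep = sample_report(conv_net, conv_input, 2, [layer], k=width)
        acc = sum(h for _, _, h in rep[layer])
        unc = relevance(conv_net, conv_input, 2).heatmap
        assert np.abs(acc - unc).max() / (np.abs(unc).max() + 1e-12) < 1e-6

    def test_k_zero_empty(self, conv_net, conv_input):
        rep = sample_report(conv_net, conv_input, 0, ["fc_1"], k=0)
        assert rep["fc_1"] == []

    def test_k_exceeding_width_rejected(self, conv_net, conv_input):
        with pytest.raises(ValueError, match="exceeds width"):
            sample_report(conv_net, conv_input, 0, ["output"], k=9)


class TestSelectCentral:
    def test_whole_class_when_n_equals_size(self):
        specs = [np.full((4, 4), v) for v in (0.0, 1.0, 2.0)]
        assert sorted(select_central(specs, 3)) == [0, 1, 2]

    def test_outlier_excluded(self):
        specs = [np.zeros((4, 4)), np.full((4, 4), 0.1), np.full((4, 4), 10.0)]
        assert sorted(select_central(specs, 2)) == [0, 1]

    def test_brute_force_agreement(self):
        rng = np.random.default_rng(12)
        specs = [rng.standard_normal((8, 8)) for _ in range(30)]
        X = np.stack(specs).reshape(30, -1)
        d = np.linalg.norm(X - X.mean(axis=0), axis=1)
        expected = list(np.argsort(d, kind="stable")[:10])
        assert select_central(specs, 10) == expected

    def test_invariant_under_duplicating_non_selected(self):
        rng = np.random.default_rng(13)
        specs = [rng.standard_normal((4, 4)) for _ in range(6)]
        chosen = select_central(specs, 2)
        far = max(range(6), key=lambda i: np.linalg.norm(
            specs[i] - np.mean(specs, axis=0)))
        assert far not in chosen

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="cannot select"):
            select_central([np.zeros((2, 2))], 5)


class TestClassAverage:
    def test_m_bar_formula(self):
        spec = ClassHeatmapSpec(dictionary_size=8, n_spectrograms=100, g_channels=20)
        assert spec.m_bar == 16000

    def test_single_sample_single_channel(self, conv_net, conv_input):
        rep = sample_report(conv_net, conv_input, 0, ["fc_1"], k=1)
        _, _, expected = rep["fc_1"][0]
        hm = class_average_heatmap(conv_net, [conv_input], "heat", 0, ["fc_1"],
                                   ClassHeatmapSpec(8, 1, 1))
        assert np.allclose(hm.heatmap, expected)
        assert hm.n_contributors == 1

    def test_identical_samples_idempotent(self, conv_net, conv_input):
        hm1 = class_average_heatmap(conv_net, [conv_input], "heat", 0, ["fc_1"],
                                    ClassHeatmapSpec(8, 1, 2))
        hm2 = class_average_heatmap(conv_net, [conv_input, conv_input.copy()], "heat",
                                    0, ["fc_1"], ClassHeatmapSpec(8, 2, 2))
        assert np.allclose(hm1.heatmap, hm2.heatmap, atol=1e-7)

    def test_contributor_count(self, conv_net):
        rng = np.random.default_rng(20)
        samples = [rng.standard_normal((32, 16)).astype(np.float32) for _ in range(4)]
        layers = ["block_3/conv_1", "block_4/conv_2", "fc_1"]
        hm = class_average_heatmap(conv_net, samples, "feed", 1, layers,
                                   ClassHeatmapSpec(8, 4, 2))
        assert hm.n_contributors == 4 * 2 * 3
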