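"""Relevance propagation: worked examples, conservation, oracle equivalence."""

import numpy as np
import pytest

from prefog import synthetic as sg
from prefog.lrp import (
    GroupAttribution,
    ZeroDenominatorError,
    aggregate_group_relevance,
    conservation_report,
    layer_relevance_linear,
    layer_relevance_pool,
    lrp_epsilon,
    relevance_to_frame,
)
from prefog.model import Hyperparameters, build_cnn
from prefog.nn import Dense, GlobalAvgPool, Network, ReLU, Softmax

from _oracles import conv_as_dense, eps_lrp_dense_oracle, gap_as_dense


class TestLinearRule:
    def test_proportional_split_of_equal_contributions(self):
        R, absorbed = layer_relevance_linear([2.0, 1.0], [[0.5], [1.0]], [0.0],
                                             [2.0], eps=0.0)
        assert np.allclose(R, [1.0, 1.0])
        assert absorbed == 0.0

    def test_epsilon_absorbs_relevance(self):
        R, absorbed = layer_relevance_linear([2.0, 1.0], [[0.5], [1.0]], [0.0],
                                             [2.0], eps=0.2)
        assert np.allclose(R, [10.0 / 11.0, 10.0 / 11.0])
        leak = (2.0 - R.sum() - absorbed) / 2.0
        assert leak == pytest.approx(0.182 / 2.0, abs=1e-3)

    def test_negative_denominator_sign(self):
        R, _ = layer_relevance_linear([1.0], [[-1.0]], [0.0], [1.0], eps=0.5)
        assert np.allclose(R, [2.0 / 3.0])

    def test_zero_denominator_at_zero_eps_rejected(self):
        with pytest.raises(ZeroDenominatorError):
            layer_relevance_linear([1.0, -1.0], [[1.0], [1.0]], [0.0], [1.0], eps=0.0)

    def test_bias_share_reported(self):
        R, absorbed = layer_relevance_linear([1.0], [[1.0]], [1.0], [2.0], eps=0.0)
        # z = 1, denominator = 2: input gets half, bias absorbs half
        assert np.allclose(R, [1.0])
        assert absorbed == pytest.approx(1.0)


class TestPoolRules:
    def test_max_pool_winner_take_all(self):
        windows = np.array([3.0, 1.0]).reshape(1, 2, 1)
        R = layer_relevance_pool("max", windows, np.array([[2.0]]), 0.0)
        assert np.allclose(R.ravel(), [2.0, 0.0])

    def test_max_pool_tie_split_equally(self):
        windows = np.array([4.0, 4.0]).reshape(1, 2, 1)
        R = layer_relevance_pool("max", windows, np.array([[2.0]]), 0.0)
        assert np.allclose(R.ravel(), [1.0, 1.0])

    def test_gap_uniform_split(self):
        R = layer_relevance_pool("gap", np.full((5, 1), 2.0), np.array([3.0]), 0.0)
        assert np.allclose(R.ravel(), 0.6)


def _bias_free_cnn(h=None, seed=0):
    net = build_cnn(h or Hyperparameters(n_blocks=2, filters=4, kernel=5,
                                         dropout=0.0, seed=seed))
    for layer in net.parametric_layers():
        layer.b[:] = 0.0
    return net


class TestLrpEpsilon:
    def test_conservation_bias_free(self):
        net = _bias_free_cnn()
        x = np.random.default_rng(0).uniform(-1, 1, (101, 3))
        m = lrp_epsilon(net, x, "pre-FOG", eps=0.0)
        rep = conservation_report(m)
        assert rep["conserved"] and rep["relative_gap"] < 1e-4

    def test_relevance_starts_at_logit(self):
        net = _bias_free_cnn()
        x = np.random.default_rng(1).uniform(-1, 1, (101, 3))
        m = lrp_epsilon(net, x, "FGC", eps=0.0)
        assert m.start_value == pytest.approx(float(net.logits(x[None])[0, 0]))

    def test_single_linear_layer_is_input_times_weight(self):
        rng = np.random.default_rng(2)
        net = Network([Dense(6, 2, rng), Softmax()])
        net.layers[0].b = np.zeros(2)
        x = rng.normal(size=6)
        m = lrp_epsilon(net, x.reshape(1, 6), "pre-FOG", eps=0.0)
        assert np.allclose(m.relevance.ravel(), x * net.layers[0].W[:, 1])

    def test_zero_input_degenerate(self):
        # all-zero input of a bias-free net: zero start value, exactly zero map
        net = _bias_free_cnn()
        for eps in (0.0, 1e-4):
            m = lrp_epsilon(net, np.zeros((101, 3)), "pre-FOG", eps=eps)
            assert np.abs(m.relevance).max() < 1e-12
            assert m.start_value == 0.0
        # a zero denominator that would swallow nonzero relevance is rejected
        with pytest.raises(ZeroDenominatorError):
            layer_relevance_linear([1.0, -1.0], [[1.0], [1.0]], [0.0], [1.0], eps=0.0)

    def test_unknown_target_rejected(self):
        with pytest.raises(ValueError):
            lrp_epsilon(_bias_free_cnn(), np.ones((101, 3)), "walking")

    def test_scale_covariance_of_final_dense(self):
        x = np.random.default_rng(3).uniform(-1, 1, (101, 3))
        base = lrp_epsilon(_bias_free_cnn(seed=5), x, "pre-FOG", 0.0)
        scaled_net = _bias_free_cnn(seed=5)
        dense = [l for l in scaled_net.layers if isinstance(l, Dense)][0]
        dense.W *= 3.0
        scaled = lrp_epsilon(scaled_net, x, "pre-FOG", 0.0)
        assert np.allclose(scaled.relevance, 3.0 * base.relevance, atol=1e-10)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(20))
    def test_matches_literal_rule_on_random_dense_nets(self, seed):
        rng = np.random.default_rng(seed)
        hidden = [int(rng.integers(2, 10)) for _ in range(int(rng.integers(0, 2)))]
        dims = [int(rng.integers(2, 10))] + hidden + [2]  # <= 3 dense layers
        layers, wb = [], []
        for i in range(len(dims) - 1):
            d = Dense(dims[i], dims[i + 1], rng)
            layers.append(d)
            if i < len(dims) - 2:
                layers.append(ReLU())
            wb.append((d.W, d.b))
        layers.append(Softmax())
        net = Network(layers)
        x = rng.normal(size=dims[0])
        eps = float(rng.uniform(0.0, 0.3)) + 1e-3
        m = lrp_epsilon(net, x.reshape(1, -1), "pre-FOG", eps)
        expect = eps_lrp_dense_oracle(wb, x, 1, eps)
        assert np.abs(m.relevance.ravel() - expect).max() < 1e-8

    def test_matches_unrolled_convolution(self):
        """Weight-shared conv relevance equals the rule on the unrolled matrix."""
        h = Hyperparameters(n_blocks=1, filters=3, kernel=5, pool_width=1,
                            dropout=0.0, seed=9)
        net = build_cnn(h)
        conv = net.layers[0]
        dense = [l for l in net.layers if isinstance(l, Dense)][0]
        rng = np.random.default_rng(4)
        x = rng.uniform(-1, 1, (101, 3))
        eps = 0.05
        m = lrp_epsilon(net, x, "pre-FOG", eps)
        # oracle: conv and GAP unrolled to explicit matrices, ReLU between
        Wc, bc = conv_as_dense(conv.W, conv.b, 101, conv.pad)
        Wg, bg = gap_as_dense(101, h.filters)
        wb = [(Wc, bc), (Wg, bg), (dense.W, dense.b)]
        expect = eps_lrp_dense_oracle(wb, x.ravel(), 1, eps)
        assert np.abs(m.relevance.ravel() - expect).max() < 1e-8


class TestConservationReport:
    def test_epsilon_leakage_of_worked_example(self):
        from prefog.lrp import RelevanceMap

        R, absorbed = layer_relevance_linear([2.0, 1.0], [[0.5], [1.0]], [0.0],
                                             [2.0], eps=0.2)
        m = RelevanceMap(relevance=R.reshape(1, 2), target_class="pre-FOG",
                         start_value=2.0, bias_absorbed=absorbed)
        rep = conservation_report(m)
        assert rep["leakage"] == pytest.approx(0.091, abs=1e-3)

    def test_zero_start_flagged_undefined(self):
        from prefog.lrp import RelevanceMap

        m = RelevanceMap(relevance=np.zeros((1, 2)), target_class="pre-FOG",
                         start_value=0.0, bias_absorbed=0.0)
        assert conservation_report(m)["undefined"]


class TestGroupAttribution:
    def _maps(self, trained, cycles, n=6):
        sel = cycles[:n]
        maps = [trained.relevance(c, "pre-FOG", 1e-4) for c in sel]
        return maps, sel

    def test_single_cycle_group(self, trained_small, small_matched):
        _, eval_cycles, _ = small_matched
        maps, sel = self._maps(trained_small, eval_cycles, n=1)
        g = aggregate_group_relevance(maps, sel, name="one")
        assert np.allclose(g.mean_trajectory, sel[0].values)
        assert np.allclose(g.sd_trajectory, 0.0)
        assert np.allclose(g.mean_relevance, maps[0].relevance)

    def test_identical_maps_mean_is_either(self, trained_small, small_matched):
        _, eval_cycles, _ = small_matched
        maps, sel = self._maps(trained_small, eval_cycles, n=1)
        g = aggregate_group_relevance(maps * 2, sel * 2, name="two")
        assert np.allclose(g.mean_relevance, maps[0].relevance)

    def test_per_subject_equal_contribution(self, trained_small, small_matched):
        _, eval_cycles, _ = small_matched
        prefog = [c for c in eval_cycles if c.label == "pre-FOG"]
        maps = [trained_small.relevance(c, "pre-FOG", 1e-4) for c in prefog]
        g = aggregate_group_relevance(maps, prefog, name="grp", per_subject=2, seed=0)
        n_subjects = len({c.subject_id for c in prefog})
        assert g.n_cycles <= 2 * n_subjects

    def test_mixed_target_classes_rejected(self, trained_small, small_matched):
        _, eval_cycles, _ = small_matched
        a = trained_small.relevance(eval_cycles[0], "pre-FOG", 1e-4)
        b = trained_small.relevance(eval_cycles[1], "FGC", 1e-4)
        with pytest.raises(ValueError):
            aggregate_group_relevance([a, b], eval_cycles[:2])

    def test_unmatched_cycles_rejected(self, trained_small, small_matched):
        matched, _, _ = small_matched
        assert matched.unmatched_fgc_ids
        c = matched.cycle(matched.unmatched_fgc_ids[0])
        m = trained_small.relevance(c, "pre-FOG", 1e-4)
        with pytest.raises(ValueError, match="unmatched"):
            aggregate_group_relevance([m], [c])

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            aggregate_group_relevance([], [])

    def test_long_format_export(self, trained_small, small_matched):
        _, eval_cycles, _ = small_matched
        maps, sel = self._maps(trained_small, eval_cycles, n=3)
        for m, c in zip(maps, sel):
            m.cycle_id = c.cycle_id
        frame = relevance_to_frame(maps, sel)
        assert set(frame.columns) == {"cycle_id", "joint", "cycle_percent",
                                      "angle", "relevance"}
        assert len(frame) == 3 * 3 * 101

    def test_plot_renders_to_file(self, tmp_path, trained_small, small_matched):
        from prefog.lrp import plot_group_attribution

        _, eval_cycles, _ = small_matched
        maps, sel = self._maps(trained_small, eval_cycles, n=4)
        g = aggregate_group_relevance(maps, sel, name="grp")
        out = tmp_path / "att.png"
        plot_group_attribution([g], out)
        assert out.exists() and out.stat().st_size > 0
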