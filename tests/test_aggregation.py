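"""Aggregation terms, combination modes, server optimizers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fedsim import (
    AggregationHistory,
    ClientRoundStats,
    CombinationSpec,
    ModelParameters,
    ServerOptimizerState,
    TermSpec,
    WeightingTermResult,
    aggregate,
    broadcast_term,
    combine_terms,
    regularize_by_param_change,
    server_update,
    term_cost_ratio,
    term_fedavg,
    term_inv_param_distance,
    term_inv_train_dsc,
    term_pid,
    term_val_loss,
)


def stats_record(val_loss=1.0, pre=0.5, post=0.6, train_dsc=0.7, delta=1.0):
    return ClientRoundStats(
        val_loss=val_loss,
        val_dsc_pre=pre,
        val_dsc_post=post,
        train_dsc=train_dsc,
        param_delta_norm=delta,
    )


def history_with(sizes, rounds):
    h = AggregationHistory(sizes)
    for r in rounds:
        h.record(r)
    return h


def scalar_params(*values):
    layout = (("w", (1,)),)
    return {
        f"c{i}": ModelParameters(values=np.array([v], dtype=float), layout=layout)
        for i, v in enumerate(values)
    }


def term_of(mapping, term_id="t"):
    clients = tuple(mapping)
    return WeightingTermResult(
        term_id=term_id,
        clients=clients,
        weights=np.array([[mapping[c]] for c in clients]),
    )


class TestFedavgTerm:
    def test_sizes_normalized(self):
        w = term_fedavg({"a": 10, "b": 30}).as_mapping()
        assert w == {"a": pytest.approx(0.25), "b": pytest.approx(0.75)}

    def test_single_client_gets_one(self):
        assert term_fedavg({"solo": 7}).as_mapping() == {"solo": 1.0}

    def test_equal_sizes_uniform(self):
        w = term_fedavg({c: 5 for c in "abcd"}).as_mapping()
        assert all(v == pytest.approx(0.25) for v in w.values())

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            term_fedavg({"a": 0, "b": 0})


class TestValLossTerm:
    def test_proportional_to_loss(self):
        h = history_with({"a": 1, "b": 1}, [{"a": stats_record(1.0), "b": stats_record(3.0)}])
        w = term_val_loss(h, 0).as_mapping()
        assert w == {"a": pytest.approx(0.25), "b": pytest.approx(0.75)}

    def test_equal_losses_uniform(self):
        h = history_with({"a": 1, "b": 1}, [{"a": stats_record(2.0), "b": stats_record(2.0)}])
        w = term_val_loss(h, 0).as_mapping()
        assert all(v == pytest.approx(0.5) for v in w.values())

    def test_zero_loss_client_gets_zero_weight(self):
        h = history_with(
            {"a": 1, "b": 1, "c": 1},
            [{"a": stats_record(1.0), "b": stats_record(1.0), "c": stats_record(0.0)}],
        )
        assert term_val_loss(h, 0).as_mapping()["c"] == 0.0

    def test_all_zero_losses_fall_back_to_uniform(self):
        h = history_with({"a": 1, "b": 1}, [{"a": stats_record(0.0), "b": stats_record(0.0)}])
        result = term_val_loss(h, 0)
        assert result.as_mapping() == {"a": pytest.approx(0.5), "b": pytest.approx(0.5)}
        assert any("uniform" in f for f in result.flags)


class TestCostRatioTerm:
    def test_ratio_of_post_to_pre(self):
        h = history_with(
            {"a": 1, "b": 1},
            [{"a": stats_record(pre=0.5, post=0.6), "b": stats_record(pre=0.5, post=0.4)}],
        )
        w = term_cost_ratio(h, 0).as_mapping()
        assert w == {"a": pytest.approx(0.6), "b": pytest.approx(0.4)}

    def test_equal_ratios_uniform(self):
        h = history_with(
            {"a": 1, "b": 1},
            [{"a": stats_record(pre=0.4, post=0.6), "b": stats_record(pre=0.2, post=0.3)}],
        )
        w = term_cost_ratio(h, 0).as_mapping()
        assert all(v == pytest.approx(0.5) for v in w.values())

    def test_no_improvement_vs_doubling(self):
        h = history_with(
            {"a": 1, "b": 1},
            [{"a": stats_record(pre=0.3, post=0.3), "b": stats_record(pre=0.3, post=0.6)}],
        )
        w = term_cost_ratio(h, 0).as_mapping()
        assert w == {"a": pytest.approx(1 / 3), "b": pytest.approx(2 / 3)}

    def test_zero_denominator_clamped_and_flagged(self):
        h = history_with(
            {"a": 1, "b": 1},
            [{"a": stats_record(pre=0.0, post=0.5), "b": stats_record(pre=0.5, post=0.5)}],
        )
        result = term_cost_ratio(h, 0)
        assert any("clamp" in f for f in result.flags)
        assert result.as_mapping()["a"] > 0.99


class TestInvParamDistanceTerm:
    def test_symmetric_clients_equal_weights(self):
        w = term_inv_param_distance(scalar_params(0.0, 2.0)).as_mapping()
        assert w == {"c0": pytest.approx(0.5), "c1": pytest.approx(0.5)}

    def test_equal_distances_from_asymmetric_values(self):
        w = term_inv_param_distance(scalar_params(0.9, 3.0)).as_mapping()
        assert w == {"c0": pytest.approx(0.5), "c1": pytest.approx(0.5)}

    def test_three_clients_inverse_distance(self):
        w = term_inv_param_distance(scalar_params(0.0, 0.0, 3.0)).as_mapping()
        assert w == {
            "c0": pytest.approx(0.4),
            "c1": pytest.approx(0.4),
            "c2": pytest.approx(0.2),
        }

    def test_tensor_granularity_normalizes_per_tensor(self):
        layout = (("w", (2,)), ("b", (1,)))
        params = {
            "a": ModelParameters(values=np.array([0.0, 0.0, 1.0]), layout=layout),
            "b": ModelParameters(values=np.array([2.0, 2.0, 1.0]), layout=layout),
        }
        result = term_inv_param_distance(params, granularity="tensor")
        assert result.weights.shape == (2, 2)
        np.testing.assert_allclose(result.weights.sum(axis=0), 1.0)
        # identical "b" tensors -> epsilon clamp -> equal weights there
        np.testing.assert_allclose(result.weights[:, 1], [0.5, 0.5])

    def test_scalar_granularity_shapes(self):
        layout = (("w", (3,)),)
        params = {
            "a": ModelParameters(values=np.array([0.0, 1.0, 5.0]), layout=layout),
            "b": ModelParameters(values=np.array([2.0, 3.0, 5.0]), layout=layout),
        }
        result = term_inv_param_distance(params, granularity="scalar")
        assert result.weights.shape == (2, 3)
        np.testing.assert_allclose(result.weights.sum(axis=0), 1.0)

    def test_needs_two_clients(self):
        with pytest.raises(ValueError, match="2 clients"):
            term_inv_param_distance(scalar_params(1.0))


class TestPidTerms:
    def test_derivative_is_positive_part_of_loss_reduction(self):
        h = history_with(
            {"a": 1, "b": 1},
            [
                {"a": stats_record(0.5), "b": stats_record(0.5)},
                {"a": stats_record(0.3), "b": stats_record(0.5)},
            ],
        )
        _, p_d, _ = term_pid(h, 1)
        assert p_d.as_mapping() == {"a": pytest.approx(1.0), "b": pytest.approx(0.0)}

    def test_identical_histories_give_uniform_integral(self):
        rounds = [{"a": stats_record(0.4), "b": stats_record(0.4)} for _ in range(3)]
        h = history_with({"a": 1, "b": 2}, rounds)
        _, _, p_i = term_pid(h, 2)
        assert p_i.as_mapping() == {"a": pytest.approx(0.5), "b": pytest.approx(0.5)}

    def test_window_one_reduces_to_val_loss_term(self):
        rounds = [
            {"a": stats_record(0.9), "b": stats_record(0.1)},
            {"a": stats_record(0.2), "b": stats_record(0.6)},
        ]
        h = history_with({"a": 1, "b": 1}, rounds)
        _, _, p_i = term_pid(h, 1, window=1)
        assert p_i.as_mapping() == term_val_loss(h, 1).as_mapping()

    def test_round_zero_fallbacks_flagged(self):
        h = history_with({"a": 1, "b": 3}, [{"a": stats_record(), "b": stats_record()}])
        p_p, p_d, p_i = term_pid(h, 0)
        assert p_d.as_mapping() == {"a": pytest.approx(0.5), "b": pytest.approx(0.5)}
        assert any("round 0" in f for f in p_d.flags)
        assert p_p.as_mapping() == {"a": pytest.approx(0.25), "b": pytest.approx(0.75)}

    def test_integral_sums_trailing_window(self):
        losses_a = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        losses_b = [1.0] * 6
        rounds = [
            {"a": stats_record(la), "b": stats_record(lb)}
            for la, lb in zip(losses_a, losses_b)
        ]
        h = history_with({"a": 1, "b": 1}, rounds)
        _, _, p_i = term_pid(h, 5, window=5)
        # a: 2+3+4+5+6=20, b: 5 -> (0.8, 0.2)
        assert p_i.as_mapping() == {"a": pytest.approx(0.8), "b": pytest.approx(0.2)}


class TestInvTrainDscTerm:
    def test_inverse_proportionality(self):
        h = history_with(
            {"a": 1, "b": 1},
            [{"a": stats_record(train_dsc=0.5), "b": stats_record(train_dsc=1.0)}],
        )
        w = term_inv_train_dsc(h, 0).as_mapping()
        assert w == {"a": pytest.approx(2 / 3), "b": pytest.approx(1 / 3)}

    def test_equal_dsc_uniform(self):
        h = history_with(
            {"a": 1, "b": 1},
            [{"a": stats_record(train_dsc=0.8), "b": stats_record(train_dsc=0.8)}],
        )
        w = term_inv_train_dsc(h, 0).as_mapping()
        assert all(v == pytest.approx(0.5) for v in w.values())

    def test_raising_train_dsc_lowers_weight(self):
        low = history_with(
            {"a": 1, "b": 1},
            [{"a": stats_record(train_dsc=0.5), "b": stats_record(train_dsc=0.6)}],
        )
        high = history_with(
            {"a": 1, "b": 1},
            [{"a": stats_record(train_dsc=0.9), "b": stats_record(train_dsc=0.6)}],
        )
        assert (
            term_inv_train_dsc(high, 0).as_mapping()["a"]
            < term_inv_train_dsc(low, 0).as_mapping()["a"]
        )


class TestCombineTerms:
    def test_single_term_identity_both_modes(self):
        t = term_of({"a": 0.3, "b": 0.7})
        for mode in ("additive", "multiplicative"):
            out = combine_terms([t], CombinationSpec(mode=mode))
            assert out.as_mapping() == pytest.approx({"a": 0.3, "b": 0.7})

    def test_multiplicative_worked_example(self):
        t1 = term_of({"a": 0.5, "b": 0.5})
        t2 = term_of({"a": 0.8, "b": 0.2})
        out = combine_terms([t1, t2], CombinationSpec(mode="multiplicative"))
        assert out.as_mapping() == pytest.approx({"a": 0.8, "b": 0.2})

    def test_additive_worked_example(self):
        t1 = term_of({"a": 0.5, "b": 0.5})
        t2 = term_of({"a": 0.8, "b": 0.2})
        out = combine_terms(
            [t1, t2], CombinationSpec(mode="additive", betas=(0.5, 0.5))
        )
        assert out.as_mapping() == pytest.approx({"a": 0.65, "b": 0.35})

    def test_multiplicative_uniform_term_is_neutral(self):
        t1 = term_of({"a": 0.9, "b": 0.1})
        uniform = term_of({"a": 0.5, "b": 0.5})
        out = combine_terms([t1, uniform], CombinationSpec(mode="multiplicative"))
        assert out.as_mapping() == pytest.approx({"a": 0.9, "b": 0.1})

    def test_multiplicative_all_zero_unit_names_clients(self):
        t1 = term_of({"a": 1.0, "b": 0.0})
        t2 = term_of({"a": 0.0, "b": 1.0})
        with pytest.raises(ValueError, match="offending clients.*'a'.*'b'"):
            combine_terms([t1, t2], CombinationSpec(mode="multiplicative"))

    def test_mismatched_client_sets_rejected(self):
        with pytest.raises(ValueError, match="clients"):
            combine_terms(
                [term_of({"a": 1.0}), term_of({"b": 1.0})], CombinationSpec()
            )

    @settings(derandomize=True, max_examples=40)
    @given(
        st.lists(
            st.lists(st.floats(0.01, 10.0), min_size=3, max_size=3),
            min_size=1,
            max_size=4,
        ),
        st.sampled_from(["additive", "multiplicative"]),
    )
    def test_weights_always_nonnegative_and_sum_to_one(self, raws, mode):
        clients = ("a", "b", "c")
        terms = []
        for raw in raws:
            arr = np.array([[v] for v in raw])
            terms.append(
                WeightingTermResult(
                    term_id="t", clients=clients, weights=arr / arr.sum()
                )
            )
        out = combine_terms(terms, CombinationSpec(mode=mode))
        assert np.all(out.weights >= 0)
        np.testing.assert_allclose(out.weights.sum(axis=0), 1.0, atol=1e-12)


class TestAggregate:
    def test_one_hot_returns_source_client_bitwise(self, tiny_model):
        params = {
            "a": tiny_model.init_params(1),
            "b": tiny_model.init_params(2),
        }
        weights = term_of({"a": 1.0, "b": 0.0})
        out = aggregate(params, weights)
        assert np.array_equal(out.values, params["a"].values)

    def test_midpoint_of_two_scalars(self):
        out = aggregate(scalar_params(0.0, 2.0), term_of({"c0": 0.5, "c1": 0.5}))
        assert out.values[0] == pytest.approx(1.0)

    def test_result_within_convex_envelope(self, tiny_model):
        params = {f"c{i}": tiny_model.init_params(i) for i in range(3)}
        weights = term_of({"c0": 0.2, "c1": 0.5, "c2": 0.3})
        out = aggregate(params, weights)
        stack = np.stack([p.values for p in params.values()])
        assert np.all(out.values <= stack.max(axis=0) + 1e-12)
        assert np.all(out.values >= stack.min(axis=0) - 1e-12)

    def test_fedavg_weights_match_brute_force_mean(self):
        sizes = {"a": 10, "b": 30, "c": 60}
        params = scalar_params(1.0, 2.0, 3.0)
        renamed = {k: params[f"c{i}"] for i, k in enumerate(sizes)}
        out = aggregate(renamed, term_fedavg(sizes))
        expected = sum(sizes[k] * renamed[k].values for k in sizes) / sum(sizes.values())
        np.testing.assert_allclose(out.values, expected)

    def test_permutation_equivariance(self, tiny_model):
        params = {"a": tiny_model.init_params(1), "b": tiny_model.init_params(2)}
        w1 = term_of({"a": 0.3, "b": 0.7})
        w2 = term_of({"b": 0.7, "a": 0.3})
        np.testing.assert_allclose(
            aggregate(params, w1).values, aggregate(params, w2).values
        )

    def test_tensor_granularity_broadcast(self):
        layout = (("w", (2,)), ("b", (1,)))
        params = {
            "a": ModelParameters(values=np.array([0.0, 0.0, 10.0]), layout=layout),
            "b": ModelParameters(values=np.array([4.0, 4.0, 20.0]), layout=layout),
        }
        weights = WeightingTermResult(
            term_id="t",
            clients=("a", "b"),
            weights=np.array([[0.5, 1.0], [0.5, 0.0]]),
            granularity="tensor",
        )
        out = aggregate(params, weights)
        np.testing.assert_allclose(out.values, [2.0, 2.0, 10.0])

    def test_unnormalized_weights_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            aggregate(scalar_params(0.0, 1.0), term_of({"c0": 0.5, "c1": 0.7}))


class TestBroadcastTerm:
    def test_model_to_scalar_preserves_normalization(self):
        layout = (("w", (2,)), ("b", (3,)))
        t = term_of({"a": 0.3, "b": 0.7})
        lifted = broadcast_term(t, "scalar", layout)
        assert lifted.weights.shape == (2, 5)
        np.testing.assert_allclose(lifted.weights.sum(axis=0), 1.0)

    def test_cannot_coarsen(self):
        t = WeightingTermResult(
            term_id="t", clients=("a",), weights=np.array([[1.0, 1.0]]), granularity="tensor"
        )
        with pytest.raises(ValueError, match="coarsen"):
            broadcast_term(t, "model")


class TestServerUpdate:
    def test_none_returns_aggregated_verbatim(self):
        prev = scalar_params(0.0)["c0"]
        agg = scalar_params(2.0)["c0"]
        out = server_update(prev, agg, ServerOptimizerState(kind="none"))
        assert out is agg

    def test_sgd_unit_lr_recovers_plain_aggregation(self):
        prev = scalar_params(5.0)["c0"]
        agg = scalar_params(2.0)["c0"]
        out = server_update(prev, agg, ServerOptimizerState(kind="sgd", server_lr=1.0))
        np.testing.assert_allclose(out.values, agg.values)

    def test_sgd_half_lr_worked_example(self):
        prev = scalar_params(0.0)["c0"]
        agg = scalar_params(2.0)["c0"]
        out = server_update(prev, agg, ServerOptimizerState(kind="sgd", server_lr=0.5))
        assert out.values[0] == pytest.approx(1.0, abs=1e-15)

    def test_adam_moves_toward_aggregated(self):
        prev = scalar_params(0.0)["c0"]
        agg = scalar_params(2.0)["c0"]
        state = ServerOptimizerState(kind="adam", server_lr=0.1)
        out = server_update(prev, agg, state)
        assert 0.0 < out.values[0] <= 2.0
        assert state.step_count == 1
        # repeated steps keep approaching the target
        for _ in range(50):
            out = server_update(out, agg, state)
        assert out.values[0] == pytest.approx(2.0, abs=0.5)


class TestRegularizeByParamChange:
    def history(self, norms):
        return history_with(
            {c: 1 for c in norms},
            [{c: stats_record(delta=n) for c, n in norms.items()}],
        )

    def test_strength_zero_identity(self):
        w = term_of({"a": 0.5, "b": 0.5})
        h = self.history({"a": 1.0, "b": 3.0})
        assert regularize_by_param_change(w, h, 0, strength=0.0) is w

    def test_equal_norms_unchanged(self):
        w = term_of({"a": 0.4, "b": 0.6})
        h = self.history({"a": 2.0, "b": 2.0})
        out = regularize_by_param_change(w, h, 0, strength=-1.0)
        # round 0 passes through; use round 1 with a two-round history
        h2 = history_with(
            {"a": 1, "b": 1},
            [
                {"a": stats_record(), "b": stats_record()},
                {"a": stats_record(delta=2.0), "b": stats_record(delta=2.0)},
            ],
        )
        out = regularize_by_param_change(w, h2, 1, strength=-1.0)
        assert out.as_mapping() == pytest.approx({"a": 0.4, "b": 0.6})

    def test_positive_strength_upweights_large_movers(self):
        w = term_of({"a": 0.5, "b": 0.5})
        h2 = history_with(
            {"a": 1, "b": 1},
            [
                {"a": stats_record(), "b": stats_record()},
                {"a": stats_record(delta=1.0), "b": stats_record(delta=3.0)},
            ],
        )
        out = regularize_by_param_change(w, h2, 1, strength=1.0)
        assert out.as_mapping() == pytest.approx({"a": 0.25, "b": 0.75})

    def test_default_negative_strength_downweights_large_movers(self):
        w = term_of({"a": 0.5, "b": 0.5})
        h2 = history_with(
            {"a": 1, "b": 1},
            [
                {"a": stats_record(), "b": stats_record()},
                {"a": stats_record(delta=1.0), "b": stats_record(delta=3.0)},
            ],
        )
        out = regularize_by_param_change(w, h2, 1, strength=-1.0)
        assert out.as_mapping()["a"] > out.as_mapping()["b"]

    def test_round_zero_identity_flagged(self):
        w = term_of({"a": 0.5, "b": 0.5})
        h = self.history({"a": 1.0, "b": 3.0})
        out = regularize_by_param_change(w, h, 0, strength=-1.0)
        assert out.as_mapping() == pytest.approx({"a": 0.5, "b": 0.5})
        assert any("round 0" in f for f in out.flags)
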