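from itertools import combinations

import numpy as np
import pytest

from lupine.quantio import QuantMatrix
from lupine.partition import mcar_partition, PartitionMask
from lupine.model import (
    HyperParams,
    ModelState,
    TrainingTrace,
    init_model,
    forward,
    predict_all,
    train_model,
    convergence_check,
    save_checkpoint,
    load_checkpoint,
)

from conftest import make_qm

SMALL_HP = HyperParams(
    n_protein_factors=8,
    n_sample_factors=8,
    n_hidden_layers=1,
    nodes_per_layer=32,
)


class TestInitModel:
    def test_deterministic_given_seed(self):
        a = init_model(10, 5, SMALL_HP, seed=3)
        b = init_model(10, 5, SMALL_HP, seed=3)
        np.testing.assert_array_equal(a.W, b.W)
        np.testing.assert_array_equal(a.H, b.H)
        for (wa, ba), (wb, bb) in zip(a.mlp, b.mlp):
            np.testing.assert_array_equal(wa, wb)
            np.testing.assert_array_equal(ba, bb)

    def test_mlp_shapes_chain(self):
        hp = HyperParams(
            n_protein_factors=2,
            n_sample_factors=2,
            n_hidden_layers=1,
            nodes_per_layer=4,
        )
        state = init_model(3, 3, hp, seed=0)
        assert [w.shape for w, _ in state.mlp] == [(4, 4), (1, 4)]
        assert [b.shape for _, b in state.mlp] == [(4,), (1,)]

    def test_embedding_entries_bounded_by_init_law(self):
        hp = HyperParams(n_protein_factors=16, n_sample_factors=9)
        state = init_model(200, 100, hp, seed=1)
        assert np.abs(state.W).max() <= 1 / np.sqrt(16)
        assert np.abs(state.H).max() <= 1 / np.sqrt(9)

    def test_invalid_dims_raise(self):
        with pytest.raises(ValueError):
            init_model(0, 5, SMALL_HP)


class TestForward:
    def _zero_state(self, hp=SMALL_HP, n=4, m=3):
        state = init_model(n, m, hp, seed=0)
        state.W[:] = 0
        state.H[:] = 0
        for w, b in state.mlp:
            w[:] = 0
            b[:] = 0
        return state

    def test_zero_weights_predict_zero(self):
        state = self._zero_state()
        for i in range(4):
            for j in range(3):
                assert forward(state, i, j) == 0.0

    def test_negative_preactivation_uses_leaky_slope(self):
        # single hidden unit whose pre-activation is -1; output weight 1
        hp = HyperParams(
            n_protein_factors=1,
            n_sample_factors=1,
            n_hidden_layers=1,
            nodes_per_layer=1,
        )
        state = self._zero_state(hp, n=1, m=1)
        state.mlp[0][1][:] = -1.0  # hidden bias -> pre-activation -1
        state.mlp[1][0][:] = 1.0  # output weight 1, bias 0
        assert forward(state, 0, 0) == pytest.approx(-0.1)

    def test_matches_hand_computed_toy_network(self):
        # 2 protein factors, 2 sample factors, one hidden layer of 2:
        # the oracle below is explicit matrix arithmetic, independent of
        # the library's forward pass
        hp = HyperParams(
            n_protein_factors=2,
            n_sample_factors=2,
            n_hidden_layers=1,
            nodes_per_layer=2,
        )
        state = init_model(1, 1, hp, seed=0)
        state.W[0] = [0.5, -1.0]
        state.H[:, 0] = [2.0, 0.25]
        W1 = np.array([[1.0, 0.0, -1.0, 2.0], [0.5, 0.5, 0.5, 0.5]])
        b1 = np.array([0.1, -2.0])
        W2 = np.array([[1.0, -3.0]])
        b2 = np.array([0.2])
        state.mlp = [(W1, b1), (W2, b2)]

        x = np.array([0.5, -1.0, 2.0, 0.25])
        a = W1 @ x + b1
        h = np.where(a > 0, a, 0.1 * a)
        expected = (W2 @ h + b2)[0]
        assert forward(state, 0, 0) == pytest.approx(expected, rel=1e-12)

    def test_out_of_range_raises(self):
        state = self._zero_state()
        with pytest.raises(IndexError):
            forward(state, 4, 0)


class TestPredictAll:
    def test_equals_entrywise_forward(self):
        state = init_model(6, 5, SMALL_HP, seed=11)
        pred = predict_all(state)
        assert not np.isnan(pred).any()
        for i in range(6):
            for j in range(5):
                assert pred[i, j] == pytest.approx(forward(state, i, j))


def _exact_ranksum_p_less(older, recent):
    """Exact one-sided rank-sum p-value by enumeration of all 5-vs-5 splits."""
    pooled = np.concatenate([older, recent])
    ranks = np.argsort(np.argsort(pooled)) + 1
    obs = ranks[:5].sum()
    n = len(pooled)
    count = sum(
        1
        for combo in combinations(range(n), 5)
        if ranks[list(combo)].sum() <= obs
    )
    from math import comb

    return count / comb(n, 5)


class TestConvergenceCheck:
    def test_steadily_halving_losses_never_stop(self):
        trace = [1.0 / 2**k for k in range(40)]
        stop, _ = convergence_check(trace)
        assert not stop

    def test_plateau_triggers_tolerance_stop(self):
        trace = [2.0, 1.0] + [1.0] * 10
        stop, reason = convergence_check(trace)
        assert stop and reason == "tolerance"

    def test_rising_error_triggers_wilcoxon_stop(self):
        trace = [1.0] * 10 + [0.5] * 5 + [0.9] * 5
        # at n=20: older window = five 0.5s, recent = five 0.9s
        stop, reason = convergence_check(trace[:20])
        assert stop and reason == "wilcoxon"

    def test_short_traces_do_not_stop(self):
        assert convergence_check([1.0, 0.9, 0.8]) == (False, None)

    def test_wilcoxon_agrees_with_exact_enumeration(self):
        # the stopping rule's rank-sum p-value must match a brute-force
        # enumeration of all C(10,5) window splits on random traces
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(99)
        for _ in range(1000):
            trace = rng.uniform(0, 1, 20)
            older, recent = trace[5:10], trace[15:20]
            p_scipy = mannwhitneyu(
                older, recent, alternative="less", method="exact"
            ).pvalue
            p_exact = _exact_ranksum_p_less(older, recent)
            assert p_scipy == pytest.approx(p_exact, abs=1e-12)


@pytest.fixture
def rank1_setup(rank1_qm):
    mask = mcar_partition(rank1_qm, 0.2, seed=1, to_label="validation")
    return rank1_qm, mask


class TestTrainModel:
    def test_recovers_additive_structure(self, rank1_setup):
        X, mask = rank1_setup
        hp = HyperParams(
            n_protein_factors=8,
            n_sample_factors=8,
            n_hidden_layers=1,
            nodes_per_layer=32,
            max_epochs=400,
        )
        state, trace = train_model(X, mask, hp, seed=2)
        assert trace.val_mse_by_epoch[-1] < 0.1
        # substantial improvement over the untrained starting point
        assert min(trace.val_mse_by_epoch) < trace.val_mse_by_epoch[0] / 5

    def test_single_epoch_cap(self, rank1_setup):
        X, mask = rank1_setup
        hp = HyperParams(
            n_protein_factors=4,
            n_sample_factors=4,
            nodes_per_layer=8,
            max_epochs=1,
        )
        _, trace = train_model(X, mask, hp, seed=0)
        assert trace.epochs_run == 1
        assert len(trace.val_mse_by_epoch) == 1
        assert trace.stop_reason == "max_epochs"

    def test_deterministic_given_seed(self, rank1_setup):
        X, mask = rank1_setup
        hp = HyperParams(
            n_protein_factors=4,
            n_sample_factors=4,
            nodes_per_layer=8,
            max_epochs=3,
        )
        _, t1 = train_model(X, mask, hp, seed=5)
        _, t2 = train_model(X, mask, hp, seed=5)
        assert t1.val_mse_by_epoch == t2.val_mse_by_epoch

    def test_empty_validation_raises(self, rank1_qm):
        mask = mcar_partition(rank1_qm, 0.0, seed=0)
        with pytest.raises(ValueError, match="validation"):
            train_model(rank1_qm, mask, SMALL_HP, seed=0)

    def test_validation_values_do_not_touch_gradients(self, rank1_setup):
        # perturbing held-out validation values must leave every learned
        # parameter bit-identical (they only drive the stopping rule)
        X, mask = rank1_setup
        hp = HyperParams(
            n_protein_factors=4,
            n_sample_factors=4,
            nodes_per_layer=8,
            max_epochs=2,
        )
        state_a, _ = train_model(X, mask, hp, seed=3)
        X2 = X.copy()
        val_flat = mask.val_indices
        X2.values.ravel()[val_flat] += 1000.0
        state_b, _ = train_model(X2, mask, hp, seed=3)
        np.testing.assert_array_equal(state_a.W, state_b.W)
        np.testing.assert_array_equal(state_a.H, state_b.H)
        for (wa, ba), (wb, bb) in zip(state_a.mlp, state_b.mlp):
            np.testing.assert_array_equal(wa, wb)
            np.testing.assert_array_equal(ba, bb)


class TestCheckpoint:
    def test_round_trip_exact(self, tmp_path):
        hp = HyperParams(
            n_protein_factors=4,
            n_sample_factors=3,
            n_hidden_layers=2,
            nodes_per_layer=8,
        )
        state = init_model(7, 5, hp, seed=13)
        path = tmp_path / "model.npz"
        save_checkpoint(state, hp, path)
        state2, hp2 = load_checkpoint(path)
        assert hp2 == hp
        np.testing.assert_array_equal(state.W, state2.W)
        np.testing.assert_array_equal(state.H, state2.H)
        for (wa, ba), (wb, bb) in zip(state.mlp, state2.mlp):
            np.testing.assert_array_equal(wa, wb)
            np.testing.assert_array_equal(ba, bb)
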