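"""LSTM cell oracle, backprop correctness, training behavior, checkpointing."""

import numpy as np
import pytest

from tftslstm.model import (
    BiLSTMClassifier,
    LSTMWeights,
    TrainConfig,
    _init_params,
    _loss_and_grads,
    bilstm_forward,
    load_model,
    lstm_cell_step,
    save_model,
    train,
)
from tftslstm.pipeline import FeatureSequence


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def scalar_cell_oracle(A, R, b, u, h_prev, c_prev):
    """Element-by-element recomputation of the gate and state recurrences."""
    H = len(h_prev)
    i = np.empty(H)
    f = np.empty(H)
    g = np.empty(H)
    o = np.empty(H)
    for n in range(H):
        zi = b[n] + sum(A[n, k] * u[k] for k in range(len(u)))
        zf = b[H + n] + sum(A[H + n, k] * u[k] for k in range(len(u)))
        zg = b[2 * H + n] + sum(A[2 * H + n, k] * u[k] for k in range(len(u)))
        zo = b[3 * H + n] + sum(A[3 * H + n, k] * u[k] for k in range(len(u)))
        for m in range(H):
            zi += R[n, m] * h_prev[m]
            zf += R[H + n, m] * h_prev[m]
            zg += R[2 * H + n, m] * h_prev[m]
            zo += R[3 * H + n, m] * h_prev[m]
        i[n], f[n], g[n], o[n] = sigmoid(zi), sigmoid(zf), np.tanh(zg), sigmoid(zo)
    c = f * c_prev + i * g
    h = o * np.tanh(c)
    return c, h


class TestCellStep:
    def test_zero_weights_closed_form(self):
        w = LSTMWeights(A=np.zeros((4, 1)), R=np.zeros((4, 1)), b=np.zeros(4))
        st = lstm_cell_step(w, [0.7], [0.0], [0.0])
        assert st.c[0] == 0.0 and st.h[0] == 0.0  # i=f=o=0.5, g=0

    def test_zero_weights_with_carried_cell_state(self):
        w = LSTMWeights(A=np.zeros((4, 1)), R=np.zeros((4, 1)), b=np.zeros(4))
        st = lstm_cell_step(w, [0.0], [0.0], [1.0])
        assert st.c[0] == pytest.approx(0.5)  # f*c_prev = 0.5*1
        assert st.h[0] == pytest.approx(0.5 * np.tanh(0.5))

    @pytest.mark.parametrize("hidden", [1, 2, 3, 4])
    def test_matches_scalar_oracle(self, hidden, rng):
        q = 3
        A = rng.normal(size=(4 * hidden, q))
        R = rng.normal(size=(4 * hidden, hidden))
        b = rng.normal(size=4 * hidden)
        u = rng.normal(size=q)
        h_prev = rng.normal(size=hidden)
        c_prev = rng.normal(size=hidden)
        st = lstm_cell_step(LSTMWeights(A, R, b), u, h_prev, c_prev)
        c_exp, h_exp = scalar_cell_oracle(A, R, b, u, h_prev, c_prev)
        np.testing.assert_allclose(st.c, c_exp, atol=1e-12)
        np.testing.assert_allclose(st.h, h_exp, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        w = LSTMWeights(A=np.zeros((8, 2)), R=np.zeros((8, 2)), b=np.zeros(8))
        with pytest.raises(ValueError, match="shape mismatch"):
            lstm_cell_step(w, [1.0, 2.0, 3.0], [0.0, 0.0], [0.0, 0.0])


class TestForward:
    def test_softmax_sums_to_one(self, rng):
        params = _init_params(rng, 5, 4)
        p = bilstm_forward(params, rng.normal(size=(7, 6, 4)))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(p >= 0)

    def test_single_step_directions_see_same_input(self, rng):
        """With M=1 the forward and reversed sequences are identical."""
        U = rng.normal(size=(3, 1, 4))
        np.testing.assert_array_equal(U, U[:, ::-1])
        params = _init_params(rng, 4, 4)
        p = bilstm_forward(params, U)
        # swapping direction weights must not change outputs when fc is symmetric
        hs = 4
        params.W_fc[:, :hs], params.W_fc[:, hs:] = (
            params.W_fc[:, hs:].copy(),
            params.W_fc[:, :hs].copy(),
        )
        params.fwd, params.bwd = params.bwd, params.fwd
        np.testing.assert_allclose(bilstm_forward(params, U), p, atol=1e-12)

    def test_nonfinite_input_rejected(self, rng):
        params = _init_params(rng, 3, 2)
        U = np.full((1, 4, 2), np.nan)
        with pytest.raises(ValueError, match="non-finite"):
            bilstm_forward(params, U)


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        rng = np.random.default_rng(3)
        params = _init_params(rng, 3, 2)
        U = rng.normal(size=(3, 4, 2))
        y = np.array([0, 1, 1])
        _, grads, _ = _loss_and_grads(params, U, y, l2=1e-3)
        eps = 1e-6
        for name, arr in params.all_arrays().items():
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                ix = it.multi_index
                orig = arr[ix]
                arr[ix] = orig + eps
                lp = _loss_and_grads(params, U, y, l2=1e-3)[0]
                arr[ix] = orig - eps
                lm = _loss_and_grads(params, U, y, l2=1e-3)[0]
                arr[ix] = orig
                fd = (lp - lm) / (2 * eps)
                assert abs(fd - grads[name][ix]) <= 1e-5 * max(1.0, abs(fd)), name


class TestTraining:
    def small_config(self, **kw):
        kw.setdefault("hidden_size", 8)
        kw.setdefault("max_epochs", 40)
        kw.setdefault("batch_size", 4)
        return TrainConfig(**kw)

    def test_fixed_seed_reproducible(self, separable_sequences):
        r1 = train(separable_sequences, self.small_config(max_epochs=5), seed=3)
        r2 = train(separable_sequences, self.small_config(max_epochs=5), seed=3)
        assert r1.final_loss == r2.final_loss
        np.testing.assert_array_equal(r1.params.W_fc, r2.params.W_fc)

    def test_overfits_separable_toy_set(self, separable_sequences):
        res = train(separable_sequences, self.small_config(), seed=0)
        assert res.final_train_accuracy == 1.0
        assert res.training_log[-1]["loss"] <= res.training_log[0]["loss"]
        preds = res.predict(separable_sequences)
        assert all(lbl == s.label for (lbl, _), s in zip(preds, separable_sequences))
        assert all(p >= 0.5 for _, p in preds)

    def test_gradient_norm_clipped(self, separable_sequences):
        cfg = self.small_config(max_epochs=10, grad_clip=1.0)
        res = train(separable_sequences, cfg, seed=1)
        assert all(e["grad_norm_postclip"] <= 1.0 + 1e-12 for e in res.training_log)

    def test_single_class_rejected(self, separable_sequences):
        only_pos = [s for s in separable_sequences if s.label == "pos"]
        with pytest.raises(ValueError, match="two classes"):
            BiLSTMClassifier(only_pos)

    def test_mixed_sequence_lengths_rejected(self, rng):
        seqs = [
            FeatureSequence(id="a", features=rng.normal(size=(3, 2)), label="x"),
            FeatureSequence(id="b", features=rng.normal(size=(4, 2)), label="y"),
        ]
        with pytest.raises(ValueError, match="share M"):
            BiLSTMClassifier(seqs)

    def test_prediction_invariant_to_batch_duplication(self, separable_sequences):
        res = train(separable_sequences, self.small_config(max_epochs=3), seed=0)
        single = res.predict_proba(separable_sequences[:1])
        doubled = res.predict_proba([separable_sequences[0], separable_sequences[0]])
        np.testing.assert_allclose(doubled[0], single[0], atol=1e-12)
        np.testing.assert_allclose(doubled[1], single[0], atol=1e-12)

    def test_summary_mentions_config(self, separable_sequences):
        res = train(separable_sequences, self.small_config(max_epochs=2), seed=0)
        text = res.summary()
        assert "Adam" in text and "Hidden units" in text


class TestCheckpoint:
    def test_round_trip(self, tmp_path, separable_sequences):
        from tftslstm.pipeline import StandardizationParams

        std = StandardizationParams(mean=np.zeros(4), sd=np.ones(4))
        res = BiLSTMClassifier(
            separable_sequences, config=TrainConfig(hidden_size=6, max_epochs=3, batch_size=5),
            standardizer=std,
        ).fit(seed=2)
        path = tmp_path / "model.npz"
        save_model(res, str(path))
        loaded = load_model(str(path))
        np.testing.assert_array_equal(loaded.params.W_fc, res.params.W_fc)
        assert loaded.model.classes_ == res.model.classes_
        assert loaded.seed == 2
        np.testing.assert_allclose(
            loaded.predict_proba(separable_sequences),
            res.predict_proba(separable_sequences),
            atol=0,
        )
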