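"""Bidirectional LSTM sequence classifier.

The classifier consumes an (n, M, Q) batch of feature sequences.  One LSTM
layer reads each sequence forward, a second reads a time-reversed copy;
their final hidden states are concatenated (2H-dimensional) and mapped by a
fully connected layer to two class scores, followed by softmax.

Cell recurrences, per time step tau (o is the Hadamard product):

    i_t = sigmoid(a_i u_t + r_i h_{t-1} + b_i)      input gate
    f_t = sigmoid(a_f u_t + r_f h_{t-1} + b_f)      forget gate
    g_t = tanh   (a_g u_t + r_g h_{t-1} + b_g)      cell candidate
    o_t = sigmoid(a_o u_t + r_o h_{t-1} + b_o)      output gate
    c_t = f_t o c_{t-1} + i_t o g_t
    h_t = o_t o tanh(c_t)

Training minimizes softmax cross-entropy with Adam, an L2 penalty on the
weight matrices, and global L2 gradient-norm clipping.  Everything is
plain NumPy with explicit backpropagation through time; forward
correctness is checked against a scalar oracle and gradients against
finite differences in the test suite.

The public surface follows the statsmodels convention: a
:class:`BiLSTMClassifier` model object is built from data and configuration,
``fit()`` returns a :class:`BiLSTMResults` carrying the learned weights,
the training log, ``predict``/``predict_proba`` and ``summary()``.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict

import numpy as np

from .pipeline import FeatureSequence, StandardizationParams

__all__ = [
    "LSTMWeights",
    "LSTMState",
    "TrainConfig",
    "lstm_cell_step",
    "lstm_layer_forward",
    "bilstm_forward",
    "BiLSTMClassifier",
    "BiLSTMResults",
    "train",
    "predict",
    "save_model",
    "load_model",
]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class LSTMWeights:
    """Gate-stacked LSTM parameters.

    ``A`` (4H x Q) input weights, ``R`` (4H x H) recurrent weights and ``b``
    (4H,) biases, stacked in gate order input, forget, candidate, output.
    """

    A: np.ndarray
    R: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        h4, q = self.A.shape
        if h4 % 4 != 0:
            raise ValueError("first dimension of A must be 4*hidden")
        h = h4 // 4
        if self.R.shape != (h4, h) or self.b.shape != (h4,):
            raise ValueError(
                f"inconsistent shapes: A {self.A.shape}, R {self.R.shape}, b {self.b.shape}"
            )

    @property
    def hidden_size(self) -> int:
        return self.A.shape[0] // 4

    @property
    def input_size(self) -> int:
        return self.A.shape[1]


@dataclass(frozen=True)
class LSTMState:
    """Cell state c and hidden state h after one step."""

    c: np.ndarray
    h: np.ndarray


@dataclass
class TrainConfig:
    """Training configuration.

    Defaults follow the reference setting: hidden size 100, two classes,
    Adam at initial learning rate 0.01, at most 80 epochs, mini-batches of
    150, gradient-norm threshold 1, and a small L2 factor on weights.
    """

    hidden_size: int = 100
    n_classes: int = 2
    l2: float = 1e-4
    max_epochs: int = 80
    batch_size: int = 150
    learning_rate: float = 0.01
    grad_clip: float = 1.0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes != 2:
            raise ValueError("only binary classification is supported (n_classes = 2)")
        for name in ("hidden_size", "max_epochs", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("learning_rate", "grad_clip"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.l2 < 0:
            raise ValueError("l2 must be >= 0")


def lstm_cell_step(
    w: LSTMWeights, u: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray
) -> LSTMState:
    """One LSTM cell update.

    Gates use the sigmoid activation, the candidate and state activations
    use tanh.  Accepts single vectors or (B, .) batches.
    """
    u = np.atleast_1d(np.asarray(u, dtype=float))
    h_prev = np.atleast_1d(np.asarray(h_prev, dtype=float))
    c_prev = np.atleast_1d(np.asarray(c_prev, dtype=float))
    hs = w.hidden_size
    if u.shape[-1] != w.input_size or h_prev.shape[-1] != hs or c_prev.shape[-1] != hs:
        raise ValueError(
            f"shape mismatch: input {u.shape}, h {h_prev.shape}, c {c_prev.shape} "
            f"for hidden={hs}, input_size={w.input_size}"
        )
    z = u @ w.A.T + h_prev @ w.R.T + w.b
    i = _sigmoid(z[..., :hs])
    f = _sigmoid(z[..., hs : 2 * hs])
    g = np.tanh(z[..., 2 * hs : 3 * hs])
    o = _sigmoid(z[..., 3 * hs :])
    c = f * c_prev + i * g
    h = o * np.tanh(c)
    return LSTMState(c=c, h=h)


def lstm_layer_forward(w: LSTMWeights, U: np.ndarray, return_cache: bool = False):
    """Run one direction over a (B, M, Q) batch; returns the final hidden state.

    With ``return_cache=True`` also returns the per-step activations needed
    by backpropagation through time.
    """
    B, M, _ = U.shape
    hs = w.hidden_size
    pre = U @ w.A.T  # (B, M, 4H): input contribution for all steps at once
    h = np.zeros((B, hs))
    c = np.zeros((B, hs))
    cache = [] if return_cache else None
    for t in range(M):
        z = pre[:, t] + h @ w.R.T + w.b
        i = _sigmoid(z[:, :hs])
        f = _sigmoid(z[:, hs : 2 * hs])
        g = np.tanh(z[:, 2 * hs : 3 * hs])
        o = _sigmoid(z[:, 3 * hs :])
        c_new = f * c + i * g
        tc = np.tanh(c_new)
        h_new = o * tc
        if return_cache:
            cache.append((i, f, g, o, c, h, tc))
        h, c = h_new, c_new
    if return_cache:
        return h, cache
    return h


def _lstm_layer_backward(
    w: LSTMWeights, U: np.ndarray, cache: list, dh_last: np.ndarray
) -> tuple[dict[str, np.ndarray], None]:
    """BPTT through one direction given the gradient at the final hidden state."""
    B, M, _ = U.shape
    hs = w.hidden_size
    dA = np.zeros_like(w.A)
    dR = np.zeros_like(w.R)
    db = np.zeros_like(w.b)
    dh = dh_last
    dc = np.zeros((B, hs))
    dz = np.empty((B, 4 * hs))
    for t in range(M - 1, -1, -1):
        i, f, g, o, c_prev, h_prev, tc = cache[t]
        dc = dc + dh * o * (1.0 - tc * tc)
        do = dh * tc
        di = dc * g
        dg = dc * i
        df = dc * c_prev
        np.multiply(di * i, 1.0 - i, out=dz[:, :hs])
        np.multiply(df * f, 1.0 - f, out=dz[:, hs : 2 * hs])
        np.multiply(dg, 1.0 - g * g, out=dz[:, 2 * hs : 3 * hs])
        np.multiply(do * o, 1.0 - o, out=dz[:, 3 * hs :])
        dA += dz.T @ U[:, t]
        dR += dz.T @ h_prev
        db += dz.sum(axis=0)
        dh = dz @ w.R
        dc = dc * f
    return {"A": dA, "R": dR, "b": db}, None


@dataclass
class _Params:
    """All learnable parameters of the bidirectional model."""

    fwd: LSTMWeights
    bwd: LSTMWeights
    W_fc: np.ndarray  # (2, 2H)
    b_fc: np.ndarray  # (2,)

    def flat_weight_arrays(self) -> list[np.ndarray]:
        return [self.fwd.A, self.fwd.R, self.bwd.A, self.bwd.R, self.W_fc]

    def all_arrays(self) -> dict[str, np.ndarray]:
        return {
            "fwd_A": self.fwd.A,
            "fwd_R": self.fwd.R,
            "fwd_b": self.fwd.b,
            "bwd_A": self.bwd.A,
            "bwd_R": self.bwd.R,
            "bwd_b": self.bwd.b,
            "W_fc": self.W_fc,
            "b_fc": self.b_fc,
        }


def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    limit = np.sqrt(6.0 / sum(shape))
    return rng.uniform(-limit, limit, size=shape)


def _orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    a = rng.normal(size=(n, n))
    q, r = np.linalg.qr(a)
    return q * np.sign(np.diag(r))


def _init_direction(rng: np.random.Generator, hidden: int, q: int) -> LSTMWeights:
    A = _glorot(rng, (4 * hidden, q))
    R = np.vstack([_orthogonal(rng, hidden) for _ in range(4)])
    b = np.zeros(4 * hidden)
    b[hidden : 2 * hidden] = 1.0  # forget-gate bias 1: remember by default
    return LSTMWeights(A=A, R=R, b=b)


def _init_params(rng: np.random.Generator, hidden: int, q: int) -> _Params:
    return _Params(
        fwd=_init_direction(rng, hidden, q),
        bwd=_init_direction(rng, hidden, q),
        W_fc=_glorot(rng, (2, 2 * hidden)),
        b_fc=np.zeros(2),
    )


def bilstm_forward(params: _Params, U: np.ndarray) -> np.ndarray:
    """Class probabilities for a (B, M, Q) batch (softmax over 2 classes)."""
    if not np.all(np.isfinite(U)):
        raise ValueError("non-finite values in classifier input")
    hf = lstm_layer_forward(params.fwd, U)
    hb = lstm_layer_forward(params.bwd, U[:, ::-1])
    s = np.concatenate([hf, hb], axis=1)
    logits = s @ params.W_fc.T + params.b_fc
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=1, keepdims=True)


def _loss_and_grads(
    params: _Params, U: np.ndarray, y: np.ndarray, l2: float
) -> tuple[float, dict[str, np.ndarray], np.ndarray]:
    """Mean cross-entropy (+ L2/2 penalty) and gradients for a batch."""
    B = U.shape[0]
    hf, cache_f = lstm_layer_forward(params.fwd, U, return_cache=True)
    Ub = U[:, ::-1]
    hb, cache_b = lstm_layer_forward(params.bwd, Ub, return_cache=True)
    s = np.concatenate([hf, hb], axis=1)
    logits = s @ params.W_fc.T + params.b_fc
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    p = e / e.sum(axis=1, keepdims=True)
    eps = 1e-12
    ce = -np.mean(np.log(p[np.arange(B), y] + eps))
    loss = ce + 0.5 * l2 * sum(float(np.sum(w * w)) for w in params.flat_weight_arrays())

    dlogits = p.copy()
    dlogits[np.arange(B), y] -= 1.0
    dlogits /= B
    dW_fc = dlogits.T @ s
    db_fc = dlogits.sum(axis=0)
    ds = dlogits @ params.W_fc
    hs = params.fwd.hidden_size
    gf, _ = _lstm_layer_backward(params.fwd, U, cache_f, ds[:, :hs])
    gb, _ = _lstm_layer_backward(params.bwd, Ub, cache_b, ds[:, hs:])
    grads = {
        "fwd_A": gf["A"] + l2 * params.fwd.A,
        "fwd_R": gf["R"] + l2 * params.fwd.R,
        "fwd_b": gf["b"],
        "bwd_A": gb["A"] + l2 * params.bwd.A,
        "bwd_R": gb["R"] + l2 * params.bwd.R,
        "bwd_b": gb["b"],
        "W_fc": dW_fc + l2 * params.W_fc,
        "b_fc": db_fc,
    }
    return float(loss), grads, p


def _clip_global_norm(grads: dict[str, np.ndarray], threshold: float) -> float:
    """Scale all gradients so their global L2 norm is at most ``threshold``."""
    total = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
    if total > threshold:
        scale = threshold / total
        for g in grads.values():
            g *= scale
        return threshold
    return total


def _stack_inputs(
    sequences: list[FeatureSequence], classes: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    ms = {fs.n_segments for fs in sequences}
    if len(ms) != 1:
        raise ValueError(f"all sequences in a batch must share M; got lengths {sorted(ms)}")
    qs = {fs.features.shape[1] for fs in sequences}
    if len(qs) != 1:
        raise ValueError("all sequences must share the feature dimension Q")
    U = np.stack([fs.features for fs in sequences])
    idx = {c: k for k, c in enumerate(classes)}
    try:
        y = np.array([idx[fs.label] for fs in sequences])
    except KeyError as err:
        raise ValueError(f"unknown class label {err.args[0]!r}") from None
    return U, y


class BiLSTMClassifier:
    """Bidirectional-LSTM sequence classification model (statsmodels-style).

    Parameters
    ----------
    sequences : list of FeatureSequence
        Training sequences; all must share M and Q.  Standardize first.
    config : TrainConfig, optional
        Architecture and optimizer settings.
    standardizer : StandardizationParams, optional
        Carried along for provenance/checkpointing; not applied here.

    Examples
    --------
    >>> model = BiLSTMClassifier(train_seqs, config=TrainConfig(hidden_size=8))
    >>> res = model.fit(seed=0)
    >>> res.predict(test_seqs)
    """

    def __init__(
        self,
        sequences: list[FeatureSequence],
        config: TrainConfig | None = None,
        standardizer: StandardizationParams | None = None,
    ) -> None:
        if not sequences:
            raise ValueError("training set is empty")
        self.config = config or TrainConfig()
        self.classes_ = sorted({fs.label for fs in sequences})
        if len(self.classes_) != 2:
            raise ValueError(f"need exactly two classes in training data, got {self.classes_}")
        self.endog, self.y_ = _stack_inputs(sequences, self.classes_)
        self.standardizer = standardizer

    def fit(self, seed: int | None = None) -> "BiLSTMResults":
        """Train with Adam; deterministic for a fixed seed.

        Returns a results object with the learned parameters and a per-epoch
        log of loss, training accuracy, post-clip gradient norm and wall
        time.
        """
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        rng = np.random.default_rng(seed)
        U_all, y_all = self.endog, self.y_
        n, _, q = U_all.shape
        params = _init_params(rng, cfg.hidden_size, q)

        arrays = params.all_arrays()
        m1 = {k: np.zeros_like(v) for k, v in arrays.items()}
        m2 = {k: np.zeros_like(v) for k, v in arrays.items()}
        step = 0
        bs = min(cfg.batch_size, n)
        log: list[dict] = []
        for epoch in range(1, cfg.max_epochs + 1):
            t0 = time.perf_counter()
            order = rng.permutation(n)
            losses, correct, max_norm = [], 0, 0.0
            for start in range(0, n, bs):
                idx = order[start : start + bs]
                loss, grads, p = _loss_and_grads(params, U_all[idx], y_all[idx], cfg.l2)
                norm = _clip_global_norm(grads, cfg.grad_clip)
                max_norm = max(max_norm, norm)
                step += 1
                bc1 = 1.0 - cfg.beta1**step
                bc2 = 1.0 - cfg.beta2**step
                arrays = params.all_arrays()
                for k, g in grads.items():
                    m1[k] = cfg.beta1 * m1[k] + (1 - cfg.beta1) * g
                    m2[k] = cfg.beta2 * m2[k] + (1 - cfg.beta2) * (g * g)
                    arrays[k] -= (
                        cfg.learning_rate * (m1[k] / bc1) / (np.sqrt(m2[k] / bc2) + cfg.eps)
                    )
                losses.append(loss * len(idx))
                correct += int(np.sum(p.argmax(axis=1) == y_all[idx]))
            log.append(
                {
                    "epoch": epoch,
                    "loss": sum(losses) / n,
                    "train_acc": correct / n,
                    "grad_norm_postclip": max_norm,
                    "epoch_seconds": time.perf_counter() - t0,
                }
            )
        return BiLSTMResults(model=self, params=params, training_log=log, seed=seed)


@dataclass
class BiLSTMResults:
    """Fit results: learned weights, training log, prediction and summary."""

    model: BiLSTMClassifier
    params: _Params
    training_log: list[dict]
    seed: int

    @property
    def final_loss(self) -> float:
        return self.training_log[-1]["loss"]

    @property
    def final_train_accuracy(self) -> float:
        return self.training_log[-1]["train_acc"]

    def predict_proba(self, sequences: list[FeatureSequence]) -> np.ndarray:
        """(n, 2) class probabilities, columns ordered as ``model.classes_``."""
        U = np.stack([fs.features for fs in sequences])
        return bilstm_forward(self.params, U)

    def predict(self, sequences: list[FeatureSequence]) -> list[tuple[str, float]]:
        """Winning class label and its probability for each sequence."""
        proba = self.predict_proba(sequences)
        out = []
        for row in proba:
            k = int(row.argmax())
            out.append((self.model.classes_[k], float(row[k])))
        return out

    def summary(self) -> str:
        cfg = self.model.config
        n, m, q = self.model.endog.shape
        lines = [
            "Bidirectional LSTM sequence classifier",
            "=" * 46,
            f"Observations:        {n}",
            f"Sequence length M:   {m}",
            f"Features Q:          {q}",
            f"Classes:             {self.model.classes_}",
            f"Hidden units:        {cfg.hidden_size} per direction",
            f"Optimizer:           Adam (lr={cfg.learning_rate}, L2={cfg.l2}, "
            f"clip={cfg.grad_clip})",
            f"Epochs:              {len(self.training_log)} (max {cfg.max_epochs}, "
            f"batch {cfg.batch_size})",
            f"Seed:                {self.seed}",
            "-" * 46,
            f"Final training loss: {self.final_loss:.6f}",
            f"Final training acc:  {self.final_train_accuracy:.4f}",
        ]
        return "\n".join(lines)

    def save(self, path: str) -> None:
        save_model(self, path)


def train(
    train_set: list[FeatureSequence], config: TrainConfig | None = None, seed: int | None = None
) -> BiLSTMResults:
    """Functional wrapper: build a :class:`BiLSTMClassifier` and fit it."""
    return BiLSTMClassifier(train_set, config=config).fit(seed=seed)


def predict(results: BiLSTMResults, sequences: list[FeatureSequence]):
    """Functional wrapper for :meth:`BiLSTMResults.predict`."""
    return results.predict(sequences)


def save_model(results: BiLSTMResults, path: str) -> None:
    """Checkpoint config, classes, weights, standardizer and seed to one .npz."""
    model = results.model
    meta = {
        "config": asdict(model.config),
        "classes": model.classes_,
        "seed": results.seed,
        "training_log": results.training_log,
    }
    arrays = dict(results.params.all_arrays())
    if model.standardizer is not None:
        arrays["std_mean"] = model.standardizer.mean
        arrays["std_sd"] = model.standardizer.sd
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_model(path: str) -> BiLSTMResults:
    """Restore a checkpoint written by :func:`save_model`."""
    data = np.load(path)
    meta = json.loads(bytes(data["meta"]).decode())
    params = _Params(
        fwd=LSTMWeights(A=data["fwd_A"], R=data["fwd_R"], b=data["fwd_b"]),
        bwd=LSTMWeights(A=data["bwd_A"], R=data["bwd_R"], b=data["bwd_b"]),
        W_fc=data["W_fc"],
        b_fc=data["b_fc"],
    )
    model = BiLSTMClassifier.__new__(BiLSTMClassifier)
    model.config = TrainConfig(**meta["config"])
    model.classes_ = list(meta["classes"])
    model.endog = np.zeros((1, 1, params.fwd.input_size))
    model.y_ = np.zeros(1, dtype=int)
    model.standardizer = (
        StandardizationParams(mean=data["std_mean"], sd=data["std_sd"])
        if "std_mean" in data
        else None
    )
    return BiLSTMResults(
        model=model, params=params, training_log=meta["training_log"], seed=meta["seed"]
    )
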