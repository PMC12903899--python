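"""Sequence-to-activity regressors.

Two regressors share a scikit-learn-style ``fit``/``predict`` surface over
(n, 4, N) one-hot inputs:

* :class:`HybridRegressor` -- the dual-branch convolutional/recurrent
  network: an initial convolutional block feeds both a stack of further
  convolutional blocks (local motif features) and a bidirectional GRU
  (sequential features); each branch passes through two dense layers with
  dropout before concatenation into a single linear output node.  Trained
  with Adam on mean squared error.
* :class:`LinearSurrogate` -- a closed-form ridge regression on the
  flattened one-hot features.  Deterministic and cheap, it is the
  workhorse for the data-curation sweeps, which need hundreds of fits and
  whose conclusions are about the data rather than the architecture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import Ridge

from . import _nn
from ._nn import Tensor

__all__ = [
    "ModelConfig",
    "HybridRegressor",
    "LinearSurrogate",
    "build_hybrid",
    "build_linear",
    "tiny_config",
    "TrainingDivergedError",
]


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""

    def __init__(self, epoch: int):
        super().__init__(f"training loss became non-finite at epoch {epoch}")
        self.epoch = epoch


@dataclass
class ModelConfig:
    """Hyper-parameters for the hybrid network.

    ``conv_blocks`` lists (filters, kernel, pool) triples; the first entry
    is the shared initial block, the remainder form the convolutional
    branch.  ``batch_size`` defaults to 1,024 and ``learning_rate`` to
    0.0005 (settings chosen for large screen datasets); the batch is
    clamped to the dataset size for small runs.  Training epochs are a
    tuned hyper-parameter, typically selected by cross-validation.
    """

    input_length: int = 37
    conv_blocks: tuple[tuple[int, int, int], ...] = ((32, 5, 2), (64, 3, 2), (64, 3, 2))
    gru_units: int = 32
    dense: tuple[int, int] = (64, 32)
    dropout: float = 0.3
    learning_rate: float = 0.0005
    batch_size: int = 1024
    epochs: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not self.conv_blocks:
            raise ValueError("need at least the initial convolutional block")


def tiny_config(input_length: int, seed: int = 0, epochs: int = 40) -> ModelConfig:
    """Small, fast configuration for desk-scale synthetic runs.

    The initial block uses pool width 1: positional base preferences are
    position-specific, and early pooling discards exactly that information
    on short windows.  Capacity is kept low (a few thousand parameters) so
    the network generalizes from a few thousand guides.
    """
    return ModelConfig(
        input_length=input_length,
        conv_blocks=((12, 3, 1), (16, 3, 1)),
        gru_units=8,
        dense=(16, 8),
        dropout=0.1,
        learning_rate=0.002,
        batch_size=128,
        epochs=epochs,
        seed=seed,
    )


class HybridRegressor:
    """Dual-branch CNN + bidirectional-GRU regression network.

    Labels are standardized internally during ``fit`` (predictions are
    returned in original score units); ``history_`` therefore records the
    per-epoch mean squared error on the standardized scale.
    """

    def __init__(self, config: ModelConfig):
        self.config = config
        self.history_: list[float] = []
        self._rng = np.random.default_rng(config.seed)
        self._build()

    # -- construction -------------------------------------------------

    def _build(self) -> None:
        cfg = self.config
        rng = self._rng
        length = cfg.input_length
        in_ch = 4
        self._conv: list[tuple[Tensor, Tensor, int]] = []
        for i, (filters, kernel, pool) in enumerate(cfg.conv_blocks):
            if length - kernel + 1 < 1:
                raise ValueError(
                    f"conv block {i}: kernel {kernel} exceeds remaining length {length}"
                )
            length = length - kernel + 1
            if length // pool < 1:
                raise ValueError(
                    f"conv block {i}: pooling by {pool} exhausts sequence of length {length}"
                )
            length //= pool
            w = _nn.glorot(rng, (filters, in_ch, kernel), in_ch * kernel, filters)
            b = _nn.zeros((filters,))
            self._conv.append((w, b, pool))
            if i == 0:
                self._shared_len = length
                self._shared_ch = filters
            in_ch = filters
        self._branch_a_flat = in_ch * length

        f0, k0, p0 = cfg.conv_blocks[0]
        self._gru_f = _nn.GRUCell(rng, self._shared_ch, cfg.gru_units)
        self._gru_b = _nn.GRUCell(rng, self._shared_ch, cfg.gru_units)

        d1, d2 = cfg.dense
        def dense_pair(n_in: int):
            w1 = _nn.glorot(rng, (n_in, d1), n_in, d1)
            b1 = _nn.zeros((d1,))
            w2 = _nn.glorot(rng, (d1, d2), d1, d2)
            b2 = _nn.zeros((d2,))
            return (w1, b1, w2, b2)

        self._dense_a = dense_pair(self._branch_a_flat)
        self._dense_b = dense_pair(2 * cfg.gru_units)
        self._w_out = _nn.glorot(rng, (2 * d2, 1), 2 * d2, 1)
        self._b_out = _nn.zeros((1,))

    @property
    def params(self) -> list[Tensor]:
        ps: list[Tensor] = []
        for w, b, _ in self._conv:
            ps += [w, b]
        ps += self._gru_f.params + self._gru_b.params
        for pack in (self._dense_a, self._dense_b):
            ps += list(pack)
        ps += [self._w_out, self._b_out]
        return ps

    @property
    def n_params_(self) -> int:
        return int(sum(p.data.size for p in self.params))

    # -- forward ------------------------------------------------------

    def _forward(self, x: np.ndarray, training: bool, rng: np.random.Generator) -> Tensor:
        cfg = self.config
        t = Tensor(x)
        w0, b0, p0 = self._conv[0]
        shared = _nn.maxpool1d(_nn.leaky_relu(_nn.conv1d(t, w0, b0)), p0)

        a = shared
        for w, b, pool in self._conv[1:]:
            a = _nn.maxpool1d(_nn.leaky_relu(_nn.conv1d(a, w, b)), pool)
        a = _nn.reshape(a, (x.shape[0], self._branch_a_flat))
        w1, b1, w2, b2 = self._dense_a
        a = _nn.dropout(_nn.leaky_relu(_nn.add(_nn.matmul(a, w1), b1)), cfg.dropout, rng, training)
        a = _nn.dropout(_nn.leaky_relu(_nn.add(_nn.matmul(a, w2), b2)), cfg.dropout, rng, training)

        steps = [
            _nn.take(shared, (slice(None), slice(None), ti)) for ti in range(self._shared_len)
        ]
        hf = self._gru_f.run(steps)
        hb = self._gru_b.run(steps[::-1])
        b_ = _nn.concat([hf, hb], axis=1)
        w1b, b1b, w2b, b2b = self._dense_b
        b_ = _nn.dropout(_nn.leaky_relu(_nn.add(_nn.matmul(b_, w1b), b1b)), cfg.dropout, rng, training)
        b_ = _nn.dropout(_nn.leaky_relu(_nn.add(_nn.matmul(b_, w2b), b2b)), cfg.dropout, rng, training)

        z = _nn.concat([a, b_], axis=1)
        out = _nn.add(_nn.matmul(z, self._w_out), self._b_out)
        return _nn.reshape(out, (x.shape[0],))

    # -- training / inference -----------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "HybridRegressor":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if X.ndim != 3 or X.shape[1] != 4 or X.shape[2] != self.config.input_length:
            raise ValueError(
                f"expected input of shape (n, 4, {self.config.input_length}), got {X.shape}"
            )
        if not np.isfinite(y).all():
            raise ValueError("labels must be finite")
        # standardize labels internally; predictions are mapped back to score units
        self._y_mean = float(y.mean())
        self._y_sd = float(y.std()) or 1.0
        y = (y - self._y_mean) / self._y_sd
        n = X.shape[0]
        batch = min(self.config.batch_size, n)
        opt = _nn.Adam(self.params, lr=self.config.learning_rate)
        rng = self._rng
        self.history_ = []
        for epoch in range(self.config.epochs):
            order = rng.permutation(n)
            losses, weights = [], []
            for start in range(0, n, batch):
                idx = order[start : start + batch]
                opt.zero_grad()
                pred = self._forward(X[idx], training=True, rng=rng)
                diff = _nn.sub(pred, Tensor(y[idx]))
                loss = _nn.mean_all(_nn.mul(diff, diff))
                if not np.isfinite(loss.data):
                    raise TrainingDivergedError(epoch)
                _nn.backward(loss)
                opt.step()
                losses.append(float(loss.data))
                weights.append(len(idx))
            self.history_.append(float(np.average(losses, weights=weights)))
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.shape[0] == 0:
            return np.empty(0)
        if X.ndim != 3 or X.shape[1] != 4 or X.shape[2] != self.config.input_length:
            raise ValueError(
                f"expected input of shape (n, 4, {self.config.input_length}), got {X.shape}"
            )
        out = []
        rng = np.random.default_rng(0)  # unused in eval mode
        for start in range(0, X.shape[0], 1024):
            out.append(self._forward(X[start : start + 1024], training=False, rng=rng).data)
        pred = np.concatenate(out)
        if hasattr(self, "_y_mean"):
            pred = pred * self._y_sd + self._y_mean
        return pred


class LinearSurrogate:
    """Ridge regression on flattened 4 x N one-hot features (closed form)."""

    def __init__(self, alpha: float = 1.0):
        if alpha <= 0:
            raise ValueError("ridge penalty must be > 0")
        self.alpha = alpha
        self._ridge = Ridge(alpha=alpha, solver="cholesky")
        self._shape: tuple[int, int] | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LinearSurrogate":
        X = np.asarray(X, dtype=float)
        self._shape = X.shape[1:]
        self._ridge.fit(X.reshape(X.shape[0], -1), np.asarray(y, dtype=float))
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[0] == 0:
            return np.empty(0)
        if self._shape is not None and X.shape[1:] != self._shape:
            raise ValueError(f"input shape {X.shape[1:]} does not match training shape {self._shape}")
        return self._ridge.predict(X.reshape(X.shape[0], -1))

    @property
    def coef_matrix_(self) -> np.ndarray:
        """Learned weights reshaped to (4, N), matching the one-hot layout."""
        if self._shape is None:
            raise ValueError("model is not fitted")
        return self._ridge.coef_.reshape(self._shape)

    def training_mse(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean((self.predict(X) - np.asarray(y, dtype=float)) ** 2))


def build_hybrid(config: ModelConfig) -> HybridRegressor:
    """Construct (and shape-validate) the hybrid network for a given input length."""
    return HybridRegressor(config)


def build_linear(alpha: float = 1.0) -> LinearSurrogate:
    return LinearSurrogate(alpha=alpha)
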