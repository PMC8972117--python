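"""Minimal dense neural network for tabular regression, in numpy.

Architecture and training follow the configuration used throughout this
package: a single ReLU hidden layer (default 128 nodes) with inverted
dropout, He-uniform initialization, mean-absolute-error loss, the Adam
optimizer, and early stopping on validation MAE with best-weight restore.
A single seed drives initialization, minibatch shuffling and dropout
masks, so training is bit-reproducible on one thread.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["AnnConfig", "DenseRegressor"]


@dataclass(frozen=True)
class AnnConfig:
    """Hyperparameters of the dense age regressor.

    Defaults are the optimal configuration used by the package: 78 inputs,
    one hidden layer of 128 ReLU nodes, dropout 0.5, He-uniform init, MAE
    loss, Adam at learning rate 0.001, early-stopping patience 50 epochs.
    ``max_epochs`` and ``batch_size`` bound the training loop.
    """

    n_input: int = 78
    hidden_nodes: int = 128
    dropout_p: float = 0.5
    learning_rate: float = 1e-3
    early_stopping_patience: int = 50
    max_epochs: int = 500
    batch_size: int = 32
    seed: int = 0

    def with_seed(self, seed: int) -> "AnnConfig":
        return replace(self, seed=int(seed))


@dataclass
class _AdamState:
    m: list[np.ndarray]
    v: list[np.ndarray]
    t: int = 0


class DenseRegressor:
    """78 -> hidden (ReLU, dropout) -> 1 regressor trained with Adam on MAE.

    Dropout is active only during training (inverted scaling); prediction
    is a deterministic forward pass.
    """

    def __init__(self, config: AnnConfig):
        self.config = config
        self._rng = np.random.default_rng(config.seed)
        h, d = config.hidden_nodes, config.n_input
        # He-uniform: U(-sqrt(6/fan_in), +sqrt(6/fan_in))
        lim1 = np.sqrt(6.0 / d)
        lim2 = np.sqrt(6.0 / h)
        self.W1 = self._rng.uniform(-lim1, lim1, (d, h))
        self.b1 = np.zeros(h)
        self.W2 = self._rng.uniform(-lim2, lim2, (h, 1))
        self.b2 = np.zeros(1)
        self._adam = _AdamState(
            m=[np.zeros_like(p) for p in self._params()],
            v=[np.zeros_like(p) for p in self._params()],
        )
        self.history_: dict[str, list[float]] = {"train_mae": [], "val_mae": []}
        self.best_epoch_: int | None = None

    # -- parameters ------------------------------------------------------
    def _params(self) -> list[np.ndarray]:
        return [self.W1, self.b1, self.W2, self.b2]

    def _set_params(self, params: list[np.ndarray]) -> None:
        self.W1, self.b1, self.W2, self.b2 = [p.copy() for p in params]

    # -- forward / backward ---------------------------------------------
    def predict(self, X: np.ndarray) -> np.ndarray:
        """Deterministic forward pass; returns shape (n,)."""
        X = np.asarray(X, dtype=float)
        h = np.maximum(X @ self.W1 + self.b1, 0.0)
        return (h @ self.W2 + self.b2).ravel()

    def _step(self, X: np.ndarray, y: np.ndarray) -> float:
        cfg = self.config
        n = X.shape[0]
        z1 = X @ self.W1 + self.b1
        h = np.maximum(z1, 0.0)
        if cfg.dropout_p > 0:
            keep = 1.0 - cfg.dropout_p
            mask = (self._rng.random(h.shape) < keep) / keep
            hd = h * mask
        else:
            mask = None
            hd = h
        out = (hd @ self.W2 + self.b2).ravel()
        resid = out - y
        loss = float(np.mean(np.abs(resid)))

        g_out = np.sign(resid)[:, None] / n
        gW2 = hd.T @ g_out
        gb2 = g_out.sum(axis=0)
        g_hd = g_out @ self.W2.T
        if mask is not None:
            g_hd = g_hd * mask
        g_z1 = g_hd * (z1 > 0)
        gW1 = X.T @ g_z1
        gb1 = g_z1.sum(axis=0)

        self._adam.t += 1
        t = self._adam.t
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        for p, g, m, v in zip(
            self._params(), [gW1, gb1, gW2, gb2], self._adam.m, self._adam.v
        ):
            m[:] = beta1 * m + (1 - beta1) * g
            v[:] = beta2 * v + (1 - beta2) * g**2
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            p -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
        return loss

    # -- training --------------------------------------------------------
    def fit(
        self,
        X_train: np.ndarray,
        y_train: np.ndarray,
        X_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
    ) -> "DenseRegressor":
        """Train with minibatch Adam; early-stop on validation MAE.

        When a validation set is given, training stops once validation MAE
        has not improved for ``early_stopping_patience`` epochs and the
        weights of the best (earliest, on ties) epoch are restored.
        Non-finite inputs are rejected.
        """
        X_train = np.asarray(X_train, dtype=float)
        y_train = np.asarray(y_train, dtype=float).ravel()
        arrays = [X_train, y_train]
        if X_val is not None:
            X_val = np.asarray(X_val, dtype=float)
            y_val = np.asarray(y_val, dtype=float).ravel()
            arrays += [X_val, y_val]
        for a in arrays:
            if not np.all(np.isfinite(a)):
                raise ValueError("non-finite values in training data")

        cfg = self.config
        n = X_train.shape[0]
        if self._adam.t == 0:
            # start the output at the training-target mean: with MAE loss and
            # a small Adam step the bias otherwise crawls toward it for
            # thousands of steps before any shape learning happens
            self.b2[:] = float(np.mean(y_train))
        best_val = np.inf
        best_params: list[np.ndarray] | None = None
        patience_left = cfg.early_stopping_patience

        for epoch in range(cfg.max_epochs):
            order = self._rng.permutation(n)
            losses = []
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                losses.append(self._step(X_train[idx], y_train[idx]))
            self.history_["train_mae"].append(float(np.mean(losses)))

            if X_val is not None and X_val.shape[0] > 0:
                val_mae = float(np.mean(np.abs(self.predict(X_val) - y_val)))
                self.history_["val_mae"].append(val_mae)
                if val_mae < best_val:  # strict: ties keep the earlier epoch
                    best_val = val_mae
                    best_params = [p.copy() for p in self._params()]
                    self.best_epoch_ = epoch
                    patience_left = cfg.early_stopping_patience
                else:
                    patience_left -= 1
                    if patience_left <= 0:
                        break
        if best_params is not None:
            self._set_params(best_params)
        return self
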