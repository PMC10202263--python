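"""Projection-head probing of inversion latents.

A shallow MLP (1-3 layers, 512 hidden units, ReLU, sigmoid output, no
batch normalization anywhere) trained with binary cross-entropy, full-batch
Adam at learning rate 0.001 for 200 epochs — the linear-probing protocol
used to measure how much disease signal the frozen generative features
carry. Also provides the sample-size/depth stress-test harness.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from ._autodiff import DTYPE, Tensor, grad, no_grad
from .nn import Adam, Dense
from .evaluate import auroc


class LatentProbe(BaseEstimator, ClassifierMixin):
    """Shallow MLP classifier over latent features (sklearn estimator API).

    Parameters
    ----------
    n_layers:
        Total affine layers, 1-3. ``1`` is a logistic probe; deeper heads
        insert 512-unit ReLU hidden layers. No batch normalization.
    standardize:
        Per-dimension z-scoring fit on the training rows; stabilizes
        full-batch optimization at the small fixed learning rate.
    """

    def __init__(self, n_layers: int = 2, hidden_dim: int = 512,
                 epochs: int = 200, lr: float = 0.001, seed: int = 0,
                 standardize: bool = True):
        self.n_layers = n_layers
        self.hidden_dim = hidden_dim
        self.epochs = epochs
        self.lr = lr
        self.seed = seed
        self.standardize = standardize

    # -- internals ----------------------------------------------------------
    def _validate(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be (n, d) aligned with y")
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training labels contain a single class")
        if not np.isin(classes, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
        counts = np.bincount(y.astype(int), minlength=2)
        if counts[0] != counts[1]:
            warnings.warn(
                f"probe expects a 1:1 balanced set; got {counts[0]}:{counts[1]}",
                stacklevel=3,
            )
        if self.n_layers not in (1, 2, 3):
            raise ValueError("n_layers must be 1, 2 or 3")
        return X, y.astype(int)

    def _forward(self, X: np.ndarray) -> Tensor:
        h = Tensor(X.astype(DTYPE))
        for layer in self.layers_[:-1]:
            h = layer(h).leaky_relu(0.0)          # plain ReLU
        return self.layers_[-1](h)                # logits

    # -- sklearn API --------------------------------------------------------
    def fit(self, X, y):
        X, y = self._validate(X, y)
        if self.standardize:
            self.mean_ = X.mean(axis=0)
            scale = X.std(axis=0)
            self.scale_ = np.where(scale > 0, scale, 1.0)
        else:
            self.mean_ = np.zeros(X.shape[1])
            self.scale_ = np.ones(X.shape[1])
        Xs = (X - self.mean_) / self.scale_

        rng = np.random.default_rng(self.seed)
        dims = (
            [X.shape[1]]
            + [self.hidden_dim] * (self.n_layers - 1)
            + [1]
        )
        self.layers_ = [
            Dense(dims[i], dims[i + 1], rng) for i in range(self.n_layers)
        ]
        params = [p for layer in self.layers_ for p in layer.parameters()]
        opt = Adam(params, self.lr)
        yt = Tensor(y.astype(DTYPE).reshape(-1, 1))

        # BCE via the numerically stable softplus form:
        # mean( softplus(logit) - y * logit )
        for _ in range(self.epochs):
            logits = self._forward(Xs)
            loss = (logits.softplus() - yt * logits).mean()
            opt.step(grad(loss, params))
        self.final_bce_ = float(loss.data)
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError("feature dimension mismatch")
        Xs = (X - self.mean_) / self.scale_
        with no_grad():
            return self._forward(Xs).data.ravel().astype(np.float64)

    def predict_proba(self, X):
        p = 1.0 / (1.0 + np.exp(-self.decision_function(X)))
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        return (self.decision_function(X) >= 0.0).astype(int)

    def score_samples(self, X):
        """Sigmoid likelihood of disease in (0, 1), the screening score."""
        return self.predict_proba(X)[:, 1]


def train_probe(latents, labels, **params) -> LatentProbe:
    """Functional wrapper: fit a :class:`LatentProbe` on a latent table."""
    return LatentProbe(**params).fit(latents, labels)


def predict(model: LatentProbe, latents) -> np.ndarray:
    """Disease likelihoods in (0, 1) for a fitted probe."""
    return model.score_samples(latents)


def _balanced_subsample(y: np.ndarray, n: int, rng: np.random.Generator):
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if n // 2 > min(pos.size, neg.size):
        raise ValueError("not enough rows per class for the requested n")
    take_pos = rng.choice(pos, size=n // 2, replace=False)
    take_neg = rng.choice(neg, size=n - n // 2, replace=False)
    idx = np.concatenate([take_pos, take_neg])
    rng.shuffle(idx)
    return idx


def stress_test(
    train_latents, train_labels, test_latents, test_labels,
    layer_grid: Sequence[int] = (1, 2, 3),
    n_grid: Optional[Sequence[int]] = None,
    seeds: Sequence[int] = (0,),
    probe_params: Optional[dict] = None,
) -> pd.DataFrame:
    """AUROC grid over head depth and training-set size.

    For each (n_layers, n, seed): train on a seeded balanced subsample of
    the downstream latents and evaluate AUROC on the held-out test split.
    Sizes start at 32 and double by default; sizes exceeding the available
    balanced rows are skipped with a warning.
    """
    X = np.asarray(train_latents, dtype=np.float64)
    y = np.asarray(train_labels, dtype=int)
    Xt = np.asarray(test_latents, dtype=np.float64)
    yt = np.asarray(test_labels, dtype=int)
    max_n = 2 * min(np.sum(y == 1), np.sum(y == 0))
    if n_grid is None:
        n_grid = []
        n = 32
        while n <= max_n:
            n_grid.append(n)
            n *= 2

    rows = []
    for n in n_grid:
        if n > max_n:
            warnings.warn(f"skipping n={n}: only {max_n} balanced rows available")
            continue
        for n_layers in layer_grid:
            for seed in seeds:
                rng = np.random.default_rng(seed)
                idx = _balanced_subsample(y, n, rng)
                probe = LatentProbe(
                    n_layers=n_layers, seed=seed, **(probe_params or {})
                )
                probe.fit(X[idx], y[idx])
                rows.append(
                    dict(
                        layers=n_layers, n=n, seed=seed,
                        auroc=auroc(probe.score_samples(Xt), yt),
                    )
                )
    return pd.DataFrame(rows)
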