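"""SAR-to-optical biomass transfer network.

Biomass retrieved from C-band backscatter and biomass estimated from optical
vegetation indices sit on systematically different scales.  A small
feed-forward network — one input (SAR biomass), 10 tanh hidden units, one
linear output — is trained to map one onto the other so that biomass can be
monitored regardless of which satellite supplied the estimate.

Training follows the classic curve-fitting recipe: inputs and targets are
min-max normalized to [-1, 1], weights start from a seeded uniform(-1, 1)
draw, and the squared error on the training split is minimized by
Levenberg-Marquardt.  Of n supplied pairs, ceil(0.7 * n) are used for
training and the remainder held out purely for reporting (no early
stopping): 23 pairs give the 17/6 split.  Applied outputs pass through an
absolute value, so adjusted biomass is always non-negative.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from ._optim import levenberg_marquardt

__all__ = ["TransferNetwork", "train_transfer", "apply_transfer", "split_sizes"]


def split_sizes(n: int, train_fraction: float = 0.7) -> tuple[int, int]:
    """(train, holdout) sizes: training takes ceil(train_fraction * n)."""
    n_train = math.ceil(train_fraction * n)
    return n_train, n - n_train


def _normalize(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    if hi == lo:
        raise ValueError("cannot normalize a constant vector to [-1, 1]")
    return 2.0 * (x - lo) / (hi - lo) - 1.0


def _denormalize(z: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return (z + 1.0) / 2.0 * (hi - lo) + lo


class TransferNetwork(BaseEstimator, RegressorMixin):
    """1-H-1 tanh network trained by Levenberg-Marquardt.

    Parameters
    ----------
    n_hidden : int
        Hidden tanh units (default 10).
    train_fraction : float
        Fraction of pairs used for training; the split takes
        ``ceil(train_fraction * n)`` shuffled by ``random_state``.
    max_iter : int
        Levenberg-Marquardt iteration cap.
    tol : float
        Gradient/step tolerance stopping the training.
    random_state : int
        Seeds both the split shuffle and the weight initialization.

    Fitted attributes (normalized scale unless noted): ``hidden_weights_``,
    ``hidden_bias_`` (each shape (n_hidden,)), ``output_weights_`` (shape
    (n_hidden,)), ``output_bias_`` (scalar), ``input_scaling_`` /
    ``output_scaling_`` ((min, max) pairs in physical units), ``train_idx_``,
    ``holdout_idx_``, ``train_mse_``, ``holdout_mse_`` (normalized scale),
    ``initial_train_sse_``, ``n_iter_``.
    """

    def __init__(
        self,
        n_hidden: int = 10,
        train_fraction: float = 0.7,
        max_iter: int = 1000,
        tol: float = 1e-7,
        random_state: int = 0,
    ):
        self.n_hidden = n_hidden
        self.train_fraction = train_fraction
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    # -- parameter vector layout: [w1 (H), b1 (H), w2 (H), b2 (1)] ----------
    def _unpack(self, w: np.ndarray):
        H = self.n_hidden
        return w[:H], w[H: 2 * H], w[2 * H: 3 * H], w[3 * H]

    @staticmethod
    def _forward_normalized(x: np.ndarray, w1, b1, w2, b2) -> np.ndarray:
        # x: (n,) -> hidden (n, H) -> output (n,)
        h = np.tanh(np.outer(x, w1) + b1)
        return h @ w2 + b2

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        t = np.asarray(y, dtype=float).reshape(-1)
        if x.shape != t.shape:
            raise ValueError("input and target biomass lists must have equal length")
        if len(x) < 2:
            raise ValueError("at least two pairs are needed to train the network")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(t))):
            raise ValueError("inputs and targets must be finite")

        self.input_scaling_ = (float(x.min()), float(x.max()))
        self.output_scaling_ = (float(t.min()), float(t.max()))
        xn = _normalize(x, *self.input_scaling_)
        tn = _normalize(t, *self.output_scaling_)

        rng = np.random.default_rng(self.random_state)
        n_train, n_holdout = split_sizes(len(x), self.train_fraction)
        order = rng.permutation(len(x))
        self.train_idx_ = np.sort(order[:n_train])
        self.holdout_idx_ = np.sort(order[n_train:])
        xt, tt = xn[self.train_idx_], tn[self.train_idx_]

        H = self.n_hidden
        w0 = rng.uniform(-1.0, 1.0, size=3 * H + 1)

        def residual(w):
            w1, b1, w2, b2 = self._unpack(w)
            return self._forward_normalized(xt, w1, b1, w2, b2) - tt

        def jacobian(w):
            w1, b1, w2, b2 = self._unpack(w)
            a = np.outer(xt, w1) + b1          # (n, H)
            h = np.tanh(a)
            dh = 1.0 - h ** 2                  # (n, H)
            d_w1 = dh * w2 * xt[:, None]       # (n, H)
            d_b1 = dh * w2                     # (n, H)
            d_w2 = h                           # (n, H)
            d_b2 = np.ones((len(xt), 1))
            return np.hstack([d_w1, d_b1, d_w2, d_b2])

        res = levenberg_marquardt(
            residual,
            jacobian,
            w0,
            max_iter=self.max_iter,
            grad_tol=self.tol,
            step_tol=self.tol,
        )
        w1, b1, w2, b2 = self._unpack(res.x)
        self.hidden_weights_ = w1.copy()
        self.hidden_bias_ = b1.copy()
        self.output_weights_ = w2.copy()
        self.output_bias_ = float(b2)
        self.n_iter_ = res.n_iter
        self.converged_ = res.converged
        self.initial_train_sse_ = res.initial_sse
        self.train_mse_ = res.sse / len(xt)
        if n_holdout:
            pred_h = self._forward_normalized(
                xn[self.holdout_idx_], w1, b1, w2, b2
            )
            self.holdout_mse_ = float(np.mean((pred_h - tn[self.holdout_idx_]) ** 2))
        else:
            self.holdout_mse_ = float("nan")
        self.n_train_ = n_train
        self.n_holdout_ = n_holdout
        return self

    def predict(self, X):
        """Adjusted biomass: normalize, forward pass, denormalize, abs."""
        if not hasattr(self, "hidden_weights_"):
            raise AttributeError("TransferNetwork must be fitted before predicting")
        x = np.asarray(X, dtype=float).reshape(-1)
        xn = _normalize(x, *self.input_scaling_)
        out = self._forward_normalized(
            xn,
            self.hidden_weights_,
            self.hidden_bias_,
            self.output_weights_,
            self.output_bias_,
        )
        return np.abs(_denormalize(out, *self.output_scaling_))

    def output_bound(self) -> float:
        """Upper bound on |prediction| for ANY input.

        The tanh layer saturates, so the normalized output magnitude never
        exceeds sum(|w2|) + |b2|; denormalizing bounds the physical output.
        """
        if not hasattr(self, "hidden_weights_"):
            raise AttributeError("TransferNetwork must be fitted first")
        zmax = float(np.sum(np.abs(self.output_weights_)) + abs(self.output_bias_))
        lo, hi = self.output_scaling_
        return max(abs(_denormalize(np.array(zmax), lo, hi)),
                   abs(_denormalize(np.array(-zmax), lo, hi)))

    # -- serialization -------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        if not hasattr(self, "hidden_weights_"):
            raise AttributeError("TransferNetwork must be fitted before saving")
        payload = {
            "n_hidden": self.n_hidden,
            "train_fraction": self.train_fraction,
            "max_iter": self.max_iter,
            "tol": self.tol,
            "random_state": self.random_state,
            "hidden_weights": self.hidden_weights_.tolist(),
            "hidden_bias": self.hidden_bias_.tolist(),
            "output_weights": self.output_weights_.tolist(),
            "output_bias": self.output_bias_,
            "input_scaling": list(self.input_scaling_),
            "output_scaling": list(self.output_scaling_),
            "train_idx": self.train_idx_.tolist(),
            "holdout_idx": self.holdout_idx_.tolist(),
            "train_mse": self.train_mse_,
            "holdout_mse": self.holdout_mse_,
            "n_iter": self.n_iter_,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TransferNetwork":
        payload = json.loads(Path(path).read_text())
        net = cls(
            n_hidden=payload["n_hidden"],
            train_fraction=payload["train_fraction"],
            max_iter=payload["max_iter"],
            tol=payload["tol"],
            random_state=payload["random_state"],
        )
        net.hidden_weights_ = np.asarray(payload["hidden_weights"], dtype=float)
        net.hidden_bias_ = np.asarray(payload["hidden_bias"], dtype=float)
        net.output_weights_ = np.asarray(payload["output_weights"], dtype=float)
        net.output_bias_ = float(payload["output_bias"])
        net.input_scaling_ = tuple(payload["input_scaling"])
        net.output_scaling_ = tuple(payload["output_scaling"])
        net.train_idx_ = np.asarray(payload["train_idx"], dtype=int)
        net.holdout_idx_ = np.asarray(payload["holdout_idx"], dtype=int)
        net.train_mse_ = float(payload["train_mse"])
        net.holdout_mse_ = float(payload["holdout_mse"])
        net.n_iter_ = int(payload["n_iter"])
        net.n_train_ = len(net.train_idx_)
        net.n_holdout_ = len(net.holdout_idx_)
        return net


def train_transfer(
    sar_biomass: Sequence[float],
    optical_biomass: Sequence[float],
    hidden: int = 10,
    train_fraction: float = 0.7,
    seed: int = 0,
    max_iter: int = 1000,
) -> TransferNetwork:
    """Train the SAR-to-optical transfer network on paired estimates."""
    net = TransferNetwork(
        n_hidden=hidden,
        train_fraction=train_fraction,
        max_iter=max_iter,
        random_state=seed,
    )
    return net.fit(sar_biomass, optical_biomass)


def apply_transfer(net: TransferNetwork, sar_biomass: Sequence[float]) -> np.ndarray:
    """Adjust SAR biomass estimates onto the optical scale (non-negative)."""
    return net.predict(sar_biomass)
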