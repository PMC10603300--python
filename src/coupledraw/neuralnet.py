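"""Shallow 3600-100-1 feedforward CI regressor.

A single-hidden-layer network (tanh hidden units, identity output) is
trained by full-batch gradient descent on mean squared error with momentum
and a variable learning rate: after an epoch whose training error
decreased, the rate grows by ``lr_inc``; a step that increases the error by
more than ``max_perf_inc`` is rejected outright, the rate shrinks by
``lr_dec`` and momentum is suppressed for that step.  Training halts by
early stopping — ``patience`` consecutive epochs without a new best
validation error — and returns the best-validation parameters.

The session-level procedure repeats, for ``n_iter`` random 85/5/10
train/validation/test splits: fresh initialisation, input scaling to
[-1, 1] fitted on the training set only, training with early stopping, and
recording of the test-set predictions.  Each trial's final prediction is
the mean over the iterations in which it fell in the test set; a coverage
check enforces at least ``min_appearances`` test appearances per trial,
extending the iteration budget if needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import substream


@dataclass
class ShallowNet:
    """Weights and biases of the input-hidden-output regressor."""

    W1: np.ndarray  # (hidden, input)
    b1: np.ndarray  # (hidden,)
    W2: np.ndarray  # (1, hidden)
    b2: np.ndarray  # (1,)

    def __post_init__(self) -> None:
        h, d = self.W1.shape
        if self.b1.shape != (h,) or self.W2.shape != (1, h) or self.b2.shape != (1,):
            raise ValueError("inconsistent parameter shapes")
        for p in (self.W1, self.b1, self.W2, self.b2):
            if not np.all(np.isfinite(p)):
                raise ValueError("non-finite parameters")

    @property
    def input_dim(self) -> int:
        return self.W1.shape[1]

    @property
    def hidden_dim(self) -> int:
        return self.W1.shape[0]

    def copy(self) -> "ShallowNet":
        return ShallowNet(self.W1.copy(), self.b1.copy(), self.W2.copy(), self.b2.copy())


@dataclass(frozen=True)
class TrainConfig:
    """Variable-learning-rate backpropagation hyperparameters."""

    lr0: float = 0.01
    lr_inc: float = 1.05
    lr_dec: float = 0.7
    max_perf_inc: float = 1.04
    momentum: float = 0.9
    max_epochs: int = 300
    patience: int = 20

    def __post_init__(self) -> None:
        if not (self.lr_inc > 1 > self.lr_dec > 0):
            raise ValueError("need lr_inc > 1 > lr_dec > 0")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must lie in [0, 1)")


#: Nguyen-Widrow-style overlap factor for the hidden layer.
INIT_BETA = 0.7


def init_network(input_dim: int, hidden_dim: int, rng: np.random.Generator) -> ShallowNet:
    """Nguyen-Widrow-style initialisation for [-1, 1]-scaled inputs.

    Hidden weight rows are random directions of norm ``INIT_BETA`` with
    biases spread uniformly over (-INIT_BETA, INIT_BETA), which places the
    tanh units' active regions across the input range; the linear readout
    starts small and symmetric.
    """
    W1 = rng.standard_normal((hidden_dim, input_dim))
    W1 *= INIT_BETA / np.linalg.norm(W1, axis=1, keepdims=True)
    s2 = 1.0 / np.sqrt(hidden_dim)
    return ShallowNet(
        W1=W1,
        b1=rng.uniform(-INIT_BETA, INIT_BETA, size=hidden_dim),
        W2=rng.uniform(-s2, s2, size=(1, hidden_dim)),
        b2=rng.uniform(-s2, s2, size=1),
    )


def forward(net: ShallowNet, X: np.ndarray) -> np.ndarray:
    """Predictions for X of shape (n, input_dim) or a single vector."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != net.input_dim:
        raise ValueError(f"expected input dim {net.input_dim}, got {X.shape[1]}")
    H = np.tanh(X @ net.W1.T + net.b1)
    y = H @ net.W2.T + net.b2
    return y[:, 0]


def loss_and_grads(net: ShallowNet, X: np.ndarray, y: np.ndarray
                   ) -> tuple[float, dict[str, np.ndarray]]:
    """Full-batch MSE and its analytic gradients."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    H = np.tanh(X @ net.W1.T + net.b1)
    pred = (H @ net.W2.T + net.b2)[:, 0]
    err = pred - y
    mse = float(np.mean(err**2))
    d_out = (2.0 / n) * err[:, None]               # (n, 1)
    gW2 = d_out.T @ H                               # (1, hidden)
    gb2 = d_out.sum(axis=0)                         # (1,)
    dH = (d_out @ net.W2) * (1.0 - H**2)            # (n, hidden)
    gW1 = dH.T @ X                                  # (hidden, input)
    gb1 = dH.sum(axis=0)                            # (hidden,)
    return mse, {"W1": gW1, "b1": gb1, "W2": gW2, "b2": gb2}


@dataclass
class _OptState:
    lr: float
    velocity: dict[str, np.ndarray]


def backprop_step(net: ShallowNet, X: np.ndarray, y: np.ndarray,
                  state: _OptState, cfg: TrainConfig) -> tuple[ShallowNet, _OptState, float]:
    """One variable-learning-rate epoch.

    Proposes a momentum gradient step; if the new MSE exceeds the old by
    more than ``max_perf_inc`` the step is rejected, the learning rate
    shrinks and the momentum memory is cleared.  If the MSE decreased, the
    learning rate grows.  Returns (net, state, current training MSE).
    """
    mse_old, grads = loss_and_grads(net, X, y)
    if not np.isfinite(mse_old):
        raise FloatingPointError("non-finite training loss")
    mc = cfg.momentum
    vel = {
        k: mc * state.velocity[k] - (1 - mc) * state.lr * g
        for k, g in grads.items()
    }
    candidate = ShallowNet(
        W1=net.W1 + vel["W1"], b1=net.b1 + vel["b1"],
        W2=net.W2 + vel["W2"], b2=net.b2 + vel["b2"],
    )
    mse_new, _ = loss_and_grads(candidate, X, y)
    if mse_new > mse_old * cfg.max_perf_inc:
        # reject: keep old parameters, damp the rate, forget momentum
        state = _OptState(lr=state.lr * cfg.lr_dec,
                          velocity={k: np.zeros_like(v) for k, v in vel.items()})
        return net, state, mse_old
    lr = state.lr * cfg.lr_inc if mse_new < mse_old else state.lr
    return candidate, _OptState(lr=lr, velocity=vel), mse_new


@dataclass
class TrainingTrace:
    train_mse: list[float] = field(default_factory=list)
    val_mse: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stop_reason: str = ""

    @property
    def epochs_run(self) -> int:
        return len(self.train_mse)


def train(net: ShallowNet, X_train: np.ndarray, y_train: np.ndarray,
          X_val: np.ndarray, y_val: np.ndarray, cfg: TrainConfig
          ) -> tuple[ShallowNet, TrainingTrace]:
    """Train with early stopping; returns the best-validation parameters."""
    if len(y_train) == 0 or len(y_val) == 0:
        raise ValueError("train and validation sets must be non-empty")
    state = _OptState(lr=cfg.lr0, velocity={
        "W1": np.zeros_like(net.W1), "b1": np.zeros_like(net.b1),
        "W2": np.zeros_like(net.W2), "b2": np.zeros_like(net.b2),
    })
    trace = TrainingTrace()
    best = net.copy()
    best_val = np.inf
    fails = 0
    for epoch in range(cfg.max_epochs):
        net, state, mse = backprop_step(net, X_train, y_train, state, cfg)
        val = float(np.mean((forward(net, X_val) - y_val) ** 2))
        trace.train_mse.append(mse)
        trace.val_mse.append(val)
        if val < best_val:
            best_val = val
            best = net.copy()
            trace.best_epoch = epoch
            fails = 0
        else:
            fails += 1
            if fails >= cfg.patience:
                trace.stop_reason = "early_stopping"
                break
    else:
        trace.stop_reason = "max_epochs"
    return best, trace


# ---------------------------------------------------------------------------
# input scaling


class FeatureScaler:
    """Per-feature affine map to [-1, 1], fitted on the training set only.

    Values outside the training range map outside [-1, 1] (no clipping);
    constant features map to 0.
    """

    def fit(self, X: np.ndarray) -> "FeatureScaler":
        X = np.asarray(X, dtype=float)
        self.min_ = X.min(axis=0)
        self.max_ = X.max(axis=0)
        span = self.max_ - self.min_
        self.constant_ = span == 0
        self.span_ = np.where(self.constant_, 1.0, span)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = 2.0 * (X - self.min_) / self.span_ - 1.0
        out[:, self.constant_] = 0.0
        return out

    def inverse_transform(self, Xs: np.ndarray) -> np.ndarray:
        Xs = np.asarray(Xs, dtype=float)
        out = (Xs + 1.0) / 2.0 * self.span_ + self.min_
        out[:, self.constant_] = self.min_[self.constant_]
        return out


# ---------------------------------------------------------------------------
# iterated random splits


@dataclass(frozen=True)
class SplitScheme:
    """Disjoint train/validation/test index sets covering all trials."""

    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray

    def __post_init__(self) -> None:
        allidx = np.concatenate([self.train_idx, self.val_idx, self.test_idx])
        if len(np.unique(allidx)) != len(allidx):
            raise ValueError("split sets must be disjoint")


def make_split(n: int, fractions: tuple[float, float, float],
               rng: np.random.Generator) -> SplitScheme:
    """Random split by rounded fractions; remainder goes to the training set.

    For 240 trials at (0.85, 0.05, 0.10) every split is exactly 204/12/24.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n_val = int(round(n * fractions[1]))
    n_test = int(round(n * fractions[2]))
    n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(f"n={n} too small for fractions {fractions}")
    perm = rng.permutation(n)
    return SplitScheme(
        train_idx=np.sort(perm[:n_train]),
        val_idx=np.sort(perm[n_train:n_train + n_val]),
        test_idx=np.sort(perm[n_train + n_val:]),
    )


@dataclass
class ANNResult:
    """Outcome of the iterated-split procedure."""

    predictions: pd.DataFrame   # trial_id, mean_predicted_ci, n_test_appearances
    iterations: pd.DataFrame    # iteration, r_test, epochs_run, stop_reason
    mean_r: float
    n_iterations: int


def iterate_splits(features: pd.DataFrame, ci: pd.Series, *,
                   n_iter: int = 1000,
                   fractions: tuple[float, float, float] = (0.85, 0.05, 0.10),
                   hidden_dim: int = 100,
                   cfg: TrainConfig = TrainConfig(),
                   seed: int = 0,
                   min_appearances: int = 5,
                   max_extra_iter: int | None = None) -> ANNResult:
    """Random-split prediction averaging.

    ``features`` is a trials x features DataFrame indexed by trial_id;
    ``ci`` the aligned per-trial coupling index.  Per iteration: fresh
    split, fresh initialisation, train-set [-1, 1] scaling, training with
    early stopping, test-set prediction.  A trial's averaged prediction
    only ever uses iterations where the trial was held out in the test set.
    If any trial appears fewer than ``min_appearances`` times, extra
    iterations are run (up to ``max_extra_iter``, default n_iter) before
    failing hard.

    Bit-reproducible given ``seed``.
    """
    ci = ci.loc[features.index]
    X = features.to_numpy(float)
    y = ci.to_numpy(float)
    n = len(y)
    if max_extra_iter is None:
        max_extra_iter = n_iter

    sums = np.zeros(n)
    counts = np.zeros(n, dtype=int)
    iter_rows = []

    def one_iteration(k: int) -> None:
        rng = substream(seed, "ann-iteration", k)
        split = make_split(n, fractions, rng)
        scaler = FeatureScaler().fit(X[split.train_idx])
        # the CI target is min-max scaled to [-1, 1] on the training set
        # (as inputs are), so the loss is well-conditioned regardless of
        # the target's physical scale; predictions are mapped back
        ylo, yhi = y[split.train_idx].min(), y[split.train_idx].max()
        yspan = (yhi - ylo) or 1.0
        ys = 2.0 * (y - ylo) / yspan - 1.0
        net = init_network(X.shape[1], hidden_dim, rng)
        net, trace = train(
            net,
            scaler.transform(X[split.train_idx]), ys[split.train_idx],
            scaler.transform(X[split.val_idx]), ys[split.val_idx],
            cfg,
        )
        pred_s = forward(net, scaler.transform(X[split.test_idx]))
        pred = (pred_s + 1.0) / 2.0 * yspan + ylo
        sums[split.test_idx] += pred
        counts[split.test_idx] += 1
        yt = y[split.test_idx]
        if np.std(pred) > 0 and np.std(yt) > 0:
            r = float(np.corrcoef(pred, yt)[0, 1])
        else:
            r = np.nan
        iter_rows.append(
            {"iteration": k, "r_test": r, "epochs_run": trace.epochs_run,
             "stop_reason": trace.stop_reason}
        )

    for k in range(n_iter):
        one_iteration(k)
    total = n_iter
    while counts.min() < min_appearances and total < n_iter + max_extra_iter:
        one_iteration(total)
        total += 1
    if counts.min() < min_appearances:
        short = features.index[counts < min_appearances].tolist()
        raise RuntimeError(
            f"trials {short} appeared in fewer than {min_appearances} test sets "
            f"after {total} iterations"
        )

    mean_pred = np.divide(sums, counts, out=np.full_like(sums, np.nan),
                          where=counts > 0)
    predictions = pd.DataFrame(
        {
            "trial_id": features.index.to_numpy(),
            "mean_predicted_ci": mean_pred,
            "n_test_appearances": counts,
        }
    )
    iterations = pd.DataFrame(iter_rows)
    return ANNResult(
        predictions=predictions,
        iterations=iterations,
        mean_r=float(iterations.r_test.mean()),
        n_iterations=total,
    )
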