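"""MLP-ensemble regression of TBARS% on time, temperature and sample identity.

The search protocol mirrors the study: encode each observation as 16 inputs
(14 one-hot sample indicators + storage time + temperature, min-max scaled),
split 2:1:1 into train/validation/test, train 20 candidate single-hidden-
layer perceptrons (hidden size 3-9, tanh/logistic hidden units, exponential/
logistic output units) with a BFGS optimizer on sum-of-squares loss for at
most 200 iterations with validation-based early stopping, retain the best 5
by validation R^2, and predict with the ensemble mean.

The network itself is implemented directly (forward pass + analytic
gradients) because the search space includes exponential/logistic *output*
activations and quasi-Newton training with validation early stopping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .dataio import SAMPLE_GROUPS, DataError, TBARSSeries

__all__ = [
    "AnnConfig",
    "AnnEnsemble",
    "FeatureScaling",
    "TrainedNetwork",
    "MLPEnsembleRegressor",
    "encode_inputs",
    "split_dataset",
    "train_candidates",
    "select_ensemble",
    "predict_ensemble",
]


@dataclass(frozen=True)
class AnnConfig:
    """Search-protocol settings for the candidate MLPs."""

    hidden_sizes: tuple[int, ...] = (3, 4, 5, 6, 7, 8, 9)
    hidden_activations: tuple[str, ...] = ("tanh", "logistic")
    output_activations: tuple[str, ...] = ("exponential", "logistic")
    max_iterations: int = 200
    n_candidates: int = 20
    n_retained: int = 5
    split_ratio: tuple[int, int, int] = (2, 1, 1)
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_retained > self.n_candidates:
            raise ValueError("cannot retain more candidates than are trained")
        if any(r <= 0 for r in self.split_ratio):
            raise ValueError("split ratio parts must be positive")


@dataclass(frozen=True)
class FeatureScaling:
    """Min-max parameters for the continuous inputs and the target."""

    x_min: np.ndarray
    x_max: np.ndarray
    y_min: float
    y_max: float

    # targets live in [0.1, 0.9] so both exp and logistic outputs can reach them
    _Y_LO = 0.1
    _Y_HI = 0.9

    def scale_x(self, X: np.ndarray) -> np.ndarray:
        span = np.where(self.x_max > self.x_min, self.x_max - self.x_min, 1.0)
        return (X - self.x_min) / span

    def scale_y(self, y: np.ndarray) -> np.ndarray:
        if self.y_max == self.y_min:
            return np.full_like(np.asarray(y, dtype=float), 0.5)
        u = (np.asarray(y, dtype=float) - self.y_min) / (self.y_max - self.y_min)
        return self._Y_LO + (self._Y_HI - self._Y_LO) * u

    def unscale_y(self, ys: np.ndarray) -> np.ndarray:
        if self.y_max == self.y_min:
            return np.full_like(np.asarray(ys, dtype=float), self.y_min)
        u = (np.asarray(ys, dtype=float) - self._Y_LO) / (self._Y_HI - self._Y_LO)
        return self.y_min + u * (self.y_max - self.y_min)


def encode_inputs(
    dataset: Sequence[TBARSSeries],
    labels: Sequence[str] = SAMPLE_GROUPS,
) -> tuple[np.ndarray, np.ndarray]:
    """Encode series rows as [14 one-hot indicators, time, temperature].

    Returns the unscaled feature matrix (n, 16) and the TBARS% target; the
    estimator applies min-max scaling with parameters learned from the
    training data.
    """
    labels = list(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    rows, target = [], []
    for s in dataset:
        if s.sample_label not in index:
            raise DataError(f"unknown sample label {s.sample_label!r}")
        if s.percent_values is None:
            raise DataError(f"series {s.key()} is not normalized to percent")
        onehot = np.zeros(len(labels))
        onehot[index[s.sample_label]] = 1.0
        for t, p in zip(s.times, s.percent_values):
            rows.append(np.concatenate([onehot, [t, s.temperature]]))
            target.append(p)
    return np.asarray(rows, dtype=float), np.asarray(target, dtype=float)


def split_dataset(
    n_rows: int, ratio: tuple[int, int, int] = (2, 1, 1), seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random disjoint, exhaustive train/validation/test index split.

    Subset sizes are within one row of the exact ratio proportions and the
    partition is reproducible for a given seed.
    """
    if n_rows < sum(ratio) * 2:
        raise DataError(f"too few rows ({n_rows}) for a {ratio} split")
    total = sum(ratio)
    perm = np.random.default_rng(seed).permutation(n_rows)
    n_val = int(round(n_rows * ratio[1] / total))
    n_test = int(round(n_rows * ratio[2] / total))
    n_train = n_rows - n_val - n_test
    return (
        np.sort(perm[:n_train]),
        np.sort(perm[n_train : n_train + n_val]),
        np.sort(perm[n_train + n_val :]),
    )


# --- single-hidden-layer perceptron -------------------------------------------

_HIDDEN = {
    "tanh": (np.tanh, lambda a: 1.0 - a**2),
    "logistic": (
        lambda z: 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500))),
        lambda a: a * (1.0 - a),
    ),
}


def _out_exp(z):
    return np.exp(np.clip(z, -500, 50))


def _out_logistic(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


_OUTPUT = {
    "exponential": (_out_exp, lambda o: o),
    "logistic": (_out_logistic, lambda o: o * (1.0 - o)),
}


@dataclass
class TrainedNetwork:
    """One trained candidate with its architecture and split performance."""

    hidden_size: int
    hidden_activation: str
    output_activation: str
    seed: int
    weights: np.ndarray  # flat parameter vector
    n_iterations: int = 0
    train_r2: float = float("nan")
    val_r2: float = float("nan")
    test_r2: float = float("nan")
    val_error: float = float("inf")
    failed: bool = False

    @property
    def n_weights(self) -> int:
        h = self.hidden_size
        n_in = (self.weights.size - 2 * h - 1) // h if self.weights.size else 0
        return self.weights.size


def _n_params(n_in: int, h: int) -> int:
    return n_in * h + h + h + 1


def _unpack(w: np.ndarray, n_in: int, h: int):
    i = 0
    w1 = w[i : i + n_in * h].reshape(n_in, h); i += n_in * h
    b1 = w[i : i + h]; i += h
    w2 = w[i : i + h].reshape(h, 1); i += h
    b2 = w[i]
    return w1, b1, w2, b2


def _forward(w, X, n_in, h, hidden, output):
    w1, b1, w2, b2 = _unpack(w, n_in, h)
    f_h, _ = _HIDDEN[hidden]
    f_o, _ = _OUTPUT[output]
    a1 = f_h(X @ w1 + b1)
    out = f_o((a1 @ w2).ravel() + b2)
    return out, a1


def _loss_grad(w, X, ys, n_in, h, hidden, output):
    w1, b1, w2, b2 = _unpack(w, n_in, h)
    f_h, d_h = _HIDDEN[hidden]
    f_o, d_o = _OUTPUT[output]
    a1 = f_h(X @ w1 + b1)
    z2 = (a1 @ w2).ravel() + b2
    out = f_o(z2)
    err = out - ys
    loss = 0.5 * float(err @ err)
    delta2 = err * d_o(out)
    gw2 = a1.T @ delta2
    gb2 = float(delta2.sum())
    delta1 = np.outer(delta2, w2.ravel()) * d_h(a1)
    gw1 = X.T @ delta1
    gb1 = delta1.sum(axis=0)
    grad = np.concatenate([gw1.ravel(), gb1, gw2.ravel(), [gb2]])
    return loss, grad


def _r2(observed: np.ndarray, predicted: np.ndarray) -> float:
    sst = float(np.sum((observed - observed.mean()) ** 2))
    if sst == 0:
        return float("nan")
    return 1.0 - float(np.sum((observed - predicted) ** 2)) / sst


def _train_one(
    arch_seed: int,
    hidden_size: int,
    hidden_activation: str,
    output_activation: str,
    Xtr, ytr_s, Xval, yval_s,
    max_iterations: int,
    patience: int,
) -> TrainedNetwork:
    n_in = Xtr.shape[1]
    h = hidden_size
    rng = np.random.default_rng(arch_seed)
    # Glorot-style init; output bias starts at the scaled-target mean pullback
    w0 = np.concatenate(
        [
            rng.normal(0.0, np.sqrt(2.0 / (n_in + h)), n_in * h),
            np.zeros(h),
            rng.normal(0.0, np.sqrt(2.0 / (h + 1)), h),
            [np.log(max(ytr_s.mean(), 1e-6)) if output_activation == "exponential" else 0.0],
        ]
    )
    state = {
        "best_w": w0.copy(),
        "best_val": np.inf,
        "rises": 0,
        "prev_val": np.inf,
        "iters": 0,
    }

    def val_loss(w):
        out, _ = _forward(w, Xval, n_in, h, hidden_activation, output_activation)
        err = out - yval_s
        return 0.5 * float(err @ err)

    def callback(wk):
        state["iters"] += 1
        v = val_loss(wk)
        if v < state["best_val"]:
            state["best_val"] = v
            state["best_w"] = wk.copy()
        state["rises"] = state["rises"] + 1 if v > state["prev_val"] else 0
        state["prev_val"] = v
        if state["rises"] >= patience:
            raise StopIteration

    net = TrainedNetwork(
        hidden_size=h,
        hidden_activation=hidden_activation,
        output_activation=output_activation,
        seed=arch_seed,
        weights=w0,
    )
    try:
        res = minimize(
            _loss_grad,
            w0,
            args=(Xtr, ytr_s, n_in, h, hidden_activation, output_activation),
            jac=True,
            method="BFGS",
            callback=callback,
            options={"maxiter": max_iterations, "gtol": 1e-8},
        )
        final_w = res.x
    except StopIteration:
        final_w = state["best_w"]
    except Exception:
        net.failed = True
        return net
    # keep whichever parameters validated best
    if val_loss(final_w) <= state["best_val"]:
        state["best_w"] = final_w
    if not np.all(np.isfinite(state["best_w"])):
        net.failed = True
        return net
    net.weights = state["best_w"]
    net.n_iterations = state["iters"]
    return net


def train_candidates(
    config: AnnConfig,
    X: np.ndarray,
    y: np.ndarray,
    splits: tuple[np.ndarray, np.ndarray, np.ndarray],
    scaling: FeatureScaling,
) -> list[TrainedNetwork]:
    """Train ``config.n_candidates`` randomly drawn architectures.

    Architectures (hidden size, hidden and output activation) are sampled
    uniformly from the searched sets with per-candidate seeds derived from
    ``config.seed``; a candidate whose optimizer fails or diverges is marked
    failed and excluded from selection.
    """
    tr, val, te = splits
    Xs = scaling.scale_x(X)
    ys = scaling.scale_y(y)
    nets: list[TrainedNetwork] = []
    for i in range(config.n_candidates):
        cand_seed = int((config.seed * 100_003 + i) % (2**31 - 1))
        rng = np.random.default_rng(cand_seed)
        hsize = int(rng.choice(config.hidden_sizes))
        hact = str(rng.choice(config.hidden_activations))
        oact = str(rng.choice(config.output_activations))
        net = _train_one(
            cand_seed, hsize, hact, oact,
            Xs[tr], ys[tr], Xs[val], ys[val],
            config.max_iterations, config.patience,
        )
        if not net.failed:
            n_in = X.shape[1]
            for name, idx in (("train_r2", tr), ("val_r2", val), ("test_r2", te)):
                out, _ = _forward(net.weights, Xs[idx], n_in, net.hidden_size,
                                  net.hidden_activation, net.output_activation)
                setattr(net, name, _r2(y[idx], scaling.unscale_y(out)))
            out, _ = _forward(net.weights, Xs[val], n_in, net.hidden_size,
                              net.hidden_activation, net.output_activation)
            net.val_error = 0.5 * float(np.sum((out - ys[val]) ** 2))
        nets.append(net)
    return nets


@dataclass
class AnnEnsemble:
    """The retained networks plus the scaling used to encode their inputs."""

    members: list[TrainedNetwork]
    scaling: FeatureScaling
    labels: tuple[str, ...] = tuple(SAMPLE_GROUPS)


def select_ensemble(
    candidates: Sequence[TrainedNetwork],
    scaling: FeatureScaling,
    n_retained: int = 5,
) -> AnnEnsemble:
    """Retain the top networks by validation R^2.

    Ties break on lower validation error, then on lower candidate seed.
    """
    ok = [c for c in candidates if not c.failed]
    if len(ok) < n_retained:
        failures = [c.seed for c in candidates if c.failed]
        raise DataError(
            f"only {len(ok)} successful candidates (< {n_retained}); "
            f"failed seeds: {failures}"
        )
    ranked = sorted(ok, key=lambda c: (-np.nan_to_num(c.val_r2, nan=-np.inf),
                                       c.val_error, c.seed))
    return AnnEnsemble(members=list(ranked[:n_retained]), scaling=scaling)


def predict_ensemble(ensemble: AnnEnsemble, X: np.ndarray) -> np.ndarray:
    """Mean of the member predictions, inverse-scaled to TBARS%."""
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        return np.empty(0)
    if X.shape[1] != ensemble.scaling.x_min.size:
        raise DataError("feature dimension does not match the ensemble's scaling")
    Xs = ensemble.scaling.scale_x(X)
    preds = []
    for net in ensemble.members:
        out, _ = _forward(net.weights, Xs, X.shape[1], net.hidden_size,
                          net.hidden_activation, net.output_activation)
        preds.append(ensemble.scaling.unscale_y(out))
    return np.mean(preds, axis=0)


class MLPEnsembleRegressor(RegressorMixin, BaseEstimator):
    """Ensemble-of-5 MLP regressor following the candidate-search protocol.

    Parameters mirror `AnnConfig`; ``random_state`` seeds both the 2:1:1
    split and the candidate architecture draws.

    Attributes
    ----------
    ensemble_ : AnnEnsemble
        Retained members with their scaling.
    candidates_ : list of TrainedNetwork
        All trained candidates (including failures).
    splits_ : (train, validation, test) index arrays.
    """

    def __init__(
        self,
        hidden_sizes: tuple[int, ...] = (3, 4, 5, 6, 7, 8, 9),
        hidden_activations: tuple[str, ...] = ("tanh", "logistic"),
        output_activations: tuple[str, ...] = ("exponential", "logistic"),
        max_iterations: int = 200,
        n_candidates: int = 20,
        n_retained: int = 5,
        split_ratio: tuple[int, int, int] = (2, 1, 1),
        patience: int = 10,
        random_state: int = 0,
    ):
        self.hidden_sizes = hidden_sizes
        self.hidden_activations = hidden_activations
        self.output_activations = output_activations
        self.max_iterations = max_iterations
        self.n_candidates = n_candidates
        self.n_retained = n_retained
        self.split_ratio = split_ratio
        self.patience = patience
        self.random_state = random_state

    def _config(self) -> AnnConfig:
        return AnnConfig(
            hidden_sizes=tuple(self.hidden_sizes),
            hidden_activations=tuple(self.hidden_activations),
            output_activations=tuple(self.output_activations),
            max_iterations=self.max_iterations,
            n_candidates=self.n_candidates,
            n_retained=self.n_retained,
            split_ratio=tuple(self.split_ratio),
            patience=self.patience,
            seed=self.random_state,
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).reshape(-1)
        if X.ndim != 2 or X.shape[0] != y.size:
            raise DataError("X must be 2-D with one target per row")
        config = self._config()
        splits = split_dataset(X.shape[0], config.split_ratio, seed=config.seed)
        tr = splits[0]
        scaling = FeatureScaling(
            x_min=X[tr].min(axis=0),
            x_max=X[tr].max(axis=0),
            y_min=float(y[tr].min()),
            y_max=float(y[tr].max()),
        )
        self.candidates_ = train_candidates(config, X, y, splits, scaling)
        self.ensemble_ = select_ensemble(self.candidates_, scaling, config.n_retained)
        self.splits_ = splits
        return self

    def predict(self, X):
        check_is_fitted(self, "ensemble_")
        return predict_ensemble(self.ensemble_, np.asarray(X, dtype=float))
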