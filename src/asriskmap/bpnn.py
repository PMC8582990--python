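"""Feed-forward back-propagation network (BPNN) trained by Levenberg-Marquardt.

The network maps planar well coordinates (2 inputs) to log10 concentration
(1 linear output) through one or two hyperbolic-tangent hidden layers.  Each
neuron computes

    net_j = sum_i X_i W_ji - b_j,      Y = f(net_j)

i.e. the bias is *subtracted* (equivalent to the usual added bias with its
sign flipped; implemented exactly in this form so serialized parameters are
unambiguous).

Training minimizes the sum of squared residuals with the Levenberg-Marquardt
(LM) scheme: solve (J^T J + lambda I) delta = -J^T r on the full-batch
Jacobian of residuals, accept the step and divide lambda by a factor when the
SSE decreases, otherwise multiply lambda and retry.  Large lambda makes the
step a damped gradient descent, small lambda a Gauss-Newton step.  Weights
and biases are initialized uniformly in [-1, 1].

Raw planar coordinates (tens of kilometers) would saturate tanh units, so
training scales inputs by the centroid and half-extent of the training data;
the scaling constants are stored with the model (`TrainedNetwork`) and
inverted transparently at prediction time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd


class TrainingDivergence(RuntimeError):
    """LM damping overflowed without finding a descent step.

    Carries the best parameters seen so far in ``best_params``.
    """

    def __init__(self, message: str, best_params: "NetworkParams | None" = None):
        super().__init__(message)
        self.best_params = best_params


@dataclass(frozen=True)
class NetworkSpec:
    """Layer structure, e.g. (2, 10, 10, 1): 2 coordinate inputs, two hidden
    tanh layers of 10 neurons, 1 linear ("pureline") output."""

    layer_sizes: tuple[int, ...]

    def __post_init__(self):
        ls = tuple(int(s) for s in self.layer_sizes)
        object.__setattr__(self, "layer_sizes", ls)
        if len(ls) not in (3, 4):
            raise ValueError("network must have 1 or 2 hidden layers")
        if ls[0] != 2:
            raise ValueError("input layer must have 2 nodes (x, y)")
        if ls[-1] != 1:
            raise ValueError("output layer must have 1 neuron")
        if any(h < 1 for h in ls[1:-1]):
            raise ValueError("hidden layers need at least one neuron")

    @property
    def n_params(self) -> int:
        return sum(
            (nin + 1) * nout
            for nin, nout in zip(self.layer_sizes[:-1], self.layer_sizes[1:])
        )

    def __str__(self) -> str:
        return "(" + ",".join(map(str, self.layer_sizes)) + ")"


def table4_candidates(
    h1_sizes: Sequence[int] = range(2, 51, 2),
    h2_sizes: Sequence[int] = range(0, 51, 2),
) -> list[NetworkSpec]:
    """The standard architecture-search space: first hidden layer of even
    size 2-50, optional second hidden layer of even size 2-50 (0 = absent)."""
    specs = []
    for h1 in h1_sizes:
        for h2 in h2_sizes:
            sizes = (2, h1, 1) if h2 == 0 else (2, h1, h2, 1)
            specs.append(NetworkSpec(sizes))
    return specs


@dataclass(frozen=True)
class NetworkParams:
    """Per-layer weight matrices W[l] of shape (n_out, n_in) and bias
    vectors b[l] of shape (n_out,)."""

    weights: tuple[np.ndarray, ...]
    biases: tuple[np.ndarray, ...]

    def __post_init__(self):
        if len(self.weights) != len(self.biases):
            raise ValueError("one bias vector per weight matrix required")
        for w, b in zip(self.weights, self.biases):
            if w.shape[0] != b.shape[0]:
                raise ValueError(f"weight/bias shape mismatch: {w.shape} vs {b.shape}")

    @property
    def spec(self) -> NetworkSpec:
        sizes = (self.weights[0].shape[1],) + tuple(w.shape[0] for w in self.weights)
        return NetworkSpec(sizes)

    def flatten(self) -> np.ndarray:
        return np.concatenate(
            [np.concatenate([w.ravel(), b]) for w, b in zip(self.weights, self.biases)]
        )

    @classmethod
    def unflatten(cls, spec: NetworkSpec, theta: np.ndarray) -> "NetworkParams":
        ws, bs, k = [], [], 0
        for nin, nout in zip(spec.layer_sizes[:-1], spec.layer_sizes[1:]):
            ws.append(theta[k : k + nin * nout].reshape(nout, nin))
            k += nin * nout
            bs.append(theta[k : k + nout])
            k += nout
        if k != len(theta):
            raise ValueError("parameter vector length does not match spec")
        return cls(tuple(ws), tuple(bs))


def init_params(spec: NetworkSpec, rng: np.random.Generator) -> NetworkParams:
    """Uniform [-1, 1] initialization of every weight and bias."""
    theta = rng.uniform(-1.0, 1.0, size=spec.n_params)
    return NetworkParams.unflatten(spec, theta)


@dataclass(frozen=True)
class TrainConfig:
    """LM training hyperparameters.

    ``mse_goal`` is the convergence criterion on the training mean squared
    error (default 1e-2, in squared target units — here (log10 ug/L)^2).
    """

    mse_goal: float = 1e-2
    max_epochs: int = 1000
    lm_lambda_init: float = 1e-3
    lm_lambda_factor: float = 10.0
    lm_lambda_max: float = 1e12
    seed: int = 0

    def __post_init__(self):
        if not self.mse_goal > 0:
            raise ValueError("mse_goal must be > 0")
        if not self.lm_lambda_factor > 1:
            raise ValueError("lm_lambda_factor must be > 1")


def _forward_cached(params: NetworkParams, X: np.ndarray):
    """Forward pass keeping hidden activations for the Jacobian."""
    acts = [X]
    a = X
    last = len(params.weights) - 1
    for l, (w, b) in enumerate(zip(params.weights, params.biases)):
        net = a @ w.T - b
        a = net if l == last else np.tanh(net)
        acts.append(a)
    return acts


def forward(params: NetworkParams, inputs) -> np.ndarray:
    """Network output for (n, 2) scaled inputs (or a single (2,) input);
    returns shape (n,) (or a scalar)."""
    X = np.asarray(inputs, dtype=float)
    single = X.ndim == 1
    if single:
        X = X[None, :]
    if X.shape[1] != params.spec.layer_sizes[0]:
        raise ValueError(
            f"input dimension {X.shape[1]} does not match network input "
            f"{params.spec.layer_sizes[0]}"
        )
    y = _forward_cached(params, X)[-1][:, 0]
    return float(y[0]) if single else y


def jacobian(params: NetworkParams, X: np.ndarray) -> np.ndarray:
    """d output / d theta for every sample: shape (n, n_params).

    Reverse-mode accumulation; with net = a W^T - b the bias column of the
    Jacobian is the *negative* of the usual added-bias convention.
    """
    X = np.asarray(X, dtype=float)
    acts = _forward_cached(params, X)
    n = len(X)
    L = len(params.weights)
    # delta[l]: d y / d net_l, shape (n, size_l)
    delta = np.ones((n, 1))
    blocks: list[np.ndarray | None] = [None] * L
    for l in range(L - 1, -1, -1):
        a_prev = acts[l]
        # dW block: delta_j * a_i, laid out row-major like W.ravel()
        dW = delta[:, :, None] * a_prev[:, None, :]
        db = -delta
        blocks[l] = np.concatenate([dW.reshape(n, -1), db], axis=1)
        if l > 0:
            back = delta @ params.weights[l]          # d y / d a_{l-1}
            delta = back * (1.0 - acts[l] ** 2)       # tanh'(net) = 1 - a^2
    return np.concatenate(blocks, axis=1)


@dataclass
class TrainingHistory:
    """Per-epoch record of the LM run (epoch 0 is the initial state)."""

    mse: list[float] = field(default_factory=list)
    lm_lambda: list[float] = field(default_factory=list)
    n_epochs: int = 0
    converged: bool = False

    @property
    def final_mse(self) -> float:
        return self.mse[-1]


def lm_train(
    spec: NetworkSpec,
    data: tuple[np.ndarray, np.ndarray],
    config: TrainConfig = TrainConfig(),
) -> tuple[NetworkParams, TrainingHistory]:
    """Full-batch Levenberg-Marquardt training.

    ``data`` is (inputs, targets) with inputs already scaled to O(1); at
    least 10 finite training points are required.  Deterministic for a given
    ``config.seed``.  Raises :class:`TrainingDivergence` (carrying the best
    parameters) if the damping overflows ``lm_lambda_max`` without finding a
    descent step.
    """
    X = np.asarray(data[0], dtype=float)
    y = np.asarray(data[1], dtype=float).ravel()
    if len(X) < 10:
        raise ValueError("LM training requires at least 10 points")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("training data must be finite")
    rng = np.random.default_rng(config.seed)
    params = init_params(spec, rng)
    theta = params.flatten()
    n = len(y)

    def sse_of(t):
        r = forward(NetworkParams.unflatten(spec, t), X) - y
        return float(r @ r), r

    sse, resid = sse_of(theta)
    lam = config.lm_lambda_init
    hist = TrainingHistory(mse=[sse / n], lm_lambda=[lam])
    eye = np.eye(spec.n_params)
    for epoch in range(config.max_epochs):
        if hist.mse[-1] <= config.mse_goal:
            hist.converged = True
            break
        J = jacobian(NetworkParams.unflatten(spec, theta), X)
        jtj = J.T @ J
        g = J.T @ resid
        while True:
            try:
                delta = np.linalg.solve(jtj + lam * eye, -g)
            except np.linalg.LinAlgError:
                delta = None
            if delta is not None:
                sse_new, resid_new = sse_of(theta + delta)
                if sse_new < sse:
                    theta = theta + delta
                    sse, resid = sse_new, resid_new
                    lam = max(lam / config.lm_lambda_factor, 1e-300)
                    break
            lam *= config.lm_lambda_factor
            if lam > config.lm_lambda_max:
                raise TrainingDivergence(
                    f"LM damping overflowed {config.lm_lambda_max:g} at epoch "
                    f"{epoch} (mse {sse / n:.4g})",
                    NetworkParams.unflatten(spec, theta),
                )
        hist.mse.append(sse / n)
        hist.lm_lambda.append(lam)
        hist.n_epochs = epoch + 1
    else:
        hist.converged = hist.mse[-1] <= config.mse_goal
    if hist.mse[-1] <= config.mse_goal:
        hist.converged = True
    return NetworkParams.unflatten(spec, theta), hist


@dataclass(frozen=True)
class InputScaling:
    """Affine map from planar meters to O(1) tanh-friendly inputs:
    x_scaled = (x - center) / half_extent (per axis)."""

    center: tuple[float, float]
    half_extent: tuple[float, float]

    @classmethod
    def from_data(cls, X: np.ndarray) -> "InputScaling":
        X = np.asarray(X, dtype=float)
        lo, hi = X.min(axis=0), X.max(axis=0)
        half = np.maximum((hi - lo) / 2.0, 1e-12)
        return cls(tuple((lo + hi) / 2.0), tuple(half))

    def apply(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - np.asarray(self.center)) / np.asarray(self.half_extent)


@dataclass(frozen=True)
class TrainedNetwork:
    """A trained network plus the input scaling it was trained under."""

    params: NetworkParams
    scaling: InputScaling
    history: TrainingHistory

    def predict(self, coords) -> np.ndarray:
        """Log10-concentration prediction at raw planar coordinates."""
        return forward(self.params, self.scaling.apply(coords))

    def to_dict(self) -> dict:
        return {
            "layer_sizes": list(self.params.spec.layer_sizes),
            "weights": [w.tolist() for w in self.params.weights],
            "biases": [b.tolist() for b in self.params.biases],
            "scaling_center": list(self.scaling.center),
            "scaling_half_extent": list(self.scaling.half_extent),
            "final_mse": self.history.final_mse,
            "n_epochs": self.history.n_epochs,
            "converged": self.history.converged,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedNetwork":
        params = NetworkParams(
            tuple(np.asarray(w, float) for w in d["weights"]),
            tuple(np.asarray(b, float) for b in d["biases"]),
        )
        hist = TrainingHistory(
            mse=[d["final_mse"]],
            lm_lambda=[np.nan],
            n_epochs=d["n_epochs"],
            converged=d["converged"],
        )
        return cls(
            params,
            InputScaling(tuple(d["scaling_center"]), tuple(d["scaling_half_extent"])),
            hist,
        )

    @classmethod
    def from_json(cls, path) -> "TrainedNetwork":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_network(
    coords: np.ndarray,
    targets: np.ndarray,
    spec: NetworkSpec,
    config: TrainConfig = TrainConfig(),
    restarts: int = 3,
) -> TrainedNetwork:
    """Train from raw coordinates with ``restarts`` random initializations,
    keeping the best run by final training mse.

    Restart seeds derive deterministically from ``config.seed``.  A restart
    that diverges is kept as a candidate at its best parameters only if every
    restart diverges; otherwise it is simply dropped.
    """
    coords = np.asarray(coords, dtype=float)
    scaling = InputScaling.from_data(coords)
    Xs = scaling.apply(coords)
    seeds = np.random.SeedSequence(config.seed).generate_state(max(restarts, 1)) >> 1
    best: tuple[float, NetworkParams, TrainingHistory] | None = None
    failures = []
    for s in seeds:
        cfg = replace(config, seed=int(s))
        try:
            params, hist = lm_train(spec, (Xs, targets), cfg)
        except TrainingDivergence as exc:
            failures.append(exc)
            continue
        if best is None or hist.final_mse < best[0]:
            best = (hist.final_mse, params, hist)
        if hist.converged:
            break
    if best is None:
        raise TrainingDivergence(
            f"all {len(seeds)} restarts diverged for {spec}", failures[-1].best_params
        )
    _, params, hist = best
    return TrainedNetwork(params, scaling, hist)


def architecture_search(
    folds: dict[str, tuple[np.ndarray, np.ndarray]],
    candidate_specs: Sequence[NetworkSpec],
    config: TrainConfig = TrainConfig(),
    restarts: int = 3,
) -> "SearchReport":
    """Cross-validated comparison of candidate network structures.

    ``folds`` maps fold label (e.g. "A", "B", "C") to (coords, log10 targets).
    For every candidate and every fold, the network is trained on the union
    of the *other* folds (``restarts`` restarts, best by training mse) and
    evaluated on the held-out fold.  Candidates are ranked by highest average
    validation R^2, ties broken by lowest average validation RMSE.  A fold
    where training diverges is recorded as NaN; a candidate is disqualified
    only if every fold fails.
    """
    from .evaluate import r_squared, rmse

    labels = sorted(folds)
    if len(labels) < 2:
        raise ValueError("architecture search needs >= 2 folds")
    rows = []
    seed_root = np.random.SeedSequence(config.seed)
    for ispec, spec in enumerate(candidate_specs):
        for ifold, held in enumerate(labels):
            train = [l for l in labels if l != held]
            Xtr = np.vstack([folds[l][0] for l in train])
            ytr = np.concatenate([folds[l][1] for l in train])
            Xva, yva = folds[held]
            seed = int(seed_root.spawn(1)[0].generate_state(1)[0] >> 1)
            cfg = replace(config, seed=seed)
            row = {"structure": str(spec), "held_out": held}
            try:
                net = fit_network(Xtr, ytr, spec, cfg, restarts=restarts)
                ptr, pva = net.predict(Xtr), net.predict(Xva)
                row.update(
                    train_r2=r_squared(ytr, ptr),
                    val_r2=r_squared(yva, pva),
                    train_rmse=rmse(ytr, ptr),
                    val_rmse=rmse(yva, pva),
                    error="",
                )
            except TrainingDivergence as exc:
                row.update(
                    train_r2=np.nan, val_r2=np.nan,
                    train_rmse=np.nan, val_rmse=np.nan, error=str(exc),
                )
            rows.append(row)
    table = pd.DataFrame(rows)
    return SearchReport(table)


@dataclass
class SearchReport:
    """Per-fold and average metrics for every candidate structure."""

    table: pd.DataFrame  # columns: structure, held_out, {train,val}_{r2,rmse}, error

    @property
    def averages(self) -> pd.DataFrame:
        cols = ["train_r2", "val_r2", "train_rmse", "val_rmse"]
        return self.table.groupby("structure", sort=False)[cols].mean()

    @property
    def selected(self) -> str:
        """Best structure: highest average validation R^2, ties by lowest
        average validation RMSE; all-failed candidates are disqualified."""
        avg = self.averages.dropna(subset=["val_r2"])
        if avg.empty:
            raise TrainingDivergence("every candidate failed on every fold")
        ranked = avg.sort_values(["val_r2", "val_rmse"], ascending=[False, True])
        return str(ranked.index[0])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)
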