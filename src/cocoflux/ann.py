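"""Compact 2-5-2 feed-forward surrogate trained by Levenberg-Marquardt.

The network maps (pressure, temperature) to (permeate flux, fouling
index).  Inputs and outputs are min-max scaled to [-1, 1]; the hidden
layer uses the hyperbolic-tangent sigmoid (tansig), the output layer is
linear (purelin).  Training minimizes the regularized performance

    perf = (1 - lambda) * MSE_scaled + lambda * MSW

where MSW is the mean squared weight/bias, via damped Gauss-Newton steps
(J'J + mu*I) delta = -J'r with an adaptive damping factor mu, early
stopping on a held-out validation subset, and multi-restart selection of
the best validation performer.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from cocoflux.doe import FCDDataset

__all__ = [
    "tansig",
    "purelin",
    "MinMaxScaler",
    "TrainConfig",
    "TrainDiagnostics",
    "MLPSurrogate",
    "split_samples",
    "train",
    "select_best",
]

N_HIDDEN = 5


def tansig(n):
    """Hyperbolic-tangent sigmoid, 2/(1+exp(-2n)) - 1, bounded in (-1, 1)."""
    return np.tanh(n)


def purelin(n):
    """Linear (identity) transfer function."""
    return n


@dataclass
class MinMaxScaler:
    """Per-variable affine map from [min, max] onto [-1, +1].

    A constant variable (max == min) maps to 0 and inverts back to the
    constant, mirroring the usual toolbox handling of degenerate rows.
    """

    mins: np.ndarray
    maxs: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "MinMaxScaler":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return cls(mins=X.min(axis=0), maxs=X.max(axis=0))

    @property
    def _span(self) -> np.ndarray:
        span = self.maxs - self.mins
        return np.where(span > 0, span, 1.0)

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = 2.0 * (X - self.mins) / self._span - 1.0
        return np.where(self.maxs > self.mins, out, 0.0)

    def inverse(self, Xs: np.ndarray) -> np.ndarray:
        Xs = np.asarray(Xs, dtype=float)
        out = (Xs + 1.0) / 2.0 * self._span + self.mins
        return np.where(self.maxs > self.mins, out, self.mins)


@dataclass
class TrainConfig:
    """Training hyperparameters.

    ``reg_lambda`` is the performance-regularization weight (0.10 by
    default); split fractions apply at the sample level with
    largest-remainder rounding, remainder preference test > validation
    (29 samples -> 20/4/5).
    """

    reg_lambda: float = 0.10
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    max_epochs: int = 1000
    mu0: float = 1e-3
    mu_inc: float = 10.0
    mu_dec: float = 10.0
    mu_max: float = 1e10
    patience: int = 6
    n_restarts: int = 20
    seed: int = 0
    scaler_scope: str = "all"  # fit scalers on "all" samples or "train" only

    def __post_init__(self) -> None:
        if not (0.0 <= self.reg_lambda < 1.0):
            raise ValueError("reg_lambda must lie in [0, 1)")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass
class TrainDiagnostics:
    split: dict[str, list[int]]
    mse: dict[str, float]  # scaled-space MSE per subset
    r2: dict[str, float]   # pooled-output R^2 per subset (scaled space)
    epochs: int
    stop_reason: str
    seed: int | None = None
    restarts: list[dict] = field(default_factory=list)


@dataclass
class MLPSurrogate:
    """Trained 2-5-2 network with its scalers (physical-unit interface)."""

    W1: np.ndarray  # (5, 2)
    b1: np.ndarray  # (5,)
    W2: np.ndarray  # (2, 5)
    b2: np.ndarray  # (2,)
    x_scaler: MinMaxScaler
    y_scaler: MinMaxScaler
    response_names: tuple[str, str]
    diagnostics: TrainDiagnostics | None = None

    def forward_scaled(self, Xs: np.ndarray) -> np.ndarray:
        """Forward pass in scaled space; Xs of shape (n, 2) -> (n, 2)."""
        h = tansig(Xs @ self.W1.T + self.b1)
        return purelin(h @ self.W2.T + self.b2)

    def predict(self, pressure, temperature) -> np.ndarray:
        """Physical-unit prediction -> array (..., 2): (flux, fouling index)."""
        X = np.column_stack([np.atleast_1d(pressure), np.atleast_1d(temperature)])
        out = self.y_scaler.inverse(self.forward_scaled(self.x_scaler.transform(X)))
        return out[0] if np.isscalar(pressure) else out

    def predict_physical(self, pressure: float, temperature: float) -> tuple[float, float]:
        flux, fi = self.predict(float(pressure), float(temperature))
        return float(flux), float(fi)

    # ---- serialization -------------------------------------------------

    def to_json_dict(self) -> dict:
        d = {
            "W1": self.W1.tolist(),
            "b1": self.b1.tolist(),
            "W2": self.W2.tolist(),
            "b2": self.b2.tolist(),
            "x_scaler": {"mins": self.x_scaler.mins.tolist(),
                         "maxs": self.x_scaler.maxs.tolist()},
            "y_scaler": {"mins": self.y_scaler.mins.tolist(),
                         "maxs": self.y_scaler.maxs.tolist()},
            "response_names": list(self.response_names),
        }
        if self.diagnostics is not None:
            d["diagnostics"] = asdict(self.diagnostics)
        return d

    def save_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_json_dict(), fh, indent=1)

    @classmethod
    def from_json_dict(cls, d: dict) -> "MLPSurrogate":
        diag = None
        if "diagnostics" in d:
            diag = TrainDiagnostics(**d["diagnostics"])
        return cls(
            W1=np.asarray(d["W1"], dtype=float),
            b1=np.asarray(d["b1"], dtype=float),
            W2=np.asarray(d["W2"], dtype=float),
            b2=np.asarray(d["b2"], dtype=float),
            x_scaler=MinMaxScaler(np.asarray(d["x_scaler"]["mins"], dtype=float),
                                  np.asarray(d["x_scaler"]["maxs"], dtype=float)),
            y_scaler=MinMaxScaler(np.asarray(d["y_scaler"]["mins"], dtype=float),
                                  np.asarray(d["y_scaler"]["maxs"], dtype=float)),
            response_names=tuple(d["response_names"]),
            diagnostics=diag,
        )

    @classmethod
    def load_json(cls, path) -> "MLPSurrogate":
        with open(path, encoding="utf-8") as fh:
            return cls.from_json_dict(json.load(fh))


# ---- splitting ---------------------------------------------------------

def split_samples(
    n: int,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random disjoint train/validation/test index sets.

    Subset sizes use largest-remainder apportionment with ties resolved in
    favor of test over validation over train; n = 29 with the default
    fractions gives (20, 4, 5).
    """
    if n < 3:
        raise ValueError("need at least 3 samples for a three-way split")
    rng = np.random.default_rng(rng)
    quotas = np.array(fractions, dtype=float) * n
    sizes = np.floor(quotas).astype(int)
    remainders = quotas - sizes
    # preference order on ties: test (2) > validation (1) > train (0)
    order = sorted(range(3), key=lambda i: (-remainders[i], -i))
    for i in range(n - sizes.sum()):
        sizes[order[i % 3]] += 1
    if min(sizes) < 1:
        raise ValueError(f"n={n} too small for non-empty subsets at {fractions}")
    perm = rng.permutation(n)
    i1, i2 = sizes[0], sizes[0] + sizes[1]
    return np.sort(perm[:i1]), np.sort(perm[i1:i2]), np.sort(perm[i2:])


# ---- parameter packing -------------------------------------------------

def _unpack(theta: np.ndarray):
    W1 = theta[:10].reshape(N_HIDDEN, 2)
    b1 = theta[10:15]
    W2 = theta[15:25].reshape(2, N_HIDDEN)
    b2 = theta[25:27]
    return W1, b1, W2, b2


def _forward(theta: np.ndarray, X: np.ndarray):
    W1, b1, W2, b2 = _unpack(theta)
    h = np.tanh(X @ W1.T + b1)
    return h @ W2.T + b2, h


def _jacobian(theta: np.ndarray, X: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Analytic Jacobian of the flattened residuals wrt the 27 parameters.

    Rows are ordered sample-major, output-minor to match ``err.ravel()``.
    """
    n = X.shape[0]
    W1, b1, W2, b2 = _unpack(theta)
    J = np.zeros((n * 2, 27))
    dh = 1.0 - h * h  # (n, 5)
    # o_k = sum_j W2[k,j] h_j + b2[k]
    for k in range(2):
        idx = np.arange(n) * 2 + k
        # wrt W2[k, :] and b2[k]
        J[idx, 15 + k * N_HIDDEN:15 + (k + 1) * N_HIDDEN] = h
        J[idx, 25 + k] = 1.0
        # wrt W1[j, i] and b1[j]: W2[k, j] * (1 - h_j^2) * x_i
        back = W2[k] * dh  # (n, 5)
        for i in range(2):
            J[idx, i:10:2] = back * X[:, [i]]
        J[idx, 10:15] = back
    return J


def _perf(theta, X, Y, lam):
    out, _ = _forward(theta, X)
    mse = np.mean((out - Y) ** 2)
    msw = np.mean(theta**2)
    return (1.0 - lam) * mse + lam * msw


def _subset_stats(theta, X, Y):
    out, _ = _forward(theta, X)
    err = out - Y
    mse = float(np.mean(err**2))
    ss_tot = float(np.sum((Y - Y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(err**2)) / ss_tot if ss_tot > 0 else 1.0
    return mse, r2


def _train_lm(Xtr, Ytr, Xval, Yval, config: TrainConfig, theta0: np.ndarray):
    """Damped Gauss-Newton minimization of the regularized performance."""
    lam = config.reg_lambda
    n_out = Ytr.size
    w_data = np.sqrt((1.0 - lam) / n_out)
    w_reg = np.sqrt(lam / theta0.size)
    theta = theta0.copy()
    mu = config.mu0
    perf = _perf(theta, Xtr, Ytr, lam)
    best_val = np.inf
    best_theta = theta.copy()
    val_fails = 0
    stop = "max_epochs"
    epoch = 0
    eye = np.eye(theta.size)
    for epoch in range(1, config.max_epochs + 1):
        out, h = _forward(theta, Xtr)
        r = np.concatenate([w_data * (out - Ytr).ravel(), w_reg * theta])
        J = np.vstack([w_data * _jacobian(theta, Xtr, h), w_reg * eye])
        g = J.T @ r
        if np.max(np.abs(g)) < 1e-12:
            stop = "gradient"
            break
        JtJ = J.T @ J
        accepted = False
        while mu <= config.mu_max:
            try:
                delta = np.linalg.solve(JtJ + mu * eye, -g)
            except np.linalg.LinAlgError:
                mu *= config.mu_inc
                continue
            cand = theta + delta
            cand_perf = _perf(cand, Xtr, Ytr, lam)
            if not np.isfinite(cand_perf):
                raise FloatingPointError("non-finite training loss")
            if cand_perf < perf:
                theta, perf = cand, cand_perf
                mu = max(mu / config.mu_dec, 1e-20)
                accepted = True
                break
            mu *= config.mu_inc
        if not accepted:
            stop = "mu_overflow"
            break
        if Xval is not None and len(Xval):
            val_mse, _ = _subset_stats(theta, Xval, Yval)
            if val_mse < best_val - 1e-15:
                best_val = val_mse
                best_theta = theta.copy()
                val_fails = 0
            else:
                val_fails += 1
                if val_fails >= config.patience:
                    stop = "validation_patience"
                    break
        else:
            best_theta = theta.copy()
    if Xval is not None and len(Xval) and np.isfinite(best_val):
        theta = best_theta
    return theta, epoch, stop


def _prepare(dataset: FCDDataset, config: TrainConfig):
    Xp, y_flux = dataset.samples(dataset.response_names[0])
    _, y_fi = dataset.samples(dataset.response_names[1])
    # coded -> actual units for the scaler interface
    X = np.column_stack([
        [dataset.factors[0].decode(c) for c in Xp[:, 0]],
        [dataset.factors[1].decode(c) for c in Xp[:, 1]],
    ])
    Y = np.column_stack([y_flux, y_fi])
    return X, Y


def train(
    dataset: FCDDataset,
    config: TrainConfig | None = None,
    rng: np.random.Generator | int | None = None,
    split: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> MLPSurrogate:
    """Train one 2-5-2 network on the dataset's two responses.

    Weight initialization is uniform in [-0.5, 0.5] from ``rng`` (falling
    back to ``config.seed``); the random 70/15/15 split is drawn from the
    same stream unless supplied explicitly.
    """
    config = config or TrainConfig()
    rng = np.random.default_rng(config.seed if rng is None else rng)
    X, Y = _prepare(dataset, config)
    if split is None:
        split = split_samples(len(X), config.fractions, rng)
    itr, iva, ite = split
    x_scaler = MinMaxScaler.fit(X if config.scaler_scope == "all" else X[itr])
    y_scaler = MinMaxScaler.fit(Y if config.scaler_scope == "all" else Y[itr])
    Xs, Ys = x_scaler.transform(X), y_scaler.transform(Y)
    theta0 = rng.uniform(-0.5, 0.5, size=27)
    theta, epochs, stop = _train_lm(
        Xs[itr], Ys[itr], Xs[iva], Ys[iva], config, theta0
    )
    W1, b1, W2, b2 = _unpack(theta)
    mse, r2 = {}, {}
    for name, idx in (("train", itr), ("validation", iva), ("test", ite)):
        mse[name], r2[name] = _subset_stats(theta, Xs[idx], Ys[idx])
    mse["all"], r2["all"] = _subset_stats(theta, Xs, Ys)
    diag = TrainDiagnostics(
        split={"train": itr.tolist(), "validation": iva.tolist(), "test": ite.tolist()},
        mse=mse,
        r2=r2,
        epochs=epochs,
        stop_reason=stop,
    )
    return MLPSurrogate(
        W1=W1, b1=b1, W2=W2, b2=b2,
        x_scaler=x_scaler, y_scaler=y_scaler,
        response_names=tuple(dataset.response_names[:2]),  # type: ignore[arg-type]
        diagnostics=diag,
    )


def select_best(dataset: FCDDataset, config: TrainConfig | None = None) -> MLPSurrogate:
    """Multi-restart training; returns the restart with the lowest
    validation-subset MSE.

    Each restart draws a fresh random 70/15/15 split and a fresh weight
    initialization from the config seed (mirroring toolbox practice of
    re-dividing the data on every training call); selecting on a freshly
    drawn validation subset each time avoids overfitting the selection to
    one small validation set.  Per-restart diagnostics are recorded on
    the winner.
    """
    config = config or TrainConfig()
    if config.n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    ss = np.random.SeedSequence(config.seed)
    best: MLPSurrogate | None = None
    history = []
    for i, child in enumerate(ss.spawn(config.n_restarts)):
        model = train(dataset, config, rng=np.random.default_rng(child))
        assert model.diagnostics is not None
        model.diagnostics.seed = i
        history.append({
            "restart": i,
            "val_mse": model.diagnostics.mse["validation"],
            "all_r2": model.diagnostics.r2["all"],
            "epochs": model.diagnostics.epochs,
            "stop": model.diagnostics.stop_reason,
        })
        if best is None or (
            model.diagnostics.mse["validation"]
            < best.diagnostics.mse["validation"]  # type: ignore[union-attr]
        ):
            best = model
    assert best is not None and best.diagnostics is not None
    best.diagnostics.restarts = history
    n_bad = sum(1 for hrec in history if not np.isfinite(hrec["val_mse"]))
    if n_bad:
        warnings.warn(f"{n_bad} restart(s) ended with non-finite validation MSE")
    return best
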