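"""Exponential tumor-growth fitting and network-based growth prediction.

Each tumor's longitudinal volume series is fit to the one-term exponential
V(t) = alpha * exp(beta * t) by trust-region nonlinear least squares,
initialized from a log-linear regression.  A shallow feedforward network
(33 texture-feature inputs, one hidden layer of 33 sigmoid units, linear
two-unit output) then learns to map first-imaging-session features to the
fitted (alpha, beta), trained on a class-stratified 60/35/5
train/validation/test split with early stopping on the validation
partition.  Prediction error is reported as the mean squared error of
min-max-normalized targets, expressed as a percentage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .imaging import ValidationError
from .phantoms import GrowthSeries

__all__ = [
    "GrowthParams",
    "GrowthFitResult",
    "ExponentialGrowthModel",
    "fit_exponential",
    "split_cohort",
    "GrowthNetwork",
    "train_growth_network",
    "predict_growth",
    "evaluate_growth_mse",
]


@dataclass(frozen=True)
class GrowthParams:
    """(alpha, beta) of V(t) = alpha * exp(beta * t).

    alpha (mm^3) is the initial-volume scale; beta (per day) the growth
    rate.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValidationError("alpha must be positive")

    def curve(self, times: Sequence[float]) -> np.ndarray:
        return self.alpha * np.exp(self.beta * np.asarray(times, dtype=float))


@dataclass
class GrowthFitResult:
    """Fitted growth parameters with least-squares diagnostics."""

    params: GrowthParams
    rss: float
    converged: bool
    n_points: int
    message: str = ""

    def summary(self) -> str:
        return (
            f"V(t) = {self.params.alpha:.4g} * exp({self.params.beta:.4g} t)   "
            f"RSS={self.rss:.4g}  n={self.n_points}  "
            f"converged={self.converged}"
        )


class ExponentialGrowthModel:
    """One-term exponential growth model for a single tumor's volume series."""

    def __init__(self, series: GrowthSeries):
        if series.times.size < 2:
            raise ValidationError("need at least two time points to fit growth")
        if np.unique(series.times).size < 2:
            raise ValidationError("degenerate series: all time points equal")
        self.series = series

    def fit(self) -> GrowthFitResult:
        t = self.series.times
        v = self.series.volumes
        # log-linear initialization: log V = log alpha + beta t
        slope, intercept = np.polyfit(t, np.log(v), 1)
        x0 = np.array([np.exp(intercept), slope])

        def resid(p):
            return p[0] * np.exp(p[1] * t) - v

        sol = least_squares(resid, x0, method="trf",
                            bounds=([1e-12, -np.inf], [np.inf, np.inf]))
        params = GrowthParams(float(sol.x[0]), float(sol.x[1]))
        return GrowthFitResult(
            params=params,
            rss=float(2.0 * sol.cost),
            converged=bool(sol.success),
            n_points=int(t.size),
            message=sol.message,
        )


def fit_exponential(series: GrowthSeries) -> GrowthFitResult:
    """Convenience wrapper: fit V(t) = alpha * exp(beta t) to one series."""
    return ExponentialGrowthModel(series).fit()


def split_cohort(
    labels: Sequence[str],
    fractions: tuple[float, float, float] = (0.60, 0.35, 0.05),
    seed: int = 0,
) -> pd.Series:
    """Class-stratified train/validation/test assignment.

    Per class, ``floor(n * f_train)`` records go to training and
    ``floor(n * f_val)`` to validation; the remainder is the test set, so
    every class is represented in every partition when sizes allow.
    Returns a Series of {"train", "val", "test"} aligned with ``labels``.
    """
    if not np.isclose(sum(fractions), 1.0):
        raise ValidationError("fractions must sum to 1")
    y = pd.Series(list(labels))
    rng = np.random.default_rng(seed)
    out = pd.Series(index=y.index, dtype=object)
    for cls, idx in y.groupby(y).groups.items():
        idx = np.asarray(list(idx))
        perm = rng.permutation(idx)
        n = len(idx)
        n_tr = int(np.floor(n * fractions[0]))
        n_va = int(np.floor(n * fractions[1]))
        n_te = n - n_tr - n_va
        if min(n_tr, n_va, n_te) < 1:
            raise ValidationError(
                f"class {cls!r} has too few records ({n}) for a "
                f"{fractions} split"
            )
        out.iloc[perm[:n_tr]] = "train"
        out.iloc[perm[n_tr:n_tr + n_va]] = "val"
        out.iloc[perm[n_tr + n_va:]] = "test"
    return out


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


@dataclass
class GrowthNetwork:
    """A fitted 33-sigmoid-hidden-unit, linear-output growth predictor.

    Feature standardization and target min-max constants are fitted on the
    training partition only and stored with the weights, so predictions
    and the normalized-MSE metric are well-defined outside training.
    """

    w1: np.ndarray  # (n_features, n_hidden)
    b1: np.ndarray
    w2: np.ndarray  # (n_hidden, 2)
    b2: np.ndarray
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_min: np.ndarray  # length 2: (alpha, beta)
    y_max: np.ndarray
    seed: int = 0
    n_stages: int = 0
    val_mse: float = float("nan")

    @property
    def n_features(self) -> int:
        return self.w1.shape[0]

    def _forward_normalized(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self.x_mean) / self.x_sd
        H = _sigmoid(Z @ self.w1 + self.b1)
        return H @ self.w2 + self.b2

    def predict_normalized(self, features: pd.DataFrame | np.ndarray) -> np.ndarray:
        X = np.asarray(features, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features:
            raise ValidationError(
                f"feature vector width {X.shape[1]} != {self.n_features}"
            )
        return self._forward_normalized(X)

    def predict_params(self, features) -> pd.DataFrame:
        yn = self.predict_normalized(features)
        y = self.y_min + yn * (self.y_max - self.y_min)
        return pd.DataFrame(y, columns=["alpha", "beta"])

    def normalize_targets(self, targets: np.ndarray) -> np.ndarray:
        return (np.asarray(targets, float) - self.y_min) / (self.y_max - self.y_min)

    def to_json(self) -> str:
        payload = {
            k: np.asarray(getattr(self, k)).tolist()
            for k in ("w1", "b1", "w2", "b2", "x_mean", "x_sd", "y_min", "y_max")
        }
        payload["seed"] = self.seed
        payload["n_stages"] = self.n_stages
        payload["val_mse"] = self.val_mse
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "GrowthNetwork":
        d = json.loads(text)
        arrays = {k: np.asarray(d[k], dtype=float)
                  for k in ("w1", "b1", "w2", "b2", "x_mean", "x_sd", "y_min", "y_max")}
        return cls(**arrays, seed=int(d["seed"]), n_stages=int(d["n_stages"]),
                   val_mse=float(d["val_mse"]))


def train_growth_network(
    features: pd.DataFrame,
    targets: pd.DataFrame,
    partition: pd.Series,
    seed: int = 0,
    n_hidden: int = 33,
    max_stages: int = 60,
    iters_per_stage: int = 40,
    patience: int = 8,
) -> GrowthNetwork:
    """Fit the shallow growth network with validation early stopping.

    Full-batch L-BFGS minimizes the MSE of min-max-normalized targets,
    run in stages of ``iters_per_stage`` iterations; after each stage the
    validation MSE is measured and the best weights retained, stopping
    after ``patience`` stages without improvement.  Deterministic for a
    fixed seed.
    """
    from scipy.optimize import minimize

    X = np.asarray(features, dtype=float)
    Y = np.asarray(targets, dtype=float)
    part = np.asarray(partition)
    if X.shape[0] != Y.shape[0] or X.shape[0] != part.shape[0]:
        raise ValidationError("features, targets and partition disagree in length")
    tr = part == "train"
    va = part == "val"
    if tr.sum() < 2 or va.sum() < 1:
        raise ValidationError("need nonempty training and validation partitions")

    y_min = Y[tr].min(axis=0)
    y_max = Y[tr].max(axis=0)
    if np.any(y_max - y_min <= 0):
        raise ValidationError("degenerate targets: zero variance on training set")
    x_mean = X[tr].mean(axis=0)
    x_sd = X[tr].std(axis=0)
    x_sd[x_sd == 0] = 1.0

    d = X.shape[1]
    rng = np.random.default_rng(seed)
    shapes = [(d, n_hidden), (n_hidden,), (n_hidden, 2), (2,)]
    sizes = [int(np.prod(s)) for s in shapes]

    def unpack(theta):
        parts = np.split(theta, np.cumsum(sizes)[:-1])
        return [p.reshape(s) for p, s in zip(parts, shapes)]

    theta = np.concatenate([
        (rng.standard_normal(sizes[0]) / np.sqrt(d)),
        np.zeros(sizes[1]),
        rng.standard_normal(sizes[2]) / np.sqrt(n_hidden),
        np.zeros(sizes[3]),
    ])

    Xtr = (X[tr] - x_mean) / x_sd
    Ytr = (Y[tr] - y_min) / (y_max - y_min)
    Xva = (X[va] - x_mean) / x_sd
    Yva = (Y[va] - y_min) / (y_max - y_min)

    def loss_grad(th):
        w1, b1, w2, b2 = unpack(th)
        A = Xtr @ w1 + b1
        H = _sigmoid(A)
        P = H @ w2 + b2
        R = P - Ytr
        n = Xtr.shape[0]
        loss = float((R**2).mean())
        gP = 2.0 * R / (n * R.shape[1])
        gw2 = H.T @ gP
        gb2 = gP.sum(axis=0)
        gH = gP @ w2.T
        gA = gH * H * (1 - H)
        gw1 = Xtr.T @ gA
        gb1 = gA.sum(axis=0)
        return loss, np.concatenate([g.ravel() for g in (gw1, gb1, gw2, gb2)])

    def val_mse(th):
        w1, b1, w2, b2 = unpack(th)
        P = _sigmoid(Xva @ w1 + b1) @ w2 + b2
        return float(((P - Yva) ** 2).mean())

    best_theta = theta.copy()
    best_val = val_mse(theta)
    since_best = 0
    stage = 0
    for stage in range(1, max_stages + 1):
        res = minimize(loss_grad, theta, jac=True, method="L-BFGS-B",
                       options={"maxiter": iters_per_stage})
        theta = res.x
        v = val_mse(theta)
        if v < best_val - 1e-12:
            best_val = v
            best_theta = theta.copy()
            since_best = 0
        else:
            since_best += 1
            if since_best >= patience:
                break

    w1, b1, w2, b2 = unpack(best_theta)
    return GrowthNetwork(
        w1=w1, b1=b1, w2=w2, b2=b2,
        x_mean=x_mean, x_sd=x_sd, y_min=y_min, y_max=y_max,
        seed=seed, n_stages=stage, val_mse=best_val,
    )


def predict_growth(
    network: GrowthNetwork,
    features: pd.DataFrame | np.ndarray,
    horizon_days: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Predicted (alpha, beta) and, optionally, the growth curve V(t).

    When ``horizon_days`` is given, one extra column per requested day
    carries alpha_hat * exp(beta_hat * day).
    """
    params = network.predict_params(features)
    if horizon_days is not None:
        for day in horizon_days:
            params[f"volume_d{day:g}"] = params["alpha"] * np.exp(
                params["beta"] * float(day)
            )
    return params


def evaluate_growth_mse(
    predicted: pd.DataFrame | np.ndarray,
    true_params: pd.DataFrame | np.ndarray,
    network: GrowthNetwork,
) -> float:
    """Percent MSE of min-max-normalized (alpha, beta) targets.

    Both predictions and truth are mapped through the network's stored
    training-set normalization; the mean squared residual over all entries
    is multiplied by 100.  Identical predictions score 0%.
    """
    P = np.asarray(predicted, dtype=float)
    T = np.asarray(true_params, dtype=float)
    if P.size == 0 or P.shape != T.shape:
        raise ValidationError("predicted and true parameter arrays must match")
    pn = network.normalize_targets(P)
    tn = network.normalize_targets(T)
    return float(((pn - tn) ** 2).mean() * 100.0)
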