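"""Annual-series projection with a minimal from-scratch LSTM cell.

A single recurrent layer with the standard gated recurrence — input,
forget and output gates through a logistic squash, a tanh candidate,
``c_t = f ⊙ c_{t-1} + i ⊙ g`` and ``h_t = o_t ⊙ tanh(c_t)`` — and a
linear head mapping the final hidden state to the next annual value.
The network is univariate: it sees a sliding window of the min-max
scaled series and predicts one step ahead; multi-step projection feeds
predictions back recursively. Training is full-batch backpropagation
through time with an Adam update (plain gradient descent is available
via ``optimizer="gd"``), deterministic given the seed.

A damped-linear-trend forecaster is available for runs that must avoid
stochastic training altogether.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .core_io import ValidationError

logger = logging.getLogger("nfootprint.forecast")

GATE_NAMES = ("i", "f", "o", "g")


@dataclass
class LSTMParams:
    """Hyper-parameters, gate weights and fitted scaling of the forecaster.

    ``weights`` holds one (hidden_size, 1 + hidden_size) block and one
    bias vector per gate, plus the linear head ``Wy``/``by``; ``scaling``
    is the (min, max) of the training series.
    """

    seed: int
    hidden_size: int = 8
    window: int = 5
    epochs: int = 300
    learning_rate: float = 0.02
    optimizer: str = "adam"  # or "gd"
    weights: dict[str, np.ndarray] | None = None
    scaling: tuple[float, float] | None = None
    loss_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.hidden_size < 1 or self.window < 1:
            raise ValidationError("hidden_size and window must be >= 1")
        if self.optimizer not in ("adam", "gd"):
            raise ValidationError(f"unknown optimizer {self.optimizer!r}")
        if self.weights is not None:
            H = self.hidden_size
            for name in GATE_NAMES:
                if self.weights[f"W{name}"].shape != (H, 1 + H):
                    raise ValidationError(f"W{name} has wrong shape")
                if self.weights[f"b{name}"].shape != (H,):
                    raise ValidationError(f"b{name} has wrong shape")
            if self.weights["Wy"].shape != (H,):
                raise ValidationError("Wy has wrong shape")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def init_weights(params: LSTMParams) -> dict[str, np.ndarray]:
    """Small random gate weights; forget-gate bias starts at 1 (standard)."""
    rng = np.random.default_rng(params.seed)
    H = params.hidden_size
    w: dict[str, np.ndarray] = {}
    for name in GATE_NAMES:
        w[f"W{name}"] = rng.normal(0.0, 0.2, size=(H, 1 + H))
        w[f"b{name}"] = np.zeros(H)
    w["bf"] = np.ones(H)
    w["Wy"] = rng.normal(0.0, 0.2, size=H)
    w["by"] = np.zeros(1)
    return w


def lstm_cell_step(
    x_t: float,
    h_prev: np.ndarray,
    c_prev: np.ndarray,
    params: LSTMParams,
) -> tuple[np.ndarray, np.ndarray]:
    """One gated recurrence step; returns (h_t, C_t).

    Every component of h_t lies strictly inside (-1, 1) because it is an
    output gate in (0, 1) times a tanh in (-1, 1).
    """
    if params.weights is None:
        raise ValidationError("parameters are untrained (weights missing)")
    H = params.hidden_size
    h_prev = np.asarray(h_prev, dtype=float)
    c_prev = np.asarray(c_prev, dtype=float)
    if h_prev.shape != (H,) or c_prev.shape != (H,):
        raise ValidationError(
            f"state dimension mismatch: expected ({H},), got "
            f"{h_prev.shape} and {c_prev.shape}"
        )
    w = params.weights
    z = np.concatenate(([float(x_t)], h_prev))
    i = _sigmoid(w["Wi"] @ z + w["bi"])
    f = _sigmoid(w["Wf"] @ z + w["bf"])
    o = _sigmoid(w["Wo"] @ z + w["bo"])
    g = np.tanh(w["Wg"] @ z + w["bg"])
    c_t = f * c_prev + i * g
    h_t = o * np.tanh(c_t)
    return h_t, c_t


def _forward_batch(
    X: np.ndarray, w: dict[str, np.ndarray], H: int
) -> tuple[np.ndarray, np.ndarray, list[dict[str, np.ndarray]]]:
    """Run n windows of length T through the cell simultaneously.

    Returns predictions (n,), final hidden states (n, H) and the
    per-step activation cache needed for backpropagation through time.
    """
    n, T = X.shape
    h = np.zeros((n, H))
    c = np.zeros((n, H))
    cache: list[dict[str, np.ndarray]] = []
    for t in range(T):
        z = np.concatenate([X[:, t : t + 1], h], axis=1)  # (n, 1+H)
        i = _sigmoid(z @ w["Wi"].T + w["bi"])
        f = _sigmoid(z @ w["Wf"].T + w["bf"])
        o = _sigmoid(z @ w["Wo"].T + w["bo"])
        g = np.tanh(z @ w["Wg"].T + w["bg"])
        c_new = f * c + i * g
        h_new = o * np.tanh(c_new)
        cache.append({"z": z, "i": i, "f": f, "o": o, "g": g,
                      "c_prev": c, "c": c_new})
        h, c = h_new, c_new
    y = h @ w["Wy"] + w["by"][0]
    return y, h, cache


def _backward_batch(
    dy: np.ndarray,
    h_last: np.ndarray,
    cache: list[dict[str, np.ndarray]],
    w: dict[str, np.ndarray],
) -> dict[str, np.ndarray]:
    """Gradients of the summed squared-error loss; ``dy`` is (n,)."""
    grads = {k: np.zeros_like(v) for k, v in w.items()}
    grads["Wy"] = dy @ h_last
    grads["by"] = np.array([dy.sum()])
    dh = np.outer(dy, w["Wy"])  # (n, H)
    dc = np.zeros_like(dh)
    for step in reversed(cache):
        i, f, o, g = step["i"], step["f"], step["o"], step["g"]
        c, c_prev, z = step["c"], step["c_prev"], step["z"]
        tc = np.tanh(c)
        do = dh * tc
        dc = dc + dh * o * (1.0 - tc * tc)
        di = dc * g
        dg = dc * i
        df = dc * c_prev
        dzi = di * i * (1.0 - i)
        dzf = df * f * (1.0 - f)
        dzo = do * o * (1.0 - o)
        dzg = dg * (1.0 - g * g)
        grads["Wi"] += dzi.T @ z
        grads["Wf"] += dzf.T @ z
        grads["Wo"] += dzo.T @ z
        grads["Wg"] += dzg.T @ z
        grads["bi"] += dzi.sum(axis=0)
        grads["bf"] += dzf.sum(axis=0)
        grads["bo"] += dzo.sum(axis=0)
        grads["bg"] += dzg.sum(axis=0)
        dh = dzi @ w["Wi"][:, 1:] + dzf @ w["Wf"][:, 1:] \
            + dzo @ w["Wo"][:, 1:] + dzg @ w["Wg"][:, 1:]
        dc = dc * f
    return grads


def _scale(values: np.ndarray, scaling: tuple[float, float]) -> np.ndarray:
    lo, hi = scaling
    if hi == lo:  # zero-variance series scales to 0 and inverts exactly
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def _inverse_scale(values: np.ndarray, scaling: tuple[float, float]) -> np.ndarray:
    lo, hi = scaling
    return values * (hi - lo) + lo


def _windows(scaled: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([scaled[i : i + window] for i in range(len(scaled) - window)])
    y = scaled[window:]
    return X, y


def fit_forecaster(series: Sequence[float], params: LSTMParams) -> LSTMParams:
    """Train the forecaster on an annual series; deterministic given
    ``params.seed``.

    Min-max scaling is fitted on the training series only. Full-batch
    gradients are applied with Adam by default (plain gradient descent
    via ``optimizer="gd"``). The recorded loss history is monitored:
    a final loss above 5% over its running best emits a warning.
    """
    values = np.asarray(list(series), dtype=float)
    if values.size <= params.window + 1:
        raise ValidationError(
            f"series of length {values.size} too short for window {params.window}"
        )
    if not np.isfinite(values).all():
        raise ValidationError("series contains non-finite values")
    scaling = (float(values.min()), float(values.max()))
    scaled = _scale(values, scaling)
    X, y = _windows(scaled, params.window)
    n = len(X)
    w = init_weights(params)
    H = params.hidden_size
    losses: list[float] = []
    m = {k: np.zeros_like(v) for k, v in w.items()}
    v = {k: np.zeros_like(v_) for k, v_ in w.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    for epoch in range(1, params.epochs + 1):
        preds, h_last, cache = _forward_batch(X, w, H)
        err = preds - y
        losses.append(float(0.5 * np.mean(err**2)))
        grads = _backward_batch(err / n, h_last, cache, w)
        if params.optimizer == "adam":
            for k in w:
                m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                v[k] = beta2 * v[k] + (1 - beta2) * grads[k] ** 2
                mhat = m[k] / (1 - beta1**epoch)
                vhat = v[k] / (1 - beta2**epoch)
                w[k] = w[k] - params.learning_rate * mhat / (np.sqrt(vhat) + eps)
        else:
            for k in w:
                w[k] = w[k] - params.learning_rate * grads[k]
    if losses and losses[-1] > 1.05 * min(losses):
        logger.warning(
            "training loss ended above its running best (%.3g > %.3g); "
            "consider a smaller learning rate",
            losses[-1],
            min(losses),
        )
    return replace(params, weights=w, scaling=scaling, loss_history=losses)


@dataclass(frozen=True)
class ProjectionResult:
    """Recursive multi-step projection with in-sample one-step RMSE."""

    scenario: str
    years: tuple[int, ...]
    values: tuple[float, ...]
    rmse: float
    seed: int


def one_step_predictions(series: Sequence[float], trained: LSTMParams) -> np.ndarray:
    """In-sample one-step-ahead predictions on the original scale."""
    if trained.weights is None or trained.scaling is None:
        raise ValidationError("forecaster is not trained")
    values = np.asarray(list(series), dtype=float)
    scaled = _scale(values, trained.scaling)
    X, _ = _windows(scaled, trained.window)
    preds, _, _ = _forward_batch(X, trained.weights, trained.hidden_size)
    return _inverse_scale(preds, trained.scaling)


def project(
    series: Sequence[float],
    trained: LSTMParams,
    horizon: int,
    last_year: int = 2013,
    scenario: str = "BAU",
) -> ProjectionResult:
    """Project annual values from ``last_year + 1`` through ``horizon``.

    Predictions are fed back as inputs (recursive multi-step forecast)
    and inverse-scaled to kg-N. The reported RMSE is the in-sample
    one-step error on the training span.
    """
    if trained.weights is None or trained.scaling is None:
        raise ValidationError("forecaster is not trained")
    if horizon <= last_year:
        raise ValidationError(
            f"horizon {horizon} not beyond last observed year {last_year}"
        )
    values = np.asarray(list(series), dtype=float)
    scaled = list(_scale(values, trained.scaling))
    preds_scaled: list[float] = []
    for _ in range(horizon - last_year):
        window = np.asarray(scaled[-trained.window :])[None, :]
        pred, _, _ = _forward_batch(window, trained.weights, trained.hidden_size)
        preds_scaled.append(float(pred[0]))
        scaled.append(float(pred[0]))
    projected = _inverse_scale(np.asarray(preds_scaled), trained.scaling)
    fit = one_step_predictions(values, trained)
    fit_rmse = rmse(fit, values[trained.window :])
    return ProjectionResult(
        scenario=scenario,
        years=tuple(range(last_year + 1, horizon + 1)),
        values=tuple(float(v) for v in projected),
        rmse=fit_rmse,
        seed=trained.seed,
    )


def rmse(predicted: Sequence[float], observed: Sequence[float]) -> float:
    """Root mean square error between two equal-length series."""
    p = np.asarray(list(predicted), dtype=float)
    o = np.asarray(list(observed), dtype=float)
    if p.shape != o.shape or p.size == 0:
        raise ValidationError(
            f"length mismatch or empty input: {p.shape} vs {o.shape}"
        )
    return float(np.sqrt(np.mean((p - o) ** 2)))


def trend_projection(
    series: Sequence[float],
    horizon: int,
    last_year: int = 2013,
    damping: float = 0.98,
    scenario: str = "BAU",
) -> ProjectionResult:
    """Deterministic damped-linear-trend fallback forecaster.

    The recent trend (mean first difference of the last ten points) is
    extrapolated with geometric damping — no stochastic training.
    """
    values = np.asarray(list(series), dtype=float)
    if values.size < 2:
        raise ValidationError("series too short for a trend")
    if horizon <= last_year:
        raise ValidationError(
            f"horizon {horizon} not beyond last observed year {last_year}"
        )
    tail = values[-10:]
    slope = float(np.mean(np.diff(tail)))
    level = float(values[-1])
    out = []
    step = slope
    for _ in range(horizon - last_year):
        level += step
        step *= damping
        out.append(level)
    naive_fit = values[:-1]
    return ProjectionResult(
        scenario=scenario,
        years=tuple(range(last_year + 1, horizon + 1)),
        values=tuple(out),
        rmse=rmse(naive_fit, values[1:]),
        seed=0,
    )
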