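"""One-day-ahead forecasting of the smoothed DF signal with an LSTM.

The forecaster follows the classical sequence-to-sequence regression recipe:
the resampled DF signal up to soaking day n-1 is z-scored with its own mean
and standard deviation, the network is trained to map each sample to the next
(inputs x[1..T-1], targets x[2..T]), and day n is generated closed-loop — the
state first consumes the whole training sequence, then each predicted sample
is fed back as the next input until the day's ``samples_per_day`` samples are
produced. Walk-forward validation repeats this with a fresh model per day,
training only on history strictly before the predicted day.

The LSTM itself is a compact univariate implementation (fused-gate forward,
full backpropagation through time, Adam, global-norm gradient clipping) whose
defaults are 200 hidden units, 250 epochs, initial learning rate 0.005 and
gradient threshold 1. Training is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import DegenerateInputError, ValidationError
from .smoothing import SmoothedSignal

__all__ = [
    "ForecasterConfig",
    "TrainedForecaster",
    "ForecastResult",
    "train_one_step_model",
    "predict_day",
    "walk_forward",
    "persistence_forecast",
    "write_forecast_csv",
]

_STD_FLOOR = 1e-12  # constant training signals get std = 1 (see docs/methods.md)


@dataclass
class ForecasterConfig:
    """Training protocol of the one-step-ahead LSTM."""

    hidden_units: int = 200
    epochs: int = 250
    learning_rate: float = 0.005
    gradient_clip_threshold: float = 1.0
    optimizer: str = "adam"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.hidden_units, self.epochs) < 1:
            raise ValidationError("hidden_units and epochs must be positive")
        if self.learning_rate <= 0 or self.gradient_clip_threshold <= 0:
            raise ValidationError("learning_rate and gradient_clip_threshold must be > 0")
        if self.optimizer != "adam":
            raise ValidationError("only the adam solver is supported")
        if self.seed is None:
            raise ValidationError("a seed is mandatory for any training run")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ForecasterConfig":
        with open(path) as fh:
            spec = yaml.safe_load(fh) or {}
        return cls(**spec)


class _LSTMParams:
    """Fused-gate LSTM weights: gate order (input, forget, candidate, output)."""

    def __init__(self, hidden: int, rng: np.random.Generator):
        h = hidden
        lim_x = np.sqrt(6.0 / (1 + h))
        wx = rng.uniform(-lim_x, lim_x, size=(4 * h, 1))
        # orthogonal recurrent blocks, one per gate
        wh = np.concatenate(
            [np.linalg.qr(rng.standard_normal((h, h)))[0] for _ in range(4)], axis=0
        )
        self.w = np.concatenate([wx, wh], axis=1)       # (4h, 1 + h)
        self.b = np.zeros(4 * h)
        self.b[h: 2 * h] = 1.0                          # unit forget-gate bias
        lim_y = np.sqrt(6.0 / (h + 1))
        self.wy = rng.uniform(-lim_y, lim_y, size=h)
        self.by = 0.0
        self.h = h

    def flat(self) -> list[np.ndarray]:
        return [self.w, self.b, self.wy, np.atleast_1d(self.by)]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _forward(p: _LSTMParams, inputs: np.ndarray, h0=None, c0=None, cache: bool = False):
    """Run the sequence; returns outputs y[t], final (h, c) and optional tape."""
    hsz = p.h
    h = np.zeros(hsz) if h0 is None else h0
    c = np.zeros(hsz) if c0 is None else c0
    t_len = inputs.size
    ys = np.empty(t_len)
    tape = [] if cache else None
    for t in range(t_len):
        xh = np.concatenate(([inputs[t]], h))
        z = p.w @ xh + p.b
        i = _sigmoid(z[:hsz])
        f = _sigmoid(z[hsz: 2 * hsz])
        g = np.tanh(z[2 * hsz: 3 * hsz])
        o = _sigmoid(z[3 * hsz:])
        c_prev = c
        c = f * c + i * g
        tc = np.tanh(c)
        h = o * tc
        ys[t] = p.wy @ h + p.by
        if cache:
            tape.append((xh, i, f, g, o, c_prev, tc, h))
    return ys, h, c, tape


def _backward(p: _LSTMParams, tape, dys: np.ndarray):
    """BPTT gradients of the summed per-step losses w.r.t. all parameters."""
    hsz = p.h
    dw = np.zeros_like(p.w)
    db = np.zeros_like(p.b)
    dwy = np.zeros_like(p.wy)
    dby = 0.0
    dh_next = np.zeros(hsz)
    dc_next = np.zeros(hsz)
    for t in range(len(tape) - 1, -1, -1):
        xh, i, f, g, o, c_prev, tc, h = tape[t]
        dy = dys[t]
        dwy += dy * h
        dby += dy
        dh = dy * p.wy + dh_next
        do = dh * tc
        dc = dh * o * (1.0 - tc * tc) + dc_next
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dc_next = dc * f
        dz = np.concatenate([
            di * i * (1.0 - i),
            df * f * (1.0 - f),
            dg * (1.0 - g * g),
            do * o * (1.0 - o),
        ])
        dw += np.outer(dz, xh)
        db += dz
        dh_next = (p.w.T @ dz)[1:]
    return [dw, db, dwy, np.atleast_1d(dby)]


@dataclass
class TrainedForecaster:
    """An LSTM trained through ``trained_through`` plus its standardization constants."""

    params: _LSTMParams
    train_mean: float
    train_std: float
    trained_through: float
    samples_per_day: int
    last_hidden: np.ndarray
    last_cell: np.ndarray
    next_sample: float          # one-step-ahead output after consuming the training run
    loss_history: np.ndarray
    config: ForecasterConfig = field(repr=False, default=None)


def train_one_step_model(
    signal: SmoothedSignal, upto_day: float, config: ForecasterConfig
) -> TrainedForecaster:
    """Train the one-step-ahead LSTM on all samples at positions <= upto_day.

    The training segment is z-scored, shifted by one step into (input, target)
    pairs, and fit with Adam for exactly ``config.epochs`` full-sequence
    epochs (no early stopping). Deterministic given ``config.seed``.
    """
    series = signal.upto(upto_day)
    if series.size < 2:
        raise DegenerateInputError("need at least 2 training samples")
    if not np.all(np.isfinite(series)):
        raise ValidationError("training signal contains non-finite values")

    mean = float(series.mean())
    std = float(series.std())
    if std < _STD_FLOOR:
        std = 1.0
    x = (series - mean) / std
    inputs, targets = x[:-1], x[1:]

    rng = np.random.default_rng(config.seed)
    p = _LSTMParams(config.hidden_units, rng)
    adam_m = [np.zeros_like(a) for a in p.flat()]
    adam_v = [np.zeros_like(a) for a in p.flat()]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    n = inputs.size
    losses = np.empty(config.epochs)

    for epoch in range(config.epochs):
        ys, _, _, tape = _forward(p, inputs, cache=True)
        err = ys - targets
        losses[epoch] = float(np.mean(err**2))
        grads = _backward(p, tape, 2.0 * err / n)
        gnorm = np.sqrt(sum(float(np.sum(g * g)) for g in grads))
        if gnorm > config.gradient_clip_threshold:
            scale = config.gradient_clip_threshold / gnorm
            grads = [g * scale for g in grads]
        t_step = epoch + 1
        params = p.flat()
        for k, (a, g) in enumerate(zip(params, grads)):
            adam_m[k] = beta1 * adam_m[k] + (1 - beta1) * g
            adam_v[k] = beta2 * adam_v[k] + (1 - beta2) * g * g
            m_hat = adam_m[k] / (1 - beta1**t_step)
            v_hat = adam_v[k] / (1 - beta2**t_step)
            a -= config.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
        p.by = float(params[3][0])

    # consume the full training sequence so the state is ready to generate day n
    ys, h, c, _ = _forward(p, x)
    return TrainedForecaster(
        params=p, train_mean=mean, train_std=std,
        trained_through=float(upto_day), samples_per_day=signal.samples_per_day,
        last_hidden=h, last_cell=c, next_sample=float(ys[-1]),
        loss_history=losses, config=config,
    )


@dataclass
class ForecastResult:
    """Predicted vs. actual resampled DF samples for one held-out soaking day."""

    day_predicted: int
    positions: np.ndarray
    predicted: np.ndarray
    actual: np.ndarray
    train_last_day: float
    method: str = "lstm"


def predict_day(model: TrainedForecaster, signal: SmoothedSignal, day: float) -> ForecastResult:
    """Generate day ``day``'s samples closed-loop and pair them with the actuals.

    Each predicted sample is fed back as the next input; outputs are
    de-standardized with the training constants. Requires the model to be
    trained exactly through day-1.
    """
    if not np.isclose(model.trained_through, day - 1):
        raise ValidationError(
            f"model trained through {model.trained_through}, cannot predict day {day}"
        )
    positions, actual = signal.segment(day)
    n = signal.samples_per_day
    if positions.size != n:
        raise ValidationError(f"signal does not cover day {day}")

    preds_std = np.empty(n)
    preds_std[0] = model.next_sample
    h, c = model.last_hidden, model.last_cell
    p = model.params
    for k in range(1, n):
        ys, h, c, _ = _forward(p, np.array([preds_std[k - 1]]), h0=h, c0=c)
        preds_std[k] = ys[0]
    predicted = preds_std * model.train_std + model.train_mean
    return ForecastResult(
        day_predicted=int(round(day)), positions=positions,
        predicted=predicted, actual=actual,
        train_last_day=float(day - 1), method="lstm",
    )


def persistence_forecast(signal: SmoothedSignal, day: float) -> ForecastResult:
    """Deterministic baseline: repeat the last observed training value."""
    positions, actual = signal.segment(day)
    if positions.size != signal.samples_per_day:
        raise ValidationError(f"signal does not cover day {day}")
    last = signal.upto(day - 1)
    if last.size == 0:
        raise ValidationError(f"no history before day {day}")
    return ForecastResult(
        day_predicted=int(round(day)), positions=positions,
        predicted=np.full(positions.size, last[-1]), actual=actual,
        train_last_day=float(day - 1), method="persistence",
    )


def walk_forward(
    signal: SmoothedSignal,
    first_predicted_day: int = 4,
    config: ForecasterConfig | None = None,
    baseline: str | None = None,
    max_history_days: int | None = None,
) -> list[ForecastResult]:
    """Per-day walk-forward evaluation over the tail of the soak test.

    For each integer day n from ``first_predicted_day`` to the last day, a
    fresh model is trained on data strictly before day n (all history by
    default, the trailing ``max_history_days`` days when set) and day n's
    samples are predicted closed-loop. ``baseline="persistence"`` swaps in the
    deterministic last-value forecaster.
    """
    first_day = int(round(signal.positions[0]))
    last_day = int(round(signal.positions[-1]))
    if first_predicted_day - first_day < 3:
        raise ValidationError(
            f"need >= 3 training days before day {first_predicted_day}"
        )
    if first_predicted_day > last_day:
        raise ValidationError("first_predicted_day beyond the signal")

    results = []
    for day in range(first_predicted_day, last_day + 1):
        if baseline == "persistence":
            results.append(persistence_forecast(signal, day))
            continue
        train_signal = signal
        if max_history_days is not None:
            eps = 0.5 / signal.samples_per_day
            keep = signal.positions >= day - 1 - max_history_days - eps / 2
            train_signal = SmoothedSignal(
                positions=signal.positions[keep], values=signal.values[keep],
                samples_per_day=signal.samples_per_day, knot_days=signal.knot_days,
            )
        model = train_one_step_model(train_signal, day - 1, config or ForecasterConfig())
        results.append(predict_day(model, signal, day))
    return results


def write_forecast_csv(result: ForecastResult, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("position_day,actual,predicted\n")
        for p_, a, y in zip(result.positions, result.actual, result.predicted):
            fh.write(f"{p_:.17g},{a:.17g},{y:.17g}\n")
    return path
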