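"""Spline conversion of discrete per-day DF values into a continuous signal.

Soaking days are sparse and may have calendar gaps, while the forecaster wants
a densely, uniformly sampled sequence. A cubic spline is fitted through (or
near) the (day, normalized DF) points and evaluated on a uniform fractional-day
grid spanning [first day, last day], with ``samples_per_day`` points per day.

Modes
-----
``interpolate`` (default)
    Not-a-knot interpolating cubic spline — parameter-free and exactly
    reproduces the DF values at the knot days.
``pchip``
    Monotone shape-preserving cubic (no overshoot between sparse points).
``smooth``
    Smoothing spline with residual budget ``smoothing``; at smoothing → 0 it
    degenerates to the interpolant.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline, PchipInterpolator, UnivariateSpline

from .errors import DegenerateInputError, ValidationError
from .reduction import DFSeries

__all__ = ["SmoothedSignal", "fit_and_resample", "write_signal_csv", "read_signal_csv"]


@dataclass
class SmoothedSignal:
    """A resampled continuous DF signal on a uniform fractional-day axis."""

    positions: np.ndarray
    values: np.ndarray
    samples_per_day: int
    knot_days: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.knot_days = np.asarray(self.knot_days)
        if self.positions.size != self.values.size:
            raise ValidationError("positions and values must have equal length")

    def segment(self, day: float) -> tuple[np.ndarray, np.ndarray]:
        """Positions and values of the samples covering (day-1, day]."""
        eps = 0.5 / self.samples_per_day
        mask = (self.positions > day - 1 + eps / 2) & (self.positions <= day + eps / 2)
        return self.positions[mask], self.values[mask]

    def upto(self, day: float) -> np.ndarray:
        """Values at positions <= day (the training prefix for forecasting)."""
        eps = 0.5 / self.samples_per_day
        return self.values[self.positions <= day + eps / 2]


def fit_and_resample(
    series: DFSeries,
    samples_per_day: int = 10,
    mode: str = "interpolate",
    smoothing: float = 0.0,
) -> SmoothedSignal:
    """Fit a cubic spline to the normalized DF points and resample uniformly.

    The grid spans [first day, last day] with spacing ``1/samples_per_day``,
    giving ``(last - first) * samples_per_day + 1`` samples; calendar gaps
    between soaking days are spanned by the spline rather than collapsed.
    """
    days = np.asarray(series.days, dtype=float)
    values = np.asarray(series.normalized, dtype=float)
    if days.size < 2:
        raise DegenerateInputError("need at least 2 days to fit a spline")
    if np.unique(days).size != days.size:
        raise ValidationError("duplicate day labels")
    if samples_per_day < 1:
        raise ValidationError("samples_per_day must be >= 1")

    if mode == "interpolate":
        if days.size >= 4:
            curve = CubicSpline(days, values, bc_type="not-a-knot")
        else:  # not-a-knot needs 4 points; fall back to the max possible degree
            curve = UnivariateSpline(days, values, k=days.size - 1, s=0.0)
    elif mode == "pchip":
        curve = PchipInterpolator(days, values)
    elif mode == "smooth":
        if smoothing < 0:
            raise ValidationError("smoothing must be >= 0")
        k = min(3, days.size - 1)
        curve = UnivariateSpline(days, values, k=k, s=float(smoothing))
    else:
        raise ValidationError(f"unknown mode {mode!r}")

    n = int(round((days[-1] - days[0]) * samples_per_day)) + 1
    positions = days[0] + np.arange(n) / samples_per_day
    resampled = np.asarray(curve(positions), dtype=float)
    if mode in ("interpolate", "pchip"):
        # pin exact endpoint/knot values against spline round-off
        knot_idx = np.rint((days - days[0]) * samples_per_day).astype(int)
        resampled[knot_idx] = values
    return SmoothedSignal(
        positions=positions, values=resampled,
        samples_per_day=int(samples_per_day), knot_days=series.days,
    )


def write_signal_csv(signal: SmoothedSignal, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("position_day,value\n")
        for p, v in zip(signal.positions, signal.values):
            fh.write(f"{p:.17g},{v:.17g}\n")
    return path


def read_signal_csv(path: str | Path, samples_per_day: int | None = None) -> SmoothedSignal:
    """Load a resampled signal; infers samples_per_day from the grid spacing."""
    frame = pd.read_csv(path)
    positions = frame["position_day"].to_numpy(dtype=float)
    if samples_per_day is None:
        samples_per_day = int(round(1.0 / np.diff(positions).mean()))
    knots = positions[np.isclose(positions, np.round(positions))]
    return SmoothedSignal(
        positions=positions,
        values=frame["value"].to_numpy(dtype=float),
        samples_per_day=samples_per_day,
        knot_days=np.round(knots).astype(int),
    )
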