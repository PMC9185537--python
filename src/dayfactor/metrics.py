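"""Prediction-quality statistics for the walk-forward DF forecasts.

Two complementary accuracies, both in percent:

* AFS (accuracy of final state) — how close the last predicted sample of the
  held-out day lands to the true last sample, with the error normalized by the
  full range (max - min) of the actual smoothed DF signal:
  ``100 * (1 - |pred_final - act_final| / range)``. By default the error is
  taken in absolute value so AFS <= 100; a ``signed=True`` mode evaluates the
  raw formula, in which under-prediction can push AFS above 100.
  Over-shooting by more than the full range gives a negative AFS; it is
  reported, not clamped.

* ACC (accuracy of correlation coefficients) — the absolute Pearson
  correlation between the predicted and actual sample vectors of the held-out
  day, i.e. whether the forecast reproduced the day's slope and shape
  regardless of offset or scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import UndefinedMetricError
from .forecast import ForecastResult
from .smoothing import SmoothedSignal

__all__ = ["EvalReport", "afs", "acc", "evaluate", "write_report_csv"]


@dataclass
class EvalReport:
    """Per-day accuracy summary; acc_percent is None when undefined."""

    day_predicted: int
    afs_percent: float
    acc_percent: float | None


def afs(result: ForecastResult, actual_series: SmoothedSignal, signed: bool = False) -> float:
    """Accuracy of final state, percent.

    The range in the denominator is taken over the entire actual smoothed DF
    signal, not just the predicted day's segment.
    """
    rng = float(actual_series.values.max() - actual_series.values.min())
    if rng == 0.0:
        raise UndefinedMetricError("actual DF signal has zero range; AFS undefined")
    err = result.predicted[-1] - result.actual[-1]
    if not signed:
        err = abs(err)
    return float(100.0 * (1.0 - err / rng))


def acc(result: ForecastResult) -> float:
    """Accuracy of correlation coefficients, percent: 100 * |Pearson r|."""
    a = np.asarray(result.actual, dtype=float)
    b = np.asarray(result.predicted, dtype=float)
    if a.std() == 0.0 or b.std() == 0.0:
        raise UndefinedMetricError(
            "zero-variance segment; the correlation coefficient is undefined"
        )
    r = np.corrcoef(a, b)[0, 1]
    return float(100.0 * abs(r))


def evaluate(
    results: list[ForecastResult], actual_series: SmoothedSignal, signed: bool = False
) -> list[EvalReport]:
    """AFS/ACC per walk-forward day; undefined ACCs are reported as None."""
    reports = []
    for res in results:
        try:
            acc_val = acc(res)
        except UndefinedMetricError:
            acc_val = None
        reports.append(
            EvalReport(
                day_predicted=res.day_predicted,
                afs_percent=afs(res, actual_series, signed=signed),
                acc_percent=acc_val,
            )
        )
    return reports


def write_report_csv(reports: list[EvalReport], path: str | Path,
                     header_meta: dict | None = None) -> Path:
    """CSV export (day, afs_percent, acc_percent); metadata as '#' header lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for key, val in (header_meta or {}).items():
            fh.write(f"# {key}={val}\n")
        fh.write("day,afs_percent,acc_percent\n")
        for r in reports:
            acc_str = "" if r.acc_percent is None else f"{r.acc_percent:.17g}"
            fh.write(f"{r.day_predicted},{r.afs_percent:.17g},{acc_str}\n")
    return path
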