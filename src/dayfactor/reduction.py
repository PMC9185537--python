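"""Day-factor (DF) reduction of EIS spectra, and the PCA first-component baseline.

The day factor collapses one day's impedance sweep into a single scalar

    DF_raw(d) = sum_k w_k * |log Z_k(d)|,     w_k = 1 / f_k  (default),

a frequency-weighted sum of absolute log-magnitudes, and reports the series
normalized to the first soaking day,

    DF(d) = DF_raw(d) / DF_raw(1),

so DF(1) == 1 and values below/above 1 flag impedance moving below/above the
day-1 reference. The reciprocal-frequency weights make the low end of the
sweep — the band most diagnostic of electrode aging — dominate the summary.
The weight scheme is pluggable: custom per-frequency weights let the analyst
emphasise other bands without touching the formula.

The PCA baseline treats frequencies as observations and soaking days as
variables, column-centers, takes the first right singular vector (one loading
per day) and normalizes it to the first day's coefficient, mirroring how the
DF series is normalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .eis_data import MeanSpectrumSeries
from .errors import DegenerateInputError, ValidationError

__all__ = [
    "WeightScheme",
    "DFSeries",
    "PCAResult",
    "raw_day_factor",
    "df_series",
    "per_channel_df",
    "pca_first_component",
    "write_series_csv",
]

_LOG = {"natural": np.log, "base10": np.log10}


@dataclass
class WeightScheme:
    """Per-frequency weights w_k and the log base used inside the day factor.

    ``kind="reciprocal_frequency"`` (default) sets w_k = 1/f_k; ``kind="custom"``
    uses user-supplied positive weights, one per grid frequency.
    """

    kind: str = "reciprocal_frequency"
    weights: np.ndarray | None = None
    log_base: str = "natural"

    def __post_init__(self) -> None:
        if self.kind not in ("reciprocal_frequency", "custom"):
            raise ValidationError(f"unknown weight scheme kind {self.kind!r}")
        if self.log_base not in _LOG:
            raise ValidationError(f"log_base must be 'natural' or 'base10', got {self.log_base!r}")
        if self.kind == "custom":
            if self.weights is None:
                raise ValidationError("custom scheme requires explicit weights")
            self.weights = np.asarray(self.weights, dtype=float)
            if np.any(self.weights <= 0) or not np.all(np.isfinite(self.weights)):
                raise ValidationError("custom weights must be finite and > 0")

    def weights_for(self, frequencies: np.ndarray) -> np.ndarray:
        frequencies = np.asarray(frequencies, dtype=float)
        if self.kind == "reciprocal_frequency":
            return 1.0 / frequencies
        if self.weights.size != frequencies.size:
            raise ValidationError(
                f"custom weights length {self.weights.size} != grid length {frequencies.size}"
            )
        return self.weights

    def log(self, values: np.ndarray) -> np.ndarray:
        return _LOG[self.log_base](values)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "WeightScheme":
        with open(path) as fh:
            spec = yaml.safe_load(fh) or {}
        return cls(
            kind=spec.get("kind", "reciprocal_frequency"),
            weights=spec.get("weights"),
            log_base=spec.get("log_base", "natural"),
        )


@dataclass
class DFSeries:
    """Raw and day-1-normalized day-factor values, one per soaking day."""

    days: np.ndarray
    raw: np.ndarray
    normalized: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=int)
        self.raw = np.asarray(self.raw, dtype=float)
        self.normalized = np.asarray(self.normalized, dtype=float)
        if not (self.days.size == self.raw.size == self.normalized.size):
            raise ValidationError("days, raw and normalized must have equal length")


@dataclass
class PCAResult:
    """First-principal-component loadings per day, raw and first-day-normalized."""

    coefficients: np.ndarray
    normalized_coefficients: np.ndarray


def raw_day_factor(
    magnitudes: np.ndarray, frequencies: np.ndarray, scheme: WeightScheme | None = None
) -> float:
    """One day's raw day factor: sum_k w_k * |log Z_k|.

    ``magnitudes`` are impedance magnitudes in ohms (the log is unit-dependent,
    so ohms are part of the contract), ``frequencies`` in Hz.
    """
    scheme = scheme or WeightScheme()
    magnitudes = np.asarray(magnitudes, dtype=float)
    frequencies = np.asarray(frequencies, dtype=float)
    if magnitudes.shape != frequencies.shape or magnitudes.ndim != 1:
        raise ValidationError("magnitudes and frequencies must be 1-D of equal length")
    if np.any(magnitudes <= 0) or np.any(frequencies <= 0):
        raise ValidationError("magnitudes and frequencies must be > 0")
    w = scheme.weights_for(frequencies)
    return float(np.sum(w * np.abs(scheme.log(magnitudes))))


def df_series(series: MeanSpectrumSeries, scheme: WeightScheme | None = None) -> DFSeries:
    """Day-factor series of a channel-averaged spectrum set, normalized to day 1."""
    scheme = scheme or WeightScheme()
    w = scheme.weights_for(series.frequencies)
    raw = np.sum(w * np.abs(scheme.log(series.mean_magnitude)), axis=1)
    if raw[0] == 0.0:
        raise DegenerateInputError(
            "day-1 raw day factor is zero; cannot normalize to the reference day"
        )
    return DFSeries(days=series.days, raw=raw, normalized=raw / raw[0])


def per_channel_df(
    magnitude: np.ndarray, days: np.ndarray, frequencies: np.ndarray,
    scheme: WeightScheme | None = None,
) -> list[DFSeries]:
    """Convenience loop: a DF series per channel of a ``[day, freq, channel]`` tensor.

    The reference pipeline averages channels first (see :func:`df_series`);
    this per-channel view is for inspecting individual recording sites.
    """
    return [
        df_series(
            MeanSpectrumSeries(days=days, frequencies=frequencies,
                               mean_magnitude=magnitude[:, :, c]),
            scheme,
        )
        for c in range(magnitude.shape[2])
    ]


def pca_first_component(series: MeanSpectrumSeries) -> PCAResult:
    """First principal component of the day-by-day spectra, one loading per day.

    Frequencies are the observations (rows), soaking days the variables
    (columns). The matrix is column-centered and decomposed by SVD; the first
    right singular vector is the coefficient vector. Its sign is fixed so the
    first entry is positive, then the vector is normalized to its first entry —
    after which the sign choice is immaterial.
    """
    if series.days.size < 2 or series.frequencies.size < 2:
        raise DegenerateInputError("PCA needs at least 2 days and 2 frequencies")
    x = series.mean_magnitude.T.astype(float)          # (n_freqs, n_days)
    centered = x - x.mean(axis=0, keepdims=True)
    if not np.any(np.abs(centered) > 0):
        raise DegenerateInputError("zero-variance matrix after centering")
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    coeff = vt[0]
    # tie-break orientation: first nonzero entry positive
    nz = np.flatnonzero(np.abs(coeff) > 0)
    if coeff[nz[0]] < 0:
        coeff = -coeff
    if coeff[0] == 0.0:
        raise DegenerateInputError("first-day coefficient is zero; cannot normalize")
    return PCAResult(coefficients=coeff, normalized_coefficients=coeff / coeff[0])


def write_series_csv(days: np.ndarray, values: np.ndarray, path: str | Path,
                     value_name: str = "value") -> Path:
    """Two-column (day, value) CSV export shared by the DF and PCA series."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"day,{value_name}\n")
        for d, v in zip(days, values):
            fh.write(f"{d},{v:.17g}\n")
    return path
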