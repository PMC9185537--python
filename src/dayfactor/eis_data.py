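"""Data model and file I/O for multi-day, multi-channel EIS sweeps.

An electrochemical impedance spectroscopy (EIS) soak test yields, for every
soaking day and every recording channel of a microarray, one impedance sweep:
magnitude (ohms) and optionally phase (degrees) over a shared frequency grid.
The canonical in-memory container is :class:`EISDataset`, a dense
``[day, frequency, channel]`` tensor; the canonical file format is a flat
long-format CSV (columns ``day, channel, frequency_hz, magnitude_ohm`` and
optionally ``phase_deg``).

Day labels are calendar indices, not measurement ordinals, so gaps between
soaking days stay visible to the downstream spline smoother.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, GridMismatchError, ValidationError

__all__ = [
    "EISDataset",
    "MeanSpectrumSeries",
    "read_eis_csv",
    "write_eis_csv",
    "mean_over_channels",
]

_REQUIRED_COLUMNS = ("day", "channel", "frequency_hz", "magnitude_ohm")


@dataclass
class EISDataset:
    """A multi-day, multi-channel set of impedance sweeps.

    Parameters
    ----------
    days
        Strictly increasing integer soaking-day labels (day 1 = first
        measurement). Calendar gaps are allowed and preserved.
    frequencies
        Strictly increasing frequency grid in Hz, shared by every sweep.
    magnitude
        Impedance magnitudes in ohms, shape ``(n_days, n_freqs, n_channels)``,
        all finite and strictly positive.
    phase
        Optional phase in degrees, same shape as ``magnitude``.
    meta
        Free-form provenance (instrument, RMS excitation, soaking medium...).
    """

    days: np.ndarray
    frequencies: np.ndarray
    magnitude: np.ndarray
    phase: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=int)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        if self.phase is not None:
            self.phase = np.asarray(self.phase, dtype=float)
        self._validate()

    def _validate(self) -> None:
        if self.days.ndim != 1 or self.days.size < 1:
            raise ValidationError("need at least one soaking day")
        if np.any(np.diff(self.days) <= 0):
            raise ValidationError("day labels must be strictly increasing")
        if self.frequencies.ndim != 1 or self.frequencies.size < 1:
            raise ValidationError("need at least one frequency")
        if np.any(self.frequencies <= 0) or not np.all(np.isfinite(self.frequencies)):
            raise ValidationError("frequencies must be finite and > 0")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValidationError("frequency grid must be strictly increasing")
        expected = (self.days.size, self.frequencies.size)
        if self.magnitude.ndim != 3 or self.magnitude.shape[:2] != expected:
            raise ValidationError(
                f"magnitude must have shape (n_days={expected[0]}, "
                f"n_freqs={expected[1]}, n_channels); got {self.magnitude.shape}"
            )
        if self.n_channels < 1:
            raise ValidationError("need at least one channel")
        if not np.all(np.isfinite(self.magnitude)) or np.any(self.magnitude <= 0):
            raise ValidationError("all magnitudes must be finite and > 0")
        if self.phase is not None and self.phase.shape != self.magnitude.shape:
            raise ValidationError("phase must have the same shape as magnitude")

    @property
    def n_days(self) -> int:
        return self.days.size

    @property
    def n_frequencies(self) -> int:
        return self.frequencies.size

    @property
    def n_channels(self) -> int:
        return self.magnitude.shape[2]


@dataclass
class MeanSpectrumSeries:
    """Channel-averaged impedance spectra: one magnitude per (day, frequency).

    This is the representation the day-factor reduction consumes — the
    arithmetic mean of the magnitudes of all recording sites, expressed as one
    impedance value for each frequency and soaking day.
    """

    days: np.ndarray
    frequencies: np.ndarray
    mean_magnitude: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=int)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.mean_magnitude = np.asarray(self.mean_magnitude, dtype=float)
        if self.mean_magnitude.shape != (self.days.size, self.frequencies.size):
            raise ValidationError("mean_magnitude must have shape (n_days, n_freqs)")
        if np.any(self.mean_magnitude <= 0) or not np.all(np.isfinite(self.mean_magnitude)):
            raise ValidationError("mean magnitudes must be finite and > 0")


def mean_over_channels(dataset: EISDataset) -> MeanSpectrumSeries:
    """Average impedance magnitude over all recording channels.

    The arithmetic mean of magnitudes (not of complex impedance) per
    (day, frequency) cell.
    """
    return MeanSpectrumSeries(
        days=dataset.days,
        frequencies=dataset.frequencies,
        mean_magnitude=dataset.magnitude.mean(axis=2),
    )


def read_eis_csv(path: str | Path) -> EISDataset:
    """Read a long-format EIS CSV into a validated :class:`EISDataset`.

    Expected columns: ``day, channel, frequency_hz, magnitude_ohm`` and
    optionally ``phase_deg``. Rows may arrive in any order; every
    (day, channel) pair must carry the identical frequency grid. Descending
    sweeps are accepted and sorted ascending.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    has_phase = "phase_deg" in frame.columns

    days = np.sort(frame["day"].unique())
    channels = np.sort(frame["channel"].unique())
    freqs = np.sort(frame["frequency_hz"].unique().astype(float))
    if np.any(freqs <= 0):
        raise ValidationError(f"{path}: frequencies must be > 0")

    n_d, n_f, n_c = days.size, freqs.size, channels.size
    if len(frame) != n_d * n_f * n_c:
        raise GridMismatchError(
            f"{path}: expected a full {n_d} day x {n_f} frequency x {n_c} channel "
            f"grid ({n_d * n_f * n_c} rows), found {len(frame)} rows"
        )
    key = frame.set_index(["day", "channel", "frequency_hz"])
    if key.index.duplicated().any():
        raise GridMismatchError(f"{path}: duplicate (day, channel, frequency) rows")

    day_pos = {d: i for i, d in enumerate(days)}
    chan_pos = {c: i for i, c in enumerate(channels)}
    freq_pos = {f: i for i, f in enumerate(freqs)}
    magnitude = np.empty((n_d, n_f, n_c))
    phase = np.empty((n_d, n_f, n_c)) if has_phase else None
    di = frame["day"].map(day_pos).to_numpy()
    ci = frame["channel"].map(chan_pos).to_numpy()
    fi = frame["frequency_hz"].astype(float).map(freq_pos).to_numpy()
    magnitude[di, fi, ci] = frame["magnitude_ohm"].to_numpy(dtype=float)
    if has_phase:
        phase[di, fi, ci] = frame["phase_deg"].to_numpy(dtype=float)

    return EISDataset(days=days, frequencies=freqs, magnitude=magnitude, phase=phase)


def write_eis_csv(dataset: EISDataset, path: str | Path) -> Path:
    """Write a dataset to long-format CSV, lossless to better than 12 significant digits.

    Rows are emitted sorted by (day, channel, frequency) so identical datasets
    produce byte-identical files.
    """
    path = Path(path)
    dataset._validate()
    n_d, n_f, n_c = dataset.magnitude.shape
    di, fi, ci = np.meshgrid(np.arange(n_d), np.arange(n_f), np.arange(n_c), indexing="ij")
    frame = pd.DataFrame(
        {
            "day": dataset.days[di.ravel()],
            "channel": ci.ravel(),
            "frequency_hz": dataset.frequencies[fi.ravel()],
            "magnitude_ohm": dataset.magnitude.ravel(),
        }
    )
    if dataset.phase is not None:
        frame["phase_deg"] = dataset.phase.ravel()
    frame = frame.sort_values(["day", "channel", "frequency_hz"], kind="stable")
    frame.to_csv(path, index=False, float_format="%.17g")
    return path
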