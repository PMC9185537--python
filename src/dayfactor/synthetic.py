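"""Synthetic multi-day EIS generator built on a Randles equivalent circuit.

Soak-test datasets are emulated, not resampled: each soaking day has a set of
Randles-circuit parameters (solution resistance R_s, charge-transfer
resistance R_ct in parallel with a double-layer capacitance C_dl, optionally a
Warburg diffusion element in series with R_ct),

    Z(f) = R_s + 1 / ( 1/(R_ct + Z_W) + j*2*pi*f*C_dl ),
    Z_W  = (1 - j) * sigma_w / sqrt(2*pi*f),

and every recording channel observes the day's spectrum through seeded
multiplicative log-normal noise (impedance spreads across recording sites are
scale-proportional). Drift across days is expressed as a trajectory of
circuit parameters, giving the characteristic soak-test narratives: a stable
plateau, a mid-experiment dip, and a sharp impedance rise on the last two
days. Parameter magnitudes are calibrated so day-1 |Z| at 1 kHz falls in the
50-250 kOhm window typical of ECoG microarray recording sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .eis_data import EISDataset
from .errors import ValidationError

__all__ = [
    "CircuitParams",
    "DriftScenario",
    "impedance_complex",
    "impedance_magnitude",
    "simulate_dataset",
    "scenario_preset",
    "scenario_from_yaml",
    "SWEEPS",
    "PRESET_NAMES",
]

# 30-point logarithmic grids mirroring the two potentiostat sweeps
SWEEPS = {
    "1hz_2mhz": np.geomspace(1.0, 2e6, 30),
    "0.1hz_10khz": np.geomspace(0.1, 1e4, 30),
}

PRESET_NAMES = ("stable", "dip_then_rise", "fluctuating")


@dataclass(frozen=True)
class CircuitParams:
    """Randles-circuit parameters of one soaking day.

    r_s and r_ct in ohms, c_dl in farads, sigma_w (optional Warburg
    coefficient) in ohm * s^(-1/2).
    """

    r_s: float
    r_ct: float
    c_dl: float
    sigma_w: float | None = None

    def __post_init__(self) -> None:
        for name in ("r_s", "r_ct", "c_dl", "sigma_w"):
            value = getattr(self, name)
            if value is None:
                continue
            object.__setattr__(self, name, float(value))  # YAML 1.1 reads 4.0e6 as str
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")


@dataclass
class DriftScenario:
    """A fully specified synthetic soak test.

    ``trajectory`` holds one :class:`CircuitParams` per soaking day;
    ``noise_sigma`` is the standard deviation of the per-channel log-normal
    multiplicative magnitude noise (``noise_kind="additive"`` switches to
    relative Gaussian noise, magnitude * (1 + eps)).
    """

    name: str
    days: np.ndarray
    trajectory: list[CircuitParams]
    channel_count: int = 32
    noise_sigma: float = 0.05
    noise_kind: str = "multiplicative"
    seed: int = 0
    frequencies: np.ndarray = field(default_factory=lambda: SWEEPS["1hz_2mhz"].copy())

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=int)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if len(self.trajectory) != self.days.size:
            raise ValidationError("trajectory length must equal the number of days")
        if self.channel_count < 1:
            raise ValidationError("channel_count must be >= 1")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if self.noise_kind not in ("multiplicative", "additive"):
            raise ValidationError("noise_kind must be 'multiplicative' or 'additive'")


def impedance_complex(params: CircuitParams, f: np.ndarray | float) -> np.ndarray:
    """Complex Randles impedance at frequency f (Hz)."""
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValidationError("frequency must be > 0")
    omega = 2.0 * np.pi * f
    branch = params.r_ct + (
        (1.0 - 1.0j) * params.sigma_w / np.sqrt(omega) if params.sigma_w else 0.0
    )
    return params.r_s + 1.0 / (1.0 / branch + 1.0j * omega * params.c_dl)


def impedance_magnitude(params: CircuitParams, f: np.ndarray | float) -> np.ndarray | float:
    """|Z(f)| in ohms; R_s as f -> inf, R_s + R_ct as f -> 0 (no Warburg)."""
    mag = np.abs(impedance_complex(params, f))
    return float(mag) if np.isscalar(f) or np.ndim(f) == 0 else mag


def simulate_dataset(
    scenario: DriftScenario, frequencies: np.ndarray | None = None
) -> EISDataset:
    """Generate a seeded EIS dataset from a drift scenario.

    magnitude[d, k, c] = |Z(params_d, f_k)| * exp(eps_{d,k,c}),
    eps ~ Normal(0, noise_sigma^2); phases are the noise-free circuit phases.
    """
    freqs = scenario.frequencies if frequencies is None else np.asarray(frequencies, float)
    rng = np.random.default_rng(scenario.seed)
    n_d, n_f, n_c = scenario.days.size, freqs.size, scenario.channel_count
    base = np.stack([impedance_complex(p, freqs) for p in scenario.trajectory])
    mag = np.abs(base)[:, :, None]
    if scenario.noise_sigma > 0:
        eps = rng.normal(0.0, scenario.noise_sigma, size=(n_d, n_f, n_c))
        if scenario.noise_kind == "multiplicative":
            mag = mag * np.exp(eps)
        else:
            mag = mag * (1.0 + eps)
            if np.any(mag <= 0):
                raise ValidationError("additive noise drove a magnitude non-positive")
    else:
        mag = np.broadcast_to(mag, (n_d, n_f, n_c)).copy()
    phase = np.broadcast_to(np.degrees(np.angle(base))[:, :, None], mag.shape).copy()
    return EISDataset(
        days=scenario.days, frequencies=freqs, magnitude=mag, phase=phase,
        meta={"scenario": scenario.name, "seed": scenario.seed,
              "noise_sigma": scenario.noise_sigma, "medium": "PBS"},
    )


# Baseline day-1 electrode: |Z(1 kHz)| ~ 134 kOhm, dominated by the
# double-layer branch; low frequencies see R_s + R_ct ~ 4 MOhm.
_BASE = CircuitParams(r_s=2.0e3, r_ct=4.0e6, c_dl=1.2e-9)


def _scaled(r_ct_factor: float = 1.0, c_factor: float = 1.0) -> CircuitParams:
    return replace(_BASE, r_ct=_BASE.r_ct * r_ct_factor, c_dl=_BASE.c_dl * c_factor)


def scenario_preset(name: str, seed: int = 0) -> DriftScenario:
    """A named 11-day drift scenario.

    * ``stable`` — constant circuit parameters; only channel noise moves.
    * ``dip_then_rise`` — slight impedance reduction on days 5-7, recovery,
      then a sharp rise over the last two days.
    * ``fluctuating`` — brief dips on days 5 and 9 and the final-two-day rise.
    """
    days = np.arange(1, 12)
    if name == "stable":
        traj = [_BASE] * 11
        freqs, channels = SWEEPS["1hz_2mhz"], 32
    elif name == "dip_then_rise":
        factors = [
            (1.0, 1.0), (1.0, 1.0), (1.0, 1.0), (1.0, 1.0),
            (0.72, 1.15), (0.65, 1.2), (0.75, 1.1),
            (0.95, 1.0), (1.0, 1.0),
            (2.0, 0.85), (3.5, 0.7),
        ]
        traj = [_scaled(rf, cf) for rf, cf in factors]
        freqs, channels = SWEEPS["0.1hz_10khz"], 32
    elif name == "fluctuating":
        factors = [
            (1.0, 1.0), (1.05, 0.98), (0.97, 1.02), (1.02, 1.0),
            (0.78, 1.12), (1.0, 1.0), (1.04, 0.97),
            (0.99, 1.01), (0.8, 1.1),
            (1.8, 0.88), (3.0, 0.75),
        ]
        traj = [_scaled(rf, cf) for rf, cf in factors]
        freqs, channels = SWEEPS["0.1hz_10khz"], 16
    else:
        raise ValidationError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    return DriftScenario(
        name=name, days=days, trajectory=traj, channel_count=channels,
        noise_sigma=0.05, seed=seed, frequencies=freqs,
    )


def scenario_from_yaml(path: str | Path) -> DriftScenario:
    """Load a scenario from YAML: either a preset reference or a full definition.

    Preset form: ``{preset: dip_then_rise, seed: 3}`` plus optional overrides
    (channel_count, noise_sigma, noise_kind). Full form lists ``days`` and a
    ``trajectory`` of {r_s, r_ct, c_dl, sigma_w} mappings, plus
    ``frequencies`` either as a list or as {start, stop, num} (log-spaced).
    """
    with open(path) as fh:
        spec = yaml.safe_load(fh) or {}
    if "preset" in spec:
        scenario = scenario_preset(spec["preset"], seed=int(spec.get("seed", 0)))
        for key in ("channel_count", "noise_sigma", "noise_kind"):
            if key in spec:
                setattr(scenario, key, spec[key])
        scenario.__post_init__()
        return scenario
    freqs = spec.get("frequencies", SWEEPS["1hz_2mhz"])
    if isinstance(freqs, dict):
        freqs = np.geomspace(float(freqs["start"]), float(freqs["stop"]), int(freqs["num"]))
    return DriftScenario(
        name=spec.get("name", "custom"),
        days=np.asarray(spec["days"], dtype=int),
        trajectory=[CircuitParams(**p) for p in spec["trajectory"]],
        channel_count=int(spec.get("channel_count", 32)),
        noise_sigma=float(spec.get("noise_sigma", 0.05)),
        noise_kind=spec.get("noise_kind", "multiplicative"),
        seed=int(spec.get("seed", 0)),
        frequencies=np.asarray(freqs, dtype=float),
    )
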