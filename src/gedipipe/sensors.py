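"""Equilibrium Hill-model fluorescence of calcium biosensors.

Genetically encoded calcium indicators (GECIs such as GCaMP6f) and
genetically encoded death indicators (GEDIs such as RGEDI or GC150) differ
chiefly in their Ca2+ affinity: a GECI's dissociation constant sits inside
the range of physiological cytosolic transients, while a GEDI's Kd is high
enough that its fluorescence only rises when cytosolic Ca2+ approaches
organellar or extracellular levels — a catastrophic, death-associated event.
At equilibrium the occupancy of either sensor follows the Hill equation, so
a single parametric model covers both families; the parameters are supplied
by the user (e.g. from the sensor's characterization literature), never
hard-coded here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SensorSpec",
    "FluorescenceTrace",
    "hill_fluorescence",
    "response_curve",
    "delta_f_over_f",
    "stim_death_ratio",
    "load_sensor_registry",
]


@dataclass(frozen=True)
class SensorSpec:
    """Equilibrium fluorescence parameters of one biosensor.

    Parameters
    ----------
    name : str
        Free-text label (e.g. ``"RGEDI"``).
    kd : float
        Ca2+ concentration (molar) at half occupancy; must be positive.
    hill_n : float
        Hill coefficient (dimensionless cooperativity exponent); positive.
    f_min : float
        Relative fluorescence at zero Ca2+ (arbitrary units).
    f_max : float
        Relative fluorescence at saturation; ``f_max >= f_min >= 0``.
    """

    name: str
    kd: float
    hill_n: float
    f_min: float = 0.0
    f_max: float = 1.0

    def __post_init__(self) -> None:
        if not self.kd > 0:
            raise ValueError(f"kd must be positive, got {self.kd}")
        if not self.hill_n > 0:
            raise ValueError(f"hill_n must be positive, got {self.hill_n}")
        if not (self.f_max >= self.f_min >= 0):
            raise ValueError(
                f"require f_max >= f_min >= 0, got f_min={self.f_min}, f_max={self.f_max}"
            )


@dataclass
class FluorescenceTrace:
    """A single-cell intensity time series with a declared baseline window.

    ``times`` are strictly increasing (seconds or hours — the caller declares
    the unit and keeps it consistent); ``values`` are raw intensities after
    background subtraction. ``baseline_window`` is the half-open index range
    ``[start, stop)`` whose mean defines F0 for fold-change computations; by
    convention it covers all samples before the first stimulus.
    """

    times: np.ndarray
    values: np.ndarray
    baseline_window: tuple[int, int] = field(default=(0, 1))

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-D and the same length")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        start, stop = self.baseline_window
        if not (0 <= start < stop <= len(self.times)):
            raise ValueError(
                f"baseline_window {self.baseline_window} empty or out of range "
                f"for trace of length {len(self.times)}"
            )

    @property
    def f0(self) -> float:
        start, stop = self.baseline_window
        return float(np.mean(self.values[start:stop]))

    @classmethod
    def from_csv(cls, path: str | Path, baseline_window: tuple[int, int] | None = None) -> "FluorescenceTrace":
        """Read a trace from a CSV with columns ``time`` and ``value``."""
        df = pd.read_csv(path)
        bw = baseline_window if baseline_window is not None else (0, 1)
        return cls(df["time"].to_numpy(), df["value"].to_numpy(), bw)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time": self.times, "value": self.values}).to_csv(path, index=False)


def hill_fluorescence(sensor: SensorSpec, ca: float | np.ndarray) -> float | np.ndarray:
    """Equilibrium relative fluorescence at free-Ca2+ concentration ``ca``.

    Implements ``f_min + (f_max - f_min) * ca^n / (kd^n + ca^n)``: continuous,
    non-decreasing in ``ca``, equal to the midpoint of ``f_min`` and ``f_max``
    at ``ca = kd`` for any Hill coefficient.

    Raises
    ------
    ValueError
        If any concentration is negative.
    """
    ca_arr = np.asarray(ca, dtype=float)
    if np.any(ca_arr < 0):
        raise ValueError("Ca2+ concentration must be non-negative")
    # compute occupancy in log space ratio form to avoid overflow at large ca
    with np.errstate(divide="ignore"):
        ratio = np.where(ca_arr > 0, (sensor.kd / np.maximum(ca_arr, 1e-300)) ** sensor.hill_n, np.inf)
    occupancy = 1.0 / (1.0 + ratio)
    out = sensor.f_min + (sensor.f_max - sensor.f_min) * occupancy
    return float(out) if np.isscalar(ca) or np.ndim(ca) == 0 else out


def response_curve(
    sensor: SensorSpec,
    ca_grid: Sequence[float] | np.ndarray,
    normalize: bool = False,
) -> np.ndarray:
    """Hill fluorescence evaluated over a concentration grid.

    With ``normalize=True`` the curve is min-max rescaled to [0, 1] (a no-op
    for a flat curve, which maps to zeros).
    """
    grid = np.asarray(ca_grid, dtype=float)
    if grid.size == 0:
        return np.empty(0)
    vals = np.asarray(hill_fluorescence(sensor, grid), dtype=float)
    if normalize:
        span = vals.max() - vals.min()
        vals = (vals - vals.min()) / span if span > 0 else np.zeros_like(vals)
    return vals


def delta_f_over_f(trace: FluorescenceTrace) -> np.ndarray:
    """Fold change (F - F0)/F0 per timepoint, with F0 the baseline-window mean.

    Raises
    ------
    ValueError
        If F0 <= 0, which leaves the fold change undefined.
    """
    f0 = trace.f0
    if f0 <= 0:
        raise ValueError(f"baseline F0 must be positive to form dF/F0, got {f0}")
    return (trace.values - f0) / f0


def stim_death_ratio(stim_trace: FluorescenceTrace, death_trace: FluorescenceTrace) -> float:
    """Ratio of peak dF/F0 under stimulation to peak dF/F0 at death.

    Near 0 for a death-specific sensor (no response to physiological
    transients), near 1 for an activity sensor that responds equally to both.
    Reported unclamped: a stimulation window dipping below baseline yields a
    negative ratio.

    Raises
    ------
    ValueError
        If the peak death response is not positive (ratio undefined).
    """
    death_peak = float(np.max(delta_f_over_f(death_trace)))
    if death_peak <= 0:
        raise ValueError("peak death response must be positive to form the ratio")
    stim_peak = float(np.max(delta_f_over_f(stim_trace)))
    return stim_peak / death_peak


def load_sensor_registry(path: str | Path) -> dict[str, SensorSpec]:
    """Load named SensorSpecs from a YAML/JSON mapping.

    Expected layout::

        sensors:
          RGEDI: {kd: 1.0e-3, hill_n: 1.0, f_min: 0.0, f_max: 1.0}

    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    entries = doc.get("sensors", doc)
    registry: dict[str, SensorSpec] = {}
    for name, params in entries.items():
        registry[name] = SensorSpec(name=name, **{k: float(v) for k, v in params.items()})
    return registry
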