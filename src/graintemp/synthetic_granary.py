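"""Synthetic granary sensor layouts and stored-grain temperature series.

Real warehouse monitoring data are rarely shareable, so this module generates
a stand-in: a regular 3-D grid of temperature-measuring points inside a flat
warehouse and, per sensor, an evenly sampled temperature series built from a
seasonal sinusoid, a small diurnal sinusoid, a linear drift, a per-layer
offset and phase lag (deeper grain reacts later and stays warmer), and an
AR(1) residual for sensor noise.  Optional gap segments emulate the missing
stretches produced by manually triggered sensors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GranaryLayout",
    "SimulationConfig",
    "TemperatureSeries",
    "generate_layout",
    "simulate_temperatures",
    "inject_gaps",
    "layer_mean_series",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GranaryLayout:
    """Regular sensor grid: ``rows x cols x layers`` measuring points.

    Defaults follow the national-standard cable layout for a bungalow
    warehouse: 5 m horizontal pitch, 1.8 m vertical pitch, 0.5 m clearance
    from grain surface, floor and walls.
    """

    rows: int = 6
    cols: int = 10
    layers: int = 7
    horizontal_spacing: float = 5.0   # meters
    vertical_spacing: float = 1.8     # meters
    boundary_offset: float = 0.5      # meters from walls/floor/surface

    def __post_init__(self) -> None:
        if min(self.rows, self.cols, self.layers) < 1:
            raise ValidationError("rows, cols and layers must all be >= 1")
        if min(self.horizontal_spacing, self.vertical_spacing, self.boundary_offset) <= 0:
            raise ValidationError("spacings and boundary offset must be > 0")

    def sensor_count(self) -> int:
        return self.rows * self.cols * self.layers

    def coordinates(self) -> np.ndarray:
        """(n_sensors, 3) array of (x, y, z) positions in meters.

        Origin at the warehouse corner; x runs along the columns (length),
        y along the rows (width), z upward through the layers.  Iteration
        order is row-major over (row, col, layer).
        """
        off, h, v = self.boundary_offset, self.horizontal_spacing, self.vertical_spacing
        coords = [
            (off + c * h, off + r * h, off + l * v)
            for r in range(self.rows)
            for c in range(self.cols)
            for l in range(self.layers)
        ]
        return np.asarray(coords, dtype=float)

    def sensor_ids(self) -> list[str]:
        return [
            f"r{r}_c{c}_l{l}"
            for r in range(self.rows)
            for c in range(self.cols)
            for l in range(self.layers)
        ]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic temperature field.

    Amplitudes and baseline are in degrees Celsius, periods/lags in days.
    ``layer_lag`` shifts the seasonal phase by that many days per layer
    (deeper grain lags the annual cycle); ``layer_gradient`` adds a constant
    per-layer offset.  The residual is a stationary AR(1) process.
    """

    start_time: pd.Timestamp = pd.Timestamp("2024-01-01T00:00:00")
    duration_days: float = 365.0
    cadence_hours: float = 4.0
    annual_amplitude: float = 17.0
    annual_period_days: float = 365.0
    # sine time offset in days; the default puts the annual minimum at the
    # start of February and the maximum at the start of August, as in a
    # northern-hemisphere warehouse (31 + P/4 for a Jan-1 start)
    annual_phase_days: float = 122.25
    daily_amplitude: float = 0.2
    trend_slope: float = 0.0          # °C per day
    baseline: float = 5.0
    ar_coefficient: float = 0.8
    innovation_sd: float = 0.3
    layer_gradient: float = 0.3       # °C per layer index
    layer_lag: float = 5.0            # days of seasonal lag per layer index
    gap_schedule: tuple[tuple[int, int], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cadence_hours <= 0 or 24.0 % self.cadence_hours != 0:
            raise ValidationError("cadence_hours must divide 24 evenly")
        if not (0.0 <= self.ar_coefficient < 1.0):
            raise ValidationError("ar_coefficient must lie in [0, 1)")
        if self.innovation_sd < 0:
            raise ValidationError("innovation_sd must be >= 0")
        if self.duration_days <= 0:
            raise ValidationError("duration_days must be > 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_days * 24.0 / self.cadence_hours))


@dataclass
class TemperatureSeries:
    """Evenly sampled temperature record.

    ``values`` are °C with NaN marking missing samples; ``timestamps`` are
    strictly increasing with constant spacing equal to ``cadence_hours``.
    """

    timestamps: pd.DatetimeIndex
    values: np.ndarray
    cadence_hours: float
    label: str = ""

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.timestamps) != len(self.values):
            raise ValidationError("timestamps and values must have equal length")
        if len(self.timestamps) > 1:
            deltas = np.diff(self.timestamps.asi8)
            expected = int(round(self.cadence_hours * 3600 * 1e9))
            if (deltas <= 0).any():
                raise ValidationError("timestamps must be strictly increasing")
            if not (deltas == expected).all():
                raise ValidationError(
                    "timestamps must be evenly spaced at the stated cadence"
                )

    def __len__(self) -> int:
        return len(self.values)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def is_gap_free(self) -> bool:
        return not np.isnan(self.values).any()

    def with_values(self, values: np.ndarray, label: str | None = None) -> "TemperatureSeries":
        """New series sharing this one's time axis."""
        return TemperatureSeries(
            timestamps=self.timestamps,
            values=np.asarray(values, dtype=float),
            cadence_hours=self.cadence_hours,
            label=self.label if label is None else label,
        )

    @property
    def samples_per_day(self) -> float:
        return 24.0 / self.cadence_hours


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def generate_layout(
    rows: int = 6,
    cols: int = 10,
    layers: int = 7,
    horizontal_spacing: float = 5.0,
    vertical_spacing: float = 1.8,
    boundary_offset: float = 0.5,
) -> tuple[GranaryLayout, np.ndarray]:
    """Build a sensor grid and return (layout, coordinate array)."""
    layout = GranaryLayout(
        rows=rows,
        cols=cols,
        layers=layers,
        horizontal_spacing=horizontal_spacing,
        vertical_spacing=vertical_spacing,
        boundary_offset=boundary_offset,
    )
    return layout, layout.coordinates()


def _time_axis(config: SimulationConfig) -> tuple[pd.DatetimeIndex, np.ndarray]:
    n = config.n_samples
    idx = pd.date_range(
        start=config.start_time, periods=n, freq=pd.Timedelta(hours=config.cadence_hours)
    )
    t_days = np.arange(n) * (config.cadence_hours / 24.0)
    return idx, t_days


def _ar1(n: int, phi: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) residual; the initial state is drawn from the
    stationary distribution so early samples are not systematically calmer."""
    if sd == 0.0:
        return np.zeros(n)
    e = np.empty(n)
    e[0] = rng.normal(0.0, sd / np.sqrt(1.0 - phi**2)) if phi > 0 else rng.normal(0.0, sd)
    innov = rng.normal(0.0, sd, size=n - 1) if n > 1 else np.empty(0)
    for i in range(1, n):
        e[i] = phi * e[i - 1] + innov[i - 1]
    return e


def simulate_temperatures(
    layout: GranaryLayout, config: SimulationConfig
) -> list[TemperatureSeries]:
    """One synthetic series per sensor, reproducible given ``config.seed``.

    value(t) = baseline + trend·t
             + A_annual·sin(2π(t − phase − lag·layer)/P_annual)
             + A_daily·sin(2π t) + gradient·layer + AR(1) residual
    with t in days.
    """
    idx, t = _time_axis(config)
    rng = np.random.default_rng(config.seed)
    out: list[TemperatureSeries] = []
    for sensor_id in layout.sensor_ids():
        layer = int(sensor_id.rsplit("_l", 1)[1])
        seasonal = config.annual_amplitude * np.sin(
            2.0
            * np.pi
            * (t - config.annual_phase_days - config.layer_lag * layer)
            / config.annual_period_days
        )
        diurnal = config.daily_amplitude * np.sin(2.0 * np.pi * t)
        values = (
            config.baseline
            + config.trend_slope * t
            + seasonal
            + diurnal
            + config.layer_gradient * layer
            + _ar1(len(t), config.ar_coefficient, config.innovation_sd, rng)
        )
        series = TemperatureSeries(idx, values, config.cadence_hours, label=sensor_id)
        if config.gap_schedule:
            series = inject_gaps(series, config.gap_schedule)
        out.append(series)
    return out


def inject_gaps(
    series: TemperatureSeries, gap_schedule: Sequence[tuple[int, int]]
) -> TemperatureSeries:
    """Blank out the scheduled segments; everything else is untouched.

    ``gap_schedule`` is a list of (start_index, length) pairs; gaps must lie
    within bounds and must not overlap.
    """
    if not gap_schedule:
        return series
    n = len(series)
    occupied = np.zeros(n, dtype=bool)
    values = series.values.copy()
    for start, length in gap_schedule:
        if length < 1 or start < 0 or start + length > n:
            raise ValidationError(
                f"gap ({start}, {length}) falls outside the series of length {n}"
            )
        if occupied[start : start + length].any():
            raise ValidationError(f"gap ({start}, {length}) overlaps a previous gap")
        occupied[start : start + length] = True
        values[start : start + length] = np.nan
    return series.with_values(values)


def layer_of(series: TemperatureSeries) -> int:
    """Layer index parsed from a sensor label of the form ``r*_c*_l<k>``."""
    try:
        return int(series.label.rsplit("_l", 1)[1])
    except (IndexError, ValueError) as exc:
        raise ValidationError(f"label {series.label!r} carries no layer index") from exc


def layer_mean_series(
    series_set: Sequence[TemperatureSeries], layer: int
) -> TemperatureSeries:
    """Element-wise mean over one layer's sensors, skipping missing values.

    The result is missing only where every sensor of the layer is missing.
    """
    members = [s for s in series_set if layer_of(s) == layer]
    if not members:
        raise ValidationError(f"no sensors found for layer {layer}")
    ref = members[0]
    for s in members[1:]:
        if not s.timestamps.equals(ref.timestamps):
            raise ValidationError("all series must share the same time axis")
    stacked = np.vstack([s.values for s in members])
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stacked, axis=0)
    return ref.with_values(mean, label=f"layer-{layer}-mean")


def aggregate_daily(series: TemperatureSeries) -> TemperatureSeries:
    """Collapse a sub-daily series to daily means (trailing partial day kept).

    The forecasting pipeline reads its lookback in days, so the raw 4-hourly
    record is reduced to one sample per day before windowing.
    """
    per_day = int(round(series.samples_per_day))
    if per_day <= 1:
        return series
    frame = pd.Series(series.values, index=series.timestamps)
    daily = frame.resample("1D").mean()
    return TemperatureSeries(
        timestamps=daily.index,
        values=daily.to_numpy(),
        cadence_hours=24.0,
        label=series.label,
    )
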