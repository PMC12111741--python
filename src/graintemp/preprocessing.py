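"""Normalization, chronological splitting and sliding-window dataset assembly.

The pipeline contract: split first, augment only the training slice, fit the
Z-score on the augmented training pool, and window the untouched test slice
with the train-fitted parameters.  Test windows therefore never contain
augmented values and no test statistic leaks into the normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .augmentation import AugmentationSettings, augment_training_set
from .synthetic_granary import TemperatureSeries, ValidationError, aggregate_daily

__all__ = [
    "NormalizationParams",
    "WindowedDataset",
    "zscore_fit",
    "zscore_apply",
    "zscore_invert",
    "chronological_split",
    "make_windows",
    "build_datasets",
]

DEFAULT_LOOKBACK_DAYS = 10
DEFAULT_TRAIN_FRACTION = 0.8


@dataclass(frozen=True)
class NormalizationParams:
    """Mean and population standard deviation of the training pool (°C)."""

    mean: float
    std: float

    def __post_init__(self) -> None:
        if self.std <= 0:
            raise ValidationError("std must be > 0")


@dataclass(frozen=True)
class WindowedDataset:
    """Supervised one-step pairs: row i of ``inputs`` spans samples
    [i, i+lookback) and ``targets[i]`` is sample i+lookback (normalized)."""

    inputs: np.ndarray    # (n_windows, lookback)
    targets: np.ndarray   # (n_windows,)
    lookback: int
    horizon: int = 1

    def __post_init__(self) -> None:
        if self.inputs.ndim != 2 or self.inputs.shape[1] != self.lookback:
            raise ValidationError("inputs must be (n_windows, lookback)")
        if len(self.targets) != len(self.inputs):
            raise ValidationError("inputs and targets must align")

    @property
    def n_windows(self) -> int:
        return len(self.targets)

    @staticmethod
    def concatenate(parts: list["WindowedDataset"]) -> "WindowedDataset":
        if not parts:
            raise ValidationError("nothing to concatenate")
        lookback = parts[0].lookback
        if any(p.lookback != lookback for p in parts):
            raise ValidationError("lookbacks differ across parts")
        return WindowedDataset(
            inputs=np.vstack([p.inputs for p in parts]),
            targets=np.concatenate([p.targets for p in parts]),
            lookback=lookback,
        )


def zscore_fit(values: np.ndarray | TemperatureSeries) -> NormalizationParams:
    """Mean and population std (ddof=0) of a gap-free, non-constant sample."""
    x = values.values if isinstance(values, TemperatureSeries) else np.asarray(values, float)
    if np.isnan(x).any():
        raise ValidationError("cannot fit normalization on missing values")
    if len(x) < 2:
        raise ValidationError("need at least 2 samples to fit a Z-score")
    std = float(np.std(x))
    if std == 0.0:
        raise ValidationError("series is constant; Z-score undefined")
    return NormalizationParams(mean=float(np.mean(x)), std=std)


def zscore_apply(values: np.ndarray, params: NormalizationParams) -> np.ndarray:
    return (np.asarray(values, float) - params.mean) / params.std


def zscore_invert(values: np.ndarray, params: NormalizationParams) -> np.ndarray:
    return np.asarray(values, float) * params.std + params.mean


def chronological_split(
    series: TemperatureSeries, train_fraction: float = DEFAULT_TRAIN_FRACTION
) -> tuple[TemperatureSeries, TemperatureSeries]:
    """First ``floor(n * fraction)`` samples for training, the rest for test."""
    if not (0.0 < train_fraction < 1.0):
        raise ValidationError("train_fraction must lie strictly between 0 and 1")
    n = len(series)
    cut = int(np.floor(n * train_fraction))
    if cut < 1 or cut >= n:
        raise ValidationError("series too short for the requested split")
    train = TemperatureSeries(
        series.timestamps[:cut], series.values[:cut], series.cadence_hours,
        label=f"{series.label}[train]",
    )
    test = TemperatureSeries(
        series.timestamps[cut:], series.values[cut:], series.cadence_hours,
        label=f"{series.label}[test]",
    )
    return train, test


def make_windows(
    values: np.ndarray, lookback: int = DEFAULT_LOOKBACK_DAYS, horizon: int = 1
) -> WindowedDataset:
    """Sliding one-step windows over an already-normalized value array."""
    x = np.asarray(values, float)
    if horizon != 1:
        raise ValidationError("only one-step-ahead prediction is supported")
    if len(x) <= lookback:
        raise ValidationError(
            f"series of length {len(x)} cannot yield a window of lookback {lookback}"
        )
    windows = np.lib.stride_tricks.sliding_window_view(x, lookback)[:-1]
    targets = x[lookback:]
    return WindowedDataset(inputs=windows.copy(), targets=targets.copy(), lookback=lookback)


def build_datasets(
    series: TemperatureSeries,
    aug_settings: AugmentationSettings | None = None,
    lookback: int = DEFAULT_LOOKBACK_DAYS,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    daily: bool = True,
) -> tuple[WindowedDataset, WindowedDataset, NormalizationParams]:
    """Full dataset assembly for one series.

    With ``daily`` (default), a sub-daily series is first reduced to daily
    means so that ``lookback`` counts days.  Augmented variants are windowed
    independently and concatenated — windows never straddle a variant
    boundary.  ``aug_settings=None`` disables augmentation.
    """
    if not series.is_gap_free:
        raise ValidationError(
            "the forecasting pipeline needs a gap-free series; "
            "exclude gap segments or simulate without gaps"
        )
    working = aggregate_daily(series) if daily else series
    train_slice, test_slice = chronological_split(working, train_fraction)
    if len(train_slice) <= lookback or len(test_slice) <= lookback:
        raise ValidationError("series too short to window both slices")

    if aug_settings is not None:
        variants = augment_training_set(train_slice, aug_settings)
    else:
        variants = [train_slice]

    pool = np.concatenate([v.values for v in variants])
    params = zscore_fit(pool)

    train = WindowedDataset.concatenate(
        [make_windows(zscore_apply(v.values, params), lookback) for v in variants]
    )
    test = make_windows(zscore_apply(test_slice.values, params), lookback)
    return train, test, params
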