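"""Training, MAE/RMSE evaluation and the ablation ladder.

Networks are trained on mean-squared error with Adam over shuffled
mini-batches; L2 regularization is added on weight matrices and dropout is
active only during training.  Metrics are reported on the normalized scale
by default (the scale on which the models are trained and compared);
``metrics_in_celsius`` scores the denormalized predictions instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .augmentation import AugmentationSettings
from .model_zoo import LeastSquaresModel, Network, build_model
from .preprocessing import (
    DEFAULT_LOOKBACK_DAYS,
    DEFAULT_TRAIN_FRACTION,
    NormalizationParams,
    WindowedDataset,
    build_datasets,
    zscore_invert,
)
from .synthetic_granary import (
    GranaryLayout,
    SimulationConfig,
    TemperatureSeries,
    ValidationError,
    aggregate_daily,
    simulate_temperatures,
)

__all__ = [
    "TrainConfig",
    "Metrics",
    "EvaluationReport",
    "mae",
    "rmse",
    "train_model",
    "predict",
    "run_ablation",
    "default_benchmark_series",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; 100 epochs of Adam on MSE by default."""

    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    loss: str = "mse"
    dropout: float = 0.2
    l2_coefficient: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be > 0")
        if self.optimizer != "adam":
            raise ValidationError("only the adam optimizer is implemented")
        if self.loss != "mse":
            raise ValidationError("only the mse loss is implemented")


@dataclass(frozen=True)
class Metrics:
    mae: float
    rmse: float
    n: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.mae <= self.rmse + 1e-12):
            raise ValidationError("metrics must satisfy 0 <= MAE <= RMSE")


@dataclass
class EvaluationReport:
    """Per-model metric table plus the configuration that produced it."""

    rows: list[dict] = field(default_factory=list)
    config: dict = field(default_factory=dict)
    seeds: tuple[int, ...] = ()

    def row(self, model: str) -> dict:
        for r in self.rows:
            if r["model"] == model:
                return r
        raise KeyError(model)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.rows).to_csv(path, index=False)


def mae(actual: np.ndarray, predicted: np.ndarray) -> float:
    """Mean absolute error, (1/m) * sum |x_i - xhat_i|."""
    a, p = np.asarray(actual, float), np.asarray(predicted, float)
    if a.shape != p.shape or a.size == 0:
        raise ValidationError("actual and predicted must be equal-length, non-empty")
    return float(np.mean(np.abs(a - p)))


def rmse(actual: np.ndarray, predicted: np.ndarray) -> float:
    """Root mean squared error, sqrt((1/m) * sum (x_i - xhat_i)^2)."""
    a, p = np.asarray(actual, float), np.asarray(predicted, float)
    if a.shape != p.shape or a.size == 0:
        raise ValidationError("actual and predicted must be equal-length, non-empty")
    return float(np.sqrt(np.mean((a - p) ** 2)))


def evaluate(actual: np.ndarray, predicted: np.ndarray) -> Metrics:
    return Metrics(mae=mae(actual, predicted), rmse=rmse(actual, predicted),
                   n=len(np.asarray(actual)))


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


class _Adam:
    def __init__(self, params, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train_model(
    model, train_dataset: WindowedDataset, config: TrainConfig = TrainConfig()
) -> list[float]:
    """Fit a model on (window, next-step) pairs; returns per-epoch MSE.

    The least-squares baseline is fitted in closed form and reports a
    single-entry history.  Networks are trained with Adam on mini-batches;
    the run is fully reproducible from ``config.seed``.
    """
    X, y = train_dataset.inputs, train_dataset.targets
    if len(X) == 0:
        raise ValidationError("training dataset is empty")

    if isinstance(model, LeastSquaresModel):
        model.fit(X, y)
        resid = model.predict_batch(X) - y
        return [float(np.mean(resid**2))]

    rng = np.random.default_rng(config.seed)
    opt = _Adam(model.params.values(), config.learning_rate)
    weights = model.weight_tensors()
    history: list[float] = []
    n = len(X)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss, seen = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            pred = model.forward(X[idx], train=True, rng=rng)
            err = pred.reshape(len(idx)) - y[idx]
            loss = err.square().mean()
            if config.l2_coefficient > 0:
                reg = None
                for w in weights:
                    term = w.square().sum()
                    reg = term if reg is None else reg + term
                loss = loss + config.l2_coefficient * reg
            value = float(loss.data)
            if not math.isfinite(value):
                raise ValidationError(
                    f"non-finite loss at epoch {epoch}; reduce the learning rate"
                )
            loss.backward()
            opt.step()
            epoch_loss += value * len(idx)
            seen += len(idx)
        history.append(epoch_loss / seen)
    return history


def predict(model, test_dataset: WindowedDataset, norm_params: NormalizationParams) -> np.ndarray:
    """One °C prediction per test window (denormalized model output)."""
    normalized = model.predict_batch(test_dataset.inputs)
    return zscore_invert(normalized, norm_params)


def save_checkpoint(model, norm_params: NormalizationParams, path) -> None:
    """Persist trained weights (.npz) plus a JSON sidecar with the model
    spec, seeds and normalization parameters."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    path = Path(path)
    if isinstance(model, LeastSquaresModel):
        np.savez(path, coef=model.coef)
    else:
        np.savez(path, **{name: t.data for name, t in model.params.items()})
    sidecar = {
        "spec": asdict(model.spec),
        "lookback": model.lookback,
        "init_seed": model.seed,
        "normalization": {"mean": norm_params.mean, "std": norm_params.std},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path) -> tuple[object, NormalizationParams]:
    """Rebuild a model and its normalization parameters from a checkpoint."""
    import json
    from pathlib import Path

    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    weights = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
    model = build_model(sidecar["spec"]["name"], lookback=sidecar["lookback"],
                        seed=sidecar["init_seed"],
                        dropout=sidecar["spec"]["dropout"], l2=sidecar["spec"]["l2"])
    if isinstance(model, LeastSquaresModel):
        model.coef = weights["coef"]
    else:
        for name, t in model.params.items():
            t.data = weights[name]
    norm = NormalizationParams(**sidecar["normalization"])
    return model, norm


# ---------------------------------------------------------------------------
# Benchmark + ablation ladder
# ---------------------------------------------------------------------------


def default_benchmark_series(seed: int = 0, duration_days: float = 365.0) -> TemperatureSeries:
    """The synthetic benchmark series: one mid-pile sensor simulated at the
    4-hour cadence for a year and reduced to daily means (365 points)."""
    layout = GranaryLayout(rows=1, cols=1, layers=4)
    config = SimulationConfig(duration_days=duration_days, seed=seed)
    sensors = simulate_temperatures(layout, config)
    mid = [s for s in sensors if s.label.endswith("_l2")][0]
    return aggregate_daily(mid)


def run_ablation(
    series: TemperatureSeries,
    model_names: tuple[str, ...] = ("LSTM", "CNN-LSTM", "CNN-SE-LSTM", "FTA-CNN-SE-LSTM"),
    config: TrainConfig = TrainConfig(),
    repeats: int = 1,
    lookback: int = DEFAULT_LOOKBACK_DAYS,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    metrics_in_celsius: bool = False,
    daily: bool = True,
) -> EvaluationReport:
    """Train every requested model on the same series and score the clean
    test slice.

    Dual-domain augmentation is switched on only for ``FTA-``-prefixed
    models; all models share the identical test windows.  With
    ``repeats > 1`` each model is retrained under ``repeats`` derived seeds
    and the report carries mean and standard deviation per metric.
    """
    report = EvaluationReport(
        config={
            "epochs": config.epochs, "batch_size": config.batch_size,
            "learning_rate": config.learning_rate, "lookback": lookback,
            "train_fraction": train_fraction, "repeats": repeats,
            "metrics_scale": "celsius" if metrics_in_celsius else "normalized",
        },
        seeds=tuple(config.seed + r for r in range(repeats)),
    )
    for name in model_names:
        augmented = name.startswith("FTA-")
        maes, rmses = [], []
        for r in range(repeats):
            run_seed = config.seed + r
            aug = AugmentationSettings(seed=run_seed) if augmented else None
            train_ds, test_ds, params = build_datasets(
                series, aug, lookback=lookback, train_fraction=train_fraction,
                daily=daily,
            )
            model = build_model(name, lookback=lookback, seed=run_seed,
                                dropout=config.dropout, l2=config.l2_coefficient)
            train_model(model, train_ds, replace(config, seed=run_seed))
            if metrics_in_celsius:
                pred = predict(model, test_ds, params)
                actual = zscore_invert(test_ds.targets, params)
            else:
                pred = model.predict_batch(test_ds.inputs)
                actual = test_ds.targets
            maes.append(mae(actual, pred))
            rmses.append(rmse(actual, pred))
        row = {"model": name, "mae": float(np.mean(maes)), "rmse": float(np.mean(rmses))}
        if repeats > 1:
            row["mae_sd"] = float(np.std(maes, ddof=1))
            row["rmse_sd"] = float(np.std(rmses, ddof=1))
        report.rows.append(row)
    return report
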