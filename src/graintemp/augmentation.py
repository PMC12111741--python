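"""Dual-domain augmentation for temperature series.

Two variants are generated from a training slice:

* time domain — additive Gaussian jitter, N(mu, sigma^2) per sample, with
  sigma = 0.01 °C by default: small enough not to move the signal, large
  enough to make subtle fluctuations visible to the model;
* frequency domain — the jittered series is taken to its DFT, every non-DC
  amplitude is multiplied by a fixed factor (default 1.2) with phases kept,
  and the spectrum is inverse-transformed.  The DC bin carries the series
  mean and is left alone by default, so the augmented series oscillates
  more strongly around the same mean level.

The DFT convention is the unnormalized forward sum
X_k = sum_n x_n exp(-2*pi*i*n*k/N) with the 1/N-scaled inverse; the k-th bin
maps to frequency k*fT/N cycles per day where fT is the sampling rate in
samples per day.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic_granary import TemperatureSeries, ValidationError

__all__ = [
    "NoiseConfig",
    "Spectrum",
    "FreqAugConfig",
    "AugmentationSettings",
    "add_gaussian_noise",
    "dft_forward",
    "dft_inverse",
    "amplify_spectrum",
    "frequency_augment",
    "dominant_periods",
    "augment_training_set",
]


@dataclass(frozen=True)
class NoiseConfig:
    """Gaussian jitter parameters (°C)."""

    mu: float = 0.0
    sigma: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValidationError("sigma must be >= 0")


@dataclass(frozen=True)
class FreqAugConfig:
    """Spectrum amplification parameters."""

    amplification_factor: float = 1.2
    amplify_dc: bool = False

    def __post_init__(self) -> None:
        if self.amplification_factor <= 0:
            raise ValidationError("amplification_factor must be > 0")


@dataclass(frozen=True)
class Spectrum:
    """Complex DFT coefficients of a real series plus its sampling rate.

    ``sampling_frequency`` is in samples per day, so ``frequency_of(k)``
    is in cycles per day and ``1/frequency_of(k)`` is a period in days.
    """

    coefficients: np.ndarray
    sampling_frequency: float

    @property
    def n_samples(self) -> int:
        return len(self.coefficients)

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.coefficients)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.coefficients)

    def frequency_of(self, k: int | np.ndarray) -> float | np.ndarray:
        return np.asarray(k) * self.sampling_frequency / self.n_samples


def add_gaussian_noise(
    series: TemperatureSeries, config: NoiseConfig = NoiseConfig()
) -> TemperatureSeries:
    """Return a jittered copy: output[i] = input[i] + N(mu, sigma^2)."""
    if not series.is_gap_free:
        raise ValidationError("series must be gap-free before augmentation")
    rng = np.random.default_rng(config.seed)
    noise = rng.normal(config.mu, config.sigma, size=len(series))
    return series.with_values(series.values + noise, label=f"{series.label}+noise")


def dft_forward(series: TemperatureSeries) -> Spectrum:
    """Unnormalized forward DFT of a gap-free series."""
    if not series.is_gap_free:
        raise ValidationError("series must be gap-free for the DFT")
    if len(series) < 1:
        raise ValidationError("series must contain at least one sample")
    coeffs = np.fft.fft(series.values)
    return Spectrum(coefficients=coeffs, sampling_frequency=series.samples_per_day)


def dft_inverse(
    spectrum: Spectrum, template: TemperatureSeries
) -> TemperatureSeries:
    """1/N-scaled inverse DFT, returned on the template's time axis.

    For conjugate-symmetric spectra (any spectrum of a real series) the
    imaginary residue is at round-off level and dropped.
    """
    x = np.fft.ifft(spectrum.coefficients)
    scale = max(1.0, float(np.max(np.abs(spectrum.coefficients))))
    if np.max(np.abs(x.imag)) > 1e-9 * scale:
        raise ValidationError(
            "spectrum is not conjugate-symmetric; inverse is not real-valued"
        )
    if len(x) != len(template):
        raise ValidationError("spectrum length does not match the template series")
    return template.with_values(x.real)


def amplify_spectrum(
    spectrum: Spectrum, config: FreqAugConfig = FreqAugConfig()
) -> Spectrum:
    """Scale every non-DC coefficient by the amplification factor.

    Multiplying the complex coefficient scales the amplitude and preserves
    the phase; applying the same factor to a bin and its mirror keeps the
    conjugate symmetry of real-series spectra intact.  The DC bin (the
    series mean) is scaled only when ``amplify_dc`` is set.
    """
    factors = np.full(spectrum.n_samples, config.amplification_factor, dtype=float)
    if not config.amplify_dc:
        factors[0] = 1.0
    return Spectrum(
        coefficients=spectrum.coefficients * factors,
        sampling_frequency=spectrum.sampling_frequency,
    )


def frequency_augment(
    series: TemperatureSeries,
    noise_config: NoiseConfig = NoiseConfig(),
    freq_config: FreqAugConfig = FreqAugConfig(),
) -> TemperatureSeries:
    """Full frequency-domain variant: jitter, DFT, amplify, inverse DFT."""
    noisy = add_gaussian_noise(series, noise_config)
    spectrum = amplify_spectrum(dft_forward(noisy), freq_config)
    out = dft_inverse(spectrum, series)
    return out.with_values(out.values, label=f"{series.label}+freqaug")


def dominant_periods(spectrum: Spectrum, top_n: int = 3) -> list[tuple[float, float]]:
    """Strongest periodic components as (period_days, amplitude) pairs.

    Only the non-DC half-spectrum (k = 1 .. N//2) is ranked; ties go to the
    lower index, i.e. the longer period.
    """
    if top_n < 1:
        raise ValidationError("top_n must be >= 1")
    n = spectrum.n_samples
    if n < 2:
        raise ValidationError("spectrum must have at least 2 bins")
    ks = np.arange(1, n // 2 + 1)
    amps = spectrum.amplitude[ks]
    # stable sort on -amplitude keeps lower k first among ties
    order = np.argsort(-amps, kind="stable")[:top_n]
    out = []
    for i in order:
        k = int(ks[i])
        freq = float(spectrum.frequency_of(k))
        out.append((1.0 / freq, float(amps[i])))
    return out


@dataclass(frozen=True)
class AugmentationSettings:
    """Which variants to generate and with what parameters.

    ``seed`` derives independent streams for the time-domain variant and the
    jitter stage of the frequency-domain variant.
    """

    sigma: float = 0.01
    mu: float = 0.0
    amplification_factor: float = 1.2
    amplify_dc: bool = False
    time_domain: bool = True
    freq_domain: bool = True
    seed: int = 0

    def noise_config(self, stream: int) -> NoiseConfig:
        child = np.random.SeedSequence(self.seed).spawn(stream + 1)[stream]
        return NoiseConfig(mu=self.mu, sigma=self.sigma,
                           seed=int(child.generate_state(1)[0] % (2**31)))

    def freq_config(self) -> FreqAugConfig:
        return FreqAugConfig(
            amplification_factor=self.amplification_factor, amplify_dc=self.amplify_dc
        )


def augment_training_set(
    series: TemperatureSeries,
    settings: AugmentationSettings = AugmentationSettings(),
) -> list[TemperatureSeries]:
    """Expand a training slice into [original, jittered, frequency-augmented].

    Disabled variants are simply omitted; the original is always first and
    is returned untouched.  Each variant has the same length and time axis
    as the input, so downstream windowing can treat them as extra samples.
    """
    if not series.is_gap_free:
        raise ValidationError("training slice must be gap-free")
    variants = [series]
    if settings.time_domain:
        variants.append(add_gaussian_noise(series, settings.noise_config(0)))
    if settings.freq_domain:
        variants.append(
            frequency_augment(series, settings.noise_config(1), settings.freq_config())
        )
    return variants
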