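"""Generative models for synthetic spike trains.

Three generators are provided, all built on the same conditional
interval law (a gamma density with shape ``kappa`` and mean ``1/rate``):

* a constant-rate gamma renewal process,
* a doubly-stochastic ("superstatistical") process whose rate parameter
  is redrawn from a gamma distribution, either per interval or per block
  of consecutive intervals,
* a discrete-rate mixture in which each interval's rate is sampled from
  a finite set.

Internally intervals are handled in milliseconds and rates in spikes/s;
the conversion rate[1/ms] = rate[spikes/s] / 1000 happens at a single
boundary (:func:`_hz_to_per_ms`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import gammaln

from .errors import ValidationError

__all__ = [
    "GammaGenerator",
    "GammaRateModel",
    "DiscreteRateModel",
    "SpikeTrain",
    "draw_rates",
    "simulate_constant_rate",
    "simulate_superstat",
    "simulate_discrete_mixture",
]

MS_PER_S = 1000.0


def _hz_to_per_ms(rate_hz: float | np.ndarray) -> float | np.ndarray:
    """Single unit boundary: spikes/s -> spikes/ms."""
    return np.asarray(rate_hz, dtype=float) / MS_PER_S


def _split_rng(seed: int, n: int = 2) -> list[np.random.Generator]:
    """Counter-based stream split: one seed deterministically yields
    independent generators for rate draws and interval draws."""
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]


@dataclass(frozen=True)
class GammaGenerator:
    """Conditional interval law: gamma with shape ``kappa`` and mean
    ``1/rate`` for every rate (a scale-invariant family).

    ``1/kappa`` measures the irregularity of firing at fixed rate.
    """

    kappa: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.kappa) and self.kappa > 0):
            raise ValidationError(f"kappa must be positive, got {self.kappa}")

    def log_conditional_pdf(self, t_ms: np.ndarray, rate_hz: float) -> np.ndarray:
        """log q(T | xi) with T in ms and xi given in spikes/s."""
        xi = _hz_to_per_ms(rate_hz)
        t = np.asarray(t_ms, dtype=float)
        k = self.kappa
        return (
            k * np.log(k * xi)
            + (k - 1.0) * np.log(t)
            - k * xi * t
            - gammaln(k)
        )

    def conditional_pdf(self, t_ms: np.ndarray, rate_hz: float) -> np.ndarray:
        """q(T | xi): density per ms at interval ``t_ms`` given a rate."""
        return np.exp(self.log_conditional_pdf(t_ms, rate_hz))


@dataclass(frozen=True)
class GammaRateModel:
    """Latent firing-rate distribution: gamma with shape ``alpha`` and
    mean ``rate_hz`` (spikes/s). ``1/alpha`` measures the degree of rate
    modulation; the density collapses to a point mass at the mean as
    ``alpha`` grows."""

    alpha: float
    rate_hz: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.alpha) and self.alpha > 0):
            raise ValidationError(f"alpha must be positive, got {self.alpha}")
        if not (np.isfinite(self.rate_hz) and self.rate_hz > 0):
            raise ValidationError(f"rate must be positive, got {self.rate_hz}")

    @property
    def rate_per_ms(self) -> float:
        return float(_hz_to_per_ms(self.rate_hz))

    def log_pdf_per_ms(self, xi_per_ms: np.ndarray) -> np.ndarray:
        """log k(xi) with xi in 1/ms (density per 1/ms)."""
        a = self.alpha
        scale = self.rate_per_ms / a
        xi = np.asarray(xi_per_ms, dtype=float)
        return (a - 1.0) * np.log(xi) - xi / scale - a * np.log(scale) - gammaln(a)

    def pdf_per_ms(self, xi_per_ms: np.ndarray) -> np.ndarray:
        return np.exp(self.log_pdf_per_ms(xi_per_ms))


@dataclass(frozen=True)
class DiscreteRateModel:
    """Finite set of firing rates with sampling weights (the rate law
    predicted by mutual-information maximization for gamma-interval
    channels)."""

    rates_hz: tuple[float, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        rates = tuple(float(r) for r in self.rates_hz)
        weights = tuple(float(w) for w in self.weights)
        object.__setattr__(self, "rates_hz", rates)
        object.__setattr__(self, "weights", weights)
        if len(rates) < 1:
            raise ValidationError("at least one rate component required")
        if len(rates) != len(weights):
            raise ValidationError("rates and weights must have equal length")
        if any(r <= 0 for r in rates):
            raise ValidationError("all rates must be positive")
        if any(w < 0 for w in weights):
            raise ValidationError("weights must be nonnegative")
        if abs(sum(weights) - 1.0) > 1e-12:
            raise ValidationError(f"weights must sum to 1, got {sum(weights)}")


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times in seconds.

    ``rates_hz``, when present, holds the true per-interval rates used by
    a simulator (one entry per interval), so parameter-recovery tests do
    not need a rate estimator.
    """

    times: np.ndarray
    metadata: dict = field(default_factory=dict)
    rates_hz: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.ndim != 1 or times.size < 2:
            raise ValidationError("a spike train needs at least 2 spikes")
        if np.any(times < 0):
            raise ValidationError("spike times must be nonnegative")
        if np.any(np.diff(times) <= 0):
            raise ValidationError("spike times must be strictly increasing")
        if self.rates_hz is not None:
            rates = np.asarray(self.rates_hz, dtype=float)
            object.__setattr__(self, "rates_hz", rates)
            if rates.size != times.size - 1:
                raise ValidationError("need one rate per inter-spike interval")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def duration_s(self) -> float:
        return float(self.times[-1] - self.times[0])

    @property
    def mean_rate_hz(self) -> float:
        return (self.n_spikes - 1) / self.duration_s


def draw_rates(n: int, model: GammaRateModel, seed: int) -> np.ndarray:
    """Draw ``n`` i.i.d. firing rates (spikes/s) from a gamma rate model."""
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    return rng.gamma(model.alpha, model.rate_hz / model.alpha, size=n)


def _isis_from_rates(
    rng: np.random.Generator, kappa: float, rates_hz: np.ndarray
) -> np.ndarray:
    """Gamma intervals (ms) with shape kappa and mean 1/rate."""
    xi = _hz_to_per_ms(rates_hz)
    return rng.gamma(kappa, 1.0 / (kappa * xi))


def _train_from_isis(isis_ms: np.ndarray, rates_hz: np.ndarray, meta: dict) -> SpikeTrain:
    times_s = np.concatenate([[0.0], np.cumsum(isis_ms)]) / MS_PER_S
    return SpikeTrain(times=times_s, metadata=meta, rates_hz=rates_hz)


def simulate_constant_rate(
    n_spikes: int, kappa: float, rate_hz: float, seed: int
) -> SpikeTrain:
    """Gamma renewal train at a fixed rate: ``n_spikes`` spikes whose
    ``n_spikes - 1`` intervals are i.i.d. gamma(kappa, mean 1/rate)."""
    if n_spikes < 2:
        raise ValidationError("need n_spikes >= 2")
    gen = GammaGenerator(kappa)
    if not (np.isfinite(rate_hz) and rate_hz > 0):
        raise ValidationError(f"rate must be positive, got {rate_hz}")
    (_, isi_rng) = _split_rng(seed)
    rates = np.full(n_spikes - 1, float(rate_hz))
    isis = _isis_from_rates(isi_rng, gen.kappa, rates)
    meta = {"model": "constant_rate", "kappa": kappa, "rate_hz": rate_hz, "seed": seed}
    return _train_from_isis(isis, rates, meta)


def simulate_superstat(
    n_spikes: int,
    kappa: float,
    rate_model: GammaRateModel,
    scheme: str = "per-interval",
    block_size: int = 100,
    seed: int = 0,
) -> SpikeTrain:
    """Doubly-stochastic gamma train.

    ``per-interval`` redraws the rate independently for every interval and
    realizes the compound (beta-2) marginal exactly; ``blockwise`` holds one
    rate draw for ``block_size`` consecutive intervals (slow modulation,
    same marginal law).
    """
    if n_spikes < 2:
        raise ValidationError("need n_spikes >= 2")
    gen = GammaGenerator(kappa)
    if scheme not in ("per-interval", "blockwise"):
        raise ValidationError(f"unknown scheme {scheme!r}")
    if scheme == "blockwise" and block_size < 1:
        raise ValidationError("block_size must be >= 1")
    rate_rng, isi_rng = _split_rng(seed)
    n_isi = n_spikes - 1
    if scheme == "per-interval":
        rates = rate_rng.gamma(
            rate_model.alpha, rate_model.rate_hz / rate_model.alpha, size=n_isi
        )
    else:
        n_blocks = -(-n_isi // block_size)
        block_rates = rate_rng.gamma(
            rate_model.alpha, rate_model.rate_hz / rate_model.alpha, size=n_blocks
        )
        rates = np.repeat(block_rates, block_size)[:n_isi]
    isis = _isis_from_rates(isi_rng, gen.kappa, rates)
    meta = {
        "model": "superstat",
        "kappa": kappa,
        "alpha": rate_model.alpha,
        "rate_hz": rate_model.rate_hz,
        "scheme": scheme,
        "block_size": block_size if scheme == "blockwise" else None,
        "seed": seed,
    }
    return _train_from_isis(isis, rates, meta)


def simulate_discrete_mixture(
    n_spikes: int, kappa: float, model: DiscreteRateModel, seed: int
) -> SpikeTrain:
    """Gamma train whose per-interval rate is sampled from a finite set."""
    if n_spikes < 2:
        raise ValidationError("need n_spikes >= 2")
    gen = GammaGenerator(kappa)
    rate_rng, isi_rng = _split_rng(seed)
    n_isi = n_spikes - 1
    idx = rate_rng.choice(len(model.rates_hz), size=n_isi, p=np.asarray(model.weights))
    rates = np.asarray(model.rates_hz)[idx]
    isis = _isis_from_rates(isi_rng, gen.kappa, rates)
    meta = {
        "model": "discrete_mixture",
        "kappa": kappa,
        "rates_hz": list(model.rates_hz),
        "weights": list(model.weights),
        "seed": seed,
    }
    return _train_from_isis(isis, rates, meta)
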