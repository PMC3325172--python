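"""Information measures of the doubly-stochastic firing model.

All entropies are differential, in nats by default, with intervals in
milliseconds and rates in 1/ms — differential entropy is unit-dependent,
so every report records both conventions. The mutual information
between rate and interval is unit- and base-invariant.

Closed forms used (xi in 1/ms, R_ms = mean rate in 1/ms):

* generator entropy of the unit-mean gamma law of shape kappa:
  S = kappa - log kappa + log Gamma(kappa) + (1 - kappa) psi(kappa)
* rate entropy of the gamma law (alpha, mean R_ms):
  H[Xi] = alpha + log(R_ms/alpha) + log Gamma(alpha) + (1-alpha) psi(alpha)
* conditional interval entropy: H[T|Xi] = S - E[log xi]
  with E[log xi] = psi(alpha) + log(R_ms/alpha)
* interval entropy H[T]: quadrature over the compound beta-2 law.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy.special import digamma, gammaln

from .beta2 import Beta2Params, beta2_logpdf
from .errors import NumericError, ValidationError
from .simulate import GammaGenerator, GammaRateModel
from .superstat import compound_params

__all__ = [
    "EntropyReport",
    "generator_entropy",
    "rate_entropy",
    "conditional_entropy",
    "isi_entropy",
    "mutual_information",
    "entropy_report",
]


def generator_entropy(kappa: float) -> float:
    """Rate-independent entropy S of the unit-mean gamma generator, nats."""
    if not (np.isfinite(kappa) and kappa > 0):
        raise ValidationError(f"kappa must be positive, got {kappa}")
    k = kappa
    return float(k - math.log(k) + gammaln(k) + (1.0 - k) * digamma(k))


def rate_entropy(model: GammaRateModel) -> float:
    """Differential entropy H[Xi] of the gamma rate law, rate in 1/ms, nats."""
    a = model.alpha
    scale = model.rate_per_ms / a
    return float(a + math.log(scale) + gammaln(a) + (1.0 - a) * digamma(a))


def mean_log_rate(model: GammaRateModel) -> float:
    """E[log xi] (xi in 1/ms) for the gamma rate law."""
    return float(digamma(model.alpha) + math.log(model.rate_per_ms / model.alpha))


def conditional_entropy(generator: GammaGenerator, rates: GammaRateModel) -> float:
    """H[T|Xi] = S(kappa) - E[log xi], intervals in ms, nats."""
    return generator_entropy(generator.kappa) - mean_log_rate(rates)


def isi_entropy(params: Beta2Params) -> float:
    """H[T] = -integral P log P of the beta-2 interval law, ms, nats."""

    def integrand(u: np.ndarray) -> np.ndarray:
        t = np.exp(u)
        log_p = beta2_logpdf(t, params)
        return -np.exp(log_p + u) * log_p

    u0 = math.log(params.tau_ms)
    val, err = integrate.quad(
        integrand, u0 - 45.0, u0 + 45.0, epsabs=1e-12, epsrel=1e-10, limit=500
    )
    if not np.isfinite(val):
        raise NumericError("interval-entropy quadrature failed")
    return float(val)


def mutual_information(generator: GammaGenerator, rates: GammaRateModel) -> float:
    """I[T, Xi] = H[T] - H[T|Xi], nats (unit- and base-invariant)."""
    return isi_entropy(compound_params(generator, rates)) - conditional_entropy(
        generator, rates
    )


@dataclass(frozen=True)
class EntropyReport:
    """All information measures for one (generator, rate-law) pair."""

    H_rate: float  # H[Xi]
    S_generator: float
    H_cond: float  # H[T|Xi]
    H_isi: float  # H[T]
    MI: float  # I[T, Xi]
    log_base: str = "e"
    isi_unit: str = "ms"

    def in_bits(self) -> "EntropyReport":
        if self.log_base == "2":
            return self
        f = 1.0 / math.log(2.0)
        return EntropyReport(
            H_rate=self.H_rate * f,
            S_generator=self.S_generator * f,
            H_cond=self.H_cond * f,
            H_isi=self.H_isi * f,
            MI=self.MI * f,
            log_base="2",
            isi_unit=self.isi_unit,
        )


def entropy_report(generator: GammaGenerator, rates: GammaRateModel) -> EntropyReport:
    h_cond = conditional_entropy(generator, rates)
    h_isi = isi_entropy(compound_params(generator, rates))
    return EntropyReport(
        H_rate=rate_entropy(rates),
        S_generator=generator_entropy(generator.kappa),
        H_cond=h_cond,
        H_isi=h_isi,
        MI=h_isi - h_cond,
    )
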