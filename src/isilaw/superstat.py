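"""Compounding and decomposition of the doubly-stochastic interval law.

Forward direction: the marginal interval density is the mixture

    P(T) = integral q(T | xi) k(xi) dxi

of the conditional gamma law over the rate distribution, evaluated here
by adaptive quadrature (or a finite sum for discrete rate models). For
gamma rates this mixture has the beta-2 closed form; the quadrature is
kept deliberately independent of that closed form so the two can act as
mutual oracles.

Inverse direction: a fitted beta-2 law (alpha, kappa, tau) decomposes
uniquely into a gamma interval generator of shape kappa and a gamma rate
law of shape alpha and mean R = alpha/(tau*kappa) in 1/ms. The
analytical inverse-Laplace route reduces to exactly this parameter
identification, which is what is implemented.
"""

from __future__ import annotations

from typing import Union

import numpy as np
from scipy import integrate

from .beta2 import Beta2Params, beta2_logpdf
from .errors import NumericError, ValidationError
from .simulate import DiscreteRateModel, GammaGenerator, GammaRateModel

__all__ = ["mixture_pdf", "rate_model_from_beta2", "delta_limit_gap"]

MS_PER_S = 1000.0

RateModel = Union[GammaRateModel, DiscreteRateModel]


def _mixture_pdf_scalar(
    t_ms: float, generator: GammaGenerator, rates: GammaRateModel
) -> float:
    """Quadrature of q(T|xi) k(xi) over xi in log coordinates.

    The integrand in xi is unimodal with an analytically known peak; the
    integration window spans a generous e^(+/-40) around it.
    """
    k = generator.kappa
    a = rates.alpha
    r_ms = rates.rate_per_ms

    def integrand(u: np.ndarray) -> np.ndarray:
        xi = np.exp(u)
        log_q = generator.log_conditional_pdf(t_ms, xi * MS_PER_S)
        log_k = rates.log_pdf_per_ms(xi)
        return np.exp(log_q + log_k + u)  # + u: Jacobian of xi = e^u

    xi_peak = (k + a - 1.0) / (k * t_ms + a / r_ms)
    if xi_peak <= 0:
        xi_peak = 1.0 / (k * t_ms + a / r_ms)
    u0 = np.log(xi_peak)
    val, err = integrate.quad(
        integrand, u0 - 40.0, u0 + 40.0, epsabs=0, epsrel=1e-11, limit=500
    )
    if not np.isfinite(val) or (val > 0 and err / val > 1e-7):
        raise NumericError(
            f"mixture quadrature failed at T={t_ms} ms (value {val}, error {err})"
        )
    return float(val)


def mixture_pdf(
    t_ms: np.ndarray, generator: GammaGenerator, rates: RateModel
) -> np.ndarray:
    """Marginal interval density (per ms) of the compound process."""
    t = np.atleast_1d(np.asarray(t_ms, dtype=float))
    if np.any(t <= 0):
        raise ValidationError("intervals must be positive")
    if isinstance(rates, DiscreteRateModel):
        out = np.zeros_like(t)
        for r, w in zip(rates.rates_hz, rates.weights):
            out += w * generator.conditional_pdf(t, r)
    elif isinstance(rates, GammaRateModel):
        out = np.array([_mixture_pdf_scalar(ti, generator, rates) for ti in t])
    else:
        raise ValidationError(f"unsupported rate model {type(rates).__name__}")
    return out if np.ndim(t_ms) else float(out[0])


def rate_model_from_beta2(params: Beta2Params) -> GammaRateModel:
    """Decompose a beta-2 interval law into its gamma rate distribution:
    shape alpha, mean alpha/(tau*kappa) per ms."""
    return GammaRateModel(alpha=params.alpha, rate_hz=params.rate_hz)


def compound_params(generator: GammaGenerator, rates: GammaRateModel) -> Beta2Params:
    """Forward identification: gamma generator + gamma rates -> beta-2."""
    tau = rates.alpha / (rates.rate_per_ms * generator.kappa)
    return Beta2Params(alpha=rates.alpha, kappa=generator.kappa, tau_ms=tau)


def delta_limit_gap(generator: GammaGenerator, rate_hz: float, alpha: float) -> float:
    """Kullback-Leibler divergence (nats) between the compound interval
    law at (alpha, R, kappa) and the constant-rate gamma law at (kappa, R).

    Measures how far the rate distribution is from its large-alpha
    point-mass limit; it decays to zero as alpha grows.
    """
    if not (np.isfinite(alpha) and alpha > 0):
        raise ValidationError(f"alpha must be positive, got {alpha}")
    rates = GammaRateModel(alpha=alpha, rate_hz=rate_hz)
    p = compound_params(generator, rates)

    def integrand(u: np.ndarray) -> np.ndarray:
        t = np.exp(u)
        log_p = beta2_logpdf(t, p)
        log_q = generator.log_conditional_pdf(t, rate_hz)
        return np.exp(log_p + u) * (log_p - log_q)

    u0 = np.log(1.0 / (rate_hz / MS_PER_S))  # mean interval, ms
    val, err = integrate.quad(
        integrand, u0 - 40.0, u0 + 40.0, epsabs=1e-13, epsrel=1e-10, limit=500
    )
    if not np.isfinite(val):
        raise NumericError("KL quadrature failed")
    return float(val)
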