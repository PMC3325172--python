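"""The beta-2 (generalized beta prime) interval law and its fitting.

Density, with T in ms:

    p(T) = [Gamma(a+k) / (Gamma(a) Gamma(k))] (1/tau) (T/tau)^(k-1)
           (1 + T/tau)^(-(a+k))

with tail shape ``alpha`` (power-law tail exponent eta = alpha + 1),
small-interval shape ``kappa`` (log-log slope kappa - 1 at small T) and
scale ``tau`` in ms. It arises exactly as a gamma interval law of shape
kappa compounded over a gamma rate law of shape alpha and mean
R = alpha / (tau * kappa) (in 1/ms).

Fitting follows the binned least-squares procedure: the log density at
nonzero bins is fit with the reparameterization

    log p = c1 log T - c2 log(1 + T/c3) + C(c1, c2, c3)

where kappa = c1 + 1, alpha = c2 - c1 - 1, tau = c3 and C is the log
normalization constant, using bounded trust-region least squares (the
bounded analogue of Levenberg-Marquardt).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import integrate, optimize
from scipy.special import betaln

from .errors import MomentsUndefinedError, NumericError, ValidationError
from .histogram import LogBinnedHistogram
from .tailfit import InsufficientTailError, fit_tail, find_mode

__all__ = ["Beta2Params", "Beta2Fit", "beta2_pdf", "beta2_logpdf", "beta2_mean",
           "beta2_cv", "fit_beta2"]

MS_PER_S = 1000.0

# (c1, c2, c3) box constraints keeping alpha, kappa, tau positive
_C1_BOUNDS = (-0.99, 50.0)
_C2_MARGIN = 1.01  # c2 > c1 + 1.01 so alpha > 0.01
_C2_MAX = 100.0
_C3_BOUNDS = (1e-2, 1e5)


@dataclass(frozen=True)
class Beta2Params:
    """Beta-2 parameters: tail shape ``alpha``, small-T shape ``kappa``,
    scale ``tau_ms``."""

    alpha: float
    kappa: float
    tau_ms: float

    def __post_init__(self) -> None:
        for name in ("alpha", "kappa", "tau_ms"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValidationError(f"{name} must be positive, got {v}")

    @property
    def eta(self) -> float:
        """Power-law tail exponent."""
        return self.alpha + 1.0

    @property
    def rate_per_ms(self) -> float:
        """Mean firing rate implied by the decomposition, in 1/ms."""
        return self.alpha / (self.tau_ms * self.kappa)

    @property
    def rate_hz(self) -> float:
        return self.rate_per_ms * MS_PER_S

    @property
    def mode_ms(self) -> Optional[float]:
        """Density peak tau (kappa-1)/(alpha+1); None when the density is
        monotone decreasing (kappa <= 1)."""
        if self.kappa <= 1.0:
            return None
        return self.tau_ms * (self.kappa - 1.0) / (self.alpha + 1.0)


def beta2_logpdf(t_ms: np.ndarray, params: Beta2Params) -> np.ndarray:
    t = np.asarray(t_ms, dtype=float)
    if np.any(t <= 0):
        raise ValidationError("intervals must be positive")
    a, k, tau = params.alpha, params.kappa, params.tau_ms
    return (
        -betaln(a, k)
        - np.log(tau)
        + (k - 1.0) * np.log(t / tau)
        - (a + k) * np.log1p(t / tau)
    )


def beta2_pdf(t_ms: np.ndarray, params: Beta2Params) -> np.ndarray:
    """Beta-2 density (per ms) at interval ``t_ms``."""
    return np.exp(beta2_logpdf(t_ms, params))


def beta2_mean(params: Beta2Params) -> float:
    """Mean interval tau*kappa/(alpha-1) ms; requires alpha > 1."""
    if params.alpha <= 1.0:
        raise MomentsUndefinedError(
            f"mean requires alpha > 1, got alpha={params.alpha}"
        )
    return params.tau_ms * params.kappa / (params.alpha - 1.0)


def beta2_cv(params: Beta2Params) -> float:
    """Coefficient of variation via numeric quadrature; requires alpha > 2."""
    if params.alpha <= 2.0:
        raise MomentsUndefinedError(
            f"CV requires alpha > 2, got alpha={params.alpha}"
        )
    mean = beta2_mean(params)

    def _moment(n: int) -> float:
        # integrate T^n p(T) over log T for numerical stability
        def integrand(u: np.ndarray) -> np.ndarray:
            t = np.exp(u)
            return np.exp(n * u + beta2_logpdf(t, params) + u)

        lo = np.log(params.tau_ms) - 40.0
        hi = np.log(params.tau_ms) + 40.0
        val, err = integrate.quad(integrand, lo, hi, epsabs=0, epsrel=1e-11, limit=300)
        return val

    m2 = _moment(2)
    var = m2 - mean**2
    if var <= 0:
        raise NumericError("quadrature produced a nonpositive variance")
    return float(np.sqrt(var) / mean)


@dataclass(frozen=True)
class Beta2Fit:
    """Result of the binned log-density least-squares fit."""

    params: Beta2Params
    c1: float
    c2: float
    c3: float
    residual: float  # sum of squared log-density residuals
    converged: bool
    n_iter: int
    unstable: bool  # parameters pinned near the box boundary
    cd: float  # coefficient of determination of log density vs data

    @property
    def rate_model(self):
        """Implied gamma rate law (import-cycle-free accessor)."""
        from .superstat import rate_model_from_beta2

        return rate_model_from_beta2(self.params)


def _log_model(t: np.ndarray, c1: float, c2: float, c3: float) -> np.ndarray:
    a = c2 - c1 - 1.0
    k = c1 + 1.0
    norm = -betaln(a, k) - k * np.log(c3)
    return c1 * np.log(t) - c2 * np.log1p(t / c3) + norm


def _initial_guess(hist: LogBinnedHistogram) -> tuple[float, float, float]:
    """Read rough (alpha0, kappa0, tau0) off the histogram itself: tail
    slope for alpha, pre-mode log-log slope for kappa, mode for tau."""
    alpha0 = 1.5
    try:
        tail = fit_tail(hist, scale="loglog")
        alpha0 = max(tail.eta - 1.0, 0.2)
    except InsufficientTailError:
        pass
    mode = find_mode(hist)
    centers = hist.centers_ms
    counts = np.asarray(hist.counts, dtype=float)
    pre = (centers < mode) & (counts > 0)
    kappa0 = 1.0
    if int(pre.sum()) >= 3:
        s, _ = np.polyfit(np.log10(centers[pre]), np.log10(hist.densities[pre]), 1)
        kappa0 = float(np.clip(1.0 + s, 0.05, 30.0))
    tau0 = float(np.clip(mode * (alpha0 + 1.0) / max(kappa0 - 1.0, 0.1), *_C3_BOUNDS))
    return alpha0, kappa0, tau0


def fit_beta2(
    hist: LogBinnedHistogram,
    init: Optional[Beta2Params] = None,
    min_bins: int = 10,
    weights: str = "count",
) -> Beta2Fit:
    """Fit the beta-2 law to the log densities of all nonzero bins.

    Least squares in log-density space over the (c1, c2, c3) box. With
    ``weights="count"`` (default) residuals are weighted by the square
    root of the bin count — the inverse standard deviation of a log
    Poisson count — so sparsely populated tail bins, whose log density
    is dominated by shot noise, do not drag the fit; ``weights="none"``
    gives every nonzero bin equal weight. The fit is flagged
    ``unstable`` when a parameter lands near the box boundary (e.g.
    data from a constant-rate train push alpha toward infinity).
    """
    if weights not in ("count", "none"):
        raise ValidationError(f"unknown weights mode {weights!r}")
    counts = np.asarray(hist.counts, dtype=float)
    sel = counts > 0
    if int(sel.sum()) < min_bins:
        raise ValidationError(
            f"need at least {min_bins} nonzero bins, got {int(sel.sum())}"
        )
    t = hist.centers_ms[sel]
    y = np.log(hist.densities[sel])
    if weights == "count":
        w = np.sqrt(counts[sel] / counts[sel].max())
    else:
        w = np.ones(int(sel.sum()))

    if init is None:
        a0, k0, tau0 = _initial_guess(hist)
    else:
        a0, k0, tau0 = init.alpha, init.kappa, init.tau_ms
    x0 = np.array([k0 - 1.0, a0 + k0, tau0])

    lo = np.array([_C1_BOUNDS[0], 0.0, _C3_BOUNDS[0]])
    hi = np.array([_C1_BOUNDS[1], _C2_MAX, _C3_BOUNDS[1]])

    def residuals(c: np.ndarray) -> np.ndarray:
        c1, c2, c3 = c
        c2 = max(c2, c1 + _C2_MARGIN)  # keep alpha positive inside the solver
        return w * (_log_model(t, c1, c2, c3) - y)

    x0 = np.clip(x0, lo + 1e-6, hi - 1e-6)
    x0[1] = max(x0[1], x0[0] + _C2_MARGIN + 1e-6)
    result = optimize.least_squares(
        residuals, x0, bounds=(lo, hi), method="trf", max_nfev=2000
    )
    c1, c2, c3 = result.x
    c2 = max(c2, c1 + _C2_MARGIN)
    alpha, kappa, tau = c2 - c1 - 1.0, c1 + 1.0, c3
    if alpha <= 0 or kappa <= 0:
        raise NumericError(
            f"fit produced invalid parameters alpha={alpha}, kappa={kappa}"
        )
    params = Beta2Params(alpha=alpha, kappa=kappa, tau_ms=tau)
    unstable = bool(
        alpha > 0.9 * (_C2_MAX - _C1_BOUNDS[0] - 1.0)
        or kappa > 0.9 * (_C1_BOUNDS[1] + 1.0)
        or not result.success
    )
    raw_resid = _log_model(t, c1, c2, c3) - y
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    cd = 1.0 - float(np.sum(raw_resid**2)) / ss_tot if ss_tot > 0 else 0.0
    return Beta2Fit(
        params=params,
        c1=float(c1),
        c2=float(c2),
        c3=float(c3),
        residual=float(np.sum(raw_resid**2)),
        converged=bool(result.success),
        n_iter=int(result.nfev),
        unstable=unstable,
        cd=float(cd),
    )
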