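"""Tail regression of log-binned interval histograms.

The tail of the histogram is regressed linearly in double-logarithmic
(log density vs log interval) and semi-logarithmic (log density vs
interval) coordinates, over bins at least twice the histogram mode. A
coefficient of determination above 0.95 in one scale but not the other
classifies the tail as power-law or exponential.

The mode is taken as the most populated bin of the raw count histogram
(ties to the smallest interval). On a logarithmic grid the count peak
sits where density*T is maximal, i.e. deeper into the tail than the
density peak; starting the fit at twice this point is what makes the
regressed slope track the asymptotic power-law exponent (fitting from
twice the density peak instead systematically underestimates it, badly
so for monotone densities whose density peak is the first bin).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import InsufficientTailError, ValidationError
from .histogram import LogBinnedHistogram

__all__ = ["TailFitResult", "TailClass", "find_mode", "fit_tail", "classify_tail"]

CD_THRESHOLD = 0.95
TAIL_MULTIPLIER = 2.0
MIN_TAIL_BINS = 5


@dataclass(frozen=True)
class TailFitResult:
    """One linear tail regression.

    ``slope`` is the raw least-squares slope of log10 density against
    log10 T (``loglog``) or against T (``semilog``); ``eta`` is its
    magnitude, the power-law exponent in the double-log case.
    """

    scale: str
    slope: float
    intercept: float
    cd: float
    fit_range_ms: tuple[float, float]
    n_bins_used: int

    @property
    def eta(self) -> float:
        return -self.slope


@dataclass(frozen=True)
class TailClass:
    verdict: str  # power_law | exponential | both | neither
    cd_loglog: Optional[float]
    cd_semilog: Optional[float]
    fit_loglog: Optional[TailFitResult] = None
    fit_semilog: Optional[TailFitResult] = None


def find_mode(hist: LogBinnedHistogram, weight: str = "count") -> float:
    """Geometric center (ms) of the maximal bin.

    ``weight="count"`` (default) uses raw bin counts — the histogram
    mode as drawn; ``weight="density"`` uses the width-normalized
    densities, i.e. the density peak. Ties break to the smallest
    interval.
    """
    if weight == "count":
        values = np.asarray(hist.counts, dtype=float)
    elif weight == "density":
        values = hist.densities
    else:
        raise ValidationError(f"unknown mode weight {weight!r}")
    if not np.any(values > 0):
        raise ValidationError("histogram is empty")
    return float(hist.centers_ms[int(np.argmax(values))])


def _tail_selection(hist: LogBinnedHistogram, multiplier: float) -> np.ndarray:
    mode = find_mode(hist)
    centers = hist.centers_ms
    return (centers >= multiplier * mode) & (np.asarray(hist.counts, dtype=float) > 0)


def fit_tail(
    hist: LogBinnedHistogram,
    scale: str = "loglog",
    multiplier: float = TAIL_MULTIPLIER,
    min_bins: int = MIN_TAIL_BINS,
) -> TailFitResult:
    """Ordinary least squares on the histogram tail.

    The ordinate is log10 density in both scales; the abscissa is log10 T
    (``loglog``) or T in ms (``semilog``). Bins used: nonzero counts with
    center at least ``multiplier`` times the histogram mode, up to the
    last nonzero bin. The coefficient of determination is computed in the
    regression's ordinate space.
    """
    if scale not in ("loglog", "semilog"):
        raise ValidationError(f"unknown scale {scale!r}")
    sel = _tail_selection(hist, multiplier)
    if int(sel.sum()) < min_bins:
        raise InsufficientTailError(
            f"only {int(sel.sum())} usable tail bins (< {min_bins})"
        )
    t = hist.centers_ms[sel]
    y = np.log10(hist.densities[sel])
    x = np.log10(t) if scale == "loglog" else t
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    cd = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    return TailFitResult(
        scale=scale,
        slope=float(slope),
        intercept=float(intercept),
        cd=float(cd),
        fit_range_ms=(float(t[0]), float(t[-1])),
        n_bins_used=int(sel.sum()),
    )


def classify_tail(
    hist: LogBinnedHistogram,
    threshold: float = CD_THRESHOLD,
    multiplier: float = TAIL_MULTIPLIER,
) -> TailClass:
    """Power-law / exponential verdict from the two tail regressions."""
    fits: dict[str, Optional[TailFitResult]] = {}
    for scale in ("loglog", "semilog"):
        try:
            fits[scale] = fit_tail(hist, scale=scale, multiplier=multiplier)
        except InsufficientTailError:
            fits[scale] = None
    cd_ll = fits["loglog"].cd if fits["loglog"] else None
    cd_sl = fits["semilog"].cd if fits["semilog"] else None
    ok_ll = cd_ll is not None and cd_ll > threshold
    ok_sl = cd_sl is not None and cd_sl > threshold
    if ok_ll and ok_sl:
        verdict = "both"
    elif ok_ll:
        verdict = "power_law"
    elif ok_sl:
        verdict = "exponential"
    else:
        verdict = "neither"
    return TailClass(
        verdict=verdict,
        cd_loglog=cd_ll,
        cd_semilog=cd_sl,
        fit_loglog=fits["loglog"],
        fit_semilog=fits["semilog"],
    )
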