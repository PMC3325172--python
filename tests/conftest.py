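import numpy as np
import pytest

from isilaw import (
    Beta2Params,
    GammaRateModel,
    LogBinnedHistogram,
    beta2_pdf,
    compute_isis,
    log_binned_histogram,
    simulate_superstat,
)


@pytest.fixture(scope="session")
def reference_params() -> Beta2Params:
    """The worked beta-2 example used throughout: alpha=1.91, kappa=2,
    R=10 spikes/s -> tau = alpha/(R_ms*kappa) = 95.5 ms."""
    return Beta2Params(alpha=1.91, kappa=2.0, tau_ms=95.5)


@pytest.fixture(scope="session")
def exact_hist(reference_params) -> LogBinnedHistogram:
    """Zero-noise histogram: reference beta-2 density tabulated at bin centers."""
    return LogBinnedHistogram.from_density(lambda t: beta2_pdf(t, reference_params))


@pytest.fixture(scope="session")
def superstat_hist() -> LogBinnedHistogram:
    """One seeded 1e5-interval doubly-stochastic train, histogrammed."""
    train = simulate_superstat(
        100_001, 2.0, GammaRateModel(alpha=1.91, rate_hz=10.0), seed=1234
    )
    return log_binned_histogram(compute_isis(train))


def beta2_scipy(params: Beta2Params):
    """Independent oracle: the beta-2 law as a scipy frozen distribution
    (beta prime with shapes (kappa, alpha) and scale tau)."""
    from scipy import stats

    return stats.betaprime(params.kappa, params.alpha, scale=params.tau_ms)
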