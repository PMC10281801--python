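"""MCMC convergence diagnostics and gates.

The convergence gates follow common practice for long thinned chains:
effective sample size above 1000 and lag-1 sampling autocorrelation below
0.1 for every monitored parameter.
"""

from __future__ import annotations

import warnings

import arviz as az
import numpy as np

__all__ = [
    "effective_sample_size",
    "lag_autocorrelation",
    "convergence_gates",
    "ESS_THRESHOLD",
    "AUTOCORR_THRESHOLD",
]

ESS_THRESHOLD = 1000.0
AUTOCORR_THRESHOLD = 0.1


def effective_sample_size(draws: np.ndarray) -> float:
    """Autocorrelation-time effective sample size of a single chain."""
    draws = np.asarray(draws, dtype=float)
    if draws.size < 4 or np.ptp(draws) == 0:
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.ess(draws[None, :]))


def lag_autocorrelation(draws: np.ndarray, lag: int = 1) -> float:
    """Sample autocorrelation at the given lag; NaN for constant chains."""
    draws = np.asarray(draws, dtype=float)
    if draws.size <= lag or np.ptp(draws) == 0:
        return float("nan")
    a = draws[:-lag] - draws.mean()
    b = draws[lag:] - draws.mean()
    denom = np.sum((draws - draws.mean()) ** 2)
    if denom == 0:
        return float("nan")
    return float(np.sum(a * b) / denom)


def convergence_gates(
    draws: np.ndarray,
    ess_min: float = ESS_THRESHOLD,
    autocorr_max: float = AUTOCORR_THRESHOLD,
) -> dict:
    """Per-parameter pass/fail of the ESS and autocorrelation gates.

    Constant chains (undefined autocorrelation) are flagged as failing.
    """
    ess = effective_sample_size(draws)
    ac = lag_autocorrelation(draws, lag=1)
    ok = bool(np.isfinite(ess) and np.isfinite(ac) and ess > ess_min and abs(ac) < autocorr_max)
    return {"ess": ess, "autocorr_lag1": ac, "converged": ok}
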