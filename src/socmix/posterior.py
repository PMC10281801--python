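"""Posterior post-processing: repeatability, intervals and significance.

Repeatability is the intraclass correlation ``R = V_I / (V_I + V_R)``
applied draw-wise to the posterior of the variance components; year variance
is conditioned out (adjusted repeatability).  For traits modelled with a
Poisson distribution on a log link, variance components live on the latent
scale and are transformed to the observed-count scale with the standard
log-normal-Poisson moments:

    Lambda  = exp(mu + (V_I + V_R) / 2)
    V_I,obs = Lambda^2 (exp(V_I) - 1)
    V_P,obs = Lambda^2 (exp(V_I + V_R) - 1) + Lambda
    R_obs   = V_I,obs / V_P,obs

Posterior intervals default to highest-posterior-density intervals; a
parameter is called significantly non-zero when its 95% interval excludes
zero.  The probability of direction pd converts to a two-sided p-value as
``p = 2 (1 - pd)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import arviz as az
import numpy as np

__all__ = [
    "RepeatabilityEstimate",
    "repeatability_latent",
    "repeatability_observed_poisson",
    "hpd_interval",
    "quantile_interval",
    "significant_nonzero",
    "pd_to_p",
    "probability_of_direction",
    "sex_difference",
    "summarize_draws",
]


def repeatability_latent(v_i: np.ndarray, v_r: np.ndarray) -> np.ndarray:
    """Draw-wise latent-scale repeatability V_I / (V_I + V_R).

    Draws with non-positive total variance are discarded (count logged via
    the returned array's length).
    """
    v_i = np.asarray(v_i, dtype=float)
    v_r = np.asarray(v_r, dtype=float)
    tot = v_i + v_r
    ok = tot > 0
    return v_i[ok] / tot[ok]


def repeatability_observed_poisson(
    mu: np.ndarray, v_i: np.ndarray, v_r: np.ndarray
) -> np.ndarray:
    """Draw-wise observed(count)-scale repeatability for a Poisson-log trait.

    Uses the closed-form moments of a Poisson with log-normal rate; the
    latent mean is the intercept (covariates being centred).
    """
    mu, v_i, v_r = (np.asarray(a, dtype=float) for a in (mu, v_i, v_r))
    if not (np.isfinite(mu).all() and np.isfinite(v_i).all() and np.isfinite(v_r).all()):
        raise ValueError("non-finite inputs to observed-scale transformation")
    lam = np.exp(mu + (v_i + v_r) / 2.0)
    v_i_obs = lam**2 * (np.exp(v_i) - 1.0)
    v_p_obs = lam**2 * (np.exp(v_i + v_r) - 1.0) + lam
    return v_i_obs / v_p_obs


def hpd_interval(draws: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Highest-posterior-density interval of a sample."""
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("empty sample")
    if np.ptp(draws) == 0:
        return float(draws[0]), float(draws[0])
    if mass >= 1.0:
        return float(draws.min()), float(draws.max())
    lo, hi = az.hdi(draws, hdi_prob=mass)
    return float(lo), float(hi)


def quantile_interval(draws: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Central (equal-tailed) credible interval."""
    a = (1.0 - mass) / 2.0
    lo, hi = np.quantile(np.asarray(draws, dtype=float), [a, 1.0 - a])
    return float(lo), float(hi)


def significant_nonzero(interval: tuple[float, float]) -> bool:
    """True when the credible interval does not overlap zero."""
    lo, hi = interval
    return bool(lo > 0.0 or hi < 0.0)


def probability_of_direction(draws: np.ndarray) -> float:
    """Posterior probability that the parameter has its majority sign."""
    draws = np.asarray(draws, dtype=float)
    p_pos = float((draws > 0).mean())
    return max(p_pos, 1.0 - p_pos)


def pd_to_p(pd_value: float) -> float:
    """Two-sided p-value from a probability of direction: p = 2 (1 - pd)."""
    if not 0.5 <= pd_value <= 1.0:
        raise ValueError("probability of direction must lie in [0.5, 1]")
    return 2.0 * (1.0 - pd_value)


def sex_difference(
    draws_f: np.ndarray, draws_m: np.ndarray, seed: int | None = None
) -> dict:
    """pd and two-sided p for a parameter difference between two chains.

    The two chains are independent fits, so the difference distribution is
    formed by pairing draws (after random permutation to break any shared
    iteration ordering).
    """
    draws_f = np.asarray(draws_f, dtype=float)
    draws_m = np.asarray(draws_m, dtype=float)
    n = min(len(draws_f), len(draws_m))
    rng = np.random.default_rng(seed)
    d = rng.permutation(draws_f)[:n] - rng.permutation(draws_m)[:n]
    pd_val = probability_of_direction(d)
    return {
        "mean_difference": float(d.mean()),
        "pd": pd_val,
        "p": pd_to_p(pd_val),
        "interval": hpd_interval(d),
    }


@dataclass
class RepeatabilityEstimate:
    """Latent- and observed-scale repeatability summaries for one trait."""

    trait: str
    sex: str
    latent_mean: float
    latent_interval: tuple[float, float]
    data_mean: float | None = None
    data_interval: tuple[float, float] | None = None
    v_i_mean: float = float("nan")
    v_r_mean: float = float("nan")

    def as_row(self) -> dict:
        row = {
            "trait": self.trait,
            "sex": self.sex,
            "latent_R": self.latent_mean,
            "latent_lo": self.latent_interval[0],
            "latent_hi": self.latent_interval[1],
            "V_I": self.v_i_mean,
            "V_R": self.v_r_mean,
        }
        if self.data_mean is not None:
            row |= {
                "data_R": self.data_mean,
                "data_lo": self.data_interval[0],
                "data_hi": self.data_interval[1],
            }
        return row


def summarize_draws(draws: np.ndarray, mass: float = 0.95, hpd: bool = True) -> dict:
    """Posterior mean, credible interval and significance call."""
    draws = np.asarray(draws, dtype=float)
    interval = hpd_interval(draws, mass) if hpd else quantile_interval(draws, mass)
    return {
        "mean": float(draws.mean()),
        "lo": interval[0],
        "hi": interval[1],
        "significant": significant_nonzero(interval),
    }
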