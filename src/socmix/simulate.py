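"""Synthetic data generators with known ground truth.

Two levels of simulation are provided:

* :func:`simulate_trait_panel` draws yearly trait measures directly from the
  assumed multivariate mixed model (latent Gaussian individual, year and
  residual effects; Gaussian or Poisson-log observation models).  It is used
  to validate the sampler against known variance components and
  among-individual correlations.
* :func:`simulate_sightings` generates survey-level georeferenced sighting
  records around per-individual home-range centres, with proximity structure
  controlled by a latent gregariousness, so that the full
  sightings -> home ranges -> social metrics pipeline can be exercised
  end to end.

:func:`simulate_fitness` attaches a single Poisson-distributed offspring
count per individual whose log-rate is correlated, at a specified magnitude,
with the latent individual social effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TraitSimConfig",
    "SightingSimConfig",
    "TraitPanelTruth",
    "simulate_trait_panel",
    "simulate_fitness",
    "simulate_sightings",
]


def _check_correlation_matrix(omega: np.ndarray, name: str = "Omega_I") -> np.ndarray:
    omega = np.asarray(omega, dtype=float)
    if omega.ndim != 2 or omega.shape[0] != omega.shape[1]:
        raise ValueError(f"{name} must be a square matrix, got shape {omega.shape}")
    if not np.allclose(omega, omega.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric:\n{omega}")
    if not np.allclose(np.diag(omega), 1.0, atol=1e-10):
        raise ValueError(f"{name} must have unit diagonal:\n{omega}")
    eigvals = np.linalg.eigvalsh(omega)
    if eigvals.min() < -1e-10:
        raise ValueError(
            f"{name} is not positive semi-definite (min eigenvalue "
            f"{eigvals.min():.3g}):\n{omega}"
        )
    return omega


@dataclass
class TraitSimConfig:
    """Generative parameters for a yearly trait panel.

    Parameters mirror the variance-component decomposition of the analysis
    model: for trait ``k``, individual ``i``, year ``t`` the latent value is

        l = mu_k + a_ik + y_kt + e_ikt

    with ``a_i.`` drawn jointly across traits from the among-individual
    correlation matrix ``Omega_I`` scaled by ``sqrt(V_I)``, and ``y``, ``e``
    independent Gaussians with variances ``V_year``, ``V_R``.  Gaussian
    traits observe ``l`` directly; ``poisson_log`` traits observe a Poisson
    draw with rate ``exp(l)``.
    """

    n_individuals: int
    n_years: int
    trait_names: Sequence[str]
    distributions: Mapping[str, str]
    mu: Mapping[str, float]
    V_I: Mapping[str, float]
    V_year: Mapping[str, float]
    V_R: Mapping[str, float]
    Omega_I: np.ndarray | None = None
    seed: int = 0
    obs_per_individual_year: int = 1
    unbalanced: bool = False
    presence_prob: float = 0.75  # per-year inclusion prob when unbalanced

    def __post_init__(self) -> None:
        k = len(self.trait_names)
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")
        if self.Omega_I is None:
            self.Omega_I = np.eye(k)
        self.Omega_I = _check_correlation_matrix(np.asarray(self.Omega_I), "Omega_I")
        if self.Omega_I.shape[0] != k:
            raise ValueError("Omega_I dimension must match number of traits")
        for tr in self.trait_names:
            if self.distributions[tr] not in ("gaussian", "poisson_log"):
                raise ValueError(f"unknown distribution for {tr!r}")
            for d, label in ((self.V_I, "V_I"), (self.V_year, "V_year"), (self.V_R, "V_R")):
                if d[tr] < 0:
                    raise ValueError(f"{label}[{tr!r}] must be >= 0")


@dataclass
class TraitPanelTruth:
    """Ground-truth record of all latent effects behind a simulated panel."""

    config: TraitSimConfig
    individual_effects: pd.DataFrame  # index individual_id, one column per trait
    year_effects: pd.DataFrame  # index year, one column per trait
    residuals: pd.DataFrame  # long: individual_id, year, trait columns

    def to_json_dict(self) -> dict:
        cfg = self.config
        return {
            "n_individuals": cfg.n_individuals,
            "n_years": cfg.n_years,
            "trait_names": list(cfg.trait_names),
            "mu": dict(cfg.mu),
            "V_I": dict(cfg.V_I),
            "V_year": dict(cfg.V_year),
            "V_R": dict(cfg.V_R),
            "Omega_I": np.asarray(cfg.Omega_I).tolist(),
            "seed": cfg.seed,
            "individual_effects": self.individual_effects.reset_index().to_dict("list"),
            "year_effects": self.year_effects.reset_index().to_dict("list"),
        }


def simulate_trait_panel(cfg: TraitSimConfig) -> tuple[pd.DataFrame, TraitPanelTruth]:
    """Draw a yearly trait panel from the generative mixed model.

    Returns a long-format panel (one row per individual-year present in the
    design, one column per trait) and the :class:`TraitPanelTruth` holding
    every latent effect used.
    """
    rng = np.random.default_rng(cfg.seed)
    traits = list(cfg.trait_names)
    k = len(traits)
    n, t = cfg.n_individuals, cfg.n_years

    sd_i = np.sqrt([cfg.V_I[tr] for tr in traits])
    cov_a = np.outer(sd_i, sd_i) * cfg.Omega_I
    a = rng.multivariate_normal(np.zeros(k), cov_a, size=n, method="svd")
    y_eff = np.column_stack(
        [rng.normal(0.0, np.sqrt(cfg.V_year[tr]), size=t) for tr in traits]
    )

    ids = np.repeat(np.arange(n), t)
    years = np.tile(np.arange(t), n)
    if cfg.unbalanced and t > 1:
        # each individual keeps a random subset of years, at least one
        keep = rng.random(n * t) < cfg.presence_prob
        for i in range(n):
            sl = slice(i * t, (i + 1) * t)
            if not keep[sl].any():
                keep[i * t + rng.integers(t)] = True
        ids, years = ids[keep], years[keep]

    m = len(ids)
    resid = np.column_stack(
        [rng.normal(0.0, np.sqrt(cfg.V_R[tr]), size=m) for tr in traits]
    )
    latent = (
        np.array([cfg.mu[tr] for tr in traits])[None, :]
        + a[ids]
        + y_eff[years]
        + resid
    )
    obs = latent.copy()
    for j, tr in enumerate(traits):
        if cfg.distributions[tr] == "poisson_log":
            obs[:, j] = rng.poisson(np.exp(latent[:, j]))

    panel = pd.DataFrame({"individual_id": ids, "year": years})
    for j, tr in enumerate(traits):
        panel[tr] = obs[:, j]

    truth = TraitPanelTruth(
        config=cfg,
        individual_effects=pd.DataFrame(a, columns=traits).rename_axis("individual_id"),
        year_effects=pd.DataFrame(y_eff, columns=traits).rename_axis("year"),
        residuals=pd.concat(
            [panel[["individual_id", "year"]], pd.DataFrame(resid, columns=traits)],
            axis=1,
        ),
    )
    return panel, truth


def simulate_fitness(
    truth: TraitPanelTruth,
    rho_fit: float | Mapping[str, float],
    base_log_rate: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate one Poisson offspring count per individual.

    The log-rate is ``base_log_rate + b_i`` where ``(a_i, b_i)`` are jointly
    Gaussian with unit variances and the requested correlation(s); with a
    scalar ``rho_fit`` the correlation is to the first trait's standardized
    individual effect.  Unit variances match the fixed-to-1 convention used
    when fitting single-measure fitness traits.
    """
    cfg = truth.config
    traits = list(cfg.trait_names)
    if np.isscalar(rho_fit):
        rho = np.zeros(len(traits))
        rho[0] = float(rho_fit)  # type: ignore[arg-type]
    else:
        rho = np.array([rho_fit.get(tr, 0.0) for tr in traits])  # type: ignore[union-attr]
    if np.any(np.abs(rho) > 1):
        raise ValueError(f"|rho_fit| must be <= 1, got {rho}")

    omega = np.asarray(cfg.Omega_I)
    # b = w' z + noise, z the standardized individual effects; solve w so that
    # corr(b, z_k) = rho_k, then top up to unit variance with independent noise
    w = np.linalg.solve(omega, rho)
    explained = float(w @ omega @ w)
    if explained > 1 + 1e-9:
        raise ValueError(
            f"requested fitness correlations {rho} are jointly infeasible "
            f"under Omega_I (implied variance {explained:.3f} > 1)"
        )
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    a = truth.individual_effects[traits].to_numpy()
    sd_i = np.sqrt([max(cfg.V_I[tr], 1e-300) for tr in traits])
    z = a / sd_i[None, :]
    b = z @ w + rng.normal(0.0, np.sqrt(max(0.0, 1.0 - explained)), size=len(z))
    counts = rng.poisson(np.exp(base_log_rate + b))
    return pd.DataFrame(
        {
            "individual_id": truth.individual_effects.index.to_numpy(),
            "offspring": counts,
            "latent_fitness_effect": b,
        }
    )


@dataclass
class SightingSimConfig:
    """Survey design and movement parameters for sighting-level simulation.

    Individuals move around fixed home-range centres with bivariate-normal
    scatter of scale ``hr_sd``; in each half-day survey each individual is
    detected independently with probability ``detection_prob``.  A detected
    individual may be relocated next to a concurrently detected neighbour
    with probability ``sigmoid((g_focal + g_neighbour) / 2)`` where ``g`` is
    the latent gregariousness, producing dyadic proximity associations.
    """

    n_individuals: int
    n_surveys_per_year: int
    n_years: int = 1
    sex_ratio: float = 0.5
    hr_center: np.ndarray | None = None  # (n, 2) metres
    hr_sd: float = 10.0
    gregariousness: np.ndarray | float = 0.0
    association_radius: float = 1.85
    detection_prob: float = 0.8
    arena_size: float = 100.0
    behaviour_probs: tuple[float, float, float] = (0.75, 0.1, 0.15)  # rest/aggr/other
    seed: int = 0

    def __post_init__(self) -> None:
        if self.association_radius <= 0:
            raise ValueError("association_radius must be > 0")
        if self.hr_sd <= 0:
            raise ValueError("hr_sd must be > 0")
        if not 0 <= self.sex_ratio <= 1:
            raise ValueError("sex_ratio must be in [0, 1]")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def simulate_sightings(cfg: SightingSimConfig) -> pd.DataFrame:
    """Generate a sighting table conforming to the standard input schema.

    Columns: ``individual_id, sex, year, survey_id, x_m, y_m, behaviour``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_individuals
    n_f = int(round(cfg.sex_ratio * n))
    sexes = np.array(["F"] * n_f + ["M"] * (n - n_f))
    centers = cfg.hr_center
    if centers is None:
        centers = rng.uniform(0.0, cfg.arena_size, size=(n, 2))
    centers = np.asarray(centers, dtype=float)
    greg = np.broadcast_to(np.asarray(cfg.gregariousness, dtype=float), (n,)).copy()

    rows: list[tuple] = []
    behaviours = np.array(["rest", "aggressive", "other"])
    survey_counter = 0
    for year in range(cfg.n_years):
        for _ in range(cfg.n_surveys_per_year):
            survey_id = survey_counter
            survey_counter += 1
            detected = np.flatnonzero(rng.random(n) < cfg.detection_prob)
            if len(detected) == 0:
                continue
            pos = centers[detected] + rng.normal(
                0.0, cfg.hr_sd, size=(len(detected), 2)
            )
            if len(detected) > 1:
                # relocate gregarious individuals next to a random neighbour
                for idx in rng.permutation(len(detected)):
                    others = np.delete(np.arange(len(detected)), idx)
                    nb = others[rng.integers(len(others))]
                    p = _sigmoid(
                        np.array([(greg[detected[idx]] + greg[detected[nb]]) / 2.0])
                    )[0]
                    if rng.random() < p:
                        ang = rng.uniform(0, 2 * np.pi)
                        # strictly inside the closed radius
                        r = cfg.association_radius * 0.9 * np.sqrt(rng.random())
                        pos[idx] = pos[nb] + r * np.array([np.cos(ang), np.sin(ang)])
            beh = behaviours[
                rng.choice(3, size=len(detected), p=np.asarray(cfg.behaviour_probs))
            ]
            for j, ind in enumerate(detected):
                rows.append(
                    (
                        f"ind{ind:03d}",
                        sexes[ind],
                        year,
                        survey_id,
                        pos[j, 0],
                        pos[j, 1],
                        beh[j],
                    )
                )
    return pd.DataFrame(
        rows,
        columns=["individual_id", "sex", "year", "survey_id", "x_m", "y_m", "behaviour"],
    )
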