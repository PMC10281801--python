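"""End-to-end orchestration of the four analyses.

From a yearly-measures table the pipeline runs, per sex and per associate-sex
category (opposite-sex OS, same-sex SS):

* **repeatability models** — one multivariate idh model per sex x category
  over {tendency, degree, HWI, density}, yielding latent- and (for the
  Poisson degree) observed-scale repeatabilities;
* **within-category correlation models** — the same four traits under a
  corgh individual block (variances fixed to 1, free correlations);
* **OS-SS bivariate models** — per trait, the OS and SS versions under
  corgh, estimating cross-category among-individual correlations;
* **fitness models** — the four repeated traits of a category plus a
  single-measure Poisson offspring count with residual and individual
  variances fixed to 1, estimating behaviour-fitness correlations.

Gaussian-modelled traits (tendency, HWI, density) are centred and scaled to
unit variance over the modelled rows; count traits stay on their observed
scale.  Every filtering step logs rows in / rows out.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metrics as met
from . import posterior as post
from . import spatial as sp
from .model import ModelSpec, MultiTraitMixedModel, TraitSpec

__all__ = [
    "RunConfig",
    "compute_measures",
    "run_repeatability",
    "run_correlations",
    "run_fitness",
]

logger = logging.getLogger(__name__)

GAUSSIAN_TRAITS = ("tendency", "hwi", "density")
SOCIAL_TRAITS = ("tendency", "degree", "hwi", "density")


@dataclass
class RunConfig:
    """Thresholds, chain lengths and seeds for a full pipeline run."""

    association_radius: float = met.ASSOCIATION_RADIUS
    smoothing_h: float = 7.0
    cell_size: float = 1.0
    min_sightings_social: int = met.MIN_SIGHTINGS_SOCIAL
    min_sightings_home_range: int = sp.MIN_SIGHTINGS_HOME_RANGE
    iterations: int = 8_000
    burn_in: int = 1_500
    thin: int = 4
    seed: int = 1
    maturity_cutoff_year: int | None = None  # exclude late maturers from fitness
    fixed_effects: tuple[str, ...] = ("n_sightings",)
    output_dir: str | None = None

    def __post_init__(self) -> None:
        for name in (
            "association_radius", "smoothing_h", "cell_size",
            "min_sightings_social", "min_sightings_home_range",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "fixed_effects" in raw:
            raw["fixed_effects"] = tuple(raw["fixed_effects"])
        return cls(**raw)

    def manifest(self) -> dict:
        from . import __version__

        payload = {k: v for k, v in asdict(self).items()}
        digest = hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
        return {"config": payload, "config_hash": digest, "version": __version__}


# --------------------------------------------------------------- measures
def compute_measures(
    sightings: pd.DataFrame,
    config: RunConfig | None = None,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Sightings -> filtered yearly social measures table."""
    config = config or RunConfig()
    collapsed = met.collapse_to_surveys(sightings)
    hr_table, ranges = sp.home_range_table(
        collapsed,
        h=config.smoothing_h,
        cell_size=config.cell_size,
        min_sightings=config.min_sightings_home_range,
    )
    measures = met.yearly_measures(
        collapsed, ranges, hr_table, radius=config.association_radius
    )
    measures = met.filter_min_sightings(measures, config.min_sightings_social)
    if covariates is not None:
        measures = met.attach_covariates(measures, covariates)
    return measures


def _standardized(measures: pd.DataFrame, cls: str) -> pd.DataFrame:
    cols = [f"{t}_{cls}" for t in GAUSSIAN_TRAITS]
    return met.standardize(measures, cols)


def _fixed_effects(config: RunConfig, measures: pd.DataFrame) -> tuple[str, ...]:
    return tuple(c for c in (*config.fixed_effects, "age") if c in measures.columns)


# --------------------------------------------------------- repeatability
def run_repeatability(
    measures: pd.DataFrame, config: RunConfig | None = None
) -> dict:
    """Four multivariate idh models (sex x category) -> repeatability table.

    Returns the table (one row per trait x sex x category with latent and,
    for degree, observed-scale R), the per-model results objects and the
    between-sex difference tests on latent R.
    """
    config = config or RunConfig()
    rows, fits = [], {}
    r_draws: dict[tuple, np.ndarray] = {}
    for si, sex in enumerate(("F", "M")):
        for ci, cls in enumerate(("os", "ss")):
            sub = measures[measures["sex"] == sex].dropna(
                subset=[f"{t}_{cls}" for t in SOCIAL_TRAITS]
            )
            if sub["individual_id"].nunique() < 2 or len(sub) == 0:
                raise ValueError(f"no usable rows for sex={sex}, category={cls}")
            sub = _standardized(sub.copy(), cls)
            fe = _fixed_effects(config, sub)
            traits = [
                TraitSpec(
                    name=f"{t}_{cls}",
                    distribution="poisson_log" if t == "degree" else "gaussian",
                    fixed_effects=fe,
                )
                for t in SOCIAL_TRAITS
            ]
            model = MultiTraitMixedModel(sub, ModelSpec(traits=traits))
            res = model.fit(
                iterations=config.iterations,
                burn_in=config.burn_in,
                thin=config.thin,
                seed=config.seed + 10 * si + ci,
                store_individual_effects=False,
            )
            fits[(sex, cls)] = res
            for t in SOCIAL_TRAITS:
                est = res.repeatability(f"{t}_{cls}", sex=sex)
                k = res.trait_names.index(f"{t}_{cls}")
                r_draws[(sex, cls, t)] = post.repeatability_latent(
                    res.v_i[:, k], res.v_r[:, k]
                )
                row = est.as_row() | {"category": cls, "converged": res.converged}
                rows.append(row)
    table = pd.DataFrame(rows)

    sex_tests = {}
    for cls in ("os", "ss"):
        for t in SOCIAL_TRAITS:
            d = post.sex_difference(
                r_draws[("F", cls, t)], r_draws[("M", cls, t)], seed=config.seed
            )
            sex_tests[f"{t}_{cls}"] = d
    return {"table": table, "fits": fits, "sex_differences": sex_tests}


# ---------------------------------------------------------- correlations
def run_correlations(
    measures: pd.DataFrame, config: RunConfig | None = None
) -> dict:
    """Within-category corgh models and OS-SS bivariate models.

    Returns Table-2-style (six pairwise within-category correlations per sex
    x category) and Table-3-style (per-trait OS-SS correlation per sex)
    DataFrames plus the fitted results.
    """
    config = config or RunConfig()
    within_rows, fits = [], {}
    for si, sex in enumerate(("F", "M")):
        for ci, cls in enumerate(("os", "ss")):
            sub = measures[measures["sex"] == sex].dropna(
                subset=[f"{t}_{cls}" for t in SOCIAL_TRAITS]
            )
            sub = _standardized(sub.copy(), cls)
            fe = _fixed_effects(config, sub)
            traits = [
                TraitSpec(
                    name=f"{t}_{cls}",
                    distribution="poisson_log" if t == "degree" else "gaussian",
                    fixed_effects=fe,
                )
                for t in SOCIAL_TRAITS
            ]
            model = MultiTraitMixedModel(
                sub, ModelSpec(traits=traits, individual_structure="corgh")
            )
            res = model.fit(
                iterations=config.iterations,
                burn_in=config.burn_in,
                thin=config.thin,
                seed=config.seed + 100 + 10 * si + ci,
                store_individual_effects=False,
            )
            fits[(sex, cls)] = res
            for t1, t2 in res.corr_pairs:
                s = res.correlation(t1, t2)
                within_rows.append(
                    {
                        "trait_1": t1, "trait_2": t2, "sex": sex, "category": cls,
                        "correlation": s["mean"], "hpd_lo": s["lo"], "hpd_hi": s["hi"],
                        "significant": s["significant"], "converged": res.converged,
                    }
                )
    within = pd.DataFrame(within_rows)

    cross_rows = []
    for si, sex in enumerate(("F", "M")):
        for ti, t in enumerate(SOCIAL_TRAITS):
            sub = measures[measures["sex"] == sex].dropna(
                subset=[f"{t}_os", f"{t}_ss"]
            )
            if t in GAUSSIAN_TRAITS:
                sub = met.standardize(sub.copy(), [f"{t}_os", f"{t}_ss"])
            fe = _fixed_effects(config, sub)
            dist = "poisson_log" if t == "degree" else "gaussian"
            traits = [
                TraitSpec(name=f"{t}_os", distribution=dist, fixed_effects=fe),
                TraitSpec(name=f"{t}_ss", distribution=dist, fixed_effects=fe),
            ]
            model = MultiTraitMixedModel(
                sub, ModelSpec(traits=traits, individual_structure="corgh")
            )
            res = model.fit(
                iterations=config.iterations,
                burn_in=config.burn_in,
                thin=config.thin,
                seed=config.seed + 200 + 10 * si + ti,
                store_individual_effects=False,
            )
            fits[(sex, f"{t}_os_ss")] = res
            s = res.correlation(f"{t}_os", f"{t}_ss")
            cross_rows.append(
                {
                    "trait": t, "sex": sex,
                    "correlation": s["mean"], "hpd_lo": s["lo"], "hpd_hi": s["hi"],
                    "significant": s["significant"], "converged": res.converged,
                }
            )
    cross = pd.DataFrame(cross_rows)
    return {"within": within, "cross": cross, "fits": fits}


# --------------------------------------------------------------- fitness
def run_fitness(
    measures: pd.DataFrame, config: RunConfig | None = None
) -> dict:
    """Behaviour-fitness correlation models (two per sex: OS and SS traits).

    The offspring count enters as a single-measure Poisson trait with
    residual and individual-level variances fixed to 1; its fixed effects
    are social dominance and heterozygosity (when present).  Individuals
    maturing after ``config.maturity_cutoff_year`` are excluded.
    """
    config = config or RunConfig()
    if "offspring" not in measures.columns:
        raise ValueError("measures table lacks an 'offspring' column")
    data = measures
    if config.maturity_cutoff_year is not None and "maturity_year" in data:
        before = len(data)
        data = data[data["maturity_year"] < config.maturity_cutoff_year]
        logger.info(
            "maturity cutoff (<%d): %d rows in, %d rows out",
            config.maturity_cutoff_year, before, len(data),
        )
    rows, fits = [], {}
    for si, sex in enumerate(("F", "M")):
        for ci, cls in enumerate(("os", "ss")):
            sub = data[data["sex"] == sex].dropna(
                subset=[f"{t}_{cls}" for t in SOCIAL_TRAITS]
            )
            sub = _standardized(sub.copy(), cls)
            if sub["offspring"].notna().any() and (sub["offspring"].fillna(0) == 0).all():
                logger.warning("all-zero offspring for sex=%s: model degenerate", sex)
                rows.append(
                    {"trait": None, "sex": sex, "category": cls, "degenerate": True}
                )
                continue
            # one fitness row per individual, social traits missing on it
            fit_cov = ["dominance"] + (
                ["heterozygosity"] if "heterozygosity" in sub else []
            )
            per_ind = (
                sub.groupby("individual_id")
                .agg({"offspring": "first", **{c: "mean" for c in fit_cov}})
                .reset_index()
            )
            per_ind = per_ind[per_ind["offspring"].notna()]
            social = sub.copy()
            social["offspring"] = np.nan
            stacked = pd.concat([social, per_ind], ignore_index=True)

            fe = _fixed_effects(config, sub)
            traits = [
                TraitSpec(
                    name=f"{t}_{cls}",
                    distribution="poisson_log" if t == "degree" else "gaussian",
                    fixed_effects=fe,
                )
                for t in SOCIAL_TRAITS
            ] + [
                TraitSpec(
                    name="offspring",
                    distribution="poisson_log",
                    repeated=False,
                    residual_variance_fixed=1.0,
                    individual_variance_fixed=1.0,
                    fixed_effects=tuple(c for c in fit_cov if c in stacked),
                )
            ]
            model = MultiTraitMixedModel(
                stacked, ModelSpec(traits=traits, individual_structure="corgh")
            )
            res = model.fit(
                iterations=config.iterations,
                burn_in=config.burn_in,
                thin=config.thin,
                seed=config.seed + 300 + 10 * si + ci,
                store_individual_effects=False,
            )
            fits[(sex, cls)] = res
            for t in SOCIAL_TRAITS:
                s = res.correlation(f"{t}_{cls}", "offspring")
                rows.append(
                    {
                        "trait": t, "sex": sex, "category": cls,
                        "correlation": s["mean"], "hpd_lo": s["lo"], "hpd_hi": s["hi"],
                        "significant": s["significant"], "converged": res.converged,
                        "degenerate": False,
                    }
                )
    return {"table": pd.DataFrame(rows), "fits": fits}
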