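"""Posterior results container for fitted multivariate mixed models."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from . import posterior as post
from .diagnostics import convergence_gates

if TYPE_CHECKING:  # pragma: no cover
    from .model import ModelSpec, MultiTraitMixedModel

__all__ = ["MixedModelResults"]


@dataclass
class MixedModelResults:
    """Thinned posterior draws and their summaries.

    Attributes hold one row per retained draw: per-trait variance
    components (``v_i``, ``v_year``, ``v_r``), fixed-effect coefficient
    DataFrames per trait, among-individual correlation draws for corgh
    blocks, and (optionally) the per-individual effect draws used for
    visualization.
    """

    model: "MultiTraitMixedModel"
    spec: "ModelSpec"
    individuals: np.ndarray
    v_i: np.ndarray  # (draws, K)
    v_year: np.ndarray
    v_r: np.ndarray
    betas: dict[str, pd.DataFrame]
    correlations: np.ndarray | None
    corr_pairs: list[tuple[str, str]]
    individual_draws: np.ndarray | None
    seed: int
    _summary: pd.DataFrame | None = field(default=None, repr=False)

    # ------------------------------------------------------------ parameters
    @property
    def trait_names(self) -> list[str]:
        return self.spec.trait_names

    def parameter_draws(self) -> dict[str, np.ndarray]:
        """All monitored scalar parameter chains, keyed by name."""
        out: dict[str, np.ndarray] = {}
        for k, name in enumerate(self.trait_names):
            tr = self.spec.traits[k]
            if tr.individual_variance_fixed is None:
                out[f"V_I[{name}]"] = self.v_i[:, k]
            if self.v_year[:, k].any():
                out[f"V_year[{name}]"] = self.v_year[:, k]
            if tr.residual_variance_fixed is None:
                out[f"V_R[{name}]"] = self.v_r[:, k]
            for col in self.betas[name].columns:
                out[f"beta[{name}.{col}]"] = self.betas[name][col].to_numpy()
        if self.correlations is not None:
            for e, (t1, t2) in enumerate(self.corr_pairs):
                out[f"corr[{t1},{t2}]"] = self.correlations[:, e]
        return out

    # -------------------------------------------------------------- summaries
    def summary(self) -> pd.DataFrame:
        """Posterior mean, 95% HPD interval and convergence gates per parameter."""
        if self._summary is None:
            rows = []
            for name, draws in self.parameter_draws().items():
                s = post.summarize_draws(draws)
                g = convergence_gates(draws)
                rows.append(
                    {
                        "parameter": name,
                        "mean": s["mean"],
                        "hpd_lo": s["lo"],
                        "hpd_hi": s["hi"],
                        "significant": s["significant"],
                        "ess": g["ess"],
                        "autocorr_lag1": g["autocorr_lag1"],
                        "converged": g["converged"],
                    }
                )
            self._summary = pd.DataFrame(rows).set_index("parameter")
        return self._summary

    @property
    def converged(self) -> bool:
        """All monitored variance/correlation parameters pass the gates."""
        s = self.summary()
        watch = s.index.str.startswith(("V_", "corr["))
        if not watch.any():
            return True
        return bool(s.loc[watch, "converged"].all())

    # ---------------------------------------------------------- repeatability
    def _trait_index(self, trait: str) -> int:
        try:
            return self.trait_names.index(trait)
        except ValueError:
            raise KeyError(f"unknown trait {trait!r}") from None

    def repeatability(self, trait: str, sex: str = "") -> post.RepeatabilityEstimate:
        """Latent (and, for Poisson traits, observed-scale) repeatability.

        The year variance is conditioned out of the denominator (adjusted
        repeatability); the observed-scale transformation uses the trait's
        intercept as the latent mean.
        """
        k = self._trait_index(trait)
        r_lat = post.repeatability_latent(self.v_i[:, k], self.v_r[:, k])
        est = post.RepeatabilityEstimate(
            trait=trait,
            sex=sex,
            latent_mean=float(r_lat.mean()),
            latent_interval=post.hpd_interval(r_lat),
            v_i_mean=float(self.v_i[:, k].mean()),
            v_r_mean=float(self.v_r[:, k].mean()),
        )
        if self.spec.traits[k].distribution == "poisson_log":
            mu = self.betas[trait]["intercept"].to_numpy()
            r_obs = post.repeatability_observed_poisson(
                mu, self.v_i[:, k], self.v_r[:, k]
            )
            est.data_mean = float(r_obs.mean())
            est.data_interval = post.hpd_interval(r_obs)
        return est

    def correlation(self, trait1: str, trait2: str) -> dict:
        """Posterior summary of an among-individual correlation (corgh)."""
        if self.correlations is None:
            raise ValueError("model was not fitted with a corgh individual block")
        for e, (a, b) in enumerate(self.corr_pairs):
            if {a, b} == {trait1, trait2}:
                return post.summarize_draws(self.correlations[:, e])
        raise KeyError(f"no correlation for pair ({trait1!r}, {trait2!r})")

    def correlation_draws(self, trait1: str, trait2: str) -> np.ndarray:
        for e, (a, b) in enumerate(self.corr_pairs):
            if {a, b} == {trait1, trait2}:
                return self.correlations[:, e]
        raise KeyError(f"no correlation for pair ({trait1!r}, {trait2!r})")

    # ----------------------------------------------------- individual effects
    def individual_effects(self, trait: str) -> pd.DataFrame:
        """Marginal posterior summaries of individual effects (BLUP analogues).

        Intended for visualization only; downstream inference should use the
        full posterior, never these point summaries, because their
        uncertainty must not be discarded.
        """
        if self.individual_draws is None:
            raise ValueError("individual effects were not stored")
        k = self._trait_index(trait)
        draws = self.individual_draws[:, :, k]
        lohi = np.array([post.hpd_interval(draws[:, i]) for i in range(draws.shape[1])])
        return pd.DataFrame(
            {
                "individual_id": self.individuals,
                "mean": draws.mean(axis=0),
                "sd": draws.std(axis=0, ddof=1),
                "hpd_lo": lohi[:, 0],
                "hpd_hi": lohi[:, 1],
            }
        )

    # ------------------------------------------------------------ persistence
    def chains_frame(self) -> pd.DataFrame:
        """All monitored chains as one DataFrame (one row per retained draw)."""
        return pd.DataFrame(self.parameter_draws())

    def save(self, directory: str | Path, stem: str = "model") -> None:
        """Persist chains as CSV and the summary as JSON."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.chains_frame().to_csv(directory / f"{stem}_chains.csv", index=False)
        summ = self.summary().reset_index().to_dict("records")
        payload = {"seed": self.seed, "converged": self.converged, "parameters": summ}
        (directory / f"{stem}_summary.json").write_text(json.dumps(payload, indent=1))

    # ---------------------------------------------------------------- display
    def plot_individual_effects(self, trait: str, ax=None):
        """Caterpillar plot of individual-effect posteriors for one trait."""
        import matplotlib.pyplot as plt

        eff = self.individual_effects(trait).sort_values("mean").reset_index(drop=True)
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        x = np.arange(len(eff))
        ax.errorbar(
            x, eff["mean"],
            yerr=[eff["mean"] - eff["hpd_lo"], eff["hpd_hi"] - eff["mean"]],
            fmt=".", ms=3, lw=0.5, alpha=0.7,
        )
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.set_xlabel("individual (ranked)")
        ax.set_ylabel(f"posterior individual effect: {trait}")
        return ax
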