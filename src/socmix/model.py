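"""Bayesian multivariate mixed models for repeated social traits.

The model, per trait ``k``, row ``r`` (an individual-year or, for
single-measure traits, an individual):

    l_kr = x_kr' beta_k + a_{i(r),k} + u_{t(r),k} + e_kr

Gaussian traits observe ``l`` directly (``e`` is the residual); Poisson
traits observe ``y ~ Poisson(exp(l))`` with ``e`` an observation-level
latent residual (log-normal overdispersion), so variance components are
defined on the latent scale.

Random structures:

* ``idh`` — heterogeneous per-trait variances, zero covariances (the
  repeatability models);
* ``corgh`` — variances fixed (to 1 by convention) with free correlations,
  used to estimate among-individual correlations directly, including
  correlations with a single-measure fitness trait whose residual and
  individual variances are both fixed to 1.

Variance priors are scaled-inverse-chi-square (the univariate marginal of
an inverse Wishart) with scale ``V`` and degree of belief ``nu``; the
defaults are the weakly informative ``V = 1, nu = 0.002`` for random
effects and ``nu = 0.02`` for residuals.  Fixed effects get flat-ish normal
priors.  The correlation block uses a uniform prior over valid correlation
matrices, sampled by element-wise adaptive Metropolis on ``atanh(r)``.

The sampler is a Gibbs sweep with conjugate updates for all Gaussian
conditionals, adaptive Metropolis for Poisson latents and correlations, and
an optional parameter-expansion (scale) move for unfixed variance blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .results import MixedModelResults

__all__ = ["TraitSpec", "ModelSpec", "MultiTraitMixedModel"]

logger = logging.getLogger(__name__)

_BETA_PRIOR_VAR = 1e8
_PX_PRIOR_VAR = 1e3


@dataclass
class TraitSpec:
    """Declaration of one response trait.

    Single-measure traits (``repeated=False``, e.g. lifetime offspring
    count) have no within-individual replication, so both their residual
    and individual-level variances must be fixed (conventionally to 1).
    """

    name: str
    distribution: str = "gaussian"  # gaussian | poisson_log
    repeated: bool = True
    fixed_effects: tuple[str, ...] = ()
    residual_variance_fixed: float | None = None
    individual_variance_fixed: float | None = None

    def __post_init__(self) -> None:
        if self.distribution not in ("gaussian", "poisson_log"):
            raise ValueError(f"unknown distribution {self.distribution!r}")
        if not self.repeated and (
            self.residual_variance_fixed is None
            or self.individual_variance_fixed is None
        ):
            raise ValueError(
                f"single-measure trait {self.name!r} must fix both residual "
                "and individual variances"
            )


@dataclass
class ModelSpec:
    """Declarative description of a multivariate mixed model."""

    traits: list[TraitSpec]
    individual_structure: str = "idh"  # idh | corgh
    year_structure: str = "idh"
    include_year: bool = True
    prior_V: float = 1.0
    prior_nu: float = 0.002
    prior_nu_residual: float = 0.02
    parameter_expansion: bool = False

    def __post_init__(self) -> None:
        if self.individual_structure not in ("idh", "corgh"):
            raise ValueError("individual_structure must be 'idh' or 'corgh'")
        if self.year_structure != "idh":
            raise ValueError("only idh year structure is supported")
        if self.individual_structure == "corgh":
            for tr in self.traits:
                if tr.individual_variance_fixed is None:
                    # corgh fixes variances (to 1) and estimates correlations
                    tr.individual_variance_fixed = 1.0

    @property
    def trait_names(self) -> list[str]:
        return [t.name for t in self.traits]


@dataclass
class _TraitDesign:
    y: np.ndarray  # observed response
    X: np.ndarray  # fixed-effect design (incl. intercept)
    ind_idx: np.ndarray  # codes into the global individual list
    year_idx: np.ndarray | None  # codes into this trait's year list, or None
    n_years: int
    colnames: list[str]


class MultiTraitMixedModel:
    """Multivariate mixed model fitted by MCMC.

    Parameters
    ----------
    data : long DataFrame with one row per individual-year (or per
        individual for single-measure traits), carrying ``individual_id``,
        ``year``, the trait columns and any fixed-effect covariates.
    spec : the model declaration.

    Rows missing a trait value are dropped from that trait's likelihood
    only (unbalanced multivariate layout); rows missing a covariate of a
    trait are rejected from that trait with a log entry.
    """

    def __init__(self, data: pd.DataFrame, spec: ModelSpec) -> None:
        self.spec = spec
        self.data = data.reset_index(drop=True)
        self._build_design()

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        traits: list[TraitSpec] | list[str],
        **spec_kwargs,
    ) -> "MultiTraitMixedModel":
        tr = [t if isinstance(t, TraitSpec) else TraitSpec(name=t) for t in traits]
        return cls(data, ModelSpec(traits=tr, **spec_kwargs))

    # ------------------------------------------------------------------ design
    def _build_design(self) -> None:
        spec, data = self.spec, self.data
        self.individuals = np.asarray(sorted(data["individual_id"].unique()))
        ind_codes = {v: i for i, v in enumerate(self.individuals)}
        self.n_ind = len(self.individuals)
        self.designs: list[_TraitDesign] = []
        for tr in spec.traits:
            sub = data[data[tr.name].notna()].copy()
            covs = list(tr.fixed_effects)
            if covs:
                complete = sub[covs].notna().all(axis=1)
                if (~complete).any():
                    logger.info(
                        "trait %s: %d rows rejected for missing covariates",
                        tr.name, int((~complete).sum()),
                    )
                sub = sub[complete]
            if sub["individual_id"].nunique() < 2:
                raise ValueError(f"trait {tr.name!r} has fewer than 2 individuals")
            if not tr.repeated:
                dup = sub.duplicated("individual_id")
                if dup.any():
                    raise ValueError(
                        f"single-measure trait {tr.name!r} has repeated rows"
                    )
            X = np.column_stack(
                [np.ones(len(sub))] + [sub[c].to_numpy(dtype=float) for c in covs]
            )
            use_year = spec.include_year and tr.repeated and "year" in sub
            if use_year:
                years = np.asarray(sorted(sub["year"].unique()))
                ycodes = {v: i for i, v in enumerate(years)}
                year_idx = sub["year"].map(ycodes).to_numpy()
                n_years = len(years)
            else:
                year_idx, n_years = None, 0
            self.designs.append(
                _TraitDesign(
                    y=sub[tr.name].to_numpy(dtype=float),
                    X=X,
                    ind_idx=sub["individual_id"].map(ind_codes).to_numpy(),
                    year_idx=year_idx,
                    n_years=n_years,
                    colnames=["intercept"] + covs,
                )
            )

    # --------------------------------------------------------------- sampling
    def fit(
        self,
        iterations: int = 30_000,
        burn_in: int = 3_000,
        thin: int = 15,
        seed: int = 0,
        store_individual_effects: bool = True,
        progress: bool = False,
    ) -> MixedModelResults:
        """Run the sampler and return posterior results.

        ``iterations`` counts post-burn-in sweeps; every ``thin``-th sweep is
        retained.  Step sizes for the Metropolis components adapt during
        burn-in only, so the retained chain is a fixed-kernel Markov chain.
        """
        rng = np.random.default_rng(seed)
        spec = self.spec
        K = len(spec.traits)
        N = self.n_ind
        corgh = spec.individual_structure == "corgh"

        # --- state initialisation
        ell = []  # working (latent) response per trait
        beta = []
        V_R = np.empty(K)
        V_I = np.empty(K)
        V_Y = np.empty(K)
        u = []
        for k, (tr, d) in enumerate(zip(spec.traits, self.designs)):
            if tr.distribution == "poisson_log":
                w = np.log(d.y + 0.5)
            else:
                w = d.y.copy()
            ell.append(w)
            beta.append(np.zeros(d.X.shape[1]))
            beta[k][0] = w.mean()
            v = max(w.var(), 1e-3)
            V_R[k] = tr.residual_variance_fixed if tr.residual_variance_fixed is not None else v / 2
            V_I[k] = tr.individual_variance_fixed if tr.individual_variance_fixed is not None else v / 2
            V_Y[k] = v / 10 if d.year_idx is not None else 0.0
            u.append(np.zeros(d.n_years))
        a = np.zeros((N, K))
        R = np.eye(K)
        v_fix = np.array(
            [
                tr.individual_variance_fixed if tr.individual_variance_fixed is not None else 1.0
                for tr in spec.traits
            ]
        )
        d_fix = np.sqrt(v_fix)

        resid_fixed = np.array([tr.residual_variance_fixed is not None for tr in spec.traits])
        ind_fixed = np.array([tr.individual_variance_fixed is not None for tr in spec.traits])
        pois = np.array([tr.distribution == "poisson_log" for tr in spec.traits])

        # Metropolis step sizes (adapted during burn-in)
        step_ell = np.full(K, 0.5)
        tri = np.triu_indices(K, 1)
        n_corr = len(tri[0])
        step_r = np.full(n_corr, 0.3)

        # counts per individual per trait, for effect updates
        n_ik = np.zeros((N, K))
        for k, d in enumerate(self.designs):
            np.add.at(n_ik[:, k], d.ind_idx, 1.0)

        total = burn_in + iterations
        n_store = iterations // thin
        store = {
            "V_I": np.empty((n_store, K)),
            "V_Y": np.empty((n_store, K)),
            "V_R": np.empty((n_store, K)),
            "beta": [np.empty((n_store, d.X.shape[1])) for d in self.designs],
            "corr": np.empty((n_store, n_corr)) if corgh else None,
            "a": np.empty((n_store, N, K)) if store_individual_effects else None,
        }
        XtX = [d.X.T @ d.X for d in self.designs]
        s_idx = 0
        acc_ell = np.zeros(K)
        acc_r = np.zeros(n_corr)
        adapt_count = 0

        for it in range(total):
            adapting = it < burn_in
            # ---- per-trait Gaussian-conditional updates
            for k, (tr, d) in enumerate(zip(spec.traits, self.designs)):
                w = ell[k]
                a_row = a[d.ind_idx, k]
                u_row = u[k][d.year_idx] if d.year_idx is not None else 0.0

                # fixed effects
                r_beta = w - a_row - u_row
                prec = XtX[k] / V_R[k] + np.eye(d.X.shape[1]) / _BETA_PRIOR_VAR
                rhs = d.X.T @ r_beta / V_R[k]
                L = np.linalg.cholesky(prec)
                mean = np.linalg.solve(prec, rhs)
                beta[k] = mean + np.linalg.solve(
                    L.T, rng.standard_normal(d.X.shape[1])
                )
                xb = d.X @ beta[k]

                # year effects
                if d.year_idx is not None:
                    r_year = w - xb - a_row
                    s = np.bincount(d.year_idx, weights=r_year, minlength=d.n_years)
                    n_t = np.bincount(d.year_idx, minlength=d.n_years)
                    prec_t = n_t / V_R[k] + 1.0 / max(V_Y[k], 1e-12)
                    mu_t = (s / V_R[k]) / prec_t
                    u[k] = mu_t + rng.standard_normal(d.n_years) / np.sqrt(prec_t)
                    u_row = u[k][d.year_idx]

                # individual effects under idh (corgh handled jointly below)
                if not corgh:
                    r_ind = w - xb - u_row
                    s = np.bincount(d.ind_idx, weights=r_ind, minlength=N)
                    prec_i = n_ik[:, k] / V_R[k] + 1.0 / max(V_I[k], 1e-12)
                    mu_i = (s / V_R[k]) / prec_i
                    a[:, k] = mu_i + rng.standard_normal(N) / np.sqrt(prec_i)

            # ---- joint individual-effect update under corgh
            if corgh:
                Rinv = np.linalg.inv(R)
                prior_prec = (Rinv / d_fix[:, None]) / d_fix[None, :]
                P = np.broadcast_to(prior_prec, (N, K, K)).copy()
                C = np.zeros((N, K))
                for k, d in enumerate(self.designs):
                    xb = d.X @ beta[k]
                    u_row = u[k][d.year_idx] if d.year_idx is not None else 0.0
                    r_ind = ell[k] - xb - u_row
                    np.add.at(C[:, k], d.ind_idx, r_ind / V_R[k])
                    P[:, k, k] += n_ik[:, k] / V_R[k]
                Lb = np.linalg.cholesky(P)
                mean = np.linalg.solve(P, C[:, :, None])[:, :, 0]
                z = rng.standard_normal((N, K, 1))
                a = mean + np.linalg.solve(np.transpose(Lb, (0, 2, 1)), z)[:, :, 0]

                # correlation matrix: element-wise Metropolis on atanh(r)
                Z = a / d_fix[None, :]
                S = Z.T @ Z
                sign, logdet = np.linalg.slogdet(R)
                ll_cur = -0.5 * N * logdet - 0.5 * np.trace(np.linalg.solve(R, S))
                for e in range(n_corr):
                    i, j = tri[0][e], tri[1][e]
                    r_old = R[i, j]
                    z_new = np.arctanh(r_old) + step_r[e] * rng.standard_normal()
                    r_new = np.tanh(z_new)
                    R_new = R.copy()
                    R_new[i, j] = R_new[j, i] = r_new
                    try:
                        np.linalg.cholesky(R_new)
                    except np.linalg.LinAlgError:
                        continue
                    sign, logdet_new = np.linalg.slogdet(R_new)
                    ll_new = -0.5 * N * logdet_new - 0.5 * np.trace(
                        np.linalg.solve(R_new, S)
                    )
                    # tanh jacobian keeps the prior uniform on r
                    log_acc = (
                        ll_new + np.log1p(-r_new**2) - ll_cur - np.log1p(-r_old**2)
                    )
                    if np.log(rng.random()) < log_acc:
                        R = R_new
                        ll_cur = ll_new
                        acc_r[e] += 1

            # ---- variance updates
            nu, V0 = spec.prior_nu, spec.prior_V
            for k, (tr, d) in enumerate(zip(spec.traits, self.designs)):
                if not corgh and not ind_fixed[k]:
                    ss = float(a[:, k] @ a[:, k])
                    V_I[k] = (nu * V0 + ss) / rng.chisquare(nu + N)
                if d.year_idx is not None:
                    ss = float(u[k] @ u[k])
                    V_Y[k] = (nu * V0 + ss) / rng.chisquare(nu + d.n_years)
                if not resid_fixed[k]:
                    xb = d.X @ beta[k]
                    u_row = u[k][d.year_idx] if d.year_idx is not None else 0.0
                    e_res = ell[k] - xb - a[d.ind_idx, k] - u_row
                    ss = float(e_res @ e_res)
                    nu_r = spec.prior_nu_residual
                    V_R[k] = (nu_r * V0 + ss) / rng.chisquare(nu_r + len(e_res))

            # ---- optional parameter-expansion scale move (idh blocks)
            if spec.parameter_expansion and not corgh:
                for k, (tr, d) in enumerate(zip(spec.traits, self.designs)):
                    if ind_fixed[k]:
                        continue
                    xb = d.X @ beta[k]
                    u_row = u[k][d.year_idx] if d.year_idx is not None else 0.0
                    r_px = ell[k] - xb - u_row
                    a_row = a[d.ind_idx, k]
                    prec_c = float(a_row @ a_row) / V_R[k] + 1.0 / _PX_PRIOR_VAR
                    mu_c = (float(a_row @ r_px) / V_R[k]) / prec_c
                    c = mu_c + rng.standard_normal() / np.sqrt(prec_c)
                    a[:, k] *= c
                    ss = float(a[:, k] @ a[:, k])
                    V_I[k] = (nu * V0 + ss) / rng.chisquare(nu + N)

            # ---- Poisson latent updates
            for k, (tr, d) in enumerate(zip(spec.traits, self.designs)):
                if not pois[k]:
                    continue
                xb = d.X @ beta[k]
                u_row = u[k][d.year_idx] if d.year_idx is not None else 0.0
                m = xb + a[d.ind_idx, k] + u_row
                cur = ell[k]
                prop = cur + step_ell[k] * rng.standard_normal(len(cur))
                logr = (
                    d.y * (prop - cur)
                    - (np.exp(prop) - np.exp(cur))
                    - ((prop - m) ** 2 - (cur - m) ** 2) / (2.0 * V_R[k])
                )
                acc = np.log(rng.random(len(cur))) < logr
                cur[acc] = prop[acc]
                acc_ell[k] += acc.mean()

            # ---- adaptation during burn-in
            if adapting:
                adapt_count += 1
                if adapt_count % 50 == 0:
                    for k in range(K):
                        if pois[k]:
                            rate = acc_ell[k] / 50.0
                            step_ell[k] *= np.exp(0.5 * (rate - 0.44))
                    acc_ell[:] = 0.0
                    if corgh:
                        rate_r = acc_r / 50.0
                        step_r *= np.exp(0.5 * (rate_r - 0.44))
                        np.clip(step_r, 1e-3, 5.0, out=step_r)
                        acc_r[:] = 0.0

            # ---- storage
            if not adapting and (it - burn_in) % thin == thin - 1 and s_idx < n_store:
                store["V_I"][s_idx] = V_I if not corgh else v_fix
                store["V_Y"][s_idx] = V_Y
                store["V_R"][s_idx] = V_R
                for k in range(K):
                    store["beta"][k][s_idx] = beta[k]
                if corgh:
                    store["corr"][s_idx] = R[tri]
                if store["a"] is not None:
                    store["a"][s_idx] = a
                s_idx += 1

        return MixedModelResults(
            model=self,
            spec=spec,
            individuals=self.individuals,
            v_i=store["V_I"][:s_idx],
            v_year=store["V_Y"][:s_idx],
            v_r=store["V_R"][:s_idx],
            betas={
                spec.traits[k].name: pd.DataFrame(
                    store["beta"][k][:s_idx], columns=self.designs[k].colnames
                )
                for k in range(K)
            },
            correlations=store["corr"][:s_idx] if corgh else None,
            corr_pairs=[
                (spec.traits[i].name, spec.traits[j].name)
                for i, j in zip(*tri)
            ]
            if corgh
            else [],
            individual_draws=store["a"][:s_idx] if store["a"] is not None else None,
            seed=seed,
        )
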