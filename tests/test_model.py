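"""Sampler correctness: variance components, correlations, effects."""

import numpy as np
import pandas as pd
import pytest

from socmix.model import ModelSpec, MultiTraitMixedModel, TraitSpec
from socmix.simulate import TraitSimConfig, simulate_trait_panel

from _oracles import anova_repeatability


def _fit(panel, traits, iterations=6000, burn_in=1000, thin=3, seed=7, **spec_kw):
    model = MultiTraitMixedModel(panel, ModelSpec(traits=traits, **spec_kw))
    return model.fit(
        iterations=iterations, burn_in=burn_in, thin=thin, seed=seed,
        store_individual_effects=False,
    )


class TestGaussianRepeatability:
    def test_posterior_matches_anova_oracle(self, gaussian_panel):
        """Posterior mean R agrees with the one-way ANOVA intraclass
        correlation on a balanced design, and recovers the generating value."""
        panel, _ = gaussian_panel
        res = _fit(panel, [TraitSpec("t1")])
        est = res.repeatability("t1")
        oracle = anova_repeatability(panel, "t1")
        assert est.latent_mean == pytest.approx(oracle, abs=0.05)
        assert est.latent_mean == pytest.approx(0.4, abs=0.07)
        lo, hi = est.latent_interval
        assert lo < 0.4 < hi

    def test_no_signal_shrinks_to_zero(self):
        cfg = TraitSimConfig(
            n_individuals=200, n_years=4, trait_names=["t1"],
            distributions={"t1": "gaussian"}, mu={"t1": 0.0},
            V_I={"t1": 0.0}, V_year={"t1": 0.0}, V_R={"t1": 1.0}, seed=77,
        )
        panel, _ = simulate_trait_panel(cfg)
        res = _fit(panel, [TraitSpec("t1")])
        assert res.repeatability("t1").latent_mean < 0.1

    def test_parameter_expansion_leaves_estimates_unchanged(self, gaussian_panel):
        """Parameter-expanded refits must agree on posterior mean variances."""
        panel, _ = gaussian_panel
        res0 = _fit(panel, [TraitSpec("t1")], seed=11)
        res1 = _fit(panel, [TraitSpec("t1")], seed=12, parameter_expansion=True)
        assert abs(res0.v_i.mean() - res1.v_i.mean()) < 0.05
        assert abs(res0.v_r.mean() - res1.v_r.mean()) < 0.05

    def test_same_seed_reproducible(self, gaussian_panel):
        panel, _ = gaussian_panel
        r1 = _fit(panel, [TraitSpec("t1")], iterations=600, burn_in=200, seed=5)
        r2 = _fit(panel, [TraitSpec("t1")], iterations=600, burn_in=200, seed=5)
        assert np.array_equal(r1.v_i, r2.v_i)
        assert np.array_equal(r1.v_r, r2.v_r)


@pytest.fixture(scope="module")
def corr_panel():
    omega = np.array([[1.0, 0.5], [0.5, 1.0]])
    cfg = TraitSimConfig(
        n_individuals=200, n_years=4, trait_names=["t1", "t2"],
        distributions={"t1": "gaussian", "t2": "gaussian"},
        mu={"t1": 0.0, "t2": 0.0},
        V_I={"t1": 1.0, "t2": 1.0}, V_year={"t1": 0.05, "t2": 0.05},
        V_R={"t1": 1.0, "t2": 1.0}, Omega_I=omega, seed=31,
    )
    return simulate_trait_panel(cfg)


class TestCorgh:
    def test_recovers_among_individual_correlation(self, corr_panel):
        panel, truth = corr_panel
        res = _fit(
            panel, [TraitSpec("t1"), TraitSpec("t2")],
            iterations=8000, burn_in=1500, thin=4, individual_structure="corgh",
        )
        s = res.correlation("t1", "t2")
        a = truth.individual_effects
        realized = np.corrcoef(a["t1"], a["t2"])[0, 1]
        assert s["mean"] == pytest.approx(realized, abs=0.10)
        assert s["lo"] < realized < s["hi"]

    def test_corgh_fixes_variances(self, corr_panel):
        panel, _ = corr_panel
        res = _fit(
            panel, [TraitSpec("t1"), TraitSpec("t2")],
            iterations=400, burn_in=100, individual_structure="corgh",
        )
        assert np.all(res.v_i == 1.0)
        # only correlations and betas and residuals are monitored for the block
        assert not any(p.startswith("V_I") for p in res.parameter_draws())

    def test_correlation_draws_in_range(self, corr_panel):
        panel, _ = corr_panel
        res = _fit(
            panel, [TraitSpec("t1"), TraitSpec("t2")],
            iterations=1000, burn_in=200, individual_structure="corgh",
        )
        r = res.correlation_draws("t1", "t2")
        assert np.all((-1 < r) & (r < 1))


class TestDesignValidation:
    def test_single_measure_must_fix_variances(self):
        with pytest.raises(ValueError, match="must fix"):
            TraitSpec("fitness", distribution="poisson_log", repeated=False)

    def test_fewer_than_two_individuals(self):
        df = pd.DataFrame({"individual_id": ["a"] * 4, "year": range(4), "t1": 1.0})
        with pytest.raises(ValueError, match="fewer than 2"):
            MultiTraitMixedModel(df, ModelSpec(traits=[TraitSpec("t1")]))

    def test_missing_covariate_rows_rejected(self, gaussian_panel):
        panel, _ = gaussian_panel
        panel = panel.copy()
        panel["cov"] = 1.0 * np.arange(len(panel)) % 3
        panel.loc[panel.index[:10], "cov"] = np.nan
        model = MultiTraitMixedModel(
            panel, ModelSpec(traits=[TraitSpec("t1", fixed_effects=("cov",))])
        )
        assert len(model.designs[0].y) == len(panel) - 10

    def test_duplicated_single_measure_rows_error(self):
        df = pd.DataFrame(
            {"individual_id": ["a", "a", "b"], "year": [0, 1, 0], "w": [1.0, 2.0, 3.0]}
        )
        spec = ModelSpec(
            traits=[
                TraitSpec(
                    "w", repeated=False,
                    residual_variance_fixed=1.0, individual_variance_fixed=1.0,
                )
            ]
        )
        with pytest.raises(ValueError, match="repeated rows"):
            MultiTraitMixedModel(df, spec)


class TestIndividualEffects:
    def test_strong_signal_rank_correlation(self):
        """Extracted effects track the true individual effects."""
        cfg = TraitSimConfig(
            n_individuals=80, n_years=6, trait_names=["t1"],
            distributions={"t1": "gaussian"}, mu={"t1": 0.0},
            V_I={"t1": 2.0}, V_year={"t1": 0.0}, V_R={"t1": 0.5}, seed=55,
        )
        panel, truth = simulate_trait_panel(cfg)
        model = MultiTraitMixedModel(panel, ModelSpec(traits=[TraitSpec("t1")]))
        res = model.fit(iterations=3000, burn_in=600, thin=3, seed=9)
        eff = res.individual_effects("t1")
        rho = pd.Series(eff["mean"].to_numpy()).corr(
            pd.Series(truth.individual_effects["t1"].to_numpy()), method="spearman"
        )
        assert rho > 0.8
        # intervals have nonzero width
        assert (eff["hpd_hi"] > eff["hpd_lo"]).all()

    def test_no_signal_shrinkage(self):
        cfg = TraitSimConfig(
            n_individuals=80, n_years=4, trait_names=["t1"],
            distributions={"t1": "gaussian"}, mu={"t1": 0.0},
            V_I={"t1": 0.0}, V_year={"t1": 0.0}, V_R={"t1": 1.0}, seed=56,
        )
        panel, _ = simulate_trait_panel(cfg)
        model = MultiTraitMixedModel(panel, ModelSpec(traits=[TraitSpec("t1")]))
        res = model.fit(iterations=2000, burn_in=500, thin=2, seed=10)
        eff = res.individual_effects("t1")
        dev = panel.groupby("individual_id")["t1"].mean() - panel["t1"].mean()
        assert eff["mean"].abs().max() < dev.abs().max()


class TestUnbalancedAndPoisson:
    def test_unbalanced_panel_fits(self):
        cfg = TraitSimConfig(
            n_individuals=100, n_years=4, trait_names=["t1"],
            distributions={"t1": "gaussian"}, mu={"t1": 0.0},
            V_I={"t1": 0.5}, V_year={"t1": 0.02}, V_R={"t1": 0.5},
            unbalanced=True, seed=57,
        )
        panel, _ = simulate_trait_panel(cfg)
        res = _fit(panel, [TraitSpec("t1")], iterations=2000, burn_in=400)
        r = res.repeatability("t1")
        assert 0.0 < r.latent_mean < 1.0

    def test_poisson_latent_and_data_scale(self):
        cfg = TraitSimConfig(
            n_individuals=150, n_years=4, trait_names=["deg"],
            distributions={"deg": "poisson_log"}, mu={"deg": 1.0},
            V_I={"deg": 0.3}, V_year={"deg": 0.02}, V_R={"deg": 0.3}, seed=58,
        )
        panel, _ = simulate_trait_panel(cfg)
        res = _fit(
            panel, [TraitSpec("deg", distribution="poisson_log")],
            iterations=8000, burn_in=1500, thin=4,
        )
        est = res.repeatability("deg")
        assert est.latent_mean == pytest.approx(0.5, abs=0.15)
        assert est.data_mean is not None
        assert est.data_mean < est.latent_mean  # Poisson noise adds variance
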