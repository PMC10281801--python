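# socmix

Proximity-based social metrics and Bayesian multivariate mixed models for
studying consistent among-individual differences in affiliative behaviour —
and their fitness consequences — in longitudinally monitored wild
populations.

## The problem

In gregarious species such as fission–fusion reptiles, individuals differ
consistently in how social they are. Quantifying that consistency requires
three layers of machinery:

1. **From sightings to social traits.** Repeated georeferenced sightings of
   identified individuals are turned into yearly, sex-partitioned social
   traits: *social tendency* (the proportion of an individual's in-core
   sightings with a conspecific within 1.85 m), *degree* (number of distinct
   associates), the mean *half-weight association index*

   HWI = x / (x + y_AB + ½ (y_A + y_B)),

   where x counts sampling periods with both members of a dyad seen and
   associated, y_A/y_B periods with only one seen and y_AB periods with both
   seen but apart, and *conspecific density* — the number of distinct
   opposite- or same-sex individuals sighted inside the focal's 50% kernel
   home range (Gaussian kernel, 7 m smoothing), divided by its area. Social
   metrics use individual-years with ≥ 30 sightings; home ranges require
   ≥ 25.

2. **Variance partitioning.** Yearly trait values y_ikt are modelled with
   multivariate generalized mixed models

   y_ikt = x′β_k + a_ik + u_kt + e_ikt,

   with individual (a) and year (u) random effects, Gaussian responses for
   tendency/HWI/density and a Poisson log-link for counts (degree,
   offspring), fitted by Gibbs / Metropolis-within-Gibbs sampling.
   Repeatability is the intraclass correlation R = V_I / (V_I + V_R); for
   Poisson traits it is additionally transformed from the latent to the
   observed count scale.

3. **Among-individual correlations and fitness.** Refitting with variances
   fixed to 1 and free correlations (a corgh structure) yields
   among-individual correlations between traits — the behavioural-syndrome
   structure — and, by adding a single-measure Poisson offspring count with
   residual and individual variances fixed to 1, correlations between
   sociality and reproductive success.

A synthetic-data generator produces both trait panels drawn directly from
this model (with known variance components, correlation matrices and
behaviour–fitness linkage) and sighting-level point clouds whose aggregation
through the full pipeline yields the social metrics, so every stage can be
validated against ground truth.

## Worked example

```python
import numpy as np
from socmix.simulate import TraitSimConfig, simulate_trait_panel
from socmix import MultiTraitMixedModel, ModelSpec, TraitSpec

cfg = TraitSimConfig(
    n_individuals=200, n_years=4,
    trait_names=["tendency", "degree"],
    distributions={"tendency": "gaussian", "degree": "poisson_log"},
    mu={"tendency": 0.0, "degree": 1.0},
    V_I={"tendency": 0.4, "degree": 0.3},
    V_year={"tendency": 0.05, "degree": 0.02},
    V_R={"tendency": 0.6, "degree": 0.3},
    Omega_I=np.array([[1.0, 0.5], [0.5, 1.0]]),
    seed=11,
)
panel, truth = simulate_trait_panel(cfg)

model = MultiTraitMixedModel(panel, ModelSpec(traits=[
    TraitSpec("tendency"),
    TraitSpec("degree", distribution="poisson_log"),
]))
res = model.fit(iterations=10_000, burn_in=2_000, thin=5, seed=1)
for t in ("tendency", "degree"):
    est = res.repeatability(t)
    print(f"{t}: latent R = {est.latent_mean:.2f} "
          f"[{est.latent_interval[0]:.2f}, {est.latent_interval[1]:.2f}]"
          + (f", data-scale R = {est.data_mean:.2f}" if est.data_mean else ""))
```

prints

```
tendency: latent R = 0.36 [0.28, 0.43]
degree: latent R = 0.50 [0.39, 0.61], data-scale R = 0.31
```

The tendency trait was generated with V_I = 0.4, V_R = 0.6 (true R = 0.4);
its posterior interval covers the truth. The Poisson degree trait's latent
repeatability (V_I = V_R = 0.3, true latent R = 0.5) exceeds its
observed-scale value because Poisson sampling noise only adds phenotypic
variance on the count scale. `res.summary()` reports posterior means, 95%
HPD intervals, effective sample sizes and the convergence gates
(ESS > 1000, lag-1 autocorrelation < 0.1) per parameter.

The pipeline is also scriptable from the shell:

```bash
socmix simulate --n-individuals 40 --n-surveys 80 --gregariousness 0.5 --out sightings.csv
socmix metrics sightings.csv --out run/
socmix fit-repeatability run/yearly_measures.csv --out run/
socmix report run/
```

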