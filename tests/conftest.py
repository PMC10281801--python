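"""Shared fixtures: a hand-built toy social network and small simulations."""

import numpy as np
import pandas as pd
import pytest

from socmix.spatial import CoreHomeRange, UtilizationGrid


def _open_core_range(individual_id: str, year: int = 0) -> CoreHomeRange:
    """A core home range covering the whole toy arena (all cells in-core)."""
    nx = ny = 240
    values = np.full((ny, nx), 1.0 / (nx * ny))
    grid = UtilizationGrid(origin_x=-20.0, origin_y=-20.0, cell_size=1.0, values=values)
    return CoreHomeRange(
        individual_id=individual_id,
        year=year,
        mask=np.ones((ny, nx), dtype=bool),
        grid=grid,
        area_m2=float(nx * ny),
        n_sightings=8,
    )


@pytest.fixture(scope="session")
def toy_network() -> dict:
    """Five individuals, eight surveys, fully hand-countable.

    Dyad A-B (opposite-sex): together and associated in surveys 0-3, only A
    in 4-5, only B in 6-7 -> x=4, yA=2, yB=2, yAB=0, HWI = 4/6 = 2/3.
    Dyad C-D (same-sex): C seen in all 8 surveys, D only in 0-1 where the
    pair is 1.5 m apart -> x=2, HWI from C = 2/(2+3) = 0.4.
    E never associates with anyone.
    """
    rows = []
    # A (F) and B (M)
    for s in range(4):
        rows.append(("A", "F", 0, s, 0.0, 0.0, "rest"))
        rows.append(("B", "M", 0, s, 1.0, 0.0, "rest"))
    for s in (4, 5):
        rows.append(("A", "F", 0, s, 0.0, 0.0, "aggressive"))
    for s in (6, 7):
        rows.append(("B", "M", 0, s, 40.0, 40.0, "rest"))
    # C (F) all surveys; D (F) joins for surveys 0-1 at 1.5 m
    for s in range(8):
        rows.append(("C", "F", 0, s, 100.0, 100.0, "rest"))
    for s in (0, 1):
        rows.append(("D", "F", 0, s, 101.5, 100.0, "rest"))
    # E (M), solitary
    for s in range(8):
        rows.append(("E", "M", 0, s, 200.0, 100.0, "other"))
    sightings = pd.DataFrame(
        rows,
        columns=["individual_id", "sex", "year", "survey_id", "x_m", "y_m", "behaviour"],
    )
    core_ranges = {(i, 0): _open_core_range(i) for i in "ABCDE"}
    return {"sightings": sightings, "core_ranges": core_ranges}


def make_measures_panel(
    n_individuals=40,
    n_years=3,
    rho_fit=0.0,
    fit_trait="tendency_ss",
    seed=100,
    omega=None,
):
    """A synthetic yearly-measures table with the eight social traits.

    Gaussian latents for tendency/HWI/density (OS and SS), Poisson counts
    for degree, plus sex, a varying sighting count, social dominance and an
    offspring count whose latent log-rate correlates with ``fit_trait``'s
    individual effect at ``rho_fit``.
    """
    from socmix.simulate import TraitSimConfig, simulate_fitness, simulate_trait_panel

    traits = [
        "tendency_os", "tendency_ss", "degree_os", "degree_ss",
        "hwi_os", "hwi_ss", "density_os", "density_ss",
    ]
    k = len(traits)
    if omega is None:
        omega = np.full((k, k), 0.2)
        np.fill_diagonal(omega, 1.0)
    dist = {t: "poisson_log" if t.startswith("degree") else "gaussian" for t in traits}
    cfg = TraitSimConfig(
        n_individuals=n_individuals,
        n_years=n_years,
        trait_names=traits,
        distributions=dist,
        mu={t: (1.0 if t.startswith("degree") else 0.0) for t in traits},
        V_I={t: 1.0 for t in traits},
        V_year={t: 0.05 for t in traits},
        V_R={t: 1.0 for t in traits},
        Omega_I=omega,
        seed=seed,
    )
    panel, truth = simulate_trait_panel(cfg)
    rng = np.random.default_rng(seed + 7)
    panel["individual_id"] = panel["individual_id"].map("ind{:03d}".format)
    sexes = {f"ind{i:03d}": ("F" if i < n_individuals // 2 else "M") for i in range(n_individuals)}
    panel["sex"] = panel["individual_id"].map(sexes)
    panel["n_sightings"] = rng.integers(30, 60, size=len(panel)).astype(float)
    panel["dominance"] = rng.uniform(0, 0.3, size=len(panel))
    rho = {fit_trait: rho_fit}
    fit = simulate_fitness(truth, rho_fit=rho, base_log_rate=0.0, seed=seed + 11)
    fit["individual_id"] = fit["individual_id"].map("ind{:03d}".format)
    panel = panel.merge(fit[["individual_id", "offspring"]], on="individual_id")
    return panel, truth


@pytest.fixture(scope="session")
def gaussian_panel():
    """200 individuals x 4 years, one Gaussian trait with true R = 0.4."""
    from socmix.simulate import TraitSimConfig, simulate_trait_panel

    cfg = TraitSimConfig(
        n_individuals=200,
        n_years=4,
        trait_names=["t1"],
        distributions={"t1": "gaussian"},
        mu={"t1": 0.0},
        V_I={"t1": 0.4},
        V_year={"t1": 0.05},
        V_R={"t1": 0.6},
        seed=1234,
    )
    return simulate_trait_panel(cfg)
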