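"""Proximity-based social metrics from longitudinal sighting records.

A *survey* is a half-day session; multiple fixes of one individual within a
survey collapse to a single presence at the first fix.  Two individuals are
*associated* in a survey when their fixes lie within the association radius
(1.85 m, closed boundary) and the focal's own fix falls inside its 50% core
home range — metrics are tied to each individual's core range, so dyadic
event sets may differ between the two members of a dyad.

Yearly, per individual and partitioned by associate sex (opposite-sex OS vs
same-sex SS relative to the focal), three traits are computed:

* **social tendency** — proportion of the focal's in-core sightings with at
  least one associate of the sex class;
* **degree** — number of distinct associates;
* **mean HWI** — average half-weight association index over the focal's
  dyads, ``HWI = x / (x + yAB + 0.5 (yA + yB))``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .spatial import CoreHomeRange

__all__ = [
    "ASSOCIATION_RADIUS",
    "MIN_SIGHTINGS_SOCIAL",
    "collapse_to_surveys",
    "detect_associations",
    "half_weight_index",
    "dyad_table",
    "social_dominance",
    "yearly_measures",
    "filter_min_sightings",
    "standardize",
    "attach_covariates",
]

logger = logging.getLogger(__name__)

#: association radius in metres (closed boundary: distance <= radius)
ASSOCIATION_RADIUS = 1.85
#: minimum sightings per individual-year for inclusion of social metrics
MIN_SIGHTINGS_SOCIAL = 30

SIGHTING_COLUMNS = ["individual_id", "sex", "year", "survey_id", "x_m", "y_m", "behaviour"]


def collapse_to_surveys(sightings: pd.DataFrame) -> pd.DataFrame:
    """One presence per individual per survey, keeping the first fix."""
    if not np.isfinite(sightings[["x_m", "y_m"]].to_numpy()).all():
        raise ValueError("sighting coordinates must be finite")
    return (
        sightings.groupby(["survey_id", "individual_id"], as_index=False, sort=True)
        .first()
        .reindex(columns=SIGHTING_COLUMNS)
    )


def detect_associations(
    survey: pd.DataFrame,
    core_ranges: dict[tuple[str, int], CoreHomeRange],
    radius: float = ASSOCIATION_RADIUS,
) -> pd.DataFrame:
    """Association events within one survey.

    For every ordered focal-other pair at Euclidean distance <= ``radius``,
    an event (focal, associate, survey) is recorded iff the focal's fix lies
    inside the focal's own core home range for that year.  Focals without a
    core range are skipped and logged.
    """
    if survey["survey_id"].nunique() > 1:
        raise ValueError("detect_associations expects sightings of a single survey")
    events: list[tuple] = []
    if len(survey) < 2:
        return pd.DataFrame(events, columns=["focal", "associate", "survey_id", "year"])
    pos = survey[["x_m", "y_m"]].to_numpy()
    ids = survey["individual_id"].to_numpy()
    years = survey["year"].to_numpy()
    survey_id = survey["survey_id"].iloc[0]

    in_core = np.zeros(len(survey), dtype=bool)
    for i in range(len(survey)):
        hr = core_ranges.get((ids[i], years[i]))
        if hr is None:
            logger.debug("no core range for %s year %s; focal events skipped", ids[i], years[i])
            continue
        in_core[i] = bool(hr.contains(pos[i : i + 1, 0], pos[i : i + 1, 1])[0])

    pairs = cKDTree(pos).query_pairs(r=radius, output_type="ndarray")
    for i, j in pairs:
        if in_core[i]:
            events.append((ids[i], ids[j], survey_id, years[i]))
        if in_core[j]:
            events.append((ids[j], ids[i], survey_id, years[j]))
    return pd.DataFrame(events, columns=["focal", "associate", "survey_id", "year"])


def half_weight_index(x: float, yA: float, yB: float, yAB: float) -> float:
    """Half-weight association index ``x / (x + yAB + 0.5 (yA + yB))``.

    ``x`` counts sampling periods with both individuals seen and associated,
    ``yA``/``yB`` periods with only one seen, ``yAB`` periods with both seen
    but not associated.  Returns NaN when all counts are zero.
    """
    if min(x, yA, yB, yAB) < 0:
        raise ValueError("dyad counts must be non-negative")
    denom = x + yAB + 0.5 * (yA + yB)
    if denom == 0:
        return float("nan")
    return x / denom


def dyad_table(
    collapsed: pd.DataFrame,
    events: pd.DataFrame,
) -> pd.DataFrame:
    """Focal-sided dyadic association counts and HWI per year.

    For each (focal, associate, year) with at least one association event,
    counts over the year's surveys: ``x`` both seen and associated, ``yAB``
    both seen not associated, ``yA`` only the focal seen, ``yB`` only the
    associate seen.  Association is the focal-sided event, so the table is
    directed: each focal's HWI uses its own event set.
    """
    # surveys each individual was seen in, per year
    seen = collapsed.groupby(["year", "individual_id"])["survey_id"].agg(set)
    rows = []
    if len(events):
        ev_sets = events.groupby(["year", "focal", "associate"])["survey_id"].agg(set)
        for (year, focal, assoc), ev in ev_sets.items():
            sA = seen[(year, focal)]
            sB = seen[(year, assoc)]
            both = sA & sB
            x = len(ev & both)
            yAB = len(both) - x
            yA = len(sA - sB)
            yB = len(sB - sA)
            rows.append(
                (focal, assoc, year, x, yA, yB, yAB, half_weight_index(x, yA, yB, yAB))
            )
    return pd.DataFrame(
        rows, columns=["focal_id", "associate_id", "year", "x", "yA", "yB", "yAB", "hwi"]
    )


def social_dominance(behaviours: pd.Series) -> float:
    """Proportion of sightings with an aggressive display."""
    if len(behaviours) == 0:
        return float("nan")
    return float((behaviours == "aggressive").mean())


def yearly_measures(
    sightings: pd.DataFrame,
    core_ranges: dict[tuple[str, int], CoreHomeRange],
    hr_table: pd.DataFrame,
    radius: float = ASSOCIATION_RADIUS,
) -> pd.DataFrame:
    """Per individual-year social traits, partitioned by associate sex.

    Produces one row per individual-year holding tendency, degree and mean
    HWI for opposite-sex and same-sex associates, conspecific densities from
    ``hr_table``, sighting counts and social dominance.  No sighting-count
    filter is applied here; see :func:`filter_min_sightings`.
    """
    collapsed = collapse_to_surveys(sightings)
    sex_of = collapsed.groupby("individual_id")["sex"].first()

    all_events = []
    for _, survey in collapsed.groupby("survey_id"):
        ev = detect_associations(survey, core_ranges, radius=radius)
        if len(ev):
            all_events.append(ev)
    events = (
        pd.concat(all_events, ignore_index=True)
        if all_events
        else pd.DataFrame(columns=["focal", "associate", "survey_id", "year"])
    )
    dyads = dyad_table(collapsed, events)
    if len(events):
        events = events.assign(
            associate_sex=events["associate"].map(sex_of).to_numpy(),
            focal_sex=events["focal"].map(sex_of).to_numpy(),
        )
        events["sex_class"] = np.where(
            events["associate_sex"] == events["focal_sex"], "ss", "os"
        )
    if len(dyads):
        dyads = dyads.assign(
            sex_class=np.where(
                dyads["associate_id"].map(sex_of).to_numpy()
                == dyads["focal_id"].map(sex_of).to_numpy(),
                "ss",
                "os",
            )
        )

    hr_idx = hr_table.set_index(["individual_id", "year"]) if len(hr_table) else None
    rows = []
    for (ind, year), grp in collapsed.groupby(["individual_id", "year"]):
        hr = core_ranges.get((ind, year))
        n_sight = len(grp)
        dom = social_dominance(grp["behaviour"])
        rec: dict = {
            "individual_id": ind,
            "sex": sex_of[ind],
            "year": year,
            "n_sightings": n_sight,
            "dominance": dom,
        }
        if hr is None:
            # no core range: social traits and densities undefined
            for c in (
                "tendency_os", "tendency_ss", "degree_os", "degree_ss",
                "hwi_os", "hwi_ss", "density_os", "density_ss",
            ):
                rec[c] = np.nan
            rows.append(rec)
            continue

        in_core = hr.contains(grp["x_m"].to_numpy(), grp["y_m"].to_numpy())
        core_surveys = set(grp.loc[in_core, "survey_id"])
        my_ev = events[(events["focal"] == ind) & (events["year"] == year)] if len(events) else events
        my_dy = dyads[(dyads["focal_id"] == ind) & (dyads["year"] == year)] if len(dyads) else dyads
        for cls in ("os", "ss"):
            ev_c = my_ev[my_ev["sex_class"] == cls] if len(my_ev) else my_ev
            n_core = len(core_surveys)
            if n_core == 0:
                rec[f"tendency_{cls}"] = np.nan
            else:
                assoc_surveys = set(ev_c["survey_id"]) & core_surveys if len(ev_c) else set()
                rec[f"tendency_{cls}"] = len(assoc_surveys) / n_core
            rec[f"degree_{cls}"] = int(ev_c["associate"].nunique()) if len(ev_c) else 0
            if len(my_dy):
                dy_c = my_dy[(my_dy["sex_class"] == cls) & (my_dy["x"] >= 1)]
            else:
                dy_c = my_dy
            rec[f"hwi_{cls}"] = float(dy_c["hwi"].mean()) if len(dy_c) else 0.0
        if hr_idx is not None and (ind, year) in hr_idx.index:
            rec["density_os"] = float(hr_idx.loc[(ind, year), "density_os"])
            rec["density_ss"] = float(hr_idx.loc[(ind, year), "density_ss"])
        else:
            rec["density_os"] = np.nan
            rec["density_ss"] = np.nan
        rows.append(rec)
    out = pd.DataFrame(rows)
    col_order = [
        "individual_id", "sex", "year", "n_sightings",
        "tendency_os", "tendency_ss", "degree_os", "degree_ss",
        "hwi_os", "hwi_ss", "density_os", "density_ss", "dominance",
    ]
    return out.reindex(columns=col_order)


def filter_min_sightings(
    measures: pd.DataFrame, min_sightings: int = MIN_SIGHTINGS_SOCIAL
) -> pd.DataFrame:
    """Keep individual-years with at least ``min_sightings`` sightings.

    Logs the rows-in/rows-out accounting of the filter step.
    """
    out = measures[measures["n_sightings"] >= min_sightings].reset_index(drop=True)
    logger.info(
        "min-sightings filter (>=%d): %d rows in, %d rows out (%d individuals)",
        min_sightings, len(measures), len(out), out["individual_id"].nunique(),
    )
    return out


def attach_covariates(
    measures: pd.DataFrame, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Merge per-individual covariates and derive the age covariate.

    ``covariates`` carries ``individual_id`` plus any of ``maturity_year``,
    ``heterozygosity``, ``offspring``.  Age is calendar year minus the first
    adult year, in whole years.
    """
    out = measures.merge(covariates, on="individual_id", how="left")
    if "maturity_year" in out:
        out["age"] = out["year"] - out["maturity_year"]
    return out


def standardize(
    measures: pd.DataFrame,
    columns: list[str],
) -> pd.DataFrame:
    """Centre and scale the given columns to mean 0, SD 1 over modelled rows.

    Count-valued traits (degree, offspring) are left on their observed scale
    and must not be passed here.  A constant column is an error.
    """
    out = measures.copy()
    for c in columns:
        v = out[c].to_numpy(dtype=float)
        sd = np.nanstd(v, ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"cannot standardize constant column {c!r}")
        out[c] = (v - np.nanmean(v)) / sd
    return out
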