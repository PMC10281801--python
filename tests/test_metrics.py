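"""Social-metric checks against hand counts and invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from socmix import metrics as met
from socmix.simulate import SightingSimConfig, simulate_sightings
from socmix.spatial import home_range_table


def _measures(toy):
    collapsed = met.collapse_to_surveys(toy["sightings"])
    return met.yearly_measures(collapsed, toy["core_ranges"], hr_table=pd.DataFrame())


class TestHalfWeightIndex:
    @pytest.mark.parametrize(
        "x,yA,yB,yAB,expected",
        [
            (4, 2, 2, 0, 2 / 3),  # 8 toy surveys, together in 4
            (0, 1, 2, 3, 0.0),
            (5, 0, 0, 0, 1.0),  # always together
            (2, 6, 0, 0, 0.4),
        ],
    )
    def test_hand_counts(self, x, yA, yB, yAB, expected):
        assert met.half_weight_index(x, yA, yB, yAB) == pytest.approx(expected)

    def test_all_zero_counts_missing(self):
        assert np.isnan(met.half_weight_index(0, 0, 0, 0))

    @settings(max_examples=200, derandomize=True)
    @given(
        x=st.integers(0, 50), yA=st.integers(0, 50),
        yB=st.integers(0, 50), yAB=st.integers(0, 50),
    )
    def test_range_and_symmetry(self, x, yA, yB, yAB):
        """HWI lies in [0, 1] and is symmetric under swapping yA and yB."""
        if x + yA + yB + yAB == 0:
            return
        v = met.half_weight_index(x, yA, yB, yAB)
        assert 0.0 <= v <= 1.0
        assert v == met.half_weight_index(x, yB, yA, yAB)


class TestAssociationDetection:
    def _survey(self, positions):
        return pd.DataFrame(
            [
                (f"i{j}", "F", 0, 0, x, y, "rest")
                for j, (x, y) in enumerate(positions)
            ],
            columns=["individual_id", "sex", "year", "survey_id", "x_m", "y_m", "behaviour"],
        )

    def _open_ranges(self, toy_network, ids):
        hr = next(iter(toy_network["core_ranges"].values()))
        return {(f"i{j}", 0): hr for j in ids}

    def test_closed_boundary_at_radius(self, toy_network):
        survey = self._survey([(0.0, 0.0), (1.85, 0.0)])
        ev = met.detect_associations(survey, self._open_ranges(toy_network, range(2)))
        assert len(ev) == 2  # both directions

    def test_beyond_radius_no_association(self, toy_network):
        survey = self._survey([(0.0, 0.0), (1.86, 0.0)])
        ev = met.detect_associations(survey, self._open_ranges(toy_network, range(2)))
        assert len(ev) == 0

    def test_no_transitive_closure(self, toy_network):
        """A-B and B-C within radius but A-C beyond: no A-C event."""
        survey = self._survey([(0.0, 0.0), (1.5, 0.0), (3.0, 0.0)])
        ev = met.detect_associations(survey, self._open_ranges(toy_network, range(3)))
        pairs = set(zip(ev["focal"], ev["associate"]))
        assert ("i0", "i2") not in pairs and ("i2", "i0") not in pairs
        assert ("i0", "i1") in pairs and ("i1", "i2") in pairs

    def test_focal_without_core_range_skipped(self, toy_network):
        survey = self._survey([(0.0, 0.0), (1.0, 0.0)])
        ranges = {("i0", 0): next(iter(toy_network["core_ranges"].values()))}
        ev = met.detect_associations(survey, ranges)
        assert set(ev["focal"]) == {"i0"}


class TestToyNetwork:
    def test_dyadic_hwi_match_hand_counts(self, toy_network):
        collapsed = met.collapse_to_surveys(toy_network["sightings"])
        events = pd.concat(
            [
                met.detect_associations(s, toy_network["core_ranges"])
                for _, s in collapsed.groupby("survey_id")
            ],
            ignore_index=True,
        )
        dyads = met.dyad_table(collapsed, events).set_index(["focal_id", "associate_id"])
        ab = dyads.loc[("A", "B")]
        assert (ab["x"], ab["yA"], ab["yB"], ab["yAB"]) == (4, 2, 2, 0)
        assert ab["hwi"] == pytest.approx(2 / 3)
        ba = dyads.loc[("B", "A")]
        assert (ba["x"], ba["yA"], ba["yB"], ba["yAB"]) == (4, 2, 2, 0)
        cd = dyads.loc[("C", "D")]
        assert (cd["x"], cd["yA"], cd["yB"], cd["yAB"]) == (2, 6, 0, 0)
        assert cd["hwi"] == pytest.approx(0.4)

    def test_tendency_degree_hwi(self, toy_network):
        m = _measures(toy_network).set_index("individual_id")
        assert m.loc["A", "tendency_os"] == pytest.approx(4 / 6)
        assert m.loc["A", "tendency_ss"] == 0.0
        assert m.loc["A", "degree_os"] == 1 and m.loc["A", "degree_ss"] == 0
        assert m.loc["A", "hwi_os"] == pytest.approx(2 / 3)
        assert m.loc["C", "tendency_ss"] == pytest.approx(2 / 8)
        assert m.loc["C", "hwi_ss"] == pytest.approx(0.4)
        assert m.loc["D", "tendency_ss"] == 1.0
        assert m.loc["E", "degree_os"] == 0 and m.loc["E", "hwi_os"] == 0.0
        assert m.loc["E", "tendency_os"] == 0.0

    def test_degree_partition_sums_to_total(self, toy_network):
        m = _measures(toy_network)
        collapsed = met.collapse_to_surveys(toy_network["sightings"])
        events = pd.concat(
            [
                met.detect_associations(s, toy_network["core_ranges"])
                for _, s in collapsed.groupby("survey_id")
            ],
            ignore_index=True,
        )
        total = events.groupby("focal")["associate"].nunique()
        for _, row in m.iterrows():
            assert row["degree_os"] + row["degree_ss"] == total.get(
                row["individual_id"], 0
            )

    def test_dominance_proportion(self, toy_network):
        m = _measures(toy_network).set_index("individual_id")
        assert m.loc["A", "dominance"] == pytest.approx(2 / 6)
        assert m.loc["C", "dominance"] == 0.0


class TestFilterAndStandardize:
    def test_filter_never_increases_and_respects_threshold(self):
        df = pd.DataFrame(
            {"individual_id": list("abcd"), "n_sightings": [29, 30, 31, 5]}
        )
        out = met.filter_min_sightings(df, 30)
        assert len(out) <= len(df)
        assert (out["n_sightings"] >= 30).all()
        assert set(out["individual_id"]) == {"b", "c"}

    def test_standardize_closed_form(self):
        df = pd.DataFrame({"v": [0.0, 1.0]})
        out = met.standardize(df, ["v"])
        sd = np.std([0, 1], ddof=1)
        assert out["v"].tolist() == pytest.approx([-0.5 / sd, 0.5 / sd])
        assert out["v"].mean() == pytest.approx(0.0, abs=1e-12)

    def test_standardize_constant_errors(self):
        df = pd.DataFrame({"v": [2.0, 2.0, 2.0]})
        with pytest.raises(ValueError, match="constant"):
            met.standardize(df, ["v"])

    def test_nonfinite_coordinates_rejected(self):
        s = pd.DataFrame(
            [("a", "F", 0, 0, np.nan, 0.0, "rest")],
            columns=["individual_id", "sex", "year", "survey_id", "x_m", "y_m", "behaviour"],
        )
        with pytest.raises(ValueError, match="finite"):
            met.collapse_to_surveys(s)


class TestSimulatorDownstream:
    def test_zero_gregariousness_means_zero_tendency(self):
        """Infinitely asocial individuals never associate downstream."""
        centers = np.array([[200.0 * i, 0.0] for i in range(6)])
        cfg = SightingSimConfig(
            n_individuals=6, n_surveys_per_year=40, n_years=1,
            hr_center=centers, hr_sd=5.0, gregariousness=-np.inf,
            detection_prob=1.0, seed=2,
        )
        s = simulate_sightings(cfg)
        collapsed = met.collapse_to_surveys(s)
        _, ranges = home_range_table(collapsed, h=7.0)
        m = met.yearly_measures(collapsed, ranges, hr_table=pd.DataFrame())
        assert (m["tendency_os"].fillna(0) == 0).all()
        assert (m["tendency_ss"].fillna(0) == 0).all()

    def test_inseparable_pair_hwi_one(self):
        """Two always-detected, always-together individuals: HWI = 1."""
        cfg = SightingSimConfig(
            n_individuals=2, n_surveys_per_year=40, n_years=1,
            hr_center=np.array([[0.0, 0.0], [0.0, 0.0]]), hr_sd=3.0,
            gregariousness=50.0, detection_prob=1.0, seed=4,
        )
        s = simulate_sightings(cfg)
        collapsed = met.collapse_to_surveys(s)
        # wide (99%) contour so every fix is in-core and the pure dyadic
        # hand count applies: co-detected in all 40 surveys, always together
        _, ranges = home_range_table(collapsed, h=7.0, level=0.99)
        m = met.yearly_measures(collapsed, ranges, hr_table=pd.DataFrame())
        m = m.set_index("individual_id")
        assert m.loc["ind000", "hwi_os"] == pytest.approx(1.0)
        assert m.loc["ind001", "hwi_os"] == pytest.approx(1.0)

    def test_single_individual_degree_zero(self):
        cfg = SightingSimConfig(
            n_individuals=1, n_surveys_per_year=40, n_years=1,
            hr_center=np.array([[0.0, 0.0]]), hr_sd=3.0, detection_prob=1.0, seed=5,
        )
        s = simulate_sightings(cfg)
        collapsed = met.collapse_to_surveys(s)
        _, ranges = home_range_table(collapsed, h=7.0)
        m = met.yearly_measures(collapsed, ranges, hr_table=pd.DataFrame())
        assert (m["degree_os"] == 0).all() and (m["degree_ss"] == 0).all()
        assert (m["hwi_os"] == 0).all() and (m["hwi_ss"] == 0).all()
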