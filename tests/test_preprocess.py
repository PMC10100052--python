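"""Settlement and nest-timing rules turning raw tables into analysis units."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

from settlemate import (
    GridRaster,
    cluster_territories,
    estimate_nest_initiation,
    filter_settled_males,
)
from settlemate.preprocess import (
    anonymous_male_ids,
    build_choice_events,
    events_from_frame,
    events_to_frame,
)


def obs(male, locs, site="EW", year=2017):
    return pd.DataFrame(
        {
            "male_id": male,
            "site": site,
            "year": year,
            "x": [x for x, *_ in locs],
            "y": [y for _, y, *_ in locs],
            "first_seen": [rest[0] for _, _, *rest in locs],
            "last_seen": [rest[1] for _, _, *rest in locs],
        }
    )


class TestClusterTerritories:
    def test_locations_under_threshold_merge(self):
        t = cluster_territories(
            obs("A", [(0, 0, "2017-05-01", "2017-05-03"), (120, 0, "2017-05-04", "2017-05-08")])
        )
        assert len(t) == 1
        assert t[0].centre == (60.0, 0.0)
        assert t[0].tenure == 8  # May 1 .. May 8 inclusive

    def test_locations_at_exact_threshold_split(self):
        t = cluster_territories(
            obs("A", [(0, 0, "2017-05-01", "2017-05-05"), (150, 0, "2017-05-06", "2017-05-12")])
        )
        assert len(t) == 2

    def test_single_location_single_territory(self):
        t = cluster_territories(obs("A", [(42, 17, "2017-05-01", "2017-05-06")]))
        assert len(t) == 1
        assert t[0].centre == (42.0, 17.0)

    def test_chaining_links_through_intermediate_location(self):
        # 0 -- 140 -- 280: each neighbour pair < 150 m, ends 280 m apart;
        # single linkage chains all three into one territory
        t = cluster_territories(
            obs(
                "A",
                [
                    (0, 0, "2017-05-01", "2017-05-02"),
                    (140, 0, "2017-05-03", "2017-05-04"),
                    (280, 0, "2017-05-05", "2017-05-06"),
                ],
            )
        )
        assert len(t) == 1

    def test_mixed_males_rejected(self):
        frames = pd.concat(
            [obs("A", [(0, 0, "2017-05-01", "2017-05-06")]),
             obs("B", [(10, 0, "2017-05-01", "2017-05-06")])]
        )
        with pytest.raises(ValueError):
            cluster_territories(frames)


class TestFilterSettledMales:
    def test_presence_boundary_at_five_days(self):
        four = obs("A", [(0, 0, "2017-05-01", "2017-05-04")])
        five = obs("B", [(0, 0, "2017-05-01", "2017-05-05")])
        out = filter_settled_males(pd.concat([four, five]))
        assert list(out["male_id"]) == ["B"]
        assert out["tenure"].iloc[0] == 5

    def test_longest_tenure_territory_wins(self):
        o = obs(
            "A",
            [
                (0, 0, "2017-05-01", "2017-05-10"),  # 10 days
                (500, 0, "2017-05-12", "2017-05-18"),  # 7 days
            ],
        )
        out = filter_settled_males(o)
        assert len(out) == 1
        assert out["x"].iloc[0] == 0.0

    def test_tenure_tie_goes_to_first_territory(self):
        o = obs(
            "A",
            [
                (500, 0, "2017-05-10", "2017-05-16"),  # later, 7 days
                (0, 0, "2017-05-01", "2017-05-07"),  # earlier, 7 days
            ],
        )
        out = filter_settled_males(o)
        assert out["x"].iloc[0] == 0.0

    def test_one_record_per_male_per_site_year(self):
        o = pd.concat(
            [
                obs("A", [(0, 0, "2017-05-01", "2017-05-09"), (400, 0, "2017-05-10", "2017-05-20")]),
                obs("A", [(50, 50, "2018-05-01", "2018-05-09")], year=2018),
                obs("B", [(900, 900, "2017-05-01", "2017-05-20")]),
            ]
        )
        out = filter_settled_males(o)
        assert len(out) == 3
        assert out.groupby(["male_id", "site", "year"]).size().max() == 1


class TestNestTiming:
    def test_back_calculation_from_clutch(self):
        rec = estimate_nest_initiation(
            {"clutch_completion": "2017-05-20", "clutch_size": 6}
        )
        assert rec["clutch_initiation"] == date(2017, 5, 15)
        assert rec["nest_initiation"] == date(2017, 5, 8)
        assert rec["incubation_end"] == date(2017, 6, 3)

    def test_single_egg_clutch(self):
        rec = estimate_nest_initiation(
            {"clutch_completion": "2017-05-20", "clutch_size": 1}
        )
        assert rec["clutch_initiation"] == date(2017, 5, 20)

    def test_empty_clutch_is_an_error(self):
        with pytest.raises(ValueError):
            estimate_nest_initiation({"clutch_completion": "2017-05-20", "clutch_size": 0})


class TestBuildChoiceEvents:
    @pytest.fixture
    def hab(self):
        vals = np.tile(np.linspace(1.0, 10.0, 50), (50, 1))
        return GridRaster(0.0, 0.0, 10.0, vals)

    @pytest.fixture
    def surveys(self):
        rows = []
        for d, males in [
            ("2017-05-06", [("M1", 100, 100), ("M2", 300, 120), ("M3", 400, 300)]),
            ("2017-05-12", [("M1", 100, 100), ("M4", 250, 250)]),
        ]:
            for mid, x, y in males:
                rows.append({"site": "EW", "survey_date": d, "male_id": mid, "x": x, "y": y})
        return pd.DataFrame(rows)

    @pytest.fixture
    def female(self):
        # nest initiation = May 15 - 5 - 7 = May 3 -> nearer to May 6
        return pd.DataFrame(
            [
                {
                    "site": "EW",
                    "year": 2017,
                    "female_id": "F1",
                    "x": 310.0,
                    "y": 118.0,
                    "clutch_size": 6,
                    "clutch_completion": "2017-05-15",
                }
            ]
        )

    def test_snapshot_nearest_in_time_selected(self, female, surveys, hab):
        events = build_choice_events(female, surveys, hab)
        assert len(events) == 1
        assert set(events[0].male_ids) == {"M1", "M2", "M3"}

    def test_time_ties_resolve_to_earlier_snapshot(self, surveys, hab):
        # nest initiation May 9: 3 days to both surveys
        female = pd.DataFrame(
            [
                {
                    "site": "EW", "year": 2017, "female_id": "F2", "x": 100.0, "y": 100.0,
                    "clutch_size": 6, "clutch_completion": "2017-05-21",
                }
            ]
        )
        events = build_choice_events(female, surveys, hab)
        assert set(events[0].male_ids) == {"M1", "M2", "M3"}

    def test_chosen_is_named_mate_when_present(self, female, surveys, hab):
        female = female.assign(mate_id="M3")
        ev = build_choice_events(female, surveys, hab)[0]
        assert ev.male_ids[ev.chosen] == "M3"

    def test_chosen_defaults_to_male_nearest_nest(self, female, surveys, hab):
        ev = build_choice_events(female, surveys, hab)[0]
        assert ev.male_ids[ev.chosen] == "M2"

    def test_playbacks_raise_connectivity_but_are_not_candidates(
        self, female, surveys, hab
    ):
        playbacks = pd.DataFrame(
            [{"site": "EW", "year": 2017, "ax": 250, "ay": 100, "bx": 350, "by": 100,
              "song_rate_class": "low"}]
        )
        with_pb = build_choice_events(female, surveys, hab, playbacks)[0]
        without = build_choice_events(female, surveys, hab)[0]
        assert with_pb.male_ids == without.male_ids  # candidate set unchanged
        assert np.all(with_pb.C > without.C)
        np.testing.assert_array_equal(with_pb.H, without.H)

    def test_missing_site_survey_errors(self, female, hab):
        surveys = pd.DataFrame(
            [{"site": "LB", "survey_date": "2017-05-06", "male_id": "M9", "x": 1, "y": 1}]
        )
        with pytest.raises(ValueError):
            build_choice_events(female, surveys, hab)

    def test_single_male_site_yields_single_candidate_event(self, female, hab):
        surveys = pd.DataFrame(
            [{"site": "EW", "survey_date": "2017-05-06", "male_id": "M1", "x": 50, "y": 50}]
        )
        ev = build_choice_events(female, surveys, hab)[0]
        assert ev.n_candidates == 1
        assert ev.chosen == 0


def test_events_frame_round_trip(small_scene):
    frame = events_to_frame(small_scene.events)
    back = events_from_frame(frame)
    assert len(back) == len(small_scene.events)
    for a, b in zip(small_scene.events, back):
        assert a.male_ids == b.male_ids
        assert a.chosen == b.chosen
        np.testing.assert_allclose(a.H, b.H)
        np.testing.assert_allclose(a.C, b.C)


def test_anonymous_ids_are_site_year_scoped():
    o = pd.concat(
        [
            obs("", [(0, 0, "2017-05-01", "2017-05-06")]),
            obs("", [(9, 9, "2018-05-01", "2018-05-06")], year=2018),
        ]
    )
    tagged = anonymous_male_ids(o)
    assert tagged["male_id"].nunique() == 2
    assert tagged["male_id"].str.contains("anon").all()
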