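"""Semimonth calendar, composite grid geometry, filtering and aggregation."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import Point

from conftest import make_segments, make_sightings
from winterhab import detection, surveys
from winterhab.config import PipelineConfig
from winterhab.surveys import (
    Grid,
    TransectZone,
    aggregate,
    assign_semimonth,
    build_grid,
    filter_on_effort,
)


class TestSemiMonth:
    @pytest.mark.parametrize(
        "date, month, half, season, index",
        [
            ("2009-12-15", 12, "A", "2009/2010", 1),
            ("2009-12-16", 12, "B", "2009/2010", 2),
            ("2010-02-28", 2, "B", "2009/2010", 6),
            ("2010-03-16", 3, "B", "2009/2010", 8),
            ("2010-01-01", 1, "A", "2009/2010", 3),
        ],
    )
    def test_examples(self, date, month, half, season, index):
        sm = assign_semimonth(date)
        assert (sm.month, sm.half, sm.season_label, sm.index) == \
            (month, half, season, index)

    def test_outside_season_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            assign_semimonth("2010-07-01")

    @settings(max_examples=200, deadline=None)
    @given(st.dates(min_value=dt.date(2003, 1, 1),
                    max_value=dt.date(2013, 12, 31)))
    def test_every_season_date_maps_to_one_of_eight(self, date):
        if date.month not in (12, 1, 2, 3):
            return
        sm = assign_semimonth(date)
        assert 1 <= sm.index <= 8
        assert sm.half == ("A" if date.day <= 15 else "B")

    def test_vectorized_matches_scalar(self):
        dates = pd.Series(["2009-12-01", "2010-01-16", "2010-03-31"])
        seasons, ords = surveys.semimonth_key(dates)
        for d, s, o in zip(dates, seasons, ords):
            sm = assign_semimonth(d)
            assert (sm.season_label, sm.index) == (s, o)


class TestGrid:
    def test_single_transect_cell_count_and_centers(self):
        """One east-west transect of 55.6 km yields 10 south-zone cells
        centred on the line."""
        zone = TransectZone("S", (0.0, 0.0), 0.0, 5.56, 1, 10)
        grid = Grid([zone], split_northing=1e9)
        assert len(grid) == 10
        for c in grid.cells:
            assert c.center[1] == pytest.approx(0.0)  # on the track line
        assert grid.cells[0].center[0] == pytest.approx(2.78)

    def test_shared_edge_goes_to_lower_cell_id(self):
        zone = TransectZone("S", (0.0, 0.0), 0.0, 5.56, 2, 4)
        grid = Grid([zone], split_northing=1e9)
        # point exactly on the edge between col 0 and col 1
        cid = grid.assign([5.56], [0.0])[0]
        assert cid == "S-000-000"
        # and exactly on the row boundary between rows 0 and 1
        cid = grid.assign([2.0], [2.78])[0]
        assert cid == "S-000-000"

    def test_rotated_zone_perpendicular_membership(self):
        """A point 3.7 km perpendicular from a NW-SE transect stays inside
        that transect's 7.52-km cell row (half-width 3.76 km)."""
        grid = build_grid()
        north = grid.zones[1]
        p0, p1 = north.transect_endpoints(2)
        mid = 0.5 * (p0 + p1)
        n_hat = north.unit_across
        probe = mid + 3.7 * n_hat
        cid = grid.assign([probe[0]], [probe[1]])[0]
        assert cid is not None and cid.startswith("N-002-")
        # check against an explicit rotation-matrix computation
        theta = np.deg2rad(north.azimuth_deg)
        R = np.array([[np.cos(theta), np.sin(theta)],
                      [-np.sin(theta), np.cos(theta)]])
        uv = R @ (probe - np.array(north.origin))
        assert abs(uv[1] - 2 * 7.52) == pytest.approx(3.7, abs=1e-9)

    def test_assignment_partitions_points(self, rng):
        grid = build_grid()
        xs = rng.uniform(0, 40, 500)
        ys = rng.uniform(0, 300, 500)
        ids = grid.assign(xs, ys)
        for x, y, cid in zip(xs, ys, ids):
            if cid is None:
                continue
            cell = grid.cell(cid)
            assert cell.polygon.buffer(1e-9).contains(Point(x, y))

    def test_cell_polygon_area(self):
        grid = build_grid()
        for c in (grid.cells[0], grid.cells[-1]):
            assert c.polygon.area == pytest.approx(c.size_km**2, rel=1e-9)

    def test_clip_segment_conserves_length(self, rng):
        grid = build_grid()
        for _ in range(50):
            x0, y0 = rng.uniform(2, 35), rng.uniform(2, 290)
            ang = rng.uniform(0, 2 * np.pi)
            ln = rng.uniform(0.5, 20)
            x1, y1 = x0 + ln * np.cos(ang), y0 + ln * np.sin(ang)
            pieces = grid.clip_segment(x0, y0, x1, y1)
            total = sum(p[1] for p in pieces)
            assert total <= ln + 1e-9
            # pieces must match a dense-sampling oracle of in-cell length
            ts = np.linspace(0, 1, 4001)
            px, py = x0 + ts * (x1 - x0), y0 + ts * (y1 - y0)
            frac = np.mean([c is not None for c in grid.assign(px, py)])
            assert total == pytest.approx(ln * frac, abs=ln * 2e-3 + 1e-6)


class TestFilterOnEffort:
    def test_constructed_fixture_counts(self):
        """10 segments with exactly 3 violating one rule each -> 7 kept."""
        segs = make_segments([
            {}, {}, {}, {}, {}, {}, {},
            {"seastate": 4},
            {"altitude_m": 400.0},
            {"visibility_km": 2.0},
        ])
        out, _, report = filter_on_effort(segs, make_sightings([]))
        assert len(out) == 7
        assert report["segments_removed_by_rule"]["seastate"] == 1
        assert report["segments_removed_by_rule"]["altitude"] == 1
        assert report["segments_removed_by_rule"]["visibility"] == 1

    def test_boundary_values_inclusive(self):
        segs = make_segments([
            {"seastate": 3, "altitude_m": 365.0, "visibility_km": 3.7},
        ])
        out, _, _ = filter_on_effort(segs, make_sightings([]))
        assert len(out) == 1

    def test_off_track_and_verification_removed(self):
        segs = make_segments([
            {"status": "transit"},
            {"status": "circling"},
            {"is_verification": True},
            {},
        ])
        out, _, report = filter_on_effort(segs, make_sightings([]))
        assert len(out) == 1
        assert report["segments_removed_by_rule"]["off_track"] == 2
        assert report["segments_removed_by_rule"]["verification"] == 1

    def test_unknown_status_rejected_with_row(self):
        segs = make_segments([{}, {"status": "hovering"}])
        with pytest.raises(ValueError, match=r"status at rows \[1\]"):
            filter_on_effort(segs, make_sightings([]))

    def test_sighting_rules(self):
        sig = make_sightings([
            {},
            {"is_duplicate": True},
            {"is_verification": True},
            {"initial_status_on_effort": False},
        ])
        _, out, report = filter_on_effort(make_segments([{}]), sig)
        assert len(out) == 1
        assert report["sightings_removed_by_rule"] == {
            "not_on_effort": 1, "duplicate": 1, "verification": 1,
        }

    def test_idempotent(self, processed):
        f2_seg, f2_sig, _ = filter_on_effort(
            processed["fseg"], processed["fsig"], processed["pcfg"]
        )
        assert len(f2_seg) == len(processed["fseg"])
        assert len(f2_sig) == len(processed["fsig"])


def _flat_model(platform="TwinOtter", esw=1.5):
    m = detection.DetectionModel(platform, np.log(esw), 0.0, 3.0,
                                 detection.DEFAULT_BLIND_SPOT[platform])
    m.esw_table = {s: esw for s in range(7)}
    return m


class TestAggregate:
    def test_effort_additivity_and_exact_value(self):
        """Two Twin Otter segments in one cell: effort = sum of
        length x 2 x ESW."""
        segs = make_segments([
            {"platform": "TwinOtter", "x0": 0.0, "x1": 4.0},
            {"platform": "TwinOtter", "x0": 4.0, "x1": 5.0},
        ])
        grid = Grid([TransectZone("S", (0.0, 2.78), 0.0, 5.56, 1, 2)], 1e9)
        units, rep = aggregate(segs, make_sightings([]).iloc[:0],
                               {"TwinOtter": _flat_model()}, grid)
        assert len(units) == 1
        assert units["effort_km2"].iloc[0] == pytest.approx(5.0 * 2 * 1.5)

    def test_effort_outlier_flagged(self):
        segs = make_segments([
            {"platform": "TwinOtter", "x0": 0.0, "x1": 5.56,
         "survey_id": f"T{i}"} for i in range(41)
        ])
        grid = Grid([TransectZone("S", (0.0, 2.78), 0.0, 5.56, 1, 1)], 1e9)
        units, rep = aggregate(segs, make_sightings([]).iloc[:0],
                               {"TwinOtter": _flat_model()}, grid)
        # 41 passes x 16.68 km2 = 683.9 km2 > 340
        assert units["excluded"].iloc[0]
        assert units["exclude_reason"].iloc[0] == "effort_outlier"
        assert rep["units_excluded_effort"] == 1

    def test_conservation_on_default_run(self, processed):
        """Total unit effort equals the sum of per-segment swath areas and
        total whales equals the retained sighted whales."""
        units = processed["units"]
        fseg, fsig = processed["fseg"], processed["fsig"]
        models = processed["models"]
        lengths = np.hypot(fseg.x1 - fseg.x0, fseg.y1 - fseg.y0)
        swath = np.zeros(len(fseg))
        for plat, m in models.items():
            sel = (fseg.platform == plat).to_numpy()
            hw = np.array([
                m.esw(int(s)) - m.blind_spot_km
                for s in fseg.seastate.to_numpy()[sel]
            ])
            swath[sel] = 2 * lengths.to_numpy()[sel] * hw
        assert units["effort_km2"].sum() == pytest.approx(
            swath.sum(), abs=1e-6
        )
        assert units["whales"].sum() == fsig["group_size"].sum()
        assert rep_conserves_counts(units)

    def test_sampling_unit_invariants(self, processed):
        u = processed["units"]
        assert (u["effort_km2"] >= 0).all()
        assert (u["whales"] >= u["sightings"]).all()
        assert (u.loc[u["sightings"] == 0, "whales"] == 0).all()


def rep_conserves_counts(units):
    return (units.loc[units.sightings == 0, "whales"] == 0).all()
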