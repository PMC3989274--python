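"""Survey data processing: on-effort filtering, composite grid, aggregation.

Flight tracks and sightings live in pandas DataFrames on a single projected
plane (km east/north, UTM-like). The composite sampling grid has east-west
5.56-km cell rows in the southern zone and northwest-southeast 7.52-km rows in
the northern zone, with each cell row centred on its transect line so all
effort in a cell is associated with one track line. A sampling unit is one
grid cell summarized over one semimonthly period (days 1-15 = half A, day 16
to month end = half B; eight periods December A through March B per season).

Segment DataFrame schema (one row per flight-path piece flown under constant
conditions; a segment spanning a condition change must be pre-split upstream):
    survey_id, date (ISO), platform, x0, y0, x1, y1 (km), seastate (0-6),
    altitude_m, visibility_km, status (on_transect|transit|circling),
    is_verification (bool)

Sighting DataFrame schema:
    sighting_id, survey_id, date, x, y (km), group_size (>=1), calf_present,
    perp_distance_km, platform, seastate, is_duplicate, is_verification,
    initial_status_on_effort (bool)
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from winterhab.config import PipelineConfig
from winterhab.detection import DetectionModel

_EDGE_TOL = 1e-9

# ---------------------------------------------------------------------------
# Semimonthly calendar
# ---------------------------------------------------------------------------

_MONTH_ORDER = {12: 0, 1: 1, 2: 2, 3: 3}
_MONTH_NAME = {12: "Dec", 1: "Jan", 2: "Feb", 3: "Mar"}


@dataclass(frozen=True)
class SemiMonth:
    """One of the eight semimonthly periods of a calving season."""

    season_label: str  # e.g. "2009/2010"
    month: int         # 12, 1, 2 or 3
    half: str          # "A" (days 1-15) or "B" (day 16 to month end)

    @property
    def index(self) -> int:
        """Ordinal 1 (December A) through 8 (March B)."""
        return 2 * _MONTH_ORDER[self.month] + (1 if self.half == "A" else 2)

    def __str__(self) -> str:
        return f"{self.season_label} {_MONTH_NAME[self.month]}{self.half}"


def assign_semimonth(date: dt.date | str | pd.Timestamp) -> SemiMonth:
    """Map a December-March date to its semimonthly period.

    December dates belong to the season labelled "year/year+1"; January-March
    dates to "year-1/year".
    """
    if isinstance(date, str):
        date = dt.date.fromisoformat(date)
    elif isinstance(date, pd.Timestamp):
        date = date.date()
    if date.month not in _MONTH_ORDER:
        raise ValueError(f"date {date} outside the December-March calving season")
    if date.month == 12:
        season = f"{date.year}/{date.year + 1}"
    else:
        season = f"{date.year - 1}/{date.year}"
    half = "A" if date.day <= 15 else "B"
    return SemiMonth(season, date.month, half)


def semimonth_key(dates: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Vectorized (season_label, semimonth ordinal 1-8) for a date Series."""
    d = pd.to_datetime(dates)
    month, day, year = d.dt.month, d.dt.day, d.dt.year
    bad = ~month.isin(list(_MONTH_ORDER))
    if bad.any():
        raise ValueError(
            f"dates outside December-March at rows {list(d.index[bad])[:5]}"
        )
    start_year = np.where(month == 12, year, year - 1)
    season = pd.Series(
        [f"{y}/{y + 1}" for y in start_year], index=d.index, dtype=object
    )
    ordinal = month.map(_MONTH_ORDER) * 2 + np.where(day <= 15, 1, 2)
    return season, ordinal.astype(int)


def season_days(season_label: str) -> list[dt.date]:
    """All dates of a season (Dec 1 through Mar 31)."""
    y0 = int(season_label.split("/")[0])
    start = dt.date(y0, 12, 1)
    end = dt.date(y0 + 1, 3, 31)
    return [start + dt.timedelta(days=i) for i in range((end - start).days + 1)]


# ---------------------------------------------------------------------------
# Composite sampling grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransectZone:
    """A block of parallel transect lines with cell rows centred on them.

    Frame coordinates: u along the transect direction, v across it. Transect
    ``i`` is the line v = i * cell_km (u in [0, length]); its cell row spans
    v in [(i - 1/2) cell, (i + 1/2) cell) and is cut into columns of width
    cell_km along u.
    """

    name: str
    origin: tuple[float, float]
    azimuth_deg: float  # direction of the transect lines (0 = due east)
    cell_km: float
    n_transects: int
    n_cells_along: int
    # stagger shifts row i's columns by stagger*i cells along u, letting a
    # rotated block of transects follow the coastline (one cell west per row
    # for the NW-SE zone); row i's columns span
    # u in [stagger*i*cell, (stagger*i + n_cells_along)*cell)
    stagger: int = 0

    @property
    def unit_along(self) -> np.ndarray:
        a = np.deg2rad(self.azimuth_deg)
        return np.array([np.cos(a), np.sin(a)])

    @property
    def unit_across(self) -> np.ndarray:
        a = np.deg2rad(self.azimuth_deg)
        return np.array([-np.sin(a), np.cos(a)])

    @property
    def length(self) -> float:
        return self.n_cells_along * self.cell_km

    def to_frame(self, x, y):
        """Project points onto (u, v) frame coordinates."""
        rx = np.asarray(x, dtype=float) - self.origin[0]
        ry = np.asarray(y, dtype=float) - self.origin[1]
        eu, ev = self.unit_along, self.unit_across
        return rx * eu[0] + ry * eu[1], rx * ev[0] + ry * ev[1]

    def from_frame(self, u, v):
        eu, ev = self.unit_along, self.unit_across
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        return (
            self.origin[0] + u * eu[0] + v * ev[0],
            self.origin[1] + u * eu[1] + v * ev[1],
        )

    def row_u_start(self, i: int) -> float:
        return self.stagger * i * self.cell_km

    def transect_endpoints(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        u0 = self.row_u_start(i)
        x0, y0 = self.from_frame(u0, i * self.cell_km)
        x1, y1 = self.from_frame(u0 + self.length, i * self.cell_km)
        return np.array([x0, y0]), np.array([x1, y1])


@dataclass(frozen=True)
class GridCell:
    cell_id: str
    zone: str
    row: int
    col: int
    center: tuple[float, float]
    size_km: float
    polygon: Polygon = field(compare=False)


class Grid:
    """Composite grid over the study zones, with deterministic assignment.

    Points are routed to a zone by northing (south of ``split_northing`` goes
    to the first zone), then to the cell whose (row, col) frame bin contains
    them. A point exactly on a shared cell edge goes to the lower-index
    (hence lower cell_id) neighbour.
    """

    def __init__(self, zones: list[TransectZone], split_northing: float):
        self.zones = zones
        self.split_northing = split_northing
        self.cells: list[GridCell] = []
        for z in zones:
            for i in range(z.n_transects):
                for j in range(z.n_cells_along):
                    cid = f"{z.name}-{i:03d}-{j:03d}"
                    uc = z.row_u_start(i) + (j + 0.5) * z.cell_km
                    vc = i * z.cell_km
                    cx, cy = z.from_frame(uc, vc)
                    h = z.cell_km / 2.0
                    corners = [
                        z.from_frame(uc + du, vc + dv)
                        for du, dv in ((-h, -h), (h, -h), (h, h), (-h, h))
                    ]
                    poly = Polygon([(float(px), float(py)) for px, py in corners])
                    self.cells.append(
                        GridCell(cid, z.name, i, j, (float(cx), float(cy)),
                                 z.cell_km, poly)
                    )
        self._by_id = {c.cell_id: c for c in self.cells}

    def __len__(self) -> int:
        return len(self.cells)

    def cell(self, cell_id: str) -> GridCell:
        return self._by_id[cell_id]

    @property
    def cell_ids(self) -> list[str]:
        return [c.cell_id for c in self.cells]

    def centers(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": [c.cell_id for c in self.cells],
                "zone": [c.zone for c in self.cells],
                "easting": [c.center[0] for c in self.cells],
                "northing": [c.center[1] for c in self.cells],
                "size_km": [c.size_km for c in self.cells],
            }
        )

    def _zone_for(self, y: np.ndarray) -> np.ndarray:
        return np.where(np.asarray(y, dtype=float) < self.split_northing, 0, 1)

    def assign(self, x, y) -> np.ndarray:
        """Vectorized point -> cell_id (object array; None if outside)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        out = np.full(x.shape, None, dtype=object)
        zidx = self._zone_for(y) if len(self.zones) > 1 else np.zeros(len(x), int)
        for k, z in enumerate(self.zones):
            sel = zidx == k
            if not sel.any():
                continue
            u, v = z.to_frame(x[sel], y[sel])
            col = self._edge_floor(u / z.cell_km)
            row = self._edge_floor(v / z.cell_km + 0.5)
            col = col - z.stagger * row
            ok = (col >= 0) & (col < z.n_cells_along) & \
                 (row >= 0) & (row < z.n_transects)
            ids = np.full(u.shape, None, dtype=object)
            rr, cc = row[ok], col[ok]
            ids[ok] = [f"{z.name}-{i:03d}-{j:03d}" for i, j in zip(rr, cc)]
            out[sel] = ids
        return out

    @staticmethod
    def _edge_floor(q: np.ndarray) -> np.ndarray:
        """floor(), but values exactly on a bin edge drop to the lower bin."""
        idx = np.floor(q + _EDGE_TOL).astype(int)
        on_edge = np.abs(q - np.round(q)) <= _EDGE_TOL
        return np.where(on_edge, np.round(q).astype(int) - 1, idx)

    def clip_segment(self, x0: float, y0: float, x1: float, y1: float
                     ) -> list[tuple[str, float]]:
        """Split a straight segment at cell boundaries.

        Returns (cell_id, in-cell length km) pairs; pieces outside all cells
        are dropped. Swath area is later apportioned proportionally to these
        in-cell track lengths.
        """
        length = float(np.hypot(x1 - x0, y1 - y0))
        if length == 0.0:
            return []
        # break additionally at the zone split so each piece has one zone
        ts = {0.0, 1.0}
        if len(self.zones) > 1 and (y1 - y0) != 0.0:
            t = (self.split_northing - y0) / (y1 - y0)
            if 0.0 < t < 1.0:
                ts.add(t)
        pieces: list[tuple[str, float]] = []
        bounds = sorted(ts)
        for ta, tb in zip(bounds[:-1], bounds[1:]):
            my = y0 + 0.5 * (ta + tb) * (y1 - y0)
            z = self.zones[int(self._zone_for(np.array([my]))[0])] \
                if len(self.zones) > 1 else self.zones[0]
            pieces.extend(
                self._clip_in_zone(z, x0, y0, x1, y1, ta, tb, length)
            )
        return pieces

    def _clip_in_zone(self, z: TransectZone, x0, y0, x1, y1, ta, tb, length):
        (u0,), (v0,) = z.to_frame([x0], [y0])
        (u1,), (v1,) = z.to_frame([x1], [y1])
        du, dv = u1 - u0, v1 - v0
        ts = {ta, tb}
        for delta, lo in ((du, u0), (dv, v0 + 0.5 * z.cell_km)):
            if abs(delta) < _EDGE_TOL:
                continue
            k0 = int(np.floor(min(lo, lo + delta) / z.cell_km)) - 1
            k1 = int(np.ceil(max(lo, lo + delta) / z.cell_km)) + 1
            for k in range(k0, k1 + 1):
                t = (k * z.cell_km - lo) / delta
                if ta < t < tb:
                    ts.add(t)
        out = []
        bounds = sorted(ts)
        for a, b in zip(bounds[:-1], bounds[1:]):
            tm = 0.5 * (a + b)
            cid = self.assign(
                np.array([x0 + tm * (x1 - x0)]), np.array([y0 + tm * (y1 - y0)])
            )[0]
            if cid is not None:
                out.append((cid, (b - a) * length))
        return out

    def to_geojson(self) -> dict:
        return {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "properties": {
                        "cell_id": c.cell_id, "zone": c.zone,
                        "size_km": c.size_km,
                    },
                    "geometry": {
                        "type": "Polygon",
                        "coordinates": [list(c.polygon.exterior.coords)],
                    },
                }
                for c in self.cells
            ],
        }


def build_grid(
    south_transects: int = 27,
    south_cells_along: int = 9,
    north_transects: int = 11,
    north_cells_along: int = 7,
    split_northing: float | None = None,
    cfg: PipelineConfig | None = None,
) -> Grid:
    """Default composite study-area grid.

    Southern zone: east-west rows of 5.56-km cells starting just offshore of
    the x = 0 coastline. Northern zone: rows rotated to the northwest-southeast
    transect azimuth (-45 deg) with 7.52-km cells, origins placed so the
    rotated rows stay north of the zone split.
    """
    cfg = cfg or PipelineConfig()
    if split_northing is None:
        # the split must coincide with the southern block's upper cell edge
        # so no cell straddles it
        split_northing = south_transects * cfg.south_cell_km
    south = TransectZone(
        name="S",
        origin=(0.0, cfg.south_cell_km / 2.0),
        azimuth_deg=0.0,
        cell_km=cfg.south_cell_km,
        n_transects=south_transects,
        n_cells_along=south_cells_along,
    )
    # NW-SE lines: heading southeast from coast origins spaced so that the
    # perpendicular spacing equals the cell size
    az = -45.0
    spacing_y = cfg.north_cell_km / np.cos(np.deg2rad(45.0))
    drop = north_cells_along * cfg.north_cell_km * np.sin(np.deg2rad(45.0))
    first_y = split_northing + drop + cfg.north_cell_km
    north = TransectZone(
        name="N",
        origin=(0.0, first_y),
        azimuth_deg=az,
        cell_km=cfg.north_cell_km,
        n_transects=north_transects,
        n_cells_along=north_cells_along,
        stagger=-1,  # each row starts one cell west: rows follow the coast
    )
    return Grid([south, north], split_northing)


# ---------------------------------------------------------------------------
# On-effort filtering
# ---------------------------------------------------------------------------

_VALID_STATUS = {"on_transect", "transit", "circling"}


def filter_on_effort(
    segments: pd.DataFrame,
    sightings: pd.DataFrame,
    cfg: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Retain on-effort survey records.

    Segments are on-effort when sea state <= 3, altitude <= 365 m, visibility
    >= 3.7 km and the aircraft was flying a designated track line (all
    boundaries inclusive); verification-survey segments are removed with their
    effort. Sightings are retained when the survey status at the initial
    sighting was on-effort, excluding verification and duplicate records.
    The report counts removals per rule (a record can violate several rules).
    """
    cfg = cfg or PipelineConfig()
    bad_status = ~segments["status"].isin(_VALID_STATUS)
    if bad_status.any():
        idx = list(segments.index[bad_status])[:5]
        raise ValueError(f"unknown segment status at rows {idx}")

    rules = {
        "seastate": segments["seastate"] > cfg.max_seastate,
        "altitude": segments["altitude_m"] > cfg.max_altitude_m,
        "visibility": segments["visibility_km"] < cfg.min_visibility_km,
        "off_track": segments["status"] != "on_transect",
        "verification": segments["is_verification"].astype(bool),
    }
    keep_seg = ~np.logical_or.reduce(list(rules.values()))
    seg_report = {name: int(mask.sum()) for name, mask in rules.items()}

    if len(sightings):
        s_rules = {
            "not_on_effort":
                ~sightings["initial_status_on_effort"].astype(bool),
            "duplicate": sightings["is_duplicate"].astype(bool),
            "verification": sightings["is_verification"].astype(bool),
        }
        keep_sig = ~np.logical_or.reduce(list(s_rules.values()))
        sig_report = {name: int(mask.sum()) for name, mask in s_rules.items()}
    else:
        keep_sig = np.zeros(0, dtype=bool)
        sig_report = {"not_on_effort": 0, "duplicate": 0, "verification": 0}

    report = {
        "segments_in": int(len(segments)),
        "segments_kept": int(keep_seg.sum()),
        "segments_removed_by_rule": seg_report,
        "sightings_in": int(len(sightings)),
        "sightings_kept": int(keep_sig.sum()) if len(sightings) else 0,
        "sightings_removed_by_rule": sig_report,
    }
    return (
        segments.loc[keep_seg].copy(),
        sightings.loc[keep_sig].copy() if len(sightings) else sightings.copy(),
        report,
    )


# ---------------------------------------------------------------------------
# Aggregation into sampling units
# ---------------------------------------------------------------------------

def _strict_interior_integers(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Count integers strictly between a and b (endpoints-on-integer excluded)."""
    lo, hi = np.minimum(a, b), np.maximum(a, b)
    return np.maximum(
        0.0, np.floor(hi - _EDGE_TOL) - np.ceil(lo + _EDGE_TOL) + 1
    ).astype(int)


def _single_cell_mask(grid: Grid, x0, y0, x1, y1) -> np.ndarray:
    """True where a straight segment crosses no cell or zone boundary.

    Such segments (the vast majority: GPS fixes are dense relative to cell
    size, and synthetic segments are cell-aligned) can be attributed to their
    midpoint cell with their full length; the rest go through the exact
    boundary-splitting path.
    """
    n = len(x0)
    crossings = np.zeros(n, dtype=int)
    if len(grid.zones) > 1:
        s = grid.split_northing
        crossings += (
            ((y0 - s) < -_EDGE_TOL) & ((y1 - s) > _EDGE_TOL)
            | ((y0 - s) > _EDGE_TOL) & ((y1 - s) < -_EDGE_TOL)
        ).astype(int)
    my = 0.5 * (np.asarray(y0) + np.asarray(y1))
    zidx = grid._zone_for(my) if len(grid.zones) > 1 else np.zeros(n, int)
    for k, z in enumerate(grid.zones):
        sel = zidx == k
        if not sel.any():
            continue
        u0, v0 = z.to_frame(np.asarray(x0)[sel], np.asarray(y0)[sel])
        u1, v1 = z.to_frame(np.asarray(x1)[sel], np.asarray(y1)[sel])
        c = _strict_interior_integers(u0 / z.cell_km, u1 / z.cell_km)
        c += _strict_interior_integers(
            v0 / z.cell_km + 0.5, v1 / z.cell_km + 0.5
        )
        crossings[sel] += c
    return crossings == 0

def aggregate(
    segments: pd.DataFrame,
    sightings: pd.DataFrame,
    models: dict[str, DetectionModel],
    grid: Grid,
    cfg: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Sum effort-corrected searched area and whale counts per sampling unit.

    Each on-effort segment is clipped to grid cells; its swath area
    (length x 2 x (ESW - blind spot), with the platform/sea-state effective
    search width) is apportioned by in-cell track length and summed per
    cell x semimonth. Whale counts are sums of group sizes of on-effort
    sightings in the cell during the period. Units whose summed effort
    exceeds the configured outlier threshold (340 km2) are flagged excluded.

    Returns the sampling-unit table (one row per cell x season x semimonth
    with any effort or sightings) and a bookkeeping report.
    """
    cfg = cfg or PipelineConfig()
    season, ordinal = semimonth_key(segments["date"])

    # per-row swath half-width = ESW(platform, seastate) - blind spot
    half_width = np.empty(len(segments))
    for plat, model in models.items():
        sel = (segments["platform"] == plat).to_numpy()
        if not sel.any():
            continue
        ss = segments.loc[sel, "seastate"].astype(int).to_numpy()
        hw = np.array([model.esw(s) - model.blind_spot_km for s in ss])
        if np.any(hw <= 0):
            raise ValueError(f"ESW does not exceed blind spot for {plat}")
        half_width[sel] = hw

    x0 = segments["x0"].to_numpy(float)
    y0 = segments["y0"].to_numpy(float)
    x1 = segments["x1"].to_numpy(float)
    y1 = segments["y1"].to_numpy(float)
    single = _single_cell_mask(grid, x0, y0, x1, y1)

    rows: list[tuple] = []
    mx, my = 0.5 * (x0 + x1), 0.5 * (y0 + y1)
    lengths = np.hypot(x1 - x0, y1 - y0)
    cid_mid = grid.assign(mx[single], my[single])
    seas_arr, ord_arr = season.to_numpy(), ordinal.to_numpy()
    for cid, seas, sm, ln, hw in zip(
        cid_mid, seas_arr[single], ord_arr[single],
        lengths[single], half_width[single],
    ):
        if cid is not None:
            rows.append((cid, seas, sm, 2.0 * ln * hw))
    for i in np.nonzero(~single)[0]:
        for cid, ln in grid.clip_segment(x0[i], y0[i], x1[i], y1[i]):
            rows.append((cid, seas_arr[i], ord_arr[i], 2.0 * ln * half_width[i]))

    effort = (
        pd.DataFrame(rows, columns=["cell_id", "season", "semimonth", "area"])
        .groupby(["cell_id", "season", "semimonth"], as_index=False)["area"]
        .sum()
        .rename(columns={"area": "effort_km2"})
    )

    unassigned: list = []
    if len(sightings):
        s_season, s_ord = semimonth_key(sightings["date"])
        cid = grid.assign(sightings["x"].to_numpy(), sightings["y"].to_numpy())
        mask = pd.Series([c is not None for c in cid], index=sightings.index)
        unassigned = list(sightings.index[~mask])
        sig = pd.DataFrame(
            {
                "cell_id": cid[mask.to_numpy()],
                "season": s_season[mask],
                "semimonth": s_ord[mask],
                "whales": sightings.loc[mask, "group_size"].to_numpy(),
            }
        )
        counts = sig.groupby(
            ["cell_id", "season", "semimonth"], as_index=False
        ).agg(whales=("whales", "sum"), sightings=("whales", "size"))
    else:
        counts = pd.DataFrame(
            columns=["cell_id", "season", "semimonth", "whales", "sightings"]
        )

    units = effort.merge(counts, on=["cell_id", "season", "semimonth"],
                         how="outer")
    for col in ("effort_km2", "whales", "sightings"):
        units[col] = pd.to_numeric(units[col], errors="coerce").fillna(0.0)
    units["whales"] = units["whales"].astype(int)
    units["sightings"] = units["sightings"].astype(int)
    units["excluded"] = units["effort_km2"] > cfg.max_effort_km2
    units["exclude_reason"] = np.where(units["excluded"], "effort_outlier", "")

    centers = grid.centers()
    units = units.merge(centers, on="cell_id", how="left")
    units = units.sort_values(
        ["season", "semimonth", "cell_id"], ignore_index=True
    )
    report = {
        "units": int(len(units)),
        "units_excluded_effort": int(units["excluded"].sum()),
        "total_effort_km2": float(units["effort_km2"].sum()),
        "total_whales": int(units["whales"].sum()),
        "unassigned_sightings": unassigned,
    }
    return units, report
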