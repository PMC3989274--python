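"""Environmental covariates for sampling units.

Derives, per grid cell: mean bottom depth (m, positive down), mean bottom
slope (degrees, Horn 3x3 operator), distance from the cell centre to the
shoreline (km), semimonthly composited sea surface temperature (degC, mean of
cloud-free daily pixels), and signed distance to the 22 degC SST isotherm
(negative where the cell is on the warm -- Gulf Stream -- side).

Rasters are plain numpy arrays with an affine-free south-west anchored
geometry (square pixels, row 0 southernmost), matching the ESRI ASCII grid
interchange format written by :mod:`winterhab.io_utils`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely import contains_xy
from shapely.geometry import LineString, MultiLineString, Point
from skimage import measure

from winterhab.config import PipelineConfig
from winterhab.surveys import Grid, GridCell


@dataclass
class Raster:
    """A square-pixel raster anchored at its south-west corner."""

    x0: float  # west edge (km)
    y0: float  # south edge (km)
    pixel_km: float
    data: np.ndarray  # (ny, nx); np.nan = missing

    @property
    def nx(self) -> int:
        return self.data.shape[1]

    @property
    def ny(self) -> int:
        return self.data.shape[0]

    def xs(self) -> np.ndarray:
        return self.x0 + (np.arange(self.nx) + 0.5) * self.pixel_km

    def ys(self) -> np.ndarray:
        return self.y0 + (np.arange(self.ny) + 0.5) * self.pixel_km

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.xs(), self.ys())

    def same_geometry(self, other: "Raster") -> bool:
        return (
            self.data.shape == other.data.shape
            and self.x0 == other.x0
            and self.y0 == other.y0
            and self.pixel_km == other.pixel_km
        )

    def sample(self, x: float, y: float) -> float:
        """Nearest-pixel point sample (nan outside coverage)."""
        j = int(np.floor((x - self.x0) / self.pixel_km))
        i = int(np.floor((y - self.y0) / self.pixel_km))
        if 0 <= i < self.ny and 0 <= j < self.nx:
            return float(self.data[i, j])
        return float("nan")


@dataclass
class SSTComposite:
    """Semimonthly mean SST over cloud-free daily observations."""

    season: str
    semimonth: int
    raster: Raster
    n_images: int
    valid_count: np.ndarray  # per-pixel count of cloud-free observations


def _cell_pixels(raster: Raster, cell: GridCell) -> np.ndarray:
    """Boolean mask of pixels whose centres fall inside the cell polygon."""
    minx, miny, maxx, maxy = cell.polygon.bounds
    xs, ys = raster.xs(), raster.ys()
    jj = np.nonzero((xs > minx - raster.pixel_km) & (xs < maxx + raster.pixel_km))[0]
    ii = np.nonzero((ys > miny - raster.pixel_km) & (ys < maxy + raster.pixel_km))[0]
    mask = np.zeros(raster.data.shape, dtype=bool)
    if len(ii) == 0 or len(jj) == 0:
        return mask
    gx, gy = np.meshgrid(xs[jj], ys[ii])
    inside = contains_xy(cell.polygon, gx.ravel(), gy.ravel()).reshape(gx.shape)
    mask[np.ix_(ii, jj)] = inside
    return mask


def cell_depth(
    bathymetry: Raster, cell: GridCell, cfg: PipelineConfig | None = None
) -> tuple[float, bool, str]:
    """Mean in-cell depth (m, positive down) with a validity flag.

    Cells whose mean depth is above sea level or deeper than the configured
    maximum (70 m) are flagged invalid; cells with no covered pixels are
    missing.
    """
    cfg = cfg or PipelineConfig()
    mask = _cell_pixels(bathymetry, cell)
    vals = bathymetry.data[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return float("nan"), False, "no_coverage"
    mean = float(np.mean(vals))
    if mean <= 0:
        return mean, False, "above_sea_level"
    if mean > cfg.max_depth_m:
        return mean, False, f"depth>{cfg.max_depth_m:g}"
    return mean, True, ""


def horn_slope(bathymetry: Raster) -> Raster:
    """Per-pixel slope (degrees) via the Horn 3x3 finite-difference operator."""
    z = bathymetry.data
    if z.shape[0] < 2 or z.shape[1] < 2:
        raise ValueError("slope requires a grid of at least 2x2 pixels")
    zp = np.pad(z, 1, mode="edge")
    d = bathymetry.pixel_km * 1000.0  # metres
    a = zp[:-2, :-2]; b = zp[:-2, 1:-1]; c = zp[:-2, 2:]
    dd = zp[1:-1, :-2]; f = zp[1:-1, 2:]
    g = zp[2:, :-2]; h = zp[2:, 1:-1]; i = zp[2:, 2:]
    dzdx = ((c + 2 * f + i) - (a + 2 * dd + g)) / (8.0 * d)
    dzdy = ((g + 2 * h + i) - (a + 2 * b + c)) / (8.0 * d)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    return Raster(bathymetry.x0, bathymetry.y0, bathymetry.pixel_km, slope)


def cell_slope(bathymetry: Raster, cell: GridCell) -> float:
    """Mean in-cell slope (degrees)."""
    slope = horn_slope(bathymetry)
    mask = _cell_pixels(slope, cell)
    vals = slope.data[mask]
    vals = vals[np.isfinite(vals)]
    return float(np.mean(vals)) if vals.size else float("nan")


def distance_to_shore(x: float, y: float, shoreline: LineString) -> float:
    """Minimum Euclidean distance (km) from a point to the shoreline polyline."""
    if shoreline.is_empty:
        raise ValueError("empty shoreline")
    return float(Point(x, y).distance(shoreline))


def composite_sst(
    stack: np.ndarray,
    cloud_mask: np.ndarray,
    geometry: Raster,
    season: str,
    semimonth: int,
) -> SSTComposite:
    """Per-pixel mean SST over cloud-free daily observations.

    ``stack`` is (n_days, ny, nx); ``cloud_mask`` the same shape with True
    marking cloud-interfered pixels. Pixels with zero cloud-free observations
    are missing (NaN), never zero.
    """
    if stack.ndim != 3 or stack.shape != cloud_mask.shape:
        raise ValueError("stack and cloud mask shapes differ")
    if stack.shape[1:] != geometry.data.shape:
        raise ValueError("stack geometry mismatch")
    if stack.shape[0] < 1:
        raise ValueError("need at least one daily image")
    vals = np.where(cloud_mask, np.nan, stack)
    count = np.sum(~cloud_mask, axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, np.nansum(vals, axis=0) / np.maximum(count, 1),
                        np.nan)
    return SSTComposite(
        season, semimonth,
        Raster(geometry.x0, geometry.y0, geometry.pixel_km, mean),
        stack.shape[0], count,
    )


def cell_sst(composite: SSTComposite, cell: GridCell) -> float:
    """Mean of non-missing composite pixels in the cell (nan if all missing)."""
    mask = _cell_pixels(composite.raster, cell)
    vals = composite.raster.data[mask]
    vals = vals[np.isfinite(vals)]
    return float(np.mean(vals)) if vals.size else float("nan")


def isotherm_contours(
    composite: SSTComposite, level: float = 22.0
) -> MultiLineString | None:
    """Extract the SST isotherm by marching squares with linear interpolation.

    Returns None when the level is not crossed anywhere in the (non-missing)
    field. Contour vertices lie on pixel-centre grid edges where the
    interpolated SST equals the level.
    """
    r = composite.raster
    contours = measure.find_contours(r.data, level)
    lines = []
    for c in contours:
        if len(c) < 2:
            continue
        # (row, col) index space -> km
        xs = r.x0 + (c[:, 1] + 0.5) * r.pixel_km
        ys = r.y0 + (c[:, 0] + 0.5) * r.pixel_km
        lines.append(LineString(np.column_stack([xs, ys])))
    if not lines:
        return None
    return MultiLineString(lines)


def isotherm_distance(
    composite: SSTComposite,
    cell: GridCell,
    level: float = 22.0,
    contours: MultiLineString | None = None,
    sst_value: float | None = None,
) -> float:
    """Signed distance (km) from the cell centre to the SST isotherm.

    Negative where the cell's SST exceeds the isotherm level (east/south of
    the isotherm, i.e. the warm Gulf Stream side); non-negative at exactly the
    level. NaN when the cell SST is missing or no isotherm exists in the
    domain.
    """
    if contours is None:
        contours = isotherm_contours(composite, level)
    if contours is None:
        return float("nan")
    sst = cell_sst(composite, cell) if sst_value is None else sst_value
    if not np.isfinite(sst):
        return float("nan")
    d = float(Point(cell.center).distance(contours))
    return -d if sst > level else d


# ---------------------------------------------------------------------------
# Batch covariate table
# ---------------------------------------------------------------------------

def covariate_table(
    bathymetry: Raster,
    shoreline: LineString,
    composites: list[SSTComposite],
    grid: Grid,
    cfg: PipelineConfig | None = None,
) -> pd.DataFrame:
    """One row per cell x season x semimonth with all model covariates.

    Static covariates (depth, slope, distance to shore, northing) repeat
    across periods; SST and isotherm distance come from each period's
    composite. Cells failing the depth rule or with missing SST carry an
    ``exclude_reason``.
    """
    cfg = cfg or PipelineConfig()
    slope_raster = horn_slope(bathymetry)

    static_rows = []
    for cell in grid.cells:
        depth, valid, reason = cell_depth(bathymetry, cell, cfg)
        mask = _cell_pixels(slope_raster, cell)
        svals = slope_raster.data[mask]
        svals = svals[np.isfinite(svals)]
        static_rows.append(
            {
                "cell_id": cell.cell_id,
                "depth_m": depth,
                "depth_valid": valid,
                "depth_reason": reason,
                "slope_deg": float(np.mean(svals)) if svals.size else np.nan,
                "dist_to_shore_km": distance_to_shore(*cell.center, shoreline),
                "easting": cell.center[0],
                "northing": cell.center[1],
            }
        )
    static = pd.DataFrame(static_rows)

    # composites share one raster geometry; cache in-cell pixel masks
    pixmask: dict[str, np.ndarray] = {}
    if composites:
        geom = composites[0].raster
        for comp in composites:
            if not comp.raster.same_geometry(geom):
                raise ValueError("composites have mismatched raster geometry")
        pixmask = {c.cell_id: _cell_pixels(geom, c) for c in grid.cells}

    rows = []
    for comp in composites:
        contours = isotherm_contours(comp, cfg.isotherm_c)
        for cell in grid.cells:
            vals = comp.raster.data[pixmask[cell.cell_id]]
            vals = vals[np.isfinite(vals)]
            sst = float(np.mean(vals)) if vals.size else float("nan")
            iso = isotherm_distance(
                comp, cell, cfg.isotherm_c, contours=contours, sst_value=sst
            ) if contours is not None else float("nan")
            rows.append(
                {
                    "cell_id": cell.cell_id,
                    "season": comp.season,
                    "semimonth": comp.semimonth,
                    "sst_c": sst,
                    "dist_to_22iso_km": iso,
                }
            )
    dynamic = pd.DataFrame(rows)
    out = dynamic.merge(static, on="cell_id", how="left")

    reason = np.where(~out["depth_valid"], out["depth_reason"], "")
    missing_sst = ~np.isfinite(out["sst_c"])
    reason = np.where(
        missing_sst, np.where(reason == "", "missing_SST", reason), reason
    )
    missing_iso = np.isfinite(out["sst_c"]) & ~np.isfinite(out["dist_to_22iso_km"])
    reason = np.where(
        missing_iso, np.where(reason == "", "missing_isotherm", reason), reason
    )
    out["exclude_reason"] = reason
    out["covariates_ok"] = reason == ""
    return out
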