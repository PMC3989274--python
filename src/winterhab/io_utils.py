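"""Readers, writers and run reporting.

Tabular interchange is CSV with documented schemas (matching the synthetic
generator's outputs), vector geometry is GeoJSON, rasters are ESRI ASCII
grids, configuration is YAML, and run reports are JSON plus a human-readable
text rendering with per-stage row accounting.
"""

from __future__ import annotations

import json
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import LineString

from winterhab.enviro import Raster

SEGMENT_COLUMNS = {
    "survey_id": str, "date": str, "platform": str,
    "x0": float, "y0": float, "x1": float, "y1": float,
    "seastate": int, "altitude_m": float, "visibility_km": float,
    "status": str, "is_verification": bool,
}
SIGHTING_COLUMNS = {
    "sighting_id": str, "survey_id": str, "date": str,
    "x": float, "y": float, "group_size": int, "calf_present": bool,
    "perp_distance_km": float, "platform": str, "seastate": int,
    "is_duplicate": bool, "is_verification": bool,
    "initial_status_on_effort": bool,
}


def derive_seed(seed: int, label: str) -> int:
    """Stable sub-seed for a named pipeline stage (single seeded hierarchy)."""
    return (seed * 1000003 + zlib.crc32(label.encode())) % (2 ** 31)


# ---------------------------------------------------------------------------
# Survey tables
# ---------------------------------------------------------------------------

def _read_table(path: str, schema: dict) -> tuple[pd.DataFrame, list[dict]]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if len(df) == 0:
        import warnings
        warnings.warn(f"{path}: empty table")
        return pd.DataFrame(columns=list(schema)), []
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")
    bad_rows: list[dict] = []
    out = {}
    ok = np.ones(len(df), dtype=bool)
    for col, typ in schema.items():
        raw = df[col]
        if typ is bool:
            vals = raw.str.lower().map(
                {"true": True, "false": False, "1": True, "0": False}
            )
            fail = vals.isna()
        elif typ in (int, float):
            vals = pd.to_numeric(raw, errors="coerce")
            fail = vals.isna()
            if typ is int:
                vals = vals.astype("Int64")
        elif col == "date":
            vals = pd.to_datetime(raw, errors="coerce", format="%Y-%m-%d")
            fail = vals.isna()
            vals = vals.dt.strftime("%Y-%m-%d")
        else:
            vals = raw
            fail = pd.Series(False, index=df.index)
        for i in df.index[fail]:
            bad_rows.append({"row": int(i), "column": col,
                             "value": str(raw.iloc[i])})
        ok &= ~fail.to_numpy()
        out[col] = vals
    clean = pd.DataFrame(out).loc[ok].reset_index(drop=True)
    for col, typ in schema.items():
        if typ is int:
            clean[col] = clean[col].astype(int)
        elif typ is float:
            clean[col] = clean[col].astype(float)
        elif typ is bool:
            clean[col] = clean[col].astype(bool)
    return clean, bad_rows


def read_survey_tables(segments_path: str, sightings_path: str
                       ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Typed segment and sighting tables; malformed rows are collected in the
    report, never silently dropped."""
    segments, bad_seg = _read_table(segments_path, SEGMENT_COLUMNS)
    sightings, bad_sig = _read_table(sightings_path, SIGHTING_COLUMNS)
    report = {
        "segments_parsed": int(len(segments)),
        "segments_bad_rows": bad_seg,
        "sightings_parsed": int(len(sightings)),
        "sightings_bad_rows": bad_sig,
    }
    return segments, sightings, report


def write_survey_tables(segments: pd.DataFrame, sightings: pd.DataFrame,
                        segments_path: str, sightings_path: str) -> None:
    segments[list(SEGMENT_COLUMNS)].to_csv(segments_path, index=False)
    cols = [c for c in SIGHTING_COLUMNS if c in sightings.columns]
    sightings[cols].to_csv(sightings_path, index=False)


# ---------------------------------------------------------------------------
# Rasters (ESRI ASCII grid) and GeoJSON
# ---------------------------------------------------------------------------

def write_ascii_grid(raster: Raster, path: str, nodata: float = -9999.0
                     ) -> None:
    data = np.where(np.isfinite(raster.data), raster.data, nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.nx}\n")
        fh.write(f"nrows {raster.ny}\n")
        fh.write(f"xllcorner {raster.x0}\n")
        fh.write(f"yllcorner {raster.y0}\n")
        fh.write(f"cellsize {raster.pixel_km}\n")
        fh.write(f"NODATA_value {nodata}\n")
        # ASCII grids store the top row first
        for row in data[::-1]:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


def read_ascii_grid(path: str) -> Raster:
    header: dict[str, float] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0].lower() in {"ncols", "nrows", "xllcorner",
                                    "yllcorner", "cellsize", "nodata_value"}:
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    data = np.array(rows)[::-1]
    nodata = header.get("nodata_value")
    if nodata is not None:
        data = np.where(data == nodata, np.nan, data)
    return Raster(header["xllcorner"], header["yllcorner"],
                  header["cellsize"], data)


def shoreline_to_geojson(shoreline: LineString) -> dict:
    return {
        "type": "FeatureCollection",
        "features": [{
            "type": "Feature",
            "properties": {"name": "shoreline"},
            "geometry": {
                "type": "LineString",
                "coordinates": [list(c) for c in shoreline.coords],
            },
        }],
    }


def write_geojson(obj: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh)


# ---------------------------------------------------------------------------
# Run report
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    return obj


def write_report(stages: dict, json_path: str, text_path: str | None = None
                 ) -> None:
    """Single structured run report: machine-readable JSON plus text."""
    payload = _jsonable(stages)
    Path(json_path).write_text(json.dumps(payload, indent=2, sort_keys=True))
    if text_path is not None:
        lines = []
        for stage, content in payload.items():
            lines.append(f"== {stage} ==")
            lines.append(json.dumps(content, indent=2, sort_keys=True))
            lines.append("")
        Path(text_path).write_text("\n".join(lines))
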