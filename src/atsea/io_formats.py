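"""Domain types, CSV readers/writers and per-bird derived quantities.

Tabular data are carried as pandas DataFrames with fixed column schemas:

``gps``          : bird_id (str), t (int64 epoch s), lat, lon (WGS84 degrees)
``tdr``          : bird_id, t, depth (m, >= 0 after correction), wet (bool)
``deployments``  : bird_id, colony_id, stage, clutch, sex, mass (g),
                   flipper (mm), nest_lat, nest_lon, colony_lat, colony_lon

Timestamps are normalised to integer epoch seconds on ingestion; sub-second
precision is discarded (loggers sample at >= 2 s intervals).  Duplicate
(bird, t) rows keep the first occurrence.  All distances are great-circle
distances on a sphere — sub-metre geodesic accuracy is irrelevant at the
500-m scale of the association criterion.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: mean Earth radius in metres (IUGG)
EARTH_RADIUS_M = 6_371_008.8

GPS_COLUMNS = ["bird_id", "t", "lat", "lon"]
TDR_COLUMNS = ["bird_id", "t", "depth", "wet"]
DEPLOYMENT_COLUMNS = [
    "bird_id", "colony_id", "stage", "clutch", "sex",
    "mass", "flipper", "nest_lat", "nest_lon", "colony_lat", "colony_lon",
]


class FormatError(ValueError):
    """A CSV file does not match the expected schema."""


class RowError(ValueError):
    """A row of an input file could not be parsed; carries the line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message if line is None else f"line {line}: {message}")
        self.line = line


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")


def parse_timestamps(values: pd.Series) -> pd.Series:
    """Parse ISO-8601 strings or epoch seconds to integer epoch seconds.

    Raises :class:`RowError` naming the first offending row (1-based data
    line, header excluded) on failure.
    """
    numeric = pd.to_numeric(values, errors="coerce")
    if numeric.notna().all():
        return numeric.astype(np.int64)
    parsed = pd.to_datetime(values, errors="coerce", utc=True, format="ISO8601")
    bad = parsed.isna() & numeric.isna()
    if bad.any():
        idx = int(np.flatnonzero(bad.to_numpy())[0])
        raise RowError(f"unparseable timestamp {values.iloc[idx]!r}", line=idx + 1)
    # mixed numeric/ISO inputs: prefer the per-row successful parse
    epoch = parsed.astype("int64") // 10**9
    out = numeric.where(numeric.notna(), epoch)
    return out.astype(np.int64)


def _sort_dedupe(df: pd.DataFrame) -> pd.DataFrame:
    n = len(df)
    df = df.drop_duplicates(subset=["bird_id", "t"], keep="first")
    if len(df) < n:
        logger.info("dropped %d duplicate (bird, t) rows", n - len(df))
    return df.sort_values(["bird_id", "t"], kind="mergesort").reset_index(drop=True)


def read_gps_csv(path) -> pd.DataFrame:
    """Read GPS fixes; returns the ``gps`` schema, per-bird time-sorted."""
    raw = pd.read_csv(path, dtype={"bird_id": str})
    _require_columns(raw, ["bird_id", "timestamp", "lat", "lon"], path)
    df = pd.DataFrame(
        {
            "bird_id": raw["bird_id"],
            "t": parse_timestamps(raw["timestamp"]) if len(raw) else
                pd.Series([], dtype=np.int64),
            "lat": raw["lat"].astype(float),
            "lon": raw["lon"].astype(float),
        }
    )
    if ((df["lat"].abs() > 90) | (df["lon"] <= -180) | (df["lon"] > 180)).any():
        raise RowError("coordinate outside WGS84 domain")
    return _sort_dedupe(df)


def _parse_wet(values: pd.Series) -> pd.Series:
    mapping = {"0": False, "1": True, "true": True, "false": False}
    s = values.astype(str).str.strip().str.lower().map(mapping)
    if s.isna().any():
        idx = int(np.flatnonzero(s.isna().to_numpy())[0])
        raise RowError(f"unparseable wet flag {values.iloc[idx]!r}", line=idx + 1)
    return s.astype(bool)


def read_tdr_csv(path, interval: int = 4) -> pd.DataFrame:
    """Read TDR samples; returns the ``tdr`` schema.

    Depths below -1 m raise a row-level error; mild negatives (sensor noise)
    are clamped to 0.  Irregular sampling (per-bird spacing differing from
    ``interval``) is logged as a warning, one per gap.
    """
    raw = pd.read_csv(path, dtype={"bird_id": str})
    _require_columns(raw, ["bird_id", "timestamp", "depth", "wet"], path)
    if len(raw) == 0:
        return pd.DataFrame({
            "bird_id": pd.Series([], dtype=str),
            "t": pd.Series([], dtype=np.int64),
            "depth": pd.Series([], dtype=float),
            "wet": pd.Series([], dtype=bool),
        })
    depth = raw["depth"].astype(float)
    if (depth < -1.0).any():
        idx = int(np.flatnonzero((depth < -1.0).to_numpy())[0])
        raise RowError(f"depth {depth.iloc[idx]} m below tolerance", line=idx + 1)
    df = pd.DataFrame(
        {
            "bird_id": raw["bird_id"],
            "t": parse_timestamps(raw["timestamp"]),
            "depth": depth.clip(lower=0.0),
            "wet": _parse_wet(raw["wet"]),
        }
    )
    df = _sort_dedupe(df)
    for bird, grp in df.groupby("bird_id", sort=False):
        gaps = np.diff(grp["t"].to_numpy())
        irregular = int((gaps != interval).sum())
        if irregular:
            logger.warning(
                "bird %s: %d irregular sampling interval(s)", bird, irregular
            )
    return df


def read_deployments_csv(path, mass_unit: str = "g") -> pd.DataFrame:
    """Read deployment metadata; ``mass_unit`` in {"g", "kg"}.

    Field balances read kilograms; masses are stored in grams internally.
    """
    raw = pd.read_csv(path, dtype={"bird_id": str, "colony_id": str})
    _require_columns(raw, DEPLOYMENT_COLUMNS, path)
    df = raw[DEPLOYMENT_COLUMNS].copy()
    if mass_unit == "kg":
        df["mass"] = df["mass"].astype(float) * 1000.0
    elif mass_unit != "g":
        raise ValueError(f"unknown mass unit {mass_unit!r}")
    df["mass"] = df["mass"].astype(float)
    df["flipper"] = df["flipper"].astype(float)
    df["clutch"] = df["clutch"].astype(int)
    if (df["mass"] <= 0).any() or (df["flipper"] <= 0).any():
        raise RowError("non-positive mass or flipper length")
    return df.reset_index(drop=True)


def write_gps_csv(df: pd.DataFrame, path) -> None:
    """Write fixes back out in the reader's dialect (RFC-4180)."""
    out = df.rename(columns={"t": "timestamp"})[["bird_id", "timestamp", "lat", "lon"]]
    out.to_csv(path, index=False, lineterminator="\n")


def write_tdr_csv(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["wet"] = out["wet"].astype(int)
    out = out.rename(columns={"t": "timestamp"})[["bird_id", "timestamp", "depth", "wet"]]
    out.to_csv(path, index=False, lineterminator="\n")


def condition_index(mass_g, flipper_mm):
    """Body Condition Index: body mass divided by flipper length (g/mm)."""
    mass_g = np.asarray(mass_g, dtype=float)
    flipper_mm = np.asarray(flipper_mm, dtype=float)
    if (mass_g <= 0).any() or (flipper_mm <= 0).any():
        raise ValueError("mass and flipper length must be strictly positive")
    out = mass_g / flipper_mm
    return float(out) if out.ndim == 0 else out


def haversine_m(lat1, lon1, lat2, lon2):
    """Great-circle distance in metres on a sphere of radius 6 371 008.8 m.

    Accepts scalars or broadcastable arrays of decimal degrees.
    """
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_M * np.arcsin(np.minimum(1.0, np.sqrt(a)))
    return float(d) if d.ndim == 0 else d


def tracks_to_geojson(tracks: pd.DataFrame) -> dict:
    """Export interpolated tracks as a GeoJSON FeatureCollection.

    One LineString feature per (bird, trip).
    """
    features = []
    for (bird, trip), grp in tracks.groupby(["bird_id", "trip_index"]):
        coords = [[float(x), float(y)] for x, y in zip(grp["lon"], grp["lat"])]
        features.append(
            {
                "type": "Feature",
                "properties": {"bird_id": str(bird), "trip_index": int(trip)},
                "geometry": {"type": "LineString", "coordinates": coords},
            }
        )
    return {"type": "FeatureCollection", "features": features}
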