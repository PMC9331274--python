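"""Readers and writers for the standard interchange formats.

Three CSV schemas (``water_points.csv``, ``epi_samples.csv``,
``env_surveys.csv``) persist a full study; GeoJSON and ESRI shapefile exports
carry the point layer (and derived layers such as proportional symbols and
heatmap cells) into downstream GIS tools. All writers are deterministic —
fixed field order, fixed float formatting — so identical stores produce
byte-identical files.

CSV dialect: UTF-8, comma-delimited, mandatory header row, ISO-8601 dates.
Coordinates are written with six decimal places (≈0.1 m); every other float is
written with ``repr`` so values round-trip exactly and
``read_study_csv(write_study_csv(store)) == store``.
"""

from __future__ import annotations

import csv
import json
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from ._esri import write_point_shapefile
from .core_model import (
    Category,
    EnvSurvey,
    EpiSample,
    StudyStore,
    ValidationError,
    WaterPoint,
)
from .geoviz import HeatmapGrid, SymbolSpec

__all__ = [
    "WATER_POINT_FIELDS",
    "EPI_SAMPLE_FIELDS",
    "ENV_SURVEY_FIELDS",
    "read_study_csv",
    "write_study_csv",
    "write_geojson",
    "write_shapefile",
    "point_features",
    "symbol_features",
    "heatmap_features",
    "write_ascii_grid",
    "export_bundle",
]

WATER_POINT_FIELDS = ("point_id", "neighborhood", "category", "lon", "lat", "address", "image_ref")
EPI_SAMPLE_FIELDS = (
    "point_id", "sample_date", "fc_count", "temperature", "turbidity",
    "tds", "ph", "do_mgl", "salinity", "image_ref",
)
ENV_SURVEY_FIELDS = ("point_id", "survey_date", "mud", "water", "trash", "activity", "image_ref")

WATER_POINTS_CSV = "water_points.csv"
EPI_SAMPLES_CSV = "epi_samples.csv"
ENV_SURVEYS_CSV = "env_surveys.csv"


# --------------------------------------------------------------------------
# CSV
# --------------------------------------------------------------------------

def _fmt_number(v) -> str:
    """Exact-roundtrip numeric formatting; integral floats print as ints."""
    if v is None:
        return ""
    if isinstance(v, int) or (isinstance(v, float) and v.is_integer()):
        return str(int(v))
    return repr(float(v))


def _parse_float(raw: str, column: str, row_num: int, fname: str) -> Optional[float]:
    if raw == "":
        return None
    try:
        return float(raw)
    except ValueError:
        raise ValidationError(
            column, f"{fname} row {row_num}: cannot parse {raw!r} as a number"
        ) from None


def _open_rows(path: Path, required: Sequence[str]):
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in required if c not in header]
        if missing:
            raise ValidationError(
                missing[0], f"{path.name}: missing required column {missing[0]!r}"
            )
        yield from ((i, row) for i, row in enumerate(reader, start=2))


def read_study_csv(directory: "str | Path") -> StudyStore:
    """Load a study from the three schema CSVs in ``directory``.

    ``water_points.csv`` is required; the two record tables are optional
    (a points-only study is valid). Validation failures name the offending
    column, file and row.
    """
    directory = Path(directory)
    store = StudyStore()

    wp_path = directory / WATER_POINTS_CSV
    if not wp_path.exists():
        raise FileNotFoundError(f"{wp_path}: water point table is required")
    for row_num, row in _open_rows(wp_path, WATER_POINT_FIELDS):
        try:
            store.add_water_point(
                WaterPoint(
                    point_id=row["point_id"],
                    neighborhood=row["neighborhood"],
                    category=row["category"],
                    lon=float(row["lon"]),
                    lat=float(row["lat"]),
                    address=row.get("address") or "",
                    image_ref=row.get("image_ref") or "",
                )
            )
        except ValueError as exc:
            raise ValidationError(
                "lon/lat", f"{wp_path.name} row {row_num}: {exc}"
            ) from None

    epi_path = directory / EPI_SAMPLES_CSV
    if epi_path.exists():
        for row_num, row in _open_rows(epi_path, ("point_id", "sample_date", "fc_count")):
            fc = _parse_float(row["fc_count"], "fc_count", row_num, epi_path.name)
            if fc is None or fc < 0:
                raise ValidationError(
                    "fc_count",
                    f"{epi_path.name} row {row_num}: fc_count must be a number >= 0, "
                    f"got {row['fc_count']!r}",
                )
            try:
                sample = EpiSample(
                    point_id=row["point_id"],
                    sample_date=row["sample_date"],
                    fc_count=fc,
                    temperature=_parse_float(row.get("temperature", ""), "temperature", row_num, epi_path.name),
                    turbidity=_parse_float(row.get("turbidity", ""), "turbidity", row_num, epi_path.name),
                    tds=_parse_float(row.get("tds", ""), "tds", row_num, epi_path.name),
                    ph=_parse_float(row.get("ph", ""), "ph", row_num, epi_path.name),
                    do_mgl=_parse_float(row.get("do_mgl", ""), "do_mgl", row_num, epi_path.name),
                    salinity=_parse_float(row.get("salinity", ""), "salinity", row_num, epi_path.name),
                    image_ref=row.get("image_ref") or "",
                )
            except ValidationError as exc:
                raise ValidationError(
                    exc.field_name, f"{epi_path.name} row {row_num}: {exc}"
                ) from None
            store.add_epi_sample(sample)

    env_path = directory / ENV_SURVEYS_CSV
    if env_path.exists():
        for row_num, row in _open_rows(env_path, ("point_id", "survey_date", "mud", "water", "trash", "activity")):
            try:
                survey = EnvSurvey(
                    point_id=row["point_id"],
                    survey_date=row["survey_date"],
                    mud=int(row["mud"]),
                    water=int(row["water"]),
                    trash=int(row["trash"]),
                    activity=int(row["activity"]),
                    image_ref=row.get("image_ref") or "",
                )
            except (ValueError, ValidationError) as exc:
                name = exc.field_name if isinstance(exc, ValidationError) else "mud/water/trash/activity"
                raise ValidationError(
                    name, f"{env_path.name} row {row_num}: {exc}"
                ) from None
            store.add_env_survey(survey)

    return store


def write_study_csv(store: StudyStore, directory: "str | Path") -> list[Path]:
    """Write the three schema CSVs; returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    wp_path = directory / WATER_POINTS_CSV
    with open(wp_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(WATER_POINT_FIELDS)
        for p in store.water_points:
            w.writerow([
                p.point_id, p.neighborhood, p.category.value,
                f"{p.lon:.6f}", f"{p.lat:.6f}", p.address, p.image_ref,
            ])

    epi_path = directory / EPI_SAMPLES_CSV
    with open(epi_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(EPI_SAMPLE_FIELDS)
        for s in store.epi_samples:
            w.writerow([
                s.point_id, s.sample_date.isoformat(), _fmt_number(s.fc_count),
                _fmt_number(s.temperature), _fmt_number(s.turbidity),
                _fmt_number(s.tds), _fmt_number(s.ph), _fmt_number(s.do_mgl),
                _fmt_number(s.salinity), s.image_ref,
            ])

    env_path = directory / ENV_SURVEYS_CSV
    with open(env_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(ENV_SURVEY_FIELDS)
        for e in store.env_surveys:
            w.writerow([
                e.point_id, e.survey_date.isoformat(),
                e.mud, e.water, e.trash, e.activity, e.image_ref,
            ])

    return [wp_path, epi_path, env_path]


# --------------------------------------------------------------------------
# GeoJSON
# --------------------------------------------------------------------------

def point_features(points: Iterable[WaterPoint]) -> list[dict]:
    """GeoJSON Features (coordinates [lon, lat]) for water points."""
    return [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [p.lon, p.lat]},
            "properties": {
                "point_id": p.point_id,
                "neighborhood": p.neighborhood,
                "category": p.category.value,
                "address": p.address,
                "image_ref": p.image_ref,
            },
        }
        for p in points
    ]


def symbol_features(symbols: Iterable[SymbolSpec]) -> list[dict]:
    """GeoJSON Features for proportional symbols (radius/fill as properties)."""
    return [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [s.lon, s.lat]},
            "properties": {
                "point_id": s.point_id,
                "value": s.value,
                "radius_px": s.radius_px,
                "fill": s.fill,
            },
        }
        for s in symbols
    ]


def heatmap_features(grid: HeatmapGrid, min_intensity: float = 0.0) -> list[dict]:
    """GeoJSON polygon Features for heatmap cells above ``min_intensity``."""
    lon_min, lat_min, lon_max, lat_max = grid.bounds
    nrows, ncols = grid.shape
    dlon = (lon_max - lon_min) / ncols
    dlat = (lat_max - lat_min) / nrows
    feats = []
    for r in range(nrows):
        lat_top = lat_max - r * dlat
        lat_bot = lat_top - dlat
        for c in range(ncols):
            val = float(grid.intensity[r, c])
            if val <= min_intensity:
                continue
            lon_l = lon_min + c * dlon
            lon_r = lon_l + dlon
            ring = [
                [lon_l, lat_bot], [lon_r, lat_bot], [lon_r, lat_top],
                [lon_l, lat_top], [lon_l, lat_bot],
            ]
            feats.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Polygon", "coordinates": [ring]},
                    "properties": {
                        "row": r, "col": c, "period": grid.period, "intensity": val,
                    },
                }
            )
    return feats


def write_geojson(features: Sequence[dict], path: "str | Path") -> Path:
    """Write a FeatureCollection; deterministic key order and formatting."""
    path = Path(path)
    doc = {"type": "FeatureCollection", "features": list(features)}
    path.write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n", encoding="utf-8")
    return path


# --------------------------------------------------------------------------
# Shapefile
# --------------------------------------------------------------------------

def _feature_records(features: Sequence[dict]) -> list[tuple[float, float, dict]]:
    recs = []
    for f in features:
        geom = f.get("geometry") or {}
        if geom.get("type") != "Point":
            raise ValidationError(
                "geometry", f"shapefile export supports point layers only, got {geom.get('type')!r}"
            )
        lon, lat = geom["coordinates"]
        recs.append((float(lon), float(lat), dict(f.get("properties") or {})))
    return recs


def write_shapefile(features: Sequence[dict], base_path: "str | Path") -> list[Path]:
    """Write a GeoJSON-style point Feature list as an ESRI shapefile.

    Produces .shp/.shx/.dbf/.prj with WGS84 in the .prj; attribute names are
    truncated to the 10-character DBF limit with deterministic de-duplication,
    and dates are encoded as YYYYMMDD strings.
    """
    return write_point_shapefile(_feature_records(features), base_path)


# --------------------------------------------------------------------------
# ASCII raster
# --------------------------------------------------------------------------

def write_ascii_grid(grid: HeatmapGrid, path: "str | Path") -> Path:
    """Write a heatmap as an ASCII-grid-style text raster.

    Header lines carry the grid geometry (corner in lon/lat degrees, cell size
    in meters — the grid lives in the local metric projection); data rows run
    north to south, matching the in-memory row order.
    """
    path = Path(path)
    nrows, ncols = grid.shape
    lon_min, lat_min, _, _ = grid.bounds
    lines = [
        f"ncols {ncols}",
        f"nrows {nrows}",
        f"xllcorner_lon {lon_min:.6f}",
        f"yllcorner_lat {lat_min:.6f}",
        f"cellsize_m {grid.cell_size_m:g}",
        f"bandwidth_m {grid.bandwidth_m:g}",
        f"period {grid.period}",
        "NODATA_value -1",
    ]
    for row in grid.intensity:
        lines.append(" ".join(f"{v:.8g}" for v in row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


# --------------------------------------------------------------------------
# Bundled export
# --------------------------------------------------------------------------

def export_bundle(store: StudyStore, directory: "str | Path", fmt: str = "csv") -> list[Path]:
    """Export the study for downstream GIS use.

    ``csv`` writes the three schema tables; ``geojson`` and ``shapefile``
    additionally write the water-point layer in that spatial format.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = write_study_csv(store, directory)
    if fmt == "csv":
        pass
    elif fmt == "geojson":
        paths.append(write_geojson(point_features(store.water_points), directory / "water_points.geojson"))
    elif fmt == "shapefile":
        paths.extend(write_shapefile(point_features(store.water_points), directory / "water_points.shp"))
    else:
        raise ValidationError("format", f"unknown export format {fmt!r}; use csv, geojson or shapefile")
    return paths
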