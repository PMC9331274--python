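"""Minimal ESRI shapefile writer for 2-D point layers.

Writes the four sidecar files (.shp geometry, .shx index, .dbf attribute
table, .prj CRS) for a WGS84 point layer. Only writing is supported, and only
points — that is all the exporter needs. Output is deterministic: field order
is fixed by the caller, the DBF "last updated" header date is a constant, and
numeric formatting is fixed-width.

DBF constraints honored here:
* field names are at most 10 bytes; longer names are truncated with a
  deterministic ``_1``, ``_2`` ... de-duplication suffix;
* character fields are left-justified space-padded, numeric fields
  right-justified;
* dates are encoded as ``YYYYMMDD`` character strings.
"""

from __future__ import annotations

import struct
from datetime import date
from pathlib import Path
from typing import Sequence

from .core_model import ValidationError

__all__ = ["dedup_field_names", "write_point_shapefile", "WGS84_WKT"]

WGS84_WKT = (
    'GEOGCS["GCS_WGS_1984",DATUM["D_WGS_1984",'
    'SPHEROID["WGS_1984",6378137.0,298.257223563]],'
    'PRIMEM["Greenwich",0.0],UNIT["Degree",0.0174532925199433]]'
)

# Fixed DBF header date so identical layers serialize byte-identically.
_DBF_STAMP = (2022, 1, 1)


def dedup_field_names(names: Sequence[str]) -> list[str]:
    """Truncate field names to 10 characters, de-duplicating collisions.

    The first name to claim a 10-character form keeps it; later collisions
    get ``_1``, ``_2``, ... suffixes (``_10`` and beyond shorten the stem
    further). More than 99 collisions on one stem is an error.
    """
    out: list[str] = []
    taken: set[str] = set()
    for name in names:
        candidate = name[:10]
        if candidate in taken:
            for i in range(1, 100):
                suffix = f"_{i}"
                candidate = name[: 10 - len(suffix)] + suffix
                if candidate not in taken:
                    break
            else:
                raise ValidationError(
                    "field", f"cannot de-duplicate field name {name!r} (>99 collisions)"
                )
        taken.add(candidate)
        out.append(candidate)
    return out


def _field_descriptor(values: list) -> tuple[str, int, int]:
    """Infer (type, width, decimals) for one DBF column."""
    present = [v for v in values if v is not None]
    if any(isinstance(v, date) for v in present):
        return "C", 8, 0
    if all(isinstance(v, bool) for v in present) and present:
        return "C", 5, 0
    if present and all(isinstance(v, (int, float)) for v in present):
        if all(isinstance(v, int) or float(v).is_integer() for v in present):
            return "N", 18, 0
        return "N", 19, 6
    width = max([len(str(v)) for v in present], default=1)
    return "C", max(1, min(254, width)), 0


def _format_value(v, ftype: str, width: int, dec: int) -> bytes:
    if v is None:
        return b" " * width
    if isinstance(v, date):
        s = f"{v.year:04d}{v.month:02d}{v.day:02d}"
    elif ftype == "N":
        s = f"{float(v):.{dec}f}" if dec else f"{int(v):d}"
        return s.rjust(width).encode("ascii")[:width]
    else:
        s = str(v)
    return s.encode("utf-8")[:width].ljust(width)


def write_point_shapefile(
    records: Sequence[tuple[float, float, dict]], base_path: "str | Path"
) -> list[Path]:
    """Write ``(lon, lat, properties)`` records as a WGS84 point shapefile.

    ``base_path`` may end in ``.shp`` or be extensionless; returns the paths
    of the four files written (.shp, .shx, .dbf, .prj).
    """
    base = Path(base_path)
    if base.suffix == ".shp":
        base = base.with_suffix("")
    if not records:
        raise ValidationError("records", "cannot write an empty shapefile layer")

    lons = [r[0] for r in records]
    lats = [r[1] for r in records]

    # --- .shp / .shx ------------------------------------------------------
    # 100-byte header; per record: 8-byte record header + 20-byte point body.
    n = len(records)
    shp_len_words = (100 + n * (8 + 20)) // 2
    shx_len_words = (100 + n * 8) // 2

    def header(length_words: int) -> bytes:
        return (
            struct.pack(">i5i i", 9994, 0, 0, 0, 0, 0, length_words)
            + struct.pack("<ii", 1000, 1)  # version, shape type 1 = point
            + struct.pack("<4d", min(lons), min(lats), max(lons), max(lats))
            + struct.pack("<4d", 0.0, 0.0, 0.0, 0.0)  # z/m ranges unused
        )

    shp = bytearray(header(shp_len_words))
    shx = bytearray(header(shx_len_words))
    offset_words = 50
    for i, (lon, lat, _) in enumerate(records, start=1):
        body = struct.pack("<i2d", 1, lon, lat)
        shp += struct.pack(">ii", i, len(body) // 2) + body
        shx += struct.pack(">ii", offset_words, len(body) // 2)
        offset_words += (8 + len(body)) // 2

    # --- .dbf -------------------------------------------------------------
    raw_names = list(records[0][2].keys())
    names = dedup_field_names(raw_names)
    columns = {
        raw: _field_descriptor([props.get(raw) for _, _, props in records])
        for raw in raw_names
    }
    header_size = 32 + 32 * len(names) + 1
    record_size = 1 + sum(columns[raw][1] for raw in raw_names)
    yy, mm, dd = _DBF_STAMP
    dbf = bytearray(
        struct.pack(
            "<4Bi2H20x", 3, yy - 1900, mm, dd, n, header_size, record_size
        )
    )
    for raw, short in zip(raw_names, names):
        ftype, width, dec = columns[raw]
        dbf += struct.pack(
            "<11sc4xBB14x", short.encode("ascii"), ftype.encode("ascii"), width, dec
        )
    dbf += b"\x0d"
    for _, _, props in records:
        dbf += b" "  # not-deleted flag
        for raw in raw_names:
            ftype, width, dec = columns[raw]
            dbf += _format_value(props.get(raw), ftype, width, dec)
    dbf += b"\x1a"

    paths = {
        ".shp": bytes(shp),
        ".shx": bytes(shx),
        ".dbf": bytes(dbf),
        ".prj": WGS84_WKT.encode("ascii"),
    }
    written = []
    for ext, payload in paths.items():
        p = base.with_suffix(ext)
        p.write_bytes(payload)
        written.append(p)
    return written
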