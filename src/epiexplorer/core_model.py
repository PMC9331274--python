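"""Domain types and the queryable study store.

A *water point* is a fixed community water-access or testing site (pipe/cistern,
drainage channel, ocean site, or a combined site). Each point accumulates two
longitudinal record streams collected on roughly monthly field visits:

* :class:`EpiSample` — laboratory / in-situ water-quality measurements, most
  importantly the fecal coliform count (CFU per 100 mL, mFC agar method), plus
  an optional physiochemical panel (temperature, turbidity, TDS, pH, dissolved
  oxygen, salinity).
* :class:`EnvSurvey` — ordinal 1–5 scores of the micro-environment around the
  point (mud, standing water, trash, human activity; 1 = least).

The analysis granularity is the calendar month: full dates are stored, but
record uniqueness, charts and joins key on ``(year, month)``. The store is an
in-memory collection with referential integrity (every sample/survey must
reference a registered water point) and upsert semantics for duplicate keys.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date
from enum import Enum
from typing import Iterable, Optional, Sequence

__all__ = [
    "Category",
    "WaterPoint",
    "EpiSample",
    "EnvSurvey",
    "StudyStore",
    "EpiExplorerError",
    "ValidationError",
    "ReferentialIntegrityError",
    "UnknownPointError",
    "haversine_m",
    "month_key",
    "parse_month",
    "EARTH_RADIUS_M",
]

#: Mean Earth radius used for all great-circle distances, in meters.
EARTH_RADIUS_M = 6_371_000.0

#: Environmental survey score range (ordinal, 1 = least).
ENV_SCORE_MIN, ENV_SCORE_MAX = 1, 5


class EpiExplorerError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(EpiExplorerError):
    """A record field violates its domain constraint.

    The offending field name is carried in :attr:`field_name` and always
    appears in the message.
    """

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


class ReferentialIntegrityError(EpiExplorerError):
    """A sample or survey references a water point not in the store."""


class UnknownPointError(EpiExplorerError, KeyError):
    """A query names a water point that does not exist."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep a plain message
        return self.args[0] if self.args else ""


class Category(str, Enum):
    """The four site categories used in the field protocol."""

    PIPE_CISTERN = "pipe_cistern"
    DRAINAGE = "drainage"
    OCEAN = "ocean"
    COMBINED = "combined"

    @classmethod
    def coerce(cls, value: "Category | str") -> "Category":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value))
        except ValueError:
            valid = ", ".join(c.value for c in cls)
            raise ValidationError(
                "category", f"unknown category {value!r}; expected one of: {valid}"
            ) from None


def month_key(d: date) -> str:
    """Return the ``YYYY-MM`` month key of a date."""
    return f"{d.year:04d}-{d.month:02d}"


def parse_month(period: str) -> tuple[int, int]:
    """Parse a ``YYYY-MM`` period string into ``(year, month)``."""
    try:
        y, m = period.split("-")
        year, month = int(y), int(m)
        if not 1 <= month <= 12:
            raise ValueError
    except (ValueError, AttributeError):
        raise ValidationError("period", f"expected YYYY-MM, got {period!r}") from None
    return year, month


def _coerce_date(value: "date | str", field_name: str) -> date:
    if isinstance(value, date):
        return value
    try:
        return date.fromisoformat(str(value))
    except ValueError:
        raise ValidationError(
            field_name, f"expected ISO-8601 date (YYYY-MM-DD), got {value!r}"
        ) from None


@dataclass(frozen=True)
class WaterPoint:
    """A fixed sampling site.

    ``point_id`` is a short unique label such as ``"M13"``; by fixture
    convention its leading alphabetic prefix is the neighborhood code.
    Coordinates are WGS84 decimal degrees.
    """

    point_id: str
    neighborhood: str
    category: Category
    lon: float
    lat: float
    address: str = ""
    image_ref: str = ""

    def __post_init__(self):
        if not self.point_id:
            raise ValidationError("point_id", "must be non-empty")
        object.__setattr__(self, "category", Category.coerce(self.category))
        if not -90.0 <= self.lat <= 90.0:
            raise ValidationError("lat", f"{self.lat} outside [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise ValidationError("lon", f"{self.lon} outside [-180, 180]")


def _check_optional_float(name: str, value, lo=None, hi=None):
    if value is None:
        return None
    v = float(value)
    if lo is not None and v < lo or hi is not None and v > hi:
        raise ValidationError(name, f"{v} outside [{lo}, {hi}]")
    return v


@dataclass(frozen=True)
class EpiSample:
    """One dated water-quality measurement record for a site.

    ``fc_count`` (CFU/100 mL) and ``sample_date`` are required; the
    physiochemical panel is optional so that sites tested with a reduced
    protocol (e.g. drainage or ocean sites) are representable.
    """

    point_id: str
    sample_date: date
    fc_count: float
    temperature: Optional[float] = None  # °C
    turbidity: Optional[float] = None    # NTU
    tds: Optional[float] = None          # mg/L
    ph: Optional[float] = None           # unitless, [0, 14]
    do_mgl: Optional[float] = None       # mg/L
    salinity: Optional[float] = None     # ppt
    image_ref: str = ""

    def __post_init__(self):
        object.__setattr__(
            self, "sample_date", _coerce_date(self.sample_date, "sample_date")
        )
        if self.fc_count is None or float(self.fc_count) < 0:
            raise ValidationError("fc_count", f"must be >= 0, got {self.fc_count}")
        object.__setattr__(self, "ph", _check_optional_float("ph", self.ph, 0, 14))

    @property
    def month(self) -> str:
        return month_key(self.sample_date)


@dataclass(frozen=True)
class EnvSurvey:
    """One dated 1–5 ordinal scoring of the surroundings of a site."""

    point_id: str
    survey_date: date
    mud: int
    water: int
    trash: int
    activity: int
    image_ref: str = ""

    def __post_init__(self):
        object.__setattr__(
            self, "survey_date", _coerce_date(self.survey_date, "survey_date")
        )
        for name in ("mud", "water", "trash", "activity"):
            v = getattr(self, name)
            if not (isinstance(v, int) and ENV_SCORE_MIN <= v <= ENV_SCORE_MAX):
                raise ValidationError(
                    name, f"score must be an integer in 1..5, got {v!r}"
                )

    @property
    def month(self) -> str:
        return month_key(self.survey_date)


def haversine_m(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in meters between two WGS84 points.

    Uses the haversine formula on a sphere of radius :data:`EARTH_RADIUS_M`;
    sub-meter geodesic accuracy is irrelevant at the 30 m – 1 km scales this
    package works at.
    """
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * EARTH_RADIUS_M * math.asin(min(1.0, math.sqrt(a)))


class StudyStore:
    """Queryable in-memory collection of points, samples and surveys.

    Mirrors a small embedded database: a ``water_point`` table keyed by
    ``point_id``, and one table each for epidemiological samples and
    environmental surveys, keyed by ``(point_id, year-month)`` — at most one
    record per site per calendar month, with latest-wins upsert on re-add.
    Queries never mutate the store.
    """

    def __init__(self):
        self._points: dict[str, WaterPoint] = {}
        self._samples: dict[tuple[str, str], EpiSample] = {}
        self._surveys: dict[tuple[str, str], EnvSurvey] = {}

    # -- mutation -----------------------------------------------------------

    def add_water_point(self, wp: WaterPoint) -> "StudyStore":
        """Register (or replace) a water point."""
        if not isinstance(wp, WaterPoint):
            wp = WaterPoint(**wp)  # type: ignore[arg-type]
        self._points[wp.point_id] = wp
        return self

    def add_epi_sample(self, s: EpiSample) -> "StudyStore":
        """Store a sample; same (point, month) replaces the prior record."""
        self._require_point(s.point_id)
        self._samples[(s.point_id, s.month)] = s
        return self

    def add_env_survey(self, e: EnvSurvey) -> "StudyStore":
        """Store a survey; same (point, month) replaces the prior record."""
        self._require_point(e.point_id)
        self._surveys[(e.point_id, e.month)] = e
        return self

    def _require_point(self, point_id: str) -> WaterPoint:
        try:
            return self._points[point_id]
        except KeyError:
            raise ReferentialIntegrityError(
                f"unknown water point {point_id!r}"
            ) from None

    # -- access -------------------------------------------------------------

    @property
    def water_points(self) -> list[WaterPoint]:
        """All water points, sorted by point_id."""
        return [self._points[k] for k in sorted(self._points)]

    @property
    def epi_samples(self) -> list[EpiSample]:
        """All samples, sorted by (point_id, date)."""
        return sorted(
            self._samples.values(), key=lambda s: (s.point_id, s.sample_date)
        )

    @property
    def env_surveys(self) -> list[EnvSurvey]:
        """All surveys, sorted by (point_id, date)."""
        return sorted(
            self._surveys.values(), key=lambda e: (e.point_id, e.survey_date)
        )

    def __len__(self) -> int:
        return len(self._points)

    def __contains__(self, point_id: str) -> bool:
        return point_id in self._points

    def get_point(self, point_id: str) -> WaterPoint:
        try:
            return self._points[point_id]
        except KeyError:
            raise UnknownPointError(f"unknown water point {point_id!r}") from None

    def __eq__(self, other) -> bool:
        if not isinstance(other, StudyStore):
            return NotImplemented
        return (
            self._points == other._points
            and self._samples == other._samples
            and self._surveys == other._surveys
        )

    # -- queries ------------------------------------------------------------

    def query_points(
        self,
        category: "Category | str | None" = None,
        neighborhood: Optional[str] = None,
        text: Optional[str] = None,
    ) -> list[WaterPoint]:
        """Filter points; supplied filters compose as a conjunction.

        ``text`` matches case-insensitively as a substring of the point_id or
        the address. Result is sorted by point_id ascending.
        """
        cat = Category.coerce(category) if category is not None else None
        needle = text.lower() if text is not None else None
        out = []
        for pid in sorted(self._points):
            wp = self._points[pid]
            if cat is not None and wp.category is not cat:
                continue
            if neighborhood is not None and wp.neighborhood != neighborhood:
                continue
            if needle is not None and (
                needle not in wp.point_id.lower()
                and needle not in wp.address.lower()
            ):
                continue
            out.append(wp)
        return out

    def query_samples(
        self,
        point_id: str,
        date_from: "date | str | None" = None,
        date_to: "date | str | None" = None,
    ) -> list[EpiSample]:
        """Samples for a point with ``date_from <= d <= date_to`` (closed),
        ascending by date."""
        self.get_point(point_id)
        lo = _coerce_date(date_from, "date_from") if date_from is not None else None
        hi = _coerce_date(date_to, "date_to") if date_to is not None else None
        out = [
            s
            for (pid, _), s in self._samples.items()
            if pid == point_id
            and (lo is None or s.sample_date >= lo)
            and (hi is None or s.sample_date <= hi)
        ]
        return sorted(out, key=lambda s: s.sample_date)

    def query_surveys(
        self,
        point_id: str,
        date_from: "date | str | None" = None,
        date_to: "date | str | None" = None,
    ) -> list[EnvSurvey]:
        """Environmental analogue of :meth:`query_samples`."""
        self.get_point(point_id)
        lo = _coerce_date(date_from, "date_from") if date_from is not None else None
        hi = _coerce_date(date_to, "date_to") if date_to is not None else None
        out = [
            e
            for (pid, _), e in self._surveys.items()
            if pid == point_id
            and (lo is None or e.survey_date >= lo)
            and (hi is None or e.survey_date <= hi)
        ]
        return sorted(out, key=lambda e: e.survey_date)

    def sample_for(self, point_id: str, period: str) -> Optional[EpiSample]:
        """The sample for (point, YYYY-MM period), or None."""
        parse_month(period)
        return self._samples.get((point_id, period))

    def survey_for(self, point_id: str, period: str) -> Optional[EnvSurvey]:
        """The survey for (point, YYYY-MM period), or None."""
        parse_month(period)
        return self._surveys.get((point_id, period))

    def nearest_neighbors(
        self, point_id: str, k: int
    ) -> list[tuple[WaterPoint, float]]:
        """The ``k`` nearest *other* points by great-circle distance.

        Ascending by distance; exact distance ties break by point_id.
        """
        if k < 0:
            raise ValidationError("k", f"must be >= 0, got {k}")
        origin = self.get_point(point_id)
        scored = [
            (haversine_m(origin.lat, origin.lon, wp.lat, wp.lon), wp.point_id, wp)
            for wp in self._points.values()
            if wp.point_id != point_id
        ]
        scored.sort(key=lambda t: (t[0], t[1]))
        return [(wp, d) for d, _, wp in scored[:k]]
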