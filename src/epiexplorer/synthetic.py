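"""Synthetic surveillance studies and the printed case-study fixtures.

The original field data (38 water points across the "M", "S" and "P"
neighborhoods of Port-au-Prince, sampled monthly from October 2016) are
confidential, so this module generates stand-in studies with the same
structure: neighborhood point clusters at 20–200 m spacing, one water sample
and one environmental survey per point per month, fecal coliform counts that
are mostly low with rare multi-order-of-magnitude spikes, and environmental
"water"/"mud" scores that rise in spike months.

Contamination model
-------------------
Real FC series are temporally coherent: a site is either clean (counts at or
near zero month after month) or persistently contaminated around some site
level, and contamination *events* then stand out by orders of magnitude.
The generator reproduces that structure:

* ~65% of points are clean — FC is 0 every month;
* the rest carry a site level ``b`` drawn log-uniformly, with monthly values
  ``b × U`` for jitter ``U ∈ [0.5, 2]`` and a 15% chance of a zero month
  (dry well / non-detect).

Marginally over point-months this yields roughly 70% zeros with nonzero
values spanning ~1–1000 CFU/100 mL. Spikes are injected independently per
point-month (default probability 0.02) as ``multiplier × (1 + baseline)``
with the multiplier log-uniform in [1e3, 1e6]; the +1 keeps spikes nonzero at
clean sites. Spike months also raise the ordinal water and mud scores by the
coupling amount (default +3, capped at 5), emulating the standing-water
conditions observed around contaminated sites.

Everything is driven by a single integer seed through one numpy PCG64
generator, so a given config reproduces the identical store on any platform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date
from typing import Optional, Sequence

import numpy as np

from .core_model import (
    Category,
    EARTH_RADIUS_M,
    EnvSurvey,
    EpiSample,
    StudyStore,
    ValidationError,
    WaterPoint,
)

__all__ = [
    "StudyConfig",
    "SpikeTruth",
    "default_months",
    "generate_study",
    "case_study_fixture",
    "generate_rainfall",
    "CASE_STUDY_SERIES",
]

#: Degrees of latitude per meter on the sphere used throughout the package.
_DEG_PER_M_LAT = 180.0 / (math.pi * EARTH_RADIUS_M)

# Neighborhood cluster anchors (coastal Port-au-Prince surroundings).
_NEIGHBORHOOD_ANCHORS = {
    "M": (-72.3370, 18.5780),
    "S": (-72.3460, 18.5330),
    "P": (-72.3540, 18.5570),
}
_FALLBACK_ANCHOR = (-72.3400, 18.5600)


def default_months(start: str = "2016-10", end: str = "2017-12") -> list[str]:
    """Inclusive list of YYYY-MM months from start to end."""
    y0, m0 = (int(x) for x in start.split("-"))
    y1, m1 = (int(x) for x in end.split("-"))
    out = []
    y, m = y0, m0
    while (y, m) <= (y1, m1):
        out.append(f"{y:04d}-{m:02d}")
        m += 1
        if m == 13:
            y, m = y + 1, 1
    return out


@dataclass(frozen=True)
class StudyConfig:
    """Parameters of a synthetic study; defaults mirror the field deployment.

    ``spike_rate`` is a per point-month probability; ``spike_magnitude`` is
    the (low, high) range of the log-uniform spike multiplier applied to
    ``1 + baseline``; ``env_coupling`` is added to the water and mud scores
    in spike months (capped at 5).
    """

    n_points: int = 38
    neighborhoods: tuple[str, ...] = ("M", "S", "P")
    months: tuple[str, ...] = tuple(default_months())
    spike_rate: float = 0.02
    spike_magnitude: tuple[float, float] = (1e3, 1e6)
    clean_point_fraction: float = 0.65
    baseline_level_range: tuple[float, float] = (1.0, 500.0)
    baseline_dropout: float = 0.15
    env_coupling: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_points < 1:
            raise ValidationError("n_points", f"must be >= 1, got {self.n_points}")
        if not self.months:
            raise ValidationError("months", "must be non-empty")
        if not self.neighborhoods:
            raise ValidationError("neighborhoods", "must be non-empty")
        for name in ("spike_rate", "clean_point_fraction", "baseline_dropout"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(name, f"probability must be in [0, 1], got {v}")


@dataclass(frozen=True)
class SpikeTruth:
    """Ground truth for one injected spike (used to calibrate detection)."""

    point_id: str
    month: str
    value: float
    baseline: float


def _month_mid_date(period: str) -> date:
    y, m = (int(x) for x in period.split("-"))
    return date(y, m, 15)


def _place_points(config: StudyConfig, rng: np.random.Generator):
    """Cluster points per neighborhood with 20–200 m nearest spacing.

    Points are laid on a jittered grid: consecutive points step 20–200 m in a
    random direction from the previous one, re-anchored at the neighborhood
    center, which keeps each cluster compact (sub-kilometer) while bounding
    inter-point spacing.
    """
    sizes = [
        len(range(i, config.n_points, len(config.neighborhoods)))
        for i in range(len(config.neighborhoods))
    ]
    points = []
    for hood, size in zip(config.neighborhoods, sizes):
        lon0, lat0 = _NEIGHBORHOOD_ANCHORS.get(hood, _FALLBACK_ANCHOR)
        deg_per_m_lon = _DEG_PER_M_LAT / math.cos(math.radians(lat0))
        placed: list[tuple[float, float]] = []
        for i in range(size):
            if not placed:
                x = y = 0.0
            else:
                # random 20-200 m step from the previous point, rejected if it
                # lands within 20 m of any sited point or >600 m off-anchor
                px, py = placed[-1]
                for _ in range(200):
                    step = rng.uniform(20.0, 200.0)
                    theta = rng.uniform(0.0, 2.0 * math.pi)
                    x = px + step * math.cos(theta)
                    y = py + step * math.sin(theta)
                    if math.hypot(x, y) > 600.0:
                        continue
                    if all(math.hypot(x - qx, y - qy) >= 20.0 for qx, qy in placed):
                        break
            placed.append((x, y))
            category = Category(
                rng.choice(
                    [c.value for c in Category], p=[0.55, 0.25, 0.1, 0.1]
                )
            )
            points.append(
                WaterPoint(
                    point_id=f"{hood}{i + 1}",
                    neighborhood=hood,
                    category=category,
                    lon=round(lon0 + x * deg_per_m_lon, 6),
                    lat=round(lat0 + y * _DEG_PER_M_LAT, 6),
                    address=f"{hood} neighborhood site {i + 1}",
                )
            )
    return points


def _env_base_score(rng: np.random.Generator) -> int:
    # ordinary months skew low on the 1–5 scale
    return int(rng.choice([1, 2, 3], p=[0.5, 0.3, 0.2]))


def generate_study(
    config: StudyConfig = StudyConfig(), with_truth: bool = False
):
    """Generate a full synthetic study; deterministic under ``config.seed``.

    Every point gets one :class:`EpiSample` and one :class:`EnvSurvey` per
    month. With ``with_truth=True`` also returns the list of injected
    :class:`SpikeTruth` records, for detector calibration.
    """
    rng = np.random.default_rng(config.seed)
    store = StudyStore()
    truth: list[SpikeTruth] = []

    points = _place_points(config, rng)
    for wp in points:
        store.add_water_point(wp)

    lo_mag, hi_mag = config.spike_magnitude
    lo_b, hi_b = config.baseline_level_range
    for wp in points:
        clean = rng.random() < config.clean_point_fraction
        level = 0.0 if clean else float(np.exp(rng.uniform(np.log(lo_b), np.log(hi_b))))
        for period in config.months:
            d = _month_mid_date(period)
            if clean or rng.random() < config.baseline_dropout:
                baseline = 0.0
            else:
                baseline = round(level * rng.uniform(0.5, 2.0))
            fc = baseline
            spiked = rng.random() < config.spike_rate
            if spiked:
                mag = float(np.exp(rng.uniform(np.log(lo_mag), np.log(hi_mag))))
                fc = round(mag * (1.0 + baseline))
                truth.append(
                    SpikeTruth(point_id=wp.point_id, month=period, value=fc, baseline=baseline)
                )
            store.add_epi_sample(
                EpiSample(
                    point_id=wp.point_id,
                    sample_date=d,
                    fc_count=float(fc),
                    temperature=round(rng.uniform(24.0, 33.0), 1),
                    turbidity=round(float(np.exp(rng.uniform(0.0, np.log(50.0)))), 1),
                    tds=round(rng.uniform(200.0, 1500.0), 0),
                    ph=round(rng.uniform(6.0, 8.5), 2),
                    do_mgl=round(rng.uniform(2.0, 9.0), 2),
                    salinity=round(rng.uniform(0.0, 2.0), 2),
                )
            )
            mud = _env_base_score(rng)
            water = _env_base_score(rng)
            if spiked:
                mud = min(5, mud + config.env_coupling)
                water = min(5, water + config.env_coupling)
            store.add_env_survey(
                EnvSurvey(
                    point_id=wp.point_id,
                    survey_date=d,
                    mud=mud,
                    water=water,
                    trash=_env_base_score(rng),
                    activity=int(rng.integers(1, 6)),
                )
            )

    if with_truth:
        return store, truth
    return store


# --------------------------------------------------------------------------
# Printed case-study fixtures
# --------------------------------------------------------------------------

#: The published monthly FC series of the three case-study sites (CFU/100 mL).
CASE_STUDY_SERIES = {
    "M13": {
        **{m: 0.0 for m in default_months("2016-10", "2017-12")},
        "2017-07": 35_800_000.0,
    },
    "M1": {m: 0.0 for m in default_months("2016-10", "2017-12")},
    "S17": {
        "2017-02": 100.0,
        "2017-05": 3_868_250.0,
        "2017-06": 890_000.0,
        "2017-07": 209_800.0,
        "2017-08": 98.0,
        "2017-09": 855.0,
        "2017-11": 855.0,
    },
    "P1": {
        "2017-05": 33_000.0,
        "2017-06": 1_050_000.0,
        "2017-10": 0.0,
        "2017-11": 2.0,
        "2017-12": 0.0,
    },
}

# M13 sits 30 m due north of its nearest neighbor M1 ("the water point south
# of M13 is M1"); 30 m of meridional separation exactly.
_M13_LONLAT = (-72.337000, 18.578000)
_M1_LONLAT = (-72.337000, round(18.578000 - 30.0 * _DEG_PER_M_LAT, 6))


def _fixture_env_survey(point_id: str, period: str) -> EnvSurvey:
    # July 2017 was the wettest and muddiest month around M13.
    wet = point_id == "M13" and period == "2017-07"
    return EnvSurvey(
        point_id=point_id,
        survey_date=_month_mid_date(period),
        mud=5 if wet else 2,
        water=5 if wet else 1,
        trash=2,
        activity=2,
    )


def case_study_fixture(name: str) -> StudyStore:
    """A store encoding one published case study: "M13_M1", "S17" or "P1".

    Each fixture carries exactly the printed monthly FC series, plus
    environmental surveys encoding the narrated conditions (high water/mud at
    M13 in July 2017).
    """
    store = StudyStore()
    if name == "M13_M1":
        store.add_water_point(
            WaterPoint("M13", "M", Category.PIPE_CISTERN, *_M13_LONLAT,
                       address="M neighborhood cistern 13")
        )
        store.add_water_point(
            WaterPoint("M1", "M", Category.PIPE_CISTERN, *_M1_LONLAT,
                       address="M neighborhood cistern 1")
        )
        ids = ("M13", "M1")
    elif name == "S17":
        store.add_water_point(
            WaterPoint("S17", "S", Category.PIPE_CISTERN, -72.346000, 18.533000,
                       address="S neighborhood tank/pipe site 17")
        )
        ids = ("S17",)
    elif name == "P1":
        store.add_water_point(
            WaterPoint("P1", "P", Category.PIPE_CISTERN, -72.354000, 18.557000,
                       address="P neighborhood tank site 1")
        )
        ids = ("P1",)
    else:
        raise ValidationError(
            "name", f"unknown case study {name!r}; expected M13_M1, S17 or P1"
        )
    for pid in ids:
        for period, fc in sorted(CASE_STUDY_SERIES[pid].items()):
            store.add_epi_sample(
                EpiSample(point_id=pid, sample_date=_month_mid_date(period), fc_count=fc)
            )
            store.add_env_survey(_fixture_env_survey(pid, period))
    return store


def generate_rainfall(
    months: Sequence[str],
    seed: int = 0,
    mean_mm: float = 120.0,
    sd_mm: float = 60.0,
) -> dict[str, float]:
    """Synthetic monthly rainfall totals (mm), deterministic under ``seed``.

    Gaussian around ``mean_mm`` truncated at zero; a stand-in series for
    pairing with FC counts in the correlation workflow, not a climatology.
    """
    if sd_mm < 0:
        raise ValidationError("sd_mm", f"must be >= 0, got {sd_mm}")
    rng = np.random.default_rng(seed)
    return {
        m: float(max(0.0, round(rng.normal(mean_mm, sd_mm), 1))) for m in months
    }
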