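"""Exploratory statistics behind the charts.

Time series, percent-of-max, rank tables, spike flagging, paired comparison of
neighboring points, and the rainfall correlation. All operations are pure
functions of a :class:`~epiexplorer.core_model.StudyStore` returning plain
records that the io layer can serialize.

Spike rule
----------
The surveillance series here are counts that sit near zero (or near a stable
site level) for most months and jump by several orders of magnitude when a
site is contaminated. A month is flagged when

    value(m) > K * (offset + median of all other months' values)

with defaults ``K=100`` and ``offset=1``. The multiplicative form matches the
orders-of-magnitude structure of fecal coliform counts; the median of the
*other* months is a spike-resistant baseline, and the +1 offset keeps the rule
meaningful for all-zero baselines (a count must exceed 100 to be anomalous
against a silent history).
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import scipy.stats

from .core_model import StudyStore, ValidationError, parse_month

__all__ = [
    "EPI_VARIABLES",
    "ENV_VARIABLES",
    "VARIABLES",
    "TimeSeries",
    "RankTable",
    "SpikeReport",
    "CorrelationResult",
    "PairedSeries",
    "time_chart",
    "percent_of_max",
    "rank_chart",
    "flag_spikes",
    "compare_points",
    "rainfall_correlation",
]

EPI_VARIABLES = ("fc_count", "temperature", "turbidity", "tds", "ph", "do_mgl", "salinity")
ENV_VARIABLES = ("mud", "water", "trash", "activity")
VARIABLES = EPI_VARIABLES + ENV_VARIABLES


def _check_variable(variable: str) -> str:
    if variable not in VARIABLES:
        raise ValidationError(
            "variable",
            f"unknown variable {variable!r}; valid names: {', '.join(VARIABLES)}",
        )
    return variable


@dataclass(frozen=True)
class TimeSeries:
    """Monthly series of one variable at one point; entries ascend in time.

    Months without an observation are omitted, never zero-filled.
    """

    point_id: str
    variable: str
    entries: tuple[tuple[str, float], ...]  # ((YYYY-MM, value), ...)

    @property
    def months(self) -> tuple[str, ...]:
        return tuple(m for m, _ in self.entries)

    @property
    def values(self) -> tuple[float, ...]:
        return tuple(v for _, v in self.entries)

    def value_at(self, period: str) -> Optional[float]:
        for m, v in self.entries:
            if m == period:
                return v
        return None

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class RankTable:
    """Points rank-ordered (descending) by one variable in one period.

    ``rows`` are ``(rank, point_id, value)`` with dense 1..n ranks; ties take
    consecutive ranks ordered by point_id. Points in scope that lack an
    observation for the period are excluded from the ranking and listed in
    ``missing``.
    """

    variable: str
    period: str
    scope: tuple[str, ...]
    rows: tuple[tuple[int, str, float], ...]
    missing: tuple[str, ...] = ()


@dataclass(frozen=True)
class SpikeReport:
    """Months at which a variable spikes above its own history."""

    point_id: str
    variable: str
    flagged: tuple[str, ...]
    rule: Mapping[str, float]


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation between two month-aligned series."""

    n: int
    r: float
    excluded: tuple[str, ...] = ()


@dataclass(frozen=True)
class PairedSeries:
    """Two points' series for one variable, aligned on common months."""

    point_a: str
    point_b: str
    variable: str
    entries: tuple[tuple[str, float, float], ...]  # (month, value_a, value_b)


def _variable_value(store: StudyStore, point_id: str, period: str, variable: str):
    """The observation of `variable` at (point, month), or None."""
    if variable in EPI_VARIABLES:
        rec = store.sample_for(point_id, period)
    else:
        rec = store.survey_for(point_id, period)
    if rec is None:
        return None
    return getattr(rec, variable)


def time_chart(store: StudyStore, point_id: str, variable: str) -> TimeSeries:
    """Longitudinal monthly series of one variable at one point.

    One entry per observed month, ascending; months where the variable was not
    recorded (no record, or an optional field left blank) are omitted.
    """
    _check_variable(variable)
    store.get_point(point_id)
    if variable in EPI_VARIABLES:
        records = [(s.month, getattr(s, variable)) for s in store.query_samples(point_id)]
    else:
        records = [(e.month, getattr(e, variable)) for e in store.query_surveys(point_id)]
    entries = tuple((m, v) for m, v in records if v is not None)
    return TimeSeries(point_id=point_id, variable=variable, entries=entries)


def percent_of_max(store: StudyStore, point_id: str, period: str) -> float:
    """FC count for a month as a percentage of the point's own maximum.

    The denominator is the maximum over the point's entire observed FC
    history, including the queried month, so the result is always in
    [0, 100]. A point whose history is all zeros returns 0.0 (0/0 convention).
    """
    parse_month(period)
    series = time_chart(store, point_id, "fc_count")
    value = series.value_at(period)
    if value is None:
        raise ValidationError(
            "period", f"no FC observation for {point_id} in {period}"
        )
    peak = max(series.values)
    if peak == 0:
        return 0.0
    # ratio first: value/peak is exactly 1.0 at the argmax, keeping the
    # result inside [0, 100] in floating point
    return 100.0 * (value / peak)


def _resolve_scope(
    store: StudyStore, scope: Union[str, Sequence[str]]
) -> list[str]:
    """Scope is a list of ids, a neighborhood code, or "all"."""
    if isinstance(scope, str):
        if scope == "all":
            return [wp.point_id for wp in store.water_points]
        ids = [wp.point_id for wp in store.query_points(neighborhood=scope)]
        if not ids and scope in store:
            return [scope]  # a single point_id also accepted
        return ids
    return [store.get_point(pid).point_id for pid in scope]


def rank_chart(
    store: StudyStore,
    variable: str,
    period: str,
    scope: Union[str, Sequence[str]] = "all",
) -> RankTable:
    """Rank points in scope by a variable's value in one month, descending.

    Ties take consecutive ranks ordered by point_id, so output is
    deterministic and invariant to the input order of the scope.
    """
    _check_variable(variable)
    parse_month(period)
    ids = sorted(set(_resolve_scope(store, scope)))
    if not ids:
        raise ValidationError("scope", f"scope {scope!r} resolves to no points")
    observed, missing = [], []
    for pid in ids:
        v = _variable_value(store, pid, period, variable)
        if v is None:
            missing.append(pid)
        else:
            observed.append((pid, float(v)))
    if not observed:
        raise ValidationError(
            "period", f"no point in scope has a {variable} observation for {period}"
        )
    observed.sort(key=lambda t: (-t[1], t[0]))
    rows = tuple((i + 1, pid, v) for i, (pid, v) in enumerate(observed))
    return RankTable(
        variable=variable,
        period=period,
        scope=tuple(ids),
        rows=rows,
        missing=tuple(missing),
    )


def flag_spikes(
    store: StudyStore,
    point_id: str,
    variable: str = "fc_count",
    k: float = 100.0,
    offset: float = 1.0,
) -> SpikeReport:
    """Flag months whose value dwarfs the median of the rest of the series.

    Month ``m`` is flagged iff ``value(m) > k * (offset + median of all other
    months' values)``. Requires at least 3 observed months; a constant series
    yields no flags.
    """
    series = time_chart(store, point_id, variable)
    if len(series) < 3:
        raise ValidationError(
            "point_id",
            f"{point_id} has only {len(series)} {variable} observations; "
            "spike detection needs at least 3",
        )
    flagged = []
    values = list(series.values)
    for i, (m, v) in enumerate(series.entries):
        others = values[:i] + values[i + 1 :]
        if v > k * (offset + median(others)):
            flagged.append(m)
    return SpikeReport(
        point_id=point_id,
        variable=series.variable,
        flagged=tuple(flagged),
        rule={"k": k, "offset": offset},
    )


def compare_points(
    store: StudyStore, point_a: str, point_b: str, variable: str
) -> PairedSeries:
    """Align two points' series on their common observed months."""
    sa = time_chart(store, point_a, variable)
    sb = time_chart(store, point_b, variable)
    b_by_month = dict(sb.entries)
    entries = tuple(
        (m, va, b_by_month[m]) for m, va in sa.entries if m in b_by_month
    )
    return PairedSeries(
        point_a=point_a, point_b=point_b, variable=sa.variable, entries=entries
    )


def rainfall_correlation(
    fc: Union[TimeSeries, Mapping[str, float], Iterable[tuple[str, float]]],
    rain: Union[Mapping[str, float], Iterable[tuple[str, float]]],
    exclude: Sequence[str] = (),
) -> CorrelationResult:
    """Pearson correlation between a monthly FC series and monthly rainfall.

    ``fc`` may be a :class:`TimeSeries` (a single point's series or any
    pre-aggregated monthly series) or a month→value mapping; ``rain`` is a
    month→mm mapping. Pairs are aligned on common months; ``exclude`` months
    are removed first (and recorded in the result), which is how a suspected
    outlier month can be dropped from the comparison. Requires at least 3
    remaining pairs and nonzero variance in both series.
    """
    fc_map = dict(fc.entries) if isinstance(fc, TimeSeries) else dict(fc)
    rain_map = dict(rain)
    for m, mm in rain_map.items():
        if mm < 0:
            raise ValidationError("rain", f"negative rainfall {mm} in {m}")
    excluded = tuple(sorted(set(exclude)))
    months = sorted((fc_map.keys() & rain_map.keys()) - set(excluded))
    if len(months) < 3:
        raise ValidationError(
            "fc", f"only {len(months)} common months after exclusions; need >= 3"
        )
    x = np.array([float(fc_map[m]) for m in months])
    y = np.array([float(rain_map[m]) for m in months])
    if np.ptp(x) == 0.0:
        raise ValidationError("fc", "zero variance; correlation undefined")
    if np.ptp(y) == 0.0:
        raise ValidationError("rain", "zero variance; correlation undefined")
    r = float(scipy.stats.pearsonr(x, y).statistic)
    return CorrelationResult(n=len(months), r=r, excluded=excluded)
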