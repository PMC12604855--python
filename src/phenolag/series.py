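"""Daily mean temperature series and degree-day arithmetic.

A :class:`TemperatureSeries` holds one climate's daily mean temperatures
indexed by 1-based day-of-year. Spring forcing is accumulated as degree days
above a base temperature (default 0 °C) using daily means clipped at the base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "TemperatureSeries",
    "CoverageError",
    "accumulate_degree_days",
    "spring_warming",
    "average_years",
]

#: end of the spring window (Julian day 1..182) used for spring warming
SPRING_WINDOW_END = 182


class CoverageError(ValueError):
    """A requested day-of-year lies outside the series coverage."""


@dataclass(frozen=True)
class TemperatureSeries:
    """One climate's daily mean temperatures on contiguous days-of-year.

    Parameters
    ----------
    days : array-like of int
        1-based day-of-year values, strictly increasing with step 1.
    temps : array-like of float
        Daily mean temperature (°C), one per day; no missing values.
    label : str
        Climate identifier, e.g. ``"baseline"`` or ``"warmer"``.
    """

    days: np.ndarray
    temps: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=np.int64)
        temps = np.asarray(self.temps, dtype=float)
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "temps", temps)
        if days.ndim != 1 or temps.ndim != 1 or days.size != temps.size:
            raise ValueError("days and temps must be 1-D arrays of equal length")
        if days.size == 0:
            raise ValueError("empty temperature series")
        if days[0] < 1:
            raise ValueError("day-of-year values are 1-based")
        if days.size > 1 and not np.all(np.diff(days) == 1):
            raise ValueError("days must be contiguous (step 1)")
        if not np.all(np.isfinite(temps)):
            raise ValueError("temperature series contains non-finite values")

    def __len__(self) -> int:
        return int(self.days.size)

    @property
    def start_day(self) -> int:
        return int(self.days[0])

    @property
    def end_day(self) -> int:
        return int(self.days[-1])

    def covers(self, start_day: int, end_day: int) -> bool:
        return self.start_day <= start_day and end_day <= self.end_day

    def _require(self, day: int) -> None:
        if not (self.start_day <= day <= self.end_day):
            raise CoverageError(
                f"day {day} outside coverage [{self.start_day}, {self.end_day}]"
                + (f" of series {self.label!r}" if self.label else "")
            )

    def temp_at(self, day: int) -> float:
        self._require(int(day))
        return float(self.temps[int(day) - self.start_day])

    def slice_temps(self, start_day: int, end_day: int) -> np.ndarray:
        """Temperatures over ``[start_day, end_day]`` inclusive."""
        start_day, end_day = int(start_day), int(end_day)
        if start_day > end_day:
            raise ValueError(f"start_day {start_day} > end_day {end_day}")
        self._require(start_day)
        self._require(end_day)
        i = start_day - self.start_day
        j = end_day - self.start_day + 1
        return self.temps[i:j]

    def clipped_cumsum(self, base_temp: float = 0.0) -> np.ndarray:
        """Cumulative degree days from the first covered day, per day."""
        return np.cumsum(np.maximum(self.temps - base_temp, 0.0))

    def with_offset(self, offset: np.ndarray | float, label: str | None = None) -> "TemperatureSeries":
        return TemperatureSeries(self.days, self.temps + offset, label if label is not None else self.label)


def accumulate_degree_days(
    series: TemperatureSeries,
    start_day: int,
    end_day: int,
    base_temp: float = 0.0,
) -> float:
    """Sum of ``max(T_d - base_temp, 0)`` over days ``[start_day, end_day]``.

    This is the spring-forcing accumulator: daily mean temperatures are
    clipped at ``base_temp`` (0 °C by default) before summing, so the result
    is always non-negative.
    """
    temps = series.slice_temps(start_day, end_day)
    return float(np.maximum(temps - base_temp, 0.0).sum())


def spring_warming(
    baseline: TemperatureSeries,
    warmer: TemperatureSeries,
    window_end: int = SPRING_WINDOW_END,
) -> float:
    """Mean daily temperature change (warmer − baseline) over days 1..182.

    The window end is the Julian-day bound of the spring period; both series
    must cover days 1 through ``window_end``.
    """
    b = baseline.slice_temps(1, window_end)
    w = warmer.slice_temps(1, window_end)
    return float(np.mean(w - b))


def average_years(
    series_list: Sequence[TemperatureSeries], label: str = ""
) -> TemperatureSeries:
    """Average several years day-by-day into one representative series.

    All series must share identical day coverage. Used to collapse a
    multi-year climate regime into the single daily series the partitioning
    operates on.
    """
    if not series_list:
        raise ValueError("no series to average")
    first = series_list[0]
    for s in series_list[1:]:
        if s.start_day != first.start_day or s.end_day != first.end_day:
            raise ValueError("series to average must share day coverage")
    temps = np.mean([s.temps for s in series_list], axis=0)
    return TemperatureSeries(first.days, temps, label=label)
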