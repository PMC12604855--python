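"""Partitioning observed budburst shifts into their thermal drivers.

Given a baseline and a warmer daily-temperature series and a species'
baseline budburst day ``O_Ci``, the observed shift ``N_O`` is decomposed via

* forcing change ``F_C`` — difference in degree days (>0 °C) accumulated from
  Julian day 1 to ``O_Ci`` between the warmer and baseline climates;
* expected response ``N_E`` — the day shift ``n`` minimizing
  ``|sum_1^{O_Ci - n} T_W - sum_1^{O_Ci} T_C|``, i.e. how many days earlier
  (or later) the warmer climate reaches the baseline forcing threshold;
* budburst temperature ``T_B = F_C / N_E`` — the average rate of forcing
  accumulation over the expected-response window;
* phenological lag ``N_C = N_E - N_O`` — the shortfall of the observed shift
  relative to expectation, attributable to aggregate constraints (chilling,
  photoperiod, moisture, frost).

``N_C > 0`` means constraints increased with warming, ``N_C < 0`` that they
relaxed. The day search runs over integer days by default, matching the
whole-day indexing of the defining sums; a linear-interpolation mode refines
the crossing day sub-daily.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import math

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .records import PhenologyRecord
from .series import (
    SPRING_WINDOW_END,
    TemperatureSeries,
    accumulate_degree_days,
    spring_warming,
)

__all__ = [
    "PartitionResult",
    "SearchWindowError",
    "forcing_change",
    "expected_response",
    "budburst_temperature",
    "phenological_lag",
    "partition_record",
    "forcing_day_equivalent",
    "budburst_temp_day_equivalent",
    "PhenologyPartitioner",
]


class SearchWindowError(ValueError):
    """The warmer series never attains the baseline forcing threshold."""


@dataclass(frozen=True)
class PartitionResult:
    """Per-record output of the partitioning.

    ``t_b`` is NaN with ``t_b_defined=False`` when ``n_e == 0`` (a zero-day
    expected response leaves the forcing rate undefined); such records are
    excluded from downstream means rather than imputed.
    """

    f_c: float  # forcing change, degree days
    n_e: float  # expected response, days (positive = advance)
    e_wi: float  # expected budburst day-of-year under the warmer climate
    t_b: float  # budburst temperature, degC (NaN when undefined)
    t_b_defined: bool
    n_c: float  # phenological lag, days
    s_w: float  # spring warming, degC
    residual_mismatch: float  # achieved minimum |forcing mismatch|, degree days

    def to_dict(self) -> dict:
        return asdict(self)


def forcing_change(
    baseline: TemperatureSeries,
    warmer: TemperatureSeries,
    budburst_day: int,
    base_temp: float = 0.0,
) -> float:
    """F_C: degree-day difference (warmer − baseline) over days 1..O_Ci.

    Negative values indicate a cooling climate.
    """
    return accumulate_degree_days(warmer, 1, budburst_day, base_temp) - \
        accumulate_degree_days(baseline, 1, budburst_day, base_temp)


def _warmer_cumsum(warmer: TemperatureSeries, base_temp: float) -> np.ndarray:
    if warmer.start_day != 1:
        raise SearchWindowError(
            f"warmer series must start at day 1 (starts at {warmer.start_day})"
        )
    return warmer.clipped_cumsum(base_temp)


def expected_response(
    baseline: TemperatureSeries,
    warmer: TemperatureSeries,
    budburst_day: int,
    base_temp: float = 0.0,
    mode: str = "integer",
) -> tuple[float, float, float]:
    """N_E, E_Wi and the residual forcing mismatch for one record.

    The baseline forcing threshold is the degree-day sum at ``budburst_day``
    under the baseline climate. Candidate shifts ``n`` range over all values
    keeping the expected day ``E_Wi = O_Ci - n`` inside the warmer series'
    coverage; the returned ``n`` minimizes the absolute forcing mismatch.
    Ties prefer the smaller ``|n|`` (the more conservative response), then
    the positive (advancing) ``n``.

    With ``mode="linear"`` the integer minimizer is refined by linear
    interpolation of the cumulative forcing across the crossing day, giving
    a fractional ``N_E`` and zero residual wherever forcing is accumulating.

    Raises
    ------
    SearchWindowError
        If the threshold lies outside the forcing range attainable within
        the warmer series (never reached, or already exceeded on day 1).
    """
    if mode not in ("integer", "linear"):
        raise ValueError(f"unknown mode {mode!r}")
    budburst_day = int(budburst_day)
    threshold = accumulate_degree_days(baseline, 1, budburst_day, base_temp)
    cum = _warmer_cumsum(warmer, base_temp)
    end_day = warmer.end_day

    # candidate expected days E_Wi = budburst_day - n over [1, end_day];
    # the threshold is bracketed as long as the warmer series reaches it
    hi = cum[-1]
    if threshold > hi + 1e-9:
        raise SearchWindowError(
            f"baseline forcing threshold {threshold:.2f} degree days exceeds the "
            f"attainable warmer-climate forcing range [0, {hi:.2f}] over days "
            f"1..{end_day}"
        )

    mismatch = cum - threshold  # index d-1 holds mismatch at day d
    absm = np.abs(mismatch)
    best = absm.min()
    candidates = np.flatnonzero(np.isclose(absm, best, rtol=0.0, atol=1e-9))
    # tie-break on n = budburst_day - day: smaller |n| first, then positive n
    ns = budburst_day - (candidates + 1)
    order = np.lexsort((-np.sign(ns), np.abs(ns)))
    pick = candidates[order[0]]
    n = int(budburst_day - (pick + 1))
    e_wi = float(pick + 1)
    residual = float(mismatch[pick])

    if mode == "linear" and not math.isclose(residual, 0.0, abs_tol=1e-9):
        e_wi, residual = _refine_crossing(cum, pick, residual, end_day)
        n = budburst_day - e_wi
    return float(n), float(e_wi), float(abs(residual))


def _refine_crossing(
    cum: np.ndarray, pick: int, residual: float, end_day: int
) -> tuple[float, float]:
    """Interpolate the threshold crossing inside the day it happens."""
    day = pick + 1
    if residual > 0:
        # overshoot: threshold crossed within this day
        inc = cum[pick] - (cum[pick - 1] if pick > 0 else 0.0)
        if inc > 0:
            return day - residual / inc, 0.0
    else:
        # undershoot: crossing occurs within the following day
        if day < end_day:
            inc = cum[pick + 1] - cum[pick]
            if inc > 0:
                return day - residual / inc, 0.0
    return float(day), residual


def budburst_temperature(f_c: float, n_e: float) -> float:
    """T_B = F_C / N_E, the average forcing-accumulation rate (°C).

    Returns NaN — the undefined flag — when ``n_e`` is zero; never raises.
    """
    if n_e == 0:
        return float("nan")
    return f_c / n_e


def phenological_lag(n_e: float, n_o: float) -> float:
    """N_C = N_E − N_O: positive when constraints increased with warming."""
    return n_e - n_o


def forcing_day_equivalent(delta_f_c: float, t_b: float) -> float:
    """Convert a forcing-change difference into expected-response days.

    ``delta_f_c / t_b`` expresses a between-group forcing difference as the
    number of days of expected response it is worth at budburst temperature
    ``t_b``. NaN (undefined) when ``t_b`` is zero.
    """
    if t_b == 0:
        return float("nan")
    return delta_f_c / t_b


def budburst_temp_day_equivalent(f_c: float, t_b_low: float, t_b_high: float) -> float:
    """Days of response explained by a budburst-temperature difference.

    ``f_c / t_b_low - f_c / t_b_high``: the same forcing converts into more
    days at the lower rate. NaN when either temperature is zero.
    """
    if t_b_low == 0 or t_b_high == 0:
        return float("nan")
    return f_c / t_b_low - f_c / t_b_high


def partition_record(
    record: PhenologyRecord | dict,
    baseline: TemperatureSeries,
    warmer: TemperatureSeries,
    base_temp: float = 0.0,
    mode: str = "integer",
    spring_window_end: int = SPRING_WINDOW_END,
) -> PartitionResult:
    """Full decomposition of one phenology record against a climate pair."""
    if isinstance(record, dict):
        record = PhenologyRecord(**record)
    ident = f"{record.species} @ {record.location}"
    try:
        f_c = forcing_change(baseline, warmer, record.o_ci, base_temp)
        n_e, e_wi, residual = expected_response(
            baseline, warmer, record.o_ci, base_temp, mode
        )
        s_w = spring_warming(baseline, warmer, spring_window_end)
    except (ValueError, KeyError) as exc:
        raise type(exc)(f"{ident}: {exc}") from exc
    t_b = budburst_temperature(f_c, n_e)
    return PartitionResult(
        f_c=f_c,
        n_e=n_e,
        e_wi=e_wi,
        t_b=t_b,
        t_b_defined=not math.isnan(t_b),
        n_c=phenological_lag(n_e, record.n_o),
        s_w=s_w,
        residual_mismatch=residual,
    )


def partition_table(
    records: pd.DataFrame,
    store: dict[str, tuple[TemperatureSeries, TemperatureSeries]],
    base_temp: float = 0.0,
    mode: str = "integer",
    spring_window_end: int = SPRING_WINDOW_END,
) -> pd.DataFrame:
    """Partition a record table against per-location climate pairs.

    ``store`` maps each record's ``location`` to its ``(baseline, warmer)``
    series — the shape :func:`phenolag.simulate.generate_dataset` returns.
    """
    rows = []
    for _, row in records.iterrows():
        baseline, warmer = store[row["location"]]
        res = partition_record(
            {
                "species": row["species"],
                "location": row["location"],
                "event": row["event"],
                "o_ci": row["o_ci"],
                "n_o": row.get("n_o"),
            },
            baseline,
            warmer,
            base_temp=base_temp,
            mode=mode,
            spring_window_end=spring_window_end,
        )
        rows.append(res.to_dict())
    return pd.concat(
        [records.reset_index(drop=True), pd.DataFrame(rows)], axis=1
    )


class PhenologyPartitioner(BaseEstimator, TransformerMixin):
    """Transformer decomposing phenology records against a fitted climate pair.

    Parameters
    ----------
    base_temp : float, default 0.0
        Degree-day base temperature (°C); daily means are clipped at this
        value before accumulation.
    mode : {"integer", "linear"}, default "integer"
        Day search granularity for the expected response.
    spring_window_end : int, default 182
        Last Julian day of the spring-warming window.

    After :meth:`fit` the estimator exposes ``baseline_``, ``warmer_`` and
    ``spring_warming_``; :meth:`transform` appends the partition columns
    (``f_c, n_e, e_wi, t_b, t_b_defined, n_c, s_w, residual_mismatch``) to a
    record table.

    Examples
    --------
    >>> part = PhenologyPartitioner().fit((baseline, warmer))  # doctest: +SKIP
    >>> results = part.transform(records)                      # doctest: +SKIP
    """

    def __init__(
        self,
        base_temp: float = 0.0,
        mode: str = "integer",
        spring_window_end: int = SPRING_WINDOW_END,
    ):
        self.base_temp = base_temp
        self.mode = mode
        self.spring_window_end = spring_window_end

    def fit(self, X, y=None):
        """Store the climate pair ``X = (baseline, warmer)``."""
        baseline, warmer = X
        if not isinstance(baseline, TemperatureSeries) or not isinstance(
            warmer, TemperatureSeries
        ):
            raise TypeError("X must be a (baseline, warmer) TemperatureSeries pair")
        if self.mode not in ("integer", "linear"):
            raise ValueError(f"unknown mode {self.mode!r}")
        self.baseline_ = baseline
        self.warmer_ = warmer
        self.spring_warming_ = spring_warming(baseline, warmer, self.spring_window_end)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Partition every record row; returns the table plus result columns."""
        if not hasattr(self, "baseline_"):
            raise RuntimeError("PhenologyPartitioner is not fitted")
        rows = []
        for _, row in X.iterrows():
            rec = PhenologyRecord(
                species=row.get("species", ""),
                location=row.get("location", ""),
                event=row.get("event", "leafing"),
                o_ci=row["o_ci"],
                n_o=row.get("n_o"),
                o_wi=row.get("o_wi"),
            )
            res = partition_record(
                rec,
                self.baseline_,
                self.warmer_,
                base_temp=self.base_temp,
                mode=self.mode,
                spring_window_end=self.spring_window_end,
            )
            rows.append(res.to_dict())
        out = X.reset_index(drop=True).copy()
        return pd.concat([out, pd.DataFrame(rows)], axis=1)
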