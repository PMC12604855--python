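"""CSV ingestion and output for temperature series and phenology records.

Dialects
--------
Temperature CSV: columns ``doy`` (int), ``temp_c`` (float), optional ``year``
and ``climate`` (``baseline``/``warmer``); UTF-8 with a header. Gaps of up to
five days are linearly interpolated with a logged note; longer gaps are
rejected. Multiple years of one climate are averaged day-by-day into the
single representative series the partitioning uses.

Phenology CSV: columns ``species, location, event, o_ci`` and ``n_o`` or
``o_wi``, plus ``approach, origin, region, growth_form, altitude_m,
latitude, mat_c, map_mm``; enumerations are case-insensitive. Rows violating
the selection rules (budburst day past 213, boreal/temperate MAT mismatch,
inconsistent o_wi vs n_o) are reported per row, never silently dropped.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .records import validate_record_frame
from .series import TemperatureSeries, average_years

__all__ = [
    "read_temperature_csv",
    "read_phenology_csv",
    "write_partition_csv",
    "read_partition_csv",
    "file_digest",
]

logger = logging.getLogger(__name__)

MAX_GAP_DAYS = 5


def read_temperature_csv(path: str | Path) -> dict[str, TemperatureSeries]:
    """Read a temperature CSV into one series per climate label.

    Returns a mapping from climate label (``"baseline"`` if the file has no
    ``climate`` column) to a validated :class:`TemperatureSeries`.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = {"doy", "temp_c"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: temperature CSV needs columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    bad = df[pd.to_numeric(df["temp_c"], errors="coerce").isna() | pd.to_numeric(df["doy"], errors="coerce").isna()]
    if len(bad):
        lines = [int(i) + 2 for i in bad.index[:5]]  # +2: header + 1-based
        raise ValueError(f"{path}: malformed rows at lines {lines}")
    df["doy"] = df["doy"].astype(int)
    df["temp_c"] = df["temp_c"].astype(float)

    out: dict[str, TemperatureSeries] = {}
    climates = df.groupby(df["climate"].astype(str)) if "climate" in df.columns else [("baseline", df)]
    for label, cdf in climates:
        years = cdf.groupby(cdf["year"].astype(int)) if "year" in cdf.columns else [(None, cdf)]
        series_list = [
            _build_series(ydf, str(label), path) for _, ydf in years
        ]
        out[str(label)] = (
            series_list[0]
            if len(series_list) == 1
            else average_years(series_list, label=str(label))
        )
    return out


def _build_series(df: pd.DataFrame, label: str, path: Path) -> TemperatureSeries:
    df = df.sort_values("doy")
    days = df["doy"].to_numpy()
    temps = df["temp_c"].to_numpy(dtype=float)
    if len(np.unique(days)) != len(days):
        raise ValueError(f"{path}: duplicate day-of-year values in climate {label!r}")
    full = np.arange(days[0], days[-1] + 1)
    if len(full) != len(days):
        gaps = np.diff(days)
        worst = int(gaps.max() - 1)
        if worst > MAX_GAP_DAYS:
            at = int(days[int(np.argmax(gaps))])
            raise ValueError(
                f"{path}: climate {label!r} has a {worst}-day gap after day {at} "
                f"(interpolation allowed only up to {MAX_GAP_DAYS} days)"
            )
        temps = np.interp(full, days, temps)
        logger.warning(
            "%s: climate %r: interpolated %d missing day(s)",
            path,
            label,
            len(full) - len(days),
        )
        days = full
    return TemperatureSeries(days, temps, label=label)


def read_phenology_csv(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate a phenology CSV.

    Returns ``(records, errors)``: accepted rows with normalized enums and a
    cross-checked ``n_o``, and a per-row error report for rejected rows.
    """
    df = pd.read_csv(path)
    needed = {"species", "location", "event", "o_ci"}
    if not needed.issubset(df.columns):
        raise ValueError(
            f"{path}: phenology CSV needs at least columns {sorted(needed)}"
        )
    records, errors = validate_record_frame(df)
    if len(errors):
        logger.warning("%s: rejected %d of %d rows", path, len(errors), len(df))
    return records, errors


def write_partition_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a partition table at full float precision (round-trip safe)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g")


def read_partition_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def file_digest(path: str | Path) -> str:
    """SHA-256 digest of a file, for reproducibility logging."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
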