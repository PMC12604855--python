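"""Phenology-response records and their validation rules.

One record is one species × location × study response: the baseline budburst
Julian day (``o_ci``, also the "spring phenology" predictor), the observed
response in days (``n_o``, positive = advance) and/or the observed budburst
day under the warmer climate (``o_wi``), the grouping factors and the site
covariates used by the meta-analysis layer.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import math

import pandas as pd

__all__ = [
    "PhenologyRecord",
    "RecordValidationError",
    "EVENTS",
    "APPROACHES",
    "ORIGINS",
    "REGIONS",
    "GROWTH_FORMS",
    "MAX_BUDBURST_DAY",
    "BOREAL_MAT_LIMIT",
    "validate_record_frame",
]

EVENTS = ("leafing", "flowering")
APPROACHES = ("observational", "experimental")
ORIGINS = ("native", "exotic")
REGIONS = ("boreal", "temperate")
GROWTH_FORMS = ("tree", "shrub", "herb", "grass")

# selection rules: spring budburst before Julian day 213 (July 31), and the
# boreal/temperate split at long-term MAT of 6 degC
MAX_BUDBURST_DAY = 213
BOREAL_MAT_LIMIT = 6.0


class RecordValidationError(ValueError):
    """A phenology record violates a selection or consistency rule."""


@dataclass
class PhenologyRecord:
    species: str
    location: str
    event: str
    o_ci: int
    n_o: Optional[float] = None
    o_wi: Optional[float] = None
    approach: Optional[str] = None
    origin: Optional[str] = None
    region: Optional[str] = None
    growth_form: Optional[str] = None
    altitude_m: Optional[float] = None
    latitude: Optional[float] = None
    mat_c: Optional[float] = None
    map_mm: Optional[float] = None

    def __post_init__(self) -> None:
        self.event = _norm_enum("event", self.event, EVENTS)
        self.approach = _norm_enum("approach", self.approach, APPROACHES, optional=True)
        self.origin = _norm_enum("origin", self.origin, ORIGINS, optional=True)
        self.region = _norm_enum("region", self.region, REGIONS, optional=True)
        self.growth_form = _norm_enum("growth_form", self.growth_form, GROWTH_FORMS, optional=True)

        self.o_ci = int(self.o_ci)
        if not (1 <= self.o_ci <= MAX_BUDBURST_DAY):
            raise RecordValidationError(
                f"baseline budburst day {self.o_ci} outside 1..{MAX_BUDBURST_DAY} "
                f"(spring budburst must occur before Julian day {MAX_BUDBURST_DAY})"
            )

        if self.o_wi is None and self.n_o is None:
            raise RecordValidationError(
                "record needs an observed response: provide n_o or o_wi"
            )
        if self.o_wi is not None and self.n_o is not None:
            implied = self.o_ci - self.o_wi
            if not math.isclose(implied, self.n_o, abs_tol=1e-9):
                raise RecordValidationError(
                    f"inconsistent observed response: n_o={self.n_o} but "
                    f"o_ci - o_wi = {implied}"
                )
        elif self.o_wi is not None:
            self.n_o = float(self.o_ci - self.o_wi)

        if self.region is not None and self.mat_c is not None:
            if self.region == "boreal" and self.mat_c >= BOREAL_MAT_LIMIT:
                raise RecordValidationError(
                    f"region 'boreal' inconsistent with MAT={self.mat_c} degC "
                    f"(boreal requires MAT < {BOREAL_MAT_LIMIT})"
                )
            if self.region == "temperate" and self.mat_c < BOREAL_MAT_LIMIT:
                raise RecordValidationError(
                    f"region 'temperate' inconsistent with MAT={self.mat_c} degC "
                    f"(temperate requires MAT >= {BOREAL_MAT_LIMIT})"
                )

    def to_dict(self) -> dict:
        return asdict(self)


def _norm_enum(name, value, allowed, optional=False):
    if value is None or (isinstance(value, float) and math.isnan(value)):
        if optional:
            return None
        raise RecordValidationError(f"missing required field {name!r}")
    v = str(value).strip().lower()
    if v not in allowed:
        raise RecordValidationError(
            f"invalid {name} {value!r}; expected one of {allowed}"
        )
    return v


def validate_record_frame(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Validate a table of phenology records row by row.

    Returns ``(accepted, errors)`` where ``accepted`` holds normalized valid
    rows and ``errors`` has one row per rejected record with its original row
    index and the rule it violated. Validation is fail-loud per row; nothing
    is silently dropped.
    """
    accepted, errors = [], []
    known = {f for f in PhenologyRecord.__dataclass_fields__}
    for idx, row in df.iterrows():
        kwargs = {k: (None if pd.isna(v) else v) for k, v in row.items() if k in known}
        try:
            rec = PhenologyRecord(**kwargs)
        except (RecordValidationError, TypeError) as exc:
            errors.append({"row": idx, "error": str(exc)})
            continue
        accepted.append(rec.to_dict())
    acc = pd.DataFrame(accepted) if accepted else pd.DataFrame(columns=list(known))
    err = pd.DataFrame(errors) if errors else pd.DataFrame(columns=["row", "error"])
    return acc, err
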