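"""ISO-8601 dates with explicit precision.

Spontaneous reports routinely carry partial dates ("2014", "2014-03").
``FuzzyDate`` keeps the parsed calendar date together with its precision so
downstream code can distinguish a precise day from a year-only stamp:
time-to-onset is only *estimable* from day-precise dates, and completeness
scoring penalises imprecise onsets.
"""
from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass
from typing import Any, Literal

from pydantic import GetCoreSchemaHandler
from pydantic_core import core_schema

Precision = Literal["day", "month", "year"]

_YEAR_RE = re.compile(r"^\d{4}$")
_MONTH_RE = re.compile(r"^\d{4}-\d{2}$")
_DAY_RE = re.compile(r"^\d{4}-\d{2}-\d{2}$")


@dataclass(frozen=True, order=True)
class FuzzyDate:
    """A calendar date plus the precision it was reported at.

    Partial dates are anchored at the first day of the period
    (``"2014" -> 2014-01-01`` at year precision) so comparisons stay
    well-defined; ``precise`` tells you whether the day is trustworthy.
    """

    date: dt.date
    precision: Precision = "day"

    @property
    def precise(self) -> bool:
        return self.precision == "day"

    @classmethod
    def parse(cls, value: "FuzzyDate | dt.date | str") -> "FuzzyDate":
        if isinstance(value, FuzzyDate):
            return value
        if isinstance(value, dt.date):
            return cls(value, "day")
        s = str(value).strip()
        if _DAY_RE.match(s):
            return cls(dt.date.fromisoformat(s), "day")
        if _MONTH_RE.match(s):
            y, m = int(s[:4]), int(s[5:7])
            return cls(dt.date(y, m, 1), "month")
        if _YEAR_RE.match(s):
            return cls(dt.date(int(s), 1, 1), "year")
        raise ValueError(f"not an ISO-8601 (partial) date: {s!r}")

    def isoformat(self) -> str:
        if self.precision == "year":
            return f"{self.date.year:04d}"
        if self.precision == "month":
            return f"{self.date.year:04d}-{self.date.month:02d}"
        return self.date.isoformat()

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.isoformat()

    # pydantic v2 integration: validate from str/date, serialise back to str
    @classmethod
    def __get_pydantic_core_schema__(
        cls, source_type: Any, handler: GetCoreSchemaHandler
    ) -> core_schema.CoreSchema:
        return core_schema.no_info_plain_validator_function(
            cls.parse,
            serialization=core_schema.plain_serializer_function_ser_schema(
                lambda v: v.isoformat(), return_schema=core_schema.str_schema()
            ),
        )


def days_between(start: FuzzyDate, end: FuzzyDate) -> int:
    """Day difference end - start on the anchored calendar dates."""
    return (end.date - start.date).days
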