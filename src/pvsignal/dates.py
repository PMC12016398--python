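"""Partial calendar dates as they occur in spontaneous-report archives.

FAERS date fields (FDA_DT, START_DT, EVENT_DT) are digit strings of length
8 (YYYYMMDD), 6 (YYYYMM) or 4 (YYYY); JADER dates use the same precisions
with ``/`` separators. Anything else is treated as missing. Precision is
kept first-class because onset-interval analyses must exclude dates coarser
than a day.
"""
from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass
from typing import Optional

__all__ = ["PartialDate", "parse_partial_date"]

_DIGITS = re.compile(r"^\d+$")


@dataclass(frozen=True, order=False)
class PartialDate:
    """A calendar date with explicit precision (day, month, year or missing)."""

    year: Optional[int] = None
    month: Optional[int] = None
    day: Optional[int] = None

    @property
    def precision(self) -> str:
        if self.year is None:
            return "missing"
        if self.month is None:
            return "year"
        if self.day is None:
            return "month"
        return "day"

    def __post_init__(self) -> None:
        if self.month is None and self.day is not None:
            raise ValueError("day given without month")
        if self.year is None and self.month is not None:
            raise ValueError("month given without year")
        if self.month is not None and not 1 <= self.month <= 12:
            raise ValueError(f"month out of range: {self.month}")
        if self.day is not None:
            # must form a valid calendar date when day-precise
            _dt.date(self.year, self.month, self.day)

    def to_date(self) -> _dt.date:
        """The exact date; only defined at day precision."""
        if self.precision != "day":
            raise ValueError(f"not day-precise: {self!r}")
        return _dt.date(self.year, self.month, self.day)

    def sort_key(self) -> tuple[int, int, int]:
        """Total order with missing components treated as smallest.

        Used for deduplication tie-breaks so that a day-precise date always
        beats the same year/month with missing components.
        """
        return (
            -1 if self.year is None else self.year,
            -1 if self.month is None else self.month,
            -1 if self.day is None else self.day,
        )

    def __str__(self) -> str:
        if self.year is None:
            return ""
        if self.month is None:
            return f"{self.year:04d}"
        if self.day is None:
            return f"{self.year:04d}{self.month:02d}"
        return f"{self.year:04d}{self.month:02d}{self.day:02d}"


def parse_partial_date(raw: object) -> PartialDate:
    """Parse an archive date string into a :class:`PartialDate`.

    Accepts 8-digit YYYYMMDD, 6-digit YYYYMM and 4-digit YYYY forms, with
    or without ``/`` or ``-`` separators. Unparseable or out-of-range input
    yields the missing date rather than an error: malformed dates are data,
    not failures.
    """
    if raw is None:
        return PartialDate()
    s = str(raw).strip().replace("/", "").replace("-", "")
    if s.endswith(".0"):  # pandas float round-trip of numeric date columns
        s = s[:-2]
    if not s or not _DIGITS.match(s):
        return PartialDate()
    try:
        if len(s) == 8:
            return PartialDate(int(s[:4]), int(s[4:6]), int(s[6:8]))
        if len(s) == 6:
            return PartialDate(int(s[:4]), int(s[4:6]))
        if len(s) == 4:
            return PartialDate(int(s))
    except ValueError:
        return PartialDate()
    return PartialDate()
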