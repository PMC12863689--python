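"""Partial-date handling for FAERS date columns.

FAERS dates are stored as bare digit strings: ``YYYYMMDD`` (day precision),
``YYYYMM`` (month precision) or ``YYYY`` (year precision).  Blank fields and
anything else (non-numeric, impossible calendar dates) are common in real
quarters.  Downstream logic — time-to-onset in particular — must distinguish
"day-precise" from "partially known" dates, so partial dates are never
coerced to a full date.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass
from typing import Optional

DAY = "day"
MONTH = "month"
YEAR = "year"
MISSING = "missing"
INVALID = "invalid"


@dataclass(frozen=True, slots=True)
class ParsedDate:
    """A FAERS date: the raw field plus its parsed form and precision flag."""

    raw: str
    precision: str  # one of DAY, MONTH, YEAR, MISSING, INVALID
    date: Optional[datetime.date] = None  # set only at day precision
    year: Optional[int] = None
    month: Optional[int] = None

    @property
    def is_day(self) -> bool:
        return self.precision == DAY

    def sort_key(self) -> int:
        """Comparable integer: raw digits right-padded with zeros to 8 places.

        Unparseable dates sort before every valid date (key -1), matching the
        deduplication convention of treating them as the oldest.
        """
        if self.precision in (MISSING, INVALID):
            return -1
        return int(self.raw.ljust(8, "0"))


def parse_date(raw: str) -> ParsedDate:
    """Parse a FAERS date field into a :class:`ParsedDate`.

    Whitespace is stripped; an empty field is MISSING; a non-numeric field,
    a field of unexpected length, or an impossible calendar date is INVALID.
    """
    text = (raw or "").strip()
    if not text:
        return ParsedDate(raw=text, precision=MISSING)
    if not text.isdigit():
        return ParsedDate(raw=text, precision=INVALID)
    if len(text) == 4:
        year = int(text)
        if 1900 <= year <= 2100:
            return ParsedDate(raw=text, precision=YEAR, year=year)
        return ParsedDate(raw=text, precision=INVALID)
    if len(text) == 6:
        year, month = int(text[:4]), int(text[4:6])
        if 1900 <= year <= 2100 and 1 <= month <= 12:
            return ParsedDate(raw=text, precision=MONTH, year=year, month=month)
        return ParsedDate(raw=text, precision=INVALID)
    if len(text) == 8:
        try:
            d = datetime.date(int(text[:4]), int(text[4:6]), int(text[6:8]))
        except ValueError:
            return ParsedDate(raw=text, precision=INVALID)
        return ParsedDate(raw=text, precision=DAY, date=d, year=d.year, month=d.month)
    return ParsedDate(raw=text, precision=INVALID)
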