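"""Calendar-month arithmetic on (year, month) pairs.

The whole pipeline works at month resolution; a calendar month is addressed
either as a ``(year, month)`` pair (month in 1..12) or as a flat integer index
``year * 12 + month - 1`` so that consecutive months differ by one.
"""
from __future__ import annotations

from collections.abc import Iterator

MONTHS_PER_YEAR = 12

YearMonth = tuple[int, int]


def month_index(year: int, month: int) -> int:
    """Flat month index of calendar month ``(year, month)``."""
    if not 1 <= int(month) <= 12:
        raise ValueError(f"month must be in 1..12, got {month!r}")
    return int(year) * MONTHS_PER_YEAR + int(month) - 1


def index_to_ym(index: int) -> YearMonth:
    """Inverse of :func:`month_index`."""
    year, m = divmod(int(index), MONTHS_PER_YEAR)
    return year, m + 1


def iter_months(start: YearMonth, end: YearMonth) -> Iterator[YearMonth]:
    """Yield every calendar month from ``start`` to ``end`` inclusive."""
    lo, hi = month_index(*start), month_index(*end)
    if lo > hi:
        raise ValueError(f"start {start} is after end {end}")
    for idx in range(lo, hi + 1):
        yield index_to_ym(idx)


def n_months(start: YearMonth, end: YearMonth) -> int:
    """Number of calendar months in the inclusive span ``[start, end]``."""
    return month_index(*end) - month_index(*start) + 1
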