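"""Piecewise-constant radon release timeline for the K-65 storage silos.

The source term is a short table of release *events*: calendar-month spans
with a constant joint Rn release rate from the two silos, given as a median
bracketed by 5th/95th percentile estimates in Ci·y⁻¹.  The shipped default
timeline covers Jul 1952 – Dec 1988 (438 months): active filling of each
silo, the long unsealed-dome era, the post-sealing era, and the final year of
foam insulation of the silo airspace.

Consecutive events in the printed record share their boundary month (the
month one event ends is the month the next begins).  Boundary months are
assigned to the *earlier* event — the transition happens at the end of the
boundary month — which yields a contiguous, non-overlapping monthly timeline
whose median integral is 1.6 × 10⁵ Ci at two significant figures.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

from .months import YearMonth, index_to_ym, month_index

QUANTILES = ("median", "p05", "p95")

#: Seconds in a Julian year; used when converting Ci·y⁻¹ fluxes to Ci·s⁻¹.
SECONDS_PER_YEAR = 3.1557e7

#: Default exposure window, matching the coverage of the shipped timeline.
WINDOW_START: YearMonth = (1952, 7)
WINDOW_END: YearMonth = (1988, 12)


@dataclass(frozen=True)
class EmissionEvent:
    """One constant-rate release event.

    ``start`` and ``end`` are inclusive ``(year, month)`` pairs as printed in
    the source record; overlap of one boundary month with the next event is
    resolved by :class:`EmissionTimeline`.
    """

    label: str
    start: YearMonth
    end: YearMonth
    rate_median: float
    rate_p05: float
    rate_p95: float

    def __post_init__(self) -> None:
        if month_index(*self.start) > month_index(*self.end):
            raise ValueError(f"{self.label}: start {self.start} after end {self.end}")
        if not 0 <= self.rate_p05 <= self.rate_median <= self.rate_p95:
            raise ValueError(
                f"{self.label}: rates must satisfy 0 <= p05 <= median <= p95"
            )

    def rate(self, quantile: str = "median") -> float:
        if quantile not in QUANTILES:
            raise ValueError(f"quantile must be one of {QUANTILES}, got {quantile!r}")
        return getattr(self, f"rate_{quantile}")


class EmissionTimeline:
    """Ordered, boundary-resolved sequence of :class:`EmissionEvent`.

    Events may share at most their single boundary month; the shared month is
    kept by the earlier event and the later event's effective start advances
    by one month.  After resolution the spans must be non-overlapping and
    contiguous (no gap months between consecutive events).
    """

    def __init__(self, events: Iterable[EmissionEvent]):
        evs = sorted(events, key=lambda e: month_index(*e.start))
        if not evs:
            raise ValueError("timeline requires at least one event")
        spans: list[tuple[int, int, EmissionEvent]] = []
        prev_end = None
        for ev in evs:
            lo, hi = month_index(*ev.start), month_index(*ev.end)
            if prev_end is not None:
                if lo < prev_end:
                    raise ValueError(
                        f"event {ev.label!r} overlaps the previous event by more "
                        "than the shared boundary month"
                    )
                if lo == prev_end:  # shared boundary month -> earlier event keeps it
                    lo += 1
                if lo != prev_end + 1:
                    raise ValueError(
                        f"gap in timeline before event {ev.label!r}; coverage must "
                        "be contiguous"
                    )
                if lo > hi:
                    raise ValueError(f"event {ev.label!r} vanishes after boundary resolution")
            spans.append((lo, hi, ev))
            prev_end = hi
        self._spans = spans
        self.events = tuple(ev for _, _, ev in spans)

    # -- queries -----------------------------------------------------------

    @property
    def coverage(self) -> tuple[YearMonth, YearMonth]:
        """First and last covered calendar month."""
        return index_to_ym(self._spans[0][0]), index_to_ym(self._spans[-1][1])

    @property
    def n_covered_months(self) -> int:
        return self._spans[-1][1] - self._spans[0][0] + 1

    def event_month_counts(self) -> dict[str, int]:
        """Months owned by each event after boundary resolution."""
        return {ev.label: hi - lo + 1 for lo, hi, ev in self._spans}

    def _rate_at(self, idx: int, quantile: str) -> float:
        for lo, hi, ev in self._spans:
            if lo <= idx <= hi:
                return ev.rate(quantile)
        return 0.0

    def monthly_rate(self, year: int, month: int, quantile: str = "median") -> float:
        """Release rate (Ci·y⁻¹) in force during the given calendar month.

        Zero outside timeline coverage; piecewise constant within it.
        """
        if quantile not in QUANTILES:
            raise ValueError(f"quantile must be one of {QUANTILES}, got {quantile!r}")
        return self._rate_at(month_index(year, month), quantile)

    def annual_rate(self, year: int, quantile: str = "median") -> float:
        """Arithmetic mean of the 12 monthly rates of a calendar year (Ci·y⁻¹)."""
        return sum(self.monthly_rate(year, m, quantile) for m in range(1, 13)) / 12.0

    def total_release(
        self, start: YearMonth, end: YearMonth, quantile: str = "median"
    ) -> float:
        """Integrated release (Ci) over the inclusive month span ``[start, end]``.

        Each covered month contributes one twelfth of its annual-rate value.
        """
        lo, hi = month_index(*start), month_index(*end)
        if lo > hi:
            raise ValueError(f"start {start} after end {end}")
        total = 0.0
        for span_lo, span_hi, ev in self._spans:
            overlap = min(hi, span_hi) - max(lo, span_lo) + 1
            if overlap > 0:
                total += overlap * ev.rate(quantile) / 12.0
        return total

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EmissionTimeline":
        events = [
            EmissionEvent(
                label=str(row.label),
                start=(int(row.start_year), int(row.start_month)),
                end=(int(row.end_year), int(row.end_month)),
                rate_median=float(row.rate_median),
                rate_p05=float(row.rate_p05),
                rate_p95=float(row.rate_p95),
            )
            for row in df.itertuples(index=False)
        ]
        return cls(events)

    @classmethod
    def from_csv(cls, path: str | Path) -> "EmissionTimeline":
        return cls.from_frame(pd.read_csv(path, comment="#"))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": [e.label for e in self.events],
                "start_year": [e.start[0] for e in self.events],
                "start_month": [e.start[1] for e in self.events],
                "end_year": [e.end[0] for e in self.events],
                "end_month": [e.end[1] for e in self.events],
                "rate_median": [e.rate_median for e in self.events],
                "rate_p05": [e.rate_p05 for e in self.events],
                "rate_p95": [e.rate_p95 for e in self.events],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def default(cls) -> "EmissionTimeline":
        """The shipped K-65 silo release timeline (Jul 1952 – Dec 1988)."""
        with resources.files("radonrecon.data").joinpath("k65_emissions.csv").open() as fh:
            return cls.from_frame(pd.read_csv(fh))
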